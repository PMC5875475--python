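"""Accuracy/precision statistics: percent error vs specification and z-tests.

The comparison forms are a one-sample z against the manufacturer value and a
Welch-style two-sample z between measurement sets, both two-sided, with
significance at p < 0.05.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, DegenerateVarianceError, InputError

ALPHA = 0.05

#: manufacturer-specified FWHM (mm) per nominal slice thickness (mm)
DEFAULT_SPECS = {0.625: 0.98, 1.25: 1.38, 2.5: 2.88, 5.0: 6.00}


@dataclass
class SpecTable:
    """Nominal slice thickness (mm) -> manufacturer-specified FWHM (mm)."""

    values: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_SPECS))

    def __post_init__(self) -> None:
        for t, s in self.values.items():
            if not (t > 0 and s > 0):
                raise ConfigError(f"spec entries must be positive, got {t}: {s}")
            if s < t:
                raise ConfigError(f"specified FWHM {s} mm below nominal thickness {t} mm")

    def lookup(self, thickness: float) -> float:
        for t, s in self.values.items():
            if math.isclose(t, thickness, rel_tol=1e-9, abs_tol=1e-9):
                return s
        raise ConfigError(f"no specification for slice thickness {thickness} mm")


def percent_error(measured: float, spec: float) -> float:
    """100·|measured − spec| / spec."""
    if not spec > 0:
        raise InputError(f"spec must be > 0, got {spec}")
    return 100.0 * abs(measured - spec) / spec


def one_sample_z(measurements: Sequence[float], spec: float) -> tuple[float, float]:
    """Two-sided one-sample z of the mean against *spec*; returns (z, p)."""
    x = np.asarray(measurements, dtype=float)
    if len(x) < 2:
        raise InputError("need at least 2 measurements for a z-test")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateVarianceError("zero standard deviation; z undefined")
    z = (float(np.mean(x)) - spec) / (sd / math.sqrt(len(x)))
    return z, 2.0 * float(norm.sf(abs(z)))


def two_sample_z(set_a: Sequence[float], set_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch z between two measurement sets; returns (z, p)."""
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("need at least 2 measurements per set")
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    denom = math.sqrt(var_a / len(a) + var_b / len(b))
    if denom == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise DegenerateVarianceError("both sets have zero variance; z undefined")
    z = (float(np.mean(a)) - float(np.mean(b))) / denom
    return z, 2.0 * float(norm.sf(abs(z)))


@dataclass
class ComparisonReport:
    """Per-group summary vs specification plus the grand mean percent error."""

    table: pd.DataFrame
    grand_mean_percent_error: float

    def to_csv(self) -> str:
        """Deterministic CSV with percent errors at one decimal place."""
        out = self.table.copy()
        out["percent_error"] = out["percent_error"].map(lambda x: f"{x:.1f}")
        for col in ("mean_fwhm_mm", "sd_mm", "error_mm", "spec_mm"):
            out[col] = out[col].map(lambda x: f"{x:.6g}")
        buf = io.StringIO()
        out.to_csv(buf, index=False, lineterminator="\n")
        return buf.getvalue()


def aggregate_report(
    results: Mapping[tuple[str, float], Sequence[float]],
    specs: SpecTable | None = None,
) -> ComparisonReport:
    """Summarize repeat FWHM measurements grouped by (condition, thickness).

    Each group contributes n, mean, sd, error vs spec, percent error of the
    mean, and a one-sample z-test (NaN when the group is degenerate).  The
    grand mean is the average of the groups' percent errors.
    """
    if specs is None:
        specs = SpecTable()
    rows = []
    for (condition, thickness), values in results.items():
        x = np.asarray(list(values), dtype=float)
        if len(x) == 0:
            raise InputError(f"empty measurement group {(condition, thickness)}")
        spec = specs.lookup(thickness)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        try:
            z, p = one_sample_z(x, spec)
        except (InputError, DegenerateVarianceError):
            z, p = float("nan"), float("nan")
        rows.append(
            {
                "condition": condition,
                "thickness_mm": thickness,
                "spec_mm": spec,
                "n": len(x),
                "mean_fwhm_mm": mean,
                "sd_mm": sd,
                "error_mm": mean - spec,
                "percent_error": percent_error(mean, spec),
                "z": z,
                "p": p,
                "significant": bool(p < ALPHA) if not math.isnan(p) else False,
            }
        )
    table = pd.DataFrame(rows).sort_values(["condition", "thickness_mm"], kind="stable")
    table = table.reset_index(drop=True)
    grand = float(table["percent_error"].mean())
    return ComparisonReport(table=table, grand_mean_percent_error=grand)
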