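# ctssp — slice sensitivity profile analysis for helical CT QA

`ctssp` measures the effective slice thickness of a helical CT system from an
overlapping-slice image series of a point-response phantom. It builds slice
sensitivity profiles (SSPs) from ROI statistics — per-slice mean or maximum
HU, background-corrected using the two outermost slices and normalized to
unit peak — and estimates the FWHM four ways: half level from the left side's
minimum, from the right side's, each side independently (linear interpolation
in all three), and a Gaussian least-squares fit. Results are compared against
manufacturer-specified widths with percent errors and one-/two-sample
z-tests (two-sided, α = 0.05).

A synthetic phantom-series generator with exactly known ground-truth FWHM
makes the whole pipeline testable without scanner data: a 2-D Gaussian blob
whose amplitude follows a Gaussian (or triangular) axial weight, on a grid
spanning ±5 slice thicknesses at an interval of thickness/k, with
configurable background HU, additive noise, and optional z-dependent in-plane
blur (which reproduces the broadening of mean-ROI profiles relative to
max-ROI profiles).

DICOM I/O is self-contained: a minimal single-frame CT codec (Explicit VR
Little Endian writer; Explicit/Implicit LE reader, uncompressed only) that
applies rescale slope/intercept for HU and sorts slices by axial position.

## CLI

```sh
# simulate a phantom series (YAML SimConfig) into a DICOM directory + truth.json
ssp simulate -c config.yaml -o series_dir

# build SSPs and estimate FWHMs (CSV report + SSP plot data alongside)
ssp analyze series_dir --statistic max --method gaussian --roi auto -o out.csv

# aggregate repeated runs: mean/sd/error/percent error/z/p per group
ssp report out1.csv out2.csv ... -o table.csv
```

Minimal `config.yaml`:

```yaml
true_fwhm: 2.88   # ground-truth axial FWHM, mm
thickness: 2.5    # nominal slice thickness, mm
noise_sd: 2.0     # additive HU noise
seed: 11
```

Exit codes: 0 success, 2 input/config error, 3 computation error.

## Layout

- `src/ctssp/dicom_io.py` — series reader/writer (`_dicom.py` holds the codec)
- `src/ctssp/ssp_core.py` — ROI sampling, background correction, normalization
- `src/ctssp/fwhm.py` — the four FWHM estimators
- `src/ctssp/stats.py` — percent error, z-tests, report aggregation
- `src/ctssp/synthetic.py` — ground-truth phantom series generator
- `src/ctssp/cli.py` — `ssp` command group
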