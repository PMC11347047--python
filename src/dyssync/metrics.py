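"""The 24 mechanical dyssynchrony metrics and global strain.

For each of the six deformation measurements, four timing metrics are
computed from the segmental curves after piecewise-linear interpolation to a
1-ms periodic grid:

* **SDTTP** — sample standard deviation of segmental times-to-peak.
* **MOWD** — maximum opposing-wall delay: the largest absolute difference in
  slice-pooled mean time-to-peak between the sector pairs (1,4), (2,5), (3,6).
* **BAD** — base-to-apex delay: absolute difference in mean time-to-peak
  between the most basal and most apical slices.
* **CCD** — cross-correlation delay: for each segment, the magnitude of the
  integer-ms circular shift that maximally aligns its (mean-subtracted) curve
  with the average curve of all segments; the 80th percentile of the
  segmental values summarizes global dyssynchrony.

"Time-to-peak" is the time of the signed extremum in the measurement's
physiologic polarity direction (minimum for circumferential strain and
strain rate, maximum otherwise), with ties broken by the earliest time.
Global circumferential/radial strain are the polarity extrema of the
pointwise mean curve over all segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .curves import (
    ALL_KINDS,
    N_PHASES,
    DeformationCurve,
    MeasurementKind,
    VentricleDataset,
)
from .errors import CurveDataError, DegenerateCurveError, InsufficientDataError

#: Absolute flatness tolerance, in the curve's native units.
FLAT_TOL = 1e-9

#: Default percentile summarizing segmental CCDs.
CCD_PERCENTILE = 80.0

#: Wide-format feature columns: 4 metrics x 6 kinds, grouped by kind.
FEATURE_COLUMNS: List[str] = [
    f"{metric}_{kind.abbrev}"
    for kind in ALL_KINDS
    for metric in ("sdttp", "mowd", "bad", "ccd")
]
GLOBAL_STRAIN_COLUMNS = ["gcs", "grs"]
ALL_FEATURE_COLUMNS = FEATURE_COLUMNS + GLOBAL_STRAIN_COLUMNS


def _grid_length(cycle_length_ms: float) -> int:
    return int(round(cycle_length_ms))


def _interp_matrix(values: np.ndarray, cycle_length_ms: float) -> np.ndarray:
    """Linearly interpolate rows of 30-phase curves onto the 1-ms grid.

    The cycle is treated as periodic: the segment between sample 29 and the
    cycle end wraps back to sample 0.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != N_PHASES:
        raise CurveDataError(f"expected {N_PHASES} phases, got {values.shape[1]}")
    if not np.all(np.isfinite(values)):
        raise CurveDataError("non-finite sample in deformation curve")
    if not cycle_length_ms > N_PHASES:
        raise CurveDataError("cycle_length_ms must exceed the phase count")
    L = _grid_length(cycle_length_ms)
    t = np.arange(L, dtype=float)
    sample_t = np.arange(N_PHASES + 1) * (cycle_length_ms / N_PHASES)
    idx = np.clip(np.searchsorted(sample_t, t, side="right") - 1, 0, N_PHASES - 1)
    w = (t - sample_t[idx]) / (sample_t[idx + 1] - sample_t[idx])
    ext = np.concatenate([values, values[:, :1]], axis=1)
    return ext[:, idx] * (1.0 - w) + ext[:, idx + 1] * w


def interpolate_1ms(curve: DeformationCurve | np.ndarray, cycle_length_ms: float | None = None) -> np.ndarray:
    """Resample one curve to 1-ms spacing over one periodic cycle.

    Accepts a :class:`DeformationCurve` or a raw 30-sample array plus an
    explicit ``cycle_length_ms``.  The result has ``round(cycle_length_ms)``
    points and agrees exactly with the input at the native sample times.
    """
    if isinstance(curve, DeformationCurve):
        samples, L_ms = curve.samples, curve.cycle_length_ms
    else:
        if cycle_length_ms is None:
            raise TypeError("cycle_length_ms required for raw sample arrays")
        samples, L_ms = np.asarray(curve, dtype=float), float(cycle_length_ms)
    return _interp_matrix(samples[None, :], L_ms)[0]


def _ttp_rows(values: np.ndarray, cycle_length_ms: float, polarity: int) -> np.ndarray:
    """Sub-sample time-to-peak (ms) per row of 30-phase curves.

    The extremum sample in the polarity direction is located first
    (earliest-time tie-break, equivalent to the extremum knot of the 1-ms
    linear interpolant); its time is then refined to sub-sample precision by
    the vertex of the quadratic through the three native samples around the
    peak (with periodic wrap).  The refinement never moves the peak by more
    than half the native spacing, and is exact for locally quadratic curves.
    """
    V = np.atleast_2d(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(V)):
        raise CurveDataError("non-finite sample in deformation curve")
    ptp = V.max(axis=1) - V.min(axis=1)
    if np.any(ptp < FLAT_TOL):
        row = int(np.argmax(ptp < FLAT_TOL))
        raise DegenerateCurveError(f"flat deformation curve (segment row {row})")
    # argmin/argmax return the first occurrence: earliest-time tie-break.
    m = V.argmin(axis=1) if polarity < 0 else V.argmax(axis=1)
    rows = np.arange(V.shape[0])
    y0 = V[rows, m]
    ym = V[rows, (m - 1) % N_PHASES]
    yp = V[rows, (m + 1) % N_PHASES]
    denom = ym - 2.0 * y0 + yp
    with np.errstate(divide="ignore", invalid="ignore"):
        offset = np.where(np.abs(denom) > FLAT_TOL, 0.5 * (ym - yp) / denom, 0.0)
    offset = np.clip(offset, -0.5, 0.5)
    dt = cycle_length_ms / N_PHASES
    return (m + offset) * dt % cycle_length_ms


def time_to_peak(curve: DeformationCurve) -> float:
    """Time (ms) of the curve's polarity extremum, sub-sample refined."""
    return float(
        _ttp_rows(curve.samples[None, :], curve.cycle_length_ms, curve.kind.polarity)[0]
    )


def sdttp(ttps_ms: Sequence[float] | np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) of segmental TTPs."""
    ttps = np.asarray(ttps_ms, dtype=float).ravel()
    if ttps.size < 2:
        raise InsufficientDataError("sdttp requires at least 2 segments")
    return float(np.std(ttps, ddof=1))


def max_opposing_wall_delay(ttp_grid: np.ndarray) -> float:
    """Largest |mean TTP difference| over the three opposing wall pairs.

    ``ttp_grid`` is ``(n_slices, 6)``; wall means pool each sector over all
    slices.
    """
    grid = np.asarray(ttp_grid, dtype=float)
    if grid.ndim != 2 or grid.shape[1] != 6 or not np.all(np.isfinite(grid)):
        raise InsufficientDataError("mowd requires a complete (n_slices, 6) TTP grid")
    wall_means = grid.mean(axis=0)
    delays = np.abs(wall_means[:3] - wall_means[3:])
    return float(delays.max())


def base_to_apex_delay(ttp_grid: np.ndarray) -> float:
    """|mean TTP of the most basal slice - mean TTP of the most apical slice|."""
    grid = np.asarray(ttp_grid, dtype=float)
    if grid.ndim != 2 or grid.shape[0] < 2 or not np.all(np.isfinite(grid)):
        raise InsufficientDataError("bad requires at least 2 complete slices")
    return float(abs(grid[-1].mean() - grid[0].mean()))


def _ccd_shifts(interp: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Signed optimal circular shifts (ms) of each row against a reference.

    The shift tau* maximizes the circular cross-correlation
    ``sum_t x(t) * r(t - tau)`` of the mean-subtracted curves over integer
    tau in (-L/2, L/2].  The bulk scan uses the FFT correlation theorem;
    near-maximal candidates are then re-scored with exact dot products so the
    result (including ties, broken by smallest |tau| then negative before
    positive) matches an exhaustive scan exactly.
    """
    X = np.atleast_2d(np.asarray(interp, dtype=float))
    r = np.asarray(reference, dtype=float).ravel()
    L = r.size
    if X.shape[1] != L:
        raise CurveDataError("segment and reference curves must share the 1-ms grid")
    if r.max() - r.min() < FLAT_TOL:
        raise DegenerateCurveError("flat reference curve")
    ptp = X.max(axis=1) - X.min(axis=1)
    if np.any(ptp < FLAT_TOL):
        raise DegenerateCurveError(
            f"flat deformation curve (segment row {int(np.argmax(ptp < FLAT_TOL))})"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    rc = r - r.mean()
    C = np.fft.irfft(np.fft.rfft(Xc, axis=1) * np.conj(np.fft.rfft(rc)), n=L, axis=1)
    return _pick_shifts(C, Xc, rc)


def _pick_shifts(C: np.ndarray, Xc: np.ndarray, rc: np.ndarray) -> np.ndarray:
    """Choose the optimal shift per row from a circular correlation matrix.

    Index tau in 0..L-1 corresponds to shift tau (if <= L//2) or tau - L.
    Rows whose FFT-scan maximum is within a 1e-9 relative band of other
    candidates are re-scored with exact dot products, so the returned shift
    (including ties: smallest |tau|, then negative before positive) matches
    an exhaustive scan exactly.
    """
    L = rc.size
    cmax = C.max(axis=1)
    scale = np.abs(C).max(axis=1)
    tol = 1e-9 * np.maximum(scale, 1e-300)
    shifts = np.empty(C.shape[0])
    for i in range(C.shape[0]):
        cand = np.nonzero(C[i] >= cmax[i] - tol[i])[0]
        if cand.size == 1:
            tau = int(cand[0])
            shifts[i] = tau if tau <= L // 2 else tau - L
            continue
        cand_shifts = np.where(cand <= L // 2, cand, cand - L)
        exact = np.array(
            [np.dot(Xc[i], np.roll(rc, int(s))) for s in cand_shifts], dtype=float
        )
        best = exact.max()
        tied = cand_shifts[exact == best]
        # smallest |tau|, then negative before positive
        order = sorted(tied, key=lambda s: (abs(int(s)), int(s) > 0))
        shifts[i] = order[0]
    return shifts


def ccd_segment(
    segment_curve: np.ndarray, reference_curve: np.ndarray, signed: bool = False
) -> float:
    """Cross-correlation delay (ms) of one interpolated curve vs a reference."""
    shift = _ccd_shifts(np.asarray(segment_curve)[None, :], reference_curve)[0]
    return float(shift if signed else abs(shift))


def ccd_global(
    segment_ccds: Sequence[float] | np.ndarray, percentile: float = CCD_PERCENTILE
) -> float:
    """Percentile (linear interpolation between order statistics) of segmental CCDs."""
    vals = np.asarray(segment_ccds, dtype=float).ravel()
    if vals.size < 5:
        raise InsufficientDataError("ccd_global requires at least 5 segmental values")
    return float(np.percentile(vals, percentile))


def global_strain(dataset: VentricleDataset, kind: MeasurementKind) -> float:
    """Signed polarity extremum of the all-segment mean curve (GCS / GRS), %."""
    if kind not in (MeasurementKind.CIRC_STRAIN, MeasurementKind.RAD_STRAIN):
        raise ValueError("global strain is defined for circ_strain and rad_strain")
    mean_curve = dataset.segment_matrix(kind).mean(axis=0)
    interp = interpolate_1ms(mean_curve, dataset.cycle_length_ms)
    if interp.max() - interp.min() < FLAT_TOL:
        raise DegenerateCurveError(f"{dataset.subject_id}: degenerate mean {kind.value} curve")
    return float(interp.min() if kind.polarity < 0 else interp.max())


@dataclass
class DyssyncFeatures:
    """The 24 dyssynchrony metrics plus global strains for one subject."""

    subject_id: str
    cycle_length_ms: float
    metrics: Dict[str, float]  # keyed by FEATURE_COLUMNS
    gcs_pct: float  # <= 0 by polarity convention
    grs_pct: float  # >= 0

    def __post_init__(self) -> None:
        missing = set(FEATURE_COLUMNS) - set(self.metrics)
        if missing:
            raise ValueError(f"missing feature values {sorted(missing)}")

    def to_dict(self) -> Dict[str, float]:
        out = {c: self.metrics[c] for c in FEATURE_COLUMNS}
        out["gcs"] = self.gcs_pct
        out["grs"] = self.grs_pct
        return out


def compute_features(
    dataset: VentricleDataset, ccd_percentile: float = CCD_PERCENTILE
) -> DyssyncFeatures:
    """All 24 dyssynchrony metrics (+GCS/GRS) for one ventricle.

    Deterministic given the input.  Delay metrics are in ms and lie in
    ``[0, cycle_length_ms)``.
    """
    L_ms = dataset.cycle_length_ms
    n_seg = dataset.n_segments
    metrics: Dict[str, float] = {}
    # One stacked interpolation + batched FFT over all six kinds; the
    # per-kind mean-subtracted correlation against that kind's mean curve
    # follows by zeroing the DC bin of the spectral product.
    stacked = np.concatenate([dataset.segment_matrix(k) for k in ALL_KINDS])
    try:
        interp = _interp_matrix(stacked, L_ms)
    except CurveDataError as exc:
        raise type(exc)(f"{dataset.subject_id}: {exc}") from exc
    L = interp.shape[1]
    F = np.fft.rfft(interp, axis=1)
    for i, kind in enumerate(ALL_KINDS):
        block = interp[i * n_seg:(i + 1) * n_seg]
        try:
            ttps = _ttp_rows(dataset.segment_matrix(kind), L_ms, kind.polarity)
            grid = ttps.reshape(dataset.n_slices, 6)
            reference = block.mean(axis=0)
            if reference.max() - reference.min() < FLAT_TOL:
                raise DegenerateCurveError("flat reference curve")
            if np.any(block.max(axis=1) - block.min(axis=1) < FLAT_TOL):
                raise DegenerateCurveError("flat deformation curve")
            Fb = F[i * n_seg:(i + 1) * n_seg]
            P = Fb * np.conj(Fb.mean(axis=0))
            P[:, 0] = 0.0  # mean subtraction of both curves
            C = np.fft.irfft(P, n=L, axis=1)
            Xc = block - block.mean(axis=1, keepdims=True)
            ccds = np.abs(_pick_shifts(C, Xc, reference - reference.mean()))
        except (CurveDataError, InsufficientDataError) as exc:
            raise type(exc)(f"{dataset.subject_id}/{kind.value}: {exc}") from exc
        ab = kind.abbrev
        metrics[f"sdttp_{ab}"] = sdttp(ttps)
        metrics[f"mowd_{ab}"] = max_opposing_wall_delay(grid)
        metrics[f"bad_{ab}"] = base_to_apex_delay(grid)
        metrics[f"ccd_{ab}"] = ccd_global(ccds, percentile=ccd_percentile)
    return DyssyncFeatures(
        subject_id=dataset.subject_id,
        cycle_length_ms=L_ms,
        metrics=metrics,
        gcs_pct=global_strain(dataset, MeasurementKind.CIRC_STRAIN),
        grs_pct=global_strain(dataset, MeasurementKind.RAD_STRAIN),
    )


def features_table(datasets, ccd_percentile: float = CCD_PERCENTILE):
    """Feature matrix (subjects x 26) as a DataFrame indexed by subject_id."""
    import pandas as pd

    rows = {}
    for ds in datasets:
        rows[ds.subject_id] = compute_features(ds, ccd_percentile).to_dict()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=ALL_FEATURE_COLUMNS)
    df.index.name = "subject_id"
    return df
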