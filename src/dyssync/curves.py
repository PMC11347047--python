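"""Domain types for segmental myocardial deformation data and cohort I/O.

A subject's feature-tracking output is organized as a short-axis stack of
``n_slices`` slices (slice 0 = most apical, highest index = most basal), each
divided into 6 sectors numbered 1..6 counter-clockwise so that (1,4), (2,5)
and (3,6) are opposing-wall pairs.  Every segment carries one deformation
curve per measurement kind, sampled at 30 phases over one cardiac cycle;
phase 0 is end-diastole and sample ``i`` sits at ``i * cycle_length_ms / 30``
on a periodic cycle of length ``60000 / heart_rate_bpm`` ms.

On disk a cohort is a pair of CSV files:

* ``curves.csv`` (long format): subject_id, kind, slice_index, sector,
  phase_index, value — strain in %, strain rate in 1/s, displacement in mm.
* ``subjects.csv``: one row per subject with cycle metadata
  (heart_rate_bpm, n_slices), covariates and the composite outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from enum import Enum
from pathlib import Path
from typing import Dict, Iterator, List, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import CohortFormatError, CohortJoinError, IncompleteGridError

N_PHASES = 30
N_SECTORS = 6
MIN_SLICES = 4
#: Opposing short-axis wall pairs, by sector number.
WALL_PAIRS = ((1, 4), (2, 5), (3, 6))


class MeasurementKind(str, Enum):
    """The six feature-tracking deformation measurements."""

    CIRC_STRAIN = "circ_strain"
    CIRC_STRAIN_RATE = "circ_strain_rate"
    CIRC_DISPLACEMENT = "circ_displacement"
    RAD_STRAIN = "rad_strain"
    RAD_STRAIN_RATE = "rad_strain_rate"
    RAD_DISPLACEMENT = "rad_displacement"

    @property
    def polarity(self) -> int:
        """Sign of the physiologic systolic extremum (+1 or -1).

        Circumferential shortening makes circumferential strain (and its
        systolic rate) peak negative; radial thickening and both
        displacements peak positive.
        """
        return _POLARITY[self]

    @property
    def abbrev(self) -> str:
        """Short feature-column suffix (cs, csr, cd, rs, rsr, rd)."""
        return _ABBREV[self]

    @property
    def units(self) -> str:
        return _UNITS[self]


_POLARITY = {
    MeasurementKind.CIRC_STRAIN: -1,
    MeasurementKind.CIRC_STRAIN_RATE: -1,
    MeasurementKind.CIRC_DISPLACEMENT: +1,
    MeasurementKind.RAD_STRAIN: +1,
    MeasurementKind.RAD_STRAIN_RATE: +1,
    MeasurementKind.RAD_DISPLACEMENT: +1,
}

_ABBREV = {
    MeasurementKind.CIRC_STRAIN: "cs",
    MeasurementKind.CIRC_STRAIN_RATE: "csr",
    MeasurementKind.CIRC_DISPLACEMENT: "cd",
    MeasurementKind.RAD_STRAIN: "rs",
    MeasurementKind.RAD_STRAIN_RATE: "rsr",
    MeasurementKind.RAD_DISPLACEMENT: "rd",
}

_UNITS = {
    MeasurementKind.CIRC_STRAIN: "%",
    MeasurementKind.CIRC_STRAIN_RATE: "1/s",
    MeasurementKind.CIRC_DISPLACEMENT: "mm",
    MeasurementKind.RAD_STRAIN: "%",
    MeasurementKind.RAD_STRAIN_RATE: "1/s",
    MeasurementKind.RAD_DISPLACEMENT: "mm",
}

ALL_KINDS: Tuple[MeasurementKind, ...] = tuple(MeasurementKind)


class SegmentId(NamedTuple):
    """Position of a segment in the slices x sectors grid."""

    slice_index: int  # 0 = most apical
    sector: int  # 1..6, counter-clockwise

    def validate(self, n_slices: int) -> "SegmentId":
        if not 0 <= self.slice_index < n_slices:
            raise ValueError(
                f"slice_index {self.slice_index} outside 0..{n_slices - 1}"
            )
        if not 1 <= self.sector <= N_SECTORS:
            raise ValueError(f"sector {self.sector} outside 1..{N_SECTORS}")
        return self


@dataclass
class DeformationCurve:
    """One segment's deformation time-series over one cardiac cycle."""

    kind: MeasurementKind
    segment: SegmentId
    samples: np.ndarray
    cycle_length_ms: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (N_PHASES,):
            raise CohortFormatError(
                f"curve must have exactly {N_PHASES} samples, "
                f"got shape {self.samples.shape}"
            )
        if not self.cycle_length_ms > 0:
            raise CohortFormatError("cycle_length_ms must be positive")

    @property
    def native_dt_ms(self) -> float:
        """Native inter-sample spacing (e.g. 20 ms at a heart rate of 100)."""
        return self.cycle_length_ms / N_PHASES

    @property
    def sample_times_ms(self) -> np.ndarray:
        return np.arange(N_PHASES) * self.native_dt_ms


def cycle_length_ms(heart_rate_bpm: float) -> float:
    """Cardiac cycle length in ms for a given heart rate."""
    return 60000.0 / heart_rate_bpm


@dataclass
class VentricleDataset:
    """Complete slices x 6-sector curve grid for one subject.

    ``values[kind]`` is an ``(n_slices, 6, 30)`` array; element
    ``[s, j, p]`` is phase ``p`` of the curve for segment
    ``SegmentId(s, j + 1)``.
    """

    subject_id: str
    heart_rate_bpm: float
    n_slices: int
    values: Dict[MeasurementKind, np.ndarray]

    def __post_init__(self) -> None:
        if self.n_slices < MIN_SLICES:
            raise CohortFormatError(
                f"{self.subject_id}: at least {MIN_SLICES} slices required, "
                f"got {self.n_slices}"
            )
        if not self.heart_rate_bpm > 0:
            raise CohortFormatError(f"{self.subject_id}: non-positive heart rate")
        missing = [k for k in ALL_KINDS if k not in self.values]
        if missing:
            raise IncompleteGridError(
                f"{self.subject_id}: missing measurement kinds {missing}"
            )
        shape = (self.n_slices, N_SECTORS, N_PHASES)
        for kind in ALL_KINDS:
            arr = np.asarray(self.values[kind], dtype=float)
            if arr.shape != shape:
                raise CohortFormatError(
                    f"{self.subject_id}/{kind.value}: expected grid {shape}, "
                    f"got {arr.shape}"
                )
            self.values[kind] = arr

    @property
    def cycle_length_ms(self) -> float:
        return cycle_length_ms(self.heart_rate_bpm)

    @property
    def n_segments(self) -> int:
        return self.n_slices * N_SECTORS

    def segment_ids(self) -> List[SegmentId]:
        """Slice-major ordering matching the rows of :meth:`segment_matrix`."""
        return [
            SegmentId(s, j + 1)
            for s in range(self.n_slices)
            for j in range(N_SECTORS)
        ]

    def segment_matrix(self, kind: MeasurementKind) -> np.ndarray:
        """All curves of one kind as an ``(n_segments, 30)`` matrix."""
        return self.values[kind].reshape(self.n_segments, N_PHASES)

    def curve(self, kind: MeasurementKind, segment: SegmentId) -> DeformationCurve:
        segment = SegmentId(*segment).validate(self.n_slices)
        return DeformationCurve(
            kind=kind,
            segment=segment,
            samples=self.values[kind][segment.slice_index, segment.sector - 1],
            cycle_length_ms=self.cycle_length_ms,
        )

    def iter_curves(self) -> Iterator[DeformationCurve]:
        for kind in ALL_KINDS:
            for seg in self.segment_ids():
                yield self.curve(kind, seg)


GROUPS = ("fontan", "control")
MORPHOLOGIES = ("LV", "RV", "mixed", "control_LV")

#: subjects.csv column order.
SUBJECT_COLUMNS = [
    "subject_id", "group", "morphology", "heart_rate_bpm", "n_slices",
    "age_y", "sex", "bsa_m2", "qrs_ms", "edvi_ml_m2", "esvi_ml_m2",
    "massi_g_m2", "ef_pct", "event", "followup_y",
]

CURVE_COLUMNS = ["subject_id", "kind", "slice_index", "sector", "phase_index", "value"]


@dataclass
class SubjectRecord:
    """Per-subject covariates and composite outcome (death/transplant/listing)."""

    subject_id: str
    group: str
    morphology: str
    heart_rate_bpm: float
    n_slices: int
    age_y: float = np.nan
    sex: str = ""
    bsa_m2: float = np.nan
    qrs_ms: float = np.nan
    edvi_ml_m2: float = np.nan
    esvi_ml_m2: float = np.nan
    massi_g_m2: float = np.nan
    ef_pct: float = np.nan
    event: int = 0
    followup_y: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortFormatError(f"{self.subject_id}: unknown group {self.group!r}")
        if self.morphology not in MORPHOLOGIES:
            raise CohortFormatError(
                f"{self.subject_id}: unknown morphology {self.morphology!r}"
            )
        if self.group == "control" and self.morphology != "control_LV":
            raise CohortFormatError(
                f"{self.subject_id}: controls must have morphology control_LV"
            )
        if self.event not in (0, 1):
            raise CohortFormatError(f"{self.subject_id}: event must be 0/1")
        if self.followup_y < 0:
            raise CohortFormatError(f"{self.subject_id}: negative follow-up")


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = [{f.name: getattr(r, f.name) for f in dc_fields(r)} for r in records]
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


def _records_from_frame(df: pd.DataFrame) -> List[SubjectRecord]:
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortFormatError(f"subjects file missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = {c: getattr(row, c) for c in SUBJECT_COLUMNS}
        d["subject_id"] = str(d["subject_id"])
        d["sex"] = "" if pd.isna(d["sex"]) else str(d["sex"])
        d["n_slices"] = int(d["n_slices"])
        d["event"] = int(d["event"])
        records.append(SubjectRecord(**d))
    return records


def read_cohort(
    curves_path: Path | str, subjects_path: Path | str
) -> Tuple[List[VentricleDataset], List[SubjectRecord]]:
    """Read a cohort from the long-format curves CSV and the subjects CSV.

    Validates grid completeness (every kind x segment cell present with
    exactly 30 phases) and the one-to-one join between the two files.
    """
    subjects = pd.read_csv(subjects_path, dtype={"subject_id": str},
                           float_precision="round_trip")
    records = _records_from_frame(subjects)
    by_id = {r.subject_id: r for r in records}
    if len(by_id) != len(records):
        raise CohortJoinError("duplicate subject_id in subjects file")

    curves = pd.read_csv(curves_path, dtype={"subject_id": str, "kind": str},
                         float_precision="round_trip")
    missing = set(CURVE_COLUMNS) - set(curves.columns)
    if missing:
        raise CohortFormatError(f"curves file missing columns {sorted(missing)}")

    curve_ids = set(curves["subject_id"].unique())
    record_ids = set(by_id)
    if curve_ids - record_ids:
        raise CohortJoinError(
            f"curves without subject record: {sorted(curve_ids - record_ids)[:5]}"
        )
    if record_ids - curve_ids:
        raise CohortJoinError(
            f"subject records without curves: {sorted(record_ids - curve_ids)[:5]}"
        )

    kind_order = {k.value: i for i, k in enumerate(ALL_KINDS)}
    bad_kinds = set(curves["kind"].unique()) - set(kind_order)
    if bad_kinds:
        raise CohortFormatError(f"unknown measurement kinds {sorted(bad_kinds)}")

    datasets = []
    for sid, sub in curves.groupby("subject_id", sort=True):
        rec = by_id[sid]
        S = rec.n_slices
        sub = sub.sort_values(
            ["kind", "slice_index", "sector", "phase_index"],
            key=lambda col: col.map(kind_order) if col.name == "kind" else col,
        )
        expected = len(ALL_KINDS) * S * N_SECTORS * N_PHASES
        _check_subject_grid(sid, sub, S, expected)
        vals = sub["value"].to_numpy(dtype=float)
        grid = vals.reshape(len(ALL_KINDS), S, N_SECTORS, N_PHASES)
        datasets.append(
            VentricleDataset(
                subject_id=sid,
                heart_rate_bpm=rec.heart_rate_bpm,
                n_slices=S,
                values={k: grid[i] for i, k in enumerate(ALL_KINDS)},
            )
        )
    return datasets, records


def _check_subject_grid(sid: str, sub: pd.DataFrame, n_slices: int, expected: int) -> None:
    """Verify a sorted per-subject frame covers the full grid exactly once."""
    counts = sub.groupby(["kind", "slice_index", "sector"], sort=False).size()
    bad = counts[counts != N_PHASES]
    if len(bad):
        kind, sl, sec = bad.index[0]
        raise CohortFormatError(
            f"{sid}: segment (kind={kind}, slice={sl}, sector={sec}) has "
            f"{bad.iloc[0]} phase rows, expected {N_PHASES}"
        )
    if len(sub) != expected:
        have = {
            (k, int(s), int(c))
            for k, s, c in counts.index
        }
        for kind in ALL_KINDS:
            for s in range(n_slices):
                for c in range(1, N_SECTORS + 1):
                    if (kind.value, s, c) not in have:
                        raise IncompleteGridError(
                            f"{sid}: missing curve for kind={kind.value}, "
                            f"slice={s}, sector={c}"
                        )
        raise CohortFormatError(
            f"{sid}: unexpected rows (slice_index/sector outside the "
            f"{n_slices}x{N_SECTORS} grid, or duplicates)"
        )
    # Full coverage + correct total implies indices are in range; still guard
    # against out-of-range slices masquerading as complete grids.
    if (
        sub["slice_index"].min() < 0
        or sub["slice_index"].max() >= n_slices
        or sub["sector"].min() < 1
        or sub["sector"].max() > N_SECTORS
        or sub["phase_index"].min() < 0
        or sub["phase_index"].max() >= N_PHASES
    ):
        raise CohortFormatError(f"{sid}: curve indices outside the declared grid")


def write_cohort(
    datasets: Sequence[VentricleDataset],
    records: Sequence[SubjectRecord],
    out_dir: Path | str,
) -> Tuple[Path, Path]:
    """Write a cohort to ``curves.csv`` + ``subjects.csv`` under ``out_dir``.

    Floats are written at full round-trip precision so that
    ``read_cohort(write_cohort(x))`` reproduces the values bit-for-bit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curves_path = out_dir / "curves.csv"
    subjects_path = out_dir / "subjects.csv"

    frames = []
    for ds in datasets:
        n_seg = ds.n_segments
        n_rows = len(ALL_KINDS) * n_seg * N_PHASES
        slice_idx = np.repeat(np.arange(ds.n_slices), N_SECTORS * N_PHASES)
        sector = np.tile(np.repeat(np.arange(1, N_SECTORS + 1), N_PHASES), ds.n_slices)
        phase = np.tile(np.arange(N_PHASES), n_seg)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(ds.subject_id, n_rows),
                    "kind": np.repeat([k.value for k in ALL_KINDS], n_seg * N_PHASES),
                    "slice_index": np.tile(slice_idx, len(ALL_KINDS)),
                    "sector": np.tile(sector, len(ALL_KINDS)),
                    "phase_index": np.tile(phase, len(ALL_KINDS)),
                    "value": np.concatenate(
                        [ds.values[k].ravel() for k in ALL_KINDS]
                    ),
                }
            )
        )
    if frames:
        curves_df = pd.concat(frames, ignore_index=True)
    else:
        curves_df = pd.DataFrame(columns=CURVE_COLUMNS)
    curves_df.to_csv(curves_path, index=False, float_format="%.17g")
    records_to_frame(records).to_csv(subjects_path, index=False, float_format="%.17g")
    return curves_path, subjects_path
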