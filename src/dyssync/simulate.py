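"""Synthetic single-ventricle cohort generator.

Real feature-tracking cohorts of this kind are not publicly deposited, so
every pipeline stage is exercised against simulated cohorts with the
statistical structure the analysis assumes: four latent dyssynchrony
phenotypes of increasing severity, segment-level activation delays that the
timing metrics can recover, amplitude (strain-magnitude) differences, a
control group drawn from the two most synchronous phenotypes, and
phenotype-dependent hazards for the composite outcome.

Curve model
-----------
Each segment's deformation is a raised-cosine bump on a periodic cycle of
length L ms: the bump occupies 70% of the cycle starting at 0.15 L,
reaches its polarity extremum at ``0.5 L + delta`` where ``delta`` is the
segment's activation delay, and is zero (end-diastolic baseline) elsewhere.
Strain-rate curves are the analytic time derivative of the strain template;
displacement curves share the strain shift with their own amplitude.  The
segment delay decomposes into the phenotype's systematic opposing-wall shift
(sectors 4-6 late), a base-to-apex gradient (basal slices late), and
Gaussian segmental jitter drawn orthogonal to those contrasts and normalized
to the phenotype's dispersion, so each subject expresses the phenotype's
SDTTP / MOWD / BAD signature exactly up to measurement noise.

Outcome model
-------------
Event times are exponential with hazard ``lambda0 * HR(phenotype)``;
independent uniform administrative censoring on (0, censor_max_y) is
calibrated by solving for ``lambda0`` so the expected event fraction matches
the target (11.5% at defaults).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .curves import (
    ALL_KINDS,
    N_PHASES,
    N_SECTORS,
    DeformationCurve,
    MeasurementKind,
    SegmentId,
    SubjectRecord,
    VentricleDataset,
    cycle_length_ms,
    write_cohort,
)

#: Fraction of the cycle at which the deformation bump begins.
BUMP_ONSET_FRACTION = 0.15
#: Fraction of the cycle occupied by the deformation bump.
BUMP_WIDTH_FRACTION = 0.70
#: Strain/displacement peak sits at onset + width/2 = half the cycle; the
#: strain-rate peak at onset + width/4.  Delays are clipped so both stay
#: strictly inside the cycle for every segment.
SHIFT_CLIP_FRACTIONS = (-0.30, 0.45)


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generative parameters of one latent dyssynchrony phenotype."""

    name: str
    mixing: float  # proportion of patients
    ttp_sd_ms: float  # total segmental time-to-peak dispersion (sample SD)
    wall_delay_ms: float  # systematic sector 4-6 vs 1-3 delay (-> MOWD)
    base_apex_delay_ms: float  # basal-vs-apical systematic delay (-> BAD)
    gcs_pct: float  # global circumferential strain amplitude (<= 0)
    grs_pct: float  # global radial strain amplitude (>= 0)
    edvi: Tuple[float, float]  # (mean, sd), mL/m^2
    ef: Tuple[float, float]  # (mean, sd), %
    qrs: Tuple[float, float]  # (mean, sd), ms
    age: Tuple[float, float]  # (mean, sd), y
    male_prob: float
    morphology_probs: Dict[str, float]  # over LV / RV / mixed
    hazard_ratio: float  # vs phenotype 1

    def __post_init__(self) -> None:
        if self.ttp_sd_ms < 0 or self.wall_delay_ms < 0 or self.base_apex_delay_ms < 0:
            raise ValueError("delay parameters must be nonnegative")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if abs(sum(self.morphology_probs.values()) - 1.0) > 1e-9:
            raise ValueError("morphology probabilities must sum to 1")


#: Default phenotypes, ordered by increasing dyssynchrony.  Dyssynchrony,
#: volumetric and electrical anchors follow the four observed cluster
#: profiles (SDTTP-GCS ~ 43/48/77/132 ms, GCS ~ -16/-16/-13/-8%, EDVi ~
#: 101/101/111/169 mL/m^2, EF ~ 56/56/51/34%); hazard is monotone in
#: dyssynchrony with the worst-vs-best ratio 6.4.
DEFAULT_PHENOTYPES: Tuple[PhenotypeSpec, ...] = (
    PhenotypeSpec("synchronous_young", 0.518, 43.0, 44.0, 28.0, -16.0, 24.0,
                  (101.0, 27.0), (55.0, 7.0), (94.0, 14.0), (12.5, 5.0), 0.53,
                  {"LV": 0.55, "RV": 0.28, "mixed": 0.17}, 1.0),
    PhenotypeSpec("synchronous_older", 0.222, 48.0, 52.0, 37.0, -16.0, 26.0,
                  (101.0, 22.0), (56.0, 7.0), (101.0, 15.0), (17.5, 6.0), 0.59,
                  {"LV": 0.65, "RV": 0.23, "mixed": 0.12}, 1.4),
    PhenotypeSpec("intermediate", 0.217, 77.0, 78.0, 51.0, -13.0, 18.0,
                  (111.0, 30.0), (50.0, 9.0), (106.0, 17.0), (17.6, 6.0), 0.66,
                  {"LV": 0.40, "RV": 0.40, "mixed": 0.20}, 1.6),
    PhenotypeSpec("dilated_dyssynchronous", 0.043, 132.0, 128.0, 68.0, -8.0, 11.0,
                  (169.0, 55.0), (36.0, 9.0), (122.0, 18.0), (16.7, 6.0), 0.83,
                  {"LV": 0.15, "RV": 0.55, "mixed": 0.30}, 6.4),
)

#: Control-LV anchors (dyssynchrony near the synchronous phenotypes but with
#: normal volumes, function and QRS).
CONTROL_COVARIATES = {
    "edvi": (82.0, 14.0), "ef": (60.0, 5.0), "qrs": (84.0, 10.0),
    "age": (15.5, 5.0), "male_prob": 0.43,
}


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_patients: int = 512
    n_controls: int = 42
    seed: int = 0
    heart_rate: Tuple[float, float] = (82.0, 13.0)  # mean, sd (bpm)
    heart_rate_range: Tuple[float, float] = (50.0, 115.0)
    n_slices_range: Tuple[int, int] = (4, 8)  # inclusive, uniform
    rel_noise: float = 0.003  # additive noise SD as a fraction of amplitude
    subject_scatter: float = 0.02  # within-phenotype relative parameter scatter
    amplitude_scatter: float = 0.08  # relative scatter of strain amplitudes
    event_fraction: float = 0.115  # target expected patient event fraction
    censor_max_y: float = 12.0  # uniform administrative censoring bound
    phenotypes: Tuple[PhenotypeSpec, ...] = DEFAULT_PHENOTYPES

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if self.rel_noise < 0:
            raise ValueError("rel_noise must be nonnegative")
        total = sum(p.mixing for p in self.phenotypes)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"phenotype mixing proportions sum to {total}, not 1")
        if not 0 < self.event_fraction < 1:
            raise ValueError("event_fraction must lie in (0, 1)")


def _bump(u: np.ndarray) -> np.ndarray:
    """Raised-cosine template on cycle fraction u in [0, 1): peak 1 at 0.35."""
    out = np.zeros_like(u)
    inside = u < BUMP_WIDTH_FRACTION
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u[inside] / BUMP_WIDTH_FRACTION))
    return out


def _bump_derivative(u: np.ndarray) -> np.ndarray:
    """d(bump)/du; used analytically for the strain-rate curves."""
    out = np.zeros_like(u)
    inside = u < BUMP_WIDTH_FRACTION
    out[inside] = (np.pi / BUMP_WIDTH_FRACTION) * np.sin(
        2.0 * np.pi * u[inside] / BUMP_WIDTH_FRACTION
    )
    return out


def _kind_amplitudes(gcs_pct: float, grs_pct: float, L_ms: float) -> Dict[MeasurementKind, float]:
    """Signed peak values per kind given the strain amplitudes.

    Strain-rate peaks follow from the analytic derivative of the strain
    template (units 1/s); displacement amplitudes scale with radial strain
    (~0.25 mm per % radial strain, ~60% of that circumferentially).
    """
    rate_gain = (np.pi / BUMP_WIDTH_FRACTION) * 1000.0 / L_ms  # peak |db/dt| in 1/ms -> 1/s
    return {
        MeasurementKind.CIRC_STRAIN: gcs_pct,
        MeasurementKind.CIRC_STRAIN_RATE: (gcs_pct / 100.0) * rate_gain,
        MeasurementKind.CIRC_DISPLACEMENT: 0.15 * grs_pct,
        MeasurementKind.RAD_STRAIN: grs_pct,
        MeasurementKind.RAD_STRAIN_RATE: (grs_pct / 100.0) * rate_gain,
        MeasurementKind.RAD_DISPLACEMENT: 0.25 * grs_pct,
    }


def generate_curve(
    kind: MeasurementKind,
    segment: SegmentId,
    shift_ms: float,
    amplitude: float,
    heart_rate_bpm: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> DeformationCurve:
    """One synthetic deformation curve sampled at 30 phases.

    ``amplitude`` is the signed peak value in the kind's native units;
    ``noise_sd`` is the additive Gaussian noise SD in those units.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    L = cycle_length_ms(heart_rate_bpm)
    t = np.arange(N_PHASES) * (L / N_PHASES)
    u = ((t - shift_ms - BUMP_ONSET_FRACTION * L) % L) / L
    if kind in (MeasurementKind.CIRC_STRAIN_RATE, MeasurementKind.RAD_STRAIN_RATE):
        base = amplitude / (np.pi / BUMP_WIDTH_FRACTION) * _bump_derivative(u)
    else:
        base = amplitude * _bump(u)
    samples = base + rng.normal(0.0, noise_sd, size=N_PHASES)
    return DeformationCurve(kind=kind, segment=segment, samples=samples,
                            cycle_length_ms=L)


def _segment_shifts(
    n_slices: int,
    ttp_sd_ms: float,
    wall_delay_ms: float,
    base_apex_delay_ms: float,
    L_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-segment activation delays (ms), shape (n_slices, 6).

    The systematic part encodes the wall-pair and base-apex contrasts
    exactly; jitter is projected orthogonal to those contrast directions
    (and the grand mean) and normalized to make the total sample SD of the
    delays equal ``ttp_sd_ms``.  Delays are finally clipped so every peak
    stays inside the cycle.
    """
    S, n = n_slices, n_slices * N_SECTORS
    wall = np.tile(np.array([-0.5, -0.5, -0.5, 0.5, 0.5, 0.5]) * wall_delay_ms, (S, 1))
    ramp = np.linspace(0.0, 1.0, S)
    apex_base = base_apex_delay_ms * (ramp - ramp.mean())[:, None] * np.ones((1, N_SECTORS))
    systematic = (wall + apex_base).ravel()

    # contrast directions the jitter must not disturb
    basis = [np.ones(n)]
    for s in range(3):
        d = np.zeros((S, N_SECTORS))
        d[:, s], d[:, s + 3] = 1.0, -1.0
        basis.append(d.ravel())
    d = np.zeros((S, N_SECTORS))
    d[0, :], d[-1, :] = 1.0, -1.0
    basis.append(d.ravel())
    Q, _ = np.linalg.qr(np.column_stack(basis))

    # Stratified (permuted-quantile) normal sample: each subject realizes the
    # phenotype's delay distribution itself, not an i.i.d. draw from it, so
    # distribution summaries (dispersion, percentiles of |delay|) are stable
    # across subjects of a phenotype.
    from scipy.stats import norm

    g = rng.permutation(norm.ppf((np.arange(n) + 0.5) / n))
    g = g - Q @ (Q.T @ g)
    sd = g.std(ddof=1)
    if sd < 1e-12:  # pathologically tiny grid; keep zero jitter
        g = np.zeros(n)
    else:
        g = g / sd
    syst_var = np.var(systematic, ddof=1)
    jitter_var = max(ttp_sd_ms**2 - syst_var, 0.0)
    shifts = systematic + np.sqrt(jitter_var) * g
    lo, hi = (f * L_ms for f in SHIFT_CLIP_FRACTIONS)
    return np.clip(shifts, lo, hi).reshape(S, N_SECTORS)


def simulate_ventricle(
    subject_id: str,
    phenotype: PhenotypeSpec,
    heart_rate_bpm: float,
    n_slices: int,
    rng: np.random.Generator,
    rel_noise: float = 0.003,
    subject_scatter: float = 0.02,
    amplitude_scatter: float = 0.08,
) -> VentricleDataset:
    """One subject's full curve grid drawn from a phenotype."""
    L = cycle_length_ms(heart_rate_bpm)
    timing_factor = float(np.exp(rng.normal(0.0, subject_scatter)))
    amp_factor = float(np.exp(rng.normal(0.0, amplitude_scatter)))
    shifts = _segment_shifts(
        n_slices,
        phenotype.ttp_sd_ms * timing_factor,
        phenotype.wall_delay_ms * timing_factor,
        phenotype.base_apex_delay_ms * timing_factor,
        L,
        rng,
    )
    amps = _kind_amplitudes(phenotype.gcs_pct * amp_factor,
                            phenotype.grs_pct * amp_factor, L)
    t = np.arange(N_PHASES) * (L / N_PHASES)
    u = ((t[None, None, :] - shifts[:, :, None] - BUMP_ONSET_FRACTION * L) % L) / L  # (S, 6, 30)
    bump = _bump(u)
    dbump = _bump_derivative(u)
    values: Dict[MeasurementKind, np.ndarray] = {}
    for kind in ALL_KINDS:
        amp = amps[kind]
        if kind in (MeasurementKind.CIRC_STRAIN_RATE, MeasurementKind.RAD_STRAIN_RATE):
            base = amp / (np.pi / BUMP_WIDTH_FRACTION) * dbump
        else:
            base = amp * bump
        noise_sd = rel_noise * abs(amp)
        values[kind] = base + rng.normal(0.0, noise_sd, size=base.shape)
    return VentricleDataset(subject_id=subject_id, heart_rate_bpm=heart_rate_bpm,
                            n_slices=n_slices, values=values)


def _expected_event_fraction(lambda0: float, hrs: np.ndarray, mixing: np.ndarray,
                             censor_max: float) -> float:
    lam = lambda0 * hrs
    # P(T < C), C ~ U(0, c): 1 - (1 - exp(-lam c)) / (lam c)
    with np.errstate(over="ignore"):
        p = 1.0 - (1.0 - np.exp(-lam * censor_max)) / (lam * censor_max)
    return float(np.sum(mixing * p))


def solve_baseline_hazard(
    phenotypes: Sequence[PhenotypeSpec], event_fraction: float, censor_max_y: float
) -> float:
    """Baseline hazard (1/y) giving the target expected event fraction."""
    hrs = np.array([p.hazard_ratio for p in phenotypes])
    mixing = np.array([p.mixing for p in phenotypes])
    f = lambda lam: _expected_event_fraction(lam, hrs, mixing, censor_max_y) - event_fraction
    return float(brentq(f, 1e-8, 10.0))


def generate_outcomes(
    phenotype_labels: np.ndarray,
    hazard_ratios: Sequence[float],
    baseline_hazard: float,
    censor_max_y: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exponential event times under phenotype hazards with uniform censoring.

    ``phenotype_labels`` are 1-based; returns ``(event 0/1, followup_y)``.
    """
    hrs = np.asarray(hazard_ratios, dtype=float)
    if np.any(hrs <= 0):
        raise ValueError("hazard ratios must be positive")
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    lam = baseline_hazard * hrs[np.asarray(phenotype_labels, dtype=int) - 1]
    event_times = rng.exponential(1.0 / lam)
    censor_times = rng.uniform(0.0, censor_max_y, size=lam.size)
    event = (event_times <= censor_times).astype(int)
    followup = np.minimum(event_times, censor_times)
    return event, followup


@dataclass
class SimulatedCohort:
    """In-memory cohort plus the planted ground truth."""

    datasets: List[VentricleDataset]
    records: List[SubjectRecord]
    planted_labels: np.ndarray  # 1-based phenotype per subject (incl. controls)
    config: CohortConfig
    baseline_hazard: float


def _draw_covariates(
    phenotype: PhenotypeSpec, is_control: bool, rng: np.random.Generator
) -> Dict[str, object]:
    if is_control:
        edvi_m, edvi_s = CONTROL_COVARIATES["edvi"]
        ef_m, ef_s = CONTROL_COVARIATES["ef"]
        qrs_m, qrs_s = CONTROL_COVARIATES["qrs"]
        age_m, age_s = CONTROL_COVARIATES["age"]
        male_p = CONTROL_COVARIATES["male_prob"]
        morphology = "control_LV"
    else:
        edvi_m, edvi_s = phenotype.edvi
        ef_m, ef_s = phenotype.ef
        qrs_m, qrs_s = phenotype.qrs
        age_m, age_s = phenotype.age
        male_p = phenotype.male_prob
        morphs = list(phenotype.morphology_probs)
        morphology = morphs[rng.choice(len(morphs), p=[phenotype.morphology_probs[m] for m in morphs])]
    edvi = max(rng.normal(edvi_m, edvi_s), 25.0)
    ef = float(np.clip(rng.normal(ef_m, ef_s), 10.0, 75.0))
    return {
        "morphology": morphology,
        "age_y": max(rng.normal(age_m, age_s), 0.5),
        "sex": "M" if rng.random() < male_p else "F",
        "bsa_m2": float(np.clip(rng.normal(1.45, 0.35), 0.4, 2.6)),
        "qrs_ms": float(np.clip(rng.normal(qrs_m, qrs_s), 55.0, 210.0)),
        "edvi_ml_m2": edvi,
        "esvi_ml_m2": edvi * (1.0 - ef / 100.0),
        "massi_g_m2": max(rng.normal(0.45 * edvi_m, 10.0), 20.0),
        "ef_pct": ef,
    }


def simulate_cohort(config: CohortConfig = CohortConfig()) -> SimulatedCohort:
    """Generate a full cohort (patients + controls), deterministic given seed.

    Patients are drawn from the phenotype mixture; controls reuse the curve
    parameters of the two most synchronous phenotypes with control-LV
    covariates and do not contribute events.
    """
    rng = np.random.default_rng(config.seed)
    phen = config.phenotypes
    n_phen = len(phen)

    patient_labels = 1 + rng.choice(
        n_phen, size=config.n_patients, p=[p.mixing for p in phen]
    )
    control_source = 1 + rng.choice(min(2, n_phen), size=config.n_controls)

    baseline = solve_baseline_hazard(phen, config.event_fraction, config.censor_max_y)
    event, followup = generate_outcomes(
        patient_labels, [p.hazard_ratio for p in phen], baseline,
        config.censor_max_y, rng,
    )

    datasets: List[VentricleDataset] = []
    records: List[SubjectRecord] = []
    planted: List[int] = []

    def _make_subject(sid: str, label: int, is_control: bool, ev: int, fu: float) -> None:
        spec = phen[label - 1]
        hr = float(np.clip(rng.normal(*config.heart_rate), *config.heart_rate_range))
        n_slices = int(rng.integers(config.n_slices_range[0], config.n_slices_range[1] + 1))
        ds = simulate_ventricle(
            sid, spec, hr, n_slices, rng,
            rel_noise=config.rel_noise,
            subject_scatter=config.subject_scatter,
            amplitude_scatter=config.amplitude_scatter,
        )
        cov = _draw_covariates(spec, is_control, rng)
        records.append(SubjectRecord(
            subject_id=sid, group="control" if is_control else "fontan",
            heart_rate_bpm=hr, n_slices=n_slices, event=ev, followup_y=fu, **cov,
        ))
        datasets.append(ds)
        planted.append(label)

    for i in range(config.n_patients):
        _make_subject(f"P{i + 1:04d}", int(patient_labels[i]), False,
                      int(event[i]), float(followup[i]))
    for j in range(config.n_controls):
        fu = float(rng.uniform(0.0, config.censor_max_y))
        _make_subject(f"C{j + 1:04d}", int(control_source[j]), True, 0, fu)

    return SimulatedCohort(
        datasets=datasets, records=records,
        planted_labels=np.array(planted, dtype=int),
        config=config, baseline_hazard=baseline,
    )


def generate_cohort(config: CohortConfig, out_dir: Path | str) -> Dict[str, Path]:
    """Simulate a cohort and write it in the cohort CSV dialects.

    Also writes ``simulation.json`` echoing the seed and phenotype table
    (plus the planted labels) for reproducibility.
    """
    cohort = simulate_cohort(config)
    out_dir = Path(out_dir)
    curves_path, subjects_path = write_cohort(cohort.datasets, cohort.records, out_dir)
    echo = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "n_controls": config.n_controls,
        "baseline_hazard_per_y": cohort.baseline_hazard,
        "config": {
            k: v for k, v in asdict(config).items() if k != "phenotypes"
        },
        "phenotypes": [asdict(p) for p in config.phenotypes],
        "planted_labels": {
            r.subject_id: int(l)
            for r, l in zip(cohort.records, cohort.planted_labels)
        },
    }
    echo_path = out_dir / "simulation.json"
    echo_path.write_text(json.dumps(echo, indent=2, sort_keys=True))
    return {"curves": curves_path, "subjects": subjects_path, "echo": echo_path}
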