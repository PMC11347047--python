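import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dyssync.curves import (
    ALL_KINDS,
    N_PHASES,
    N_SECTORS,
    MeasurementKind,
    SegmentId,
    SubjectRecord,
    VentricleDataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def cosine_bump(n_phases: int = N_PHASES, peak_phase: float = 0.5,
                width: float = 0.7, amplitude: float = 1.0) -> np.ndarray:
    """Reference raised-cosine curve built independently of the simulator."""
    t = np.arange(n_phases) / n_phases
    u = (t - (peak_phase - width / 2.0)) % 1.0
    y = np.where(u < width, 0.5 * (1 - np.cos(2 * np.pi * u / width)), 0.0)
    return amplitude * y


def make_ventricle(
    n_slices: int = 4,
    heart_rate_bpm: float = 100.0,
    shifts_ms=None,
    subject_id: str = "S1",
) -> VentricleDataset:
    """Ventricle whose every kind shares one cosine template, optionally with
    per-segment circular shifts (ms), built directly from the template."""
    L = 60000.0 / heart_rate_bpm
    if shifts_ms is None:
        shifts_ms = np.zeros((n_slices, N_SECTORS))
    shifts_ms = np.asarray(shifts_ms, dtype=float)
    t = np.arange(N_PHASES) * (L / N_PHASES)
    values = {}
    for kind in ALL_KINDS:
        amp = -15.0 if kind.polarity < 0 else 15.0
        u = ((t[None, None, :] - shifts_ms[:, :, None]) / L - 0.15) % 1.0
        base = np.where(u < 0.7, 0.5 * (1 - np.cos(2 * np.pi * u / 0.7)), 0.0)
        values[kind] = amp * base
    return VentricleDataset(subject_id=subject_id, heart_rate_bpm=heart_rate_bpm,
                            n_slices=n_slices, values=values)


@pytest.fixture
def uniform_ventricle() -> VentricleDataset:
    """Fully synchronous 4-slice ventricle (all segments identical)."""
    return make_ventricle()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort with planted labels (session-wide)."""
    from dyssync.simulate import CohortConfig, simulate_cohort

    return simulate_cohort(CohortConfig(seed=20260924))
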