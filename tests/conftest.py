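import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from fpvstag.paradigm import StimulationParadigm
from fpvstag.synthgen import SimulationConfig


UNIT_GAINS = {"LOT": 1.0, "MO": 1.0, "ROT": 1.0}


@pytest.fixture
def noise_free_cfg() -> SimulationConfig:
    """Signal-only EEG config: exact spectral ground truth."""
    return SimulationConfig(
        seed=11,
        pink_sd_uv=0.0,
        white_sd_uv=0.0,
        subject_amp_sd=0.0,
        roi_gains_base=UNIT_GAINS,
        roi_gains_response=UNIT_GAINS,
    )


@pytest.fixture
def noisy_cfg() -> SimulationConfig:
    """Realistic noise floor, unit topography."""
    return SimulationConfig(
        seed=12,
        roi_gains_base=UNIT_GAINS,
        roi_gains_response=UNIT_GAINS,
    )


@pytest.fixture
def oddball_paradigm() -> StimulationParadigm:
    return StimulationParadigm(kind="oddball", content="social")


@pytest.fixture
def multiinput_paradigm() -> StimulationParadigm:
    return StimulationParadigm(kind="multi_input", content="social")


def balanced_two_way(
    n_subjects: int,
    effects: tuple[float, float, float] = (0.5, 0.3, 0.2),
    sigma_subject: float = 0.0,
    sigma: float = 1.0,
    seed: int = 0,
    center_within: bool = False,
) -> pd.DataFrame:
    """Balanced 2x2 within-subject layout with +/-0.5 coded factors.

    ``center_within=True`` removes each subject's mean residual, which pins
    the between-subject variance estimate to zero (the compound-symmetry
    boundary) so mixed-model F tests coincide with fixed-effects ANOVA.
    """
    rng = np.random.default_rng(seed)
    a_eff, b_eff, ab_eff = effects
    eps = rng.normal(0, sigma, (n_subjects, 4))
    if center_within:
        eps -= eps.mean(axis=1, keepdims=True)
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0, sigma_subject) if sigma_subject > 0 else 0.0
        j = 0
        for a in (-0.5, 0.5):
            for b in (-0.5, 0.5):
                rows.append(
                    {
                        "subject": f"s{s:03d}",
                        "a": a,
                        "b": b,
                        "y": 1.0 + a_eff * a + b_eff * b + ab_eff * a * b
                        + u + eps[s, j],
                    }
                )
                j += 1
    return pd.DataFrame(rows)
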