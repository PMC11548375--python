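import numpy as np
import pytest

from nirsleep.optics import convert_recording
from nirsleep.synthetic import SimulationConfig, simulate
from nirsleep.types import FeatureEpoch

#: Config overrides with no label-dependent structure at all.
ZERO_SEPARATION = dict(
    hr_range_by_state={s: (110.0, 170.0) for s in ("AS", "QS", "Wake")},
    rr_range_by_state={s: (30.0, 70.0) for s in ("AS", "QS", "Wake")},
    wander_scale_by_state={s: 1.0 for s in ("AS", "QS", "Wake")},
    motion_rate_by_state={s: 0.1 for s in ("AS", "QS", "Wake")},
    qs_fraction=0.4,
    wake_fraction=0.0,
)

#: Config overrides with strongly state-dependent HR/RR/motion.
STRONG_SEPARATION = dict(
    hr_range_by_state={"AS": (150.0, 175.0), "QS": (105.0, 130.0),
                       "Wake": (150.0, 175.0)},
    rr_range_by_state={"AS": (55.0, 75.0), "QS": (25.0, 40.0),
                       "Wake": (55.0, 75.0)},
    wander_scale_by_state={"AS": 1.0, "QS": 0.25, "Wake": 1.2},
    motion_rate_by_state={"AS": 0.6, "QS": 0.0, "Wake": 1.0},
    qs_fraction=0.4,
    wake_fraction=0.0,
)


@pytest.fixture(scope="session")
def sim_10min():
    """One 10-minute default-config simulation shared across tests."""
    cfg = SimulationConfig(seed=42, duration=10)
    rec, ref, truth = simulate(cfg)
    return cfg, rec, ref, truth


@pytest.fixture(scope="session")
def hemo_10min(sim_10min):
    _, rec, _, _ = sim_10min
    return convert_recording(rec)[0]


def make_toy_epochs(n_per_class: int = 20, separation: float = 5.0, seed: int = 0,
                    n_recordings: int = 2) -> list[FeatureEpoch]:
    """Linearly separable synthetic feature epochs (no pipeline involved)."""
    rng = np.random.default_rng(seed)
    epochs = []
    for i in range(2 * n_per_class):
        label = "QS" if i < n_per_class else "AS"
        shift = separation if label == "QS" else 0.0
        mat = rng.normal(shift * (1 if label == "QS" else 0), 1.0, (8, 60))
        mat[0] += shift if label == "QS" else 0.0
        rid = f"m{(i % n_recordings) + 1}"
        epochs.append(FeatureEpoch(matrix=mat, label=label, epoch_start=60.0 * i,
                                   recording_id=rid, subject_id=rid))
    return epochs
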