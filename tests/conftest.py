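import numpy as np
import pytest

from decflow.dynec import ECMatrix, ECWindowStack, WindowSpec
from decflow.synthdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny default-regime cohort shared across read-only tests."""
    cfg = SimConfig(n_subjects=(4, 4), n_timepoints=120)
    return simulate_cohort(cfg, seed=42)


def make_stack(matrices, subject_id="sub-001", group=None, width=18, step=2):
    """Build an ECWindowStack directly from an iterable of square arrays."""
    mats = [np.asarray(m, dtype=float) for m in matrices]
    d = mats[0].shape[0]
    names = [f"c{i + 1:02d}" for i in range(d)]
    return ECWindowStack(
        subject_id=subject_id,
        matrices=[ECMatrix(values=m, component_names=names, window=i)
                  for i, m in enumerate(mats)],
        spec=WindowSpec(width, step),
        order=1,
        ridge=0.0,
        mode="coef",
        group=group,
    )


@pytest.fixture
def planted_stacks():
    """Two well-separated planted centroids: 100 windows of C1, 50 of C2."""
    rng = np.random.default_rng(0)
    d = 5
    c1 = np.zeros((d, d))
    c2 = np.zeros((d, d))
    c2[0, 1] = c2[2, 3] = 5.0
    mats_a = [c1 + rng.normal(0, 0.05, (d, d)) for _ in range(100)]
    mats_b = [c2 + rng.normal(0, 0.05, (d, d)) for _ in range(50)]
    half = len(mats_a) // 2
    s1 = make_stack(mats_a[:half] + mats_b[:25], subject_id="sub-001")
    s2 = make_stack(mats_a[half:] + mats_b[25:], subject_id="sub-002")
    truth = np.concatenate([np.ones(half), np.full(25, 2), np.ones(half), np.full(25, 2)])
    return [s1, s2], truth.astype(int)
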