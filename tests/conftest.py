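import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rohkit as rk

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def admixed_bundle():
    """One admixed+inbred scenario with panels, shared across tests."""
    lengths = {f"s{i}": 30_000_000 for i in range(2)}
    return rk.scenario(
        "admixed_inbred",
        2,
        sizes={"scaffold_lengths": lengths, "n_panel": 3},
        seed=5,
    )


@pytest.fixture(scope="session")
def isolated_bundle():
    """One isolated inbred scenario (g=3, bottleneck founders), rendered."""
    lengths = {f"s{i}": 25_000_000 for i in range(6)}
    return rk.scenario(
        "isolated_inbred",
        3,
        sizes={"scaffold_lengths": lengths, "n_founders": 4, "n_panel": 0},
        seed=11,
    )


def bp_confusion(called_tracts, truth_tracts, scaffold_lengths, grid=1000):
    """bp-level (TP, FP, FN) between interval sets on a coarse grid."""
    tp = fp = fn = 0
    for name, L in scaffold_lengths.items():
        n = L // grid
        called = np.zeros(n, bool)
        truth = np.zeros(n, bool)
        for iv in called_tracts:
            if iv.scaffold == name:
                called[iv.start // grid : iv.end // grid] = True
        for iv in truth_tracts:
            if iv.scaffold == name:
                truth[iv.start // grid : iv.end // grid] = True
        tp += int((called & truth).sum())
        fp += int((called & ~truth).sum())
        fn += int((~called & truth).sum())
    return tp, fp, fn
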