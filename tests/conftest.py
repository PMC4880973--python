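import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from evencap.intervals import GenomicInterval, TargetDesign
from evencap.synthetic_data import SimulationConfig, make_reference, make_subclones

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_ref():
    """A compact reference: 40 exon-like targets, one long one, tiled baits."""
    return make_reference(n_targets=40, n_long_targets=1, seed=7)


@pytest.fixture(scope="session")
def small_subclones(small_ref):
    return make_subclones(small_ref, n_subclones=2, n_shared=10, n_private=3, seed=7)


@pytest.fixture(scope="session")
def small_sim_cfg():
    return SimulationConfig(seed=7, n_pairs=800, insert_peak=130)


def random_design(rng: np.random.Generator, max_intervals: int = 20,
                  coord_max: int = 10_000, name: str = "d") -> TargetDesign:
    n = int(rng.integers(1, max_intervals + 1))
    ivs = []
    for _ in range(n):
        ref = f"ref{int(rng.integers(0, 2))}"
        start = int(rng.integers(0, coord_max - 1))
        length = int(rng.integers(1, 300))
        ivs.append(GenomicInterval(ref, start, min(start + length, coord_max)))
    return TargetDesign(name, ivs)


def design_base_set(design: TargetDesign) -> set:
    """Brute-force per-base set representation of a design."""
    return {(iv.ref_name, p) for iv in design for p in range(iv.start, iv.end)}
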