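import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture()
def tiny_array_obs():
    """A small two-replicate loop experiment (4 genes, 8 arrays, 2 flocks)."""
    from fleecerot.simulate import ArraySimConfig, simulate_intensities
    from fleecerot.normalization import VarianceComponents

    cfg = ArraySimConfig(
        n_genes=4, n_blocks_per_array=1,
        treatments=("RH0", "SH0", "RH1", "SH1"),
        n_replicates=2, flocks=("Trangie", "CSIRO"),
        true_components=VarianceComponents(0.5, 0.1, 0.15, 0.1, 0.3, 0.2),
        seed=3)
    obs, truth = simulate_intensities(cfg)
    return obs, truth


@pytest.fixture()
def small_population():
    from fleecerot.simulate import PopulationSimConfig, simulate_population

    cfg = PopulationSimConfig(n_founders=30, n_generations=2,
                              offspring_per_mating=3, h2=0.4, seed=2)
    return simulate_population(cfg)


def eight_array_loop():
    """Single-loop design over eight sub-line x time samples, two flocks."""
    from fleecerot.simulate import Sample

    treatments = ("RH0", "RL0", "SH0", "SL0", "RH1", "RL1", "SH1", "SL1")
    samples = [Sample(t, "Trangie" if i < 4 else "CSIRO", 0)
               for i, t in enumerate(treatments)]
    loop = [(f"A{i + 1:03d}", samples[i], samples[(i + 1) % 8]) for i in range(8)]
    return loop, treatments
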