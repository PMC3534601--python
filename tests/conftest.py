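"""Shared fixtures: small deterministic simulated experiments."""
from __future__ import annotations

import pytest
from hypothesis import settings

from xbias.simulate import ClusterSpec, SimConfig, TissueEffects, generate_experiment

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A two-tissue, reduced-probe experiment that runs in well under a second."""
    defaults = dict(
        seed=seed,
        samples_per_sex=20,
        n_probes_a=1200,
        n_probes_x=300,
        n_probes_y=6,
        n_probes_na=4,
        tissues=(
            TissueEffects("kidney", 0.05, 0.05, 0.08, 0.03, a_delta_range=(0.07, 3.0)),
            TissueEffects("liver", 0.04, 0.04, 0.06, 0.02, a_delta_range=(0.07, 3.0)),
        ),
        clusters=(ClusterSpec(5, 40_000), ClusterSpec(2, 40_000)),
        cluster_delta=0.8,
        n_escapees=4,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_experiment():
    return generate_experiment(small_config())


@pytest.fixture(scope="session")
def small_results(small_experiment):
    from xbias.stats import test_tissue

    exp = small_experiment
    return {
        t: test_tissue(exp.matrices[t], exp.samples.for_tissue(t), 0.001)
        for t in exp.tissues
    }
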