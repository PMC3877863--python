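import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fungiflow as ff

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


THREE_COMPONENT_SPEC = ff.MixtureSpec(
    weights=(0.2, 0.5, 0.3),
    means=(-4.0, 0.0, 4.0),
    variances=(1.0, 1.0, 1.0),
    n_genes=10_000,
)

RECOVERY_SEEDS = tuple(range(20))


@pytest.fixture(scope="session")
def three_component_spec():
    return THREE_COMPONENT_SPEC


@pytest.fixture(scope="session")
def three_component_recovery(three_component_spec):
    """Model selection on 20 seeded replicates of the 3-component mixture.

    Expensive (full K x family sweep per replicate), so computed once per
    session and shared by the selection-rate and parameter-error checks.
    """
    results = []
    for seed in RECOVERY_SEEDS:
        vector, _ = ff.simulate_mixture(three_component_spec.with_seed(seed))
        best, _ = ff.select_model(vector)
        results.append(best)
    return results


@pytest.fixture()
def sam_fixture_on_disk(tmp_path):
    """Default 6-read SAM+FASTA fixture written to disk with its manifest."""
    fixture = ff.generate_sam_fixture(ff.default_sam_fixture_spec(seed=7))
    fasta = tmp_path / "loci.fa"
    sam = tmp_path / "reads.sam"
    fasta.write_text(fixture.fasta_text)
    sam.write_text(fixture.sam_text)
    return fixture, fasta, sam
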