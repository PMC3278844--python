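import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from ptigsid import (  # noqa: E402
    SyntheticSpec,
    build_reference_db,
    generate_dataset,
)


def separable_spec(intra_sub: float = 0.01, seed: int = 101) -> SyntheticSpec:
    """10 species x 3 individuals with inter-species divergence 0.20 per
    tree edge; intra-species divergence is the knob."""
    return SyntheticSpec(
        seed=seed,
        n_families=2,
        n_genera_per_family=1,
        n_species_per_genus=5,
        n_individuals_per_species=3,
        inter_species_sub_rate=0.20,
        intra_species_sub_rate=intra_sub,
    )


@pytest.fixture(scope="session")
def small_ds():
    """2 families x 2 genera x 2 species x 3 individuals (24 records)."""
    return generate_dataset(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def separable_ds():
    return generate_dataset(separable_spec())


@pytest.fixture(scope="session")
def separable_db(separable_ds):
    return build_reference_db(
        separable_ds.core_records(),
        separable_ds.taxonomy,
        min_seqs_per_species=2,
    )


@pytest.fixture(scope="session")
def small_db(small_ds):
    return build_reference_db(
        small_ds.core_records(), small_ds.taxonomy, min_seqs_per_species=2
    )
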