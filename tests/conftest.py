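"""Shared fixtures: small synthetic references and species panels."""

from __future__ import annotations

import pytest

from gbspaint.simulate import (
    AncestralModel,
    SimulatedReference,
    SpeciesSpec,
    default_model,
    simulate_reference_model,
)


def ideal_spec(name: str, genomes: tuple[str, ...], depth: float = 30.0) -> SpeciesSpec:
    """A species with no divergence, no dropout and no lineage locus loss,
    so its presence pattern is forced exactly by its genome composition."""
    return SpeciesSpec(name, genomes, depth=depth, dropout=0.0,
                       divergence_scale=0.0, locus_dropout=0.0)


@pytest.fixture(scope="session")
def small_ref() -> SimulatedReference:
    """210 loci on the default 21-chromosome model (10 per chromosome,
    70 per subgenome), no translocations."""
    model = AncestralModel(n_loci=210)
    return simulate_reference_model(model, seed=7)


@pytest.fixture(scope="session")
def study_ref() -> SimulatedReference:
    """The default study-scale model (2100 loci, one planted C->D translocation)."""
    return simulate_reference_model(default_model(), seed=1)
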