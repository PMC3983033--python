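import numpy as np
import pytest

from intbias.genome import find_motif_sites, find_restriction_sites
from intbias.simulate import (
    BiasModel,
    FeatureSpec,
    make_annotation,
    make_assembly,
    make_feature_tracks,
    simulate_integrations,
)


@pytest.fixture(scope="session")
def assembly():
    """1 Mb single-chromosome random assembly (sequence attached)."""
    return make_assembly({"chr1": 1_000_000}, gc=0.42, seed=11)


@pytest.fixture(scope="session")
def annotation(assembly):
    return make_annotation(
        assembly,
        n_genes=40,
        gene_length_dist=(12_000, 6_000),
        tad_size_dist=(80_000, 20_000),
        boundary_size_dist=(15_000, 4_000),
        seed=7,
    )


@pytest.fixture(scope="session")
def ta_sites(assembly):
    return find_motif_sites(assembly, "TA")


@pytest.fixture(scope="session")
def gatc_map(assembly):
    return find_restriction_sites(assembly, "GATC")


@pytest.fixture(scope="session")
def feature_tracks(assembly, annotation):
    tracks, _ = make_feature_tracks(
        assembly,
        annotation,
        [
            FeatureSpec(name="open_chromatin", noise_sd=1.0,
                        autocorr_length=2000, bumps=[("tss", 3.0, 500)]),
            FeatureSpec(name="heterochromatin", noise_sd=1.0,
                        autocorr_length=5000),
        ],
        bin_size=100,
        seed=3,
    )
    return {t.name: t for t in tracks}


@pytest.fixture(scope="session")
def uniform_ta_integrations(assembly, ta_sites, gatc_map):
    """Unbiased (beta=0) TA-constrained integration profile."""
    model = BiasModel(motif="TA")
    return simulate_integrations(
        assembly, model, n=4000, restriction_map=gatc_map,
        max_restriction_distance=1000, seed=5,
    )
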