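"""Shared fixtures: synthetic studies generated once per session."""

import warnings

import pytest

from picevo import cluster_caller, core_io, pseudogenes
from picevo.synthetic_data import (
    ReadModel,
    SimulationConfig,
    simulate_species_set,
    simulate_study,
)


@pytest.fixture(scope="session")
def default_study():
    """The default 3-species / 5-Mb / 20-cluster / 100k-read study."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        species_tree=(("near", 1.0), ("far", 40.0)),
        genome_length=1_200_000,
        n_genes=40,
        n_clusters=5,
        cluster_size_range=(5_000, 8_000),
        n_pseudogenes=12,
        n_repeats=60,
        n_peaks=40,
        read_model=ReadModel(total_reads=8_000, multimap_fraction=0.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_study_dir(small_config, tmp_path_factory):
    """Small study written to disk for file-format round trips."""
    outdir = tmp_path_factory.mktemp("fixture")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        study = simulate_species_set(small_config, outdir)
    return outdir, study


@pytest.fixture(scope="session")
def lenient_calls(default_study):
    """Lenient-preset cluster calls for every species of the default study."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, fx in default_study.species.items():
            reads = core_io.filter_by_length(fx.reads)
            out[name] = cluster_caller.call_clusters(
                reads, fx.genome.lengths(), cluster_caller.LENIENT
            )
    return out


@pytest.fixture(scope="session")
def predicted_units(default_study):
    """Pseudogene units predicted on the root-nearest species."""
    fx = default_study.species["spcA"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pseudogenes.predict_pseudogenes(fx.cds, fx.genome, fx.genes)
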