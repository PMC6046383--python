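import warnings

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from netomix.pipeline import PipelineConfig, run_pipeline
from netomix.simulate import GeneratorConfig, GroundTruth, generate_proteome, simulate_psm_tables


def make_psm_row(
    donor="D1",
    treatment="untreated",
    dnase="plus",
    accession="P1",
    peptide="MK",
    start=1,
    end=2,
    score=35.0,
    charge=2,
    modifications="",
    is_decoy=False,
):
    return {
        "donor": donor,
        "treatment": treatment,
        "dnase": dnase,
        "protein_accession": accession,
        "peptide": peptide,
        "start": start,
        "end": end,
        "score": score,
        "charge": charge,
        "modifications": modifications,
        "is_decoy": is_decoy,
    }


def psm_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_experiment():
    """The default synthetic experiment (3 donors, 100 NET + 50 background)."""
    config = GeneratorConfig(seed=1)
    proteome, truth = generate_proteome(config)
    psms = simulate_psm_tables(proteome, truth, config)
    return config, proteome, truth, psms


@pytest.fixture(scope="session")
def pipeline_run(default_experiment, tmp_path_factory):
    """Full pipeline outputs on the default synthetic experiment."""
    from netomix.io import write_fasta, write_psm_table

    config, proteome, truth, psms = default_experiment
    root = tmp_path_factory.mktemp("pipeline")
    write_fasta(proteome, root / "proteome.fasta")
    write_psm_table(psms, root / "psms_all.tsv")
    pcfg = PipelineConfig(
        fasta=str(root / "proteome.fasta"),
        psm_table=str(root / "psms_all.tsv"),
        out_dir=str(root / "results"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        manifest = run_pipeline(pcfg)
    return pcfg, truth, manifest, root / "results"


@pytest.fixture(scope="session")
def small_experiment():
    """A fast, reduced experiment for smoke and distribution tests."""
    config = GeneratorConfig(
        seed=11,
        n_background_proteins=6,
        n_net_proteins=15,
        protein_length_range=(80, 160),
        decoy_match_rate=8.0,
    )
    proteome, truth = generate_proteome(config)
    psms = simulate_psm_tables(proteome, truth, config)
    return config, proteome, truth, psms
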