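import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from netomix.digestion import observable_peptides
from netomix.simulate import (
    ELANE_LIKE_ACCESSION,
    H4_ACCESSION,
    H4_SEQUENCE,
    GeneratorConfig,
    GroundTruth,
    default_planted_deletions,
    elane_like_fixture,
    generate_proteome,
    simulate_psm_tables,
    write_simulation,
)


class TestGenerateProteome:
    def test_counts_and_classes(self, small_experiment):
        config, proteome, truth, _ = small_experiment
        assert len(proteome) == config.n_background_proteins + config.n_net_proteins + 2
        assert len(truth.background_accessions) == config.n_background_proteins
        assert H4_ACCESSION in truth.net_accessions
        assert ELANE_LIKE_ACCESSION in truth.net_accessions

    def test_deterministic_for_fixed_seed(self):
        cfg = GeneratorConfig(seed=5, n_background_proteins=3, n_net_proteins=3,
                              protein_length_range=(60, 100))
        p1, t1 = generate_proteome(cfg)
        p2, t2 = generate_proteome(cfg)
        assert [(r.accession, r.sequence) for r in p1] == [(r.accession, r.sequence) for r in p2]
        assert t1.abundance == t2.abundance

    def test_every_protein_has_observable_peptides(self, small_experiment):
        _, proteome, _, _ = small_experiment
        counts = [len(observable_peptides(r.sequence)) for r in proteome]
        assert min(counts) >= 1
        assert np.mean(counts) >= 5

    def test_h4_fixture_is_the_canonical_precursor(self):
        assert len(H4_SEQUENCE) == 103
        assert H4_SEQUENCE[60:78] == "VFLENVIRDAVTYTEHAK"

    def test_elane_fixture_deletions_are_isolated_tryptic_peptides(self):
        record, regions = elane_like_fixture()
        peps = observable_peptides(record.sequence)
        by_coord = {(p.start, p.end): p for p in peps}
        for start, end in regions:
            assert (start, end) in by_coord  # each planted region is observable
            overlapping = [
                p for p in peps if p.start <= end and p.end >= start and (p.start, p.end) != (start, end)
            ]
            assert overlapping == []  # and nothing else observable overlaps it

    def test_infeasible_length_bounds_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(protein_length_range=(10, 5))


class TestSimulatePsmTables:
    def test_deterministic_for_fixed_seed(self):
        cfg = GeneratorConfig(seed=5, n_background_proteins=3, n_net_proteins=3,
                              protein_length_range=(60, 100), decoy_match_rate=3.0)
        proteome, truth = generate_proteome(cfg)
        df1 = simulate_psm_tables(proteome, truth, cfg)
        df2 = simulate_psm_tables(proteome, truth, cfg)
        pd.testing.assert_frame_equal(df1, df2)

    def test_net_proteins_never_in_minus_dnase(self, small_experiment):
        _, _, truth, psms = small_experiment
        minus = psms[psms.dnase == "minus"]
        assert not minus["protein_accession"].isin(set(truth.net_accessions)).any()

    def test_background_proteins_present_in_both_arms(self, small_experiment):
        _, _, truth, psms = small_experiment
        bg = psms[psms["protein_accession"].isin(set(truth.background_accessions))]
        assert set(bg.dnase) == {"plus", "minus"}

    def test_planted_deletions_suppress_overlapping_psms(self, small_experiment):
        _, _, truth, psms = small_experiment
        for deletion in truth.planted_deletions:
            hit = psms[
                (psms.protein_accession == deletion.accession)
                & psms.treatment.isin(deletion.treatments)
                & (psms.start <= deletion.end)
                & (psms.end >= deletion.start)
            ]
            assert hit.empty
            control = psms[
                (psms.protein_accession == deletion.accession)
                & (psms.treatment == "untreated")
                & (psms.start <= deletion.end)
                & (psms.end >= deletion.start)
            ]
            assert not control.empty  # the region is detected where not deleted

    def test_decoy_psms_marked_and_low_scoring(self, small_experiment):
        _, _, _, psms = small_experiment
        decoys = psms[psms.is_decoy]
        assert len(decoys) > 0
        assert decoys["protein_accession"].str.startswith("DECOY_").all()
        assert decoys["score"].mean() < psms.loc[~psms.is_decoy, "score"].mean()

    def test_null_protease_effect_leaves_detection_unchanged(self):
        """With protease_effect=1 treated and untreated peptide counts match in distribution."""
        cfg = GeneratorConfig(
            seed=21, n_background_proteins=0, n_net_proteins=40,
            protein_length_range=(80, 160), protease_effect=1.0,
            protease_sensitive_fraction=1.0, include_fixture_proteins=False,
            decoy_match_rate=0.0,
        )
        proteome, truth = generate_proteome(cfg)
        psms = simulate_psm_tables(proteome, truth, cfg)
        counts = (
            psms.groupby(["treatment", "protein_accession", "donor"])["peptide"].nunique().reset_index()
        )
        untreated = counts[counts.treatment == "untreated"]["peptide"]
        thrombin = counts[counts.treatment == "thrombin"]["peptide"]
        assert sps.ks_2samp(untreated, thrombin).pvalue > 0.01

    def test_protease_effect_reduces_detection(self, small_experiment):
        _, _, truth, psms = small_experiment
        sensitive = set(truth.protease_sensitive) - {H4_ACCESSION, ELANE_LIKE_ACCESSION}
        if not sensitive:
            pytest.skip("no sensitive regular proteins in this draw")
        sel = psms[psms.protein_accession.isin(sensitive) & (psms.dnase == "plus")]
        n_control = sel[sel.treatment == "untreated"]["peptide"].nunique()
        n_treated = sel[sel.treatment == "thrombin"]["peptide"].nunique()
        assert n_treated < n_control


class TestEffectRecovery:
    def test_normalized_ratio_recovers_protease_effect(self, pipeline_run):
        """With protease_effect 0.4 the donor-matched emPAI ratio of the
        sensitive (non-fixture) proteins lands in the pre-registered
        [0.25, 0.55] band (emPAI responds sublinearly to detection odds)."""
        import pandas as pd

        from netomix.differential import aggregate_group, normalize_to_control

        _, truth, _, results_dir = pipeline_run
        quants = pd.read_csv(results_dir / "quant.tsv", sep="\t")
        sensitive = sorted(set(truth.protease_sensitive) - {H4_ACCESSION, ELANE_LIKE_ACCESSION})
        assert sensitive
        ratios = []
        for acc in sensitive:
            out = normalize_to_control(aggregate_group(quants, [acc], acc))
            ratios.extend(out.loc[out.treatment.isin(("thrombin", "plasmin")), "ratio"])
        estimate = float(np.mean(ratios))
        assert 0.25 <= estimate <= 0.55


class TestSerialization:
    def test_ground_truth_round_trip(self, tmp_path, small_experiment):
        _, _, truth, _ = small_experiment
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert back.protein_class == truth.protein_class
        assert sorted(back.protease_sensitive) == sorted(truth.protease_sensitive)
        assert back.planted_deletions == truth.planted_deletions

    def test_write_simulation_outputs(self, tmp_path):
        cfg = GeneratorConfig(seed=3, n_background_proteins=2, n_net_proteins=3,
                              protein_length_range=(60, 100), decoy_match_rate=2.0)
        summary = write_simulation(tmp_path / "sim", cfg)
        assert summary["n_samples"] == 18
        assert (tmp_path / "sim" / "proteome.fasta").exists()
        assert (tmp_path / "sim" / "ground_truth.json").exists()
        design = pd.read_csv(tmp_path / "sim" / "design.tsv", sep="\t")
        assert len(design) == 18

    def test_default_deletions_cover_h4_and_elane(self):
        dels = default_planted_deletions()
        assert (dels[0].accession, dels[0].start, dels[0].end) == (H4_ACCESSION, 61, 78)
        assert sum(d.accession == ELANE_LIKE_ACCESSION for d in dels) == 4
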