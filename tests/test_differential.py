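import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from netomix.differential import (
    aggregate_group,
    dunnett_test,
    hierarchical_cluster,
    normalize_to_control,
    significance_code,
)


def quant_rows(entries):
    return pd.DataFrame(
        entries, columns=["accession", "donor", "treatment", "dnase", "empai"]
    )


class TestAggregateGroup:
    def test_subtypes_sum_per_sample(self):
        q = quant_rows(
            [
                ("H2B_E", "D1", "untreated", "plus", 2.0),
                ("H2B_F", "D1", "untreated", "plus", 3.0),
                ("H2B_E", "D1", "thrombin", "plus", 1.0),
            ]
        )
        out = aggregate_group(q, ["H2B_E", "H2B_F"], "H2B")
        byt = out.set_index("treatment")["empai"]
        assert byt["untreated"] == 5.0 and byt["thrombin"] == 1.0
        assert (out["group_label"] == "H2B").all()

    def test_single_accession_is_identity_and_order_irrelevant(self):
        q = quant_rows([("A", "D1", "untreated", "plus", 2.5), ("B", "D1", "untreated", "plus", 1.0)])
        single = aggregate_group(q, ["A"], "A")
        assert single["empai"].tolist() == [2.5]
        ab = aggregate_group(q, ["A", "B"], "G")["empai"].tolist()
        ba = aggregate_group(q, ["B", "A"], "G")["empai"].tolist()
        assert ab == ba

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            aggregate_group(quant_rows([]), [], "X")


def grouped_rows(entries):
    return pd.DataFrame(
        entries, columns=["group_label", "donor", "treatment", "dnase", "empai"]
    )


class TestNormalizeToControl:
    def test_ratios(self):
        g = grouped_rows(
            [
                ("H4", "D1", "untreated", "plus", 3.0),
                ("H4", "D1", "thrombin", "plus", 1.5),
                ("H4", "D1", "plasmin", "plus", 3.0),
            ]
        )
        out = normalize_to_control(g)
        ratios = out.set_index("treatment")["ratio"]
        assert ratios["untreated"] == 1.0
        assert ratios["thrombin"] == 0.5
        assert ratios["plasmin"] == 1.0

    def test_scale_invariance_per_donor(self):
        g = grouped_rows(
            [
                ("H4", "D1", "untreated", "plus", 3.0),
                ("H4", "D1", "thrombin", "plus", 1.5),
                ("H4", "D2", "untreated", "plus", 30.0),
                ("H4", "D2", "thrombin", "plus", 15.0),
            ]
        )
        out = normalize_to_control(g)
        thrombin = out[out.treatment == "thrombin"].set_index("donor")["ratio"]
        assert thrombin["D1"] == pytest.approx(thrombin["D2"])

    def test_zero_control_donor_excluded_and_flagged(self):
        g = grouped_rows(
            [
                ("H4", "D1", "untreated", "plus", 0.0),
                ("H4", "D1", "thrombin", "plus", 1.0),
                ("H4", "D2", "untreated", "plus", 2.0),
                ("H4", "D2", "thrombin", "plus", 1.0),
            ]
        )
        out = normalize_to_control(g)
        assert set(out["donor"]) == {"D2"}
        assert ("H4", "D1") in out.attrs["excluded"]


class TestDunnett:
    def test_extreme_effect_flags_both_treatments(self):
        rng = np.random.default_rng(0)
        groups = {
            "untreated": rng.normal(10.0, 0.1, 6),
            "thrombin": rng.normal(0.0, 0.1, 6),
            "plasmin": rng.normal(0.0, 0.1, 6),
        }
        res = dunnett_test(groups)
        assert res["significant"].all()
        assert set(res["code"]) == {"****"}

    def test_symmetric_groups_get_identical_p_values(self):
        control = np.array([1.0, 2.0, 3.0, 4.0])
        shifted = control + 0.5
        res = dunnett_test(
            {"untreated": control, "thrombin": shifted.copy(), "plasmin": shifted.copy()}
        )
        p = res.set_index("treatment")["p_adjusted"]
        # equal up to the accuracy of the quasi-Monte Carlo multivariate-t integral
        assert p["thrombin"] == pytest.approx(p["plasmin"], abs=1e-3)

    def test_adjusted_p_not_below_unadjusted_pooled_t(self):
        rng = np.random.default_rng(5)
        control = rng.normal(0, 1, 8)
        t1 = rng.normal(0.8, 1, 8)
        t2 = rng.normal(-0.3, 1, 8)
        res = dunnett_test({"untreated": control, "thrombin": t1, "plasmin": t2})
        # unadjusted p from the same pooled-variance many-to-one model
        groups = [control, t1, t2]
        df = sum(len(g) for g in groups) - len(groups)
        s2 = sum((len(g) - 1) * g.var(ddof=1) for g in groups) / df
        for name, sample in (("thrombin", t1), ("plasmin", t2)):
            se = np.sqrt(s2 * (1 / len(sample) + 1 / len(control)))
            tstat = (sample.mean() - control.mean()) / se
            raw = 2 * sps.t.sf(abs(tstat), df)
            adj = res.set_index("treatment").loc[name, "p_adjusted"]
            assert adj >= raw - 1e-6

    def test_degenerate_input_errors(self):
        with pytest.raises(ValueError):
            dunnett_test({"untreated": [1.0], "thrombin": [1.0, 2.0]})
        with pytest.raises(ValueError):
            dunnett_test({"untreated": [1.0, 1.0], "thrombin": [2.0, 2.0]})
        with pytest.raises(ValueError):
            dunnett_test({"thrombin": [1.0, 2.0], "plasmin": [2.0, 3.0]})

    def test_significance_codes_follow_the_legend(self):
        assert significance_code(0.2) == "ns"
        assert significance_code(0.09) == "#"
        assert significance_code(0.04) == "*"
        assert significance_code(0.009) == "**"
        assert significance_code(0.0009) == "***"
        assert significance_code(0.00009) == "****"


def block_matrix():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 0.05, (6, 3)) + np.array([5.0, 0.0, 0.0])
    b = rng.normal(0, 0.05, (7, 3)) + np.array([0.0, 0.0, 5.0])
    mat = pd.DataFrame(
        np.vstack([a, b]),
        index=[f"P{i:02d}" for i in range(13)],
        columns=["untreated", "thrombin", "plasmin"],
    )
    return mat


class TestHierarchicalCluster:
    def test_two_separated_blocks_recovered(self):
        mat = block_matrix()
        assignments, leaf_order = hierarchical_cluster(mat, n_clusters=2)
        labels = {a.accession: a.cluster_id for a in assignments}
        block_a = {labels[f"P{i:02d}"] for i in range(6)}
        block_b = {labels[f"P{i:02d}"] for i in range(6, 13)}
        assert len(block_a) == 1 and len(block_b) == 1 and block_a != block_b
        assert sorted(leaf_order) == sorted(mat.index)

    def test_row_permutation_gives_same_partition(self):
        mat = block_matrix()
        perm = mat.sample(frac=1.0, random_state=9)
        a1 = {a.accession: a.cluster_id for a in hierarchical_cluster(mat, 2)[0]}
        a2 = {a.accession: a.cluster_id for a in hierarchical_cluster(perm, 2)[0]}
        groups1 = {}
        groups2 = {}
        for acc in mat.index:
            groups1.setdefault(a1[acc], set()).add(acc)
            groups2.setdefault(a2[acc], set()).add(acc)
        assert sorted(map(sorted, groups1.values())) == sorted(map(sorted, groups2.values()))

    def test_duplicated_row_leaves_other_assignments_unchanged(self):
        mat = block_matrix()
        dup = pd.concat([mat, mat.iloc[[0]].rename(index={"P00": "P00_copy"})])
        base = {a.accession: a.cluster_id for a in hierarchical_cluster(mat, 2)[0]}
        withdup = {a.accession: a.cluster_id for a in hierarchical_cluster(dup, 2)[0]}
        # partition restricted to original rows is identical up to relabeling
        mapping = {}
        for acc in mat.index:
            mapping.setdefault(withdup[acc], set()).add(base[acc])
        assert all(len(v) == 1 for v in mapping.values())
        assert withdup["P00_copy"] == withdup["P00"]

    def test_cluster_count_matches_request(self):
        mat = block_matrix()
        assignments, _ = hierarchical_cluster(mat, n_clusters=5)
        assert len({a.cluster_id for a in assignments}) == 5

    def test_too_many_clusters_is_an_error(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(block_matrix(), n_clusters=100)
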