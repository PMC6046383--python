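"""Donor-matched differential abundance and hierarchical clustering.

Protein groups (e.g. histone subtypes sharing an epitope) are summed per
sample, each donor's treated value is divided by that donor's untreated
control, and treatments are compared against the control with a one-way
ANOVA followed by Dunnett's many-to-one comparisons. The NETome abundance
matrix (proteins x treatment conditions) is clustered agglomeratively on
z-scored rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

#: Significance codes: (upper p bound, code), most stringent first.
SIGNIFICANCE_CODES = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
    (0.1, "#"),
)


def significance_code(p: float) -> str:
    """GraphPad-style code: **** p<0.0001 ... * p<0.05, # p<0.1 (ns), else ns."""
    for bound, code in SIGNIFICANCE_CODES:
        if p < bound:
            return code
    return "ns"


@dataclass(frozen=True)
class ClusterAssignment:
    accession: str
    cluster_id: int
    linkage_order: int


def aggregate_group(
    quants: pd.DataFrame, accession_list: Sequence[str], label: str
) -> pd.DataFrame:
    """Sum emPAI over the listed accessions, per sample.

    Returns a tidy table (group_label, donor, treatment, dnase, empai); a
    single-accession group is the identity.
    """
    if not accession_list:
        raise ValueError("empty accession list")
    sel = quants[quants["accession"].isin(set(accession_list))]
    grouped = (
        sel.groupby(["donor", "treatment", "dnase"], as_index=False)["empai"].sum()
    )
    grouped.insert(0, "group_label", label)
    return grouped


def normalize_to_control(
    grouped: pd.DataFrame, control_treatment: str = "untreated", dnase: str = "plus"
) -> pd.DataFrame:
    """Ratio of each donor's treated value to that donor's untreated control.

    Operates on the +DNase arm by default. Donors whose control value is
    zero or missing are excluded (flagged in the ``excluded`` attribute of
    the returned frame's attrs). Untreated rows come out as exactly 1.
    """
    sel = grouped[grouped["dnase"] == dnase]
    rows = []
    excluded: list[tuple[str, str]] = []
    for label, sub in sel.groupby("group_label"):
        controls = sub[sub["treatment"] == control_treatment].set_index("donor")["empai"]
        for row in sub.itertuples(index=False):
            ctrl = controls.get(row.donor, 0.0)
            if ctrl is None or ctrl <= 0 or np.isnan(ctrl):
                excluded.append((label, row.donor))
                continue
            rows.append(
                {
                    "group_label": label,
                    "donor": row.donor,
                    "treatment": row.treatment,
                    "ratio": float(row.empai / ctrl),
                }
            )
    out = pd.DataFrame(rows, columns=["group_label", "donor", "treatment", "ratio"])
    out.attrs["excluded"] = sorted(set(excluded))
    return out


def dunnett_test(
    ratios_by_treatment: dict[str, np.ndarray | list[float]],
    control_label: str = "untreated",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA with Dunnett's many-to-one correction.

    Compares every treatment against the control; returns one row per
    treatment with the Dunnett-adjusted p-value and its significance code,
    plus the ANOVA p-value replicated for reference.
    """
    if control_label not in ratios_by_treatment:
        raise ValueError(f"control group {control_label!r} missing")
    groups = {k: np.asarray(v, dtype=float) for k, v in ratios_by_treatment.items()}
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("every group needs >= 2 observations")
    if all(np.ptp(v) == 0 for v in groups.values()):
        raise ValueError("all groups are degenerate (zero variance)")
    control = groups[control_label]
    labels = [k for k in groups if k != control_label]
    with warnings.catch_warnings():
        # a constant control group (donor-matched ratios are exactly 1) is a
        # legitimate input; scipy warns about the resulting precision loss
        warnings.simplefilter("ignore", RuntimeWarning)
        anova_p = float(stats.f_oneway(*groups.values()).pvalue)
        # fixed rng: the multivariate-t integration is quasi-Monte Carlo and
        # the pipeline guarantees byte-identical reruns
        res = stats.dunnett(*(groups[k] for k in labels), control=control, rng=0)
    rows = []
    for label, p in zip(labels, np.atleast_1d(res.pvalue)):
        rows.append(
            {
                "treatment": label,
                "p_adjusted": float(p),
                "code": significance_code(float(p)),
                "anova_p": anova_p,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def hierarchical_cluster(
    netome_matrix: pd.DataFrame,
    n_clusters: int = 8,
    metric: str = "euclidean",
    method: str = "average",
    standardize: bool = True,
) -> tuple[list[ClusterAssignment], list[str]]:
    """Agglomerative clustering of the protein x condition abundance matrix.

    Rows are z-scored across conditions by default (constant rows stay
    zero). Returns cluster assignments (labels renumbered 1..k in dendrogram
    leaf order) and the leaf-ordered accession list. Deterministic for a
    fixed input.
    """
    if n_clusters > len(netome_matrix):
        raise ValueError(f"n_clusters={n_clusters} exceeds {len(netome_matrix)} rows")
    X = netome_matrix.to_numpy(dtype=float)
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    leaves = hierarchy.leaves_list(Z)
    # Renumber clusters by first appearance along the dendrogram leaf order.
    renumber: dict[int, int] = {}
    for leaf in leaves:
        renumber.setdefault(int(flat[leaf]), len(renumber) + 1)
    accessions = list(netome_matrix.index)
    leaf_pos = {int(leaf): pos for pos, leaf in enumerate(leaves)}
    assignments = [
        ClusterAssignment(
            accession=accessions[i],
            cluster_id=renumber[int(flat[i])],
            linkage_order=leaf_pos[i],
        )
        for i in range(len(accessions))
    ]
    leaf_order = [accessions[int(i)] for i in leaves]
    return assignments, leaf_order
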