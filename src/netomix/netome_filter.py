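"""The DNase-subtraction NET-association filter.

A protein is called NET-bound in a (donor, treatment) pair when its emPAI
in the +DNase arm exceeds its emPAI in the matched -DNase arm: the -DNase
signal is the constitutively released background and is subtracted
(clamped at zero). A consensus NETome per treatment then requires the call
in a minimum number of donors (default 2 of 3). Treatment NETomes are
compared with 3-set Venn counts, and between-donor reproducibility is
summarised by Pearson correlations of log-transformed emPAI vectors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from netomix.io import TREATMENTS


@dataclass(frozen=True)
class NetomeEntry:
    """Background-subtracted abundance for one protein in one donor/treatment."""

    accession: str
    donor: str
    treatment: str
    empai_plus: float
    empai_minus: float

    @property
    def empai_net(self) -> float:
        return max(0.0, self.empai_plus - self.empai_minus)

    @property
    def net_bound(self) -> bool:
        return self.empai_net > 0.0


@dataclass(frozen=True)
class VennCounts:
    """Region cardinalities of a 3-set Venn diagram."""

    set_names: tuple[str, str, str]
    regions: dict[str, int]  # keys: '100','010','001','110','101','011','111'
    union_size: int
    intersection_size: int

    @property
    def shared_percent(self) -> float:
        if self.union_size == 0:
            return 0.0
        return round(100.0 * self.intersection_size / self.union_size, 1)


def subtract_background(quants: pd.DataFrame, donor: str, treatment: str) -> list[NetomeEntry]:
    """Per-protein +DNase minus -DNase emPAI for one (donor, treatment) pair.

    ``quants`` is the tidy quantification table (accession, donor,
    treatment, dnase, empai). Proteins absent from an arm count as emPAI 0
    in that arm, but the -DNase arm must exist in the table.
    """
    sel = quants[(quants["donor"] == donor) & (quants["treatment"] == treatment)]
    if sel.empty:
        raise ValueError(f"no quantifications for donor={donor!r}, treatment={treatment!r}")
    if not (sel["dnase"] == "minus").any():
        raise ValueError(f"missing -DNase arm for donor={donor!r}, treatment={treatment!r}")
    plus = sel[sel["dnase"] == "plus"].set_index("accession")["empai"]
    minus = sel[sel["dnase"] == "minus"].set_index("accession")["empai"]
    entries = []
    for acc in sorted(set(plus.index) | set(minus.index)):
        entries.append(
            NetomeEntry(
                accession=acc,
                donor=donor,
                treatment=treatment,
                empai_plus=float(plus.get(acc, 0.0)),
                empai_minus=float(minus.get(acc, 0.0)),
            )
        )
    return entries


def consensus_netome(entries: list[NetomeEntry], min_donors: int = 2) -> dict[str, set[str]]:
    """Per-treatment NETome sets: net_bound in at least ``min_donors`` donors."""
    donors = {e.donor for e in entries}
    if min_donors > len(donors):
        raise ValueError(f"min_donors={min_donors} exceeds the {len(donors)} donors present")
    votes: dict[tuple[str, str], set[str]] = {}
    treatments = sorted({e.treatment for e in entries}, key=lambda t: (TREATMENTS + (t,)).index(t))
    for e in entries:
        if e.net_bound:
            votes.setdefault((e.treatment, e.accession), set()).add(e.donor)
    out: dict[str, set[str]] = {t: set() for t in treatments}
    for (treatment, acc), ds in votes.items():
        if len(ds) >= min_donors:
            out[treatment].add(acc)
    return out


def venn(sets: dict[str, set[str]]) -> VennCounts:
    """Exact region cardinalities for exactly three named sets."""
    if len(sets) != 3:
        raise ValueError(f"venn requires exactly 3 sets, got {len(sets)}")
    names = tuple(sets)
    a, b, c = (sets[n] for n in names)
    union = a | b | c
    regions = {}
    for mask in ("100", "010", "001", "110", "101", "011", "111"):
        inc = [s for s, bit in zip((a, b, c), mask) if bit == "1"]
        exc = [s for s, bit in zip((a, b, c), mask) if bit == "0"]
        region = set.intersection(*inc) if inc else set()
        for s in exc:
            region -= s
        regions[mask] = len(region)
    return VennCounts(
        set_names=names,
        regions=regions,
        union_size=len(union),
        intersection_size=len(a & b & c),
    )


def donor_correlation(
    quants: pd.DataFrame,
    transform: str = "log10_offset",
    offset: float = 0.01,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pairwise between-donor Pearson correlations per (treatment, dnase) stratum.

    Each donor's vector spans the union of proteins quantified in the
    stratum (absent proteins enter as emPAI 0 before the offset). The
    default transform is log10(empai + offset); alternatives are ``raw``
    (Pearson on raw emPAI) and ``spearman``.
    """
    if transform not in {"log10_offset", "raw", "spearman"}:
        raise ValueError(f"unknown transform {transform!r}")
    rows = []
    for (treatment, dnase), stratum in quants.groupby(["treatment", "dnase"]):
        mat = stratum.pivot_table(index="accession", columns="donor", values="empai", fill_value=0.0)
        if mat.shape[1] < 2:
            continue
        if transform == "log10_offset":
            mat = np.log10(mat + offset)
        for d1, d2 in itertools.combinations(sorted(mat.columns), 2):
            pair = mat[[d1, d2]]
            if len(pair) < min_shared:
                raise ValueError(
                    f"only {len(pair)} shared proteins for donors {d1}/{d2} in "
                    f"({treatment}, {dnase}); need >= {min_shared}"
                )
            if transform == "spearman":
                r = pair[d1].corr(pair[d2], method="spearman")
            else:
                r = pair[d1].corr(pair[d2])
            rows.append(
                {"treatment": treatment, "dnase": dnase, "donor_a": d1, "donor_b": d2, "r": float(r)}
            )
    if not rows:
        raise ValueError("fewer than two donors share proteins in every stratum")
    return pd.DataFrame(rows)
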