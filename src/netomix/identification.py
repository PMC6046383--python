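"""Decoy generation and target-decoy FDR filtering of protein evidence.

The false-discovery statistic is the concatenated-database estimator
FDR = 2*Md/(Md + Mt), with Md the number of decoy matches and Mt the
number of target matches. Filtering is applied at the protein level:
proteins (targets and decoys alike) are ranked by descending protein
score, the running FDR is evaluated along the ranking, and the retained
set is the largest prefix whose running FDR stays at or below the
threshold (default 1%). Decoys are excluded from the returned set but
counted in Md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from netomix.io import DECOY_PREFIX, ProteinRecord


@dataclass(frozen=True)
class DecoySummary:
    """Target/decoy match counts and the resulting FDR statistic."""

    Md: int
    Mt: int

    @property
    def fdr(self) -> float:
        """The statistic 2*Md/(Md+Mt) as a fraction (0..2)."""
        return target_decoy_fdr(self.Md, self.Mt)

    @property
    def fdr_percent(self) -> float:
        return 100.0 * self.fdr


@dataclass
class ProteinEvidence:
    """Aggregated PSM evidence for one retained target protein."""

    accession: str
    psms: pd.DataFrame
    protein_score: float
    n_obsd: int
    fdr_percent: float


@dataclass
class FilterResult:
    """Output of :func:`filter_proteins`: retained targets plus the cutoff summary."""

    proteins: list[ProteinEvidence]
    summary: DecoySummary
    n_ranked: int = 0
    retained_accessions: set[str] = field(default_factory=set)


def generate_decoys(database: list[ProteinRecord], decoy_prefix: str = DECOY_PREFIX) -> list[ProteinRecord]:
    """Append one reversed-sequence decoy per target record.

    The output is the concatenated target-decoy database: all targets in
    their original order followed by their decoys, 2x the input size.
    """
    if any(r.is_decoy for r in database):
        raise ValueError("database already contains decoy records")
    decoys = [
        ProteinRecord(
            accession=decoy_prefix + r.accession,
            sequence=r.sequence[::-1],
            description=f"reversed {r.accession}",
            is_decoy=True,
        )
        for r in database
    ]
    return list(database) + decoys


def target_decoy_fdr(Md: int, Mt: int) -> float:
    """FDR estimate 2*Md/(Md+Mt) as a fraction."""
    if Md < 0 or Mt < 0:
        raise ValueError("match counts must be non-negative")
    if Md + Mt == 0:
        raise ValueError("Md + Mt must be positive")
    return 2.0 * Md / (Md + Mt)


def peptide_score_filter(psm_table: pd.DataFrame, min_score: float = 20.0) -> pd.DataFrame:
    """Keep PSMs whose score is strictly greater than ``min_score``."""
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    return psm_table[psm_table["score"] > min_score].reset_index(drop=True)


def filter_proteins(
    psm_table: pd.DataFrame,
    fdr_threshold_percent: float = 1.0,
    score_agg: str = "sum",
) -> FilterResult:
    """Protein-level target-decoy filtering of a PSM table.

    Protein score is the sum (or max, ``score_agg='max'``) of the protein's
    PSM scores. Proteins are ranked by descending score with ties broken by
    accession; the retained set is the largest ranking prefix whose running
    FDR (percent) stays <= the threshold.
    """
    if psm_table.empty:
        raise ValueError("empty PSM table")
    if fdr_threshold_percent <= 0:
        raise ValueError("fdr threshold must be > 0")
    if score_agg not in {"sum", "max"}:
        raise ValueError("score_agg must be 'sum' or 'max'")

    grouped = psm_table.groupby("protein_accession", sort=False)
    scores = grouped["score"].sum() if score_agg == "sum" else grouped["score"].max()
    is_decoy = grouped["is_decoy"].any()
    ranking = (
        pd.DataFrame({"protein_score": scores, "is_decoy": is_decoy})
        .sort_values(["protein_score", "protein_accession"], ascending=[False, True], kind="mergesort")
    )

    md = mt = 0
    best_len = 0
    best_md = best_mt = 0
    running: list[float] = []
    for decoy in ranking["is_decoy"]:
        if decoy:
            md += 1
        else:
            mt += 1
        fdr_pct = 100.0 * target_decoy_fdr(md, mt)
        running.append(fdr_pct)
        if fdr_pct <= fdr_threshold_percent:
            best_len = md + mt
            best_md, best_mt = md, mt

    retained = ranking.iloc[:best_len]
    retained_targets = retained[~retained["is_decoy"]]
    proteins: list[ProteinEvidence] = []
    for rank, (acc, row) in enumerate(retained_targets.iterrows()):
        psms = psm_table[psm_table["protein_accession"] == acc].reset_index(drop=True)
        proteins.append(
            ProteinEvidence(
                accession=acc,
                psms=psms,
                protein_score=float(row["protein_score"]),
                n_obsd=int(psms["peptide"].nunique()),
                fdr_percent=running[ranking.index.get_loc(acc)],
            )
        )
    return FilterResult(
        proteins=proteins,
        summary=DecoySummary(Md=best_md, Mt=best_mt),
        n_ranked=len(ranking),
        retained_accessions={p.accession for p in proteins},
    )
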