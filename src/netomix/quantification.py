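"""PAI and emPAI: label-free protein abundance from peptide counts.

PAI = N_obsd / N_obsbl, the ratio of observed to observable peptides of a
protein; emPAI = 10^PAI - 1, which is approximately proportional to molar
protein amount. N_obsd counts unique matched peptide sequences (modification
labels are carried separately and do not split a peptide into variants);
N_obsbl comes from the in-silico digest restricted to the detectability
window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from netomix.digestion import DetectabilityWindow, observable_count
from netomix.io import ProteinRecord, SampleKey


@dataclass(frozen=True)
class ProteinQuant:
    """Per-sample abundance record for one protein."""

    accession: str
    sample: SampleKey
    n_obsd: int
    n_obsbl: int
    pai: float
    empai: float


def count_observed(psms: pd.DataFrame, count_modified_as_distinct: bool = False) -> int:
    """N_obsd: unique peptide sequences matched to a protein in one sample.

    By default a peptide observed with and without a modification label
    counts once (uniqueness on the plain sequence). With
    ``count_modified_as_distinct`` every (sequence, modification) pair
    counts separately.
    """
    if psms.empty:
        return 0
    if count_modified_as_distinct:
        return int(psms.groupby(["peptide", "modifications"]).ngroups)
    return int(psms["peptide"].nunique())


def compute_empai(n_obsd: int, n_obsbl: int) -> tuple[float, float]:
    """(PAI, emPAI) from observed and observable peptide counts.

    PAI is not clamped: a protein matched by more peptides than the window
    deems observable legitimately has PAI > 1.
    """
    if n_obsbl < 1:
        raise ValueError("protein has no observable peptides; quantification undefined")
    if n_obsd < 0:
        raise ValueError("n_obsd must be >= 0")
    pai = n_obsd / n_obsbl
    return pai, 10.0 ** pai - 1.0


def quantify_all(
    psm_table: pd.DataFrame,
    database: Sequence[ProteinRecord],
    window: DetectabilityWindow | None = None,
    design: Sequence[SampleKey] | None = None,
    accessions: Sequence[str] | None = None,
    max_missed_cleavages: int = 2,
) -> pd.DataFrame:
    """emPAI for every (protein, sample) pair of the design.

    Returns a tidy table with one row per protein per sample; samples in
    which a protein has no PSMs get n_obsd = 0 and emPAI = 0. ``accessions``
    restricts quantification (e.g. to FDR-retained proteins); otherwise all
    target accessions present in the PSM table are quantified. Proteins
    whose N_obsbl is zero are reported with n_obsbl = 0 and NaN abundances
    rather than silently dropped.
    """
    window = window or DetectabilityWindow()
    by_acc = {r.accession: r for r in database}
    if accessions is None:
        accessions = sorted(psm_table.loc[~psm_table["is_decoy"], "protein_accession"].unique())
    missing = [a for a in accessions if a not in by_acc]
    if missing:
        raise KeyError(f"accessions absent from database: {missing[:5]}")
    if design is None:
        samples = psm_table[["donor", "treatment", "dnase"]].drop_duplicates()
        design = sorted(SampleKey(*row) for row in samples.itertuples(index=False))

    n_obsbl = {
        a: observable_count(by_acc[a].sequence, window, max_missed_cleavages) for a in accessions
    }
    counts = (
        psm_table[psm_table["protein_accession"].isin(set(accessions))]
        .groupby(["protein_accession", "donor", "treatment", "dnase"])["peptide"]
        .nunique()
    )

    rows = []
    for acc in accessions:
        for s in design:
            n_obsd = int(counts.get((acc, s.donor, s.treatment, s.dnase), 0))
            if n_obsbl[acc] >= 1:
                pai, empai = compute_empai(n_obsd, n_obsbl[acc])
            else:
                pai = empai = float("nan")
            rows.append(
                {
                    "accession": acc,
                    "donor": s.donor,
                    "treatment": s.treatment,
                    "dnase": s.dnase,
                    "n_obsd": n_obsd,
                    "n_obsbl": n_obsbl[acc],
                    "pai": pai,
                    "empai": empai,
                }
            )
    return pd.DataFrame(rows)
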