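"""Peptigrams: per-residue peptide-coverage tracks and missing-region calls.

A track assigns to each residue of a protein the sum of the scores of
every PSM covering it, counting only PSMs whose peptide score exceeds a
threshold (default 20, strictly). Duplicate detections of the same peptide
therefore add up. Comparing a control track against a treated track yields
maximal residue runs that are covered in the control and empty in the
treatment — candidate protease-targeted regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netomix.identification import peptide_score_filter


@dataclass
class PeptigramTrack:
    """Per-residue summed peptide-score vector for one protein/condition."""

    accession: str
    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("track values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def __add__(self, other: "PeptigramTrack") -> "PeptigramTrack":
        if len(self) != len(other) or self.accession != other.accession:
            raise ValueError("cannot add tracks of different proteins/lengths")
        return PeptigramTrack(self.accession, f"{self.condition}+{other.condition}", self.values + other.values)


@dataclass(frozen=True)
class MissingRegion:
    """Residue run covered in the reference conditions but empty in others."""

    accession: str
    start: int  # 1-based inclusive
    end: int
    present_in: tuple[str, ...] = field(default_factory=tuple)
    absent_in: tuple[str, ...] = field(default_factory=tuple)


def build_track(
    psms_for_protein: pd.DataFrame,
    protein_length: int,
    min_score: float = 20.0,
    accession: str | None = None,
    condition: str = "",
) -> PeptigramTrack:
    """Sum the scores of passing PSMs onto every residue they cover.

    Only PSMs with score strictly greater than ``min_score`` contribute.
    PSM coordinates must lie within [1, protein_length].
    """
    if accession is None:
        accession = (
            str(psms_for_protein["protein_accession"].iloc[0]) if len(psms_for_protein) else ""
        )
    values = np.zeros(protein_length, dtype=float)
    passing = peptide_score_filter(psms_for_protein, min_score)
    for row in passing.itertuples(index=False):
        if row.start < 1 or row.end > protein_length:
            raise ValueError(
                f"PSM {row.peptide} [{row.start},{row.end}] outside protein of length {protein_length}"
            )
        values[row.start - 1 : row.end] += row.score
    return PeptigramTrack(accession=accession, condition=condition, values=values)


def compare_tracks(track_a: PeptigramTrack, track_b: PeptigramTrack) -> list[MissingRegion]:
    """Maximal runs of residues covered in ``track_a`` but empty in ``track_b``."""
    if len(track_a) != len(track_b) or track_a.accession != track_b.accession:
        raise ValueError("tracks must describe the same protein")
    lost = (track_a.values > 0) & (track_b.values == 0)
    regions: list[MissingRegion] = []
    start = None
    for i, flag in enumerate(lost):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append(_region(track_a, track_b, start, i - 1))
            start = None
    if start is not None:
        regions.append(_region(track_a, track_b, start, len(lost) - 1))
    return regions


def _region(a: PeptigramTrack, b: PeptigramTrack, i0: int, i1: int) -> MissingRegion:
    return MissingRegion(
        accession=a.accession,
        start=i0 + 1,
        end=i1 + 1,
        present_in=(a.condition,),
        absent_in=(b.condition,),
    )


def missing_peptides(
    psm_table: pd.DataFrame,
    accession: str,
    control_treatment: str = "untreated",
    min_score: float = 20.0,
    min_absent_donors: int = 2,
    dnase: str = "plus",
) -> pd.DataFrame:
    """Peptide-level absence report for one protein.

    A peptide is reported for a treatment when it passes the score filter
    in the control for at least one donor but yields no passing PSM in that
    treatment for at least ``min_absent_donors`` donors. Returns a tidy
    table (peptide, start, end, treatment, n_absent_donors, donors_absent).
    """
    sel = psm_table[
        (psm_table["protein_accession"] == accession) & (psm_table["dnase"] == dnase)
    ]
    passing = peptide_score_filter(sel, min_score)
    donors = sorted(psm_table.loc[psm_table["dnase"] == dnase, "donor"].unique())
    treatments = sorted(
        t for t in psm_table["treatment"].unique() if t != control_treatment
    )
    seen: dict[tuple[str, str], set[str]] = {}
    coords: dict[str, tuple[int, int]] = {}
    for row in passing.itertuples(index=False):
        seen.setdefault((row.treatment, row.peptide), set()).add(row.donor)
        coords.setdefault(row.peptide, (int(row.start), int(row.end)))

    rows = []
    control_peps = sorted({p for (t, p) in seen if t == control_treatment})
    for treatment in treatments:
        for pep in control_peps:
            present = seen.get((treatment, pep), set())
            absent = [d for d in donors if d not in present]
            if len(absent) >= min_absent_donors:
                start, end = coords[pep]
                rows.append(
                    {
                        "peptide": pep,
                        "start": start,
                        "end": end,
                        "treatment": treatment,
                        "n_absent_donors": len(absent),
                        "donors_absent": ",".join(absent),
                    }
                )
    return pd.DataFrame(
        rows, columns=["peptide", "start", "end", "treatment", "n_absent_donors", "donors_absent"]
    )


def plot_track(track: PeptigramTrack, ax=None):
    """Simple residue-vs-score step plot of one track (optional helper)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2))
    x = np.arange(1, len(track) + 1)
    ax.fill_between(x, track.values, step="mid", alpha=0.7)
    ax.set_xlabel("residue")
    ax.set_ylabel("summed score")
    ax.set_title(f"{track.accession} [{track.condition}]")
    return ax
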