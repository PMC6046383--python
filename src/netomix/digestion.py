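"""In-silico tryptic digestion and observable-peptide counting.

This is the denominator machinery for emPAI: N_obsbl, the number of
peptides of a protein an instrument could have seen, is the count of unique
tryptic peptide sequences that fall inside a detectability window (length
and m/z bounds at a set of charge states).

Cleavage follows the Mascot-style trypsin rule: after K or R, except when
the next residue is P. Coordinates are 1-based inclusive on the precursor
sequence (initiator methionine retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from pyteomics import mass as _pt_mass

from netomix.io import CANONICAL_RESIDUES

#: Monoisotopic mass of a proton, Da (charge carrier for m/z).
PROTON_MASS = 1.00727646688

#: Monoisotopic mass of water, Da (added once per peptide chain).
WATER_MASS = 18.0105646863


@dataclass(frozen=True)
class DigestPeptide:
    """One tryptic peptide with precursor coordinates (1-based inclusive)."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    monoisotopic_mass: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DetectabilityWindow:
    """Instrument constraint deciding whether a peptide is observable.

    Defaults: length 6-40 residues, charge 2+ or 3+, and m/z within the
    350-1,600 full-MS scan range.
    """

    min_length: int = 6
    max_length: int = 40
    mz_min: float = 350.0
    mz_max: float = 1600.0
    charges: frozenset[int] = field(default_factory=lambda: frozenset({2, 3}))

    def __post_init__(self) -> None:
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("invalid length bounds")
        if not self.charges or any(z < 1 for z in self.charges):
            raise ValueError("charges must be a non-empty set of positive integers")
        object.__setattr__(self, "charges", frozenset(self.charges))

    def admits(self, peptide: str, mono_mass: float | None = None) -> bool:
        """True when the peptide length and any charge state's m/z fit."""
        if not self.min_length <= len(peptide) <= self.max_length:
            return False
        m = monoisotopic_mass(peptide) if mono_mass is None else mono_mass
        return any(self.mz_min <= (m + z * PROTON_MASS) / z <= self.mz_max for z in self.charges)


def _check_canonical(sequence: str) -> None:
    bad = set(sequence) - CANONICAL_RESIDUES
    if bad:
        raise ValueError(f"non-canonical residues {sorted(bad)} in sequence")


@lru_cache(maxsize=65536)
def monoisotopic_mass(peptide_sequence: str) -> float:
    """Monoisotopic peptide mass in Da: sum of residue masses plus one water."""
    _check_canonical(peptide_sequence)
    return float(_pt_mass.fast_mass(peptide_sequence, ion_type="M", charge=0))


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cleaves between i and i+1.

    Cleaves after K or R unless the following residue is P; the chain end
    is not a site.
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(sequence: str, max_missed_cleavages: int = 2) -> list[DigestPeptide]:
    """Tryptic digest with 0..max_missed_cleavages missed cleavage sites.

    Returns every peptide together with its precursor coordinates, ordered
    by (start, end). The 0-missed-cleavage peptides tile the parent
    sequence exactly.
    """
    if not sequence:
        raise ValueError("empty sequence")
    _check_canonical(sequence)
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    # Fragment boundaries: starts of the 0-missed peptides, plus the end.
    cuts = [0] + [i + 1 for i in cleavage_sites(sequence)] + [len(sequence)]
    peptides: list[DigestPeptide] = []
    nfrag = len(cuts) - 1
    for i in range(nfrag):
        for m in range(0, max_missed_cleavages + 1):
            j = i + m + 1
            if j > nfrag:
                break
            sub = sequence[cuts[i] : cuts[j]]
            peptides.append(
                DigestPeptide(
                    sequence=sub,
                    start=cuts[i] + 1,
                    end=cuts[j],
                    missed_cleavages=m,
                    monoisotopic_mass=monoisotopic_mass(sub),
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def observable_peptides(
    sequence: str,
    window: DetectabilityWindow | None = None,
    max_missed_cleavages: int = 2,
) -> list[DigestPeptide]:
    """Unique observable peptides (first occurrence by coordinates).

    A peptide is observable when its length lies within the window's bounds
    and at least one allowed charge state puts (mass + z*proton)/z inside
    [mz_min, mz_max]. Uniqueness is by peptide sequence.
    """
    window = window or DetectabilityWindow()
    seen: set[str] = set()
    out: list[DigestPeptide] = []
    for pep in digest(sequence, max_missed_cleavages):
        if pep.sequence in seen:
            continue
        if window.admits(pep.sequence, pep.monoisotopic_mass):
            seen.add(pep.sequence)
            out.append(pep)
    return out


def observable_count(
    sequence: str,
    window: DetectabilityWindow | None = None,
    max_missed_cleavages: int = 2,
) -> int:
    """N_obsbl: the number of observable peptides of a protein."""
    return len(observable_peptides(sequence, window, max_missed_cleavages))
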