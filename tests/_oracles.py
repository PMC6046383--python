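"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

from pyteomics import mass as pt_mass

PROTON = 1.00727646688


def bruteforce_tryptic_peptides(sequence: str, max_missed: int) -> set[tuple[str, int, int, int]]:
    """All tryptic peptides by exhaustive substring enumeration.

    A substring [i, j) is a valid peptide when its left boundary is the
    chain start or follows a cleavage point, its right boundary is the
    chain end or a cleavage point, and the number of internal cleavage
    points is at most ``max_missed``. A position p (0-based, between
    residues p and p+1) is a cleavage point when sequence[p] is K/R and
    sequence[p+1] is not P. Returns (sequence, start_1based, end_1based,
    missed) tuples.
    """
    n = len(sequence)
    cut_after = [
        p for p in range(n - 1) if sequence[p] in "KR" and sequence[p + 1] != "P"
    ]
    boundaries = {-1, n - 1} | set(cut_after)  # position after which a peptide may end
    out = set()
    for i in range(n):
        if (i - 1) not in boundaries:
            continue
        for j in range(i, n):
            if j not in boundaries:
                continue
            internal = sum(1 for p in cut_after if i <= p < j)
            if internal <= max_missed:
                out.add((sequence[i : j + 1], i + 1, j + 1, internal))
    return out


def bruteforce_observable_count(
    sequence: str,
    max_missed: int,
    min_length: int,
    max_length: int,
    mz_min: float,
    mz_max: float,
    charges: tuple[int, ...],
) -> int:
    """Observable-peptide count by full enumeration over peptides and charges."""
    unique = {p for (p, *_rest) in bruteforce_tryptic_peptides(sequence, max_missed)}
    n = 0
    for pep in unique:
        if not (min_length <= len(pep) <= max_length):
            continue
        m = pt_mass.fast_mass(pep, ion_type="M", charge=0)
        if any(mz_min <= (m + z * PROTON) / z <= mz_max for z in charges):
            n += 1
    return n
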