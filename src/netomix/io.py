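"""Reading and writing of protein databases and PSM tables.

On-disk formats
---------------
* Protein databases are plain FASTA. Decoy entries are marked in-file by a
  reserved accession prefix (default ``DECOY_``), mirroring a concatenated
  target-decoy database.
* Peptide-spectrum matches (PSMs) travel as a TSV with one row per PSM and
  the exact column order given by :data:`PSM_COLUMNS`. Coordinates are
  1-based and inclusive on both ends, matching UniProt precursor residue
  numbering (e.g. "61V-78K").
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default accession prefix marking decoy entries in a concatenated database.
DECOY_PREFIX = "DECOY_"

#: Exact column order of the PSM interchange TSV.
PSM_COLUMNS = (
    "donor", "treatment", "dnase", "protein_accession", "peptide",
    "start", "end", "score", "charge", "modifications", "is_decoy",
)

TREATMENTS = ("untreated", "thrombin", "plasmin")
DNASE_STATES = ("plus", "minus")


class FormatError(ValueError):
    """Raised when an input file violates the documented on-disk format."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry: the digestible unit.

    ``is_decoy`` carries the target/decoy distinction of a concatenated
    target-decoy database.
    """

    accession: str
    sequence: str
    description: str = ""
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class SampleKey:
    """Donor x treatment x DNase status; indexes every quantification."""

    donor: str
    treatment: str
    dnase: str

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}")
        if self.dnase not in DNASE_STATES:
            raise ValueError(f"unknown dnase state {self.dnase!r}; expected one of {DNASE_STATES}")
        if not self.donor:
            raise ValueError("donor identifier must be non-empty")


def full_design(donors: Sequence[str]) -> list[SampleKey]:
    """Every donor x treatment x dnase combination, in deterministic order."""
    return [SampleKey(d, t, a) for d in donors for t in TREATMENTS for a in DNASE_STATES]


def read_fasta(path: str | Path, decoy_prefix: str = DECOY_PREFIX, strict: bool = True) -> list[ProteinRecord]:
    """Read a protein FASTA into a list of :class:`ProteinRecord`.

    Sequences are upper-cased; order is preserved. Entries whose sequence
    contains non-canonical residue letters are an error in strict mode and
    are skipped (with no record produced) otherwise. Duplicate accessions
    are an error in strict mode.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = entry.id
        seq = str(entry.seq).upper()
        bad = set(seq) - CANONICAL_RESIDUES
        if bad or not seq:
            msg = f"{accession}: non-canonical residues {sorted(bad)}" if bad else f"{accession}: empty sequence"
            if strict:
                raise FormatError(msg)
            continue
        if accession in seen:
            if strict:
                raise FormatError(f"duplicate accession {accession}")
            continue
        seen.add(accession)
        records.append(
            ProteinRecord(
                accession=accession,
                sequence=seq,
                description=entry.description[len(entry.id):].strip(),
                is_decoy=accession.startswith(decoy_prefix),
            )
        )
    if not records:
        raise FormatError(f"empty database: {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, preserving accession and sequence exactly."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.accession}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _parse_modifications(cell: object) -> str:
    # Stored as a semicolon-joined label list; empty cell = no modifications.
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ""
    return str(cell)


def read_psm_table(path: str | Path, database: Sequence[ProteinRecord] | None = None) -> pd.DataFrame:
    """Read and validate a PSM TSV.

    Every row is checked against the PSM invariants: ``end >= start``,
    ``len(peptide) == end - start + 1``, ``score >= 0``, and — when
    ``database`` is given — that the peptide equals the protein subsequence
    at ``[start, end]``. Violations raise :class:`FormatError` naming the
    offending 1-based data row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column: {', '.join(missing)}")
    df = df[list(PSM_COLUMNS)].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["score"] = df["score"].astype(float)
    df["charge"] = df["charge"].astype(int)
    df["modifications"] = df["modifications"].map(_parse_modifications)
    df["is_decoy"] = df["is_decoy"].str.lower().isin({"true", "1", "yes"})
    return validate_psm_table(df, database)


def validate_psm_table(df: pd.DataFrame, database: Sequence[ProteinRecord] | None = None) -> pd.DataFrame:
    """Validate an in-memory PSM table against the PSM invariants."""
    errors: list[str] = []
    by_acc: Mapping[str, ProteinRecord] = {r.accession: r for r in database} if database else {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.end < row.start:
            errors.append(f"row {i}: end {row.end} < start {row.start}")
            continue
        if len(row.peptide) != row.end - row.start + 1:
            errors.append(f"row {i}: peptide length {len(row.peptide)} != span {row.end - row.start + 1}")
            continue
        if row.score < 0:
            errors.append(f"row {i}: negative score {row.score}")
            continue
        if row.charge < 1:
            errors.append(f"row {i}: non-positive charge {row.charge}")
            continue
        try:
            SampleKey(row.donor, row.treatment, row.dnase)
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
            continue
        if by_acc:
            rec = by_acc.get(row.protein_accession)
            if rec is None:
                errors.append(f"row {i}: unknown accession {row.protein_accession}")
                continue
            if rec.sequence[row.start - 1 : row.end] != row.peptide:
                errors.append(
                    f"row {i}: peptide {row.peptide} does not match "
                    f"{row.protein_accession}[{row.start}:{row.end}]"
                )
    if errors:
        shown = "; ".join(errors[:10])
        more = f" (+{len(errors) - 10} more)" if len(errors) > 10 else ""
        raise FormatError(f"invalid PSM rows: {shown}{more}")
    return df.reset_index(drop=True)


def write_psm_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a PSM table as TSV with the canonical column order."""
    out = df[list(PSM_COLUMNS)].copy()
    out["is_decoy"] = out["is_decoy"].map(lambda b: "true" if b else "false")
    out.to_csv(path, sep="\t", index=False)


def write_outputs(tables: Mapping[str, object], out_dir: str | Path) -> dict:
    """Persist pipeline result tables and return a manifest.

    ``tables`` maps output names to either a DataFrame (written as TSV) or
    a JSON-serialisable object (written as JSON; a name ending in ``.json``
    forces JSON). The manifest lists every file with its row count and is
    itself written as ``manifest.json``. Output is deterministic: files are
    written in sorted-name order with sorted JSON keys.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for name in sorted(tables):
        obj = tables[name]
        if isinstance(obj, pd.DataFrame):
            fname = name if name.endswith(".tsv") else f"{name}.tsv"
            obj.to_csv(out_dir / fname, sep="\t", index=False)
            manifest[fname] = {"rows": int(len(obj))}
        else:
            fname = name if name.endswith(".json") else f"{name}.json"
            with (out_dir / fname).open("w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True)
                fh.write("\n")
            nrows = len(obj) if isinstance(obj, (list, dict)) else 1
            manifest[fname] = {"rows": int(nrows)}
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
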