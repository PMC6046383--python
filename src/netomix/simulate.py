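"""Synthetic proteome and PSM-table generator with exported ground truth.

The generator emulates the study design the analysis assumes: 3 donors x
3 treatments (untreated / thrombin / plasmin) x 2 DNase arms, with
technical duplicate injections per sample. Proteins fall into three
classes:

* ``background`` — constitutively released; present in both DNase arms.
  Within a donor the two arms sample the same conditioned medium, so a
  peptide's detectability is a latent per-(donor, peptide) draw shared
  between arms, with an independent small per-run dropout on top.
* ``net`` — NET-bound; released only upon DNase digestion, hence PSMs only
  in +DNase samples. A configurable fraction is protease-sensitive: their
  detection odds are multiplied by ``protease_effect`` under thrombin or
  plasmin.
* ``net_high`` — highly abundant NET proteins (histone-like fixtures) with
  near-saturated peptide detectability and high peptide scores; used to
  plant region deletions (peptides overlapping a planted region are never
  detected under the listed treatments).

Detection is Bernoulli per observable tryptic peptide, which makes emPAI
the natural recovered abundance. Peptide scores follow shifted gamma
distributions (location 15) so a realistic fraction falls below the
score-20 peptigram threshold; decoy matches are injected at a configurable
per-sample rate with low scores.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from netomix.digestion import DetectabilityWindow, observable_peptides
from netomix.identification import generate_decoys
from netomix.io import ProteinRecord, write_fasta

#: Canonical human histone H4 precursor sequence (103 residues, initiator
#: methionine retained; UniProt accession P62805). The tryptic peptide
#: spanning precursor residues 61-78 is VFLENVIRDAVTYTEHAK.
H4_SEQUENCE = (
    "MSGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLK"
    "VFLENVIRDAVTYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG"
)
H4_ACCESSION = "P62805"

ELANE_LIKE_ACCESSION = "ELANE_SYNTH"

#: Average residue frequencies (approximate vertebrate proteome values);
#: K+R together ~11% so tryptic fragments average ~9 residues.
_RESIDUE_FREQS = {
    "A": 0.074, "C": 0.015, "D": 0.053, "E": 0.064, "F": 0.038,
    "G": 0.069, "H": 0.026, "I": 0.055, "K": 0.058, "L": 0.092,
    "M": 0.022, "N": 0.044, "P": 0.042, "Q": 0.038, "R": 0.052,
    "S": 0.071, "T": 0.056, "V": 0.063, "W": 0.012, "Y": 0.032,
}


@dataclass(frozen=True)
class PlantedDeletion:
    """A residue region never detected under the listed treatments."""

    accession: str
    start: int
    end: int
    treatments: tuple[str, ...]

    def overlaps(self, start: int, end: int) -> bool:
        return start <= self.end and end >= self.start


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic experiment; defaults ARE the study conditions."""

    seed: int = 0
    n_background_proteins: int = 50
    n_net_proteins: int = 100
    protein_length_range: tuple[int, int] = (200, 500)
    donors: int = 3
    treatments: tuple[str, str, str] = ("untreated", "thrombin", "plasmin")
    protease_treatments: tuple[str, ...] = ("thrombin", "plasmin")
    n_technical_replicates: int = 2
    base_detect_prob: float = 0.5
    high_abundance_detect_prob: float = 0.995
    background_release_prob: float = 0.7
    run_dropout: float = 0.03
    protease_effect: float = 0.4
    protease_sensitive_fraction: float = 0.3
    protein_abundance_sd: float = 1.5
    donor_noise_sd: float = 0.15
    decoy_match_rate: float = 25.0
    score_loc: float = 15.0
    score_shape: float = 2.0
    score_scale: float = 8.0
    high_score_shape: float = 4.0
    high_score_scale: float = 10.0
    decoy_score_shape: float = 1.0
    decoy_score_scale: float = 3.0
    max_missed_cleavages: int = 2
    include_fixture_proteins: bool = True
    planted_deletions: tuple[PlantedDeletion, ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "base_detect_prob", "high_abundance_detect_prob",
            "background_release_prob", "run_dropout", "protease_sensitive_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.protease_effect <= 1.0:
            raise ValueError("protease_effect must lie in (0, 1]")
        lo, hi = self.protein_length_range
        if lo < 30 or hi < lo:
            raise ValueError("infeasible protein length bounds")


@dataclass
class GroundTruth:
    """What the generator planted, serialised alongside its outputs."""

    protein_class: dict[str, str]
    protease_sensitive: list[str]
    abundance: dict[str, float]
    planted_deletions: list[PlantedDeletion]

    def accessions(self, cls: str) -> list[str]:
        return sorted(a for a, c in self.protein_class.items() if c == cls)

    @property
    def net_accessions(self) -> list[str]:
        return sorted(a for a, c in self.protein_class.items() if c in ("net", "net_high"))

    @property
    def background_accessions(self) -> list[str]:
        return self.accessions("background")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "protein_class": self.protein_class,
            "protease_sensitive": sorted(self.protease_sensitive),
            "abundance": self.abundance,
            "planted_deletions": [asdict(d) for d in self.planted_deletions],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            protein_class=payload["protein_class"],
            protease_sensitive=list(payload["protease_sensitive"]),
            abundance=payload["abundance"],
            planted_deletions=[
                PlantedDeletion(
                    accession=d["accession"], start=d["start"], end=d["end"],
                    treatments=tuple(d["treatments"]),
                )
                for d in payload["planted_deletions"]
            ],
        )


def elane_like_fixture() -> tuple[ProteinRecord, list[tuple[int, int]]]:
    """Synthetic neutrophil-elastase-like protein with 4 deletion targets.

    The sequence is built from designed tryptic blocks: every cleavage
    fragment is a single observable peptide, and the four deletion-target
    fragments (28-34 residues) are flanked by fragments long enough that
    any missed-cleavage variant overlapping them exceeds the 40-residue
    observability bound. Peptide-level absence calls on this protein are
    therefore exactly the planted fragments. Synthetic stand-in — not the
    real ELANE sequence.
    """
    rng = np.random.default_rng(97)  # fixture identity, independent of experiment seed
    body_alphabet = list("ACDEFGHILMNQSTVWY")  # no K/R (sites) and no P (rule exception)
    lengths = [24, 30, 26, 32, 22, 28, 25, 34, 21]
    deletion_idx = {1, 3, 5, 7}
    segments = []
    for i, n in enumerate(lengths):
        body = "".join(rng.choice(body_alphabet, size=n - 1))
        terminal = "K" if i % 2 == 0 else "R"
        segments.append(body + terminal)
    sequence = "".join(segments)
    regions = []
    pos = 1
    for i, seg in enumerate(segments):
        if i in deletion_idx:
            regions.append((pos, pos + len(seg) - 1))
        pos += len(seg)
    record = ProteinRecord(
        accession=ELANE_LIKE_ACCESSION,
        sequence=sequence,
        description="synthetic elastase-like fixture protein",
    )
    return record, regions


def default_planted_deletions() -> list[PlantedDeletion]:
    """Fixture deletions: the H4 61-78 region and 4 elastase-like peptides."""
    _, regions = elane_like_fixture()
    dels = [PlantedDeletion(H4_ACCESSION, 61, 78, ("thrombin", "plasmin"))]
    dels += [PlantedDeletion(ELANE_LIKE_ACCESSION, s, e, ("thrombin", "plasmin")) for s, e in regions]
    return dels


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    letters = np.array(list(_RESIDUE_FREQS))
    probs = np.array(list(_RESIDUE_FREQS.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def generate_proteome(
    config: GeneratorConfig, window: DetectabilityWindow | None = None
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Random target proteome plus planted fixtures and ground truth.

    Sequences use natural residue frequencies (K+R ~11%), so tryptic
    fragments average ~9 residues and each protein carries tens of
    observable peptides; generation retries until a protein has at least
    five. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    window = window or DetectabilityWindow()
    lo, hi = config.protein_length_range
    records: list[ProteinRecord] = []
    classes: dict[str, str] = {}
    sensitive: list[str] = []
    abundance: dict[str, float] = {}

    def make(accession: str, cls: str) -> None:
        for _ in range(50):
            length = int(rng.integers(lo, hi + 1))
            seq = _random_sequence(rng, length)
            if len(observable_peptides(seq, window, config.max_missed_cleavages)) >= 5:
                break
        else:
            raise RuntimeError(f"could not generate an observable protein for {accession}")
        records.append(ProteinRecord(accession=accession, sequence=seq, description=f"synthetic {cls}"))
        classes[accession] = cls
        abundance[accession] = float(np.exp(rng.normal(0.0, config.protein_abundance_sd)))

    for i in range(config.n_background_proteins):
        make(f"BG{i:04d}", "background")
    for i in range(config.n_net_proteins):
        acc = f"NET{i:04d}"
        make(acc, "net")
        if rng.random() < config.protease_sensitive_fraction:
            sensitive.append(acc)

    deletions = list(config.planted_deletions)
    if config.include_fixture_proteins:
        records.append(ProteinRecord(H4_ACCESSION, H4_SEQUENCE, "Histone H4"))
        elane, _ = elane_like_fixture()
        records.append(elane)
        for acc in (H4_ACCESSION, ELANE_LIKE_ACCESSION):
            classes[acc] = "net_high"
            abundance[acc] = 1.0
            sensitive.append(acc)
        deletions.extend(default_planted_deletions())

    truth = GroundTruth(
        protein_class=classes,
        protease_sensitive=sensitive,
        abundance=abundance,
        planted_deletions=deletions,
    )
    return records, truth


def _class_base_prob(cls: str, config: GeneratorConfig) -> float:
    return {
        "background": config.background_release_prob,
        "net": config.base_detect_prob,
        "net_high": config.high_abundance_detect_prob,
    }[cls]


def _score(rng: np.random.Generator, cls: str, config: GeneratorConfig) -> float:
    if cls == "net_high":
        draw = rng.gamma(config.high_score_shape, config.high_score_scale)
    else:
        draw = rng.gamma(config.score_shape, config.score_scale)
    return round(config.score_loc + draw, 2)


def _modification(rng: np.random.Generator, peptide: str) -> str:
    if "M" in peptide and rng.random() < 0.15:
        return "Oxidation (M)"
    if ("N" in peptide or "Q" in peptide) and rng.random() < 0.10:
        return "Deamidation (NQ)"
    return ""


def simulate_psm_tables(
    proteome: list[ProteinRecord],
    truth: GroundTruth,
    config: GeneratorConfig,
    window: DetectabilityWindow | None = None,
) -> pd.DataFrame:
    """Simulate the full-design PSM table for a generated proteome.

    For every sample, each present protein's observable peptides are
    detected via a latent Bernoulli (odds = class base odds x protein
    abundance x donor jitter x protease factor) followed by per-run
    Binomial retention over the technical replicates; detected replicates
    each yield one PSM row. NET-class proteins never produce PSMs in
    -DNase samples; peptides overlapping a planted deletion are suppressed
    in the listed treatments; decoy PSMs are injected per sample at a
    Poisson rate. Deterministic for a fixed seed.
    """
    window = window or DetectabilityWindow()
    rng = np.random.default_rng(config.seed + 1_000_003)
    donors = [f"D{i + 1}" for i in range(config.donors)]
    decoys = [r for r in generate_decoys(proteome) if r.is_decoy]
    decoy_peptides = {
        r.accession: observable_peptides(r.sequence, window, config.max_missed_cleavages)
        for r in decoys
    }
    obs_peps = {
        r.accession: observable_peptides(r.sequence, window, config.max_missed_cleavages)
        for r in proteome
    }
    deletions_by_acc: dict[str, list[PlantedDeletion]] = {}
    for d in truth.planted_deletions:
        deletions_by_acc.setdefault(d.accession, []).append(d)

    p_run = 1.0 - config.run_dropout
    rows: list[dict] = []
    for donor in donors:
        jitter = {
            r.accession: float(np.exp(rng.normal(0.0, config.donor_noise_sd))) for r in proteome
        }
        for treatment in config.treatments:
            for rec in proteome:
                cls = truth.protein_class[rec.accession]
                base_p = _class_base_prob(cls, config)
                odds = (base_p / (1.0 - base_p)) * truth.abundance[rec.accession] * jitter[rec.accession]
                if (
                    rec.accession in set(truth.protease_sensitive)
                    and treatment in config.protease_treatments
                ):
                    odds *= config.protease_effect
                p_detect = odds / (1.0 + odds)
                arms = ("plus", "minus") if cls == "background" else ("plus",)
                dels = [
                    d for d in deletions_by_acc.get(rec.accession, ())
                    if treatment in d.treatments
                ]
                for pep in obs_peps[rec.accession]:
                    if any(d.overlaps(pep.start, pep.end) for d in dels):
                        continue
                    latent = rng.random() < p_detect  # shared by both DNase arms
                    if not latent:
                        continue
                    for arm in arms:
                        k = int(rng.binomial(config.n_technical_replicates, p_run))
                        for _ in range(k):
                            rows.append(
                                {
                                    "donor": donor,
                                    "treatment": treatment,
                                    "dnase": arm,
                                    "protein_accession": rec.accession,
                                    "peptide": pep.sequence,
                                    "start": pep.start,
                                    "end": pep.end,
                                    "score": _score(rng, cls, config),
                                    "charge": int(rng.choice([2, 3], p=[0.7, 0.3])),
                                    "modifications": _modification(rng, pep.sequence),
                                    "is_decoy": False,
                                }
                            )
            # Decoy matches: search noise hitting the reversed half of the database.
            for arm in ("plus", "minus"):
                n_decoy = int(rng.poisson(config.decoy_match_rate))
                for _ in range(n_decoy):
                    dec = decoys[int(rng.integers(len(decoys)))]
                    peps = decoy_peptides[dec.accession]
                    if not peps:
                        continue
                    pep = peps[int(rng.integers(len(peps)))]
                    rows.append(
                        {
                            "donor": donor,
                            "treatment": treatment,
                            "dnase": arm,
                            "protein_accession": dec.accession,
                            "peptide": pep.sequence,
                            "start": pep.start,
                            "end": pep.end,
                            "score": round(config.score_loc + rng.gamma(
                                config.decoy_score_shape, config.decoy_score_scale), 2),
                            "charge": int(rng.choice([2, 3], p=[0.7, 0.3])),
                            "modifications": "",
                            "is_decoy": True,
                        }
                    )
    return pd.DataFrame(rows)


def write_simulation(out_dir: str | Path, config: GeneratorConfig) -> dict:
    """Run the generator and persist FASTA, per-sample PSM TSVs and truth."""
    from netomix.io import PSM_COLUMNS, write_psm_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteome, truth = generate_proteome(config)
    psms = simulate_psm_tables(proteome, truth, config)
    write_fasta(proteome, out_dir / "proteome.fasta")
    truth.to_json(out_dir / "ground_truth.json")
    design_rows = []
    for (donor, treatment, dnase), sub in psms.groupby(["donor", "treatment", "dnase"]):
        name = f"psms_{donor}_{treatment}_{dnase}.tsv"
        write_psm_table(sub.reset_index(drop=True)[list(PSM_COLUMNS)], out_dir / name)
        design_rows.append({"donor": donor, "treatment": treatment, "dnase": dnase, "file": name})
    design = pd.DataFrame(design_rows)
    design.to_csv(out_dir / "design.tsv", sep="\t", index=False)
    write_psm_table(psms, out_dir / "psms_all.tsv")
    return {"n_proteins": len(proteome), "n_psms": int(len(psms)), "n_samples": len(design_rows)}


def simulate_fdr_experiment(
    n_true: int = 900,
    n_false: int = 200,
    seed: int = 0,
    signal: tuple[float, float] = (6.0, 10.0),
    null: tuple[float, float] = (1.5, 5.0),
    score_loc: float = 15.0,
) -> tuple[pd.DataFrame, set[str]]:
    """Protein-level target-decoy calibration experiment.

    ``n_true`` confidently matched target proteins draw scores from the
    signal distribution; ``n_false`` spurious matches draw from the null
    distribution and land on the target or decoy half of the database with
    equal probability — the symmetry the 2*Md/(Md+Mt) estimator assumes.
    Returns a one-PSM-per-protein table and the set of false target
    accessions (the planted ground truth).
    """
    rng = np.random.default_rng(seed)
    rows = []
    false_targets: set[str] = set()
    for i in range(n_true):
        rows.append((f"T{i:05d}", False, score_loc + rng.gamma(*signal)))
    for i in range(n_false):
        if rng.random() < 0.5:
            acc = f"F{i:05d}"
            false_targets.add(acc)
            rows.append((acc, False, score_loc + rng.gamma(*null)))
        else:
            rows.append((f"DECOY_F{i:05d}", True, score_loc + rng.gamma(*null)))
    table = pd.DataFrame(
        {
            "donor": "D1",
            "treatment": "untreated",
            "dnase": "plus",
            "protein_accession": [r[0] for r in rows],
            "peptide": "SYNTHETIC",
            "start": 1,
            "end": 9,
            "score": [r[2] for r in rows],
            "charge": 2,
            "modifications": "",
            "is_decoy": [r[1] for r in rows],
        }
    )
    return table, false_targets


def dunnett_null_rejection_rate(
    n_datasets: int = 2000,
    n_per_group: int = 6,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise type-I error of the Dunnett procedure under the null.

    Simulates ``n_datasets`` experiments with all three treatment groups
    drawn from the same normal distribution and reports the fraction in
    which any treatment-vs-control comparison rejects at ``alpha``.
    """
    from netomix.differential import dunnett_test

    rng = np.random.default_rng(seed)
    labels = ("untreated", "thrombin", "plasmin")
    rejections = 0
    for _ in range(n_datasets):
        groups = {lab: rng.normal(size=n_per_group) for lab in labels}
        res = dunnett_test(groups, control_label="untreated", alpha=alpha)
        rejections += bool(res["significant"].any())
    return rejections / n_datasets
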