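"""Pipeline orchestration: configuration, stage ordering and reporting.

Stages run in the fixed order digest -> identify -> quantify -> netome ->
differential -> peptigram. Every stage logs row counts and filter
attrition; all outputs plus the fully-resolved effective configuration are
persisted next to each other so a run can be reproduced exactly from its
own output directory.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from netomix import differential, netome_filter, peptigram, quantification
from netomix.digestion import DetectabilityWindow
from netomix.identification import filter_proteins, peptide_score_filter
from netomix.io import (
    DECOY_PREFIX,
    read_fasta,
    read_psm_table,
    write_outputs,
)
from netomix.simulate import ELANE_LIKE_ACCESSION, H4_ACCESSION

log = logging.getLogger("netomix")


def _strict_from_dict(cls, payload: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in payload:
            continue
        value = payload[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _strict_from_dict(f.type, value)
        kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class DigestionConfig:
    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 40
    mz_min: float = 350.0
    mz_max: float = 1600.0
    charges: tuple[int, ...] = (2, 3)

    def window(self) -> DetectabilityWindow:
        return DetectabilityWindow(
            min_length=self.min_length,
            max_length=self.max_length,
            mz_min=self.mz_min,
            mz_max=self.mz_max,
            charges=frozenset(self.charges),
        )


@dataclass
class IdentificationConfig:
    fdr_threshold_percent: float = 1.0
    min_peptide_score: float = 20.0
    decoy_prefix: str = DECOY_PREFIX
    score_agg: str = "sum"
    #: apply the peptide-score filter before identification too (default:
    #: the score filter is used only for peptigrams)
    score_filter_identification: bool = False


@dataclass
class NetomeConfig:
    min_donors: int = 2
    correlation_transform: str = "log10_offset"
    correlation_offset: float = 0.01


@dataclass
class DifferentialConfig:
    n_clusters: int = 8
    metric: str = "euclidean"
    linkage: str = "average"
    standardize: bool = True
    control_treatment: str = "untreated"
    #: protein groups for donor-matched ratio analysis; empty means
    #: "fixture proteins if present, else none"
    groups: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class PeptigramConfig:
    min_score: float = 20.0
    min_absent_donors: int = 2
    #: accessions to build tracks for; empty means fixtures if present
    proteins: list[str] = field(default_factory=list)


@dataclass
class PipelineConfig:
    fasta: str = "proteome.fasta"
    psm_table: str = "psms_all.tsv"
    out_dir: str = "results"
    seed: int = 0
    digestion: DigestionConfig = field(default_factory=DigestionConfig)
    identification: IdentificationConfig = field(default_factory=IdentificationConfig)
    netome: NetomeConfig = field(default_factory=NetomeConfig)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    peptigram: PeptigramConfig = field(default_factory=PeptigramConfig)

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "PipelineConfig":
        payload = dict(payload)
        for key, sub in (
            ("digestion", DigestionConfig),
            ("identification", IdentificationConfig),
            ("netome", NetomeConfig),
            ("differential", DifferentialConfig),
            ("peptigram", PeptigramConfig),
        ):
            if key in payload and isinstance(payload[key], dict):
                payload[key] = _strict_from_dict(sub, payload[key])
        return _strict_from_dict(cls, payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and persist outputs; returns the file manifest.

    The attrition log (counts in/out of each filter) is stored in the
    returned manifest under ``attrition`` and written to ``report.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    attrition: dict[str, Any] = {}

    # -- load ---------------------------------------------------------------
    database = read_fasta(config.fasta, decoy_prefix=config.identification.decoy_prefix)
    targets = [r for r in database if not r.is_decoy]
    if len(targets) == len(database):
        from netomix.identification import generate_decoys

        database = generate_decoys(targets, config.identification.decoy_prefix)
    psms = read_psm_table(config.psm_table, database)
    attrition["psms_loaded"] = int(len(psms))
    attrition["proteins_in_database"] = len(targets)

    window = config.digestion.window()
    mmc = config.digestion.max_missed_cleavages

    # -- identify -----------------------------------------------------------
    ident_input = psms
    if config.identification.score_filter_identification:
        ident_input = peptide_score_filter(psms, config.identification.min_peptide_score)
    result = filter_proteins(
        ident_input,
        fdr_threshold_percent=config.identification.fdr_threshold_percent,
        score_agg=config.identification.score_agg,
    )
    retained = sorted(result.retained_accessions)
    attrition["proteins_ranked"] = result.n_ranked
    attrition["proteins_retained_fdr"] = len(retained)
    attrition["decoy_matches_at_cutoff"] = result.summary.Md
    attrition["target_matches_at_cutoff"] = result.summary.Mt
    attrition["fdr_percent_at_cutoff"] = result.summary.fdr_percent
    log.info("FDR filter: %d/%d proteins retained (Md=%d, Mt=%d)",
             len(retained), result.n_ranked, result.summary.Md, result.summary.Mt)

    # -- quantify -----------------------------------------------------------
    quants = quantification.quantify_all(
        psms, database, window=window, accessions=retained, max_missed_cleavages=mmc
    )
    attrition["quant_rows"] = int(len(quants))

    # -- netome -------------------------------------------------------------
    entries = []
    pairs = quants[["donor", "treatment"]].drop_duplicates()
    for donor, treatment in pairs.itertuples(index=False):
        entries.extend(netome_filter.subtract_background(quants, donor, treatment))
    netome_sets = netome_filter.consensus_netome(entries, config.netome.min_donors)
    attrition["netome_sizes"] = {t: len(s) for t, s in netome_sets.items()}
    venn_counts = netome_filter.venn(netome_sets) if len(netome_sets) == 3 else None
    correlations = netome_filter.donor_correlation(
        quants,
        transform=config.netome.correlation_transform,
        offset=config.netome.correlation_offset,
    )

    netome_table = pd.DataFrame(
        [
            {
                "accession": e.accession,
                "donor": e.donor,
                "treatment": e.treatment,
                "empai_plus": e.empai_plus,
                "empai_minus": e.empai_minus,
                "empai_net": e.empai_net,
                "net_bound": e.net_bound,
                "in_consensus": e.accession in netome_sets.get(e.treatment, set()),
            }
            for e in entries
        ]
    )

    # -- differential -------------------------------------------------------
    union = sorted(set().union(*netome_sets.values())) if netome_sets else []
    matrix = _netome_matrix(entries, union, list(netome_sets))
    clusters_df = pd.DataFrame(columns=["accession", "cluster_id", "leaf_order"])
    if len(matrix) >= config.differential.n_clusters:
        assignments, _ = differential.hierarchical_cluster(
            matrix,
            n_clusters=config.differential.n_clusters,
            metric=config.differential.metric,
            method=config.differential.linkage,
            standardize=config.differential.standardize,
        )
        clusters_df = pd.DataFrame(
            [
                {"accession": a.accession, "cluster_id": a.cluster_id, "leaf_order": a.linkage_order}
                for a in sorted(assignments, key=lambda a: a.linkage_order)
            ]
        )
    attrition["clustered_proteins"] = int(len(clusters_df))

    groups = dict(config.differential.groups)
    if not groups:
        present = {r for r in (H4_ACCESSION, ELANE_LIKE_ACCESSION) if quants["accession"].eq(r).any()}
        groups = {acc: [acc] for acc in sorted(present)}
    ratios_frames, stats_rows = [], []
    for label, accs in groups.items():
        grouped = differential.aggregate_group(quants, accs, label)
        ratios = differential.normalize_to_control(
            grouped, control_treatment=config.differential.control_treatment
        )
        ratios_frames.append(ratios)
        by_treatment = {
            t: sub["ratio"].to_numpy() for t, sub in ratios.groupby("treatment")
        }
        if len(by_treatment) >= 2 and all(len(v) >= 2 for v in by_treatment.values()):
            try:
                stats = differential.dunnett_test(
                    by_treatment, control_label=config.differential.control_treatment
                )
            except ValueError:
                continue
            for row in stats.itertuples(index=False):
                stats_rows.append(
                    {
                        "group_label": label,
                        "treatment": row.treatment,
                        "p_adjusted": row.p_adjusted,
                        "code": row.code,
                        "anova_p": row.anova_p,
                    }
                )
    ratios_df = (
        pd.concat(ratios_frames, ignore_index=True)
        if ratios_frames
        else pd.DataFrame(columns=["group_label", "donor", "treatment", "ratio"])
    )
    stats_df = pd.DataFrame(stats_rows, columns=["group_label", "treatment", "p_adjusted", "code", "anova_p"])

    # -- peptigram ----------------------------------------------------------
    track_accs = list(config.peptigram.proteins)
    if not track_accs:
        track_accs = [
            a for a in (H4_ACCESSION, ELANE_LIKE_ACCESSION) if psms["protein_accession"].eq(a).any()
        ]
    by_acc = {r.accession: r for r in database}
    tracks_payload: dict[str, dict[str, list[float]]] = {}
    missing_frames = []
    for acc in track_accs:
        length = len(by_acc[acc].sequence)
        tracks_payload[acc] = {}
        plus = psms[(psms["protein_accession"] == acc) & (psms["dnase"] == "plus")]
        for treatment, sub in plus.groupby("treatment"):
            track = peptigram.build_track(
                sub, length, config.peptigram.min_score, accession=acc, condition=str(treatment)
            )
            tracks_payload[acc][str(treatment)] = track.values.tolist()
        report = peptigram.missing_peptides(
            psms,
            acc,
            control_treatment=config.differential.control_treatment,
            min_score=config.peptigram.min_score,
            min_absent_donors=config.peptigram.min_absent_donors,
        )
        report.insert(0, "accession", acc)
        missing_frames.append(report)
    missing_df = (
        pd.concat(missing_frames, ignore_index=True)
        if missing_frames
        else pd.DataFrame(columns=["accession", "peptide", "start", "end", "treatment",
                                   "n_absent_donors", "donors_absent"])
    )
    attrition["peptigram_proteins"] = len(track_accs)

    # -- persist ------------------------------------------------------------
    tables: dict[str, Any] = {
        "netome": netome_table,
        "clusters": clusters_df,
        "quant": quants,
        "ratios": ratios_df,
        "stats": stats_df,
        "correlations": correlations,
        "missing_regions": missing_df,
        "peptigrams.json": tracks_payload,
        "report.json": attrition,
    }
    if venn_counts is not None:
        tables["venn.json"] = {
            "set_names": list(venn_counts.set_names),
            "regions": venn_counts.regions,
            "union_size": venn_counts.union_size,
            "intersection_size": venn_counts.intersection_size,
            "shared_percent": venn_counts.shared_percent,
        }
    manifest = write_outputs(tables, out_dir)
    config.to_yaml(out_dir / "effective_config.yaml")
    manifest["attrition"] = attrition
    return manifest


def _netome_matrix(entries, accessions, treatments) -> pd.DataFrame:
    """Donor-averaged net emPAI matrix: proteins x treatments."""
    df = pd.DataFrame(
        [
            {"accession": e.accession, "treatment": e.treatment, "empai_net": e.empai_net}
            for e in entries
            if e.accession in set(accessions)
        ]
    )
    if df.empty:
        return pd.DataFrame(index=pd.Index([], name="accession"), columns=treatments)
    mat = df.pivot_table(index="accession", columns="treatment", values="empai_net", aggfunc="mean")
    mat = mat.reindex(index=accessions, columns=treatments).fillna(0.0)
    return mat
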