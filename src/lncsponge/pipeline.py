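"""End-to-end driver: stage functions over an artifact directory.

Each stage reads its inputs from the output directory (or from user-supplied
files named in the configuration), writes its results as TSV/FASTA, and is
independently rerunnable; all randomness flows from the configured seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_transcripts, filter_lncrna_candidates, find_orfs, orf_table_rows
from .cluster import Cluster, cluster_table_rows, greedy_cluster, select_consensus
from .expression import (
    classify_de,
    compute_fpkm,
    de_counts,
    estimate_common_dispersion,
    expression_filter,
    nb_exact_test,
    tmm_factors,
)
from .report import de_summary, expression_share, length_histogram
from .seqio import TranscriptRecord, read_fasta, read_mirnas, read_transcripts, write_fasta
from .simulate import (
    SOURCES,
    default_sponge_plan,
    SimulationConfig,
    simulate_counts,
    simulate_mirnas,
    simulate_transcriptomes,
)
from .sponge import (
    candidate_log2fc_table,
    itemset_significance,
    mine_itemsets,
    normalized_target_ratio,
    select_sponge_candidates,
)
from .targets import TargetParams, build_null, predict_targets, sites_table_rows

logger = logging.getLogger("lncsponge")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    # synthetic data
    "n_clusters": 60,
    "p_coding": 0.6,
    "source_presence": [0.9, 0.7, 0.6],
    "length_min": 300,
    "length_max": 1500,
    "mutation_rate": 0.005,
    "n_samples_per_group": 6,
    "dispersion": 0.15,
    "de_fraction": 0.25,
    "de_log2fc": 2.0,
    "n_mirnas": 20,
    "plant_sponges": True,
    "lncrna_share": 0.3,
    # external inputs (override the synthetic stage)
    "counts_file": None,
    "samples_file": None,
    "hit_table_file": None,
    # classification
    "min_orf_aa": 50,
    "homology_score_threshold": 60.0,
    "both_strands": True,
    # clustering / consensus
    "identity_threshold": 0.98,
    "coverage_threshold": 0.80,
    "require_mgsg_representative": False,
    # lncRNA length gate
    "min_lncrna_length": 200,
    "max_lncrna_length": 1800,
    # expression / DE
    "min_fpkm": 5.0,
    "alpha": 0.05,
    # target prediction
    "min_site_type": "7mer-A1",
    "min_hybrid_score": 70.0,
    "window_3p": 30,
    # shuffled null
    "n_null_replicates": 19,
    "shuffle_mode": "mono",
    # sponge detection
    "min_support": None,
    "max_groups": 3,
    # report
    "length_bin_width": 100,
}


def load_config(source: str | Path | Mapping[str, Any] | None = None) -> dict:
    """Merge a YAML file or mapping over the defaults; unknown keys error."""
    cfg = dict(DEFAULT_CONFIG)
    if source is None:
        return cfg
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    for key, value in user.items():
        if key not in DEFAULT_CONFIG:
            raise KeyError(f"unknown configuration key {key!r}")
        cfg[key] = value
    return cfg


def _sim_config(cfg: Mapping[str, Any]) -> SimulationConfig:
    return SimulationConfig(
        seed=cfg["seed"],
        n_clusters=cfg["n_clusters"],
        p_coding=cfg["p_coding"],
        source_presence=tuple(cfg["source_presence"]),
        length_range=(cfg["length_min"], cfg["length_max"]),
        mutation_rate=cfg["mutation_rate"],
        n_samples_per_group=cfg["n_samples_per_group"],
        dispersion=cfg["dispersion"],
        de_fraction=cfg["de_fraction"],
        de_log2fc=cfg["de_log2fc"],
        n_mirnas=cfg["n_mirnas"],
        sponge_plan=default_sponge_plan() if cfg["plant_sponges"] else (),
        lncrna_share=cfg["lncrna_share"],
    )


def _params(cfg: Mapping[str, Any]) -> TargetParams:
    return TargetParams(
        min_site_type=cfg["min_site_type"],
        min_hybrid_score=cfg["min_hybrid_score"],
        window_3p=cfg["window_3p"],
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def stage_simulate(outdir: Path, cfg: Mapping[str, Any]) -> None:
    sim = _sim_config(cfg)
    sets, truth = simulate_transcriptomes(sim)
    mirnas = simulate_mirnas(sim)
    for src in SOURCES:
        write_fasta(outdir / f"transcripts_{src}.fasta", sets[src])
    write_fasta(outdir / "mirnas.fasta", mirnas)
    write_fasta(
        outdir / "reference_proteins.fasta",
        [(f"refprot{i:04d}", p) for i, p in enumerate(truth.reference_proteins)],
    )
    # Ground-truth tables: written for inspection, never read by the pipeline.
    _write_tsv(
        pd.DataFrame(
            [
                {"transcript_id": t, "class": c,
                 "cluster_id": truth.cluster_by_transcript[t]}
                for t, c in sorted(truth.class_by_transcript.items())
            ]
        ),
        outdir / "truth_transcripts.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            truth.planted_sites,
            columns=["transcript_id", "mirna_id", "start", "site_type"],
        ),
        outdir / "truth_planted_sites.tsv",
    )


def _read_source_sets(outdir: Path) -> dict[str, list[TranscriptRecord]]:
    return {
        src: read_transcripts(outdir / f"transcripts_{src}.fasta", src)
        for src in SOURCES
    }


def stage_classify(outdir: Path, cfg: Mapping[str, Any]) -> None:
    sets = _read_source_sets(outdir)
    if cfg["hit_table_file"]:
        table = pd.read_csv(cfg["hit_table_file"], sep="\t")
        gate: Any = dict(zip(table.iloc[:, 0], table.iloc[:, 1].astype(bool)))
    else:
        gate = [seq for _, seq in
                _read_protein_fasta(outdir / "reference_proteins.fasta")]
    rows = []
    orf_rows = []
    for src, records in sets.items():
        coding, noncoding = classify_transcripts(
            records,
            gate,
            min_aa=cfg["min_orf_aa"],
            score_threshold=cfg["homology_score_threshold"],
            both_strands=cfg["both_strands"],
        )
        lnc = filter_lncrna_candidates(
            noncoding, cfg["min_lncrna_length"], cfg["max_lncrna_length"]
        )
        write_fasta(outdir / f"coding_{src}.fasta", coding)
        write_fasta(outdir / f"lncrna_{src}.fasta", lnc)
        for rec in records:
            orf_rows.extend(orf_table_rows(find_orfs(rec, cfg["min_orf_aa"],
                                                     cfg["both_strands"])))
        lnc_ids = {r.id for r in lnc}
        for rec in records:
            cls = "coding" if any(rec.id == c.id for c in coding) else "noncoding"
            rows.append(
                {"transcript_id": rec.id, "source": src, "class": cls,
                 "lncrna_candidate": int(rec.id in lnc_ids)}
            )
    _write_tsv(pd.DataFrame(rows), outdir / "classification.tsv")
    _write_tsv(pd.DataFrame(orf_rows), outdir / "orfs.tsv")


def _read_protein_fasta(path: Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def _cluster_class(outdir: Path, cfg: Mapping[str, Any], prefix: str) -> list[Cluster]:
    pooled: list[TranscriptRecord] = []
    for src in SOURCES:
        pooled.extend(read_transcripts(outdir / f"{prefix}_{src}.fasta", src))
    clusters = greedy_cluster(
        pooled, cfg["identity_threshold"], cfg["coverage_threshold"]
    )
    _write_tsv(
        pd.DataFrame(cluster_table_rows(clusters)),
        outdir / f"clusters_{prefix}.tsv",
    )
    return clusters


def stage_cluster(outdir: Path, cfg: Mapping[str, Any]) -> None:
    _cluster_class(outdir, cfg, "lncrna")
    _cluster_class(outdir, cfg, "coding")


def stage_consensus(outdir: Path, cfg: Mapping[str, Any]) -> None:
    for prefix in ("lncrna", "coding"):
        pooled = {}
        for src in SOURCES:
            for rec in read_transcripts(outdir / f"{prefix}_{src}.fasta", src):
                pooled[rec.id] = rec
        table = pd.read_csv(outdir / f"clusters_{prefix}.tsv", sep="\t")
        clusters = []
        for cid, sub in table.groupby("cluster_id", sort=True):
            clusters.append(
                Cluster(
                    sub.iloc[0]["representative_id"],
                    list(zip(sub["member_id"], sub["source"])),
                )
            )
        consensus = select_consensus(
            clusters, pooled,
            require_mgsg_representative=cfg["require_mgsg_representative"],
        )
        # refresh the retained flags in the cluster table
        _write_tsv(pd.DataFrame(cluster_table_rows(clusters)),
                   outdir / f"clusters_{prefix}.tsv")
        consensus.sort(key=lambda r: r.id)
        write_fasta(outdir / f"consensus_{prefix}.fasta", consensus)


def _read_consensus(outdir: Path) -> tuple[list[TranscriptRecord], pd.Series, pd.Series]:
    lnc = read_transcripts(outdir / "consensus_lncrna.fasta")
    cod = read_transcripts(outdir / "consensus_coding.fasta")
    records = lnc + cod
    classes = pd.Series(
        {r.id: ("lncRNA" if i < len(lnc) else "coding") for i, r in enumerate(records)}
    )
    lengths = pd.Series({r.id: r.length for r in records})
    return records, classes, lengths


def stage_express(outdir: Path, cfg: Mapping[str, Any]) -> None:
    records, classes, lengths = _read_consensus(outdir)
    if cfg["counts_file"] and cfg["samples_file"]:
        counts = pd.read_csv(cfg["counts_file"], sep="\t", index_col=0)
        samples = pd.read_csv(cfg["samples_file"], sep="\t", index_col=0)
        de_truth = None
    else:
        sim = _sim_config(cfg)
        sponge_ids = _planted_consensus_ids(outdir)
        counts, samples, de_truth = simulate_counts(
            records, sim, classes.to_dict(), force_up_fed=sponge_ids
        )
    _write_tsv(counts, outdir / "counts.tsv", index=True)
    _write_tsv(samples, outdir / "samples.tsv", index=True)
    if de_truth is not None:
        _write_tsv(de_truth, outdir / "truth_de.tsv", index=True)
    fpkm = compute_fpkm(counts, lengths)
    _write_tsv(fpkm, outdir / "fpkm.tsv", index=True)
    retained = expression_filter(fpkm, samples, cfg["min_fpkm"])
    pd.Series(sorted(retained), name="transcript_id").to_csv(
        outdir / "expression_retained.tsv", sep="\t", index=False
    )
    factors = tmm_factors(counts)
    factors.rename("tmm_factor").to_csv(outdir / "tmm_factors.tsv", sep="\t")


def _planted_consensus_ids(outdir: Path) -> list[str]:
    """Consensus lncRNA ids of sponge-planted clusters (via the truth table
    written by the synthetic stage; used only to plant DE structure)."""
    path = outdir / "truth_planted_sites.tsv"
    if not path.exists():
        return []
    planted = pd.read_csv(path, sep="\t")
    if planted.empty:
        return []
    consensus_ids = {r.id for r in read_transcripts(outdir / "consensus_lncrna.fasta")}
    return sorted(set(planted["transcript_id"]) & consensus_ids)


def stage_de(outdir: Path, cfg: Mapping[str, Any]) -> None:
    counts = pd.read_csv(outdir / "counts.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(outdir / "samples.tsv", sep="\t", index_col=0)
    retained = pd.read_csv(outdir / "expression_retained.tsv", sep="\t")[
        "transcript_id"
    ].tolist()
    _, classes, _ = _read_consensus(outdir)
    summary_rows = []
    for tissue in sorted(samples["tissue"].unique()):
        cols = samples.index[samples["tissue"] == tissue]
        sub = counts[cols]
        labels = samples.loc[cols, "condition"]
        factors = tmm_factors(sub)
        phi = estimate_common_dispersion(sub, labels, factors)
        de = nb_exact_test(sub.loc[sub.index.isin(retained)], labels, phi, factors)
        de = classify_de(de, cfg["alpha"])
        de.insert(0, "class", classes.reindex(de.index))
        _write_tsv(de, outdir / f"de_{tissue}.tsv", index=True)
        for cls in ("lncRNA", "coding"):
            stats = de_counts(de[de["class"] == cls])
            n_total = int((classes == cls).sum())
            summary_rows.append(
                {
                    "tissue": tissue,
                    "class": cls,
                    "n_consensus": n_total,
                    "n_de": stats["n_de"],
                    "n_up_fed": stats["n_up_fed"],
                    "n_up_unfed": stats["n_up_unfed"],
                    "pct_de": de_summary(stats["n_de"], n_total),
                    "dispersion": phi,
                }
            )
    _write_tsv(pd.DataFrame(summary_rows), outdir / "de_summary.tsv")


def stage_targets(outdir: Path, cfg: Mapping[str, Any]) -> None:
    lncrnas = read_transcripts(outdir / "consensus_lncrna.fasta")
    mirnas = read_mirnas(outdir / "mirnas.fasta")
    sites, counts = predict_targets(mirnas, lncrnas, _params(cfg))
    _write_tsv(pd.DataFrame(sites_table_rows(sites)), outdir / "target_sites.tsv")
    _write_tsv(counts, outdir / "target_counts.tsv", index=True)


def stage_null(outdir: Path, cfg: Mapping[str, Any]) -> None:
    lncrnas = read_transcripts(outdir / "consensus_lncrna.fasta")
    mirnas = read_mirnas(outdir / "mirnas.fasta")
    nulls = build_null(
        lncrnas,
        mirnas,
        cfg["n_null_replicates"],
        cfg["seed"],
        _params(cfg),
        cfg["shuffle_mode"],
    )
    long = pd.concat(
        [m.assign(replicate=r, mirna_id=m.index) for r, m in enumerate(nulls)],
        ignore_index=True,
    )
    _write_tsv(long, outdir / "null_counts.tsv")


def _read_null(outdir: Path) -> list[pd.DataFrame]:
    long = pd.read_csv(outdir / "null_counts.tsv", sep="\t")
    out = []
    for _, sub in long.groupby("replicate", sort=True):
        out.append(
            sub.set_index("mirna_id").drop(columns="replicate").astype(np.int64)
        )
    return out


def stage_sponge(outdir: Path, cfg: Mapping[str, Any]) -> None:
    counts = pd.read_csv(outdir / "target_counts.tsv", sep="\t", index_col=0)
    lncrnas = read_transcripts(outdir / "consensus_lncrna.fasta")
    lengths = pd.Series({r.id: r.length for r in lncrnas})
    nulls = _read_null(outdir)
    itemsets = mine_itemsets(counts, cfg["min_support"])
    itemsets = itemset_significance(itemsets, nulls)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "mirnas": ",".join(r.items),
                    "size": len(r.items),
                    "support": r.support,
                    "empirical_p": r.empirical_p,
                    "fdr": r.fdr,
                    "lncrnas": ",".join(r.supporting_lncrnas),
                }
                for r in itemsets
            ]
        ),
        outdir / "itemsets.tsv",
    )
    candidates = select_sponge_candidates(
        counts, lengths, nulls, itemsets, cfg["max_groups"], cfg["alpha"]
    )
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "approach": c.approach,
                    "lncrnas": ",".join(c.lncrna_ids),
                    "mirnas": ",".join(c.mirna_ids),
                    "score": c.score,
                    "null_comparison": c.null_comparison,
                }
                for c in candidates
            ]
        ),
        outdir / "sponge_candidates.tsv",
    )
    de_by_tissue = {}
    samples = pd.read_csv(outdir / "samples.tsv", sep="\t", index_col=0)
    for tissue in sorted(samples["tissue"].unique()):
        path = outdir / f"de_{tissue}.tsv"
        if path.exists():
            de_by_tissue[tissue] = pd.read_csv(path, sep="\t", index_col=0)
    _write_tsv(
        candidate_log2fc_table(candidates, de_by_tissue),
        outdir / "candidate_log2fc.tsv",
    )
    # per-tissue miRNA prioritization by feeding-regulated target load
    for tissue, de in de_by_tissue.items():
        lnc_de = de[de["class"] == "lncRNA"] if "class" in de.columns else de
        up_fed = [i for i in lnc_de.index[lnc_de["direction"] == "up_fed"]
                  if i in counts.columns]
        up_unfed = [i for i in lnc_de.index[lnc_de["direction"] == "up_unfed"]
                    if i in counts.columns]
        ratio = normalized_target_ratio(
            counts[up_fed].sum(axis=1), counts[up_unfed].sum(axis=1)
        )
        _write_tsv(ratio, outdir / f"mirna_ratio_{tissue}.tsv", index=True)


def stage_report(outdir: Path, cfg: Mapping[str, Any]) -> None:
    records, classes, lengths = _read_consensus(outdir)
    counts = pd.read_csv(outdir / "counts.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(outdir / "samples.tsv", sep="\t", index_col=0)
    factors = pd.read_csv(outdir / "tmm_factors.tsv", sep="\t", index_col=0)[
        "tmm_factor"
    ]
    eff = counts.sum(axis=0) * factors
    normalized = counts / eff * float(np.exp(np.log(eff).mean()))
    share, per_condition = expression_share(normalized, classes, samples)
    per_condition.rename("lncrna_share").to_csv(
        outdir / "expression_share.tsv", sep="\t"
    )
    hist = length_histogram(
        [r.length for r in records if classes[r.id] == "lncRNA"],
        cfg["length_bin_width"],
    )
    hist.rename("count").to_csv(outdir / "length_histogram_lncrna.tsv", sep="\t")


STAGES = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "cluster": stage_cluster,
    "consensus": stage_consensus,
    "express": stage_express,
    "de": stage_de,
    "targets": stage_targets,
    "null": stage_null,
    "sponge": stage_sponge,
    "report": stage_report,
}


def run_pipeline(config: str | Path | Mapping[str, Any] | None, outdir: str | Path) -> Path:
    """Run every stage in order into ``outdir``; returns the directory."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_config.json", "w") as fh:
        json.dump({"version": __version__, "config": cfg}, fh, indent=2, default=str)
    for name, stage in STAGES.items():
        logger.info("stage %s", name)
        stage(outdir, cfg)
    return outdir
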