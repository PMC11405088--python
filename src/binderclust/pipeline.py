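"""Two-stage pipeline drivers: clustering, then ranking/visualization.

``run_cluster`` goes load -> ipTM gate -> PAE trim -> sequence +
structure clustering -> joint merge -> per-cluster all-vs-all ->
representative selection -> CSV tables.  ``run_rank`` consumes its
outputs: ranking table, per-cluster viewer directories, optional fold
subclustering of the top clusters.  Both write a run manifest (full
config echo + stage counts) so every run is reproducible and
auditable, and neither mutates its input directory.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from binderclust import afm_io, clustering, ranking, trimming
from binderclust.afm_io import ChainStructure
from binderclust.pairwise_align import AlignmentTable, all_vs_all

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage could not proceed; the message says why and what to try."""


@dataclass
class PipelineConfig:
    """All tunable parameters of both stages, with their defaults."""

    models_dir: str = ""
    out_dir: str = ""
    iptm_threshold: float = 0.75
    pae_cutoff: float = trimming.DEFAULT_PAE_CUTOFF
    pad: int = trimming.DEFAULT_PAD
    max_gap: int = trimming.DEFAULT_MAX_GAP
    min_segment: int = trimming.DEFAULT_MIN_SEGMENT
    min_id: float = clustering.DEFAULT_MIN_SEQ_ID
    seq_min_cov: float = clustering.DEFAULT_SEQ_MIN_COV
    min_tm: float = clustering.DEFAULT_MIN_TM
    struct_min_cov: float = clustering.DEFAULT_STRUCT_MIN_COV
    min_cluster_size: int = clustering.DEFAULT_MIN_CLUSTER_SIZE
    top_n: int = ranking.DEFAULT_TOP_N
    subcluster_min_tm: float = ranking.DEFAULT_SUBCLUSTER_MIN_TM
    do_subcluster: bool = False
    cpus: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cpus < 1:
            raise ValueError("cpus must be >= 1")
        if not 0.0 <= self.iptm_threshold <= 1.0:
            raise ValueError("iptm_threshold outside [0, 1]")


def _write_manifest(out_dir: Path, stage: str, config: PipelineConfig, counts: dict) -> None:
    from binderclust import __version__

    payload = {
        "stage": stage,
        "version": __version__,
        "config": asdict(config),
        "counts": counts,
    }
    with open(out_dir / f"run_manifest_{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=1)


def run_cluster(config: PipelineConfig) -> dict:
    """Run the clustering stage; returns the stage counts."""
    t0 = time.monotonic()
    models_dir = Path(config.models_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = afm_io.load_screen(models_dir)
    logger.info("loaded %d complexes from %s", len(records), models_dir)

    gated = trimming.filter_by_iptm(records, config.iptm_threshold)
    logger.info(
        "%d/%d complexes at ipTM >= %.2f", len(gated), len(records), config.iptm_threshold
    )
    if not gated:
        raise PipelineError(
            f"no complexes passed the ipTM threshold {config.iptm_threshold}; "
            "consider lowering --iptm_threshold"
        )

    trimmed = []
    discarded = []
    for rec in gated:
        tc = trimming.trim_complex(
            rec,
            pae_cutoff=config.pae_cutoff,
            pad=config.pad,
            max_gap=config.max_gap,
            min_segment=config.min_segment,
        )
        if tc is None:
            discarded.append(
                {"complex_id": rec.complex_id,
                 "reason": f"no confident region at PAE cutoff {config.pae_cutoff}"}
            )
        else:
            trimmed.append(tc)
    logger.info("trimmed %d complexes (%d discarded)", len(trimmed), len(discarded))
    with open(out_dir / "discarded.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["complex_id", "reason"])
        writer.writeheader()
        writer.writerows(sorted(discarded, key=lambda r: r["complex_id"]))
    if not trimmed:
        raise PipelineError(
            f"no complexes retained any confident region at PAE cutoff "
            f"{config.pae_cutoff}; consider raising --pae_cutoff"
        )

    trimmed_dir = out_dir / "trimmed"
    trimmed_dir.mkdir(exist_ok=True)
    for tc in trimmed:
        trimming.write_trimmed_pdb(tc, trimmed_dir / f"{tc.complex_id}.pdb")
    trimming.write_trimmed_fasta(trimmed, out_dir / "trimmed_targets.fasta")

    seqs = {tc.complex_id: tc.target_trimmed.sequence for tc in trimmed}
    seq_part = clustering.cluster_sequences(
        seqs, min_id=config.min_id, min_cov=config.seq_min_cov
    )
    targets = {tc.complex_id: tc.target_trimmed for tc in trimmed}
    struct_part = clustering.cluster_structures(
        targets, min_tm=config.min_tm, min_cov=config.struct_min_cov
    )
    merged = clustering.merge_partitions(seq_part, struct_part)
    logger.info(
        "clusters: %d sequence, %d structure, %d merged",
        seq_part.n_clusters, struct_part.n_clusters, merged.n_clusters,
    )

    pairwise_dir = out_dir / "pairwise"
    pairwise_dir.mkdir(exist_ok=True)
    by_id = {tc.complex_id: tc for tc in trimmed}
    medians: dict[str, tuple[float | None, float | None]] = {}
    summaries: dict[str, clustering.ClusterSummary] = {}
    for label, members in merged.clusters().items():
        if len(members) < 2:
            summaries[label] = clustering.summarize_cluster(label, members, None)
            medians[members[0]] = (None, None)
            continue
        table = all_vs_all([by_id[m] for m in members], cpus=config.cpus)
        table.save(
            pairwise_dir / f"{label}.csv", pairwise_dir / f"{label}_transforms.json"
        )
        summaries[label] = clustering.summarize_cluster(label, members, table)
        medians.update(clustering.member_medians(members, table))

    records_by_id = {rec.complex_id: rec for rec in gated}
    clustering.write_cluster_tables(
        records_by_id, seq_part, struct_part, merged, medians, summaries, out_dir
    )
    _write_summaries_csv(summaries, out_dir / "cluster_summaries.csv")

    counts = {
        "loaded": len(records),
        "passed_iptm": len(gated),
        "trimmed": len(trimmed),
        "discarded": len(discarded),
        "seq_clusters": seq_part.n_clusters,
        "struct_clusters": struct_part.n_clusters,
        "merged_clusters": merged.n_clusters,
    }
    _write_manifest(out_dir, "cluster", config, counts)
    logger.info("clustering stage finished in %.1f s", time.monotonic() - t0)
    return counts


def _write_summaries_csv(summaries: dict, path: Path) -> None:
    rows = []
    for label in sorted(summaries):
        s = summaries[label]
        rows.append(
            {
                "label": s.label,
                "size": s.size,
                "representative": s.representative,
                "median_rmsd": "" if s.median_rmsd is None else f"{s.median_rmsd:.4f}",
                "median_tm": "" if s.median_tm is None else f"{s.median_tm:.4f}",
                "rep_coverage": "" if s.rep_coverage is None else f"{s.rep_coverage:.4f}",
                "members": ";".join(s.members),
            }
        )
    pd.DataFrame(
        rows,
        columns=["label", "size", "representative", "median_rmsd", "median_tm",
                 "rep_coverage", "members"],
    ).to_csv(path, index=False)


def _load_summaries(path: Path) -> list[clustering.ClusterSummary]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            clustering.ClusterSummary(
                label=str(row.label),
                members=str(row.members).split(";"),
                representative=str(row.representative),
                median_rmsd=float(row.median_rmsd) if row.median_rmsd != "" else None,
                median_tm=float(row.median_tm) if row.median_tm != "" else None,
                rep_coverage=float(row.rep_coverage) if row.rep_coverage != "" else None,
            )
        )
    return out


def _combined_chain(pdb_path: Path) -> ChainStructure:
    """Bait+target CA traces of a trimmed complex as one chain, so that
    subclustering separates binding poses, not just target folds."""
    import numpy as np

    chains = afm_io.read_chains(pdb_path)
    return ChainStructure(
        chain_id="X",
        sequence="".join(c.sequence for c in chains),
        ca_coords=np.concatenate([c.ca_coords for c in chains]),
        residue_numbers=np.arange(1, sum(len(c) for c in chains) + 1),
    )


def run_rank(config: PipelineConfig) -> dict:
    """Run the ranking/visualization stage; returns the stage counts."""
    t0 = time.monotonic()
    out_dir = Path(config.out_dir)
    summaries_csv = out_dir / "cluster_summaries.csv"
    merged_csv = out_dir / "merged_clusters" / "merged_clusters.csv"
    for needed in (summaries_csv, merged_csv):
        if not needed.exists():
            raise PipelineError(
                f"missing clustering output {needed}; run the cluster stage first"
            )

    summaries = _load_summaries(summaries_csv)
    ranked = ranking.rank_clusters(summaries, min_cluster_size=config.min_cluster_size)
    ranking.write_ranking_csv(ranked, out_dir / "ranking.csv")
    logger.info(
        "%d/%d clusters ranked (min size %d)",
        len(ranked), len(summaries), config.min_cluster_size,
    )

    pairwise_dir = out_dir / "pairwise"
    tables: dict[str, AlignmentTable] = {}
    for r in ranked[: config.top_n]:
        label = r.summary.label
        csv_path = pairwise_dir / f"{label}.csv"
        if csv_path.exists():
            tables[label] = AlignmentTable.load(
                csv_path, pairwise_dir / f"{label}_transforms.json"
            )
    cluster_dirs = ranking.write_viewer_sessions(
        ranked, tables, out_dir / "trimmed", out_dir, top_n=config.top_n
    )

    n_subclustered = 0
    if config.do_subcluster:
        for r, cdir in zip(ranked[: config.top_n], cluster_dirs):
            members = {
                m: _combined_chain(out_dir / "trimmed" / f"{m}.pdb")
                for m in r.summary.members
            }
            part = ranking.subcluster(
                r.summary, members, min_tm=config.subcluster_min_tm
            )
            if part is not None:
                ranking.write_subclusters_csv(part, cdir / "subclusters.csv")
                n_subclustered += 1

    counts = {
        "clusters_ranked": len(ranked),
        "viewer_sessions": len(cluster_dirs),
        "subclustered": n_subclustered,
    }
    _write_manifest(out_dir, "rank", config, counts)
    logger.info("ranking stage finished in %.1f s", time.monotonic() - t0)
    return counts
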