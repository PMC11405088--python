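"""Cluster ranking, optional fold subclustering, and viewer sessions.

Clusters are ranked lexicographically: size descending, then the
representative's median RMSD ascending, then median TM descending,
then representative coverage descending, then label.  A large cluster
of consistently superposable targets is the signature of a true
binder family; singletons and near-singletons (below
``min_cluster_size``) are excluded because a binder without homologs
in the screen cannot form a supporting cluster.

Subclustering re-runs fold clustering *within* a top cluster at a
stricter TM threshold, on the whole trimmed complex (bait + target)
rather than the target alone, so distinct binding poses of the same
target topology separate.

Viewer sessions are plain-text PyMOL command scripts (deterministic
and diffable), one per top cluster, that load every member, apply the
stored member-onto-representative superposition, color baits blue and
targets gray, and group the objects.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from binderclust.afm_io import ChainStructure
from binderclust.clustering import ClusterSummary, Partition, cluster_structures
from binderclust.pairwise_align import AlignmentTable

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 5
DEFAULT_SUBCLUSTER_MIN_TM = 0.7

_INF = float("inf")


@dataclass
class RankedCluster:
    summary: ClusterSummary
    rank: int

    @property
    def score_components(self) -> dict[str, float | None]:
        s = self.summary
        return {
            "size": s.size,
            "median_tm": s.median_tm,
            "median_rmsd": s.median_rmsd,
            "rep_coverage": s.rep_coverage,
        }


def _rank_key(s: ClusterSummary) -> tuple:
    return (
        -s.size,
        s.median_rmsd if s.median_rmsd is not None else _INF,
        -(s.median_tm if s.median_tm is not None else -_INF),
        -(s.rep_coverage if s.rep_coverage is not None else -_INF),
        s.label,
    )


def rank_clusters(
    summaries: list[ClusterSummary],
    min_cluster_size: int = 4,
    weights: Mapping[str, float] | None = None,
) -> list[RankedCluster]:
    """Total ordering of clusters of at least ``min_cluster_size``.

    Default comparator: size desc, median RMSD asc, median TM desc,
    representative coverage desc, label asc.  Passing ``weights``
    (keys ``size``, ``median_tm``, ``median_rmsd``, ``rep_coverage``)
    switches to a weighted composite score instead (higher = better;
    the RMSD weight enters negatively), with the label as final
    tie-break.
    """
    eligible = [s for s in summaries if s.size >= min_cluster_size]
    if weights is None:
        ordered = sorted(eligible, key=_rank_key)
    else:
        def composite(s: ClusterSummary) -> float:
            return (
                weights.get("size", 0.0) * s.size
                + weights.get("median_tm", 0.0) * (s.median_tm or 0.0)
                - weights.get("median_rmsd", 0.0) * (s.median_rmsd or 0.0)
                + weights.get("rep_coverage", 0.0) * (s.rep_coverage or 0.0)
            )
        ordered = sorted(eligible, key=lambda s: (-composite(s), s.label))
    return [RankedCluster(summary=s, rank=i + 1) for i, s in enumerate(ordered)]


def write_ranking_csv(ranked: list[RankedCluster], path: str | Path) -> None:
    rows = []
    for r in ranked:
        s = r.summary
        rows.append(
            {
                "rank": r.rank,
                "label": s.label,
                "size": s.size,
                "median_rmsd": "" if s.median_rmsd is None else f"{s.median_rmsd:.4f}",
                "median_tm": "" if s.median_tm is None else f"{s.median_tm:.4f}",
                "rep_coverage": "" if s.rep_coverage is None else f"{s.rep_coverage:.4f}",
                "representative": s.representative,
            }
        )
    pd.DataFrame(
        rows,
        columns=["rank", "label", "size", "median_rmsd", "median_tm",
                 "rep_coverage", "representative"],
    ).to_csv(path, index=False)


def subcluster(
    summary: ClusterSummary,
    members: Mapping[str, ChainStructure],
    min_tm: float = DEFAULT_SUBCLUSTER_MIN_TM,
) -> Partition | None:
    """Fold clustering within one cluster at a stricter TM threshold.

    ``members`` maps each member id to the structure to compare --
    pass the concatenated bait+target trace to separate binding poses,
    or the target alone to separate target folds.  Returns ``None``
    (logged) for clusters of fewer than two members.
    """
    if summary.size < 2:
        logger.info("cluster %s has < 2 members; skipping subclustering", summary.label)
        return None
    subset = {cid: members[cid] for cid in summary.members}
    return cluster_structures(subset, min_tm=min_tm)


def write_subclusters_csv(partition: Partition, path: str | Path) -> None:
    pd.DataFrame(
        sorted(
            ({"complex_id": cid, "subcluster": lab} for cid, lab in partition.label_of.items()),
            key=lambda r: (r["subcluster"], r["complex_id"]),
        )
    ).to_csv(path, index=False)


def _matrix_line(obj: str, rotation: np.ndarray, translation: np.ndarray) -> str:
    r = np.asarray(rotation)
    t = np.asarray(translation)
    flat = [
        r[0, 0], r[0, 1], r[0, 2], t[0],
        r[1, 0], r[1, 1], r[1, 2], t[1],
        r[2, 0], r[2, 1], r[2, 2], t[2],
        0.0, 0.0, 0.0, 1.0,
    ]
    numbers = ", ".join(f"{v:.6f}" for v in flat)
    return f"transform_selection {obj}, [{numbers}], homogenous=1"


def write_viewer_sessions(
    ranked: list[RankedCluster],
    tables: Mapping[str, AlignmentTable],
    trimmed_dir: str | Path,
    out_dir: str | Path,
    top_n: int = DEFAULT_TOP_N,
    bait_chain: str = "A",
    target_chain: str = "B",
) -> list[Path]:
    """Per-cluster directories with member PDBs and a viewer script.

    For each of the top ``top_n`` clusters, writes
    ``rank{r}_{label}/`` containing the members' trimmed coordinate
    files and ``view_cluster.pml``: loads the representative first and
    the remaining members in sorted order, superposes each member's
    target onto the representative's via the stored pairwise
    transform, colors bait chains blue and target chains gray, and
    groups the objects.
    """
    trimmed_dir = Path(trimmed_dir)
    out_dir = Path(out_dir)
    written: list[Path] = []
    for r in ranked[:top_n]:
        s = r.summary
        cdir = out_dir / f"rank{r.rank}_{s.label}"
        cdir.mkdir(parents=True, exist_ok=True)
        table = tables.get(s.label)
        ordered = [s.representative] + [m for m in sorted(s.members) if m != s.representative]
        lines = [f"# cluster {s.label}: rank {r.rank}, {s.size} members"]
        for member in ordered:
            src = trimmed_dir / f"{member}.pdb"
            shutil.copyfile(src, cdir / f"{member}.pdb")
            lines.append(f"load {member}.pdb, {member}")
            if member != s.representative and table is not None:
                res = table.result_for(s.representative, member)
                if res.superposition is not None:
                    # maps the member's target trace onto the representative's
                    lines.append(
                        _matrix_line(member, res.superposition.rotation,
                                     res.superposition.translation)
                    )
            lines.append(f"color blue, {member} and chain {bait_chain}")
            lines.append(f"color gray80, {member} and chain {target_chain}")
        lines.append(f"group cluster_{s.label}, {' '.join(ordered)}")
        lines.append("")
        script = cdir / "view_cluster.pml"
        script.write_text("\n".join(lines))
        written.append(cdir)
    return written
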