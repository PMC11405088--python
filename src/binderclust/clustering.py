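"""Sequence clustering, fold clustering, joint merging and
representative selection for trimmed screen targets.

Both clusterings are greedy-incremental: members are visited by
(length descending, id ascending), each joining the first existing
cluster whose founder it matches (sequence identity + coverage, or
TM-score + coverage), else founding a new cluster.  The longest member
of a family therefore founds its cluster, and the procedure is fully
deterministic.

Sequence clusters and structure clusters are then merged into joint
clusters: two complexes share a joint cluster iff their clusters are
connected in the bipartite graph whose edges join a sequence cluster
and a structure cluster sharing at least one member.  This catches
remote homologs that only one of the two criteria groups together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from binderclust.afm_io import ChainStructure, ComplexRecord, ValidationError
from binderclust.pairwise_align import (
    AlignmentTable,
    alignment_identity_coverage,
    structural_align,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_SEQ_ID = 0.30
DEFAULT_SEQ_MIN_COV = 0.8
DEFAULT_MIN_TM = 0.5
DEFAULT_STRUCT_MIN_COV = 0.8
DEFAULT_MIN_CLUSTER_SIZE = 4


@dataclass
class Partition:
    """A labeled clustering of complex ids (a partition, not a cover)."""

    label_of: dict[str, str]
    kind: str  # "sequence" | "structure" | "merged"

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cid, label in self.label_of.items():
            out.setdefault(label, []).append(cid)
        return {label: sorted(members) for label, members in sorted(out.items())}

    @property
    def n_clusters(self) -> int:
        return len(set(self.label_of.values()))


@dataclass
class ClusterSummary:
    """Size, representative and the representative's median alignment
    statistics for one (usually merged) cluster.

    Medians are ``None`` for singletons -- never zero-filled.
    ``rep_coverage`` is the representative's median pairwise alignment
    coverage against the other members.
    """

    label: str
    members: list[str]
    representative: str
    median_rmsd: float | None
    median_tm: float | None
    rep_coverage: float | None

    @property
    def size(self) -> int:
        return len(self.members)


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} outside [0, 1]")


def _greedy_cluster(
    ordered_ids: list[str],
    matches_founder,
) -> dict[str, str]:
    founders: list[str] = []
    label_of: dict[str, str] = {}
    for cid in ordered_ids:
        for rep in founders:
            if matches_founder(rep, cid):
                label_of[cid] = rep
                break
        else:
            founders.append(cid)
            label_of[cid] = cid
    return label_of


def cluster_sequences(
    seqs: Mapping[str, str],
    min_id: float = DEFAULT_MIN_SEQ_ID,
    min_cov: float = DEFAULT_SEQ_MIN_COV,
) -> Partition:
    """Greedy sequence clustering of trimmed target sequences.

    A sequence joins the first founder with global-alignment identity
    >= ``min_id`` (matches / alignment columns, gaps counted) and
    bidirectional span coverage >= ``min_cov``.
    """
    _check_fraction("min_id", min_id)
    _check_fraction("min_cov", min_cov)
    if not seqs:
        raise ValueError("cluster_sequences: empty input")
    order = sorted(seqs, key=lambda cid: (-len(seqs[cid]), cid))

    def matches(rep: str, cid: str) -> bool:
        ident, cov_a, cov_b = alignment_identity_coverage(seqs[rep], seqs[cid])
        return ident >= min_id and cov_a >= min_cov and cov_b >= min_cov

    return Partition(label_of=_greedy_cluster(order, matches), kind="sequence")


def cluster_structures(
    targets: Mapping[str, ChainStructure],
    min_tm: float = DEFAULT_MIN_TM,
    min_cov: float = DEFAULT_STRUCT_MIN_COV,
) -> Partition:
    """Greedy fold clustering of trimmed target structures.

    A structure joins the first founder against which the pairwise
    alignment gives a TM-score (normalized by the shorter chain) >=
    ``min_tm`` and coverage >= ``min_cov``.
    """
    _check_fraction("min_tm", min_tm)
    _check_fraction("min_cov", min_cov)
    if not targets:
        raise ValueError("cluster_structures: empty input")
    order = sorted(targets, key=lambda cid: (-len(targets[cid]), cid))

    def matches(rep: str, cid: str) -> bool:
        res = structural_align(targets[rep], targets[cid])
        if not res.defined:
            return False
        tm_shorter = res.tm_1 if len(targets[rep]) <= len(targets[cid]) else res.tm_2
        return tm_shorter >= min_tm and res.coverage >= min_cov

    return Partition(label_of=_greedy_cluster(order, matches), kind="structure")


def merge_partitions(seq: Partition, struct: Partition) -> Partition:
    """Merge sequence and structure clusters into joint clusters.

    Two ids share a merged label iff their clusters are connected in
    the bipartite sequence-cluster / structure-cluster graph (edges
    join clusters sharing >= 1 id).  Merged labels are named after the
    lexicographically smallest member id.
    """
    if set(seq.label_of) != set(struct.label_of):
        raise ValidationError("merge_partitions: partitions cover different id sets")
    graph = nx.Graph()
    for cid in seq.label_of:
        graph.add_edge(("seq", seq.label_of[cid]), ("struct", struct.label_of[cid]))
    label_of: dict[str, str] = {}
    for component in nx.connected_components(graph):
        seq_labels = {lab for kind, lab in component if kind == "seq"}
        members = sorted(cid for cid, lab in seq.label_of.items() if lab in seq_labels)
        label = members[0]
        for cid in members:
            label_of[cid] = label
    return Partition(label_of=label_of, kind="merged")


def member_medians(
    members: list[str], table: AlignmentTable
) -> dict[str, tuple[float | None, float | None]]:
    """Per-member median RMSD and TM against the other members.

    TM is normalized by the member whose median is computed.  Pairs
    with undefined statistics are excluded; a member with no defined
    pair gets ``(None, None)``.
    """
    out: dict[str, tuple[float | None, float | None]] = {}
    for m in members:
        rmsds, tms = [], []
        for other in members:
            if other == m:
                continue
            res = table.result_for(m, other)
            if res.defined:
                rmsds.append(res.rmsd)
                tms.append(res.tm_1)
        if rmsds:
            out[m] = (float(np.median(rmsds)), float(np.median(tms)))
        else:
            out[m] = (None, None)
    return out


def select_representative(
    members: list[str], table: AlignmentTable
) -> tuple[str, dict[str, tuple[float | None, float | None]]]:
    """The member with the lowest median RMSD against the others.

    Ties break toward higher median TM, then the lexicographically
    smaller id.  A member with no defined pairwise result cannot be
    representative.
    """
    if len(members) < 2:
        raise ValueError("select_representative needs >= 2 members")
    medians = member_medians(members, table)
    candidates = [m for m in members if medians[m][0] is not None]
    if not candidates:
        raise ValueError("no member has a defined median RMSD")
    rep = min(candidates, key=lambda m: (medians[m][0], -medians[m][1], m))
    return rep, medians


def rep_median_coverage(rep: str, members: list[str], table: AlignmentTable) -> float:
    covs = [table.result_for(rep, m).coverage for m in members if m != rep]
    return float(np.median(covs))


def summarize_cluster(
    label: str, members: list[str], table: AlignmentTable | None
) -> ClusterSummary:
    members = sorted(members)
    if len(members) == 1 or table is None:
        return ClusterSummary(
            label=label, members=members, representative=members[0],
            median_rmsd=None, median_tm=None, rep_coverage=None,
        )
    rep, medians = select_representative(members, table)
    return ClusterSummary(
        label=label,
        members=members,
        representative=rep,
        median_rmsd=medians[rep][0],
        median_tm=medians[rep][1],
        rep_coverage=rep_median_coverage(rep, members, table),
    )


def _fmt(value: float | None, spec: str = ".4f") -> str:
    return "" if value is None else format(value, spec)


def write_cluster_tables(
    records: Mapping[str, ComplexRecord],
    seq_part: Partition,
    struct_part: Partition,
    merged_part: Partition,
    medians: Mapping[str, tuple[float | None, float | None]],
    summaries: Mapping[str, ClusterSummary],
    out_dir: str | Path,
) -> Path:
    """Write the clustering-stage CSV tables.

    ``merged_clusters/merged_clusters.csv`` lists every complex with
    its AlphaFold confidences, its three cluster labels, its median
    RMSD/TM within the merged cluster and a representative flag, sorted
    by (merged cluster size descending, merged label, complex id).
    ``sequence_clusters.csv`` and ``structure_clusters.csv`` hold the
    single-criterion partitions.  Missing medians are empty fields.
    Returns the merged-clusters CSV path.
    """
    out_dir = Path(out_dir)
    merged_dir = out_dir / "merged_clusters"
    merged_dir.mkdir(parents=True, exist_ok=True)
    cluster_size = {
        label: len(members) for label, members in merged_part.clusters().items()
    }
    rows = []
    for cid in merged_part.label_of:
        mlabel = merged_part.label_of[cid]
        med_rmsd, med_tm = medians.get(cid, (None, None))
        rows.append(
            {
                "complex_id": cid,
                "iptm": _fmt(records[cid].scores.iptm),
                "iptm_ptm": _fmt(records[cid].scores.combined),
                "seq_cluster": seq_part.label_of[cid],
                "struct_cluster": struct_part.label_of[cid],
                "merged_cluster": mlabel,
                "median_rmsd": _fmt(med_rmsd),
                "median_tm": _fmt(med_tm),
                "is_representative": str(summaries[mlabel].representative == cid),
                "_size": cluster_size[mlabel],
            }
        )
    rows.sort(key=lambda r: (-r["_size"], r["merged_cluster"], r["complex_id"]))
    df = pd.DataFrame(rows).drop(columns=["_size"])
    merged_csv = merged_dir / "merged_clusters.csv"
    df.to_csv(merged_csv, index=False)
    for part, name in ((seq_part, "sequence_clusters.csv"), (struct_part, "structure_clusters.csv")):
        simple = pd.DataFrame(
            sorted(
                ({"complex_id": cid, "cluster": lab} for cid, lab in part.label_of.items()),
                key=lambda r: (r["cluster"], r["complex_id"]),
            )
        )
        simple.to_csv(out_dir / name, index=False)
    return merged_csv
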