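import itertools

import numpy as np
import pytest

from binderclust import (
    ChainStructure,
    cluster_sequences,
    cluster_structures,
    make_fold,
    merge_partitions,
    select_representative,
    write_cluster_tables,
)
from binderclust.clustering import Partition, summarize_cluster
from binderclust.pairwise_align import AlignmentResult, AlignmentTable, Superposition

AA = "ACDEFGHIKLMNPQRSTVWY"


def _mutate(rng, seq, rate):
    out = []
    for aa in seq:
        if rng.random() < rate:
            out.append(rng.choice([c for c in AA if c != aa]))
        else:
            out.append(aa)
    return "".join(out)


def _table(rmsds: dict, tms: dict | None = None, lengths=None, ids=None):
    """Build an AlignmentTable from hand-specified pairwise values."""
    ids = ids or sorted({i for pair in rmsds for i in pair})
    lengths = lengths or {i: 50 for i in ids}
    results = {}
    for (i, j), rmsd in rmsds.items():
        i, j = sorted((i, j))
        tm = (tms or {}).get((i, j), 0.8)
        results[(i, j)] = AlignmentResult(
            rmsd=rmsd, tm_1=tm, tm_2=tm, coverage=1.0, n_pairs=lengths[i],
            superposition=Superposition.identity(),
        )
    return AlignmentTable(lengths=lengths, results=results)


class TestClusterSequences:
    def test_identical_sequences_form_one_cluster(self):
        seqs = {f"s{i}": "MKTAYIAKQRQISFVK" for i in range(5)}
        part = cluster_sequences(seqs)
        assert part.n_clusters == 1

    def test_two_families_separate(self, rng):
        fam_a = "".join(rng.choice(list(AA), size=50))
        fam_b = "".join(rng.choice(list(AA), size=50))
        seqs = {}
        for i in range(4):
            seqs[f"a{i}"] = _mutate(rng, fam_a, 0.1)
            seqs[f"b{i}"] = _mutate(rng, fam_b, 0.1)
        part = cluster_sequences(seqs, min_id=0.3)
        assert part.n_clusters == 2
        labels_a = {part.label_of[f"a{i}"] for i in range(4)}
        labels_b = {part.label_of[f"b{i}"] for i in range(4)}
        assert len(labels_a) == 1 and len(labels_b) == 1 and labels_a != labels_b

    def test_full_identity_threshold_gives_singletons(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list(AA), size=30)) for i in range(5)}
        part = cluster_sequences(seqs, min_id=1.0)
        assert part.n_clusters == 5

    def test_parameter_range(self):
        with pytest.raises(ValueError):
            cluster_sequences({"a": "ACD"}, min_id=1.5)


class TestClusterStructures:
    def _noisy_copies(self, rng, fold, seq, n, sigma=0.3, prefix="m"):
        out = {}
        for i in range(n):
            coords = fold + rng.normal(scale=sigma, size=fold.shape)
            out[f"{prefix}{i}"] = ChainStructure(
                "B", seq, coords, np.arange(1, len(fold) + 1)
            )
        return out

    def test_rigid_copies_cluster_together(self, rng):
        from scipy.spatial.transform import Rotation

        fold = make_fold(0, 35)
        seq = "".join(rng.choice(list(AA), size=35))
        targets = {}
        for i in range(4):
            q = rng.normal(size=4)
            R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
            targets[f"m{i}"] = ChainStructure(
                "B", seq, fold @ R.T + rng.normal(size=3) * 10, np.arange(1, 36)
            )
        assert cluster_structures(targets).n_clusters == 1

    def test_two_fold_families_separate(self, rng):
        seq1 = "".join(rng.choice(list(AA), size=40))
        seq2 = "".join(rng.choice(list(AA), size=40))
        targets = self._noisy_copies(rng, make_fold(0, 40), seq1, 3, prefix="helix")
        targets.update(self._noisy_copies(rng, make_fold(1, 40), seq2, 3, prefix="hairpin"))
        part = cluster_structures(targets, min_tm=0.5)
        assert part.n_clusters == 2

    def test_extreme_threshold_gives_singletons(self, rng):
        fold = make_fold(0, 30)
        seq = "".join(rng.choice(list(AA), size=30))
        targets = self._noisy_copies(rng, fold, seq, 4, sigma=0.5)
        assert cluster_structures(targets, min_tm=0.999).n_clusters == 4


class TestMergePartitions:
    def test_minimal_chain_merge(self):
        seq = Partition({"A": "A", "B": "A", "C": "C"}, "sequence")
        struct = Partition({"A": "A", "B": "B", "C": "B"}, "structure")
        merged = merge_partitions(seq, struct)
        assert merged.clusters() == {"A": ["A", "B", "C"]}

    def test_identical_partitions_unchanged(self):
        seq = Partition({"A": "x", "B": "x", "C": "y"}, "sequence")
        struct = Partition({"A": "x2", "B": "x2", "C": "y2"}, "structure")
        merged = merge_partitions(seq, struct)
        assert merged.clusters() == {"A": ["A", "B"], "C": ["C"]}

    def test_id_universe_mismatch_rejected(self):
        with pytest.raises(ValueError):
            merge_partitions(
                Partition({"A": "x"}, "sequence"), Partition({"B": "y"}, "structure")
            )

    def test_random_partitions_match_transitive_closure(self, rng):
        ids = [f"id{i:02d}" for i in range(30)]
        for _ in range(20):
            seq = Partition({i: f"s{rng.integers(6)}" for i in ids}, "sequence")
            struct = Partition({i: f"t{rng.integers(6)}" for i in ids}, "structure")
            merged = merge_partitions(seq, struct)
            assert _partition_sets(merged) == _closure_oracle(seq, struct)

    def test_merged_coarsens_both_and_bounds_cluster_count(self, rng):
        ids = [f"id{i}" for i in range(25)]
        seq = Partition({i: f"s{rng.integers(5)}" for i in ids}, "sequence")
        struct = Partition({i: f"t{rng.integers(5)}" for i in ids}, "structure")
        merged = merge_partitions(seq, struct)
        for part in (seq, struct):
            for members in part.clusters().values():
                assert len({merged.label_of[m] for m in members}) == 1
        assert 1 <= merged.n_clusters <= min(seq.n_clusters, struct.n_clusters)


def _partition_sets(partition):
    return {frozenset(m) for m in partition.clusters().values()}


def _closure_oracle(seq, struct):
    """Repeated pairwise union of overlapping clusters until fixpoint."""
    groups = [set(m) for m in seq.clusters().values()]
    groups += [set(m) for m in struct.clusters().values()]
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(groups)), 2):
            if groups[a] and groups[b] and groups[a] & groups[b]:
                groups[a] |= groups[b]
                groups[b] = set()
                changed = True
        groups = [g for g in groups if g]
    return {frozenset(g) for g in groups}


class TestSelectRepresentative:
    def test_hand_computed_medians(self):
        table = _table({("A", "B"): 1.0, ("A", "C"): 2.0, ("B", "C"): 3.0})
        rep, medians = select_representative(["A", "B", "C"], table)
        assert medians["A"][0] == pytest.approx(1.5)
        assert medians["B"][0] == pytest.approx(2.0)
        assert medians["C"][0] == pytest.approx(2.5)
        assert rep == "A"

    def test_all_equal_ties_to_smallest_id(self):
        table = _table({("A", "B"): 1.0, ("A", "C"): 1.0, ("B", "C"): 1.0})
        rep, _ = select_representative(["C", "B", "A"], table)
        assert rep == "A"

    def test_tm_breaks_rmsd_ties(self):
        table = _table(
            {("A", "B"): 1.0, ("A", "C"): 1.0, ("B", "C"): 1.0},
            tms={("A", "B"): 0.9, ("A", "C"): 0.5, ("B", "C"): 0.9},
        )
        # medians rmsd all 1.0; median tm: A=0.7, B=0.9, C=0.7
        rep, _ = select_representative(["A", "B", "C"], table)
        assert rep == "B"

    def test_matches_brute_force_on_random_tables(self, rng):
        ids = ["v", "w", "x", "y", "z"]
        for _ in range(20):
            rmsds = {p: float(rng.uniform(0.5, 5.0)) for p in itertools.combinations(ids, 2)}
            tms = {p: float(rng.uniform(0.3, 1.0)) for p in itertools.combinations(ids, 2)}
            table = _table(rmsds, tms)
            rep, medians = select_representative(ids, table)
            brute = min(
                ids,
                key=lambda m: (
                    np.median([rmsds[tuple(sorted((m, o)))] for o in ids if o != m]),
                    -np.median([tms[tuple(sorted((m, o)))] for o in ids if o != m]),
                    m,
                ),
            )
            assert rep == brute

    def test_member_order_does_not_change_representative(self, rng):
        ids = ["a", "b", "c", "d"]
        rmsds = {p: float(rng.uniform(1, 4)) for p in itertools.combinations(ids, 2)}
        table = _table(rmsds)
        rep0, _ = select_representative(ids, table)
        for perm in itertools.permutations(ids):
            rep, _ = select_representative(list(perm), table)
            assert rep == rep0


class TestWriteClusterTables:
    def test_fixture_screen_tables(self, small_records, tmp_path):
        import pandas as pd

        from binderclust import all_vs_all, filter_by_iptm, trim_complex
        from binderclust.clustering import member_medians

        gated = filter_by_iptm(small_records, 0.75)
        trimmed = [trim_complex(r) for r in gated]
        trimmed = [t for t in trimmed if t is not None]
        seq_part = cluster_sequences({t.complex_id: t.target_trimmed.sequence for t in trimmed})
        struct_part = cluster_structures({t.complex_id: t.target_trimmed for t in trimmed})
        merged = merge_partitions(seq_part, struct_part)
        by_id = {t.complex_id: t for t in trimmed}
        medians, summaries = {}, {}
        for label, members in merged.clusters().items():
            table = all_vs_all([by_id[m] for m in members]) if len(members) > 1 else None
            summaries[label] = summarize_cluster(label, members, table)
            if table is not None:
                medians.update(member_medians(members, table))
        records_by_id = {r.complex_id: r for r in gated}
        csv_path = write_cluster_tables(
            records_by_id, seq_part, struct_part, merged, medians, summaries, tmp_path
        )
        df = pd.read_csv(csv_path)
        assert len(df) == 12
        assert df.merged_cluster.nunique() == 3
        assert df.is_representative.sum() == 3
        # determinism: re-run is byte-identical
        first = csv_path.read_bytes()
        write_cluster_tables(
            records_by_id, seq_part, struct_part, merged, medians, summaries, tmp_path
        )
        assert csv_path.read_bytes() == first

    def test_single_complex_row(self, small_records, tmp_path):
        rec = small_records[0]
        part_s = Partition({rec.complex_id: rec.complex_id}, "sequence")
        part_t = Partition({rec.complex_id: rec.complex_id}, "structure")
        merged = merge_partitions(part_s, part_t)
        summaries = {rec.complex_id: summarize_cluster(rec.complex_id, [rec.complex_id], None)}
        csv_path = write_cluster_tables(
            {rec.complex_id: rec}, part_s, part_t, merged,
            {rec.complex_id: (None, None)}, summaries, tmp_path,
        )
        lines = csv_path.read_text().strip().splitlines()
        assert len(lines) == 2
        row = lines[1].split(",")
        assert row[6] == "" and row[7] == ""  # medians stay empty
        assert row[8] == "True"
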