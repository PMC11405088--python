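"""Sequence-guided rigid-body structural comparison.

The aligner is intended for comparing homologous trimmed targets
inside a cluster, so the residue correspondence is taken from a global
sequence alignment (Needleman-Wunsch, BLOSUM62, linear gap penalty)
rather than from a sequence-independent structure search.  On that
correspondence, a Kabsch superposition is refined iteratively in the
TM-score style: superpose on the current pair subset, keep pairs
closer than max(4.5 A, d0), repeat until stable.  TM-scores are then
computed over *all* correspondence pairs under the final superposition,

    TM_i = (1/L_i) * sum_k 1 / (1 + (d_k / d0(L_i))^2),

once normalized by each structure's length, with the standard
length-dependent scale d0(L) = 1.24 (L-15)^(1/3) - 1.8 (floored at
0.5 A).  RMSD is reported over the final kept subset.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from functools import lru_cache
from multiprocessing import Pool
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from biotite.sequence.align import SubstitutionMatrix

from binderclust.afm_io import ChainStructure

GAP_PENALTY = -6
MAX_REFINE_ITERATIONS = 20
MIN_PAIRS = 3

# BLOSUM62 lookup table indexed by ASCII code of the one-letter symbol
_BLOSUM62 = SubstitutionMatrix.std_protein_matrix()
_SCORE_LUT = np.full((128, 128), -4, dtype=np.int64)
for _a in _BLOSUM62.get_alphabet1():
    for _b in _BLOSUM62.get_alphabet2():
        _SCORE_LUT[ord(_a), ord(_b)] = _BLOSUM62.get_score(_a, _b)


@dataclass(frozen=True)
class Correspondence:
    """Matched residue index pairs, strictly increasing in both columns."""

    pairs: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        arr = np.asarray(self.pairs, dtype=int)
        return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class Superposition:
    """Rigid transform: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ np.asarray(self.rotation).T + np.asarray(self.translation)

    def inverse(self) -> "Superposition":
        r = np.asarray(self.rotation)
        return Superposition(rotation=r.T, translation=-(r.T @ np.asarray(self.translation)))

    @staticmethod
    def identity() -> "Superposition":
        return Superposition(rotation=np.eye(3), translation=np.zeros(3))


@dataclass
class AlignmentResult:
    """Pairwise comparison: RMSD over the refined pair subset, TM-scores
    normalized by each structure's length, and the fraction of the
    shorter structure covered by the correspondence.

    When fewer than three residue pairs could be matched, ``rmsd``,
    ``tm_1``, ``tm_2`` and ``superposition`` are ``None`` (undefined,
    never fabricated).
    """

    rmsd: float | None
    tm_1: float | None
    tm_2: float | None
    coverage: float
    n_pairs: int
    superposition: Superposition | None

    @property
    def defined(self) -> bool:
        return self.rmsd is not None

    def swapped(self) -> "AlignmentResult":
        """The same comparison seen from the other structure's side."""
        return AlignmentResult(
            rmsd=self.rmsd,
            tm_1=self.tm_2,
            tm_2=self.tm_1,
            coverage=self.coverage,
            n_pairs=self.n_pairs,
            superposition=None if self.superposition is None else self.superposition.inverse(),
        )


@lru_cache(maxsize=16384)
def _align_cached(a: str, b: str) -> tuple[tuple[int, int], ...]:
    la, lb = len(a), len(b)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    sub = _SCORE_LUT[np.ix_(av, bv)]
    F = np.empty((la + 1, lb + 1), dtype=np.int64)
    P = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 0 diag, 1 up, 2 left
    F[0, :] = GAP_PENALTY * np.arange(lb + 1)
    F[:, 0] = GAP_PENALTY * np.arange(la + 1)
    P[0, 1:] = 2
    P[1:, 0] = 1
    for i in range(1, la + 1):
        row = F[i]
        srow = sub[i - 1]
        fprev = F[i - 1]
        for j in range(1, lb + 1):
            d = fprev[j - 1] + srow[j - 1]
            u = fprev[j] + GAP_PENALTY
            l = row[j - 1] + GAP_PENALTY
            # deterministic tie precedence: diagonal > up > left
            if d >= u and d >= l:
                row[j] = d
                P[i, j] = 0
            elif u >= l:
                row[j] = u
                P[i, j] = 1
            else:
                row[j] = l
                P[i, j] = 2
    pairs: list[tuple[int, int]] = []
    i, j = la, lb
    while i > 0 or j > 0:
        p = P[i, j]
        if p == 0:
            i -= 1
            j -= 1
            pairs.append((i, j))
        elif p == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return tuple(pairs)


def align_sequences(a: str, b: str) -> Correspondence:
    """Global Needleman-Wunsch alignment of two amino-acid strings.

    BLOSUM62 substitution scores, linear gap penalty of -6, and a
    deterministic traceback (tie precedence diagonal > up > left).
    Only the matched (non-gap) columns are returned.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return Correspondence(pairs=_align_cached(a, b))


def alignment_identity_coverage(a: str, b: str) -> tuple[float, float, float]:
    """Identity and per-sequence span coverages of the global alignment.

    Identity is matches / alignment columns (gap columns included);
    coverage of each sequence is its aligned span divided by its
    length.
    """
    corr = align_sequences(a, b)
    n_pairs = len(corr)
    columns = len(a) + len(b) - n_pairs
    if n_pairs == 0:
        return 0.0, 0.0, 0.0
    ia, ib = corr.as_arrays()
    matches = sum(1 for x, y in corr.pairs if a[x] == b[y])
    cov_a = (ia[-1] - ia[0] + 1) / len(a)
    cov_b = (ib[-1] - ib[0] + 1) / len(b)
    return matches / columns, cov_a, cov_b


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[Superposition, float]:
    """Optimal rigid superposition of Q onto P (Kabsch, via SVD).

    Returns the transform minimizing the RMSD of the mapped Q against
    P, with the reflection corrected (det = +1) by flipping the sign
    of the smallest singular component when needed.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need at least 3 three-dimensional points")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    diff = Q @ R.T + t - P
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return Superposition(rotation=R, translation=t), rmsd


def tm_d0(L: int) -> float:
    """TM-score distance scale d0(L) = 1.24 (L-15)^(1/3) - 1.8, >= 0.5 A."""
    if L < 1:
        raise ValueError(f"length must be >= 1, got {L}")
    return max(0.5, 1.24 * np.cbrt(L - 15.0) - 1.8)


def structural_align(s1: ChainStructure, s2: ChainStructure) -> AlignmentResult:
    """Align two CA chains: sequence correspondence, iterative Kabsch
    refinement, TM-scores and RMSD.  Deterministic.

    The refinement distance cutoff is max(4.5 A, d0) with d0 taken at
    the shorter chain's length.  If the pair subset would fall below
    three, the three closest pairs are retained instead.
    """
    if len(s1) < 5 or len(s2) < 5:
        raise ValueError("structural alignment requires chains of >= 5 residues")
    corr = align_sequences(s1.sequence, s2.sequence)
    n_pairs = len(corr)
    L1, L2 = len(s1), len(s2)
    coverage = n_pairs / min(L1, L2)
    if n_pairs < MIN_PAIRS:
        return AlignmentResult(
            rmsd=None, tm_1=None, tm_2=None, coverage=coverage,
            n_pairs=n_pairs, superposition=None,
        )
    i1, i2 = corr.as_arrays()
    P = s1.ca_coords[i1]
    Q = s2.ca_coords[i2]
    cutoff = max(4.5, tm_d0(min(L1, L2)))
    subset = np.ones(n_pairs, dtype=bool)
    for _ in range(MAX_REFINE_ITERATIONS):
        sup, _ = kabsch(P[subset], Q[subset])
        dist = np.linalg.norm(sup.apply(Q) - P, axis=1)
        new_subset = dist < cutoff
        if new_subset.sum() < MIN_PAIRS:
            closest = np.argsort(dist, kind="stable")[:MIN_PAIRS]
            new_subset = np.zeros(n_pairs, dtype=bool)
            new_subset[closest] = True
        if np.array_equal(new_subset, subset):
            break
        subset = new_subset
    sup, rmsd = kabsch(P[subset], Q[subset])
    dist = np.linalg.norm(sup.apply(Q) - P, axis=1)
    tm_1 = float(np.sum(1.0 / (1.0 + (dist / tm_d0(L1)) ** 2)) / L1)
    tm_2 = float(np.sum(1.0 / (1.0 + (dist / tm_d0(L2)) ** 2)) / L2)
    return AlignmentResult(
        rmsd=rmsd, tm_1=tm_1, tm_2=tm_2, coverage=coverage,
        n_pairs=n_pairs, superposition=sup,
    )


def _self_result(length: int) -> AlignmentResult:
    return AlignmentResult(
        rmsd=0.0, tm_1=1.0, tm_2=1.0, coverage=1.0,
        n_pairs=length, superposition=Superposition.identity(),
    )


class AlignmentTable:
    """Symmetric all-vs-all table of pairwise alignment results.

    Results are stored once per unordered id pair (computed with the
    lexicographically smaller id as structure 1); ``result_for(i, j)``
    returns the view oriented with ``i`` as structure 1, synthesizing
    the trivial self-alignment on the diagonal.
    """

    def __init__(
        self,
        lengths: Mapping[str, int],
        results: Mapping[tuple[str, str], AlignmentResult],
    ) -> None:
        self.lengths = dict(lengths)
        self.results = {}
        for (i, j), res in results.items():
            if i >= j:
                raise ValueError(f"table keys must be ordered pairs, got {(i, j)}")
            self.results[(i, j)] = res

    @property
    def ids(self) -> list[str]:
        return sorted(self.lengths)

    def result_for(self, id1: str, id2: str) -> AlignmentResult:
        if id1 == id2:
            return _self_result(self.lengths[id1])
        if id1 < id2:
            return self.results[(id1, id2)]
        return self.results[(id2, id1)].swapped()

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "id1": i,
                "id2": j,
                "rmsd": r.rmsd,
                "tm_1": r.tm_1,
                "tm_2": r.tm_2,
                "coverage": r.coverage,
                "n_pairs": r.n_pairs,
            }
            for (i, j), r in sorted(self.results.items())
        ]
        return pd.DataFrame(
            rows, columns=["id1", "id2", "rmsd", "tm_1", "tm_2", "coverage", "n_pairs"]
        )

    def save(self, csv_path: str | Path, transforms_path: str | Path) -> None:
        """Serialize to a CSV of scores plus a JSON of superpositions."""
        self.to_dataframe().to_csv(csv_path, index=False)
        payload = {"lengths": {k: int(v) for k, v in sorted(self.lengths.items())}}
        transforms = {}
        for (i, j), r in sorted(self.results.items()):
            if r.superposition is not None:
                transforms[f"{i}|{j}"] = {
                    "rotation": r.superposition.rotation.tolist(),
                    "translation": r.superposition.translation.tolist(),
                }
        payload["transforms"] = transforms
        with open(transforms_path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, csv_path: str | Path, transforms_path: str | Path) -> "AlignmentTable":
        df = pd.read_csv(csv_path)
        with open(transforms_path) as fh:
            payload = json.load(fh)
        transforms = payload["transforms"]
        results = {}
        for row in df.itertuples(index=False):
            key = f"{row.id1}|{row.id2}"
            sup = None
            if key in transforms:
                sup = Superposition(
                    rotation=np.asarray(transforms[key]["rotation"]),
                    translation=np.asarray(transforms[key]["translation"]),
                )
            rmsd = None if pd.isna(row.rmsd) else float(row.rmsd)
            results[(str(row.id1), str(row.id2))] = AlignmentResult(
                rmsd=rmsd,
                tm_1=None if pd.isna(row.tm_1) else float(row.tm_1),
                tm_2=None if pd.isna(row.tm_2) else float(row.tm_2),
                coverage=float(row.coverage),
                n_pairs=int(row.n_pairs),
                superposition=sup,
            )
        lengths = {k: int(v) for k, v in payload["lengths"].items()}
        return cls(lengths=lengths, results=results)


def _align_pair(args: tuple[ChainStructure, ChainStructure]) -> AlignmentResult:
    return structural_align(args[0], args[1])


def _as_target_map(members: Iterable) -> dict[str, ChainStructure]:
    out: dict[str, ChainStructure] = {}
    for m in members:
        if isinstance(m, tuple):
            out[m[0]] = m[1]
        else:  # TrimmedComplex-like
            out[m.complex_id] = m.target_trimmed
    return out


def all_vs_all(members: Iterable, cpus: int = 1) -> AlignmentTable:
    """All-vs-all structural alignment of trimmed target chains.

    ``members`` may be TrimmedComplex objects or ``(id, chain)``
    tuples.  Each unordered pair is computed exactly once, with the
    lexicographically smaller id as structure 1; results are identical
    for any ``cpus`` value (workers only change wall time).
    """
    targets = _as_target_map(members)
    if len(targets) < 2:
        raise ValueError("all_vs_all needs at least 2 members")
    if cpus < 1:
        raise ValueError("cpus must be >= 1")
    pairs = list(itertools.combinations(sorted(targets), 2))
    jobs = [(targets[i], targets[j]) for i, j in pairs]
    if cpus == 1 or len(jobs) < 8:
        aligned = [_align_pair(job) for job in jobs]
    else:
        with Pool(processes=cpus) as pool:
            aligned = pool.map(_align_pair, jobs, chunksize=max(1, len(jobs) // (4 * cpus)))
    results = dict(zip(pairs, aligned))
    lengths = {k: len(v) for k, v in targets.items()}
    return AlignmentTable(lengths=lengths, results=results)
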