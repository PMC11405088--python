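"""ipTM gating and PAE-based interface trimming.

A residue of the target is kept when some bait residue "sees" it with
low predicted aligned error, i.e. when the model is confident about
its position *relative to the partner chain*; the bait is trimmed
symmetrically against the target block.  Because PAE is asymmetric,
the inter-chain block is symmetrized by taking the elementwise minimum
of the two orientations before aggregating.

Trimming turns a confidence vector into kept intervals in four steps:
seed residues (confidence <= cutoff), bridge seed runs separated by at
most ``max_gap`` unconfident residues, drop bridged runs shorter than
``min_segment``, then pad each surviving run by ``pad`` residues on
both sides (clipped to the chain ends, overlaps merged).  A complex
whose bait or target retains nothing is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from binderclust.afm_io import (
    ChainStructure,
    ComplexRecord,
    PaeMatrix,
    ScoreSet,
    ValidationError,
    write_pdb,
)

logger = logging.getLogger(__name__)

DEFAULT_PAE_CUTOFF = 12.0
DEFAULT_PAD = 2
DEFAULT_MAX_GAP = 5
DEFAULT_MIN_SEGMENT = 10

Interval = tuple[int, int]


def filter_by_iptm(records: list[ComplexRecord], threshold: float = 0.75) -> list[ComplexRecord]:
    """Keep records with ipTM greater than or equal to ``threshold``.

    The gate is inclusive: a complex exactly at the threshold passes.
    Input order is preserved.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"iptm threshold {threshold} outside [0, 1]")
    return [r for r in records if r.scores.iptm >= threshold]


def interface_confidence(pae: PaeMatrix, bait_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue interface confidence for bait and target (lower = better).

    For target residue j the confidence is the minimum over bait
    residues i of min(PAE[i, L+j], PAE[L+j, i]) where L is the bait
    length; bait confidences are defined symmetrically against the
    target block.  Returns ``(bait_conf, target_conf)`` in Angstrom.
    """
    if not 0 < bait_len < pae.size:
        raise ValidationError(
            f"bait length {bait_len} incompatible with PAE size {pae.size}"
        )
    inter = np.minimum(pae.values[:bait_len, bait_len:], pae.values[bait_len:, :bait_len].T)
    return inter.min(axis=1), inter.min(axis=0)


def _runs(mask: np.ndarray) -> list[Interval]:
    """Half-open intervals of consecutive True entries."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b]) + 1) for a, b in zip(starts, stops)]


def confident_intervals(
    confidence: np.ndarray,
    pae_cutoff: float,
    pad: int,
    max_gap: int,
    min_segment: int,
) -> list[Interval]:
    """Kept residue intervals (half-open, 0-based) for one chain."""
    if min_segment <= 0:
        raise ValueError(f"min_segment must be positive, got {min_segment}")
    if pad < 0 or max_gap < 0:
        raise ValueError("pad and max_gap must be non-negative")
    seeds = _runs(np.asarray(confidence) <= pae_cutoff)
    if not seeds:
        return []
    # bridge seed runs separated by <= max_gap unconfident residues
    bridged: list[Interval] = [seeds[0]]
    for start, stop in seeds[1:]:
        prev_start, prev_stop = bridged[-1]
        if start - prev_stop <= max_gap:
            bridged[-1] = (prev_start, stop)
        else:
            bridged.append((start, stop))
    kept = [(s, e) for s, e in bridged if e - s >= min_segment]
    n = len(confidence)
    padded = [(max(0, s - pad), min(n, e + pad)) for s, e in kept]
    merged: list[Interval] = []
    for s, e in padded:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _interval_indices(intervals: list[Interval]) -> np.ndarray:
    if not intervals:
        return np.empty(0, dtype=int)
    return np.concatenate([np.arange(s, e) for s, e in intervals])


@dataclass
class TrimmedComplex:
    """A complex reduced to its confidently-placed regions.

    ``bait_kept``/``target_kept`` are sorted, disjoint half-open
    intervals of 0-based residue indices into the original chains.
    ``scores`` is the untouched original score set.
    """

    complex_id: str
    bait_kept: list[Interval]
    target_kept: list[Interval]
    bait_trimmed: ChainStructure
    target_trimmed: ChainStructure
    scores: ScoreSet
    original_bait_len: int

    def as_record(self) -> ComplexRecord:
        """View the trimmed complex as a ComplexRecord.

        pLDDT and PAE are restricted to the kept residues so the
        record satisfies the size invariants; scalar scores carry over.
        """
        bi = _interval_indices(self.bait_kept)
        ti = _interval_indices(self.target_kept) + self.original_bait_len
        keep = np.concatenate([bi, ti])
        sub_scores = ScoreSet(
            iptm=self.scores.iptm,
            ptm=self.scores.ptm,
            combined=self.scores.combined,
            plddt=self.scores.plddt[keep],
            pae=PaeMatrix(self.scores.pae.values[np.ix_(keep, keep)]),
        )
        return ComplexRecord(
            complex_id=self.complex_id,
            bait=self.bait_trimmed,
            target=self.target_trimmed,
            scores=sub_scores,
        )


def trim_complex(
    rec: ComplexRecord,
    pae_cutoff: float = DEFAULT_PAE_CUTOFF,
    pad: int = DEFAULT_PAD,
    max_gap: int = DEFAULT_MAX_GAP,
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> TrimmedComplex | None:
    """Trim both chains to their confidently-placed regions.

    Returns ``None`` (with a logged reason) when either chain retains
    no residues.  Bait and target use the same parameters.
    """
    bait_len = len(rec.bait)
    bait_conf, target_conf = interface_confidence(rec.scores.pae, bait_len)
    bait_kept = confident_intervals(bait_conf, pae_cutoff, pad, max_gap, min_segment)
    target_kept = confident_intervals(target_conf, pae_cutoff, pad, max_gap, min_segment)
    if not bait_kept or not target_kept:
        which = "bait" if not bait_kept else "target"
        logger.info(
            "%s discarded: no confident %s region at PAE cutoff %.1f",
            rec.complex_id,
            which,
            pae_cutoff,
        )
        return None
    return TrimmedComplex(
        complex_id=rec.complex_id,
        bait_kept=bait_kept,
        target_kept=target_kept,
        bait_trimmed=rec.bait.subset(_interval_indices(bait_kept)),
        target_trimmed=rec.target.subset(_interval_indices(target_kept)),
        scores=rec.scores,
        original_bait_len=bait_len,
    )


def _author_number_remark(chain: ChainStructure) -> str:
    nums = chain.residue_numbers
    parts: list[str] = []
    start = prev = int(nums[0])
    for n in nums[1:]:
        n = int(n)
        if n == prev + 1:
            prev = n
            continue
        parts.append(f"{start}-{prev}" if prev > start else f"{start}")
        start = prev = n
    parts.append(f"{start}-{prev}" if prev > start else f"{start}")
    return f"CHAIN {chain.chain_id} AUTHOR NUMBERS: {','.join(parts)}"


def write_trimmed_pdb(tc: TrimmedComplex, path: str | Path) -> None:
    """Write the trimmed complex as a two-chain PDB.

    Chains are renumbered 1..n; the original author numbers are kept
    in REMARK 300 lines.
    """
    bait = ChainStructure(
        chain_id=tc.bait_trimmed.chain_id,
        sequence=tc.bait_trimmed.sequence,
        ca_coords=tc.bait_trimmed.ca_coords,
        residue_numbers=np.arange(1, len(tc.bait_trimmed) + 1),
    )
    target = ChainStructure(
        chain_id=tc.target_trimmed.chain_id,
        sequence=tc.target_trimmed.sequence,
        ca_coords=tc.target_trimmed.ca_coords,
        residue_numbers=np.arange(1, len(tc.target_trimmed) + 1),
    )
    write_pdb(
        [bait, target],
        path,
        remarks=[
            _author_number_remark(tc.bait_trimmed),
            _author_number_remark(tc.target_trimmed),
        ],
    )


def write_trimmed_fasta(trimmed: list[TrimmedComplex], path: str | Path) -> None:
    """FASTA of the trimmed target sequences, one entry per complex."""
    with open(path, "w") as fh:
        for tc in trimmed:
            fh.write(f">{tc.complex_id}\n{tc.target_trimmed.sequence}\n")
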