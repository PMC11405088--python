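"""Synthetic AlphaFold-Multimer screens with known ground truth.

The generator emits the exact directory layout the pipeline consumes
(per-complex PDB + ranking JSON + score JSON) plus a ``manifest.csv``
recording which complexes are planted binder-family members and which
are decoys.  Family members share a parametric fold (with Gaussian
coordinate noise) and a mutated consensus sequence, carry a
confidently low inter-chain PAE block over a contiguous interface
span, and have ipTM above the gating threshold; decoys are random
coils at random placements with uniformly high PAE and sub-threshold
ipTM.

Everything is reproducible: one pseudo-random stream per complex,
seeded by (seed, complex index), so regenerating any subset is
stable and two runs with the same spec are byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from binderclust.afm_io import (
    ChainStructure,
    ComplexRecord,
    PaeMatrix,
    ScoreSet,
    write_complex,
    write_ranking,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# helix geometry: 1.5 A rise, 2.3 A radius, 100 deg turn per residue
_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TURN = np.deg2rad(100.0)
# beta strands: 3.3 A rise with a +-0.95 A pleat, 4.8 A strand separation
_STRAND_RISE = 3.3
_PLEAT = 0.95
_STRAND_SEP = 4.8


def _helix(length: int) -> np.ndarray:
    i = np.arange(length)
    return np.column_stack(
        [
            _HELIX_RADIUS * np.cos(_HELIX_TURN * i),
            _HELIX_RADIUS * np.sin(_HELIX_TURN * i),
            _HELIX_RISE * i,
        ]
    )


def _hairpin(length: int) -> np.ndarray:
    n1 = (length - 2) // 2
    n2 = length - 2 - n1
    i = np.arange(n1)
    strand1 = np.column_stack(
        [_PLEAT * (-1.0) ** i, np.zeros(n1), _STRAND_RISE * i]
    )
    xa = strand1[-1, 0]
    ztop = strand1[-1, 2]
    turn = np.array(
        [[xa + 0.5, 3.6, ztop + 1.0], [xa + _STRAND_SEP - 0.5, 3.6, ztop + 1.0]]
    )
    j = np.arange(n2)
    strand2 = np.column_stack(
        [
            xa + _STRAND_SEP - _PLEAT + _PLEAT * (-1.0) ** j,
            np.zeros(n2),
            ztop - _STRAND_RISE * j,
        ]
    )
    return np.concatenate([strand1, turn, strand2])


def _helix_turn_helix(family: int, length: int) -> np.ndarray:
    n1 = (length - 3) // 2
    n2 = length - 3 - n1
    arm1 = _helix(n1)
    end = arm1[-1]
    phi = 0.5 + 0.3 * (family - 2)
    u = np.array([np.cos(phi), np.sin(phi), 0.2])
    u /= np.linalg.norm(u)
    turn = end + 3.8 * u * np.arange(1, 4)[:, None]
    start2 = end + 3.8 * 4 * u
    theta = np.deg2rad(100.0 + 25.0 * (family - 2))
    rot = Rotation.from_euler("x", theta).as_matrix()
    arm2 = _helix(n2) @ rot.T
    arm2 = arm2 - arm2[0] + start2
    return np.concatenate([arm1, turn, arm2])


def make_fold(family: int, length: int) -> np.ndarray:
    """Deterministic parametric CA trace for a fold family.

    Family 0 is an ideal alpha-helix, family 1 a two-strand
    antiparallel beta-hairpin, and families >= 2 are helix-turn-helix
    variants with family-specific turn directions and inter-arm
    angles.  Consecutive CA-CA distances lie in [3.7, 3.9] A.
    """
    if length < 10:
        raise ValueError(f"fold length must be >= 10, got {length}")
    if family < 0:
        raise ValueError(f"family index must be >= 0, got {family}")
    if family == 0:
        return _helix(length)
    if family == 1:
        return _hairpin(length)
    return _helix_turn_helix(family, length)


@dataclass
class ScreenSpec:
    """Study conditions for one synthetic screen.

    Defaults describe the documented reference screen: three binder
    families of twelve members each against fifty decoys, a 40-residue
    bait, 60-residue targets whose residues 10..49 form the interface,
    0.5 A coordinate noise within a family, a 10% per-residue mutation
    rate off the family consensus, and ipTM centered at 0.85 for true
    members versus 0.50 for decoys (the gate default being 0.75).
    """

    n_families: int = 3
    members_per_family: int = 12
    n_decoys: int = 50
    bait_length: int = 40
    target_length: int = 60
    interface_span: tuple[int, int] = (10, 50)
    coord_noise_sigma: float = 0.5
    mutation_rate: float = 0.1
    iptm_true: float = 0.85
    iptm_decoy: float = 0.50
    seed: int = 0

    def __post_init__(self) -> None:
        s, e = self.interface_span
        if not 0 <= s < e <= self.target_length:
            raise ValueError(
                f"interface span {self.interface_span} outside "
                f"[0, {self.target_length})"
            )
        for name in ("n_families", "members_per_family", "n_decoys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate outside [0, 1]")

    @property
    def n_complexes(self) -> int:
        return self.n_families * self.members_per_family + self.n_decoys


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, consensus: str, rate: float) -> str:
    out = []
    for aa in consensus:
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(aa, "")
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def _random_rigid(rng: np.random.Generator, coords: np.ndarray, distance: float) -> np.ndarray:
    q = rng.normal(size=4)
    rot = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    centered = coords - coords.mean(axis=0)
    return centered @ rot.T + distance * direction


def _random_coil(rng: np.random.Generator, length: int) -> np.ndarray:
    steps = rng.normal(size=(length - 1, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    return np.concatenate([np.zeros((1, 3)), np.cumsum(steps, axis=0)])


def _pae_matrix(
    rng: np.random.Generator,
    bait_len: int,
    target_len: int,
    interface: tuple[int, int] | None,
) -> np.ndarray:
    n = bait_len + target_len
    pae = rng.uniform(25.0, 30.0, size=(n, n))
    if interface is not None:
        s, e = interface
        cols = np.arange(bait_len + s, bait_len + e)
        pae[np.ix_(np.arange(bait_len), cols)] = rng.uniform(
            2.0, 6.0, size=(bait_len, e - s)
        )
        pae[np.ix_(cols, np.arange(bait_len))] = rng.uniform(
            2.0, 6.0, size=(e - s, bait_len)
        )
    return np.round(pae, 2)


def _make_record(
    spec: ScreenSpec,
    complex_id: str,
    idx: int,
    bait_seq: str,
    bait_coords: np.ndarray,
    consensus: str | None,
    fold: np.ndarray | None,
) -> ComplexRecord:
    rng = np.random.default_rng([spec.seed, idx])
    is_true = consensus is not None
    if is_true:
        seq = _mutate(rng, consensus, spec.mutation_rate)
        coords = fold + rng.normal(scale=spec.coord_noise_sigma, size=fold.shape)
        interface = spec.interface_span
        iptm_center, plddt_lo, plddt_hi = spec.iptm_true, 70.0, 95.0
    else:
        seq = _random_sequence(rng, spec.target_length)
        coords = _random_coil(rng, spec.target_length)
        interface = None
        iptm_center, plddt_lo, plddt_hi = spec.iptm_decoy, 40.0, 70.0
    coords = _random_rigid(rng, coords, distance=30.0)
    n_total = spec.bait_length + spec.target_length
    iptm = float(np.clip(round(iptm_center + rng.uniform(-0.02, 0.02), 4), 0.0, 1.0))
    ptm = float(np.clip(round(iptm_center - 0.05 + rng.uniform(-0.02, 0.02), 4), 0.0, 1.0))
    combined = round(0.8 * iptm + 0.2 * ptm, 4)
    scores = ScoreSet(
        iptm=iptm,
        ptm=ptm,
        combined=combined,
        plddt=np.round(rng.uniform(plddt_lo, plddt_hi, size=n_total), 2),
        pae=PaeMatrix(
            _pae_matrix(rng, spec.bait_length, spec.target_length, interface)
        ),
    )
    bait = ChainStructure(
        chain_id="A",
        sequence=bait_seq,
        ca_coords=np.round(bait_coords, 3),
        residue_numbers=np.arange(1, spec.bait_length + 1),
    )
    target = ChainStructure(
        chain_id="B",
        sequence=seq,
        ca_coords=np.round(coords, 3),
        residue_numbers=np.arange(1, spec.target_length + 1),
    )
    return ComplexRecord(complex_id=complex_id, bait=bait, target=target, scores=scores)


def generate_screen(spec: ScreenSpec, out_dir: str | Path) -> Path:
    """Write a full synthetic screen directory; returns the manifest path.

    Layout: ``out_dir/<complex_id>/{ranking_debug.json, model_1.pdb,
    model_1_scores.json}`` plus ``out_dir/manifest.csv`` with columns
    complex_id, family, is_decoy, interface_start, interface_end.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bait_rng = np.random.default_rng([spec.seed, 999_999])
    bait_seq = _random_sequence(bait_rng, spec.bait_length)
    bait_fold = make_fold(2, spec.bait_length)
    bait_coords = bait_fold - bait_fold.mean(axis=0)
    consensus = {
        f: _random_sequence(np.random.default_rng([spec.seed, 500_000 + f]), spec.target_length)
        for f in range(spec.n_families)
    }
    folds = {f: make_fold(f, spec.target_length) for f in range(spec.n_families)}

    manifest_rows = []
    idx = 0
    for f in range(spec.n_families):
        for m in range(spec.members_per_family):
            cid = f"fam{f}_mem{m:02d}"
            rec = _make_record(
                spec, cid, idx, bait_seq, bait_coords, consensus[f], folds[f]
            )
            _write_entry(rec, out_dir / cid)
            manifest_rows.append(
                {
                    "complex_id": cid,
                    "family": f,
                    "is_decoy": False,
                    "interface_start": spec.interface_span[0],
                    "interface_end": spec.interface_span[1],
                }
            )
            idx += 1
    for d in range(spec.n_decoys):
        cid = f"decoy_{d:02d}"
        rec = _make_record(spec, cid, idx, bait_seq, bait_coords, None, None)
        _write_entry(rec, out_dir / cid)
        manifest_rows.append(
            {
                "complex_id": cid,
                "family": -1,
                "is_decoy": True,
                "interface_start": "",
                "interface_end": "",
            }
        )
        idx += 1

    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["complex_id", "family", "is_decoy", "interface_start", "interface_end"],
        )
        writer.writeheader()
        writer.writerows(sorted(manifest_rows, key=lambda r: r["complex_id"]))
    return manifest_path


def _write_entry(rec: ComplexRecord, cdir: Path) -> None:
    cdir.mkdir(parents=True, exist_ok=True)
    write_ranking(
        cdir / "ranking_debug.json", ["model_1"], {"model_1": rec.scores.combined}
    )
    write_complex(rec, cdir / "model_1.pdb", cdir / "model_1_scores.json")
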