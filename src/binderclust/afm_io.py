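"""Read and write AlphaFold-Multimer screen outputs.

A screen directory holds one subdirectory per modeled bait-target
complex, named by the target identifier.  Each subdirectory contains

* ``ranking_debug.json`` -- the AlphaFold ranking file: an ``"order"``
  list of model names plus a map from model name to the ipTM+pTM
  ranking confidence;
* ``<model>.pdb`` -- CA-traceable coordinates, two chains, bait first;
* ``<model>_scores.json`` -- a JSON score dialect with keys ``iptm``,
  ``ptm``, ``iptm_ptm``, ``plddt`` (per residue, 0-100) and ``pae``
  (the N x N predicted-aligned-error matrix in Angstrom, N = bait +
  target residues).

AlphaFold itself emits the scores as a pickle; converting to this
dialect is one line per file, e.g.::

    import pickle, json, numpy as np
    d = pickle.load(open("result_model_1.pkl", "rb"))
    json.dump({"iptm": float(d["iptm"]), "ptm": float(d["ptm"]),
               "iptm_ptm": 0.8 * float(d["iptm"]) + 0.2 * float(d["ptm"]),
               "plddt": np.asarray(d["plddt"]).round(2).tolist(),
               "pae": np.asarray(d["predicted_aligned_error"]).round(2).tolist()},
              open("model_1_scores.json", "w"))

Only CA atoms enter the data model: trimming, alignment and clustering
all operate at residue resolution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from biotite.sequence import ProteinSequence

logger = logging.getLogger(__name__)

_VALID_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class ValidationError(ValueError):
    """An input file violated the screen-layout contract."""


def _three_to_one(res_name: str) -> str:
    try:
        letter = ProteinSequence.convert_letter_3to1(res_name)
    except Exception:
        return "X"
    return letter if letter in _VALID_LETTERS else "X"


def _one_to_three(letter: str) -> str:
    try:
        return ProteinSequence.convert_letter_1to3(letter)
    except Exception:
        return "UNK"


@dataclass
class ChainStructure:
    """A single protein chain reduced to its CA trace.

    ``sequence``, ``ca_coords`` and ``residue_numbers`` are parallel:
    one entry per residue, in chain order.  ``residue_numbers`` are the
    author numbers from the coordinate file and must be strictly
    increasing; internal residue indices are 0-based and contiguous.
    """

    chain_id: str
    sequence: str
    ca_coords: np.ndarray
    residue_numbers: np.ndarray

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        n = len(self.sequence)
        if self.ca_coords.shape != (n, 3):
            raise ValidationError(
                f"chain {self.chain_id}: {n} residues but coords of shape "
                f"{self.ca_coords.shape}"
            )
        if self.residue_numbers.shape != (n,):
            raise ValidationError(
                f"chain {self.chain_id}: {n} residues but "
                f"{self.residue_numbers.shape} residue numbers"
            )
        if n > 1 and not np.all(np.diff(self.residue_numbers) > 0):
            raise ValidationError(
                f"chain {self.chain_id}: residue numbers not strictly increasing"
            )
        bad = set(self.sequence) - _VALID_LETTERS
        if bad:
            raise ValidationError(
                f"chain {self.chain_id}: invalid residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def subset(self, indices: np.ndarray) -> "ChainStructure":
        """Chain restricted to the given 0-based residue indices."""
        indices = np.asarray(indices, dtype=int)
        return ChainStructure(
            chain_id=self.chain_id,
            sequence="".join(self.sequence[i] for i in indices),
            ca_coords=self.ca_coords[indices],
            residue_numbers=self.residue_numbers[indices],
        )


@dataclass
class PaeMatrix:
    """Square predicted-aligned-error matrix in Angstrom.

    Entry (i, j) is the expected error of residue i's position when the
    model is aligned on residue j; the matrix need not be symmetric.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError(f"PAE matrix not square: shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ValidationError("PAE matrix has negative entries")

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class ScoreSet:
    """Model confidences: ipTM, pTM, the combined ranking confidence
    (0.8*ipTM + 0.2*pTM), per-residue pLDDT and the PAE matrix."""

    iptm: float
    ptm: float
    combined: float
    plddt: np.ndarray
    pae: PaeMatrix

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        for name in ("iptm", "ptm", "combined"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if len(self.plddt) != self.pae.size:
            raise ValidationError(
                f"plddt length {len(self.plddt)} != PAE size {self.pae.size}"
            )


@dataclass
class ComplexRecord:
    """One bait-target model: two chains plus its score set."""

    complex_id: str
    bait: ChainStructure
    target: ChainStructure
    scores: ScoreSet

    def __post_init__(self) -> None:
        total = len(self.bait) + len(self.target)
        if self.scores.pae.size != total:
            raise ValidationError(
                f"{self.complex_id}: PAE size {self.scores.pae.size} != "
                f"bait+target residues {total}"
            )


@dataclass
class Ranking:
    """Parsed ranking file: model order plus the confidence map."""

    order: list[str]
    confidences: dict[str, float]

    @property
    def best(self) -> str:
        return self.order[0]


def read_ranking(path: str | Path) -> Ranking:
    """Parse a ``ranking_debug.json`` file.

    The best model is the first element of the ``order`` list,
    regardless of the confidence values.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed JSON in ranking file {path}: {exc}") from exc
    order = data.get("order")
    if not order:
        raise ValidationError(f"ranking file {path} has an empty or missing order list")
    conf = None
    for key in ("iptm+ptm", "confidences"):
        if isinstance(data.get(key), dict):
            conf = data[key]
            break
    if conf is None:
        conf = next(
            (v for k, v in data.items() if k != "order" and isinstance(v, dict)), None
        )
    if conf is None:
        raise ValidationError(f"ranking file {path} has no confidence map")
    return Ranking(order=list(order), confidences={k: float(v) for k, v in conf.items()})


def read_chains(pdb_path: str | Path) -> list[ChainStructure]:
    """Read the CA trace of every chain in a PDB file, in file order."""
    pdb_path = Path(pdb_path)
    pdb_file = pdbio.PDBFile.read(pdb_path)
    atoms = pdb_file.get_structure(model=1)
    aa_mask = struc.filter_amino_acids(atoms)
    ca_mask = (atoms.atom_name == "CA") & aa_mask
    n_res_total = struc.get_residue_count(atoms[aa_mask])
    if int(ca_mask.sum()) < n_res_total:
        logger.warning(
            "%s: %d residue(s) lack a CA atom and were dropped",
            pdb_path,
            n_res_total - int(ca_mask.sum()),
        )
    ca = atoms[ca_mask]
    chains: list[ChainStructure] = []
    for chain_id in list(dict.fromkeys(ca.chain_id)):
        sub = ca[ca.chain_id == chain_id]
        chains.append(
            ChainStructure(
                chain_id=str(chain_id),
                sequence="".join(_three_to_one(rn) for rn in sub.res_name),
                ca_coords=sub.coord.astype(float),
                residue_numbers=sub.res_id.astype(int),
            )
        )
    return chains


def _read_scores(scores_path: Path) -> ScoreSet:
    try:
        with open(scores_path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed JSON in score file {scores_path}: {exc}") from exc
    try:
        iptm = float(data["iptm"])
        ptm = float(data["ptm"])
        plddt = np.asarray(data["plddt"], dtype=float)
        pae = PaeMatrix(np.asarray(data["pae"], dtype=float))
    except KeyError as exc:
        raise ValidationError(f"score file {scores_path} missing key {exc}") from exc
    combined = float(data.get("iptm_ptm", 0.8 * iptm + 0.2 * ptm))
    return ScoreSet(iptm=iptm, ptm=ptm, combined=combined, plddt=plddt, pae=pae)


def read_complex(
    pdb_path: str | Path,
    scores_path: str | Path,
    complex_id: str | None = None,
) -> ComplexRecord:
    """Read one bait-target model from a coordinate + score file pair.

    The coordinate file must contain exactly two chains; the first is
    the bait, the second the target.  The PAE matrix side must equal
    the total residue count of both chains.
    """
    pdb_path = Path(pdb_path)
    if complex_id is None:
        complex_id = pdb_path.parent.name
    chains = read_chains(pdb_path)
    if len(chains) != 2:
        raise ValidationError(
            f"{pdb_path}: expected exactly 2 chains, found {len(chains)}"
        )
    bait, target = chains
    scores = _read_scores(Path(scores_path))
    total = len(bait) + len(target)
    if scores.pae.size != total:
        raise ValidationError(
            f"{complex_id}: PAE size {scores.pae.size} does not match "
            f"bait+target residue count {total}"
        )
    return ComplexRecord(complex_id=complex_id, bait=bait, target=target, scores=scores)


def load_screen(models_dir: str | Path) -> list[ComplexRecord]:
    """Load the best model of every complex in a screen directory.

    Subdirectories are visited in lexicographic order, so the result
    order is independent of filesystem enumeration.  Complexes that
    fail validation are skipped with a logged warning, never fatal.
    """
    models_dir = Path(models_dir)
    subdirs = sorted(
        (d for d in models_dir.iterdir() if d.is_dir()), key=lambda d: d.name
    )
    records: list[ComplexRecord] = []
    for sub in subdirs:
        ranking_path = sub / "ranking_debug.json"
        if not ranking_path.exists():
            logger.warning("skipping %s: no ranking_debug.json", sub)
            continue
        try:
            best = read_ranking(ranking_path).best
            rec = read_complex(
                sub / f"{best}.pdb", sub / f"{best}_scores.json", complex_id=sub.name
            )
        except (ValidationError, OSError) as exc:
            logger.warning("skipping %s: %s", sub.name, exc)
            continue
        records.append(rec)
    if not records:
        logger.warning("no valid complexes found in %s", models_dir)
    return records


# ---------------------------------------------------------------------------
# Writers (used by the synthetic-screen generator and for round trips)


def _chains_to_atom_array(
    chains: list[ChainStructure], b_factors: list[np.ndarray] | None = None
) -> struc.AtomArray:
    n = sum(len(c) for c in chains)
    arr = struc.AtomArray(n)
    arr.coord = np.concatenate([c.ca_coords for c in chains])
    arr.chain_id = np.concatenate([[c.chain_id] * len(c) for c in chains])
    arr.res_id = np.concatenate([c.residue_numbers for c in chains])
    arr.res_name = np.array(
        [_one_to_three(a) for c in chains for a in c.sequence]
    )
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    if b_factors is not None:
        arr.set_annotation("b_factor", np.concatenate(b_factors))
    return arr


def write_pdb(
    chains: list[ChainStructure],
    path: str | Path,
    b_factors: list[np.ndarray] | None = None,
    remarks: list[str] | None = None,
) -> None:
    """Write CA-trace chains to a PDB file, optionally with REMARK lines."""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_chains_to_atom_array(chains, b_factors))
    if remarks:
        pdb_file.lines = [f"REMARK 300 {r}" for r in remarks] + pdb_file.lines
    pdb_file.write(Path(path))


def write_complex(record: ComplexRecord, pdb_path: str | Path, scores_path: str | Path) -> None:
    """Write a ComplexRecord as a coordinate + score file pair.

    pLDDT goes into the B-factor column, as AlphaFold does.  Output is
    deterministic: writing, reading back and writing again yields
    byte-identical files.
    """
    nb = len(record.bait)
    write_pdb(
        [record.bait, record.target],
        pdb_path,
        b_factors=[record.scores.plddt[:nb], record.scores.plddt[nb:]],
    )
    payload = {
        "iptm": record.scores.iptm,
        "ptm": record.scores.ptm,
        "iptm_ptm": record.scores.combined,
        "plddt": record.scores.plddt.tolist(),
        "pae": record.scores.pae.values.tolist(),
    }
    with open(scores_path, "w") as fh:
        json.dump(payload, fh)


def write_ranking(path: str | Path, order: list[str], confidences: dict[str, float]) -> None:
    with open(path, "w") as fh:
        json.dump({"order": order, "iptm+ptm": confidences}, fh)
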