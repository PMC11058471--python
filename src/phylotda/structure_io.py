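"""Protein structure parsing and point-cloud extraction.

A protein structure is reduced to one of five point clouds (alpha carbons,
all heavy atoms, or the carbon/nitrogen/oxygen subsets), which are the
inputs to the topological filtrations.  Per-residue prediction confidence
(AlphaFold2 pLDDT, stored in the PDB B-factor column) travels with every
atom of the residue, so that whole residues can be masked either by
confidence or because they sit opposite a gap in a pairwise alignment.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "PointCloud",
    "SELECTORS",
    "read_structure",
    "structure_to_pdb",
    "extract_point_cloud",
    "mask_low_confidence",
    "mask_indel_residues",
    "deduplicate_points",
]

#: Valid atom selectors for :func:`extract_point_cloud`.
SELECTORS = ("CA", "ALL_ATOMS", "ALL_C", "ALL_N", "ALL_O")

_AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA_1TO3 = {v: k for k, v in _AA_3TO1.items()}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a parsed structure.

    ``residue_index`` is the 1-based position in the protein sequence (after
    renumbering; PDB author numbering is discarded).  ``confidence`` is the
    per-residue index in [0, 100] read from the B-factor of the residue's CA
    atom and inherited by every atom of that residue.
    """

    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    coords: np.ndarray
    confidence: float

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if not 0.0 <= self.confidence <= 100.0:
            raise ValueError("confidence must lie in [0, 100]")


@dataclass
class ProteinStructure:
    """A single-chain protein: ordered heavy atoms plus derived sequence."""

    id: str
    atoms: list[AtomRecord]
    sequence: str = field(default="")

    def __post_init__(self) -> None:
        if not self.sequence:
            self.sequence = self._derive_sequence()

    def _derive_sequence(self) -> str:
        seen: dict[int, str] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_index, _AA_3TO1.get(a.residue_name, "X"))
        return "".join(seen[i] for i in sorted(seen))

    @property
    def n_residues(self) -> int:
        return len({a.residue_index for a in self.atoms})

    def confidence_by_residue(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for a in self.atoms:
            out.setdefault(a.residue_index, a.confidence)
        return out


@dataclass
class PointCloud:
    """Ordered 3D points with residue provenance.

    ``n_residues`` records the residue count of the source structure so that
    indel masks (which refer to ungapped residue indices) can be validated
    even after some residues were already removed by confidence masking.
    """

    points: np.ndarray            # (n, 3) float, Angstrom
    residue_of_point: np.ndarray  # (n,) int, 1-based
    selector: str
    n_residues: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.residue_of_point = np.asarray(self.residue_of_point, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(self.points) != len(self.residue_of_point):
            raise ValueError("points and residue_of_point lengths differ")
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.n_residues == 0 and len(self.residue_of_point):
            self.n_residues = int(self.residue_of_point.max())

    @property
    def n(self) -> int:
        return len(self.points)


def read_structure(pdb_text: str, id: str = "", chain: str | None = None) -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Only the first model is used.  HETATM records (waters, ligands),
    hydrogens and non-primary altlocs are skipped.  ``chain`` selects a chain
    ID; by default the first chain encountered is used.  A residue without a
    CA atom is dropped with a warning; the per-residue confidence is the CA
    B-factor.
    """
    pdb = PDBFile.read(io.StringIO(pdb_text))
    try:
        arr = pdb.get_structure(model=1, extra_fields=["b_factor"], altloc="first")
    except Exception as exc:  # biotite raises on empty input
        raise ValueError("no atoms found in PDB text") from exc
    arr = arr[~arr.hetero]
    arr = arr[arr.element != "H"]
    if arr.array_length() == 0:
        raise ValueError("no atoms found in PDB text")
    chain_id = chain if chain is not None else arr.chain_id[0]
    arr = arr[arr.chain_id == chain_id]
    if arr.array_length() == 0:
        raise ValueError(f"chain {chain_id!r} not present")

    atoms: list[AtomRecord] = []
    seq_pos = 0
    for res_id in np.unique(arr.res_id):  # res_id is sorted; order of chain
        res = arr[arr.res_id == res_id]
        ca = res[res.atom_name == "CA"]
        if ca.array_length() == 0:
            warnings.warn(
                f"residue {int(res_id)} of {id or chain_id} has no CA atom; dropped",
                stacklevel=2,
            )
            continue
        seq_pos += 1
        conf = float(np.clip(ca.b_factor[0], 0.0, 100.0))
        for i in range(res.array_length()):
            atoms.append(
                AtomRecord(
                    residue_index=seq_pos,
                    residue_name=str(res.res_name[i]),
                    atom_name=str(res.atom_name[i]),
                    element=str(res.element[i]),
                    coords=np.array(res.coord[i], dtype=float),
                    confidence=conf,
                )
            )
    if not atoms:
        raise ValueError("no complete residues parsed from PDB text")
    return ProteinStructure(id=id, atoms=atoms)


def structure_to_pdb(s: ProteinStructure) -> str:
    """Serialize a structure back to PDB text (B-factor = confidence)."""
    n = len(s.atoms)
    arr = struc.AtomArray(n)
    arr.coord = np.array([a.coords for a in s.atoms], dtype=float)
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.array([a.residue_index for a in s.atoms])
    arr.res_name = np.array([a.residue_name for a in s.atoms])
    arr.atom_name = np.array([a.atom_name for a in s.atoms])
    arr.element = np.array([a.element for a in s.atoms])
    arr.set_annotation("b_factor", np.array([a.confidence for a in s.atoms]))
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def extract_point_cloud(
    s: ProteinStructure, selector: str = "CA", sidechain_only: bool = False
) -> PointCloud:
    """Build one of the five atom-selection point clouds.

    ``CA`` keeps one point per residue (its alpha carbon); ``ALL_ATOMS``
    keeps every parsed heavy atom; ``ALL_C``/``ALL_N``/``ALL_O`` keep atoms
    of that element.  By default ``ALL_C`` includes backbone carbons (CA and
    the carbonyl C); ``sidechain_only=True`` restricts the element selectors
    to side-chain atoms.
    """
    if selector not in SELECTORS:
        raise ValueError(f"unknown selector {selector!r}")
    backbone = {"N", "CA", "C", "O"}

    def keep(a: AtomRecord) -> bool:
        if selector == "CA":
            return a.atom_name == "CA"
        if selector == "ALL_ATOMS":
            return True
        want = selector[-1]  # C, N or O
        if a.element != want:
            return False
        if sidechain_only and a.atom_name in backbone:
            return False
        return True

    kept = [a for a in s.atoms if keep(a)]
    points = np.array([a.coords for a in kept], dtype=float).reshape(len(kept), 3)
    residues = np.array([a.residue_index for a in kept], dtype=int)
    return PointCloud(
        points=points,
        residue_of_point=residues,
        selector=selector,
        n_residues=s.n_residues,
    )


def mask_low_confidence(
    pc: PointCloud,
    s: ProteinStructure,
    threshold: float = 70.0,
    strict: bool = False,
) -> PointCloud:
    """Remove points of residues whose confidence index is below ``threshold``.

    With ``strict=False`` (default) residues with confidence equal to the
    threshold are retained; ``strict=True`` requires strictly greater.
    Whole residues are masked, for every selector.
    """
    conf = s.confidence_by_residue()
    ok = np.array(
        [
            (conf[r] > threshold) if strict else (conf[r] >= threshold)
            for r in pc.residue_of_point
        ],
        dtype=bool,
    ) if pc.n else np.zeros(0, dtype=bool)
    if pc.n and not ok.any():
        raise ValueError("empty cloud after CI masking")
    return replace(
        pc,
        points=pc.points[ok],
        residue_of_point=pc.residue_of_point[ok],
        n_residues=pc.n_residues,
    )


def mask_indel_residues(pcA: PointCloud, pcB: PointCloud, pair_map) -> tuple[PointCloud, PointCloud]:
    """Remove, from each cloud, the residues sitting opposite a gap in the pair.

    ``pair_map`` is a :class:`phylotda.evodist.PairIndelMap` for the same two
    sequences.  Masking is pair-specific: the residues removed from a
    structure depend on which other structure it is compared with.  Residues
    already absent from a cloud (e.g. removed by confidence masking) are
    ignored; mask indices beyond the source structure's residue range raise.
    """

    def apply(pc: PointCloud, mask: list[int]) -> PointCloud:
        if mask and max(mask) > pc.n_residues:
            raise ValueError(
                "indel mask refers to residue "
                f"{max(mask)} but structure has {pc.n_residues} residues"
            )
        bad = set(mask)
        ok = np.array([r not in bad for r in pc.residue_of_point], dtype=bool)
        return replace(pc, points=pc.points[ok], residue_of_point=pc.residue_of_point[ok])

    return apply(pcA, pair_map.residues_to_mask_A), apply(pcB, pair_map.residues_to_mask_B)


def deduplicate_points(pc: PointCloud, scale: float = 1e-6, seed: int = 0) -> PointCloud:
    """Jitter coincident points by ``scale`` Angstrom with a fixed seed.

    Delaunay triangulation requires points in general position; synthetic
    clouds can contain exact duplicates.  The jitter is deterministic and far
    below any biologically meaningful length scale.
    """
    pts = pc.points
    if len(np.unique(pts, axis=0)) == len(pts):
        return pc
    rng = np.random.default_rng(seed)
    jit = pts + rng.normal(scale=scale, size=pts.shape)
    return replace(pc, points=jit)
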