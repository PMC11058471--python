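"""Synthetic protein families with coupled sequence and structure divergence.

The generator produces, from a single seed, a complete family: a pure-birth
(Yule) tree with >= 7 taxa, sequences evolved along it under a 20-state
Jukes-Cantor-type substitution model with Poisson indel events, the true
multiple alignment implied by the event history, and CA-trace structures
whose coordinates diverge by Brownian motion along the same tree.  Sequence
divergence and geometric divergence therefore increase together with
patristic distance, which is the statistical structure the downstream
correlation analyses assume; no claim of physical realism is made (see the
methods note).

A per-residue confidence index imitates AlphaFold2 pLDDT: a configurable
fraction of residues is flagged low-confidence (index in [40, 70)) and
receives extra coordinate noise, so that confidence masking measurably
improves the structural signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace as dc_replace

import dendropy
import numpy as np

from .evodist import MultipleAlignment, alignment_to_fasta, patristic_matrix
from .structure_io import _AA_1TO3, AtomRecord, ProteinStructure, structure_to_pdb

__all__ = [
    "SyntheticFamilyConfig",
    "SyntheticFamily",
    "simulate_tree",
    "evolve_family",
    "build_structures",
    "assign_confidence",
    "make_family",
    "write_bundle",
]

_AMINO = "ACDEFGHIKLMNPQRSTVWY"

#: distance between consecutive alpha carbons along a protein backbone (Angstrom)
CA_SPACING = 3.8


@dataclass(frozen=True)
class SyntheticFamilyConfig:
    """Parameters of one synthetic protein family.

    Units: branch lengths are in expected substitutions per site, so
    ``sub_rate`` is fixed at 1 per unit branch length by convention;
    ``struct_noise_sd`` is the per-coordinate Brownian displacement in
    Angstrom per square root of unit branch length; ``indel_rate`` is the
    expected number of indel events per sequence per unit branch length.
    ``low_ci_fraction`` defaults to 0.06, imitating predicted structure sets
    in which ~94% of residues have confidence >= 70.
    """

    n_taxa: int = 8
    seq_length: int = 120
    birth_rate: float = 3.0
    sub_rate: float = 1.0
    indel_rate: float = 0.05
    indel_len_mean: float = 3.0
    struct_noise_sd: float = 0.5
    low_ci_fraction: float = 0.06
    seed: int = 0
    sidechain_atoms: bool = False
    root_fold_seed: int | None = None  # distinct values give distinct root folds
    tree_seed: int | None = None  # fix the tree across families (paired designs)

    def __post_init__(self) -> None:
        if self.n_taxa < 7:
            raise ValueError("families need at least 7 taxa")
        if self.seq_length < 30:
            raise ValueError("seq_length must be >= 30")
        for name in ("birth_rate", "sub_rate", "indel_rate", "struct_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.low_ci_fraction <= 1.0:
            raise ValueError("low_ci_fraction must lie in [0, 1]")


@dataclass
class SyntheticFamily:
    """A generated family: tree, true alignment, structures, true distances."""

    tree: dendropy.Tree
    alignment: MultipleAlignment
    structures: list[ProteinStructure]
    truth: "object"  # pandas DataFrame of true patristic distances
    config: SyntheticFamilyConfig


def simulate_tree(n_taxa: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Yule (pure-birth) tree with exponential waiting times.

    Starting from a single lineage, each of the k extant lineages splits at
    total rate k * birth_rate; simulation stops when n_taxa lineages exist
    and pendant branches are extended to that final time.  Leaves are
    labelled T1..Tn.  Deterministic under the seed.
    """
    if n_taxa < 7:
        raise ValueError("families need at least 7 taxa")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"T{i + 1}" for i in range(n_taxa)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    # active lineages: (node, birth_time)
    active = [(tree.seed_node, 0.0)]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = rng.integers(k)
        node, born = active.pop(idx)
        node.edge.length = t - born
        children = [dendropy.Node(), dendropy.Node()]
        for ch in children:
            node.add_child(ch)
            active.append((ch, t))
    k = len(active)
    t += rng.exponential(1.0 / (k * birth_rate))
    for i, (node, born) in enumerate(active):
        node.edge.length = t - born
        node.taxon = taxa[i]
    tree.seed_node.edge.length = None
    return tree


def _substitute(letters: list[str], t: float, sub_rate: float, rng) -> None:
    """Continuous-time 20-state Jukes-Cantor kernel along a branch of length t.

    A site changes to one of the 19 other letters with probability
    (19/20) * (1 - exp(-(20/19) * sub_rate * t)); this composes exactly
    along paths, giving E[p-distance] = (19/20)(1 - exp(-(20/19) d)) at
    patristic distance d.
    """
    p_change = (19.0 / 20.0) * (1.0 - np.exp(-(20.0 / 19.0) * sub_rate * t))
    hits = np.flatnonzero(rng.random(len(letters)) < p_change)
    for i in hits:
        old = letters[i]
        choices = _AMINO.replace(old, "")
        letters[i] = choices[rng.integers(19)]


def evolve_family(
    tree: dendropy.Tree, config: SyntheticFamilyConfig, rng: np.random.Generator | None = None
) -> tuple[MultipleAlignment, dict[str, list[int]], dict[int, list[tuple[int, str]]]]:
    """Evolve sequences with substitutions and indels along the tree.

    Returns the true alignment, the per-leaf ordered lists of homology
    column ids (the residue genealogies), and the per-node site lists needed
    to evolve structures along the same history.  Column ids are kept in a
    global master order so the true alignment can be assembled exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    L = config.seq_length
    master: list[int] = list(range(L))
    next_col = L
    geom_p = 1.0 / max(config.indel_len_mean, 1.0)

    # node.id -> ordered list of (column_id, letter)
    states: dict[int, list[tuple[int, str]]] = {}
    root = tree.seed_node
    root_letters = [_AMINO[i] for i in rng.integers(20, size=L)]
    states[id(root)] = list(zip(range(L), root_letters))

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length
        seq = list(states[id(node.parent_node)])
        letters = [aa for _, aa in seq]
        _substitute(letters, t, config.sub_rate, rng)
        seq = [(cid, aa) for (cid, _), aa in zip(seq, letters)]
        n_events = rng.poisson(config.indel_rate * t)
        for _ in range(n_events):
            length = int(rng.geometric(geom_p))
            if rng.random() < 0.5 and len(seq) > length:  # deletion
                start = int(rng.integers(len(seq)))
                del seq[start : start + length]
            else:  # insertion
                pos = int(rng.integers(len(seq) + 1))
                new_letters = [_AMINO[i] for i in rng.integers(20, size=length)]
                anchor = master.index(seq[pos - 1][0]) + 1 if pos > 0 else 0
                new_ids = list(range(next_col, next_col + length))
                next_col += length
                master[anchor:anchor] = new_ids
                seq[pos:pos] = list(zip(new_ids, new_letters))
        states[id(node)] = seq

    leaves = {leaf.taxon.label: states[id(leaf)] for leaf in tree.leaf_node_iter()}
    occupied = sorted(
        {cid for seq in leaves.values() for cid, _ in seq}, key=master.index
    )
    col_pos = {cid: i for i, cid in enumerate(occupied)}
    ids = sorted(leaves)
    rows = []
    genealogies: dict[str, list[int]] = {}
    for label in ids:
        row = ["-"] * len(occupied)
        for cid, aa in leaves[label]:
            row[col_pos[cid]] = aa
        rows.append("".join(row))
        genealogies[label] = [cid for cid, _ in leaves[label]]
    return MultipleAlignment(ids=ids, rows=rows), genealogies, states


def _root_backbone(L: int, rng: np.random.Generator) -> np.ndarray:
    """A compact, self-avoiding CA trace with consecutive spacing exactly 3.8 A.

    A persistent random walk with fixed step length is confined to a ball of
    the globular radius of gyration (~2.2 * L^0.38 A) by a centripetal pull
    and kept self-avoiding by a soft repulsion from earlier residues.
    Compactness matters: globular folds have large-scale cycles and cavities
    whose spatial scale grows with chain length, as in real proteins,
    whereas an extended curve only has turn-scale features.
    """
    target_r = 2.5 * L**0.38
    x = np.zeros((L, 3))
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    for i in range(1, L):
        cur = x[i - 1]
        noise = rng.normal(size=3) * 0.6
        r = float(np.linalg.norm(cur))
        pull = -cur / max(r, 1e-9) * 1.2 * max(0.0, r / target_r - 0.6)
        rep = np.zeros(3)
        if i > 3:
            diff = cur - x[: i - 2]
            dist = np.linalg.norm(diff, axis=1)
            close = dist < 5.5
            if close.any():
                rep = (diff[close] / (dist[close][:, None] ** 2 + 1e-9)).sum(0) * 3.0
        d = 0.75 * d + noise + pull + rep
        d /= np.linalg.norm(d)
        x[i] = cur + CA_SPACING * d
    return x - x.mean(axis=0)


def _smooth_chain_noise(
    rng: np.random.Generator, n: int, sd: float, window: int = 9
) -> np.ndarray:
    """Gaussian displacement field correlated along the chain.

    A moving average over ``window`` residues of i.i.d. normals, rescaled so
    every residue keeps marginal standard deviation ``sd`` per coordinate.
    Homologous structures deform coherently (helices shift, domains move)
    rather than by independent per-residue scatter; the smoothing models
    that while preserving the Brownian variance identity
    E[squared displacement] = 3 * sd^2 * t per residue.
    """
    if n == 0:
        return np.zeros((0, 3))
    w = min(window, n)
    raw = rng.normal(size=(n + w - 1, 3))
    kernel = np.ones(w) / w
    out = np.column_stack(
        [np.convolve(raw[:, c], kernel, mode="valid") for c in range(3)]
    )
    return sd * np.sqrt(w) * out


def build_structures(
    tree: dendropy.Tree,
    alignment: MultipleAlignment,
    genealogies: dict[str, list[int]],
    config: SyntheticFamilyConfig,
    rng: np.random.Generator | None = None,
    node_states: dict[int, list[tuple[int, str]]] | None = None,
) -> list[ProteinStructure]:
    """Evolve CA coordinates by Brownian motion along the tree.

    Each branch of length t adds a Gaussian displacement field of standard
    deviation ``struct_noise_sd * sqrt(t)`` per coordinate to every
    inherited residue; the field is smoothed along the chain (window 9)
    so neighbouring residues move coherently, with the per-residue marginal
    variance preserved.  Inserted residues are placed by linear interpolation
    between their flanking residues plus noise, terminal insertions extend
    the last chain direction.  Only CA atoms are emitted unless
    ``sidechain_atoms`` also adds one dummy carbon plus one alternating
    nitrogen/oxygen per residue (to exercise the element selectors).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if node_states is None:
        raise ValueError("node_states from evolve_family are required")
    root = tree.seed_node
    fold_seed = config.root_fold_seed
    fold_rng = rng if fold_seed is None else np.random.default_rng(fold_seed)
    root_cols = [cid for cid, _ in node_states[id(root)]]
    root_xyz = _root_backbone(len(root_cols), fold_rng)
    coords: dict[int, dict[int, np.ndarray]] = {
        id(root): {cid: root_xyz[i] for i, cid in enumerate(root_cols)}
    }

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length
        parent = coords[id(node.parent_node)]
        seq = node_states[id(node)]
        here: dict[int, np.ndarray] = {}
        sd = config.struct_noise_sd * np.sqrt(t)
        inherited = [cid for cid, _ in seq if cid in parent]
        disp = _smooth_chain_noise(rng, len(inherited), sd)
        for (cid, d) in zip(inherited, disp):
            here[cid] = parent[cid] + d
        # place inserted runs by interpolation between flanking residues
        order = [cid for cid, _ in seq]
        for i, cid in enumerate(order):
            if cid in here:
                continue
            left = next((here[order[j]] for j in range(i - 1, -1, -1) if order[j] in here), None)
            right = next((here[order[j]] for j in range(i + 1, len(order)) if order[j] in here), None)
            if left is not None and right is not None:
                base = (left + right) / 2.0
            elif left is not None:
                base = left + rng.normal(scale=1.0, size=3) + np.array([CA_SPACING, 0, 0])
            elif right is not None:
                base = right + rng.normal(scale=1.0, size=3) - np.array([CA_SPACING, 0, 0])
            else:
                base = np.zeros(3)
            here[cid] = base + rng.normal(scale=0.5, size=3)
        coords[id(node)] = here

    structures = []
    for leaf in sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label):
        label = leaf.taxon.label
        seq = node_states[id(leaf)]
        here = coords[id(leaf)]
        atoms: list[AtomRecord] = []
        for res_i, (cid, aa) in enumerate(seq, start=1):
            res3 = _AA_1TO3[aa]
            ca = np.asarray(here[cid], dtype=float)
            atoms.append(AtomRecord(res_i, res3, "CA", "C", ca, 90.0))
            if config.sidechain_atoms:
                d1 = rng.normal(size=3)
                d1 = 1.5 * d1 / np.linalg.norm(d1)
                atoms.append(AtomRecord(res_i, res3, "CB", "C", ca + d1, 90.0))
                d2 = rng.normal(size=3)
                d2 = 1.5 * d2 / np.linalg.norm(d2)
                if res_i % 2 == 0:
                    atoms.append(AtomRecord(res_i, res3, "ND1", "N", ca + d2, 90.0))
                else:
                    atoms.append(AtomRecord(res_i, res3, "OD1", "O", ca + d2, 90.0))
        structures.append(ProteinStructure(id=label, atoms=atoms))
    return structures


def assign_confidence(
    structures: list[ProteinStructure],
    low_ci_fraction: float,
    seed: int,
    extra_noise_sd: float = 3.0,
    low_residues: dict[str, set[int]] | None = None,
) -> list[ProteinStructure]:
    """Assign per-residue confidence and degrade low-confidence coordinates.

    A ``low_ci_fraction`` of residues per structure gets a confidence index
    drawn Uniform(40, 70) plus extra i.i.d. Gaussian coordinate noise of
    standard deviation ``extra_noise_sd`` (imitating flexible, poorly
    predicted segments), the rest Uniform(85, 99); confidence masking
    therefore removes the noisiest residues.  ``low_residues`` can prescribe
    the low-confidence residue set per structure id -- the family generator
    uses this to place low-confidence regions at homologous alignment
    columns, the way flexible loops are conserved across a family; without
    it the selection is uniform per structure.
    """
    if not 0.0 <= low_ci_fraction <= 1.0:
        raise ValueError("low_ci_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for s in structures:
        n_res = s.n_residues
        if low_residues is not None:
            low = {r for r in low_residues.get(s.id, set()) if 1 <= r <= n_res}
        else:
            n_low = int(round(low_ci_fraction * n_res))
            low = set(rng.choice(np.arange(1, n_res + 1), size=n_low, replace=False).tolist())
        conf = {
            r: (rng.uniform(40.0, 70.0) if r in low else rng.uniform(85.0, 99.0))
            for r in range(1, n_res + 1)
        }
        shift = {r: rng.normal(scale=extra_noise_sd, size=3) for r in low}
        atoms = [
            AtomRecord(
                a.residue_index,
                a.residue_name,
                a.atom_name,
                a.element,
                a.coords + shift.get(a.residue_index, 0.0),
                conf[a.residue_index],
            )
            for a in s.atoms
        ]
        out.append(ProteinStructure(id=s.id, atoms=atoms))
    return out


def make_family(config: SyntheticFamilyConfig) -> SyntheticFamily:
    """Generate a complete family from a single seed (fully deterministic).

    Low-confidence regions are placed at family-conserved alignment columns
    (flexible loops are homologous features), so that confidence masking
    removes nearly the same residues from every member of the family.
    """
    tree = simulate_tree(
        config.n_taxa,
        config.birth_rate,
        config.seed if config.tree_seed is None else config.tree_seed,
    )
    rng = np.random.default_rng(config.seed + 1)
    alignment, genealogies, node_states = evolve_family(tree, config, rng)
    structures = build_structures(tree, alignment, genealogies, config, rng, node_states)
    ci_rng = np.random.default_rng(config.seed + 3)
    ncol = alignment.ncol
    low_cols = set(
        ci_rng.choice(ncol, size=int(round(config.low_ci_fraction * ncol)), replace=False).tolist()
    )
    low_residues = {}
    for sid in alignment.ids:
        row = alignment.row(sid)
        pos = 0
        low = set()
        for col, ch in enumerate(row):
            if ch != "-":
                pos += 1
                if col in low_cols:
                    low.add(pos)
        low_residues[sid] = low
    structures = assign_confidence(
        structures,
        config.low_ci_fraction,
        seed=config.seed + 3,
        extra_noise_sd=3.0 * max(config.struct_noise_sd, 0.5),
        low_residues=low_residues,
    )
    truth = patristic_matrix(tree)
    return SyntheticFamily(
        tree=tree,
        alignment=alignment,
        structures=structures,
        truth=truth,
        config=config,
    )


def write_bundle(family: SyntheticFamily, path: str) -> None:
    """Write a family bundle: per-leaf PDB, aligned FASTA, Newick, truth CSV."""
    os.makedirs(os.path.join(path, "structures"), exist_ok=True)
    with open(os.path.join(path, "alignment.fasta"), "w") as fh:
        fh.write(alignment_to_fasta(family.alignment))
    with open(os.path.join(path, "tree.nwk"), "w") as fh:
        fh.write(family.tree.as_string(schema="newick", suppress_rooting=True))
    family.truth.to_csv(os.path.join(path, "truth.csv"))
    for s in family.structures:
        with open(os.path.join(path, "structures", f"{s.id}.pdb"), "w") as fh:
            fh.write(structure_to_pdb(s))
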