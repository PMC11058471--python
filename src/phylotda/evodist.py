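"""Evolutionary distances from alignments and trees, and per-pair indel maps.

Two sequence-derived distances are used as the reference against which the
topological distances are compared: the observed proportion of differing
sites between two aligned sequences (p-distance, pairwise deletion of gap
columns), and the patristic distance, i.e. the sum of branch lengths on the
path between two leaves of a maximum-likelihood tree, in expected
substitutions per site.

The indel map of a pair records, for every alignment column gapped in
exactly one of the two rows, the ungapped residue index of the opposing
residue; those residues are removed from the point clouds before computing
pair-specific topological distances.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "MultipleAlignment",
    "PairIndelMap",
    "read_alignment",
    "alignment_to_fasta",
    "p_distance",
    "pair_indel_map",
    "read_newick",
    "patristic_matrix",
]


@dataclass
class MultipleAlignment:
    """An aligned protein family: equal-length rows over amino acids and '-'."""

    ids: list[str]
    rows: list[str]
    ncol: int = 0

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        if not self.rows:
            raise ValueError("empty alignment")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.ncol = lengths.pop()

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError as exc:
            raise KeyError(f"sequence {seq_id!r} not in alignment") from exc

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")


@dataclass
class PairIndelMap:
    """Alignment columns gapped in exactly one row of a pair, and the
    ungapped residue indices (1-based) of the residues opposite those gaps."""

    idA: str
    idB: str
    columns_gapped: list[int] = field(default_factory=list)
    residues_to_mask_A: list[int] = field(default_factory=list)
    residues_to_mask_B: list[int] = field(default_factory=list)
    gap_count: int = 0


def read_alignment(fasta_text: str) -> MultipleAlignment:
    """Parse an aligned FASTA with at least two sequences."""
    try:
        aln = AlignIO.read(io.StringIO(fasta_text), "fasta")
    except ValueError as exc:
        raise ValueError(f"could not parse aligned FASTA: {exc}") from exc
    if len(aln) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    return MultipleAlignment(
        ids=[rec.id for rec in aln], rows=[str(rec.seq) for rec in aln]
    )


def alignment_to_fasta(m: MultipleAlignment) -> str:
    return "".join(f">{i}\n{r}\n" for i, r in zip(m.ids, m.rows))


def p_distance(m: MultipleAlignment, idA: str, idB: str) -> float:
    """Proportion of differing sites among columns ungapped in both rows."""
    a, b = m.row(idA), m.row(idB)
    both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not both:
        raise ValueError(f"no overlapping sites between {idA!r} and {idB!r}")
    diff = sum(1 for x, y in both if x != y)
    return diff / len(both)


def pair_indel_map(m: MultipleAlignment, idA: str, idB: str) -> PairIndelMap:
    """Identify residues of a pair involved in indels.

    A column gapped in exactly one row contributes the opposing residue to
    that sequence's mask list; columns gapped in both rows carry no residue
    on either side and are ignored.
    """
    a, b = m.row(idA), m.row(idB)
    out = PairIndelMap(idA=idA, idB=idB)
    pos_a = pos_b = 0
    for col, (x, y) in enumerate(zip(a, b)):
        if x != "-":
            pos_a += 1
        if y != "-":
            pos_b += 1
        if (x == "-") != (y == "-"):
            out.columns_gapped.append(col)
            if x == "-":
                out.residues_to_mask_B.append(pos_b)
            else:
                out.residues_to_mask_A.append(pos_a)
    out.gap_count = len(out.columns_gapped)
    return out


def read_newick(newick_text: str) -> dendropy.Tree:
    """Parse a Newick tree, requiring branch lengths and >= 2 leaves."""
    try:
        tree = dendropy.Tree.get(
            data=newick_text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("tree has fewer than 2 leaves")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("branch lengths required for patristic distances")
        if edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric matrix of path-length distances between all leaf pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((leaf.taxon for leaf in tree.leaf_nodes()), key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)
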