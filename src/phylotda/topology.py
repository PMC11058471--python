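"""Filtrations and persistent homology over Z/2Z.

Two filtrations of a 3D point cloud are supported:

* Vietoris--Rips (VR): a simplex enters at the *diameter* of its vertex set
  (maximum pairwise Euclidean distance), up to dimension 3 so that H2 is
  computable.
* Alpha complex (AC): simplices are those of the 3D Delaunay triangulation;
  a simplex with an empty smallest circumscribing ball (Gabriel) enters at
  its squared circumradius, other faces inherit the smallest value among
  their cofaces.  Values are in squared-length units, the convention of the
  standard computational-geometry tooling, so AC- and VR-scales must not be
  mixed in one analysis.

Persistence is computed by the standard left-to-right boundary-matrix
column reduction over the field with two elements, with columns stored as
Python integer bitsets.  An independent persistent-cohomology route
(reduction of the anti-transposed matrix) is provided for cross-checking;
both produce identical barcodes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FilteredComplex",
    "Barcode",
    "build_vietoris_rips",
    "build_alpha_complex",
    "compute_persistence",
]


@dataclass
class Barcode:
    """Multiset of (birth, death) intervals in one homological dimension."""

    k: int
    intervals: np.ndarray  # (m, 2), birth < death; death may be +inf for k=0

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        # canonical order for comparison and reproducible output
        if len(self.intervals):
            order = np.lexsort((self.intervals[:, 1], self.intervals[:, 0]))
            self.intervals = self.intervals[order]

    def __len__(self) -> int:
        return len(self.intervals)

    def persistences(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]


@dataclass
class FilteredComplex:
    """A filtered simplicial complex: (sorted vertex tuple, value) pairs.

    ``threshold`` records the VR cutoff when one was applied, so that
    classes still alive at the cutoff can be capped there.
    """

    simplices: list[tuple[tuple[int, ...], float]]
    kind: str  # "VR" | "AC"
    threshold: float | None = None

    def sorted_simplices(self) -> list[tuple[tuple[int, ...], float]]:
        return sorted(self.simplices, key=lambda sv: (sv[1], len(sv[0]), sv[0]))

    def validate(self) -> None:
        """Check the filtration property: faces present, with <= values."""
        value = {s: v for s, v in self.simplices}
        if len(value) != len(self.simplices):
            raise ValueError("duplicate simplices in complex")
        for s, v in self.simplices:
            if list(s) != sorted(set(s)):
                raise ValueError(f"simplex vertices not strictly increasing: {s}")
            if len(s) == 1:
                continue
            for f in itertools.combinations(s, len(s) - 1):
                if f not in value:
                    raise ValueError(f"face {f} of {s} missing from complex")
                if value[f] > v + 1e-12:
                    raise ValueError(f"face {f} enters after coface {s}")

    def to_text(self) -> str:
        lines = [f"# kind={self.kind} threshold={self.threshold}"]
        for s, v in self.sorted_simplices():
            lines.append(" ".join(map(str, s)) + f" : {v!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "FilteredComplex":
        kind, threshold = "VR", None
        simplices = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    key, _, val = tok.partition("=")
                    if key == "kind":
                        kind = val
                    elif key == "threshold" and val != "None":
                        threshold = float(val)
                continue
            verts, _, val = line.partition(":")
            simplices.append((tuple(int(v) for v in verts.split()), float(val)))
        return cls(simplices=simplices, kind=kind, threshold=threshold)


def _points_of(pc) -> np.ndarray:
    pts = getattr(pc, "points", pc)
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (n, 3) point array")
    return pts


def build_vietoris_rips(
    pc,
    max_dim: int = 3,
    threshold: float | None = None,
    max_points: int = 150,
) -> FilteredComplex:
    """Vietoris--Rips filtration with the diameter convention.

    Every subset of at most ``max_dim + 1`` points whose diameter is at most
    ``threshold`` becomes a simplex, entering at that diameter.
    ``threshold=None`` uses the cloud diameter, which guarantees that all
    positive-dimensional classes die.  Above ``max_points`` points the
    construction is refused (combinatorial blowup): use the alpha complex.
    """
    pts = _points_of(pc)
    n = len(pts)
    if n < 4:
        raise ValueError("cloud too small for 3D filtration (need >= 4 points)")
    if n > max_points:
        raise ValueError(
            f"{n} points exceed the VR cap ({max_points}); "
            "use build_alpha_complex for large clouds"
        )
    d = squareform(pdist(pts))
    diameter = float(d.max())
    thr = diameter if threshold is None else float(threshold)

    simplices: list[tuple[tuple[int, ...], float]] = [((i,), 0.0) for i in range(n)]
    # incremental expansion over lower neighbours keeps only simplices
    # within the threshold
    lower = [np.flatnonzero((d[v] <= thr) & (np.arange(n) < v)) for v in range(n)]

    def expand(simplex: tuple[int, ...], cand: np.ndarray, value: float) -> None:
        for u in cand:
            val = max(value, float(d[u, list(simplex)].max()))
            new = (int(u),) + simplex
            simplices.append((tuple(sorted(new)), val))
            if len(new) <= max_dim:
                expand(new, np.intersect1d(cand, lower[u]), val)

    for v in range(n):
        expand((v,), lower[v], 0.0)
    return FilteredComplex(simplices=simplices, kind="VR", threshold=thr)


def _circumsphere(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Center and squared radius of the smallest circumscribing ball of a
    simplex (the circumsphere within its affine hull)."""
    p0 = pts[0]
    rel = pts[1:] - p0
    if len(rel) == 0:
        return p0, 0.0
    rhs = 0.5 * np.einsum("ij,ij->i", rel, rel)
    sol, *_ = np.linalg.lstsq(rel, rhs, rcond=None)
    center = p0 + sol
    return center, float(np.dot(sol, sol))


def build_alpha_complex(pc, jitter_scale: float = 1e-6, seed: int = 0) -> FilteredComplex:
    """3D alpha-complex filtration (squared-circumradius values).

    Simplices are the Delaunay simplices of the cloud.  Gabriel simplices
    (empty smallest circumscribing ball) take their squared circumradius;
    non-Gabriel faces inherit the minimum filtration value of their cofaces.
    Degenerate inputs are retried once after a deterministic 1e-6 Angstrom
    jitter.
    """
    pts = _points_of(pc)
    if len(pts) < 4:
        raise ValueError("cloud too small for 3D filtration (need >= 4 points)")
    try:
        tri = Delaunay(pts)
    except QhullError:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(scale=jitter_scale, size=pts.shape)
        try:
            tri = Delaunay(pts)
        except QhullError as exc:
            raise ValueError("degenerate point cloud: Delaunay triangulation failed") from exc

    by_dim: dict[int, set[tuple[int, ...]]] = {0: set(), 1: set(), 2: set(), 3: set()}
    for tet in tri.simplices:
        tet = tuple(sorted(int(v) for v in tet))
        for dim in range(4):
            for f in itertools.combinations(tet, dim + 1):
                by_dim[dim].add(f)

    value: dict[tuple[int, ...], float] = {}
    for dim in (3, 2, 1):
        for s in by_dim[dim]:
            if s not in value:
                _, r2 = _circumsphere(pts[list(s)])
                value[s] = r2
            v_s = value[s]
            for f in itertools.combinations(s, dim):
                if f in value:
                    value[f] = min(value[f], v_s)
                else:
                    center, r2 = _circumsphere(pts[list(f)])
                    extra = set(s) - set(f)
                    inside = any(
                        np.dot(pts[v] - center, pts[v] - center) < r2 for v in extra
                    )
                    if inside:  # not Gabriel w.r.t. this coface
                        value[f] = v_s
    for v0 in by_dim[0]:
        value[v0] = 0.0
    # numerical guard: clamp every face below all of its cofaces
    for dim in (3, 2, 1):
        for s in by_dim[dim]:
            for f in itertools.combinations(s, dim):
                if value[f] > value[s]:
                    value[f] = value[s]
    simplices = [(s, value[s]) for dim in range(4) for s in sorted(by_dim[dim])]
    return FilteredComplex(simplices=simplices, kind="AC", threshold=None)


def _reduce_columns(columns: list[int]) -> dict[int, int]:
    """Left-to-right GF(2) column reduction; returns {low_row: column_index}.

    Columns are bitsets over row indices; after the loop, column j either is
    zero (creator) or has a unique lowest row (its pair).
    """
    low_inv: dict[int, int] = {}
    for j in range(len(columns)):
        col = columns[j]
        while col:
            low = col.bit_length() - 1
            other = low_inv.get(low)
            if other is None:
                break
            col ^= columns[other]
        columns[j] = col
        if col:
            low_inv[col.bit_length() - 1] = j
    return low_inv


def compute_persistence(
    fc: FilteredComplex,
    include_dim0: bool = False,
    method: str = "boundary",
    validate: bool = True,
) -> dict[int, Barcode]:
    """Persistence barcodes of a filtered complex over Z/2Z.

    Simplices are ordered by (filtration value, dimension, lexicographic
    vertex tuple); any tie-break yields the same barcode, a fixed one makes
    runs bit-for-bit reproducible.  Zero-persistence pairs are discarded.
    Positive-dimensional classes still alive at a VR threshold are capped at
    the threshold (with a warning); unpaired components get death = +inf.

    ``method='coboundary'`` reduces the anti-transposed matrix instead
    (persistent cohomology); the pairing is provably identical and serves as
    an internal cross-check.

    Returns ``{1: Barcode, 2: Barcode}`` (plus ``0`` if ``include_dim0``).
    """
    if method not in ("boundary", "coboundary"):
        raise ValueError(f"unknown method {method!r}")
    if validate:
        fc.validate()
    order = fc.sorted_simplices()
    m = len(order)
    index = {s: i for i, (s, _) in enumerate(order)}
    dims = [len(s) - 1 for s, _ in order]
    values = [v for _, v in order]

    pairs: list[tuple[int, int]]
    if method == "boundary":
        columns = []
        for s, _ in order:
            col = 0
            if len(s) > 1:
                for f in itertools.combinations(s, len(s) - 1):
                    col |= 1 << index[f]
            columns.append(col)
        low_inv = _reduce_columns(columns)
        pairs = [(low, j) for low, j in low_inv.items()]
    else:
        # anti-transpose: row/column i' of the cohomology matrix corresponds
        # to simplex m-1-i'; entries are coface incidences
        cofaces: list[list[int]] = [[] for _ in range(m)]
        for j, (s, _) in enumerate(order):
            if len(s) > 1:
                for f in itertools.combinations(s, len(s) - 1):
                    cofaces[index[f]].append(j)
        columns = []
        for ip in range(m):
            i = m - 1 - ip
            col = 0
            for j in cofaces[i]:
                col |= 1 << (m - 1 - j)
            columns.append(col)
        low_inv = _reduce_columns(columns)
        pairs = [(m - 1 - jp, m - 1 - lowp) for lowp, jp in low_inv.items()]

    paired = set()
    bars: dict[int, list[tuple[float, float]]] = {0: [], 1: [], 2: []}
    for i, j in pairs:
        paired.add(i)
        paired.add(j)
        b, d = values[i], values[j]
        k = dims[i]
        if d > b and k in bars:
            bars[k].append((b, d))
    capped = 0
    for i in range(m):
        if i in paired:
            continue
        k = dims[i]
        if k == 0:
            bars[0].append((values[i], np.inf))
        elif k in bars:
            if fc.threshold is not None and fc.threshold > values[i]:
                bars[k].append((values[i], fc.threshold))
                capped += 1
            # otherwise the class never dies within the complex; for VR at
            # threshold = diameter and for AC this cannot happen in dims 1-2
            elif fc.threshold is None and fc.kind == "VR":
                bars[k].append((values[i], np.inf))
    if capped:
        warnings.warn(
            f"{capped} classes still alive at the VR threshold were capped there",
            stacklevel=2,
        )
    ks = (0, 1, 2) if include_dim0 else (1, 2)
    return {k: Barcode(k=k, intervals=np.array(bars[k]).reshape(-1, 2)) for k in ks}


def barcode_to_csv(barcodes: dict[int, Barcode]) -> str:
    """Serialize barcodes as CSV text with columns k, birth, death."""
    lines = ["k,birth,death"]
    for k in sorted(barcodes):
        for b, d in barcodes[k].intervals:
            lines.append(f"{k},{float(b)!r},{float(d)!r}")
    return "\n".join(lines) + "\n"
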