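"""Per-family pipeline: topological vs evolutionary distances.

For every unordered pair of structures in a family, the pipeline builds the
selected point clouds (optionally masked by confidence and/or pair-specific
indel maps), computes persistence barcodes in dimensions 1 and 2 under the
chosen filtration, derives the six PH-distances (bottleneck, Wasserstein
and landscape distance in each dimension), normalizes them by the average
point count of the pair, and compares them with the sequence-derived
distances (p-distance and patristic distance) by Pearson correlation.

Because indel masking is pair-specific, barcodes are cached keyed by the
retained-residue set of a structure, not by the structure alone.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import descriptors, evodist, structure_io, synthetic_data, topology

__all__ = [
    "FamilyBundle",
    "CorrelationResult",
    "load_bundle",
    "family_ph_distances",
    "family_ev_distances",
    "correlate_distances",
    "size_correlation_check",
    "gap_stratified_correlation",
    "homolog_null_comparison",
    "run_pipeline",
]

log = logging.getLogger("phylotda")

DEFAULT_GAP_BINS = ((0, 0), (1, 9), (10, 49), (50, None))


@dataclass
class FamilyBundle:
    """One protein family: structures + alignment + tree (+ optional truth)."""

    family_id: str
    structures: dict[str, structure_io.ProteinStructure]
    alignment: evodist.MultipleAlignment
    tree: "object"  # dendropy.Tree
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = set(self.structures)
        if ids != set(self.alignment.ids):
            raise ValueError(
                f"structure ids {sorted(ids)} do not match alignment ids "
                f"{sorted(self.alignment.ids)}"
            )
        leaf_ids = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        if ids != leaf_ids:
            raise ValueError("tree leaves do not match structure ids")
        for sid, s in self.structures.items():
            if s.sequence != self.alignment.ungapped(sid):
                raise ValueError(f"sequence of structure {sid!r} differs from alignment row")

    @classmethod
    def from_synthetic(cls, family: synthetic_data.SyntheticFamily, family_id: str) -> "FamilyBundle":
        return cls(
            family_id=family_id,
            structures={s.id: s for s in family.structures},
            alignment=family.alignment,
            tree=family.tree,
            truth=family.truth,
        )


def load_bundle(path: str, family_id: str | None = None) -> FamilyBundle:
    """Load a family bundle directory (alignment.fasta, tree.nwk, structures/)."""
    with open(os.path.join(path, "alignment.fasta")) as fh:
        alignment = evodist.read_alignment(fh.read())
    with open(os.path.join(path, "tree.nwk")) as fh:
        tree = evodist.read_newick(fh.read())
    structures = {}
    sdir = os.path.join(path, "structures")
    for fname in sorted(os.listdir(sdir)):
        if not fname.endswith(".pdb"):
            continue
        sid = fname[:-4]
        with open(os.path.join(sdir, fname)) as fh:
            structures[sid] = structure_io.read_structure(fh.read(), id=sid)
    truth = None
    tpath = os.path.join(path, "truth.csv")
    if os.path.exists(tpath):
        truth = pd.read_csv(tpath, index_col=0)
    return FamilyBundle(
        family_id=family_id or os.path.basename(os.path.normpath(path)),
        structures=structures,
        alignment=alignment,
        tree=tree,
        truth=truth,
    )


def _masked_cloud(
    bundle: FamilyBundle,
    sid: str,
    selector: str,
    use_ci: bool,
    ci_threshold: float,
    ci_strict: bool,
    indel_mask: list[int] | None,
) -> structure_io.PointCloud:
    s = bundle.structures[sid]
    pc = structure_io.extract_point_cloud(s, selector)
    if use_ci:
        pc = structure_io.mask_low_confidence(pc, s, threshold=ci_threshold, strict=ci_strict)
    if indel_mask:
        bad = set(indel_mask)
        keep = np.array([r not in bad for r in pc.residue_of_point], dtype=bool)
        from dataclasses import replace

        pc = replace(pc, points=pc.points[keep], residue_of_point=pc.residue_of_point[keep])
    return structure_io.deduplicate_points(pc)


class _BarcodeCache:
    """Barcodes keyed by (structure id, retained residue set, selector, filtration)."""

    def __init__(self) -> None:
        self._store: dict[tuple, dict[int, topology.Barcode]] = {}

    def get(self, pc: structure_io.PointCloud, sid: str, filtration: str):
        key = (sid, pc.selector, filtration, tuple(pc.residue_of_point.tolist()))
        if key not in self._store:
            if filtration == "AC":
                fc = topology.build_alpha_complex(pc)
            else:
                fc = topology.build_vietoris_rips(pc)
            self._store[key] = topology.compute_persistence(fc, validate=False)
        return self._store[key]


def family_ph_distances(
    bundle: FamilyBundle,
    filtration: str = "AC",
    metrics: tuple[str, ...] = ("btk", "ws", "ls"),
    ks: tuple[int, ...] = (1, 2),
    selector: str = "CA",
    masking: str = "none",
    ci_threshold: float = 70.0,
    ci_strict: bool = False,
    ws_root: bool = True,
    ls_root: bool = True,
    cache: _BarcodeCache | None = None,
) -> pd.DataFrame:
    """Long-format table of PH-distances for every unordered pair of a family.

    ``masking`` is one of ``none``, ``ci``, ``indel``, ``ci+indel``.  Pairs
    whose masked cloud drops below 4 points are skipped with a warning.
    Both the raw and the point-count-normalized distance are reported,
    together with the point counts actually used.  ``ws_root=False`` /
    ``ls_root=False`` switch to the literal sum-of-squares forms of the
    Wasserstein and landscape distances (no enclosing square root); the
    sum-of-squares form grows linearly with the number of points, which is
    the scaling for which the point-count normalization is exact.
    """
    if masking not in ("none", "ci", "indel", "ci+indel"):
        raise ValueError(f"unknown masking {masking!r}")
    if filtration not in ("AC", "VR"):
        raise ValueError(f"unknown filtration {filtration!r}")
    use_ci = "ci" in masking
    use_indel = "indel" in masking
    cache = cache or _BarcodeCache()
    ids = sorted(bundle.structures)
    records = []
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            idA, idB = ids[a_i], ids[b_i]
            pmap = evodist.pair_indel_map(bundle.alignment, idA, idB)
            maskA = pmap.residues_to_mask_A if use_indel else None
            maskB = pmap.residues_to_mask_B if use_indel else None
            try:
                pcA = _masked_cloud(bundle, idA, selector, use_ci, ci_threshold, ci_strict, maskA)
                pcB = _masked_cloud(bundle, idB, selector, use_ci, ci_threshold, ci_strict, maskB)
                if pcA.n < 4 or pcB.n < 4:
                    raise ValueError("cloud too small for 3D filtration")
                barsA = cache.get(pcA, idA, filtration)
                barsB = cache.get(pcB, idB, filtration)
            except ValueError as exc:
                log.warning("skipping pair (%s, %s) of %s: %s", idA, idB, bundle.family_id, exc)
                continue
            lsA = {k: descriptors.build_landscape(barsA[k]) for k in ks if "ls" in metrics}
            lsB = {k: descriptors.build_landscape(barsB[k]) for k in ks if "ls" in metrics}
            for k in ks:
                for metric in metrics:
                    if metric == "btk":
                        raw = descriptors.bottleneck_distance(barsA[k], barsB[k])
                    elif metric == "ws":
                        raw = descriptors.wasserstein_distance(barsA[k], barsB[k], root=ws_root)
                    elif metric == "ls":
                        raw = descriptors.landscape_distance(lsA[k], lsB[k], root=ls_root)
                    else:
                        raise ValueError(f"unknown metric {metric!r}")
                    records.append(
                        dict(
                            family_id=bundle.family_id,
                            idA=idA,
                            idB=idB,
                            metric=metric,
                            k=k,
                            filtration=filtration,
                            selector=selector,
                            masking=masking,
                            raw=raw,
                            normalized=descriptors.normalize_distance(raw, pcA.n, pcB.n),
                            nA=pcA.n,
                            nB=pcB.n,
                            gap_count=pmap.gap_count,
                        )
                    )
    return pd.DataFrame.from_records(records)


def family_ev_distances(bundle: FamilyBundle) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric p-distance and patristic (ML-)distance matrices, keyed by id."""
    ids = sorted(bundle.structures)
    n = len(ids)
    pmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pmat[i, j] = pmat[j, i] = evodist.p_distance(bundle.alignment, ids[i], ids[j])
    p_df = pd.DataFrame(pmat, index=ids, columns=ids)
    ml_df = evodist.patristic_matrix(bundle.tree).loc[ids, ids]
    return p_df, ml_df


@dataclass
class CorrelationResult:
    """Pearson correlation with parametric and optional permutation p-value."""

    r: float
    p_t: float
    p_perm: float | None
    n_pairs: int
    grouping: str = ""


def correlate_distances(
    x,
    y,
    permutations: int = 0,
    rng: np.random.Generator | int | None = None,
    labels: list[tuple[str, str, str]] | None = None,
    grouping: str = "",
) -> CorrelationResult:
    """Pearson correlation between two paired distance vectors.

    The parametric p-value comes from the usual t transform; because
    distance pairs sharing a protein are not independent, an optional
    permutation p-value is computed by permuting protein labels within each
    family (Mantel-style) when ``labels`` (family_id, idA, idB) are given,
    or by plain permutation of ``y`` otherwise.  One-sided toward the sign
    of the observed correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in distance vectors")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    r, p_t = stats.pearsonr(x, y)
    p_perm = None
    if permutations > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        sign = 1.0 if r >= 0 else -1.0
        hits = 0
        if labels is None:
            for _ in range(permutations):
                rp = stats.pearsonr(x, gen.permutation(y))[0]
                if sign * rp >= sign * r:
                    hits += 1
        else:
            by_family: dict[str, list[int]] = {}
            for idx, (fam, _, _) in enumerate(labels):
                by_family.setdefault(fam, []).append(idx)
            value = {
                (fam, frozenset((a, b))): y[idx]
                for idx, (fam, a, b) in enumerate(labels)
            }
            fam_ids = {
                fam: sorted({p for i in idxs for p in (labels[i][1], labels[i][2])})
                for fam, idxs in by_family.items()
            }
            for _ in range(permutations):
                yp = np.empty_like(y)
                for fam, idxs in by_family.items():
                    members = fam_ids[fam]
                    perm = dict(zip(members, gen.permutation(members)))
                    for i in idxs:
                        _, a, b = labels[i]
                        yp[i] = value[(fam, frozenset((perm[a], perm[b])))]
                rp = stats.pearsonr(x, yp)[0]
                if sign * rp >= sign * r:
                    hits += 1
        p_perm = (1 + hits) / (1 + permutations)
    return CorrelationResult(
        r=float(r), p_t=float(p_t), p_perm=p_perm, n_pairs=len(x), grouping=grouping
    )


def size_correlation_check(table: pd.DataFrame, use_normalized: bool) -> CorrelationResult:
    """Correlate (raw or normalized) distance against mean pair point count."""
    if table.empty:
        raise ValueError("empty distance table")
    col = "normalized" if use_normalized else "raw"
    size = (table["nA"] + table["nB"]) / 2.0
    return correlate_distances(
        size.to_numpy(), table[col].to_numpy(), grouping=f"size-vs-{col}"
    )


def _pair_ev(table: pd.DataFrame, ev: dict[str, pd.DataFrame]) -> np.ndarray:
    return np.array(
        [ev[f].loc[a, b] for f, a, b in zip(table["family_id"], table["idA"], table["idB"])]
    )


def gap_stratified_correlation(
    table: pd.DataFrame,
    ev: dict[str, pd.DataFrame],
    bins=DEFAULT_GAP_BINS,
) -> list[tuple[str, CorrelationResult]]:
    """Per-gap-count-bin correlation of normalized PH- vs EV-distance.

    ``ev`` maps family_id to a square EV-distance matrix.  Bins with fewer
    than 3 pairs are dropped with a log warning.
    """
    out = []
    gaps = table["gap_count"].to_numpy()
    evv = _pair_ev(table, ev)
    for lo, hi in bins:
        label = f"{lo}+" if hi is None else f"{lo}-{hi}"
        sel = (gaps >= lo) if hi is None else (gaps >= lo) & (gaps <= hi)
        if sel.sum() < 3:
            log.warning("gap bin %s has %d pairs; dropped", label, int(sel.sum()))
            continue
        try:
            res = correlate_distances(
                evv[sel], table["normalized"].to_numpy()[sel], grouping=f"gaps {label}"
            )
        except ValueError as exc:
            log.warning("gap bin %s: %s", label, exc)
            continue
        out.append((label, res))
    return out


def homolog_null_comparison(
    families: list[FamilyBundle],
    n_pairs: int = 500,
    seed: int = 0,
    filtration: str = "AC",
    k: int = 1,
    selector: str = "CA",
) -> dict:
    """Compare normalized Wasserstein distances of homologous vs nonhomologous pairs.

    Samples ``n_pairs`` within-family (homologous) and ``n_pairs``
    cross-family (nonhomologous) structure pairs, computes normalized
    Ws-distances for both sets and tests one-sided (rank-sum) whether
    nonhomologous distances are larger.
    """
    if len(families) < 2:
        raise ValueError("need at least 2 families")
    rng = np.random.default_rng(seed)
    cache = _BarcodeCache()

    def barcode(fam: FamilyBundle, sid: str):
        pc = structure_io.deduplicate_points(
            structure_io.extract_point_cloud(fam.structures[sid], selector)
        )
        return cache.get(pc, f"{fam.family_id}/{sid}", filtration), pc.n

    within_pool = [
        (fi, a, b)
        for fi, fam in enumerate(families)
        for i, a in enumerate(sorted(fam.structures))
        for b in sorted(fam.structures)[i + 1 :]
    ]
    cross_pool = []
    for fi in range(len(families)):
        for fj in range(fi + 1, len(families)):
            for a in sorted(families[fi].structures):
                for b in sorted(families[fj].structures):
                    cross_pool.append((fi, a, fj, b))
    if len(within_pool) < 1 or len(cross_pool) < 1:
        raise ValueError("insufficient pairs")
    n_within = min(n_pairs, len(within_pool))
    n_cross = min(n_pairs, len(cross_pool))
    within_sel = [within_pool[i] for i in rng.choice(len(within_pool), n_within, replace=False)]
    cross_sel = [cross_pool[i] for i in rng.choice(len(cross_pool), n_cross, replace=False)]

    hom = []
    for fi, a, b in within_sel:
        (barsA, nA), (barsB, nB) = barcode(families[fi], a), barcode(families[fi], b)
        d = descriptors.wasserstein_distance(barsA[k], barsB[k])
        hom.append(descriptors.normalize_distance(d, nA, nB))
    nonhom = []
    for fi, a, fj, b in cross_sel:
        (barsA, nA), (barsB, nB) = barcode(families[fi], a), barcode(families[fj], b)
        d = descriptors.wasserstein_distance(barsA[k], barsB[k])
        nonhom.append(descriptors.normalize_distance(d, nA, nB))
    u, p = stats.mannwhitneyu(nonhom, hom, alternative="greater")
    return dict(
        n_homologous=len(hom),
        n_nonhomologous=len(nonhom),
        median_homologous=float(np.median(hom)),
        median_nonhomologous=float(np.median(nonhom)),
        u_statistic=float(u),
        p_value=float(p),
        homologous=hom,
        nonhomologous=nonhom,
    )


def run_pipeline(config_path: str) -> str:
    """Run the full pipeline from a YAML config; returns the output directory.

    The config lists family bundle paths (``families:``) or synthesis
    parameters (``synth:``), plus distance options.  Outputs: the long
    distance table, per-family EV matrices, a JSON correlation report, a
    scatter plot and a log file.  A family-level failure is logged and the
    family skipped; the run fails only if every family fails.
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out_dir = cfg.get("out_dir", "phylotda_out")
    os.makedirs(out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out_dir, "pipeline.log"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seed = int(cfg.get("seed", 0))

    bundles: list[FamilyBundle] = []
    for path in cfg.get("families", []):
        try:
            bundles.append(load_bundle(path))
        except Exception as exc:
            log.error("failed to load family %s: %s", path, exc)
    synth = cfg.get("synth")
    if synth:
        n_families = int(synth.pop("n_families", 1))
        for i in range(n_families):
            fam_cfg = synthetic_data.SyntheticFamilyConfig(
                seed=seed + 1000 * i, **{k: v for k, v in synth.items() if k != "seed"}
            )
            fam = synthetic_data.make_family(fam_cfg)
            bundles.append(FamilyBundle.from_synthetic(fam, f"synth{i}"))
    if not bundles:
        raise SystemExit("no families to process")

    filtration = cfg.get("filtration", "AC")
    selector = cfg.get("selector", "CA")
    masking = cfg.get("masking", "none")
    metrics = tuple(cfg.get("metrics", ["btk", "ws", "ls"]))
    ks = tuple(cfg.get("k", [1, 2]))
    permutations = int(cfg.get("permutations", 0))

    tables, ev_p, ev_ml = [], {}, {}
    failed = 0
    for bundle in bundles:
        try:
            tab = family_ph_distances(
                bundle,
                filtration=filtration,
                metrics=metrics,
                ks=ks,
                selector=selector,
                masking=masking,
                ci_threshold=float(cfg.get("ci_threshold", 70.0)),
            )
            p_df, ml_df = family_ev_distances(bundle)
        except Exception as exc:
            log.error("family %s failed: %s", bundle.family_id, exc)
            failed += 1
            continue
        tables.append(tab)
        ev_p[bundle.family_id] = p_df
        ev_ml[bundle.family_id] = ml_df
        p_df.to_csv(os.path.join(out_dir, f"pdist_{bundle.family_id}.csv"))
        ml_df.to_csv(os.path.join(out_dir, f"mldist_{bundle.family_id}.csv"))
    if failed == len(bundles):
        raise SystemExit("all families failed")
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(os.path.join(out_dir, "ph_distances.csv"), index=False)

    report = {}
    for metric in metrics:
        for k in ks:
            sub = table[(table["metric"] == metric) & (table["k"] == k)]
            if sub.empty:
                continue
            labels = list(zip(sub["family_id"], sub["idA"], sub["idB"]))
            for ev_name, ev in (("p", ev_p), ("ml", ev_ml)):
                res = correlate_distances(
                    _pair_ev(sub, ev),
                    sub["normalized"].to_numpy(),
                    permutations=permutations,
                    rng=seed,
                    labels=labels,
                    grouping=f"{metric}{k} vs {ev_name}-distance",
                )
                report[f"{metric}{k}_vs_{ev_name}"] = dict(
                    r=res.r, p_t=res.p_t, p_perm=res.p_perm, n_pairs=res.n_pairs
                )
    with open(os.path.join(out_dir, "correlations.json"), "w") as fh:
        json.dump(report, fh, indent=2)

    try:  # basic scatter of the headline comparison
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        sub = table[(table["metric"] == "ws") & (table["k"] == 1)]
        if not sub.empty:
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter(_pair_ev(sub, ev_ml), sub["normalized"], s=8, alpha=0.5)
            ax.set_xlabel("patristic distance (subst./site)")
            ax.set_ylabel("normalized Ws-distance (k=1)")
            fig.tight_layout()
            fig.savefig(os.path.join(out_dir, "ws1_vs_ml.png"), dpi=120)
            plt.close(fig)
    except Exception as exc:  # plotting is best-effort
        log.warning("plotting failed: %s", exc)
    log.removeHandler(handler)
    handler.close()
    return out_dir
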