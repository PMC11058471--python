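import numpy as np
import pytest
from scipy import stats

import phylotda as pt
from phylotda import synthetic_data as sd


class TestSimulateTree:
    def test_shape_and_determinism(self):
        t1 = sd.simulate_tree(7, 1.0, seed=1)
        assert len(t1.leaf_nodes()) == 7
        edges = [e for e in t1.preorder_edge_iter() if e.length is not None]
        assert len(edges) == 2 * 7 - 2
        t2 = sd.simulate_tree(7, 1.0, seed=1)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_small_family_rejected(self):
        with pytest.raises(ValueError, match="at least 7"):
            sd.simulate_tree(5, 1.0, seed=0)

    def test_birth_rate_scales_tree_length(self):
        """Yule expectation: total length scales as 1/birth_rate."""

        def total(rate, seed):
            t = sd.simulate_tree(10, rate, seed)
            return sum(e.length for e in t.preorder_edge_iter() if e.length is not None)

        lo = np.mean([total(1.0, s) for s in range(30)])
        hi = np.mean([total(10.0, s) for s in range(30)])
        assert lo / hi == pytest.approx(10.0, rel=0.35)


class TestEvolveFamily:
    def test_null_model(self):
        cfg = sd.SyntheticFamilyConfig(n_taxa=7, seq_length=40, sub_rate=0.0, indel_rate=0.0, seed=3)
        tree = sd.simulate_tree(7, 1.0, seed=3)
        aln, _, _ = sd.evolve_family(tree, cfg)
        assert len(set(aln.rows)) == 1 and "-" not in aln.rows[0]
        for a in aln.ids:
            for b in aln.ids:
                if a != b:
                    assert pt.p_distance(aln, a, b) == 0.0

    def test_no_indels_keeps_alignment_length(self):
        cfg = sd.SyntheticFamilyConfig(n_taxa=7, seq_length=55, indel_rate=0.0, seed=4)
        aln, _, _ = sd.evolve_family(sd.simulate_tree(7, 1.0, seed=4), cfg)
        assert aln.ncol == 55

    def test_p_distance_matches_20_state_closed_form(self):
        """E[p] = (19/20)(1 - exp(-(20/19) d)) at patristic distance d."""
        cfg = sd.SyntheticFamilyConfig(n_taxa=7, seq_length=1000, indel_rate=0.0, seed=5)
        tree = sd.simulate_tree(7, 1.0, seed=5)
        aln, _, _ = sd.evolve_family(tree, cfg)
        truth = pt.patristic_matrix(tree)
        errs = []
        for i, a in enumerate(aln.ids):
            for b in aln.ids[i + 1 :]:
                d = truth.loc[a, b]
                expected = (19 / 20) * (1 - np.exp(-(20 / 19) * d))
                errs.append(pt.p_distance(aln, a, b) - expected)
        # per-pair binomial error ~ sqrt(p(1-p)/1000) <= 0.016
        assert np.max(np.abs(errs)) < 0.05
        assert abs(np.mean(errs)) < 0.02


class TestBuildStructures:
    def test_null_model_identical_structures(self):
        cfg = sd.SyntheticFamilyConfig(
            n_taxa=7, seq_length=40, sub_rate=0.0, indel_rate=0.0,
            struct_noise_sd=0.0, low_ci_fraction=0.0, seed=6,
        )
        fam = sd.make_family(cfg)
        ref = np.array([a.coords for a in fam.structures[0].atoms])
        for s in fam.structures[1:]:
            np.testing.assert_allclose(np.array([a.coords for a in s.atoms]), ref, atol=1e-12)

    def test_root_backbone_spacing_exact(self):
        rng = np.random.default_rng(0)
        xyz = sd._root_backbone(80, rng)
        steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        np.testing.assert_allclose(steps, sd.CA_SPACING, atol=1e-9)

    def test_brownian_displacement_variance(self):
        """Mean squared CA displacement between leaves is 3*sd^2*patristic."""
        sd_noise = 0.8
        cfg = sd.SyntheticFamilyConfig(
            n_taxa=8, seq_length=400, indel_rate=0.0, sub_rate=0.0,
            struct_noise_sd=sd_noise, low_ci_fraction=0.0, seed=7,
        )
        tree = sd.simulate_tree(8, 1.0, seed=7)
        rng = np.random.default_rng(8)
        aln, gen, states = sd.evolve_family(tree, cfg, rng)
        structs = {s.id: s for s in sd.build_structures(tree, aln, gen, cfg, rng, states)}
        truth = pt.patristic_matrix(tree)
        ratios = []
        ids = sorted(structs)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                xa = np.array([at.coords for at in structs[a].atoms])
                xb = np.array([at.coords for at in structs[b].atoms])
                msd = np.mean(np.sum((xa - xb) ** 2, axis=1))
                ratios.append(msd / (3 * sd_noise**2 * truth.loc[a, b]))
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.2)

    def test_sequences_match_ungapped_rows_with_indels(self):
        fam = sd.make_family(
            sd.SyntheticFamilyConfig(n_taxa=8, seq_length=60, indel_rate=0.8, seed=9)
        )
        assert any("-" in row for row in fam.alignment.rows)
        for s in fam.structures:
            assert s.sequence == fam.alignment.ungapped(s.id)
            assert s.n_residues == len(s.sequence)

    def test_sidechain_atoms_flag(self):
        fam = sd.make_family(
            sd.SyntheticFamilyConfig(n_taxa=7, seq_length=40, seed=10, sidechain_atoms=True)
        )
        s = fam.structures[0]
        for sel, lo in (("ALL_C", 80), ("ALL_N", 15), ("ALL_O", 15)):
            assert pt.extract_point_cloud(s, sel).n >= lo


class TestAssignConfidence:
    def test_boundaries(self, small_family):
        base = small_family.structures
        all_high = sd.assign_confidence(base, 0.0, seed=1)
        assert all(min(s.confidence_by_residue().values()) >= 85 for s in all_high)
        all_low = sd.assign_confidence(base, 1.0, seed=1)
        assert all(max(s.confidence_by_residue().values()) < 70 for s in all_low)
        s = all_low[0]
        pc = pt.extract_point_cloud(s, "CA")
        with pytest.raises(ValueError, match="empty cloud"):
            pt.mask_low_confidence(pc, s, threshold=70)

    def test_deterministic(self, small_family):
        a = sd.assign_confidence(small_family.structures, 0.1, seed=5)
        b = sd.assign_confidence(small_family.structures, 0.1, seed=5)
        for sa, sb in zip(a, b):
            assert sa.confidence_by_residue() == sb.confidence_by_residue()

    def test_fraction_validated(self, small_family):
        with pytest.raises(ValueError):
            sd.assign_confidence(small_family.structures, 1.5, seed=0)


class TestDeterminism:
    def test_family_byte_identical(self, tmp_path):
        from phylotda.structure_io import structure_to_pdb
        from phylotda.evodist import alignment_to_fasta

        cfg = sd.SyntheticFamilyConfig(n_taxa=7, seq_length=50, indel_rate=0.3, seed=42)
        f1, f2 = sd.make_family(cfg), sd.make_family(cfg)
        assert alignment_to_fasta(f1.alignment) == alignment_to_fasta(f2.alignment)
        assert f1.tree.as_string(schema="newick") == f2.tree.as_string(schema="newick")
        for a, b in zip(f1.structures, f2.structures):
            assert structure_to_pdb(a) == structure_to_pdb(b)

    def test_bundle_roundtrip(self, tmp_path, small_family):
        sd.write_bundle(small_family, str(tmp_path / "fam"))
        bundle = pt.load_bundle(str(tmp_path / "fam"))
        assert set(bundle.structures) == set(small_family.alignment.ids)
        assert bundle.truth is not None
        np.testing.assert_allclose(
            bundle.truth.values, small_family.truth.values, atol=1e-6
        )


def test_structural_signal_increases_with_noise():
    """Spearman(truth, raw Ws) grows with the Brownian scale.

    Under the default conditions the low-confidence residues contribute a
    fixed noise floor, so the coupling strengthens as the evolutionary
    displacement rises above it (and would decay again once the cloud
    scrambles, beyond the compared regime).
    """

    def spearmans(noise_sd):
        rhos = []
        for seed in (1, 2, 3):
            fam = sd.make_family(
                sd.SyntheticFamilyConfig(
                    n_taxa=10, seq_length=120,
                    struct_noise_sd=noise_sd, seed=seed,
                )
            )
            bundle = pt.FamilyBundle.from_synthetic(fam, f"n{noise_sd}s{seed}")
            tab = pt.family_ph_distances(bundle, metrics=("ws",), ks=(1,))
            ev = [fam.truth.loc[a, b] for a, b in zip(tab.idA, tab.idB)]
            rhos.append(stats.spearmanr(ev, tab.raw).statistic)
        return np.array(rhos)

    # compared within the small-noise regime: at large noise the cloud
    # scrambles, topological distances saturate and the coupling decays;
    # paired per-seed comparison controls the family-level randomness
    lo, hi = spearmans(0.15), spearmans(0.5)
    assert hi.mean() > 0
    assert hi.mean() > lo.mean()
    assert (hi > lo).sum() >= 2
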