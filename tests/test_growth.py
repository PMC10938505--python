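"""Chain-growth engine tests: merging, pools, full ensembles, mixed assembly."""

import numpy as np
import pytest

from rnagrow.errors import GrowthFailureError, InputError
from rnagrow.fragments import plan_tiling, synth_fragment_library
from rnagrow.growth import (ChainEnsemble, GrowthConfig, MergeRejection,
                            assemble_mixed, attempt_merge, grow_ensemble,
                            grow_level, validate_ensemble, validate_member)
from rnagrow.model import radius_of_gyration
from rnagrow.templates import build_chain_from_torsions, build_ideal_aform, \
    ideal_internal_coords


class TestAttemptMerge:
    def test_ideal_pair_accepted(self, ideal_a4):
        merged = attempt_merge(ideal_a4, ideal_a4)
        assert not isinstance(merged, MergeRejection)
        assert merged.sequence == "AAAAAA"
        assert merged.n_residues == 6
        d = np.linalg.norm(merged.atom_coords(3, "O3'") - merged.atom_coords(4, "P"))
        assert d < 1.8

    def test_merged_is_continuous(self, ideal_a4):
        merged = attempt_merge(ideal_a4, ideal_a4)
        merged.check_continuity()

    def test_merged_equals_ideal_hexamer(self, ideal_a4):
        # merging ideal pieces reproduces the ideal helix (after superposition)
        from rnagrow.geom import weighted_superposition
        merged = attempt_merge(ideal_a4, ideal_a4)
        ideal6 = build_ideal_aform("A" * 6)
        assert merged.n_atoms == ideal6.n_atoms
        _, _, w = weighted_superposition(merged.coords, ideal6.coords)
        assert w < 1e-6

    def test_rmsd_rejection(self, ideal_a4):
        # flip the base of piece2's second nucleotide: overlap atoms cannot fit
        bad = build_chain_from_torsions(
            "AAAA", chi_offsets=[0.0, 170.0, 0.0, 0.0])
        res = attempt_merge(ideal_a4, bad)
        assert isinstance(res, MergeRejection)
        assert res.reason == "rmsd"
        assert res.value >= 0.64

    def test_clash_rejection(self, ideal_a4):
        # piece2 bends back sharply after its overlap region so its tail
        # collides with piece1 (junction geometry itself stays ideal)
        ic = ideal_internal_coords()
        n = 8
        eps = np.full(n, ic["epsilon"])
        zeta = np.full(n, ic["zeta"])
        alpha = np.full(n, ic["alpha"])
        # A hairpin-like kink right after the aligned nucleotides
        eps[1] += 120.0
        zeta[2] -= 140.0
        alpha[3] += 120.0
        piece2 = build_chain_from_torsions(
            "A" * n, {"epsilon": eps, "zeta": zeta, "alpha": alpha})
        piece1 = build_ideal_aform("A" * 8)
        res = attempt_merge(piece1, piece2)
        assert isinstance(res, MergeRejection)
        assert res.reason == "clash"

    def test_junction_phosphate_from_piece2(self, ideal_a4):
        # mark piece2's bridging P by a tiny offset and find it in the merge
        p2 = ideal_a4.copy()
        idx = p2.atom_index(2, "P")
        p2.coords[idx] += 1e-4
        merged = attempt_merge(ideal_a4, p2)
        # bridging phosphate lives at merged residue 4
        from rnagrow.geom import weighted_superposition
        assert merged.sequence == "AAAAAA"


class TestGrowLevel:
    def test_single_conformer_pools(self, ideal_a4):
        rng = np.random.default_rng(0)
        out, rate = grow_level([ideal_a4], [ideal_a4], 5, GrowthConfig(), rng)
        assert len(out) == 5
        assert rate == 1.0
        for a, b in zip(out, out[1:]):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_determinism(self, noisy_a4_lib):
        cfg = GrowthConfig(n_chains=10)
        pool = noisy_a4_lib.conformers
        out1, _ = grow_level(pool, pool, 10, cfg, np.random.default_rng(42))
        out2, _ = grow_level(pool, pool, 10, cfg, np.random.default_rng(42))
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_zero_noise_acceptance_one(self, single_conformer_a4_lib):
        pool = single_conformer_a4_lib.conformers
        _, rate = grow_level(pool, pool, 20, GrowthConfig(),
                             np.random.default_rng(1))
        assert rate == 1.0

    def test_exhaustion_raises(self, ideal_a4):
        bad = build_chain_from_torsions("AAAA", chi_offsets=[0, 170.0, 0, 0])
        cfg = GrowthConfig(max_attempts=5)
        with pytest.raises(GrowthFailureError) as err:
            grow_level([ideal_a4], [bad], 3, cfg, np.random.default_rng(0))
        assert err.value.acceptance_rate == 0.0

    def test_empty_pool(self, ideal_a4):
        with pytest.raises(InputError):
            grow_level([], [ideal_a4], 1, GrowthConfig(), np.random.default_rng(0))


class TestGrowEnsemble:
    def test_degenerate_identity_ra30(self, single_conformer_a4_lib):
        plan = plan_tiling("A" * 30, "homopolymer")
        cfg = GrowthConfig(n_chains=1, seed=0)
        ens = grow_ensemble(plan, {"AAAA": single_conformer_a4_lib}, cfg)
        assert len(ens) == 1
        member = ens.members[0]
        assert member.sequence == "A" * 30
        rg_direct = radius_of_gyration(build_ideal_aform("A" * 30))
        assert radius_of_gyration(member) == pytest.approx(rg_direct, abs=1e-6)

    def test_hexamer_heteropolymer_sequence(self):
        plan = plan_tiling("UCAAUC", "heteropolymer")
        libs = {k: synth_fragment_library(k, 20, noise=3.0, seed=i)
                for i, k in enumerate(set(plan.fragment_keys))}
        cfg = GrowthConfig(n_chains=15, seed=5)
        ens = grow_ensemble(plan, libs, cfg)
        assert len(ens) == 15
        assert all(m.sequence == "UCAAUC" for m in ens.members)
        np.testing.assert_allclose(ens.weights.sum(), 1.0, atol=1e-12)

    def test_seeded_reproducibility(self, noisy_a4_lib):
        plan = plan_tiling("A" * 10, "homopolymer")
        cfg = GrowthConfig(n_chains=8, seed=77)
        e1 = grow_ensemble(plan, {"AAAA": noisy_a4_lib}, cfg)
        e2 = grow_ensemble(plan, {"AAAA": noisy_a4_lib}, cfg)
        for a, b in zip(e1.members, e2.members):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_odd_length_with_cap(self, noisy_a4_lib):
        plan = plan_tiling("A" * 19, "homopolymer")
        ens = grow_ensemble(plan, {"AAAA": noisy_a4_lib},
                            GrowthConfig(n_chains=5, seed=1))
        assert all(m.sequence == "A" * 19 for m in ens.members)

    def test_missing_library(self):
        plan = plan_tiling("A" * 10, "homopolymer")
        with pytest.raises(InputError):
            grow_ensemble(plan, {}, GrowthConfig(n_chains=2))

    def test_members_validate_clean(self, noisy_a4_lib):
        plan = plan_tiling("A" * 14, "homopolymer")
        ens = grow_ensemble(plan, {"AAAA": noisy_a4_lib},
                            GrowthConfig(n_chains=20, seed=3))
        report = validate_ensemble(ens)
        assert report["total_clashes"] == 0

    def test_torsion_distributions_retained(self, noisy_a4_lib):
        # interior torsions of grown chains match the library's (KS distance)
        from rnagrow.model import backbone_torsions
        plan = plan_tiling("A" * 14, "homopolymer")
        ens = grow_ensemble(plan, {"AAAA": noisy_a4_lib},
                            GrowthConfig(n_chains=60, seed=8))
        for key in ("beta", "gamma", "chi"):
            lib_vals = np.concatenate([
                backbone_torsions(c)[key][1:3] for c in noisy_a4_lib.conformers])
            grown_vals = np.concatenate([
                backbone_torsions(m)[key][2:-2] for m in ens.members[:30]])
            lib_vals = np.sort(lib_vals[~np.isnan(lib_vals)])
            grown_vals = np.sort(grown_vals[~np.isnan(grown_vals)])
            from scipy.stats import ks_2samp
            stat = ks_2samp(lib_vals, grown_vals).statistic
            assert stat < 0.12, key


class TestAssembleMixed:
    def _hairpin_library(self, n=1, seq="GGGAAACCC"):
        # a rigid 'structured' segment: single ideal-helix conformer(s)
        from rnagrow.fragments import FragmentLibrary
        confs = [build_ideal_aform(seq) for _ in range(n)]
        return FragmentLibrary(seq, confs, {"structured": True})

    def test_structured_parts_internally_rigid(self):
        hp = self._hairpin_library()
        # overlap convention: segments overlap by 2 nt, so the 5' flank's
        # untrimmed chain must end with the hairpin's first 2 nt (G,G) and
        # the 3' flank's untrimmed chain starts G,C against its ...C,C end
        plan5 = plan_tiling("AAAAGG", "heteropolymer", final_cap_base="G")
        plan3 = plan_tiling("CCUUUU", "heteropolymer")
        libs = {}
        for key in set(plan5.fragment_keys) | set(plan3.fragment_keys):
            libs[key] = synth_fragment_library(key, 15, noise=2.5, seed=hash(key) % 100)
        cfg = GrowthConfig(rmsd_cutoff=1.0, n_chains=6, seed=2, max_attempts=2000)
        ens = assemble_mixed(
            [{"flexible": plan5}, {"structured": hp}, {"flexible": plan3}],
            cfg, libraries=libs)
        # the hairpin interior must be rigid: superimposing its atoms back
        # onto the source conformer gives ~0 RMSD
        from rnagrow.geom import weighted_superposition
        src = hp.conformers[0]
        n5 = len(plan5.assembled_sequence())
        for m in ens.members:
            # hairpin occupies residues n5-1 .. n5+7 (2-nt overlaps merge)
            start = n5 - 1
            idx = [m.atom_index(start + i, nm)
                   for i in range(1, 8)
                   for nm in ("P", "C1'", "N9" if src.sequence[i] in "AG" else "N1")
                   if m.has_atom(start + i, nm)]
            src_idx = [src.atom_index(1 + i, nm)
                       for i in range(1, 8)
                       for nm in ("P", "C1'", "N9" if src.sequence[i] in "AG" else "N1")
                       if src.has_atom(1 + i, nm)]
            _, _, w = weighted_superposition(
                m.coords[idx], src.coords[src_idx])
            assert w < 1e-6

    def test_all_structured_deterministic(self):
        a = self._hairpin_library(seq="GGGGAAAA")
        b = self._hairpin_library(seq="AAUUUUCC")
        cfg = GrowthConfig(rmsd_cutoff=1.0, n_chains=3, seed=0)
        ens = assemble_mixed([{"structured": a}, {"structured": b}], cfg)
        assert len(ens) == 3
        for m in ens.members:
            assert m.sequence == "GGGGAAA" + "AUUUUCC"
            np.testing.assert_array_equal(m.coords, ens.members[0].coords)

    def test_members_continuous(self):
        a = self._hairpin_library(seq="GGGGAAAA")
        b = self._hairpin_library(seq="AAUUUUCC")
        cfg = GrowthConfig(rmsd_cutoff=1.0, n_chains=2, seed=0)
        ens = assemble_mixed([{"structured": a}, {"structured": b}], cfg)
        for m in ens.members:
            m.check_continuity()


class TestLibraryEquivalence:
    def test_homo_and_hetero_tilings_indistinguishable(self):
        # same poly-A target grown from rA4 vs G-capped rGA3 libraries gives
        # statistically indistinguishable R_G distributions (alpha = 0.01)
        from scipy.stats import ks_2samp
        kw = dict(noise=8.0, unstack_prob=0.35, kink_prob=0.4)
        lib_a4 = synth_fragment_library("AAAA", 200, seed=31, **kw)
        lib_ga3 = synth_fragment_library("GAAA", 200, seed=32, **kw)
        e1 = grow_ensemble(plan_tiling("A" * 30, "homopolymer"),
                           {"AAAA": lib_a4}, GrowthConfig(n_chains=400, seed=33))
        e2 = grow_ensemble(plan_tiling("A" * 30, "heteropolymer"),
                           {"GAAA": lib_ga3}, GrowthConfig(n_chains=400, seed=34))
        rg1 = [radius_of_gyration(m) for m in e1.members]
        rg2 = [radius_of_gyration(m) for m in e2.members]
        assert ks_2samp(rg1, rg2).pvalue > 0.01


class TestEnsembleInvariants:
    def test_weights_normalized(self, noisy_a4_lib):
        plan = plan_tiling("A" * 8, "homopolymer")
        ens = grow_ensemble(plan, {"AAAA": noisy_a4_lib},
                            GrowthConfig(n_chains=12, seed=0))
        assert abs(ens.weights.sum() - 1.0) < 1e-12
        assert len({m.sequence for m in ens.members}) == 1

    def test_mismatched_weights_rejected(self, ideal_a4):
        with pytest.raises(InputError):
            ChainEnsemble([ideal_a4], np.array([0.5, 0.5]))
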