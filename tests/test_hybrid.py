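"""Fixed-difference ascertainment, F_He arithmetic, hybrid classification."""

import numpy as np
import pytest

from hyploscan import hybrid
from hyploscan.hybrid import (
    HybridReport,
    ascertain_fixed,
    classify,
    f_he,
    score_all,
    score_sample,
)
from hyploscan.simulate import SimConfig, simulate_dataset
from hyploscan.vcfio import MISSING

from conftest import make_gm


def groups(n_s=6, n_n=6):
    return ([f"S{i:02d}" for i in range(1, n_s + 1)],
            [f"N{i:02d}" for i in range(1, n_n + 1)])


class TestFHeArithmetic:
    # printed (n_All, n_He) pairs from deep-resequenced hybrid genets
    @pytest.mark.parametrize("n_all,n_he,expected", [
        (905_228, 898_702, 0.9928),
        (896_152, 775_251, 0.8651),
    ])
    def test_ratio_reproduces_published_value(self, n_all, n_he, expected):
        assert round(f_he(n_he, n_all), 4) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            f_he(5, 0)
        with pytest.raises(ValueError):
            f_he(10, 5)


class TestAscertainment:
    def test_simple_fixed_locus_oriented(self):
        # S group hom-ALT, N group hom-REF at locus 0; polymorphic at locus 1
        gm = make_gm([[2, 1], [2, 0], [0, 2], [0, 2]], samples=["a", "b", "c", "d"])
        panel = ascertain_fixed(gm, ["a", "b"], ["c", "d"])
        assert list(panel.variant_idx) == [0]
        assert panel.s_is_alt.tolist() == [True]

    def test_within_group_polymorphism_blocks_ascertainment(self):
        gm = make_gm([[2, 2], [2, 1], [0, 0], [0, 0]], samples=["a", "b", "c", "d"])
        panel = ascertain_fixed(gm, ["a", "b"], ["c", "d"], freq_tol=0.0)
        assert list(panel.variant_idx) == [0]

    def test_matches_truth_fixed_set_exactly(self):
        # no U-shaped within-clade polymorphism: chance reciprocal fixation
        # of a non-fixed locus is essentially impossible, so the
        # ascertained set is exactly the generator's fixed set
        cfg = SimConfig(n_loci=5000, prop_fixed=0.3, prop_shared_poly=0.0,
                        n_S=6, n_N=6, error_rate=0.0, genotype_error_rate=0.0,
                        missing_rate=0.0, seed=31)
        gm, _, panel_truth = simulate_dataset(cfg)
        gs, gn = groups()
        panel = ascertain_fixed(gm, gs, gn, freq_tol=0.0)
        assert np.array_equal(panel.variant_idx, np.flatnonzero(panel_truth.is_fixed))
        assert np.array_equal(panel.s_is_alt, panel_truth.s_is_alt[panel_truth.is_fixed])

    def test_superset_of_truth_and_bruteforce_consistent(self, mixed_panel):
        # with within-clade polymorphism, sampling can fix extra loci in
        # the finite parental sample; ascertainment must still contain all
        # truth-fixed loci and agree with a naive recomputation
        gm, truth, panel_truth = mixed_panel
        gs, gn = groups()
        panel = ascertain_fixed(gm, gs, gn, freq_tol=0.0, max_missing=0.0)
        assert set(np.flatnonzero(panel_truth.is_fixed)) <= set(panel.variant_idx)
        s_idx = [gm.sample_index(s) for s in gs]
        n_idx = [gm.sample_index(s) for s in gn]
        naive = []
        for j in range(gm.n_variants):
            s_g, n_g = gm.g[s_idx, j], gm.g[n_idx, j]
            if (s_g == MISSING).any() or (n_g == MISSING).any():
                continue
            fs, fn = s_g.mean() / 2, n_g.mean() / 2
            if (fs == 1 and fn == 0) or (fs == 0 and fn == 1):
                naive.append(j)
        assert list(panel.variant_idx) == naive

    def test_group_preconditions(self):
        gm = make_gm([[0, 1], [0, 1], [2, 1], [2, 1]], samples=list("abcd"))
        with pytest.raises(ValueError):
            ascertain_fixed(gm, [], ["c", "d"])
        with pytest.raises(ValueError):
            ascertain_fixed(gm, ["a", "b"], ["b", "c"])

    def test_zero_ascertained_warns(self):
        gm = make_gm([[1, 1], [1, 1], [1, 1], [1, 1]], samples=list("abcd"))
        with pytest.warns(UserWarning):
            panel = ascertain_fixed(gm, ["a", "b"], ["c", "d"])
        assert panel.n_loci == 0


class TestScoring:
    def test_pure_parent_scores(self, mixed_panel):
        gm, _, _ = mixed_panel
        gs, gn = groups()
        panel = ascertain_fixed(gm, gs, gn)
        rep_s = score_sample(gm, panel, "S02")
        assert rep_s.f_he == 0.0 and rep_s.h == 1.0 and rep_s.interclass_het == 0.0
        rep_n = score_sample(gm, panel, "N02")
        assert rep_n.f_he == 0.0 and rep_n.h == 0.0

    def test_f1_fully_heterozygous_without_error(self, mixed_panel):
        gm, _, _ = mixed_panel
        gs, gn = groups()
        panel = ascertain_fixed(gm, gs, gn)
        rep = score_sample(gm, panel, "F1_01")
        assert rep.f_he == 1.0 and rep.h == pytest.approx(0.5)

    def test_no_called_loci_unclassified(self):
        gm = make_gm([[2, 2], [2, 2], [0, 0], [0, 0], [MISSING, MISSING]],
                     samples=list("abcde"))
        panel = ascertain_fixed(gm, ["a", "b"], ["c", "d"])
        rep = classify(score_sample(gm, panel, "e"))
        assert rep.label == hybrid.UNCLASSIFIED and rep.n_all == 0


class TestClassification:
    def test_f1_with_small_error_still_called_f1(self):
        cfg = SimConfig(n_loci=5000, prop_fixed=1.0, prop_shared_poly=0.0,
                        n_S=10, n_N=10, hybrid_spec=(("F1", 1),),
                        genotype_error_rate=0.002, missing_rate=0.0,
                        error_rate=0.0, seed=37)
        gm, _, _ = simulate_dataset(cfg)
        gs, gn = groups(10, 10)
        panel = ascertain_fixed(gm, gs, gn)
        rep = classify(score_sample(gm, panel, "F1_01"))
        assert rep.f_he > 0.99
        assert rep.label == hybrid.F1

    def test_backcross_is_later_generation_not_f1(self, mixed_panel):
        gm, _, _ = mixed_panel
        gs, gn = groups()
        panel = ascertain_fixed(gm, gs, gn)
        rep = classify(score_sample(gm, panel, "BC_N_01"))
        assert rep.label == hybrid.LATER_GEN
        assert 0.1 < rep.h < 0.45  # Mendelian expectation 0.25
        assert 0.3 < rep.interclass_het < 0.7  # expectation 0.5

    def test_triploid_suspect_requires_ploidy_evidence(self):
        rep = HybridReport(sample="y", n_all=896_152, n_he=775_251,
                           f_he=0.8651, h=0.55, interclass_het=0.8651)
        assert classify(rep, ploidy_call="TRIPLOID").label == hybrid.TRIPLOID_SUSPECT
        assert classify(rep, ploidy_call=None).label != hybrid.TRIPLOID_SUSPECT

    def test_f_he_monotone_in_genotype_error(self):
        vals = []
        for err in (0.0, 0.01, 0.05):
            cfg = SimConfig(n_loci=3000, prop_fixed=1.0, prop_shared_poly=0.0,
                            n_S=4, n_N=4, hybrid_spec=(("F1", 1),),
                            genotype_error_rate=err, missing_rate=0.0,
                            error_rate=0.0, seed=41)
            gm, _, panel_truth = simulate_dataset(cfg)
            idx = np.flatnonzero(panel_truth.is_fixed)
            from hyploscan.hybrid import DiagnosticPanel
            panel = DiagnosticPanel(variant_idx=idx,
                                    s_is_alt=panel_truth.s_is_alt[idx],
                                    freq_tol=0.0, max_missing=0.2)
            vals.append(score_sample(gm, panel, "F1_01").f_he)
        assert vals[0] >= vals[1] >= vals[2]
        assert vals[0] == 1.0


class TestTriangleGeometry:
    def test_all_points_inside_triangle(self, noisy_panel):
        gm, _, _ = noisy_panel
        gs, gn = groups()
        panel = ascertain_fixed(gm, gs, gn, freq_tol=0.01)
        df = score_all(gm, panel)
        h = df["hybrid_index"].to_numpy()
        H = df["interclass_het"].to_numpy()
        slack = 1e-9
        assert np.all(H <= 2 * h + slack)
        assert np.all(H <= 2 * (1 - h) + slack)
        assert np.all((0 <= h) & (h <= 1) & (0 <= H) & (H <= 1))

    def test_expected_triangle_positions_by_class(self):
        # replicate means of (h, H) against Mendelian expectations
        want = {"F1": (0.5, 1.0), "F2": (0.5, 0.5), "BC_S": (0.75, 0.5), "BC_N": (0.25, 0.5)}
        obs = {k: [] for k in want}
        for seed in range(50):
            cfg = SimConfig(n_loci=600, prop_fixed=1.0, prop_shared_poly=0.0,
                            n_S=2, n_N=2,
                            hybrid_spec=(("F1", 1), ("F2", 1), ("BC_S", 1), ("BC_N", 1)),
                            error_rate=0.0, genotype_error_rate=0.0,
                            missing_rate=0.0, seed=1000 + seed)
            gm, _, panel_truth = simulate_dataset(cfg)
            idx = np.flatnonzero(panel_truth.is_fixed)
            from hyploscan.hybrid import DiagnosticPanel
            panel = DiagnosticPanel(variant_idx=idx, s_is_alt=panel_truth.s_is_alt[idx],
                                    freq_tol=0.0, max_missing=0.2)
            for cls in want:
                rep = score_sample(gm, panel, f"{cls}_01")
                obs[cls].append((rep.h, rep.interclass_het))
        for cls, (eh, eH) in want.items():
            arr = np.array(obs[cls])
            for col, expected in ((0, eh), (1, eH)):
                mean = arr[:, col].mean()
                se = arr[:, col].std(ddof=1) / np.sqrt(len(arr))
                assert abs(mean - expected) <= 3 * se + 1e-12, (cls, col, mean)
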