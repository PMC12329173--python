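"""Generator bookkeeping: dosages, gametes, read model, chloroplast clusters."""

import numpy as np
import pytest

from hyploscan.simulate import (
    DosagePanel,
    SimConfig,
    SimConfigError,
    simulate_chloroplast,
    simulate_dataset,
    simulate_panel,
    simulate_reads,
)


def constant_panel(n_loci, dosage, ploidy, n_samples=1):
    """Single-class panel with a constant ALT dosage at every locus."""
    return DosagePanel(
        samples=[f"x{i}" for i in range(n_samples)],
        ploidy=np.full(n_samples, ploidy, dtype=np.int8),
        chrom=np.array(["Chr01"] * n_loci, dtype=object),
        pos=np.arange(1, n_loci + 1, dtype=np.int64),
        ref=np.array(["A"] * n_loci, dtype=object),
        alt=np.array(["G"] * n_loci, dtype=object),
        dosage=np.full((n_samples, n_loci), dosage, dtype=np.int8),
        s_is_alt=np.ones(n_loci, dtype=bool),
        is_fixed=np.zeros(n_loci, dtype=bool),
    )


class TestPanel:
    def test_f1_heterozygous_at_every_fixed_locus(self):
        cfg = SimConfig(n_loci=500, prop_fixed=1.0, prop_shared_poly=0.0,
                        n_S=1, n_N=1, hybrid_spec=(("F1", 1),), seed=3)
        panel, truth = simulate_panel(cfg)
        f1 = panel.dosage[panel.samples.index("F1_01")]
        assert np.all(f1 == 1)

    def test_triploid_carries_one_s_allele_at_fixed_loci(self):
        # unreduced F1 gamete (one S + one N allele) + one N gamete:
        # ALT dosage is 1 where ALT is the S allele, else 2
        cfg = SimConfig(n_loci=500, prop_fixed=1.0, prop_shared_poly=0.0,
                        n_S=1, n_N=1, hybrid_spec=(("TRIPLOID", 1),), seed=3)
        panel, _ = simulate_panel(cfg)
        tri = panel.dosage[panel.samples.index("TRIPLOID_01")]
        expected = np.where(panel.s_is_alt, 1, 2)
        assert np.array_equal(tri, expected)

    def test_fixed_locus_count_exact(self):
        cfg = SimConfig(n_loci=10_000, prop_fixed=0.1, prop_shared_poly=0.9,
                        n_S=3, n_N=3, seed=5)
        panel, _ = simulate_panel(cfg)
        assert int(panel.is_fixed.sum()) == 1000

    def test_parents_fixed_homozygous_before_error(self):
        cfg = SimConfig(n_loci=2000, prop_fixed=0.5, prop_shared_poly=0.5,
                        n_S=4, n_N=4, seed=9)
        panel, truth = simulate_panel(cfg)
        fixed = panel.is_fixed
        s_dose = np.where(panel.s_is_alt[fixed], 2, 0)
        for i, s in enumerate(panel.samples):
            want = s_dose if truth.loc[s, "class"] == "PARENT_S" else 2 - s_dose
            assert np.array_equal(panel.dosage[i, fixed], want)

    def test_ramets_share_dosages(self):
        cfg = SimConfig(n_loci=1000, n_S=2, n_N=2, clone_spec=(("N01", 2),), seed=1)
        panel, truth = simulate_panel(cfg)
        src = panel.samples.index("N01")
        for r in ("N01_r01", "N01_r02"):
            assert np.array_equal(panel.dosage[panel.samples.index(r)], panel.dosage[src])
            assert truth.loc[r, "genet_id"] == truth.loc["N01", "genet_id"]

    def test_f1_without_both_parents_is_config_error(self):
        with pytest.raises(SimConfigError):
            SimConfig(n_S=0, n_N=4, hybrid_spec=(("F1", 1),))

    @pytest.mark.parametrize("kwargs", [
        dict(prop_fixed=0.7, prop_shared_poly=0.7),
        dict(mean_depth=0),
        dict(missing_rate=0.7),
        dict(n_loci=0),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(SimConfigError):
            SimConfig(**kwargs)

    def test_inversion_interval_loci_are_fixed(self):
        cfg = SimConfig(n_loci=2000, prop_fixed=0.1, prop_shared_poly=0.5,
                        n_S=2, n_N=2, seed=2,
                        chrom_lengths={"Chr01": 1_000_000},
                        inversion=("Chr01", 100_000, 400_000))
        panel, _ = simulate_panel(cfg)
        inside = (panel.pos >= 100_000) & (panel.pos <= 400_000)
        assert inside.sum() >= 50
        assert panel.is_fixed[inside].all()


class TestReads:
    def test_expected_alt_fraction_diploid_het(self):
        panel = constant_panel(50_000, dosage=1, ploidy=2)
        reads = simulate_reads(panel, mean_depth=30, error_rate=0.0, seed=0)
        vrf = reads.ad_alt[reads.dp > 0] / reads.dp[reads.dp > 0]
        se = vrf.std() / np.sqrt(vrf.size)
        assert abs(vrf.mean() - 0.5) < 3 * se + 1e-12

    def test_expected_alt_fraction_triploid_two_copies(self):
        panel = constant_panel(50_000, dosage=2, ploidy=3)
        reads = simulate_reads(panel, mean_depth=30, error_rate=0.0, seed=0)
        vrf = reads.ad_alt[reads.dp > 0] / reads.dp[reads.dp > 0]
        se = vrf.std() / np.sqrt(vrf.size)
        assert abs(vrf.mean() - 2 / 3) < 3 * se

    def test_vrf_converges_at_high_depth(self):
        # law of large numbers: at depth 1000 the per-site VRF is tight
        panel = constant_panel(2000, dosage=1, ploidy=3)
        reads = simulate_reads(panel, mean_depth=1000, error_rate=0.0, seed=4)
        vrf = reads.ad_alt / reads.dp
        assert abs(vrf.mean() - 1 / 3) < 0.005
        assert np.all(np.abs(vrf - 1 / 3) < 0.1)

    def test_error_rate_shifts_homozygote_fraction(self):
        panel = constant_panel(20_000, dosage=0, ploidy=2)
        reads = simulate_reads(panel, mean_depth=50, error_rate=0.01, seed=1)
        frac = reads.ad_alt.sum() / reads.dp.sum()
        assert 0.005 < frac < 0.02


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = SimConfig(n_loci=500, n_S=2, n_N=2, hybrid_spec=(("F1", 1),), seed=42)
        gm1, truth1, panel1 = simulate_dataset(cfg)
        gm2, truth2, panel2 = simulate_dataset(cfg)
        assert np.array_equal(gm1.g, gm2.g)
        assert np.array_equal(gm1.ad_alt, gm2.ad_alt)
        assert np.array_equal(panel1.dosage, panel2.dosage)
        assert truth1.equals(truth2)

    def test_chloroplast_deterministic(self):
        a = simulate_chloroplast(3, 3, steps_between=10, intra_steps=2, seed=8)
        b = simulate_chloroplast(3, 3, steps_between=10, intra_steps=2, seed=8)
        assert a == b


class TestChloroplast:
    @staticmethod
    def hamming(a, b):
        return sum(x != y for x, y in zip(a, b))

    def test_min_intercluster_distance_is_steps_between(self):
        haps, labels = simulate_chloroplast(6, 6, steps_between=126, intra_steps=0, seed=0)
        s = [h for n, h in haps.items() if labels[n] == "S"]
        n_ = [h for n, h in haps.items() if labels[n] == "N"]
        dists = [self.hamming(a, b) for a in s for b in n_]
        assert min(dists) == 126

    def test_two_haplotypes_single_step(self):
        haps, _ = simulate_chloroplast(1, 1, steps_between=1, intra_steps=0, seed=0)
        a, b = haps.values()
        assert self.hamming(a, b) == 1

    def test_intra_cluster_spread_bounded(self):
        haps, labels = simulate_chloroplast(8, 8, steps_between=30, intra_steps=3, seed=2)
        for cluster in "SN":
            members = [h for n, h in haps.items() if labels[n] == cluster]
            center = members[0]  # first haplotype is the cluster center
            assert all(self.hamming(center, h) <= 3 for h in members)

    def test_sequence_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            simulate_chloroplast(5, 5, steps_between=126, intra_steps=3, seed=0, n_sites=100)
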