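import numpy as np
import pytest

from hyploscan.vcfio import GenotypeMatrix


def make_gm(g, samples=None, pos=None, chrom="Chr01", ad=None, dp=None):
    """Build a small GenotypeMatrix from a dosage array for unit tests.

    ``g`` is (n_samples, n_variants) with -1 for missing.  AD defaults to
    a depth-20 split consistent with the dosage; DP to AD_ref + AD_alt.
    """
    g = np.asarray(g, dtype=np.int8)
    n, m = g.shape
    samples = samples or [f"s{i}" for i in range(n)]
    pos = np.asarray(pos if pos is not None else np.arange(1, m + 1) * 100, dtype=np.int64)
    if ad is None:
        frac = np.clip(g, 0, 2) / 2.0
        ad_alt = np.round(20 * frac).astype(np.int32)
        ad_ref = (20 - ad_alt).astype(np.int32)
        ad_alt[g == -1] = -1
        ad_ref[g == -1] = -1
    else:
        ad_ref, ad_alt = (np.asarray(a, dtype=np.int32) for a in ad)
    if dp is None:
        dp = np.where(ad_ref >= 0, ad_ref + ad_alt, -1).astype(np.int32)
    else:
        dp = np.asarray(dp, dtype=np.int32)
    return GenotypeMatrix(
        samples=list(samples),
        chrom=np.array([chrom] * m, dtype=object),
        pos=pos,
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["G"] * m, dtype=object),
        g=g,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        dp=dp,
    )


@pytest.fixture(scope="session")
def mixed_panel():
    """Error-free two-clade panel with hybrids, a triploid and clones."""
    from hyploscan.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        n_loci=4000,
        prop_fixed=0.3,
        prop_shared_poly=0.7,
        n_S=6,
        n_N=6,
        hybrid_spec=(("F1", 2), ("F2", 1), ("BC_N", 1), ("TRIPLOID", 1)),
        clone_spec=(("S01", 2),),
        mean_depth=30,
        error_rate=0.0,
        genotype_error_rate=0.0,
        missing_rate=0.0,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_panel():
    """Same structure with realistic error and missingness."""
    from hyploscan.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        n_loci=4000,
        prop_fixed=0.3,
        prop_shared_poly=0.7,
        n_S=6,
        n_N=6,
        hybrid_spec=(("F1", 2), ("F2", 1), ("BC_N", 1), ("TRIPLOID", 1)),
        clone_spec=(("S01", 2),),
        mean_depth=30,
        error_rate=0.001,
        genotype_error_rate=0.002,
        missing_rate=0.02,
        seed=13,
    )
    return simulate_dataset(cfg)
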