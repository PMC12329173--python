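"""Inversion genotyping by local PCA.

A chromosomal inversion suppresses recombination between orientations,
so SNPs inside the inverted interval behave as one giant locus: a PCA
restricted to the region separates samples into three clusters along
PC1 — the two orientation homozygotes at the extremes and heterozygotes
(one copy of each orientation) in between.  Heterozygotes are also
expected to show elevated heterozygosity across region SNPs, which is
used as a consistency check on the cluster labelling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcfio import MISSING, GenotypeMatrix

HOM_A = "HOM_A"
HET = "HET"
HOM_B = "HOM_B"


@dataclass
class InversionCall:
    sample: str
    pc1: float
    cluster: str  # HOM_A / HET / HOM_B
    region_het: float
    low_confidence: bool = False


def parse_interval(text: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive; commas tolerated)."""
    m = re.fullmatch(r"\s*([^:\s]+):([\d,]+)\s*[-–]\s*([\d,]+)\s*", text)
    if not m:
        raise ValueError(f"cannot parse interval {text!r}; expected chrom:start-end")
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if start > end:
        raise ValueError("interval start exceeds end")
    return m.group(1), start, end


def _region_index(gm: GenotypeMatrix, chrom: str, start: int, end: int) -> np.ndarray:
    chroms = np.asarray([str(c) for c in gm.chrom], dtype=object)
    return np.flatnonzero((chroms == chrom) & (gm.pos >= start) & (gm.pos <= end))


def region_pca(gm: GenotypeMatrix, chrom: str, start: int, end: int, n_components: int = 10):
    """PCA of genotypes restricted to a 1-based inclusive interval.

    Missing genotypes are imputed to the per-SNP mean (for the PCA only),
    each SNP is mean-centred, and the sample coordinates are obtained by
    SVD (equivalent to eigendecomposition of the sample covariance).

    Returns ``(coords, var_frac)``: an (n_samples, k) coordinate array
    and the fraction of variance per component.
    """
    idx = _region_index(gm, chrom, start, end)
    if idx.size == 0:
        raise ValueError(f"no SNPs in {chrom}:{start}-{end}")
    g = gm.g[:, idx].astype(float)
    g[g == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    filled = np.where(np.isnan(g), col_mean[None, :], g)
    x = filled - col_mean[None, :]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    coords = u[:, :k] * s[:k]
    total = (s ** 2).sum()
    var_frac = (s[:k] ** 2 / total) if total > 0 else np.zeros(k)
    return coords, var_frac


def region_heterozygosity(gm: GenotypeMatrix, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-sample fraction of het calls among called region SNPs."""
    idx = _region_index(gm, chrom, start, end)
    g = gm.g[:, idx]
    called = (g != MISSING).sum(axis=1)
    return np.where(called > 0, (g == 1).sum(axis=1) / np.maximum(called, 1), np.nan)


def _kmeans_1d(x: np.ndarray, k: int = 3) -> np.ndarray:
    """Deterministic 1-D k-means with quantile initialisation."""
    from sklearn.cluster import KMeans

    init = np.percentile(x, [10, 50, 90])[:, None]
    km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=300)
    return km.fit_predict(x[:, None]), km.cluster_centers_.ravel()


def genotype_inversion(
    pc1: np.ndarray,
    region_het: np.ndarray,
    samples: list[str],
) -> list[InversionCall]:
    """Assign HOM_A / HET / HOM_B from PC1 coordinates.

    Clusters come from 1-D k-means (k=3) initialised at the 10th, 50th
    and 90th PC1 percentiles; the middle cluster (by centre) is labelled
    HET.  If the HET cluster's mean region heterozygosity does not exceed
    both homozygote clusters' means, every call is flagged low
    confidence.  Labels are invariant to a PC1 sign flip.
    """
    pc1 = np.asarray(pc1, dtype=float)
    if np.unique(pc1).size < 3:
        raise ValueError("fewer than 3 distinct PC1 values: no cluster structure")
    assign, centers = _kmeans_1d(pc1, 3)
    order = np.argsort(centers)  # low, mid, high
    label_of = {order[0]: HOM_A, order[1]: HET, order[2]: HOM_B}
    labels = [label_of[a] for a in assign]

    def mean_het(lbl):
        vals = [h for l, h in zip(labels, region_het) if l == lbl and np.isfinite(h)]
        return float(np.mean(vals)) if vals else float("nan")

    het_mid, het_a, het_b = mean_het(HET), mean_het(HOM_A), mean_het(HOM_B)
    low_conf = not (het_mid > het_a and het_mid > het_b)
    return [
        InversionCall(
            sample=s,
            pc1=float(p),
            cluster=l,
            region_het=float(h),
            low_confidence=low_conf,
        )
        for s, p, l, h in zip(samples, pc1, labels, region_het)
    ]


def genotype_region(gm: GenotypeMatrix, chrom: str, start: int, end: int) -> pd.DataFrame:
    """Convenience: region PCA + clustering, as a per-sample DataFrame."""
    coords, var_frac = region_pca(gm, chrom, start, end)
    het = region_heterozygosity(gm, chrom, start, end)
    calls = genotype_inversion(coords[:, 0], het, gm.samples)
    df = pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "pc1": [c.pc1 for c in calls],
            "cluster": [c.cluster for c in calls],
            "region_het": [c.region_het for c in calls],
            "low_confidence": [c.low_confidence for c in calls],
        }
    ).set_index("sample")
    df.attrs["pc1_var_frac"] = float(var_frac[0])
    return df
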