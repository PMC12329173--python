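"""Ploidy inference from variant-read-frequency (VRF) histograms.

At a truly heterozygous diploid site the two homologs contribute reads in
equal expectation, so the fraction of reads supporting the ALT allele —
the VRF — concentrates at 0.5.  A triploid carrying one ALT copy yields
an expected VRF of 1/3, two copies 2/3.  A sample's VRF histogram over
its heterozygous calls therefore separates diploids (single peak at 0.5)
from triploids (peaks at 1/3 and/or 2/3).

Peak finding is made reproducible by smoothing the histogram with a
Gaussian kernel (bandwidth two bins) and taking the argmax; a
concentration gate (modal height at least twice the mean height) rejects
flat profiles before any call is made.  Tetraploid-like profiles (modes
near 1/4 or 3/4) are reported AMBIGUOUS with an annotation rather than
called: they are outside the model space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .vcfio import MISSING, GenotypeMatrix

DIPLOID = "DIPLOID"
TRIPLOID = "TRIPLOID"
AMBIGUOUS = "AMBIGUOUS"


@dataclass
class VRFProfile:
    """Per-sample VRF vector, histogram, and ploidy call."""

    sample: str
    vrf: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    mode_vrf: float | None = None
    call: str = AMBIGUOUS
    reason: str = ""

    @property
    def n_sites(self) -> int:
        return int(self.vrf.size)


def compute_vrf(gm: GenotypeMatrix, sample, min_dp: int = 10) -> np.ndarray:
    """VRF = AD_alt / (AD_ref + AD_alt) at het calls with DP >= min_dp."""
    i = sample if isinstance(sample, (int, np.integer)) else gm.sample_index(sample)
    g = gm.g[i]
    ar = gm.ad_ref[i].astype(np.int64)
    aa = gm.ad_alt[i].astype(np.int64)
    tot = ar + aa
    use = (g == 1) & (ar != MISSING) & (aa != MISSING) & (tot >= min_dp) & (tot > 0)
    if not use.any():
        warnings.warn(f"no qualifying heterozygous sites for sample index {i}")
        return np.empty(0)
    return aa[use] / tot[use]


def vrf_histogram(vrf: np.ndarray, bin_width: float = 0.02):
    """Histogram on bins tiling [0, 1]; left-closed, last bin closed.

    Returns ``(edges, counts)``; counts sum to ``len(vrf)``.
    """
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(vrf, bins=edges)
    return edges, counts


def profile_sample(
    gm: GenotypeMatrix, sample, min_dp: int = 10, bin_width: float = 0.02
) -> VRFProfile:
    name = sample if isinstance(sample, str) else gm.samples[sample]
    vrf = compute_vrf(gm, sample, min_dp=min_dp)
    edges, counts = vrf_histogram(vrf, bin_width) if vrf.size else vrf_histogram(np.empty(0), bin_width)
    return VRFProfile(sample=name, vrf=vrf, bin_edges=edges, counts=counts)


def classify_ploidy(
    profile: VRFProfile,
    peak_tol: float = 0.07,
    min_sites: int = 500,
    smooth_bins: float = 2.0,
) -> VRFProfile:
    """Call DIPLOID / TRIPLOID / AMBIGUOUS from a VRF profile.

    The histogram is Gaussian-smoothed (sigma = ``smooth_bins`` bins) and
    the modal bin located.  DIPLOID requires the mode within ``peak_tol``
    of 0.5 with neither the 1/3 nor the 2/3 region exceeding half the
    modal height; TRIPLOID requires the mode within ``peak_tol`` of 1/3
    or 2/3, or secondary peaks at both 1/3 and 2/3 exceeding half the
    height near 0.5.  Profiles with fewer than ``min_sites`` sites, no
    concentrated peak, or tetraploid-like modes (near 1/4 or 3/4) are
    AMBIGUOUS.  The call is deterministic given the profile.
    """
    prof = VRFProfile(
        sample=profile.sample,
        vrf=profile.vrf,
        bin_edges=profile.bin_edges,
        counts=profile.counts,
    )
    if prof.n_sites == 0:
        prof.call, prof.reason = AMBIGUOUS, "empty VRF profile"
        return prof
    if prof.n_sites < min_sites:
        prof.call, prof.reason = AMBIGUOUS, f"only {prof.n_sites} sites (< {min_sites})"
        return prof

    centers = 0.5 * (prof.bin_edges[:-1] + prof.bin_edges[1:])
    smooth = gaussian_filter1d(prof.counts.astype(float), sigma=smooth_bins, mode="constant")
    mode_idx = int(np.argmax(smooth))
    mode = float(centers[mode_idx])
    prof.mode_vrf = mode

    def height_at(x: float) -> float:
        return float(smooth[np.argmin(np.abs(centers - x))])

    # concentration gate: a flat (e.g. uniform) profile has a smoothed
    # maximum close to its mean (ratio ~1.1), while genuine allele-balance
    # peaks stay well above it even when a triploid's 1/3 + 2/3 mixture
    # spreads the mass at moderate depth; 1.5x separates the regimes
    h_mode = smooth[mode_idx]
    if h_mode < 1.5 * smooth.mean():
        prof.call, prof.reason = AMBIGUOUS, "no concentrated VRF peak"
        return prof

    h_third, h_two_thirds, h_half = height_at(1 / 3), height_at(2 / 3), height_at(0.5)
    if abs(mode - 0.5) <= peak_tol and h_third <= 0.5 * h_mode and h_two_thirds <= 0.5 * h_mode:
        prof.call, prof.reason = DIPLOID, "mode at 0.5"
        return prof
    if min(abs(mode - 1 / 3), abs(mode - 2 / 3)) <= peak_tol:
        prof.call, prof.reason = TRIPLOID, f"mode at {mode:.2f}"
        return prof
    if h_third > 0.5 * h_half and h_two_thirds > 0.5 * h_half:
        prof.call, prof.reason = TRIPLOID, "secondary peaks at 1/3 and 2/3"
        return prof
    if min(abs(mode - 0.25), abs(mode - 0.75)) <= peak_tol:
        prof.call, prof.reason = AMBIGUOUS, "tetraploid-like mode (outside model space)"
        return prof
    prof.call, prof.reason = AMBIGUOUS, f"unclassified mode at {mode:.2f}"
    return prof


def classify_all(
    gm: GenotypeMatrix,
    min_dp: int = 10,
    bin_width: float = 0.02,
    peak_tol: float = 0.07,
    min_sites: int = 500,
) -> pd.DataFrame:
    """Per-sample ploidy table: sample, n_sites, mode, call, reason."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in gm.samples:
            prof = classify_ploidy(
                profile_sample(gm, s, min_dp=min_dp, bin_width=bin_width),
                peak_tol=peak_tol,
                min_sites=min_sites,
            )
            rows.append(
                {
                    "sample": s,
                    "n_sites": prof.n_sites,
                    "mode_vrf": prof.mode_vrf,
                    "call": prof.call,
                    "reason": prof.reason,
                }
            )
    return pd.DataFrame(rows).set_index("sample")
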