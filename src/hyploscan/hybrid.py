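"""Fixed-difference ascertainment and hybrid classification.

Given two parental groups (clades S and N), loci at which the groups are
homozygous for opposite alleles are diagnostic: an F1 hybrid must be
heterozygous at every one of them, while later-generation hybrids (F2,
backcrosses) lose half of that heterozygosity per sexual generation
through Mendelian segregation.  For each sample we report, over the
diagnostic panel:

* ``n_All`` — diagnostic loci with a genotype call, ``n_He`` — the
  heterozygous ones, and ``F_He = n_He / n_All``;
* the hybrid index ``h`` — the fraction of the sample's alleles that are
  S-clade alleles; and
* interclass heterozygosity ``H`` — the fraction of diagnostic loci
  carrying one allele from each clade (on a strictly fixed panel this
  equals F_He; it is reported separately because the (h, H) triangle plot
  is defined in these terms).

Triploids genotyped through a diploid caller appear highly but not fully
heterozygous (their 1/3-VRF sites are occasionally called homozygous), so
an F_He between 0.8 and the F1 threshold combined with a triploid
read-balance call flags TRIPLOID_SUSPECT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ploidy as ploidy_mod
from .vcfio import MISSING, GenotypeMatrix

PARENT_S = "PARENT_S"
PARENT_N = "PARENT_N"
F1 = "F1"
LATER_GEN = "LATER_GEN"
TRIPLOID_SUSPECT = "TRIPLOID_SUSPECT"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class DiagnosticPanel:
    """Ascertained fixed-difference loci with per-locus orientation."""

    variant_idx: np.ndarray  # indices into the source GenotypeMatrix
    s_is_alt: np.ndarray  # per ascertained locus: is ALT the S allele?
    freq_tol: float
    max_missing: float

    @property
    def n_loci(self) -> int:
        return int(self.variant_idx.size)


@dataclass
class HybridReport:
    sample: str
    n_all: int
    n_he: int
    f_he: float
    h: float  # hybrid index: fraction of S alleles
    interclass_het: float
    label: str = UNCLASSIFIED
    reason: str = ""


def f_he(n_he: int, n_all: int) -> float:
    """Proportion of heterozygous genotypes among called diagnostic loci."""
    if n_all <= 0:
        raise ValueError("n_all must be positive")
    if not 0 <= n_he <= n_all:
        raise ValueError("need 0 <= n_he <= n_all")
    return n_he / n_all


def ascertain_fixed(
    gm: GenotypeMatrix,
    group_S: list[str],
    group_N: list[str],
    freq_tol: float = 0.0,
    max_missing: float = 0.2,
) -> DiagnosticPanel:
    """Find loci fixed for opposite alleles between the parental groups.

    A locus is ascertained when the S-group ALT frequency (over
    non-missing calls) is >= 1 - freq_tol while the N-group's is
    <= freq_tol, or the mirror image, and each group's missingness at the
    locus is <= ``max_missing``.  At ``freq_tol=0`` this is strict
    reciprocal fixation.  The S-allele orientation is recorded per locus.
    """
    if not group_S or not group_N:
        raise ValueError("both parental groups must be non-empty")
    if len(group_S) < 2 or len(group_N) < 2:
        raise ValueError("each parental group needs >= 2 samples")
    if set(group_S) & set(group_N):
        raise ValueError("parental groups must be disjoint")

    def group_stats(names):
        sub = gm.take_samples(names)
        valid = sub.g != MISSING
        n_valid = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            af = np.where(valid, sub.g, 0).sum(axis=0) / np.maximum(2 * n_valid, 1)
        miss = 1.0 - n_valid / len(names)
        return af, miss, n_valid

    af_s, miss_s, n_s = group_stats(group_S)
    af_n, miss_n, n_n = group_stats(group_N)
    callable_ = (miss_s <= max_missing) & (miss_n <= max_missing) & (n_s > 0) & (n_n > 0)
    s_alt = (af_s >= 1 - freq_tol) & (af_n <= freq_tol)
    s_ref = (af_s <= freq_tol) & (af_n >= 1 - freq_tol)
    keep = callable_ & (s_alt | s_ref)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        warnings.warn("no fixed differences ascertained between the groups")
    return DiagnosticPanel(
        variant_idx=idx,
        s_is_alt=s_alt[idx],
        freq_tol=freq_tol,
        max_missing=max_missing,
    )


def score_sample(gm: GenotypeMatrix, panel: DiagnosticPanel, sample) -> HybridReport:
    """F_He, hybrid index and interclass heterozygosity for one sample."""
    i = sample if isinstance(sample, (int, np.integer)) else gm.sample_index(sample)
    name = gm.samples[i]
    g = gm.g[i, panel.variant_idx]
    called = g != MISSING
    n_all = int(called.sum())
    if n_all == 0:
        return HybridReport(
            sample=name, n_all=0, n_he=0, f_he=float("nan"), h=float("nan"),
            interclass_het=float("nan"), label=UNCLASSIFIED,
            reason="no called diagnostic loci",
        )
    gc = g[called]
    n_he = int((gc == 1).sum())
    s_alleles = np.where(panel.s_is_alt[called], gc, 2 - gc).sum()
    fhe = n_he / n_all
    return HybridReport(
        sample=name,
        n_all=n_all,
        n_he=n_he,
        f_he=fhe,
        h=float(s_alleles) / (2 * n_all),
        interclass_het=fhe,  # identical on a strictly fixed panel
    )


def classify(
    report: HybridReport,
    ploidy_call: str | None = None,
    f1_threshold: float = 0.99,
) -> HybridReport:
    """Attach a class label to a scored report.

    Rules (first match wins): F1 when F_He > ``f1_threshold`` with h near
    0.5; pure parent when h is extreme and F_He ~ 0; TRIPLOID_SUSPECT when
    0.8 < F_He <= f1_threshold and the read-balance ploidy call is
    TRIPLOID; LATER_GEN for intermediate (h, H); else UNCLASSIFIED.
    """
    r = HybridReport(**{**report.__dict__})
    if r.n_all == 0:
        r.label = UNCLASSIFIED
        return r
    h, H, fhe = r.h, r.interclass_het, r.f_he
    if fhe > f1_threshold and 0.4 <= h <= 0.6:
        r.label = F1
    elif h >= 0.95 and fhe < 0.05:
        r.label = PARENT_S
    elif h <= 0.05 and fhe < 0.05:
        r.label = PARENT_N
    elif 0.8 < fhe <= f1_threshold and ploidy_call == ploidy_mod.TRIPLOID:
        r.label = TRIPLOID_SUSPECT
    elif 0.25 < H < 0.8 and 0.1 <= h <= 0.9:
        r.label = LATER_GEN
    else:
        r.label = UNCLASSIFIED
    return r


def score_all(
    gm: GenotypeMatrix,
    panel: DiagnosticPanel,
    samples: list[str] | None = None,
    ploidy_calls: dict | None = None,
    f1_threshold: float = 0.99,
) -> pd.DataFrame:
    """Scored and classified report for a set of samples (default: all)."""
    samples = list(gm.samples) if samples is None else list(samples)
    ploidy_calls = ploidy_calls or {}
    rows = []
    for s in samples:
        rep = classify(
            score_sample(gm, panel, s),
            ploidy_call=ploidy_calls.get(s),
            f1_threshold=f1_threshold,
        )
        rows.append(
            {
                "sample": rep.sample,
                "n_All": rep.n_all,
                "n_He": rep.n_he,
                "F_He": rep.f_he,
                "hybrid_index": rep.h,
                "interclass_het": rep.interclass_het,
                "class": rep.label,
            }
        )
    return pd.DataFrame(rows).set_index("sample")
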