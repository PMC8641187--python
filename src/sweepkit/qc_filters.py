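"""SNP quality-control filters and LD pruning.

Thresholds default to MAF > 0.01, call rate >= 0.90 and exact-test
HWE p > 1e-5, applied over all samples pooled.  LD pruning is a greedy
sliding-window thinning of pairwise genotype r^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "QcThresholds",
    "PruneParams",
    "minor_allele_frequency",
    "call_rate",
    "hwe_exact_test",
    "hwe_pvalues",
    "apply_qc_filters",
    "ld_prune",
    "pairwise_r2_matrix",
]


@dataclass(frozen=True)
class QcThresholds:
    maf_min: float = 0.01
    call_rate_min: float = 0.90
    hwe_p_min: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class PruneParams:
    window_snps: int = 100
    step_snps: int = 50
    r2_max: float = 0.1

    def __post_init__(self) -> None:
        if not self.window_snps >= self.step_snps >= 1:
            raise ValueError("need window_snps >= step_snps >= 1")
        if not 0.0 <= self.r2_max <= 1.0:
            raise ValueError("r2_max must be in [0,1]")


def minor_allele_frequency(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus MAF over all samples pooled; NaN where no calls."""
    called = g.dosage != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, g.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
    return np.minimum(p, 1.0 - p)


def call_rate(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of samples with a non-missing call, per locus."""
    if g.n_samples == 0:
        return np.zeros(g.n_loci)
    return (g.dosage != MISSING).mean(axis=0)


def hwe_exact_test(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test (Wigginton et al. 2005).

    Enumerates all heterozygote counts compatible with the observed
    allele counts and sums the probabilities of configurations no more
    likely than the observed one.  Monomorphic loci return p = 1.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_ref + het + hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")
    rare = 2 * min(hom_ref, hom_alt) + het
    if rare == 0:
        return 1.0
    # unnormalised probabilities over het in {rare%2, ..., rare}
    probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid % 2) != (rare % 2):
        mid += 1
    probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 (hr+1)(hc+1))
    h = mid
    hom_r = (rare - h) // 2          # rare homozygotes at h hets
    hom_c = n - h - hom_r
    while h > 1:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        hom_r += 1
        hom_c += 1
    h = mid
    hom_r = (rare - h) // 2
    hom_c = n - h - hom_r
    while h <= rare - 2:
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
        hom_r -= 1
        hom_c -= 1
    probs /= probs.sum()
    p_obs = probs[het]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus exact HWE p over pooled samples; NaN where no calls."""
    out = np.ones(g.n_loci)
    for j in range(g.n_loci):
        col = g.dosage[:, j]
        hom_ref = int((col == 0).sum())
        het = int((col == 1).sum())
        hom_alt = int((col == 2).sum())
        if hom_ref + het + hom_alt == 0:
            out[j] = np.nan
        else:
            out[j] = hwe_exact_test(hom_ref, het, hom_alt)
    return out


def apply_qc_filters(
    g: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep loci with MAF > maf_min, call rate >= call_rate_min and
    HWE p > hwe_p_min.  Returns the filtered matrix and a per-locus
    report; a locus failing several criteria is listed under each.
    """
    maf = minor_allele_frequency(g)
    cr = call_rate(g)
    hwe = hwe_pvalues(g)
    fail_maf = ~(maf > t.maf_min)  # NaN fails
    fail_cr = ~(cr >= t.call_rate_min)
    fail_hwe = ~(hwe > t.hwe_p_min)
    keep = ~(fail_maf | fail_cr | fail_hwe)
    removed_by = []
    for j in range(g.n_loci):
        tags = []
        if fail_maf[j]:
            tags.append("maf")
        if fail_cr[j]:
            tags.append("call_rate")
        if fail_hwe[j]:
            tags.append("hwe")
        removed_by.append(",".join(tags))
    report = pd.DataFrame(
        {
            "locus_id": [loc.locus_id for loc in g.loci],
            "chrom": g.chromosomes(),
            "pos_bp": g.positions(),
            "maf": maf,
            "call_rate": cr,
            "hwe_p": hwe,
            "removed_by": removed_by,
            "kept": keep,
        }
    )
    if not keep.any():
        import warnings

        warnings.warn("no loci survive QC filters", stacklevel=2)
    return g.subset_loci(np.flatnonzero(keep)), report


def pairwise_r2_matrix(d: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared Pearson correlation between dosage rows.

    ``d`` is loci x samples with MISSING entries; returns an LxL matrix
    with NaN where a pair has <2 complete samples or zero variance.
    """
    d = np.asarray(d, dtype=float)
    m = (d != MISSING).astype(float)
    x = np.where(m > 0, d, 0.0)
    n = m @ m.T
    sx = x @ m.T          # sum of row-i values over pairwise-complete samples
    sxx = (x * x) @ m.T
    sxy = x @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = sx / n
        my = sx.T / n
        cov = sxy / n - mx * my
        vx = sxx / n - mx**2
        vy = sxx.T / n - my**2
        r2 = cov**2 / (vx * vy)
    r2[(n < 2) | ~np.isfinite(r2)] = np.nan
    return np.clip(r2, 0.0, 1.0, out=r2)


def ld_prune(g: GenotypeMatrix, p: PruneParams = PruneParams(), seed: int = 0) -> list[int]:
    """Greedy sliding-window LD pruning; returns retained locus indices.

    Within each window of ``window_snps`` consecutive loci (per
    chromosome), while any retained pair has r^2 > r2_max the member of
    the first offending pair with the lower MAF is dropped (tie: the
    later position).  Windows slide by ``step_snps``.  Deterministic;
    ``seed`` is accepted for interface symmetry only.
    """
    del seed
    maf = minor_allele_frequency(g)
    keep = np.ones(g.n_loci, dtype=bool)
    chroms = np.array(g.chromosomes())
    for chrom in dict.fromkeys(g.chromosomes()):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            win = idx[start : start + p.window_snps]
            active = [int(j) for j in win if keep[j]]
            if len(active) > 1:
                sub = g.dosage[:, active].T.astype(float)
                r2 = pairwise_r2_matrix(sub)
                alive = {j: k for k, j in enumerate(active)}
                changed = True
                while changed:
                    changed = False
                    cur = [j for j in active if keep[j]]
                    for a in range(len(cur)):
                        for b in range(a + 1, len(cur)):
                            v = r2[alive[cur[a]], alive[cur[b]]]
                            if np.isfinite(v) and v > p.r2_max:
                                ja, jb = cur[a], cur[b]
                                if maf[ja] < maf[jb]:
                                    drop = ja
                                elif maf[jb] < maf[ja]:
                                    drop = jb
                                else:
                                    drop = max(ja, jb)  # later position
                                keep[drop] = False
                                changed = True
                                break
                        if changed:
                            break
            if start + p.window_snps >= len(idx):
                break
            start += p.step_snps
    return [int(j) for j in np.flatnonzero(keep)]
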