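"""Locus and windowed FST, windowed nucleotide diversity, and empirical
outlier detection.

The locus estimator is the mean-square form

    FST = (MSP - MSG) / (MSP + (n_c - 1) * MSG)

with MSP the among-population mean square, MSG the within-population
mean square and n_c the mean per-subpopulation sample size (diploid
individuals with a call at the locus).  Two typography-ambiguous knobs
are exposed: ``nc_mode`` ('mean' as printed, or 'wc' for the
Weir-Cockerham variance-corrected n_c) and ``msg_denom`` ('pooled' for
(sum n_i) - 1, or 'akey' for sum (n_i - 1)).

Windows are half-open [start, start+window) in 1-based bp, tiled from
position 1 with a fixed step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PopulationScheme,
    allele_frequencies,
    subset_by_group,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FstComponents",
    "GenomicWindow",
    "WindowStatistic",
    "locus_fst_components",
    "locus_fst",
    "make_windows",
    "windowed_fst",
    "site_pi",
    "windowed_pi",
    "delta_pi_scan",
    "empirical_outliers",
]


@dataclass(frozen=True)
class FstComponents:
    """Per-locus mean-square components of the FST estimator."""

    msp: float
    msg: float
    n_c: float
    s: int
    p_bar: float

    def __post_init__(self) -> None:
        if self.s < 2:
            raise ValueError("need s >= 2 subpopulations")
        if self.n_c <= 0:
            raise ValueError("n_c must be positive")
        if self.msp < 0 or self.msg < 0:
            raise ValueError("mean squares must be non-negative")


@dataclass(frozen=True)
class GenomicWindow:
    """Half-open genomic interval [start_bp, end_bp) in 1-based bp."""

    chrom: str
    start_bp: int
    end_bp: int
    n_loci: int = 0

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("end_bp must exceed start_bp")
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start_bp, self.end_bp)

    def contains(self, pos_bp: int) -> bool:
        return self.start_bp <= pos_bp < self.end_bp


@dataclass
class WindowStatistic:
    window: GenomicWindow
    value: float
    percentile_rank: float | None = None
    extra: dict = field(default_factory=dict)


def locus_fst_components(
    freqs: Sequence[tuple[float, float]],
    nc_mode: str = "mean",
    msg_denom: str = "pooled",
) -> FstComponents:
    """Mean-square components from per-subpopulation (n_i, p_Ai) pairs.

    p_bar = sum n_i p_i / sum n_i;
    MSP   = 1/(s-1) * sum n_i (p_i - p_bar)^2;
    MSG   = sum n_i p_i (1-p_i) / D, with D = (sum n_i) - 1 ('pooled',
            default) or sum (n_i - 1) ('akey');
    n_c   = mean(n_i) ('mean', default) or the Weir-Cockerham
            (sum n_i - sum n_i^2 / sum n_i)/(s-1) ('wc').
    """
    n = np.asarray([f[0] for f in freqs], dtype=float)
    p = np.asarray([f[1] for f in freqs], dtype=float)
    s = len(n)
    if s < 2:
        raise ValueError("need >= 2 subpopulations")
    if np.any(n < 1) or np.any(~np.isfinite(p)):
        raise ValueError("every subpopulation needs n_i >= 1 and a defined frequency")
    n_tot = n.sum()
    p_bar = float((n * p).sum() / n_tot)
    msp = float((n * (p - p_bar) ** 2).sum() / (s - 1))
    if msg_denom == "pooled":
        denom = n_tot - 1.0
    elif msg_denom == "akey":
        denom = (n - 1.0).sum()
    else:
        raise ValueError("msg_denom must be 'pooled' or 'akey'")
    if denom <= 0:
        raise ValueError("MSG denominator non-positive")
    msg = float((n * p * (1.0 - p)).sum() / denom)
    if nc_mode == "mean":
        n_c = float(n.mean())
    elif nc_mode == "wc":
        n_c = float((n_tot - (n**2).sum() / n_tot) / (s - 1))
    else:
        raise ValueError("nc_mode must be 'mean' or 'wc'")
    return FstComponents(msp=msp, msg=msg, n_c=n_c, s=s, p_bar=p_bar)


def locus_fst(c: FstComponents) -> float:
    """FST = (MSP - MSG)/(MSP + (n_c - 1) MSG); NaN when MSP = MSG = 0."""
    denom = c.msp + (c.n_c - 1.0) * c.msg
    if denom == 0.0:
        return float("nan")
    return (c.msp - c.msg) / denom


def make_windows(
    chrom_extents: dict[str, int], window_bp: int, step_bp: int
) -> list[GenomicWindow]:
    """Tile half-open windows starting at 1, 1+step, ... while start <= extent."""
    if not window_bp >= step_bp >= 1:
        raise ValueError("need window_bp >= step_bp >= 1")
    out: list[GenomicWindow] = []
    for chrom, extent in chrom_extents.items():
        start = 1
        while start <= extent:
            out.append(GenomicWindow(chrom, start, start + window_bp))
            start += step_bp
    return out


def _group_freqs(g: GenotypeMatrix, scheme: PopulationScheme, group: str):
    sub = subset_by_group(g, scheme, group)
    tbl = allele_frequencies(sub, set(sub.populations.values()))
    return tbl["n_i"].to_numpy(), tbl["p_ai"].to_numpy()


def _locus_components_arrays(
    ns: Sequence[np.ndarray],
    ps: Sequence[np.ndarray],
    nc_mode: str,
    msg_denom: str,
):
    """Vectorised components across loci; subpopulations stacked on axis 0."""
    n = np.stack(ns).astype(float)  # s x L
    p = np.stack(ps).astype(float)
    s = n.shape[0]
    defined = np.all(n >= 1, axis=0) & np.all(np.isfinite(p), axis=0)
    n = np.where(defined, n, 1.0)
    p = np.where(defined, p, 0.0)
    n_tot = n.sum(axis=0)
    p_bar = (n * p).sum(axis=0) / n_tot
    msp = (n * (p - p_bar) ** 2).sum(axis=0) / (s - 1)
    denom = n_tot - 1.0 if msg_denom == "pooled" else (n - 1.0).sum(axis=0)
    msg = (n * p * (1.0 - p)).sum(axis=0) / denom
    if nc_mode == "mean":
        n_c = n.mean(axis=0)
    else:
        n_c = (n_tot - (n**2).sum(axis=0) / n_tot) / (s - 1)
    return msp, msg, n_c, defined


def windowed_fst(
    g: GenotypeMatrix,
    scheme: PopulationScheme,
    groups: tuple[str, str],
    window_bp: int = 100_000,
    step_bp: int = 50_000,
    mode: str = "weighted",
    nc_mode: str = "mean",
    msg_denom: str = "pooled",
    pool_groups: bool = True,
    clamp_negative: bool = False,
) -> list[WindowStatistic]:
    """Sliding-window FST between two population groups.

    ``weighted`` (default) is the ratio-of-sums
    sum(MSP-MSG) / sum(MSP + (n_c-1) MSG) over informative loci in the
    window; ``mean`` averages defined locus FST values.  Windows with no
    informative locus are omitted.  With ``pool_groups`` each group is a
    single subpopulation (s=2); otherwise each member breed is its own
    subpopulation (s = total breeds across both groups).
    """
    g1, g2 = groups
    if scheme[g1] == scheme[g2]:
        raise ValueError("the two groups are identical")
    if mode not in ("weighted", "mean"):
        raise ValueError("mode must be 'weighted' or 'mean'")
    if pool_groups:
        units: list[Iterable[str]] = [scheme[g1], scheme[g2]]
    else:
        units = [{pop} for grp in (g1, g2) for pop in sorted(scheme[grp])]
    ns, ps = [], []
    for pops in units:
        tbl = allele_frequencies(g, pops)
        ns.append(tbl["n_i"].to_numpy())
        ps.append(tbl["p_ai"].to_numpy())
    msp, msg, n_c, defined = _locus_components_arrays(ns, ps, nc_mode, msg_denom)
    num = msp - msg
    den = msp + (n_c - 1.0) * msg
    informative = defined & (den != 0.0)
    n_skipped = int((~defined).sum())
    if n_skipped:
        logger.info("windowed_fst: %d loci skipped (undefined frequencies)", n_skipped)

    pos = g.positions()
    chroms = np.array(g.chromosomes())
    out: list[WindowStatistic] = []
    for w in make_windows(g.chrom_extents(), window_bp, step_bp):
        in_w = (chroms == w.chrom) & (pos >= w.start_bp) & (pos < w.end_bp) & informative
        k = int(in_w.sum())
        if k == 0:
            continue
        if mode == "weighted":
            d = float(den[in_w].sum())
            value = float(num[in_w].sum()) / d if d != 0.0 else float("nan")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                value = float(np.nanmean(num[in_w] / den[in_w]))
        if not np.isfinite(value):
            continue
        if clamp_negative:
            value = max(value, 0.0)
        out.append(
            WindowStatistic(
                window=GenomicWindow(w.chrom, w.start_bp, w.end_bp, n_loci=k),
                value=value,
            )
        )
    return out


def site_pi(n_chr: int, alt_count: int) -> float:
    """Per-site diversity: mismatching pairs / all pairs of chromosomes."""
    if n_chr < 2:
        raise ValueError("need n_chr >= 2")
    if not 0 <= alt_count <= n_chr:
        raise ValueError("alt_count out of range")
    return alt_count * (n_chr - alt_count) / (n_chr * (n_chr - 1) / 2.0)


def windowed_pi(
    g: GenotypeMatrix,
    populations: Iterable[str],
    window_bp: int = 50_000,
    step_bp: int = 25_000,
    drop_empty: bool = False,
) -> list[WindowStatistic]:
    """Per-bp nucleotide diversity in sliding windows over pooled
    chromosomes of the given populations.  Monomorphic positions
    contribute zero via the window_bp denominator; windows without
    variant sites are kept at 0 unless ``drop_empty``.
    """
    idx = g.sample_indices(populations)
    if len(idx) == 0:
        raise ValueError("no samples in requested populations")
    sub = g.dosage[idx, :]
    called = sub != MISSING
    n_chr = 2 * called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    ok = n_chr >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(
            ok, alt * (n_chr - alt) / np.maximum(n_chr * (n_chr - 1) / 2.0, 1e-300), 0.0
        )
    pos = g.positions()
    chroms = np.array(g.chromosomes())
    out: list[WindowStatistic] = []
    for w in make_windows(g.chrom_extents(), window_bp, step_bp):
        in_w = (chroms == w.chrom) & (pos >= w.start_bp) & (pos < w.end_bp) & ok
        k = int(in_w.sum())
        if k == 0 and drop_empty:
            continue
        value = float(pi_site[in_w].sum()) / window_bp
        out.append(
            WindowStatistic(
                window=GenomicWindow(w.chrom, w.start_bp, w.end_bp, n_loci=k),
                value=value,
            )
        )
    return out


def delta_pi_scan(
    pi_other: Sequence[WindowStatistic],
    pi_focal: Sequence[WindowStatistic],
    top_fraction: float = 0.01,
) -> list[WindowStatistic]:
    """Per-window difference pi_other - pi_focal; returns the empirical
    top fraction (large positive = diversity loss in the focal group).
    Windows present in only one input are dropped with a log entry.
    """
    a = {s.window.key: s for s in pi_other}
    b = {s.window.key: s for s in pi_focal}
    common = [k for k in a if k in b]
    if not common:
        raise ValueError("window tilings are disjoint")
    dropped = (len(a) - len(common)) + (len(b) - len(common))
    if dropped:
        logger.info("delta_pi_scan: %d windows present in only one input dropped", dropped)
    deltas = [
        WindowStatistic(
            window=GenomicWindow(*k, n_loci=min(a[k].window.n_loci, b[k].window.n_loci)),
            value=a[k].value - b[k].value,
        )
        for k in common
    ]
    return empirical_outliers(deltas, top_fraction)


def empirical_outliers(
    stats: Sequence[WindowStatistic], top_fraction: float
) -> list[WindowStatistic]:
    """Windows in the empirical top ``top_fraction`` of the value
    distribution (nearest-rank threshold; ties at the threshold are all
    included).  Fills ``percentile_rank`` on every input statistic.
    """
    if not stats:
        raise ValueError("empty statistic list")
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0,1)")
    n = len(stats)
    if n < 1.0 / top_fraction:
        warnings.warn(
            f"only {n} windows for top_fraction={top_fraction}; "
            "threshold is the maximum value",
            stacklevel=2,
        )
    values = np.array([s.value for s in stats], dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=float)
    # percentile_rank = fraction of windows with value <= own value
    sorted_vals = values[order]
    counts_le = np.searchsorted(sorted_vals, values, side="right")
    ranks = counts_le / n
    for s, r in zip(stats, ranks):
        s.percentile_rank = float(r)
    k = max(1, int(np.floor(top_fraction * n)))
    threshold = sorted_vals[n - k]
    if np.all(values == values[0]):
        warnings.warn("all window values identical; returning every window", stacklevel=2)
    return [s for s in stats if s.value >= threshold]
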