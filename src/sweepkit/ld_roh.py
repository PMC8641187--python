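"""LD-decay profiling over fixed distance classes and per-sample runs of
homozygosity (ROH).

ROH detection uses a maximal-run definition rather than PLINK's full
scanning-window machinery: per sample and chromosome, maximal
consecutive-SNP stretches of homozygous genotypes allowing a bounded
number of heterozygous and missing calls, reported when they meet
length and SNP-count thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "LdPair",
    "RohSegment",
    "genotype_r2",
    "ld_decay_profile",
    "detect_roh",
    "roh_counts_by_population",
]

DEFAULT_CLASS_EDGES_KB = (2.5, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0)


@dataclass(frozen=True)
class LdPair:
    i: int
    j: int
    distance_bp: int
    r2: float

    def __post_init__(self) -> None:
        if self.distance_bp <= 0:
            raise ValueError("distance_bp must be positive")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must be in [0,1]")


@dataclass(frozen=True)
class RohSegment:
    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        # 1-based inclusive span
        return self.end_bp - self.start_bp + 1


def genotype_r2(x: Sequence[int], y: Sequence[int]) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples; NaN if <2 complete samples or either
    vector is constant among them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(min(1.0, cov * cov / (vx * vy)))


def ld_decay_profile(
    g: GenotypeMatrix,
    populations: Iterable[str],
    class_edges_kb: Sequence[float] = DEFAULT_CLASS_EDGES_KB,
    max_pairs_per_class: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean r^2 per distance class over intra-chromosome locus pairs.

    A pair at distance d is counted in the first class whose upper edge
    (in kb) is >= d, i.e. bins (0, e1], (e1, e2], ...; pairs beyond the
    last edge are ignored.  ``max_pairs_per_class`` triggers uniform
    seeded subsampling.  Returns columns class_upper_kb, n_pairs,
    mean_r2 (NaN for empty classes).
    """
    edges_bp = np.asarray(sorted(class_edges_kb), dtype=float) * 1000.0
    idx = g.sample_indices(populations)
    sub = g.dosage[idx, :]
    pos = g.positions()
    chroms = np.array(g.chromosomes())

    pairs_by_class: list[list[tuple[int, int]]] = [[] for _ in edges_bp]
    for chrom in dict.fromkeys(g.chromosomes()):
        loc = np.flatnonzero(chroms == chrom)
        p = pos[loc]
        for a in range(len(loc)):
            hi = np.searchsorted(p, p[a] + edges_bp[-1], side="right")
            for b in range(a + 1, hi):
                d = p[b] - p[a]
                if d <= 0:
                    continue
                c = int(np.searchsorted(edges_bp, d, side="left"))
                if c < len(edges_bp):
                    pairs_by_class[c].append((int(loc[a]), int(loc[b])))

    rng = np.random.default_rng(seed)
    rows = []
    for c, edge in enumerate(edges_bp):
        pairs = pairs_by_class[c]
        if max_pairs_per_class is not None and len(pairs) > max_pairs_per_class:
            sel = rng.choice(len(pairs), size=max_pairs_per_class, replace=False)
            pairs = [pairs[int(k)] for k in np.sort(sel)]
        vals = [genotype_r2(sub[:, i], sub[:, j]) for i, j in pairs]
        vals = [v for v in vals if np.isfinite(v)]
        rows.append(
            {
                "class_upper_kb": edge / 1000.0,
                "n_pairs": len(vals),
                "mean_r2": float(np.mean(vals)) if vals else np.nan,
            }
        )
    return pd.DataFrame(rows)


def detect_roh(
    g: GenotypeMatrix,
    min_length_kb: float = 1000.0,
    min_snps: int = 50,
    max_het: int = 0,
    max_missing: int = 1,
    min_density_snp_per_kb: float | None = None,
) -> list[RohSegment]:
    """Per-sample maximal homozygous runs meeting length/SNP thresholds.

    A run starts and ends on a homozygous call and may contain at most
    ``max_het`` heterozygous and ``max_missing`` missing calls.  Runs are
    extracted greedily left-to-right; a reported segment must span at
    least ``min_length_kb`` kb, contain at least ``min_snps`` SNPs and,
    if set, have SNP density >= ``min_density_snp_per_kb``.
    """
    pos = g.positions()
    chroms = np.array(g.chromosomes())
    segments: list[RohSegment] = []
    for chrom in dict.fromkeys(g.chromosomes()):
        loc = np.flatnonzero(chroms == chrom)
        p = pos[loc]
        for si, sample in enumerate(g.samples):
            d = g.dosage[si, loc]
            hom = (d == 0) | (d == 2)
            het = d == 1
            miss = d == MISSING
            L = len(loc)
            i = 0
            while i < L:
                if not hom[i]:
                    i += 1
                    continue
                n_het = n_miss = 0
                j = i
                last_hom = i
                while j + 1 < L:
                    nxt = j + 1
                    nh = n_het + int(het[nxt])
                    nm = n_miss + int(miss[nxt])
                    if nh > max_het or nm > max_missing:
                        break
                    n_het, n_miss = nh, nm
                    j = nxt
                    if hom[j]:
                        last_hom = j
                start, end = i, last_hom
                n_snps = end - start + 1
                span = int(p[end] - p[start] + 1)
                if n_snps >= min_snps and span >= min_length_kb * 1000.0:
                    dens_ok = (
                        min_density_snp_per_kb is None
                        or n_snps / (span / 1000.0) >= min_density_snp_per_kb
                    )
                    if dens_ok:
                        segments.append(
                            RohSegment(
                                sample=sample,
                                chrom=chrom,
                                start_bp=int(p[start]),
                                end_bp=int(p[end]),
                                n_snps=n_snps,
                            )
                        )
                i = last_hom + 1
    return segments


def roh_counts_by_population(
    segments: Sequence[RohSegment], populations: Mapping[str, str]
) -> dict[str, float]:
    """Mean number of segments per individual, by population.

    ``populations`` must cover every sample of the cohort (samples
    without segments count as zero).
    """
    counts: dict[str, int] = {s: 0 for s in populations}
    for seg in segments:
        counts[seg.sample] = counts.get(seg.sample, 0) + 1
    by_pop: dict[str, list[int]] = {}
    for sample, pop in populations.items():
        by_pop.setdefault(pop, []).append(counts[sample])
    return {pop: float(np.mean(v)) for pop, v in by_pop.items() if v}


def roh_segments_to_frame(segments: Sequence[RohSegment], populations: Mapping[str, str]) -> pd.DataFrame:
    """PLINK .hom-style table (FID IID CHR POS1 POS2 KB NSNP)."""
    return pd.DataFrame(
        [
            {
                "FID": populations.get(s.sample, "0"),
                "IID": s.sample,
                "CHR": s.chrom,
                "POS1": s.start_bp,
                "POS2": s.end_bp,
                "KB": s.length_bp / 1000.0,
                "NSNP": s.n_snps,
            }
            for s in segments
        ],
        columns=["FID", "IID", "CHR", "POS1", "POS2", "KB", "NSNP"],
    )
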