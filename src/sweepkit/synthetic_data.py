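"""Forward Wright-Fisher simulator emitting a multi-breed SNP-chip-like
cohort with known selected loci, plus text fixture writers.

Loci are unlinked: each breed's allele frequency evolves independently
by binomial drift from a shared ancestral frequency, with an optional
deterministic directional-selection update at designated loci in the
commercial groups.  An optional block-copy mode perturbs within-block
frequencies around a block anchor so that nearby loci are correlated,
giving the LD module a monotone decay signal without coalescent
machinery.  A single global seed drives a hierarchical SeedSequence
scheme (ancestral draw, per-breed drift, sampling, missingness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PopulationScheme,
    VariantLocus,
    write_allele_ref,
    write_ped_map,
    write_population_map,
    write_vcf,
)
from .selection_scan import GenomicWindow, WindowStatistic

__all__ = [
    "BreedSpec",
    "SimConfig",
    "SweepTruth",
    "simulate_cohort",
    "write_fixtures",
    "score_recovery",
    "default_scheme",
]

GROUPS = ("indigenous", "commercial_meat", "commercial_milk")


@dataclass(frozen=True)
class BreedSpec:
    label: str
    group: str
    sample_n: int
    ne: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sample_n < 1 or self.ne < 1:
            raise ValueError("sample_n and ne must be positive")


def _default_breeds() -> list[BreedSpec]:
    return [
        BreedSpec("native_a", "indigenous", 34, 400),
        BreedSpec("native_b", "indigenous", 37, 400),
        BreedSpec("native_c", "indigenous", 35, 400),
        BreedSpec("meat_a", "commercial_meat", 21, 200),
        BreedSpec("meat_b", "commercial_meat", 46, 200),
        BreedSpec("milk_a", "commercial_milk", 103, 200),
        BreedSpec("milk_b", "commercial_milk", 9, 200),
        BreedSpec("milk_c", "commercial_milk", 39, 200),
    ]


@dataclass
class SimConfig:
    n_chromosomes: int = 10
    chrom_length_bp: int = 50_000_000
    n_snps: int = 20_000
    breeds: list[BreedSpec] = field(default_factory=_default_breeds)
    generations_split: int = 50
    generations_group: int = 20  # shared drift per group before breed split
    group_ne: int = 500
    selection_coefficient_s: float = 0.1
    n_selected_loci: int = 30
    missing_rate: float = 0.02
    seed: int = 0
    selected_groups: tuple[str, ...] = ("commercial_meat", "commercial_milk")
    # >0 enables linked-genealogy sampling: base LD correlation length in
    # bp at Ne = ld_ref_ne, scaled per breed by ld_ref_ne / Ne
    block_bp: int = 0
    ld_ref_ne: int = 100

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chrom_length_bp, self.n_snps) < 1:
            raise ValueError("counts must be positive")
        if self.selection_coefficient_s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")
        if self.n_selected_loci < 0 or self.n_selected_loci > self.n_snps:
            raise ValueError("n_selected_loci out of range")
        if isinstance(self.breeds, list) and self.breeds and isinstance(self.breeds[0], (list, tuple)):
            self.breeds = [BreedSpec(*b) for b in self.breeds]
        labels = [b.label for b in self.breeds]
        if len(set(labels)) != len(labels):
            raise ValueError("breed labels must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "breeds" in raw:
            raw["breeds"] = [BreedSpec(**b) for b in raw["breeds"]]
        if "selected_groups" in raw:
            raw["selected_groups"] = tuple(raw["selected_groups"])
        return cls(**raw)


@dataclass
class SweepTruth:
    """Loci under directional selection: (chrom, pos_bp, group tag, s)."""

    records: list[tuple[str, int, str, float]] = field(default_factory=list)

    def positions(self) -> set[tuple[str, int]]:
        return {(chrom, pos) for chrom, pos, _, _ in self.records}


def default_scheme(cfg: SimConfig, pooled_commercial: bool = False) -> PopulationScheme:
    """PopulationScheme mirroring the simulated breed groups."""
    groups: dict[str, set[str]] = {}
    for b in cfg.breeds:
        if pooled_commercial and b.group != "indigenous":
            groups.setdefault("commercial", set()).add(b.label)
        else:
            groups.setdefault(b.group, set()).add(b.label)
    return PopulationScheme(groups=groups)


def _draw_positions(rng: np.random.Generator, cfg: SimConfig) -> list[tuple[str, int]]:
    per_chrom = [cfg.n_snps // cfg.n_chromosomes] * cfg.n_chromosomes
    for k in range(cfg.n_snps % cfg.n_chromosomes):
        per_chrom[k] += 1
    out: list[tuple[str, int]] = []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        want = per_chrom[c]
        pos: set[int] = set()
        while len(pos) < want:
            draw = rng.integers(1, cfg.chrom_length_bp + 1, size=want - len(pos))
            pos.update(int(x) for x in draw)
        out.extend((chrom, p) for p in sorted(pos))
    return out


def _ancestral_frequencies(rng: np.random.Generator, n: int) -> np.ndarray:
    """Beta(0.5, 0.5) truncated to [0.05, 0.95] by rejection."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.beta(0.5, 0.5, size=2 * (n - filled))
        keep = draw[(draw >= 0.05) & (draw <= 0.95)][: n - filled]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def _sample_linked(
    rng: np.random.Generator,
    p: np.ndarray,
    coords: list[tuple[str, int]],
    breed: BreedSpec,
    cfg: SimConfig,
) -> np.ndarray:
    """Haplotype sampling with distance-decaying linkage.

    Each haplotype carries a latent uniform that persists from one locus
    to the next with probability exp(-d / corr_len) (redrawn otherwise);
    the allele is the indicator u < p.  Marginal frequencies are exactly
    ``p`` while nearby loci share the latent uniform, so within-breed
    genotype r^2 decays monotonically with distance and the correlation
    length scales like 1/Ne.
    """
    corr_len = cfg.block_bp * cfg.ld_ref_ne / breed.ne
    n_hap = 2 * breed.sample_n
    alleles = np.empty((n_hap, cfg.n_snps), dtype=np.int8)
    u = rng.random(n_hap)
    prev_key: tuple[str, int] | None = None
    for j, (chrom, pos) in enumerate(coords):
        if prev_key is None or prev_key[0] != chrom:
            keep = np.zeros(n_hap, dtype=bool)
        else:
            retain = np.exp(-(pos - prev_key[1]) / corr_len) if corr_len > 0 else 0.0
            keep = rng.random(n_hap) < retain
        fresh = ~keep
        if fresh.any():
            u[fresh] = rng.random(int(fresh.sum()))
        alleles[:, j] = u < p[j]
        prev_key = (chrom, pos)
    return (alleles[0::2] + alleles[1::2]).astype(np.int8)


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, SweepTruth]:
    """Simulate the cohort; fully reproducible from ``cfg.seed``.

    Ancestral frequencies first drift ``generations_group`` generations
    per group (shared by the group's breeds), then each breed drifts
    independently for ``generations_split`` generations at its Ne; at
    selected loci in breeds of ``selected_groups`` the deterministic
    update p' = p(1+s)/(1+sp) precedes drift each generation.
    Individual dosages are Binomial(2, p_breed) draws; missingness is
    uniform at ``missing_rate``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(6 + len(GROUPS) + len(cfg.breeds))
    anc_ss, pos_ss, sel_ss, samp_ss, miss_ss, block_ss = children[:6]
    group_ss = dict(zip(GROUPS, children[6 : 6 + len(GROUPS)]))
    breed_ss = children[6 + len(GROUPS) :]
    coords = _draw_positions(np.random.default_rng(pos_ss), cfg)
    p_anc = _ancestral_frequencies(np.random.default_rng(anc_ss), cfg.n_snps)

    sel_rng = np.random.default_rng(sel_ss)
    candidates = np.flatnonzero(p_anc <= 0.5)  # selection lifts the alt allele
    if len(candidates) < cfg.n_selected_loci:
        candidates = np.arange(cfg.n_snps)
    selected = np.sort(
        sel_rng.choice(candidates, size=cfg.n_selected_loci, replace=False)
    )
    sel_mask = np.zeros(cfg.n_snps, dtype=bool)
    sel_mask[selected] = True

    s = cfg.selection_coefficient_s
    # shared group-level drift so breeds of a group have common history
    p_group: dict[str, np.ndarray] = {}
    for grp in GROUPS:
        rng = np.random.default_rng(group_ss[grp])
        p = p_anc.copy()
        two_ne = 2 * cfg.group_ne
        for _ in range(cfg.generations_group):
            p = rng.binomial(two_ne, p) / two_ne
        p_group[grp] = p

    dosage = np.empty((sum(b.sample_n for b in cfg.breeds), cfg.n_snps), dtype=np.int8)
    samples: list[str] = []
    populations: dict[str, str] = {}
    row = 0
    samp_rng = np.random.default_rng(samp_ss)
    block_rng = np.random.default_rng(block_ss)
    for b, bss in zip(cfg.breeds, breed_ss):
        rng = np.random.default_rng(bss)
        p = p_group[b.group].copy()
        sel_here = sel_mask if b.group in cfg.selected_groups else None
        two_ne = 2 * b.ne
        for _ in range(cfg.generations_split):
            if sel_here is not None and s > 0:
                ps = p[sel_here]
                p[sel_here] = ps * (1.0 + s) / (1.0 + s * ps)
            p = rng.binomial(two_ne, p) / two_ne
        if cfg.block_bp > 0:
            dos = _sample_linked(block_rng, p, coords, b, cfg)
        else:
            dos = samp_rng.binomial(2, p, size=(b.sample_n, cfg.n_snps)).astype(np.int8)
        dosage[row : row + b.sample_n] = dos
        for k in range(b.sample_n):
            name = f"{b.label}_{k + 1:03d}"
            samples.append(name)
            populations[name] = b.label
        row += b.sample_n

    if cfg.missing_rate > 0:
        miss_rng = np.random.default_rng(miss_ss)
        mask = miss_rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = MISSING

    loci = [
        VariantLocus(chrom, pos, f"snp_{chrom}_{pos}", "A", "G")
        for chrom, pos in coords
    ]
    truth = SweepTruth(
        records=[
            (coords[j][0], coords[j][1], "+".join(cfg.selected_groups), s)
            for j in selected
        ]
    )
    return GenotypeMatrix(loci, samples, dosage, populations), truth


def write_fixtures(
    g: GenotypeMatrix,
    truth: SweepTruth,
    outdir: str | Path,
    gene_length_bp: int = 30_000,
    gene_spacing_bp: int = 50_000,
    n_background_terms: int = 5,
    term_seed: int = 0,
) -> dict[str, Path]:
    """Write the full text fixture set: PED/MAP, VCF, population map,
    truth BED (0-based half-open), a synthetic gene BED tiling the
    chromosomes, and a GMT term map with one term enriched for
    truth-adjacent genes.  All formats round-trip through genotype_io /
    annotation readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": outdir / "cohort.ped",
        "map": outdir / "cohort.map",
        "vcf": outdir / "cohort.vcf",
        "pop_map": outdir / "populations.tsv",
        "allele_ref": outdir / "alleles.tsv",
        "truth_bed": outdir / "truth.bed",
        "genes_bed": outdir / "genes.bed",
        "gmt": outdir / "terms.gmt",
    }
    write_ped_map(g, paths["ped"], paths["map"])
    write_vcf(g, paths["vcf"])
    write_population_map(g, paths["pop_map"])
    write_allele_ref(g, paths["allele_ref"])

    with open(paths["truth_bed"], "w") as fh:
        for chrom, pos, group, s in truth.records:
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\tsel_{chrom}_{pos}\t{s:g}\t{group}\n")

    extents = g.chrom_extents()
    gene_rows: list[tuple[str, int, int, str]] = []
    k = 0
    for chrom in extents:
        start = 0  # 0-based BED starts
        while start + gene_length_bp <= extents[chrom]:
            k += 1
            gene_rows.append((chrom, start, start + gene_length_bp, f"gene{k}"))
            start += gene_spacing_bp
    with open(paths["genes_bed"], "w") as fh:
        for chrom, s0, e0, gid in gene_rows:
            fh.write(f"{chrom}\t{s0}\t{e0}\t{gid}\t0\t+\n")

    truth_pos = truth.positions()
    sweep_genes = {
        gid
        for chrom, s0, e0, gid in gene_rows
        if any(c == chrom and s0 < p < e0 for c, p in truth_pos)
    }
    all_genes = [gid for _, _, _, gid in gene_rows]
    rng = np.random.default_rng(term_seed)
    with open(paths["gmt"], "w") as fh:
        if sweep_genes:
            fh.write(
                "SWEEP_ADJACENT\tgenes overlapping selected loci\t"
                + "\t".join(sorted(sweep_genes))
                + "\n"
            )
        for t in range(n_background_terms):
            size = min(len(all_genes), int(rng.integers(10, 40)))
            members = rng.choice(all_genes, size=size, replace=False)
            fh.write(
                f"BG_TERM_{t + 1}\tbackground term {t + 1}\t" + "\t".join(sorted(members)) + "\n"
            )
    return paths


def score_recovery(
    outliers: Sequence[WindowStatistic | GenomicWindow],
    truth: SweepTruth,
    genome_bp: int | None = None,
    chrom_extents: dict[str, int] | None = None,
) -> dict[str, float]:
    """Recall / precision / fold enrichment of truth loci vs outlier
    windows.

    recall: fraction of truth loci inside >= 1 outlier window.
    precision: fraction of outlier windows containing >= 1 truth locus
    (NaN for an empty outlier set).
    fold_enrichment: truth density inside the union of outlier windows
    over genome-wide truth density (requires the genome size, supplied
    directly or via chrom_extents).
    """
    windows = [o.window if isinstance(o, WindowStatistic) else o for o in outliers]
    truth_pos = sorted(truth.positions())
    n_truth = len(truth_pos)
    if not windows:
        return {"recall": 0.0, "precision": float("nan"), "fold_enrichment": float("nan")}
    covered = 0
    for chrom, pos in truth_pos:
        if any(w.chrom == chrom and w.contains(pos) for w in windows):
            covered += 1
    hit_windows = sum(
        1 for w in windows if any(c == w.chrom and w.contains(p) for c, p in truth_pos)
    )
    recall = covered / n_truth if n_truth else float("nan")
    precision = hit_windows / len(windows)
    # union span of outlier windows (merge overlaps per chromosome)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append((w.start_bp, w.end_bp))
    union_bp = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s0, e0 in ivs[1:]:
            if s0 > cur_e:
                union_bp += cur_e - cur_s
                cur_s, cur_e = s0, e0
            else:
                cur_e = max(cur_e, e0)
        union_bp += cur_e - cur_s
    if genome_bp is None and chrom_extents is not None:
        genome_bp = sum(chrom_extents.values())
    if genome_bp and n_truth and union_bp:
        dens_in = covered / union_bp
        dens_all = n_truth / genome_bp
        fold = dens_in / dens_all if dens_all > 0 else float("nan")
    else:
        fold = float("nan")
    return {"recall": recall, "precision": precision, "fold_enrichment": fold}
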