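"""End-to-end scan orchestration: QC once, then per-comparison windowed
FST with top-1%/5% outliers, per-group windowed pi with a top-1%
delta-pi scan, gene annotation of the union of outlier regions, and the
structure diagnostics (LD pruning -> NJ + bootstrap; ROH and LD decay
per population).

The pruned SNP set feeds only the tree/structure stages; the FST and pi
scans run on the full post-QC set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    enrichment_bh,
    enrichment_to_frame,
    genes_in_regions,
    read_gene_intervals,
    read_gmt,
)
from .genotype_io import (
    GenotypeMatrix,
    PopulationScheme,
    read_ped_map,
    read_vcf,
    subset_by_group,
)
from .ld_roh import (
    DEFAULT_CLASS_EDGES_KB,
    detect_roh,
    ld_decay_profile,
    roh_counts_by_population,
    roh_segments_to_frame,
)
from .population_structure import bootstrap_support, ibs_distance, write_newick
from .qc_filters import PruneParams, QcThresholds, apply_qc_filters, ld_prune
from .selection_scan import (
    WindowStatistic,
    delta_pi_scan,
    empirical_outliers,
    windowed_fst,
    windowed_pi,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_scan_pipeline", "windows_to_frame"]


@dataclass
class RunConfig:
    # input: either vcf+pop_map or ped+map
    vcf: str | None = None
    pop_map: str | None = None
    ped: str | None = None
    map: str | None = None
    scheme: dict[str, list[str]] = field(default_factory=dict)
    reference_group: str = "indigenous"
    comparison_groups: list[str] = field(default_factory=lambda: ["commercial_meat", "commercial_milk"])
    qc: QcThresholds = field(default_factory=QcThresholds)
    prune: PruneParams = field(default_factory=PruneParams)
    fst_window_bp: int = 100_000
    fst_step_bp: int = 50_000
    pi_window_bp: int = 50_000
    pi_step_bp: int = 25_000
    outlier_fractions: tuple[float, float] = (0.01, 0.05)
    delta_pi_top_fraction: float = 0.01
    roh_min_length_kb: float = 1000.0
    roh_min_snps: int = 50
    roh_max_het: int = 0
    roh_max_missing: int = 1
    ld_class_edges_kb: tuple[float, ...] = DEFAULT_CLASS_EDGES_KB
    ld_max_pairs_per_class: int | None = 20_000
    tree_level: str = "population"
    bootstrap_replicates: int = 100
    genes: str | None = None
    gene_format: str | None = None
    terms_gmt: str | None = None
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if isinstance(self.qc, dict):
            self.qc = QcThresholds(**self.qc)
        if isinstance(self.prune, dict):
            self.prune = PruneParams(**self.prune)
        if self.fst_window_bp < self.fst_step_bp or self.pi_window_bp < self.pi_step_bp:
            raise ValueError("window must be >= step")
        for f in (*self.outlier_fractions, self.delta_pi_top_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("outlier fractions must be in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_inputs(self) -> None:
        if self.vcf is not None:
            missing = [p for p in (self.vcf, self.pop_map) if p is None or not Path(p).exists()]
        elif self.ped is not None:
            missing = [p for p in (self.ped, self.map) if p is None or not Path(p).exists()]
        else:
            raise ValueError("config must provide vcf+pop_map or ped+map input")
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if not self.scheme:
            raise ValueError("config must define a population scheme")

    def load_genotypes(self) -> GenotypeMatrix:
        if self.vcf is not None:
            return read_vcf(self.vcf, self.pop_map)
        return read_ped_map(self.ped, self.map)

    def population_scheme(self) -> PopulationScheme:
        return PopulationScheme(groups={k: set(v) for k, v in self.scheme.items()})


def windows_to_frame(stats: list[WindowStatistic]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.window.chrom,
                "start": s.window.start_bp,
                "end": s.window.end_bp,
                "n_loci": s.window.n_loci,
                "value": s.value,
                "percentile_rank": s.percentile_rank,
            }
            for s in stats
        ],
        columns=["chrom", "start", "end", "n_loci", "value", "percentile_rank"],
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return len(df)


def _write_bed(stats: list[WindowStatistic], path: Path) -> int:
    with open(path, "w") as fh:
        for s in stats:
            # internal 1-based half-open -> BED 0-based half-open
            fh.write(
                f"{s.window.chrom}\t{s.window.start_bp - 1}\t{s.window.end_bp - 1}"
                f"\t.\t{s.value:.10g}\n"
            )
    return len(stats)


def run_scan_pipeline(cfg: RunConfig) -> dict:
    """Run the full scan; returns the manifest (also written as JSON)."""
    cfg.validate_inputs()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "qc": vars(cfg.qc),
            "prune": vars(cfg.prune),
            "fst_window_bp": cfg.fst_window_bp,
            "fst_step_bp": cfg.fst_step_bp,
            "pi_window_bp": cfg.pi_window_bp,
            "pi_step_bp": cfg.pi_step_bp,
            "outlier_fractions": list(cfg.outlier_fractions),
            "delta_pi_top_fraction": cfg.delta_pi_top_fraction,
        },
        "stages": {},
        "files": {},
    }

    def record(stage: str, name: str, path: Path, rows: int) -> None:
        manifest["stages"].setdefault(stage, {})[name] = rows
        manifest["files"][name] = str(path)

    logger.info("stage qc: loading genotypes")
    g = cfg.load_genotypes()
    scheme = cfg.population_scheme()
    g_qc, qc_report = apply_qc_filters(g, cfg.qc)
    p = out / "qc_report.tsv"
    record("qc", "qc_report", p, _write_tsv(qc_report, p))
    manifest["stages"]["qc"]["n_loci_in"] = g.n_loci
    manifest["stages"]["qc"]["n_loci_kept"] = g_qc.n_loci
    manifest["stages"]["qc"]["n_samples"] = g.n_samples

    ref = cfg.reference_group
    outlier_union: list[WindowStatistic] = []
    for comp in cfg.comparison_groups:
        tag = f"{ref}_vs_{comp}"
        logger.info("stage fst: %s", tag)
        fst = windowed_fst(
            g_qc, scheme, (ref, comp), cfg.fst_window_bp, cfg.fst_step_bp
        )
        p = out / f"fst_windows_{tag}.tsv"
        # fill percentile ranks via the larger outlier fraction call below
        for frac in sorted(cfg.outlier_fractions):
            outs = empirical_outliers(fst, frac)
            pb = out / f"fst_outliers_top{frac:g}_{tag}.bed"
            record(f"fst:{tag}", f"fst_outliers_top{frac:g}_{tag}", pb, _write_bed(outs, pb))
            if frac == max(cfg.outlier_fractions):
                outlier_union.extend(outs)
        record(f"fst:{tag}", f"fst_windows_{tag}", p, _write_tsv(windows_to_frame(fst), p))

        logger.info("stage pi: %s", tag)
        pi_ref = windowed_pi(g_qc, scheme[ref], cfg.pi_window_bp, cfg.pi_step_bp)
        pi_comp = windowed_pi(g_qc, scheme[comp], cfg.pi_window_bp, cfg.pi_step_bp)
        for name, stats in ((ref, pi_ref), (comp, pi_comp)):
            pp = out / f"pi_windows_{name}.tsv"
            record(f"pi:{tag}", f"pi_windows_{name}", pp, _write_tsv(windows_to_frame(stats), pp))
        # large delta = diversity loss in the comparison (focal) group
        dpi = delta_pi_scan(pi_ref, pi_comp, cfg.delta_pi_top_fraction)
        pb = out / f"delta_pi_outliers_{tag}.bed"
        record(f"pi:{tag}", f"delta_pi_outliers_{tag}", pb, _write_bed(dpi, pb))
        outlier_union.extend(dpi)

    if cfg.genes is not None:
        logger.info("stage annotate")
        genes = read_gene_intervals(cfg.genes, cfg.gene_format)
        region_map = genes_in_regions([s.window for s in outlier_union], genes)
        rows = []
        for w, hits in region_map.items():
            for gi in hits:
                rows.append(
                    {
                        "chrom": w.chrom,
                        "start": w.start_bp,
                        "end": w.end_bp,
                        "gene_id": gi.gene_id,
                        "gene_name": gi.gene_name,
                    }
                )
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "gene_name"])
        p = out / "outlier_region_genes.tsv"
        record("annotate", "outlier_region_genes", p, _write_tsv(df, p))
        if cfg.terms_gmt is not None and rows:
            term_map, descriptions = read_gmt(cfg.terms_gmt)
            # universe: genes overlapping any scanned window (chip coverage)
            from .selection_scan import make_windows

            scanned = make_windows(g_qc.chrom_extents(), cfg.fst_window_bp, cfg.fst_step_bp)
            universe_hits = genes_in_regions(scanned, genes)
            universe = {gi.gene_id for hits in universe_hits.values() for gi in hits}
            query = {r["gene_id"] for r in rows} & universe
            results = enrichment_bh(query, term_map, universe, descriptions)
            p = out / "enrichment.tsv"
            record("annotate", "enrichment", p, _write_tsv(enrichment_to_frame(results), p))

    logger.info("stage structure: LD pruning + NJ tree")
    kept = ld_prune(g_qc, cfg.prune, seed=cfg.seed)
    g_pruned = g_qc.subset_loci(kept)
    manifest["stages"]["prune"] = {"n_loci_kept": len(kept)}
    dm = ibs_distance(g_pruned, level=cfg.tree_level)
    p = out / "distances.tsv"
    dm.to_tsv(p)
    record("structure", "distances", p, len(dm.labels))
    tree = bootstrap_support(
        g_pruned, cfg.bootstrap_replicates, seed=cfg.seed, level=cfg.tree_level
    )
    p = out / "nj_tree.nwk"
    write_newick(tree, p)
    record("structure", "nj_tree", p, 1)

    logger.info("stage roh")
    roh = detect_roh(
        g_qc,
        min_length_kb=cfg.roh_min_length_kb,
        min_snps=cfg.roh_min_snps,
        max_het=cfg.roh_max_het,
        max_missing=cfg.roh_max_missing,
    )
    p = out / "roh_segments.tsv"
    record("roh", "roh_segments", p, _write_tsv(roh_segments_to_frame(roh, g_qc.populations), p))
    means = roh_counts_by_population(roh, g_qc.populations)
    df = pd.DataFrame(
        sorted(means.items()), columns=["population", "mean_roh_per_individual"]
    )
    p = out / "roh_by_population.tsv"
    record("roh", "roh_by_population", p, _write_tsv(df, p))

    logger.info("stage ld decay")
    ld_rows = []
    for pop in sorted(set(g_qc.populations.values())):
        prof = ld_decay_profile(
            g_qc,
            {pop},
            class_edges_kb=cfg.ld_class_edges_kb,
            max_pairs_per_class=cfg.ld_max_pairs_per_class,
            seed=cfg.seed,
        )
        prof.insert(0, "population", pop)
        ld_rows.append(prof)
    p = out / "ld_decay.tsv"
    record("ld", "ld_decay", p, _write_tsv(pd.concat(ld_rows, ignore_index=True), p))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
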