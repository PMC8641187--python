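"""Gene annotation of outlier windows and hypergeometric
overrepresentation testing with Benjamini-Hochberg correction.

Gene intervals are stored 1-based half-open internally; BED input
(0-based half-open) and GFF3 gene features (1-based inclusive) are
converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genotype_io import _natural_key
from .selection_scan import GenomicWindow

__all__ = [
    "GeneInterval",
    "EnrichmentResult",
    "read_gene_intervals",
    "read_gmt",
    "genes_in_regions",
    "enrichment_bh",
]


class AnnotationParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneInterval:
    chrom: str
    start_bp: int  # 1-based half-open [start, end)
    end_bp: int
    gene_id: str
    gene_name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError(f"empty interval for {self.gene_id}")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    description: str
    overlap_count: int
    term_size: int
    query_size: int
    universe_size: int
    p_value: float
    bh_adjusted_p: float


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.split(";"):
        part = part.strip()
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gene_intervals(path: str | Path, fmt: str | None = None) -> list[GeneInterval]:
    """Read gene intervals from BED or GFF3 (``fmt`` inferred from the
    file extension when omitted).  Duplicate gene ids are an error.
    Strand is recorded but ignored for overlap.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "GFF3" if suffix in (".gff", ".gff3") else "BED"
    fmt = fmt.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError("fmt must be 'BED' or 'GFF3'")
    genes: list[GeneInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            try:
                if fmt == "BED":
                    chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
                    gene_id = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{end0}"
                    strand = parts[5] if len(parts) > 5 else "."
                    # BED [start0, end0) 0-based maps to [start0+1, end0) in
                    # the internal 1-based half-open convention
                    gi = GeneInterval(chrom, start0 + 1, end0, gene_id, gene_id, strand)
                else:
                    if len(parts) < 9:
                        raise ValueError("GFF3 line with <9 fields")
                    if parts[2].lower() != "gene":
                        continue
                    chrom, start1, end1 = parts[0], int(parts[3]), int(parts[4])
                    attrs = _parse_gff3_attributes(parts[8])
                    gene_id = attrs.get("ID") or attrs.get("gene_id")
                    if not gene_id:
                        raise ValueError("gene feature without ID attribute")
                    name = attrs.get("Name", gene_id)
                    # 1-based inclusive -> 1-based half-open
                    gi = GeneInterval(chrom, start1, end1 + 1, gene_id, name, parts[6])
            except (ValueError, IndexError) as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
            if gi.gene_id in seen:
                raise AnnotationParseError(f"{path}:{lineno}: duplicate gene_id {gi.gene_id!r}")
            seen.add(gi.gene_id)
            genes.append(gi)
    return genes


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GMT term map: term<TAB>description<TAB>gene...; returns
    (term -> gene set, term -> description)."""
    term_map: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationParseError(f"{path}:{lineno}: expected >= 3 columns")
            term_map[parts[0]] = set(parts[2:])
            descriptions[parts[0]] = parts[1]
    return term_map, descriptions


def genes_in_regions(
    regions: Sequence[GenomicWindow], genes: Sequence[GeneInterval]
) -> dict[GenomicWindow, list[GeneInterval]]:
    """Genes overlapping each region by >= 1 bp under the shared 1-based
    half-open convention; a gene spanning several regions is listed under
    each.  Interval sweep per chromosome over sorted inputs."""
    by_chrom: dict[str, list[GeneInterval]] = {}
    for gi in genes:
        by_chrom.setdefault(gi.chrom, []).append(gi)
    for lst in by_chrom.values():
        lst.sort(key=lambda gi: (gi.start_bp, gi.end_bp, gi.gene_id))
    out: dict[GenomicWindow, list[GeneInterval]] = {}
    regions_sorted = sorted(
        regions, key=lambda w: (_natural_key(w.chrom), w.start_bp, w.end_bp)
    )
    for w in regions_sorted:
        hits: list[GeneInterval] = []
        for gi in by_chrom.get(w.chrom, ()):
            if gi.start_bp >= w.end_bp:
                break
            if gi.end_bp > w.start_bp:
                hits.append(gi)
        out[w] = hits
    return out


def enrichment_bh(
    query_genes: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    descriptions: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric overrepresentation P(X >= overlap) per
    term, BH step-up adjusted across tested terms, sorted by adjusted p.
    Terms with no gene in the universe are skipped.
    """
    universe = set(universe)
    query = set(query_genes)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for term, genes in term_map.items():
        term_genes = set(genes) & universe
        if not term_genes:
            continue
        overlap = len(term_genes & query)
        p = float(hypergeom.sf(overlap - 1, len(universe), len(term_genes), len(query)))
        rows.append((term, overlap, len(term_genes), min(p, 1.0)))
    if not rows:
        return []
    m = len(rows)
    raw = np.array([r[3] for r in rows])
    order = np.argsort(raw, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running = min(running, raw[i] * m / (rank_from_top + 1))
        adj[i] = running
    results = [
        EnrichmentResult(
            term_id=term,
            description=(descriptions or {}).get(term, ""),
            overlap_count=overlap,
            term_size=size,
            query_size=len(query),
            universe_size=len(universe),
            p_value=p,
            bh_adjusted_p=float(adj[i]),
        )
        for i, (term, overlap, size, p) in enumerate(rows)
    ]
    results.sort(key=lambda r: (r.bh_adjusted_p, r.p_value, r.term_id))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "description": r.description,
                "overlap": r.overlap_count,
                "term_size": r.term_size,
                "query_size": r.query_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
                "bh_adjusted_p": r.bh_adjusted_p,
            }
            for r in results
        ]
    )
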