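"""Genotype container and I/O for multi-population diploid SNP data.

Supports PLINK PED/MAP text format and VCF (via cyvcf2), with population
labels carried alongside the dosage matrix.  Dosages count copies of the
alt allele (0/1/2) with ``MISSING = -1`` as a distinct, never-imputed
symbol.  Loci are stored natural-sorted by chromosome and ascending by
1-based physical position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

MISSING = -1

__all__ = [
    "MISSING",
    "VariantLocus",
    "GenotypeMatrix",
    "PopulationScheme",
    "read_ped_map",
    "read_vcf",
    "read_population_map",
    "allele_frequencies",
    "subset_by_group",
    "write_ped_map",
    "write_vcf",
    "write_population_map",
]


class GenotypeParseError(ValueError):
    """Raised on malformed genotype input files."""


@dataclass(frozen=True)
class VariantLocus:
    """A biallelic SNP with 1-based physical coordinates."""

    chrom: str
    pos_bp: int
    locus_id: str
    ref_allele: str = "A"
    alt_allele: str = "B"

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp} at {self.locus_id}")


def _natural_key(chrom: str) -> tuple:
    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", chrom))


def _locus_sort_key(loc: VariantLocus) -> tuple:
    return (_natural_key(loc.chrom), loc.pos_bp, loc.locus_id)


class GenotypeMatrix:
    """samples x loci diploid dosage matrix with population labels.

    Parameters
    ----------
    loci : sequence of VariantLocus
    samples : sequence of str
    dosage : ndarray, shape (n_samples, n_loci)
        Values in {0, 1, 2, MISSING}.
    populations : mapping sample -> population label
    sort_loci : bool
        If True (default) loci (and dosage columns) are re-sorted into
        canonical order: natural chromosome sort, then position, then id.
    """

    def __init__(
        self,
        loci: Sequence[VariantLocus],
        samples: Sequence[str],
        dosage: np.ndarray,
        populations: Mapping[str, str],
        sort_loci: bool = True,
    ) -> None:
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(samples), len(loci)):
            raise ValueError(
                f"dosage shape {dosage.shape} != (n_samples={len(samples)}, n_loci={len(loci)})"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"dosage contains values outside {{0,1,2,{MISSING}}}")
        missing_pop = [s for s in samples if s not in populations]
        if missing_pop:
            raise ValueError(f"samples without population label: {missing_pop[:5]}")
        loci = list(loci)
        if sort_loci:
            order = sorted(range(len(loci)), key=lambda i: _locus_sort_key(loci[i]))
            loci = [loci[i] for i in order]
            dosage = dosage[:, order]
        seen: set[tuple[str, int]] = set()
        for loc in loci:
            key = (loc.chrom, loc.pos_bp)
            if key in seen:
                raise ValueError(f"duplicate locus coordinate {key}")
            seen.add(key)
        self.loci: list[VariantLocus] = loci
        self.samples: list[str] = list(samples)
        self.dosage: np.ndarray = dosage
        self.populations: dict[str, str] = {s: populations[s] for s in samples}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def positions(self) -> np.ndarray:
        return np.array([loc.pos_bp for loc in self.loci], dtype=np.int64)

    def chromosomes(self) -> list[str]:
        return [loc.chrom for loc in self.loci]

    def chrom_extents(self) -> dict[str, int]:
        """Max observed position per chromosome."""
        out: dict[str, int] = {}
        for loc in self.loci:
            out[loc.chrom] = max(out.get(loc.chrom, 0), loc.pos_bp)
        return out

    def population_of(self, sample: str) -> str:
        return self.populations[sample]

    def sample_indices(self, populations: Iterable[str]) -> np.ndarray:
        pops = set(populations)
        unknown = pops - set(self.populations.values())
        if unknown:
            raise KeyError(f"unknown population labels: {sorted(unknown)}")
        return np.array(
            [i for i, s in enumerate(self.samples) if self.populations[s] in pops],
            dtype=np.intp,
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        samples = [self.samples[i] for i in idx]
        return GenotypeMatrix(
            self.loci, samples, self.dosage[idx, :], self.populations, sort_loci=False
        )

    def subset_loci(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        loci = [self.loci[i] for i in idx]
        return GenotypeMatrix(
            loci, self.samples, self.dosage[:, idx], self.populations, sort_loci=True
        )


@dataclass
class PopulationScheme:
    """Named groups of population labels (disjoint, non-empty)."""

    groups: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, pops in self.groups.items():
            pops = set(pops)
            if not pops:
                raise ValueError(f"group {name!r} is empty")
            clash = seen & pops
            if clash:
                raise ValueError(f"populations in multiple groups: {sorted(clash)}")
            seen |= pops
            self.groups[name] = pops

    def __getitem__(self, group: str) -> set[str]:
        if group not in self.groups:
            raise KeyError(f"group {group!r} not in scheme (have {sorted(self.groups)})")
        return self.groups[group]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(groups={k: set(v) for k, v in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: sorted(v) for k, v in self.groups.items()}, fh)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_population_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample<TAB>population."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GenotypeParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            out[parts[0]] = parts[1]
    return out


def read_allele_ref(path: str | Path) -> dict[str, tuple[str, str]]:
    """Three-column TSV locus_id<TAB>ref<TAB>alt fixing allele orientation."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.strip().split("\t")
            if not parts or not parts[0] or parts[0].startswith("#"):
                continue
            if len(parts) != 3:
                raise GenotypeParseError(f"{path}:{lineno}: expected 3 columns")
            out[parts[0]] = (parts[1], parts[2])
    return out


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    allele_ref: Mapping[str, tuple[str, str]] | str | Path | None = None,
) -> GenotypeMatrix:
    """Parse PLINK text PED/MAP into a GenotypeMatrix.

    The PED family-ID column becomes the population label.  ``0 0`` allele
    pairs (and half-calls) become MISSING.  By default the alt allele is
    the minor allele over all samples; ``allele_ref`` (a mapping or the
    path of a TSV written by :func:`write_allele_ref`) maps
    locus_id -> (ref, alt) to override orientation.
    """
    if allele_ref is not None and not isinstance(allele_ref, Mapping):
        allele_ref = read_allele_ref(allele_ref)
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise GenotypeParseError(f"{map_path}:{lineno}: expected 3-4 columns")
            chrom, locus_id = parts[0], parts[1]
            pos = int(parts[-1])
            map_rows.append((chrom, locus_id, pos))
    n_loci = len(map_rows)

    samples: list[str] = []
    populations: dict[str, str] = {}
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_loci:
                raise GenotypeParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} columns "
                    f"(6 + 2x{n_loci} loci), got {len(parts)}"
                )
            fam, iid = parts[0], parts[1]
            samples.append(iid)
            populations[iid] = fam
            allele_rows.append(parts[6:])

    n_samples = len(samples)
    dosage = np.full((n_samples, n_loci), MISSING, dtype=np.int8)
    loci: list[VariantLocus] = []
    for j, (chrom, locus_id, pos) in enumerate(map_rows):
        a1 = [row[2 * j] for row in allele_rows]
        a2 = [row[2 * j + 1] for row in allele_rows]
        counts: dict[str, int] = {}
        for a, b in zip(a1, a2):
            if a == "0" or b == "0":
                continue
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise GenotypeParseError(
                f"locus {locus_id} ({chrom}:{pos}) has >2 alleles: {alleles}"
            )
        if allele_ref is not None and locus_id in allele_ref:
            ref, alt = allele_ref[locus_id]
        elif len(alleles) == 2:
            # minor allele = alt; ties broken lexicographically for determinism
            alleles.sort(key=lambda a: (counts[a], a))
            alt, ref = alleles[0], alleles[1]
        elif len(alleles) == 1:
            ref, alt = alleles[0], "."
        else:  # all missing
            ref, alt = "A", "B"
        loci.append(VariantLocus(chrom, pos, locus_id, ref, alt))
        for i, (a, b) in enumerate(zip(a1, a2)):
            if a == "0" or b == "0":
                continue
            dosage[i, j] = (a == alt) + (b == alt)
    return GenotypeMatrix(loci, samples, dosage, populations)


def read_vcf(
    vcf_path: str | Path,
    pop_map_path: str | Path | Mapping[str, str],
    multiallelic: str = "reject",
) -> GenotypeMatrix:
    """Read a VCF (GT field only) plus a sample->population map.

    ``./.`` becomes MISSING; phased and unphased separators are treated
    identically.  Multi-allelic records raise under ``multiallelic='reject'``
    (default) or are split into one pseudo-biallelic locus per alt allele
    under ``'split'``.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("reject", "split"):
        raise ValueError("multiallelic must be 'reject' or 'split'")
    if isinstance(pop_map_path, Mapping):
        pop_map = dict(pop_map_path)
    else:
        pop_map = read_population_map(pop_map_path)

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pop_map]
    if absent:
        raise GenotypeParseError(f"samples absent from population map: {absent[:5]}")

    loci: list[VariantLocus] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        alts = var.ALT
        if len(alts) > 1 and multiallelic == "reject":
            raise GenotypeParseError(
                f"multi-allelic record at {var.CHROM}:{var.POS} rejected"
            )
        gts = var.genotypes  # [[a0, a1, phased], ...]
        for k, alt in enumerate(alts, start=1):
            dos = np.full(len(samples), MISSING, dtype=np.int8)
            for i, gt in enumerate(gts):
                a0, a1 = gt[0], gt[1]
                if a0 < 0 or a1 < 0:
                    continue
                dos[i] = (a0 == k) + (a1 == k)
            locus_id = var.ID or f"{var.CHROM}:{var.POS}"
            if len(alts) > 1:
                locus_id = f"{locus_id}__alt{k}"
            loci.append(VariantLocus(str(var.CHROM), var.POS, locus_id, var.REF, alt))
            cols.append(dos)
    vcf.close()
    dosage = np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(loci, samples, dosage, pop_map)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeMatrix, populations: Iterable[str]):
    """Per-locus non-missing diploid count and alt-allele frequency.

    Returns a pandas DataFrame indexed like ``g.loci`` with columns
    ``n_i`` (diploid samples with a call), ``p_ai`` (alt frequency, NaN
    where undefined) and ``defined`` (bool).
    """
    import pandas as pd

    idx = g.sample_indices(populations)
    sub = g.dosage[idx, :]
    called = sub != MISSING
    n_i = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_i > 0, alt / (2.0 * np.maximum(n_i, 1)), np.nan)
    return pd.DataFrame(
        {
            "locus_id": [loc.locus_id for loc in g.loci],
            "chrom": g.chromosomes(),
            "pos_bp": g.positions(),
            "n_i": n_i.astype(np.int64),
            "p_ai": p,
            "defined": n_i > 0,
        }
    )


def subset_by_group(g: GenotypeMatrix, scheme: PopulationScheme, group: str) -> GenotypeMatrix:
    """Samples whose population belongs to ``scheme.groups[group]``; loci unchanged."""
    pops = scheme[group]
    present = pops & set(g.populations.values())
    if not present:
        raise ValueError(f"group {group!r} matches no samples")
    idx = g.sample_indices(present)
    return g.subset_samples(idx)


# ---------------------------------------------------------------------------
# Writers (fixture round-trip support)
# ---------------------------------------------------------------------------

def write_ped_map(g: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    with open(map_path, "w") as fh:
        for loc in g.loci:
            fh.write(f"{loc.chrom}\t{loc.locus_id}\t0\t{loc.pos_bp}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(g.samples):
            fields = [g.populations[s], s, "0", "0", "0", "-9"]
            row = g.dosage[i]
            for j, loc in enumerate(g.loci):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [loc.ref_allele, loc.ref_allele]
                elif d == 1:
                    fields += [loc.ref_allele, loc.alt_allele]
                else:
                    fields += [loc.alt_allele, loc.alt_allele]
            fh.write(" ".join(fields) + "\n")


def write_vcf(g: GenotypeMatrix, vcf_path: str | Path) -> None:
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chroms = []
    for loc in g.loci:
        if loc.chrom not in chroms:
            chroms.append(loc.chrom)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepkit\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, loc in enumerate(g.loci):
            ref = loc.ref_allele if loc.ref_allele not in (".", "") else "A"
            alt = loc.alt_allele if loc.alt_allele not in (".", "") else "T"
            gts = "\t".join(gt_code[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{loc.chrom}\t{loc.pos_bp}\t{loc.locus_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_population_map(g: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in g.samples:
            fh.write(f"{s}\t{g.populations[s]}\n")


def write_allele_ref(g: GenotypeMatrix, path: str | Path) -> None:
    """Record ref/alt orientation so PED round-trips reproduce dosages."""
    with open(path, "w") as fh:
        for loc in g.loci:
            fh.write(f"{loc.locus_id}\t{loc.ref_allele}\t{loc.alt_allele}\n")
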