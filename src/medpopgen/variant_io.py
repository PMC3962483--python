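"""Reading/writing standard formats and pedigree-aware genotype filters.

VCF parsing is delegated to cyvcf2; writing emits minimal VCF 4.2 text.
Internally all coordinates are 0-based half-open (see :mod:`containers`).

The post-phasing quality filter mirrors trio-aware phasing pipelines that
annotate each site with an empirical r^2 between inferred and expected
genotypes and an observed Mendelian error rate (ERATE); sites failing
either bound (r^2 >= 0.6, ERATE <= 0.1 by default, bounds inclusive) are
removed.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import MISSING, GenotypeTable, HaplotypeSet, Pedigree, VariantSite

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "filter_biallelic_maf_missing",
    "mendel_check",
    "MendelResult",
    "filter_phasing_quality",
    "polarize_by_outgroup",
]

_ANNOT_INFO_KEYS = {"r2": "R2", "erate": "ERATE"}


def read_vcf(path, phased: bool = False, region: str | None = None):
    """Read a VCF into a :class:`GenotypeTable` or, with ``phased=True``,
    a :class:`HaplotypeSet`.

    Phased extraction requires every genotype to use the ``|`` separator;
    an unphased record raises ``ValueError`` naming the offending site.
    Multiallelic sites are retained in genotype mode and rejected in
    haplotype mode.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path), gts012=False)
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    annots: dict[str, list[float]] = {"r2": [], "erate": []}
    phase_flags: list[bool] = []
    it = vcf(region) if region else vcf
    for rec_no, v in enumerate(it, start=1):
        if not v.ALT:
            continue
        aa = v.INFO.get("AA")
        try:
            site = VariantSite(
                v.CHROM, v.POS - 1, v.REF, tuple(v.ALT),
                aa if aa and aa in (v.REF, *v.ALT) else None,
            )
        except ValueError as exc:
            raise ValueError(f"malformed VCF record {rec_no} ({v.CHROM}:{v.POS}): {exc}")
        sites.append(site)
        gts = np.array([g[:3] for g in v.genotypes], dtype=np.int16)
        rows.append(gts[:, :2])
        phase_flags.append(bool(gts[:, 2].all()) if len(gts) else True)
        for key, info_key in _ANNOT_INFO_KEYS.items():
            val = v.INFO.get(info_key)
            annots[key].append(float(val) if val is not None else np.nan)
    geno = (
        np.stack(rows, axis=1)
        if rows
        else np.zeros((len(samples), 0, 2), dtype=np.int16)
    )
    site_annotations = {
        k: np.array(v) for k, v in annots.items() if not np.all(np.isnan(v))
    }
    table = GenotypeTable(sites, samples, geno, site_annotations)
    if not phased:
        return table
    for j, flag in enumerate(phase_flags):
        if not flag:
            s = sites[j]
            raise ValueError(
                f"unphased genotype at {s.chrom}:{s.pos + 1}; phased haplotypes "
                "require '|'-separated GT"
            )
    if (table.genotypes == MISSING).any():
        raise ValueError("missing genotypes cannot be lifted to haplotypes")
    for s in sites:
        if len(s.alts) != 1:
            raise ValueError(f"multiallelic site {s.chrom}:{s.pos + 1} in haplotype mode")
    haps = np.empty((2 * len(samples), len(sites)), dtype=np.uint8)
    haps[0::2] = table.genotypes[:, :, 0]
    haps[1::2] = table.genotypes[:, :, 1]
    return HaplotypeSet(sites, samples, haps)


def write_vcf(data: GenotypeTable | HaplotypeSet, path) -> None:
    """Write VCF 4.2. HaplotypeSet genotypes are phased ('|'), tables unphased."""
    if isinstance(data, HaplotypeSet):
        table = data.to_genotype_table()
        sep = "|"
    else:
        table = data
        sep = "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Empirical r2">\n')
        fh.write('##INFO=<ID=ERATE,Number=1,Type=Float,Description="Mendelian error rate">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in table.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples) + "\n"
        )
        ann = table.site_annotations
        for j, s in enumerate(table.sites):
            info = []
            if s.ancestral is not None:
                info.append(f"AA={s.ancestral}")
            for key, info_key in _ANNOT_INFO_KEYS.items():
                if key in ann and np.isfinite(ann[key][j]):
                    info.append(f"{info_key}={ann[key][j]:g}")
            gts = []
            for i in range(table.n_samples):
                a, b = table.genotypes[i, j]
                gts.append(
                    f".{sep}." if a == MISSING else f"{a}{sep}{b}"
                )
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{','.join(s.alts)}\t.\tPASS\t"
                f"{';'.join(info) or '.'}\tGT\t" + "\t".join(gts) + "\n"
            )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, os.fspath(path), "fasta")
    del width  # Biopython wraps at its default width


def read_bed(path) -> pd.DataFrame:
    """BED intervals as a DataFrame (chrom, start, end), 0-based half-open."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=[0, 1, 2],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return df


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def filter_biallelic_maf_missing(
    table: GenotypeTable,
    min_alleles: int = 2,
    max_alleles: int = 2,
    max_missing_fraction: float = 0.2,
    min_maf: float = 0.0,
) -> GenotypeTable:
    """Keep biallelic sites with call rate >= 1 - max_missing_fraction and
    minor allele frequency >= min_maf, preserving site order.

    Allele counts (and the allele number bounds) refer to alleles actually
    observed among called genotypes, so a nominally triallelic record where
    only two alleles segregate survives a biallelic filter.
    """
    for name, val in (("max_missing_fraction", max_missing_fraction), ("min_maf", min_maf)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    counts = table.allele_counts()
    n_observed = (counts > 0).sum(axis=1)
    called = counts.sum(axis=1)
    total = 2 * table.n_samples
    call_rate = called / total if total else np.zeros(table.n_sites)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / np.maximum(called, 1)[:, None]
    # minor allele frequency among observed alleles
    maf = np.where(
        n_observed >= 2,
        np.sort(freqs, axis=1)[:, -2],
        0.0,
    )
    keep = (
        (n_observed >= min_alleles)
        & (n_observed <= max_alleles)
        & (call_rate >= 1.0 - max_missing_fraction)
        & (maf >= min_maf)
    )
    return table.take_sites(np.nonzero(keep)[0])


@dataclass
class MendelResult:
    per_site: np.ndarray          # error count per site
    per_trio: dict[str, int]      # child label -> error count
    n_trios_checked: int

    @property
    def total(self) -> int:
        return int(self.per_site.sum())


def mendel_check(table: GenotypeTable, pedigree: Pedigree) -> MendelResult:
    """Count Mendelian-impossible child genotypes per site and per trio.

    An error is a child genotype that cannot be formed by drawing one allele
    from each parent. Missing genotypes in any trio member never count.
    """
    per_site = np.zeros(table.n_sites, dtype=np.int64)
    per_trio: dict[str, int] = {}
    n_checked = 0
    sample_set = set(table.samples)
    for child, father, mother in pedigree.trios():
        if not {child, father, mother} <= sample_set:
            continue
        n_checked += 1
        gc = table.genotypes[table.sample_index(child)]
        gf = table.genotypes[table.sample_index(father)]
        gm = table.genotypes[table.sample_index(mother)]
        called = (gc != MISSING).all(1) & (gf != MISSING).all(1) & (gm != MISSING).all(1)
        c1, c2 = gc[:, 0], gc[:, 1]

        def _from(parent, allele):
            return (parent[:, 0] == allele) | (parent[:, 1] == allele)

        ok = (_from(gf, c1) & _from(gm, c2)) | (_from(gf, c2) & _from(gm, c1))
        err = called & ~ok
        per_site += err
        per_trio[child] = int(err.sum())
    return MendelResult(per_site, per_trio, n_checked)


def filter_phasing_quality(
    table: GenotypeTable,
    min_empirical_r2: float = 0.6,
    max_erate: float = 0.1,
    missing_annotation: str = "pass",
) -> GenotypeTable:
    """Remove sites failing the post-phasing bounds r2 >= min_empirical_r2
    or ERATE <= max_erate (both inclusive).

    ``missing_annotation`` controls sites lacking an annotation: "pass"
    retains them, "fail" removes them.
    """
    if missing_annotation not in ("pass", "fail"):
        raise ValueError("missing_annotation must be 'pass' or 'fail'")
    nan_default = missing_annotation == "pass"
    n = table.n_sites
    r2 = table.site_annotations.get("r2", np.full(n, np.nan))
    erate = table.site_annotations.get("erate", np.full(n, np.nan))

    def _ok(values, predicate):
        out = np.full(n, nan_default, dtype=bool)
        finite = np.isfinite(values)
        out[finite] = predicate(values[finite])
        return out

    keep = _ok(np.asarray(r2, float), lambda v: v >= min_empirical_r2) & _ok(
        np.asarray(erate, float), lambda v: v <= max_erate
    )
    return table.take_sites(np.nonzero(keep)[0])


def polarize_by_outgroup(
    data: GenotypeTable | HaplotypeSet,
    outgroup_sequence: dict[str, str] | str,
):
    """Set per-site ancestral alleles from an outgroup sequence on reference
    coordinates.

    The ancestral allele is the outgroup base when it matches the ref or an
    alt; otherwise (mismatch, N, gap) the site's ancestral state is unknown.
    Raises if the outgroup sequence does not cover a site.
    """
    if isinstance(outgroup_sequence, str):
        chroms = {s.chrom for s in data.sites}
        if len(chroms) > 1:
            raise ValueError("single outgroup string but sites span multiple chromosomes")
        outgroup_sequence = {c: outgroup_sequence for c in chroms}
    new_sites = []
    for s in data.sites:
        seq = outgroup_sequence.get(s.chrom)
        if seq is None or s.pos >= len(seq):
            raise ValueError(f"outgroup sequence does not cover {s.chrom}:{s.pos + 1}")
        base = seq[s.pos].upper()
        new_sites.append(s.with_ancestral(base if base in s.alleles else None))
    if isinstance(data, HaplotypeSet):
        return HaplotypeSet(new_sites, list(data.samples), data.haplotypes.copy())
    return GenotypeTable(
        new_sites, list(data.samples), data.genotypes.copy(),
        {k: v.copy() for k, v in data.site_annotations.items()},
    )
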