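"""Windowed heterozygosity profiles, block classification and inbreeding F.

Heterozygosity is profiled per sample in fixed windows (default 50 kb,
non-overlapping) as heterozygous calls per bp; a genome-wide threshold
derived from a wild profile (the quantile leaving a stated fraction of
windows above it) classifies windows into wild-origin heterozygous blocks.
The inbreeding coefficient uses F = 1 - H_obs / H_exp with
H_exp = 1 - sum(p_i^2) from sample allele frequencies, uncorrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeTable

__all__ = [
    "HetProfile",
    "MicrosatTable",
    "window_heterozygosity",
    "derive_het_threshold",
    "classify_het_blocks",
    "inbreeding_coefficient",
    "FResult",
    "divergent_site_het_fraction",
    "monoallelic_fraction",
]


@dataclass
class HetProfile:
    """Per-window heterozygosity: DataFrame (chrom, start, end, het, is_gap)."""

    windows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "het"}
        if not required <= set(self.windows.columns):
            raise ValueError(f"profile needs columns {sorted(required)}")
        if "is_gap" not in self.windows.columns:
            self.windows = self.windows.assign(is_gap=False)
        if (self.windows["het"].dropna() < 0).any():
            raise ValueError("negative heterozygosity")

    @property
    def values(self) -> np.ndarray:
        return self.windows.loc[~self.windows["is_gap"], "het"].to_numpy()

    def to_bed(self, path) -> None:
        self.windows.to_csv(path, sep="\t", header=False, index=False,
                            columns=["chrom", "start", "end", "het"])


class MicrosatTable:
    """Microsatellite genotypes: allele lengths per individual per locus."""

    def __init__(self, loci: list[str], individuals: list[str], genotypes: np.ndarray):
        self.loci = list(loci)
        self.individuals = list(individuals)
        self.genotypes = np.asarray(genotypes, dtype=np.int64)
        if self.genotypes.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError("genotype array shape inconsistent with labels")
        valid = self.genotypes[self.genotypes != MISSING]
        if (valid <= 0).any():
            raise ValueError("allele lengths must be positive integers")

    def to_csv(self, path) -> None:
        rows = {}
        for j, locus in enumerate(self.loci):
            col = []
            for i in range(len(self.individuals)):
                a, b = self.genotypes[i, j]
                col.append("." if a == MISSING else f"{a}/{b}")
            rows[locus] = col
        pd.DataFrame(rows, index=self.individuals).to_csv(path, index_label="individual")

    @classmethod
    def from_csv(cls, path) -> "MicrosatTable":
        df = pd.read_csv(path, index_col=0)
        geno = np.full((len(df), len(df.columns), 2), MISSING, dtype=np.int64)
        for j, locus in enumerate(df.columns):
            for i, val in enumerate(df[locus]):
                if isinstance(val, str) and "/" in val:
                    a, b = val.split("/")
                    geno[i, j] = (int(a), int(b))
        return cls(list(df.columns), list(df.index), geno)


def window_heterozygosity(
    table: GenotypeTable,
    sample: str,
    window_size: int = 50_000,
    step: int | None = None,
    sequence_length: int | dict[str, int] | None = None,
    reference: dict[str, str] | None = None,
    gap_fraction: float = 0.5,
) -> HetProfile:
    """Heterozygous calls per bp in sliding windows for one sample.

    Windows tile each chromosome from 0 to its length (inferred from the
    last site if not given). When a reference is supplied, windows whose
    N-content exceeds ``gap_fraction`` are marked as assembly gaps and
    reported separately rather than as heterozygosity.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    step = step or window_size
    si = table.sample_index(sample)
    het = table.het_mask()[si]
    pos = table.positions
    chroms = np.array(table.chroms)
    rows = []
    for chrom in dict.fromkeys(table.chroms):
        on = chroms == chrom
        cpos, chet = pos[on], het[on]
        if isinstance(sequence_length, dict):
            L = sequence_length[chrom]
        elif sequence_length is not None:
            L = int(sequence_length)
        else:
            L = int(cpos.max()) + 1 if len(cpos) else window_size
        refseq = reference.get(chrom) if reference else None
        for start in range(0, L, step):
            end = min(start + window_size, L)
            in_win = (cpos >= start) & (cpos < end)
            h = chet[in_win].sum() / (end - start)
            is_gap = False
            if refseq is not None:
                frac_n = refseq[start:end].upper().count("N") / (end - start)
                is_gap = frac_n > gap_fraction
            rows.append((chrom, start, end, h, is_gap))
    return HetProfile(pd.DataFrame(rows, columns=["chrom", "start", "end", "het", "is_gap"]))


def derive_het_threshold(
    wild_profile: HetProfile, classified_fraction: float = 0.9
) -> float:
    """Heterozygosity threshold above which ``classified_fraction`` of the
    wild windows fall: the (1 - fraction) quantile of window values."""
    values = wild_profile.values
    if len(values) == 0:
        raise ValueError("empty profile")
    if np.ptp(values) == 0:
        warnings.warn("degenerate profile: all windows equal; threshold is that value")
        return float(values[0])
    return float(np.quantile(values, 1.0 - classified_fraction))


def classify_het_blocks(profile: HetProfile, threshold: float) -> pd.DataFrame:
    """Maximal runs of consecutive non-gap windows strictly above threshold,
    merged across adjacent windows; DataFrame (chrom, start, end, n_windows)."""
    blocks = []
    df = profile.windows
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        above = (sub["het"] > threshold) & ~sub["is_gap"]
        run_start = None
        prev_end = None
        n_run = 0
        for _, row in sub.iterrows():
            contiguous = prev_end is not None and row["start"] <= prev_end
            if above.loc[row.name] and (run_start is not None and contiguous):
                prev_end, n_run = row["end"], n_run + 1
            elif above.loc[row.name]:
                if run_start is not None:
                    blocks.append((chrom, run_start, prev_end, n_run))
                run_start, prev_end, n_run = row["start"], row["end"], 1
            else:
                if run_start is not None:
                    blocks.append((chrom, run_start, prev_end, n_run))
                    run_start, n_run = None, 0
                prev_end = row["end"]
        if run_start is not None:
            blocks.append((chrom, run_start, prev_end, n_run))
    return pd.DataFrame(blocks, columns=["chrom", "start", "end", "n_windows"])


@dataclass
class FResult:
    per_locus: pd.Series       # F per locus; NaN where undefined (monomorphic)
    mean: float
    h_obs: pd.Series = field(repr=False, default=None)
    h_exp: pd.Series = field(repr=False, default=None)


def _f_from_genotype_pairs(geno: np.ndarray) -> tuple[float, float, float]:
    """(F, H_obs, H_exp) from an (n, 2) array of allele codes, MISSING-aware."""
    called = (geno != MISSING).all(axis=1)
    g = geno[called]
    if len(g) < 2:
        return np.nan, np.nan, np.nan
    h_obs = float((g[:, 0] != g[:, 1]).mean())
    alleles, counts = np.unique(g.ravel(), return_counts=True)
    p = counts / counts.sum()
    h_exp = float(1.0 - (p**2).sum())
    if h_exp == 0.0:
        return np.nan, h_obs, 0.0
    return 1.0 - h_obs / h_exp, h_obs, h_exp


def inbreeding_coefficient(
    table: "MicrosatTable | GenotypeTable", locus: str | int | None = None
) -> FResult:
    """Inbreeding coefficient F = 1 - H_obs / H_exp per locus and its mean.

    H_obs is the observed heterozygote fraction; H_exp = 1 - sum(p_i^2) from
    sample allele frequencies (no small-sample correction). Monomorphic loci
    (H_exp = 0) are undefined and reported as NaN; negative F (heterozygote
    excess) is allowed.
    """
    if isinstance(table, GenotypeTable):
        labels = [f"{s.chrom}:{s.pos + 1}" for s in table.sites]
        geno_by_locus = [table.genotypes[:, j, :] for j in range(table.n_sites)]
    else:
        labels = table.loci
        geno_by_locus = [table.genotypes[:, j, :] for j in range(len(table.loci))]
    if locus is not None:
        idx = labels.index(locus) if isinstance(locus, str) else int(locus)
        labels, geno_by_locus = [labels[idx]], [geno_by_locus[idx]]
    f_vals, ho_vals, he_vals = [], [], []
    for g in geno_by_locus:
        f, ho, he = _f_from_genotype_pairs(np.asarray(g))
        f_vals.append(f)
        ho_vals.append(ho)
        he_vals.append(he)
    per_locus = pd.Series(f_vals, index=labels, name="F")
    return FResult(
        per_locus,
        float(per_locus.mean()),
        pd.Series(ho_vals, index=labels, name="H_obs"),
        pd.Series(he_vals, index=labels, name="H_exp"),
    )


def divergent_site_het_fraction(
    table: GenotypeTable, sample: str, reference_allele: int = 0
) -> float:
    """Among sites where the sample carries a non-reference allele, the
    fraction called heterozygous."""
    si = table.sample_index(sample)
    g = table.genotypes[si]
    called = (g != MISSING).all(axis=1)
    divergent = called & (g != reference_allele).any(axis=1)
    if not divergent.any():
        return 0.0
    het = g[:, 0] != g[:, 1]
    return float(het[divergent].mean())


def monoallelic_fraction(table: GenotypeTable) -> float:
    """Fraction of variant sites fixed homozygous non-reference across all
    called genotypes (sites with no calls are excluded)."""
    g = table.genotypes
    called = (g != MISSING).all(axis=2)
    any_called = called.any(axis=0)
    nonref = (g > 0) & called[:, :, None]
    is_variant = nonref.any(axis=(0, 2)) & any_called
    if not is_variant.any():
        return float("nan")
    hom_nonref = (g[:, :, 0] == g[:, :, 1]) & (g[:, :, 0] > 0)
    fixed = np.where(called, hom_nonref, True).all(axis=0) & any_called
    return float((fixed & is_variant).sum() / is_variant.sum())
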