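"""Extended haplotype homozygosity, iHS and the composite sweep filter.

EHH at a flanking site is the probability that two random carriers of the
core allele are identical over the whole interval from the core:
EHH = sum_h C(n_h, 2) / C(n_c, 2) over distinct extended haplotypes h.
iHH integrates each allele's EHH curve (trapezoid, physical bp) out to an
EHH cutoff in both directions; the unstandardized iHS is
ln(iHH_ancestral / iHH_derived), standardized within derived-allele
frequency bins. Strongly negative standardized iHS marks derived alleles
on unusually long haplotypes — the footprint of recent positive selection.

The composite window filter retains clusters of extreme negative iHS:
a SNP passes when (1) |iHS| is in the top quantile, and within a window
around it (2a) the iHS standard deviation is in the lower half of window
SDs, (2b) at least ``min_peak_snps`` SNPs reach ``peak_ratio`` of the
window's max |iHS| and (2c) those SNPs are at least ``min_peak_fraction``
of the window. Passing SNPs merge into regions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .containers import HaplotypeSet

__all__ = [
    "EhhCurve",
    "IhsRecord",
    "SelectedRegion",
    "ehh",
    "ihs_unstandardized",
    "ihs_scan",
    "standardize_ihs",
    "composite_filter",
    "conserved_enrichment",
]


@njit(cache=True)
def _ehh_one_side(mat, rows, core, step, cutoff, out):  # pragma: no cover - jit
    """EHH values among the haplotypes in ``rows`` walking from the core in
    one direction; stops after the first value below cutoff (that value is
    still emitted). Returns the number of values written."""
    m = rows.shape[0]
    S = mat.shape[1]
    npairs = m * (m - 1) // 2
    labels = np.zeros(m, dtype=np.int64)
    remap = np.empty(2 * m + 2, dtype=np.int64)
    counts = np.empty(m + 1, dtype=np.int64)
    j = core + step
    k = 0
    while 0 <= j < S and k < out.shape[0]:
        # refine the haplotype partition by the allele at column j
        for t in range(2 * m + 2):
            remap[t] = -1
        c = 0
        for t in range(m):
            key = labels[t] * 2 + mat[rows[t], j]
            if remap[key] < 0:
                remap[key] = c
                c += 1
            labels[t] = remap[key]
        for t in range(c):
            counts[t] = 0
        for t in range(m):
            counts[labels[t]] += 1
        s = 0
        for t in range(c):
            s += counts[t] * (counts[t] - 1) // 2
        e = s / npairs
        out[k] = e
        k += 1
        if e < cutoff or s == 0:
            break
        j += step
    return k


@dataclass
class EhhCurve:
    """EHH decay around a core site for one core allele.

    ``left``/``right`` are (distance_bp, ehh) arrays ordered by increasing
    distance from the core; both start at (0, 1).
    """

    core_index: int
    core_pos: int
    core_allele: str  # "ancestral" | "derived"
    n_carriers: int
    left: np.ndarray
    right: np.ndarray

    def at_distance(self, distance: float, side: str = "right") -> float:
        """EHH at a physical distance (step function between curve points)."""
        arr = self.right if side == "right" else self.left
        k = np.searchsorted(arr[:, 0], distance, side="right") - 1
        return float(arr[min(k, len(arr) - 1), 1]) if len(arr) else 1.0


def _one_curve(mat: np.ndarray, rows: np.ndarray, positions: np.ndarray, core: int,
               cutoff: float) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """Both sides of an EHH curve plus per-side edge-truncation flags.

    A side is edge-truncated when the walk ran out of sites while EHH was
    still at or above the cutoff (only meaningful for cutoff > 0).
    """
    S = mat.shape[1]
    buf = np.empty(S, dtype=np.float64)
    sides: list[np.ndarray] = []
    truncated: list[bool] = []
    for step in (-1, 1):
        k = _ehh_one_side(mat, rows, core, step, cutoff, buf)
        if step == -1:
            cols = np.arange(core - 1, core - 1 - k, -1)
        else:
            cols = np.arange(core + 1, core + 1 + k)
        dist = np.abs(positions[cols] - positions[core]).astype(np.float64)
        vals = buf[:k].copy()
        sides.append(np.column_stack([np.concatenate([[0.0], dist]),
                                      np.concatenate([[1.0], vals])]))
        reached_cutoff = k > 0 and vals[-1] < cutoff
        truncated.append(cutoff > 0 and not reached_cutoff)
    left, right = sides
    return left, right, truncated[0], truncated[1]


def ehh(haps: HaplotypeSet, core_site: int, core_allele: str,
        cutoff: float = 0.0) -> EhhCurve:
    """EHH curve among carriers of the core allele, both directions.

    ``core_allele`` is "ancestral" or "derived" (requires a known ancestral
    state at the core site). At least two carriers are required. With the
    default cutoff 0 the curve extends to the chromosome ends.
    """
    if core_allele not in ("ancestral", "derived"):
        raise ValueError("core_allele must be 'ancestral' or 'derived'")
    mat = haps.derived_matrix()
    if haps.sites[core_site].ancestral is None:
        raise ValueError(f"core site {core_site} has unknown ancestral allele")
    want = 1 if core_allele == "derived" else 0
    carriers = np.nonzero(mat[:, core_site] == want)[0]
    if len(carriers) < 2:
        raise ValueError(
            f"need >= 2 carriers of the {core_allele} allele, found {len(carriers)}"
        )
    left, right, _, _ = _one_curve(mat, carriers.astype(np.int64),
                                   haps.positions, core_site, cutoff)
    return EhhCurve(core_site, int(haps.positions[core_site]), core_allele,
                    len(carriers), left, right)


@dataclass
class IhsRecord:
    site: int
    pos: int
    daf: float                  # derived allele frequency
    ihh_ancestral: float
    ihh_derived: float
    ihs: float                  # unstandardized ln(iHH_A / iHH_D)
    ihs_std: float | None = None
    freq_bin: int | None = None
    edge_truncated: bool = False


def _trapezoid_ihh(curve: np.ndarray, cutoff: float) -> float:
    """Area under one side of an EHH curve down to the cutoff crossing
    (linear interpolation at the crossing point)."""
    d, e = curve[:, 0], curve[:, 1]
    below = np.nonzero(e < cutoff)[0]
    if not len(below):
        return float(np.trapezoid(e, d))
    k = int(below[0])
    area = float(np.trapezoid(e[:k], d[:k]))
    if k > 0:
        e0, e1 = e[k - 1], e[k]
        frac = (e0 - cutoff) / (e0 - e1) if e0 > e1 else 1.0
        area += 0.5 * (e0 + cutoff) * (d[k] - d[k - 1]) * frac
    return area


def ihs_unstandardized(
    haps: HaplotypeSet,
    site: int,
    ehh_cutoff: float = 0.05,
    min_carriers: int = 2,
) -> IhsRecord:
    """Unstandardized iHS at one site: ln(iHH_ancestral / iHH_derived).

    iHH is the trapezoidal area under the allele's EHH curve out to the
    cutoff in both directions (summed). Records whose curve runs off the
    chromosome edge before reaching the cutoff are flagged
    ``edge_truncated`` (and excluded from scans by default).
    """
    if haps.sites[site].ancestral is None:
        raise ValueError(f"site {site} has unknown ancestral allele")
    return _ihs_from_matrix(haps.derived_matrix(), haps.positions, site,
                            ehh_cutoff, min_carriers)


def _ihs_from_matrix(
    mat: np.ndarray,
    positions: np.ndarray,
    site: int,
    ehh_cutoff: float,
    min_carriers: int,
) -> IhsRecord:
    ihh = {}
    truncated = False
    for allele, want in (("ancestral", 0), ("derived", 1)):
        carriers = np.nonzero(mat[:, site] == want)[0]
        if len(carriers) < min_carriers:
            raise ValueError(
                f"{allele} allele has {len(carriers)} carriers (< {min_carriers})"
            )
        left, right, lt, rt = _one_curve(mat, carriers.astype(np.int64),
                                         positions, site, ehh_cutoff)
        truncated = truncated or lt or rt
        ihh[allele] = _trapezoid_ihh(left, ehh_cutoff) + _trapezoid_ihh(right, ehh_cutoff)
    daf = float(mat[:, site].mean())
    if ihh["ancestral"] <= 0 or ihh["derived"] <= 0:
        raise ValueError("degenerate EHH curve: zero integrated area")
    return IhsRecord(
        site, int(positions[site]), daf, ihh["ancestral"], ihh["derived"],
        float(np.log(ihh["ancestral"] / ihh["derived"])), edge_truncated=truncated,
    )


def ihs_scan(
    haps: HaplotypeSet,
    min_maf: float = 0.05,
    ehh_cutoff: float = 0.05,
    include_edge_truncated: bool = False,
) -> list[IhsRecord]:
    """Unstandardized iHS for every polarizable site with derived frequency
    in [min_maf, 1 - min_maf]; edge-truncated records are dropped unless
    requested."""
    mat = haps.derived_matrix()
    known = haps.known_ancestral()
    freq = mat.mean(axis=0)
    counts = mat.sum(axis=0)
    n = mat.shape[0]
    eligible = (
        known
        & (freq >= min_maf) & (freq <= 1 - min_maf)
        & (counts >= 2) & (n - counts >= 2)
    )
    positions = haps.positions
    records = []
    for site in np.nonzero(eligible)[0]:
        rec = _ihs_from_matrix(mat, positions, int(site), ehh_cutoff, 2)
        if rec.edge_truncated and not include_edge_truncated:
            continue
        records.append(rec)
    return records


def standardize_ihs(
    records: list[IhsRecord],
    n_bins: int = 20,
    reference: list[IhsRecord] | None = None,
) -> list[IhsRecord]:
    """Standardize iHS within derived-allele-frequency bins.

    Within each bin the unstandardized values get the bin mean subtracted
    and are divided by the bin standard deviation. By default the bin
    statistics come from ``records`` themselves (so each bin has mean 0 and
    SD 1 by construction); a ``reference`` record set — e.g. a genome-wide
    scan when ``records`` cover only a candidate region — supplies the bin
    statistics instead when given. Bins with fewer than two (reference)
    records, where the SD is undefined, are excluded from the output.
    """
    if not records:
        return []
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    def _binned(recs):
        daf = np.array([r.daf for r in recs])
        vals = np.array([r.ihs for r in recs])
        return np.clip(np.searchsorted(edges, daf, side="right") - 1, 0, n_bins - 1), vals

    bins, vals = _binned(records)
    ref_bins, ref_vals = _binned(reference) if reference is not None else (bins, vals)
    out: list[IhsRecord] = []
    for b in range(n_bins):
        ref_mask = ref_bins == b
        if ref_mask.sum() < 2:
            continue
        mu = ref_vals[ref_mask].mean()
        sd = ref_vals[ref_mask].std(ddof=0)
        if sd == 0:
            continue
        for k in np.nonzero(bins == b)[0]:
            out.append(replace(records[k], ihs_std=float((vals[k] - mu) / sd),
                               freq_bin=b))
    out.sort(key=lambda r: r.pos)
    return out


@dataclass(frozen=True)
class SelectedRegion:
    chrom: str
    start: int
    end: int
    snp_positions: tuple[int, ...]

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)


def composite_filter(
    records: list[IhsRecord],
    chrom: str = "chr1",
    window_bp: int = 20_000,
    top_fraction: float = 0.0005,
    sd_quantile: float = 0.5,
    peak_ratio: float = 0.8,
    min_peak_snps: int = 4,
    min_peak_fraction: float = 0.1,
    abs_ihs_threshold: float | None = None,
) -> list[SelectedRegion]:
    """Composite windowed filter for sweep regions on standardized iHS.

    By default the extreme-value criterion is the top ``top_fraction``
    quantile of |iHS|; a literal threshold can be supplied instead via
    ``abs_ihs_threshold``. Only negative-iHS (derived-allele) clusters are
    retained; passing SNPs within one window width merge into regions.
    """
    if not records:
        raise ValueError("empty record set")
    recs = [r for r in records if r.ihs_std is not None]
    pos = np.array([r.pos for r in recs])
    ihs = np.array([r.ihs_std for r in recs])
    order = np.argsort(pos)
    pos, ihs = pos[order], ihs[order]
    a = np.abs(ihs)
    thr = (
        abs_ihs_threshold
        if abs_ihs_threshold is not None
        else float(np.quantile(a, 1.0 - top_fraction))
    )
    half = window_bp // 2
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    n = len(pos)
    win_sd = np.empty(n)
    peak_count = np.empty(n, dtype=np.int64)
    win_n = hi - lo
    for k in range(n):
        w = ihs[lo[k]:hi[k]]
        win_sd[k] = w.std(ddof=1) if len(w) > 1 else 0.0
        wmax = np.abs(w).max()
        peak_count[k] = int((np.abs(w) >= peak_ratio * wmax).sum())
    sd_thr = float(np.quantile(win_sd, sd_quantile))
    passing = (
        (a >= thr)
        & (ihs < 0)
        & (win_sd <= sd_thr)
        & (peak_count >= min_peak_snps)
        & (peak_count >= min_peak_fraction * win_n)
    )
    hits = pos[passing]
    regions: list[SelectedRegion] = []
    if len(hits):
        start = prev = hits[0]
        members = [int(hits[0])]
        for p in hits[1:]:
            if p - prev <= window_bp:
                members.append(int(p))
            else:
                regions.append(SelectedRegion(chrom, int(start), int(prev), tuple(members)))
                start, members = p, [int(p)]
            prev = p
        regions.append(SelectedRegion(chrom, int(start), int(prev), tuple(members)))
    return regions


@dataclass
class EnrichmentResult:
    observed_fraction: float
    null_mean: float
    fold: float
    p_value: float
    n_selected: int
    n_permutations: int


def conserved_enrichment(
    selected_positions: np.ndarray,
    conserved_intervals: pd.DataFrame,
    all_positions: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation enrichment of selected SNPs in conserved intervals.

    The null draws equally sized SNP subsets from all tested SNPs; fold is
    observed / mean(null) and the p-value uses the add-one estimator
    (1 + #null >= observed) / (1 + n_permutations).
    """
    selected_positions = np.asarray(selected_positions)
    all_positions = np.asarray(all_positions)
    starts = np.sort(conserved_intervals["start"].to_numpy())
    ends = conserved_intervals.sort_values("start")["end"].to_numpy()

    def _in_intervals(p: np.ndarray) -> np.ndarray:
        k = np.searchsorted(starts, p, side="right") - 1
        ok = k >= 0
        ok[ok] &= p[ok] < ends[k[ok]]
        return ok

    observed = float(_in_intervals(selected_positions).mean())
    rng = np.random.default_rng(seed)
    all_in = _in_intervals(all_positions)
    m = len(selected_positions)
    null = np.empty(n_permutations)
    for t in range(n_permutations):
        pick = rng.choice(len(all_positions), size=m, replace=False)
        null[t] = all_in[pick].mean()
    null_mean = float(null.mean())
    fold = observed / null_mean if null_mean > 0 else float("nan")
    p = float((1 + (null >= observed).sum()) / (1 + n_permutations))
    return EnrichmentResult(observed, null_mean, fold, p, m, n_permutations)
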