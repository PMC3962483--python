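"""Pairwise linkage disequilibrium, decay summaries and haplotype blocks.

All statistics are computed from directly counted phased haplotype
frequencies: D = p_AB - p_A p_B, r^2 = D^2 / (p_A q_A p_B q_B), D' = D /
D_max, and a LOD score from the likelihood ratio of linkage vs
independence. Haplotype blocks follow the confidence-interval method of
Gabriel et al.: per-pair likelihood-profiled bounds on |D'| classify pairs
as strong LD or strong recombination, and a block is a maximal span whose
outermost pair is in strong LD and whose informative pairs are
overwhelmingly in strong LD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import HaplotypeSet
from .coding import ExonModel

__all__ = [
    "LDPair",
    "HaploBlock",
    "pair_ld",
    "ld_scan",
    "dprime_confidence_interval",
    "gabriel_blocks",
    "block_size_summary",
    "high_ld_colocalization",
]


@dataclass(frozen=True)
class LDPair:
    i: int
    j: int
    pos_i: int
    pos_j: int
    r2: float
    dprime: float
    lod: float

    @property
    def distance(self) -> int:
        return abs(self.pos_j - self.pos_i)


@dataclass(frozen=True)
class HaploBlock:
    chrom: str
    start_pos: int
    end_pos: int
    marker_indices: tuple[int, ...]

    @property
    def n_markers(self) -> int:
        return len(self.marker_indices)

    @property
    def span(self) -> int:
        """First-to-last marker, counting 1 bp at each marker."""
        return self.end_pos - self.start_pos + 1


def _gamete_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """2x2 gamete counts [[n00, n01], [n10, n11]] from two 0/1 columns."""
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    return np.array([[n00, n01], [n10, n11]], dtype=np.int64)


def _ld_from_counts(counts: np.ndarray) -> tuple[float, float, float]:
    """(D, r2, D') from a 2x2 gamete count table."""
    n = counts.sum()
    pA = (counts[1, 0] + counts[1, 1]) / n
    pB = (counts[0, 1] + counts[1, 1]) / n
    D = counts[1, 1] / n - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D * D / denom
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = D / dmax if dmax > 0 else 0.0
    return D, r2, dprime


def _lod(counts: np.ndarray) -> float:
    n = counts.sum()
    pA = (counts[1, 0] + counts[1, 1]) / n
    pB = (counts[0, 1] + counts[1, 1]) / n
    marg = np.array([[(1 - pA) * (1 - pB), (1 - pA) * pB],
                     [pA * (1 - pB), pA * pB]])
    obs = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        ll1 = np.where(counts > 0, counts * np.log10(obs), 0.0).sum()
        ll0 = np.where(counts > 0, counts * np.log10(marg), 0.0).sum()
    return float(ll1 - ll0)


def pair_ld(haps: HaplotypeSet, i: int, j: int) -> LDPair:
    """LD between two sites from directly counted phased haplotypes."""
    a = haps.haplotypes[:, i]
    b = haps.haplotypes[:, j]
    for name, col in (("i", a), ("j", b)):
        if col.min() == col.max():
            raise ValueError(f"site {name} is monomorphic; LD undefined")
    counts = _gamete_counts(a, b)
    _, r2, dprime = _ld_from_counts(counts)
    pos = haps.positions
    return LDPair(i, j, int(pos[i]), int(pos[j]), float(r2), float(dprime),
                  _lod(counts))


def ld_scan(
    haps: HaplotypeSet,
    pair_window_bp: int = 50_000,
    window_bp: int = 1_000_000,
    step_bp: int = 500_000,
    min_r2: float = 0.001,
    bin_width_bp: int = 500,
    plateau_tolerance: float = 0.05,
    plateau_tail_bins: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, float | None]:
    """All-pairs LD within ``pair_window_bp`` plus a per-distance-bin decay
    summary.

    Pairs with r^2 below ``min_r2`` are dropped. The summary reports the
    median r^2 per distance bin and the distance at which the median first
    comes within ``plateau_tolerance`` of the plateau level (the median over
    the final ``plateau_tail_bins`` bins). Monomorphic sites are skipped.
    The window/step parameters chunk the computation; with step <= window
    every qualifying pair is emitted exactly once.
    """
    if step_bp > window_bp:
        raise ValueError("step_bp must not exceed window_bp")
    mat = haps.haplotypes
    pos = haps.positions
    poly = (mat.min(axis=0) != mat.max(axis=0))
    idx = np.nonzero(poly)[0]
    pos_p = pos[idx]
    m = mat[:, idx].astype(np.float64)
    n = mat.shape[0]
    p = m.mean(axis=0)
    var = p * (1 - p)
    rows = []
    for a in range(len(idx)):
        hi = np.searchsorted(pos_p, pos_p[a] + pair_window_bp, side="right")
        if hi <= a + 1:
            continue
        js = np.arange(a + 1, hi)
        p11 = (m[:, a:a + 1] * m[:, js]).mean(axis=0)
        D = p11 - p[a] * p[js]
        r2 = D**2 / (var[a] * var[js])
        dmax = np.where(
            D >= 0,
            np.minimum(p[a] * (1 - p[js]), (1 - p[a]) * p[js]),
            np.minimum(p[a] * p[js], (1 - p[a]) * (1 - p[js])),
        )
        dprime = np.where(dmax > 0, D / dmax, 0.0)
        keep = r2 >= min_r2
        for jj, r2v, dpv in zip(js[keep], r2[keep], dprime[keep]):
            rows.append((int(idx[a]), int(idx[jj]), int(pos_p[a]), int(pos_p[jj]),
                         int(pos_p[jj] - pos_p[a]), float(r2v), float(dpv)))
    pairs = pd.DataFrame(
        rows, columns=["i", "j", "pos_i", "pos_j", "distance", "r2", "dprime"]
    )
    del n, window_bp, step_bp
    if pairs.empty:
        return pairs, pd.DataFrame(columns=["bin_start", "bin_end", "n", "median_r2"]), None
    bins = (pairs["distance"] // bin_width_bp).astype(int)
    summary = (
        pairs.assign(bin=bins)
        .groupby("bin")["r2"]
        .agg(n="size", median_r2="median")
        .reset_index()
    )
    summary["bin_start"] = summary["bin"] * bin_width_bp
    summary["bin_end"] = summary["bin_start"] + bin_width_bp
    summary = summary[["bin_start", "bin_end", "n", "median_r2"]]
    med = summary["median_r2"].to_numpy()
    plateau = float(np.median(med[-plateau_tail_bins:]))
    plateau_distance = None
    for k in range(len(med)):
        if abs(med[k] - plateau) <= plateau_tolerance * max(plateau, 1e-12):
            plateau_distance = float(summary["bin_start"].iloc[k])
            break
    return pairs, summary, plateau_distance


def dprime_confidence_interval(
    counts: np.ndarray, grid: float = 0.001, alpha: float = 0.05
) -> tuple[float, float]:
    """(lower, upper) bounds on |D'| by profiling the multinomial likelihood
    over a |D'| grid with allele frequencies fixed at their MLEs, in the
    spirit of the Gabriel/Haploview confidence-bound computation."""
    n = counts.sum()
    pA = (counts[1, 0] + counts[1, 1]) / n
    pB = (counts[0, 1] + counts[1, 1]) / n
    D = counts[1, 1] / n - pA * pB
    sign = 1.0 if D >= 0 else -1.0
    if sign >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax <= 0:
        return 0.0, 0.0
    dgrid = np.arange(0.0, 1.0 + grid / 2, grid)
    d = sign * dgrid * dmax
    p11 = pA * pB + d
    p10 = pA * (1 - pB) - d
    p01 = (1 - pA) * pB - d
    p00 = (1 - pA) * (1 - pB) + d
    probs = np.stack([p00, p01, p10, p11])
    probs = np.clip(probs, 0.0, 1.0)
    cvec = np.array([counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1]],
                    dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(cvec[:, None] > 0, cvec[:, None] * np.log(probs), 0.0).sum(axis=0)
    ll[np.any((probs <= 0) & (cvec[:, None] > 0), axis=0)] = -np.inf
    w = np.exp(ll - ll.max())
    cdf = np.cumsum(w) / w.sum()
    lower = float(dgrid[int(np.searchsorted(cdf, alpha))])
    upper = float(dgrid[min(int(np.searchsorted(cdf, 1 - alpha)), len(dgrid) - 1)])
    return lower, upper


def gabriel_blocks(
    haps: HaplotypeSet,
    maf_min: float = 0.05,
    ci_lower_strong: float = 0.70,
    ci_upper_strong: float = 0.98,
    ci_upper_recomb: float = 0.90,
    informative_fraction: float = 0.95,
    max_pair_bp: int = 500_000,
    grid: float = 0.001,
) -> list[HaploBlock]:
    """Haplotype blocks by the Gabriel confidence-interval rules.

    A pair is in strong LD when its |D'| CI bounds reach
    (ci_lower_strong, ci_upper_strong) and shows strong recombination when
    the upper bound falls below ci_upper_recomb; other pairs are
    uninformative. A candidate block spans markers i..j when pair (i, j) is
    in strong LD and at least ``informative_fraction`` of the informative
    pairs inside are in strong LD; maximal candidates are kept greedily by
    span without overlap. Sub-MAF markers never enter blocks.
    """
    mat = haps.haplotypes
    pos = haps.positions
    freq = mat.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    idx = np.nonzero(maf >= maf_min)[0]
    if len(idx) < 2:
        return []
    S = len(idx)
    strong = np.zeros((S, S), dtype=bool)
    informative = np.zeros((S, S), dtype=bool)
    for a in range(S):
        for b in range(a + 1, S):
            if pos[idx[b]] - pos[idx[a]] > max_pair_bp:
                break
            counts = _gamete_counts(mat[:, idx[a]], mat[:, idx[b]])
            lo, hi = dprime_confidence_interval(counts, grid=grid)
            if lo >= ci_lower_strong and hi >= ci_upper_strong:
                strong[a, b] = informative[a, b] = True
            elif hi < ci_upper_recomb:
                informative[a, b] = True
    candidates = []
    for a in range(S):
        for b in range(a + 1, S):
            if not strong[a, b]:
                continue
            sub_inf = informative[a:b + 1, a:b + 1]
            sub_str = strong[a:b + 1, a:b + 1]
            n_inf = int(sub_inf.sum())
            if n_inf == 0:
                continue
            if sub_str.sum() / n_inf >= informative_fraction:
                candidates.append((a, b))
    candidates.sort(key=lambda ab: (pos[idx[ab[1]]] - pos[idx[ab[0]]], ab[1] - ab[0]),
                    reverse=True)
    taken = np.zeros(S, dtype=bool)
    blocks: list[HaploBlock] = []
    for a, b in candidates:
        if taken[a:b + 1].any():
            continue
        taken[a:b + 1] = True
        members = tuple(int(k) for k in idx[a:b + 1])
        blocks.append(
            HaploBlock(haps.chrom, int(pos[idx[a]]), int(pos[idx[b]]), members)
        )
    blocks.sort(key=lambda blk: blk.start_pos)
    return blocks


def block_size_summary(blocks: list[HaploBlock]) -> dict[str, float] | None:
    """Mean, median and max block span in bp; None for an empty block list."""
    if not blocks:
        return None
    spans = np.array([b.span for b in blocks], dtype=float)
    return {
        "n_blocks": int(len(spans)),
        "mean": float(spans.mean()),
        "median": float(np.median(spans)),
        "max": float(spans.max()),
    }


def high_ld_colocalization(
    pairs: pd.DataFrame, model: ExonModel, r2_min: float = 0.8, chrom: str | None = None
) -> dict[str, float]:
    """Fractions of high-LD SNP pairs falling in the same gene / same exon.

    A pair co-localizes to a gene (exon) when both positions lie within the
    same gene's (same exon's) span. Fractions are over pairs with
    r^2 > r2_min.
    """
    high = pairs[pairs["r2"] > r2_min]
    if high.empty:
        return {"same_gene": float("nan"), "same_exon": float("nan"), "n_pairs": 0}
    genes = model.gene_spans()
    exons = model.exon_intervals()
    if chrom is not None:
        genes = genes[genes["chrom"] == chrom]
        exons = exons[exons["chrom"] == chrom]

    def _shared(df: pd.DataFrame, key: str, p1: int, p2: int) -> bool:
        inside1 = (df["start"] <= p1) & (p1 < df["end"])
        inside2 = (df["start"] <= p2) & (p2 < df["end"])
        return bool(set(df.loc[inside1, key]) & set(df.loc[inside2, key]))

    exons_keyed = exons.assign(
        exon_key=exons["gene_id"] + ":" + exons["start"].astype(str)
    )
    same_gene = same_exon = 0
    for row in high.itertuples():
        if _shared(genes, "gene_id", row.pos_i, row.pos_j):
            same_gene += 1
        if _shared(exons_keyed, "exon_key", row.pos_i, row.pos_j):
            same_exon += 1
    n = len(high)
    return {"same_gene": same_gene / n, "same_exon": same_exon / n, "n_pairs": n}
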