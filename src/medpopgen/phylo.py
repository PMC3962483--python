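"""Distance-based phylogenetics, clustering, and in-silico mitotyping.

Sequence distances use the Kimura two-parameter model,
d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P/Q the transition and
transversion fractions; saturated pairs (log arguments <= 0) are flagged.
Trees come from neighbor joining (scikit-bio) with midpoint rooting.
Mitotyping amplifies a mitochondrial segment in silico, digests it with a
standard five-enzyme panel and groups samples by gel-resolution-binned
fragment-length patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .containers import HaplotypeSet, GenotypeTable, MISSING

__all__ = [
    "k2p_distance",
    "k2p_matrix",
    "majority_vote_consensus",
    "neighbor_joining",
    "midpoint_root",
    "gower_distances",
    "gower_cluster",
    "insilico_pcr",
    "restriction_digest",
    "assign_mitotype",
    "dloop_typing",
    "DEFAULT_ENZYMES",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class K2PResult:
    distance: float      # nan when saturated
    P: float             # transition fraction
    Q: float             # transversion fraction
    n_sites: int
    saturated: bool


def k2p_distance(seq_a: str, seq_b: str, full: bool = False):
    """Kimura two-parameter distance between two aligned sequences.

    Columns where either base is not an unambiguous nucleotide are dropped
    pairwise. Saturated pairs (1 - 2P - Q <= 0 or 1 - 2Q <= 0, where the
    distance is inestimable) return NaN with the ``saturated`` flag set when
    ``full=True``.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    P = Q = n = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in _TRANSITIONS:
            P += 1
        else:
            Q += 1
    if n == 0:
        raise ValueError("no comparable sites")
    p, q = P / n, Q / n
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        result = K2PResult(float("nan"), p, q, n, True)
    else:
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        result = K2PResult(float(d), p, q, n, False)
    return result if full else result.distance


def k2p_matrix(sequences: dict[str, str]) -> tuple[DistanceMatrix, list[tuple[str, str]]]:
    """Pairwise K2P distance matrix; saturated pairs are listed and their
    distances set to the largest finite estimate (branch underestimates)."""
    labels = list(sequences)
    n = len(labels)
    mat = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(sequences[labels[i]], sequences[labels[j]])
            if np.isnan(d):
                saturated.append((labels[i], labels[j]))
            mat[i, j] = mat[j, i] = d
    if saturated:
        finite_max = np.nanmax(mat) if np.isfinite(np.nanmax(mat)) else 1.0
        mat = np.where(np.isnan(mat), finite_max, mat)
        np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(mat, labels), saturated


def majority_vote_consensus(haps: HaplotypeSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-site strict-majority allele across haplotypes.

    Returns (consensus allele vector, tie mask); ties resolve to the
    reference allele (0) and are flagged.
    """
    counts_alt = haps.haplotypes.sum(axis=0)
    n = haps.n_haplotypes
    consensus = (counts_alt * 2 > n).astype(np.uint8)
    ties = counts_alt * 2 == n
    consensus[ties] = 0
    return consensus, ties


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch-length estimates are clamped
    to zero (scikit-bio's standard adjustment)."""
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    return nj(dm)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    return tree.root_at_midpoint()


def gower_distances(table: GenotypeTable, encoding: str = "dosage") -> DistanceMatrix:
    """Pairwise Gower dissimilarity on genotypes.

    Dosage encoding scores |x_i - y_i| / range_i per site (range over
    non-missing dosages) averaged over sites where both samples are called;
    categorical encoding scores genotype mismatch 0/1.
    """
    if encoding not in ("dosage", "categorical"):
        raise ValueError("encoding must be 'dosage' or 'categorical'")
    n = table.n_samples
    if encoding == "dosage":
        d = table.dosage()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rng_ = np.nanmax(d, axis=0) - np.nanmin(d, axis=0)
        usable = np.isfinite(rng_) & (rng_ > 0)
        d = d[:, usable] / rng_[usable]
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                diff = np.abs(d[i] - d[j])
                ok = np.isfinite(diff)
                mat[i, j] = mat[j, i] = diff[ok].mean() if ok.any() else 0.0
    else:
        g = np.sort(table.genotypes, axis=2)
        called = (g != MISSING).all(axis=2)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = called[i] & called[j]
                mism = (g[i][ok] != g[j][ok]).any(axis=1)
                mat[i, j] = mat[j, i] = mism.mean() if ok.any() else 0.0
    return DistanceMatrix(mat, list(table.samples))


def gower_cluster(
    table: GenotypeTable, encoding: str = "dosage", method: str = "average"
) -> tuple[DistanceMatrix, np.ndarray]:
    """Hierarchical clustering of samples on Gower distances.

    Returns the distance matrix and a scipy linkage matrix (default average
    linkage; the linkage method is configurable).
    """
    dm = gower_distances(table, encoding=encoding)
    return dm, linkage(squareform(dm.data, checks=False), method=method)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _find_with_mismatches(template: str, probe: str, max_mismatches: int) -> list[int]:
    hits = []
    L = len(probe)
    for i in range(len(template) - L + 1):
        window = template[i:i + L]
        if max_mismatches == 0:
            if window == probe:
                hits.append(i)
        elif sum(a != b for a, b in zip(window, probe)) <= max_mismatches:
            hits.append(i)
    return hits


def insilico_pcr(
    template: str,
    forward_primer: str,
    reverse_primer: str,
    max_mismatches: int = 0,
    circular: bool = False,
) -> str:
    """Amplicon between a forward primer and the reverse complement of a
    reverse primer.

    The amplicon runs from the forward primer's first base through the
    reverse primer's binding site inclusive. Circular templates are honored
    (products may span the origin). No hit or multiple possible products
    raise ``ValueError``.
    """
    template = template.upper()
    fwd = forward_primer.upper()
    rev_site = _revcomp(reverse_primer.upper())
    search = template + template[: max(len(fwd), len(rev_site)) - 1] if circular else template
    f_hits = [h % len(template) for h in _find_with_mismatches(search, fwd, max_mismatches)]
    r_hits = [h % len(template) for h in _find_with_mismatches(search, rev_site, max_mismatches)]
    f_hits, r_hits = sorted(set(f_hits)), sorted(set(r_hits))
    if not f_hits:
        raise ValueError("forward primer not found")
    if not r_hits:
        raise ValueError("reverse primer not found")
    products = []
    L = len(template)
    for f in f_hits:
        for r in r_hits:
            end = r + len(rev_site)
            if f <= r and end <= L:
                products.append(template[f:end])
            elif circular:
                e = end % L
                if e <= f and (f > r or end > L):
                    products.append(template[f:] + template[:e])
    products = sorted(set(products))
    if not products:
        raise ValueError("primers do not face each other; no product")
    if len(products) > 1:
        raise ValueError(f"ambiguous amplification: {len(products)} possible products")
    return products[0]


#: Recognition sites and cut offsets (bp 5' of the cut within the site).
DEFAULT_ENZYMES: dict[str, tuple[str, int]] = {
    "HaeIII": ("GGCC", 2),   # GG^CC
    "MboI": ("GATC", 0),     # ^GATC
    "MspI": ("CCGG", 1),     # C^CGG
    "RsaI": ("GTAC", 2),     # GT^AC
    "TaqI": ("TCGA", 1),     # T^CGA
}


def restriction_digest(
    amplicon: str, enzymes: dict[str, tuple[str, int]] | None = None
) -> dict[str, tuple[int, ...]]:
    """Fragment-length pattern per enzyme for a linear amplicon.

    Fragments are sorted lengths between all recognition-site cuts; with no
    site the pattern is the full amplicon length. Fragments always sum to
    the amplicon length.
    """
    enzymes = enzymes or DEFAULT_ENZYMES
    seq = amplicon.upper()
    pattern: dict[str, tuple[int, ...]] = {}
    for name, (site, offset) in enzymes.items():
        cuts = [0]
        start = 0
        while True:
            k = seq.find(site, start)
            if k < 0:
                break
            cut = k + offset
            if 0 < cut < len(seq):
                cuts.append(cut)
            start = k + 1
        cuts.append(len(seq))
        cuts = sorted(set(cuts))
        pattern[name] = tuple(sorted(b - a for a, b in zip(cuts[:-1], cuts[1:])))
    return pattern


def assign_mitotype(
    patterns: dict[str, dict[str, tuple[int, ...]]], bin_bp: int = 20
) -> dict[str, str]:
    """Group samples into mitotypes by their five-enzyme fragment patterns.

    Fragment lengths are binned to ``bin_bp`` resolution (emulating gel
    resolution) before comparison; mitotype labels M1, M2, ... follow the
    order of first appearance.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")

    def _key(pat: dict[str, tuple[int, ...]]):
        return tuple(
            (enzyme, tuple(length // bin_bp for length in sorted(lengths)))
            for enzyme, lengths in sorted(pat.items())
        )

    classes: dict[tuple, str] = {}
    out = {}
    for sample in patterns:
        k = _key(patterns[sample])
        if k not in classes:
            classes[k] = f"M{len(classes) + 1}"
        out[sample] = classes[k]
    return out


def dloop_typing(
    sequences: dict[str, str], trim_to: int = 508
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Trim D-loop sequences and collapse exact duplicates into variants.

    Sequences shorter than ``trim_to`` are excluded with a warning. Returns
    a variant summary (variant id, sequence, count) and the sample ->
    variant-index membership.
    """
    variants: list[str] = []
    membership: dict[str, int] = {}
    for name, seq in sequences.items():
        seq = seq.upper()
        if len(seq) < trim_to:
            warnings.warn(f"sequence {name!r} shorter than {trim_to} bp; excluded")
            continue
        trimmed = seq[:trim_to]
        if trimmed not in variants:
            variants.append(trimmed)
        membership[name] = variants.index(trimmed)
    counts = pd.Series(list(membership.values())).value_counts().sort_index()
    table = pd.DataFrame(
        {
            "variant": [f"V{k + 1}" for k in range(len(variants))],
            "sequence": variants,
            "count": [int(counts.get(k, 0)) for k in range(len(variants))],
        }
    )
    return table, membership
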