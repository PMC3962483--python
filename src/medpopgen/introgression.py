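"""ABBA-BABA (D statistic) introgression tests with a ghost-population control.

For a quartet (((P1, P2), P3), O) polarized by the outgroup, derived-allele
frequencies p1, p2, p3 give per-site pattern weights
ABBA = (1 - p1) p2 p3 and BABA = p1 (1 - p2) p3; the D statistic is
(sum ABBA - sum BABA) / (sum ABBA + sum BABA). Under incomplete lineage
sorting alone D is 0; an excess of ABBA (D > 0) indicates gene flow between
P2 and P3. Uncertainty comes from a leave-one-out block jackknife over
contiguous genomic blocks.

A positive D for a test population can be a "ghost" artifact of its close
relatedness to a truly introgressed sister sample; restricting to sites
whose frequencies differentiate the test population from the sister removes
the shared signal and is exposed here as ``ghost_control``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeTable, HaplotypeSet

__all__ = [
    "QuartetSpec",
    "QuartetData",
    "site_patterns",
    "d_statistic",
    "ghost_control",
    "DstatResult",
]


@dataclass(frozen=True)
class QuartetSpec:
    """Panel labels for (((P1, P2), P3), O)."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self) -> None:
        labels = (self.p1, self.p2, self.p3, self.outgroup)
        if len(set(labels)) != 4:
            raise ValueError(f"quartet labels must be distinct, got {labels}")


def _derived_freqs(panel) -> np.ndarray:
    if isinstance(panel, HaplotypeSet):
        return panel.derived_frequency()
    if isinstance(panel, GenotypeTable):
        raise TypeError("convert GenotypeTable panels to HaplotypeSet or frequencies")
    return np.asarray(panel, dtype=float)


@dataclass
class QuartetData:
    """Aligned per-site derived-allele frequencies for named panels."""

    positions: np.ndarray
    frequencies: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        for label, f in self.frequencies.items():
            f = np.asarray(f, dtype=float)
            if f.shape != self.positions.shape:
                raise ValueError(f"panel {label!r} length mismatch")
            self.frequencies[label] = f

    @classmethod
    def from_haplotype_sets(cls, panels: dict[str, HaplotypeSet]) -> "QuartetData":
        """Align panels on their shared polarizable positions."""
        pos_sets = [set(h.positions[h.known_ancestral()]) for h in panels.values()]
        common = np.array(sorted(set.intersection(*pos_sets)), dtype=np.int64)
        freqs = {}
        for label, h in panels.items():
            pos = h.positions
            idx = np.searchsorted(pos, common)
            freqs[label] = h.derived_frequency()[idx]
        return cls(common, freqs)


def site_patterns(
    data: QuartetData, spec: QuartetSpec, require_outgroup_ancestral: bool = True
) -> pd.DataFrame:
    """Per-site ABBA/BABA weights from derived-allele frequencies.

    Sites where the outgroup is not fixed ancestral (derived frequency > 0)
    are excluded when the outgroup panel is present, matching polarization
    by a fixed outgroup; missing frequencies exclude a site listwise.
    """
    p1 = data.frequencies[spec.p1]
    p2 = data.frequencies[spec.p2]
    p3 = data.frequencies[spec.p3]
    ok = np.isfinite(p1) & np.isfinite(p2) & np.isfinite(p3)
    if spec.outgroup in data.frequencies and require_outgroup_ancestral:
        po = data.frequencies[spec.outgroup]
        ok &= np.isfinite(po) & (po == 0.0)
    abba = (1 - p1) * p2 * p3
    baba = p1 * (1 - p2) * p3
    return pd.DataFrame(
        {
            "position": data.positions[ok],
            "abba": abba[ok],
            "baba": baba[ok],
        }
    )


@dataclass
class DstatResult:
    abba: float
    baba: float
    d: float
    se: float | None
    z: float | None
    n_sites: int
    n_blocks: int
    subset: str = "all"


def d_statistic(
    weights: pd.DataFrame,
    block_size_bp: int = 1_000_000,
    n_blocks_min: int = 5,
    subset: str = "all",
) -> DstatResult:
    """D from summed pattern weights with block-jackknife uncertainty.

    SE comes from leave-one-block-out recomputation over contiguous blocks
    of ``block_size_bp``; Z = D / SE is withheld (None) when fewer than
    ``n_blocks_min`` non-empty blocks exist.
    """
    abba = weights["abba"].to_numpy()
    baba = weights["baba"].to_numpy()
    pos = weights["position"].to_numpy()
    tot_a, tot_b = abba.sum(), baba.sum()
    if tot_a + tot_b == 0:
        raise ValueError("no informative sites (ABBA + BABA = 0)")
    d = (tot_a - tot_b) / (tot_a + tot_b)
    block_ids = pos // block_size_bp
    blocks = np.unique(block_ids[(abba + baba) > 0])
    if len(blocks) < n_blocks_min:
        return DstatResult(float(tot_a), float(tot_b), float(d), None, None,
                           len(weights), len(blocks), subset)
    d_loo = np.empty(len(blocks))
    for k, b in enumerate(blocks):
        keep = block_ids != b
        a_k, b_k = abba[keep].sum(), baba[keep].sum()
        d_loo[k] = (a_k - b_k) / (a_k + b_k) if (a_k + b_k) > 0 else d
    B = len(blocks)
    se = float(np.sqrt((B - 1) / B * ((d_loo - d_loo.mean()) ** 2).sum()))
    z = d / se if se > 0 else None
    return DstatResult(float(tot_a), float(tot_b), float(d), se,
                       None if z is None else float(z), len(weights), B, subset)


def ghost_control(
    data: QuartetData,
    spec: QuartetSpec,
    sister_label: str,
    frequency_floor: float = 0.0,
    block_size_bp: int = 1_000_000,
    n_blocks_min: int = 5,
) -> tuple[np.ndarray, DstatResult]:
    """Recompute D on sites differentiating the test population (P2) from a
    closely related sister panel.

    Keeps sites where |p2 - p_sister| > frequency_floor (default: any
    difference). Returns the boolean site mask and the subset D result. An
    empty subset (test identical to sister) raises with a clear message.
    """
    if sister_label not in data.frequencies:
        raise KeyError(f"sister panel {sister_label!r} not in quartet data")
    p2 = data.frequencies[spec.p2]
    ps = data.frequencies[sister_label]
    mask = np.isfinite(p2) & np.isfinite(ps) & (np.abs(p2 - ps) > frequency_floor)
    if not mask.any():
        raise ValueError(
            "test population is identical to the sister at every site; "
            "no differentiating sites to test"
        )
    sub = QuartetData(
        data.positions[mask],
        {label: f[mask] for label, f in data.frequencies.items()},
    )
    weights = site_patterns(sub, spec)
    result = d_statistic(weights, block_size_bp=block_size_bp,
                         n_blocks_min=n_blocks_min,
                         subset="sister-differentiating")
    return mask, result
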