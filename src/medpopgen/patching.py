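"""Reference-assembly patching from deep-coverage consensus calls.

A reference built from older Sanger data can be revised with a deep
short-read consensus of the same strain: bases the assembly left
unresolved ('N') are filled from any defined consensus call, and bases
that disagree with the consensus are revised — either only when the call
quality reaches a threshold ("thresholded", default 100) or regardless
("unthresholded"). Ambiguous consensus calls (IUPAC codes supporting two
bases) are never used for revision. Validation metrics compare the
revised bases against an independently sequenced population panel and
against a presumed-ancestral outgroup base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeTable

__all__ = [
    "ConsensusCall",
    "ConsensusCallSet",
    "PatchRecord",
    "PatchResult",
    "patch_reference",
    "panel_concordance",
    "ancestral_consistency_fold",
    "supplement_from_strains",
]

PATCH_CLASSES = ("N-fill", "discrepant-revision", "strain-supplement")


@dataclass(frozen=True)
class ConsensusCall:
    """One consensus base call: 0-based position, base, phred-like quality, depth."""

    position: int
    base: str
    quality: float
    depth: int = 0

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("negative position")
        if self.quality < 0:
            raise ValueError("negative quality")
        if len(self.base) != 1:
            raise ValueError(f"consensus call base must be one character, got {self.base!r}")

    @property
    def unambiguous(self) -> bool:
        return self.base.upper() in "ACGT"


class ConsensusCallSet:
    """Per-position consensus calls; duplicate positions are rejected."""

    def __init__(self, calls: Iterable[ConsensusCall]):
        self.calls = list(calls)
        positions = [c.position for c in self.calls]
        if len(set(positions)) != len(positions):
            dupes = pd.Series(positions).value_counts()
            first = int(dupes.index[0])
            raise ValueError(f"conflicting calls at position {first}")
        self._by_pos = {c.position: c for c in self.calls}

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def get(self, position: int) -> ConsensusCall | None:
        return self._by_pos.get(position)

    @classmethod
    def from_tsv(cls, path) -> "ConsensusCallSet":
        """4-column TSV: 1-based position, base, quality, depth."""
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["pos", "base", "qual", "depth"], comment="#")
        return cls(
            ConsensusCall(int(r.pos) - 1, str(r.base), float(r.qual), int(r.depth))
            for r in df.itertuples()
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.calls:
                fh.write(f"{c.position + 1}\t{c.base}\t{c.quality:g}\t{c.depth}\n")


@dataclass(frozen=True)
class PatchRecord:
    """One applied base revision (0-based position)."""

    position: int
    old_base: str
    new_base: str
    quality: float
    patch_class: str

    def __post_init__(self) -> None:
        if self.patch_class not in PATCH_CLASSES:
            raise ValueError(f"unknown patch class {self.patch_class!r}")
        if self.new_base == self.old_base:
            raise ValueError("patch must change the base")
        old_is_n = self.old_base.upper() == "N"
        if self.patch_class == "discrepant-revision" and old_is_n:
            raise ValueError("discrepant revision requires a defined old base")
        if self.patch_class in ("N-fill", "strain-supplement") and not old_is_n:
            raise ValueError(f"{self.patch_class} requires old base N")


@dataclass
class PatchResult:
    sequence: str
    records: list[PatchRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.position, r.old_base, r.new_base, r.quality, r.patch_class)
             for r in self.records],
            columns=["position", "old_base", "new_base", "quality", "class"],
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df["position"] = df["position"] + 1  # 1-based in the ledger
        df.to_csv(path, sep="\t", index=False)


def patch_reference(
    reference: str,
    calls: ConsensusCallSet,
    quality_threshold: float = 100.0,
    mode: str = "thresholded",
) -> PatchResult:
    """Apply consensus-call revisions to a reference sequence.

    'N' positions with any defined (unambiguous) call are filled in both
    modes regardless of quality; discrepant positions are revised only when
    quality >= threshold in thresholded mode and always in unthresholded
    mode. Every change is emitted as a :class:`PatchRecord`; the output
    sequence has the same length as the input.
    """
    if mode not in ("thresholded", "unthresholded"):
        raise ValueError(f"mode must be 'thresholded' or 'unthresholded', got {mode!r}")
    seq = np.array(list(reference))
    n = len(seq)
    records: list[PatchRecord] = []
    for call in calls:
        if call.position >= n:
            raise ValueError(f"call at {call.position} beyond reference length {n}")
        if not call.unambiguous:
            continue  # two-base/ambiguous support never revises
        old = str(seq[call.position]).upper()
        new = call.base.upper()
        if old == "N":
            seq[call.position] = new
            records.append(PatchRecord(call.position, "N", new, call.quality, "N-fill"))
        elif old != new:
            if mode == "unthresholded" or call.quality >= quality_threshold:
                seq[call.position] = new
                records.append(
                    PatchRecord(call.position, old, new, call.quality,
                                "discrepant-revision")
                )
    return PatchResult("".join(seq), records)


@dataclass
class PanelConcordance:
    fraction_all_samples: float
    fraction_any_sample: float
    n_records: int
    n_uncovered: int


def panel_concordance(
    records: Sequence[PatchRecord], panel: GenotypeTable
) -> PanelConcordance:
    """Fractions of revised bases matching an independent population panel.

    A record "matches" a sample when the new base is among that sample's
    called alleles at the position; the all-samples fraction requires a
    match in every non-missing sample. Records at positions the panel does
    not cover are excluded from the denominators and counted separately.
    Only revisions (not N-fills) are assessed, since an N carries no prior
    claim to contradict.
    """
    site_by_pos = {s.pos: j for j, s in enumerate(panel.sites)}
    n_all = n_any = n_used = n_uncovered = 0
    for rec in records:
        if rec.patch_class == "N-fill":
            continue
        j = site_by_pos.get(rec.position)
        if j is None:
            n_uncovered += 1
            continue
        site = panel.sites[j]
        try:
            allele_idx = site.alleles.index(rec.new_base)
        except ValueError:
            allele_idx = -2  # base absent from panel alleles: matches nobody
        g = panel.genotypes[:, j, :]
        called = (g != -1).all(axis=1)
        if not called.any():
            n_uncovered += 1
            continue
        has = (g == allele_idx).any(axis=1)
        n_used += 1
        if (has | ~called).all() and called.any():
            n_all += 1
        if (has & called).any():
            n_any += 1
    return PanelConcordance(
        n_all / n_used if n_used else float("nan"),
        n_any / n_used if n_used else float("nan"),
        n_used,
        n_uncovered,
    )


@dataclass
class AncestralFold:
    fold: float | None          # None when the denominator is zero (undefined)
    new_match_fraction: float
    old_match_fraction: float
    n_assessed: int


def ancestral_consistency_fold(
    records: Sequence[PatchRecord], outgroup_sequence: str
) -> AncestralFold:
    """Fold change in agreement with the presumed ancestral (outgroup) base
    after revision: (fraction new == outgroup) / (fraction old == outgroup).

    Positions where the outgroup base is undefined (N/gap) are excluded.
    A zero denominator yields an undefined (None) fold, not infinity.
    """
    n = old_match = new_match = 0
    for rec in records:
        if rec.patch_class == "N-fill":
            continue
        if rec.position >= len(outgroup_sequence):
            continue
        out = outgroup_sequence[rec.position].upper()
        if out not in "ACGT":
            continue
        n += 1
        old_match += rec.old_base.upper() == out
        new_match += rec.new_base.upper() == out
    if n == 0:
        return AncestralFold(None, float("nan"), float("nan"), 0)
    new_frac, old_frac = new_match / n, old_match / n
    fold = None if old_frac == 0 else new_frac / old_frac
    return AncestralFold(fold, new_frac, old_frac, n)


def supplement_from_strains(
    patched_sequence: str,
    strain_calls: Sequence[ConsensusCallSet],
    min_strains_agreeing: int | None = None,
) -> PatchResult:
    """Fill positions still undefined after patching using agreement across
    independently sequenced strains.

    A position is supplemented only when at least ``min_strains_agreeing``
    strains (default: all supplied strains) call the same unambiguous base
    there. Emitted records carry class 'strain-supplement' and the minimum
    quality among agreeing calls.
    """
    if min_strains_agreeing is None:
        min_strains_agreeing = len(strain_calls)
    seq = np.array(list(patched_sequence))
    records: list[PatchRecord] = []
    undefined = {i for i, b in enumerate(patched_sequence) if b.upper() == "N"}
    for pos in sorted(undefined):
        bases: dict[str, list[ConsensusCall]] = {}
        for cs in strain_calls:
            call = cs.get(pos)
            if call is not None and call.unambiguous:
                bases.setdefault(call.base.upper(), []).append(call)
        if len(bases) != 1:
            continue  # disagreement or no coverage: leave undefined
        base, agreeing = next(iter(bases.items()))
        if len(agreeing) < min_strains_agreeing:
            continue
        seq[pos] = base
        records.append(
            PatchRecord(pos, "N", base, min(c.quality for c in agreeing),
                        "strain-supplement")
        )
    return PatchResult("".join(seq), records)
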