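"""Coding-effect classification and codon-enumeration expectations.

A coding SNP is classified per overlapping transcript from its codon
change (strand- and frame-aware): synonymous, missense, nonsense
(sense codon -> stop) or stop-codon (stop -> sense, i.e. stop loss).
Ambiguities across overlapping transcripts resolve by severity:
nonsense > stop-codon > missense > synonymous.

Expected class fractions under random substitution enumerate all nine
single-nucleotide changes of every codon, weighted by observed codon
frequencies; comparing observed class counts against these expectations
with a one-sided binomial test quantifies the depletion of
protein-altering changes by purifying selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import VariantSite

__all__ = [
    "Exon",
    "Transcript",
    "ExonModel",
    "EFFECT_CLASSES",
    "classify_codon_change",
    "classify_snp",
    "expected_class_fractions",
    "codon_frequencies_from_cds",
    "depletion_test",
    "standard_genetic_code",
]

EFFECT_CLASSES = ("nonsense", "stop-codon", "missense", "synonymous")
_SEVERITY = {c: i for i, c in enumerate(EFFECT_CLASSES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASES = "ACGT"


def standard_genetic_code() -> dict[str, str]:
    """Standard codon -> amino-acid table ('*' for stop)."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


@dataclass(frozen=True)
class Exon:
    """Coding exon, 0-based half-open on the forward strand."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad exon interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    """Complete CDS: exons in genomic order; translation follows strand."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValueError("exons must be in genomic order")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def cds_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def genomic_to_cds(self, pos: int) -> int | None:
        """CDS offset (0-based, in translation direction) of a genomic
        position, or None if the position is not in a coding exon."""
        offset = 0
        for exon in self.exons:
            if exon.start <= pos < exon.end:
                fwd = offset + (pos - exon.start)
                if self.strand == "+":
                    return fwd
                return self.cds_length - 1 - fwd
            offset += len(exon)
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        fwd = cds_pos if self.strand == "+" else self.cds_length - 1 - cds_pos
        offset = 0
        for exon in self.exons:
            if fwd < offset + len(exon):
                return exon.start + (fwd - offset)
            offset += len(exon)
        raise IndexError(f"CDS position {cds_pos} beyond transcript")

    def cds_sequence(self, reference: Mapping[str, str]) -> str:
        seq = "".join(reference[self.chrom][e.start:e.end] for e in self.exons)
        if self.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        return seq.upper()


class ExonModel:
    """Collection of transcripts with gene links, indexed by chromosome."""

    def __init__(self, transcripts: Sequence[Transcript]):
        self.transcripts = list(transcripts)
        self._by_chrom: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)

    def overlapping(self, chrom: str, pos: int) -> list[Transcript]:
        return [
            t for t in self._by_chrom.get(chrom, [])
            if any(e.start <= pos < e.end for e in t.exons)
        ]

    def gene_spans(self) -> pd.DataFrame:
        rows: dict[str, list] = {}
        for t in self.transcripts:
            lo = min(e.start for e in t.exons)
            hi = max(e.end for e in t.exons)
            if t.gene_id in rows:
                rows[t.gene_id][1] = min(rows[t.gene_id][1], lo)
                rows[t.gene_id][2] = max(rows[t.gene_id][2], hi)
            else:
                rows[t.gene_id] = [t.chrom, lo, hi]
        return pd.DataFrame(
            [(g, c, s, e) for g, (c, s, e) in rows.items()],
            columns=["gene_id", "chrom", "start", "end"],
        )

    def exon_intervals(self) -> pd.DataFrame:
        rows = [
            (t.gene_id, t.transcript_id, e.chrom, e.start, e.end)
            for t in self.transcripts for e in t.exons
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "transcript_id", "chrom", "start", "end"]
        )

    @classmethod
    def from_gff3(cls, path) -> "ExonModel":
        """Build from GFF3 CDS features grouped by Parent (transcript) with
        gene links from the transcript features' Parent attributes."""
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        transcripts = []
        for t in db.features_of_type(("mRNA", "transcript")):
            exons = sorted(db.children(t, featuretype="CDS"), key=lambda f: f.start)
            if not exons:
                continue
            gene = t.attributes.get("Parent", [t.id])[0]
            transcripts.append(
                Transcript(
                    t.id, gene, t.strand,
                    tuple(Exon(e.seqid, e.start - 1, e.end) for e in exons),
                )
            )
        return cls(transcripts)


def classify_codon_change(old_codon: str, new_codon: str, code: Mapping[str, str]) -> str:
    old_aa, new_aa = code[old_codon.upper()], code[new_codon.upper()]
    if old_aa == new_aa:
        return "synonymous"
    if new_aa == "*":
        return "nonsense"
    if old_aa == "*":
        return "stop-codon"
    return "missense"


@dataclass
class SnpEffect:
    per_transcript: dict[str, str]
    resolved: str | None
    unclassifiable: list[str]  # transcripts where the codon was incomplete


def classify_snp(
    site: VariantSite,
    model: ExonModel,
    reference: Mapping[str, str],
    genetic_code: Mapping[str, str] | None = None,
    alt_index: int = 0,
) -> SnpEffect:
    """Classify a SNP against every overlapping transcript and resolve by
    severity (nonsense > stop-codon > missense > synonymous).

    Sites whose codon is incomplete (CDS length not a multiple of three at
    a contig edge) are reported as unclassifiable for that transcript.
    """
    code = genetic_code or standard_genetic_code()
    alt = site.alts[alt_index]
    if len(site.ref) != 1 or len(alt) != 1:
        raise ValueError("only single-nucleotide substitutions are classified")
    per_transcript: dict[str, str] = {}
    unclassifiable: list[str] = []
    for t in model.overlapping(site.chrom, site.pos):
        cds_pos = t.genomic_to_cds(site.pos)
        codon_idx = cds_pos // 3
        codon_start = codon_idx * 3
        if codon_start + 3 > t.cds_length:
            unclassifiable.append(t.transcript_id)
            continue
        ref_base, alt_base = site.ref.upper(), alt.upper()
        if t.strand == "-":
            ref_base = ref_base.translate(_COMPLEMENT)
            alt_base = alt_base.translate(_COMPLEMENT)
        cds = t.cds_sequence(reference)
        old_codon = cds[codon_start:codon_start + 3]
        within = cds_pos - codon_start
        if old_codon[within] != ref_base:
            raise ValueError(
                f"reference mismatch at {site.chrom}:{site.pos + 1} in "
                f"{t.transcript_id}: CDS has {old_codon[within]}, site ref {site.ref}"
            )
        new_codon = old_codon[:within] + alt_base + old_codon[within + 1:]
        per_transcript[t.transcript_id] = classify_codon_change(old_codon, new_codon, code)
    resolved = (
        min(per_transcript.values(), key=_SEVERITY.__getitem__)
        if per_transcript else None
    )
    return SnpEffect(per_transcript, resolved, unclassifiable)


def codon_frequencies_from_cds(sequences: Mapping[str, str] | Sequence[str]) -> dict[str, float]:
    """Observed codon frequencies across in-frame CDS sequences."""
    if isinstance(sequences, Mapping):
        sequences = list(sequences.values())
    counts: dict[str, int] = {}
    for seq in sequences:
        seq = seq.upper()
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if set(codon) <= set(BASES):
                counts[codon] = counts.get(codon, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no complete codons found")
    return {c: n / total for c, n in counts.items()}


def expected_class_fractions(
    codon_frequencies: Mapping[str, float],
    genetic_code: Mapping[str, str] | None = None,
    include_stop_codons: bool = False,
) -> dict[str, float]:
    """Expected fraction of each effect class under random single-nucleotide
    substitution, weighting each codon's nine possible changes by its
    frequency.

    Stop codons are excluded from the source-codon weighting by default
    (exome codon usage describes sense codons); pass
    ``include_stop_codons=True`` to weight substitutions within stop codons
    too. Unnormalized frequencies are accepted and rescaled.
    """
    code = genetic_code or standard_genetic_code()
    freqs = {c.upper(): f for c, f in codon_frequencies.items()}
    for c, f in freqs.items():
        if f < 0:
            raise ValueError(f"negative frequency for codon {c}")
        if c not in code:
            raise ValueError(f"unknown codon {c!r}")
    if not include_stop_codons:
        freqs = {c: f for c, f in freqs.items() if code[c] != "*"}
    total = sum(freqs.values())
    if total <= 0:
        raise ValueError("codon frequencies sum to zero")
    out = {cls: 0.0 for cls in EFFECT_CLASSES}
    for codon, f in freqs.items():
        w = f / total
        for i in range(3):
            for b in BASES:
                if b == codon[i]:
                    continue
                new = codon[:i] + b + codon[i + 1:]
                out[classify_codon_change(codon, new, code)] += w / 9.0
    return out


def depletion_test(
    observed: Mapping[str, int],
    expected_fractions: Mapping[str, float],
) -> pd.DataFrame:
    """One-sided binomial depletion test per effect class.

    For each class, tests observed count <= n_total * expected fraction
    (alternative: fewer than expected). Returns observed/expected ratios and
    p-values; classes observed at or above expectation give p >= ~0.5.
    """
    n_total = int(sum(observed.values()))
    rows = []
    for cls in EFFECT_CLASSES:
        obs = int(observed.get(cls, 0))
        p = float(expected_fractions.get(cls, 0.0))
        expected = n_total * p
        pval = float(stats.binom.cdf(obs, n_total, p)) if n_total else float("nan")
        ratio = obs / expected if expected > 0 else float("nan")
        rows.append((cls, obs, obs / n_total if n_total else float("nan"),
                     p, ratio, pval))
    return pd.DataFrame(
        rows,
        columns=["class", "observed", "observed_fraction", "expected_fraction",
                 "obs_exp_ratio", "p_depletion"],
    ).set_index("class")
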