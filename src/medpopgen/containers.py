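"""Core in-memory containers for variant, genotype and haplotype data.

Coordinates are 0-based half-open internally; file I/O converts to each
format's native convention (VCF/GFF3 1-based, BED 0-based half-open).
Genotype alleles are coded as integer indices into ``[ref] + alts``;
``-1`` marks a missing allele.  Half-missing diploid calls are treated as
fully missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

MISSING = -1

_DNA = set("ACGTacgt")


@dataclass(frozen=True)
class VariantSite:
    """One variant position.

    ``pos`` is 0-based. ``ancestral`` is the ancestral base (polarized by an
    outgroup) or ``None`` when unknown.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    ancestral: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        for a in (self.ref, *self.alts):
            if not a or not set(a) <= _DNA:
                raise ValueError(f"invalid allele {a!r} at {self.chrom}:{self.pos}")
        if self.ancestral is not None and self.ancestral not in (self.ref, *self.alts):
            raise ValueError(
                f"ancestral allele {self.ancestral!r} not among site alleles "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref, *self.alts)

    @property
    def ancestral_index(self) -> int | None:
        """Index of the ancestral allele in ``alleles``, or None if unknown."""
        if self.ancestral is None:
            return None
        return self.alleles.index(self.ancestral)

    def with_ancestral(self, base: str | None) -> "VariantSite":
        return VariantSite(self.chrom, self.pos, self.ref, self.alts, base)


class Pedigree:
    """Child -> (father, mother) links over sample labels.

    Parents absent from the genotyped sample set are allowed ("external")
    but trios with external parents are skipped by Mendelian checks.
    """

    def __init__(self, links: dict[str, tuple[str, str]] | None = None):
        self._links: dict[str, tuple[str, str]] = dict(links or {})
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for child in self._links:
            seen = {child}
            stack = list(self._links[child])
            while stack:
                cur = stack.pop()
                if cur in seen:
                    raise ValueError(f"pedigree cycle through {cur!r}")
                seen.add(cur)
                if cur in self._links:
                    stack.extend(self._links[cur])

    def add(self, child: str, father: str, mother: str) -> None:
        self._links[child] = (father, mother)
        self._check_acyclic()

    def parents(self, child: str) -> tuple[str, str] | None:
        return self._links.get(child)

    def trios(self) -> Iterator[tuple[str, str, str]]:
        """Yield (child, father, mother) triples."""
        for child, (father, mother) in self._links.items():
            yield child, father, mother

    def __len__(self) -> int:
        return len(self._links)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Pedigree) and self._links == other._links

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tfather\tmother\n")
            for child, (father, mother) in self._links.items():
                fh.write(f"{child}\t{father}\t{mother}\n")

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        links: dict[str, tuple[str, str]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("sample"):
                fh.seek(0)
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                links[parts[0]] = (parts[1], parts[2])
        return cls(links)


def _check_sites_sorted(sites: Sequence[VariantSite]) -> None:
    last: dict[str, int] = {}
    for s in sites:
        if s.chrom in last and s.pos <= last[s.chrom]:
            raise ValueError(
                f"sites not strictly increasing by position on {s.chrom} "
                f"(pos {s.pos} after {last[s.chrom]})"
            )
        last[s.chrom] = s.pos


@dataclass
class GenotypeTable:
    """Diploid genotypes: samples x sites x 2 allele indices (-1 = missing)."""

    sites: list[VariantSite]
    samples: list[str]
    genotypes: np.ndarray
    site_annotations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.shape != (len(self.samples), len(self.sites), 2):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        _check_sites_sorted(self.sites)
        # half-missing -> missing
        half = (self.genotypes == MISSING).any(axis=2)
        self.genotypes[half] = MISSING
        for key, arr in self.site_annotations.items():
            if len(arr) != len(self.sites):
                raise ValueError(f"annotation {key!r} length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        return [s.chrom for s in self.sites]

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in table") from None

    def missing_mask(self) -> np.ndarray:
        """(n_samples, n_sites) boolean mask of missing genotypes."""
        return (self.genotypes == MISSING).any(axis=2)

    def het_mask(self) -> np.ndarray:
        """(n_samples, n_sites) boolean mask of heterozygous genotypes."""
        called = ~self.missing_mask()
        return called & (self.genotypes[:, :, 0] != self.genotypes[:, :, 1])

    def dosage(self) -> np.ndarray:
        """Count of non-reference alleles per sample per site (nan = missing)."""
        d = (self.genotypes > 0).sum(axis=2).astype(float)
        d[self.missing_mask()] = np.nan
        return d

    def take_sites(self, index: np.ndarray | list[int]) -> "GenotypeTable":
        index = np.asarray(index, dtype=np.int64)
        return GenotypeTable(
            [self.sites[i] for i in index],
            list(self.samples),
            self.genotypes[:, index, :].copy(),
            {k: np.asarray(v)[index].copy() for k, v in self.site_annotations.items()},
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeTable":
        idx = [self.sample_index(n) for n in names]
        return GenotypeTable(
            list(self.sites), list(names), self.genotypes[idx].copy(),
            {k: v.copy() for k, v in self.site_annotations.items()},
        )

    def allele_counts(self) -> np.ndarray:
        """(n_sites, max_alleles) counts of each allele index among called genotypes."""
        n_alleles = max((len(s.alleles) for s in self.sites), default=2)
        out = np.zeros((self.n_sites, n_alleles), dtype=np.int64)
        g = self.genotypes
        for k in range(n_alleles):
            out[:, k] = (g == k).sum(axis=(0, 2))
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenotypeTable)
            and self.sites == other.sites
            and self.samples == other.samples
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes over ordered biallelic sites.

    Row ``2*i`` and ``2*i + 1`` are the two haplotypes of ``samples[i]``.
    Matrix entries are 0 (ref) / 1 (alt); polarization to ancestral/derived
    uses the per-site ancestral allele via :meth:`derived_matrix`.
    """

    sites: list[VariantSite]
    samples: list[str]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (2 * len(self.samples), len(self.sites)):
            raise ValueError(
                f"haplotype matrix shape {self.haplotypes.shape} inconsistent with "
                f"{len(self.samples)} diploid samples x {len(self.sites)} sites"
            )
        _check_sites_sorted(self.sites)
        for s in self.sites:
            if len(s.alts) != 1:
                raise ValueError(f"haplotype sites must be biallelic ({s.chrom}:{s.pos})")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chrom(self) -> str:
        chroms = {s.chrom for s in self.sites}
        if len(chroms) != 1:
            raise ValueError("haplotype set spans multiple chromosomes")
        return next(iter(chroms))

    def derived_matrix(self) -> np.ndarray:
        """Matrix recoded so 0 = ancestral, 1 = derived.

        Columns whose ancestral allele is the alt are flipped; columns with
        unknown ancestral state are returned ref-coded unchanged (callers
        needing strict polarization should subset with known_ancestral()).
        """
        out = self.haplotypes.copy()
        flip = np.fromiter(
            (s.ancestral_index == 1 for s in self.sites), dtype=bool, count=len(self.sites)
        )
        out[:, flip] ^= 1
        return out

    def known_ancestral(self) -> np.ndarray:
        return np.array([s.ancestral is not None for s in self.sites], dtype=bool)

    def derived_frequency(self) -> np.ndarray:
        """Per-site derived allele frequency (nan where ancestral unknown)."""
        freq = self.derived_matrix().mean(axis=0)
        freq[~self.known_ancestral()] = np.nan
        return freq

    def take_sites(self, index: np.ndarray | list[int]) -> "HaplotypeSet":
        index = np.asarray(index, dtype=np.int64)
        return HaplotypeSet(
            [self.sites[i] for i in index], list(self.samples),
            self.haplotypes[:, index].copy(),
        )

    def to_genotype_table(self) -> GenotypeTable:
        g = self.haplotypes.reshape(len(self.samples), 2, self.n_sites)
        return GenotypeTable(
            list(self.sites), list(self.samples),
            np.stack([g[:, 0, :], g[:, 1, :]], axis=2).astype(np.int16),
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, HaplotypeSet)
            and self.sites == other.sites
            and self.samples == other.samples
            and np.array_equal(self.haplotypes, other.haplotypes)
        )
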