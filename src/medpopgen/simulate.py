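"""Synthetic-data generation for every pipeline input.

The generator emulates the statistical structure of a wild medaka founder
population and its derived inbred lines: a coalescent sample for the wild
catch (heterozygosity ~1.5e-3 at mu = 2.5e-8 with Ne ~ 1.5e4),
mother-father-offspring trios produced by explicit meiosis, brother-sister
inbreeding with residual heterozygous blocks, haplotype-copying selective
sweeps, four-population admixture with an outgroup for ABBA-BABA tests,
microsatellite panels with a controlled inbreeding coefficient, morphometric
strain panels with controlled broad-sense heritability, and planted
reference-assembly errors for patch-recovery tests.

Neutral/structured ancestry is simulated with msprime; mutations use a
binary infinite-sites model so every site is biallelic with a known
ancestral state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeTable, HaplotypeSet, Pedigree, VariantSite
from .patching import ConsensusCall, ConsensusCallSet

__all__ = [
    "SimConfig",
    "ScenarioSpec",
    "simulate_neutral_population",
    "simulate_trios",
    "inject_sweep",
    "simulate_admixture",
    "simulate_bottleneck_population",
    "simulate_inbred_line",
    "simulate_microsatellites",
    "simulate_morphometrics",
    "simulate_consensus_calls",
    "ConsensusSim",
]

#: Default per-bp per-generation mutation rate used for scaling throughout.
DEFAULT_MUTATION_RATE = 2.5e-8


@dataclass(frozen=True)
class SimConfig:
    """Parameters shared by the ancestry simulations.

    With the defaults (Ne = 15,000, mu = 2.5e-8) expected pairwise
    heterozygosity is 4*Ne*mu = 1.5e-3 per bp, the wild-catch level; inbred
    lines reach ~3e-5 after brother-sister inbreeding (see
    :func:`simulate_inbred_line`).
    """

    seed: int
    sequence_length: int = 1_000_000
    n_haplotypes: int = 48
    mutation_rate: float = DEFAULT_MUTATION_RATE
    recombination_rate: float = 2.5e-8
    effective_size: int = 15_000

    def __post_init__(self) -> None:
        if self.sequence_length <= 0:
            raise ValueError("sequence_length must be positive")
        if self.n_haplotypes <= 0:
            raise ValueError("n_haplotypes must be positive")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (diploid samples)")
        for name in ("mutation_rate", "recombination_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.effective_size <= 0:
            raise ValueError("effective_size must be positive")


@dataclass(frozen=True)
class ScenarioSpec:
    """Demographic/selective scenario on top of a neutral configuration."""

    kind: str = "neutral"  # neutral | sweep | admixture | bottleneck
    sweep_position: int | None = None
    sweep_frequency: float | None = None
    sweep_tract_mean_bp: float = 100_000.0
    admixture_fraction: float | None = None
    admixture_time: float = 500.0
    donor: str = "P3"
    recipient: str = "P2"
    bottleneck_time: float | None = None
    bottleneck_size_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("neutral", "sweep", "admixture", "bottleneck"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        for name in ("sweep_frequency", "admixture_fraction", "bottleneck_size_ratio"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0 and name != "bottleneck_size_ratio":
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.admixture_fraction is not None and not 0 <= self.admixture_fraction <= 1:
            raise ValueError("admixture_fraction must be in [0, 1]")


def _derive_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(1, 2**31 - 1, size=n)]


def _ts_to_haplotypes(ts, sample_names: list[str], chrom: str = "chr1") -> HaplotypeSet:
    """Binary infinite-sites tree sequence -> HaplotypeSet (0 = ancestral)."""
    positions = np.floor(ts.sites_position).astype(np.int64)
    matrix = ts.genotype_matrix().T.astype(np.uint8)  # (haps, sites)
    matrix[matrix > 1] = 1  # guard: collapse back-mutations to presence
    keep = np.ones(len(positions), dtype=bool)
    keep[1:] = positions[1:] > positions[:-1]  # drop integer-position collisions
    positions, matrix = positions[keep], matrix[:, keep]
    sites = [VariantSite(chrom, int(p), "A", ("T",), "A") for p in positions]
    return HaplotypeSet(sites, sample_names, matrix)


def simulate_neutral_population(config: SimConfig, chrom: str = "chr1") -> HaplotypeSet:
    """Constant-size neutral coalescent sample with recombination.

    Ancestral alleles are recorded per site (the simulation is polarized by
    construction). Fully determined by ``config.seed``.
    """
    anc_seed, mut_seed = _derive_seeds(config.seed, 2)
    ts = msprime.sim_ancestry(
        samples=config.n_haplotypes // 2,
        ploidy=2,
        sequence_length=config.sequence_length,
        recombination_rate=config.recombination_rate,
        population_size=config.effective_size,
        random_seed=anc_seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mutation_rate,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=mut_seed,
    )
    names = [f"ind{i}" for i in range(config.n_haplotypes // 2)]
    return _ts_to_haplotypes(ts, names, chrom)


def simulate_bottleneck_population(
    config: SimConfig, spec: ScenarioSpec, chrom: str = "chr1"
) -> HaplotypeSet:
    """Neutral sample from a population whose size changed to
    ``bottleneck_size_ratio * effective_size`` at ``bottleneck_time``
    generations ago (looking backwards: ancestral size is the reduced one)."""
    if spec.bottleneck_time is None or spec.bottleneck_size_ratio is None:
        raise ValueError("bottleneck scenario requires time and size ratio")
    anc_seed, mut_seed = _derive_seeds(config.seed, 2)
    demography = msprime.Demography()
    demography.add_population(name="pop", initial_size=config.effective_size)
    demography.add_population_parameters_change(
        time=spec.bottleneck_time,
        initial_size=config.effective_size * spec.bottleneck_size_ratio,
        population="pop",
    )
    ts = msprime.sim_ancestry(
        samples={"pop": config.n_haplotypes // 2},
        ploidy=2,
        sequence_length=config.sequence_length,
        recombination_rate=config.recombination_rate,
        demography=demography,
        random_seed=anc_seed,
    )
    ts = msprime.sim_mutations(
        ts, rate=config.mutation_rate, model=msprime.BinaryMutationModel(),
        discrete_genome=False, random_seed=mut_seed,
    )
    names = [f"ind{i}" for i in range(config.n_haplotypes // 2)]
    return _ts_to_haplotypes(ts, names, chrom)


# ---------------------------------------------------------------------------
# Meiosis, trios and inbred lines
# ---------------------------------------------------------------------------

def _gamete(
    rng: np.random.Generator,
    genotype: np.ndarray,          # (n_sites, 2) allele indices
    positions: np.ndarray,
    sequence_length: int,
    recombination_rate: float,
) -> np.ndarray:
    """One recombinant gamete from a phased diploid genotype.

    Crossover count is Poisson(rate * L); breakpoints are uniform. The
    starting phase is an independent fair coin.
    """
    n_cross = rng.poisson(recombination_rate * sequence_length)
    phase = np.full(len(positions), rng.integers(0, 2), dtype=np.int64)
    if n_cross:
        breaks = np.sort(rng.integers(0, sequence_length, size=n_cross))
        phase = (phase + np.searchsorted(breaks, positions, side="right")) % 2
    return genotype[np.arange(len(positions)), phase]


def simulate_trios(
    founders: GenotypeTable,
    n_trios: int,
    recombination_rate: float,
    seed: int,
    sequence_length: int | None = None,
) -> tuple[GenotypeTable, Pedigree]:
    """Mother-father-offspring trios by explicit meiosis from phased founders.

    The first ``2 * n_trios`` founder samples are paired (father, mother) in
    order. Offspring genotypes are legal meiotic products by construction,
    so a Mendelian check on the output finds zero errors. Founder allele
    order is treated as phase. Returns the founders plus offspring and the
    pedigree.
    """
    if len(founders.samples) % 2:
        raise ValueError("odd founder count; founders must pair into couples")
    if len(founders.samples) < 2 * n_trios:
        raise ValueError(
            f"need {2 * n_trios} founders for {n_trios} trios, have {len(founders.samples)}"
        )
    rng = np.random.default_rng(seed)
    positions = founders.positions
    L = int(sequence_length or (positions.max() + 1 if len(positions) else 1))
    children = []
    links: dict[str, tuple[str, str]] = {}
    child_names = []
    for t in range(n_trios):
        father, mother = founders.samples[2 * t], founders.samples[2 * t + 1]
        gf = founders.genotypes[founders.sample_index(father)]
        gm = founders.genotypes[founders.sample_index(mother)]
        pat = _gamete(rng, gf, positions, L, recombination_rate)
        mat = _gamete(rng, gm, positions, L, recombination_rate)
        child = np.stack([pat, mat], axis=1)
        child[(child == MISSING).any(axis=1)] = MISSING
        children.append(child)
        name = f"child{t}"
        child_names.append(name)
        links[name] = (father, mother)
    all_genos = np.concatenate(
        [founders.genotypes, np.array(children, dtype=np.int16)], axis=0
    ) if children else founders.genotypes.copy()
    table = GenotypeTable(
        list(founders.sites), list(founders.samples) + child_names, all_genos
    )
    return table, Pedigree(links)


def simulate_inbred_line(
    founder: GenotypeTable,
    generations: int,
    seed: int,
    recombination_rate: float = 2.5e-8,
    sequence_length: int | None = None,
) -> GenotypeTable:
    """Brother-sister inbreeding from a two-individual founder pair.

    Generation 1 is the founder pair's F1; each later generation mates the
    previous generation's sibling pair. Heterozygosity declines following
    the classical full-sib recurrence (asymptotic ratio (1 + sqrt(5))/4 per
    generation) and residual heterozygosity is arranged in contiguous
    blocks because gametes recombine. Returns the final sibling pair
    (``generations = 0`` returns the founder pair unchanged).
    """
    if len(founder.samples) != 2:
        raise ValueError("founder must contain exactly two individuals")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if generations == 0:
        return GenotypeTable(
            list(founder.sites), list(founder.samples), founder.genotypes.copy()
        )
    rng = np.random.default_rng(seed)
    positions = founder.positions
    L = int(sequence_length or (positions.max() + 1 if len(positions) else 1))
    pair = [founder.genotypes[0], founder.genotypes[1]]
    for _ in range(generations):
        nxt = []
        for _child in range(2):
            pat = _gamete(rng, pair[0], positions, L, recombination_rate)
            mat = _gamete(rng, pair[1], positions, L, recombination_rate)
            child = np.stack([pat, mat], axis=1)
            child[(child == MISSING).any(axis=1)] = MISSING
            nxt.append(child)
        pair = nxt
    return GenotypeTable(
        list(founder.sites),
        [f"gen{generations}_a", f"gen{generations}_b"],
        np.array(pair, dtype=np.int16),
    )


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def inject_sweep(haps: HaplotypeSet, spec: ScenarioSpec, seed: int) -> HaplotypeSet:
    """Plant a partial selective sweep by haplotype copying.

    A core haplotype is copied onto carriers over flanking tracts whose
    per-side lengths are exponential with mean ``spec.sweep_tract_mean_bp``,
    emulating the decay of haplotype sharing around a recently selected
    allele without a forward selection simulation: each carrier lineage
    keeps the founding haplotype until its own recombination breakpoint, so
    the per-side tract mean corresponds to 1 / (r * T) for a sweep T
    generations old (the 100-kb default is a sweep a few hundred
    generations old at r = 2.5e-8). The derived allele at the core site
    reaches round(target * n) carriers (ties toward more).
    """
    if spec.sweep_position is None or spec.sweep_frequency is None:
        raise ValueError("sweep scenario requires position and target frequency")
    n = haps.n_haplotypes
    k = int(np.floor(spec.sweep_frequency * n + 0.5))
    if spec.sweep_frequency > 0 and k == 0:
        raise ValueError(
            f"target frequency {spec.sweep_frequency} yields no carriers among {n}"
        )
    if k > n:
        raise ValueError("target frequency incompatible with sample size")
    rng = np.random.default_rng(seed)
    positions = haps.positions
    sites = list(haps.sites)
    matrix = haps.haplotypes.copy()
    # core site: exact-position site if present, else a new one is created
    hit = np.nonzero(positions == spec.sweep_position)[0]
    if hit.size:
        core = int(hit[0])
    else:
        core = int(np.searchsorted(positions, spec.sweep_position))
        sites.insert(core, VariantSite(haps.chrom, spec.sweep_position, "A", ("T",), "A"))
        matrix = np.insert(matrix, core, 0, axis=1)
        positions = np.insert(positions, core, spec.sweep_position)
    carriers = rng.choice(n, size=k, replace=False)
    donor = int(carriers[0]) if k else 0
    matrix[:, core] = 0
    matrix[carriers, core] = 1
    core_pos = positions[core]
    for h in carriers:
        if h == donor:
            continue
        left = rng.exponential(spec.sweep_tract_mean_bp)
        right = rng.exponential(spec.sweep_tract_mean_bp)
        in_tract = (positions >= core_pos - left) & (positions <= core_pos + right)
        matrix[h, in_tract] = matrix[donor, in_tract]
    return HaplotypeSet(sites, list(haps.samples), matrix)


# ---------------------------------------------------------------------------
# Four-population admixture
# ---------------------------------------------------------------------------

def simulate_admixture(
    config: SimConfig,
    f: float,
    seed: int | None = None,
    split_p1p2: float = 5_000.0,
    split_p12p3: float = 20_000.0,
    split_root: float = 100_000.0,
    admixture_time: float = 500.0,
    n_outgroup: int = 2,
    chrom: str = "chr1",
) -> dict[str, HaplotypeSet]:
    """Quartet sample (((P1,P2),P3),O) with a pulse of fraction ``f`` from
    P3 into P2 at ``admixture_time`` generations ago.

    Sites are polarized by the outgroup: only sites where all outgroup
    haplotypes agree are kept, recoded so 0 = ancestral; the outgroup is
    therefore fixed ancestral at every retained site. Each ingroup
    population holds ``config.n_haplotypes // 2`` diploids.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"admixture fraction must be in [0, 1], got {f}")
    if not admixture_time < split_p1p2 < split_p12p3 < split_root:
        raise ValueError("require admixture_time < split_p1p2 < split_p12p3 < split_root")
    seed = config.seed if seed is None else seed
    anc_seed, mut_seed = _derive_seeds(seed, 2)
    Ne = config.effective_size
    dem = msprime.Demography()
    for name in ("P1", "P2", "P3", "O", "A12", "A123", "ROOT"):
        dem.add_population(name=name, initial_size=Ne)
    if f > 0:
        dem.add_mass_migration(time=admixture_time, source="P2", dest="P3", proportion=f)
    dem.add_population_split(time=split_p1p2, derived=["P1", "P2"], ancestral="A12")
    dem.add_population_split(time=split_p12p3, derived=["A12", "P3"], ancestral="A123")
    dem.add_population_split(time=split_root, derived=["A123", "O"], ancestral="ROOT")
    n_dip = config.n_haplotypes // 2
    ts = msprime.sim_ancestry(
        samples={"P1": n_dip, "P2": n_dip, "P3": n_dip, "O": n_outgroup},
        ploidy=2,
        sequence_length=config.sequence_length,
        recombination_rate=config.recombination_rate,
        demography=dem,
        random_seed=anc_seed,
    )
    ts = msprime.sim_mutations(
        ts, rate=config.mutation_rate, model=msprime.BinaryMutationModel(),
        discrete_genome=False, random_seed=mut_seed,
    )
    positions = np.floor(ts.sites_position).astype(np.int64)
    matrix = ts.genotype_matrix().T.astype(np.uint8)
    matrix[matrix > 1] = 1
    keep = np.ones(len(positions), dtype=bool)
    keep[1:] = positions[1:] > positions[:-1]
    positions, matrix = positions[keep], matrix[:, keep]
    # haplotype blocks per population, in sampling order
    bounds = np.cumsum([0, 2 * n_dip, 2 * n_dip, 2 * n_dip, 2 * n_outgroup])
    out_block = matrix[bounds[3]:bounds[4]]
    polarizable = (out_block == out_block[0]).all(axis=0)
    positions, matrix = positions[polarizable], matrix[:, polarizable]
    flip = out_block[0, polarizable].astype(bool)
    matrix[:, flip] ^= 1  # recode so the outgroup state is ancestral (0)
    result: dict[str, HaplotypeSet] = {}
    labels = ["P1", "P2", "P3", "O"]
    sizes = [n_dip, n_dip, n_dip, n_outgroup]
    for label, lo, hi, size in zip(labels, bounds[:-1], bounds[1:], sizes):
        sites = [VariantSite(chrom, int(p), "A", ("T",), "A") for p in positions]
        names = [f"{label}_ind{i}" for i in range(size)]
        result[label] = HaplotypeSet(sites, names, matrix[lo:hi].copy())
    return result


# ---------------------------------------------------------------------------
# Microsatellites and morphometrics
# ---------------------------------------------------------------------------

def simulate_microsatellites(
    n_loci: int,
    n_individuals: int,
    allele_counts: int | list[int],
    target_F: float,
    seed: int,
):
    """Microsatellite genotype table with expected inbreeding coefficient
    ``target_F``.

    Genotypes are a mixture: with probability F an individual is a forced
    homozygote (one allele draw), otherwise two Hardy-Weinberg draws, so
    E[H_obs] = (1 - F) * H_exp. Allele frequencies per locus are Dirichlet.
    """
    from .diversity import MicrosatTable

    if not 0.0 <= target_F <= 1.0:
        raise ValueError("target_F must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(allele_counts, int):
        allele_counts = [allele_counts] * n_loci
    if len(allele_counts) != n_loci:
        raise ValueError("allele_counts length must equal n_loci")
    geno = np.zeros((n_individuals, n_loci, 2), dtype=np.int64)
    for j, n_all in enumerate(allele_counts):
        lengths = 100 + 2 * np.arange(n_all)
        freqs = rng.dirichlet(np.ones(n_all))
        forced = rng.random(n_individuals) < target_F
        a = rng.choice(lengths, size=n_individuals, p=freqs)
        b = rng.choice(lengths, size=n_individuals, p=freqs)
        b[forced] = a[forced]
        geno[:, j, 0], geno[:, j, 1] = a, b
    return MicrosatTable(
        [f"locus{j}" for j in range(n_loci)],
        [f"fish{i}" for i in range(n_individuals)],
        geno,
    )


MORPH_RATIO_TRAITS = ("L1", "L2", "L3", "D1", "D2", "D3", "D4")


def simulate_morphometrics(
    strains: list[str],
    n_per_strain: int,
    trait_h2: float | dict[str, float],
    seed: int,
    body_length_mean: float = 1000.0,
    body_length_strain_sd: float = 50.0,
    body_length_within_sd: float = 30.0,
    ratio_mean: float = 0.3,
    ratio_total_sd: float = 0.03,
) -> pd.DataFrame:
    """Morphometric measurement table (pixels) for a strain panel.

    Lateral measures L1-L3 and dorsal D1-D4 are generated as ratios to the
    body lengths L4/D5 with between-strain variance fraction ``trait_h2``
    per trait, then multiplied back by the individual's body length so that
    body size is the dominant variance source, as in real larval imaging.
    """
    if isinstance(trait_h2, (int, float)):
        trait_h2 = {t: float(trait_h2) for t in MORPH_RATIO_TRAITS}
    for t, h2 in trait_h2.items():
        if not 0.0 <= h2 <= 1.0:
            raise ValueError(f"h2 for {t} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for strain in strains:
        strain_len = rng.normal(body_length_mean, body_length_strain_sd)
        strain_fx = {
            t: rng.normal(0.0, ratio_total_sd * np.sqrt(h2))
            for t, h2 in trait_h2.items()
        }
        for _ in range(n_per_strain):
            L4 = rng.normal(strain_len, body_length_within_sd)
            D5 = L4 * rng.normal(1.0, 0.01)
            row = {"strain": strain, "L4": L4, "D5": D5}
            for t in MORPH_RATIO_TRAITS:
                h2 = trait_h2.get(t, 0.0)
                resid_sd = ratio_total_sd * np.sqrt(max(0.0, 1.0 - h2))
                ratio = ratio_mean + strain_fx.get(t, 0.0) + rng.normal(0.0, resid_sd)
                body = L4 if t.startswith("L") else D5
                row[t] = ratio * body
            rows.append(row)
    cols = ["strain", "L1", "L2", "L3", "L4", "D1", "D2", "D3", "D4", "D5"]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# Consensus-call planting for reference patching
# ---------------------------------------------------------------------------

@dataclass
class ConsensusSim:
    """Planted reference degradation plus the consensus calls that reveal it."""

    degraded_reference: str
    calls: ConsensusCallSet
    truth: pd.DataFrame  # columns: position (0-based), old_base, new_base, quality, class

    def planted_positions(self) -> np.ndarray:
        return self.truth["position"].to_numpy()


_BASES = np.array(list("ACGT"))


def simulate_consensus_calls(
    reference: str,
    n_errors: int,
    n_gaps: int,
    quality_range: tuple[float, float] = (100.0, 200.0),
    seed: int = 0,
    depth: int = 144,
) -> ConsensusSim:
    """Plant unresolved ('N') and discrepant positions in a reference and
    emit deep-coverage consensus calls carrying the true base.

    Returns the degraded reference, the call set (true base, quality drawn
    uniformly from ``quality_range``, fixed depth) and a truth table for
    patch-recovery tests.
    """
    if n_errors + n_gaps > len(reference):
        raise ValueError("more planted positions than reference bases")
    rng = np.random.default_rng(seed)
    ref = np.array(list(reference.upper()))
    picked = rng.choice(len(ref), size=n_errors + n_gaps, replace=False)
    gap_pos, err_pos = np.sort(picked[:n_gaps]), np.sort(picked[n_gaps:])
    degraded = ref.copy()
    records = []
    calls = []
    for p in gap_pos:
        true_base = ref[p] if ref[p] in "ACGT" else "A"
        degraded[p] = "N"
        q = float(rng.uniform(*quality_range))
        calls.append(ConsensusCall(int(p), str(true_base), q, depth))
        records.append((int(p), "N", str(true_base), q, "N-fill"))
    for p in err_pos:
        true_base = str(ref[p]) if ref[p] in "ACGT" else "A"
        wrong = str(rng.choice(_BASES[_BASES != true_base]))
        degraded[p] = wrong
        q = float(rng.uniform(*quality_range))
        calls.append(ConsensusCall(int(p), true_base, q, depth))
        records.append((int(p), wrong, true_base, q, "discrepant-revision"))
    truth = pd.DataFrame(
        records, columns=["position", "old_base", "new_base", "quality", "class"]
    ).sort_values("position", ignore_index=True)
    return ConsensusSim(
        "".join(degraded),
        ConsensusCallSet(sorted(calls, key=lambda c: c.position)),
        truth,
    )
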