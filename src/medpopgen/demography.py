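"""PSMC output post-processing and broad-sense heritability.

The pairwise sequentially Markovian coalescent emits scaled population
sizes lambda_k over scaled time intervals t_k together with the inferred
theta. Physical scaling uses N0 = theta / (4 * mu * s) with bin size s,
Ne = lambda * N0 and years = 2 * N0 * t * generation_years. Because
plausible generation times for this system range from well under a year to
a year, ``generation_years`` is a required explicit argument with no
default. Trajectories from many individuals are combined by sampling each
onto log10-time bins and summarizing the across-individual distribution.

Broad-sense heritability H^2 of a morphometric trait is the between-strain
sum of squares over the total sum of squares after dividing each measure
by its view's body length (lateral by L4, dorsal by D5), removing body
size as the dominant variance source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PsmcTrajectory",
    "parse_psmc_output",
    "scale_trajectory",
    "bin_and_combine",
    "broad_sense_heritability",
]


@dataclass
class PsmcTrajectory:
    """Final-round atomic intervals: scaled times t_k, scaled sizes lambda_k,
    and the scaling parameters theta0 (per bin) and rho0."""

    times: np.ndarray
    lambdas: np.ndarray
    theta0: float
    rho0: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.times.shape != self.lambdas.shape:
            raise ValueError("times and lambdas must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(self.lambdas <= 0):
            raise ValueError("scaled sizes must be positive")

    def to_text(self) -> str:
        """Render in the psmc output layout (one final round)."""
        lines = ["RD\t1", f"TR\t{self.theta0:g}\t{self.rho0:g}"]
        for k, (t, lam) in enumerate(zip(self.times, self.lambdas)):
            lines.append(f"RS\t{k}\t{t:g}\t{lam:g}\t0\t0\t0")
        lines.append("//")
        return "\n".join(lines) + "\n"


def parse_psmc_output(path) -> PsmcTrajectory:
    """Parse psmc text output, keeping the final round's atomic intervals."""
    rounds: list[dict] = []
    current: dict | None = None
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            tag = parts[0]
            if tag == "RD":
                current = {"times": [], "lambdas": [], "theta0": None, "rho0": None}
                rounds.append(current)
            elif tag == "TR" and current is not None:
                current["theta0"], current["rho0"] = float(parts[1]), float(parts[2])
            elif tag == "RS" and current is not None:
                current["times"].append(float(parts[2]))
                current["lambdas"].append(float(parts[3]))
    rounds = [r for r in rounds if r["times"] and r["theta0"] is not None]
    if not rounds:
        raise ValueError(f"no parsable psmc rounds in {path}")
    last = rounds[-1]
    return PsmcTrajectory(
        np.array(last["times"]), np.array(last["lambdas"]),
        last["theta0"], last["rho0"],
    )


def scale_trajectory(
    traj: PsmcTrajectory,
    generation_years: float,
    mutation_rate: float = 2.5e-8,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Physical (years, diploid Ne) series from a scaled trajectory.

    N0 = theta0 / (4 * mu * s); Ne = lambda * N0;
    years = 2 * N0 * t * generation_years. The transform is exactly
    invertible given the same parameters.
    """
    if generation_years <= 0 or mutation_rate <= 0 or bin_size <= 0:
        raise ValueError("generation_years, mutation_rate and bin_size must be positive")
    n0 = traj.theta0 / (4.0 * mutation_rate * bin_size)
    return pd.DataFrame(
        {
            "years": 2.0 * n0 * traj.times * generation_years,
            "Ne": traj.lambdas * n0,
        }
    )


def bin_and_combine(
    trajectories: list[pd.DataFrame], log10_bin_width: float = 0.1
) -> pd.DataFrame:
    """Combine per-individual scaled trajectories onto log10-time bins.

    Each trajectory is treated as a step function (Ne constant from one
    time point to the next) sampled at bin centers; the output summarizes
    the across-individual distribution per bin (median and quartiles).
    Bins before a trajectory's first positive time use its earliest Ne.
    """
    if not trajectories:
        raise ValueError("no trajectories to combine")
    lo = min(t.loc[t["years"] > 0, "years"].min() for t in trajectories)
    hi = max(t["years"].max() for t in trajectories)
    if not np.isfinite(lo) or hi <= 0:
        raise ValueError("trajectories contain no positive times")
    edges = np.arange(
        np.floor(np.log10(lo) / log10_bin_width) * log10_bin_width,
        np.ceil(np.log10(hi) / log10_bin_width) * log10_bin_width + log10_bin_width,
        log10_bin_width,
    )
    centers = (edges[:-1] + edges[1:]) / 2
    sampled = np.empty((len(trajectories), len(centers)))
    for i, t in enumerate(trajectories):
        years = t["years"].to_numpy()
        ne = t["Ne"].to_numpy()
        k = np.clip(np.searchsorted(years, 10.0**centers, side="right") - 1, 0,
                    len(ne) - 1)
        sampled[i] = ne[k]
    return pd.DataFrame(
        {
            "log10_years": centers,
            "years": 10.0**centers,
            "Ne_median": np.median(sampled, axis=0),
            "Ne_q25": np.quantile(sampled, 0.25, axis=0),
            "Ne_q75": np.quantile(sampled, 0.75, axis=0),
            "n_individuals": len(trajectories),
        }
    )


LATERAL = ("L1", "L2", "L3")
DORSAL = ("D1", "D2", "D3", "D4")


def broad_sense_heritability(
    table: pd.DataFrame, strain_column: str = "strain"
) -> pd.Series:
    """Broad-sense heritability per morphometric trait.

    Each lateral measure is divided by the lateral body length L4 and each
    dorsal measure by the dorsal body length D5; H^2 is then the
    between-strain sum of squares over the total sum of squares of the
    ratio in a one-way decomposition. Strains with fewer than two fish are
    excluded with a warning. H^2 lies in [0, 1] and is invariant to
    rescaling all measurements of a view.
    """
    counts = table[strain_column].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"excluding strains with a single fish: {small}")
        table = table[~table[strain_column].isin(small)]
    if table[strain_column].nunique() < 2:
        raise ValueError("need at least two strains with >= 2 fish each")
    out = {}
    for trait in LATERAL + DORSAL:
        if trait not in table.columns:
            continue
        body = table["L4"] if trait.startswith("L") else table["D5"]
        ratio = table[trait] / body
        grand = ratio.mean()
        ss_total = ((ratio - grand) ** 2).sum()
        ss_between = sum(
            len(grp) * (grp.mean() - grand) ** 2
            for _, grp in ratio.groupby(table[strain_column])
        )
        out[trait] = float(ss_between / ss_total) if ss_total > 0 else float("nan")
    return pd.Series(out, name="H2")
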