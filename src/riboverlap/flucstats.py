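"""Fluctuation-assay statistics for measuring protection experimentally.

Parallel cultures grow without selection, then each is plated on a
counter-selective medium (DOG, selecting galK loss-of-function mutants) and
on the same medium plus kanamycin (counting the mutants that kept the
overlapped resistance gene). The per-population *escape fraction* — the
fraction of costly-gene mutants that escaped the protection — is compared
between the overlap construct and an operon control with a one-sided
Mann-Whitney U test, with the rank-biserial correlation
``r = 1 - 2U/(n1 n2)`` as effect size. The expected number of mutational
events per culture (distinct from the mutant count — jackpot cultures carry
clones of early mutations) is estimated from the median mutant count with
the Jones median estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

LN2 = math.log(2)


@dataclass(frozen=True)
class PopulationCounts:
    """Colony counts for one independent culture."""

    population_id: str
    group: str  # "overlap" | "operon_control"
    strain: str = "WT"  # "WT" | "dMutS"
    dog_count: int = 0
    dog_dilution: float = 1.0
    dogkan_count: int = 0
    dogkan_dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.dog_count < 0 or self.dogkan_count < 0:
            raise ValueError("colony counts must be >= 0")


@dataclass
class FluctuationDataset:
    populations: list[PopulationCounts] = field(default_factory=list)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FluctuationDataset":
        pops = [
            PopulationCounts(
                population_id=str(r["population_id"]),
                group=str(r["group"]),
                strain=str(r.get("strain", "WT")),
                dog_count=int(r["dog_count"]),
                dog_dilution=float(r.get("dog_dilution", 1.0)),
                dogkan_count=int(r["dogkan_count"]),
                dogkan_dilution=float(r.get("dogkan_dilution", 1.0)),
            )
            for _, r in df.iterrows()
        ]
        return cls(pops)


@dataclass(frozen=True)
class TestResult:
    U: float
    p_one_sided: float
    n1: int
    n2: int
    r_rank_biserial: float
    method: str = "exact"


def escape_fraction(dataset: FluctuationDataset) -> pd.DataFrame:
    """Per-population fraction of costly-gene mutants escaping protection.

    fraction = (dog+kan count × its dilution) / (dog count × its dilution).
    Populations with zero DOG colonies are excluded with a warning;
    fractions above 1 are kept but flagged.
    """
    rows = []
    for pop in dataset.populations:
        dog = pop.dog_count * pop.dog_dilution
        if dog == 0:
            warnings.warn(
                f"population {pop.population_id}: no DOG colonies, excluded"
            )
            continue
        frac = (pop.dogkan_count * pop.dogkan_dilution) / dog
        rows.append(
            {
                "population_id": pop.population_id,
                "group": pop.group,
                "strain": pop.strain,
                "escape_fraction": frac,
                "flag_gt1": frac > 1.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["population_id", "group", "strain", "escape_fraction", "flag_gt1"],
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: number of (x_i, y_j) pairs with x_i > y_j, ties 1/2."""
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return float(u)


def mann_whitney_one_sided(x, y) -> TestResult:
    """One-sided Mann-Whitney U test of x stochastically smaller than y.

    Exact p by enumeration of all group assignments for n1 + n2 <= 12,
    normal approximation with tie correction otherwise. The rank-biserial
    effect size is filled from U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    u_obs = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; the test is uninformative")
        return TestResult(u_obs, 0.5, n1, n2, rank_biserial(u_obs, n1, n2), "degenerate")
    if n1 + n2 <= 12:
        idx = np.arange(n1 + n2)
        count = 0
        total = 0
        for chosen in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(chosen)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            count += u <= u_obs
            total += 1
        p = count / total
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    return TestResult(u_obs, float(p), n1, n2, rank_biserial(u_obs, n1, n2), method)


def rank_biserial(U: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation r = 1 - 2U/(n1 n2)."""
    if n1 * n2 == 0:
        raise ValueError("group sizes must be positive")
    if not 0 <= U <= n1 * n2:
        raise ValueError(f"U={U} outside [0, {n1 * n2}]")
    return 1.0 - 2.0 * U / (n1 * n2)


def jones_median_estimator(mutant_counts) -> float:
    """Expected mutational events per culture from the median mutant count.

    Uses the median-based closed form m = (r̃ - ln 2)/(ln r̃ - ln ln 2),
    where r̃ is the sample median mutant count. Zero-only samples give 0.
    """
    counts = np.asarray(mutant_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("mutant_counts must be nonempty")
    if np.any(counts < 0):
        raise ValueError("mutant counts must be >= 0")
    r = float(np.median(counts))
    if r <= 0:
        return 0.0
    if abs(r - LN2) < 1e-9:
        return LN2
    return max(0.0, (r - LN2) / (math.log(r) - math.log(LN2)))


def lea_coulson_median_estimator(median_count: float) -> float:
    """Numeric Lea-Coulson solution of r̃/m - ln(m) = 1.24 for m.

    The classic implicit median equation of the Luria-Delbrück
    distribution; independent of the Jones closed form.
    """
    r = float(median_count)
    if r <= 0:
        return 0.0
    f = lambda m: r / m - math.log(m) - 1.24
    lo = 1e-9
    hi = max(r, 1.0)
    while f(hi) > 0:
        hi *= 2
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def avoided_mutation_summary(dataset: FluctuationDataset) -> dict:
    """Fraction of mutations avoided by the overlap, per strain.

    Computed as 1 - overlap/control escape fraction, with both the
    median-based (matching the nonparametric test) and mean-based variants.
    """
    frac = escape_fraction(dataset)
    out = {}
    for strain, sub in frac.groupby("strain"):
        ov = sub.loc[sub["group"] == "overlap", "escape_fraction"]
        ct = sub.loc[sub["group"] == "operon_control", "escape_fraction"]
        if len(ov) == 0 or len(ct) == 0:
            continue
        entry = {}
        if ct.median() > 0:
            entry["avoided_median"] = 1.0 - ov.median() / ct.median()
        if ct.mean() > 0:
            entry["avoided_mean"] = 1.0 - ov.mean() / ct.mean()
        out[strain] = entry
    return out


def analyze(dataset: FluctuationDataset, direction: str = "overlap_lower") -> dict:
    """Full fluctuation-assay report: fractions, tests, Jones estimates."""
    frac = escape_fraction(dataset)
    report: dict = {"escape_fractions": frac.to_dict(orient="records")}
    report["avoided"] = avoided_mutation_summary(dataset)
    report["tests"] = {}
    report["jones"] = {}
    for strain, sub in frac.groupby("strain"):
        ov = sub.loc[sub["group"] == "overlap", "escape_fraction"].to_numpy()
        ct = sub.loc[sub["group"] == "operon_control", "escape_fraction"].to_numpy()
        if len(ov) and len(ct):
            x, y = (ov, ct) if direction == "overlap_lower" else (ct, ov)
            t = mann_whitney_one_sided(x, y)
            report["tests"][strain] = {
                "U": t.U,
                "p_one_sided": t.p_one_sided,
                "n1": t.n1,
                "n2": t.n2,
                "r_rank_biserial": t.r_rank_biserial,
                "method": t.method,
            }
    for (strain, group), _ in frac.groupby(["strain", "group"]):
        counts = [
            p.dogkan_count
            for p in dataset.populations
            if p.group == group and p.strain == strain
        ]
        if counts:
            report["jones"][f"{strain}/{group}"] = jones_median_estimator(counts)
    return report
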