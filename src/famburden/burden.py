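"""Genetic Burden Score (GBS) computation and within-family statistics.

The GBS of individual *i* is the unweighted sum of risk-allele dosages
G_ij in {0, 1, 2} over a fixed candidate-gene panel:

    GBS_i = sum_j G_ij

It is a within-family comparative score — not a calibrated risk, not a
disease probability, and not comparable to population polygenic-score
percentiles.  All statistics here are computed at full precision; rounding
(half-up, 1 decimal by default) happens only at display time.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import GenotypeMatrix, VariantPanel, risk_dosage
from .pedigree import Pedigree, assign_generations


class BurdenError(ValueError):
    pass


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of the reported statistics)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Burden table
# ---------------------------------------------------------------------------


class BurdenTable:
    """Per-individual, per-gene risk-allele counts plus totals.

    Wraps an individuals x genes integer DataFrame with a ``total`` column;
    the decomposition identity ``total == sum(per-gene)`` holds exactly.
    """

    def __init__(self, counts: pd.DataFrame, snps_per_gene: Mapping[str, int]):
        self.genes = list(counts.columns)
        self.snps_per_gene = dict(snps_per_gene)
        self.counts = counts.astype(int)
        self.totals = self.counts.sum(axis=1)

    @property
    def individuals(self) -> list[str]:
        return list(self.counts.index)

    def total(self, individual: str) -> int:
        return int(self.totals.loc[individual])

    def gene_count(self, individual: str, gene: str) -> int:
        return int(self.counts.loc[individual, gene])

    def gene_means(self) -> dict[str, float]:
        return {g: float(self.counts[g].mean()) for g in self.genes}

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        df["total"] = self.totals
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="individual_id")

    @classmethod
    def from_totals(
        cls, totals: Mapping[str, int], gene_counts: pd.DataFrame | None = None
    ) -> "BurdenTable":
        """Build a totals-only table (single pseudo-gene) from known GBS values."""
        if gene_counts is not None:
            return cls(gene_counts, {g: 0 for g in gene_counts.columns})
        df = pd.DataFrame({"ALL": pd.Series(totals)})
        return cls(df, {"ALL": 0})


def compute_gbs(gm: GenotypeMatrix, panel: VariantPanel) -> BurdenTable:
    """Sum risk-allele dosages per gene and in total for every sample.

    Requires a QC-passed panel: a missing call among the scored samples is a
    contract violation and raises.
    """
    genes = panel.genes
    data = {g: [0] * len(gm.samples) for g in genes}
    for r in panel:
        for i, s in enumerate(gm.samples):
            call = gm.call(s, r.rsid)
            if call is None:
                raise BurdenError(
                    f"missing call for {s}/{r.rsid}: run QC before scoring"
                )
            data[r.gene][i] += risk_dosage(call, r)
    counts = pd.DataFrame(data, index=list(gm.samples), columns=genes)
    return BurdenTable(counts, panel.per_gene_counts())


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float | None  # sample SD (n-1); undefined for n == 1
    min: float
    max: float

    def display(self, decimals: int = 1) -> str:
        mean = round_half_up(self.mean, decimals)
        if self.sd is None:
            return f"{self.label}: n={self.n}, mean {mean} (single value)"
        sd = round_half_up(self.sd, decimals)
        rng = (
            f"{self.min:g}-{self.max:g}"
        )
        return f"{self.label}: n={self.n}, mean {mean} ± {sd}, range: {rng}"


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean, sample SD (n-1 denominator), min and max of a group of values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise BurdenError("cannot summarize an empty group")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return GroupSummary(
        label=label,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
    )


def relative_discordance(a: float, b: float) -> tuple[float, float]:
    """Absolute difference and percent difference relative to the smaller value."""
    if a <= 0 or b <= 0:
        raise BurdenError("relative discordance requires positive totals")
    delta = abs(a - b)
    return float(delta), float(delta / min(a, b) * 100.0)


def gene_deltas(bt: BurdenTable, id_a: str, id_b: str) -> pd.DataFrame:
    """Signed (b - a) and absolute per-gene differences between two individuals.

    The signed deltas sum exactly to total(b) - total(a).
    """
    for iid in (id_a, id_b):
        if iid not in bt.counts.index:
            raise BurdenError(f"unknown individual {iid!r}")
    signed = bt.counts.loc[id_b] - bt.counts.loc[id_a]
    return pd.DataFrame({"signed_delta": signed, "abs_delta": signed.abs()})


def contribution_percentages(
    gene_means: Mapping[str, float], total_mean: float
) -> dict[str, float]:
    """Each gene's mean count as a percentage of the mean total burden."""
    if total_mean <= 0:
        raise BurdenError("total mean must be positive")
    return {g: float(m) / float(total_mean) * 100.0 for g, m in gene_means.items()}


@dataclass(frozen=True)
class CarrierComparison:
    carriers: GroupSummary
    non_carriers: GroupSummary
    mean_difference: float  # carrier mean - non-carrier mean, full precision


def carrier_comparison(
    bt: BurdenTable, carrier_flags: Mapping[str, bool]
) -> CarrierComparison:
    """Compare total GBS between e4 carriers and non-carriers."""
    carriers = [bt.total(i) for i in bt.individuals if carrier_flags.get(i)]
    noncar = [bt.total(i) for i in bt.individuals if not carrier_flags.get(i)]
    if not carriers or not noncar:
        raise BurdenError("both carrier groups must be non-empty")
    cs = summarize(carriers, "e4 carriers")
    ns = summarize(noncar, "non-carriers")
    return CarrierComparison(cs, ns, cs.mean - ns.mean)


def generation_summary(bt: BurdenTable, ped: Pedigree) -> list[GroupSummary]:
    """One :class:`GroupSummary` of total GBS per generation, in order."""
    gens = assign_generations(ped)
    missing = [i for i in bt.individuals if i not in gens]
    if missing:
        raise BurdenError(f"scored individual(s) without generation: {missing}")
    by_gen: dict[int, list[int]] = {}
    for iid in bt.individuals:
        by_gen.setdefault(gens[iid], []).append(bt.total(iid))
    return [
        summarize(by_gen[g], f"Generation {g}") for g in sorted(by_gen)
    ]


# ---------------------------------------------------------------------------
# Familial clustering and trends
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    icc: float
    msb: float  # between-group mean square
    msw: float  # within-group mean square
    k0: float  # average group size


def icc_oneway(values: Sequence[float], groups: Sequence[object]) -> ICCResult:
    """ICC(1): one-way random-effects intraclass correlation.

    ICC(1) = (MSB - MSW) / (MSB + (k0 - 1) * MSW), with the usual unequal-
    group-size correction k0 = (N - sum(n_g^2)/N) / (a - 1), which reduces to
    the common group size when groups are balanced.
    """
    s = pd.Series(np.asarray(values, dtype=float), index=list(groups))
    sizes = s.groupby(level=0).size()
    if (sizes == 0).any() or len(sizes) < 2:
        raise BurdenError("need >= 2 groups, each with >= 1 observation")
    n_total = int(len(s))
    a = int(len(sizes))
    grand = s.mean()
    group_means = s.groupby(level=0).mean()
    ssb = float((sizes * (group_means - grand) ** 2).sum())
    ssw = float(((s - group_means.loc[s.index].to_numpy()) ** 2).sum())
    msb = ssb / (a - 1)
    dfw = n_total - a
    if dfw == 0:
        raise BurdenError("no within-group degrees of freedom")
    msw = ssw / dfw
    k0 = (n_total - float((sizes**2).sum()) / n_total) / (a - 1)
    icc = (msb - msw) / (msb + (k0 - 1) * msw)
    return ICCResult(icc=float(icc), msb=msb, msw=msw, k0=float(k0))


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    r: float


def generation_trend(
    values: Sequence[float], generations: Sequence[float]
) -> TrendResult:
    """OLS of burden on generation code (ordinal: 1, 2, 3, ...)."""
    x = np.asarray(generations, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise BurdenError("need >= 2 distinct generation values")
    if np.allclose(y, y[0]):
        # constant response: slope and correlation are exactly zero
        return TrendResult(slope=0.0, intercept=float(y[0]), r=0.0)
    res = sps.linregress(x, y)
    return TrendResult(slope=float(res.slope), intercept=float(res.intercept), r=float(res.rvalue))
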