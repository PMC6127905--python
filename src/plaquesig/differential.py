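"""Per-gene differential screening and the plug-in FDR estimate.

The screen is the classical one: an equal-variance two-sample Student's t
per gene on log10 ratios (two-sided p from the t distribution with
n_a + n_b - 2 degrees of freedom), or a Pearson correlation of expression
against age in months. Comparison-level confidence is the plug-in FDR: the
expected false positives at cutoff alpha (detected genes x alpha) over the
observed significant count, rounded half away from zero to an integer
percentage and capped at 100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from plaquesig.io import GeneSet, ValidationError
from plaquesig.preprocess import RatioMatrix

logger = logging.getLogger(__name__)


def _log10_view(ratios) -> pd.DataFrame:
    if isinstance(ratios, RatioMatrix):
        return ratios.log10
    return pd.DataFrame(ratios)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (3.5 -> 4, -3.5 -> -4)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class DGEResult:
    """Per-gene t screen output for one two-group comparison.

    ``table`` columns: t, p, mean_a, mean_b (mean log10 ratios),
    fold_change (linear, group A over group B), direction (up/down).
    """

    table: pd.DataFrame
    group_a: str = "A"
    group_b: str = "B"
    n_a: int = 0
    n_b: int = 0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def significant(self, alpha: float = 0.001) -> pd.DataFrame:
        return self.table[self.table["p"] < alpha]


@dataclass
class AgeCorrResult:
    """Per-gene Pearson correlation of log10 ratio against age in months."""

    rho: pd.Series

    def passing(self, rho_cut: float = 0.75) -> list[str]:
        """Genes with |rho| strictly above the cutoff."""
        return self.rho.index[self.rho.abs() > rho_cut].tolist()


@dataclass
class FdrEstimate:
    """Plug-in FDR at a p-value cutoff, as a capped integer percentage."""

    alpha: float
    n_detected: int
    n_significant: int
    fdr_percent: int


def ttest_genes(ratios, group_a: Sequence[str], group_b: Sequence[str],
                group_a_label: str = "A", group_b_label: str = "B") -> DGEResult:
    """Equal-variance Student's t per gene on the log10 ratio view.

    Fold change is 10^(mean_a - mean_b); direction is the sign of the mean
    difference (ties count as up). Genes with zero pooled variance are
    reported as t = 0, p = 1 so uninformative rows cannot reach
    significance through division artifacts.
    """
    values = _log10_view(ratios)
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 samples for the t test")
    for s in group_a + group_b:
        if s not in values.columns:
            raise ValidationError(f"sample {s!r} absent from the ratio matrix")
    a = values[group_a].to_numpy(dtype=float)
    b = values[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss_a = ((a - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((b - mean_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    pooled = (ss_a + ss_b) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    table = pd.DataFrame(
        {"t": t, "p": p, "mean_a": mean_a, "mean_b": mean_b,
         "fold_change": np.power(10.0, diff),
         "direction": np.where(diff >= 0, "up", "down")},
        index=values.index)
    return DGEResult(table, group_a_label, group_b_label, na, nb)


def pearson_age(ratios, samples) -> AgeCorrResult:
    """Pearson correlation of each gene's log10 ratio against age_months.

    Constant genes (zero variance) get rho = 0 with a logged note, since
    the sample correlation is 0/0 there. A constant age vector is an error.
    """
    values = _log10_view(ratios)
    ages = samples.data.loc[values.columns, "age_months"].to_numpy(dtype=float)
    if len(values.columns) < 3:
        raise ValidationError("need >= 3 samples for the age correlation")
    if np.ptp(ages) == 0:
        raise ValidationError("age vector is constant; correlation undefined")
    x = values.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    ac = ages - ages.mean()
    denom_gene = np.sqrt((xc ** 2).sum(axis=1))
    denom_age = float(np.sqrt((ac ** 2).sum()))
    constant = denom_gene == 0
    if constant.any():
        logger.info("pearson_age: %d constant gene(s) assigned rho = 0",
                    int(constant.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(constant, 0.0,
                       (xc @ ac) / np.where(constant, 1.0, denom_gene) / denom_age)
    rho = np.clip(rho, -1.0, 1.0)
    return AgeCorrResult(pd.Series(rho, index=values.index, name="rho"))


def plugin_fdr(n_detected: int, alpha: float, n_significant: int) -> FdrEstimate:
    """Expected false positives over observed positives, as a percentage.

    fdr% = min(100, round(100 * n_detected * alpha / n_significant)), with
    rounding half away from zero; defined as 100 when nothing is
    significant.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if n_significant > n_detected:
        raise ValidationError(
            f"n_significant ({n_significant}) exceeds n_detected ({n_detected})")
    if n_significant < 0 or n_detected < 0:
        raise ValidationError("counts must be non-negative")
    if n_significant == 0:
        percent = 100
    else:
        percent = min(100, round_half_away(100.0 * n_detected * alpha / n_significant))
    return FdrEstimate(alpha, n_detected, n_significant, percent)


@dataclass
class SignificantSets:
    """Direction-partitioned significant genes; empty partitions are absent."""

    up: GeneSet | None
    down: GeneSet | None
    percent_up: int | None

    @property
    def n_up(self) -> int:
        return len(self.up) if self.up else 0

    @property
    def n_down(self) -> int:
        return len(self.down) if self.down else 0


def significant_sets(result: DGEResult, alpha: float = 0.001,
                     species: str = "mouse") -> SignificantSets:
    """Partition genes with p < alpha by direction of change.

    percent_up = round(100 * |up| / (|up| + |down|)), half away from zero;
    None when nothing is significant.
    """
    sig = result.significant(alpha)
    up = frozenset(sig.index[sig["direction"] == "up"])
    down = frozenset(sig.index[sig["direction"] == "down"])
    total = len(up) + len(down)
    return SignificantSets(
        up=GeneSet(f"{result.group_a}_vs_{result.group_b}_up", up,
                   species=species, direction="up") if up else None,
        down=GeneSet(f"{result.group_a}_vs_{result.group_b}_down", down,
                     species=species, direction="down") if down else None,
        percent_up=round_half_away(100.0 * len(up) / total) if total else None,
    )


@dataclass
class UnionSignature:
    """Union of per-age significant genes with majority-sign directions."""

    members: GeneSet
    directions: pd.Series  # gene -> "up"/"down"

    def directional_set(self, direction: str) -> GeneSet:
        genes = frozenset(self.directions.index[self.directions == direction])
        return GeneSet(f"{self.members.name}_{direction}", genes,
                       species=self.members.species, direction=direction)


def union_over_ages(results: Mapping[float, DGEResult] | Sequence[DGEResult],
                    alpha: float = 0.001, name: str = "union",
                    species: str = "mouse") -> UnionSignature:
    """Genes significant (p < alpha) at one or more ages.

    Direction is assigned by the majority sign of the mean difference across
    the ages at which the gene was significant; ties go to up (logged).
    All results must share one gene universe.
    """
    result_list = list(results.values()) if isinstance(results, Mapping) else list(results)
    if not result_list:
        raise ValidationError("need at least one per-age result")
    universe = result_list[0].table.index
    for r in result_list[1:]:
        if not r.table.index.equals(universe):
            raise ValidationError("per-age results have inconsistent gene universes")
    votes: dict[str, int] = {}
    for r in result_list:
        sig = r.significant(alpha)
        for gene, direction in sig["direction"].items():
            votes[gene] = votes.get(gene, 0) + (1 if direction == "up" else -1)
    n_ties = sum(1 for v in votes.values() if v == 0)
    if n_ties:
        logger.info("union_over_ages: %d gene(s) with tied direction assigned up", n_ties)
    directions = pd.Series({g: ("up" if v >= 0 else "down") for g, v in votes.items()},
                           dtype=object)
    members = GeneSet(name, frozenset(votes), species=species)
    return UnionSignature(members, directions)
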