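"""Negative-binomial cohort simulator with ground truth.

Counts follow the log-linear mean model

    mu_gs = lib_s * 2^( b_g + a_g * age_s + t_g * age_s * [genotype == TG]
                        + d_g * [tissue == plaque_niche] )

with ``b_g`` a gene baseline (log2 scale), ``a_g`` an aging slope per month,
``t_g`` a transgene-only slope per month, ``d_g`` a plaque-niche log2 fold
change, and ``lib_s`` a per-sample library-size factor. Counts are drawn
negative-binomial with a size-style dispersion ``r`` (variance
mu + mu^2 / r); one genome-wide value, overridable per module.

Genes belong to exactly one module: ``null`` (no effect), ``aging``,
``progressive_tg`` (transgene-dependent age ramp), ``niche`` (plaque-niche
fold change only) or ``progressive_and_niche`` (both, modelling the nesting
of the plaque-niche signature inside the progression signature). The default
designs mirror the study's printed cohorts: two transgenic strains sampled
across five ages with group sizes 3-7, and a laser-capture design of
12 plaque-niche vs 12 non-plaque samples at 6 months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from plaquesig.io import (
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    SampleTable,
    ValidationError,
)

MODULE_NAMES = ("aging", "progressive_tg", "niche", "progressive_and_niche")

# Printed cohort designs: (strain, genotype, age_months, tissue_class, n).
TGCRND8_CORTEX_DESIGN = [
    ("TgCRND8", "WT", 1.5, "whole_cortex", 6),
    ("TgCRND8", "WT", 3.0, "whole_cortex", 6),
    ("TgCRND8", "WT", 4.5, "whole_cortex", 4),
    ("TgCRND8", "WT", 6.0, "whole_cortex", 5),
    ("TgCRND8", "WT", 10.0, "whole_cortex", 6),
    ("TgCRND8", "TG", 1.5, "whole_cortex", 4),
    ("TgCRND8", "TG", 3.0, "whole_cortex", 6),
    ("TgCRND8", "TG", 4.5, "whole_cortex", 3),
    ("TgCRND8", "TG", 6.0, "whole_cortex", 5),
    ("TgCRND8", "TG", 10.0, "whole_cortex", 7),
]
TG2576_CORTEX_DESIGN = [
    (strain, genotype, age, "whole_cortex", 4)
    for age in (3.0, 6.0, 9.0, 12.0, 15.0)
    for strain, genotype in (("Tg2576", "WT"), ("Tg2576", "TG"))
]
LCM_DESIGN = [
    ("TgCRND8", "TG", 6.0, "plaque_niche", 12),
    ("TgCRND8", "TG", 6.0, "non_plaque", 12),
]


@dataclass(frozen=True)
class ModuleSpec:
    """Size and effect parameters for one gene module.

    ``aging_slope`` and ``tg_slope`` are log2 units per month;
    ``niche_log2fc`` is a (low, high) range from which per-gene plaque-niche
    log2 fold changes are drawn uniformly. ``dispersion`` overrides the
    genome-wide negative-binomial size for this module's genes.
    """

    n_genes: int
    aging_slope: float = 0.0
    tg_slope: float = 0.0
    niche_log2fc: tuple[float, float] = (0.0, 0.0)
    dispersion: float | None = None


@dataclass(frozen=True)
class SimConfig:
    """Full cohort-simulation configuration.

    ``design`` rows are (strain, genotype, age_months, tissue_class,
    n_samples). Module gene counts must sum to <= ``n_genes``; the remainder
    is the null module.
    """

    n_genes: int = 12500
    baseline_log2_mean_mu: float = 5.0
    baseline_log2_mean_sd: float = 2.0
    dispersion: float = 10.0
    library_size_log2_sd: float = 0.15
    design: tuple = ()
    modules: Mapping[str, ModuleSpec] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        unknown = set(self.modules) - set(MODULE_NAMES)
        if unknown:
            raise ValidationError(f"unknown module names: {sorted(unknown)}")
        total = sum(m.n_genes for m in self.modules.values())
        if total > self.n_genes:
            raise ValidationError(
                f"module gene counts sum to {total} > n_genes = {self.n_genes}"
            )
        if not self.design:
            raise ValidationError("design must contain at least one group")
        for row in self.design:
            if len(row) != 5 or row[4] <= 0:
                raise ValidationError(f"bad design row: {row!r}")
        object.__setattr__(self, "design", tuple(tuple(r) for r in self.design))
        object.__setattr__(self, "modules", dict(self.modules))

    @staticmethod
    def whole_cortex_default(strain: str = "TgCRND8", n_genes: int = 15000,
                             seed: int = 0, **overrides) -> "SimConfig":
        """The whole-cortex cohort: five ages, WT vs TG, printed group sizes.

        A transgene-dependent progressive module ramps at 0.2 log2/month
        (about 4x by 10 months); a small aging module drifts in both
        genotypes; the progressive_and_niche module carries the same
        transgene ramp so the cortex and plaque-niche signatures nest.
        """
        design = TGCRND8_CORTEX_DESIGN if strain == "TgCRND8" else TG2576_CORTEX_DESIGN
        modules = {
            "aging": ModuleSpec(100, aging_slope=0.12),
            "progressive_tg": ModuleSpec(296, tg_slope=0.2),
            "progressive_and_niche": ModuleSpec(
                46, tg_slope=0.2, niche_log2fc=(math.log2(1.5), math.log2(8.0))),
            "niche": ModuleSpec(21, niche_log2fc=(math.log2(1.5), math.log2(8.0))),
        }
        cfg = dict(n_genes=n_genes, design=tuple(design), modules=modules, seed=seed)
        cfg.update(overrides)
        return SimConfig(**cfg)

    @staticmethod
    def lcm_default(n_genes: int = 12500, seed: int = 0, **overrides) -> "SimConfig":
        """The laser-capture design: 12 plaque-niche vs 12 non-plaque at 6 mo.

        Niche fold changes span 1.5-8x on the linear scale; the
        progressive_and_niche module makes the niche signature largely
        nested inside the cortex progression signature, in the proportions
        of the published Venn (296 / 46 / 21).
        """
        modules = {
            "progressive_tg": ModuleSpec(296, tg_slope=0.2),
            "progressive_and_niche": ModuleSpec(
                46, tg_slope=0.2, niche_log2fc=(math.log2(1.5), math.log2(8.0))),
            "niche": ModuleSpec(21, niche_log2fc=(math.log2(1.5), math.log2(8.0))),
        }
        cfg = dict(n_genes=n_genes, design=tuple(LCM_DESIGN), modules=modules,
                   dispersion=20.0, seed=seed)
        cfg.update(overrides)
        return SimConfig(**cfg)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Per-gene module labels and realized effects; per-sample library factors."""

    genes: pd.DataFrame  # index gene_id; module, aging_slope, tg_slope, niche_log2fc
    library_factors: pd.Series  # index sample_id

    def module_members(self, module: str) -> list[str]:
        return self.genes.index[self.genes["module"] == module].tolist()


def _sample_frame(design: Sequence[tuple]) -> pd.DataFrame:
    rows = []
    counter = 0
    for strain, genotype, age, tissue, n in design:
        for _ in range(int(n)):
            counter += 1
            rows.append((f"s{counter:03d}", strain, genotype, float(age), tissue))
    return pd.DataFrame(rows, columns=["sample_id", "strain", "genotype",
                                       "age_months", "tissue_class"])


def simulate_cohort(config: SimConfig) -> tuple[CountMatrix, SampleTable, SimTruth]:
    """Draw a count cohort under the configured design; seed-deterministic.

    Returns the count matrix, the matching sample table and the ground
    truth (module labels, realized per-gene effects, library factors).
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(1, n_genes + 1)]

    # Module assignment: contiguous blocks in MODULE_NAMES order, then null.
    module = np.array(["null"] * n_genes, dtype=object)
    aging_slope = np.zeros(n_genes)
    tg_slope = np.zeros(n_genes)
    niche_l2fc = np.zeros(n_genes)
    dispersion = np.full(n_genes, float(config.dispersion))
    cursor = 0
    for name in MODULE_NAMES:
        spec = config.modules.get(name)
        if spec is None or spec.n_genes == 0:
            continue
        sl = slice(cursor, cursor + spec.n_genes)
        module[sl] = name
        aging_slope[sl] = spec.aging_slope
        tg_slope[sl] = spec.tg_slope
        lo, hi = spec.niche_log2fc
        if lo or hi:
            niche_l2fc[sl] = rng.uniform(lo, hi, spec.n_genes) if hi > lo else lo
        if spec.dispersion is not None:
            dispersion[sl] = spec.dispersion
        cursor += spec.n_genes

    baseline = rng.normal(config.baseline_log2_mean_mu,
                          config.baseline_log2_mean_sd, n_genes)

    samples = _sample_frame(config.design)
    n_samples = len(samples)
    lib = np.exp2(rng.normal(0.0, config.library_size_log2_sd, n_samples))

    age = samples["age_months"].to_numpy()
    is_tg = (samples["genotype"] == "TG").to_numpy(dtype=float)
    is_niche = (samples["tissue_class"] == "plaque_niche").to_numpy(dtype=float)

    log2_mu = (baseline[:, None]
               + aging_slope[:, None] * age[None, :]
               + tg_slope[:, None] * (age * is_tg)[None, :]
               + niche_l2fc[:, None] * is_niche[None, :])
    mu = lib[None, :] * np.exp2(log2_mu)

    r = dispersion[:, None]
    counts = rng.negative_binomial(r, r / (r + mu))

    count_frame = pd.DataFrame(counts, index=gene_ids,
                               columns=samples["sample_id"].tolist())
    truth_frame = pd.DataFrame(
        {"module": module,
         "baseline_log2": baseline,
         "aging_slope": aging_slope,
         "tg_slope": tg_slope,
         "niche_log2fc": niche_l2fc},
        index=pd.Index(gene_ids, name="gene_id"))
    truth = SimTruth(truth_frame,
                     pd.Series(lib, index=count_frame.columns, name="library_factor"))
    return CountMatrix(count_frame), SampleTable(samples), truth


def truth_sets(truth: SimTruth, species: str = "mouse") -> GeneSetCollection:
    """Ground-truth gene sets, one per non-empty module.

    Empty modules are omitted rather than emitted empty. Convenience union
    sets ``progressive_all`` (progressive_tg + progressive_and_niche) and
    ``niche_all`` (niche + progressive_and_niche) are appended when both
    constituents exist, because those unions are what the cortex-progression
    and plaque-niche screens each see as truly perturbed.
    """
    sets = []
    by_module: dict[str, frozenset] = {}
    for name in ("null",) + MODULE_NAMES:
        members = frozenset(truth.module_members(name))
        if members:
            by_module[name] = members
            sets.append(GeneSet(name, members, species=species,
                                description=f"simulated {name} module"))
    shared = by_module.get("progressive_and_niche", frozenset())
    if shared:
        if "progressive_tg" in by_module:
            sets.append(GeneSet("progressive_all",
                                by_module["progressive_tg"] | shared,
                                species=species,
                                description="all transgene-progressive genes"))
        if "niche" in by_module:
            sets.append(GeneSet("niche_all", by_module["niche"] | shared,
                                species=species,
                                description="all plaque-niche-enriched genes"))
    return GeneSetCollection("truth", sets)
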