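"""Signature scoring, ortholog projection and threshold-defined signatures.

A signature score summarizes a gene set per sample as the mean of log10
ratios over the set's genes, with the standard deviation taken across genes
within the sample (the error bar describes within-set spread, not
between-sample spread). Threshold signatures — the DAM-style definition
"fold change > 1.5 and p < 1e-5" — use strict inequalities. Ortholog
projection translates a set between species through a curated mapping,
expanding many-to-many entries and deduplicating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from plaquesig.differential import DGEResult
from plaquesig.io import GeneSet, GeneSetCollection, OrthologMap, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SignatureScore:
    """Per-sample mean +/- SD of log10 ratios over a gene set."""

    table: pd.DataFrame  # index sample_id; columns mean, sd
    set_name: str
    n_genes_used: int
    missing: tuple = ()

    @property
    def mean(self) -> pd.Series:
        return self.table["mean"]

    @property
    def sd(self) -> pd.Series:
        return self.table["sd"]


def signature_score(ratios, gene_set: GeneSet) -> SignatureScore:
    """Score a gene set: per-sample mean and across-gene sample SD.

    SD uses the n-1 denominator and is 0 for single-gene sets. Set members
    absent from the matrix are dropped and logged; a set with no members
    present is an error.
    """
    values = ratios.log10 if hasattr(ratios, "log10") else pd.DataFrame(ratios)
    if len(gene_set) == 0:
        raise ValidationError(f"gene set {gene_set.name!r} is empty")
    present = [g for g in values.index if g in gene_set.members]
    missing = sorted(gene_set.members - set(present))
    if not present:
        raise ValidationError(
            f"no members of set {gene_set.name!r} present in the matrix")
    if missing:
        logger.info("signature_score(%s): %d member(s) absent from matrix",
                    gene_set.name, len(missing))
    sub = values.loc[present]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1).fillna(0.0) if len(present) > 1 else mean * 0.0
    table = pd.DataFrame({"mean": mean, "sd": sd})
    table.index.name = "sample_id"
    return SignatureScore(table, gene_set.name, len(present), tuple(missing))


def project_orthologs(gene_set: GeneSet, omap: OrthologMap, target_species: str,
                      normalize_case: bool = False) -> GeneSet:
    """Project a gene set to another species through an ortholog map.

    Many-to-many entries expand to all targets and are deduplicated by the
    set semantics. Unmapped members are dropped and their count logged.
    ``normalize_case`` upper-cases both set members and map source ids
    before matching (symbol casing differs between mouse and human).
    """
    if gene_set.species != omap.source_species:
        raise ValidationError(
            f"set species {gene_set.species!r} does not match map source "
            f"{omap.source_species!r}")
    if target_species != omap.target_species:
        raise ValidationError(
            f"requested target {target_species!r} does not match map target "
            f"{omap.target_species!r}")
    mapping = omap.as_dict()
    if normalize_case:
        upper: dict[str, list[str]] = {}
        for src, targets in mapping.items():
            upper.setdefault(src.upper(), []).extend(targets)
        mapping = upper
    mapped: set[str] = set()
    n_unmapped = 0
    for member in gene_set.members:
        key = member.upper() if normalize_case else member
        targets = mapping.get(key)
        if targets:
            mapped.update(targets)
        else:
            n_unmapped += 1
    if n_unmapped:
        logger.info("project_orthologs(%s): %d member(s) unmapped, dropped",
                    gene_set.name, n_unmapped)
    return GeneSet(gene_set.name, frozenset(mapped), species=target_species,
                   direction=gene_set.direction, description=gene_set.description)


def threshold_signature(table: pd.DataFrame, fc_min: float, p_max: float,
                        name: str = "threshold_signature",
                        species: str = "generic") -> GeneSet:
    """Genes with fold change > fc_min and p < p_max (both strict).

    ``table`` must carry ``fold_change`` and ``p`` columns indexed by gene.
    This is the generic form of published threshold definitions such as the
    disease-associated-microglia set (> 1.5 fold, p < 1e-5).
    """
    if fc_min <= 0:
        raise ValidationError(f"fc_min must be > 0, got {fc_min}")
    for col in ("fold_change", "p"):
        if col not in table.columns:
            raise ValidationError(f"table lacks required column {col!r}")
    keep = (table["fold_change"] > fc_min) & (table["p"] < p_max)
    return GeneSet(name, frozenset(table.index[keep]), species=species,
                   direction="up")


@dataclass
class MarkerPanelReport:
    """Per-panel DE lookups with significance flags and significant-up counts."""

    tables: dict  # panel name -> DataFrame (gene, fold_change, p, direction, significant, detected)
    n_significant_up: dict  # panel name -> int
    alpha: float


def marker_panel_report(dge: DGEResult, panels: GeneSetCollection,
                        alpha: float = 0.001) -> MarkerPanelReport:
    """Look up DE results for each marker panel and count significant genes.

    Panel members absent from the DE universe appear as not-detected rows
    rather than errors. The headline count per panel is the number of
    members significantly upregulated at ``alpha``.
    """
    if len(panels) == 0:
        raise ValidationError("marker panel collection is empty")
    tables: dict[str, pd.DataFrame] = {}
    counts: dict[str, int] = {}
    universe = set(dge.table.index)
    for panel in panels:
        rows = []
        for gene in sorted(panel.members):
            if gene in universe:
                rec = dge.table.loc[gene]
                rows.append({
                    "gene": gene,
                    "fold_change": float(rec["fold_change"]),
                    "p": float(rec["p"]),
                    "direction": rec["direction"],
                    "significant": bool(rec["p"] < alpha),
                    "detected": True,
                })
            else:
                rows.append({"gene": gene, "fold_change": np.nan, "p": np.nan,
                             "direction": "", "significant": False,
                             "detected": False})
        frame = pd.DataFrame(rows).set_index("gene")
        tables[panel.name] = frame
        counts[panel.name] = int(
            (frame["significant"] & (frame["direction"] == "up")).sum())
    return MarkerPanelReport(tables, counts, alpha)
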