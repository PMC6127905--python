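"""Detection filtering, FPKM computation and reference-ratio normalization.

A gene is "detected" when at least one treatment group has >= ``min_count``
counts in at least ``group_fraction`` of its samples (both thresholds
inclusive). Abundances are ratioed per gene to the mean of a configured
reference group, with a small symmetric pseudocount so zeros stay finite on
the log10 scale used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from plaquesig.io import (
    AbundanceMatrix,
    CountMatrix,
    SampleTable,
    ValidationError,
)


@dataclass
class RatioMatrix:
    """Per-gene abundances ratioed to a reference-group mean.

    ``linear`` holds strictly positive ratios; ``log10`` is the elementwise
    log10 view used for testing, scoring and display.
    """

    linear: pd.DataFrame
    reference_group: str
    pseudocount: float

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if (self.linear.to_numpy() <= 0).any():
            raise ValidationError("ratio values must be strictly positive")

    @property
    def log10(self) -> pd.DataFrame:
        return np.log10(self.linear)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.linear.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.linear.columns)


def compute_fpkm(counts: CountMatrix,
                 gene_lengths: Mapping[str, float] | pd.Series) -> AbundanceMatrix:
    """Fragments per kilobase per million mapped fragments.

    FPKM_gs = 1e9 * count_gs / (libsize_s * length_g), with libsize the
    column sum of counts. Lengths are in bases and must cover every gene.
    """
    lengths = pd.Series(gene_lengths, dtype=float)
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise ValidationError(f"missing gene length(s) for: {missing[:10]}")
    lengths = lengths.loc[counts.gene_ids]
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be > 0")
    libsize = counts.data.sum(axis=0).astype(float)
    if (libsize <= 0).any():
        zero = libsize.index[libsize <= 0].tolist()
        raise ValidationError(f"zero library size in sample(s): {zero}")
    fpkm = 1e9 * counts.data.div(libsize, axis=1).div(lengths, axis=0)
    return AbundanceMatrix(fpkm)


def filter_detected(counts: CountMatrix, samples: SampleTable,
                    min_count: int = 10, group_fraction: float = 0.5) -> list[str]:
    """Genes detected in at least one treatment group, input order preserved.

    A gene passes in a group when the fraction of that group's samples with
    count >= ``min_count`` is >= ``group_fraction``.
    """
    samples.require_samples(counts.sample_ids)
    groups = {}
    for label, members in samples.groups().items():
        members = [s for s in members if s in counts.data.columns]
        if not members:
            continue
        groups[label] = members
    if not groups:
        raise ValidationError("no treatment group overlaps the count matrix")
    passing = np.zeros(len(counts.gene_ids), dtype=bool)
    values = counts.data
    for label, members in groups.items():
        frac = (values[members] >= min_count).sum(axis=1) / len(members)
        passing |= (frac >= group_fraction).to_numpy()
    return [g for g, keep in zip(counts.gene_ids, passing) if keep]


def ratio_to_reference(abundance: AbundanceMatrix, samples: SampleTable,
                       reference_group: str,
                       pseudocount: float = 0.01) -> RatioMatrix:
    """Ratio each gene to the mean of the reference group's samples.

    ratio_gs = (abundance_gs + eps) / mean_ref(abundance + eps). With the
    pseudocount applied symmetrically, the per-gene mean linear ratio over
    the reference samples is exactly 1.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    samples.require_samples(abundance.sample_ids)
    ref_samples = samples.samples_in_group(reference_group)
    ref_samples = [s for s in ref_samples if s in abundance.data.columns]
    if not ref_samples:
        raise ValidationError(
            f"reference group {reference_group!r} has no samples in the matrix")
    shifted = abundance.data + pseudocount
    ref_mean = shifted[ref_samples].mean(axis=1)
    linear = shifted.div(ref_mean, axis=0)
    return RatioMatrix(linear, reference_group, pseudocount)


def write_ratio_matrix(ratios: RatioMatrix, path_linear, path_log10=None,
                       comment: str | None = None) -> None:
    """Write the linear (and optionally log10) ratio views as TSV."""
    from plaquesig.io import write_matrix

    write_matrix(ratios.linear, path_linear, comment=comment)
    if path_log10 is not None:
        write_matrix(ratios.log10, path_log10, comment=comment)
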