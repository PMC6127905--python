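"""Heatmap gene ordering, p-value histograms with the expected-FDR curve,
and machine-readable run summaries.

Heatmap ordering uses agglomerative clustering on 1 - Pearson correlation
with average linkage (configurable); the FDR curve evaluates the same
plug-in estimator as the differential module along a cutoff grid.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from plaquesig.differential import plugin_fdr
from plaquesig.io import ValidationError

EXPECTED_STAGES = ("simulate", "preprocess", "differential", "signatures", "enrichment")


@dataclass
class ClusterOrder:
    """A permutation of one axis's indices from agglomerative clustering."""

    axis: str
    order: np.ndarray
    ids: list
    metric: str
    linkage: str

    def __post_init__(self) -> None:
        if sorted(self.order.tolist()) != list(range(len(self.order))):
            raise ValidationError("cluster order is not a permutation")


def _correlation_condensed(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distances with a defined rule for flat rows.

    Constant rows have no correlation; they are treated as distance 0 to
    each other (identical shape) and distance 1 to varying rows.
    """
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms == 0
    safe = np.where(flat, 1.0, norms)
    unit = centered / safe[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = 1.0 - corr
    both_flat = np.outer(flat, flat)
    one_flat = np.logical_xor.outer(flat, flat)
    dist[both_flat] = 0.0
    dist[one_flat] = 1.0
    np.fill_diagonal(dist, 0.0)
    iu = np.triu_indices_from(dist, k=1)
    return dist[iu]


def cluster_order(ratios, axis: str = "genes", metric: str = "correlation",
                  linkage: str = "average") -> ClusterOrder:
    """Dendrogram leaf order of genes or samples for heatmap display.

    Deterministic given the input; duplicated profiles (zero distance)
    merge first and end up adjacent under any linkage.
    """
    values = ratios.log10 if hasattr(ratios, "log10") else pd.DataFrame(ratios)
    if axis == "genes":
        frame = values
    elif axis == "samples":
        frame = values.T
    else:
        raise ValidationError(f"axis must be 'genes' or 'samples', got {axis!r}")
    n = frame.shape[0]
    if n == 0:
        raise ValidationError(f"no rows on axis {axis!r}")
    if n == 1:
        return ClusterOrder(axis, np.array([0]), list(frame.index), metric, linkage)
    x = frame.to_numpy(dtype=float)
    if metric == "correlation":
        condensed = _correlation_condensed(x)
    else:
        from scipy.spatial.distance import pdist
        condensed = pdist(x, metric=metric)
    z = hierarchy.linkage(condensed, method=linkage)
    order = np.asarray(hierarchy.leaves_list(z))
    return ClusterOrder(axis, order, [frame.index[i] for i in order], metric, linkage)


def fdr_curve(pvalues: Sequence[float], n_detected: int,
              cutoffs: Sequence[float]) -> pd.DataFrame:
    """Plug-in FDR percentage along a grid of p-value cutoffs.

    At cutoff t the value is plugin_fdr(n_detected, t, #{p <= t}) — the
    same estimator reported per comparison, shown as the gray expected-FDR
    line on p-value histograms. Cutoffs with no passers report the 100 cap.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    rows = []
    for t in cutoffs:
        if not 0 < t < 1:
            raise ValidationError(f"cutoff {t} outside (0, 1)")
        n_sig = int((p <= t).sum())
        est = plugin_fdr(n_detected, t, n_sig)
        rows.append({"cutoff": t, "n_significant": n_sig,
                     "fdr_percent": est.fdr_percent})
    return pd.DataFrame(rows)


def pvalue_histogram(pvalues: Sequence[float], n_detected: int, path=None,
                     bins: int = 50, title: str = ""):
    """Histogram of per-gene p-values with the expected-FDR curve overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.asarray(pvalues, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(p, bins=bins, range=(0, 1), color="#4878a8", edgecolor="white")
    ax.set_xlabel("t-test p value")
    ax.set_ylabel("genes")
    if title:
        ax.set_title(title)
    grid = np.linspace(0.01, 0.99, 50)
    curve = fdr_curve(p, n_detected, grid)
    ax2 = ax.twinx()
    ax2.plot(curve["cutoff"], curve["fdr_percent"], color="gray", lw=1.5)
    ax2.set_ylabel("expected FDR (%)", color="gray")
    ax2.set_ylim(0, 105)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def ratio_heatmap(ratios, gene_order: ClusterOrder | None = None, path=None,
                  vmax: float = 1.0):
    """log10-ratio heatmap, symmetric color scale saturating at |log10|=vmax."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = ratios.log10 if hasattr(ratios, "log10") else pd.DataFrame(ratios)
    if gene_order is not None:
        values = values.iloc[gene_order.order]
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(values.to_numpy().T, aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax, interpolation="nearest")
    ax.set_xlabel("genes (clustered)")
    ax.set_ylabel("samples")
    fig.colorbar(im, ax=ax, label="log10 ratio")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def run_summary(stages: Mapping[str, Mapping], config: Mapping, seed: int,
                expected: Sequence[str] = EXPECTED_STAGES) -> dict:
    """Assemble the machine-readable run report.

    Records tool version, the config hash, the seed and one block per
    completed stage; expected stages with no block are listed under
    ``gaps`` so partial runs are explicit rather than silent.
    """
    from plaquesig import __version__

    return {
        "tool": "plaquesig",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": dict(config),
        "stages": {k: dict(v) for k, v in stages.items()},
        "gaps": [s for s in expected if s not in stages],
    }


def write_run_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
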