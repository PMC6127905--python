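"""Config-driven composition of the pipeline stages.

A run is fully determined by a (config, seed) pair. The configuration is a
nested mapping validated against a schema of known keys and documented
ranges; unknown keys are rejected so a typo cannot silently fall back to a
default. Stage runners read/write delimited text in an output directory
and return the summary block recorded in the run report.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from plaquesig import io as pio
from plaquesig import report as prep
from plaquesig.differential import plugin_fdr, significant_sets, ttest_genes, pearson_age
from plaquesig.enrichment import annotate, enrichment_table, overlap_test
from plaquesig.io import ValidationError
from plaquesig.preprocess import filter_detected, ratio_to_reference, compute_fpkm
from plaquesig.signatures import signature_score
from plaquesig.simulate import SimConfig, simulate_cohort, truth_sets

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, dict[str, Any]] = {
    "simulate": {"preset": "lcm", "n_genes": 2000, "dispersion": None},
    "preprocess": {"min_count": 10, "group_fraction": 0.5, "pseudocount": 0.01,
                   "gene_length": 1000, "reference_group": None},
    "dge": {"group_a": None, "group_b": None, "alpha": 0.001},
    "agecorr": {"rho_cut": 0.75},
    "score": {"gmt": None},
    "enrich": {"gmt": None, "e_cut": 0.1},
    "threshold": {"fc_min": 1.5, "p_max": 1e-5},
    "cluster": {"metric": "correlation", "linkage": "average"},
}

_RANGES = {
    ("dge", "alpha"): (0.0, 1.0),
    ("agecorr", "rho_cut"): (0.0, 1.0),
    ("preprocess", "group_fraction"): (0.0, 1.0),
    ("enrich", "e_cut"): (0.0, 1.0),
    ("threshold", "p_max"): (0.0, 1.0),
}


def validate_config(config: Mapping | None) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys and
    out-of-range parameter values."""
    merged = {section: dict(values) for section, values in DEFAULTS.items()}
    config = dict(config or {})
    top_extra = {"outdir", "seed"}
    for section, values in config.items():
        if section in top_extra:
            continue
        if section not in merged:
            raise ValidationError(
                f"unknown config section {section!r}; known: {sorted(merged) + sorted(top_extra)}")
        if not isinstance(values, Mapping):
            raise ValidationError(f"config section {section!r} must be a mapping")
        for key, value in values.items():
            if key not in merged[section]:
                raise ValidationError(
                    f"unknown key {section}.{key}; known: {sorted(merged[section])}")
            merged[section][key] = value
    for (section, key), (lo, hi) in _RANGES.items():
        v = merged[section][key]
        if v is not None and not (lo < float(v) < hi):
            raise ValidationError(f"{section}.{key} must be in ({lo}, {hi}), got {v}")
    for key in ("min_count",):
        if merged["preprocess"][key] < 0:
            raise ValidationError("preprocess.min_count must be >= 0")
    if merged["preprocess"]["pseudocount"] <= 0:
        raise ValidationError("preprocess.pseudocount must be > 0")
    if merged["threshold"]["fc_min"] <= 0:
        raise ValidationError("threshold.fc_min must be > 0")
    merged["outdir"] = config.get("outdir", "plaquesig_run")
    merged["seed"] = int(config.get("seed", 0))
    return merged


def load_config(path: str | Path | None) -> dict:
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _sim_config(cfg: Mapping, seed: int) -> SimConfig:
    sim = cfg["simulate"]
    overrides = {}
    if sim.get("dispersion") is not None:
        overrides["dispersion"] = float(sim["dispersion"])
    if sim["preset"] == "lcm":
        return SimConfig.lcm_default(n_genes=int(sim["n_genes"]), seed=seed, **overrides)
    if sim["preset"] in ("whole_cortex", "tgcrnd8", "tg2576"):
        strain = "Tg2576" if sim["preset"] == "tg2576" else "TgCRND8"
        return SimConfig.whole_cortex_default(strain=strain,
                                              n_genes=int(sim["n_genes"]),
                                              seed=seed, **overrides)
    raise ValidationError(f"unknown simulate.preset {sim['preset']!r}")


def run_simulate(cfg: Mapping, outdir: Path) -> dict:
    seed = cfg["seed"]
    counts, samples, truth = simulate_cohort(_sim_config(cfg, seed))
    pio.write_matrix(counts, outdir / "counts.tsv", comment=f"plaquesig counts seed={seed}")
    pio.write_sample_table(samples, outdir / "samples.tsv")
    truth.genes.to_csv(outdir / "truth.tsv", sep="\t")
    pio.write_gmt(truth_sets(truth), outdir / "truth_sets.gmt")
    return {"n_genes": counts.shape[0], "n_samples": counts.shape[1],
            "modules": truth.genes["module"].value_counts().to_dict()}


def run_preprocess(cfg: Mapping, outdir: Path) -> dict:
    pp = cfg["preprocess"]
    counts = pio.read_matrix(outdir / "counts.tsv", kind="counts")
    samples = pio.read_sample_table(outdir / "samples.tsv")
    detected = filter_detected(counts, samples, min_count=int(pp["min_count"]),
                               group_fraction=float(pp["group_fraction"]))
    with open(outdir / "detected.txt", "w") as fh:
        fh.writelines(g + "\n" for g in detected)
    lengths = {g: float(pp["gene_length"]) for g in counts.gene_ids}
    fpkm = compute_fpkm(counts, lengths)
    sub = pio.AbundanceMatrix(fpkm.data.loc[detected])
    reference = pp["reference_group"]
    if reference is None:
        # Fall back to the first group in the sample table; a real analysis
        # should configure this explicitly.
        reference = samples.data["group_label"].iloc[0]
        logger.warning("no reference_group configured; using %r", reference)
    ratios = ratio_to_reference(sub, samples, reference,
                                pseudocount=float(pp["pseudocount"]))
    pio.write_matrix(ratios.linear, outdir / "ratios_linear.tsv")
    pio.write_matrix(ratios.log10, outdir / "ratios_log10.tsv")
    return {"n_detected": len(detected), "reference_group": reference,
            "pseudocount": float(pp["pseudocount"])}


def _load_ratios(cfg: Mapping, outdir: Path):
    from plaquesig.preprocess import RatioMatrix

    linear = pio.read_matrix(outdir / "ratios_linear.tsv", kind="abundance")
    return RatioMatrix(linear.data, cfg["preprocess"]["reference_group"] or "",
                       float(cfg["preprocess"]["pseudocount"]))


def run_dge(cfg: Mapping, outdir: Path) -> dict:
    dge_cfg = cfg["dge"]
    samples = pio.read_sample_table(outdir / "samples.tsv")
    ratios = _load_ratios(cfg, outdir)
    groups = samples.groups()
    group_a, group_b = dge_cfg["group_a"], dge_cfg["group_b"]
    if group_a is None or group_b is None:
        labels = sorted(groups)
        if len(labels) != 2:
            raise ValidationError(
                "dge.group_a/group_b must be configured when the design has "
                f"more than two groups; found {labels}")
        group_a, group_b = labels[0], labels[1]
        # Prefer plaque_niche as group A when present so fold changes read
        # as niche over distal.
        if "plaque_niche" in group_b:
            group_a, group_b = group_b, group_a
    result = ttest_genes(ratios, samples.samples_in_group(group_a),
                         samples.samples_in_group(group_b),
                         group_a_label=group_a, group_b_label=group_b)
    result.table.to_csv(outdir / "dge.tsv", sep="\t", index_label="gene")
    alpha = float(dge_cfg["alpha"])
    sig = significant_sets(result, alpha)
    est = plugin_fdr(len(result.table), alpha, sig.n_up + sig.n_down)
    for gene_set, path in ((sig.up, "dge_up.txt"), (sig.down, "dge_down.txt")):
        if gene_set is not None:
            pio.write_gene_list(gene_set, outdir / path)
    prep.pvalue_histogram(result.table["p"], len(result.table),
                          path=outdir / "pvalue_histogram.png",
                          title=f"{group_a} vs {group_b}")
    return {"group_a": group_a, "group_b": group_b, "alpha": alpha,
            "n_tested": len(result.table), "n_up": sig.n_up, "n_down": sig.n_down,
            "percent_up": sig.percent_up, "fdr_percent": est.fdr_percent}


def run_agecorr(cfg: Mapping, outdir: Path) -> dict:
    samples = pio.read_sample_table(outdir / "samples.tsv")
    if samples.data["age_months"].nunique() < 2:
        return {"skipped": "design has a single age; correlation undefined"}
    ratios = _load_ratios(cfg, outdir)
    result = pearson_age(ratios, samples)
    result.rho.to_csv(outdir / "agecorr.tsv", sep="\t", index_label="gene")
    rho_cut = float(cfg["agecorr"]["rho_cut"])
    passing = result.passing(rho_cut)
    return {"rho_cut": rho_cut, "n_passing": len(passing)}


def run_score(cfg: Mapping, outdir: Path) -> dict:
    gmt_path = cfg["score"]["gmt"] or outdir / "truth_sets.gmt"
    collection = pio.read_gmt(gmt_path)
    ratios = _load_ratios(cfg, outdir)
    present = set(ratios.gene_ids)
    block = {}
    for gene_set in collection:
        if not (gene_set.members & present):
            continue
        score = signature_score(ratios, gene_set)
        score.table.to_csv(outdir / f"score_{gene_set.name}.tsv", sep="\t")
        block[gene_set.name] = {"n_genes_used": score.n_genes_used,
                                "mean_of_means": float(score.mean.mean())}
    return block


def run_enrich(cfg: Mapping, outdir: Path) -> dict:
    gmt_path = cfg["enrich"]["gmt"] or outdir / "truth_sets.gmt"
    collection = pio.read_gmt(gmt_path)
    background = pio.read_gene_list(outdir / "detected.txt", name="detected")
    query = pio.read_gene_list(outdir / "dge_up.txt", name="dge_up")
    rows = annotate(query, collection, background, e_cut=float(cfg["enrich"]["e_cut"]))
    enrichment_table(rows).to_csv(outdir / "enrichment.tsv", sep="\t")
    top = rows[0]
    return {"n_sets": len(rows),
            "n_significant": sum(r.significant for r in rows),
            "top_set": top.set_name, "top_e_value": top.e_value}


def run_overlap(cfg: Mapping, outdir: Path) -> dict:
    """Overlap of the recovered up-signature with the truth progression set."""
    background = pio.read_gene_list(outdir / "detected.txt", name="detected")
    query = pio.read_gene_list(outdir / "dge_up.txt", name="dge_up")
    collection = pio.read_gmt(outdir / "truth_sets.gmt")
    try:
        progression = collection["progressive_all"]
    except KeyError:
        return {"skipped": "no progressive_all truth set"}
    result = overlap_test(query, progression, background)
    import json
    with open(outdir / "overlap.json", "w") as fh:
        json.dump(result.as_dict(), fh, indent=2)
    return result.as_dict()


def run_cluster(cfg: Mapping, outdir: Path) -> dict:
    ratios = _load_ratios(cfg, outdir)
    sig_genes = []
    up_path = outdir / "dge_up.txt"
    if up_path.exists():
        sig_genes = [g for g in pio.read_gene_list(up_path).members
                     if g in set(ratios.gene_ids)]
    frame = ratios.log10.loc[sorted(sig_genes)] if sig_genes else ratios.log10
    cl_cfg = cfg["cluster"]
    order = prep.cluster_order(frame, axis="genes", metric=cl_cfg["metric"],
                               linkage=cl_cfg["linkage"])
    with open(outdir / "gene_order.txt", "w") as fh:
        fh.writelines(str(g) + "\n" for g in order.ids)
    prep.ratio_heatmap(frame.iloc[order.order], path=outdir / "heatmap.png")
    return {"axis": "genes", "n": len(order.ids),
            "metric": cl_cfg["metric"], "linkage": cl_cfg["linkage"]}


STAGE_RUNNERS = {
    "simulate": run_simulate,
    "preprocess": run_preprocess,
    "dge": run_dge,
    "agecorr": run_agecorr,
    "score": run_score,
    "enrich": run_enrich,
    "overlap": run_overlap,
    "cluster": run_cluster,
}


def run_all(cfg: Mapping, outdir: Path) -> dict:
    """Compose every stage and write the run summary."""
    outdir.mkdir(parents=True, exist_ok=True)
    stages = {}
    for name in ("simulate", "preprocess", "dge", "agecorr", "score",
                 "enrich", "overlap", "cluster"):
        stages[name] = STAGE_RUNNERS[name](cfg, outdir)
    summary = prep.run_summary(stages, {k: v for k, v in cfg.items() if k != "seed"},
                               cfg["seed"],
                               expected=tuple(STAGE_RUNNERS))
    prep.write_run_summary(summary, outdir / "summary.json")
    return summary
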