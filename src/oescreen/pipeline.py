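"""End-to-end orchestration and the cross-tissue concordance report.

The pipeline runs the discovery flow on an input directory (as written by
:func:`oescreen.synthetic.emit_fixture` or assembled from real tables):
stage-1 differential expression in the olfactory-epithelium (OE) matrix,
covariate-adjusted Z-scoring of the cognition scores, the permutation
correlation screen, optional co-regulation network construction, stage-1
differential expression in both lymphoblast (LB) matrices, and the
cross-tissue table asking whether any OE candidate replicates in blood.
Every intermediate is persisted as TSV and a JSON manifest records config,
seed, input digests and per-stage row counts, so a rerun with the same
inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cognition import demographics_table, normalize_scores
from .correlation import screen_candidates, summarize_candidates
from .de import run_de
from .io_model import (
    AnalysisConfig,
    align_bundle,
    load_expression_matrix,
    load_gene_probe_map,
    load_neuropsych_table,
    load_sample_table,
    write_result_table,
)
from .network import build_coregulation_network

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "cross_tissue_table"]

_INPUT_FILES = {
    "expression_oe": "expression_oe.tsv",
    "expression_lb_paired": "expression_lb_paired.tsv",
    "expression_lb_nonpaired": "expression_lb_nonpaired.tsv",
    "samples": "samples.tsv",
    "neuropsych": "neuropsych.tsv",
    "gene_map": "gene_map.tsv",
}


def cross_tissue_table(candidates: pd.DataFrame, lb_paired_de: pd.DataFrame,
                       lb_nonpaired_de: pd.DataFrame,
                       fdr_alpha: float = 0.05) -> pd.DataFrame:
    """One row per candidate probe with both lymphoblast tissues' p and q.

    A candidate counts as replicated when its q-value falls below
    ``fdr_alpha`` in either LB data set (q-values are the transcriptome-wide
    BH adjustments computed by the LB differential-expression runs). Probes
    absent from an LB matrix get missing-value markers.
    """
    if len(candidates) == 0:
        return pd.DataFrame(columns=[
            "gene_symbol", "probe_set_id", "oe_domains",
            "lb_paired_p", "lb_paired_q", "lb_nonpaired_p", "lb_nonpaired_q",
            "replicated"])
    paired = lb_paired_de.set_index("probe_id")
    nonpaired = lb_nonpaired_de.set_index("probe_id")
    rows = []
    grouped = candidates.groupby("probe_set_id", sort=True)
    for probe, sub in grouped:
        domains = ";".join(dict.fromkeys(sub["domain"]))

        def lookup(tbl, col):
            return float(tbl.loc[probe, col]) if probe in tbl.index else np.nan

        pp, pq = lookup(paired, "p_value"), lookup(paired, "q_value")
        np_p, np_q = lookup(nonpaired, "p_value"), lookup(nonpaired, "q_value")
        replicated = bool((not np.isnan(pq) and pq < fdr_alpha)
                          or (not np.isnan(np_q) and np_q < fdr_alpha))
        rows.append({
            "gene_symbol": sub["gene_symbol"].iloc[0],
            "probe_set_id": probe, "oe_domains": domains,
            "lb_paired_p": pp, "lb_paired_q": pq,
            "lb_nonpaired_p": np_p, "lb_nonpaired_q": np_q,
            "replicated": replicated,
        })
    out = pd.DataFrame(rows).sort_values("probe_set_id",
                                         kind="mergesort").reset_index(drop=True)
    logger.info("cross-tissue: %d/%d candidates replicated in lymphoblasts",
                int(out["replicated"].sum()), len(out))
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: AnalysisConfig, input_dir, output_dir,
                 with_network: bool = False) -> dict:
    """Execute every stage on an input directory; returns the run manifest.

    The network stage is off by default (it validates the expression data
    rather than selecting candidates) and, when enabled, builds the
    co-regulation network of the control-subject OE columns at
    ``config.coexpr_cutoff``.
    """
    inp = Path(input_dir)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: inp / v for k, v in _INPUT_FILES.items()}
    for key, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"pipeline input {key} missing: {p}")

    bundle = align_bundle(
        load_expression_matrix(paths["expression_oe"]),
        load_sample_table(paths["samples"]),
        load_neuropsych_table(paths["neuropsych"]),
        load_gene_probe_map(paths["gene_map"]),
    )

    counts: dict[str, int] = {}

    de_oe = run_de(bundle.expression, bundle.samples, alpha=config.fdr_alpha)
    write_result_table(de_oe, out / "de_oe.tsv",
                       sort_by=["fold_change", "probe_id"])
    counts["de_oe_significant"] = int(de_oe["significant"].sum())

    scores = normalize_scores(bundle.neuropsych, bundle.samples, group="SZ")
    scores.z.reset_index().to_csv(out / "normalized_scores.tsv", sep="\t",
                                  index=False, float_format="%.6g")
    demo = demographics_table(bundle.samples, bundle.neuropsych)
    write_result_table(demo, out / "demographics.tsv",
                       sort_by=["characteristic"])

    candidates = screen_candidates(bundle.expression, de_oe, scores,
                                   gene_map=bundle.gene_map, config=config)
    write_result_table(candidates, out / "candidates.tsv",
                       sort_by=["domain", "permutation_p", "probe_set_id"])
    counts["candidate_rows"] = int(len(candidates))
    summary = summarize_candidates(candidates)
    counts["candidate_unique_genes"] = summary["n_unique_genes"]

    if with_network:
        ctrl_ids = bundle.samples.loc[bundle.samples["group"] == "control",
                                      "sample_id"].tolist()
        net = build_coregulation_network(
            bundle.expression.subset_samples(ctrl_ids), config.coexpr_cutoff)
        edges = pd.DataFrame(net.edge_list(),
                             columns=["probe_a", "probe_b", "r"])
        edges.to_csv(out / "coregulation_edges.tsv", sep="\t", index=False,
                     float_format="%.6g")
        counts["network_edges"] = net.n_edges

    all_samples = load_sample_table(paths["samples"])
    lb_results = {}
    for key in ("expression_lb_paired", "expression_lb_nonpaired"):
        lb = load_expression_matrix(paths[key])
        lb_groups = {s: g for s, g in zip(all_samples["sample_id"],
                                          all_samples["group"])
                     if s in lb.sample_ids}
        lb_de = run_de(lb, lb_groups, alpha=config.fdr_alpha)
        tag = key.replace("expression_", "")
        write_result_table(lb_de, out / f"de_{tag}.tsv",
                           sort_by=["fold_change", "probe_id"])
        counts[f"de_{tag}_significant"] = int(lb_de["significant"].sum())
        lb_results[tag] = lb_de

    cross = cross_tissue_table(candidates, lb_results["lb_paired"],
                               lb_results["lb_nonpaired"], config.fdr_alpha)
    write_result_table(cross, out / "cross_tissue.tsv",
                       sort_by=["probe_set_id"])
    counts["cross_tissue_replicated"] = (int(cross["replicated"].sum())
                                         if len(cross) else 0)

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "inputs": {k: {"file": str(v.name), "sha256": _digest(v)}
                   for k, v in paths.items()},
        "row_counts": counts,
        "candidate_summary": summary,
        "dropped_samples": bundle.dropped_samples,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return manifest
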