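"""Data model and tab-delimited readers/writers for every pipeline table.

All tables travel as TSV (GEO series-matrix style for expression). Stages
never read files themselves: they consume the aligned in-memory bundle
produced by :func:`load_tables`, which restricts every table to the
intersection of sample ids and reports what it dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DOMAINS",
    "SCORE_SETS",
    "ExpressionMatrix",
    "AnalysisConfig",
    "AlignedBundle",
    "load_expression_matrix",
    "write_expression_matrix",
    "load_sample_table",
    "load_neuropsych_table",
    "load_gene_probe_map",
    "invert_gene_probe_map",
    "load_tables",
    "write_result_table",
    "validate_sample_table",
    "validate_neuropsych_table",
]

# The six neuropsychological factor domains plus their composite; every
# stage that iterates "score sets" iterates these seven in this order.
DOMAINS: tuple[str, ...] = (
    "processing_speed",
    "attention_working_memory",
    "verbal_learning_memory",
    "visual_learning_memory",
    "ideational_fluency",
    "executive_functioning",
)
SCORE_SETS: tuple[str, ...] = DOMAINS + ("composite",)

SAMPLE_COLUMNS = ("sample_id", "group", "sex", "age", "race", "education",
                  "smoking_packs_per_day", "cpz_equivalent", "tissue")

# Printed precision for result tables: p-values 3 significant digits,
# rho 2 decimals, fold change 1 decimal.
_COLUMN_FORMATS: dict[str, str] = {
    "p_value": "%.3g",
    "q_value": "%.3g",
    "permutation_p": "%.3g",
    "lb_paired_p": "%.3g",
    "lb_paired_q": "%.3g",
    "lb_nonpaired_p": "%.3g",
    "lb_nonpaired_q": "%.3g",
    "rho": "%.2f",
    "fold_change": "%.1f",
}


@dataclass
class ExpressionMatrix:
    """Probe-by-sample log2 intensity matrix with aligned identifiers."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples")
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            dup = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dup):
                raise ValueError(f"duplicate {name} ids: {sorted(set(dup))}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if self.scale_tag != "log2":
            raise ValueError("in-memory matrices are always log2 scale")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.probe_ids), list(sample_ids),
                                self.values[:, idx])


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the discovery pipeline.

    Defaults follow the study design: FDR alpha 0.05 for stage-1 differential
    expression, raw permutation-p cutoff 0.01 for the stage-2 cognition
    screen (uncorrected across the seven score sets — a deliberate, documented
    choice), co-expression |r| cutoff 0.75, and one million permutations
    (reduce for exploratory runs).
    """

    fdr_alpha: float = 0.05
    corr_p_cutoff: float = 0.01
    n_permutations: int = 1_000_000
    coexpr_cutoff: float = 0.75
    seed: int = 0
    quartile_method: str = "linear"
    fold_change_scale: str = "log2_mean_diff"   # or "linear_mean_ratio"
    permutation_sided: str = "two"
    fisher_rule: str = "prob"
    pooled_t: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if not (0 < self.corr_p_cutoff <= 1):
            # cutoff 1.0 disables the stage-2 filter entirely
            raise ValueError("corr_p_cutoff must lie in (0, 1]")
        if not (0 < self.coexpr_cutoff <= 1):
            raise ValueError("coexpr_cutoff must lie in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class AlignedBundle:
    """All input tables restricted to a common, ordered set of sample ids."""

    expression: ExpressionMatrix
    samples: pd.DataFrame
    neuropsych: pd.DataFrame
    gene_map: dict[str, set[str]]
    dropped_samples: dict[str, list[str]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.sample_ids)


def load_expression_matrix(path, scale_tag: str = "log2",
                           epsilon: float = 2.0 ** -10) -> ExpressionMatrix:
    """Read a tab-delimited probe-by-sample matrix.

    First column is the probe id, header row holds sample ids. Linear-scale
    input is log2-transformed with values floored at ``epsilon`` (so a
    literal 0 maps to log2(epsilon); the flooring is logged).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate probe ids in {path}: {sorted(set(dup))}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cells in {path}: {exc}") from exc
    if scale_tag == "linear":
        n_floor = int((values < epsilon).sum())
        if n_floor:
            logger.warning("%d linear values below epsilon=%g floored before log2",
                           n_floor, epsilon)
        values = np.log2(np.maximum(values, epsilon))
    elif scale_tag != "log2":
        raise ValueError(f"unknown scale_tag {scale_tag!r}")
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "probe_set_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample table")
    bad_group = set(df["group"]) - {"SZ", "control"}
    if bad_group:
        raise ValueError(f"unknown group labels: {sorted(bad_group)}")
    return df


def validate_neuropsych_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("sample_id", *DOMAINS, "composite")
               if c not in df.columns]
    if missing:
        raise ValueError(f"neuropsych table missing columns: {missing}")
    recomputed = df[list(DOMAINS)].mean(axis=1)
    if not np.allclose(recomputed, df["composite"], atol=1e-9):
        raise ValueError("composite column is not the mean of the six domains")
    return df


def load_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_sample_table(df)


def load_neuropsych_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_neuropsych_table(df)


def load_gene_probe_map(path) -> dict[str, set[str]]:
    """Gene symbol -> probe-set-id mapping (many-to-many allowed)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_symbol", "probe_set_id"} <= set(df.columns):
        raise ValueError("gene map needs gene_symbol and probe_set_id columns")
    mapping: dict[str, set[str]] = {}
    for gene, probe in zip(df["gene_symbol"], df["probe_set_id"]):
        if not probe or probe != probe.strip():
            raise ValueError(f"invalid probe id {probe!r} for gene {gene}")
        mapping.setdefault(gene, set()).add(probe)
    return mapping


def invert_gene_probe_map(mapping: Mapping[str, set[str]]) -> dict[str, list[str]]:
    inv: dict[str, list[str]] = {}
    for gene, probes in mapping.items():
        for probe in probes:
            inv.setdefault(probe, []).append(gene)
    return {p: sorted(genes) for p, genes in inv.items()}


def align_bundle(expression: ExpressionMatrix, samples: pd.DataFrame,
                 neuropsych: pd.DataFrame,
                 gene_map: Mapping[str, set[str]]) -> AlignedBundle:
    """Restrict all tables to the common sample ids, in sorted order.

    Samples present in the metadata but absent from the expression columns
    (or vice versa) are dropped with a logged report rather than a hard
    failure; an empty intersection or the loss of an entire group aborts.
    """
    meta_ids = set(samples["sample_id"])
    expr_ids = set(expression.sample_ids)
    common = sorted(meta_ids & expr_ids)
    if not common:
        raise ValueError("no overlap between metadata and expression sample ids")
    dropped = {
        "metadata_only": sorted(meta_ids - expr_ids),
        "expression_only": sorted(expr_ids - meta_ids),
    }
    for key, ids in dropped.items():
        if ids:
            logger.warning("dropping %d samples (%s): %s", len(ids), key, ids)
    sub_samples = (samples[samples["sample_id"].isin(common)]
                   .sort_values("sample_id").reset_index(drop=True))
    for level in ("SZ", "control"):
        if not (sub_samples["group"] == level).any():
            raise ValueError(f"group {level!r} lost entirely during alignment")
    sub_np = (neuropsych[neuropsych["sample_id"].isin(common)]
              .sort_values("sample_id").reset_index(drop=True))
    return AlignedBundle(
        expression=expression.subset_samples(common),
        samples=sub_samples,
        neuropsych=sub_np,
        gene_map={g: set(p) for g, p in gene_map.items()},
        dropped_samples=dropped,
    )


def load_tables(expr_path, samples_path, neuropsych_path, map_path,
                scale_tag: str = "log2") -> AlignedBundle:
    """Load and align the four canonical inputs (see :func:`align_bundle`)."""
    return align_bundle(
        load_expression_matrix(expr_path, scale_tag=scale_tag),
        load_sample_table(samples_path),
        load_neuropsych_table(neuropsych_path),
        load_gene_probe_map(map_path),
    )


def write_result_table(df: pd.DataFrame, path, sort_by=None) -> None:
    """Deterministic TSV output at the documented printed precision.

    Rows are sorted by ``sort_by`` (falling back to all columns) so repeated
    runs with the same config and seed are byte-identical.
    """
    out = df.copy()
    if sort_by is None:
        sort_by = [c for c in out.columns]
    if len(out):
        out = out.sort_values(list(sort_by), kind="mergesort").reset_index(drop=True)
    for col, fmt in _COLUMN_FORMATS.items():
        if col in out.columns and len(out):
            out[col] = [fmt % v if pd.notna(v) else "NA" for v in out[col]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
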