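"""Synthetic cohorts, expression matrices and qPCR plates with planted truth.

The generator emulates the study design end to end: two diagnostic groups
with demographics matched in expectation, six correlated cognitive domain
scores (shared latent cognition factor plus sex and education effects, group
deficits patterned on the published cohort summaries), an olfactory-
epithelium (OE) expression matrix with planted group fold changes and
planted within-patient gene-cognition correlations, lymphoblast (LB)
matrices with no planted effects, planted co-regulated probe pairs, and
qPCR Ct triplicates generated exactly from known standard curves.

Every planted effect is recorded in a :class:`GroundTruth` object so each
downstream stage can be scored for recovery.

Calibration notes
-----------------
* Cognition-linked probes target a Spearman correlation. The generator
  mixes the covariate-adjusted score direction with in-sample orthogonalized
  noise and calibrates the mixing weight by bisection until the realized
  in-sample Spearman correlation matches the target (to the resolution the
  n-point rank lattice permits), so planted correlations land on target
  rather than merely in expectation. The bivariate-normal conversion
  r = 2 sin(pi * rho_s / 6) provides the starting bracket.
* Group effects are applied on the log2 scale, so the signed fold-change
  convention (ratio if >= 1, else negative reciprocal) is exactly
  recoverable from group mean differences.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_stats
from .io_model import (
    DOMAINS,
    ExpressionMatrix,
    validate_neuropsych_table,
    validate_sample_table,
    write_expression_matrix,
)

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_cohort",
    "simulate_expression_pair",
    "simulate_qpcr_plate",
    "emit_fixture",
    "QpcrPlate",
    "spearman_to_pearson",
]

# Published cohort pattern: (SZ mean, SZ sd, control mean, control sd) per domain.
DEFAULT_DOMAIN_PATTERN: dict[str, tuple[float, float, float, float]] = {
    "processing_speed": (8.9, 2.0, 11.0, 2.4),
    "attention_working_memory": (8.7, 2.1, 10.6, 2.6),
    "verbal_learning_memory": (9.6, 1.9, 9.8, 2.6),
    "visual_learning_memory": (9.5, 1.9, 9.6, 2.8),
    "ideational_fluency": (5.7, 1.8, 7.8, 1.7),
    "executive_functioning": (9.3, 2.4, 10.7, 2.5),
}


@dataclass
class SimulationParams:
    """Study-condition parameters; defaults mirror the cohort being emulated.

    Sample sizes (16 SZ / 15 control OE; 16/18 non-paired LB), fold-change
    magnitudes (1.2-3.3 either sign), target within-patient Spearman
    correlations (0.6-0.8) and co-regulation strength (|r| >= 0.75) follow
    the published effect ranges; free scale choices (probe noise sd, latent
    loading, qPCR curve geometry) are documented in the methods note.
    """

    n_sz: int = 16
    n_control: int = 15
    n_lb_nonpaired_sz: int = 16
    n_lb_nonpaired_control: int = 18

    # cognitive scores
    domain_pattern: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_PATTERN))
    latent_loading: float = 0.6        # fraction of domain sd via shared latent
    sex_effect: float = 0.5            # score points, male minus female
    education_effect: float = 0.2      # score points per year of education

    # expression
    n_probes: int = 5000
    n_de_probes: int = 50
    n_cognition_linked: int = 10
    fc_range: tuple[float, float] = (1.2, 3.3)       # |fold change|, either sign
    rho_range: tuple[float, float] = (0.6, 0.8)      # target Spearman magnitude
    probe_sd: float = 0.3                            # log2 within-group sd
    baseline_range: tuple[float, float] = (5.0, 12.0)
    n_coregulated_pairs: int = 20
    coreg_r: float = 0.9                             # planted pair |Pearson r|

    # qPCR
    qpcr_genes: tuple[str, ...] = ("SMAD1", "SMAD3", "SMAD5", "SMURF1")
    qpcr_reference: str = "GAPDH"
    qpcr_sz_ratio: float = 0.7          # true target/reference ratio in SZ
    qpcr_ratio_sd: float = 0.1          # between-subject sd of the true ratio
    qpcr_slope: float = -3.3219         # Ct per log10 quantity (efficiency 1.0)
    qpcr_ct_noise_sd: float = 0.1       # technical triplicate noise, cycles
    qpcr_standard_noise_sd: float = 0.0
    qpcr_standard_quantities: tuple[float, ...] = (1.0, 10.0, 100.0, 1e3, 1e4)

    def __post_init__(self) -> None:
        if self.n_de_probes + self.n_cognition_linked > self.n_probes:
            raise ValueError("planted probes exceed n_probes")
        if self.probe_sd <= 0 or self.latent_loading <= 0:
            raise ValueError("scale parameters must be positive")
        if not (0 < self.coreg_r <= 1):
            raise ValueError("coreg_r must lie in (0, 1]")
        if self.qpcr_slope >= 0:
            raise ValueError("qPCR standard-curve slope must be negative")


@dataclass
class GroundTruth:
    """Planted effects, recorded at generation time for recovery scoring."""

    de_fold_changes: dict[str, float]                  # probe -> signed FC
    cognition_links: dict[str, dict]                   # probe -> {rho, domain, fold_change}
    coregulated_pairs: list[tuple[str, str, float]]    # (probe_a, probe_b, r)
    qpcr_group_ratio: dict[str, dict[str, float]]      # gene -> {SZ, control}
    qpcr_sample_ratio: dict[str, dict[str, float]]     # gene -> sample -> true ratio

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["coregulated_pairs"] = [list(t) for t in self.coregulated_pairs]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        raw["coregulated_pairs"] = [tuple(t) for t in raw["coregulated_pairs"]]
        return cls(**raw)


@dataclass
class QpcrPlate:
    """Triplicate Ct measurements plus per-gene dilution standards."""

    measurements: pd.DataFrame   # gene, sample_id, ct1, ct2, ct3
    standards: pd.DataFrame      # gene, quantity, ct
    reference_gene: str = "GAPDH"

    def __post_init__(self) -> None:
        need = {"gene", "sample_id", "ct1", "ct2", "ct3"}
        if not need <= set(self.measurements.columns):
            raise ValueError(f"measurements need columns {sorted(need)}")
        if not {"gene", "quantity", "ct"} <= set(self.standards.columns):
            raise ValueError("standards need gene, quantity, ct columns")
        counts = self.standards.groupby("gene")["quantity"].nunique()
        if (counts < 3).any():
            raise ValueError("each gene needs >= 3 distinct standard quantities")


def spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal conversion from a Spearman target to Pearson r."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _spawn(seed: int, *path: int) -> np.random.Generator:
    """Independent generator for stream ``path`` of master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([seed, *path]))


def simulate_cohort(
    params: SimulationParams,
    seed: int,
    n_sz: int | None = None,
    n_control: int | None = None,
    tissue: str = "OE",
    id_prefix: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a matched two-group cohort and its neuropsychological scores.

    Demographics are drawn from identical distributions in both groups
    (matched in expectation). Each domain score is
    ``group mean + sex effect + education effect + loading * latent + noise``
    with one latent cognition factor shared across the six domains; the
    composite is their arithmetic mean. The latent/noise split preserves the
    published per-domain standard deviations approximately (covariate
    variance is left on top, documented in the methods note).
    """
    rng = _spawn(seed, 0)
    n_sz = params.n_sz if n_sz is None else n_sz
    n_control = params.n_control if n_control is None else n_control
    ids = ([f"{id_prefix}SZ{i + 1:02d}" for i in range(n_sz)]
           + [f"{id_prefix}C{i + 1:02d}" for i in range(n_control)])
    groups = ["SZ"] * n_sz + ["control"] * n_control
    n = len(ids)

    sex = np.where(rng.random(n) < 0.75, "male", "female")
    age = np.clip(rng.normal(40.0, 11.0, n), 18, 65).round(1)
    race = rng.choice(["Caucasian", "African American", "other"],
                      size=n, p=[0.40, 0.55, 0.05])
    education = np.clip(rng.normal(12.7, 2.5, n), 8, 20).round(0)
    smoker = rng.random(n) < 0.4
    packs = np.where(smoker, np.round(rng.uniform(0.25, 1.5, n), 2), 0.0)
    cpz = np.where(np.array(groups) == "SZ",
                   np.clip(rng.normal(400.0, 150.0, n), 50, None).round(0),
                   np.nan)

    samples = pd.DataFrame({
        "sample_id": ids, "group": groups, "sex": sex, "age": age,
        "race": race, "education": education,
        "smoking_packs_per_day": packs, "cpz_equivalent": cpz,
        "tissue": tissue,
    })

    latent = rng.normal(0.0, 1.0, n)
    sex01 = (sex == "male").astype(float)
    scores = {}
    for dom in DOMAINS:
        mu_sz, sd_sz, mu_c, sd_c = params.domain_pattern[dom]
        mu = np.where(np.array(groups) == "SZ", mu_sz, mu_c)
        sd = np.where(np.array(groups) == "SZ", sd_sz, sd_c)
        loading = params.latent_loading * sd
        noise_sd = sd * math.sqrt(1.0 - params.latent_loading**2)
        scores[dom] = (mu
                       + params.sex_effect * (sex01 - 0.75)
                       + params.education_effect * (education - 12.7)
                       + loading * latent
                       + rng.normal(0.0, noise_sd, n))
    neuropsych = pd.DataFrame({"sample_id": ids, **scores})
    neuropsych["composite"] = neuropsych[list(DOMAINS)].mean(axis=1)
    # latent is carried as a column-free attribute for inspection in tests
    neuropsych.attrs["latent_cognition"] = dict(zip(ids, latent))
    validate_sample_table(samples)
    validate_neuropsych_table(neuropsych)
    return samples, neuropsych


def _signed_fc_to_delta(fc: float) -> float:
    """Signed fold change -> log2 shift applied to the SZ group."""
    return math.log2(fc) if fc > 0 else -math.log2(-fc)


def _draw_fold_changes(rng: np.random.Generator, n: int,
                       fc_range: tuple[float, float]) -> np.ndarray:
    mag = rng.uniform(fc_range[0], fc_range[1], n)
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    return np.where(sign > 0, mag, -mag)


def _adjusted_score_unit(neuropsych: pd.DataFrame, samples: pd.DataFrame,
                         domain: str, sz_ids: list[str]) -> np.ndarray:
    """Unit-norm covariate-adjusted domain score over the SZ subjects."""
    sub_np = neuropsych.set_index("sample_id").loc[sz_ids]
    sub_sm = samples.set_index("sample_id").loc[sz_ids]
    cov = np.column_stack([
        (sub_sm["sex"] == "male").astype(float),
        sub_sm["education"].astype(float),
    ])
    resid = core_stats.ols_residualize(sub_np[domain].to_numpy(), cov)
    resid = resid - resid.mean()
    return resid / np.linalg.norm(resid)


def _exact_corr_vector(rng: np.random.Generator, u: np.ndarray,
                       r: float) -> np.ndarray:
    """Unit-norm vector whose sample Pearson correlation with u is exactly r."""
    n = u.size
    e = rng.normal(0.0, 1.0, n)
    e = e - e.mean()
    e = e - (e @ u) * u
    e /= np.linalg.norm(e)
    return r * u + math.sqrt(1.0 - r * r) * e


def _calibrated_link_vector(rng: np.random.Generator, u: np.ndarray,
                            rho_target: float) -> np.ndarray:
    """Unit-norm vector whose sample Spearman correlation with u hits the target.

    The Spearman correlation of ``r*u + sqrt(1-r^2)*e_orth`` with u is a
    monotone step function of the Pearson weight r (ranks move discretely),
    so bisection lands on the achievable value nearest the target.
    """
    n = u.size
    e = rng.normal(0.0, 1.0, n)
    e = e - e.mean()
    e = e - (e @ u) * u
    e /= np.linalg.norm(e)

    def realized(r: float) -> float:
        v = r * u + math.sqrt(1.0 - r * r) * e
        return core_stats.spearman_rho(v, u)

    lo, hi = -0.9999, 0.9999
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if realized(mid) < rho_target:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi, 0.5 * (lo + hi)),
               key=lambda r: abs(realized(r) - rho_target))
    return best * u + math.sqrt(1.0 - best * best) * e


def simulate_expression_pair(
    params: SimulationParams,
    samples: pd.DataFrame,
    neuropsych: pd.DataFrame,
    seed: int,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """OE matrix with planted effects and a paired-LB matrix with none.

    Probe layout: the first ``n_de_probes`` carry pure group shifts, the next
    ``n_cognition_linked`` carry both a group shift and a within-SZ
    correlation with one cognitive domain (or the composite), then
    ``n_coregulated_pairs`` pairs share a latent factor, and the remainder is
    independent noise. The paired-LB matrix covers the same probes and all
    subjects except the last SZ patient (emulating the one missing blood
    sample) with independent noise and no planted effects.
    """
    rng = _spawn(seed, 1)
    n_samples = len(samples)
    probe_ids = [f"P{i + 1:05d}" for i in range(params.n_probes)]
    is_sz = (samples["group"] == "SZ").to_numpy()
    sz_ids = samples.loc[is_sz, "sample_id"].tolist()

    baseline = rng.uniform(*params.baseline_range, params.n_probes)
    values = baseline[:, None] + rng.normal(0.0, params.probe_sd,
                                            (params.n_probes, n_samples))

    de_fcs = _draw_fold_changes(rng, params.n_de_probes, params.fc_range)
    de_truth: dict[str, float] = {}
    for i, fc in enumerate(de_fcs):
        values[i, is_sz] += _signed_fc_to_delta(fc)
        de_truth[probe_ids[i]] = float(fc)

    cog_truth: dict[str, dict] = {}
    score_sets = list(DOMAINS) + ["composite"]
    cog_fcs = _draw_fold_changes(rng, params.n_cognition_linked, params.fc_range)
    cog_rhos = rng.uniform(*params.rho_range, params.n_cognition_linked)
    cog_signs = np.where(rng.random(params.n_cognition_linked) < 0.5, 1.0, -1.0)
    for j in range(params.n_cognition_linked):
        i = params.n_de_probes + j
        domain = score_sets[j % len(score_sets)]
        rho_target = float(cog_signs[j] * cog_rhos[j])
        u = _adjusted_score_unit(neuropsych, samples, domain, sz_ids)
        signal = _calibrated_link_vector(rng, u, rho_target)
        n_sz = int(is_sz.sum())
        values[i, is_sz] = (baseline[i] + _signed_fc_to_delta(float(cog_fcs[j]))
                            + params.probe_sd * math.sqrt(n_sz - 1) * signal)
        cog_truth[probe_ids[i]] = {
            "rho": rho_target, "domain": domain,
            "fold_change": float(cog_fcs[j]),
        }

    coreg: list[tuple[str, str, float]] = []
    start = params.n_de_probes + params.n_cognition_linked
    a = math.sqrt(params.coreg_r)
    b = math.sqrt(1.0 - params.coreg_r)
    for j in range(params.n_coregulated_pairs):
        i1, i2 = start + 2 * j, start + 2 * j + 1
        if i2 >= params.n_probes:
            raise ValueError("not enough probes for the requested co-regulated pairs")
        f = rng.normal(0.0, 1.0, n_samples)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        values[i1] = baseline[i1] + params.probe_sd * (
            a * f + b * rng.normal(0.0, 1.0, n_samples))
        values[i2] = baseline[i2] + params.probe_sd * (
            sign * a * f + b * rng.normal(0.0, 1.0, n_samples))
        coreg.append((probe_ids[i1], probe_ids[i2], float(sign * params.coreg_r)))

    oe = ExpressionMatrix(probe_ids, samples["sample_id"].tolist(), values)

    # paired LB: same probes, all subjects except the last SZ patient,
    # independent noise, nothing planted
    lb_ids = [s for s in samples["sample_id"] if s != sz_ids[-1]]
    lb_values = (baseline[:, None]
                 + rng.normal(0.0, params.probe_sd,
                              (params.n_probes, len(lb_ids))))
    lb = ExpressionMatrix(probe_ids, lb_ids, lb_values)

    truth = GroundTruth(
        de_fold_changes=de_truth, cognition_links=cog_truth,
        coregulated_pairs=coreg, qpcr_group_ratio={}, qpcr_sample_ratio={},
    )
    return oe, lb, truth


def simulate_null_matrix(params: SimulationParams, probe_ids: list[str],
                         sample_ids: list[str], seed: int) -> ExpressionMatrix:
    """Expression matrix with no planted effects (non-paired LB cohorts)."""
    rng = _spawn(seed, 2)
    baseline = rng.uniform(*params.baseline_range, len(probe_ids))
    values = baseline[:, None] + rng.normal(
        0.0, params.probe_sd, (len(probe_ids), len(sample_ids)))
    return ExpressionMatrix(list(probe_ids), list(sample_ids), values)


def simulate_qpcr_plate(
    params: SimulationParams,
    samples: pd.DataFrame,
    seed: int,
) -> tuple[QpcrPlate, GroundTruth]:
    """Triplicate Ct plate generated exactly from known standard curves.

    Standard-series Cts follow ``Ct = slope * log10(q) + intercept`` plus
    optional noise. Sample Cts derive from true quantities: the reference
    gene carries no group effect; each target gene's true target/reference
    ratio is 1 in controls and ``qpcr_sz_ratio`` in SZ, with between-subject
    spread ``qpcr_ratio_sd``. All three replicates of a well share the same
    true quantity and differ only by technical Ct noise.
    """
    rng = _spawn(seed, 3)
    genes = list(params.qpcr_genes)
    all_genes = genes + [params.qpcr_reference]
    intercepts = {g: 34.0 + 0.5 * i for i, g in enumerate(all_genes)}

    std_rows = []
    for g in all_genes:
        for q in params.qpcr_standard_quantities:
            ct = (params.qpcr_slope * math.log10(q) + intercepts[g]
                  + (rng.normal(0.0, params.qpcr_standard_noise_sd)
                     if params.qpcr_standard_noise_sd > 0 else 0.0))
            std_rows.append({"gene": g, "quantity": q, "ct": ct})
    standards = pd.DataFrame(std_rows)

    is_sz = (samples["group"] == "SZ").to_numpy()
    q_ref = 10.0 ** rng.normal(2.0, 0.15, len(samples))
    group_ratio = {g: {"SZ": params.qpcr_sz_ratio, "control": 1.0}
                   for g in genes}
    sample_ratio: dict[str, dict[str, float]] = {g: {} for g in genes}

    rows = []
    for s_idx, sid in enumerate(samples["sample_id"]):
        for g in all_genes:
            if g == params.qpcr_reference:
                q_true = q_ref[s_idx]
            else:
                base = params.qpcr_sz_ratio if is_sz[s_idx] else 1.0
                ratio = max(base + rng.normal(0.0, params.qpcr_ratio_sd), 0.05)
                sample_ratio[g][sid] = float(ratio)
                q_true = q_ref[s_idx] * ratio
            ct_true = params.qpcr_slope * math.log10(q_true) + intercepts[g]
            cts = ct_true + (rng.normal(0.0, params.qpcr_ct_noise_sd, 3)
                             if params.qpcr_ct_noise_sd > 0 else np.zeros(3))
            rows.append({"gene": g, "sample_id": sid,
                         "ct1": cts[0], "ct2": cts[1], "ct3": cts[2]})
    plate = QpcrPlate(pd.DataFrame(rows), standards,
                      reference_gene=params.qpcr_reference)
    truth = GroundTruth({}, {}, [], group_ratio, sample_ratio)
    return plate, truth


def _merge_truth(expr_truth: GroundTruth, qpcr_truth: GroundTruth) -> GroundTruth:
    return GroundTruth(
        de_fold_changes=expr_truth.de_fold_changes,
        cognition_links=expr_truth.cognition_links,
        coregulated_pairs=expr_truth.coregulated_pairs,
        qpcr_group_ratio=qpcr_truth.qpcr_group_ratio,
        qpcr_sample_ratio=qpcr_truth.qpcr_sample_ratio,
    )


def _gene_map_frame(probe_ids: list[str]) -> pd.DataFrame:
    """1:1 synthetic gene symbols, plus a second probe for the last 3 genes
    to exercise many-to-many mapping."""
    rows = [{"gene_symbol": f"GENE{i + 1:05d}", "probe_set_id": p}
            for i, p in enumerate(probe_ids)]
    for k in range(1, 4):
        if len(probe_ids) > 3 + k:
            rows.append({"gene_symbol": f"GENE{k:05d}",
                         "probe_set_id": probe_ids[-k]})
    return pd.DataFrame(rows)


def emit_fixture(params: SimulationParams, out_dir, seed: int) -> dict:
    """Write the complete synthetic input directory plus manifest.

    Emits the OE/paired-LB/non-paired-LB expression TSVs, sample metadata,
    neuropsychological scores, gene-probe map, qPCR plate and standards, the
    ground-truth JSON and a manifest recording every parameter, seed, file
    digest and row count. Running the pipeline on this directory requires no
    further inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, neuropsych = simulate_cohort(params, seed)
    oe, lb_paired, expr_truth = simulate_expression_pair(
        params, samples, neuropsych, seed)
    np_samples, _ = simulate_cohort(
        params, seed + 104729, n_sz=params.n_lb_nonpaired_sz,
        n_control=params.n_lb_nonpaired_control,
        tissue="LB_nonpaired", id_prefix="NP")
    lb_nonpaired = simulate_null_matrix(
        params, oe.probe_ids, np_samples["sample_id"].tolist(), seed)
    plate, qpcr_truth = simulate_qpcr_plate(params, samples, seed)
    truth = _merge_truth(expr_truth, qpcr_truth)

    all_samples = pd.concat([samples, np_samples], ignore_index=True)

    paths = {
        "expression_oe": out / "expression_oe.tsv",
        "expression_lb_paired": out / "expression_lb_paired.tsv",
        "expression_lb_nonpaired": out / "expression_lb_nonpaired.tsv",
        "samples": out / "samples.tsv",
        "neuropsych": out / "neuropsych.tsv",
        "gene_map": out / "gene_map.tsv",
        "qpcr_measurements": out / "qpcr_measurements.tsv",
        "qpcr_standards": out / "qpcr_standards.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_expression_matrix(oe, paths["expression_oe"])
    write_expression_matrix(lb_paired, paths["expression_lb_paired"])
    write_expression_matrix(lb_nonpaired, paths["expression_lb_nonpaired"])
    all_samples.to_csv(paths["samples"], sep="\t", index=False,
                       float_format="%.6g")
    neuropsych.to_csv(paths["neuropsych"], sep="\t", index=False,
                      float_format="%.12g")
    _gene_map_frame(oe.probe_ids).to_csv(paths["gene_map"], sep="\t", index=False)
    plate.measurements.to_csv(paths["qpcr_measurements"], sep="\t", index=False,
                              float_format="%.8g")
    plate.standards.to_csv(paths["qpcr_standards"], sep="\t", index=False,
                           float_format="%.8g")
    truth.to_json(paths["ground_truth"])

    digests = {name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
               for name, p in paths.items()}
    manifest = {
        "seed": seed,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(params).items()},
        "files": {name: str(Path(p).name) for name, p in paths.items()},
        "sha256": digests,
        "rows": {
            "samples": int(len(all_samples)),
            "neuropsych": int(len(neuropsych)),
            "probes": int(oe.shape[0]),
            "qpcr_measurements": int(len(plate.measurements)),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
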