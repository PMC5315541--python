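"""Neuropsychological score normalization and cohort comparison tables.

Raw domain scores from SZ patients are regressed on sex and years of
education; the residuals ("actual minus expected score") are standardized to
Z-scores. The composite is treated as its own score set — regressed and
Z-scored directly, not rebuilt from the domain Zs. A cohort summary table
reproduces the demographic/cognitive group comparisons: t-tests on the
continuous rows, exact Fisher tests on the categorical ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_stats import (
    DegenerateInputError,
    fisher_exact_2x2,
    fisher_exact_rxc,
    ols_residualize,
    welch_t,
    zscore_vector,
)
from .io_model import DOMAINS, SCORE_SETS

logger = logging.getLogger(__name__)

__all__ = ["NormalizedScores", "compute_composite", "normalize_scores",
           "demographics_table"]


@dataclass
class NormalizedScores:
    """Covariate-adjusted Z-scores for one group of subjects.

    ``z`` is subjects x score-sets (six domains + composite), each column
    mean 0 / sample sd 1; ``coefficients`` records the per-score OLS fit
    (intercept, sex, education) used for the adjustment.
    """

    z: pd.DataFrame
    coefficients: pd.DataFrame
    group: str = "SZ"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.index)


def compute_composite(domain_scores) -> float:
    """Arithmetic mean of the six domain scores."""
    arr = np.asarray(domain_scores, dtype=float)
    if arr.shape != (len(DOMAINS),):
        raise ValueError(f"expected {len(DOMAINS)} domain scores, got {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("domain scores must be finite")
    return float(arr.mean())


def normalize_scores(neuropsych: pd.DataFrame, samples: pd.DataFrame,
                     group: str = "SZ") -> NormalizedScores:
    """Residualize each score set on sex + education, then Z-score.

    Restricted to the requested group (the correlation screen is limited to
    SZ patients). Sex enters coded 0/1; the residuals are provably invariant
    to that coding choice and to affine rescaling of the education units.
    """
    meta = samples.set_index("sample_id")
    ids = [s for s in neuropsych["sample_id"] if meta.loc[s, "group"] == group]
    if len(ids) < 4:
        raise ValueError(f"need >= 4 {group} subjects, got {len(ids)}")
    sub = neuropsych.set_index("sample_id").loc[ids]
    sex01 = (meta.loc[ids, "sex"] == "male").astype(float).to_numpy()
    edu = meta.loc[ids, "education"].astype(float).to_numpy()
    covariates = np.column_stack([sex01, edu])
    constant_cov = [bool(np.unique(col).size == 1) for col in covariates.T]
    if all(constant_cov):
        # both covariates constant: adjustment degenerates to plain Z-scores
        covariates = np.empty((len(ids), 0))
    elif any(constant_cov):
        covariates = covariates[:, [not c for c in constant_cov]]

    z_cols, coef_rows = {}, []
    for score in SCORE_SETS:
        y = sub[score].to_numpy(dtype=float)
        resid = ols_residualize(y, covariates)
        if np.allclose(resid, 0.0, atol=1e-10):
            raise DegenerateInputError(
                f"{score}: scores are an exact function of the covariates")
        z_cols[score] = zscore_vector(resid)
        design = np.column_stack([np.ones(len(ids)), covariates])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        row = {"score": score, "intercept": beta[0]}
        names = [n for n, c in zip(("sex", "education"), constant_cov) if not c]
        for name, b in zip(names, beta[1:]):
            row[name] = b
        coef_rows.append(row)
    z = pd.DataFrame(z_cols, index=pd.Index(ids, name="sample_id"))
    return NormalizedScores(z=z, coefficients=pd.DataFrame(coef_rows),
                            group=group)


def _categorical_row(samples: pd.DataFrame, column: str,
                     levels: list[str]) -> tuple[str, float]:
    """Counts string + Fisher p for a categorical characteristic.

    Missing values are excluded row-wise before the test (they still appear
    in the printed counts as an NA tally).
    """
    counts = {}
    for g in ("SZ", "control"):
        vals = samples.loc[samples["group"] == g, column]
        counts[g] = [int((vals == lev).sum()) for lev in levels]
        counts[g].append(int(vals.isna().sum()))
    table = np.array([counts["SZ"][:-1], counts["control"][:-1]])
    nonzero_cols = table.sum(axis=0) > 0
    table = table[:, nonzero_cols]
    if table.shape[1] < 2:
        logger.warning("%s: fewer than two observed levels, no test", column)
        p = float("nan")
    elif table.shape[1] == 2:
        p = fisher_exact_2x2(table).p_value
    else:
        p = fisher_exact_rxc(table).p_value
    fmt = "/".join(str(v) for v in counts["SZ"]) + " vs " + \
          "/".join(str(v) for v in counts["control"])
    return fmt, p


def demographics_table(samples: pd.DataFrame,
                       neuropsych: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cohort summary: continuous rows via Welch's t, categorical via Fisher.

    Continuous rows are formatted "mean±s.d. vs mean±s.d."; the smoking row
    dichotomizes packs/day into yes (>0) / no, with missing values counted
    separately and excluded from the test.
    """
    rows = []
    sz = samples[samples["group"] == "SZ"]
    ctrl = samples[samples["group"] == "control"]

    def cont_row(name, a, b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        res = welch_t(a, b)
        rows.append({
            "characteristic": name,
            "summary": f"{a.mean():.1f}±{a.std(ddof=1):.1f} vs "
                       f"{b.mean():.1f}±{b.std(ddof=1):.1f}",
            "test": res.method, "p_value": res.p_value,
        })

    cont_row("age", sz["age"], ctrl["age"])
    cont_row("education", sz["education"], ctrl["education"])

    tmp = samples.copy()
    tmp["sex_level"] = tmp["sex"]
    fmt, p = _categorical_row(tmp, "sex_level", ["male", "female"])
    rows.append({"characteristic": "sex (male/female/NA)", "summary": fmt,
                 "test": "fisher_exact", "p_value": p})

    levels = sorted(samples["race"].dropna().unique())
    fmt, p = _categorical_row(samples, "race", levels)
    rows.append({"characteristic": f"race ({'/'.join(levels)}/NA)",
                 "summary": fmt, "test": "fisher_exact", "p_value": p})

    tmp = samples.copy()
    tmp["smoking_yes"] = tmp["smoking_packs_per_day"].map(
        lambda v: np.nan if pd.isna(v) else ("yes" if v > 0 else "no"))
    fmt, p = _categorical_row(tmp, "smoking_yes", ["yes", "no"])
    rows.append({"characteristic": "smoking (yes/no/NA)", "summary": fmt,
                 "test": "fisher_exact", "p_value": p})

    if neuropsych is not None:
        merged = neuropsych.merge(samples[["sample_id", "group"]], on="sample_id")
        for score in ("composite", *DOMAINS):
            cont_row(score,
                     merged.loc[merged["group"] == "SZ", score],
                     merged.loc[merged["group"] == "control", score])
    return pd.DataFrame(rows)
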