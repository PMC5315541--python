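"""Standard-curve qPCR quantification and group comparison.

Quantification follows the standard-curve method: for each gene, an OLS fit
of Ct on log10(quantity) over a dilution series gives slope and intercept
(amplification efficiency 10^(-1/slope) - 1); triplicate sample Cts are
averaged on the Ct scale, inverted through the curve to a quantity, and
ratioed to the same sample's reference-gene quantity (GAPDH by default).
Group comparison applies Tukey 1.5-IQR outlier removal to the per-gene
ratios, then Welch's t-test; medication and smoking effects are probed with
per-gene OLS of the ratio on the covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_stats import TestResult, iqr_outlier_mask, welch_t
from .synthetic import QpcrPlate

logger = logging.getLogger(__name__)

__all__ = ["StandardCurve", "fit_standard_curve", "fit_all_curves",
           "quantify_relative", "compare_groups_qpcr", "covariate_regression",
           "load_qpcr_plate"]


@dataclass(frozen=True)
class StandardCurve:
    gene: str
    slope: float          # Ct per log10 quantity; negative for real assays
    intercept: float      # Ct at quantity 1
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(f"{self.gene}: standard-curve slope must be negative")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def quantity(self, ct: float) -> float:
        """Invert the curve: q = 10^((Ct - intercept) / slope)."""
        return 10.0 ** ((ct - self.intercept) / self.slope)


def load_qpcr_plate(measurements_path, standards_path,
                    reference_gene: str = "GAPDH") -> QpcrPlate:
    return QpcrPlate(
        measurements=pd.read_csv(measurements_path, sep="\t",
                                 dtype={"sample_id": str}),
        standards=pd.read_csv(standards_path, sep="\t"),
        reference_gene=reference_gene,
    )


def fit_standard_curve(standards: pd.DataFrame, gene: str | None = None) -> StandardCurve:
    """OLS of Ct on log10(quantity) over the dilution series of one gene."""
    df = standards
    if gene is not None:
        df = df[df["gene"] == gene]
    elif "gene" in df.columns and df["gene"].nunique() == 1:
        gene = str(df["gene"].iloc[0])
    else:
        raise ValueError("specify the gene when standards hold several")
    q = df["quantity"].to_numpy(dtype=float)
    ct = df["ct"].to_numpy(dtype=float)
    if (q <= 0).any():
        raise ValueError("standard quantities must be positive")
    distinct = np.unique(q)
    if distinct.size < 3:
        raise ValueError(f"{gene}: need >= 3 distinct standard quantities")
    span = np.log10(distinct.max() / distinct.min())
    if span < 2.0:
        raise ValueError(f"{gene}: dilution series spans only {span:.2f} log10 units")
    x = np.log10(q)
    slope, intercept = np.polyfit(x, ct, 1)
    fitted = slope * x + intercept
    ss_res = float(((ct - fitted) ** 2).sum())
    ss_tot = float(((ct - ct.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return StandardCurve(gene=gene, slope=float(slope),
                         intercept=float(intercept), r_squared=r2)


def fit_all_curves(plate: QpcrPlate) -> dict[str, StandardCurve]:
    return {g: fit_standard_curve(plate.standards, g)
            for g in plate.standards["gene"].unique()}


def quantify_relative(plate: QpcrPlate,
                      curves: dict[str, StandardCurve] | None = None) -> pd.DataFrame:
    """Relative expression of every target gene in every sample.

    Triplicate Cts are averaged first (on the Ct scale), converted to
    quantities through the gene's standard curve, and divided by the
    same-sample reference quantity.
    """
    if curves is None:
        curves = fit_all_curves(plate)
    meas = plate.measurements.copy()
    for g in meas["gene"].unique():
        if g not in curves:
            raise ValueError(f"no standard curve for gene {g}")
    meas["ct_mean"] = meas[["ct1", "ct2", "ct3"]].mean(axis=1)
    meas["quantity"] = [curves[g].quantity(ct)
                        for g, ct in zip(meas["gene"], meas["ct_mean"])]
    ref = meas[meas["gene"] == plate.reference_gene]
    ref_q = dict(zip(ref["sample_id"], ref["quantity"]))
    targets = meas[meas["gene"] != plate.reference_gene].copy()
    missing = sorted(set(targets["sample_id"]) - set(ref_q))
    if missing:
        raise ValueError(f"samples lack a reference-gene measurement: {missing}")
    targets["reference_quantity"] = targets["sample_id"].map(ref_q)
    targets["ratio"] = targets["quantity"] / targets["reference_quantity"]
    return (targets[["gene", "sample_id", "ct_mean", "quantity",
                     "reference_quantity", "ratio"]]
            .sort_values(["gene", "sample_id"], kind="mergesort")
            .reset_index(drop=True))


def compare_groups_qpcr(rel: pd.DataFrame, samples: pd.DataFrame,
                        pool_outlier_groups: bool = True,
                        quartile_method: str = "linear",
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene Welch comparison of SZ vs control relative expression.

    Ratios are screened with the 1.5-IQR Tukey rule per gene (pooled across
    groups by default, per group if ``pool_outlier_groups=False``) before
    testing. Returns the per-gene result table and an outlier report listing
    every removed point with its fence.
    """
    grp = dict(zip(samples["sample_id"], samples["group"]))
    rows, removed = [], []
    for gene, sub in rel.groupby("gene", sort=True):
        sub = sub.copy()
        sub["group"] = sub["sample_id"].map(grp)
        if sub["group"].isna().any():
            raise ValueError(f"{gene}: samples missing from the metadata")
        if pool_outlier_groups:
            mask = iqr_outlier_mask(sub["ratio"].to_numpy(),
                                    quartile_method=quartile_method)
        else:
            mask = np.zeros(len(sub), dtype=bool)
            for g in ("SZ", "control"):
                sel = (sub["group"] == g).to_numpy()
                mask[sel] = iqr_outlier_mask(sub.loc[sel, "ratio"].to_numpy(),
                                             quartile_method=quartile_method)
        for _, r in sub[mask].iterrows():
            removed.append({"gene": gene, "sample_id": r["sample_id"],
                            "ratio": r["ratio"], "reason": "outside 1.5*IQR fence"})
        kept = sub[~mask]
        a = kept.loc[kept["group"] == "SZ", "ratio"].to_numpy()
        b = kept.loc[kept["group"] == "control", "ratio"].to_numpy()
        if len(a) < 4 or len(b) < 4:
            raise ValueError(f"{gene}: a group collapsed below n=4 after "
                             "outlier removal")
        res: TestResult = welch_t(a, b)
        rows.append({"gene": gene, "n_sz": len(a), "n_control": len(b),
                     "mean_ratio_sz": a.mean(), "mean_ratio_control": b.mean(),
                     "statistic": res.statistic, "df": res.df,
                     "p_value": res.p_value, "n_outliers_removed": int(mask.sum())})
    return pd.DataFrame(rows), pd.DataFrame(
        removed, columns=["gene", "sample_id", "ratio", "reason"])


def covariate_regression(rel: pd.DataFrame, samples: pd.DataFrame,
                         covariate: str, group: str = "SZ") -> pd.DataFrame:
    """Per-gene OLS of relative expression on one clinical covariate.

    Used for the medication (chlorpromazine-equivalent dose) and smoking
    (packs/day) checks, restricted to the SZ group; subjects with a missing
    covariate are dropped row-wise.
    """
    meta = samples.set_index("sample_id")
    rows = []
    for gene, sub in rel.groupby("gene", sort=True):
        sub = sub[[s in meta.index and meta.loc[s, "group"] == group
                   for s in sub["sample_id"]]]
        x = meta.loc[sub["sample_id"], covariate].to_numpy(dtype=float)
        y = sub["ratio"].to_numpy(dtype=float)
        keep = np.isfinite(x)
        x, y = x[keep], y[keep]
        if len(x) < 4:
            raise ValueError(f"{gene}: fewer than 4 {group} subjects with "
                             f"{covariate}")
        if np.unique(x).size < 2:
            raise ValueError(f"{gene}: covariate {covariate} is constant")
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        rows.append({"gene": gene, "covariate": covariate, "n": len(x),
                     "slope": float(fit.params[1]),
                     "p_value": float(fit.pvalues[1]),
                     "r_squared": float(fit.rsquared)})
    return pd.DataFrame(rows)
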