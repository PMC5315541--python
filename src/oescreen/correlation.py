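"""Stage 2: screen FDR-significant probes against cognition within patients.

For every stage-1 significant probe and each of the seven score sets (six
domains + composite) the screen computes the Spearman correlation across SZ
patients and a permutation p-value, retaining pairs below the raw p cutoff
(0.01 by default). No multiplicity correction is applied across the seven
score sets — the design applies a raw filter after the FDR-controlled first
stage, and that choice is deliberate and documented.

Permutations are vectorized: one permutation-index matrix per score set is
shared across all probes (each probe's null is still exact; sharing only
couples the Monte-Carlo noise between probes), which keeps a 10^4-10^6
permutation screen over thousands of probes tractable. At n <= 7 patients
the screen switches to exhaustive enumeration of all n! permutations and
becomes seed-independent.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cognition import NormalizedScores
from .io_model import SCORE_SETS, AnalysisConfig, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["screen_candidates", "summarize_candidates"]

_CANDIDATE_COLUMNS = ["domain", "gene_symbol", "probe_set_id", "fold_change",
                      "rho", "permutation_p", "n_patients"]
_TIE_EPS = 1e-12
_CHUNK_CELLS = 5_000_000   # permutations x probes per vectorized block


def _rank_unit_rows(X: np.ndarray) -> np.ndarray:
    r = stats.rankdata(X, axis=1)
    r -= r.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(r, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("constant probe rows cannot be rank-correlated")
    return r / norms


def _batch_permutation_p(R: np.ndarray, u: np.ndarray, n_perm: int,
                         rng: np.random.Generator | None,
                         sided: str) -> tuple[np.ndarray, np.ndarray, bool]:
    """Observed rho and permutation p for every probe row of R against u."""
    n = u.size
    rho_obs = R @ u
    exhaustive = n <= 7
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
        total = perms.shape[0]
        perms_matrix = u[perms] @ R.T
        if sided == "two":
            extreme = (np.abs(perms_matrix) >= np.abs(rho_obs)[None, :] - _TIE_EPS).sum(axis=0)
        else:
            extreme = (perms_matrix >= rho_obs[None, :] - _TIE_EPS).sum(axis=0)
        return rho_obs, extreme / total, True

    extreme = np.zeros(R.shape[0], dtype=np.int64)
    chunk = max(1, _CHUNK_CELLS // max(1, R.shape[0]))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((m, n)), axis=1)
        rho_perm = u[idx] @ R.T
        if sided == "two":
            extreme += (np.abs(rho_perm) >= np.abs(rho_obs)[None, :] - _TIE_EPS).sum(axis=0)
        else:
            extreme += (rho_perm >= rho_obs[None, :] - _TIE_EPS).sum(axis=0)
        done += m
    return rho_obs, (1 + extreme) / (n_perm + 1), False


def screen_candidates(matrix: ExpressionMatrix, de_table: pd.DataFrame,
                      scores: NormalizedScores, gene_map=None,
                      config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Correlation filter over stage-1 significant probes.

    Parameters
    ----------
    matrix : full expression matrix (only SZ patient columns are read).
    de_table : output of :func:`oescreen.de.run_de`; rows with
        ``q_value < config.fdr_alpha`` enter the screen.
    scores : covariate-adjusted Z-scores of the SZ patients.
    gene_map : optional gene-symbol -> probe-set mapping used to annotate
        probes (multi-mapped probes get ';'-joined symbols).

    Returns one row per retained (probe, score-set) pair with the Spearman
    rho, permutation p, the probe's stage-1 fold change and the patient n.
    """
    sz_ids = scores.sample_ids
    missing = [s for s in sz_ids if s not in matrix.sample_ids]
    if missing:
        raise ValueError(f"score subjects missing from expression: {missing}")
    sig = de_table.loc[de_table["q_value"] < config.fdr_alpha]
    if sig.empty:
        logger.warning("stage-1 significant set is empty; nothing to screen")
        return pd.DataFrame(columns=_CANDIDATE_COLUMNS)

    sub = matrix.subset_samples(sz_ids)
    probe_pos = {p: i for i, p in enumerate(sub.probe_ids)}
    rows_idx = [probe_pos[p] for p in sig["probe_id"]]
    R = _rank_unit_rows(sub.values[rows_idx])
    fc = dict(zip(sig["probe_id"], sig["fold_change"]))

    probe_genes: dict[str, str] = {}
    if gene_map:
        inv: dict[str, list[str]] = {}
        for gene, probes in gene_map.items():
            for probe in probes:
                inv.setdefault(probe, []).append(gene)
        probe_genes = {p: ";".join(sorted(g)) for p, g in inv.items()}

    records = []
    n = len(sz_ids)
    for k, score_set in enumerate(SCORE_SETS):
        u = stats.rankdata(scores.z[score_set].to_numpy())
        u -= u.mean()
        u /= np.linalg.norm(u)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, k]))
        rho, p, exhaustive = _batch_permutation_p(
            R, u, config.n_permutations, rng, config.permutation_sided)
        if config.corr_p_cutoff >= 1.0:     # filter disabled
            keep = np.arange(p.size)
        else:
            keep = np.flatnonzero(p < config.corr_p_cutoff)
        for i in keep:
            probe = sig["probe_id"].iloc[i]
            records.append({
                "domain": score_set,
                "gene_symbol": probe_genes.get(probe, probe),
                "probe_set_id": probe,
                "fold_change": fc[probe],
                "rho": float(rho[i]),
                "permutation_p": float(p[i]),
                "n_patients": n,
            })
    out = pd.DataFrame(records, columns=_CANDIDATE_COLUMNS)
    if len(out):
        out["domain"] = pd.Categorical(out["domain"], categories=SCORE_SETS)
        out = (out.sort_values(["domain", "permutation_p", "probe_set_id"],
                               kind="mergesort").reset_index(drop=True))
        out["domain"] = out["domain"].astype(str)
    return out


def summarize_candidates(records: pd.DataFrame) -> dict:
    """Unique gene symbols overall and per score set.

    Probes annotated to several genes (';'-joined) contribute each symbol;
    duplicated rows are counted once. Genes retained under more than one
    score set are flagged separately.
    """
    if records is None or len(records) == 0:
        return {"n_unique_genes": 0, "unique_genes": [], "per_domain": {},
                "multi_domain_genes": []}

    def split(sym: str) -> list[str]:
        return [s for s in str(sym).split(";") if s]

    per_domain: dict[str, list[str]] = {}
    gene_domains: dict[str, set[str]] = {}
    for _, row in records.drop_duplicates().iterrows():
        for g in split(row["gene_symbol"]):
            per_domain.setdefault(row["domain"], [])
            if g not in per_domain[row["domain"]]:
                per_domain[row["domain"]].append(g)
            gene_domains.setdefault(g, set()).add(row["domain"])
    unique = sorted(gene_domains)
    multi = sorted(g for g, d in gene_domains.items() if len(d) > 1)
    return {
        "n_unique_genes": len(unique),
        "unique_genes": unique,
        "per_domain": {d: sorted(genes) for d, genes in per_domain.items()},
        "multi_domain_genes": multi,
    }
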