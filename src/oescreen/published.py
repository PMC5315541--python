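"""Printed summary inputs from the olfactory-epithelium cohort study.

These are the study's published tabular numbers — demographic counts,
mean +/- s.d. summaries, enrichment counts and the 21-row candidate list —
carried as inputs so the corresponding statistics can be recomputed from
scratch. Raw per-subject data are not public; everything here is a printed
summary, not a measurement.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "PAIRED_SMOKING", "NONPAIRED_SMOKING", "NONPAIRED_SEX", "PAIRED_SEX",
    "PAIRED_RACE", "NONPAIRED_RACE", "AGE_NONPAIRED", "EDUCATION_NONPAIRED",
    "COGNITION_SUMMARY", "ARRAY_N_PROBES", "N_DE_TRANSCRIPTS",
    "RISK_LOCI_PROBES", "RISK_LOCI_OVERLAP", "REFERENCE_NETWORK_EDGES",
    "OE_NETWORK_EDGE_OVERLAP", "DE_PAIR_EDGE_OVERLAP", "candidate_table",
]

# --- categorical demographic counts: rows = (SZ, control) ------------------
PAIRED_SMOKING = [[9, 7], [3, 12]]          # smoker yes/no; printed p 0.07
NONPAIRED_SMOKING = [[10, 5], [5, 13]]      # printed p 0.04 (1 SZ NA excluded)
PAIRED_SEX = [[12, 4], [11, 4]]             # male/female
NONPAIRED_SEX = [[11, 5], [14, 4]]          # printed p 0.70
PAIRED_RACE = [[6, 10], [6, 9]]             # Caucasian/African American
NONPAIRED_RACE = [[3, 12, 1], [9, 8, 1]]    # +others; printed p 0.09

# --- continuous summaries: (mean, sd, n) per group -------------------------
AGE_NONPAIRED = ((36.4, 11.2, 16), (35.6, 11.1, 18))       # printed p 0.84
EDUCATION_NONPAIRED = ((12.3, 2.4, 16), (12.9, 1.9, 18))   # printed p 0.35

# cognition rows, paired cohort (SZ n=16 vs control n=15)
COGNITION_SUMMARY = {
    "composite": ((8.6, 1.5, 16), (9.9, 1.6, 15)),          # printed p 0.03
    "processing_speed": ((8.9, 2.0, 16), (11.0, 2.4, 15)),
    "attention_working_memory": ((8.7, 2.1, 16), (10.6, 2.6, 15)),
    "verbal_learning_memory": ((9.6, 1.9, 16), (9.8, 2.6, 15)),
    "visual_learning_memory": ((9.5, 1.9, 16), (9.6, 2.8, 15)),
    "executive_functioning": ((9.3, 2.4, 16), (10.7, 2.5, 15)),
    "ideational_fluency": ((5.7, 1.8, 16), (7.8, 1.7, 15)),
}

# --- enrichment counts -----------------------------------------------------
ARRAY_N_PROBES = 54675          # U133 Plus 2.0 probe sets
N_DE_TRANSCRIPTS = 2574         # FDR < 0.05 in OE
RISK_LOCI_PROBES = 727          # probe sets for the 108-risk-loci gene set
RISK_LOCI_OVERLAP = 48          # of those also differentially expressed (6.6%)
REFERENCE_NETWORK_EDGES = 1645  # cell-line co-regulation network edges
OE_NETWORK_EDGE_OVERLAP = 82    # OE control-network edges shared (4.98%)
DE_PAIR_EDGE_OVERLAP = 3        # differential gene pairs on the network (<1%)

# --- published candidate list: 21 (score set, gene, probe) rows ------------
_CANDIDATE_ROWS = [
    ("composite", "SMAD5", "225223_at", -1.2, 0.65, 0.004),
    ("composite", "PABPC4L", "238865_at", -2.2, 0.63, 0.005),
    ("processing_speed", "SMAD5", "225223_at", -1.2, 0.70, 0.002),
    ("attention_working_memory", "RBM28", "218593_at", -1.4, 0.72, 0.001),
    ("attention_working_memory", "RAB4A", "203581_at", 1.3, -0.71, 0.001),
    ("attention_working_memory", "ERO1LB", "231944_at", -1.3, 0.69, 0.002),
    ("attention_working_memory", "CCL11", "210133_at", -3.3, 0.64, 0.005),
    ("attention_working_memory", "CD69", "209795_at", -2.5, 0.64, 0.005),
    ("verbal_learning_memory", "NGDN", "216263_s_at", -2.0, 0.64, 0.004),
    ("verbal_learning_memory", "SMAD5", "225223_at", -1.2, 0.62, 0.006),
    ("visual_learning_memory", "PABPC4L", "238865_at", -2.2, 0.78, 0.000),
    ("visual_learning_memory", "SRGN", "201859_at", -1.8, 0.66, 0.003),
    ("executive_functioning", "ZFP36L1", "211962_s_at", -1.2, 0.69, 0.002),
    ("executive_functioning", "AP5S1", "219706_at", 1.4, -0.64, 0.005),
    ("executive_functioning", "SERPINA12", "1552544_at", 1.02, -0.63, 0.005),
    ("executive_functioning", "LYPLA2", "215568_x_at", 1.2, -0.63, 0.005),
    ("executive_functioning", "SMC6", "218781_at", -1.4, 0.63, 0.005),
    ("ideational_fluency", "LINC01004", "235217_at", -1.3, 0.69, 0.002),
    ("ideational_fluency", "COA3", "218026_at", 1.4, 0.64, 0.004),
    ("ideational_fluency", "CBFA2T2", "238549_at", -1.9, -0.64, 0.004),
]


def candidate_table() -> pd.DataFrame:
    """The published candidate list as a candidate-record DataFrame."""
    df = pd.DataFrame(_CANDIDATE_ROWS, columns=[
        "domain", "gene_symbol", "probe_set_id", "fold_change", "rho",
        "permutation_p"])
    df["n_patients"] = 16
    return df
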