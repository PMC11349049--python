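"""TCR repertoire analytics: Chao1 diversity, cross-patient clone
sharing, and blood-tumor repertoire overlap.

Clones are identified by exact CDR3 amino-acid sequence within a chain
(TRA or TRB). Chao1 estimates total clonal richness from the observed
richness plus the singleton/doubleton counts:

    chao1 = S_obs + f1^2 / (2 f2)          (classic, f2 > 0)
    chao1 = S_obs + f1 (f1 - 1) / 2        (bias-corrected, f2 = 0)
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

_AA = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

CLONE_COLUMNS = [
    "patient_id", "chain", "cdr3_aa", "count", "compartment", "timepoint",
]


class Chao1Variant(str, Enum):
    CLASSIC = "CLASSIC"
    BIAS_CORRECTED = "BIAS_CORRECTED"


@dataclass
class DiversityResult:
    s_obs: int
    f1: int
    f2: int
    chao1: float
    variant: Chao1Variant


def validate_clone_table(records: pd.DataFrame) -> pd.DataFrame:
    """Check the AIRR-style clone table: CDR3s are uppercase amino-acid
    strings, counts positive integers."""
    if records.empty:
        raise ValueError("empty clone table")
    bad = ~records["cdr3_aa"].astype(str).str.match(_AA)
    if bad.any():
        raise ValueError(f"invalid CDR3 sequences: {records.loc[bad, 'cdr3_aa'].head().tolist()}")
    if (records["count"] < 1).any():
        raise ValueError("clone counts must be >= 1")
    return records


def chao1(counts: Sequence[int]) -> DiversityResult:
    """Chao1 richness estimate from a vector of clone abundances."""
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("empty abundance vector")
    if np.any(c < 1) or not np.issubdtype(c.dtype, np.integer):
        raise ValueError("abundances must be positive integers")
    s_obs = int(c.size)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        est = s_obs + f1 * f1 / (2.0 * f2)
        variant = Chao1Variant.CLASSIC
    else:
        est = s_obs + f1 * (f1 - 1) / 2.0
        variant = Chao1Variant.BIAS_CORRECTED
    return DiversityResult(s_obs=s_obs, f1=f1, f2=f2, chao1=float(est), variant=variant)


def diversity_table(records: pd.DataFrame, chain: str = "TRB") -> pd.DataFrame:
    """Chao1 per patient x compartment x timepoint for one chain.

    Duplicate clone rows (same clone key) are collapsed by summing
    counts before estimating.
    """
    validate_clone_table(records)
    sub = records[records["chain"] == chain]
    rows = []
    for (pat, comp, tp), grp in sub.groupby(
        ["patient_id", "compartment", "timepoint"], sort=True
    ):
        counts = grp.groupby("cdr3_aa")["count"].sum().to_numpy()
        d = chao1(counts)
        rows.append(
            {
                "patient_id": pat, "compartment": comp, "timepoint": tp,
                "chain": chain, "s_obs": d.s_obs, "f1": d.f1, "f2": d.f2,
                "chao1": d.chao1, "variant": d.variant.value,
            }
        )
    return pd.DataFrame(rows)


def shared_clones(records: pd.DataFrame, chain: str = "TRB") -> dict:
    """Cross-patient clone sharing for one chain.

    Returns a dict with a symmetric patient x patient shared-clone count
    matrix (diagonal = each patient's richness) and the list of public
    clones (carried by >= 2 patients) with their carrier sets.
    """
    validate_clone_table(records)
    sub = records[records["chain"] == chain]
    carriers = (
        sub.groupby("cdr3_aa")["patient_id"].agg(lambda s: frozenset(s)).to_dict()
    )
    patients = sorted(sub["patient_id"].unique())
    n = len(patients)
    idx = {p: i for i, p in enumerate(patients)}
    mat = np.zeros((n, n), dtype=int)
    public = []
    for cdr3, pats in carriers.items():
        ids = sorted(idx[p] for p in pats)
        for i in ids:
            for j in ids:
                mat[i, j] += 1
        if len(pats) >= 2:
            public.append({"chain": chain, "cdr3_aa": cdr3, "carriers": sorted(pats)})
    matrix = pd.DataFrame(mat, index=patients, columns=patients)
    return {"matrix": matrix, "public_clones": public}


def blood_tumor_overlap(records: pd.DataFrame, patient_id: str) -> pd.DataFrame:
    """Per peripheral T-cell subset: distinct blood clones and how many
    are also found in the same patient's tumor (exact CDR3 identity,
    within chain)."""
    validate_clone_table(records)
    sub = records[records["patient_id"] == patient_id]
    blood = sub[sub["compartment"] == "BLOOD"]
    tumor = sub[sub["compartment"] == "TUMOR"]
    if blood.empty or tumor.empty:
        raise ValueError(
            f"patient {patient_id!r}: needs records in both compartments (NOT_EVALUABLE)"
        )
    rows = []
    for chain, tsub in tumor.groupby("chain", sort=True):
        tumor_set = set(tsub["cdr3_aa"])
        bsub = blood[blood["chain"] == chain]
        if "subset_label" in bsub.columns and bsub["subset_label"].notna().any():
            groups = bsub.groupby(bsub["subset_label"].fillna("UNLABELED"), sort=True)
        else:
            groups = [("ALL", bsub)]
        for label, g in groups:
            clones = set(g["cdr3_aa"])
            rows.append(
                {
                    "patient_id": patient_id,
                    "chain": chain,
                    "subset": label,
                    "blood_richness": len(clones),
                    "in_tumor": len(clones & tumor_set),
                }
            )
    return pd.DataFrame(rows)
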