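"""Circulating tumor DNA analytics.

A tumor-informed 16-SNV panel tracks patient-specific variants in
longitudinal plasma. A sample is ctDNA positive when at least 2 of the
16 SNVs are detected; concentration is reported as mean tumor molecules
per mL of plasma (MTM/ml). Molecular response is a >= 50% decrease from
the pretreatment level; group comparisons work on baseline-adjusted
log10 concentrations, and association with clinical response uses
logistic regression on log10 baseline levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compare import student_t_two_sample
from .endpoints import LogisticFit, fit_logistic_wald


@dataclass
class CtdnaMeasurement:
    patient_id: str
    timepoint: str
    snvs_detected: int
    mtm_per_ml: float
    snvs_assayed: int = 16

    def __post_init__(self) -> None:
        if not 0 <= self.snvs_detected <= self.snvs_assayed:
            raise ValueError("snvs_detected must lie in [0, snvs_assayed]")
        if self.mtm_per_ml < 0:
            raise ValueError("mtm_per_ml must be nonnegative")


@dataclass
class MolecularResponseCall:
    patient_id: str
    baseline_mtm: float
    on_treatment_mtm: float
    decreased_50: bool | None
    evaluable: bool


def positivity(m: CtdnaMeasurement, min_snvs: int = 2) -> bool:
    """ctDNA positive iff at least `min_snvs` of the assayed SNVs are
    detected."""
    return m.snvs_detected >= min_snvs


def classify_decrease(
    baseline: CtdnaMeasurement, on_tx: CtdnaMeasurement
) -> MolecularResponseCall:
    """Molecular response: on-treatment MTM/ml at or below half of the
    baseline level. Patients with zero baseline are not evaluable."""
    if baseline.patient_id != on_tx.patient_id:
        raise ValueError("measurements belong to different patients")
    evaluable = baseline.mtm_per_ml > 0
    call = (on_tx.mtm_per_ml <= 0.5 * baseline.mtm_per_ml) if evaluable else None
    return MolecularResponseCall(
        patient_id=baseline.patient_id,
        baseline_mtm=baseline.mtm_per_ml,
        on_treatment_mtm=on_tx.mtm_per_ml,
        decreased_50=call,
        evaluable=evaluable,
    )


def baseline_adjusted_comparison(
    measurements: pd.DataFrame,
    response: Mapping[str, str],
    groups: tuple[str, str] = ("CRPR", "PD"),
    baseline_tp: str = "BL",
    on_tx_tp: str = "C2D1",
) -> tuple[float, float, pd.DataFrame]:
    """Student t between response groups on per-patient baseline-adjusted
    log10 MTM/ml: delta = log10(on-treatment) - log10(baseline).

    Patients missing either timepoint or with a nonpositive MTM value at
    either are dropped with a warning. Returns (t, p, per-patient deltas).
    """
    deltas = []
    for pat, sub in measurements.groupby("patient_id", sort=True):
        bl = sub[sub["timepoint"] == baseline_tp]["mtm_per_ml"]
        on = sub[sub["timepoint"] == on_tx_tp]["mtm_per_ml"]
        if bl.empty or on.empty or bl.iloc[0] <= 0 or on.iloc[0] <= 0:
            warnings.warn(f"patient {pat!r}: unusable baseline/C2D1 pair; dropped",
                          stacklevel=2)
            continue
        if pat not in response:
            continue
        deltas.append(
            {
                "patient_id": pat,
                "delta_log10": float(np.log10(on.iloc[0]) - np.log10(bl.iloc[0])),
                "response": response[pat],
            }
        )
    df = pd.DataFrame(deltas)
    ga, gb = groups
    a = df.loc[df["response"] == ga, "delta_log10"].to_numpy()
    b = df.loc[df["response"] == gb, "delta_log10"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 evaluable patients per response group")
    t, p = student_t_two_sample(a, b)
    return t, p, df


def association_with_response(
    baseline_mtm: Sequence[float], outcome: Sequence[int]
) -> LogisticFit:
    """Logistic regression of a binary clinical outcome on log10 baseline
    ctDNA. Zeros are handled with an offset of half the smallest positive
    observed value before the log transform."""
    x = np.asarray(baseline_mtm, dtype=float)
    if np.all(x == 0) or np.ptp(x) == 0:
        raise ValueError("baseline MTM values are constant")
    if np.any(x == 0):
        offset = 0.5 * x[x > 0].min()
        x = x + offset
    return fit_logistic_wald(outcome, np.log10(x), term_names=("intercept", "log10_mtm"))


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():  # validation via the dataclass invariants
        CtdnaMeasurement(
            patient_id=str(row["patient_id"]),
            timepoint=str(row["timepoint"]),
            snvs_detected=int(row["snvs_detected"]),
            mtm_per_ml=float(row["mtm_per_ml"]),
            snvs_assayed=int(row.get("snvs_assayed", 16)),
        )
    return df
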