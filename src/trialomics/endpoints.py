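"""Clinical endpoint statistics for a CD8-stratified basket trial.

Best-overall-response classification (objective response, disease control,
CD8 conversion), Bayesian beta-binomial credible intervals for the trial's
proportion endpoints, logistic regression with Wald tests for
marker/outcome association, and Fisher's exact test for 2x2 tables.

The trial design this supports enrols patients into a CD8-high and a
CD8-low group by the percentage of intratumoral CD8 T cells at baseline
(cutoff 15%); the coprimary endpoints are the disease control rate and,
in the CD8-low group, the proportion of tumors that convert to CD8-high
(>=15%) on treatment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class Bor(str, Enum):
    """Best overall response (RECIST category)."""

    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NE = "NE"


class Cd8Group(str, Enum):
    CD8_HIGH = "CD8_HIGH"
    CD8_LOW = "CD8_LOW"


class ConversionStatus(str, Enum):
    CONVERTER = "CONVERTER"
    NON_CONVERTER = "NON_CONVERTER"
    NOT_EVALUABLE = "NOT_EVALUABLE"


class ConversionPrior(str, Enum):
    """Reading of "no prior" for the conversion-rate credible interval.

    IMPROPER_ZERO: improper Beta(0, 0) prior, posterior Beta(s, n - s).
    UNIFORM: flat Beta(1, 1) prior, posterior Beta(s + 1, n - s + 1).
    """

    IMPROPER_ZERO = "IMPROPER_ZERO"
    UNIFORM = "UNIFORM"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, matching clinical-report display."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EndpointConfig:
    """Endpoint definitions and interval settings.

    cd8_cutoff_pct: tumoral CD8 percentage separating CD8-low from CD8-high.
    sd_min_duration_weeks: minimum SD duration to count as disease control.
    dcr_orr_prior: Beta prior (alpha0, beta0) for DCR/ORR credible intervals.
    conversion_prior: prior reading for the conversion-rate interval.
    """

    cd8_cutoff_pct: float = 15.0
    sd_min_duration_weeks: float = 24.0
    ci_level: float = 0.95
    dcr_orr_prior: tuple[float, float] = (0.4, 1.6)
    conversion_prior: ConversionPrior = ConversionPrior.IMPROPER_ZERO

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        a0, b0 = self.dcr_orr_prior
        if a0 <= 0 or b0 <= 0:
            raise ValueError("dcr_orr_prior parameters must be positive")
        self.conversion_prior = ConversionPrior(self.conversion_prior)


@dataclass
class PatientRecord:
    """One enrolled patient.

    on_treatment_cd8_pcts may be empty (no evaluable on-treatment biopsy);
    when several on-treatment biopsies exist the maximum percentage is
    what conversion classification uses.
    """

    patient_id: str
    group: Cd8Group
    tumor_type: str
    baseline_cd8_pct: float
    on_treatment_cd8_pcts: list[float] = field(default_factory=list)
    best_overall_response: Bor = Bor.NE
    sd_duration_weeks: float | None = None
    prior_ici: bool = False

    def __post_init__(self) -> None:
        self.group = Cd8Group(self.group)
        self.best_overall_response = Bor(self.best_overall_response)
        for v in [self.baseline_cd8_pct, *self.on_treatment_cd8_pcts]:
            if not 0 <= v <= 100:
                raise ValueError(
                    f"patient {self.patient_id}: CD8 percentage {v} outside [0, 100]"
                )
        if self.best_overall_response is Bor.SD:
            if self.sd_duration_weeks is None:
                raise ValueError(
                    f"patient {self.patient_id}: BOR is SD but sd_duration_weeks missing"
                )
            if self.sd_duration_weeks < 0:
                raise ValueError("sd_duration_weeks must be nonnegative")
        elif self.sd_duration_weeks is not None:
            raise ValueError(
                f"patient {self.patient_id}: sd_duration_weeks given but BOR is not SD"
            )


@dataclass
class PosteriorInterval:
    """Equal-tailed posterior credible interval for a binomial proportion."""

    successes: int
    trials: int
    posterior_alpha: float
    posterior_beta: float
    level: float
    point_estimate_pct: float
    lower_pct: float
    upper_pct: float
    lower: float = 0.0  # unrounded quantiles, probability scale
    upper: float = 1.0

    def as_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class LogisticFit:
    """Logistic regression fit with Wald inference per coefficient."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_z: np.ndarray
    p_values: np.ndarray
    converged: bool
    term_names: list[str]

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])

    @property
    def slope_p(self) -> float:
        return float(self.p_values[1])


def classify_responder(record: PatientRecord) -> bool:
    """Objective response: best overall response of CR or PR."""
    return record.best_overall_response in (Bor.CR, Bor.PR)


def classify_disease_control(
    record: PatientRecord, cfg: EndpointConfig | None = None
) -> bool:
    """Disease control: CR, PR, or SD lasting at least the configured minimum."""
    cfg = cfg or EndpointConfig()
    if classify_responder(record):
        return True
    if record.best_overall_response is Bor.SD:
        # __post_init__ guarantees sd_duration_weeks is present for SD
        return record.sd_duration_weeks >= cfg.sd_min_duration_weeks
    return False


def classify_converter(
    record: PatientRecord, cfg: EndpointConfig | None = None
) -> ConversionStatus:
    """CD8 conversion: any on-treatment biopsy at or above the cutoff.

    Defined only for CD8-low patients; patients without an on-treatment
    biopsy are not evaluable.
    """
    cfg = cfg or EndpointConfig()
    if record.group is not Cd8Group.CD8_LOW:
        raise ValueError(
            f"patient {record.patient_id}: conversion is defined only for the CD8-low group"
        )
    if not record.on_treatment_cd8_pcts:
        return ConversionStatus.NOT_EVALUABLE
    if max(record.on_treatment_cd8_pcts) >= cfg.cd8_cutoff_pct:
        return ConversionStatus.CONVERTER
    return ConversionStatus.NON_CONVERTER


def beta_binomial_interval(
    s: int,
    n: int,
    prior: tuple[float, float] = (0.4, 1.6),
    level: float = 0.95,
) -> PosteriorInterval:
    """Equal-tailed posterior credible interval for s successes in n trials.

    The posterior is Beta(alpha0 + s, beta0 + n - s); the interval is the
    pair of (1 - level)/2 and 1 - (1 - level)/2 posterior quantiles
    (numerical inversion via the regularized incomplete beta function).
    Percentages are rounded to one decimal, half up.
    """
    if n < 1 or not 0 <= s <= n:
        raise ValueError(f"invalid counts: s={s}, n={n}")
    a0, b0 = prior
    if a0 <= 0 or b0 <= 0:
        raise ValueError("prior parameters must be positive")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a, b = a0 + s, b0 + n - s
    tail = (1.0 - level) / 2.0
    lo = float(stats.beta.ppf(tail, a, b))
    hi = float(stats.beta.ppf(1.0 - tail, a, b))
    return PosteriorInterval(
        successes=int(s),
        trials=int(n),
        posterior_alpha=a,
        posterior_beta=b,
        level=level,
        point_estimate_pct=round_half_up(100.0 * s / n),
        lower_pct=round_half_up(100.0 * lo),
        upper_pct=round_half_up(100.0 * hi),
        lower=lo,
        upper=hi,
    )


def conversion_interval(
    s: int, n: int, cfg: EndpointConfig | None = None
) -> PosteriorInterval:
    """Credible interval for the conversion proportion, "no prior" reading.

    Under IMPROPER_ZERO the posterior is Beta(s, n - s), which requires
    0 < s < n; under UNIFORM it is Beta(s + 1, n - s + 1).
    """
    cfg = cfg or EndpointConfig()
    if cfg.conversion_prior is ConversionPrior.IMPROPER_ZERO:
        if s == 0 or s == n:
            raise ValueError(
                "posterior Beta(s, n-s) is improper when s is 0 or n; "
                "use conversion_prior=UNIFORM"
            )
        a, b = float(s), float(n - s)
        prior_note = (0.0, 0.0)
    else:
        a, b = s + 1.0, n - s + 1.0
        prior_note = (1.0, 1.0)
    tail = (1.0 - cfg.ci_level) / 2.0
    lo = float(stats.beta.ppf(tail, a, b))
    hi = float(stats.beta.ppf(1.0 - tail, a, b))
    return PosteriorInterval(
        successes=int(s),
        trials=int(n),
        posterior_alpha=a,
        posterior_beta=b,
        level=cfg.ci_level,
        point_estimate_pct=round_half_up(100.0 * s / n),
        lower_pct=round_half_up(100.0 * lo),
        upper_pct=round_half_up(100.0 * hi),
        lower=lo,
        upper=hi,
    )


def conversion_interval_both(s: int, n: int, level: float = 0.95) -> dict:
    """Both "no prior" readings side by side, for reporting."""
    out = {}
    for prior in ConversionPrior:
        cfg = EndpointConfig(ci_level=level, conversion_prior=prior)
        try:
            out[prior.value] = conversion_interval(s, n, cfg)
        except ValueError:
            out[prior.value] = None
    return out


def fit_logistic_wald(
    outcome: Sequence[float] | np.ndarray,
    predictor: Sequence[float] | np.ndarray,
    term_names: tuple[str, str] = ("intercept", "slope"),
) -> LogisticFit:
    """Logistic regression of a binary outcome on one predictor.

    Fit by iteratively reweighted least squares (GLM with binomial family,
    logit link); two-sided Wald p-values from the normal reference on
    coefficient / SE. Convergence is declared when the score (gradient of
    the log-likelihood) has max absolute value below 1e-8; complete or
    quasi-complete separation leaves the score away from zero and is
    reported as a non-converged fit with a warning rather than silently.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("outcome and predictor must be 1-D of equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    X = sm.add_constant(x)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-12)
    separation = any("separation" in str(w.message).lower() for w in caught)
    params = np.asarray(res.params, dtype=float)
    mu = 1.0 / (1.0 + np.exp(-(X @ params)))
    # perfect prediction: coefficients diverge while the score underflows
    separation = separation or bool(np.max(np.abs(y - mu)) < 1e-6)
    score = X.T @ (y - mu)
    converged = bool(np.max(np.abs(score)) < 1e-8) and not separation
    if not converged:
        warnings.warn(
            "logistic fit did not reach score tolerance (possible complete or "
            "quasi-complete separation); Wald inference unreliable",
            stacklevel=2,
        )
    se = np.asarray(res.bse, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        coefficients=params,
        standard_errors=se,
        wald_z=z,
        p_values=p,
        converged=converged,
        term_names=list(term_names),
    )


def fisher_exact(table: Sequence[Sequence[int]] | np.ndarray) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table.

    Sums hypergeometric probabilities no larger than the observed table's.
    An empty margin carries no information; p = 1 by convention (warned).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table cells must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("empty margin in 2x2 table; p = 1 by convention", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# cohort summaries and I/O


def summarize_cohort(
    records: Iterable[PatientRecord], cfg: EndpointConfig | None = None
) -> dict:
    """Endpoint summary for a cohort: DCR/ORR per group with credible
    intervals, and conversion in the CD8-low group under both prior
    readings."""
    cfg = cfg or EndpointConfig()
    records = list(records)
    out: dict = {"n_total": len(records), "groups": {}}
    for grp in Cd8Group:
        sub = [r for r in records if r.group is grp]
        if not sub:
            continue
        n = len(sub)
        resp = sum(classify_responder(r) for r in sub)
        ctrl = sum(classify_disease_control(r, cfg) for r in sub)
        entry = {
            "n": n,
            "orr": beta_binomial_interval(resp, n, cfg.dcr_orr_prior, cfg.ci_level).as_dict(),
            "dcr": beta_binomial_interval(ctrl, n, cfg.dcr_orr_prior, cfg.ci_level).as_dict(),
        }
        if grp is Cd8Group.CD8_LOW:
            statuses = [classify_converter(r, cfg) for r in sub]
            evaluable = [s for s in statuses if s is not ConversionStatus.NOT_EVALUABLE]
            conv = sum(s is ConversionStatus.CONVERTER for s in evaluable)
            entry["conversion"] = {
                "converters": conv,
                "evaluable": len(evaluable),
                "point_estimate_pct": round_half_up(100.0 * conv / len(evaluable))
                if evaluable
                else None,
                "intervals": {
                    k: (v.as_dict() if v is not None else None)
                    for k, v in conversion_interval_both(
                        conv, len(evaluable), cfg.ci_level
                    ).items()
                }
                if evaluable
                else {},
            }
        out["groups"][grp.value] = entry
    return out


def read_patients(path: str | Path, cfg: EndpointConfig | None = None) -> list[PatientRecord]:
    """Read a patients.tsv table; on-treatment CD8 values pipe-separated."""
    cfg = cfg or EndpointConfig()
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        on_tx = [float(v) for v in str(row.get("on_treatment_cd8_pcts", "")).split("|") if v]
        sd_dur = row.get("sd_duration_weeks", "")
        rec = PatientRecord(
            patient_id=row["patient_id"],
            group=Cd8Group(row["group"]),
            tumor_type=row.get("tumor_type", "NA"),
            baseline_cd8_pct=float(row["baseline_cd8_pct"]),
            on_treatment_cd8_pcts=on_tx,
            best_overall_response=Bor(row["best_overall_response"]),
            sd_duration_weeks=float(sd_dur) if sd_dur != "" else None,
            prior_ici=str(row.get("prior_ici", "False")).lower() in ("1", "true", "yes"),
        )
        expected = (
            Cd8Group.CD8_LOW
            if rec.baseline_cd8_pct < cfg.cd8_cutoff_pct
            else Cd8Group.CD8_HIGH
        )
        if rec.group is not expected:
            raise ValueError(
                f"patient {rec.patient_id}: group {rec.group.value} inconsistent with "
                f"baseline CD8 {rec.baseline_cd8_pct}% at cutoff {cfg.cd8_cutoff_pct}%"
            )
        records.append(rec)
    return records


def write_endpoints_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=str))
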