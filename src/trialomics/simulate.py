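"""Seeded synthetic-data generators for every input layer.

Patient-level trial data are not publicly shareable, so each pipeline
stage is exercised on simulated inputs with planted, recorded ground
truth: a cohort with a latent inflammation score driving CD8 conversion
and response, omics matrices with planted differential features,
segmented-ROI pixel tables with bimodal marker channels, trajectory
embeddings with latent pseudotime and planted gene effects, clone
tables with log-series abundances and a shared public-clone pool, and
longitudinal ctDNA series with response-dependent decline.

Every generator is a pure function of its config (which includes the
seed): one `numpy.random.default_rng` stream per call, no other entropy,
so repeated calls are byte-identical when written with the provided
writers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SimCohortConfig:
    """Trial-cohort generator.

    Defaults emulate the published cohort shape: 79 patients, 72 CD8-low
    and 7 CD8-high (frac_high ~ 0.09), baseline CD8 drawn below/above the
    15% cutoff, conversion driven by a latent inflammation score through
    a logistic model, and response driven by conversion + inflammation.
    """

    n_patients: int = 79
    frac_high: float = 7 / 79
    cd8_cutoff: float = 15.0
    tumor_types: tuple[str, ...] = ("CRPC", "HNCA", "OVCA", "UTCA", "NECA", "OTHER")
    tumor_weights: tuple[float, ...] = (0.25, 0.15, 0.15, 0.1, 0.1, 0.25)
    conversion_intercept: float = -0.8
    conversion_slope: float = 1.2
    response_intercept: float = -2.0
    response_conversion_coef: float = 1.3
    response_inflammation_coef: float = 0.5
    biopsy_prob: float = 0.54  # fraction of CD8-low patients with an on-treatment biopsy
    sd_prob: float = 0.25  # P(SD | non-responder)
    ne_prob: float = 0.08  # P(NE | non-responder, non-SD)
    seed: int = 0


def simulate_cohort(cfg: SimCohortConfig) -> tuple[pd.DataFrame, dict]:
    rng = np.random.default_rng(cfg.seed)
    rows, truth_scores = [], []
    w = np.asarray(cfg.tumor_weights) / np.sum(cfg.tumor_weights)
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        high = rng.random() < cfg.frac_high
        if high:
            baseline = float(cfg.cd8_cutoff + rng.uniform(0.5, 40.0))
        else:
            baseline = float(rng.uniform(0.0, cfg.cd8_cutoff - 0.5))
        tumor = str(rng.choice(cfg.tumor_types, p=w))
        inflammation = float(rng.normal())
        on_tx: list[float] = []
        converted = False
        if not high and rng.random() < cfg.biopsy_prob:
            p_conv = _expit(cfg.conversion_intercept + cfg.conversion_slope * inflammation)
            converted = bool(rng.random() < p_conv)
            n_biopsy = int(rng.integers(1, 3))
            for _ in range(n_biopsy):
                if converted:
                    on_tx.append(float(np.clip(cfg.cd8_cutoff + rng.uniform(0, 30), 0, 100)))
                else:
                    on_tx.append(float(np.clip(rng.uniform(0, cfg.cd8_cutoff - 0.1), 0, 100)))
        p_resp = _expit(
            cfg.response_intercept
            + cfg.response_conversion_coef * converted
            + cfg.response_inflammation_coef * inflammation
        )
        if rng.random() < p_resp:
            bor = "CR" if rng.random() < 0.1 else "PR"
            sd_weeks = None
        else:
            u = rng.random()
            if u < cfg.sd_prob:
                bor = "SD"
                sd_weeks = float(np.round(rng.uniform(6, 60), 1))
            elif u < cfg.sd_prob + cfg.ne_prob:
                bor, sd_weeks = "NE", None
            else:
                bor, sd_weeks = "PD", None
        rows.append(
            {
                "patient_id": pid,
                "group": "CD8_HIGH" if high else "CD8_LOW",
                "tumor_type": tumor,
                "baseline_cd8_pct": round(baseline, 2),
                "on_treatment_cd8_pcts": "|".join(f"{v:.2f}" for v in on_tx),
                "best_overall_response": bor,
                "sd_duration_weeks": "" if sd_weeks is None else sd_weeks,
                "prior_ici": bool(rng.random() < 0.4),
            }
        )
        truth_scores.append(
            {"patient_id": pid, "inflammation": inflammation, "converted": converted}
        )
    truth = {
        "model": {
            "conversion": [cfg.conversion_intercept, cfg.conversion_slope],
            "response": [
                cfg.response_intercept,
                cfg.response_conversion_coef,
                cfg.response_inflammation_coef,
            ],
        },
        "patients": truth_scores,
        "config": asdict(cfg),
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# omics matrices


@dataclass
class SimOmicsConfig:
    """Feature-matrix generator: Gaussian noise around a per-feature
    baseline, a planted mean shift for the first `n_true` features in
    group A, optional additive batch offsets."""

    n_features: int = 1000
    n_per_group: int = 10
    n_true: int = 50
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 5.0
    batch_offsets: tuple[float, ...] = (0.0,)
    layer: str = "RNA_TPM"
    scale: str = "LOG2"
    seed: int = 0


def simulate_omics(cfg: SimOmicsConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    rng = np.random.default_rng(cfg.seed)
    n_samp = 2 * cfg.n_per_group
    features = [f"F{i + 1:05d}" for i in range(cfg.n_features)]
    samples = [f"S{i + 1:03d}" for i in range(n_samp)]
    groups = ["A"] * cfg.n_per_group + ["B"] * cfg.n_per_group
    base = rng.normal(cfg.baseline_mean, 1.0, size=cfg.n_features)
    vals = base[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_features, n_samp))
    vals[: cfg.n_true, : cfg.n_per_group] += cfg.effect_size
    batches = [cfg.batch_offsets[i % len(cfg.batch_offsets)] for i in range(n_samp)]
    vals += np.asarray(batches)[None, :]
    matrix = pd.DataFrame(vals, index=features, columns=samples)
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "subject_id": [f"SUBJ{i + 1:03d}" for i in range(n_samp)],
            "group_label": groups,
            "timepoint": ["BL"] * n_samp,
            "batch": [f"B{i % len(cfg.batch_offsets)}" for i in range(n_samp)],
        }
    )
    truth = {
        "true_features": features[: cfg.n_true],
        "effect_size": cfg.effect_size,
        "config": asdict(cfg),
    }
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# segmented ROI images


@dataclass
class SimImageConfig:
    """Segmented-ROI pixel generator with bimodal marker channels.

    Positive cells draw pixels from the high mode, negative cells from
    the low mode; the planted per-image positive fraction per marker is
    recorded as truth. Default separation is (60 - 10) / 5 = 10 sd.
    """

    n_images: int = 10
    rois_per_image: int = 2
    cells_per_roi_mean: float = 80.0
    pixels_per_cell: tuple[int, int] = (15, 40)
    markers: tuple[str, ...] = ("CD8", "TOX")
    neg_mean: float = 10.0
    neg_sd: float = 5.0
    pos_mean: float = 60.0
    pos_sd: float = 5.0
    positive_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"CD8": 0.3, "TOX": 0.2}
    )
    seed: int = 0


def simulate_roi_images(cfg: SimImageConfig) -> tuple[pd.DataFrame, dict]:
    rng = np.random.default_rng(cfg.seed)
    rows = []
    truth_frac: dict[str, dict[str, float]] = {}
    for im in range(cfg.n_images):
        image_id = f"IMG{im + 1:03d}"
        pos_counts = {m: 0 for m in cfg.markers}
        n_total = 0
        for roi in range(cfg.rois_per_image):
            roi_id = f"ROI{roi + 1}"
            n_cells = max(3, int(rng.poisson(cfg.cells_per_roi_mean)))
            n_total += n_cells
            for c in range(n_cells):
                cell_id = f"{roi_id}_C{c + 1:04d}"
                n_px = int(rng.integers(cfg.pixels_per_cell[0], cfg.pixels_per_cell[1] + 1))
                for m in cfg.markers:
                    positive = bool(rng.random() < cfg.positive_fraction.get(m, 0.0))
                    pos_counts[m] += positive
                    mu = cfg.pos_mean if positive else cfg.neg_mean
                    sd = cfg.pos_sd if positive else cfg.neg_sd
                    px = np.clip(rng.normal(mu, sd, size=n_px), 0.0, None)
                    for k, v in enumerate(px):
                        rows.append(
                            {
                                "image_id": image_id,
                                "roi_id": roi_id,
                                "cell_id": cell_id,
                                "marker": m,
                                "pixel_index": k,
                                "intensity": round(float(v), 3),
                            }
                        )
        truth_frac[image_id] = {m: pos_counts[m] / n_total for m in cfg.markers}
    truth = {"positive_fraction_by_image": truth_frac, "config": _jsonable(asdict(cfg))}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# trajectory


@dataclass
class SimTrajectoryConfig:
    """Embedding + gene generator with a latent pseudotime.

    Cells sit on a chosen 2-D curve (line, quarter-circle arc, or
    S-curve) embedded in `dim` dimensions by a random rotation, plus
    isotropic Gaussian noise. Genes are linear in the latent time with
    optional vendor offsets and group x time interactions; all
    coefficients are recorded as truth.
    """

    n_cells: int = 2000
    dim: int = 10
    curve: str = "s_curve"  # line | arc | s_curve
    noise_sd: float = 0.1  # fraction of curve extent
    n_genes: int = 20
    traj_coefs: tuple[float, ...] = ()  # per-gene; padded with zeros
    interaction_coefs: tuple[float, ...] = ()  # group x time, padded with zeros
    gene_noise_sd: float = 0.5
    vendors: tuple[str, ...] = ("V1", "V2", "V3")
    vendor_offsets: tuple[float, ...] = (0.0, 0.4, -0.3)
    groups: tuple[str, ...] = ("PR", "PD")
    timepoints: tuple[str, ...] = ("C1D1", "C1D8")
    seed: int = 0


def _curve_xy(t: np.ndarray, family: str) -> np.ndarray:
    if family == "line":
        return np.column_stack([t, 0.5 * t])
    if family == "arc":
        ang = t * np.pi / 2
        return np.column_stack([np.cos(ang), np.sin(ang)])
    if family == "s_curve":
        return np.column_stack([t, 0.3 * np.sin(2.0 * np.pi * t)])
    raise ValueError(f"unknown curve family {family!r}")


def simulate_trajectory(
    cfg: SimTrajectoryConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    rng = np.random.default_rng(cfg.seed)
    t = rng.uniform(0.0, 1.0, size=cfg.n_cells)
    xy = _curve_xy(t, cfg.curve)
    # random rotation into `dim` dimensions
    Q, _ = np.linalg.qr(rng.normal(size=(cfg.dim, cfg.dim)))
    X = np.zeros((cfg.n_cells, cfg.dim))
    X[:, :2] = xy
    X = X @ Q.T
    extent = float(np.linalg.norm(xy.max(axis=0) - xy.min(axis=0)))
    X += rng.normal(0.0, cfg.noise_sd * extent, size=X.shape)
    cells = [f"CELL{i + 1:05d}" for i in range(cfg.n_cells)]
    embedding = pd.DataFrame(
        X, index=cells, columns=[f"HC{j + 1}" for j in range(cfg.dim)]
    )
    vendor = rng.choice(cfg.vendors, size=cfg.n_cells)
    voff = dict(zip(cfg.vendors, cfg.vendor_offsets))
    group = rng.choice(cfg.groups, size=cfg.n_cells)
    timepoint = rng.choice(cfg.timepoints, size=cfg.n_cells)
    meta = pd.DataFrame(
        {"cell_id": cells, "vendor": vendor, "response": group, "timepoint": timepoint}
    ).set_index("cell_id")
    tcoef = np.zeros(cfg.n_genes)
    tcoef[: len(cfg.traj_coefs)] = cfg.traj_coefs[: cfg.n_genes]
    icoef = np.zeros(cfg.n_genes)
    icoef[: len(cfg.interaction_coefs)] = cfg.interaction_coefs[: cfg.n_genes]
    gind = (group == cfg.groups[1]).astype(float)
    genes = {}
    for g in range(cfg.n_genes):
        expr = (
            tcoef[g] * t
            + icoef[g] * t * gind
            + np.vectorize(voff.get)(vendor)
            + rng.normal(0.0, cfg.gene_noise_sd, size=cfg.n_cells)
        )
        genes[f"G{g + 1:04d}"] = expr
    genes_df = pd.DataFrame(genes, index=cells)
    truth = {
        "latent_time": t.tolist(),
        "traj_coefs": tcoef.tolist(),
        "interaction_coefs": icoef.tolist(),
        "config": asdict(cfg),
    }
    return embedding, genes_df, meta, truth


# ---------------------------------------------------------------------------
# clones


@dataclass
class SimCloneConfig:
    """Clone-table generator: log-series abundances, public-clone pool."""

    n_patients: int = 6
    clones_per_patient: int = 500
    logseries_p: float = 0.9
    public_pool_size: int = 200
    sharing_probability: float = 0.05
    blood_tumor_overlap_rate: float = 0.2
    cdr3_length: tuple[int, int] = (10, 18)
    seed: int = 0


def _random_cdr3(rng: np.random.Generator, lo: int, hi: int) -> str:
    k = int(rng.integers(lo, hi + 1))
    return "C" + "".join(rng.choice(list(_AA_ALPHABET), size=k)) + "F"


def simulate_clones(cfg: SimCloneConfig) -> tuple[pd.DataFrame, dict]:
    rng = np.random.default_rng(cfg.seed)
    pool = [_random_cdr3(rng, *cfg.cdr3_length) for _ in range(cfg.public_pool_size)]
    rows = []
    n_public_draws = 0
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        seen: set[str] = set()
        blood_cdr3 = []
        for _ in range(cfg.clones_per_patient):
            if cfg.public_pool_size and rng.random() < cfg.sharing_probability:
                cdr3 = pool[int(rng.integers(cfg.public_pool_size))]
                n_public_draws += 1
            else:
                cdr3 = _random_cdr3(rng, *cfg.cdr3_length)
            if cdr3 in seen:
                continue
            seen.add(cdr3)
            blood_cdr3.append(cdr3)
            count = int(rng.logseries(cfg.logseries_p))
            rows.append(
                {
                    "patient_id": pid, "chain": "TRB", "cdr3_aa": cdr3,
                    "count": count, "compartment": "BLOOD", "timepoint": "BL",
                    "subset_label": str(rng.choice(["Tnaive", "Tcm", "Tem"])),
                }
            )
        # tumor repertoire: some blood clones re-observed plus private ones
        for cdr3 in blood_cdr3:
            if rng.random() < cfg.blood_tumor_overlap_rate:
                rows.append(
                    {
                        "patient_id": pid, "chain": "TRB", "cdr3_aa": cdr3,
                        "count": int(rng.logseries(cfg.logseries_p)),
                        "compartment": "TUMOR", "timepoint": "BL",
                        "subset_label": np.nan,
                    }
                )
    truth = {
        "public_pool": pool,
        "n_public_draws": n_public_draws,
        "config": asdict(cfg),
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# ctDNA


@dataclass
class SimCtdnaConfig:
    """Longitudinal ctDNA generator with response-dependent decline.

    Responders' C2D1 levels decline by a configured fraction (on the
    log10 scale) more often than progressors'.
    """

    n_responders: int = 10
    n_progressors: int = 10
    baseline_log10_mean: float = 1.5
    baseline_log10_sd: float = 0.6
    responder_decline_log10: float = -1.0
    progressor_decline_log10: float = 0.2
    decline_sd: float = 0.3
    responder_decrease_frac: float = 0.9  # fraction with >= 50% molecular response
    seed: int = 0


def simulate_ctdna(cfg: SimCtdnaConfig) -> tuple[pd.DataFrame, dict, dict]:
    rng = np.random.default_rng(cfg.seed)
    rows = []
    labels = {}
    for i in range(cfg.n_responders + cfg.n_progressors):
        pid = f"P{i + 1:03d}"
        responder = i < cfg.n_responders
        labels[pid] = "CRPR" if responder else "PD"
        bl = 10.0 ** rng.normal(cfg.baseline_log10_mean, cfg.baseline_log10_sd)
        if responder:
            shift = cfg.responder_decline_log10
            if rng.random() > cfg.responder_decrease_frac:
                shift = 0.0
        else:
            shift = cfg.progressor_decline_log10
        on = 10.0 ** (np.log10(bl) + shift + rng.normal(0.0, cfg.decline_sd))
        for tp, mtm in (("BL", bl), ("C2D1", on)):
            snvs = int(np.clip(rng.poisson(2 + 4 * np.log10(1 + mtm)), 0, 16))
            rows.append(
                {
                    "patient_id": pid, "timepoint": tp,
                    "snvs_detected": snvs, "mtm_per_ml": round(float(mtm), 4),
                }
            )
    truth = {"labels": labels, "config": asdict(cfg)}
    return pd.DataFrame(rows), labels, truth


# ---------------------------------------------------------------------------
# writers


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _expit(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def write_outputs(outdir: str | Path, truth: dict, **tables: pd.DataFrame) -> None:
    """Write generator outputs deterministically: TSV tables plus
    truth.json (sorted keys, fixed float formatting)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=not isinstance(df.index, pd.RangeIndex))
    (outdir / "truth.json").write_text(
        json.dumps(_jsonable(truth), indent=2, sort_keys=True)
    )
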