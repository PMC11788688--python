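"""Result assembly: summary tables, figures and a reproducible report bundle.

The bundle mirrors the artefacts of a model external-validation study:

* a prediction summary — median (IQR) predicted local-control probability
  per (horizon, model), in percent;
* a performance table — AUC with 95% CI, p vs 0.5, and accuracy /
  sensitivity / specificity at the recommended (Youden) threshold;
* a Hosmer-Lemeshow table and calibration-plot exports;
* confusion-matrix panels;
* TCP-BED-tumour-size response surfaces on a rectangular grid.

Everything is deterministic given the cohort, config and seed: tables are
CSV, figures SVG (with a fixed hash salt so re-renders are byte-stable),
and a ``manifest.json`` records the config hash, seed, library versions and
every convention in effect (positive class, threshold rule, quantile rule,
HL df policy).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from ._version import __version__ as _pkg_version
from .bed import dose_per_fraction_from_bed
from .config import params_to_dict
from .models import (
    MODEL_ROSTER,
    KlementParams,
    LiuParams,
    LogisticParams,
    predict_cohort,
    tcp_liu,
    tcp_logistic,
)
from .stats import calibration_plot_data, roc_auc

logger = logging.getLogger("sbrt_tcp")

plt.rcParams["svg.hashsalt"] = "sbrt-tcp"

__all__ = ["summarize_predictions", "tcp_surface", "SurfaceGrid", "build_report"]


def summarize_predictions(pred_matrix: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) predicted probability per (horizon, model), in percent.

    Quantiles use linear interpolation (NumPy default, the type-7
    convention); values are rounded to 1 decimal to match clinical
    reporting.  Empty model columns are omitted with a warning.
    """
    if pred_matrix.shape[1] == 0 or len(pred_matrix) == 0:
        raise ValueError("prediction matrix must be non-empty")
    rows = []
    for col in pred_matrix.columns:
        series = pred_matrix[col].dropna()
        horizon, model = col if isinstance(col, tuple) else (None, col)
        if len(series) == 0:
            warnings.warn(f"model column {col!r} is empty and was omitted", stacklevel=2)
            continue
        q1, med, q3 = np.percentile(series.to_numpy(), [25, 50, 75])
        rows.append(
            {
                "horizon_yr": horizon,
                "model": model,
                "median_pct": round(100.0 * med, 1),
                "iqr_pct": round(100.0 * (q3 - q1), 1),
                "n": len(series),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SurfaceGrid:
    """A TCP response surface over a (BED10, diameter) grid.

    ``tcp`` holds raw probabilities; ``tcp_display`` the same values
    windowed to the conventional 50-100% display range (clipped below at
    0.5) used for comparing surfaces across models.
    """

    bed10_gy: np.ndarray  # (nb,)
    diameter_cm: np.ndarray  # (nd,)
    tcp: np.ndarray  # (nd, nb)
    tcp_display: np.ndarray
    model: str
    horizon_yr: int


def tcp_surface(
    model: str,
    params,
    bed_range=(20.0, 200.0),
    size_range=(0.5, 8.0),
    n_points: int = 61,
    n_fractions: int = 3,
    horizon: int = 2,
) -> SurfaceGrid:
    """TCP over a rectangular (BED10, tumour size) grid for one model.

    The scenario fixes the fraction count (default 3); for the Liu model the
    BED10 axis is converted back to a per-fraction dose and re-expressed at
    the model's own alpha/beta.  Models without a size term return a grid
    constant along the size axis.
    """
    b0, b1 = bed_range
    s0, s1 = size_range
    if not (b1 > b0 and s1 > s0):
        raise ValueError("bed_range and size_range must be non-degenerate (lo < hi)")
    bed = np.linspace(b0, b1, n_points)
    size = np.linspace(s0, s1, n_points)
    B, L = np.meshgrid(bed, size)
    if isinstance(params, LogisticParams):
        diam = L if params.size_coefficient_gy_per_cm != 0 else None
        tcp = np.asarray(tcp_logistic(B, params, diameter_cm=diam))
        if diam is None:
            tcp = np.broadcast_to(tcp, B.shape).copy()
    elif isinstance(params, LiuParams):
        d = dose_per_fraction_from_bed(B, n_fractions, alpha_beta_gy=10.0)
        bed_liu = n_fractions * d * (1.0 + d / params.alpha_beta_gy)
        tcp = np.asarray(tcp_liu(bed_liu, horizon, params, diameter_cm=L))
    elif isinstance(params, KlementParams):
        # dose-size surface at reference covariates: continuous terms at their
        # reference mean (standardised 0), binaries at the +/-0.5 midpoint (0)
        refs = params.covariate_refs or {}
        eta = params.eta_intercept
        for name, coef in params.eta_coefficients.items():
            if name == "bed":
                mean, sd = refs.get("bed", (100.0, 30.0))
                eta = eta + coef * 0.5 * (B - mean) / sd
            elif name == "diameter_cm":
                mean, sd = refs.get("diameter_cm", (3.5, 2.0))
                eta = eta + coef * 0.5 * (L - mean) / sd
        from .models import tcp_klement

        tcp = np.asarray(tcp_klement(horizon, eta, params))
        tcp = np.broadcast_to(tcp, B.shape).copy()
    else:
        raise ValueError(f"unsupported parameter object for {model!r}")
    return SurfaceGrid(
        bed10_gy=bed,
        diameter_cm=size,
        tcp=tcp,
        tcp_display=np.clip(tcp, 0.5, 1.0),
        model=model,
        horizon_yr=horizon,
    )


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------


def _fmt_pct(x: float) -> float:
    return round(float(x), 1)


def _performance_rows(cohort, pred_matrix, positive_class: str, n_bins: int, df_policy: str):
    perf_rows, hl_rows, roc_results, cal_results = [], [], {}, {}
    for (h, model) in pred_matrix.columns:
        lc = cohort[f"lc_{h}yr"]
        if lc.isna().any():
            continue
        y = lc.astype(int).to_numpy()
        scores = pred_matrix[(h, model)].to_numpy(dtype=float)
        if positive_class == "recurrence":
            y, scores = 1 - y, 1.0 - scores
        roc = roc_auc(scores, y)
        cal = calibration_plot_data(scores, y, n_bins=n_bins, df_policy=df_policy)
        roc_results[(h, model)] = roc
        cal_results[(h, model)] = cal
        perf_rows.append(
            {
                "horizon_yr": h,
                "model": model,
                "auc": round(roc.auc, 3),
                "ci95_low": round(roc.ci95[0], 3),
                "ci95_high": round(roc.ci95[1], 3),
                "p_value": roc.p_value,
                "criterion": round(roc.criterion.threshold, 4),
                "accuracy_pct": _fmt_pct(roc.accuracy_pct),
                "sensitivity_pct": _fmt_pct(roc.sensitivity_pct),
                "specificity_pct": _fmt_pct(roc.specificity_pct),
                "tp": roc.confusion.tp,
                "fp": roc.confusion.fp,
                "fn": roc.confusion.fn,
                "tn": roc.confusion.tn,
            }
        )
        hl_rows.append(
            {
                "horizon_yr": h,
                "model": model,
                "chi_square": round(cal.chi_square, 3),
                "df": cal.df,
                "p_value": round(cal.p_value, 4),
                "n_bins_effective": cal.n_bins_effective,
            }
        )
    return perf_rows, hl_rows, roc_results, cal_results


def _plot_roc(roc_results, horizon, path):
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for (h, model), roc in roc_results.items():
        if h != horizon:
            continue
        ax.plot(roc.fpr, roc.tpr, label=f"{model} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{horizon}-year local control")
    ax.legend(loc="lower right", fontsize=8)
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def _plot_calibration(cal_results, horizon, path):
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for (h, model), cal in cal_results.items():
        if h != horizon:
            continue
        ax.plot(cal.bins["mean_predicted"], cal.bins["observed_rate"], "o-", label=model, ms=4)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed rate")
    ax.set_title(f"Calibration, {horizon}-year local control")
    ax.legend(loc="upper left", fontsize=8)
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def _plot_confusions(roc_results, path):
    items = list(roc_results.items())
    fig, axes = plt.subplots(1, max(len(items), 1), figsize=(2.4 * max(len(items), 1), 2.8))
    axes = np.atleast_1d(axes)
    for ax, ((h, model), roc) in zip(axes, items):
        m = np.array([[roc.confusion.tp, roc.confusion.fn], [roc.confusion.fp, roc.confusion.tn]])
        ax.imshow(m, cmap="Blues")
        for (i, j), v in np.ndenumerate(m):
            ax.text(j, i, str(v), ha="center", va="center", fontsize=9)
        ax.set_xticks([0, 1], ["pred +", "pred -"], fontsize=7)
        ax.set_yticks([0, 1], ["obs +", "obs -"], fontsize=7)
        ax.set_title(f"{model} {h}y", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def _plot_surfaces(config, horizons, path, roster):
    panels = [(h, m) for h in horizons for m in roster[h]]
    fig = plt.figure(figsize=(3.2 * 4, 3.2 * ((len(panels) + 3) // 4)))
    for k, (h, m) in enumerate(panels, start=1):
        grid = tcp_surface(m, config[m], horizon=h)
        ax = fig.add_subplot((len(panels) + 3) // 4, 4, k, projection="3d")
        B, L = np.meshgrid(grid.bed10_gy, grid.diameter_cm)
        ax.plot_surface(B, L, 100.0 * grid.tcp_display, cmap="viridis", linewidth=0)
        ax.set_zlim(50, 100)
        ax.set_xlabel("BED10 (Gy)", fontsize=7)
        ax.set_ylabel("diameter (cm)", fontsize=7)
        ax.set_zlabel("TCP (%)", fontsize=7)
        ax.set_title(f"{m}, {h}-year", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def build_report(
    cohort: pd.DataFrame,
    config: Mapping[str, object],
    out_dir: str | Path,
    *,
    horizons: Sequence[int] = (2, 3),
    n_bins: int = 10,
    positive_class: str = "control",
    df_policy: str = "external",
    seed: int | None = None,
    figures: bool = True,
    roster: Mapping[int, Sequence[str]] | None = None,
) -> dict:
    """Run the full validation over the model roster and write the bundle.

    ``roster`` maps horizon to the models to evaluate (default: the full
    published roster).  Horizons whose local-control column contains missing
    values are skipped with a logged warning.  Returns a dict of written
    paths plus the in-memory tables.
    """
    roster = dict(MODEL_ROSTER) if roster is None else dict(roster)
    if positive_class not in ("control", "recurrence"):
        raise ValueError(f"positive_class must be 'control' or 'recurrence', got {positive_class!r}")
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(parents=True, exist_ok=True)

    usable = []
    for h in horizons:
        col = f"lc_{h}yr"
        if col not in cohort or cohort[col].isna().any():
            logger.warning("skipping %d-year analyses: %s missing or incomplete", h, col)
            continue
        usable.append(h)
    if not usable:
        raise ValueError("no horizon has complete local-control outcomes")

    blocks = {}
    for h in usable:
        block = predict_cohort(cohort, h, roster[h], config)
        for col in block.columns:
            blocks[(h, col)] = block[col]
    pred = pd.DataFrame(blocks, index=cohort.index)
    pred.columns = pd.MultiIndex.from_tuples(pred.columns, names=["horizon", "model"])
    summary = summarize_predictions(pred)
    perf_rows, hl_rows, roc_results, cal_results = _performance_rows(
        cohort, pred, positive_class, n_bins, df_policy
    )
    performance = pd.DataFrame(perf_rows)
    hl_table = pd.DataFrame(hl_rows)

    cal_bins = pd.concat(
        [
            cal.bins.assign(horizon_yr=h, model=m)
            for (h, m), cal in cal_results.items()
        ],
        ignore_index=True,
    )
    roc_points = pd.concat(
        [
            pd.DataFrame({"fpr": r.fpr, "tpr": r.tpr, "threshold": r.thresholds}).assign(
                horizon_yr=h, model=m
            )
            for (h, m), r in roc_results.items()
        ],
        ignore_index=True,
    )

    paths = {}
    tables = {
        "predictions_summary": summary,
        "performance": performance,
        "hosmer_lemeshow": hl_table,
        "calibration_bins": cal_bins,
        "roc_points": roc_points,
    }
    for name, df in tables.items():
        p = out / "tables" / f"{name}.csv"
        df.to_csv(p, index=False, lineterminator="\n")
        paths[name] = p

    if figures:
        for h in usable:
            _plot_roc(roc_results, h, out / "figures" / f"roc_{h}yr.svg")
            _plot_calibration(cal_results, h, out / "figures" / f"calibration_{h}yr.svg")
        _plot_confusions(roc_results, out / "figures" / "confusion_matrices.svg")
        _plot_surfaces(config, usable, out / "figures" / "tcp_surfaces.svg", roster)

    config_json = json.dumps(params_to_dict(config), sort_keys=True, default=list)
    manifest = {
        "package_version": _pkg_version,
        "seed": seed,
        "n_patients": int(len(cohort)),
        "horizons": list(usable),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "conventions": {
            "positive_class": positive_class,
            "threshold_rule": "Youden index, ties to higher threshold, score >= threshold is positive",
            "quantile_rule": "linear interpolation (type 7)",
            "hl_df_policy": df_policy,
            "hl_n_bins": n_bins,
        },
        "versions": {
            mod.__name__: mod.__version__
            for mod in (np, pd, matplotlib)
        },
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    paths["manifest"] = mp
    return {"paths": paths, "tables": tables, "roc": roc_results, "calibration": cal_results}
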