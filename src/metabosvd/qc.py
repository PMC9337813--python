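"""Pooled-QC drift correction, feature quality filtering and transforms.

The preprocessing chain mirrors standard untargeted LC-MS practice: a LOESS
curve fitted to the pooled-QC injections of each batch models run-order
signal drift, every sample is divided by the fitted curve and rescaled to
the feature's run-wide pooled-QC median (removing within-batch drift and
between-batch offsets in one step); features are then retained only if they
meet three analytical quality criteria —

* precision:     RSD in pooled QC < 30%
* linearity:     Pearson correlation with the dilution fraction > 0.7
* information:   RSD in study samples > 1.1 x RSD in pooled QC

— before a generalized log transform and per-feature autoscaling produce
the unit-variance metabolite values the association models consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "IntensityMatrix",
    "QCParams",
    "compute_rsd",
    "loess_drift_correct",
    "dilution_response",
    "compute_feature_qc",
    "filter_features",
    "estimate_glog_lambda",
    "glog",
    "glog_transform",
    "autoscale",
    "qc_pipeline",
]

_STATES = ("raw", "corrected", "transformed", "scaled")


@dataclass
class IntensityMatrix:
    """Feature-by-sample intensity matrix with a preprocessing state tag.

    State transitions are one-way: raw -> corrected -> transformed -> scaled.
    """

    values: pd.DataFrame  # rows = features, columns = sample ids
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")

    def advance(self, values: pd.DataFrame, state: str) -> "IntensityMatrix":
        if _STATES.index(state) != _STATES.index(self.state) + 1:
            raise ValueError(f"illegal state transition {self.state} -> {state}")
        return IntensityMatrix(values=values, state=state)


@dataclass
class QCParams:
    """Thresholds and tuning knobs of the QC stage.

    The three retention thresholds (30% pooled-QC RSD, 0.7 dilution
    correlation, 1.1 study/QC RSD ratio) are strict inequalities; ties fail.
    """

    rsd_qc_max: float = 30.0
    dilution_r_min: float = 0.7
    study_to_qc_rsd_ratio_min: float = 1.1
    loess_span: float = 0.5
    loess_enabled: bool | dict[str, bool] = True
    glog_lambda: float | str = "auto"
    min_qc_per_batch: int = 3
    max_missing_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.loess_span <= 1.0):
            raise ValueError("loess_span must lie in (0, 1]")
        for name in ("rsd_qc_max", "dilution_r_min", "study_to_qc_rsd_ratio_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def loess_on(self, platform: str) -> bool:
        if isinstance(self.loess_enabled, dict):
            return bool(self.loess_enabled.get(platform, True))
        return bool(self.loess_enabled)


def compute_rsd(values) -> float:
    """Relative standard deviation, 100 * sample sd / mean, in percent.

    Returns ``nan`` (flagged-undefined) with fewer than two non-missing
    values or a non-positive mean; callers treat ``nan`` as a QC failure.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        return float("nan")
    mean = arr.mean()
    if mean <= 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)


def _row_rsd(values: pd.DataFrame) -> pd.Series:
    """Vectorized per-feature RSD with pairwise NaN removal."""
    n = values.notna().sum(axis=1)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    rsd = 100.0 * sd / mean
    rsd[(n < 2) | (mean <= 0)] = np.nan
    return rsd


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def loess_drift_correct(
    matrix: IntensityMatrix, manifest: pd.DataFrame, params: QCParams
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Divide out pooled-QC LOESS drift, batch by batch.

    For every feature and batch a locally linear LOESS curve is fitted to
    pooled-QC intensity versus run order; each sample's intensity is divided
    by the curve value at its run order (linearly interpolated, held at the
    nearest fitted QC value beyond the QC range) and multiplied by the
    feature's median pooled-QC intensity across the whole run.  Features
    whose fit turns non-positive anywhere are passed through uncorrected and
    flagged in the diagnostics.

    When LOESS is switched off for the run's platform the matrix passes
    through unchanged but still advances to the ``corrected`` state.
    """
    if matrix.state != "raw":
        raise ValueError("drift correction expects a raw matrix")
    meta = manifest.set_index("sample_id").loc[matrix.values.columns]
    platform = str(meta["platform"].iloc[0]) if len(meta) else ""
    diagnostics = pd.DataFrame(
        {"corrected": False, "reason": ""}, index=matrix.values.index
    )
    if not params.loess_on(platform):
        diagnostics["reason"] = "loess disabled for platform"
        return matrix.advance(matrix.values.copy(), "corrected"), diagnostics

    qc_meta = meta[meta["sample_type"] == "pooled_qc"]
    for batch, grp in meta.groupby("batch"):
        n_qc = (grp["sample_type"] == "pooled_qc").sum()
        if n_qc < params.min_qc_per_batch:
            raise ValueError(
                f"batch {batch}: {n_qc} pooled QC samples, "
                f"need >= {params.min_qc_per_batch}"
            )

    values = matrix.values
    qc_cols = qc_meta.index
    reference = values[qc_cols].median(axis=1)  # run-wide QC level per feature

    corrected = values.to_numpy(dtype=float, copy=True)
    col_pos = {s: i for i, s in enumerate(values.columns)}
    feat_ok = np.ones(len(values), dtype=bool)
    reasons = np.full(len(values), "", dtype=object)
    ref_arr = reference.to_numpy()
    bad_ref = ~(ref_arr > 0)
    feat_ok[bad_ref] = False
    reasons[bad_ref] = "non-positive QC reference"

    fitted_all = np.ones_like(corrected)
    for batch, grp in meta.groupby("batch"):
        cols = [col_pos[s] for s in grp.index]
        orders = grp["run_order"].to_numpy(float)
        qc_in_batch = grp[grp["sample_type"] == "pooled_qc"]
        qc_orders = qc_in_batch["run_order"].to_numpy(float)
        qc_cols_b = [col_pos[s] for s in qc_in_batch.index]
        for i in range(len(values)):
            if not feat_ok[i]:
                continue
            y = corrected[i, qc_cols_b]
            ok = ~np.isnan(y)
            if ok.sum() < 2:
                feat_ok[i] = False
                reasons[i] = f"batch {batch}: <2 usable QC values"
                continue
            x = qc_orders[ok]
            # keep at least a 5-point local window so sparse QC designs do
            # not interpolate the noise they are meant to smooth
            frac = min(1.0, max(params.loess_span, 5.0 / ok.sum()))
            fit = lowess(y[ok], x, frac=frac, return_sorted=True)
            curve = np.interp(orders, fit[:, 0], fit[:, 1])
            if np.any(curve <= 0) or np.any(~np.isfinite(curve)):
                feat_ok[i] = False
                reasons[i] = f"batch {batch}: non-positive LOESS fit"
                continue
            fitted_all[i, cols] = curve

    good = feat_ok
    corrected[good] = corrected[good] / fitted_all[good] * ref_arr[good, None]
    # anchor each feature so its pooled-QC median is exactly the raw
    # reference level (the LOESS ratio median is only approximately one)
    qc_pos = [col_pos[s] for s in qc_cols]
    med_corr = np.nanmedian(corrected[:, qc_pos], axis=1)
    anchor = np.where(good & (med_corr > 0), ref_arr / med_corr, 1.0)
    corrected *= anchor[:, None]
    diagnostics["corrected"] = good
    diagnostics["reason"] = reasons
    out = pd.DataFrame(corrected, index=values.index, columns=values.columns)
    return matrix.advance(out, "corrected"), diagnostics


# ---------------------------------------------------------------------------
# feature quality metrics
# ---------------------------------------------------------------------------

def dilution_response(matrix: IntensityMatrix, manifest: pd.DataFrame) -> pd.Series:
    """Per-feature Pearson correlation with the dilution fraction.

    ``nan`` marks an undefined response (fewer than three distinct dilution
    fractions with data, or zero intensity variance); undefined responses
    fail the linearity criterion downstream.
    """
    meta = manifest.set_index("sample_id").loc[matrix.values.columns]
    dil = meta[meta["sample_type"] == "dilution_qc"]
    out = pd.Series(np.nan, index=matrix.values.index, name="dilution_r")
    if dil.empty:
        return out
    frac = dil["dilution_fraction"].to_numpy(float)
    sub = matrix.values[dil.index].to_numpy(float)
    for i in range(sub.shape[0]):
        y = sub[i]
        ok = ~np.isnan(y)
        if len(np.unique(frac[ok])) < 3:
            continue
        yy, xx = y[ok], frac[ok]
        if np.std(yy) == 0 or np.std(xx) == 0:
            continue
        out.iloc[i] = float(np.corrcoef(xx, yy)[0, 1])
    return out


def compute_feature_qc(
    matrix: IntensityMatrix, manifest: pd.DataFrame, params: QCParams
) -> pd.DataFrame:
    """Per-feature QC metrics on the drift-corrected matrix."""
    if matrix.state != "corrected":
        raise ValueError("feature QC metrics are computed on the corrected matrix")
    meta = manifest.set_index("sample_id").loc[matrix.values.columns]
    qc_cols = meta.index[meta["sample_type"] == "pooled_qc"]
    study_cols = meta.index[meta["sample_type"] == "study"]
    dil_cols = meta.index[meta["sample_type"] == "dilution_qc"]
    values = matrix.values
    qc = pd.DataFrame(index=values.index)
    qc["rsd_qc"] = _row_rsd(values[qc_cols]) if len(qc_cols) else np.nan
    qc["rsd_study"] = _row_rsd(values[study_cols]) if len(study_cols) else np.nan
    qc["dilution_r"] = dilution_response(matrix, manifest)
    qc["n_qc_used"] = values[qc_cols].notna().sum(axis=1)
    qc["n_study_used"] = values[study_cols].notna().sum(axis=1)
    qc["n_dilution_used"] = values[dil_cols].notna().sum(axis=1)
    n_study = max(len(study_cols), 1)
    qc["missing_fraction"] = 1.0 - qc["n_study_used"] / n_study
    return qc


def filter_features(
    feature_qc: pd.DataFrame, params: QCParams, has_dilution: bool | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply the three retention criteria and assemble the QC report.

    All comparisons are strict, undefined (NaN) metrics fail their
    criterion, and the dilution criterion is vacuously true for datasets
    without a dilution series (e.g. NMR).  Features with more than
    ``max_missing_fraction`` missing study values fail regardless.
    """
    out = feature_qc.copy()
    if has_dilution is None:
        has_dilution = bool((out["n_dilution_used"] > 0).any())
    rsd_qc = out["rsd_qc"]
    rsd_study = out["rsd_study"]
    out["pass_rsd_qc"] = (rsd_qc < params.rsd_qc_max).fillna(False)
    if has_dilution:
        out["pass_dilution"] = (out["dilution_r"] > params.dilution_r_min).fillna(False)
    else:
        out["pass_dilution"] = True
    out["pass_variance_ratio"] = (
        rsd_study > params.study_to_qc_rsd_ratio_min * rsd_qc
    ).fillna(False)
    out["pass_missing"] = out["missing_fraction"] <= params.max_missing_fraction
    out["pass_overall"] = (
        out["pass_rsd_qc"] & out["pass_dilution"]
        & out["pass_variance_ratio"] & out["pass_missing"]
    )
    report = {
        "n_features": int(len(out)),
        "n_pass": int(out["pass_overall"].sum()),
        "n_fail_rsd_qc": int((~out["pass_rsd_qc"]).sum()),
        "n_fail_dilution": int((~out["pass_dilution"]).sum()),
        "n_fail_variance_ratio": int((~out["pass_variance_ratio"]).sum()),
        "n_fail_missing": int((~out["pass_missing"]).sum()),
        "dilution_criterion_applied": bool(has_dilution),
        "params": {
            "rsd_qc_max": params.rsd_qc_max,
            "dilution_r_min": params.dilution_r_min,
            "study_to_qc_rsd_ratio_min": params.study_to_qc_rsd_ratio_min,
            "max_missing_fraction": params.max_missing_fraction,
        },
    }
    return out, report


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def glog(x, lam: float):
    """Generalized log, ln((x + sqrt(x^2 + lambda)) / 2).

    Monotone increasing, defined at zero for positive lambda, and converging
    to the natural log as lambda -> 0 (for x > 0) and as x grows large.
    """
    if lam < 0:
        raise ValueError("glog lambda must be non-negative")
    x = np.asarray(x, dtype=float)
    return np.log((x + np.sqrt(x * x + lam)) / 2.0)


def estimate_glog_lambda(matrix: IntensityMatrix, manifest: pd.DataFrame) -> float:
    """Data-driven lambda: squared median pooled-QC sd of low-intensity features.

    Features in the lowest quartile of median pooled-QC intensity estimate
    the additive noise floor that the transform should damp.  Falls back to
    study samples when no QC injections exist, and to 1.0 when degenerate.
    """
    meta = manifest.set_index("sample_id").loc[matrix.values.columns]
    cols = meta.index[meta["sample_type"] == "pooled_qc"]
    if len(cols) < 3:
        cols = meta.index[meta["sample_type"] == "study"]
    sub = matrix.values[cols]
    med = sub.median(axis=1)
    cut = med.quantile(0.25)
    low = sub[med <= cut]
    if low.empty:
        return 1.0
    lam = float(np.nanmedian(low.std(axis=1, ddof=1)) ** 2)
    return lam if np.isfinite(lam) and lam > 0 else 1.0


def glog_transform(matrix: IntensityMatrix, lam: float) -> IntensityMatrix:
    if matrix.state != "corrected":
        raise ValueError("glog expects a corrected matrix")
    return matrix.advance(
        pd.DataFrame(glog(matrix.values.to_numpy(), lam),
                     index=matrix.values.index, columns=matrix.values.columns),
        "transformed",
    )


def autoscale(
    matrix: IntensityMatrix, manifest: pd.DataFrame
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Mean-centre and unit-scale each feature across study samples.

    Scaling statistics come from study samples only (QC injections are not
    participants); all columns are transformed with those statistics and the
    per-feature (mean, sd) pairs are returned for reuse.  Zero-variance
    features are dropped with reason ``zero variance``.
    """
    if matrix.state != "transformed":
        raise ValueError("autoscaling expects a transformed matrix")
    meta = manifest.set_index("sample_id").loc[matrix.values.columns]
    study_cols = meta.index[meta["sample_type"] == "study"]
    stats = pd.DataFrame(index=matrix.values.index)
    stats["mean"] = matrix.values[study_cols].mean(axis=1)
    stats["sd"] = matrix.values[study_cols].std(axis=1, ddof=1)
    keep = (stats["sd"] > 0) & stats["sd"].notna()
    stats["dropped_reason"] = np.where(keep, "", "zero variance")
    scaled = matrix.values.loc[keep].sub(stats.loc[keep, "mean"], axis=0)
    scaled = scaled.div(stats.loc[keep, "sd"], axis=0)
    return matrix.advance(scaled, "scaled"), stats


def qc_pipeline(
    raw: IntensityMatrix | pd.DataFrame,
    manifest: pd.DataFrame,
    params: QCParams | None = None,
) -> dict:
    """Run drift correction, feature filtering and transforms end to end.

    Returns a dict with the corrected matrix, feature QC table, QC report,
    the glog lambda used, and the final scaled matrix restricted to
    QC-passing features.
    """
    params = params or QCParams()
    matrix = raw if isinstance(raw, IntensityMatrix) else IntensityMatrix(raw)
    corrected, diag = loess_drift_correct(matrix, manifest, params)
    feature_qc = compute_feature_qc(corrected, manifest, params)
    feature_qc, report = filter_features(feature_qc, params)
    feature_qc["loess_corrected"] = diag["corrected"]
    feature_qc["loess_reason"] = diag["reason"]
    passed = corrected.values.loc[feature_qc["pass_overall"]]
    passed_matrix = replace(corrected, values=passed)
    lam = params.glog_lambda
    if lam == "auto":
        lam = estimate_glog_lambda(passed_matrix, manifest)
    transformed = glog_transform(passed_matrix, float(lam))
    scaled, scale_stats = autoscale(transformed, manifest)
    report["glog_lambda"] = float(lam)
    report["n_dropped_zero_variance"] = int(
        (scale_stats["dropped_reason"] == "zero variance").sum())
    return {
        "corrected": corrected,
        "loess_diagnostics": diag,
        "feature_qc": feature_qc,
        "report": report,
        "glog_lambda": float(lam),
        "scaled": scaled,
        "scale_stats": scale_stats,
    }
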