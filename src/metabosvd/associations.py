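"""Metabolome-wide association models for SVD severity.

Three model families are fitted for every metabolite x outcome pair, always
reporting the effect per 1-SD higher metabolite level:

* cross-sectional linear regression for continuous MRI/cognition endpoints
  (and lesion counts treated as continuous), logistic regression for binary
  endpoints, under a demographic (cohort + age + sex) and an extended
  (+ diabetes, hypertension, hypercholesterolaemia) adjustment set;
* linear regression of annualized change, (latest - baseline) / follow-up
  years, in each longitudinal endpoint;
* Cox proportional hazards for conversion to dementia (Efron ties).

Outcomes are first oriented so that higher values mean worse disease (mean
diffusivity peak height, brain volume, cognition scores and the Barthel
index are sign-flipped; white matter hyperintensity volume enters as its
log) and z-scored across participants, so betas are SD-per-SD.  P-values
are two-sided Wald tests; Benjamini-Hochberg q-values are computed within
each (outcome, family, adjustment, stratum) family of metabolite tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "OutcomePanel",
    "SuiteOptions",
    "AssociationResult",
    "orient_and_scale_outcomes",
    "simple_svd_score",
    "annualized_change",
    "build_covariates",
    "subject_metabolite_table",
    "fit_metabolite_outcome",
    "fit_dementia_cox",
    "bh_fdr",
    "run_analysis_suite",
    "RESULT_COLUMNS",
    "STRATA",
]

# endpoint name -> (source column stem, orientation sign, transform)
# sign -1 flips "higher is better" measurements so higher always means worse
ENDPOINTS: dict[str, tuple[str, int, str]] = {
    "mdnph": ("mdnph", -1, "identity"),
    "log_wmh": ("wmh_percent", +1, "log"),
    "brain_atrophy": ("total_brain_volume", -1, "identity"),
    "psmd": ("psmd", +1, "identity"),
    "global_cognition": ("global_cognition", -1, "identity"),
    "executive_function": ("executive_function", -1, "identity"),
    "processing_speed": ("processing_speed", -1, "identity"),
    "barthel_index": ("barthel_index", -1, "identity"),
}

COUNT_ENDPOINTS = ("microbleed_count", "lacune_count")
BINARY_ENDPOINTS = ("microbleed_presence", "lacune_presence")

DEMOGRAPHIC = ("cohort", "age", "sex")
EXTENDED = DEMOGRAPHIC + ("diabetes", "hypertension", "hypercholesterolaemia")

STRATA = ("all", "cohort_A", "cohort_B", "age_lt65", "age_ge65", "fazekas_ge2")

RESULT_COLUMNS = [
    "metabolite", "outcome", "family", "adjustment", "stratum", "n",
    "effect", "se", "ci_low", "ci_high", "p", "q", "significant",
    "estimable", "reason",
]


@dataclass
class OutcomePanel:
    """Oriented, z-scored study endpoints ready for model fitting."""

    baseline: pd.DataFrame  # z-scored continuous endpoints (incl. counts, SVD score)
    binary: pd.DataFrame  # 0/1 lesion-presence endpoints
    changes: pd.DataFrame  # z-scored annualized changes, columns change_<endpoint>
    orientation: dict[str, int]
    scale: pd.DataFrame  # per-endpoint mean/sd applied before z-scoring
    svd_score_raw: pd.Series


@dataclass
class SuiteOptions:
    """Which model families, adjustment sets and strata the suite runs."""

    adjustments: tuple[str, ...] = ("demographic", "extended")
    strata: tuple[str, ...] = ("all",)
    include_baseline: bool = True
    include_changes: bool = True
    include_cox: bool = True
    change_adjustments: tuple[str, ...] = ("demographic",)
    cox_adjustment: str = "demographic"
    min_stratum_n: int = 25
    min_events: int = 10
    fdr_alpha: float = 0.05
    orientation_overrides: dict[str, int] = field(default_factory=dict)


@dataclass
class AssociationResult:
    """One metabolite x outcome x model fit."""

    metabolite: str
    outcome: str
    family: str
    adjustment: str
    stratum: str
    n: int
    effect: float = np.nan
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p: float = np.nan
    q: float = np.nan
    significant: bool = False
    estimable: bool = True
    reason: str = ""

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in RESULT_COLUMNS}


# ---------------------------------------------------------------------------
# outcome preparation
# ---------------------------------------------------------------------------

def simple_svd_score(
    microbleed_presence, lacune_count, fazekas_grade,
    *, lacune_min: int = 1, fazekas_min: int = 2,
):
    """Simple MRI severity score in [0, 3].

    One point each for any microbleed, for ``lacune_count >= lacune_min``
    and for ``fazekas_grade >= fazekas_min``; missing components propagate
    to a missing score.
    """
    mb = pd.Series(microbleed_presence, dtype="float64")
    lac = pd.Series(lacune_count, dtype="float64")
    faz = pd.Series(fazekas_grade, dtype="float64")
    score = (mb > 0).astype(float) + (lac >= lacune_min) + (faz >= fazekas_min)
    return score.where(mb.notna() & lac.notna() & faz.notna())


def annualized_change(values, visit_times) -> float:
    """(latest non-missing value - baseline value) / elapsed years.

    Intermediate visits are ignored; a subject with only the baseline visit
    (or a missing baseline) yields ``nan`` and drops out of change models.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(visit_times, dtype=float)
    order = np.argsort(t)
    v, t = v[order], t[order]
    if len(v) == 0 or np.isnan(v[0]):
        return float("nan")
    ok = ~np.isnan(v)
    idx = np.where(ok)[0]
    last = idx[-1]
    if last == 0 or t[last] <= t[0]:
        return float("nan")
    return float((v[last] - v[0]) / (t[last] - t[0]))


def _annualized_change_matrix(vals: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Row-wise :func:`annualized_change` for a visits matrix (time-sorted)."""
    base = vals[:, 0]
    ok = ~np.isnan(vals)
    last = vals.shape[1] - 1 - np.argmax(ok[:, ::-1], axis=1)
    last = np.where(ok.any(axis=1), last, 0)
    last_val = vals[np.arange(len(vals)), last]
    dt = times[last] - times[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (last_val - base) / np.where(dt > 0, dt, np.nan)
    out[np.isnan(base)] = np.nan
    return out


def _zscore(s: pd.Series, name: str) -> tuple[pd.Series, float, float]:
    mean = s.mean()
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"outcome '{name}' has zero variance; cannot standardize")
    return (s - mean) / sd, float(mean), float(sd)


def _visit_columns(subjects: pd.DataFrame, stem: str) -> list[tuple[float, str]]:
    out = []
    prefix = f"{stem}_y"
    for col in subjects.columns:
        if col.startswith(prefix):
            try:
                out.append((float(col[len(prefix):]), col))
            except ValueError:
                continue
    return sorted(out)


def orient_and_scale_outcomes(
    subjects: pd.DataFrame,
    *,
    orientation_overrides: dict[str, int] | None = None,
) -> OutcomePanel:
    """Derive the oriented, standardized endpoint panel from phenotypes.

    Continuous endpoints are oriented (sign flips, log for WMH volume) and
    z-scored across participants; lesion counts and the simple SVD score are
    z-scored as continuous endpoints; presence/absence binaries are derived
    from the counts; annualized changes are computed on the oriented scale
    and then z-scored.
    """
    overrides = orientation_overrides or {}
    subjects = subjects.set_index("subject_id") \
        if "subject_id" in subjects.columns else subjects
    baseline = pd.DataFrame(index=subjects.index)
    changes = pd.DataFrame(index=subjects.index)
    orientation: dict[str, int] = {}
    scale_rows = {}

    def oriented_series(stem: str, sign: int, transform: str, col: str) -> pd.Series:
        s = subjects[col].astype(float)
        if transform == "log":
            s = np.log(s.where(s > 0))
        return sign * s

    for name, (stem, default_sign, transform) in ENDPOINTS.items():
        sign = overrides.get(name, default_sign)
        orientation[name] = sign
        visits = _visit_columns(subjects, stem)
        base_col = visits[0][1] if visits else stem
        if base_col not in subjects.columns:
            continue
        oriented = oriented_series(stem, sign, transform, base_col)
        baseline[name], mean, sd = _zscore(oriented, name)
        scale_rows[name] = (mean, sd)
        if len(visits) >= 2:
            mat = pd.concat(
                [oriented_series(stem, sign, transform, c) for _, c in visits],
                axis=1,
            ).to_numpy()
            times = np.array([t for t, _ in visits])
            ch = pd.Series(_annualized_change_matrix(mat, times),
                           index=subjects.index)
            if ch.notna().sum() >= 2 and ch.std(ddof=1) > 0:
                cname = f"change_{name}"
                changes[cname], cmean, csd = _zscore(ch, cname)
                scale_rows[cname] = (cmean, csd)

    binary = pd.DataFrame(index=subjects.index)
    for count_col, bin_name in zip(COUNT_ENDPOINTS, BINARY_ENDPOINTS):
        if count_col not in subjects.columns:
            continue
        counts = subjects[count_col].astype(float)
        sign = overrides.get(count_col, +1)
        orientation[count_col] = sign
        baseline[count_col], mean, sd = _zscore(sign * counts, count_col)
        scale_rows[count_col] = (mean, sd)
        binary[bin_name] = (counts > 0).astype(float).where(counts.notna())

    svd_raw = pd.Series(np.nan, index=subjects.index, name="simple_svd_score")
    if {"microbleed_count", "lacune_count", "fazekas_grade"} <= set(subjects.columns):
        svd_raw = simple_svd_score(
            (subjects["microbleed_count"] > 0).astype(float),
            subjects["lacune_count"],
            subjects["fazekas_grade"],
        )
        svd_raw.index = subjects.index
        sign = overrides.get("simple_svd_score", +1)
        orientation["simple_svd_score"] = sign
        baseline["simple_svd_score"], mean, sd = _zscore(
            sign * svd_raw, "simple_svd_score")
        scale_rows["simple_svd_score"] = (mean, sd)

    scale = pd.DataFrame.from_dict(
        scale_rows, orient="index", columns=["mean", "sd"])
    return OutcomePanel(
        baseline=baseline, binary=binary, changes=changes,
        orientation=orientation, scale=scale, svd_score_raw=svd_raw,
    )


def build_covariates(subjects: pd.DataFrame, adjustment: str) -> pd.DataFrame:
    """Design-matrix covariates (with intercept) for an adjustment set."""
    subjects = subjects.set_index("subject_id") \
        if "subject_id" in subjects.columns else subjects
    names = {"demographic": DEMOGRAPHIC, "extended": EXTENDED}.get(adjustment)
    if names is None:
        raise ValueError(f"unknown adjustment set {adjustment!r}")
    cols = {"const": pd.Series(1.0, index=subjects.index)}
    for name in names:
        if name == "cohort":
            cols["cohort_B"] = (subjects["cohort"] == "B").astype(float)
        elif name == "sex":
            cols["sex_male"] = (subjects["sex"] == "male").astype(float)
        elif name == "age":
            cols["age"] = subjects["age"].astype(float)
        else:
            cols[name] = subjects[name].astype(float)
    return pd.DataFrame(cols)


def subject_metabolite_table(scaled_values: pd.DataFrame,
                             manifest: pd.DataFrame) -> pd.DataFrame:
    """Pivot a scaled feature x sample matrix to subjects x metabolites."""
    meta = manifest.set_index("sample_id")
    study = meta[meta["sample_type"] == "study"]
    cols = [c for c in scaled_values.columns if c in study.index]
    table = scaled_values[cols].T
    table.index = study.loc[cols, "subject_id"]
    table.index.name = "subject_id"
    return table


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

_COLLINEAR_TOL = 1e-10


def _residualize(v: np.ndarray, q: np.ndarray) -> np.ndarray:
    return v - q @ (q.T @ v)


def fit_metabolite_outcome(
    z_metabolite: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    *,
    family: str = "linear",
    adjustment: str = "demographic",
    stratum: str = "all",
    metabolite: str | None = None,
    outcome_name: str | None = None,
) -> AssociationResult:
    """Fit one generalized linear model for one metabolite and one outcome.

    The effect is the metabolite coefficient (per 1-SD metabolite, since the
    metabolite is autoscaled) with its Wald two-sided p-value.  Collinear
    designs and separated logistic fits come back flagged non-estimable so
    they can be excluded from the FDR family with a reason.
    """
    res = AssociationResult(
        metabolite=metabolite or str(z_metabolite.name),
        outcome=outcome_name or str(outcome.name),
        family=family, adjustment=adjustment, stratum=stratum, n=0,
    )
    data = pd.concat(
        [outcome.rename("__y"), covariates, z_metabolite.rename("__z")], axis=1
    ).dropna()
    n = len(data)
    res.n = n
    if n < covariates.shape[1] + 2:
        res.estimable = False
        res.reason = f"too few complete cases (n={n})"
        return res
    y = data["__y"].to_numpy(float)
    c = data[covariates.columns].to_numpy(float)
    z = data["__z"].to_numpy(float)
    qmat, _ = np.linalg.qr(c)
    zr = _residualize(z, qmat)
    z_ss = float(z @ z)
    if float(zr @ zr) <= _COLLINEAR_TOL * max(z_ss, 1.0):
        res.estimable = False
        res.reason = "collinear with adjustment covariates"
        return res
    x = np.column_stack([c, z])
    try:
        if family == "linear":
            fit = sm.OLS(y, x).fit()
        elif family == "logistic":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True) or \
                    abs(fit.params[-1]) > 50:
                res.estimable = False
                res.reason = "logistic fit did not converge (separation?)"
                return res
        else:
            raise ValueError(f"unknown family {family!r}")
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        res.estimable = False
        res.reason = "singular or separated design"
        return res
    ci = fit.conf_int()[-1]
    res.effect = float(fit.params[-1])
    res.se = float(fit.bse[-1])
    res.ci_low, res.ci_high = float(ci[0]), float(ci[1])
    res.p = float(fit.pvalues[-1])
    return res


def _linear_scan(
    y: np.ndarray, met: pd.DataFrame, cov: np.ndarray
) -> pd.DataFrame:
    """Exact OLS for many metabolites against one outcome, shared covariates.

    Residualizes the outcome and every metabolite on the covariate block
    (Frisch-Waugh-Lovell), which reproduces the full-model coefficient,
    standard error and t-test while fitting all metabolites in one sweep.
    """
    n, p = cov.shape
    qmat, _ = np.linalg.qr(cov)
    yr = _residualize(y, qmat)
    zmat = met.to_numpy(float)
    zr = _residualize(zmat, qmat)
    szz = np.einsum("ij,ij->j", zr, zr)
    szy = zr.T @ yr
    df = n - p - 1
    z_ss = np.maximum(np.einsum("ij,ij->j", zmat, zmat), 1.0)
    estimable = (szz > _COLLINEAR_TOL * z_ss) & (df > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(estimable, szy / szz, np.nan)
        rss = yr @ yr - np.where(estimable, beta**2 * szz, 0.0)
        se = np.sqrt(np.maximum(rss, 0.0) / max(df, 1) / szz)
        tstat = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tstat), max(df, 1))
    tcrit = sps.t.ppf(0.975, max(df, 1))
    out = pd.DataFrame(
        {
            "effect": beta, "se": se, "p": pvals,
            "ci_low": beta - tcrit * se, "ci_high": beta + tcrit * se,
            "estimable": estimable,
        },
        index=met.columns,
    )
    out.loc[~out["estimable"], ["effect", "se", "p", "ci_low", "ci_high"]] = np.nan
    return out


def fit_dementia_cox(
    z_metabolite: pd.Series,
    dementia_time: pd.Series,
    dementia_event: pd.Series,
    covariates: pd.DataFrame,
    *,
    min_events: int = 10,
    adjustment: str = "demographic",
    stratum: str = "all",
    metabolite: str | None = None,
) -> AssociationResult:
    """Cox proportional-hazards fit for conversion to dementia.

    Effect is the log hazard ratio per 1-SD metabolite from the partial
    likelihood (Efron tie handling).  Zero events raise; monotone
    likelihoods and other convergence failures are flagged non-estimable.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    res = AssociationResult(
        metabolite=metabolite or str(z_metabolite.name),
        outcome="dementia", family="cox", adjustment=adjustment,
        stratum=stratum, n=0,
    )
    cov = covariates.drop(columns=["const"], errors="ignore")
    data = pd.concat(
        [
            z_metabolite.rename("__z"), cov,
            dementia_time.rename("__time"),
            dementia_event.astype(float).rename("__event"),
        ],
        axis=1,
    ).dropna()
    res.n = len(data)
    n_events = int(data["__event"].sum())
    if n_events == 0:
        raise ValueError("no events: cannot fit a dementia model")
    if n_events < min_events:
        res.estimable = False
        res.reason = f"too few events ({n_events} < {min_events})"
        return res
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter = CoxPHFitter()
            fitter.fit(data, duration_col="__time", event_col="__event")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        res.estimable = False
        res.reason = f"cox fit failed: {type(exc).__name__}"
        return res
    row = fitter.summary.loc["__z"]
    res.effect = float(row["coef"])
    res.se = float(row["se(coef)"])
    res.ci_low = float(row["coef lower 95%"])
    res.ci_high = float(row["coef upper 95%"])
    res.p = float(row["p"])
    return res


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    ``q[i] = min_{j: p_j >= p_i} (m * p_(j) / rank_j)``, capped at one;
    monotone nondecreasing in p within the family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1] with no missing values")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# the full suite
# ---------------------------------------------------------------------------

def _stratum_mask(subjects: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=subjects.index)
    if stratum == "cohort_A":
        return subjects["cohort"] == "A"
    if stratum == "cohort_B":
        return subjects["cohort"] == "B"
    if stratum == "age_lt65":
        return subjects["age"] < 65
    if stratum == "age_ge65":
        return subjects["age"] >= 65
    if stratum == "fazekas_ge2":
        return subjects["fazekas_grade"] >= 2
    raise ValueError(f"unknown stratum {stratum!r}")


def _scan_linear_family(
    rows: list[dict], met: pd.DataFrame, outcome: pd.Series,
    cov: pd.DataFrame, outcome_name: str, adjustment: str, stratum: str,
) -> None:
    data = pd.concat([outcome.rename("__y"), cov], axis=1).dropna()
    idx = data.index.intersection(met.index)
    met_sub = met.loc[idx]
    complete = met_sub.notna().all(axis=0)
    base = dict(outcome=outcome_name, family="linear",
                adjustment=adjustment, stratum=stratum)
    if len(idx) >= cov.shape[1] + 2 and complete.any():
        scan = _linear_scan(
            data.loc[idx, "__y"].to_numpy(float),
            met_sub.loc[:, complete],
            data.loc[idx, cov.columns].to_numpy(float),
        )
        for mid, r in scan.iterrows():
            rows.append({
                **base, "metabolite": mid, "n": len(idx),
                "effect": r["effect"], "se": r["se"], "p": r["p"],
                "ci_low": r["ci_low"], "ci_high": r["ci_high"], "q": np.nan,
                "significant": False, "estimable": bool(r["estimable"]),
                "reason": "" if r["estimable"]
                else "collinear with adjustment covariates",
            })
    # metabolites with their own missing values get an individual fit
    for mid in met.columns[~complete.reindex(met.columns, fill_value=False)]:
        res = fit_metabolite_outcome(
            met[mid], outcome, cov, family="linear", adjustment=adjustment,
            stratum=stratum, metabolite=mid, outcome_name=outcome_name)
        rows.append(res.as_row())


def run_analysis_suite(
    metabolites: pd.DataFrame,
    subjects: pd.DataFrame,
    options: SuiteOptions | None = None,
    panel: OutcomePanel | None = None,
) -> pd.DataFrame:
    """Fit every metabolite x outcome x model combination and control FDR.

    ``metabolites`` is a subjects x metabolites table of autoscaled values
    (see :func:`subject_metabolite_table`).  Returns one row per fit in a
    deterministic order, with Benjamini-Hochberg q-values computed within
    each (outcome, family, adjustment, stratum) family over its estimable
    fits and a ``significant`` flag at ``q < fdr_alpha``.  Strata smaller
    than ``min_stratum_n`` are skipped (the run log records why); change
    and dementia models are fitted on the full population only.
    """
    options = options or SuiteOptions()
    subjects = subjects.set_index("subject_id") \
        if "subject_id" in subjects.columns else subjects
    if panel is None:
        panel = orient_and_scale_outcomes(
            subjects, orientation_overrides=options.orientation_overrides)
    met = metabolites.reindex(subjects.index)
    rows: list[dict] = []
    skipped: list[str] = []

    if not met.columns.empty:
        for stratum in options.strata:
            mask = _stratum_mask(subjects, stratum)
            sub = subjects[mask]
            if len(sub) < options.min_stratum_n:
                skipped.append(
                    f"stratum {stratum}: n={len(sub)} < {options.min_stratum_n}")
                continue
            met_s = met.loc[mask[mask].index]
            for adjustment in options.adjustments:
                cov = build_covariates(sub, adjustment)
                keep = [c for c in cov.columns
                        if c == "const" or cov[c].nunique() > 1]
                cov = cov[keep]
                if options.include_baseline:
                    for name in panel.baseline.columns:
                        _scan_linear_family(
                            rows, met_s, panel.baseline.loc[mask[mask].index, name],
                            cov, name, adjustment, stratum)
                    for name in panel.binary.columns:
                        y = panel.binary.loc[mask[mask].index, name]
                        for mid in met_s.columns:
                            res = fit_metabolite_outcome(
                                met_s[mid], y, cov, family="logistic",
                                adjustment=adjustment, stratum=stratum,
                                metabolite=mid, outcome_name=name)
                            rows.append(res.as_row())
                if options.include_changes and stratum == "all" \
                        and adjustment in options.change_adjustments:
                    for name in panel.changes.columns:
                        _scan_linear_family(
                            rows, met_s, panel.changes.loc[mask[mask].index, name],
                            cov, name, adjustment, stratum)

        if options.include_cox and "dementia_time" in subjects.columns:
            cov = build_covariates(subjects, options.cox_adjustment)
            n_events = int(subjects["dementia_event"].sum())
            if n_events == 0:
                skipped.append("cox: no dementia events")
            else:
                for mid in met.columns:
                    res = fit_dementia_cox(
                        met[mid], subjects["dementia_time"],
                        subjects["dementia_event"], cov,
                        min_events=options.min_events,
                        adjustment=options.cox_adjustment, metabolite=mid)
                    rows.append(res.as_row())

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if not results.empty:
        for _, idx in results.groupby(
                ["outcome", "family", "adjustment", "stratum"],
                sort=False).groups.items():
            grp = results.loc[idx]
            ok = grp["estimable"] & grp["p"].notna()
            if ok.any():
                q = bh_fdr(grp.loc[ok, "p"].to_numpy())
                results.loc[grp.index[ok], "q"] = q
                results.loc[grp.index[ok], "significant"] = q < options.fdr_alpha
    results.attrs["skipped"] = skipped
    return results.reset_index(drop=True)
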