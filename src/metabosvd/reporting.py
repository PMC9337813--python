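"""Summary artefacts and the end-to-end pipeline runner.

Renders the association results into the two tabular summaries practitioners
expect — a metabolite x outcome significance grid (signed -log10 p with
star flags: * for p < 0.05, ** for FDR q < 0.05) and a forest-style hazard
table for the dementia Cox family — and drives simulate -> qc -> associate
-> report from a single serializable configuration, writing a run manifest
with per-stage counts and output checksums so a (config, seed) pair
reproduces every file byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from . import qc as qcmod
from . import simulate as sim

__all__ = [
    "PipelineConfig",
    "build_summary_matrix",
    "build_hazard_table",
    "run_pipeline",
]

log = logging.getLogger("metabosvd")


def build_summary_matrix(
    results: pd.DataFrame,
    *,
    family: str = "linear",
    adjustment: str = "extended",
    stratum: str = "all",
    include_logistic: bool = True,
) -> pd.DataFrame:
    """Long-format significance grid for one model specification.

    One row per metabolite x outcome with the signed significance value
    sign(effect) * (-log10 p) and star flags (* p < 0.05, ** q < 0.05).
    Raises with the list of available specifications if the requested one
    was never fitted.
    """
    families = [family] + (["logistic"] if include_logistic
                           and family == "linear" else [])
    sel = results[
        results["family"].isin(families)
        & (results["adjustment"] == adjustment)
        & (results["stratum"] == stratum)
        & results["estimable"]
    ]
    if sel.empty:
        available = sorted(
            set(map(tuple, results[["family", "adjustment", "stratum"]]
                    .drop_duplicates().to_numpy())))
        raise ValueError(
            f"no results for (family={family}, adjustment={adjustment}, "
            f"stratum={stratum}); available: {available}")
    with np.errstate(divide="ignore"):
        signed = np.sign(sel["effect"]) * (-np.log10(sel["p"]))
    stars = np.where(sel["q"] < 0.05, "**",
                     np.where(sel["p"] < 0.05, "*", ""))
    out = pd.DataFrame({
        "metabolite": sel["metabolite"].to_numpy(),
        "outcome": sel["outcome"].to_numpy(),
        "signed_log10_p": signed.to_numpy(),
        "star": stars,
        "effect": sel["effect"].to_numpy(),
        "p": sel["p"].to_numpy(),
        "q": sel["q"].to_numpy(),
    })
    return out.sort_values(["metabolite", "outcome"]).reset_index(drop=True)


def build_hazard_table(cox_results: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Forest-style dementia hazard-ratio table, sorted by p.

    Hazard ratios are exp(log HR) with 95% CI; ``significant_p05`` marks
    associations at p < 0.05.  Returns the table and the number of
    non-estimable fits excluded from it.
    """
    cox = cox_results[cox_results["family"] == "cox"]
    n_excluded = int((~cox["estimable"]).sum())
    est = cox[cox["estimable"]]
    table = pd.DataFrame({
        "metabolite": est["metabolite"].to_numpy(),
        "hr": np.exp(est["effect"].to_numpy()),
        "hr_ci_low": np.exp(est["ci_low"].to_numpy()),
        "hr_ci_high": np.exp(est["ci_high"].to_numpy()),
        "p": est["p"].to_numpy(),
        "q": est["q"].to_numpy(),
        "n": est["n"].to_numpy(),
        "significant_p05": (est["p"] < 0.05).to_numpy(),
    })
    return table.sort_values("p").reset_index(drop=True), n_excluded


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Serializable configuration of a full pipeline run."""

    out_dir: str = "metabosvd_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    qc: dict = field(default_factory=dict)  # QCParams overrides
    suite: dict = field(default_factory=dict)  # SuiteOptions overrides
    # paths to pre-existing inputs; when set, the simulate stage is skipped
    intensities: str | None = None
    samples: str | None = None
    subjects: str | None = None
    summary_adjustment: str = "extended"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_effect_matrix(effects_by_feature, feature_ids: list[str]) -> pd.DataFrame | None:
    """Accept an effect matrix as a nested dict {feature: {outcome: beta}}."""
    if effects_by_feature is None:
        return None
    if isinstance(effects_by_feature, pd.DataFrame):
        return effects_by_feature
    em = pd.DataFrame(0.0, index=feature_ids, columns=list(sim.EFFECT_OUTCOMES))
    for feat, effects in effects_by_feature.items():
        for outcome, beta in effects.items():
            em.loc[feat, outcome] = float(beta)
    return em


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate (optional) -> qc -> associate -> report.

    Returns the run manifest (also written to ``manifest.json``): seed,
    parameter hash, per-stage feature/subject counts and sha256 checksums of
    every output file.  Any stage failure is re-raised with the stage name.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": int(config.seed),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def run_stage(name, fn):
        """Run one stage; record its summary or abort naming the stage."""
        try:
            info, payload = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        manifest["stages"][name] = {"status": "ok", **info}
        log.info("stage %s: %s", name, info)
        return payload

    # --- simulate ---------------------------------------------------------
    def _simulate():
        overrides = dict(config.simulate)
        overrides.setdefault("seed", config.seed)
        n_feat = overrides.get("n_features", sim.SimulationConfig.n_features)
        overrides["effect_matrix"] = _build_effect_matrix(
            overrides.get("effect_matrix"),
            [f"met{i:04d}" for i in range(1, n_feat + 1)])
        if "n_subjects_per_cohort" in overrides:
            overrides["n_subjects_per_cohort"] = tuple(
                overrides["n_subjects_per_cohort"])
        if "dilution_design" in overrides:
            overrides["dilution_design"] = tuple(
                (float(f), int(c)) for f, c in overrides["dilution_design"])
        sim_config = sim.SimulationConfig(**overrides)
        study = sim.simulate_study(sim_config)
        paths = sim.write_dataset(out, study)
        written.extend(paths.values())
        info = {
            "n_features": int(study["intensities"].shape[0]),
            "n_samples": int(study["intensities"].shape[1]),
            "n_subjects": int(len(study["subjects"])),
        }
        return info, None

    if config.intensities is None:
        run_stage("simulate", _simulate)
        raw = pd.read_csv(out / "intensities.csv", index_col="feature_id")
        samples = pd.read_csv(out / "samples.csv")
        subjects = pd.read_csv(out / "subjects.csv")
    else:
        raw = pd.read_csv(config.intensities, index_col="feature_id")
        samples = pd.read_csv(config.samples)
        subjects = pd.read_csv(config.subjects)
        manifest["stages"]["simulate"] = {"status": "skipped (inputs provided)"}

    # --- qc ---------------------------------------------------------------
    def _qc():
        params = qcmod.QCParams(**config.qc)
        result = qcmod.qc_pipeline(raw, samples, params)
        result["corrected"].values.to_csv(out / "corrected.csv",
                                          index_label="feature_id")
        result["scaled"].values.to_csv(out / "scaled.csv",
                                       index_label="feature_id")
        result["feature_qc"].to_csv(out / "feature_qc.csv",
                                    index_label="feature_id")
        (out / "qc_report.json").write_text(
            json.dumps(result["report"], indent=1, sort_keys=True))
        written.extend(out / f for f in
                       ("corrected.csv", "scaled.csv", "feature_qc.csv",
                        "qc_report.json"))
        info = {
            "n_features_in": int(len(raw)),
            "n_features_corrected": int(
                result["loess_diagnostics"]["corrected"].sum()),
            "n_features_pass": result["report"]["n_pass"],
            "glog_lambda": result["glog_lambda"],
        }
        return info, result

    qc_result = run_stage("qc", _qc)

    # --- associate --------------------------------------------------------
    def _associate():
        met = assoc.subject_metabolite_table(qc_result["scaled"].values, samples)
        options = assoc.SuiteOptions(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in config.suite.items()})
        results = assoc.run_analysis_suite(met, subjects, options)
        results.to_csv(out / "associations.csv", index=False)
        written.append(out / "associations.csv")
        info = {
            "n_metabolites": int(met.shape[1]),
            "n_subjects": int(met.shape[0]),
            "n_fits": int(len(results)),
            "n_significant": int(results["significant"].sum()),
            "skipped": results.attrs.get("skipped", []),
        }
        return info, results

    results = run_stage("associate", _associate)

    # --- report -----------------------------------------------------------
    def _report():
        info = {}
        if (results["family"] == "cox").any():
            hazard, n_excl = build_hazard_table(results)
            hazard.to_csv(out / "dementia_hr.csv", index=False)
            written.append(out / "dementia_hr.csv")
            info["cox_non_estimable"] = n_excl
        try:
            grid = build_summary_matrix(
                results, adjustment=config.summary_adjustment)
            grid.to_csv(out / "summary_matrix.csv", index=False)
            written.append(out / "summary_matrix.csv")
            info["summary_cells"] = int(len(grid))
        except ValueError as exc:
            info["summary"] = f"skipped: {exc}"
        return info, None

    run_stage("report", _report)

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(set(written))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
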