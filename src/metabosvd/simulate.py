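"""Synthetic serum-metabolomics study generator.

Emulates a two-cohort cerebral small vessel disease (SVD) cohort study with an
LC-MS-style analytical run: study samples injected in randomized order,
pooled-QC injections interspersed at a fixed interval, a dilution series of
the pooled QC at the start and end of each analytical batch, smooth
multiplicative run-order drift, batch-level response offsets, and
multiplicative (lognormal) technical and biological variation.  Planted
standardized metabolite effects on MRI/cognition outcomes, on binary lesion
outcomes, and on the dementia hazard provide ground truth for parameter
recovery of the downstream association models.

All randomness flows from ``SimulationConfig.seed`` through independent
``numpy`` generator streams, so a fixed configuration reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SubjectData",
    "make_run_sequence",
    "simulate_subjects",
    "simulate_intensities",
    "simulate_study",
    "write_dataset",
    "CONTINUOUS_OUTCOMES",
    "BINARY_OUTCOMES",
]

# Continuous endpoints and the affine map from the unit-variance latent
# severity scale L (higher = worse) to the natural measurement scale:
#   identity: value = a + b * L        exp: value = exp(a + b * L)
# Signs of b encode the natural direction of each instrument (e.g. mean
# diffusivity normalized peak height falls as white-matter damage rises).
CONTINUOUS_OUTCOMES: dict[str, tuple[float, float, str]] = {
    "mdnph": (0.35, -0.03, "identity"),
    "wmh_percent": (0.0, 0.9, "exp"),
    "total_brain_volume": (1150.0, -60.0, "identity"),
    "psmd": (2.5, 0.5, "identity"),
    "global_cognition": (0.0, -1.0, "identity"),
    "executive_function": (0.0, -1.0, "identity"),
    "processing_speed": (0.0, -1.0, "identity"),
    "barthel_index": (90.0, -6.0, "identity"),
}

BINARY_OUTCOMES: dict[str, float] = {
    # baseline prevalence of the lesion type
    "microbleed_presence": 0.30,
    "lacune_presence": 0.40,
}

#: outcome columns accepted in ``SimulationConfig.effect_matrix``
EFFECT_OUTCOMES = tuple(CONTINUOUS_OUTCOMES) + tuple(BINARY_OUTCOMES) + ("dementia",)

_DEFAULT_DILUTION_DESIGN = (
    (1.0, 10),
    (0.8, 5),
    (0.6, 3),
    (0.4, 3),
    (0.2, 5),
    (0.01, 10),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study and analytical run.

    The cohort sizes default to the two symptomatic-SVD cohorts the pipeline
    is designed around (121 and 503 participants); the dilution-series design
    defaults to 10 x 100%, 5 x 80%, 3 x 60%, 3 x 40%, 5 x 20%, 10 x 1%
    replicates per placement block.
    """

    n_subjects_per_cohort: tuple[int, int] = (121, 503)
    n_features: int = 100
    n_batches: int = 2
    qc_interval: int = 10
    dilution_design: tuple[tuple[float, int], ...] = _DEFAULT_DILUTION_DESIGN
    dilution_blocks_per_batch: int = 2  # one at batch start, one at batch end
    drift_amplitude: float = 0.10
    batch_offset_sd: float = 0.10
    tech_cv: float = 0.10
    bio_cv: float = 0.50
    # fractions of features planted to violate each quality criterion
    frac_fail_rsd: float = 0.0
    frac_fail_dilution: float = 0.0
    frac_fail_varratio: float = 0.0
    bad_rsd_tech_cv: float = 0.60
    effect_matrix: pd.DataFrame | None = None
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.25, "sex": 0.12, "cohort": 0.20}
    )
    visit_years: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"A": (0, 1, 2, 3), "B": (0, 5, 9, 14)}
    )
    slope_mean: float = 0.05  # latent worsening per year
    slope_sd: float = 0.05
    visit_noise_sd: float = 0.20
    dementia_base_hazard: float = 0.02  # events per person-year at average risk
    dementia_age_loghr: float = 0.5
    censor_years: float = 14.0
    missing_rate: float = 0.0
    platform: str = "lipid RPC+"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_subjects_per_cohort) != 2 or any(
            int(n) < 1 for n in self.n_subjects_per_cohort
        ):
            raise ValueError("n_subjects_per_cohort must be two positive integers")
        for name in ("n_features", "n_batches", "qc_interval"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for frac, count in self.dilution_design:
            if not (0.0 < frac <= 1.0):
                raise ValueError("dilution fractions must lie in (0, 1]")
            if int(count) < 1:
                raise ValueError("dilution replicate counts must be >= 1")
        for name in ("tech_cv", "bio_cv", "bad_rsd_tech_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("drift_amplitude", "batch_offset_sd", "censor_years",
                     "dementia_base_hazard", "missing_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("frac_fail_rsd", "frac_fail_dilution", "frac_fail_varratio"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_matrix is not None:
            bad = set(self.effect_matrix.columns) - set(EFFECT_OUTCOMES)
            if bad:
                raise ValueError(f"unknown outcome(s) in effect_matrix: {sorted(bad)}")
            if len(self.effect_matrix) != self.n_features:
                raise ValueError(
                    "effect_matrix must have one row per feature "
                    f"({len(self.effect_matrix)} != {self.n_features})"
                )

    @property
    def feature_ids(self) -> list[str]:
        return [f"met{i:04d}" for i in range(1, self.n_features + 1)]

    def effects(self) -> pd.DataFrame:
        """Planted effect matrix (features x outcomes), zeros by default."""
        base = pd.DataFrame(
            0.0, index=self.feature_ids, columns=list(EFFECT_OUTCOMES)
        )
        if self.effect_matrix is not None:
            em = self.effect_matrix.copy()
            em.index = self.feature_ids
            for col in em.columns:
                base[col] = em[col].astype(float)
        return base


@dataclass
class SimulationTruth:
    """Ground truth factors behind a simulated analytical run.

    The composition invariant is exact:
    ``raw = clean * drift * batch_offset * tech_noise`` element-wise.
    """

    clean: pd.DataFrame  # features x samples, drift/noise-free intensity
    drift: pd.Series  # per sample multiplicative drift factor (=1 at batch start)
    batch_offsets: pd.DataFrame  # features x batch, multiplicative
    tech_noise: pd.DataFrame  # features x samples, mean-one lognormal
    feature_flags: pd.DataFrame  # fail_rsd / fail_dilution / fail_varratio booleans
    effect_matrix: pd.DataFrame
    seed: int

    def offset_factor(self, manifest: pd.DataFrame) -> pd.DataFrame:
        """Per-sample batch offset matrix aligned with ``clean``."""
        batches = manifest.set_index("sample_id")["batch"]
        cols = {
            s: self.batch_offsets[int(batches[s])] for s in self.clean.columns
        }
        return pd.DataFrame(cols, index=self.clean.index)


@dataclass
class SubjectData:
    """Phenotype table plus the true standardized metabolite levels."""

    phenotypes: pd.DataFrame  # one row per subject
    metabolite_z: pd.DataFrame  # subjects x features, true 1-SD scale levels


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


# ---------------------------------------------------------------------------
# run sequence
# ---------------------------------------------------------------------------

def make_run_sequence(
    config: SimulationConfig, subject_ids: list[str] | None = None
) -> pd.DataFrame:
    """Lay out the injection order of an analytical run.

    Study samples are shuffled and split contiguously across batches.  Each
    batch opens and closes with a full dilution-series block, a pooled-QC
    injection precedes the first study sample (the batch boundary), one
    follows every ``qc_interval`` study samples, and one closes the batch if
    the interval rule has not just placed one there.

    Returns a manifest with columns ``sample_id, subject_id, sample_type,
    run_order, batch, dilution_fraction, platform``.
    """
    rng = _rng(config, 1)
    if subject_ids is None:
        n_a, n_b = config.n_subjects_per_cohort
        subject_ids = [f"A{i:04d}" for i in range(1, n_a + 1)] + [
            f"B{i:04d}" for i in range(1, n_b + 1)
        ]
    order = rng.permutation(len(subject_ids))
    shuffled = [subject_ids[i] for i in order]
    chunks = np.array_split(np.arange(len(shuffled)), config.n_batches)
    for batch_idx, chunk in enumerate(chunks, start=1):
        if config.qc_interval >= max(len(chunk), 1):
            raise ValueError(
                f"degenerate QC design: qc_interval={config.qc_interval} >= "
                f"{len(chunk)} study samples in batch {batch_idx}"
            )

    rows: list[dict] = []
    run_order = 0
    qc_count = 0
    dil_count = 0

    def add(sample_id: str, sample_type: str, batch: int,
            subject_id: str | None = None, fraction: float | None = None) -> None:
        nonlocal run_order
        run_order += 1
        rows.append(
            {
                "sample_id": sample_id,
                "subject_id": subject_id if subject_id is not None else "",
                "sample_type": sample_type,
                "run_order": run_order,
                "batch": batch,
                "dilution_fraction": fraction if fraction is not None else np.nan,
                "platform": config.platform,
            }
        )

    def add_dilution_block(batch: int) -> None:
        nonlocal dil_count
        for frac, count in config.dilution_design:
            for _ in range(count):
                dil_count += 1
                add(f"dil{dil_count:04d}", "dilution_qc", batch, fraction=frac)

    def add_qc(batch: int) -> None:
        nonlocal qc_count
        qc_count += 1
        add(f"qc{qc_count:04d}", "pooled_qc", batch)

    for batch_idx, chunk in enumerate(chunks, start=1):
        if config.dilution_blocks_per_batch >= 1:
            add_dilution_block(batch_idx)
        add_qc(batch_idx)  # batch boundary
        since_qc = 0
        for pos in chunk:
            sid = shuffled[pos]
            add(f"study_{sid}", "study", batch_idx, subject_id=sid)
            since_qc += 1
            if since_qc == config.qc_interval:
                add_qc(batch_idx)
                since_qc = 0
        if since_qc > 0:  # close the batch on a QC injection
            add_qc(batch_idx)
        if config.dilution_blocks_per_batch >= 2:
            add_dilution_block(batch_idx)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subjects and outcomes
# ---------------------------------------------------------------------------

def _covariate_predictor(config: SimulationConfig, pheno: pd.DataFrame) -> np.ndarray:
    g = config.covariate_effects
    age_z = (pheno["age"].to_numpy() - 66.5) / 9.2
    sex_c = (pheno["sex"] == "male").to_numpy(float) - 0.58
    coh_c = (pheno["cohort"] == "A").to_numpy(float) - (
        config.n_subjects_per_cohort[0] / sum(config.n_subjects_per_cohort)
    )
    return (
        g.get("age", 0.0) * age_z
        + g.get("sex", 0.0) * sex_c
        + g.get("cohort", 0.0) * coh_c
    )


def simulate_subjects(config: SimulationConfig) -> SubjectData:
    """Draw the two-cohort clinical population with planted metabolite effects.

    True metabolite levels are standard-normal per subject (the 1-SD scale
    the association models report on).  Each continuous endpoint is built on
    a unit-variance latent severity scale: planted effects and covariate
    effects enter linearly and the residual variance is set so the marginal
    variance is one, which makes planted betas directly recoverable from the
    z-scored endpoint downstream.  Binary lesion outcomes use a logistic
    link; dementia conversion times are exponential with a log-hazard linear
    in the planted predictors and right-censoring at ``censor_years``.
    """
    rng = _rng(config, 2)
    n_a, n_b = config.n_subjects_per_cohort
    n = n_a + n_b
    subject_ids = [f"A{i:04d}" for i in range(1, n_a + 1)] + [
        f"B{i:04d}" for i in range(1, n_b + 1)
    ]
    cohort = np.array(["A"] * n_a + ["B"] * n_b)
    age = np.where(
        cohort == "A",
        np.clip(rng.normal(70.0, 8.5, n), 45, 90),
        np.clip(rng.normal(65.5, 8.8, n), 50, 85),
    )
    sex = np.where(rng.random(n) < 0.58, "male", "female")
    risk_p = {
        "diabetes": (0.12, 0.10),
        "hypertension": (0.80, 0.70),
        "hypercholesterolaemia": (0.60, 0.45),
    }
    pheno = pd.DataFrame({"subject_id": subject_ids, "cohort": cohort,
                          "age": np.round(age, 1), "sex": sex})
    for name, (pa, pb) in risk_p.items():
        p = np.where(cohort == "A", pa, pb)
        pheno[name] = rng.random(n) < p

    z = rng.standard_normal((n, config.n_features))
    z_df = pd.DataFrame(z, index=subject_ids, columns=config.feature_ids)
    effects = config.effects()
    cov_pred = _covariate_predictor(config, pheno)
    var_cov = float(np.var(cov_pred))

    all_years = sorted({float(t) for ys in config.visit_years.values() for t in ys})
    latent_wmh = None
    for name, (a, b, link) in CONTINUOUS_OUTCOMES.items():
        beta = effects[name].to_numpy()
        resid_var = 1.0 - float(beta @ beta) - var_cov
        if resid_var <= 1e-4:
            raise ValueError(
                f"planted effects on '{name}' exceed the unit outcome variance"
            )
        latent = cov_pred + z @ beta + rng.normal(0.0, np.sqrt(resid_var), n)
        if name == "wmh_percent":
            latent_wmh = latent
        slope = rng.normal(config.slope_mean, config.slope_sd, n)
        for t in all_years:
            lat_t = latent + slope * t
            if t > 0:
                lat_t = lat_t + rng.normal(0.0, config.visit_noise_sd, n)
            value = a + b * lat_t if link == "identity" else np.exp(a + b * lat_t)
            if name == "barthel_index":
                value = np.clip(value, 0.0, 100.0)
            # blank out visits not on the subject's cohort schedule
            on_schedule = np.array(
                [t in config.visit_years.get(c, ()) for c in cohort]
            )
            value = np.where(on_schedule, value, np.nan)
            pheno[f"{name}_y{t:g}"] = value

    # binary lesion outcomes and derived counts
    age_z = (pheno["age"].to_numpy() - 66.5) / 9.2
    for name, prevalence in BINARY_OUTCOMES.items():
        theta = effects[name].to_numpy()
        lp = np.log(prevalence / (1 - prevalence)) + z @ theta + 0.3 * age_z
        present = rng.random(n) < expit(lp)
        count = present * (1 + rng.poisson(1.2, n))
        pheno[name.replace("_presence", "_count")] = count

    # Fazekas grade follows the white-matter hyperintensity latent
    pheno["fazekas_grade"] = np.digitize(latent_wmh, [-0.8, 0.2, 1.0])

    # dementia conversion: exponential, log-hazard linear in planted predictors
    eta = effects["dementia"].to_numpy()
    log_rate = np.log(config.dementia_base_hazard) + z @ eta \
        + config.dementia_age_loghr * age_z
    latent_time = rng.exponential(1.0, n) / np.exp(log_rate)
    event = latent_time <= config.censor_years
    pheno["dementia_event"] = event
    pheno["dementia_time"] = np.where(event, latent_time, config.censor_years)

    return SubjectData(phenotypes=pheno, metabolite_z=z_df)


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def _drift_curves(config: SimulationConfig, manifest: pd.DataFrame,
                  rng: np.random.Generator) -> pd.Series:
    """Smooth multiplicative drift, one cubic curve per batch, =1 at batch start."""
    factors = pd.Series(1.0, index=manifest["sample_id"].to_numpy())
    grid = np.linspace(0.0, 1.0, 101)
    for batch, grp in manifest.groupby("batch"):
        coefs = rng.normal(size=3)
        dev = coefs[0] * grid + coefs[1] * grid**2 + coefs[2] * grid**3
        peak = np.max(np.abs(dev))
        scale = config.drift_amplitude / peak if peak > 0 else 0.0
        orders = grp["run_order"].to_numpy(float)
        span = orders.max() - orders.min()
        u = (orders - orders.min()) / span if span > 0 else np.zeros_like(orders)
        dev_u = coefs[0] * u + coefs[1] * u**2 + coefs[2] * u**3
        factors.loc[grp["sample_id"].to_numpy()] = 1.0 + scale * dev_u
    return factors


def simulate_intensities(
    config: SimulationConfig,
    sequence: pd.DataFrame,
    subjects: SubjectData,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Build the raw feature-by-sample intensity matrix for a run sequence.

    Study intensities are the subject's biological level (lognormal around a
    feature base abundance, driven by the same standardized levels the
    outcomes use); pooled-QC intensities are the feature-wise mean of the
    clean study intensities (equal parts of every study sample); dilution-QC
    intensities scale proportionally with the dilution fraction.  Everything
    is then multiplied by the batch drift curve, a per-(feature, batch)
    offset, and mean-one lognormal technical noise.

    Configured fractions of features are planted to violate each quality
    criterion: inflated technical noise (precision), a flat dilution response
    (linearity), or near-zero biological variance (information content).
    """
    rng = _rng(config, 3)
    feats = config.feature_ids
    n_feat = len(feats)

    base = 10.0 ** rng.uniform(4.0, 6.0, n_feat)
    # plant criterion violations on disjoint feature subsets
    n_bad = [int(round(f * n_feat)) for f in (
        config.frac_fail_rsd, config.frac_fail_dilution, config.frac_fail_varratio)]
    if sum(n_bad) > n_feat:
        raise ValueError("planted-failure fractions overlap: sum exceeds 1")
    perm = rng.permutation(n_feat)
    flags = pd.DataFrame(False, index=feats,
                         columns=["fail_rsd", "fail_dilution", "fail_varratio"])
    start = 0
    for col, k in zip(flags.columns, n_bad):
        flags.iloc[perm[start:start + k], flags.columns.get_loc(col)] = True
        start += k

    tech_cv = np.where(flags["fail_rsd"], config.bad_rsd_tech_cv, config.tech_cv)
    sigma_t = np.sqrt(np.log1p(tech_cv**2))
    sigma_b = np.full(n_feat, np.sqrt(np.log1p(config.bio_cv**2)))
    sigma_b[flags["fail_varratio"].to_numpy()] *= 0.05

    z = subjects.metabolite_z
    sample_ids = sequence["sample_id"].to_numpy()
    clean = pd.DataFrame(0.0, index=feats, columns=sample_ids)

    study = sequence[sequence["sample_type"] == "study"]
    # mean-one lognormal biological variation around the base abundance
    study_subj = study["subject_id"].to_numpy()
    z_mat = z.loc[study_subj].to_numpy().T  # features x study samples
    bio = np.exp(sigma_b[:, None] * z_mat - 0.5 * sigma_b[:, None] ** 2)
    clean_study = base[:, None] * bio
    clean.loc[:, study["sample_id"].to_numpy()] = clean_study

    qc_level = clean_study.mean(axis=1)  # equal parts of every study sample
    qc = sequence[sequence["sample_type"] == "pooled_qc"]
    clean.loc[:, qc["sample_id"].to_numpy()] = np.tile(
        qc_level[:, None], (1, len(qc)))

    dil = sequence[sequence["sample_type"] == "dilution_qc"]
    frac = dil["dilution_fraction"].to_numpy(float)
    dil_vals = qc_level[:, None] * frac[None, :]
    # flat responders ignore the dilution fraction entirely
    dil_vals[flags["fail_dilution"].to_numpy(), :] = qc_level[
        flags["fail_dilution"].to_numpy(), None]
    clean.loc[:, dil["sample_id"].to_numpy()] = dil_vals

    drift = _drift_curves(config, sequence, rng)
    offsets = pd.DataFrame(
        np.exp(rng.normal(0.0, config.batch_offset_sd,
                          (n_feat, config.n_batches))),
        index=feats, columns=range(1, config.n_batches + 1),
    )
    noise = pd.DataFrame(
        np.exp(sigma_t[:, None] * rng.standard_normal((n_feat, len(sample_ids)))
               - 0.5 * sigma_t[:, None] ** 2),
        index=feats, columns=sample_ids,
    )

    batch_of = sequence.set_index("sample_id")["batch"]
    offset_cols = offsets.loc[:, batch_of.loc[sample_ids].to_numpy()].to_numpy()
    raw = clean.to_numpy() * drift.loc[sample_ids].to_numpy()[None, :] \
        * offset_cols * noise.to_numpy()
    raw_df = pd.DataFrame(raw, index=feats, columns=sample_ids)

    if config.missing_rate > 0:
        mask = rng.random(raw_df.shape) < config.missing_rate
        raw_df = raw_df.mask(mask)

    truth = SimulationTruth(
        clean=clean, drift=drift, batch_offsets=offsets, tech_noise=noise,
        feature_flags=flags, effect_matrix=config.effects(), seed=config.seed,
    )
    return raw_df, truth


def simulate_study(config: SimulationConfig) -> dict:
    """Full generation pass: subjects, run sequence, raw intensities, truth."""
    subjects = simulate_subjects(config)
    sequence = make_run_sequence(
        config, subject_ids=list(subjects.phenotypes["subject_id"]))
    raw, truth = simulate_intensities(config, sequence, subjects)
    return {
        "intensities": raw,
        "manifest": sequence,
        "subjects": subjects.phenotypes,
        "metabolite_z": subjects.metabolite_z,
        "truth": truth,
    }


def write_dataset(out_dir: str | Path, study: dict) -> dict[str, Path]:
    """Write ``intensities.csv``, ``samples.csv``, ``subjects.csv`` and
    ``truth.json`` (planted effects, drift parameters, seed) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": out / "intensities.csv",
        "samples": out / "samples.csv",
        "subjects": out / "subjects.csv",
        "truth": out / "truth.json",
    }
    study["intensities"].to_csv(paths["intensities"], index_label="feature_id")
    study["manifest"].to_csv(paths["samples"], index=False)
    study["subjects"].to_csv(paths["subjects"], index=False)
    truth: SimulationTruth = study["truth"]
    nonzero = truth.effect_matrix.loc[(truth.effect_matrix != 0).any(axis=1)]
    payload = {
        "seed": int(truth.seed),
        "effects": {f: {o: v for o, v in row.items() if v != 0}
                    for f, row in nonzero.to_dict(orient="index").items()},
        "drift": {s: float(v) for s, v in truth.drift.items()},
        "batch_offsets": {
            str(b): truth.batch_offsets[b].round(6).to_dict()
            for b in truth.batch_offsets.columns
        },
        "feature_flags": {
            c: truth.feature_flags.index[truth.feature_flags[c]].tolist()
            for c in truth.feature_flags.columns
        },
    }
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths
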