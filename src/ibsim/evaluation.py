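"""Model discrimination and parameter recovery.

Closes the inferential loop on synthetic cohorts: compute the diagnostic
signature of a cohort (noticing rate as a function of exposure plus the
localisation affinities of noticers), classify which noticing model
generated it with a transparent rule set, estimate the hazard rate of a
constant-hazard cohort by maximum likelihood, and run the end-to-end
pipeline (simulate -> synthesise -> screen -> analyse -> evaluate) from a
single config with a seed manifest.

The rule-based classifier operationalises the qualitative predictions of
the candidate models: a stochastic (constant-hazard) process shows a
noticing rate that rises with exposure duration, while event-triggered
processes show flat rates but localisation clustered at their anchoring
event (onset, offset or the fixation crossing). Significance of the rate
slope uses a percentile-bootstrap interval, keeping the whole artifact
within the same bootstrap idiom as the estimation stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import analysis, display, observers, screening
from .analysis import ProportionEstimate, add_noticer_column
from .display import catalog_by_id, condition_catalog
from .observers import ExclusionProbs, NoticingModel, ReportNoise

__all__ = [
    "ModelSignature",
    "ClassifierThresholds",
    "HazardFit",
    "RecoveryResult",
    "compute_signature",
    "classify_model",
    "recover_hazard",
    "model_discrimination_study",
    "hazard_recovery_study",
    "run_pipeline",
]


@dataclass
class ModelSignature:
    """Diagnostic signature of a cohort.

    ``rate_slope`` is the weighted least-squares slope of the noticing
    rate against visible exposure duration (per second of exposure).
    ``loc_onset_affinity`` is mean(distance-to-offset - distance-to-onset)
    among noticers in px (positive = onset-clustered);
    ``loc_fixation_affinity`` is the analogue with fixation in place of
    onset.
    """

    rate_by_exposure: dict[float, ProportionEstimate]
    rate_slope: float
    slope_ci: tuple[float, float]
    loc_onset_affinity: float
    loc_fixation_affinity: float
    n_noticers: int
    single_exposure: bool = False


@dataclass(frozen=True)
class ClassifierThresholds:
    """Margins for the rule-based classifier (documented defaults)."""

    affinity_margin_px: float = 30.0
    min_noticers: int = 20


@dataclass
class HazardFit:
    hazard_per_s: float
    se: float
    n_by_exposure: dict[float, tuple[int, int]]  # T -> (n, k)
    lack_of_fit_stat: float
    lack_of_fit_p: float
    boundary: bool = False


@dataclass
class RecoveryResult:
    """Confusion matrix and per-variant accuracy of a recovery study."""

    confusion: pd.DataFrame
    accuracy: dict[str, float]
    n_runs_per_variant: int
    n_per_condition: int
    seed: int


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------

def _wls_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares slope; ``y`` may be (m,) or batched (B, m)."""
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w, axis=-1)
    num = np.sum(w * (x - xbar) * (y - np.expand_dims(ybar, -1)), axis=-1)
    den = np.sum(w * (x - xbar) ** 2)
    return num / den


def compute_signature(
    cohort: pd.DataFrame,
    catalog: dict[str, display.ConditionSpec] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> ModelSignature:
    """Assemble the diagnostic signature of a cohort.

    Noticing rates are pooled per exposure label (x = mean visible
    duration in seconds); the slope CI comes from resampling each
    exposure cell's successes. Affinities are computed on full-scale
    noticer location reports.
    """
    df = cohort[cohort["onset_type"] != "none"].copy()
    if "noticer" not in df:
        df = add_noticer_column(df)
    if catalog is None:
        catalog = {}
        for exp in df["experiment"].unique():
            catalog.update(catalog_by_id(str(exp)))
    rng = np.random.default_rng(seed)

    groups = df.groupby("exposure_label_s")
    exposures, xs, ns, ks = [], [], [], []
    rate_by_exposure: dict[float, ProportionEstimate] = {}
    for label, sub in groups:
        exposures.append(float(label))
        xs.append(float(sub["visible_s"].mean()))
        ns.append(len(sub))
        ks.append(int(sub["noticer"].sum()))
        rate_by_exposure[float(label)] = analysis.rate_with_ci(
            sub["noticer"].to_numpy(), n_boot=n_boot,
            seed=int(rng.integers(2**31 - 1)),
        )
    xs_a, ns_a, ks_a = np.array(xs), np.array(ns), np.array(ks)
    single = len(xs) < 2

    if single:
        slope, ci = np.nan, (np.nan, np.nan)
    else:
        p = ks_a / ns_a
        slope = float(_wls_slope(xs_a, p, ns_a.astype(float)))
        boots = rng.binomial(ns_a, p, size=(n_boot, len(ns_a))) / ns_a
        slopes = _wls_slope(xs_a, boots, ns_a.astype(float))
        ci = tuple(float(v) for v in np.percentile(slopes, [2.5, 97.5]))

    noticers = df[df["noticer"]]
    if len(noticers):
        x = noticers["loc_x_panel"].to_numpy(float) / observers.PANEL_SCALE
        y = noticers["loc_y_panel"].to_numpy(float) / observers.PANEL_SCALE
        onset_x = np.empty(len(noticers))
        offset_x = np.empty(len(noticers))
        for (cid, direction), sub in noticers.groupby(["condition_id", "direction"]):
            cond = catalog[cid].with_direction(str(direction))
            idx = noticers.index.get_indexer(sub.index)
            onset_x[idx] = cond.onset_point[0]
            offset_x[idx] = cond.offset_point[0]
        d_on = np.hypot(x - onset_x, y - 300.0)
        d_off = np.hypot(x - offset_x, y - 300.0)
        d_fix = np.hypot(x - 350.0, y - 300.0)
        a_on = float(np.mean(d_off - d_on))
        a_fix = float(np.mean(d_off - d_fix))
    else:
        a_on = a_fix = np.nan

    return ModelSignature(
        rate_by_exposure=rate_by_exposure,
        rate_slope=slope,
        slope_ci=ci,
        loc_onset_affinity=a_on,
        loc_fixation_affinity=a_fix,
        n_noticers=int(len(noticers)),
        single_exposure=single,
    )


def classify_model(
    signature: ModelSignature,
    thresholds: ClassifierThresholds | None = None,
) -> str:
    """Classify the generating model from a signature.

    A significantly positive rate slope (bootstrap CI above zero) is
    diagnostic of the constant-hazard account. Otherwise the noticers'
    nearest localisation anchor (onset, fixation or offset, with a px
    margin over the runner-up) picks the event-triggered variant. Any
    ambiguous signature returns ``"undetermined"``.
    """
    th = thresholds or ClassifierThresholds()
    if signature.single_exposure or signature.n_noticers < th.min_noticers:
        return "undetermined"
    if np.isnan(signature.rate_slope) or np.isnan(signature.loc_onset_affinity):
        return "undetermined"
    lo, hi = signature.slope_ci
    if lo > 0.0:
        return "constant_hazard"
    if hi < 0.0:  # no candidate model predicts falling rates
        return "undetermined"
    a_on, a_fix = signature.loc_onset_affinity, signature.loc_fixation_affinity
    # relative mean distances: offset = 0, onset = -a_on, fixation = -a_fix
    dists = {"onset_window": -a_on, "fixation_cross": -a_fix, "offset_window": 0.0}
    ranked = sorted(dists, key=dists.get)
    if dists[ranked[1]] - dists[ranked[0]] < th.affinity_margin_px:
        return "undetermined"
    return ranked[0]


# ---------------------------------------------------------------------------
# Hazard recovery
# ---------------------------------------------------------------------------

def _hazard_loglik(lam: float, T: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    p = -np.expm1(-lam * T)
    return float(np.sum(k * np.log(p) - (n - k) * lam * T))


def recover_hazard(
    cohort: pd.DataFrame | None = None,
    exposure_table: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> HazardFit:
    """Maximum-likelihood hazard rate from per-exposure noticing counts.

    Under the constant-hazard account, P(notice | visible for T seconds)
    = 1 - exp(-lambda * T); the per-exposure Bernoulli likelihood is
    maximised over lambda. The standard error comes from the curvature of
    the log likelihood, and a Pearson lack-of-fit statistic across
    exposures flags cohorts whose rates are exposure-invariant (an
    event-triggered process masquerading as a low hazard).

    Either a cohort frame or an explicit ``(T, n, k)`` table may be given.
    """
    if exposure_table is not None:
        T, n, k = (np.asarray(v, dtype=float) for v in exposure_table)
    else:
        df = cohort[cohort["onset_type"] != "none"].copy()
        if "noticer" not in df:
            df = add_noticer_column(df)
        g = df.groupby("exposure_label_s").agg(
            T=("visible_s", "mean"), n=("noticer", "size"), k=("noticer", "sum")
        )
        T, n, k = g["T"].to_numpy(), g["n"].to_numpy(float), g["k"].to_numpy(float)

    fit_extras = dict(
        n_by_exposure={float(t): (int(nn), int(kk)) for t, nn, kk in zip(T, n, k)}
    )
    if k.sum() == 0:
        return HazardFit(0.0, np.nan, fit_extras["n_by_exposure"], np.nan, np.nan, True)
    if (k >= n).all():
        return HazardFit(np.inf, np.nan, fit_extras["n_by_exposure"], np.nan, np.nan, True)

    res = optimize.minimize_scalar(
        lambda lam: -_hazard_loglik(lam, T, n, k),
        bounds=(1e-9, 100.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(res.x)
    # observed information via central finite differences of the loglik
    h = max(1e-6, lam * 1e-4)
    d2 = (
        _hazard_loglik(lam + h, T, n, k)
        - 2 * _hazard_loglik(lam, T, n, k)
        + _hazard_loglik(lam - h, T, n, k)
    ) / h**2
    se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else np.nan
    p = -np.expm1(-lam * T)
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = np.sum((k - n * p) ** 2 / (n * p * (1 - p)))
    dof = max(1, len(T) - 1)
    pval = float(stats.chi2.sf(pearson, dof))
    return HazardFit(
        hazard_per_s=lam, se=se,
        n_by_exposure=fit_extras["n_by_exposure"],
        lack_of_fit_stat=float(pearson), lack_of_fit_p=pval,
    )


# ---------------------------------------------------------------------------
# Recovery studies
# ---------------------------------------------------------------------------

def _default_models(hazard: float = 0.5) -> dict[str, NoticingModel]:
    return {
        "onset_window": NoticingModel("onset_window", p_detect=0.45),
        "offset_window": NoticingModel("offset_window", p_detect=0.45),
        "fixation_cross": NoticingModel("fixation_cross", p_detect=0.45),
        "constant_hazard": NoticingModel("constant_hazard", hazard_per_s=hazard),
    }


def model_discrimination_study(
    n_per_condition: int = 1000,
    n_runs_per_variant: int = 50,
    seed: int = 0,
    experiment: str = "E3",
    models: dict[str, NoticingModel] | None = None,
    noise: ReportNoise | None = None,
    thresholds: ClassifierThresholds | None = None,
) -> RecoveryResult:
    """Generate cohorts under each variant and classify them back.

    Uses centred two-exposure conditions by default, where all four
    variants produce distinct signatures. Bounce-count ground truth is
    drawn from a single simulated pool shared across runs (counts play no
    role in classification).
    """
    models = models or _default_models()
    noise = noise or ReportNoise()
    rng = np.random.default_rng(seed)
    pool = observers.make_count_pool(n_traces=6, seed=rng)
    catalog = catalog_by_id(experiment)
    variants = list(models)
    confusion = pd.DataFrame(
        0, index=variants, columns=list(observers.MODEL_VARIANTS) + ["undetermined"]
    )
    for variant in variants:
        for _ in range(n_runs_per_variant):
            run_seed = int(rng.integers(2**31 - 1))
            cohort = observers.generate_cohort(
                experiment, models[variant], noise,
                n_per_condition=n_per_condition, seed=run_seed,
                exclusion_probs=observers.CLEAN_COVARIATES, count_pool=pool,
            )
            sig = compute_signature(
                cohort, catalog, seed=int(rng.integers(2**31 - 1))
            )
            confusion.loc[variant, classify_model(sig, thresholds)] += 1
    accuracy = {
        v: float(confusion.loc[v, v]) / n_runs_per_variant for v in variants
    }
    return RecoveryResult(confusion, accuracy, n_runs_per_variant, n_per_condition, seed)


def hazard_recovery_study(
    hazard_true: float = 0.3,
    n_per_condition: int = 125,
    n_runs: int = 200,
    seed: int = 0,
    experiment: str = "E2",
    noise: ReportNoise | None = None,
) -> dict:
    """Repeatedly generate constant-hazard cohorts and refit lambda.

    Returns relative bias, RMSE and the per-run estimates. The default
    experiment has six conditions (three exposures x two onset types), so
    ``n_per_condition=125`` gives 250 subjects per exposure duration.
    """
    noise = noise or ReportNoise()
    model = NoticingModel("constant_hazard", hazard_per_s=hazard_true)
    rng = np.random.default_rng(seed)
    pool = observers.make_count_pool(n_traces=6, seed=rng)
    estimates = np.empty(n_runs)
    for i in range(n_runs):
        cohort = observers.generate_cohort(
            experiment, model, noise,
            n_per_condition=n_per_condition, seed=int(rng.integers(2**31 - 1)),
            exclusion_probs=observers.CLEAN_COVARIATES, count_pool=pool,
        )
        estimates[i] = recover_hazard(cohort).hazard_per_s
    bias = float(estimates.mean() - hazard_true)
    return {
        "hazard_true": hazard_true,
        "mean_estimate": float(estimates.mean()),
        "bias": bias,
        "relative_bias": bias / hazard_true,
        "rmse": float(np.sqrt(np.mean((estimates - hazard_true) ** 2))),
        "estimates": estimates,
        "n_runs": n_runs,
        "n_per_condition": n_per_condition,
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _estimate_to_dict(est) -> dict:
    return {k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in est.__dict__.items()}


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """simulate -> synthesise -> screen -> analyse -> evaluate.

    ``config`` keys: ``experiment`` (E1/E2/E3), ``model`` (dict with
    ``variant`` and model parameters), optional ``noise`` and
    ``exclusions`` parameter dicts, ``n_per_condition``, ``seed``,
    ``n_boot``. Returns a results dict including a manifest with the
    seeds used, the package version and a content hash; artifacts are
    written under ``out_dir`` when given. Any stage failure raises with a
    stage tag.
    """
    from . import __version__

    stage = "config"
    try:
        experiment = config["experiment"]
        seed = int(config.get("seed", 0))
        n_per_condition = int(config.get("n_per_condition", 100))
        n_boot = int(config.get("n_boot", 10_000))
        model_cfg = dict(config.get("model", {"variant": "onset_window"}))
        model = NoticingModel(**model_cfg)
        noise = ReportNoise(**config.get("noise", {}))
        excl = ExclusionProbs(**config.get("exclusions", {}))
        rng = np.random.default_rng(seed)

        stage = "simulate"
        catalog = catalog_by_id(experiment)
        pool = observers.make_count_pool(n_traces=6, seed=rng)

        stage = "synthesize"
        cohort = observers.generate_cohort(
            experiment, model, noise, n_per_condition=n_per_condition,
            seed=int(rng.integers(2**31 - 1)), exclusion_probs=excl,
            count_pool=pool,
        )

        stage = "screen"
        retained, report = screening.apply_exclusions(cohort, experiment)

        stage = "analyze"
        retained = add_noticer_column(retained)
        rates = {}
        for cid, sub in retained[retained["onset_type"] != "none"].groupby("condition_id"):
            rates[cid] = _estimate_to_dict(
                analysis.rate_with_ci(
                    sub["noticer"].to_numpy(), n_boot=n_boot,
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
        loc = analysis.location_analyses(retained, catalog)
        results: dict = {
            "experiment": experiment,
            "exclusions": json.loads(report.to_json()),
            "noticing_rates_by_condition": rates,
            "onset_side": loc.onset_side.to_dict(orient="records"),
        }
        if experiment == "E3":
            noticers = retained[retained["noticer"]]
            non = retained[~retained["noticer"]]
            if len(noticers):
                cs = analysis.circular_error_summary(
                    noticers["hue_report_deg"], noticers["true_hue_deg"]
                )
                results["colour_error_noticers"] = cs.__dict__
            if len(non):
                cs = analysis.circular_error_summary(
                    non["hue_report_deg"], non["true_hue_deg"]
                )
                results["colour_error_non_noticers"] = cs.__dict__
            null = analysis.colour_chance_null(seed=int(rng.integers(2**31 - 1)))
            results["colour_chance_null"] = null.__dict__

        stage = "evaluate"
        exposures = retained.loc[
            retained["onset_type"] != "none", "exposure_label_s"
        ].nunique()
        if exposures >= 2:
            sig = compute_signature(
                retained, catalog, n_boot=min(n_boot, 2000),
                seed=int(rng.integers(2**31 - 1)),
            )
            results["signature"] = {
                "rate_by_exposure": {
                    str(k): _estimate_to_dict(v) for k, v in sig.rate_by_exposure.items()
                },
                "rate_slope": sig.rate_slope,
                "slope_ci": list(sig.slope_ci),
                "loc_onset_affinity": sig.loc_onset_affinity,
                "loc_fixation_affinity": sig.loc_fixation_affinity,
                "n_noticers": sig.n_noticers,
            }
            results["classified_model"] = classify_model(sig)

        stage = "manifest"
        payload = json.dumps(results, sort_keys=True, default=str)
        results["manifest"] = {
            "seed": seed,
            "version": __version__,
            "config": config,
            "results_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        }

        if out_dir is not None:
            stage = "export"
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            observers.cohort_to_csv(
                cohort, out / "cohort.csv", out / "cohort_diagnostics.csv"
            )
            retained.drop(columns=["t_notice_s"]).to_csv(
                out / "retained.csv", index=False
            )
            report.to_frame().to_csv(out / "exclusions.csv", index=False)
            loc.distance_table.to_csv(out / "distance_table.csv", index=False)
            (out / "results.json").write_text(
                json.dumps(results, indent=2, default=str)
            )
        return results
    except Exception as exc:  # noqa: BLE001 - re-tag with the failing stage
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
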