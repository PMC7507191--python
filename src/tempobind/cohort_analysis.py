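"""Group-level analysis: pooled fits, model comparisons, correlations.

This is the cohort stage of the pipeline: pool the three conflict
conditions into a single bimodal threshold estimate per subject, compare
observed bimodal thresholds and normalized PSE shifts with the per-subject
optimal-integration predictions (paired t tests), correlate audio
performance with age and reading times, and compare correlations between
groups with a Fisher r-to-z test.  The packaged clinical table (32
dyslexic children: gender, age, education, Raven IQ, reading decode and
comprehension times) ships as a CSV fixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cue_combination import (
    MLEPrediction,
    normalize_pse,
    predict_from_unisensory,
    predictions_to_frame,
)
from .observer_models import (
    CohortSpec,
    TrialRecord,
    records_to_frame,
    sample_cohort,
)
from .psychometric_fit import (
    NonIdentifiableError,
    PsychometricEstimate,
    fit_with_bootstrap,
)
from .quest_adaptive import QuestConfig, run_session
from .stimulus_design import Condition, SessionConfig


class DegenerateVarianceError(ValueError):
    """Paired differences have zero variance; the t statistic is undefined."""


class UndefinedCorrelationError(ValueError):
    """A constant input vector makes the correlation undefined."""


class SubjectMismatchError(KeyError):
    """Subject IDs do not line up across the joined tables."""


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the clinical table; missing scores are None, never 0."""

    code: str
    gender: int
    age_months: float
    education_years: float
    raven_iq: Optional[float]
    decode_time_s: Optional[float]
    comprehension_time_s: Optional[float]


@dataclass(frozen=True)
class PairedComparison:
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float
    cohen_d: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    r_squared: float
    pearson_p: float
    spearman_rho: float
    rho_ci_low: float
    rho_ci_high: float
    p_two_sided: float
    n: int


def load_table1(path=None) -> list[SubjectRecord]:
    """Load the packaged clinical table (or a compatible CSV at ``path``).

    Returns 32 records; reading scores are missing for six subjects and
    Raven IQ for one ("NA" in the fixture).
    """
    if path is None:
        path = resources.files("tempobind.data") / "table1.csv"
    try:
        frame = pd.read_csv(path, na_values=["NA"])
    except Exception as exc:  # pragma: no cover - malformed external file
        raise ValueError(f"could not parse clinical table at {path}: {exc}") from exc

    records = []
    for i, row in frame.iterrows():
        try:
            records.append(
                SubjectRecord(
                    code=str(row["code"]),
                    gender=int(row["gender"]),
                    age_months=float(row["age_months"]),
                    education_years=float(row["education_years"]),
                    raven_iq=None if pd.isna(row["raven_iq"]) else float(row["raven_iq"]),
                    decode_time_s=None
                    if pd.isna(row["decode_time_s"])
                    else float(row["decode_time_s"]),
                    comprehension_time_s=None
                    if pd.isna(row["comprehension_time_s"])
                    else float(row["comprehension_time_s"]),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"malformed clinical table row {i}: {exc}") from exc
    return records


def table1_frame(path=None) -> pd.DataFrame:
    """The clinical table as a DataFrame (NaN for missing values)."""
    return pd.DataFrame([asdict(r) for r in load_table1(path)])


def pooled_bimodal_fit(
    trials: Sequence[TrialRecord],
    lapse: float = 0.02,
    rng: Optional[np.random.Generator] = None,
    n_boot: int = 100,
) -> PsychometricEstimate:
    """Single fit of all bimodal trials merged across conflict levels.

    The conflict does not measurably affect the threshold, so the three
    conflict conditions are pooled by trial concatenation before one fit;
    only the threshold readout of the pooled fit is interpreted.
    """
    bimodal = [t for t in trials if t.condition.is_bimodal]
    deltas = {t.delta for t in bimodal}
    if not bimodal:
        raise ValueError("no bimodal trials to pool")
    return fit_with_bootstrap(
        bimodal, lapse=lapse, n_boot=n_boot, rng=rng, condition="AV_pooled"
    )


def compare_observed_predicted(
    observed: Sequence[float], predicted: Sequence[float]
) -> PairedComparison:
    """Two-sided paired t test of observed vs predicted values.

    Cohen's d is the mean difference divided by the SD of the differences.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(
            f"paired vectors must have equal length, got {obs.size} and {pred.size}"
        )
    if obs.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = obs - pred
    sd = float(np.std(diff, ddof=1))
    mean = float(np.mean(diff))
    if sd == 0.0:
        if mean == 0.0:
            return PairedComparison(0.0, 0.0, obs.size - 1, 1.0, 0.0, obs.size)
        raise DegenerateVarianceError(
            "paired differences are constant and nonzero; t is undefined"
        )
    t_stat, p = stats.ttest_rel(obs, pred)
    return PairedComparison(
        mean_difference=mean,
        t_statistic=float(t_stat),
        df=obs.size - 1,
        p_value=float(p),
        cohen_d=mean / sd,
        n=obs.size,
    )


def _rowwise_rank_corr(x_ranked: np.ndarray, y_ranked: np.ndarray) -> np.ndarray:
    """Pearson correlation of pre-ranked rows (vectorized Spearman)."""
    xc = x_ranked - x_ranked.mean(axis=1, keepdims=True)
    yc = y_ranked - y_ranked.mean(axis=1, keepdims=True)
    num = np.sum(xc * yc, axis=1)
    den = np.sqrt(np.sum(xc**2, axis=1) * np.sum(yc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> CorrelationResult:
    """Pearson and Spearman association with resampling inference.

    Missing pairs are dropped listwise.  The Spearman rho 95% CI is a
    case-resampling bootstrap percentile interval; the two-sided p for rho
    comes from a (vectorized, seeded) permutation test.  Pearson keeps its
    analytic t-based p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 5:
        raise ValueError(f"need at least 5 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input vector")
    rng = rng if rng is not None else np.random.default_rng(0)

    r, pearson_p = stats.pearsonr(x, y)
    rho = float(stats.spearmanr(x, y).statistic)

    # permutation p: permute the ranks of y, correlation of ranks row-wise
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    rho_perm = _rowwise_rank_corr(np.broadcast_to(xr, (n_perm, n)), yr[perm_idx])
    p_perm = float((1 + np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12)) / (1 + n_perm))

    # bootstrap percentile CI for rho
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    xb = stats.rankdata(x[boot_idx], axis=1)
    yb = stats.rankdata(y[boot_idx], axis=1)
    rho_boot = _rowwise_rank_corr(xb, yb)
    rho_boot = rho_boot[np.isfinite(rho_boot)]
    ci_low, ci_high = np.percentile(rho_boot, [2.5, 97.5])

    return CorrelationResult(
        pearson_r=float(r),
        r_squared=float(r) ** 2,
        pearson_p=float(pearson_p),
        spearman_rho=rho,
        rho_ci_low=float(ci_low),
        rho_ci_high=float(ci_high),
        p_two_sided=p_perm,
        n=n,
    )


def compare_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher r-to-z test for the difference of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both groups")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# end-to-end pipeline and report


CONFLICT_CONDITIONS = {
    Condition.AV_NEG: -50.0,
    Condition.AV_POS: 50.0,
}


def fit_subject(
    records: Sequence[TrialRecord],
    lapse: float = 0.02,
    n_boot: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, PsychometricEstimate]:
    """Per-condition fits for one subject's trial log, plus the pooled
    bimodal fit under the key ``AV_pooled``."""
    rng = rng if rng is not None else np.random.default_rng(0)
    out: dict[str, PsychometricEstimate] = {}
    for cond in Condition:
        sub = [t for t in records if t.condition is cond]
        if not sub:
            continue
        out[cond.value] = fit_with_bootstrap(
            sub, lapse=lapse, n_boot=n_boot, rng=rng, condition=cond.value
        )
    out["AV_pooled"] = pooled_bimodal_fit(records, lapse=lapse, rng=rng, n_boot=n_boot)
    return out


def run_cohort(
    spec: CohortSpec,
    session_config: Optional[SessionConfig] = None,
    quest_config: Optional[QuestConfig] = None,
    seed: int = 0,
    lapse: float = 0.02,
    n_boot: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate and analyse one cohort end to end.

    Samples observers, runs one adaptive session each, fits every
    condition plus the pooled bimodal set, and computes per-subject
    optimal-integration predictions from the unisensory fits.

    Returns ``(trials, fits, predictions)`` tidy tables.  Subjects whose
    fits are non-identifiable (possible at small trial counts) are dropped.
    """
    session_config = session_config or SessionConfig()
    quest_config = quest_config or QuestConfig()
    rng = np.random.default_rng(seed)
    observers = sample_cohort(spec, rng)

    all_trials, fit_rows, preds = [], [], {}
    for i, observer in enumerate(observers):
        subject_id = f"{spec.group}-{i:02d}"
        records = run_session(
            observer, session_config, quest_config, rng, subject_id=subject_id
        )
        all_trials.extend(records)
        try:
            fits = fit_subject(records, lapse=lapse, n_boot=n_boot, rng=rng)
        except NonIdentifiableError:
            continue
        pred = predict_from_unisensory(
            sigma_v=fits[Condition.V.value].sigma,
            sigma_a=fits[Condition.A.value].sigma,
        )
        preds[subject_id] = pred
        for key, est in fits.items():
            fit_rows.append(
                {
                    "subject_id": subject_id,
                    "group": spec.group,
                    "condition": key,
                    "pse_ms": est.pse,
                    "sigma_ms": est.sigma,
                    "se_pse_ms": est.se_pse,
                    "se_sigma_ms": est.se_sigma,
                    "n_trials": est.n_trials,
                    "converged": est.converged,
                }
            )

    trials_frame = records_to_frame(all_trials, group=spec.group)
    fits_frame = pd.DataFrame(fit_rows)
    preds_frame = predictions_to_frame(preds)
    preds_frame.insert(1, "group", spec.group)
    return trials_frame, fits_frame, preds_frame


def _condition_summary(fits: pd.DataFrame) -> dict:
    out: dict = {}
    for cond, sub in fits.groupby("condition"):
        out[cond] = {
            "sigma_mean": float(sub["sigma_ms"].mean()),
            "sigma_se": float(sub["sigma_ms"].sem()),
            "pse_mean": float(sub["pse_ms"].mean()),
            "pse_se": float(sub["pse_ms"].sem()),
            "n_subjects": int(sub["subject_id"].nunique()),
        }
    return out


def _normalized_shifts(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-subject conflict PSEs normalized by the no-conflict PSE."""
    wide = fits.pivot(index="subject_id", columns="condition", values="pse_ms")
    rows = []
    for subject_id, row in wide.iterrows():
        rows.append(
            {
                "subject_id": subject_id,
                "shift_obs_neg_ms": normalize_pse(row["AV_neg"], row["AV_zero"]),
                "shift_obs_pos_ms": normalize_pse(row["AV_pos"], row["AV_zero"]),
            }
        )
    return pd.DataFrame(rows)


def group_report(
    fits: pd.DataFrame,
    predictions: pd.DataFrame,
    metadata: Optional[pd.DataFrame] = None,
    corr_rng: Optional[np.random.Generator] = None,
) -> dict:
    """Structured cohort report.

    Per group: condition means +/- SEs, paired observed-vs-predicted tests
    (pooled bimodal threshold vs predicted sigma_VA; normalized conflict
    PSE shifts vs predicted shifts) and, when metadata with matching
    subject IDs is supplied, correlations of audio threshold/PSE with age
    and reading times.  Fully reproducible under fixed seeds.
    """
    fit_ids = set(fits["subject_id"])
    pred_ids = set(predictions["subject_id"])
    if fit_ids != pred_ids:
        offenders = sorted(fit_ids.symmetric_difference(pred_ids))
        raise SubjectMismatchError(
            f"subject IDs differ between fits and predictions: {offenders}"
        )

    report: dict = {"groups": {}, "tests": {}, "correlations": {}}
    for group, gfits in fits.groupby("group"):
        gpred = predictions[predictions["group"] == group]
        report["groups"][group] = _condition_summary(gfits)

        merged = (
            gfits[gfits["condition"] == "AV_pooled"][["subject_id", "sigma_ms"]]
            .merge(gpred, on="subject_id")
            .merge(_normalized_shifts(gfits), on="subject_id")
        )
        tests = {
            "pooled_sigma_vs_prediction": asdict(
                compare_observed_predicted(
                    merged["sigma_ms"], merged["sigma_VA_pred_ms"]
                )
            ),
            "shift_neg_vs_prediction": asdict(
                compare_observed_predicted(
                    merged["shift_obs_neg_ms"],
                    merged["shift_pred_neg_ms"] - merged["shift_pred_zero_ms"],
                )
            ),
            "shift_pos_vs_prediction": asdict(
                compare_observed_predicted(
                    merged["shift_obs_pos_ms"],
                    merged["shift_pred_pos_ms"] - merged["shift_pred_zero_ms"],
                )
            ),
        }
        report["tests"][group] = tests

        if metadata is not None:
            meta = metadata.copy()
            if "subject_id" not in meta.columns and "code" in meta.columns:
                meta = meta.rename(columns={"code": "subject_id"})
            audio = gfits[gfits["condition"] == "A"][
                ["subject_id", "sigma_ms", "pse_ms"]
            ].merge(meta, on="subject_id", how="inner")
            corrs: dict = {}
            for covariate in ("age_months", "decode_time_s", "comprehension_time_s"):
                if covariate not in audio.columns:
                    continue
                for measure in ("sigma_ms", "pse_ms"):
                    pair = audio[[measure, covariate]].dropna()
                    if len(pair) < 5:
                        continue
                    res = correlate(
                        pair[measure],
                        pair[covariate],
                        rng=corr_rng or np.random.default_rng(0),
                    )
                    corrs[f"audio_{measure}_vs_{covariate}"] = asdict(res)
            if corrs:
                report["correlations"][group] = corrs
    return report


def report_to_json(report: dict, path=None) -> str:
    """Serialize a report dict (keys sorted, numpy scalars coerced)."""

    def default(obj):
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    text = json.dumps(report, indent=2, sort_keys=True, default=default)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
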