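"""Validation designs and accuracy metrics for score prediction.

Two designs: leave-one-out cross-validation (each subject predicted by a
model trained on the remaining n-1, kernel rebuilt per fold) and
cross-dataset validation (train on one cohort, test on an independent one).
The metric panel matches standard practice for this analysis: Pearson r
between predicted and actual scores with its two-sided p, RMS of the errors,
normalized RMS after z-scoring both series by the actual scores' mean and
population SD (so the mean predictor scores exactly 1.0), Spearman rho where
rank analyses are called for, and the relevance-vector ratio.

Prediction error is reported as (actual - predicted) throughout: a positive
error on a higher-is-better instrument means the subject outperforms what
their anatomy predicts (the cognitive-reserve reading).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CONVERSION_CENSOR_DAYS, Cohort
from .features import linear_kernel, build_design, mask_hash
from .rvr import RVR, FitConfig

__all__ = [
    "EvaluationReport",
    "loo_cv",
    "cross_dataset",
    "pearson_r",
    "rms_error",
    "normalized_rms",
    "spearman_rho",
    "error_vs_covariate",
    "conversion_spearman",
]


# --------------------------------------------------------------------------
# metrics


def _check_pair(a, b, min_len=1):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < min_len:
        raise ValueError(f"need at least {min_len} observations, got {a.size}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in inputs")
    return a, b


def pearson_r(pred, actual) -> tuple[float, float]:
    """Pearson correlation with two-sided p (t transform, n-2 df)."""
    pred, actual = _check_pair(pred, actual, min_len=3)
    if np.var(pred) == 0 or np.var(actual) == 0:
        raise ValueError("zero-variance input: Pearson correlation undefined")
    res = stats.pearsonr(pred, actual)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(a, b) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) with two-sided p."""
    a, b = _check_pair(a, b, min_len=3)
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero-variance input: Spearman correlation undefined")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def rms_error(pred, actual) -> float:
    """Root mean square of the prediction errors."""
    pred, actual = _check_pair(pred, actual)
    return float(np.sqrt(np.mean((pred - actual) ** 2)))


def normalized_rms(pred, actual) -> float:
    """RMS error after z-scoring by the actual scores' mean and population SD.

    Both series are mapped through ``z = (v - mean(actual)) / sd_pop(actual)``
    before the RMS, which makes scores comparable across instruments and
    pins the constant mean predictor at exactly 1.0.
    """
    pred, actual = _check_pair(pred, actual)
    sd = float(np.std(actual))  # population (1/n) convention
    if sd == 0:
        raise ValueError("zero-variance actual scores: normalized RMS undefined")
    mean = float(np.mean(actual))
    return rms_error((pred - mean) / sd, (actual - mean) / sd)


# --------------------------------------------------------------------------
# report


@dataclass
class EvaluationReport:
    """Per-subject predictions plus the aggregate metric panel."""

    table: pd.DataFrame  # id, group, actual, predicted, predictive_sd
    design: str  # "loo" | "cross_dataset"
    instrument: str
    pearson_r: float
    pearson_p: float
    rms: float
    normalized_rms: float
    relevance_ratio_mean: float
    relevance_ratio_sd: float | None = None
    spearman_rho: float | None = None
    spearman_p: float | None = None
    config_hash: str = ""

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def actual(self) -> np.ndarray:
        return self.table["actual"].to_numpy()

    @property
    def predicted(self) -> np.ndarray:
        return self.table["predicted"].to_numpy()

    @property
    def errors(self) -> np.ndarray:
        """Prediction error, fixed sign convention: actual - predicted."""
        return self.actual - self.predicted

    def metrics_dict(self) -> dict:
        return {
            "design": self.design,
            "instrument": self.instrument,
            "n": self.n,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "rms": self.rms,
            "normalized_rms": self.normalized_rms,
            "relevance_ratio_mean": self.relevance_ratio_mean,
            "relevance_ratio_sd": self.relevance_ratio_sd,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "config_hash": self.config_hash,
        }

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "predictions.csv", index=False)
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(self.metrics_dict(), fh, indent=2)

    def scatter_plot(self, path) -> None:
        """Predicted-vs-actual scatter, one marker style per group."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for group, sub in self.table.groupby("group"):
            ax.scatter(sub["actual"], sub["predicted"], s=18, label=str(group))
        lims = [
            min(self.actual.min(), self.predicted.min()),
            max(self.actual.max(), self.predicted.max()),
        ]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel(f"actual {self.instrument}")
        ax.set_ylabel(f"predicted {self.instrument}")
        ax.set_title(f"{self.design}: r = {self.pearson_r:.2f}")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _config_hash(cfg: FitConfig, extra: str = "") -> str:
    h = hashlib.sha1()
    h.update(repr(cfg).encode())
    h.update(extra.encode())
    return h.hexdigest()[:12]


def _assemble(
    cohort: Cohort,
    predicted: np.ndarray,
    predictive_sd: np.ndarray,
    design: str,
    rel_ratios: list[float],
    cfg: FitConfig,
) -> EvaluationReport:
    actual = cohort.scores
    table = pd.DataFrame(
        {
            "id": cohort.subject_ids,
            "group": [s.group for s in cohort.subjects],
            "actual": actual,
            "predicted": predicted,
            "predictive_sd": predictive_sd,
        }
    )
    # degenerate cohorts (constant actual or predicted scores) still yield a
    # report; the undefined correlation-based metrics are NaN
    try:
        r, p = pearson_r(predicted, actual)
    except ValueError:
        r, p = float("nan"), float("nan")
    try:
        nrms = normalized_rms(predicted, actual)
    except ValueError:
        nrms = float("nan")
    ratios = np.asarray(rel_ratios, dtype=float)
    return EvaluationReport(
        table=table,
        design=design,
        instrument=cohort.instrument.name,
        pearson_r=r,
        pearson_p=p,
        rms=rms_error(predicted, actual),
        normalized_rms=nrms,
        relevance_ratio_mean=float(ratios.mean()),
        relevance_ratio_sd=float(ratios.std(ddof=1)) if ratios.size > 1 else None,
        config_hash=_config_hash(cfg, design),
    )


# --------------------------------------------------------------------------
# designs


def loo_cv(
    cohort: Cohort,
    fit_cfg: FitConfig | None = None,
    fwhm_mm: float = 0.0,
) -> EvaluationReport:
    """Leave-one-out cross-validation over the cohort.

    For each subject a model is trained on the other n-1 subjects — the
    kernel is rebuilt on the reduced feature set, so its conditioning scale
    is also fold-specific — and the held-out subject's score is predicted
    from their image. Preprocessing (smoothing, masking, vectorisation) is
    unsupervised and therefore computed once, outside the folds.
    """
    cfg = fit_cfg or FitConfig()
    n = cohort.n
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    X = cohort.to_features(fwhm_mm=fwhm_mm)
    scores = cohort.scores
    predicted = np.empty(n)
    predictive_sd = np.empty(n)
    ratios = []
    for i in range(n):
        try:
            train_rows = [j for j in range(n) if j != i]
            X_train = X.subset(train_rows)
            X_test = X.subset([i])
            model = RVR.from_features(scores[train_rows], X_train)
            res = model.fit(cfg)
            K_test = linear_kernel(X_test, X_train, condition=False)
            K_test.K /= model.design.scale
            K_test.scale = model.design.scale
            mean, var = res.predict(K_test, return_var=True)
            predicted[i] = mean[0]
            predictive_sd[i] = np.sqrt(var[0])
            ratios.append(res.relevance_ratio)
        except Exception as exc:
            raise RuntimeError(
                f"LOO fold for subject {cohort.subject_ids[i]} (index {i}) failed"
            ) from exc
    return _assemble(cohort, predicted, predictive_sd, "loo", ratios, cfg)


def cross_dataset(
    train_cohort: Cohort,
    test_cohort: Cohort,
    fit_cfg: FitConfig | None = None,
    fwhm_mm: float = 0.0,
) -> EvaluationReport:
    """Train on one cohort, predict an independent one on the same grid."""
    cfg = fit_cfg or FitConfig()
    if test_cohort.n == 0:
        raise ValueError("empty test cohort")
    if train_cohort.instrument.name != test_cohort.instrument.name:
        raise ValueError(
            f"instrument mismatch: train {train_cohort.instrument.name!r} "
            f"vs test {test_cohort.instrument.name!r}"
        )
    if mask_hash(train_cohort.mask) != mask_hash(test_cohort.mask):
        raise ValueError("cohorts use different grids/masks")
    X_train = train_cohort.to_features(fwhm_mm=fwhm_mm)
    X_test = test_cohort.to_features(fwhm_mm=fwhm_mm)
    model = RVR.from_features(train_cohort.scores, X_train)
    res = model.fit(cfg)
    mean, var = res.predict_features(X_test)
    return _assemble(
        test_cohort,
        mean,
        np.sqrt(var),
        "cross_dataset",
        [res.relevance_ratio],
        cfg,
    )


# --------------------------------------------------------------------------
# covariate analyses


def error_vs_covariate(report: EvaluationReport, covariate) -> tuple[float, float]:
    """Pearson correlation of prediction error (actual - predicted) with a covariate."""
    covariate = np.asarray(covariate, dtype=float).ravel()
    if covariate.size != report.n:
        raise ValueError("covariate length != number of report subjects")
    if np.var(covariate) == 0:
        raise ValueError("constant covariate: correlation undefined")
    return pearson_r(report.errors, covariate)


def conversion_spearman(report: EvaluationReport, days) -> dict:
    """Spearman rho of actual and predicted scores with days to conversion.

    ``days`` is aligned to the report's subjects; non-converters carry the
    censoring value (1500 days). Entries may be NaN for non-MCI subjects and
    are dropped pairwise.
    """
    days = np.asarray(days, dtype=float).ravel()
    if days.size != report.n:
        raise ValueError("days length != number of report subjects")
    keep = np.isfinite(days)
    if keep.sum() < 3:
        raise ValueError("need at least 3 subjects with days-to-conversion")
    d = np.minimum(days[keep], CONVERSION_CENSOR_DAYS)
    rho_a, p_a = spearman_rho(report.actual[keep], d)
    rho_p, p_p = spearman_rho(report.predicted[keep], d)
    return {
        "actual_rho": rho_a,
        "actual_p": p_a,
        "predicted_rho": rho_p,
        "predicted_p": p_p,
        "n": int(keep.sum()),
    }
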