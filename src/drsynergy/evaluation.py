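"""Stratified repeated cross-validation and the regression metric suite.

Protocol: the continuous synergy target is quantile-binned, each bin is dealt
round-robin into k folds (stratification), the whole k-fold split is repeated
``n_repeats`` times with seeds ``base_seed + r``, and per-metric aggregates
are reported as mean, SD and a 95% t-interval over the repeat-level means.
Feature standardization is refit on each training split so no test-row
statistic leaks into training. Models are compared with a two-sided paired
t-test over repeat-level metric means.

Metrics: MSE, RMSE, R^2, Pearson, Spearman, and the AUC obtained by using
predictions as ranking scores for the binary label 1[y_true >= threshold]
(threshold 10 score units by default).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import synergy_models
from .errors import ProtocolError, ValidationError
from .feature_assembly import PairDataset
from .synergy_models import FittedModel, ModelSpec

log = logging.getLogger(__name__)

METRICS = ("mse", "rmse", "r2", "pearson", "spearman", "auc")

DEFAULT_SYNERGY_THRESHOLD = 10.0


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Stratified assignment of rows to k folds."""

    k: int
    fold_index: np.ndarray = field(repr=False)  # per-row fold id in [0, k)
    bin_index: np.ndarray = field(repr=False)  # per-row stratum id after merging
    seed: int = 0

    def test_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def make_fold_plan(y, k: int = 5, n_bins: int = 10, seed: int = 0) -> FoldPlan:
    """Quantile-bin y, then deal each bin round-robin into k folds.

    Bins with fewer than k members are merged into a neighboring bin, so every
    stratum contributes to every fold where possible; within each stratum fold
    sizes differ by at most one.
    """
    if k < 2:
        raise ValidationError(f"fold count k must be >= 2, got {k}")
    if n_bins < 1:
        raise ValidationError(f"n_bins must be >= 1, got {n_bins}")
    y = np.asarray(y, dtype=float)
    if len(y) < k:
        raise ValidationError(f"need at least k={k} rows, got {len(y)}")

    bins = pd.qcut(y, min(n_bins, len(y)), labels=False, duplicates="drop")
    bins = np.asarray(bins, dtype=int)
    # merge small bins (< k members) into their left neighbor (right for bin 0)
    while True:
        labels, counts = np.unique(bins, return_counts=True)
        small = labels[counts < k]
        if len(small) == 0 or len(labels) == 1:
            break
        b = small[0]
        pos = int(np.flatnonzero(labels == b)[0])
        target = labels[pos - 1] if pos > 0 else labels[pos + 1]
        bins[bins == b] = target
    # compact labels to 0..n_strata-1
    _, bins = np.unique(bins, return_inverse=True)

    rng = np.random.default_rng(seed)
    fold_index = np.empty(len(y), dtype=int)
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        rng.shuffle(idx)
        offset = int(rng.integers(k))
        fold_index[idx] = (offset + np.arange(len(idx))) % k
    return FoldPlan(k=k, fold_index=fold_index, bin_index=bins, seed=seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(
    y_true, y_pred, synergy_threshold: float = DEFAULT_SYNERGY_THRESHOLD
) -> dict[str, float]:
    """MSE, RMSE, R^2, Pearson, Spearman and threshold-AUC for one prediction vector.

    AUC treats predictions as ranking scores for the label
    1[y_true >= synergy_threshold]; with a one-class label it is undefined and
    reported as NaN. Correlations on a constant vector are likewise NaN.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValidationError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 2:
        raise ValidationError("need at least 2 observations")
    if not (np.all(np.isfinite(y_true)) and np.all(np.isfinite(y_pred))):
        raise ValidationError("non-finite entries in y_true or y_pred")

    residual = y_true - y_pred
    mse = float(np.mean(residual**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residual**2)) / ss_tot if ss_tot > 0 else float("nan")
    if y_true.std() == 0 or y_pred.std() == 0:
        pearson = spearman = float("nan")
    else:
        with warnings.catch_warnings():
            # scipy also flags *near*-constant inputs; NaN propagation is intended
            warnings.simplefilter("ignore")
            pearson = float(stats.pearsonr(y_true, y_pred).statistic)
            spearman = float(stats.spearmanr(y_true, y_pred).statistic)
    labels = (y_true >= synergy_threshold).astype(int)
    auc = float(roc_auc_score(labels, y_pred)) if 0 < labels.sum() < labels.size else float("nan")
    return {
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "r2": r2,
        "pearson": pearson,
        "spearman": spearman,
        "auc": auc,
    }


# ---------------------------------------------------------------------------
# per-split fitting (standardization refit on each training split)
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    """A model fitted on one training split, with that split's feature scaling."""

    fitted: FittedModel
    mu: np.ndarray | None = None
    sd: np.ndarray | None = None

    def predict(self, dataset: PairDataset, idx) -> np.ndarray:
        part = dataset.subset(idx)
        if self.mu is not None:
            X = (part.X - self.mu) / self.sd
            part = PairDataset(keys=part.keys, X=X, y=part.y, spec=part.spec,
                               provenance=part.provenance)
        return synergy_models.predict(self.fitted, part)


def fit_fold(
    dataset: PairDataset, train_idx, spec: ModelSpec, standardize: bool = True
) -> FoldModel:
    """Fit one model on the given training rows only (scaling included)."""
    train = dataset.subset(train_idx)
    mu = sd = None
    if standardize:
        mu = train.X.mean(axis=0)
        sd = train.X.std(axis=0, ddof=0).replace(0.0, 1.0)
        train = PairDataset(keys=train.keys, X=(train.X - mu) / sd, y=train.y,
                            spec=train.spec, provenance=train.provenance)
    fitted = synergy_models.train(train, spec)
    return FoldModel(fitted=fitted, mu=mu, sd=sd)


# ---------------------------------------------------------------------------
# the repeated-CV protocol
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-(repeat, fold, model, metric) records plus aggregates over repeats."""

    records: pd.DataFrame = field(repr=False)  # repeat, fold, model, regime, metric, value
    repeat_means: pd.DataFrame = field(repr=False)  # index (model, metric, repeat) -> value
    aggregates: pd.DataFrame = field(repr=False)
    k: int = 5
    n_repeats: int = 10
    base_seed: int = 0
    synergy_threshold: float = DEFAULT_SYNERGY_THRESHOLD

    def mean(self, model: str, metric: str) -> float:
        row = self.aggregates.set_index(["model", "metric"]).loc[(model, metric)]
        return float(row["mean"])


def _aggregate(records: pd.DataFrame, n_repeats: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    repeat_means = (
        records.groupby(["model", "metric", "repeat"])["value"].mean().rename("value")
    )
    rows = []
    for (model, metric), series in repeat_means.groupby(level=["model", "metric"]):
        vals = series.to_numpy()
        valid = vals[~np.isnan(vals)]
        mean = float(valid.mean()) if valid.size else float("nan")
        if n_repeats > 1 and valid.size > 1:
            sd = float(valid.std(ddof=1))
            half = stats.t.ppf(0.975, valid.size - 1) * sd / np.sqrt(valid.size)
            ci_low, ci_high, degenerate = mean - half, mean + half, False
        else:
            sd, ci_low, ci_high, degenerate = float("nan"), mean, mean, True
        rows.append(
            {"model": model, "metric": metric, "mean": mean, "sd": sd,
             "ci_low": ci_low, "ci_high": ci_high, "ci_degenerate": degenerate}
        )
    return repeat_means.to_frame().reset_index(), pd.DataFrame(rows)


def run_repeated_cv(
    dataset: PairDataset,
    model_specs: Mapping[str, ModelSpec | np.ndarray],
    k: int = 5,
    n_repeats: int = 10,
    base_seed: int = 0,
    n_bins: int = 10,
    standardize: bool = True,
    synergy_threshold: float = DEFAULT_SYNERGY_THRESHOLD,
) -> EvalReport:
    """Stratified k-fold CV repeated with seeds base_seed..base_seed+n_repeats-1.

    ``model_specs`` maps a model name to either a :class:`ModelSpec` (trained
    per split) or a precomputed score vector aligned to the dataset rows (the
    external-model hook: such scores are only ever *evaluated* on test folds).
    """
    if not model_specs:
        raise ValidationError("need at least one model spec")
    y = dataset.y.to_numpy(dtype=float)
    external: dict[str, np.ndarray] = {}
    for name, spec in model_specs.items():
        if not isinstance(spec, ModelSpec):
            arr = np.asarray(spec, dtype=float)
            if arr.shape != y.shape:
                raise ValidationError(
                    f"external score table {name!r} has shape {arr.shape}, expected {y.shape}"
                )
            external[name] = arr

    regime = dataset.spec.regime
    records = []
    for r in range(n_repeats):
        plan = make_fold_plan(y, k=k, n_bins=n_bins, seed=base_seed + r)
        for name, spec in model_specs.items():
            for f in range(k):
                test_idx = plan.test_rows(f)
                if name in external:
                    preds = external[name][test_idx]
                else:
                    fold_model = fit_fold(dataset, plan.train_rows(f), spec, standardize)
                    preds = fold_model.predict(dataset, test_idx)
                metric_values = compute_metrics(y[test_idx], preds, synergy_threshold)
                if np.isnan(metric_values["auc"]):
                    log.info("repeat %d fold %d model %s: one-class labels, AUC missing", r, f, name)
                records.extend(
                    {"repeat": r, "fold": f, "model": name, "regime": regime,
                     "metric": m, "value": v}
                    for m, v in metric_values.items()
                )
    records = pd.DataFrame(records)
    repeat_means, aggregates = _aggregate(records, n_repeats)
    return EvalReport(
        records=records, repeat_means=repeat_means, aggregates=aggregates,
        k=k, n_repeats=n_repeats, base_seed=base_seed, synergy_threshold=synergy_threshold,
    )


@dataclass
class ComparisonResult:
    p_value: float
    t_stat: float
    n_repeats: int
    degenerate: bool = False


def _repeat_series(report: EvalReport, model: str, metric: str) -> np.ndarray:
    sub = report.repeat_means
    sel = sub.loc[(sub["model"] == model) & (sub["metric"] == metric)]
    if sel.empty:
        raise ProtocolError(f"model {model!r} / metric {metric!r} not present in report")
    return sel.sort_values("repeat")["value"].to_numpy()


def compare_models(
    report: EvalReport,
    model_a: str,
    model_b: str,
    metric: str = "mse",
    report_b: EvalReport | None = None,
) -> ComparisonResult:
    """Two-sided paired t-test over the repeat-level metric means of two models.

    Both models must have been evaluated under identical fold plans; passing a
    second report is allowed only if its protocol (k, repeats, base seed)
    matches, since fold plans are a pure function of (y, k, n_bins, seed).
    """
    other = report_b or report
    if (other.k, other.n_repeats, other.base_seed) != (report.k, report.n_repeats, report.base_seed):
        raise ProtocolError(
            "mismatched fold plans: reports differ in (k, n_repeats, base_seed)"
        )
    a = _repeat_series(report, model_a, metric)
    b = _repeat_series(other, model_b, metric)
    diffs = a - b
    if np.allclose(diffs, 0.0):
        return ComparisonResult(p_value=1.0, t_stat=0.0, n_repeats=len(diffs), degenerate=True)
    t_stat, p_value = stats.ttest_rel(a, b)
    return ComparisonResult(p_value=float(p_value), t_stat=float(t_stat), n_repeats=len(diffs))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_report(report: EvalReport, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Long-format records as TSV; aggregates + protocol echo as JSON."""
    report.records.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "protocol": {
                "k": report.k,
                "n_repeats": report.n_repeats,
                "base_seed": report.base_seed,
                "synergy_threshold": report.synergy_threshold,
            },
            "aggregates": report.aggregates.to_dict(orient="records"),
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
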