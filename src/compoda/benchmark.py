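"""Benchmarking harness: classification metrics, comparator, power model.

Each synthetic dataset carries a ground-truth mask of affected cell types.
A method produces a per-cell-type decision (credible or not) and a score
(inclusion probability for the Bayesian model, 1 - p for the t-test
comparator); comparing decisions against truth gives a confusion matrix per
dataset and MCC / TPR / FDR summaries.  ROC and precision-recall curves are
pooled over all (dataset, cell type) pairs.

The power model regresses true-positive rate on log total sample size,
log-fold change and their interactions with log absolute count change
through a quasibinomial GLM with log link; inverting the linear predictor
gives the sample size required for a target power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from sklearn.metrics import average_precision_score, matthews_corrcoef, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .datacore import CompositionalDataset, apply_zero_pseudocount
from .hmc import HMCConfig, fit
from .model import ModelConfig
from .posthoc import fdr_select, inclusion_probabilities
from .simulate import SimulationConfig, generate_dataset

__all__ = [
    "BenchmarkRecord",
    "PowerModel",
    "classification_metrics",
    "roc_pr",
    "alr_ttest",
    "dirmult_decisions",
    "run_grid",
    "aggregate_records",
    "pooled_roc_pr",
    "fit_power_model",
    "required_sample_size",
]


@dataclass
class BenchmarkRecord:
    """Per-dataset outcome: truth, decisions, scores and summary metrics."""

    config: SimulationConfig
    truth: np.ndarray
    decision: np.ndarray
    score: np.ndarray
    mcc: float = 0.0
    tpr: float = 0.0
    fdr: float = 0.0
    failed: bool = False
    note: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.truth = np.asarray(self.truth, dtype=bool)
        self.decision = np.asarray(self.decision, dtype=bool)
        if not self.failed:
            self.mcc, self.tpr, self.fdr = classification_metrics(self.truth, self.decision)


@dataclass
class PowerModel:
    """Fitted quasibinomial TPR model.

    Linear predictor (log link):
        intercept + b_ss * x_ss + b_fc * x_fc + b_fc_cc * x_fc * x_cc
                  + b_ss_cc * x_ss * x_cc
    with x_ss = log total sample size, x_fc = log2 fold change of the
    affected cell type, x_cc = log absolute count change.
    """

    intercept: float
    b_ss: float
    b_fc: float
    b_fc_cc: float
    b_ss_cc: float
    link: str = "log"
    fdr_level: float = 0.05
    result: object | None = None

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.intercept, self.b_ss, self.b_fc, self.b_fc_cc, self.b_ss_cc])

    def predict_tpr(self, x_ss, x_fc, x_cc):
        lin = (self.intercept + self.b_ss * np.asarray(x_ss)
               + self.b_fc * np.asarray(x_fc)
               + self.b_fc_cc * np.asarray(x_fc) * np.asarray(x_cc)
               + self.b_ss_cc * np.asarray(x_ss) * np.asarray(x_cc))
        return np.exp(lin)


def classification_metrics(truth, decision):
    """(MCC, TPR, FDR) from boolean truth/decision vectors.

    Degenerate conventions: MCC = 0 when any confusion-matrix marginal is
    zero; TPR = 0 without positives; FDR = 0 when nothing is called.
    """
    truth = np.asarray(truth, dtype=bool)
    decision = np.asarray(decision, dtype=bool)
    if truth.shape != decision.shape:
        raise ValueError("truth and decision must have equal length")
    tp = int(np.sum(truth & decision))
    fp = int(np.sum(~truth & decision))
    fn = int(np.sum(truth & ~decision))
    tn = int(np.sum(~truth & ~decision))
    denom_parts = [tp + fp, tp + fn, tn + fp, tn + fn]
    if any(d == 0 for d in denom_parts):
        mcc = 0.0
    else:
        mcc = float(matthews_corrcoef(truth, decision))
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    return mcc, float(tpr), float(fdr)


def roc_pr(scores, truth):
    """(AUC, average precision) pooled over items.

    AUC by trapezoidal integration over all score thresholds, average
    precision as the step-wise (non-interpolated) weighted precision sum.
    Requires at least one positive and one negative item.
    """
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if truth.all() or not truth.any():
        raise ValueError("need at least one positive and one negative item")
    return float(roc_auc_score(truth, scores)), float(average_precision_score(truth, scores))


def alr_ttest(ds: CompositionalDataset, reference: int, alpha: float = 0.05):
    """Additive log-ratio transform + two-sample t-test comparator.

    Counts are pseudocounted, each non-reference cell type is transformed to
    log(count_k / count_ref), and a two-sample t-test compares groups defined
    by the (single, binary) covariate.  P-values are Benjamini-Hochberg
    corrected at level ``alpha``.  Returns (decisions, scores) over all K
    cell types; the reference coordinate is never called and scores 0.
    """
    if ds.n_covariates != 1:
        raise ValueError("comparator expects exactly one binary covariate")
    ds = apply_zero_pseudocount(ds)
    group = ds.covariates[:, 0] > 0.5
    k = ds.n_cell_types
    decisions = np.zeros(k, dtype=bool)
    scores = np.zeros(k)
    if group.sum() < 2 or (~group).sum() < 2:
        # a t-test needs >= 2 samples per group; report no discoveries
        return decisions, scores
    logratio = np.log(ds.counts / ds.counts[:, [reference]])
    others = [j for j in range(k) if j != reference]
    pvals = np.empty(len(others))
    for idx, j in enumerate(others):
        a, b = logratio[group, j], logratio[~group, j]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            pvals[idx] = 1.0
        else:
            pvals[idx] = stats.ttest_ind(a, b, equal_var=False).pvalue
    pvals = np.nan_to_num(pvals, nan=1.0)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for idx, j in enumerate(others):
        decisions[j] = reject[idx]
        scores[j] = 1.0 - pvals[idx]
    return decisions, scores


def dirmult_decisions(ds: CompositionalDataset, reference: int, alpha: float = 0.05,
                     num_iterations: int = 20_000, burn_in: int = 5_000,
                     seed: int = 0):
    """Fit the Bayesian model and select credible effects at FDR ``alpha``.

    Returns (decisions, scores) over all K cell types; scores are inclusion
    probabilities.  Decisions come from the same direct posterior-probability
    FDR rule used everywhere else (no second decision path).
    """
    ds = apply_zero_pseudocount(ds)
    model_config = ModelConfig(
        n_cell_types=ds.n_cell_types, n_covariates=ds.n_covariates,
        reference_index=reference,
    )
    hmc_config = HMCConfig(num_iterations=num_iterations, burn_in=burn_in, seed=seed)
    chain = fit(ds, model_config, hmc_config)
    p = inclusion_probabilities(chain)
    sel = fdr_select(p, alpha, reference_index=reference)
    return sel.credible[0], p[0]


def run_grid(configs, method: str = "dirmult", fdr_level: float = 0.05,
             num_iterations: int = 20_000, burn_in: int = 5_000,
             reference: str | int = "last", progress: bool = False):
    """Apply one method to every simulated dataset of a grid.

    ``reference='last'`` pins the last cell type (the convention for the
    synthetic grids, whose last cell type is never affected).  Method
    failures are caught: the record is flagged and excluded from aggregates.
    """
    records = []
    iterator = configs
    if progress:
        from tqdm import tqdm

        iterator = tqdm(configs, desc=f"benchmark[{method}]")
    for config in iterator:
        try:
            ds, truth = generate_dataset(config)
        except ValueError as exc:
            # degenerate grid cell (e.g. effects exhaust the total count)
            records.append(BenchmarkRecord(
                config=config, truth=config.truth_mask,
                decision=np.zeros(config.n_cell_types, dtype=bool),
                score=np.zeros(config.n_cell_types),
                failed=True, note=f"generation: {exc}",
            ))
            continue
        ref = ds.n_cell_types - 1 if reference == "last" else int(reference)
        try:
            if method == "dirmult":
                decision, score = dirmult_decisions(
                    ds, ref, alpha=fdr_level, num_iterations=num_iterations,
                    burn_in=burn_in, seed=config.seed,
                )
            elif method == "alr_ttest":
                decision, score = alr_ttest(ds, ref, alpha=fdr_level)
            else:
                raise ValueError(f"unknown method {method!r}")
            records.append(BenchmarkRecord(config=config, truth=truth,
                                           decision=decision, score=score))
        except Exception as exc:  # noqa: BLE001 - record and move on
            records.append(BenchmarkRecord(
                config=config, truth=truth,
                decision=np.zeros_like(truth), score=np.zeros(len(truth), dtype=float),
                failed=True, note=f"{type(exc).__name__}: {exc}",
            ))
    return records


def records_frame(records) -> pd.DataFrame:
    """Tidy one-row-per-dataset table of configs and metrics."""
    rows = []
    for rec in records:
        c = rec.config
        rows.append({
            "n_cell_types": c.n_cell_types, "n_per_group": c.n_control,
            "total": c.total, "base_count": c.base_count,
            "effect": str(c.effects), "seed": c.seed,
            "mcc": rec.mcc, "tpr": rec.tpr, "fdr": rec.fdr,
            "failed": rec.failed, "note": rec.note,
        })
    return pd.DataFrame(rows)


def aggregate_records(records) -> pd.DataFrame:
    """Mean MCC / TPR / FDR by group size, excluding failed records."""
    frame = records_frame(records)
    frame = frame[~frame["failed"]]
    return (frame.groupby("n_per_group")[["mcc", "tpr", "fdr"]]
            .mean().reset_index())


def pooled_roc_pr(records, min_group_size: int = 2):
    """Pooled (AUC, average precision) over all (dataset, cell type) pairs.

    Only datasets with at least ``min_group_size`` samples per group enter
    the pool (methods without degrees of freedom at n = 1 would contribute
    constant scores).
    """
    scores, truth = [], []
    for rec in records:
        if rec.failed or rec.config.n_control < min_group_size:
            continue
        scores.append(rec.score)
        truth.append(rec.truth)
    if not scores:
        raise ValueError("no eligible records to pool")
    return roc_pr(np.concatenate(scores), np.concatenate(truth))


def fit_power_model(frame: pd.DataFrame, fdr_level: float = 0.05) -> PowerModel:
    """Fit the quasibinomial TPR regression on aggregated benchmark results.

    ``frame`` needs columns ``tpr``, ``x_ss``, ``x_fc``, ``x_cc`` (one row
    per grid cell, TPR averaged over replicates).  The design has exactly the
    five terms of the documented linear predictor.
    """
    required = {"tpr", "x_ss", "x_fc", "x_cc"}
    if not required.issubset(frame.columns):
        raise ValueError(f"frame must contain columns {sorted(required)}")
    if len(frame) < 10 or frame["x_ss"].nunique() < 2:
        raise ValueError("need >= 10 aggregate points spanning multiple sample sizes")
    design = np.column_stack([
        np.ones(len(frame)),
        frame["x_ss"], frame["x_fc"],
        frame["x_fc"] * frame["x_cc"],
        frame["x_ss"] * frame["x_cc"],
    ])
    y = np.clip(frame["tpr"].to_numpy(dtype=float), 1e-10, 1 - 1e-10)
    import warnings

    with warnings.catch_warnings():
        # the log link leaves the binomial mean domain; intended (rates < 1 here)
        warnings.simplefilter("ignore")
        model = sm.GLM(y, design,
                       family=sm.families.Binomial(link=sm.families.links.Log()))
        try:
            result = model.fit(scale="X2")  # quasibinomial: Pearson-chi2 dispersion
        except Exception as exc:
            raise RuntimeError(
                f"power model failed to converge on {len(frame)} points "
                f"(TPR range {y.min():.3f}-{y.max():.3f}): {exc}"
            ) from exc
    params = result.params
    return PowerModel(intercept=float(params[0]), b_ss=float(params[1]),
                      b_fc=float(params[2]), b_fc_cc=float(params[3]),
                      b_ss_cc=float(params[4]), fdr_level=fdr_level, result=result)


def required_sample_size(model: PowerModel, target_power: float,
                         x_fc: float, x_cc: float) -> float:
    """Invert the power model for the log total sample size x_ss.

    Solves linear_predictor(x_ss) = log(target_power) exactly:
        x_ss = -(intercept + b_fc x_fc + b_fc_cc x_fc x_cc - y_tpr)
               / (b_ss + b_ss_cc x_cc)
    so predicting power at the returned x_ss reproduces target_power.
    """
    if not (0 < target_power < 1):
        raise ValueError("target_power must lie strictly between 0 and 1")
    y_tpr = np.log(target_power)  # log link
    denom = model.b_ss + model.b_ss_cc * x_cc
    if denom == 0:
        raise ZeroDivisionError("b_ss + b_ss_cc * x_cc is zero; sample size undefined")
    return float(-(model.intercept + model.b_fc * x_fc
                   + model.b_fc_cc * x_fc * x_cc - y_tpr) / denom)
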