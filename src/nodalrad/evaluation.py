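"""Patient-level repeated cross-validation, bootstrap bias correction, metrics.

The evaluation contract mirrors the study design:

* splits are made at the patient level (all of a patient's nodes are on one
  side of every split), by default 20 folds repeated 10 times;
* per repeat, out-of-fold predictions are pooled into one full-cohort
  prediction vector per hyperparameter configuration; metrics are computed
  per repeat on that pooled vector and averaged over repeats;
* because the best configuration is picked on the same pooled predictions it
  is evaluated on, the naive "max over configurations" estimate is
  optimistic; the bootstrap bias correction (BBC) removes this by selecting
  the winner on bootstrap draws of nodes and scoring it on the held-out
  (out-of-bootstrap) nodes only;
* the naive reference for the scaled Brier score predicts each node's
  fold-training prevalence, i.e. exactly what an uninformative model trained
  under the same CV would output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .errors import ConfigurationError, DegenerateLabelError, UndefinedMetricError
from .models import (
    HyperparameterConfig,
    fit_pipeline,
    prepare_design,
)

# --------------------------------------------------------------------------
# fold planning


@dataclass
class FoldPlan:
    repeats: int
    folds: int
    #: assignment[r][f] is the list of patient_ids in test fold f of repeat r
    assignment: list[list[list[str]]]
    seed: int

    def test_patients(self, repeat: int, fold: int) -> list[str]:
        return self.assignment[repeat][fold]


def make_patient_folds(
    patient_ids: list[str],
    folds: int = 20,
    repeats: int = 10,
    seed: int = 0,
    strata: Mapping[str, int] | None = None,
    balance: Mapping[str, tuple[int, int]] | None = None,
) -> FoldPlan:
    """Random equal-as-possible patient partitions, one per repeat.

    ``strata`` (coarse positivity bins) spreads each stratum across folds by
    round-robin dealing.  ``balance`` — a map patient -> (positive node
    count, total node count) — switches to a randomized greedy assignment
    that additionally equalizes the positive-node counts across folds.
    Balanced folds keep every training set two-class and hold the fold
    training prevalences nearly constant, which suppresses a pessimistic
    bias of pooled out-of-fold AUC: near-constant (intercept-like)
    predictions otherwise anti-correlate with fold test prevalence, because
    a fold holding the high-positivity patients was trained with them
    removed.
    """
    patients = list(dict.fromkeys(patient_ids))
    if folds > len(patients):
        raise ConfigurationError(
            f"folds={folds} exceeds the number of patients ({len(patients)})"
        )
    if folds < 2 or repeats < 1:
        raise ConfigurationError("need folds >= 2 and repeats >= 1")
    rng = np.random.default_rng(seed)
    assignment = []
    for _ in range(repeats):
        fold_lists: list[list[str]] = [[] for _ in range(folds)]
        if balance is not None:
            total_pos = sum(balance[p][0] for p in patients)
            total_n = sum(balance[p][1] for p in patients)
            prev = total_pos / max(total_n, 1)
            # each patient's prevalence residual; assigning to the fold that
            # cancels accumulated residuals keeps fold prevalences ~equal
            resid = {p: balance[p][0] - prev * balance[p][1] for p in patients}
            order = list(rng.permutation(patients))
            order.sort(key=lambda p: -abs(resid[p]))  # stable sort keeps shuffle
            fold_n = np.zeros(folds, dtype=int)
            fold_res = np.zeros(folds)
            for p in order:
                cand = np.flatnonzero(fold_n == fold_n.min())
                costs = np.abs(fold_res[cand] + resid[p])
                tied = cand[np.abs(costs - costs.min()) < 1e-12]
                f = int(tied[rng.integers(len(tied))])
                fold_lists[f].append(p)
                fold_n[f] += 1
                fold_res[f] += resid[p]
        else:
            if strata is None:
                order = list(rng.permutation(patients))
            else:
                order = []
                for s in sorted({strata[p] for p in patients}):
                    group = [p for p in patients if strata[p] == s]
                    order.extend(rng.permutation(group))
            offset = int(rng.integers(folds))
            for i, p in enumerate(order):
                fold_lists[(i + offset) % folds].append(p)
        assignment.append(fold_lists)
    return FoldPlan(repeats=repeats, folds=folds, assignment=assignment, seed=seed)


def patient_balance(patient_ids: list[str], labels: np.ndarray) -> dict[str, tuple[int, int]]:
    """Per-patient (positive node count, total node count) for fold balancing."""
    df = pd.DataFrame({"p": patient_ids, "y": labels})
    g = df.groupby("p")["y"]
    return {p: (int(s), int(n)) for p, s, n in zip(g.sum().index, g.sum(), g.count())}


def patient_positivity_strata(
    patient_ids: list[str], labels: np.ndarray, bins: int = 4
) -> dict[str, int]:
    """Quantile strata of the patient-level positive-node fraction.

    Spreading patients with similar positivity fractions across folds keeps
    fold training prevalences nearly equal, which (a) avoids single-class
    training folds and (b) suppresses the pessimistic pooled-AUC artifact
    where near-constant predictions anti-correlate with fold test prevalence.
    """
    df = pd.DataFrame({"p": patient_ids, "y": labels})
    frac = df.groupby("p")["y"].mean()
    bins = max(1, min(bins, len(frac)))
    q = pd.qcut(frac.rank(method="first"), bins, labels=False)
    return {p: int(v) for p, v in q.items()}


# --------------------------------------------------------------------------
# cross-validation


@dataclass
class PredictionMatrix:
    """Pooled out-of-fold predictions: (repeats, nodes, configs)."""

    probs: np.ndarray
    train_prev: np.ndarray  # (repeats, nodes): fold-training prevalence per node
    node_ids: list[str]
    config_ids: list[str]
    labels: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.probs.shape[1]

    @property
    def n_configs(self) -> int:
        return self.probs.shape[2]

    def select(self, config_indices: list[int]) -> "PredictionMatrix":
        return PredictionMatrix(
            probs=self.probs[:, :, config_indices],
            train_prev=self.train_prev,
            node_ids=self.node_ids,
            config_ids=[self.config_ids[i] for i in config_indices],
            labels=self.labels,
        )

    def repeat_mean(self, config_index: int) -> np.ndarray:
        """Across-repeat mean prediction per node for one configuration."""
        return self.probs[:, :, config_index].mean(axis=0)


def _features_for(features, depth_k: int) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return features[depth_k]


def cross_validate(
    features: pd.DataFrame | Mapping[int, pd.DataFrame],
    labels: np.ndarray,
    patient_ids: list[str],
    configs: list[HyperparameterConfig],
    plan: FoldPlan,
    seed: int = 0,
    max_redraws: int = 20,
) -> PredictionMatrix:
    """Fit every configuration on every (repeat, fold) training set.

    Standardization and PCA statistics are estimated on training rows only
    and reused across configurations sharing the same preprocessing.  When
    ``features`` is a mapping keyed by CNN depth, each configuration's
    ``depth_k`` selects its feature table (deep/hybrid sets).

    Folds whose training labels are single-class trigger a redraw of that
    repeat's patient partition (logged as a warning).
    """
    any_table = features if isinstance(features, pd.DataFrame) else next(iter(features.values()))
    node_ids = list(any_table.index)
    y = np.asarray(labels, dtype=int)
    pid = np.asarray(patient_ids)
    R, N, C = plan.repeats, len(node_ids), len(configs)
    probs = np.full((R, N, C), np.nan)
    train_prev = np.full((R, N), np.nan)

    balance = patient_balance(list(pid), y)
    for r in range(plan.repeats):
        fold_lists = plan.assignment[r]
        for attempt in range(max_redraws):
            ok = True
            for f in range(plan.folds):
                test_rows = np.isin(pid, fold_lists[f])
                if len(np.unique(y[~test_rows])) < 2:
                    ok = False
                    break
            if ok:
                break
            warnings.warn(
                f"repeat {r}: single-class training fold, redrawing partition "
                f"(attempt {attempt + 1})"
            )
            redraw_seed = int(
                np.random.SeedSequence([plan.seed, r, attempt, 7919]).generate_state(1)[0]
                % 2**31
            )
            fold_lists = make_patient_folds(
                list(dict.fromkeys(pid)), plan.folds, 1, redraw_seed,
                balance=balance,
            ).assignment[0]
        else:
            raise DegenerateLabelError(
                f"repeat {r}: could not build folds with two-class training sets"
            )
        plan.assignment[r] = fold_lists

        for f in range(plan.folds):
            test_rows = np.isin(pid, fold_lists[f])
            train_rows = ~test_rows
            if not test_rows.any():
                continue
            train_prev[r, test_rows] = y[train_rows].mean()
            # group configs by the preprocessing they need
            groups: dict[tuple, list[int]] = {}
            for ci, hp in enumerate(configs):
                dk = hp.depth_k if not isinstance(features, pd.DataFrame) else 0
                key = (dk, hp.use_pca, hp.variance_threshold)
                groups.setdefault(key, []).append(ci)
            for (dk, use_pca, vt), members in groups.items():
                table = _features_for(features, configs[members[0]].depth_k)
                Xtr = table.values[train_rows]
                Xte = table.values[test_rows]
                prepared = prepare_design(Xtr, use_pca, vt)
                for ci in members:
                    hp = configs[ci]
                    model_seed = int(
                        np.random.SeedSequence([seed, r, f, ci]).generate_state(1)[0]
                        % 2**31
                    )
                    pipe = fit_pipeline(Xtr, y[train_rows], hp, model_seed,
                                        prepared=prepared)
                    probs[r, test_rows, ci] = pipe.predict_probability(Xte)
    assert not np.isnan(probs).any(), "every node must be predicted once per repeat"
    return PredictionMatrix(
        probs=probs,
        train_prev=train_prev,
        node_ids=node_ids,
        config_ids=[hp.config_id for hp in configs],
        labels=y,
    )


# --------------------------------------------------------------------------
# metrics


def auc(labels: np.ndarray, probs: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score(pos) > score(neg)), ties counted 1/2."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probs, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined with a single class")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def brier(labels: np.ndarray, probs: np.ndarray) -> float:
    """Mean squared error between outcome and predicted probability."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("probabilities must lie in [0, 1]")
    return float(np.mean((y - p) ** 2))


@dataclass(frozen=True)
class NaiveReference:
    """Brier score of the always-predict-training-prevalence model."""

    bs_ref: float

    def __post_init__(self) -> None:
        if self.bs_ref <= 0:
            raise ConfigurationError("degenerate naive reference (BS_ref <= 0)")


def naive_reference(labels: np.ndarray, train_prevalence: np.ndarray | float) -> NaiveReference:
    y = np.asarray(labels, dtype=float)
    p = np.broadcast_to(np.asarray(train_prevalence, dtype=float), y.shape)
    return NaiveReference(bs_ref=float(np.mean((y - p) ** 2)))


def scaled_brier(labels: np.ndarray, probs: np.ndarray, ref: NaiveReference) -> float:
    """Percent reduction of the Brier score versus the naive model (can be < 0)."""
    return float(100.0 * (1.0 - brier(labels, probs) / ref.bs_ref))


def youden_cutoff(labels: np.ndarray, probs: np.ndarray) -> tuple[float, float, float]:
    """Exhaustive scan for the cutoff maximizing sensitivity + specificity.

    Candidate cutoffs are midpoints of consecutive sorted unique
    probabilities plus sentinels below/above the observed range; a node is
    called positive when its probability is >= the cutoff.  Ties in the
    Youden index resolve to the smallest cutoff (favouring sensitivity).
    Returns (cutoff, sensitivity, specificity).
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probs, dtype=float)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("Youden cutoff undefined with a single class")
    uniq = np.unique(p)
    cands = np.concatenate(
        [[uniq[0] - 1e-9], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1e-9]]
    )
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    best = (-np.inf, None)
    for t in cands:
        pred = p >= t
        sens = float((pred & (y == 1)).sum() / n_pos)
        spec = float((~pred & (y == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, (float(t), sens, spec))
    return best[1]


def lowess_calibration(
    labels: np.ndarray,
    probs: np.ndarray,
    smoothing_fraction: float = 0.6,
    grid_points: int = 50,
) -> np.ndarray:
    """Lowess-smoothed calibration curve: (predicted, observed) pairs.

    Constant predictions collapse to the single point (mean prediction,
    observed prevalence).  Curve values are clipped to [0, 1].
    """
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probs, dtype=float)
    if len(y) < 20:
        raise ConfigurationError("calibration curve needs n >= 20")
    if np.ptp(p) == 0:
        return np.array([[float(p.mean()), float(y.mean())]])
    grid = np.linspace(p.min(), p.max(), grid_points)
    # it=0: robustness reweighting would treat minority-class outcomes as
    # outliers and bias the curve toward the majority class
    fitted = sm_lowess(y, p, frac=smoothing_fraction, it=0, xvals=grid)
    return np.column_stack([grid, np.clip(fitted, 0.0, 1.0)])


@dataclass(frozen=True)
class PairedTestResult:
    difference: float
    z: float
    p: float
    floored: bool = False


def paired_bootstrap_z_test(
    labels: np.ndarray,
    probs_a: np.ndarray,
    probs_b: np.ndarray,
    metric: str = "auc",
    B: int = 1000,
    seed: int = 0,
) -> PairedTestResult:
    """Two-sided bootstrapped z-test on a paired metric difference.

    Nodes are resampled with replacement (jointly for both prediction
    vectors); the metric difference is computed on each draw; z is the mean
    difference over its bootstrap SD; p comes from the standard normal.
    """
    if B < 2:
        raise ConfigurationError("B must be >= 2")
    y = np.asarray(labels, dtype=int)
    pa = np.asarray(probs_a, dtype=float)
    pb = np.asarray(probs_b, dtype=float)
    if pa.shape != pb.shape or pa.shape != y.shape:
        raise ConfigurationError("prediction vectors must share the label rows")
    rng = np.random.default_rng(seed)
    n = len(y)
    diffs = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            if 0 < y[idx].sum() < n:
                break
        if metric == "auc":
            diffs[b] = auc(y[idx], pa[idx]) - auc(y[idx], pb[idx])
        elif metric == "brier":
            diffs[b] = brier(y[idx], pa[idx]) - brier(y[idx], pb[idx])
        else:
            raise ConfigurationError(f"unknown metric: {metric}")
    mean, sd = float(diffs.mean()), float(diffs.std(ddof=1))
    if metric == "auc":
        point = auc(y, pa) - auc(y, pb)
    else:
        point = brier(y, pa) - brier(y, pb)
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(difference=point, z=0.0, p=1.0)
        return PairedTestResult(
            difference=point, z=float(np.sign(mean) * np.inf),
            p=float(np.finfo(float).tiny), floored=True,
        )
    z = mean / sd
    return PairedTestResult(
        difference=point, z=float(z), p=float(2.0 * norm.sf(abs(z)))
    )


# --------------------------------------------------------------------------
# pooled metrics over the prediction matrix and bootstrap bias correction


def _metric_per_config(
    matrix: PredictionMatrix, metric: str, rows: np.ndarray | None = None
) -> np.ndarray:
    """Per-config metric, computed per repeat then averaged: shape (C,)."""
    rows = np.arange(matrix.n_nodes) if rows is None else np.asarray(rows)
    y = matrix.labels[rows]
    P = matrix.probs[:, rows, :]  # (R, n, C)
    R, n, C = P.shape
    if metric == "auc":
        n_pos = int(y.sum())
        n_neg = n - n_pos
        if n_pos == 0 or n_neg == 0:
            raise UndefinedMetricError("AUC undefined with a single class")
        flat = P.transpose(1, 0, 2).reshape(n, R * C)
        ranks = rankdata(flat, axis=0)
        pos_sum = ranks[y == 1].sum(axis=0)
        vals = (pos_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        return vals.reshape(R, C).mean(axis=0)
    if metric in ("brier", "sbs"):
        bs = ((y[None, :, None] - P) ** 2).mean(axis=1)  # (R, C)
        if metric == "brier":
            return bs.mean(axis=0)
        prev = matrix.train_prev[:, rows]  # (R, n)
        bs_ref = ((y[None, :] - prev) ** 2).mean(axis=1)  # (R,)
        return (100.0 * (1.0 - bs / bs_ref[:, None])).mean(axis=0)
    raise ConfigurationError(f"unknown metric: {metric}")


def naive_pooled_best(
    matrix: PredictionMatrix, metric: str = "auc"
) -> tuple[float, int]:
    """Uncorrected best-over-configs pooled estimate (the optimistic one)."""
    vals = _metric_per_config(matrix, metric)
    i = int(np.argmin(vals)) if metric == "brier" else int(np.argmax(vals))
    return float(vals[i]), i


@dataclass
class BbcResult:
    """Bias-corrected estimates with percentile CIs and selection profile."""

    corrected: dict[str, float]
    ci: dict[str, tuple[float, float]]
    selection_frequencies: dict[str, float]
    draws: dict[str, np.ndarray]
    selection_metric: str


def bbc_select(
    matrix: PredictionMatrix,
    labels: np.ndarray | None = None,
    selection_metric: str = "brier",
    B: int = 1000,
    seed: int = 0,
    eval_metrics: tuple[str, ...] | None = None,
) -> BbcResult:
    """Bootstrap bias correction of the config-selection optimism.

    For each of B bootstrap draws of nodes: pick the configuration optimizing
    ``selection_metric`` on the drawn rows, then score it — for every metric
    in ``eval_metrics`` — on the out-of-bootstrap rows only.  The corrected
    estimate is the mean over draws; CIs are percentile intervals.
    """
    if B < 100:
        raise ConfigurationError("B must be >= 100")
    if labels is not None and not np.array_equal(labels, matrix.labels):
        raise ConfigurationError("labels do not match the prediction matrix")
    eval_metrics = eval_metrics or (selection_metric,)
    lower_better = selection_metric == "brier"
    rng = np.random.default_rng(seed)
    N, C = matrix.n_nodes, matrix.n_configs
    y = matrix.labels
    draws = {m: np.empty(B) for m in eval_metrics}
    sel_counts = np.zeros(C)
    for b in range(B):
        while True:
            idx = rng.integers(0, N, N)
            oob = np.ones(N, dtype=bool)
            oob[idx] = False
            oob_rows = np.flatnonzero(oob)
            if oob_rows.size and 0 < y[idx].sum() < idx.size and 0 < y[oob_rows].sum() < oob_rows.size:
                break
        vals = _metric_per_config(matrix, selection_metric, rows=idx)
        best = int(np.argmin(vals)) if lower_better else int(np.argmax(vals))
        sel_counts[best] += 1
        sub = matrix.select([best])
        for m in eval_metrics:
            draws[m][b] = _metric_per_config(sub, m, rows=oob_rows)[0]
    corrected = {m: float(draws[m].mean()) for m in eval_metrics}
    ci = {
        m: tuple(np.percentile(draws[m], [2.5, 97.5]).tolist())
        for m in eval_metrics
    }
    freqs = {cid: float(c / B) for cid, c in zip(matrix.config_ids, sel_counts)}
    return BbcResult(
        corrected=corrected,
        ci=ci,
        selection_frequencies=freqs,
        draws=draws,
        selection_metric=selection_metric,
    )


# --------------------------------------------------------------------------
# per-arm report


@dataclass
class ArmReport:
    """Corrected metrics for one (feature set x model) arm."""

    feature_set: str
    model: str
    auc: float
    auc_ci: tuple[float, float]
    brier: float
    brier_ci: tuple[float, float]
    sbs: float
    sbs_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    selected_config_id: str
    selection_frequencies: dict[str, float]
    calibration_curve: np.ndarray
    pooled_predictions: np.ndarray  # repeat-mean predictions of the selected config


def evaluate_arm(
    matrix: PredictionMatrix,
    feature_set: str,
    model: str,
    B: int = 1000,
    seed: int = 0,
    selection_metric: str = "brier",
) -> ArmReport:
    """BBC-corrected AUC/BS/SBS with CIs plus the operating point and
    calibration curve of the most frequently selected configuration."""
    res = bbc_select(
        matrix,
        selection_metric=selection_metric,
        B=B,
        seed=seed,
        eval_metrics=("auc", "brier", "sbs"),
    )
    sel = max(res.selection_frequencies, key=res.selection_frequencies.get)
    sel_idx = matrix.config_ids.index(sel)
    pooled = matrix.repeat_mean(sel_idx)
    cutoff, sens, spec = youden_cutoff(matrix.labels, pooled)
    curve = lowess_calibration(matrix.labels, pooled) if matrix.n_nodes >= 20 else np.empty((0, 2))
    return ArmReport(
        feature_set=feature_set,
        model=model,
        auc=res.corrected["auc"],
        auc_ci=res.ci["auc"],
        brier=res.corrected["brier"],
        brier_ci=res.ci["brier"],
        sbs=res.corrected["sbs"],
        sbs_ci=res.ci["sbs"],
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        selected_config_id=sel,
        selection_frequencies=res.selection_frequencies,
        calibration_curve=curve,
        pooled_predictions=pooled,
    )


def compare_arms(
    labels: np.ndarray,
    report_a: ArmReport,
    report_b: ArmReport,
    B: int = 1000,
    seed: int = 0,
) -> dict[str, PairedTestResult]:
    """Paired bootstrap z-tests on the AUC and Brier-score differences."""
    return {
        "auc": paired_bootstrap_z_test(
            labels, report_a.pooled_predictions, report_b.pooled_predictions,
            metric="auc", B=B, seed=seed,
        ),
        "brier": paired_bootstrap_z_test(
            labels, report_a.pooled_predictions, report_b.pooled_predictions,
            metric="brier", B=B, seed=seed + 1,
        ),
    }
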