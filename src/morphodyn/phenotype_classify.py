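"""Supervised phenotype classification protocol.

The protocol mirrors the experimental analysis it reimplements: shuffle the
cell list, split 70/30 *at the cell level* (every timepoint row of a cell
stays on one side, so there is no temporal self-leakage), optionally truncate
to timepoints strictly below a time limit, optionally subsample the target
class's training rows down to an extreme ratio (e.g. 1/1500), z-score and
project to 14 principal components using training rows only, train a 100-round
discrete AdaBoost over depth-1 decision stumps (class coding 0 = general,
1 = target), predict per cell, score precision / recall / F1 per class, and
repeat 30 times, reporting means and standard deviations.

AdaBoost is implemented here rather than delegated: the stump search,
weighting scheme and early-stop rules are part of the analysis contract and
are oracle-tested against exhaustive search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from ._rng import substream

__all__ = [
    "ExperimentPlan",
    "Preprocessor",
    "Stump",
    "BoostModel",
    "ClassMetrics",
    "split_by_cell",
    "apply_time_limit",
    "subsample_target",
    "fit_preprocessor",
    "fit_adaboost",
    "predict_rows",
    "predict_cells",
    "score",
    "run_experiment",
    "sweep",
]


@dataclass
class ExperimentPlan:
    """Knobs of the repeated shuffled-holdout protocol."""

    train_fraction: float = 0.70
    time_limit_min: float | None = None
    target_class: int = 1
    ratio: float | None = None  # target : general training-row ratio
    repeats: int = 30
    n_components: int = 14
    n_rounds: int = 100
    aggregate: str = "majority_vote"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.ratio is not None and not 0.0 < self.ratio <= 1.0:
            raise ValueError("ratio must be in (0, 1]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


# ---------------------------------------------------------------------------
# protocol stages


def split_by_cell(
    labels_by_cell: pd.Series, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified cell-level split: floor(train_fraction * n) per class.

    Returns (train_ids, test_ids).  All timepoint rows of a cell end up on
    one side.  Raises when a class has fewer than 2 cells.
    """
    train_ids, test_ids = [], []
    for cls, cells in labels_by_cell.groupby(labels_by_cell):
        ids = np.asarray(cells.index)
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 cells")
        perm = rng.permutation(len(ids))
        n_train = int(np.floor(train_fraction * len(ids) + 1e-9))
        train_ids.append(ids[perm[:n_train]])
        test_ids.append(ids[perm[n_train:]])
    return np.concatenate(train_ids), np.concatenate(test_ids)


def apply_time_limit(table: pd.DataFrame, time_limit_min: float | None) -> pd.DataFrame:
    """Keep rows with time_min strictly below the limit ("smaller than")."""
    if time_limit_min is None or np.isinf(time_limit_min):
        return table
    out = table[table["time_min"] < time_limit_min]
    if out.empty:
        raise ValueError(f"time limit {time_limit_min} leaves no rows")
    return out


def subsample_target(
    train_table: pd.DataFrame,
    labels_by_cell: pd.Series,
    target_class: int,
    ratio: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Downsample target-class training rows to (#target / #general) = ratio.

    Whole target cells are removed first (in shuffled order); the last kept
    cell is trimmed row-wise (earliest timepoints kept) so the achieved ratio
    is exact to within one row.  The test set is never touched — this acts on
    training rows only.
    """
    is_target = train_table["cell_id"].map(labels_by_cell) == target_class
    n_general = int((~is_target).sum())
    n_target = int(is_target.sum())
    desired = int(round(ratio * n_general))
    if desired < 1:
        raise ValueError(f"ratio {ratio} leaves no target training rows")
    if desired > n_target:
        raise ValueError(
            f"ratio {ratio} exceeds the current target/general ratio "
            f"({n_target}/{n_general})"
        )
    target_cells = train_table.loc[is_target, "cell_id"].unique()
    order = rng.permutation(len(target_cells))
    keep_index = []
    remaining = desired
    for ci in order:
        if remaining <= 0:
            break
        cell_rows = train_table[train_table["cell_id"] == target_cells[ci]]
        cell_rows = cell_rows.sort_values("time_min")
        take = min(remaining, len(cell_rows))
        keep_index.extend(cell_rows.index[:take])
        remaining -= take
    kept = pd.concat([train_table[~is_target], train_table.loc[keep_index]])
    return kept.sort_index()


@dataclass
class Preprocessor:
    """Train-only z-scoring followed by an orthonormal PCA projection."""

    mean: np.ndarray
    sd: np.ndarray
    pca: PCA = field(repr=False)

    @property
    def n_components(self) -> int:
        return self.pca.n_components_

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform((np.asarray(X, float) - self.mean) / self.sd)


def fit_preprocessor(train_X: np.ndarray, n_components: int = 14) -> Preprocessor:
    """Fit z-score + PCA on training rows only (constant columns get SD 1)."""
    X = np.asarray(train_X, float)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_features)="
            f"{min(X.shape)}"
        )
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_components, svd_solver="covariance_eigh")
    pca.fit((X - mean) / sd)
    return Preprocessor(mean=mean, sd=sd, pca=pca)


# ---------------------------------------------------------------------------
# discrete AdaBoost over decision stumps


@dataclass(frozen=True)
class Stump:
    feature: int
    threshold: float
    polarity: int  # +1: predict +1 when x > threshold; -1: the reverse

    def predict_pm1(self, X: np.ndarray) -> np.ndarray:
        raw = np.where(X[:, self.feature] > self.threshold, 1, -1)
        return self.polarity * raw


@dataclass
class BoostModel:
    stumps: list[Stump]
    alphas: np.ndarray
    epsilons: np.ndarray  # weighted error of each accepted stump

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        scores = np.zeros(len(X))
        for stump, alpha in zip(self.stumps, self.alphas):
            scores += alpha * stump.predict_pm1(X)
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        """{0, 1} labels; a zero score falls to the general class 0."""
        return (self.decision_scores(X) > 0).astype(int)


def _best_stump(
    X: np.ndarray, s: np.ndarray, w: np.ndarray, order: np.ndarray
) -> tuple[Stump, float]:
    """Exact minimizer of the weighted error over all (feature, midpoint
    threshold, polarity) stumps.  Ties break toward the smallest feature
    index, then the smallest threshold, then polarity +1."""
    n, d = X.shape
    w_neg_total = float(w[s < 0].sum())
    best = None  # (eps, feature, threshold, polarity)
    for j in range(d):
        idx = order[:, j]
        xs = X[idx, j]
        cw = np.cumsum(w[idx] * s[idx])
        valid = np.nonzero(xs[:-1] < xs[1:])[0]
        if valid.size == 0:
            continue
        thresholds = 0.5 * (xs[valid] + xs[valid + 1])
        eps_plus = w_neg_total + cw[valid]
        eps_minus = 1.0 - eps_plus
        for eps_arr, pol in ((eps_plus, 1), (eps_minus, -1)):
            i = int(np.argmin(eps_arr))
            cand = (float(eps_arr[i]), j, float(thresholds[i]), pol)
            if (
                best is None
                or cand[0] < best[0] - 1e-12
                or (abs(cand[0] - best[0]) <= 1e-12 and (cand[1], cand[2], -cand[3])
                    < (best[1], best[2], -best[3]))
            ):
                best = cand
    if best is None:
        raise ValueError("no admissible stump (all features constant)")
    eps, j, thr, pol = best
    return Stump(j, thr, pol), eps


def fit_adaboost(X: np.ndarray, y: np.ndarray, n_rounds: int = 100) -> BoostModel:
    """Discrete two-class AdaBoost with depth-1 stumps.

    Round t: pick the stump minimizing the weighted error eps_t over midpoints
    of sorted unique feature values; alpha_t = 0.5 ln((1 - eps_t)/eps_t);
    multiplicative weight update and renormalization.  Stops early when
    eps_t >= 0.5 (stump rejected) or eps_t = 0 (stump accepted with clipped
    alpha — the data are separable).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if set(classes.tolist()) - {0, 1} or len(classes) < 2:
        raise ValueError("y must contain both labels 0 and 1")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    s = np.where(y == 1, 1.0, -1.0)
    n = len(y)
    w = np.full(n, 1.0 / n)
    order = np.argsort(X, axis=0, kind="stable")

    stumps, alphas, epsilons = [], [], []
    for _ in range(n_rounds):
        stump, eps = _best_stump(X, s, w, order)
        if eps >= 0.5:
            break
        eps_c = min(max(eps, 1e-12), 1 - 1e-12)
        alpha = 0.5 * np.log((1 - eps_c) / eps_c)
        stumps.append(stump)
        alphas.append(alpha)
        epsilons.append(eps)
        if eps <= 0.0:
            break
        h = stump.predict_pm1(X)
        w = w * np.exp(-alpha * s * h)
        w /= w.sum()
    if not stumps:
        raise ValueError("no stump with weighted error < 0.5")
    return BoostModel(stumps, np.asarray(alphas), np.asarray(epsilons))


# ---------------------------------------------------------------------------
# prediction and scoring


def predict_rows(
    model: BoostModel, preproc: Preprocessor, rows: pd.DataFrame, feature_cols: list[str]
) -> pd.DataFrame:
    """Row-level predictions and boosted margins for a feature table."""
    Z = preproc.transform(rows[feature_cols].to_numpy())
    scores = model.decision_scores(Z)
    return pd.DataFrame(
        {
            "cell_id": rows["cell_id"].to_numpy(),
            "score": scores,
            "pred": (scores > 0).astype(int),
        }
    )


def predict_cells(
    model: BoostModel,
    preproc: Preprocessor,
    test_rows: pd.DataFrame,
    feature_cols: list[str],
    aggregate: str = "majority_vote",
) -> pd.Series:
    """One label per test cell.

    majority_vote: majority of row labels, exact ties to the general class 0.
    mean_score: sign of the mean boosted margin over the cell's rows.
    per_row: row-level labels (index = row position, column cell_id kept).
    """
    rowpred = predict_rows(model, preproc, test_rows, feature_cols)
    if aggregate == "per_row":
        return rowpred.set_index("cell_id")["pred"]
    grouped = rowpred.groupby("cell_id")
    if aggregate == "majority_vote":
        return grouped["pred"].apply(lambda p: int(p.mean() > 0.5))
    if aggregate == "mean_score":
        return grouped["score"].apply(lambda sc: int(sc.mean() > 0))
    raise ValueError(f"unknown aggregate {aggregate!r}")


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    support: int


def score(pred, truth) -> dict[int, ClassMetrics]:
    """Per-class precision, recall and F1.

    precision = TP / (TP + FP), recall = TP / (TP + FN),
    F1 = 2 * precision * recall / (precision + recall);
    an undefined precision (TP + FP = 0) is reported as 0.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same length")
    out = {}
    for cls in (0, 1):
        tp = int(((pred == cls) & (truth == cls)).sum())
        fp = int(((pred == cls) & (truth != cls)).sum())
        fn = int(((pred != cls) & (truth == cls)).sum())
        tn = int(((pred != cls) & (truth != cls)).sum())
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        out[cls] = ClassMetrics(tp, fp, fn, tn, precision, recall, f1, tp + fn)
    return out


# ---------------------------------------------------------------------------
# the repeated protocol


def _one_repeat(
    table: pd.DataFrame,
    labels_by_cell: pd.Series,
    plan: ExperimentPlan,
    feature_cols: list[str],
    repeat: int,
) -> dict[int, ClassMetrics]:
    rng = substream(plan.seed, "experiment", repeat)
    train_ids, test_ids = split_by_cell(labels_by_cell, plan.train_fraction, rng)
    train = table[table["cell_id"].isin(train_ids)]
    test = table[table["cell_id"].isin(test_ids)]
    if plan.ratio is not None:
        train = subsample_target(
            train, labels_by_cell, plan.target_class, plan.ratio, rng
        )
    preproc = fit_preprocessor(train[feature_cols].to_numpy(), plan.n_components)
    Z = preproc.transform(train[feature_cols].to_numpy())
    y = train["cell_id"].map(labels_by_cell).to_numpy()
    model = fit_adaboost(Z, y, plan.n_rounds)
    pred = predict_cells(model, preproc, test, feature_cols, plan.aggregate)
    truth = labels_by_cell.loc[pred.index]
    return score(pred.to_numpy(), truth.to_numpy())


def run_experiment(
    table: pd.DataFrame, labels_by_cell: pd.Series, plan: ExperimentPlan
) -> dict:
    """The full repeated shuffled-holdout protocol.

    Per repeat: reshuffle -> cell-level split -> time limit -> (optional)
    target subsampling -> fit preprocessing on training rows -> transform both
    sides -> boost -> per-cell prediction -> per-class scoring.  The report
    carries each repeat's metrics plus the mean and SD over repeats.
    Deterministic given ``plan.seed``.
    """
    feature_cols = [c for c in table.columns if c not in ("cell_id", "time_min")]
    table = apply_time_limit(table, plan.time_limit_min)
    per_repeat = []
    for r in range(plan.repeats):
        try:
            metrics = _one_repeat(table, labels_by_cell, plan, feature_cols, r)
        except Exception as exc:  # annotate with the repeat index
            raise RuntimeError(f"repeat {r} failed: {exc}") from exc
        per_repeat.append(metrics)

    summary = {}
    for cls in (0, 1):
        rows = per_repeat
        summary[cls] = {
            "precision_mean": float(np.mean([m[cls].precision for m in rows])),
            "precision_sd": float(np.std([m[cls].precision for m in rows])),
            "recall_mean": float(np.mean([m[cls].recall for m in rows])),
            "recall_sd": float(np.std([m[cls].recall for m in rows])),
            "f1_mean": float(np.mean([m[cls].f1 for m in rows])),
            "f1_sd": float(np.std([m[cls].f1 for m in rows])),
            "support": int(np.mean([m[cls].support for m in rows])),
        }
    return {
        "plan": asdict(plan),
        "per_repeat": [
            {cls: asdict(m[cls]) for cls in (0, 1)} for m in per_repeat
        ],
        "summary": summary,
    }


def sweep(
    table: pd.DataFrame,
    labels_by_cell: pd.Series,
    plan: ExperimentPlan,
    time_limits: list[float | None],
    ratios: list[float | None],
) -> pd.DataFrame:
    """Grid of (time_limit, ratio) -> target-class f1 mean/SD over repeats."""
    from dataclasses import replace

    records = []
    for tl in time_limits:
        for ratio in ratios:
            rep = run_experiment(
                table, labels_by_cell, replace(plan, time_limit_min=tl, ratio=ratio)
            )
            s = rep["summary"][plan.target_class]
            records.append(
                {
                    "time_limit": np.inf if tl is None else tl,
                    "ratio": 1.0 if ratio is None else ratio,
                    "f1_mean": s["f1_mean"],
                    "f1_sd": s["f1_sd"],
                }
            )
    return pd.DataFrame.from_records(records)
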