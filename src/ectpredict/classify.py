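"""Nested cross-validated feature selection and radial-SVM classification.

The engine follows a repeated, nested design: an outer 5-repeated 5-fold
split validates final model performance; within each outer training set,
25 further feature-selection splits drive recursive feature elimination
(RFE) with radial SVMs, and features are re-ranked by the consistency
with which RFE selects them across those 25 splits.  The top-25
consistency-ranked features then feed a sweep of radial-SVM models using
the top 2, 3, ... 25 features (24 models), each tuned by inner resampling
with an AUROC objective and evaluated once on the held-out outer test set.

Radial kernels expose no coefficients, so RFE ranks features by
permutation importance: the AUROC drop on the feature-selection split's
held-out fold when that feature's column is shuffled.  Candidate subset
sizes follow a halving grid; the subset size with the best held-out AUROC
is the split's selected feature set.

All randomness flows from a single root seed through
``numpy.random.SeedSequence``; results are bit-for-bit reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

METRICS = ("balanced_accuracy", "sensitivity", "specificity")


@dataclass
class PipelineConfig:
    """Tunable knobs of the nested design (defaults mirror the full design)."""

    outer_k: int = 5
    outer_repeats: int = 5
    inner_k: int = 5  # feature-selection splits within each outer train set
    inner_repeats: int = 5
    sizes: tuple[int, ...] = tuple(range(2, 26))  # sweep: top 2..25 features
    top_n: int = 25
    rfe_max_start: int = 256  # cap of the RFE halving grid
    rfe_C: float = 1.0
    n_importance_shuffles: int = 1
    tune_k: int = 5  # folds of the hyperparameter-tuning resampling
    tune_gamma_factors: tuple[float, ...] = (0.1, 1.0, 10.0)
    tune_costs: tuple[float, ...] = (0.25, 1.0, 4.0)

    @classmethod
    def reduced(cls, **overrides) -> "PipelineConfig":
        """Scaled-down variant (2-repeated 3-fold CV, lean tuning grid) for
        simulation studies that need many pipeline replicates."""
        base = dict(
            outer_k=3, outer_repeats=2, inner_k=3, inner_repeats=2,
            tune_k=3, tune_gamma_factors=(1.0,), tune_costs=(0.25, 1.0, 4.0),
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class FoldPlan:
    """Outer train/test partitions plus nested feature-selection partitions.

    ``outer[i]`` is (repeat, fold, train_idx, test_idx); ``inner[i]`` lists
    (fit_idx, val_idx) pairs, all absolute row indices into the cohort.
    """

    outer: list[tuple[int, int, np.ndarray, np.ndarray]]
    inner: list[list[tuple[np.ndarray, np.ndarray]]]
    seed: int


def make_fold_plan(
    y: np.ndarray,
    k: int = 5,
    repeats: int = 5,
    inner_k: int = 5,
    inner_repeats: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Stratified repeated k-fold plan with nested feature-selection splits.

    Within one repeat the k test sets partition the cohort; stratification
    keeps the class ratio within one subject of balance in every partition.
    """
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("need two classes for a stratified plan")
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(
            f"smallest class ({counts.min()}) cannot be stratified into {k} folds"
        )
    ss = np.random.SeedSequence(seed)
    outer_states = ss.generate_state(repeats)
    inner_root = ss.spawn(1)[0]
    outer, inner = [], []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(outer_states[r] % 2**31))
        for f, (train_idx, test_idx) in enumerate(skf.split(np.zeros_like(y), y)):
            outer.append((r, f, train_idx, test_idx))
            inner_states = inner_root.spawn(1)[0].generate_state(inner_repeats)
            splits = []
            y_train = y[train_idx]
            # clip the nested fold count to the smallest class in this
            # training set so every feature-selection fold stays two-class
            inner_k_eff = min(inner_k, int(np.bincount(y_train).min()))
            if inner_k_eff < 2:
                raise ValueError("training set too small for nested splits")
            for ir in range(inner_repeats):
                iskf = StratifiedKFold(
                    n_splits=inner_k_eff, shuffle=True,
                    random_state=int(inner_states[ir] % 2**31))
                for fit_rel, val_rel in iskf.split(np.zeros_like(y_train), y_train):
                    splits.append((train_idx[fit_rel], train_idx[val_rel]))
            inner.append(splits)
    return FoldPlan(outer=outer, inner=inner, seed=seed)


# --- low-level helpers -------------------------------------------------


def _auroc(y: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUROC (ties get half credit)."""
    pos = y == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    r = rankdata(scores)
    u = r[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _auroc_rows(y: np.ndarray, score_rows: np.ndarray) -> np.ndarray:
    """AUROC of each row of `score_rows` against the same labels."""
    pos = y == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    r = rankdata(score_rows, axis=1)
    u = r[:, pos].sum(axis=1) - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def _median_heuristic_gamma(x: np.ndarray) -> float:
    """RBF width from the median squared pairwise distance."""
    d2 = pdist(x, metric="sqeuclidean")
    med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
    return 1.0 / med if med > 0 else 1.0


def _standardize(train: np.ndarray, *others: np.ndarray):
    """Z-score by training-set statistics only."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return tuple((a - mu) / sd for a in (train, *others))


def _halving_grid(p: int, cap: int) -> list[int]:
    """Candidate subset sizes: p, then powers of two down to 2."""
    sizes = {p}
    s = 2
    while s <= min(cap, p):
        sizes.add(s)
        s *= 2
    return sorted(sizes, reverse=True)


# --- RFE with consistency ranking -------------------------------------


def rfe_select(
    x: np.ndarray,
    y: np.ndarray,
    inner_splits: list[tuple[np.ndarray, np.ndarray]],
    config: PipelineConfig,
    seed: int = 0,
) -> list[dict]:
    """One RFE pass per feature-selection split of the outer training set.

    Returns, per split, the selected feature indices (columns of ``x``),
    the chosen subset size and its held-out AUROC.  ``inner_splits`` hold
    absolute row indices; ``x``/``y`` are the full cohort arrays — only
    rows named by the splits are ever touched, so the outer test set never
    influences selection.
    """
    rng = np.random.default_rng(seed)
    out = []
    with sklearn.config_context(assume_finite=True):
        out = _rfe_select_inner(x, y, inner_splits, config, rng)
    return out


def _rfe_select_inner(x, y, inner_splits, config, rng):
    out = []
    for fit_idx, val_idx in inner_splits:
        x_fit, x_val = _standardize(x[fit_idx], x[val_idx])
        y_fit, y_val = y[fit_idx], y[val_idx]
        gamma = _median_heuristic_gamma(x_fit)
        grid = _halving_grid(x.shape[1], config.rfe_max_start)
        current = np.arange(x.shape[1])
        best: tuple[float, int, np.ndarray] | None = None
        for size in grid:
            if size < len(current):
                current = current[:size]  # ordered by importance, best first
            model = SVC(kernel="rbf", C=config.rfe_C, gamma=gamma)
            model.fit(x_fit[:, current], y_fit)
            auroc = _auroc(y_val, model.decision_function(x_val[:, current]))
            # prefer higher AUROC; on ties the smaller (later-grid) size
            if best is None or auroc >= best[0]:
                best = (auroc, size, current.copy())
            if size > 2:
                imp = _permutation_importance(
                    model, x_val[:, current], y_val, auroc, rng,
                    config.n_importance_shuffles)
                current = current[np.argsort(-imp, kind="stable")]
        assert best is not None
        out.append({"features": best[2], "size": best[1], "auroc": best[0]})
    return out


def _permutation_importance(model, x_val, y_val, base_auroc, rng, n_shuffles):
    """AUROC drop on the held-out fold when one feature column is shuffled.

    All p shuffled copies are scored in one batched decision_function call.
    """
    n_val, p = x_val.shape
    imp = np.zeros(p)
    for _ in range(n_shuffles):
        reps = np.broadcast_to(x_val, (p, n_val, p)).copy()
        for f in range(p):
            reps[f, :, f] = x_val[rng.permutation(n_val), f]
        scores = model.decision_function(reps.reshape(p * n_val, p))
        imp += base_auroc - _auroc_rows(y_val, scores.reshape(p, n_val))
    return imp / n_shuffles


def consistency_rank(
    selected_sets: list[dict], feature_names: list[str], top_n: int = 25
) -> pd.DataFrame:
    """Rank features by how many feature-selection splits RFE chose them.

    A count equal to the number of splits (25 in the full design) means
    100% selection consistency.  Ties are broken by feature name; the top
    ``top_n`` are returned (all of them, with a warning, if fewer distinct
    features were ever selected).
    """
    counts: dict[str, int] = {}
    for sel in selected_sets:
        for ix in sel["features"]:
            name = feature_names[ix]
            counts[name] = counts.get(name, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["feature", "count"],
    )
    table["rank"] = np.arange(1, len(table) + 1)
    if len(table) < top_n:
        warnings.warn(
            f"only {len(table)} distinct features ever selected (< {top_n})",
            stacklevel=2,
        )
    return table.head(top_n).reset_index(drop=True)


# --- model sweep -------------------------------------------------------


def performance_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Standard 2x2 contingency metrics; responder (1) is the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    if tp + fn == 0 or tn + fp == 0:
        warnings.warn("a class is absent from the truth vector", stacklevel=2)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2,
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
    }


def _tune_rbf(x, y, config: PipelineConfig, seed: int) -> tuple[float, float, float]:
    """Grid-search (gamma, C) by resampled AUROC; ties keep grid order."""
    gamma0 = _median_heuristic_gamma(x)
    if len(config.tune_gamma_factors) == 1 and len(config.tune_costs) == 1:
        # degenerate grid: nothing to resample over
        return float("nan"), gamma0 * config.tune_gamma_factors[0], config.tune_costs[0]
    skf = StratifiedKFold(n_splits=config.tune_k, shuffle=True,
                          random_state=seed % 2**31)
    folds = list(skf.split(x, y))
    best = None
    for gf in config.tune_gamma_factors:
        for c in config.tune_costs:
            scores = []
            for fit_rel, val_rel in folds:
                m = SVC(kernel="rbf", C=c, gamma=gamma0 * gf)
                m.fit(x[fit_rel], y[fit_rel])
                scores.append(_auroc(y[val_rel], m.decision_function(x[val_rel])))
            mean_auroc = float(np.nanmean(scores))
            if best is None or mean_auroc > best[0]:
                best = (mean_auroc, gamma0 * gf, c)
    assert best is not None
    return best


def train_eval_sweep(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    ranked_feature_idx: np.ndarray,
    config: PipelineConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit and evaluate one radial SVM per feature-set size.

    For each size s in the sweep, the top-s consistency-ranked features are
    tuned on the training set (AUROC objective), refit on the full
    training set, and scored once on the outer test set.  The default
    sweep over sizes 2..25 yields 24 fitted models.
    """
    if not np.all(np.isfinite(x_train)) or not np.all(np.isfinite(x_test)):
        raise ValueError("non-finite feature values; filter upstream")
    with sklearn.config_context(assume_finite=True):
        return _sweep_inner(x_train, y_train, x_test, y_test,
                            ranked_feature_idx, config, seed)


def _sweep_inner(x_train, y_train, x_test, y_test, ranked_feature_idx, config, seed):
    rows = []
    for s in config.sizes:
        if s > len(ranked_feature_idx):
            break
        cols = ranked_feature_idx[:s]
        xtr, xte = _standardize(x_train[:, cols], x_test[:, cols])
        auroc, gamma, c = _tune_rbf(xtr, y_train, config, seed)
        model = SVC(kernel="rbf", C=c, gamma=gamma)
        model.fit(xtr, y_train)
        pred = model.predict(xte)
        row = {"size": s, "tune_auroc": auroc, "gamma": gamma, "cost": c}
        row.update(performance_metrics(y_test, pred))
        rows.append(row)
    return pd.DataFrame(rows)


# --- orchestration -----------------------------------------------------


@dataclass
class PipelineResult:
    fold_plan: FoldPlan
    consistency_tables: list[pd.DataFrame]  # one per outer split
    selected_sets: list[list[dict]]  # raw RFE selections per outer split
    performance: pd.DataFrame  # repeat, fold, size, metrics
    config: PipelineConfig = field(repr=False, default=None)

    def mean_by_size(self) -> pd.DataFrame:
        """Average metrics over the outer splits, per feature-set size."""
        return self.performance.groupby("size")[
            ["balanced_accuracy", "sensitivity", "specificity", "ppv", "npv"]
        ].mean()


def run_pipeline(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    config: PipelineConfig | None = None,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> PipelineResult:
    """Full nested run: fold plan, per-split RFE + consistency ranking,
    and the feature-set-size model sweep on every outer split."""
    config = config or PipelineConfig()
    if isinstance(x, pd.DataFrame):
        feature_names = list(x.columns)
        x = x.to_numpy(dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(x.shape[1])]
    y = np.asarray(y)

    ss = np.random.SeedSequence(seed)
    plan_seed, rfe_seed, tune_seed = (int(s) for s in ss.generate_state(3) % 2**31)
    plan = make_fold_plan(
        y, k=config.outer_k, repeats=config.outer_repeats,
        inner_k=config.inner_k, inner_repeats=config.inner_repeats,
        seed=plan_seed)

    name_to_ix = {n: i for i, n in enumerate(feature_names)}
    tables, all_sets, perf_rows = [], [], []
    for split_ix, (r, f, train_idx, test_idx) in enumerate(plan.outer):
        selections = rfe_select(
            x, y, plan.inner[split_ix], config, seed=rfe_seed + split_ix)
        table = consistency_rank(selections, feature_names, top_n=config.top_n)
        ranked_idx = np.array([name_to_ix[n] for n in table["feature"]])
        sweep = train_eval_sweep(
            x[train_idx], y[train_idx], x[test_idx], y[test_idx],
            ranked_idx, config, seed=tune_seed + split_ix)
        sweep.insert(0, "fold", f)
        sweep.insert(0, "repeat", r)
        tables.append(table)
        all_sets.append(selections)
        perf_rows.append(sweep)

    return PipelineResult(
        fold_plan=plan,
        consistency_tables=tables,
        selected_sets=all_sets,
        performance=pd.concat(perf_rows, ignore_index=True),
        config=config,
    )
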