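"""Honest causal forest for per-individual screening effects.

Each tree is grown on a subsample drawn without replacement, split into a
*splitting* half and an *estimation* half (honesty): splits are chosen on the
splitting half by maximizing the causal-tree heterogeneity criterion
``n_L * n_R * (tau_L - tau_R)^2`` over candidate (feature, threshold) pairs,
subject to minimum per-arm leaf counts; leaf treatment effects
(mean outcome CT minus mean outcome control) are then estimated on the
estimation half, which never influenced the splits.  Predictions average
leaf effects over trees; a leaf whose estimation half lacks both arms
inherits its nearest sufficient ancestor's estimate.

Variance is estimated by grouping trees into *little bags* that share a
common half-sample of the data: the between-bag variance of bag-level
estimates, corrected for the within-bag Monte-Carlo component, estimates the
sampling variance of the forest estimate.

The estimand is the conditional average treatment effect (CATE) on the
absolute risk scale, ``tau(x) = E[Y(CT) - Y(control) | X = x]``; negative
values are mortality reductions.  The forest-based *relative* effectiveness
divides the average predicted effect by the mean observed control-arm
outcome in the target population.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .pathmodels import build_design, _outcome_y, _outcome_label, _subgroup_mask, _subgroup_label
from .results import EffectEstimate


@dataclass
class ForestParams:
    num_trees: int = 2000
    subsample_fraction: float = 0.5
    honesty_fraction: float = 0.5
    min_leaf_treated: int = 10
    min_leaf_control: int = 10
    mtry: int | None = None          # default ceil(sqrt(p))
    max_depth: int | None = None
    little_bag_size: int = 4
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.subsample_fraction <= 0.5:
            raise ValueError("subsample_fraction must lie in (0, 0.5] so that "
                             "little bags can share half-samples")
        if not 0.0 < self.honesty_fraction < 1.0:
            raise ValueError("honesty_fraction must lie in (0, 1)")
        if self.num_trees % self.little_bag_size:
            raise ValueError("num_trees must be a multiple of little_bag_size")


@dataclass
class _Tree:
    # flat arrays indexed by node id; children -1 marks a leaf
    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=np.int32)
        active = self.left[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])
            active = self.left[node] >= 0
        return self.value[node]


@dataclass
class CausalForestModel:
    params: ForestParams
    covariates: list[str]
    feature_names: list[str]
    trees: list[_Tree]
    outcome: object = "overall_lcm"
    trial: str = "SYNTH"
    n_skipped: int = 0

    method_label: str = "causal_forest"

    def to_dict(self) -> dict:
        return {
            "kind": "causal_forest",
            "params": self.params.__dict__,
            "covariates": self.covariates,
            "feature_names": self.feature_names,
            "outcome": _outcome_label(self.outcome),
            "trial": self.trial,
            "trees": [{"feature": t.feature.tolist(),
                       "threshold": t.threshold.tolist(),
                       "left": t.left.tolist(), "right": t.right.tolist(),
                       "value": t.value.tolist()} for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CausalForestModel":
        trees = [_Tree(np.array(t["feature"], dtype=np.int32),
                       np.array(t["threshold"], dtype=float),
                       np.array(t["left"], dtype=np.int32),
                       np.array(t["right"], dtype=np.int32),
                       np.array(t["value"], dtype=float)) for t in d["trees"]]
        return cls(ForestParams(**d["params"]), list(d["covariates"]),
                   list(d["feature_names"]), trees, d["outcome"], d["trial"])


@dataclass
class CATEPrediction:
    """Per-record predicted absolute effect (CT minus control) and its
    little-bag variance estimate."""

    tau_hat: np.ndarray
    variance: np.ndarray


def _grow_tree(X: np.ndarray, y: np.ndarray, w: np.ndarray,
               split_idx: np.ndarray, est_idx: np.ndarray,
               params: ForestParams, rng: np.random.Generator,
               mtry: int) -> _Tree | None:
    """Grow one honest causal tree; returns None if the root is infeasible."""
    min_t, min_c = params.min_leaf_treated, params.min_leaf_control
    feature, threshold, left, right, value = [], [], [], [], []
    p = X.shape[1]

    def leaf_effect(idx: np.ndarray) -> float | None:
        wi = w[idx]
        nt = int(wi.sum())
        nc = len(idx) - nt
        if nt < min_t or nc < min_c:
            return None
        yt = y[idx][wi > 0].mean()
        yc = y[idx][wi == 0].mean()
        return float(yt - yc)

    root_eff = leaf_effect(est_idx)
    wi = w[split_idx]
    if root_eff is None or int(wi.sum()) < min_t or len(split_idx) - int(wi.sum()) < min_c:
        return None

    def new_node() -> int:
        feature.append(-1); threshold.append(np.nan)
        left.append(-1); right.append(-1); value.append(np.nan)
        return len(feature) - 1

    def build(s_idx: np.ndarray, e_idx: np.ndarray, depth: int,
              fallback: float) -> int:
        node = new_node()
        eff = leaf_effect(e_idx)
        node_value = eff if eff is not None else fallback
        value[node] = node_value
        if params.max_depth is not None and depth >= params.max_depth:
            return node
        best = _best_split(X, y, w, s_idx, rng, mtry, min_t, min_c)
        if best is None:
            return node
        j, thr = best
        go_left = X[s_idx, j] <= thr
        e_left = X[e_idx, j] <= thr
        sl, sr = s_idx[go_left], s_idx[~go_left]
        el, er = e_idx[e_left], e_idx[~e_left]
        feature[node] = j
        threshold[node] = thr
        left[node] = build(sl, el, depth + 1, node_value)
        right[node] = build(sr, er, depth + 1, node_value)
        return node

    build(split_idx, est_idx, 0, root_eff)
    return _Tree(np.array(feature, dtype=np.int32),
                 np.array(threshold, dtype=float),
                 np.array(left, dtype=np.int32),
                 np.array(right, dtype=np.int32),
                 np.array(value, dtype=float))


def _best_split(X, y, w, idx, rng, mtry, min_t, min_c):
    """Maximize n_L*n_R*(tau_L - tau_R)^2 over mtry random features."""
    n = len(idx)
    if n < 2 * (min_t + min_c):
        return None
    feats = rng.choice(X.shape[1], size=min(mtry, X.shape[1]), replace=False)
    wi = w[idx].astype(np.float64)
    yi = y[idx].astype(np.float64)
    best_gain, best = 0.0, None
    for j in feats:
        xj = X[idx, j]
        order = np.argsort(xj, kind="stable")
        xs = xj[order]
        ws = wi[order]
        ys = yi[order]
        ct = np.cumsum(ws)                 # treated count left of cut
        cy_t = np.cumsum(ys * ws)
        cc = np.cumsum(1.0 - ws)
        cy_c = np.cumsum(ys * (1.0 - ws))
        # candidate cuts between distinct consecutive values
        valid = xs[:-1] < xs[1:]
        ntl, ncl = ct[:-1], cc[:-1]
        ntr, ncr = ct[-1] - ntl, cc[-1] - ncl
        valid &= (ntl >= min_t) & (ncl >= min_c) & (ntr >= min_t) & (ncr >= min_c)
        if not valid.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            tau_l = cy_t[:-1] / ntl - cy_c[:-1] / ncl
            tau_r = (cy_t[-1] - cy_t[:-1]) / ntr - (cy_c[-1] - cy_c[:-1]) / ncr
        nl = ntl + ncl
        nr = ntr + ncr
        gain = np.where(valid, nl * nr * (tau_l - tau_r) ** 2, -np.inf)
        k = int(np.argmax(gain))
        if gain[k] > best_gain:
            best_gain = float(gain[k])
            best = (int(j), float((xs[k] + xs[k + 1]) / 2.0))
    return best


def fit_causal_forest(
    cohort: Cohort,
    covariates: Sequence[str] | None = None,
    params: ForestParams | None = None,
    outcome="overall_lcm",
) -> CausalForestModel:
    """Fit an honest causal forest on a complete-covariate cohort.

    Deterministic given ``params.seed``.  Trees whose root cannot satisfy
    the per-arm minimum leaf counts are skipped with a warning; if all trees
    are skipped, raises.
    """
    from .pathmodels import DEFAULT_COVARIATES

    covariates = list(covariates or DEFAULT_COVARIATES)
    params = params or ForestParams()
    params.validate()
    df = cohort.records
    X = build_design(df, covariates).to_numpy(float)
    y = _outcome_y(df, outcome)
    w = (df["arm"] == "CT").to_numpy(float)
    n = len(df)
    mtry = params.mtry or int(np.ceil(np.sqrt(X.shape[1])))
    rng = np.random.default_rng(params.seed)
    s = max(2 * (params.min_leaf_treated + params.min_leaf_control),
            int(round(params.subsample_fraction * n)))
    trees: list[_Tree] = []
    skipped = 0
    n_bags = params.num_trees // params.little_bag_size
    for _ in range(n_bags):
        half = rng.choice(n, size=n // 2, replace=False)
        for _ in range(params.little_bag_size):
            sub = half if s >= len(half) else rng.choice(half, size=s, replace=False)
            sub = rng.permutation(sub)
            cut = int(round(params.honesty_fraction * len(sub)))
            split_idx, est_idx = sub[:cut], sub[cut:]
            tree = _grow_tree(X, y, w, split_idx, est_idx, params, rng, mtry)
            if tree is None:
                skipped += 1
            else:
                trees.append(tree)
    if not trees:
        raise RuntimeError("all trees were skipped: leaf constraints cannot "
                           "be satisfied at the root")
    if skipped:
        warnings.warn(f"{skipped} of {params.num_trees} trees skipped "
                      "(infeasible root leaf constraints)")
    feature_names = list(build_design(df.head(1), covariates).columns)
    return CausalForestModel(params, covariates, feature_names, trees,
                             outcome, cohort.trial, skipped)


def _tree_matrix(model: CausalForestModel, X: np.ndarray) -> np.ndarray:
    """Per-tree predictions, shape (n_trees, n_records)."""
    return np.stack([t.predict(X) for t in model.trees])


def predict_cate(model: CausalForestModel, df: pd.DataFrame) -> CATEPrediction:
    """Predict per-record absolute screening effects.

    ``tau_hat`` is the average of leaf estimates over trees; the variance is
    the little-bag between/within decomposition per record.
    """
    X = build_design(df, model.covariates)
    if list(X.columns) != model.feature_names:
        raise ValueError(f"covariate schema mismatch: expected "
                         f"{model.feature_names}, got {list(X.columns)}")
    preds = _tree_matrix(model, X.to_numpy(float))
    tau = preds.mean(axis=0)
    var = _little_bag_variance(preds, model.params.little_bag_size)
    return CATEPrediction(tau_hat=tau, variance=var)


def _little_bag_variance(stats_per_tree: np.ndarray, bag: int) -> np.ndarray:
    """Between-bag variance of bag means with a within-bag Monte-Carlo
    correction; floored at zero.  Works on (n_trees,) or (n_trees, k)."""
    arr = np.atleast_2d(stats_per_tree.T).T  # (n_trees, k)
    n_trees = arr.shape[0]
    g = n_trees // bag
    bags = arr[:g * bag].reshape(g, bag, -1)
    bag_means = bags.mean(axis=1)                       # (g, k)
    # Each bag's mean approximates the estimator on an independent
    # half-sample; for half-sampling without replacement the finite-population
    # correction makes its dispersion estimate the full-sample sampling
    # variance directly.  The within-bag term removes Monte-Carlo noise from
    # tree randomization.
    between = bag_means.var(axis=0, ddof=1)
    within = bags.var(axis=1, ddof=1).mean(axis=0) / bag
    out = np.maximum(between - within, 0.0)
    return out if stats_per_tree.ndim > 1 else float(out.ravel()[0])


def forest_effectiveness(
    model: CausalForestModel,
    cohort: Cohort,
    subgroup=None,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Forest-based effectiveness for a (sub)population.

    The absolute effect is the mean predicted CATE; relative effectiveness
    is ``100 * (-mean tau / mu0)`` with ``mu0`` the mean observed control-arm
    outcome in the target population.  The CI comes from the little-bag
    variance of the forest mean with a delta-method transfer to the relative
    scale (control-mean variance included, treated as independent).
    """
    df = cohort.records
    mask = _subgroup_mask(df, subgroup)
    sub = df if mask is None else df[mask]
    X = build_design(sub, model.covariates).to_numpy(float)
    preds = _tree_matrix(model, X)
    mean_tau = float(preds.mean())
    var_tau = float(_little_bag_variance(preds.mean(axis=1),
                                         model.params.little_bag_size))
    y = _outcome_y(sub, model.outcome)
    ctrl = (sub["arm"] == "control").to_numpy()
    if ctrl.sum() == 0 or y[ctrl].mean() <= 0:
        return EffectEstimate(model.method_label, cohort.trial,
                              _outcome_label(model.outcome),
                              _subgroup_label(subgroup), np.nan,
                              1000.0 * -mean_tau, n_events=int(y.sum()),
                              n=len(sub), flagged="control mean outcome is zero")
    mu0 = float(y[ctrl].mean())
    var_mu0 = float(y[ctrl].var(ddof=1) / ctrl.sum())
    rel = 100.0 * (-mean_tau / mu0)
    # delta method for -t/m with independent (t, m)
    var_rel = (var_tau / mu0 ** 2 + (mean_tau ** 2 / mu0 ** 4) * var_mu0) * 100.0 ** 2
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    se_rel = float(np.sqrt(var_rel))
    se_abs = 1000.0 * float(np.sqrt(var_tau))
    return EffectEstimate(
        method=model.method_label, trial=cohort.trial,
        outcome=_outcome_label(model.outcome), subgroup=_subgroup_label(subgroup),
        relative_pct=rel, abs_per_1000=1000.0 * -mean_tau,
        rel_ci=(rel - z * se_rel, min(rel + z * se_rel, 100.0)),
        abs_ci=(1000.0 * -mean_tau - z * se_abs, 1000.0 * -mean_tau + z * se_abs),
        n_events=int(y.sum()), n=len(sub))


def save_forest(model: CausalForestModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_forest(path) -> CausalForestModel:
    with open(path) as fh:
        return CausalForestModel.from_dict(json.load(fh))
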