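"""The L1-penalized logistic binding model with cross-validated lambda tiers.

For a balanced set of labeled regulatory sequences with feature matrix
``X`` (motif scores + composition rates) and Boolean response ``y``, the
model is

    logit P(y_s = 1) = alpha + sum_m beta_m Score_{m,s} + sum_n beta_n Rate_{n,s}

fitted by minimizing the penalized average negative log-likelihood

    (1/n) sum_s -log L(y_s) + lambda * ||beta||_1

with an unpenalized intercept on internally standardized features
(coefficients are reported on both scales).  The solver is a glmnet-style
iteratively-reweighted coordinate descent with warm starts along a
decreasing lambda path.

The penalty weight is chosen by stratified k-fold cross-validation on
binomial deviance.  Three tiers are kept: ``lambda_min`` (CV-error
minimum) and ``lambda_1se`` / ``lambda_3se``, the largest penalties whose
CV error stays within 1 resp. 3 standard errors of the minimum.  Larger
penalties give sparser, higher-confidence variable sets; the three
selection sets are nested by construction (enforced by downward
intersection, with removals logged).  Out-of-fold predicted probabilities
are stored for every training sequence and are the only predictions ever
used when the model is evaluated on its own training data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

TIERS = ("min", "1se", "3se")


# ---------------------------------------------------------------------------
# Solver

@njit(cache=True)
def _cd_sweep(X, w, r, beta, lam, candidates, active_only):  # pragma: no cover
    """One coordinate-descent pass over the candidate features.

    Updates ``beta`` and the weighted working residual ``r`` in place;
    returns the largest weighted squared coefficient change
    (max_j (sum_i w_i x_ij^2 / n) * delta_j^2, the scale glmnet uses for
    convergence).
    """
    n = X.shape[0]
    dmax = 0.0
    for idx in range(candidates.shape[0]):
        j = candidates[idx]
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        g = 0.0
        wx2 = 0.0
        for i in range(n):
            wx = w[i] * X[i, j]
            g += wx * r[i]
            wx2 += wx * X[i, j]
        wx2n = wx2 / n
        g = g / n + wx2n * bj
        if g > lam:
            bn = (g - lam) / wx2n
        elif g < -lam:
            bn = (g + lam) / wx2n
        else:
            bn = 0.0
        d = bn - bj
        if d != 0.0:
            beta[j] = bn
            for i in range(n):
                r[i] -= X[i, j] * d
            change = wx2n * d * d
            if change > dmax:
                dmax = change
    return dmax


@njit(cache=True)
def _cd_irls(X, y, lam, alpha, beta, candidates, tol, max_outer,
             max_inner):  # pragma: no cover
    """IRLS + coordinate descent at one penalty over a candidate set."""
    n = X.shape[0]
    for _outer in range(max_outer):
        eta = np.full(n, alpha)
        for j in range(beta.shape[0]):
            if beta[j] != 0.0:
                for i in range(n):
                    eta[i] += X[i, j] * beta[j]
        pv = 1.0 / (1.0 + np.exp(-eta))
        w = pv * (1.0 - pv)
        for i in range(n):
            if w[i] < 1e-6:
                w[i] = 1e-6
        r = (y - pv) / w
        wsum = w.sum()
        outer_change = 0.0
        sweeps = 0
        while sweeps < max_inner:
            # intercept (unpenalized)
            num = 0.0
            for i in range(n):
                num += w[i] * r[i]
            da = num / wsum
            if da != 0.0:
                alpha += da
                for i in range(n):
                    r[i] -= da
            dmax = _cd_sweep(X, w, r, beta, lam, candidates, False)
            sweeps += 1
            da2 = (wsum / n) * da * da
            if da2 > dmax:
                dmax = da2
            if dmax > outer_change:
                outer_change = dmax
            if dmax < tol:
                break
            # iterate on the active subset until stable, then re-check all
            while sweeps < max_inner:
                d_act = _cd_sweep(X, w, r, beta, lam, candidates, True)
                num = 0.0
                for i in range(n):
                    num += w[i] * r[i]
                da = num / wsum
                if da != 0.0:
                    alpha += da
                    for i in range(n):
                        r[i] -= da
                    da2 = (wsum / n) * da * da
                    if da2 > d_act:
                        d_act = da2
                sweeps += 1
                if d_act > outer_change:
                    outer_change = d_act
                if d_act < tol:
                    break
        if outer_change < tol:
            break
    return alpha


@njit(cache=True)
def _cd_path(X, y, lambdas, tol, max_outer, max_inner,
             dev_stop=2.0):  # pragma: no cover
    """Coordinate-descent LASSO-logistic path on standardized X.

    Warm starts carry the solution down the (decreasing) lambda path; the
    sequential strong rule proposes the candidate set at each penalty and
    a full KKT check over excluded features guards its correctness.  When
    the fraction of null deviance explained exceeds ``dev_stop`` the path
    stops early (the saturated tail carries no information); the returned
    ``n_used`` counts the penalties actually fitted.
    """
    n, p = X.shape
    nl = lambdas.shape[0]
    alphas = np.zeros(nl)
    betas = np.zeros((nl, p))
    ybar = y.mean()
    alpha = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    null_dev = 0.0
    for i in range(n):
        pv0 = ybar if y[i] > 0.5 else 1.0 - ybar
        null_dev -= 2.0 * np.log(pv0)
    n_used = nl
    for k in range(nl):
        lam = lambdas[k]
        lam_prev = lambdas[k - 1] if k > 0 else lam
        # gradient at the warm-start solution
        eta = np.full(n, alpha)
        for j in range(p):
            if beta[j] != 0.0:
                for i in range(n):
                    eta[i] += X[i, j] * beta[j]
        pv = 1.0 / (1.0 + np.exp(-eta))
        grad = np.zeros(p)
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += X[i, j] * (y[i] - pv[i])
            grad[j] = s / n
        strong_thresh = 2.0 * lam - lam_prev
        in_set = np.zeros(p, dtype=np.uint8)
        for j in range(p):
            if beta[j] != 0.0 or abs(grad[j]) >= strong_thresh:
                in_set[j] = 1
        while True:
            m = int(in_set.sum())
            candidates = np.empty(m, dtype=np.int64)
            c = 0
            for j in range(p):
                if in_set[j]:
                    candidates[c] = j
                    c += 1
            alpha = _cd_irls(X, y, lam, alpha, beta, candidates, tol,
                             max_outer, max_inner)
            # KKT check on the features left out
            eta = np.full(n, alpha)
            for j in range(p):
                if beta[j] != 0.0:
                    for i in range(n):
                        eta[i] += X[i, j] * beta[j]
            pv = 1.0 / (1.0 + np.exp(-eta))
            violations = 0
            for j in range(p):
                if in_set[j]:
                    continue
                s = 0.0
                for i in range(n):
                    s += X[i, j] * (y[i] - pv[i])
                if abs(s / n) > lam:
                    in_set[j] = 1
                    violations += 1
            if violations == 0:
                break
        alphas[k] = alpha
        betas[k] = beta
        if dev_stop < 1.0:
            eta = np.full(n, alpha)
            for j in range(p):
                if beta[j] != 0.0:
                    for i in range(n):
                        eta[i] += X[i, j] * beta[j]
            dev = 0.0
            for i in range(n):
                pv_i = 1.0 / (1.0 + np.exp(-eta[i]))
                if pv_i < 1e-12:
                    pv_i = 1e-12
                elif pv_i > 1.0 - 1e-12:
                    pv_i = 1.0 - 1e-12
                if y[i] > 0.5:
                    dev -= 2.0 * np.log(pv_i)
                else:
                    dev -= 2.0 * np.log(1.0 - pv_i)
            if 1.0 - dev / null_dev >= dev_stop:
                n_used = k + 1
                break
    return alphas, betas, n_used


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma = np.where(sigma < 1e-12, 1.0, sigma)
    return (X - mu) / sigma, mu, sigma


def lambda_max(Xs: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty shrinking every coefficient to zero (standardized X)."""
    ybar = y.mean()
    return float(np.abs(Xs.T @ (y - ybar)).max() / len(y))


def make_lambda_path(Xs, y, n_lambda=60, lambda_min_ratio=None) -> np.ndarray:
    n, p = Xs.shape
    if lambda_min_ratio is None:
        lambda_min_ratio = 1e-3 if n > p else 1e-2
    lmax = lambda_max(Xs, y)
    return np.exp(np.linspace(np.log(lmax), np.log(lmax * lambda_min_ratio), n_lambda))


def fit_lasso_logistic(Xs: np.ndarray, y: np.ndarray, lam: float,
                       tol: float = 1e-16, max_outer: int = 500,
                       max_inner: int = 20000):
    """Single-lambda fit on an already-standardized matrix.

    Returns ``(alpha, beta)`` on the standardized scale.  Exposed mainly so
    the solution at a fixed penalty can be compared against independent
    solvers.
    """
    Xs = np.ascontiguousarray(Xs, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    alphas, betas, _ = _cd_path(Xs, y, np.array([lam]), tol, max_outer,
                                max_inner)
    return float(alphas[0]), betas[0]


def binomial_deviance(y, prob) -> float:
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


# ---------------------------------------------------------------------------
# Fitted model container

@dataclass
class TfcoopModel:
    """A fitted binding model: coefficients, lambda tiers, CV predictions."""

    feature_names: list
    dropped_features: list
    lambda_path: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    tier_index: dict            # tier -> index into lambda_path
    coef: dict                  # tier -> {"alpha": float, "beta": {name: value}}
    coef_std: dict              # same, on the standardized scale
    selected: dict              # tier -> ordered selected feature names
    nesting_removed: dict       # tier -> features removed to enforce nesting
    first_entry: dict           # feature -> largest lambda at which it enters
    cv_predictions: dict        # tier -> {id: out-of-fold probability}
    fold_assignment: dict       # id -> fold index
    seed: int
    nfolds: int
    training_manifest: dict     # mode/provenance/n/ids of the training data

    @property
    def lambda_min(self) -> float:
        return float(self.lambda_path[self.tier_index["min"]])

    @property
    def lambda_1se(self) -> float:
        return float(self.lambda_path[self.tier_index["1se"]])

    @property
    def lambda_3se(self) -> float:
        return float(self.lambda_path[self.tier_index["3se"]])

    def predict(self, X: pd.DataFrame, tier: str = "min") -> np.ndarray:
        """Predicted binding probabilities for new feature rows."""
        if tier not in TIERS:
            raise ValueError(f"unknown tier {tier!r}")
        beta = self.coef[tier]["beta"]
        missing = [f for f in beta if f not in X.columns]
        if missing:
            raise ValueError(f"feature columns missing from X: {missing}")
        eta = np.full(len(X), self.coef[tier]["alpha"])
        for name, b in beta.items():
            if b != 0.0:
                eta += b * X[name].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))

    def selected_variables(self, tier: str = "min", order: str = "first_entry"):
        """Selected features at a tier, most important first.

        ``first_entry`` orders by the lambda at which the feature first
        enters the regularization path (earliest entry = most important);
        ``magnitude`` orders by |standardized coefficient|.
        """
        names = list(self.selected[tier])
        if order == "first_entry":
            return sorted(names, key=lambda f: -self.first_entry.get(f, 0.0))
        if order == "magnitude":
            bstd = self.coef_std[tier]["beta"]
            return sorted(names, key=lambda f: -abs(bstd.get(f, 0.0)))
        raise ValueError(f"unknown order {order!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "feature_names": self.feature_names,
            "dropped_features": self.dropped_features,
            "lambda_path": list(self.lambda_path),
            "cv_mean": list(self.cv_mean),
            "cv_se": list(self.cv_se),
            "tier_index": self.tier_index,
            "coef": self.coef,
            "coef_std": self.coef_std,
            "selected": self.selected,
            "nesting_removed": self.nesting_removed,
            "first_entry": self.first_entry,
            "cv_predictions": self.cv_predictions,
            "fold_assignment": self.fold_assignment,
            "seed": self.seed,
            "nfolds": self.nfolds,
            "training_manifest": self.training_manifest,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TfcoopModel":
        return cls(
            feature_names=list(d["feature_names"]),
            dropped_features=list(d["dropped_features"]),
            lambda_path=np.array(d["lambda_path"]),
            cv_mean=np.array(d["cv_mean"]),
            cv_se=np.array(d["cv_se"]),
            tier_index={k: int(v) for k, v in d["tier_index"].items()},
            coef=d["coef"],
            coef_std=d["coef_std"],
            selected=d["selected"],
            nesting_removed=d["nesting_removed"],
            first_entry=d["first_entry"],
            cv_predictions=d["cv_predictions"],
            fold_assignment=d["fold_assignment"],
            seed=int(d["seed"]),
            nfolds=int(d["nfolds"]),
            training_manifest=d["training_manifest"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "TfcoopModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Fitting

def fit(dataset, nfolds: int = 10, seed: int = 0, n_lambda: int = 60,
        lambda_min_ratio: float | None = None, tol: float = 1e-8) -> TfcoopModel:
    """Fit the model with a k-fold cross-validated lambda path.

    Features are standardized internally (per training fold for CV, on the
    full data for the final path); constant columns are dropped with a
    warning.  Deterministic given ``seed``.
    """
    X_df, y, ids = dataset.X, np.asarray(dataset.y, dtype=float), list(dataset.ids)
    n = len(y)
    if int(y.sum()) < nfolds or int((1 - y).sum()) < nfolds:
        raise ValueError("need at least nfolds positives and negatives")

    sigma0 = X_df.to_numpy(dtype=float).std(axis=0)
    constant = [c for c, s in zip(X_df.columns, sigma0) if s < 1e-12]
    if constant:
        logger.warning("dropping %d constant feature columns: %s",
                       len(constant), constant[:5])
        X_df = X_df.drop(columns=constant)
    names = list(X_df.columns)
    X = np.ascontiguousarray(X_df.to_numpy(dtype=float))

    Xs_full, mu, sigma = _standardize(X)
    lambdas = make_lambda_path(Xs_full, y, n_lambda, lambda_min_ratio)

    # full-data path (also the tier refits: the path value at the tier's
    # lambda is the full-data solution at that penalty); the path stops
    # once ~all null deviance is explained
    alphas_full, betas_full, n_used = _cd_path(
        np.ascontiguousarray(Xs_full), y, lambdas, tol, 50, 500,
        dev_stop=0.999,
    )
    lambdas = lambdas[:n_used]
    alphas_full = alphas_full[:n_used]
    betas_full = betas_full[:n_used]

    # cross-validation
    skf = StratifiedKFold(n_splits=nfolds, shuffle=True, random_state=seed)
    fold_of = np.empty(n, dtype=int)
    oof = np.empty((n, len(lambdas)))
    fold_dev = np.empty((nfolds, len(lambdas)))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        fold_of[te] = f
        Xs_tr, mu_f, sg_f = _standardize(X[tr])
        a_f, b_f, _ = _cd_path(np.ascontiguousarray(Xs_tr), y[tr], lambdas,
                               tol, 50, 500)
        Xs_te = (X[te] - mu_f) / sg_f
        eta = a_f[None, :] + Xs_te @ b_f.T   # (n_te, nl)
        prob = 1.0 / (1.0 + np.exp(-eta))
        oof[te] = prob
        for k in range(len(lambdas)):
            fold_dev[f, k] = binomial_deviance(y[te], prob[:, k])
    cv_mean = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(nfolds)

    i_min = int(np.argmin(cv_mean))
    thresh1 = cv_mean[i_min] + cv_se[i_min]
    thresh3 = cv_mean[i_min] + 3 * cv_se[i_min]
    i_1se = int(np.flatnonzero(cv_mean <= thresh1)[0])
    i_3se = int(np.flatnonzero(cv_mean <= thresh3)[0])
    tier_index = {"min": i_min, "1se": i_1se, "3se": i_3se}

    # first entry along the path (largest lambda with a nonzero coefficient)
    first_entry = {}
    nz = betas_full != 0.0
    for j, name in enumerate(names):
        hits = np.flatnonzero(nz[:, j])
        if len(hits):
            first_entry[name] = float(lambdas[hits[0]])

    coef, coef_std, selected = {}, {}, {}
    for tier, idx in tier_index.items():
        b_std = betas_full[idx]
        a_std = alphas_full[idx]
        b_orig = b_std / sigma
        a_orig = a_std - float((b_std * mu / sigma).sum())
        coef[tier] = {"alpha": float(a_orig),
                      "beta": {nm: float(v) for nm, v in zip(names, b_orig)}}
        coef_std[tier] = {"alpha": float(a_std),
                          "beta": {nm: float(v) for nm, v in zip(names, b_std)}}
        selected[tier] = [nm for nm, v in zip(names, b_std) if v != 0.0]

    # enforce the documented nesting S_3se <= S_1se <= S_min
    nesting_removed = {"min": [], "1se": [], "3se": []}
    s_min = set(selected["min"])
    removed_1se = [f for f in selected["1se"] if f not in s_min]
    selected["1se"] = [f for f in selected["1se"] if f in s_min]
    s_1se = set(selected["1se"])
    removed_3se = [f for f in selected["3se"] if f not in s_1se]
    selected["3se"] = [f for f in selected["3se"] if f in s_1se]
    nesting_removed["1se"] = removed_1se
    nesting_removed["3se"] = removed_3se
    for tier in ("1se", "3se"):
        if nesting_removed[tier]:
            logger.info("nesting enforcement removed %s from S_%s",
                        nesting_removed[tier], tier)
            for f in nesting_removed[tier]:
                coef[tier]["beta"][f] = 0.0
                coef_std[tier]["beta"][f] = 0.0

    cv_predictions = {
        tier: {sid: float(oof[i, idx]) for i, sid in enumerate(ids)}
        for tier, idx in tier_index.items()
    }

    return TfcoopModel(
        feature_names=names,
        dropped_features=constant,
        lambda_path=lambdas,
        cv_mean=cv_mean,
        cv_se=cv_se,
        tier_index=tier_index,
        coef=coef,
        coef_std=coef_std,
        selected=selected,
        nesting_removed=nesting_removed,
        first_entry=first_entry,
        cv_predictions=cv_predictions,
        fold_assignment={sid: int(f) for sid, f in zip(ids, fold_of)},
        seed=int(seed),
        nfolds=int(nfolds),
        training_manifest={
            "mode": dataset.mode,
            "provenance": dataset.provenance,
            "seed": int(dataset.seed),
            "n": int(n),
        },
    )


def predict(model: TfcoopModel, X: pd.DataFrame, tier: str = "min") -> np.ndarray:
    return model.predict(X, tier=tier)


def selected_variables(model: TfcoopModel, tier: str = "min",
                       order: str = "first_entry"):
    return model.selected_variables(tier=tier, order=order)


# ---------------------------------------------------------------------------
# Evaluation

def auc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) AUC; ties receive half credit."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def self_auc(model: TfcoopModel, labels_by_id: dict | None = None,
             tier: str = "min") -> float:
    """AUC on the model's own training data, strictly from out-of-fold
    cross-validated predictions (never refit predictions).

    ``labels_by_id`` defaults to nothing and is only needed when the model
    was deserialized without its training dataset; otherwise pass the
    mapping id -> Boolean label used in training.
    """
    preds = model.cv_predictions[tier]
    if labels_by_id is None:
        raise ValueError("labels_by_id required (id -> Boolean training label)")
    ids = list(preds)
    y = np.array([bool(labels_by_id[i]) for i in ids])
    s = np.array([preds[i] for i in ids])
    return auc(y, s)


def transfer_auc(model_a: TfcoopModel, dataset_b, tier: str = "min") -> float:
    """AUC of model A evaluated on dataset B.

    For sequences of B that were part of A's training data, A's stored
    out-of-fold prediction is used (the CV cache); all other sequences go
    through the fitted linear predictor.  When B is A's own training set
    this reduces exactly to :func:`self_auc`.
    """
    cache = model_a.cv_predictions[tier]
    fresh_mask = np.array([i not in cache for i in dataset_b.ids])
    scores = np.empty(len(dataset_b.ids))
    if fresh_mask.any():
        scores[fresh_mask] = model_a.predict(dataset_b.X.iloc[fresh_mask], tier=tier)
    for i, sid in enumerate(dataset_b.ids):
        if not fresh_mask[i]:
            scores[i] = cache[sid]
    return auc(dataset_b.y, scores)


def auc_difference_analysis(pairs, models: dict, datasets: dict,
                            tier: str = "min"):
    """Model-specificity analysis over labeled pairs of experiments.

    ``pairs`` is an iterable of ``(key_a, key_b, group)`` with group labels
    such as ``same_tf_same_cell`` / ``diff_tf_same_cell``.  For each pair
    the difference ``self_auc(A) - transfer_auc(model_B on A)`` is computed;
    a small difference means model B carries over to experiment A.  Returns
    the per-pair table and Welch t-test p-values between every two groups.
    """
    rows = []
    for key_a, key_b, group in pairs:
        ds_a = datasets[key_a]
        labels_a = dict(zip(ds_a.ids, ds_a.y))
        a_self = self_auc(models[key_a], labels_a, tier=tier)
        a_transfer = transfer_auc(models[key_b], ds_a, tier=tier)
        rows.append({
            "target": key_a, "source": key_b, "group": group,
            "auc_self": a_self, "auc_transfer": a_transfer,
            "auc_difference": a_self - a_transfer,
        })
    table = pd.DataFrame(rows)
    groups = sorted(table["group"].unique())
    pvals = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            d1 = table.loc[table["group"] == g1, "auc_difference"]
            d2 = table.loc[table["group"] == g2, "auc_difference"]
            if len(d1) > 1 and len(d2) > 1:
                pvals[(g1, g2)] = float(
                    stats.ttest_ind(d1, d2, equal_var=False).pvalue
                )
    return table, pvals
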