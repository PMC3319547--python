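"""Ridge regression of spatial proximity on pairwise signal features.

The model predicts the proximity c(i, j) of an interchromosomal fragment
pair from up to 24 features: the log-scale difference D and average A of
signal strength for each of the 12 chromatin properties.

Evaluation follows a fragment-level two-fold protocol: the fragment list
is split into random halves, a pair enters the training (testing) set
only when BOTH its fragments fall in the training (testing) half — pairs
crossing the halves are discarded — and the halves are then exchanged,
so each split yields two RMSE values.  With the default 100 splits every
model is scored by 200 test-set RMSE values, compared against a baseline
that always predicts the training-set mean, with a paired two-tailed
t-test and Bonferroni correction across the screened features.

Feature selection comes in two flavours, both validated on inner
two-fold splits of the training data (10 repeats): successive selection
ranks single-feature models by validation RMSE and grows the model in
that fixed order; greedy forward selection re-scores every candidate at
each step.  Selection stability is the per-feature frequency of being
chosen within the first L steps across outer splits.

The public surface is statsmodels-flavoured: build a
:class:`ProximityRegression` model from a pair feature table, call
``fit()`` for a :class:`ProximityRegressionResults` carrying estimates,
errors and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_N_SPLITS = 100
DEFAULT_INNER_REPEATS = 10
DEFAULT_ALPHA = 1.0
ALPHA_GRID = np.logspace(-3, 3, 13)


# ---------------------------------------------------------------------------
# splits


@dataclass(frozen=True)
class FragmentSplit:
    """One random bipartition of the fragment list."""
    train_fragments: np.ndarray
    test_fragments: np.ndarray

    def swapped(self) -> "FragmentSplit":
        return FragmentSplit(self.test_fragments, self.train_fragments)


def make_splits(fragments: np.ndarray, n_splits: int = DEFAULT_N_SPLITS,
                seed: int = 0) -> list[FragmentSplit]:
    """Random equal halves of the fragment list (sizes differ by one for
    odd counts).  The same list is reused across all models so that
    paired comparisons are meaningful."""
    fragments = np.asarray(fragments)
    if len(fragments) < 4:
        raise ValueError("need at least 4 fragments to split")
    rng = np.random.default_rng(seed)
    half = len(fragments) // 2
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(fragments)
        splits.append(FragmentSplit(np.sort(perm[:half]), np.sort(perm[half:])))
    return splits


def pair_membership(idx_i: np.ndarray, idx_j: np.ndarray,
                    fragment_set: np.ndarray) -> np.ndarray:
    """Rows whose BOTH fragments belong to ``fragment_set``."""
    member = np.isin(idx_i, fragment_set) & np.isin(idx_j, fragment_set)
    return member


# ---------------------------------------------------------------------------
# ridge core (standardization on training statistics; intercept unpenalized)


class RidgeModel:
    """Closed-form ridge fit on standardized features.

    Features are centered and scaled by training statistics (constant
    features are zeroed out); the intercept is the training target mean
    and is not penalized.  An empty feature set degenerates to the
    baseline mean predictor.
    """

    def __init__(self, alpha: float):
        self.alpha = float(alpha)
        self.coef_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.y_mean_ = y.mean()
        if X.shape[1] == 0:
            self.coef_ = np.zeros(0)
            self.x_mean_ = np.zeros(0)
            self.x_scale_ = np.ones(0)
            return self
        self.x_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.x_scale_ = np.where(scale > 0, scale, 1.0)
        self._constant = scale == 0
        Z = (X - self.x_mean_) / self.x_scale_
        Z[:, self._constant] = 0.0
        yc = y - self.y_mean_
        p = Z.shape[1]
        A = Z.T @ Z + self.alpha * np.eye(p)
        self.coef_ = np.linalg.solve(A, Z.T @ yc)
        self.coef_[self._constant] = 0.0
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.coef_ is None:
            raise RuntimeError("model not fitted")
        if X.shape[1] == 0:
            return np.full(len(X), self.y_mean_)
        Z = (X - self.x_mean_) / self.x_scale_
        Z[:, self._constant] = 0.0
        return self.y_mean_ + Z @ self.coef_

    @property
    def destandardized_coef_(self) -> np.ndarray:
        """Coefficients on the original feature scale."""
        return self.coef_ / self.x_scale_


def _resolve_alpha(X: np.ndarray, y: np.ndarray, alpha_policy,
                   seed: int = 0) -> float:
    """"cv": 5-fold cross-validated grid on the training half; a number:
    fixed penalty."""
    if isinstance(alpha_policy, (int, float)):
        return float(alpha_policy)
    if alpha_policy == "cv":
        if len(y) < 10 or X.shape[1] == 0:
            return DEFAULT_ALPHA
        from sklearn.linear_model import RidgeCV
        from sklearn.preprocessing import StandardScaler
        Z = StandardScaler().fit_transform(X)
        model = RidgeCV(alphas=ALPHA_GRID, cv=5).fit(Z, y)
        return float(model.alpha_)
    raise ValueError(f"unknown alpha policy {alpha_policy!r}")


def fit_ridge(X: np.ndarray, y: np.ndarray,
              alpha_policy="cv", seed: int = 0) -> RidgeModel:
    """Fit a ridge model with the given penalty policy (training data only)."""
    if len(y) < 2:
        raise ValueError("need at least 2 training rows")
    alpha = _resolve_alpha(X, y, alpha_policy, seed)
    return RidgeModel(alpha).fit(X, y)


def rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(pred) - np.asarray(truth)) ** 2)))


def baseline_rmse(y_train: np.ndarray, y_test: np.ndarray) -> float:
    """RMSE of the train-mean predictor: the test-set root mean squared
    deviation around the training mean."""
    return rmse(np.full(len(y_test), np.mean(y_train)), y_test)


# ---------------------------------------------------------------------------
# the model object


class ProximityRegression:
    """Ridge model of spatial proximity given pairwise features.

    Parameters
    ----------
    X, y : feature matrix (rows = interchromosomal pairs) and proximity.
    idx_i, idx_j : fragment indices of each pair (drive the
        fragment-level split protocol).
    feature_names : column names of X.
    alpha_policy : "cv" (inner 5-fold grid on the training half) or a
        fixed number.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, idx_i: np.ndarray,
                 idx_j: np.ndarray, feature_names: list[str],
                 alpha_policy="cv"):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.idx_i = np.asarray(idx_i)
        self.idx_j = np.asarray(idx_j)
        self.feature_names = list(feature_names)
        self.alpha_policy = alpha_policy
        if self.X.shape != (len(self.y), len(self.feature_names)):
            raise ValueError("X shape does not match y / feature names")
        self.fragments = np.unique(np.concatenate([self.idx_i, self.idx_j]))

    @classmethod
    def from_pair_table(cls, table: pd.DataFrame,
                        features: list[str] | None = None,
                        target: str = "proximity",
                        alpha_policy="cv") -> "ProximityRegression":
        """Build from a pair feature table; by default all D_* and A_*
        columns are used.  Rows with missing values are dropped."""
        if features is None:
            features = [c for c in table.columns
                        if c.startswith(("D_", "A_"))]
        sub = table[["i", "j", target] + features].dropna()
        return cls(sub[features].to_numpy(), sub[target].to_numpy(),
                   sub["i"].to_numpy(), sub["j"].to_numpy(),
                   features, alpha_policy)

    # -- evaluation protocol ---------------------------------------------

    def _split_rows(self, split: FragmentSplit):
        train = pair_membership(self.idx_i, self.idx_j, split.train_fragments)
        test = pair_membership(self.idx_i, self.idx_j, split.test_fragments)
        return np.flatnonzero(train), np.flatnonzero(test)

    def evaluate(self, features: list[str] | list[int],
                 splits: list[FragmentSplit],
                 alpha_policy=None) -> "EvaluationResult":
        """Model and baseline test RMSE over every split in both
        orientations (2 values per split)."""
        cols = self._feature_indices(features)
        policy = self.alpha_policy if alpha_policy is None else alpha_policy
        model_rmse, base_rmse = [], []
        n_skipped = 0
        for split in splits:
            for s in (split, split.swapped()):
                tr, te = self._split_rows(s)
                if len(te) == 0 or len(tr) < 2:
                    n_skipped += 1
                    continue
                model = fit_ridge(self.X[np.ix_(tr, cols)], self.y[tr], policy)
                model_rmse.append(rmse(model.predict(self.X[np.ix_(te, cols)]),
                                       self.y[te]))
                base_rmse.append(baseline_rmse(self.y[tr], self.y[te]))
        if n_skipped:
            logger.info("evaluate: skipped %d empty split orientations",
                        n_skipped)
        return EvaluationResult(
            feature_names=[self.feature_names[c] for c in cols],
            model_rmse=np.array(model_rmse), baseline_rmse=np.array(base_rmse))

    def screen_features(self, splits: list[FragmentSplit],
                        alpha_policy=None) -> pd.DataFrame:
        """Single-feature models vs the baseline, Bonferroni-corrected
        across the screened features (one row per feature)."""
        rows = []
        n_feat = len(self.feature_names)
        for f in self.feature_names:
            res = self.evaluate([f], splits, alpha_policy=alpha_policy)
            p_corr = min(1.0, res.p_value * n_feat)
            rows.append({"feature": f, "model_rmse": res.mean_rmse,
                         "model_sd": res.sd_rmse,
                         "baseline_rmse": res.mean_baseline,
                         "baseline_sd": res.sd_baseline,
                         "p_raw": res.p_value, "p_bonferroni": p_corr,
                         "significant": p_corr < 0.05
                         and res.mean_rmse < res.mean_baseline})
        return pd.DataFrame(rows)

    # -- fitting ----------------------------------------------------------

    def fit(self, features: list[str] | None = None,
            splits: list[FragmentSplit] | None = None,
            n_splits: int = DEFAULT_N_SPLITS,
            seed: int = 0) -> "ProximityRegressionResults":
        """Fit on the full sample and evaluate on the split protocol."""
        if features is None:
            features = list(self.feature_names)
        if splits is None:
            splits = make_splits(self.fragments, n_splits, seed)
        cols = self._feature_indices(features)
        model = fit_ridge(self.X[:, cols], self.y, self.alpha_policy)
        evaluation = self.evaluate(features, splits)
        return ProximityRegressionResults(self, features, model, evaluation)

    def _feature_indices(self, features) -> list[int]:
        idx = []
        for f in features:
            if isinstance(f, (int, np.integer)):
                idx.append(int(f))
            else:
                idx.append(self.feature_names.index(f))
        return idx

    # -- selection protocols ----------------------------------------------

    def _inner_validation_rmse(self, rows: np.ndarray, cols: list[int],
                               rng: np.random.Generator,
                               n_repeats: int = DEFAULT_INNER_REPEATS,
                               alpha_policy=DEFAULT_ALPHA) -> float:
        """Mean RMSE over inner two-fold fragment splits of ``rows``."""
        frags = np.unique(np.concatenate([self.idx_i[rows], self.idx_j[rows]]))
        errs = []
        for _ in range(n_repeats):
            perm = rng.permutation(frags)
            half = len(frags) // 2
            tr_set, va_set = perm[:half], perm[half:]
            tr = rows[pair_membership(self.idx_i[rows], self.idx_j[rows], tr_set)]
            va = rows[pair_membership(self.idx_i[rows], self.idx_j[rows], va_set)]
            if len(tr) < 2 or len(va) == 0:
                continue
            model = fit_ridge(self.X[np.ix_(tr, cols)], self.y[tr], alpha_policy)
            errs.append(rmse(model.predict(self.X[np.ix_(va, cols)]), self.y[va]))
        return float(np.mean(errs)) if errs else float("inf")

    def successive_selection(self, splits: list[FragmentSplit],
                             seed: int = 0,
                             n_repeats: int = DEFAULT_INNER_REPEATS,
                             alpha_policy=DEFAULT_ALPHA) -> "SelectionResult":
        """Rank single-feature models by inner-validation RMSE, then
        evaluate cumulative models of growing size on the outer protocol."""
        rng = np.random.default_rng(seed)
        rows = np.arange(len(self.y))
        scores = [
            (self._inner_validation_rmse(rows, [c], rng, n_repeats,
                                         alpha_policy), c)
            for c in range(len(self.feature_names))
        ]
        order = [c for _, c in sorted(scores, key=lambda t: (t[0], t[1]))]
        curve = self._cumulative_curve(order, splits, alpha_policy)
        return SelectionResult(
            method="successive",
            order=[self.feature_names[c] for c in order], curve=curve)

    def _greedy_order(self, rows: np.ndarray, rng: np.random.Generator,
                      n_repeats: int, alpha_policy,
                      max_features: int | None = None) -> list[int]:
        remaining = list(range(len(self.feature_names)))
        selected: list[int] = []
        limit = max_features or len(remaining)
        while remaining and len(selected) < limit:
            best_err, best_c = np.inf, None
            for c in remaining:
                err = self._inner_validation_rmse(
                    rows, selected + [c], rng, n_repeats, alpha_policy)
                if err < best_err:
                    best_err, best_c = err, c
            selected.append(best_c)
            remaining.remove(best_c)
        return selected

    def greedy_selection(self, splits: list[FragmentSplit],
                         seed: int = 0,
                         n_repeats: int = DEFAULT_INNER_REPEATS,
                         alpha_policy=DEFAULT_ALPHA,
                         stability_splits: int | None = None,
                         max_features: int | None = None) -> "SelectionResult":
        """Greedy forward selection on inner-validation RMSE; selection is
        repeated on each outer split's training rows to estimate
        per-feature stability frequencies at each list length."""
        rng = np.random.default_rng(seed)
        rows = np.arange(len(self.y))
        order = self._greedy_order(rows, rng, n_repeats, alpha_policy,
                                   max_features)
        curve = self._cumulative_curve(order, splits, alpha_policy)
        n_stab = len(splits) if stability_splits is None else stability_splits
        p = len(order)
        counts = np.zeros((p, len(self.feature_names)))
        n_runs = 0
        for split in splits[:n_stab]:
            tr, _ = self._split_rows(split)
            if len(tr) < 2:
                continue
            sel = self._greedy_order(tr, rng, n_repeats, alpha_policy,
                                     max_features=p)
            for L in range(len(sel)):
                counts[L, sel[:L + 1]] += 1
            n_runs += 1
        freq = counts / n_runs if n_runs else counts
        stability = pd.DataFrame(freq, columns=self.feature_names)
        stability.index.name = "list_length_minus_1"
        return SelectionResult(
            method="greedy", order=[self.feature_names[c] for c in order],
            curve=curve, stability=stability)

    def _cumulative_curve(self, order: list[int],
                          splits: list[FragmentSplit],
                          alpha_policy) -> pd.DataFrame:
        rows = []
        for n in range(1, len(order) + 1):
            res = self.evaluate(order[:n], splits, alpha_policy=alpha_policy)
            rows.append({"n_features": n, "rmse_mean": res.mean_rmse,
                         "rmse_sd": res.sd_rmse,
                         "baseline_mean": res.mean_baseline,
                         "baseline_sd": res.sd_baseline})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# results


@dataclass
class EvaluationResult:
    """Per-split model and baseline RMSE with the paired comparison."""

    feature_names: list[str]
    model_rmse: np.ndarray
    baseline_rmse: np.ndarray

    @property
    def n_values(self) -> int:
        return len(self.model_rmse)

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.model_rmse))

    @property
    def sd_rmse(self) -> float:
        return float(np.std(self.model_rmse, ddof=1))

    @property
    def mean_baseline(self) -> float:
        return float(np.mean(self.baseline_rmse))

    @property
    def sd_baseline(self) -> float:
        return float(np.std(self.baseline_rmse, ddof=1))

    @property
    def p_value(self) -> float:
        """Paired two-sample two-tailed t-test of model vs baseline RMSE
        (p = 1 when the error sequences are identical)."""
        diff = self.model_rmse - self.baseline_rmse
        if np.allclose(diff, 0):
            return 1.0
        t, p = stats.ttest_rel(self.model_rmse, self.baseline_rmse)
        return float(p)


@dataclass
class SelectionResult:
    method: str
    order: list[str]
    curve: pd.DataFrame
    stability: pd.DataFrame | None = None

    def stable_features(self, list_length: int,
                        threshold: float = 0.9) -> list[str]:
        """Features selected within the first ``list_length`` steps in at
        least ``threshold`` of the stability runs."""
        if self.stability is None:
            raise ValueError("stability only estimated for greedy selection")
        row = self.stability.iloc[list_length - 1]
        return [f for f in self.stability.columns if row[f] >= threshold]


class ProximityRegressionResults:
    """Fitted coefficients plus the split-protocol evaluation."""

    def __init__(self, model: ProximityRegression, features: list[str],
                 fitted: RidgeModel, evaluation: EvaluationResult):
        self.model = model
        self.features = features
        self.fitted = fitted
        self.evaluation = evaluation

    @property
    def params(self) -> pd.Series:
        """Coefficients on the standardized feature scale."""
        return pd.Series(self.fitted.coef_, index=self.features)

    @property
    def alpha(self) -> float:
        return self.fitted.alpha

    @property
    def rmse_mean(self) -> float:
        return self.evaluation.mean_rmse

    @property
    def baseline_mean(self) -> float:
        return self.evaluation.mean_baseline

    @property
    def p_value(self) -> float:
        return self.evaluation.p_value

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.fitted.predict(X)

    def summary(self) -> str:
        lines = [
            "Proximity ridge regression",
            "=" * 60,
            f"pairs: {len(self.model.y)}   features: {len(self.features)}"
            f"   alpha: {self.alpha:g}",
            f"test RMSE (mean +- SD over {self.evaluation.n_values} split "
            f"evaluations): {self.rmse_mean:.4f} +- {self.evaluation.sd_rmse:.4f}",
            f"baseline RMSE (train-mean predictor): "
            f"{self.baseline_mean:.4f} +- {self.evaluation.sd_baseline:.4f}",
            f"paired t-test p-value: {self.p_value:.3g}",
            "-" * 60,
            f"{'feature':<24}{'coef (standardized)':>20}",
        ]
        for f, c in self.params.items():
            lines.append(f"{f:<24}{c:>20.5f}")
        return "\n".join(lines)
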