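"""Connectome-based predictive modeling (CPM).

CPM predicts a continuous behavior from functional connectivity edges with
a cross-validated, mass-univariate pipeline.  Within each training fold:

1. the target is residualized on confound covariates (OLS with intercept,
   coefficients estimated on training subjects only);
2. every edge is correlated (Pearson) with the residualized target and
   edges with |r| above a threshold (default 0.2) are selected, split into
   a positive and a negative tail by the sign of the correlation;
3. each subject's selected edge values are summed into positive and
   negative network-strength scores;
4. a linear model maps strengths to the target and is applied to the
   held-out fold.

Prediction accuracy is the Spearman correlation between observed
(residualized) and predicted scores across all subjects; the k-fold run is
repeated over many fold shuffles, significance comes from permuting
behavior against the connectomes, and edges selected in at least a given
fraction (default 97%) of all models form the robust mask reusable as the
feature set of a second-stage ("masked") CPM.

:class:`CPMRegressor` exposes steps 2-4 as a scikit-learn estimator;
:func:`run_cpm`, :func:`permutation_test`, :func:`robust_edges` and
:func:`lobewise_summary` implement the full analysis around it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .connectome import EdgeIndexMap
from .synthio import SubjectDataset

logger = logging.getLogger(__name__)

MODEL_MODES = ("combined", "positive", "negative")


# ---------------------------------------------------------------------------
# small data types


@dataclass(frozen=True)
class EdgeMask:
    """Disjoint positive- and negative-tail edge index sets."""

    positive: np.ndarray
    negative: np.ndarray

    def __post_init__(self) -> None:
        pos = np.unique(np.asarray(self.positive, dtype=int))
        neg = np.unique(np.asarray(self.negative, dtype=int))
        if np.intersect1d(pos, neg).size:
            raise ValueError("positive and negative edge sets must be disjoint")
        object.__setattr__(self, "positive", pos)
        object.__setattr__(self, "negative", neg)

    @property
    def union(self) -> np.ndarray:
        return np.union1d(self.positive, self.negative)

    @property
    def n_edges(self) -> int:
        return self.positive.size + self.negative.size

    def to_frame(self, index_map: EdgeIndexMap) -> pd.DataFrame:
        labels = np.asarray(index_map.edge_labels())
        return pd.DataFrame(
            {
                "edge": np.concatenate([labels[self.positive], labels[self.negative]]),
                "edge_index": np.concatenate([self.positive, self.negative]),
                "tail": ["positive"] * self.positive.size
                + ["negative"] * self.negative.size,
            }
        )


@dataclass(frozen=True)
class CPMConfig:
    """Tunable parameters of the CPM pipeline (defaults follow the standard
    protocol: |r| > 0.2 selection, 10-fold CV, 100 fold shuffles, 1000
    permutations, 97% robustness)."""

    threshold: float = 0.2
    k_folds: int = 10
    n_iterations: int = 100
    n_permutations: int = 1000
    robustness: float = 0.97
    model_mode: str = "combined"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0 < self.robustness <= 1:
            raise ValueError("robustness must lie in (0, 1]")
        if self.model_mode not in MODEL_MODES + ("separate_tails",):
            raise ValueError(f"model_mode must be one of {MODEL_MODES + ('separate_tails',)}")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must lie in [0, 2^31)")


@dataclass
class CPMResult:
    """Output of :func:`run_cpm`.

    ``predictions`` and ``observed_residuals`` are (n_iterations,
    n_subjects); selection frequencies are per-fold means averaged over
    iterations, one entry per edge of the full edge space.
    """

    accuracies: np.ndarray
    predictions: np.ndarray
    observed_residuals: np.ndarray
    pos_frequency: np.ndarray
    neg_frequency: np.ndarray
    config: CPMConfig
    feature_mask: EdgeMask | None = None

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.accuracies))


@dataclass
class SeparateTailsResult:
    """Per-tail CPM results for the separate-tails model mode."""

    positive: CPMResult
    negative: CPMResult


@dataclass
class PermutationResult:
    """Null accuracies and the non-parametric p-value."""

    null_accuracies: np.ndarray
    observed_median: float
    p_value: float


# ---------------------------------------------------------------------------
# elementary operations


def residualize(target: np.ndarray, confounds: np.ndarray | None = None) -> np.ndarray:
    """Residuals of the target after OLS on the confounds (with intercept).

    With no confounds the residuals are the mean-centered target.  The
    returned residuals are orthogonal to every confound column.
    """
    y = np.asarray(target, dtype=float)
    A = _augment(confounds, y.shape[0])
    _check_full_rank(A, confounds)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ beta


def _augment(confounds: np.ndarray | None, n: int) -> np.ndarray:
    if confounds is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(confounds, dtype=float))
    if C.shape[0] != n:
        C = C.T
    if C.shape[0] != n:
        raise ValueError("confounds must have one row per subject")
    return np.column_stack([np.ones(n), C])


def _check_full_rank(A: np.ndarray, confounds: np.ndarray | None) -> None:
    if np.linalg.matrix_rank(A) < A.shape[1]:
        # locate offending columns by incremental rank
        bad = []
        kept = A[:, :1]
        for j in range(1, A.shape[1]):
            cand = np.column_stack([kept, A[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(j - 1)  # 0-based confound column
            else:
                kept = cand
        raise ValueError(f"confound matrix rank-deficient; collinear columns: {bad}")


def select_edges(
    train_edges: np.ndarray, train_target: np.ndarray, threshold: float = 0.2
) -> EdgeMask:
    """Mass-univariate edge selection on training data.

    Edge k joins the positive tail iff pearson(edge_k, target) > threshold
    and the negative tail iff it is < -threshold (strict inequalities; an
    exact tie at the threshold is excluded).  Zero-variance edges are
    unselectable and logged.
    """
    X = np.asarray(train_edges, dtype=float)
    y = np.asarray(train_target, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 training subjects")
    r = _edge_correlations(X, y[:, None])[:, 0]
    return EdgeMask(np.flatnonzero(r > threshold), np.flatnonzero(r < -threshold))


def _edge_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of X with every column of Y.

    Returns (p, m).  Zero-variance columns on either side yield 0 (treated
    as unselectable)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    xn = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    yn = np.sqrt(np.einsum("ij,ij->j", Yc, Yc))
    if np.any(xn == 0):
        logger.debug("%d zero-variance edges are unselectable", int((xn == 0).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc.T @ Yc) / np.outer(xn, yn)
    return np.nan_to_num(R, nan=0.0, posinf=0.0, neginf=0.0)


def network_strength(edge_vector: np.ndarray, mask: EdgeMask) -> tuple[float, float]:
    """Sum of a subject's edge values over each tail of the mask."""
    x = np.asarray(edge_vector, dtype=float)
    return float(x[mask.positive].sum()), float(x[mask.negative].sum())


def fit_strength_model(
    strengths: np.ndarray, target: np.ndarray
) -> np.ndarray:
    """OLS coefficients of target on network strengths (intercept first).

    ``strengths`` is (n, q) with one column per strength predictor.
    Rank-deficient designs (e.g. an empty tail giving a constant-zero
    column) fall back to the minimum-norm solution, which drops the
    degenerate predictor from the fit.
    """
    S = np.atleast_2d(np.asarray(strengths, dtype=float))
    if S.shape[0] == 1 and S.shape[1] > 1 and len(np.asarray(target)) == S.shape[1]:
        S = S.T
    y = np.asarray(target, dtype=float)
    if S.shape[0] < 3:
        raise ValueError("need at least 3 training subjects")
    A = np.column_stack([np.ones(S.shape[0]), S])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


# ---------------------------------------------------------------------------
# scikit-learn estimator


class CPMRegressor(BaseEstimator, RegressorMixin):
    """Single-fit CPM model: edge selection plus network-strength OLS.

    This is the model CPM fits inside each training fold, packaged as a
    scikit-learn regressor so it composes with pipelines and model
    selection.  ``X`` is a subjects x edges matrix of Fisher-z values and
    ``y`` the (already residualized) behavior.

    Parameters
    ----------
    threshold : float, default=0.2
        |r| cutoff for mass-univariate edge selection.
    model_mode : {"combined", "positive", "negative"}, default="combined"
        "combined" fits one linear model with both tail strengths as
        predictors; "positive"/"negative" use a single tail.

    Attributes
    ----------
    mask_ : EdgeMask
        Selected positive/negative edge indices.
    coef_ : ndarray
        Strength-model coefficients (without intercept).
    intercept_ : float
    """

    def __init__(self, threshold: float = 0.2, model_mode: str = "combined"):
        self.threshold = threshold
        self.model_mode = model_mode

    def _strengths(self, X: np.ndarray, mask: EdgeMask) -> np.ndarray:
        cols = []
        if self.model_mode in ("combined", "positive"):
            cols.append(X[:, mask.positive].sum(axis=1))
        if self.model_mode in ("combined", "negative"):
            cols.append(X[:, mask.negative].sum(axis=1))
        return np.column_stack(cols)

    def fit(self, X, y):
        if self.model_mode not in MODEL_MODES:
            raise ValueError(f"model_mode must be one of {MODEL_MODES}")
        X, y = check_X_y(X, y, y_numeric=True)
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        self.mask_ = select_edges(X, y, self.threshold)
        S = self._strengths(X, self.mask_)
        coef = fit_strength_model(S, y)
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "mask_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of edges than at fit time")
        return self.intercept_ + self._strengths(X, self.mask_) @ self.coef_


# ---------------------------------------------------------------------------
# cross-validated pipeline


def make_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded uniform shuffle then contiguous chunking into k folds whose
    sizes differ by at most one."""
    if n < k:
        raise ValueError(f"cannot split {n} subjects into {k} folds")
    return np.array_split(rng.permutation(n), k)


def _spearman_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Spearman correlation (average ranks for ties)."""
    ra = rankdata(A, axis=0)
    rb = rankdata(B, axis=0)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    num = np.einsum("ij,ij->j", ra, rb)
    den = np.sqrt(np.einsum("ij,ij->j", ra, ra) * np.einsum("ij,ij->j", rb, rb))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.nan_to_num(out, nan=0.0)


def _cv_once(
    X: np.ndarray,
    Y: np.ndarray,
    C: np.ndarray | None,
    folds: list[np.ndarray],
    threshold: float,
    model_mode: str,
):
    """One k-fold CV pass, vectorized over the m target columns of Y.

    ``C`` is None, (n, q) shared across targets, or (n, q, m) per-target
    (used when permutations shuffle behavior and confounds jointly).
    Returns (accuracies (m,), predictions (n, m), observed residuals
    (n, m), positive and negative selection counts (p, m)).
    """
    n, p = X.shape
    m = Y.shape[1]
    preds = np.zeros((n, m))
    resid_obs = np.zeros((n, m))
    pos_counts = np.zeros((p, m))
    neg_counts = np.zeros((p, m))
    per_target_conf = C is not None and C.ndim == 3

    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx, assume_unique=False)
        Xtr, Xte = X[train_idx], X[test_idx]
        r_tr = np.empty((train_idx.size, m))
        r_te = np.empty((test_idx.size, m))
        for j in range(m):
            Cj = None if C is None else (C[:, :, j] if per_target_conf else C)
            Atr = _augment(None if Cj is None else Cj[train_idx], train_idx.size)
            Ate = _augment(None if Cj is None else Cj[test_idx], test_idx.size)
            beta, *_ = np.linalg.lstsq(Atr, Y[train_idx, j], rcond=None)
            r_tr[:, j] = Y[train_idx, j] - Atr @ beta
            r_te[:, j] = Y[test_idx, j] - Ate @ beta
        R = _edge_correlations(Xtr, r_tr)  # (p, m)
        pos = R > threshold
        neg = R < -threshold
        pos_counts += pos
        neg_counts += neg
        pos_f = pos.astype(float)
        neg_f = neg.astype(float)
        design_tr, design_te = [], []
        if model_mode in ("combined", "positive"):
            design_tr.append(Xtr @ pos_f)
            design_te.append(Xte @ pos_f)
        if model_mode in ("combined", "negative"):
            design_tr.append(Xtr @ neg_f)
            design_te.append(Xte @ neg_f)
        ones_tr = np.ones(train_idx.size)
        ones_te = np.ones(test_idx.size)
        for j in range(m):
            A = np.column_stack([ones_tr] + [d[:, j] for d in design_tr])
            coef, *_ = np.linalg.lstsq(A, r_tr[:, j], rcond=None)
            Ate = np.column_stack([ones_te] + [d[:, j] for d in design_te])
            preds[test_idx, j] = Ate @ coef
        resid_obs[test_idx] = r_te
    acc = _spearman_columns(resid_obs, preds)
    return acc, preds, resid_obs, pos_counts, neg_counts


def _as_confound_array(data: SubjectDataset, confounds) -> np.ndarray | None:
    """Resolve a confound specification (None, column names, or array)."""
    if confounds is None:
        return None
    if isinstance(confounds, (list, tuple)) and all(isinstance(c, str) for c in confounds):
        pool = data.confounds
        if data.traits is not None:
            pool = pd.concat([pool, data.traits], axis=1)
        missing = [c for c in confounds if c not in pool.columns]
        if missing:
            raise ValueError(f"unknown confound columns: {missing}")
        return pool[list(confounds)].to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(confounds, dtype=float)).reshape(data.n_subjects, -1)


def run_cpm(
    data: SubjectDataset,
    config: CPMConfig = CPMConfig(),
    feature_mask: EdgeMask | None = None,
    *,
    target: np.ndarray | str | None = None,
    confounds=None,
) -> CPMResult | SeparateTailsResult:
    """Repeated k-fold CPM.

    Parameters
    ----------
    data : SubjectDataset
    config : CPMConfig
    feature_mask : EdgeMask, optional
        Restrict candidate edges to this mask (second-stage "masked" CPM,
        e.g. predicting trait scores from a previously identified
        network).  Selection frequencies are still reported in the full
        edge space.
    target : array, trait-column name, or None
        Defaults to ``data.behavior``.
    confounds : None, list of column names, or array
        Covariates whose linear contribution is removed from the target
        within each training fold.  Column names are looked up in
        ``data.confounds`` and ``data.traits``.

    Iteration i shuffles subjects into folds with seed ``config.seed + i``,
    so results are reproducible edge-for-edge given the config.
    """
    if config.model_mode == "separate_tails":
        return SeparateTailsResult(
            positive=run_cpm(
                data, replace(config, model_mode="positive"), feature_mask,
                target=target, confounds=confounds,
            ),
            negative=run_cpm(
                data, replace(config, model_mode="negative"), feature_mask,
                target=target, confounds=confounds,
            ),
        )
    y = _resolve_target(data, target)
    C = _as_confound_array(data, confounds)
    X, back = _masked_edges(data, feature_mask)
    n, p_full = data.n_subjects, data.n_edges
    if n < config.k_folds:
        raise ValueError(f"{n} subjects cannot fill {config.k_folds} folds")
    accs = np.empty(config.n_iterations)
    preds = np.empty((config.n_iterations, n))
    resid = np.empty((config.n_iterations, n))
    pos_freq = np.zeros(p_full)
    neg_freq = np.zeros(p_full)
    for i in range(config.n_iterations):
        rng = np.random.default_rng(config.seed + i)
        folds = make_folds(n, config.k_folds, rng)
        acc, pr, ro, pc, nc = _cv_once(
            X, y[:, None], C, folds, config.threshold, config.model_mode
        )
        accs[i] = acc[0]
        preds[i] = pr[:, 0]
        resid[i] = ro[:, 0]
        pos_freq[back] += pc[:, 0] / config.k_folds
        neg_freq[back] += nc[:, 0] / config.k_folds
    pos_freq /= config.n_iterations
    neg_freq /= config.n_iterations
    return CPMResult(
        accuracies=accs,
        predictions=preds,
        observed_residuals=resid,
        pos_frequency=pos_freq,
        neg_frequency=neg_freq,
        config=config,
        feature_mask=feature_mask,
    )


def _resolve_target(data: SubjectDataset, target) -> np.ndarray:
    if target is None:
        return np.asarray(data.behavior, dtype=float)
    if isinstance(target, str):
        if data.traits is None or target not in data.traits.columns:
            raise ValueError(f"unknown trait target {target!r}")
        return data.traits[target].to_numpy(dtype=float)
    return np.asarray(target, dtype=float)


def _masked_edges(
    data: SubjectDataset, feature_mask: EdgeMask | None
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate edge matrix and the map from its columns back to full
    edge indices."""
    if feature_mask is None:
        return data.edges, np.arange(data.n_edges)
    back = feature_mask.union
    if back.size == 0:
        raise ValueError("feature mask is empty")
    if back.max() >= data.n_edges:
        raise ValueError("feature mask indexes edges outside the dataset")
    return data.edges[:, back], back


def permutation_test(
    data: SubjectDataset,
    config: CPMConfig,
    observed: CPMResult,
    *,
    target: np.ndarray | str | None = None,
    confounds=None,
    feature_mask: EdgeMask | None = None,
    counting: str = "plus_one",
    independent_splits: bool = False,
) -> PermutationResult:
    """Permutation-based significance of a CPM result.

    Each of ``config.n_permutations`` randomizations shuffles the behavior
    (with its confound rows attached, so only the brain-behavior link is
    broken) against the connectomes and re-runs one full k-fold CV; the
    p-value counts null accuracies that reach the median observed
    accuracy.

    ``counting="plus_one"`` (default) uses (1 + count) / (n + 1), which is
    a valid test with p > 0; ``counting="paper"`` uses the plain
    count / n convention.  By default all permutations share one seeded
    fold split (the null accuracy distribution is invariant to the split;
    this allows vectorizing across permutations); ``independent_splits``
    re-splits per permutation.
    """
    if config.model_mode not in MODEL_MODES:
        raise ValueError("permutation_test needs a single-model mode")
    if config.n_permutations < 20:
        logger.warning(
            "n_permutations=%d gives coarse p-value resolution", config.n_permutations
        )
    y = _resolve_target(data, target)
    C = _as_confound_array(data, confounds)
    X, _ = _masked_edges(data, feature_mask)
    n = data.n_subjects
    rng = np.random.default_rng(config.seed + 1_000_003)
    nperm = config.n_permutations
    perms = np.stack([rng.permutation(n) for _ in range(nperm)], axis=1)  # (n, nperm)
    Y = y[perms]
    Cp = None if C is None else C[perms].transpose(0, 2, 1)  # (n, q, nperm)
    if independent_splits:
        null = np.empty(nperm)
        for j in range(nperm):
            folds = make_folds(n, config.k_folds, np.random.default_rng(config.seed + 2_000_003 + j))
            Cj = None if Cp is None else Cp[:, :, [j]]
            null[j] = _cv_once(
                X, Y[:, [j]], Cj, folds, config.threshold, config.model_mode
            )[0][0]
    else:
        folds = make_folds(n, config.k_folds, np.random.default_rng(config.seed + 2_000_003))
        null = _cv_once(X, Y, Cp, folds, config.threshold, config.model_mode)[0]
    med = observed.median_accuracy
    count = int(np.sum(null >= med))
    if counting == "paper":
        p = count / nperm if count else 1.0 / (nperm + 1)
    elif counting == "plus_one":
        p = (1 + count) / (nperm + 1)
    else:
        raise ValueError("counting must be 'plus_one' or 'paper'")
    return PermutationResult(null_accuracies=null, observed_median=med, p_value=float(p))


def robust_edges(result: CPMResult, fraction: float | None = None) -> EdgeMask:
    """Edges whose per-tail mean selection frequency reaches ``fraction``
    (default: the config's robustness, 0.97)."""
    frac = result.config.robustness if fraction is None else fraction
    if frac > 0:
        pos = np.flatnonzero(result.pos_frequency >= frac)
        neg = np.flatnonzero(result.neg_frequency >= frac)
    else:  # fraction 0: every edge ever selected
        pos = np.flatnonzero(result.pos_frequency > 0)
        neg = np.flatnonzero(result.neg_frequency > 0)
    both = np.intersect1d(pos, neg)
    if both.size:
        # keep each shared edge in its more frequent tail
        keep_pos = result.pos_frequency[both] >= result.neg_frequency[both]
        pos = np.setdiff1d(pos, both[~keep_pos])
        neg = np.setdiff1d(neg, both[keep_pos])
    return EdgeMask(pos, neg)


# ---------------------------------------------------------------------------
# anatomical summaries


@dataclass
class LobewiseSummary:
    """Edge counts between macroscale region pairs and node degrees."""

    pair_counts: pd.DataFrame
    degrees: pd.DataFrame
    key_nodes: pd.DataFrame


def lobewise_summary(
    mask: EdgeMask,
    atlas: pd.DataFrame,
    index_map: EdgeIndexMap,
    *,
    top_m: int = 12,
) -> LobewiseSummary:
    """Summarize a mask anatomically.

    For every unordered lobe pair and each tail: the count of mask edges,
    and that count standardized by the number of possible edges between
    the pair.  Per-node degree K (incident mask edges) is reported per
    tail, with the top ``top_m`` key nodes joined to atlas metadata.
    """
    if len(atlas) != index_map.n_nodes:
        raise ValueError("atlas does not cover all nodes")
    atlas = atlas.sort_values("node_id").reset_index(drop=True)
    lobes = atlas["lobe"].to_numpy()
    if pd.isna(lobes).any():
        raise ValueError(
            f"nodes without lobe label: {atlas.loc[pd.isna(lobes), 'node_id'].tolist()}"
        )
    n_per_lobe = atlas["lobe"].value_counts().to_dict()
    unique_lobes = sorted(n_per_lobe)
    rows_all, cols_all = index_map.pairs()

    def possible(a: str, b: str) -> int:
        if a == b:
            return n_per_lobe[a] * (n_per_lobe[a] - 1) // 2
        return n_per_lobe[a] * n_per_lobe[b]

    pair_rows = []
    degree = {t: np.zeros(index_map.n_nodes, dtype=int) for t in ("positive", "negative")}
    for tail, idx in (("positive", mask.positive), ("negative", mask.negative)):
        i, j = rows_all[idx], cols_all[idx]
        np.add.at(degree[tail], i, 1)
        np.add.at(degree[tail], j, 1)
        pair_keys = [tuple(sorted((lobes[a], lobes[b]))) for a, b in zip(i, j)]
        counts = pd.Series(pair_keys).value_counts().to_dict() if pair_keys else {}
        for ai, a in enumerate(unique_lobes):
            for b in unique_lobes[ai:]:
                c = counts.get((a, b), 0)
                pos_pairs = possible(a, b)
                pair_rows.append(
                    {
                        "lobe_a": a,
                        "lobe_b": b,
                        "tail": tail,
                        "count": c,
                        "possible": pos_pairs,
                        "standardized": c / pos_pairs if pos_pairs else 0.0,
                    }
                )
    pair_counts = pd.DataFrame(pair_rows)
    degrees = atlas[["node_id", "name", "lobe"]].copy()
    degrees["K_positive"] = degree["positive"]
    degrees["K_negative"] = degree["negative"]
    key_rows = []
    for tail in ("positive", "negative"):
        k = degree[tail]
        order = np.argsort(-k, kind="stable")[:top_m]
        tab = atlas.iloc[order].copy()
        tab.insert(2, "K", k[order])
        tab.insert(0, "tail", tail)
        key_rows.append(tab)
    return LobewiseSummary(
        pair_counts=pair_counts,
        degrees=degrees,
        key_nodes=pd.concat(key_rows, ignore_index=True),
    )
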