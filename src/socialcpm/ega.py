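"""Exploratory graph analysis (EGA) of questionnaire items.

EGA assesses the dimensionality of item-response data by estimating a
sparse regularized partial-correlation network among items (graphical
lasso with EBIC penalty selection) and reading latent dimensions off the
network's communities (Louvain modularity maximization).  The bootstrap
variant (bootEGA) draws parametric replicates from a multivariate normal
with the estimated item correlations, runs EGA on each, forms a "typical"
network from the entrywise median of the replicate networks, and
summarizes structural consistency as item stability: the proportion of
replicates in which each item lands in each (label-aligned) community.
Participant-level community scores are weighted sums of member items
(weights proportional to within-community node strength), standardized.

Item-level associations are plain Pearson correlations with pairwise
deletion; this matches the multivariate-normal bootstrap generative model
(a polychoric option would be the natural extension for coarse ordinal
scales).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

from .synthio import ItemResponseMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlations


def pairwise_correlation(data: pd.DataFrame | ItemResponseMatrix) -> pd.DataFrame:
    """Item correlation matrix under pairwise deletion.

    Each entry is the Pearson correlation over participants observed on
    both items.  Every item pair must share at least 3 jointly observed
    participants.  If pairwise deletion leaves the matrix indefinite, the
    nearest positive-semidefinite repair (eigenvalue clipping with
    rediagonalization to unit diagonal) is applied and logged.
    """
    df = data.responses if isinstance(data, ItemResponseMatrix) else data
    obs = df.notna().to_numpy()
    joint = obs.T.astype(int) @ obs.astype(int)
    short = np.argwhere(np.triu(joint < 3, k=1))
    if short.size:
        i, j = short[0]
        raise ValueError(
            f"items {df.columns[i]!r} and {df.columns[j]!r} share only "
            f"{joint[i, j]} jointly observed participants (need >= 3)"
        )
    corr = df.corr(method="pearson", min_periods=3)
    if corr.isna().to_numpy().any():
        bad = corr.columns[corr.isna().any()].tolist()
        raise ValueError(f"undefined correlations (constant items?): {bad}")
    c = _nearest_psd(corr.to_numpy())
    return pd.DataFrame(c, index=corr.index, columns=corr.columns)


def _nearest_psd(c: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    w, v = np.linalg.eigh((c + c.T) / 2)
    if w.min() >= 0:
        return (c + c.T) / 2
    logger.info("pairwise-deleted correlation indefinite (min eig %.3g); clipping", w.min())
    w = np.clip(w, eps, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return (c + c.T) / 2


# ---------------------------------------------------------------------------
# GLASSO + EBIC


def glasso_network(
    corr: np.ndarray | pd.DataFrame,
    n_effective: int,
    *,
    gamma: float = 0.5,
    n_alphas: int = 30,
    min_ratio: float = 0.05,
    tol: float = 5e-3,
    max_iter: int = 60,
    patience: int = 4,
) -> tuple[np.ndarray, float]:
    """Sparse partial-correlation network via graphical lasso with EBIC
    penalty selection.

    The penalty path descends logarithmically from the largest absolute
    off-diagonal correlation (above which the network is empty) to
    ``min_ratio`` times it.  For each penalty the extended BIC is

        EBIC = -n (logdet T - tr(S T)) + E log n + 4 gamma E log p

    with T the precision estimate and E its number of nonzero
    off-diagonal edges; the path stops early once EBIC has not improved
    for ``patience`` consecutive penalties (it is quasi-convex along the
    path, and the dense small-penalty fits are by far the slowest).
    Returns (partial-correlation weights with zero diagonal, chosen
    penalty).
    """
    S = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    p = S.shape[0]
    amax = float(np.max(np.abs(S - np.diag(np.diag(S)))))
    if amax == 0:
        return np.zeros_like(S), np.inf
    alphas = np.logspace(np.log10(amax), np.log10(amax * min_ratio), n_alphas)
    best_ebic, best_alpha, best_prec = np.inf, None, None
    worse = 0
    failures = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for a in alphas:
            try:
                _, prec = graphical_lasso(S, float(a), tol=tol, max_iter=max_iter)
            except (FloatingPointError, np.linalg.LinAlgError) as err:
                failures.append((float(a), str(err)))
                continue
            n_edges = int(np.count_nonzero(np.triu(prec, k=1)))
            _, logdet = np.linalg.slogdet(prec)
            ebic = (
                -n_effective * (logdet - np.trace(S @ prec))
                + n_edges * np.log(n_effective)
                + 4.0 * gamma * n_edges * np.log(p)
            )
            if ebic < best_ebic:
                best_ebic, best_alpha, best_prec = ebic, float(a), prec
                worse = 0
            else:
                worse += 1
                if worse >= patience:
                    break
    if best_prec is None:
        raise RuntimeError(f"graphical lasso failed at every penalty: {failures}")
    d = np.sqrt(np.diag(best_prec))
    pcor = -best_prec / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return (pcor + pcor.T) / 2, best_alpha


def louvain_memberships(
    network: np.ndarray, seed: int = 0, resolution: float = 1.0
) -> np.ndarray:
    """Community membership by Louvain modularity maximization.

    Modularity is defined for nonnegative weights, so the algorithm runs
    on absolute edge weights (signs stay in the network itself).  Items
    with no edges become singleton communities.  Deterministic given seed.
    """
    W = np.abs(np.asarray(network, dtype=float))
    if not np.count_nonzero(W):
        logger.warning("empty network: every item is its own community")
        return np.arange(W.shape[0])
    G = nx.from_numpy_array(W)
    comms = nx.community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: min(c))
    memb = np.empty(W.shape[0], dtype=int)
    for ci, members in enumerate(comms):
        for i in members:
            memb[i] = ci
    return memb


def scree(corr: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Descending eigenvalues of the item correlation matrix (a simple
    dimensionality diagnostic alongside the network communities)."""
    S = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    return np.sort(np.linalg.eigvalsh(S))[::-1]


# ---------------------------------------------------------------------------
# estimators


@dataclass
class EGAResult:
    """Bootstrap EGA output.

    ``item_stability`` rows give, per item, the proportion of replicates
    in which it was assigned to each typical-network community; rows sum
    to 1 minus the (reported) mass of replicate communities that could not
    be aligned to any typical community.
    """

    typical_network: pd.DataFrame
    membership: pd.Series
    n_communities: int
    replicate_counts: np.ndarray
    item_stability: pd.DataFrame
    unmatched_mass: pd.Series
    glasso_alpha: float


class EGA(BaseEstimator):
    """Single-sample exploratory graph analysis.

    fit(X) estimates the pairwise-deletion correlation matrix, the EBIC
    graphical-lasso network and the Louvain communities of X (a
    participants x items frame; NaN marks missing responses).

    Attributes
    ----------
    correlation_ : DataFrame
    network_ : DataFrame of partial-correlation weights (zero diagonal)
    membership_ : Series mapping item -> community index
    n_communities_ : int
    alpha_ : float, selected graphical-lasso penalty
    """

    def __init__(
        self,
        gamma: float = 0.5,
        n_alphas: int = 30,
        min_ratio: float = 0.05,
        resolution: float = 1.0,
        seed: int = 0,
    ):
        self.gamma = gamma
        self.n_alphas = n_alphas
        self.min_ratio = min_ratio
        self.resolution = resolution
        self.seed = seed

    def fit(self, X, y=None):
        df = X.responses if isinstance(X, ItemResponseMatrix) else pd.DataFrame(X)
        corr = pairwise_correlation(df)
        net, alpha = glasso_network(
            corr, len(df), gamma=self.gamma, n_alphas=self.n_alphas,
            min_ratio=self.min_ratio,
        )
        memb = louvain_memberships(net, seed=self.seed, resolution=self.resolution)
        self.correlation_ = corr
        self.network_ = pd.DataFrame(net, index=corr.index, columns=corr.columns)
        self.membership_ = pd.Series(memb, index=corr.index, name="community")
        self.n_communities_ = int(memb.max()) + 1
        self.alpha_ = alpha
        return self


def _align(replicate: np.ndarray, reference: np.ndarray, n_ref: int) -> np.ndarray:
    """Relabel replicate communities to best match the reference partition
    (maximum-overlap Hungarian matching).  Unmatched replicate communities
    get label -1."""
    n_rep = int(replicate.max()) + 1
    overlap = np.zeros((n_rep, n_ref))
    for c_rep in range(n_rep):
        members = replicate == c_rep
        for c_ref in range(n_ref):
            overlap[c_rep, c_ref] = np.sum(members & (reference == c_ref))
    rows, cols = linear_sum_assignment(-overlap)
    mapping = np.full(n_rep, -1)
    mapping[rows] = cols
    return mapping[replicate]


class BootEGA(BaseEstimator):
    """Parametric bootstrap EGA.

    fit(X): estimate the item correlation matrix of X, draw ``n_boot``
    multivariate-normal replicate samples of the original size, run EGA on
    each, take the entrywise median of the replicate networks as the
    typical network, define final membership by Louvain on the typical
    network, and compute item stability by aligning every replicate
    partition to the final one.

    transform(X): standardized network scores per participant x community
    (strength-weighted member items, mean-imputed within item for missing
    entries; participants missing every item of a community score NaN).

    Parameters
    ----------
    n_boot : int, default=500
    max_failure_rate : float
        Error out if more than this fraction of replicates fail.
    """

    def __init__(
        self,
        n_boot: int = 500,
        gamma: float = 0.5,
        n_alphas: int = 30,
        min_ratio: float = 0.05,
        resolution: float = 1.0,
        uniform_weights: bool = False,
        max_failure_rate: float = 0.05,
        seed: int = 0,
    ):
        self.n_boot = n_boot
        self.gamma = gamma
        self.n_alphas = n_alphas
        self.min_ratio = min_ratio
        self.resolution = resolution
        self.uniform_weights = uniform_weights
        self.max_failure_rate = max_failure_rate
        self.seed = seed

    def fit(self, X, y=None):
        df = X.responses if isinstance(X, ItemResponseMatrix) else pd.DataFrame(X)
        items = list(df.columns)
        n, p = df.shape
        corr = pairwise_correlation(df)
        chol = np.linalg.cholesky(corr.to_numpy() + 1e-10 * np.eye(p))
        rng = np.random.default_rng(self.seed)
        networks, memberships = [], []
        failures = 0
        for _ in range(self.n_boot):
            sample = rng.standard_normal((n, p)) @ chol.T
            S = np.corrcoef(sample, rowvar=False)
            try:
                net, _ = glasso_network(
                    S, n, gamma=self.gamma, n_alphas=self.n_alphas,
                    min_ratio=self.min_ratio,
                )
            except RuntimeError:
                failures += 1
                continue
            networks.append(net)
            memberships.append(
                louvain_memberships(net, seed=self.seed, resolution=self.resolution)
            )
        if failures > self.max_failure_rate * self.n_boot:
            raise RuntimeError(
                f"{failures}/{self.n_boot} bootstrap replicates failed"
            )
        typical = np.median(np.stack(networks), axis=0)
        memb = louvain_memberships(typical, seed=self.seed, resolution=self.resolution)
        n_comm = int(memb.max()) + 1
        stability = np.zeros((p, n_comm))
        unmatched = np.zeros(p)
        for rep in memberships:
            aligned = _align(rep, memb, n_comm)
            for c in range(n_comm):
                stability[:, c] += aligned == c
            unmatched += aligned == -1
        n_ok = len(memberships)
        self.result_ = EGAResult(
            typical_network=pd.DataFrame(typical, index=items, columns=items),
            membership=pd.Series(memb, index=items, name="community"),
            n_communities=n_comm,
            replicate_counts=np.array([int(m.max()) + 1 for m in memberships]),
            item_stability=pd.DataFrame(
                stability / n_ok, index=items,
                columns=[f"community{c}" for c in range(n_comm)],
            ),
            unmatched_mass=pd.Series(unmatched / n_ok, index=items, name="unmatched"),
            glasso_alpha=float("nan"),
        )
        self.correlation_ = corr
        self.typical_network_ = self.result_.typical_network
        self.membership_ = self.result_.membership
        self.n_communities_ = n_comm
        self.item_stability_ = self.result_.item_stability
        self.n_failures_ = failures
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "result_")
        df = X.responses if isinstance(X, ItemResponseMatrix) else pd.DataFrame(X)
        return network_scores(df, self.result_, uniform_weights=self.uniform_weights)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def bootega(
    data: pd.DataFrame | ItemResponseMatrix, n_boot: int = 500, seed: int = 0, **kwargs
) -> EGAResult:
    """Functional wrapper around :class:`BootEGA`."""
    return BootEGA(n_boot=n_boot, seed=seed, **kwargs).fit(data).result_


def network_scores(
    data: pd.DataFrame | ItemResponseMatrix,
    result: EGAResult,
    *,
    uniform_weights: bool = False,
) -> pd.DataFrame:
    """Standardized community network scores.

    Per community, item weights are each member item's within-community
    strength (sum of absolute typical-network weights to the other
    members), normalized to sum to 1; with ``uniform_weights`` every
    member item weighs equally.  A participant's score is the weighted sum
    of their observed member-item responses, mean-imputed within item for
    missing entries, then standardized to mean 0 and sd 1 over scored
    participants.  Participants missing every item of a community get NaN.
    """
    df = data.responses if isinstance(data, ItemResponseMatrix) else pd.DataFrame(data)
    W = result.typical_network
    items = list(W.index)
    missing_items = [i for i in items if i not in df.columns]
    if missing_items:
        raise ValueError(f"data lacks scored items: {missing_items}")
    X = df[items].to_numpy(dtype=float)
    memb = result.membership.to_numpy()
    scores = {}
    for c in range(result.n_communities):
        members = np.flatnonzero(memb == c)
        if members.size == 1:
            logger.warning(
                "community %d has a single item %r (weight 1)", c, items[members[0]]
            )
            w = np.ones(1)
        elif uniform_weights:
            w = np.full(members.size, 1.0 / members.size)
        else:
            sub = np.abs(W.to_numpy()[np.ix_(members, members)])
            strength = sub.sum(axis=0)
            if strength.sum() == 0:
                w = np.full(members.size, 1.0 / members.size)
            else:
                w = strength / strength.sum()
        Xm = X[:, members]
        col_mean = np.nanmean(Xm, axis=0)
        n_imputed = int(np.isnan(Xm).sum())
        if n_imputed:
            logger.debug("community %d: mean-imputing %d missing entries", c, n_imputed)
        all_missing = np.isnan(Xm).all(axis=1)
        Xm = np.where(np.isnan(Xm), col_mean, Xm)
        s = Xm @ w
        s[all_missing] = np.nan
        mu, sd = np.nanmean(s), np.nanstd(s)
        scores[f"community{c}"] = (s - mu) / sd if sd > 0 else s - mu
    return pd.DataFrame(scores, index=df.index)
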