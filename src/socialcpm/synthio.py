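"""Synthetic inputs with the statistical structure the analysis assumes.

No public dataset accompanies the study design this package implements, so
every downstream stage is exercised on simulated data with known ground
truth:

* subjects x edges Fisher-z connectivity matrices in which a planted edge
  subset correlates with a continuous behavior, plus an optional
  motion-like confound (:func:`simulate_cpm_dataset`);
* one-back task runs from an equal-variance Gaussian observer with known
  sensitivity (:func:`simulate_task_trials`);
* ordinal questionnaire items loading on three correlated latent
  communities, with missing-at-random entries
  (:func:`simulate_questionnaire`);
* trait scores correlated like the questionnaire communities, of which
  exactly one shares planted edges with the behavior
  (:func:`simulate_correlated_traits`).

All generators are deterministic given their seed.  Edge signal is planted
directly on the Fisher-z edge values (CPM consumes edge vectors, and direct
planting gives controllable per-edge effect sizes); an optional latent
timecourse generator (:func:`simulate_node_timeseries`) provides correlated
node signals for connectivity-stage integration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .connectome import LOBES, EdgeIndexMap

_NETWORKS = (
    "Visual I",
    "Visual II",
    "Visual association",
    "Default mode",
    "Fronto-parietal",
    "Medial frontal",
    "Motor",
    "Basal ganglia",
    "Limbic",
    "Cerebellum",
)


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class PlantedSignalSpec:
    """Generating model for a subjects x edges CPM dataset.

    Defaults mirror the imaging study this package models: 67 subjects, a
    268-node parcellation, and a motion confound correlating with behavior
    at r = -0.30.  ``signal_edges`` is empty by default (null data).
    """

    n_subjects: int = 67
    n_nodes: int = 268
    signal_edges: tuple[int, ...] = ()
    effect_size: float = 0.5
    noise_sd: float = 1.0
    confound_r: float = -0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if not abs(self.effect_size) < 1:
            raise ValueError(f"effect_size must lie in (-1, 1), got {self.effect_size}")
        if not abs(self.confound_r) < 1:
            raise ValueError(f"confound_r must lie in (-1, 1), got {self.confound_r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        n_edges = self.n_nodes * (self.n_nodes - 1) // 2
        edges = np.asarray(self.signal_edges, dtype=int)
        if edges.size and (edges.min() < 0 or edges.max() >= n_edges):
            raise ValueError(f"signal_edges must lie in [0, {n_edges})")


@dataclass(frozen=True)
class TaskSpec:
    """Generating model for one-back task runs.

    Defaults follow the task design: six blocks per condition, 10 images
    per block with 4 or 5 "same" trials among the 9 scorable ones, and an
    unbiased equal-variance Gaussian observer.
    """

    n_blocks_per_condition: int = 6
    images_per_block: int = 10
    same_per_block: tuple[int, ...] = (4, 5)
    true_sensitivity: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.images_per_block < 2:
            raise ValueError("images_per_block must be >= 2")
        if max(self.same_per_block) >= self.images_per_block:
            raise ValueError(
                "same_per_block counts must be < images_per_block "
                "(the first image is unscorable)"
            )
        if not np.isfinite(self.true_sensitivity):
            raise ValueError("true_sensitivity must be finite")


def _simple_loadings(n_items: int = 48, n_communities: int = 3, loading: float = 0.65) -> np.ndarray:
    """Simple-structure loading matrix: equal item blocks, one dominant
    community per item."""
    if n_items % n_communities:
        raise ValueError("n_items must divide evenly into communities")
    L = np.zeros((n_items, n_communities))
    per = n_items // n_communities
    for c in range(n_communities):
        L[c * per : (c + 1) * per, c] = loading
    return L


@dataclass(frozen=True)
class LatentSpec:
    """Generating model for ordinal questionnaire items.

    Defaults emulate the trait-questionnaire structure the analysis
    targets: 48 items in three equally sized communities with loadings
    0.65, inter-community latent correlations 0.5 (the communities are
    deliberately non-orthogonal), 4 ordinal categories, and 10%
    missing-completely-at-random entries.
    """

    n_participants: int = 1000
    loading_matrix: np.ndarray = field(default_factory=_simple_loadings)
    community_correlations: np.ndarray = field(
        default_factory=lambda: np.full((3, 3), 0.5) + 0.5 * np.eye(3)
    )
    n_categories: int = 4
    missing_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        L = np.atleast_2d(np.asarray(self.loading_matrix, dtype=float))
        phi = np.atleast_2d(np.asarray(self.community_correlations, dtype=float))
        object.__setattr__(self, "loading_matrix", L)
        object.__setattr__(self, "community_correlations", phi)
        if phi.shape[0] != phi.shape[1] or L.shape[1] != phi.shape[0]:
            raise ValueError("loading_matrix columns must match community_correlations size")
        if not np.allclose(phi, phi.T) or not np.allclose(np.diag(phi), 1.0):
            raise ValueError("community_correlations must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(phi).min() <= 0:
            raise ValueError("community_correlations must be positive definite")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        commun = np.einsum("ic,cd,id->i", L, phi, L)
        if np.any(commun >= 1):
            raise ValueError("item communalities must be < 1 (unit-variance construction)")


# ---------------------------------------------------------------------------
# containers


@dataclass
class SubjectDataset:
    """Subjects x edges matrix plus behavior, confounds and atlas metadata.

    ``edges`` holds Fisher-z edge values in the row-major upper-triangle
    order of ``index_map``; ``signal_edges`` records the planted ground
    truth when the dataset is synthetic.
    """

    edges: np.ndarray
    behavior: np.ndarray
    confounds: pd.DataFrame
    subjects: list[str]
    index_map: EdgeIndexMap
    atlas: pd.DataFrame | None = None
    signal_edges: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    traits: pd.DataFrame | None = None

    @property
    def n_subjects(self) -> int:
        return self.edges.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges, index=pd.Index(self.subjects, name="subject"),
            columns=self.index_map.edge_labels(),
        )


@dataclass
class ItemResponseMatrix:
    """Participants x items ordinal responses with missing entries as NaN.

    ``latents`` and ``communities`` carry the generating ground truth for
    recovery checks; real data would leave them None.
    """

    responses: pd.DataFrame
    communities: np.ndarray | None = None
    latents: np.ndarray | None = None

    @property
    def items(self) -> list[str]:
        return list(self.responses.columns)


# ---------------------------------------------------------------------------
# generators


def synthetic_atlas(n_nodes: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic atlas node table (stand-in for a real parcellation's
    metadata): round-robin lobes, alternating hemispheres, random MNI-like
    coordinates.  For testing lobewise summaries only."""
    rng = np.random.default_rng(seed)
    lobes = [LOBES[i % len(LOBES)] for i in range(n_nodes)]
    return pd.DataFrame(
        {
            "node_id": np.arange(1, n_nodes + 1),
            "name": [f"node{str(i + 1).zfill(3)}" for i in range(n_nodes)],
            "hemisphere": ["L" if i % 2 else "R" for i in range(n_nodes)],
            "lobe": lobes,
            "network": rng.choice(_NETWORKS, size=n_nodes),
            "ba": [str(rng.integers(1, 48)) if lobes[i] not in ("Cerebellum", "Subcortical") else "n/a" for i in range(n_nodes)],
            "mni_x": np.round(rng.uniform(-70, 70, n_nodes), 2),
            "mni_y": np.round(rng.uniform(-100, 70, n_nodes), 2),
            "mni_z": np.round(rng.uniform(-45, 75, n_nodes), 2),
        }
    )


def simulate_cpm_dataset(spec: PlantedSignalSpec) -> SubjectDataset:
    """Draw a subjects x edges dataset with a planted brain-behavior signal.

    Behavior is standard normal.  Each planted edge e is
    ``effect_size * behavior + sqrt(1 - effect_size^2) * noise`` (unit
    variance by construction, then scaled by ``noise_sd``), so its
    population correlation with behavior equals ``effect_size``.
    Non-signal edges are independent noise.  The confound correlates with
    behavior at ``confound_r``.
    """
    rng = np.random.default_rng(spec.seed)
    n_edges = spec.n_nodes * (spec.n_nodes - 1) // 2
    y = rng.standard_normal(spec.n_subjects)
    X = rng.standard_normal((spec.n_subjects, n_edges))
    signal = np.asarray(spec.signal_edges, dtype=int)
    if signal.size:
        eff = spec.effect_size
        X[:, signal] = eff * y[:, None] + np.sqrt(1 - eff**2) * X[:, signal]
    X *= spec.noise_sd
    c = spec.confound_r * y + np.sqrt(1 - spec.confound_r**2) * rng.standard_normal(
        spec.n_subjects
    )
    subjects = [f"sub{str(i + 1).zfill(3)}" for i in range(spec.n_subjects)]
    return SubjectDataset(
        edges=X,
        behavior=y,
        confounds=pd.DataFrame({"fd_rms": c}, index=subjects),
        subjects=subjects,
        index_map=EdgeIndexMap(spec.n_nodes),
        atlas=synthetic_atlas(spec.n_nodes, seed=spec.seed),
        signal_edges=np.sort(signal),
    )


def simulate_correlated_traits(
    dataset: SubjectDataset,
    *,
    shared_loading: float = 0.894,
    behavior_loading: float = 0.22,
    seed: int = 0,
    names: tuple[str, str, str] = ("social_skills", "inflexibility", "social_anxiety"),
) -> pd.DataFrame:
    """Three correlated trait scores of which only the first shares planted
    edges with the dataset's behavior.

    All three traits load on a common factor with ``shared_loading`` g
    (pairwise correlations ~= g^2 ~= 0.8, mirroring the strongly correlated
    trait communities the analysis controls for).  The first trait
    additionally loads on the behavior with ``behavior_loading``, placed in
    its *unique* variance, so its marginal correlation with behavior stays
    small (the study observed near-zero trait/performance correlations)
    while its behavior association survives residualization on the other
    two traits.  The result is stored on ``dataset.traits`` and returned.
    """
    g, a = shared_loading, behavior_loading
    if not 0 < g < 1 or not 0 <= a < np.sqrt(1 - g**2):
        raise ValueError("require 0<g<1 and 0<=behavior_loading<sqrt(1-g^2)")
    rng = np.random.default_rng(seed)
    n = dataset.n_subjects
    f = rng.standard_normal(n)
    y = dataset.behavior
    e = rng.standard_normal((n, 3))
    t0 = g * f + a * y + np.sqrt(1 - g**2 - a**2) * e[:, 0]
    t1 = g * f + np.sqrt(1 - g**2) * e[:, 1]
    t2 = g * f + np.sqrt(1 - g**2) * e[:, 2]
    traits = pd.DataFrame(
        {names[0]: t0, names[1]: t1, names[2]: t2}, index=dataset.subjects
    )
    dataset.traits = traits
    return traits


def simulate_node_timeseries(
    n_nodes: int,
    n_frames: int,
    *,
    n_latents: int = 3,
    latent_loading: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Node timecourses driven by shared latent signals, for connectivity
    integration tests.  Nodes loading on the same latent are positively
    correlated; loadings alternate over latents."""
    rng = np.random.default_rng(seed)
    latents = rng.standard_normal((n_latents, n_frames))
    assign = np.arange(n_nodes) % n_latents
    ts = latent_loading * latents[assign] + np.sqrt(
        1 - latent_loading**2
    ) * rng.standard_normal((n_nodes, n_frames))
    return ts


def simulate_task_trials(spec: TaskSpec) -> pd.DataFrame:
    """Simulate one-back runs from an unbiased equal-variance Gaussian
    observer with sensitivity ``true_sensitivity``.

    Blocks alternate between the attend-faces and attend-houses
    conditions.  The first image of a block is emitted with
    ``scorable=False``; among the remaining images, 4 or 5 (per
    ``same_per_block``) are "same" trials.  On a "same" trial the observer
    draws evidence from N(d', 1), otherwise from N(0, 1), and responds
    "same" above the unbiased criterion d'/2.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.true_sensitivity
    crit = d / 2.0
    rows = []
    block = 0
    for _ in range(spec.n_blocks_per_condition):
        for condition in ("attend_faces", "attend_houses"):
            n_scorable = spec.images_per_block - 1
            n_same = int(rng.choice(spec.same_per_block))
            truth = np.array(["different"] * n_scorable, dtype=object)
            truth[rng.choice(n_scorable, size=n_same, replace=False)] = "same"
            for image in range(spec.images_per_block):
                if image == 0:
                    rows.append((block, condition, "different", "none", False))
                    continue
                t = truth[image - 1]
                evidence = rng.normal(d if t == "same" else 0.0, 1.0)
                resp = "same" if evidence > crit else "different"
                rows.append((block, condition, t, resp, True))
            block += 1
    return pd.DataFrame(
        rows, columns=["block", "condition", "truth", "response", "scorable"]
    )


def simulate_questionnaire(spec: LatentSpec) -> ItemResponseMatrix:
    """Ordinal item responses from correlated latent communities.

    Latent scores are multivariate normal with the spec's community
    correlations; each item is its loadings times the latents plus unique
    noise (unit marginal variance), discretized into ``n_categories`` by
    equal-probability normal thresholds, then thinned completely at random
    at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    L, phi = spec.loading_matrix, spec.community_correlations
    n, n_items = spec.n_participants, L.shape[0]
    latents = rng.multivariate_normal(
        np.zeros(phi.shape[0]), phi, size=n, method="cholesky"
    )
    commun = np.einsum("ic,cd,id->i", L, phi, L)
    x = latents @ L.T + rng.standard_normal((n, n_items)) * np.sqrt(1 - commun)
    cuts = norm.ppf(np.arange(1, spec.n_categories) / spec.n_categories)
    cat = np.searchsorted(cuts, x).astype(float) + 1.0  # categories 1..k
    if spec.missing_rate > 0:
        cat[rng.random(cat.shape) < spec.missing_rate] = np.nan
    items = [f"item{str(i + 1).zfill(2)}" for i in range(n_items)]
    responses = pd.DataFrame(
        cat, columns=items,
        index=pd.Index([f"p{str(i + 1).zfill(4)}" for i in range(n)], name="participant"),
    )
    return ItemResponseMatrix(
        responses=responses,
        communities=np.argmax(np.abs(L), axis=1),
        latents=latents,
    )
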