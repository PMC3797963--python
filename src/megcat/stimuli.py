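"""Two-category "blob" stimulus space.

Each stimulus is a 20-edge star-shaped polygon: vertex *k* sits at angle
2πk/20 on a ray from the origin, at a distance given by the k-th entry of
an edge-proportion vector.  A category is defined by a prototype vector
(each entry uniform on [0.3, 0.7]) and exemplars are drawn from a diagonal
Gaussian centred on the prototype, with per-edge standard deviation equal
to ``jitter_scale`` times the absolute per-edge difference between the two
prototypes.  This couples within-category variability to the direction
that separates the categories, so a pooled PCA concentrates ~90% of the
variance in the first one or two components and the two categories form
two distinct clusters along the first component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

N_EDGES = 20
EDGE_MIN = 0.3
EDGE_MAX = 0.7
#: exemplar edges are resampled into this open interval so polygons stay valid
RENDER_MIN = 0.05
RENDER_MAX = 0.95
DEFAULT_N_PER_CATEGORY = 300
DEFAULT_N_BLOCKS = 5
CATEGORIES = ("A", "B")

_REJECTION_CAP = 10_000
_RESAMPLE_CAP = 100


@dataclass(frozen=True)
class BlobCategoryPair:
    """The two category prototypes plus the jitter law of the stimulus space."""

    prototype_a: np.ndarray
    prototype_b: np.ndarray
    jitter_scale: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.prototype_a, dtype=float)
        b = np.asarray(self.prototype_b, dtype=float)
        object.__setattr__(self, "prototype_a", a)
        object.__setattr__(self, "prototype_b", b)
        if a.shape != (N_EDGES,) or b.shape != (N_EDGES,):
            raise ValueError(f"prototypes must have shape ({N_EDGES},)")
        for name, p in (("prototype_a", a), ("prototype_b", b)):
            if np.any(p < EDGE_MIN) or np.any(p > EDGE_MAX):
                raise ValueError(f"{name} entries must lie in [{EDGE_MIN}, {EDGE_MAX}]")
        if not self.jitter_scale >= 0:
            raise ValueError("jitter_scale must be >= 0")

    @property
    def edge_sd(self) -> np.ndarray:
        """Per-edge jitter standard deviation: jitter_scale x |prototype difference|."""
        return self.jitter_scale * np.abs(self.prototype_a - self.prototype_b)

    def prototype(self, category: str) -> np.ndarray:
        _check_category(category)
        return self.prototype_a if category == "A" else self.prototype_b


@dataclass(frozen=True)
class BlobExemplar:
    """A single jittered polygon sample from one category."""

    edges: np.ndarray
    category: str
    exemplar_id: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.shape != (N_EDGES,):
            raise ValueError(f"edges must have shape ({N_EDGES},)")
        if np.any(edges <= 0) or np.any(edges >= 1):
            raise ValueError("edges must lie strictly inside (0, 1)")
        _check_category(self.category)


@dataclass
class StimulusSet:
    """All exemplars of both categories plus a block-balanced presentation order.

    ``presentation_order[t]`` is the index (into ``exemplars``) of the
    exemplar shown on trial ``t``.
    """

    exemplars: list[BlobExemplar]
    presentation_order: np.ndarray
    pair: BlobCategoryPair
    n_blocks: int = DEFAULT_N_BLOCKS

    def __post_init__(self) -> None:
        self.presentation_order = np.asarray(self.presentation_order, dtype=int)
        n = len(self.exemplars)
        if sorted(self.presentation_order.tolist()) != list(range(n)):
            raise ValueError("presentation_order must be a permutation of exemplar indices")

    @property
    def n_trials(self) -> int:
        return len(self.exemplars)

    @property
    def edge_matrix(self) -> np.ndarray:
        """(n_exemplars, 20) matrix of edge vectors in exemplar order."""
        return np.stack([ex.edges for ex in self.exemplars])

    @property
    def categories(self) -> np.ndarray:
        """Category of each exemplar, in exemplar order."""
        return np.array([ex.category for ex in self.exemplars])

    @property
    def trial_labels(self) -> np.ndarray:
        """Category of each trial, in presentation order."""
        return self.categories[self.presentation_order]

    def to_csv(self, exemplar_path: str | Path, order_path: str | Path) -> None:
        df = pd.DataFrame(self.edge_matrix, columns=[f"edge_{i:02d}" for i in range(N_EDGES)])
        df.insert(0, "category", self.categories)
        df.insert(0, "exemplar_id", [ex.exemplar_id for ex in self.exemplars])
        df.to_csv(exemplar_path, index=False)
        order = pd.DataFrame(
            {"trial_index": np.arange(self.n_trials), "exemplar_id": self.presentation_order}
        )
        order.to_csv(order_path, index=False)

    @classmethod
    def from_csv(
        cls,
        exemplar_path: str | Path,
        order_path: str | Path,
        pair: BlobCategoryPair,
        n_blocks: int = DEFAULT_N_BLOCKS,
    ) -> "StimulusSet":
        df = pd.read_csv(exemplar_path)
        edge_cols = [c for c in df.columns if c.startswith("edge_")]
        exemplars = [
            BlobExemplar(
                edges=row[edge_cols].to_numpy(dtype=float),
                category=str(row["category"]),
                exemplar_id=int(row["exemplar_id"]),
            )
            for _, row in df.iterrows()
        ]
        order = pd.read_csv(order_path).sort_values("trial_index")["exemplar_id"].to_numpy()
        return cls(exemplars=exemplars, presentation_order=order, pair=pair, n_blocks=n_blocks)


@dataclass(frozen=True)
class PCASummary:
    """Cumulative explained variance and first-component edge weights."""

    cumulative_variance: np.ndarray
    first_component_weights: np.ndarray


def _check_category(category: str) -> None:
    if category not in CATEGORIES:
        raise ValueError(f"category must be one of {CATEGORIES}, got {category!r}")


def make_prototype_pair(
    seed: int | None,
    min_mean_separation: float = 0.0,
    jitter_scale: float = 0.2,
) -> BlobCategoryPair:
    """Draw the two category prototypes, uniform per edge on [0.3, 0.7].

    The pair is redrawn until the mean per-edge absolute difference reaches
    ``min_mean_separation`` (0 disables redrawing).  Deterministic given
    ``seed``.
    """
    if min_mean_separation < 0:
        raise ValueError("min_mean_separation must be >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(_REJECTION_CAP):
        a = rng.uniform(EDGE_MIN, EDGE_MAX, size=N_EDGES)
        b = rng.uniform(EDGE_MIN, EDGE_MAX, size=N_EDGES)
        if np.mean(np.abs(a - b)) >= min_mean_separation:
            return BlobCategoryPair(prototype_a=a, prototype_b=b,
                                    jitter_scale=jitter_scale, seed=seed)
    raise RuntimeError(
        f"could not reach mean separation {min_mean_separation} in {_REJECTION_CAP} draws"
    )


def sample_exemplar(
    pair: BlobCategoryPair,
    category: str,
    rng: np.random.Generator,
    exemplar_id: int = 0,
) -> BlobExemplar:
    """Draw one exemplar: prototype plus diagonal Gaussian jitter.

    Edges falling outside (0.05, 0.95) are resampled edge-wise so the
    rendered polygon never degenerates or self-crosses the origin.
    """
    _check_category(category)
    mean = pair.prototype(category)
    sd = pair.edge_sd
    edges = rng.normal(mean, sd)
    bad = (edges <= RENDER_MIN) | (edges >= RENDER_MAX)
    tries = 0
    while np.any(bad):
        tries += 1
        if tries > _RESAMPLE_CAP:
            raise RuntimeError("edge resampling cap exhausted; jitter law is degenerate")
        edges[bad] = rng.normal(mean[bad], sd[bad])
        bad = (edges <= RENDER_MIN) | (edges >= RENDER_MAX)
    return BlobExemplar(edges=edges, category=category, exemplar_id=exemplar_id)


def generate_stimulus_set(
    pair: BlobCategoryPair,
    n_per_category: int = DEFAULT_N_PER_CATEGORY,
    rng: np.random.Generator | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> StimulusSet:
    """Generate ``n_per_category`` exemplars per category and a balanced order.

    The presentation order is a permutation of all exemplars arranged in
    ``n_blocks`` equal blocks, each holding the same number of A and B
    trials (the within-block balance of the experimental session).
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    if n_per_category % n_blocks != 0:
        raise ValueError(
            f"n_per_category={n_per_category} must be divisible by n_blocks={n_blocks}"
        )
    if rng is None:
        rng = np.random.default_rng(pair.seed)
    exemplars: list[BlobExemplar] = []
    for category in CATEGORIES:
        for i in range(n_per_category):
            exemplars.append(
                sample_exemplar(pair, category, rng, exemplar_id=len(exemplars))
            )
    per_block = n_per_category // n_blocks
    a_ids = np.arange(n_per_category)
    b_ids = np.arange(n_per_category, 2 * n_per_category)
    order_blocks = []
    for blk in range(n_blocks):
        sl = slice(blk * per_block, (blk + 1) * per_block)
        block = np.concatenate([a_ids[sl], b_ids[sl]])
        order_blocks.append(rng.permutation(block))
    order = np.concatenate(order_blocks)
    return StimulusSet(exemplars=exemplars, presentation_order=order,
                       pair=pair, n_blocks=n_blocks)


def blob_to_polygon(exemplar: BlobExemplar, radius: float = 1.0) -> np.ndarray:
    """Planar vertex coordinates of the blob: (20, 2) array.

    Vertex *k* sits at angle 2πk/20, at distance ``edges[k] * radius`` from
    the origin.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    angles = 2.0 * math.pi * np.arange(N_EDGES) / N_EDGES
    r = exemplar.edges * radius
    return np.column_stack([r * np.cos(angles), r * np.sin(angles)])


def pca_summary(stimulus_set: StimulusSet) -> PCASummary:
    """PCA of the pooled edge matrix of both categories.

    Returns cumulative explained-variance fractions over all 20 components
    and the unit-norm edge weights of the first component.
    """
    X = stimulus_set.edge_matrix
    if X.shape[0] < 3:
        raise ValueError("need at least 3 exemplars for a PCA summary")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate stimulus set: zero variance")
    pca = PCA(n_components=min(X.shape[0], N_EDGES)).fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    if cum.size < N_EDGES:  # rank-deficient: pad with the saturated tail
        cum = np.concatenate([cum, np.full(N_EDGES - cum.size, cum[-1])])
    w = pca.components_[0]
    w = w / np.linalg.norm(w)
    return PCASummary(cumulative_variance=cum, first_component_weights=w)
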