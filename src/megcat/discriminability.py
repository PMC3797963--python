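"""Time-resolved multivariate category discriminability.

Per time bin, the trial x channel matrix is reduced by PCA to the leading
components retaining at least 99% of pooled variance (which also makes
the pooled covariance invertible), and the two category groups are
compared with the two-sample Hotelling T² statistic,

    T² = (n_a n_b / (n_a + n_b)) · δ' S⁻¹ δ,

with δ the group mean difference and S the pooled sample covariance.  T²
is reported against an asymptotic χ²_p reference ("chi2" convention);
the exact small-sample F reference is available for sensitivity checks.
Label-shuffled null traces use the same per-bin projection, which is fit
on the pooled trials of both groups and is therefore invariant under
label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_VARIANCE_FRACTION = 0.99
DEFAULT_N_PERM = 100


@dataclass(frozen=True)
class HotellingResult:
    """Two-sample Hotelling test outcome for one time bin."""

    t2: float
    chi2: float
    dims: int
    n_a: int
    n_b: int

    def p_value(self, reference: str = "chi2") -> float:
        """Upper-tail p; 'chi2' (asymptotic) or 'f' (exact small-sample)."""
        if reference == "chi2":
            return float(stats.chi2.sf(self.chi2, self.dims))
        if reference == "f":
            n = self.n_a + self.n_b
            p = self.dims
            dof2 = n - p - 1
            if dof2 < 1:
                raise ValueError("F reference needs n_a + n_b - dims - 1 >= 1")
            f = self.t2 * dof2 / (p * (n - 2))
            return float(stats.f.sf(f, p, dof2))
        raise ValueError("reference must be 'chi2' or 'f'")


@dataclass
class DiscriminabilityTrace:
    """Per-bin χ² statistic and retained dimensionality."""

    bin_centers_ms: np.ndarray
    chi2: np.ndarray
    dims: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers_ms = np.asarray(self.bin_centers_ms, dtype=float)
        self.chi2 = np.asarray(self.chi2, dtype=float)
        self.dims = np.asarray(self.dims, dtype=int)
        if not (self.bin_centers_ms.shape == self.chi2.shape == self.dims.shape):
            raise ValueError("trace vectors must share one length")
        if np.any(self.chi2 < 0):
            raise ValueError("chi2 must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center_ms": self.bin_centers_ms, "chi2": self.chi2, "dims": self.dims}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DiscriminabilityTrace":
        df = pd.read_csv(path)
        return cls(df["bin_center_ms"].to_numpy(), df["chi2"].to_numpy(),
                   df["dims"].to_numpy())


@dataclass
class NullTraceSet:
    """Label-shuffled null traces on the same bin grid as the observed one."""

    traces: np.ndarray  # (n_perm, n_bins)
    bin_centers_ms: np.ndarray

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        self.bin_centers_ms = np.asarray(self.bin_centers_ms, dtype=float)
        if self.traces.shape[1] != self.bin_centers_ms.size:
            raise ValueError("null traces must share the observed bin grid")

    @property
    def n_perm(self) -> int:
        return self.traces.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_center_ms": self.bin_centers_ms})
        for i in range(self.n_perm):
            df[f"perm_{i:03d}"] = self.traces[i]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NullTraceSet":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c.startswith("perm_")]
        return cls(df[cols].to_numpy().T, df["bin_center_ms"].to_numpy())


def project_pca(
    matrix: np.ndarray,
    variance_fraction: float = DEFAULT_VARIANCE_FRACTION,
    max_dims: int | None = None,
) -> tuple[np.ndarray, int]:
    """Center columns and keep the fewest leading PCs reaching the variance goal.

    Returns the component scores (trials x dims) and the retained
    dimensionality, capped at min(trials - 1, features) and ``max_dims``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("matrix must be 2-d with at least 2 trials")
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must be in (0, 1]")
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = np.sum(s**2)
    if total <= 0 or not np.isfinite(total):
        raise ValueError("degenerate input: zero total variance")
    cum = np.cumsum(s**2) / total
    dims = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    cap = min(X.shape[0] - 1, X.shape[1])
    if max_dims is not None:
        cap = min(cap, max_dims)
    dims = min(dims, cap)
    # drop numerically null directions that slipped inside the cap
    dims = min(dims, int(np.sum(s > s[0] * 1e-12)))
    return u[:, :dims] * s[:dims], dims


def hotelling_chi2(group_a: np.ndarray, group_b: np.ndarray) -> HotellingResult:
    """Two-sample Hotelling T² on already-projected data."""
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share feature dimensionality")
    n_a, n_b, p = a.shape[0], b.shape[0], a.shape[1]
    if n_a + n_b - 2 < p:
        raise ValueError(
            f"pooled covariance is singular: n_a + n_b - 2 = {n_a + n_b - 2} < dims = {p};"
            " project to fewer dimensions first"
        )
    delta = a.mean(axis=0) - b.mean(axis=0)
    sa = np.atleast_2d(np.cov(a, rowvar=False))
    sb = np.atleast_2d(np.cov(b, rowvar=False))
    pooled = ((n_a - 1) * sa + (n_b - 1) * sb) / (n_a + n_b - 2)
    try:
        solved = np.linalg.solve(pooled, delta)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular pooled covariance; PCA projection was skipped or insufficient"
        ) from err
    t2 = float(n_a * n_b / (n_a + n_b) * delta @ solved)
    t2 = max(t2, 0.0)
    return HotellingResult(t2=t2, chi2=t2, dims=p, n_a=n_a, n_b=n_b)


def _split_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"exactly two labels required, got {uniq.tolist()}")
    return labels == uniq[0], labels == uniq[1]


def _bin_projections(binned, variance_fraction: float) -> list[tuple[np.ndarray, int]]:
    n = binned.n_trials
    out = []
    for k in range(binned.n_bins):
        try:
            out.append(
                project_pca(binned.data[:, :, k], variance_fraction, max_dims=n - 2)
            )
        except ValueError as err:
            raise ValueError(f"bin {k} (centre {binned.bin_centers_ms[k]} ms): {err}") from err
    return out


def discriminability_trace(
    binned,
    labels: np.ndarray | None = None,
    variance_fraction: float = DEFAULT_VARIANCE_FRACTION,
) -> DiscriminabilityTrace:
    """χ² discriminability at every time bin of a BinnedEpochs tensor."""
    labels = binned.labels if labels is None else np.asarray(labels)
    mask_a, mask_b = _split_labels(labels)
    chi2 = np.empty(binned.n_bins)
    dims = np.empty(binned.n_bins, dtype=int)
    for k, (z, d) in enumerate(_bin_projections(binned, variance_fraction)):
        res = hotelling_chi2(z[mask_a], z[mask_b])
        chi2[k], dims[k] = res.chi2, res.dims
    return DiscriminabilityTrace(binned.bin_centers_ms.copy(), chi2, dims)


def shuffled_traces(
    binned,
    labels: np.ndarray | None = None,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
    variance_fraction: float = DEFAULT_VARIANCE_FRACTION,
) -> NullTraceSet:
    """Full discriminability traces under ``n_perm`` label permutations.

    Each permutation preserves the label multiset.  The per-bin PCA is fit
    on the pooled trials and is hence identical for every permutation; it
    is computed once and only the group statistics are recomputed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    labels = binned.labels if labels is None else np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"exactly two labels required, got {uniq.tolist()}")
    projections = _bin_projections(binned, variance_fraction)
    traces = np.empty((n_perm, binned.n_bins))
    for i in range(n_perm):
        perm_labels = labels[rng.permutation(labels.size)]
        mask_a = perm_labels == uniq[0]
        for k, (z, _) in enumerate(projections):
            traces[i, k] = hotelling_chi2(z[mask_a], z[~mask_a]).chi2
    return NullTraceSet(traces=traces, bin_centers_ms=binned.bin_centers_ms.copy())
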