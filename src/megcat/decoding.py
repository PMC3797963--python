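"""Window-averaged leave-one-trial-out logistic category decoding.

Per cortical region, learning phase (first/final 100 trials) and
canonical latency window (baseline 0-50, M100 50-150, M200 150-250,
M300 250-350 ms), the dipole ensemble is averaged over the window, the
trial x dipole matrix is PCA-reduced at 99% variance (fit once per phase,
before cross-validation), and a logistic classifier predicts the held-out
trial's category in a leave-one-out loop.  Phase and pathway contrasts
use two-proportion z-tests on the correct/total counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import config_context
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.proportion import proportions_ztest

from .discriminability import DEFAULT_VARIANCE_FRACTION, project_pca
from .epochs import EpochSet
from .preprocess import DEFAULT_PHASE_SIZE, select_phase
from .simulate import RegionLayout

logger = logging.getLogger(__name__)

PHASES = ("early", "late")


@dataclass(frozen=True)
class WindowSpec:
    """Named half-open latency window [start, end) in ms post-onset."""

    name: str
    interval_ms: tuple[float, float]

    def __post_init__(self) -> None:
        start, stop = self.interval_ms
        if not start < stop:
            raise ValueError("window interval must be non-empty")


CANONICAL_WINDOWS = (
    WindowSpec("baseline", (0.0, 50.0)),
    WindowSpec("M100", (50.0, 150.0)),
    WindowSpec("M200", (150.0, 250.0)),
    WindowSpec("M300", (250.0, 350.0)),
)


@dataclass(frozen=True)
class LooResult:
    accuracy: float
    dims: int
    n_trials: int
    n_correct: int


def window_average(epochs: EpochSet, window: WindowSpec) -> np.ndarray:
    """Trials x channels matrix of per-channel means over the window."""
    start, stop = window.interval_ms
    mask = (epochs.time_ms >= start) & (epochs.time_ms < stop)
    if not np.any(mask):
        raise ValueError(f"no samples fall inside window {window.name} [{start}, {stop})")
    return epochs.data[:, :, mask].mean(axis=2)


def _loo_fold_fit(clf, ridge, z_train, y_train):
    """Fit one fold; fall back to a lightly ridge-penalised fit on
    non-convergence (perfect separation makes the MLE diverge)."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(z_train, y_train)
            return clf
        except (ConvergenceWarning, np.linalg.LinAlgError):
            pass
    logger.warning("logistic MLE did not converge; using ridge-stabilised fit")
    ridge.fit(z_train, y_train)
    return ridge


def loo_logistic_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    variance_fraction: float = DEFAULT_VARIANCE_FRACTION,
) -> LooResult:
    """Leave-one-trial-out logistic decoding accuracy.

    The PCA projection is fit once on all trials (both labels pooled)
    before the cross-validation loop.  A held-out trial is predicted as
    the first label (alphabetically; 'A') when its predicted probability
    is >= 0.5.  Deterministic: the loop has no randomness.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"exactly two labels required, got {classes.tolist()}")
    n = X.shape[0]
    if n < 6:
        raise ValueError("need at least 6 trials for leave-one-out decoding")
    y = (labels == classes[0]).astype(int)  # 1 encodes the first label ('A')
    z, dims = project_pca(X, variance_fraction, max_dims=n - 2)
    # C=inf is the unpenalised MLE; the ridge fallback uses a weak penalty
    clf = LogisticRegression(C=np.inf, solver="lbfgs", warm_start=True, max_iter=100)
    ridge = LogisticRegression(C=1e3, solver="lbfgs", max_iter=200)
    correct = 0
    idx = np.arange(n)
    # scores are finite by construction; skipping sklearn's finiteness
    # checks keeps the n-fold refit loop cheap
    with config_context(assume_finite=True):
        for held in range(n):
            train = idx != held
            model = _loo_fold_fit(clf, ridge, z[train], y[train])
            # decision >= 0 <=> predicted P(first label) >= 0.5
            pred = 1 if model.decision_function(z[held][None, :])[0] >= 0 else 0
            correct += int(pred == y[held])
    return LooResult(
        accuracy=correct / n, dims=dims, n_trials=n, n_correct=correct
    )


def decode_grid(
    region_epochs: dict[str, EpochSet],
    windows=CANONICAL_WINDOWS,
    phases=PHASES,
    n_phase: int = DEFAULT_PHASE_SIZE,
    variance_fraction: float = DEFAULT_VARIANCE_FRACTION,
    layout: RegionLayout | None = None,
) -> pd.DataFrame:
    """Full region x window x phase decoding table.

    Epochs are expected baseline-removed (time axis covering the
    windows).  Columns: region, pathway, window, phase, accuracy,
    n_trials, n_correct, dims.
    """
    rows = []
    for region, epochs in region_epochs.items():
        pathway = layout.pathway_of(region) if layout is not None else ""
        for phase in phases:
            phase_epochs = select_phase(epochs, phase, n_phase)
            for window in windows:
                try:
                    feats = window_average(phase_epochs, window)
                    res = loo_logistic_accuracy(feats, phase_epochs.labels,
                                                variance_fraction)
                except ValueError as err:
                    raise ValueError(
                        f"decoding failed at region={region}, window={window.name}, "
                        f"phase={phase}: {err}"
                    ) from err
                rows.append(
                    {
                        "region": region,
                        "pathway": pathway,
                        "window": window.name,
                        "phase": phase,
                        "accuracy": res.accuracy,
                        "n_trials": res.n_trials,
                        "n_correct": res.n_correct,
                        "dims": res.dims,
                    }
                )
    return pd.DataFrame(rows)


def _two_proportion_p(count: np.ndarray, nobs: np.ndarray) -> float:
    """Two-sided two-proportion z-test; degenerate pooled variance -> p = 1."""
    pooled = count.sum() / nobs.sum()
    if pooled in (0.0, 1.0):
        return 1.0
    _, p = proportions_ztest(count, nobs)
    return float(p)


def compare_phases(table: pd.DataFrame) -> pd.DataFrame:
    """Early-vs-late accuracy difference per (region, window) with z-test p."""
    rows = []
    for (region, window), grp in table.groupby(["region", "window"], sort=False):
        by_phase = grp.set_index("phase")
        if not {"early", "late"}.issubset(by_phase.index):
            raise ValueError(f"both phases required for region={region}, window={window}")
        early, late = by_phase.loc["early"], by_phase.loc["late"]
        count = np.array([late["n_correct"], early["n_correct"]], dtype=int)
        nobs = np.array([late["n_trials"], early["n_trials"]], dtype=int)
        rows.append(
            {
                "region": region,
                "window": window,
                "accuracy_early": early["accuracy"],
                "accuracy_late": late["accuracy"],
                "difference": late["accuracy"] - early["accuracy"],
                "p_value": _two_proportion_p(count, nobs),
            }
        )
    return pd.DataFrame(rows)


def pool_pathways(table: pd.DataFrame, layout: RegionLayout) -> pd.DataFrame:
    """Trial-weighted pooled accuracy per pathway, window and phase.

    Returns one row per (window, phase) with the pooled ventral-visual and
    prefrontal accuracies, their difference and a two-proportion z-test p.
    """
    table = table.copy()
    table["pathway"] = [layout.pathway_of(r) for r in table["region"]]
    rows = []
    for (window, phase), grp in table.groupby(["window", "phase"], sort=False):
        pooled = {}
        counts = {}
        for pathway in ("VVP", "PFC"):
            sub = grp[grp["pathway"] == pathway]
            if sub.empty:
                raise ValueError(f"no {pathway} regions in the table")
            n_correct = int(sub["n_correct"].sum())
            n_trials = int(sub["n_trials"].sum())
            pooled[pathway] = n_correct / n_trials
            counts[pathway] = (n_correct, n_trials)
        count = np.array([counts["VVP"][0], counts["PFC"][0]])
        nobs = np.array([counts["VVP"][1], counts["PFC"][1]])
        rows.append(
            {
                "window": window,
                "phase": phase,
                "pooled_accuracy_vvp": pooled["VVP"],
                "pooled_accuracy_pfc": pooled["PFC"],
                "difference": pooled["VVP"] - pooled["PFC"],
                "p_value": _two_proportion_p(count, nobs),
            }
        )
    return pd.DataFrame(rows)
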