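"""Evaluation: selection/clustering error rates, estimation error,
prediction, and Fisher-z paired comparison.

Both variable selection and sample clustering are scored as binary
decision problems via the false selection rate and negative selection rate

    fsr = FP / (TP + FP),    nsr = FN / (TP + FN).

For per-component scoring the estimated components must first be aligned
to the true ones (mixture labels are exchangeable); alignment minimizes the
summed l2 distance between coefficient vectors over all K! permutations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .icc import MixtureModel, posterior_membership

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryDecisionCounts",
    "PredictionReport",
    "fsr_nsr",
    "selection_counts",
    "clustering_counts",
    "match_components",
    "estimation_error",
    "predict",
    "fisher_z",
    "paired_z_test",
]


@dataclass(frozen=True)
class BinaryDecisionCounts:
    """TP/FP/FN/TN counts of a binary decision problem."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")


def fsr_nsr(counts: BinaryDecisionCounts) -> tuple[float, float]:
    """False selection rate FP/(TP+FP) and negative selection rate
    FN/(TP+FN). Degenerate denominators yield 0 with a logged flag."""
    if counts.tp + counts.fp > 0:
        fsr = counts.fp / (counts.tp + counts.fp)
    else:
        logger.info("fsr denominator TP+FP = 0; reporting 0")
        fsr = 0.0
    if counts.tp + counts.fn > 0:
        nsr = counts.fn / (counts.tp + counts.fn)
    else:
        logger.info("nsr denominator TP+FN = 0; reporting 0")
        nsr = 0.0
    return fsr, nsr


def selection_counts(selected, true_support) -> BinaryDecisionCounts:
    """Decision counts for variable selection against a true support set."""
    sel = set(int(j) for j in selected)
    tru = set(int(j) for j in true_support)
    return BinaryDecisionCounts(
        tp=len(sel & tru), fp=len(sel - tru), fn=len(tru - sel)
    )


def match_components(estimated: MixtureModel, truth: MixtureModel,
                     p: int) -> tuple[int, ...]:
    """Permutation aligning estimated components to true ones.

    Returns ``perm`` with ``perm[k]`` = index of the estimated component
    matched to true component k, minimizing sum_k ||beta_est[perm[k]] -
    beta_true[k]||_2 by exhaustive search over K! permutations (K <= 6).
    """
    if estimated.K != truth.K:
        raise ValueError("component counts differ; cannot match")
    K = truth.K
    if K > 6:
        raise ValueError("exhaustive matching supported for K <= 6 only")
    est = [f.coef_array(p) for f in estimated.betas]
    tru = [f.coef_array(p) for f in truth.betas]
    dist = np.asarray([[np.linalg.norm(e - t) for e in est] for t in tru])
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(K)):
        cost = sum(dist[k, perm[k]] for k in range(K))
        if cost < best_cost:
            best, best_cost = perm, cost
    return tuple(best)


def match_by_overlap(est_labels: np.ndarray, true_labels: np.ndarray,
                     K: int) -> tuple[int, ...]:
    """Alignment by co-membership: perm[k] = estimated cluster maximizing
    total overlap with true component k (exhaustive over K!)."""
    overlap = np.zeros((K, K))
    for k in range(K):
        for j in range(K):
            overlap[k, j] = np.sum((true_labels == k) & (est_labels == j))
    best, best_cost = None, -np.inf
    for perm in itertools.permutations(range(K)):
        cost = sum(overlap[k, perm[k]] for k in range(K))
        if cost > best_cost:
            best, best_cost = perm, cost
    return tuple(best)


def clustering_counts(est_labels: np.ndarray, true_labels: np.ndarray,
                      k: int, perm: tuple[int, ...]) -> BinaryDecisionCounts:
    """Decision counts for true component k under an alignment ``perm``:
    TP = correctly assigned members, FP = intruders in the matched cluster,
    FN = members assigned elsewhere."""
    est_k = np.asarray(est_labels) == perm[k]
    true_k = np.asarray(true_labels) == k
    return BinaryDecisionCounts(
        tp=int(np.sum(est_k & true_k)),
        fp=int(np.sum(est_k & ~true_k)),
        fn=int(np.sum(~est_k & true_k)),
        tn=int(np.sum(~est_k & ~true_k)),
    )


def estimation_error(beta_hat: np.ndarray, beta_true: np.ndarray) -> float:
    """Euclidean norm ||beta_hat - beta_true||_2 (vectors include the
    intercept as their first entry when comparing full fits)."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float)
    if beta_hat.shape != beta_true.shape:
        raise ValueError("coefficient vectors must have equal dimension")
    return float(np.linalg.norm(beta_hat - beta_true))


@dataclass
class PredictionReport:
    """Predictions for a test set, with accuracy measures when the truth
    is available."""

    y_hat: np.ndarray
    clusters: np.ndarray | None
    mode: str
    corr: float | None = None
    rmse: float | None = None


def predict(
    model: MixtureModel,
    X_new: np.ndarray,
    y_new: np.ndarray | None = None,
    mode: str = "posterior-with-response",
) -> PredictionReport:
    """Predict responses for new samples under a fitted mixture.

    Modes
    -----
    ``posterior-with-response``
        Assign each test sample to the component maximizing the membership
        posterior evaluated *with the observed test response*, then predict
        from that component's regression. Requires ``y_new``. Note the
        observed response informs the cluster assignment (and hence the
        reported accuracy) under this rule.
    ``mixture-mean``
        E[y|x] = sum_k pi_k (b0_k + x' beta_k); no response access.
    ``max-prior``
        Always use the component with the largest mixing proportion.
    """
    modes = ("posterior-with-response", "mixture-mean", "max-prior")
    if mode not in modes:
        raise ValueError(f"mode must be one of {modes}")
    X_new = np.asarray(X_new, dtype=float)
    means = model.component_means(X_new)
    clusters: np.ndarray | None
    if mode == "posterior-with-response":
        if y_new is None:
            raise ValueError("posterior-with-response requires the test responses")
        probs = posterior_membership(model, X_new, np.asarray(y_new, dtype=float))
        clusters = np.argmax(probs, axis=1).astype(np.intp)
        y_hat = means[np.arange(len(clusters)), clusters]
    elif mode == "mixture-mean":
        clusters = None
        y_hat = means @ model.pi
    else:  # max-prior
        k = int(np.argmax(model.pi))
        clusters = np.full(X_new.shape[0], k, dtype=np.intp)
        y_hat = means[:, k]

    corr = rmse = None
    if y_new is not None:
        y_new = np.asarray(y_new, dtype=float)
        rmse = float(np.sqrt(np.mean((y_new - y_hat) ** 2)))
        if np.std(y_new) > 0 and np.std(y_hat) > 0:
            corr = float(np.corrcoef(y_new, y_hat)[0, 1])
    return PredictionReport(y_hat=y_hat, clusters=clusters, mode=mode,
                            corr=corr, rmse=rmse)


def fisher_z(r: float) -> float:
    """Fisher variance-stabilizing transform z = 0.5 * log((1+r)/(1-r)).

    Approximately normal with standard deviation 1/sqrt(N-3) for a Pearson
    correlation computed from N samples. |r| = 1 is rejected explicitly.
    """
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1 for the Fisher z-transform")
    return 0.5 * np.log((1.0 + r) / (1.0 - r))


def paired_z_test(r_list_a, r_list_b, n_list=None) -> float:
    """Two-sided paired t-test on Fisher z-transformed correlations.

    Items are paired (same drug/dataset under two methods); the test is on
    the per-item differences of z-scores. Identical lists give p = 1.
    ``n_list`` is accepted for interface symmetry (the per-item sample
    sizes; not needed by the paired t statistic itself).
    """
    za = np.asarray([fisher_z(r) for r in r_list_a])
    zb = np.asarray([fisher_z(r) for r in r_list_b])
    if za.shape != zb.shape:
        raise ValueError("paired lists must have equal length")
    diffs = za - zb
    if np.allclose(diffs, 0.0):
        return 1.0
    return float(stats.ttest_rel(za, zb).pvalue)
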