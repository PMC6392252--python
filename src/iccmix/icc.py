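"""Imputation-conditional consistency chain for mixture regression.

Cluster memberships are treated as missing data. The chain alternates

  I-step   : draw each sample's label from its membership posterior
             P(tau_i = k | theta) ∝ pi_k * phi(y_i | x_i' beta_k, sigma_k^2),
  CC-step  : per imputed cluster, re-estimate pi_k by the count fraction,
             beta_k by SIS-MCP on the member rows, and sigma_k by the
             residual variance with degrees-of-freedom correction
             |chi_k| - Card(beta_k) - 1.

This produces two interleaved Markov chains over labels and parameters;
post-burn-in iterations are summarized by consensus clustering (see
:mod:`iccmix.consensus`) and by the BIC recorded each iteration — by
default the observed-data (mixture-likelihood) form — whose post-burn-in
average drives the choice of K (see :mod:`iccmix.model_select`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .screening import SparseFit, default_screen_budget, sis_mcp_fit

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureModel",
    "ICCTrace",
    "ClusterCollapseError",
    "posterior_membership",
    "impute_memberships",
    "update_component",
    "complete_data_bic",
    "mixture_bic",
    "run_icc",
    "average_model",
]

#: absolute floor for sigma_k on perfect fits
SIGMA_FLOOR = 1e-4
#: relative sigma floor: sigma_k >= SIGMA_REL_FLOOR * sd(y). Prevents a tiny
#: cluster with a near-perfect fit from turning into a density spike that
#: permanently captures its own members (an absorbing state of the chain).
SIGMA_REL_FLOOR = 0.05
#: clusters below this size get an intercept-only fit (no variable selection)
MIN_CLUSTER_SIZE = 10
#: a component needing this many empty-cluster rescues within one start is
#: declared collapsed; the chain restarts from a fresh random partition
MAX_RESCUES = 8
#: a component below MIN_CLUSTER_SIZE for this many consecutive iterations
#: is likewise treated as collapsed (set None to allow persistent tiny
#: clusters, e.g. on real data where they may be genuine)
MAX_SMALL_STREAK = 50
#: number of fresh random restarts before giving up with a collapse error
MAX_RESTARTS = 5


class ClusterCollapseError(RuntimeError):
    """A mixture component kept collapsing to empty across every restart."""


class _RestartChain(Exception):
    """Internal signal: the current start is stuck; re-draw the partition."""


@dataclass
class MixtureModel:
    """K-component Gaussian mixture of sparse linear regressions."""

    pi: np.ndarray                 # (K,) mixing proportions, sum to 1
    betas: list[SparseFit]         # per-component sparse fits
    sigmas: np.ndarray             # (K,) residual standard deviations

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if not (len(self.pi) == len(self.betas) == len(self.sigmas)):
            raise ValueError("pi, betas, sigmas must have equal length K")
        if len(self.pi) < 1:
            raise ValueError("K must be >= 1")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("mixing proportions must sum to 1")
        if np.any(self.pi < 0):
            raise ValueError("mixing proportions must be nonnegative")
        if np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be positive")

    @property
    def K(self) -> int:
        return len(self.pi)

    def component_means(self, X: np.ndarray) -> np.ndarray:
        """(n, K) matrix of conditional means x_i' beta_k + intercept_k."""
        return np.column_stack([f.predict(X) for f in self.betas])

    def to_json(self) -> str:
        payload = {
            "K": self.K,
            "pi": self.pi.tolist(),
            "sigmas": self.sigmas.tolist(),
            "betas": [
                {
                    "intercept": f.intercept,
                    "coefficients": {str(j): v for j, v in f.coefficients.items()},
                }
                for f in self.betas
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MixtureModel":
        payload = json.loads(text)
        betas = [
            SparseFit(
                intercept=b["intercept"],
                coefficients={int(j): float(v) for j, v in b["coefficients"].items()},
                screened_set=np.asarray([], dtype=np.intp),
            )
            for b in payload["betas"]
        ]
        return cls(pi=payload["pi"], betas=betas, sigmas=payload["sigmas"])


@dataclass
class ICCTrace:
    """Record of one ICC run: labels, models and BIC per iteration.

    ``memberships[t]``, ``models[t]`` and ``bics[t]`` belong to the same
    iteration: the model was fit on that label vector and the BIC evaluated
    on the pair. The post-burn-in window is ``t0..T-1`` (list indices).
    """

    memberships: np.ndarray        # (T, n) int labels in 0..K-1
    models: list[MixtureModel]
    bics: np.ndarray               # (T,)
    t0: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.memberships = np.asarray(self.memberships)
        self.bics = np.asarray(self.bics, dtype=float)
        if not (len(self.memberships) == len(self.models) == len(self.bics)):
            raise ValueError("memberships, models and bics must share length T")
        if not (0 <= self.t0 < len(self.bics) or len(self.bics) == 1):
            raise ValueError("burn-in t0 must lie inside the trace")

    @property
    def T(self) -> int:
        return len(self.bics)

    @property
    def K(self) -> int:
        return self.models[0].K

    @property
    def post_burn_in(self) -> slice:
        """Slice selecting the retained iterations (length 1 traces keep all)."""
        return slice(self.t0, None) if self.T > 1 else slice(0, None)


def _log_weights(model: MixtureModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log(pi_k) + log phi(y_i | x_i' beta_k, sigma_k^2)."""
    means = model.component_means(X)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
    resid = (y[:, None] - means) / model.sigmas
    log_dens = -0.5 * resid ** 2 - np.log(model.sigmas) - 0.5 * np.log(2 * np.pi)
    return log_pi + log_dens


def _log_mixture_density(model: MixtureModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-sample log mixture density log sum_k pi_k phi(...)."""
    return logsumexp(_log_weights(model, X, y), axis=1)


def posterior_membership(model: MixtureModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Membership posterior: (n, K) matrix with rows summing to 1.

    Row i, column k is proportional to pi_k * phi(y_i | x_i' beta_k,
    sigma_k^2); computed in log space. Rows where every component
    underflows to zero density (or has pi_k = 0) fall back to uniform with
    a logged warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    log_w = _log_weights(model, X, y)
    # normalize in probability space after subtracting the row max: stable
    # even at extreme magnitudes where logsumexp loses the log-sum term
    row_max = np.max(log_w, axis=1)
    bad = ~np.isfinite(row_max)  # every component has zero density
    if np.any(bad):
        logger.warning(
            "posterior underflow on %d samples; falling back to uniform rows",
            int(bad.sum()),
        )
        row_max[bad] = 0.0
        log_w[bad] = 0.0
    w = np.exp(log_w - row_max[:, None])
    return w / w.sum(axis=1, keepdims=True)


def impute_memberships(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent categorical draw per row of a row-stochastic matrix."""
    probs = np.asarray(probs, dtype=float)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0]) * cum[:, -1]
    return (u[:, None] > cum).sum(axis=1).astype(np.intp)


def _sigma_from_residuals(rss: float, m: int, card: int,
                          floor: float = SIGMA_FLOOR) -> float:
    """Residual s.d. with denominator |chi_k| - Card(beta_k) - 1; when the
    denominator is nonpositive it falls back to 1, and the result is floored
    at ``floor`` (never below SIGMA_FLOOR)."""
    den = m - card - 1
    if den <= 0:
        den = 1
    return max(float(np.sqrt(rss / den)), floor, SIGMA_FLOOR)


def update_component(
    X: np.ndarray,
    y: np.ndarray,
    member_indices: np.ndarray,
    n_total: int | None = None,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    screen_budget: int | None = None,
    sigma_floor: float = SIGMA_FLOOR,
    **fit_kw,
) -> tuple[float, SparseFit, float]:
    """CC-step update for one component given its imputed members.

    Returns ``(pi_k, beta_fit, sigma_k)``: the count fraction, the SIS-MCP
    fit on the member rows (intercept-only below ``min_cluster_size``), and
    the degrees-of-freedom-corrected residual s.d., floored at
    ``sigma_floor``. The screening budget defaults to floor(m / log m)
    computed from the member count m.
    """
    member_indices = np.asarray(member_indices, dtype=np.intp)
    m = len(member_indices)
    if m == 0:
        raise ValueError("member_indices must be nonempty")
    if n_total is None:
        n_total = X.shape[0]
    Xk, yk = X[member_indices], y[member_indices]
    pi_k = m / n_total

    if m < min_cluster_size:
        fit = SparseFit(
            intercept=float(yk.mean()),
            coefficients={},
            screened_set=np.asarray([], dtype=np.intp),
        )
    else:
        d = screen_budget if screen_budget is not None else default_screen_budget(m)
        fit = sis_mcp_fit(Xk, yk, d=d, **fit_kw)

    rss = float(((yk - fit.predict(Xk)) ** 2).sum())
    sigma_k = _sigma_from_residuals(rss, m, fit.card, floor=sigma_floor)
    return pi_k, fit, sigma_k


def complete_data_bic(
    model: MixtureModel, X: np.ndarray, y: np.ndarray, labels: np.ndarray
) -> float:
    """Complete-data BIC of (labels, model):

        -2 * sum_k sum_{i in chi_k} log phi(y_i | x_i' beta_k, sigma_k^2)
        + df * log(n),

    with df = sum_k (Card(beta_k) + 2) + (K - 1): slopes, intercept and
    sigma per component, plus the free mixing proportions.
    """
    n = len(y)
    means = model.component_means(X)
    mu_assigned = means[np.arange(n), labels]
    sig = model.sigmas[labels]
    loglik = float(
        np.sum(-0.5 * ((y - mu_assigned) / sig) ** 2 - np.log(sig)
               - 0.5 * np.log(2 * np.pi))
    )
    return -2.0 * loglik + _model_df(model) * np.log(n)


def _model_df(model: MixtureModel) -> int:
    """Free parameters: slopes + intercept + sigma per component, plus the
    K - 1 free mixing proportions."""
    return sum(f.card + 2 for f in model.betas) + (model.K - 1)


def mixture_bic(model: MixtureModel, X: np.ndarray, y: np.ndarray,
                labels: np.ndarray | None = None) -> float:
    """Observed-data BIC: -2 * sum_i log sum_k pi_k phi(y_i | ...) + df log n.

    The partition enters through the fitted parameters (supports, sigmas,
    mixing proportions), not through an assigned-label likelihood: unlike
    the complete-data form, a redundant component cannot buy likelihood by
    adaptively claiming the samples it happens to fit best, so the
    criterion properly penalizes overfitted K. ``labels`` is accepted for
    interface symmetry with :func:`complete_data_bic`.
    """
    n = len(y)
    loglik = float(np.sum(_log_mixture_density(model, X, y)))
    return -2.0 * loglik + _model_df(model) * np.log(n)


#: BIC forms recordable along the chain (Eq-6 averaging works over either)
BIC_FORMS = {"mixture": mixture_bic, "complete": complete_data_bic}


def _align_to_reference(model: MixtureModel, ref_betas: list[np.ndarray],
                        p: int) -> tuple[int, ...]:
    """Permutation perm with perm[k] = component of *model* matched to
    reference component k, minimizing summed l2 distance between dense
    coefficient vectors (exhaustive over K!, K <= 6)."""
    import itertools

    K = model.K
    if K > 6:
        raise ValueError("exhaustive relabeling supported for K <= 6 only")
    est = [f.coef_array(p) for f in model.betas]
    dist = np.asarray([[np.linalg.norm(e - r) for e in est] for r in ref_betas])
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(K)):
        cost = sum(dist[k, perm[k]] for k in range(K))
        if cost < best_cost:
            best, best_cost = perm, cost
    return tuple(best)


def average_model(trace: ICCTrace, p: int) -> MixtureModel:
    """Average estimator over the post-burn-in chain, with relabeling.

    Component labels switch freely across iterations, so each retained
    model is first aligned to the final iteration's model (the reference)
    by the permutation minimizing summed l2 distance between coefficient
    vectors; pi, dense beta and sigma are then averaged componentwise.
    """
    models = trace.models[trace.post_burn_in]
    if not models:
        raise ValueError("empty post-burn-in window")
    K = trace.K
    ref = [f.coef_array(p) for f in models[-1].betas]
    pi_sum = np.zeros(K)
    beta_sum = np.zeros((K, p + 1))
    sigma_sum = np.zeros(K)
    for m in models:
        perm = _align_to_reference(m, ref, p)
        for k in range(K):
            pi_sum[k] += m.pi[perm[k]]
            beta_sum[k] += m.betas[perm[k]].coef_array(p)
            sigma_sum[k] += m.sigmas[perm[k]]
    nm = len(models)
    pi = pi_sum / nm
    pi = pi / pi.sum()
    betas = [
        SparseFit(
            intercept=float(beta_sum[k, 0] / nm),
            coefficients={int(j): float(v / nm)
                          for j, v in enumerate(beta_sum[k, 1:]) if v != 0},
            screened_set=np.asarray([], dtype=np.intp),
        )
        for k in range(K)
    ]
    return MixtureModel(pi=pi, betas=betas, sigmas=np.maximum(sigma_sum / nm,
                                                              SIGMA_FLOOR))


def _cc_step(
    X: np.ndarray,
    y: np.ndarray,
    labels: np.ndarray,
    K: int,
    min_cluster_size: int,
    **fit_kw,
) -> MixtureModel:
    """Fit all K components from an imputed partition. Empty components get
    a global intercept-only model with pi = 0 (counts over n are exact)."""
    n = len(y)
    sigma_floor = max(SIGMA_FLOOR, SIGMA_REL_FLOOR * float(np.std(y)))
    pis = np.zeros(K)
    fits: list[SparseFit] = []
    sigmas = np.zeros(K)
    for k in range(K):
        idx = np.flatnonzero(labels == k)
        if len(idx) == 0:
            fits.append(
                SparseFit(intercept=float(y.mean()), coefficients={},
                          screened_set=np.asarray([], dtype=np.intp))
            )
            sigmas[k] = max(float(y.std()), sigma_floor)
            pis[k] = 0.0
            continue
        pis[k], fit, sigmas[k] = update_component(
            X, y, idx, n_total=n, min_cluster_size=min_cluster_size,
            sigma_floor=sigma_floor, **fit_kw
        )
        fits.append(fit)
    return MixtureModel(pi=pis, betas=fits, sigmas=sigmas)


def _rescue_empty(
    labels: np.ndarray,
    empty: np.ndarray,
    model: MixtureModel,
    X: np.ndarray,
    y: np.ndarray,
    rescue_size: int,
) -> np.ndarray:
    """Reassign the worst-explained samples to components the imputation
    left empty, so the chain never enters the absorbing pi = 0 state."""
    labels = labels.copy()
    dens = _log_mixture_density(model, X, y)
    order = np.argsort(dens)  # worst fit first
    pos = 0
    for k in empty:
        picked = order[pos: pos + rescue_size]
        pos += rescue_size
        labels[picked] = k
        logger.warning(
            "component %d emptied; rescued with the %d worst-fit samples",
            int(k), len(picked),
        )
    return labels


def run_icc(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    T: int = 500,
    t0: int = 100,
    seed: int | None = None,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    max_rescues: int = MAX_RESCUES,
    max_small_streak: int | None = MAX_SMALL_STREAK,
    max_restarts: int = MAX_RESTARTS,
    bic_form: str = "mixture",
    on_collapse: str = "raise",
    **fit_kw,
) -> ICCTrace:
    """Run the ICC chain: random initial partition, then T iterations of
    CC-step (fit) and I-step (stochastic imputation).

    Iteration t records the label vector used for fitting, the fitted
    model, and the complete-data BIC of the pair. ``K = 1`` short-circuits
    to a single SIS-MCP fit (a one-iteration trace). Reproducible from
    *seed*.

    If an imputation leaves a component empty, the component is rescued by
    seizing the ``min_cluster_size`` samples the current model explains
    worst (lowest mixture log-density); this keeps the label chain
    irreducible — a component with pi = 0 could otherwise never regain
    members. A start is declared collapsed when a component needs more
    than ``max_rescues`` rescues or stays below ``min_cluster_size`` for
    more than ``max_small_streak`` consecutive iterations (a parasitic
    near-empty cluster); the chain then restarts from a fresh random
    partition (drawn from the same seeded stream, so the whole run stays
    reproducible).

    ``on_collapse`` controls what happens when every start (1 +
    ``max_restarts``) suffers a persistent collapse — a sign that K is too
    large for the data: ``"raise"`` aborts with
    :class:`ClusterCollapseError`; ``"fallback"`` completes one final
    chain with collapse detection disabled (rescues still active), so an
    overfitted K still yields a trace — and an average BIC that correctly
    disfavors it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K < 1:
        raise ValueError("K must be >= 1")
    if bic_form not in BIC_FORMS:
        raise ValueError(f"bic_form must be one of {sorted(BIC_FORMS)}")
    if K == 1:
        model = _cc_step(X, y, np.zeros(n, dtype=np.intp), 1,
                         min_cluster_size, **fit_kw)
        bic = BIC_FORMS[bic_form](model, X, y, np.zeros(n, dtype=np.intp))
        return ICCTrace(
            memberships=np.zeros((1, n), dtype=np.int16),
            models=[model],
            bics=np.asarray([bic]),
            t0=0,
            seed=seed,
        )
    if not (T > t0 >= 0):
        raise ValueError("need T > t0 >= 0")

    rng = np.random.default_rng(seed)
    for attempt in range(max_restarts + 1):
        try:
            return _run_chain_once(X, y, K, T, t0, rng, seed,
                                   min_cluster_size, max_rescues,
                                   max_small_streak, bic_form, **fit_kw)
        except _RestartChain as sig:
            logger.warning(
                "ICC start %d collapsed (%s); restarting from a fresh "
                "random partition", attempt + 1, sig,
            )
    if on_collapse == "fallback":
        logger.warning(
            "all %d starts collapsed for K=%d; completing a final chain "
            "with collapse detection disabled", max_restarts + 1, K,
        )
        return _run_chain_once(X, y, K, T, t0, rng, seed,
                               min_cluster_size, np.inf, None,
                               bic_form, **fit_kw)
    raise ClusterCollapseError(
        f"all {max_restarts + 1} starts collapsed for K={K}; "
        "consider a smaller K"
    )


def _run_chain_once(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    T: int,
    t0: int,
    rng: np.random.Generator,
    seed: int | None,
    min_cluster_size: int,
    max_rescues: int,
    max_small_streak: int | None,
    bic_form: str,
    **fit_kw,
) -> ICCTrace:
    bic_fn = BIC_FORMS[bic_form]
    n = len(y)
    labels = rng.integers(0, K, size=n).astype(np.intp)
    memberships = np.empty((T, n), dtype=np.int16)
    models: list[MixtureModel] = []
    bics = np.empty(T)
    rescue_counts = np.zeros(K, dtype=int)
    small_streak = np.zeros(K, dtype=int)

    for t in range(T):
        model = _cc_step(X, y, labels, K, min_cluster_size, **fit_kw)
        memberships[t] = labels
        models.append(model)
        bics[t] = bic_fn(model, X, y, labels)

        sizes = np.bincount(labels, minlength=K)
        small_streak = np.where(sizes < min_cluster_size, small_streak + 1, 0)
        if max_small_streak is not None and np.any(small_streak > max_small_streak):
            tiny = int(np.argmax(small_streak))
            raise _RestartChain(
                f"component {tiny} below {min_cluster_size} samples for "
                f"{small_streak[tiny]} consecutive iterations by t={t}"
            )
        if t % 100 == 0:
            logger.info(
                "ICC t=%d BIC=%.1f sizes=%s supports=%s",
                t, bics[t], np.bincount(labels, minlength=K).tolist(),
                [f.card for f in model.betas],
            )
        if t < T - 1:
            probs = posterior_membership(model, X, y)
            labels = impute_memberships(probs, rng)
            empty = np.flatnonzero(np.bincount(labels, minlength=K) == 0)
            if len(empty):
                rescue_counts[empty] += 1
                if np.any(rescue_counts > max_rescues):
                    dead = int(np.argmax(rescue_counts))
                    raise _RestartChain(
                        f"component {dead} rescued {rescue_counts[dead]} "
                        f"times by t={t}"
                    )
                labels = _rescue_empty(
                    labels, empty, model, X, y, min_cluster_size
                )

    return ICCTrace(memberships=memberships, models=models, bics=bics,
                    t0=t0, seed=seed)
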