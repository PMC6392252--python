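"""Synthetic mixture-regression data generation.

Generates datasets from a K-component Gaussian mixture of sparse linear
regressions: each sample i carries a latent component label tau_i, its
predictor vector is drawn from N(mu * 1_p, I_p) with a single common mean
mu ~ Uniform(0, 1) per dataset, and the response is

    y_i = b0_{tau_i} + x_i' beta_{tau_i} + eps_i,   eps_i ~ N(0, sigma_{tau_i}^2).

The default configuration is the benchmark design used throughout the test
suite: n = 600 samples in three equal blocks of 200, p = 2000 features,
sigma_k = 1, and three slope coefficients of 3 per component — one nonzero
feature shared by all components, the others mutually exclusive.

Component labels are assigned deterministically in contiguous blocks of
``n_per_component`` samples (not drawn from Multinomial(pi)), so empirical
proportions equal n_k / n exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["SimulationConfig", "Truth", "Dataset", "generate_dataset"]

#: feature indices (0-based) of the default true supports: index 0 is shared by
#: all three components, the remaining pairs are component-exclusive.
DEFAULT_SHARED = (0,)
DEFAULT_EXCLUSIVE = ((1, 2), (3, 4), (5, 6))


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a synthetic mixture-regression dataset.

    Parameters
    ----------
    n_per_component
        Number of samples generated from each component; ``sum`` gives n.
    p
        Feature dimension.
    beta_specs
        Per-component list of ``(feature_index, coefficient)`` pairs
        (0-based indices into the p features).
    intercepts
        Per-component intercept b0_k (defaults to 0 — slopes only).
    sigma
        Per-component residual standard deviation.
    mu_mode
        ``"dataset"`` draws one common predictor mean mu ~ U(0,1) per
        dataset; ``"column"`` redraws mu independently per feature column.
    seed
        Default RNG seed used when :func:`generate_dataset` is called
        without an explicit seed.
    """

    n_per_component: tuple[int, ...] = (200, 200, 200)
    p: int = 2000
    beta_specs: tuple[tuple[tuple[int, float], ...], ...] = tuple(
        tuple((j, 3.0) for j in (DEFAULT_SHARED + excl))
        for excl in DEFAULT_EXCLUSIVE
    )
    intercepts: tuple[float, ...] = (0.0, 0.0, 0.0)
    sigma: tuple[float, ...] = (1.0, 1.0, 1.0)
    mu_mode: str = "dataset"
    seed: int | None = None

    @property
    def K(self) -> int:
        return len(self.n_per_component)

    @property
    def n(self) -> int:
        return int(sum(self.n_per_component))

    @property
    def pi(self) -> np.ndarray:
        n = self.n
        return np.asarray([nk / n for nk in self.n_per_component])

    def __post_init__(self) -> None:
        if len(self.beta_specs) != self.K or len(self.sigma) != self.K:
            raise ValueError("beta_specs and sigma must have one entry per component")
        if len(self.intercepts) != self.K:
            raise ValueError("intercepts must have one entry per component")
        if any(nk <= 0 for nk in self.n_per_component):
            raise ValueError("component sample counts must be positive")
        if any(s < 0 for s in self.sigma):
            raise ValueError("sigma must be nonnegative")
        if self.mu_mode not in ("dataset", "column"):
            raise ValueError(f"unknown mu_mode {self.mu_mode!r}")
        for spec in self.beta_specs:
            idx = [j for j, _ in spec]
            if len(set(idx)) != len(idx):
                raise ValueError("duplicate feature index within a component's support")
            if any(j < 0 or j >= self.p for j in idx):
                raise ValueError("support index out of range [0, p)")

    def beta_dense(self, k: int) -> np.ndarray:
        """Length-(p+1) coefficient vector of component k, intercept first."""
        b = np.zeros(self.p + 1)
        b[0] = self.intercepts[k]
        for j, v in self.beta_specs[k]:
            b[j + 1] = v
        return b

    @classmethod
    def scaled(cls, p: int = 200, n_per_component: tuple[int, ...] = (200, 200, 200),
               **kw) -> "SimulationConfig":
        """Same structure as the default design but with a different p
        (e.g. p=200 for the lower-dimensional comparison design)."""
        return cls(n_per_component=n_per_component, p=p, **kw)

    @classmethod
    def homogeneous(cls, n: int = 150, p: int = 100, sigma: float = 1.0,
                    support: Sequence[int] = (0, 1, 2), value: float = 3.0,
                    **kw) -> "SimulationConfig":
        """Single-component (K_true = 1) design for null-K experiments."""
        return cls(
            n_per_component=(n,),
            p=p,
            beta_specs=(tuple((j, value) for j in support),),
            intercepts=(0.0,),
            sigma=(sigma,),
            **kw,
        )


@dataclass
class Truth:
    """Ground truth attached to a simulated dataset."""

    memberships: np.ndarray          # (n,) int labels in 0..K-1
    betas: list[np.ndarray]          # per-component dense (p+1,) vectors, intercept first
    sigma: np.ndarray                # (K,)
    pi: np.ndarray                   # (K,)
    mu: np.ndarray                   # scalar array or (p,) depending on mu_mode

    @property
    def K(self) -> int:
        return len(self.betas)

    def support(self, k: int) -> np.ndarray:
        """0-based feature indices with nonzero slope in component k."""
        return np.flatnonzero(self.betas[k][1:] != 0)


@dataclass
class Dataset:
    """Predictor matrix, response vector and (optionally) the generating truth."""

    X: np.ndarray                    # (n, p)
    y: np.ndarray                    # (n,)
    feature_names: list[str] | None = None
    truth: Truth | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.y.ndim != 1 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n, p) and y length n")
        if self.feature_names is None:
            self.feature_names = [f"x{j + 1}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "Dataset":
        truth = None
        if self.truth is not None:
            truth = Truth(
                memberships=self.truth.memberships[rows],
                betas=self.truth.betas,
                sigma=self.truth.sigma,
                pi=self.truth.pi,
                mu=self.truth.mu,
            )
        return Dataset(self.X[rows], self.y[rows], list(self.feature_names), truth)


def generate_dataset(config: SimulationConfig, seed: int | None = None) -> Dataset:
    """Draw one dataset from the mixture-regression design.

    Rows of X are i.i.d. N(mu * 1_p, I_p); the common mean mu is drawn once
    per dataset from Uniform(0, 1) (or once per column when
    ``config.mu_mode == "column"``). Responses follow the component-specific
    sparse linear model with Gaussian noise. Fully reproducible from *seed*.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    n, p, K = config.n, config.p, config.K
    if config.mu_mode == "dataset":
        mu = np.full(p, rng.uniform(0.0, 1.0))
    else:
        mu = rng.uniform(0.0, 1.0, size=p)

    X = rng.standard_normal((n, p)) + mu

    memberships = np.repeat(np.arange(K), config.n_per_component)
    betas = [config.beta_dense(k) for k in range(K)]

    y = np.empty(n)
    noise = rng.standard_normal(n)
    for k in range(K):
        rows = memberships == k
        b = betas[k]
        y[rows] = b[0] + X[rows] @ b[1:] + config.sigma[k] * noise[rows]

    truth = Truth(
        memberships=memberships,
        betas=betas,
        sigma=np.asarray(config.sigma, dtype=float),
        pi=config.pi,
        mu=mu,
    )
    return Dataset(X, y, truth=truth)
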