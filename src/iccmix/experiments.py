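"""Replicated simulation experiments and report aggregation.

Drives the benchmark studies end-to-end on synthetic data: fit the mixture
by ICC + consensus on independent replicate datasets, score per-component
variable selection (fsr/nsr), coefficient estimation error and sample
clustering against the generating truth, and score out-of-sample
prediction under a train/test split. Replicate counts are configurable;
the defaults here are what the package's own acceptance run uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .consensus import ConsensusResult, fit_mixture
from .icc import MixtureModel
from .io import split_train_test
from .metrics import (
    clustering_counts,
    estimation_error,
    fsr_nsr,
    match_components,
    predict,
    selection_counts,
)
from .model_select import select_K
from .screening import SparseFit
from .simulate import Dataset, SimulationConfig, Truth, generate_dataset

__all__ = [
    "truth_model",
    "score_fit",
    "replicate_recovery",
    "replicate_prediction",
    "null_k_experiment",
    "aggregate_table",
]


def truth_model(truth: Truth) -> MixtureModel:
    """Wrap the generating truth as a MixtureModel for component matching."""
    betas = []
    for b in truth.betas:
        betas.append(
            SparseFit(
                intercept=float(b[0]),
                coefficients={int(j): float(v) for j, v in enumerate(b[1:]) if v != 0},
                screened_set=np.asarray([], dtype=np.intp),
            )
        )
    return MixtureModel(pi=truth.pi, betas=betas, sigmas=np.maximum(truth.sigma, 1e-8))


def score_fit(dataset: Dataset, result: ConsensusResult) -> pd.DataFrame:
    """Per-component scores of a consensus fit against the dataset's truth.

    Components are aligned to the truth by minimal summed l2 distance
    between coefficient vectors; each row reports one true component's
    variable-selection fsr/nsr, estimation error ||beta_hat - beta||_2
    (intercept included) and clustering fsr/nsr.
    """
    if dataset.truth is None:
        raise ValueError("dataset carries no ground truth")
    truth = dataset.truth
    tm = truth_model(truth)
    perm = match_components(result.model, tm, dataset.p)
    rows = []
    for k in range(truth.K):
        fit = result.model.betas[perm[k]]
        sel = fsr_nsr(selection_counts(fit.support, truth.support(k)))
        clu = fsr_nsr(clustering_counts(result.labels, truth.memberships, k, perm))
        rows.append(
            {
                "component": k + 1,
                "sel_fsr": sel[0],
                "sel_nsr": sel[1],
                "beta_l2": estimation_error(
                    fit.coef_array(dataset.p), truth.betas[k]
                ),
                "clu_fsr": clu[0],
                "clu_nsr": clu[1],
            }
        )
    return pd.DataFrame(rows)


def _spawn_seeds(seed: int | None, n: int, tag: int) -> list[int]:
    """Deterministic per-replicate sub-seeds below 2**31."""
    return [
        int(np.random.SeedSequence([0 if seed is None else seed, tag, r])
            .generate_state(1)[0] % (2 ** 31))
        for r in range(n)
    ]


def replicate_recovery(
    n_reps: int = 20,
    seed: int | None = None,
    config: SimulationConfig | None = None,
    T: int = 500,
    t0: int = 100,
    **kw,
) -> pd.DataFrame:
    """Selection/estimation/clustering benchmark over independent datasets.

    Each replicate draws a fresh dataset from *config* (default: the
    three-component n=600, p=2000 design), runs ICC + consensus +
    clusterwise selection at the true K, and scores against the truth.
    """
    config = config or SimulationConfig()
    data_seeds = _spawn_seeds(seed, n_reps, tag=1)
    fit_seeds = _spawn_seeds(seed, n_reps, tag=2)
    frames = []
    for r in range(n_reps):
        ds = generate_dataset(config, seed=data_seeds[r])
        result, _ = fit_mixture(ds.X, ds.y, K=config.K, T=T, t0=t0,
                                seed=fit_seeds[r], **kw)
        scores = score_fit(ds, result)
        scores.insert(0, "replicate", r + 1)
        frames.append(scores)
    return pd.concat(frames, ignore_index=True)


def replicate_prediction(
    n_reps: int = 20,
    seed: int | None = None,
    config: SimulationConfig | None = None,
    fraction: float = 0.8,
    mode: str = "posterior-with-response",
    T: int = 500,
    t0: int = 100,
    **kw,
) -> pd.DataFrame:
    """Out-of-sample prediction benchmark with a shuffled train/test split.

    Trains the mixture on ``fraction`` of each replicate dataset and
    reports corr(Y_test, Y_hat_test) and RMSE(Y_hat_test) per replicate.
    """
    config = config or SimulationConfig()
    data_seeds = _spawn_seeds(seed, n_reps, tag=3)
    fit_seeds = _spawn_seeds(seed, n_reps, tag=4)
    split_seeds = _spawn_seeds(seed, n_reps, tag=5)
    rows = []
    for r in range(n_reps):
        ds = generate_dataset(config, seed=data_seeds[r])
        train, test = split_train_test(ds, fraction=fraction, scheme="shuffled",
                                       seed=split_seeds[r])
        result, _ = fit_mixture(train.X, train.y, K=config.K, T=T, t0=t0,
                                seed=fit_seeds[r], **kw)
        report = predict(result.model, test.X, test.y, mode=mode)
        rows.append({"replicate": r + 1, "corr": report.corr, "rmse": report.rmse})
    return pd.DataFrame(rows)


def null_k_experiment(
    n_reps: int = 10,
    seed: int | None = None,
    config: SimulationConfig | None = None,
    K_grid=(1, 2, 3),
    T: int = 200,
    t0: int = 50,
    **kw,
) -> pd.DataFrame:
    """Average-BIC K selection on homogeneous (single-component) data.

    Under the null of homogeneity the extra-parameter penalty should make
    K = 1 win in the large majority of replicates.
    """
    config = config or SimulationConfig.homogeneous()
    data_seeds = _spawn_seeds(seed, n_reps, tag=6)
    sel_seeds = _spawn_seeds(seed, n_reps, tag=7)
    rows = []
    for r in range(n_reps):
        ds = generate_dataset(config, seed=data_seeds[r])
        report = select_K(ds.X, ds.y, K_grid, T=T, t0=t0, seed=sel_seeds[r], **kw)
        rows.append({"replicate": r + 1, "selected_K": report.selected_K,
                     **{f"bic_K{k}": v for k, v in report.avg_bics.items()}})
    return pd.DataFrame(rows)


def aggregate_table(df: pd.DataFrame, by: str | None = "component") -> pd.DataFrame:
    """Mean (standard deviation) summary in the benchmark-table layout."""
    value_cols = [c for c in df.columns if c not in ("replicate", by)]
    if by is not None and by in df.columns:
        grouped = df.groupby(by)[value_cols]
    else:
        grouped = df[value_cols]
        return pd.DataFrame(
            {c: [f"{df[c].mean():.4g} ({df[c].std(ddof=1):.4g})"] for c in value_cols}
        )
    mean, std = grouped.mean(), grouped.std(ddof=1)
    out = mean.copy().astype(object)
    for c in value_cols:
        out[c] = [f"{m:.4g} ({s:.4g})" for m, s in zip(mean[c], std[c])]
    return out
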