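"""Choosing the number of mixture components by average BIC.

For each candidate K the ICC chain is run independently and the
complete-data BIC recorded at every iteration; the criterion for K is the
mean BIC over the post-burn-in window. The K attaining the smallest
average BIC is selected (smallest K on ties — parsimony). K = 1 reduces to
the BIC of a single sparse regression fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .icc import ICCTrace, run_icc

logger = logging.getLogger(__name__)

__all__ = ["KSelectionReport", "average_bic", "select_K"]


def average_bic(trace: ICCTrace) -> float:
    """Mean of recorded BIC values over the post-burn-in window.

    The average runs over the iterations actually retained (t0+1..T in
    1-based chain time, i.e. T - t0 terms); a length-1 trace (K = 1) uses
    its single BIC value.
    """
    window = trace.bics[trace.post_burn_in]
    if len(window) == 0:
        raise ValueError("empty post-burn-in window: T must exceed t0")
    return float(np.mean(window))


def _bic_se(trace: ICCTrace) -> float:
    """Naive Monte-Carlo standard error of the average BIC (ignores chain
    autocorrelation; a scale cue, not a confidence interval)."""
    window = trace.bics[trace.post_burn_in]
    if len(window) < 2:
        return 0.0
    return float(np.std(window, ddof=1) / np.sqrt(len(window)))


@dataclass
class KSelectionReport:
    """Outcome of an average-BIC scan over candidate component counts."""

    k_values: list[int]
    avg_bics: dict[int, float]
    std_errors: dict[int, float]
    traces: dict[int, ICCTrace]
    failures: dict[int, str]
    selected_K: int

    def __post_init__(self) -> None:
        if self.avg_bics:
            best = min(self.avg_bics.values())
            winners = [k for k, v in sorted(self.avg_bics.items()) if v == best]
            if self.selected_K != winners[0]:
                raise ValueError("selected_K must attain the minimum average BIC")


def select_K(
    X: np.ndarray,
    y: np.ndarray,
    K_grid,
    T: int = 500,
    t0: int = 100,
    seed: int | None = None,
    **icc_kw,
) -> KSelectionReport:
    """Run the ICC chain for every candidate K and pick the average-BIC
    minimizer.

    Each K gets an independent, deterministic sub-seed spawned from the
    master seed, so the scan is reproducible from one integer and the order
    of candidates does not affect any single run. A failure for one K
    (e.g. cluster collapse) is recorded in the report, not fatal, unless
    every candidate fails.
    """
    K_grid = sorted(set(int(k) for k in K_grid))
    if not K_grid:
        raise ValueError("K_grid must be nonempty")
    # deterministic sub-seed per K, independent of grid order/content
    sub_seeds = {k: int(np.random.SeedSequence([0 if seed is None else seed, k])
                        .generate_state(1)[0] % (2 ** 31)) for k in K_grid}

    avg_bics: dict[int, float] = {}
    ses: dict[int, float] = {}
    traces: dict[int, ICCTrace] = {}
    failures: dict[int, str] = {}
    icc_kw.setdefault("on_collapse", "fallback")  # every K should get a BIC
    for k in K_grid:
        try:
            trace = run_icc(X, y, K=k, T=T, t0=t0, seed=sub_seeds[k], **icc_kw)
        except Exception as exc:  # recorded, not fatal
            logger.warning("ICC run failed for K=%d: %s", k, exc)
            failures[k] = str(exc)
            continue
        traces[k] = trace
        avg_bics[k] = average_bic(trace)
        ses[k] = _bic_se(trace)

    if not avg_bics:
        raise RuntimeError(f"all candidate K failed: {failures}")
    best = min(avg_bics.values())
    selected = min(k for k, v in avg_bics.items() if v == best)
    return KSelectionReport(
        k_values=K_grid,
        avg_bics=avg_bics,
        std_errors=ses,
        traces=traces,
        failures=failures,
        selected_K=selected,
    )
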