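"""Posterior post-processing: from a chain to credible-effect decisions.

An effect (covariate m, cell type k) is *included* in a draw when
|beta_{m,k}| exceeds a small zero threshold (1e-3 by default); the inclusion
probability is the fraction of post-burn-in draws where this happens.
Credible effects are then chosen by a direct posterior-probability FDR rule:
rank effects by their posterior type-I error 1 - P and keep the longest
prefix whose running mean stays at or below the nominal FDR level.

Effect sizes are reported conditionally on inclusion: the mean of beta over
included draws, and the highest-density interval over included draws only
(posterior beta samples are zero-inflated by construction, so an
unconditional interval would be biased toward zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datacore import CompositionalDataset
from .hmc import PosteriorChain

__all__ = [
    "EffectSummary",
    "SelectionResult",
    "inclusion_probabilities",
    "fdr_select",
    "effect_estimates",
    "conditional_hdi",
    "select_reference",
    "summarize_effects",
]

ZERO_THRESHOLD = 1e-3


@dataclass
class SelectionResult:
    """Outcome of the FDR-calibrated effect selection.

    ``threshold_c`` is the largest admitted type-I error 1 - P (0 for an
    empty set); ``estimated_fdr`` the running mean of 1 - P over the credible
    set, always <= ``nominal_fdr_level``; ``credible`` a boolean M x K mask.
    """

    threshold_c: float
    estimated_fdr: float
    nominal_fdr_level: float
    credible: np.ndarray
    credible_set: list


@dataclass
class EffectSummary:
    """Tidy per-effect table plus the selection metadata."""

    table: pd.DataFrame
    selection: SelectionResult
    reference_index: int


def _beta_draws(chain) -> np.ndarray:
    beta = chain.beta if isinstance(chain, PosteriorChain) else np.asarray(chain, dtype=float)
    if beta.ndim == 2:  # (H, K) single-covariate convenience
        beta = beta[:, None, :]
    return beta


def inclusion_probabilities(chain, threshold: float = ZERO_THRESHOLD,
                            reference_index: int | None = None) -> np.ndarray:
    """Per-effect fraction of draws with |beta| >= threshold (M x K).

    The reference column is forced to zero: its beta is pinned and can never
    be credible.
    """
    beta = _beta_draws(chain)
    if beta.shape[0] < 1:
        raise ValueError("need at least one posterior draw")
    p = (np.abs(beta) >= threshold).mean(axis=0)
    ref = reference_index
    if ref is None and isinstance(chain, PosteriorChain):
        ref = chain.reference_index
    if ref is not None:
        p[:, ref] = 0.0
    return p


def fdr_select(inclusion: np.ndarray, alpha: float,
               reference_index: int | None = None) -> SelectionResult:
    """Direct posterior-probability FDR selection on an M x K inclusion matrix.

    Non-reference effects are ranked by type-I error 1 - P ascending; the
    credible set is the longest prefix whose running mean of 1 - P is <=
    ``alpha``.  Effects tied at the boundary error value are admitted
    all-or-none.  The reference column (if given) is excluded outright.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie strictly between 0 and 1")
    p = np.atleast_2d(np.asarray(inclusion, dtype=float))
    m, k = p.shape
    err = 1.0 - p
    eligible = np.ones((m, k), dtype=bool)
    if reference_index is not None:
        eligible[:, reference_index] = False
    # the admissible thresholds c lie strictly inside (0, 1): an effect with
    # zero inclusion probability (type-I error 1) can never be credible
    idx = [(i, j) for i in range(m) for j in range(k)
           if eligible[i, j] and err[i, j] < 1.0]
    order = sorted(idx, key=lambda ij: err[ij])
    credible = np.zeros((m, k), dtype=bool)
    best_len, best_fdr, best_c = 0, 0.0, 0.0
    running = 0.0
    for rank, ij in enumerate(order, start=1):
        running += err[ij]
        # all-or-none at ties: only cut where the next error value differs
        if rank < len(order) and err[order[rank]] == err[ij]:
            continue
        mean_err = running / rank
        if mean_err <= alpha:
            best_len, best_fdr, best_c = rank, mean_err, err[ij]
    for ij in order[:best_len]:
        credible[ij] = True
    return SelectionResult(
        threshold_c=float(best_c),
        estimated_fdr=float(best_fdr),
        nominal_fdr_level=float(alpha),
        credible=credible,
        credible_set=order[:best_len],
    )


def effect_estimates(chain, threshold: float = ZERO_THRESHOLD) -> np.ndarray:
    """Mean of beta over included draws per effect (M x K); 0 if never included."""
    beta = _beta_draws(chain)
    included = np.abs(beta) >= threshold
    n_inc = included.sum(axis=0)
    total = np.where(included, beta, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        est = np.where(n_inc > 0, total / np.maximum(n_inc, 1), 0.0)
    return est


def _hdi_1d(x: np.ndarray, mass: float) -> tuple[float, float]:
    """Narrowest interval containing at least ceil(mass * n) of the draws."""
    n = x.size
    if n == 0:
        return 0.0, 0.0
    x = np.sort(x)
    m_pts = max(1, int(np.ceil(mass * n)))
    if m_pts >= n:
        return float(x[0]), float(x[-1])
    widths = x[m_pts - 1:] - x[: n - m_pts + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m_pts - 1])


def conditional_hdi(chain, mass: float = 0.95,
                    threshold: float = ZERO_THRESHOLD) -> np.ndarray:
    """Highest-density interval of beta restricted to included draws.

    Returns an (M, K, 2) array of (low, high).  Intervals are computed over
    the draws where the effect was in the model (|beta| >= threshold); a
    degenerate [v, v] results from constant restricted draws and [0, 0] from
    an empty restricted set (e.g. the reference column).
    """
    if not (0 < mass < 1):
        raise ValueError("mass must lie strictly between 0 and 1")
    beta = _beta_draws(chain)
    _, m, k = beta.shape
    out = np.zeros((m, k, 2))
    for i in range(m):
        for j in range(k):
            draws = beta[:, i, j]
            restricted = draws[np.abs(draws) >= threshold]
            out[i, j] = _hdi_1d(restricted, mass)
    return out


def select_reference(ds: CompositionalDataset, presence_threshold: float = 0.95,
                     dispersion: str = "variance") -> int:
    """Pick the reference cell type automatically.

    Among cell types with a nonzero count in at least
    ``presence_threshold * N`` samples, return the one whose per-sample
    relative abundance has the least dispersion (sample variance of
    proportions by default; ``dispersion='cv'`` uses the coefficient of
    variation).  Ties break toward the lowest column index.
    """
    props = ds.proportions
    presence = (ds.counts > 0).mean(axis=0)
    eligible = presence >= presence_threshold - 1e-12
    if not np.any(eligible):
        raise ValueError(
            f"no cell type is present in at least {presence_threshold:.0%} of "
            "samples; lower presence_threshold to relax the constraint"
        )
    var = props.var(axis=0, ddof=1) if ds.n_samples > 1 else np.zeros(ds.n_cell_types)
    if dispersion == "cv":
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.sqrt(var) / props.mean(axis=0)
    elif dispersion == "variance":
        disp = var
    else:
        raise ValueError("dispersion must be 'variance' or 'cv'")
    disp = np.where(eligible, disp, np.inf)
    return int(np.argmin(disp))  # argmin takes the first (lowest index) at ties


def summarize_effects(chain: PosteriorChain, ds: CompositionalDataset,
                      fdr_level: float = 0.05, hdi_mass: float = 0.95,
                      threshold: float = ZERO_THRESHOLD) -> EffectSummary:
    """Assemble the tidy effect table from a fitted chain.

    One row per (covariate, cell type) with inclusion probability, credibility
    flag, conditional effect estimate and conditional HDI bounds.
    """
    ref = chain.reference_index
    p = inclusion_probabilities(chain, threshold)
    sel = fdr_select(p, fdr_level, reference_index=ref)
    est = effect_estimates(chain, threshold)
    hdi = conditional_hdi(chain, hdi_mass, threshold)
    rows = []
    for i, cov in enumerate(ds.covariate_names or [f"covariate_{i}" for i in range(p.shape[0])]):
        for j, ct in enumerate(ds.cell_types):
            rows.append({
                "covariate": cov,
                "cell_type": ct,
                "inclusion_probability": p[i, j],
                "credible": bool(sel.credible[i, j]),
                "effect": est[i, j] if j != ref else 0.0,
                "hdi_low": hdi[i, j, 0],
                "hdi_high": hdi[i, j, 1],
                "is_reference": j == ref,
            })
    return EffectSummary(table=pd.DataFrame(rows), selection=sel, reference_index=ref)
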