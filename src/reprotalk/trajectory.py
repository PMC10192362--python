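"""Optimal-transport trajectory inference.

Each consecutive pair of sampling days is linked by an entropic (optionally
unbalanced) transport map in the joint embedding space: squared Euclidean
cost normalised by its median, entropic regularisation ``epsilon``, a
KL-soft source marginal proportional to each cell's expected number of
descendants (from logistic birth-death rates on cell-cycle and apoptosis
enrichment scores) and a near-hard uniform target marginal, enforced exactly
by a terminal rescaling.  Trajectories start from final-day cells whose
endpoint-signature enrichment exceeds a threshold and are propagated
backwards through the couplings; a cell belongs to the trajectory at its day
when its ancestor probability exceeds that day's mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

import anndata as ad

log = logging.getLogger(__name__)

__all__ = [
    "GrowthParams", "TransportParams", "TransportMap", "TrajectoryResult",
    "compute_growth_rates", "compute_transport_map",
    "compute_all_transport_maps", "infer_trajectories",
]


@dataclass
class GrowthParams:
    beta_center: float = -0.1
    delta_center: float = 0.15
    beta_min: float = 0.3
    beta_max: float = 1.7
    delta_min: float = 0.3
    delta_max: float = 1.7
    width: float = 0.5

    def __post_init__(self) -> None:
        if self.beta_min >= self.beta_max or self.delta_min >= self.delta_max:
            raise ValueError("min must be below max for beta and delta")
        if self.width <= 0:
            raise ValueError("width must be positive")


@dataclass
class TransportParams:
    epsilon: float = 0.2
    lambda_source: float | None = 1.0     # None = hard marginal
    lambda_target: float | None = 50.0
    max_iter: int = 5000
    marginal_tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.marginal_tol <= 0:
            raise ValueError("epsilon and marginal_tol must be positive")


@dataclass
class TransportMap:
    coupling: np.ndarray
    source_marginal: np.ndarray           # prescribed (growth-weighted)
    target_marginal: np.ndarray           # prescribed (uniform)
    err_source: float
    err_target: float
    n_iter: int


@dataclass
class TrajectoryResult:
    endpoint: str
    probabilities: pd.Series              # (barcode) -> probability
    member: pd.Series                     # (barcode) -> bool
    days: list = field(default_factory=list)


def compute_growth_rates(cycle_es: np.ndarray, apoptosis_es: np.ndarray,
                         g: GrowthParams | None = None,
                         dt_days: float = 2.0) -> np.ndarray:
    """Expected descendants per cell over a ``dt_days`` interval.

    Birth rate beta is a logistic function of the cell-cycle enrichment score
    (centre ``beta_center``), death rate delta of the apoptosis score (centre
    ``delta_center``); the net per-day rate is beta - delta and the expected
    descendant count is exp((beta - delta) * dt).
    """
    g = g or GrowthParams()
    cycle_es = np.asarray(cycle_es, dtype=float)
    apoptosis_es = np.asarray(apoptosis_es, dtype=float)
    if not (np.all(np.isfinite(cycle_es)) and np.all(np.isfinite(apoptosis_es))):
        raise ValueError("enrichment scores must be finite")
    beta = g.beta_min + (g.beta_max - g.beta_min) * expit(
        (cycle_es - g.beta_center) / g.width)
    delta = g.delta_min + (g.delta_max - g.delta_min) * expit(
        (apoptosis_es - g.delta_center) / g.width)
    return np.exp((beta - delta) * dt_days)


def compute_transport_map(embed_t: np.ndarray, embed_t1: np.ndarray,
                          growth: np.ndarray,
                          p: TransportParams | None = None) -> TransportMap:
    """Entropic (unbalanced) transport between two cell sets.

    Log-domain alternating scaling iterations; a soft marginal with penalty
    ``lam`` uses the damped exponent lam / (lam + epsilon), ``lam = None``
    means a hard marginal.  The prescribed source marginal is the raw
    expected-descendant weight per source cell and the target marginal is
    uniform with the same total mass (so doubling all growth weights scales
    the coupling by the same factor).  Convergence is reached when the target
    marginal is stationary to ``marginal_tol`` (relative sup-norm); the
    coupling is then rescaled so the target marginal holds exactly.
    """
    p = p or TransportParams()
    n, m = embed_t.shape[0], embed_t1.shape[0]
    growth = np.asarray(growth, dtype=float)
    if growth.shape != (n,):
        raise ValueError("growth must have one weight per source cell")
    a = growth.copy()
    mass = a.sum()
    b = np.full(m, mass / m)

    from scipy.spatial.distance import cdist
    C = cdist(embed_t, embed_t1, metric="sqeuclidean")
    med = np.median(C)
    if med > 0:
        C = C / med
    la, lb = np.log(a), np.log(b)
    f = np.zeros(n)
    g = np.zeros(m)

    # epsilon scaling: anneal from O(1) down to the target epsilon with
    # warm-started potentials; essential for small epsilon
    levels = [p.epsilon]
    while levels[-1] < 1.0:
        levels.append(levels[-1] * 2.0)
    levels.reverse()

    def soft_exponent(lam: float | None, eps: float) -> float:
        return 1.0 if lam is None else lam / (lam + eps)

    # hard-source mode stops on the achieved source marginal; the coupling
    # is then rounded onto both exact marginals.  Soft-source mode stops on
    # potential stationarity (the KL-soft marginal deviates by design) and
    # only the target marginal is enforced exactly.
    hard_source = p.lambda_source is None
    stop_tol = max(p.marginal_tol, 1e-4) if hard_source else p.marginal_tol

    it_total = 0
    converged = False
    for level, eps in enumerate(levels):
        final = level == len(levels) - 1
        fi1 = soft_exponent(p.lambda_source, eps)
        fi2 = soft_exponent(p.lambda_target, eps)
        level_steps = 0
        while it_total < p.max_iter:
            it_total += 1
            level_steps += 1
            f_old = f
            f = fi1 * eps * (la - logsumexp((g[None, :] - C) / eps, axis=1))
            g = fi2 * eps * (lb - logsumexp((f[:, None] - C) / eps, axis=0))
            delta = np.max(np.abs(f - f_old)) / eps
            if final:
                if hard_source and it_total % 10 == 0:
                    row = np.exp(logsumexp(
                        (f[:, None] + g[None, :] - C) / eps, axis=1))
                    if np.max(np.abs(row - a)) / (mass / n) < stop_tol:
                        converged = True
                        break
                if not hard_source and delta < stop_tol:
                    converged = True
                    break
            elif delta < 1e-4 or level_steps >= 2000:
                break    # warm-start levels need only rough convergence
    if not converged:
        row = np.exp(logsumexp((f[:, None] + g[None, :] - C) / p.epsilon, axis=1))
        err = np.max(np.abs(row - a)) / (mass / n)
        raise RuntimeError(
            f"transport map did not converge in {p.max_iter} iterations "
            f"(relative source-marginal error {err:.3g})")
    it = it_total

    P = np.exp((f[:, None] + g[None, :] - C) / p.epsilon)
    if hard_source:
        # rounding onto the exact marginals (scale rows and columns down,
        # then add back the rank-one deficit)
        x = np.minimum(1.0, a / np.maximum(P.sum(axis=1), 1e-300))
        P = P * x[:, None]
        y = np.minimum(1.0, b / np.maximum(P.sum(axis=0), 1e-300))
        P = P * y[None, :]
        ea = a - P.sum(axis=1)
        eb = b - P.sum(axis=0)
        if ea.sum() > 0:
            P = P + np.outer(ea, eb) / ea.sum()
    else:
        P = P * (b / np.maximum(P.sum(axis=0), 1e-300))[None, :]
    err_target = float(np.max(np.abs(P.sum(axis=0) - b)) / (mass / m))
    err_source = float(np.max(np.abs(P.sum(axis=1) - a)) / (mass / n))
    return TransportMap(P, a, b, err_source, err_target, it)


def compute_all_transport_maps(ds: ad.AnnData, growth: np.ndarray,
                               p: TransportParams | None = None,
                               embed_key: str = "X_embed",
                               ) -> dict[tuple[int, int], TransportMap]:
    """One transport map per consecutive day pair, growth applied over the
    actual day gap."""
    p = p or TransportParams()
    days = sorted(ds.obs["day"].unique())
    maps: dict[tuple[int, int], TransportMap] = {}
    E = ds.obsm[embed_key]
    day_arr = ds.obs["day"].to_numpy()
    for d0, d1 in zip(days[:-1], days[1:]):
        i0 = np.where(day_arr == d0)[0]
        i1 = np.where(day_arr == d1)[0]
        g = growth[i0] ** ((d1 - d0) / 2.0)  # growth given per 2-day step
        maps[(d0, d1)] = compute_transport_map(E[i0], E[i1], g, p)
        log.info("transport %s->%s: %d iterations, target err %.2g",
                 d0, d1, maps[(d0, d1)].n_iter, maps[(d0, d1)].err_target)
    return maps


def infer_trajectories(maps: dict[tuple[int, int], TransportMap],
                       ds: ad.AnnData, endpoint_es: dict[str, np.ndarray],
                       threshold: float = 2.0) -> dict[str, TrajectoryResult]:
    """Back-propagate ancestor distributions from enriched final-day cells.

    ``endpoint_es`` maps an endpoint signature name to its per-cell
    enrichment scores.  The endpoint population is the set of final-day cells
    with ES > ``threshold`` (uniform distribution); at each earlier day the
    ancestor distribution is the column-normalised coupling applied to the
    next day's distribution, renormalised to sum to 1.  Membership at a day
    is probability > that day's mean probability.
    """
    days = sorted(ds.obs["day"].unique())
    day_arr = ds.obs["day"].to_numpy()
    day_index = {d: np.where(day_arr == d)[0] for d in days}
    results: dict[str, TrajectoryResult] = {}
    for name, es in endpoint_es.items():
        final_ix = day_index[days[-1]]
        hot = final_ix[np.asarray(es)[final_ix] > threshold]
        if hot.size == 0:
            raise ValueError(
                f"no final-day cell exceeds the enrichment threshold for "
                f"endpoint {name!r}")
        prob = np.zeros(ds.n_obs)
        p_next = np.zeros(final_ix.size)
        sel = np.isin(final_ix, hot)
        p_next[sel] = 1.0 / hot.size
        prob[final_ix] = p_next
        member = np.zeros(ds.n_obs, dtype=bool)
        member[final_ix] = p_next > p_next.mean()
        for d0, d1 in zip(reversed(days[:-1]), reversed(days[1:])):
            P = maps[(d0, d1)].coupling
            col = P.sum(axis=0)
            Pn = P / np.maximum(col, 1e-300)[None, :]
            p_cur = Pn @ p_next
            s = p_cur.sum()
            if s > 0:
                p_cur = p_cur / s
            ix = day_index[d0]
            prob[ix] = p_cur
            member[ix] = p_cur > p_cur.mean()
            p_next = p_cur
        results[name] = TrajectoryResult(
            endpoint=name,
            probabilities=pd.Series(prob, index=ds.obs_names),
            member=pd.Series(member, index=ds.obs_names),
            days=list(days))
    return results
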