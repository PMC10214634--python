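"""Maximum-likelihood HKA test.

Polymorphism and divergence counts at L loci are modelled as independent
Poissons:

    S_l ~ Poisson(k_l * theta_l * a_{n_l})        a_n = sum_{i<n} 1/i
    D_l ~ Poisson(theta_l * (T + k_l))

theta_l is the locus population mutation rate, T the species divergence time
in units of 2N generations, and k_l a per-locus selection parameter that
scales the effective coalescent depth of the locus: k > 1 inflates both
polymorphism and the ancestral-polymorphism share of divergence, as expected
for a locus under long-term balancing selection. Neutral loci have k = 1
fixed. The neutral model (all k = 1) is compared against a model with free k
for the candidate loci by a likelihood-ratio test with one degree of freedom
per free k.

Given (T, k) the theta_l that maximise the likelihood are available in
closed form, so fitting reduces to a low-dimensional bounded optimisation.
A Metropolis-style chain maximiser over the same likelihood is available for
cross-checking the direct optimiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

from .popgen_core import harmonic

__all__ = [
    "HKALocus",
    "HKAFit",
    "HKATestResult",
    "count_divergence",
    "loglik",
    "fit_neutral",
    "fit_selection",
    "lrt",
    "run_mlhka",
]

_T_MAX = 1000.0
_K_BOUNDS = (0.02, 50.0)


@dataclass
class HKALocus:
    locus_id: str
    S: int
    D: int
    n: int
    L: int = 0  # aligned length, bookkeeping only
    is_candidate: bool = False

    def __post_init__(self) -> None:
        if self.S < 0 or self.D < 0:
            raise ValueError("S and D must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass
class HKAFit:
    theta_hat: np.ndarray
    T_hat: float
    k_hat: dict  # locus_id -> k (free parameters only)
    loglik: float
    converged: bool
    k_on_divergence: bool = True


@dataclass
class HKATestResult:
    lrt_stat: float
    df: int
    p_value: float


def count_divergence(records, outgroup_id: str, seed: int = 0) -> int:
    """Divergent sites between the outgroup and one random ingroup haplotype.

    ``records`` is a list of aligned SeqRecord-like objects (equal length).
    Columns containing a gap in any sequence are removed before counting, and
    only A/C/G/T mismatches count (ambiguity codes are ignored).
    """
    seqs = {r.id: str(r.seq).upper() for r in records}
    if outgroup_id not in seqs:
        raise ValueError(f"outgroup {outgroup_id!r} not in alignment")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    out = seqs.pop(outgroup_id)
    ingroup_ids = sorted(seqs)
    if not ingroup_ids:
        raise ValueError("no ingroup sequences")
    rng = np.random.default_rng(seed)
    chosen = seqs[ingroup_ids[int(rng.integers(len(ingroup_ids)))]]
    all_seqs = [out] + list(seqs.values())
    cols = [
        i
        for i in range(len(out))
        if all(s[i] != "-" for s in all_seqs)
    ]
    if not cols:
        raise ValueError("alignment empty after gap-column removal")
    valid = set("ACGT")
    return sum(
        1
        for i in cols
        if out[i] in valid and chosen[i] in valid and out[i] != chosen[i]
    )


def _arrays(data: Sequence[HKALocus]):
    S = np.array([l.S for l in data], dtype=float)
    D = np.array([l.D for l in data], dtype=float)
    a = np.array([harmonic(l.n) for l in data], dtype=float)
    return S, D, a


def loglik(
    data: Sequence[HKALocus],
    theta,
    T: float,
    k,
    k_on_divergence: bool = True,
) -> float:
    """Exact Poisson log-likelihood of (S, D) at the given parameters."""
    S, D, a = _arrays(data)
    theta = np.asarray(theta, dtype=float)
    k = np.broadcast_to(np.asarray(k, dtype=float), theta.shape)
    if np.any(theta <= 0) or np.any(k <= 0) or T < 0:
        raise ValueError("require theta > 0, k > 0, T >= 0")
    lam_S = k * theta * a
    lam_D = theta * (T + k) if k_on_divergence else theta * (T + 1.0)
    ll = S * np.log(lam_S) - lam_S - gammaln(S + 1)
    ll += D * np.log(lam_D) - lam_D - gammaln(D + 1)
    return float(ll.sum())


def _profile_theta(S, D, a, T, k, k_on_divergence):
    # Closed-form per-locus theta maximising the likelihood at fixed (T, k).
    depth = T + k if k_on_divergence else np.full_like(np.atleast_1d(k), T + 1.0)
    return (S + D) / (k * a + depth)


def _profiled_loglik(data, T, kvec, k_on_divergence) -> tuple[float, np.ndarray]:
    S, D, a = _arrays(data)
    theta = _profile_theta(S, D, a, T, kvec, k_on_divergence)
    if np.any(theta <= 0):
        return -np.inf, theta
    return loglik(data, theta, T, kvec, k_on_divergence), theta


def fit_neutral(data: Sequence[HKALocus], k_on_divergence: bool = True) -> HKAFit:
    """Fit the all-neutral model (every k = 1).

    theta_l is profiled out in closed form, leaving a 1-D bounded
    optimisation over T.
    """
    if len(data) < 1:
        raise ValueError("need at least one locus")
    S, D, a = _arrays(data)
    if np.all(S + D == 0):
        raise ValueError("all-zero data: theta unidentifiable")
    if np.any(S + D == 0):
        raise ValueError(
            "locus with S = D = 0: its theta is unidentifiable; drop it first"
        )
    ones = np.ones(len(data))

    def neg(T: float) -> float:
        ll, _ = _profiled_loglik(data, T, ones, k_on_divergence)
        return -ll

    res = minimize_scalar(neg, bounds=(0.0, _T_MAX), method="bounded",
                          options={"xatol": 1e-10})
    T_hat = float(res.x)
    ll, theta = _profiled_loglik(data, T_hat, ones, k_on_divergence)
    return HKAFit(
        theta_hat=theta,
        T_hat=T_hat,
        k_hat={},
        loglik=ll,
        converged=bool(res.success),
        k_on_divergence=k_on_divergence,
    )


def fit_selection(
    data: Sequence[HKALocus],
    candidate_ids: Sequence[str],
    k_on_divergence: bool = True,
    n_starts: int = 7,
    method: str = "direct",
    chain_length: int = 20_000,
    seed: int = 0,
) -> HKAFit:
    """Fit the selection model: free k for each candidate locus, k = 1 elsewhere.

    Multi-start bounded optimisation over (T, log k) with theta profiled out;
    starts span a log-scale grid of k values. ``method="chain"`` runs the
    Metropolis maximiser over the same likelihood instead.
    """
    candidate_ids = list(candidate_ids)
    if not candidate_ids:
        raise ValueError("candidate_ids must be non-empty")
    ids = [l.locus_id for l in data]
    cand_idx = []
    for cid in candidate_ids:
        if cid not in ids:
            raise ValueError(f"candidate {cid!r} not among loci")
        cand_idx.append(ids.index(cid))
    n_cand = len(cand_idx)

    def kvec(logk: np.ndarray) -> np.ndarray:
        k = np.ones(len(data))
        k[cand_idx] = np.exp(logk)
        return k

    def neg(x: np.ndarray) -> float:
        T = x[0]
        ll, _ = _profiled_loglik(data, T, kvec(x[1:]), k_on_divergence)
        return -ll

    if method == "chain":
        return _chain_maximise(
            data, cand_idx, candidate_ids, k_on_divergence, chain_length, seed
        )

    T0 = fit_neutral(data, k_on_divergence).T_hat
    lo, hi = np.log(_K_BOUNDS[0]), np.log(_K_BOUNDS[1])
    k_starts = np.linspace(lo, hi, n_starts)
    bounds = [(0.0, _T_MAX)] + [(lo, hi)] * n_cand
    best = None
    any_ok = False
    for ks in k_starts:
        x0 = np.array([T0] + [ks] * n_cand)
        res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        any_ok = any_ok or res.success
    if not any_ok:
        fit = _fit_from_point(data, best.x, cand_idx, candidate_ids, k_on_divergence, False)
        raise RuntimeError(f"selection fit did not converge; best point: {fit}")
    return _fit_from_point(data, best.x, cand_idx, candidate_ids, k_on_divergence, True)


def _fit_from_point(data, x, cand_idx, candidate_ids, k_on_divergence, converged):
    T = float(x[0])
    k = np.ones(len(data))
    k[cand_idx] = np.exp(x[1:])
    ll, theta = _profiled_loglik(data, T, k, k_on_divergence)
    return HKAFit(
        theta_hat=theta,
        T_hat=T,
        k_hat={cid: float(k[i]) for cid, i in zip(candidate_ids, cand_idx)},
        loglik=ll,
        converged=converged,
        k_on_divergence=k_on_divergence,
    )


def _chain_maximise(data, cand_idx, candidate_ids, k_on_divergence, chain_length, seed):
    """Random-walk Metropolis maximiser (legacy-style cross-check)."""
    rng = np.random.default_rng(seed)
    n_cand = len(cand_idx)
    lo, hi = np.log(_K_BOUNDS[0]), np.log(_K_BOUNDS[1])
    x = np.array([fit_neutral(data, k_on_divergence).T_hat] + [0.0] * n_cand)

    def ll_of(x):
        k = np.ones(len(data))
        k[cand_idx] = np.exp(np.clip(x[1:], lo, hi))
        T = min(max(x[0], 0.0), _T_MAX)
        val, _ = _profiled_loglik(data, T, k, k_on_divergence)
        return val

    cur = ll_of(x)
    best_x, best_ll = x.copy(), cur
    step = np.array([0.2] + [0.1] * n_cand)
    for _ in range(chain_length):
        prop = x + rng.normal(0, step)
        ll = ll_of(prop)
        if np.isfinite(ll) and (ll >= cur or rng.random() < np.exp(ll - cur)):
            x, cur = prop, ll
            if cur > best_ll:
                best_x, best_ll = x.copy(), cur
    best_x[0] = min(max(best_x[0], 0.0), _T_MAX)
    best_x[1:] = np.clip(best_x[1:], lo, hi)
    return _fit_from_point(data, best_x, cand_idx, candidate_ids, k_on_divergence, True)


def lrt(fit0: HKAFit, fit1: HKAFit) -> HKATestResult:
    """Likelihood-ratio test of the selection model against the neutral model.

    The statistic is clamped at 0 (optimiser jitter can make it marginally
    negative); the reference distribution is chi-squared with one degree of
    freedom per free k.
    """
    df = len(fit1.k_hat) - len(fit0.k_hat)
    if df <= 0:
        raise ValueError("fit1 must free at least one k relative to fit0")
    stat = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
    return HKATestResult(lrt_stat=stat, df=df, p_value=float(chi2.sf(stat, df)))


def run_mlhka(
    data: Sequence[HKALocus],
    candidate_id: str,
    k_on_divergence: bool = True,
) -> dict:
    """Convenience wrapper: neutral fit, selection fit and LRT for one candidate."""
    fit0 = fit_neutral(data, k_on_divergence)
    fit1 = fit_selection(data, [candidate_id], k_on_divergence)
    test = lrt(fit0, fit1)
    return {
        "locus_id": candidate_id,
        "k_hat": fit1.k_hat[candidate_id],
        "T_hat": fit1.T_hat,
        "lrt": test.lrt_stat,
        "df": test.df,
        "p": test.p_value,
        "loglik_neutral": fit0.loglik,
        "loglik_selection": fit1.loglik,
    }
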