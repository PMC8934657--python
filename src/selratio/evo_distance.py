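"""Pairwise evolutionary distances under the general time-reversible model.

The distance between two gap-free aligned sequences is the maximum-likelihood
branch length under GTR/REV: rate matrix Q = R.diag(pi) with symmetric
exchangeabilities R and stationary frequencies pi, normalized so that
-sum_i pi_i Q_ii = 1 (distance in expected substitutions per site). The
stationary frequencies are taken from the empirical average base composition
of the two sequences, leaving 5 free exchangeabilities (one fixed to 1 for
identifiability) plus the distance. Jukes-Cantor, the equal-rates special
case with the closed form d = -(3/4) ln(1 - 4p/3), doubles as a fallback for
degenerate count matrices and as a validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# upper-triangle order of the exchangeability vector
PAIR_ORDER = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT

MAX_DISTANCE = 10.0


class SaturationError(ValueError):
    """p-distance at or beyond 0.75: the Jukes-Cantor distance is undefined."""


@dataclass
class SubstitutionCounts:
    """4x4 site-pattern counts between two aligned gap-free sequences.

    ``matrix[i, j]`` counts sites with base i in seq1 and base j in seq2;
    sites where either base is N (or any non-ACGT symbol) are excluded.
    """

    matrix: np.ndarray
    n_sites: int

    @property
    def p_distance(self) -> float:
        off = self.matrix.sum() - np.trace(self.matrix)
        return float(off / self.n_sites)


@dataclass
class GtrFit:
    base_freqs: np.ndarray
    exchangeabilities: np.ndarray
    distance: float
    log_likelihood: float
    converged: bool
    method: str  # "gtr_ml" or "jc69_fallback"
    capped: bool = False


def count_substitutions(seq1: str, seq2: str) -> SubstitutionCounts:
    """Tally aligned site patterns; N-containing sites are dropped."""
    if len(seq1) != len(seq2):
        raise ValueError(f"unequal sequence lengths {len(seq1)} != {len(seq2)}")
    a = np.frombuffer(seq1.upper().encode(), dtype="S1")
    b = np.frombuffer(seq2.upper().encode(), dtype="S1")
    lut = np.full(256, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
    ia = lut[a.view(np.uint8)]
    ib = lut[b.view(np.uint8)]
    valid = (ia >= 0) & (ib >= 0)
    ia, ib = ia[valid], ib[valid]
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no informative sites (all positions contain N or non-ACGT)")
    matrix = np.zeros((4, 4), dtype=np.int64)
    np.add.at(matrix, (ia, ib), 1)
    return SubstitutionCounts(matrix=matrix, n_sites=n)


def jc69_distance(p: float) -> float:
    """Closed-form Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3)."""
    if not 0 <= p < 0.75:
        raise SaturationError(f"p-distance {p} outside [0, 0.75): JC distance undefined")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def gtr_rate_matrix(base_freqs: np.ndarray, exchangeabilities: np.ndarray) -> np.ndarray:
    """Normalized GTR rate matrix Q = R.diag(pi), mean rate one."""
    pi = np.asarray(base_freqs, dtype=float)
    rates = np.asarray(exchangeabilities, dtype=float)
    if pi.shape != (4,) or not np.isclose(pi.sum(), 1.0) or (pi < 0).any():
        raise ValueError("base_freqs must be a 4-vector of proportions summing to 1")
    if rates.shape != (6,) or (rates < 0).any():
        raise ValueError("exchangeabilities must be a nonnegative 6-vector")
    R = np.zeros((4, 4))
    for r, (i, j) in zip(rates, PAIR_ORDER):
        R[i, j] = R[j, i] = r
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(np.dot(pi, np.diag(Q)))
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return Q / mean_rate


def transition_probs(Q: np.ndarray, pi: np.ndarray, d: float) -> np.ndarray:
    """P(d) = exp(Q d) via the symmetric eigendecomposition of the GTR generator."""
    sqrt_pi = np.sqrt(pi)
    # guard zero frequencies: those states are unreachable and unvisited
    safe = np.where(sqrt_pi > 0, sqrt_pi, 1.0)
    S = (Q * safe[:, None]) / safe[None, :]
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    P = (V * np.exp(w * d)) @ V.T
    P = P / safe[:, None] * safe[None, :]
    return np.clip(P, 1e-300, None)


def _empirical_freqs(matrix: np.ndarray) -> np.ndarray:
    counts = matrix.sum(axis=1) + matrix.sum(axis=0)
    return counts / counts.sum()


def _loglik(matrix: np.ndarray, pi: np.ndarray, rates: np.ndarray, d: float) -> float:
    Q = gtr_rate_matrix(pi, rates)
    P = transition_probs(Q, pi, d)
    with np.errstate(divide="ignore"):
        ll = float(np.sum(matrix * (np.log(pi)[:, None] + np.log(P))))
    return ll


def gtr_ml_distance(
    counts: SubstitutionCounts,
    min_sites: int = 50,
    tol: float = 1e-8,
) -> GtrFit:
    """Jointly fit exchangeabilities and branch length by maximum likelihood.

    Optimization is multi-start Nelder-Mead over log-parameters (5 free
    exchangeabilities, GT fixed to 1, plus log distance), followed by a
    Brent polish of the branch length at the fitted exchangeabilities down
    to ``tol`` in log-likelihood. Counts with an
    unobserved base or fewer than ``min_sites`` sites fall back to the
    Jukes-Cantor closed form (``method="jc69_fallback"``); a distance above
    10 substitutions/site is capped and flagged.
    """
    matrix = np.asarray(counts.matrix, dtype=float)
    n_sites = counts.n_sites
    if n_sites < 1:
        raise ValueError("empty count matrix")
    pi = _empirical_freqs(matrix)
    p = counts.p_distance

    if p == 0.0:
        return GtrFit(pi, np.ones(6), 0.0, _loglik_safe(matrix, pi), True, "gtr_ml")

    degenerate = (pi == 0).any() or n_sites < min_sites
    if degenerate:
        d = jc69_distance(p)  # raises SaturationError at p >= 0.75
        return GtrFit(
            np.full(4, 0.25), np.ones(6), d,
            float("nan"), True, "jc69_fallback",
        )

    # symmetrized counts: under reversibility the likelihood only depends on these
    sym = 0.5 * (matrix + matrix.T)
    pair_i = np.array([p[0] for p in PAIR_ORDER])
    pair_j = np.array([p[1] for p in PAIR_ORDER])
    sqrt_pi = np.sqrt(pi)
    log_pi_term = float(np.sum(sym * np.log(pi)[:, None]))

    def negll(x):
        # fast unvalidated path of gtr_rate_matrix + transition_probs
        if not np.all(np.isfinite(x)) or x[0] > 7.0:  # d beyond any biological scale
            return 1e12
        d = np.exp(x[0])
        rates = np.ones(6)
        rates[:5] = np.exp(x[1:6])
        R = np.zeros((4, 4))
        R[pair_i, pair_j] = rates
        R[pair_j, pair_i] = rates
        Q = R * pi[None, :]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -np.dot(pi, np.diag(Q))
        if mean_rate <= 0 or not np.isfinite(mean_rate):
            return 1e12
        Q /= mean_rate
        S = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        S = 0.5 * (S + S.T)
        try:
            w, V = np.linalg.eigh(S)
        except np.linalg.LinAlgError:
            return 1e12
        P = (V * np.exp(w * d)) @ V.T
        P = P / sqrt_pi[:, None] * sqrt_pi[None, :]
        P = np.clip(P, 1e-300, None)
        return -(log_pi_term + float(np.sum(sym * np.log(P))))

    d0 = jc69_distance(min(p, 0.74)) if p < 0.75 else 2.0
    starts = [
        np.concatenate([[np.log(d0)], np.zeros(5)]),
        np.concatenate([[np.log(d0)], np.log([1.0, 4.0, 1.0, 1.0, 4.0])]),
    ]
    best = None
    for x0 in starts:
        res = minimize(
            negll, x0, method="Nelder-Mead",
            options={"fatol": max(tol, 1e-6), "xatol": 1e-3,
                     "maxiter": 2000, "maxfev": 3000},
        )
        if best is None or res.fun < best.fun:
            best = res
    rates = np.ones(6)
    rates[:5] = np.exp(best.x[1:6])
    rates = rates / rates[5]
    # 1-D polish of the branch length at the fitted exchangeabilities
    Q = gtr_rate_matrix(pi, rates)

    def negll_d(logd):
        P = transition_probs(Q, pi, np.exp(logd))
        with np.errstate(divide="ignore"):
            return -float(np.sum(sym * np.log(P)))

    polish = minimize_scalar(
        negll_d,
        bounds=(best.x[0] - 0.5, best.x[0] + 0.5),
        method="bounded", options={"xatol": 1e-10},
    )
    # the bounded interval contains best.x[0] at the same rates, so the
    # polished optimum can only improve the likelihood
    d_hat = float(np.exp(polish.x))
    log_likelihood = log_pi_term - float(polish.fun)
    capped = d_hat > MAX_DISTANCE
    if capped:
        d_hat = MAX_DISTANCE
    converged = bool(best.success) and np.isfinite(best.fun)
    if not converged or not np.isfinite(d_hat):
        try:
            d = jc69_distance(p)
        except SaturationError:
            raise
        return GtrFit(np.full(4, 0.25), np.ones(6), d, float("nan"), False, "jc69_fallback")
    return GtrFit(pi, rates, d_hat, log_likelihood, converged, "gtr_ml", capped)


def _loglik_safe(matrix, pi) -> float:
    # identical sequences: L = prod_i pi_i^{N_ii} since P(0) = I
    logpi = np.log(np.where(pi > 0, pi, 1.0))
    return float(np.sum(np.diag(matrix) * logpi))


def pair_distance(seq1: str, seq2: str, min_sites: int = 50) -> GtrFit:
    """Convenience wrapper: count substitutions then fit the GTR distance."""
    return gtr_ml_distance(count_substitutions(seq1, seq2), min_sites=min_sites)
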