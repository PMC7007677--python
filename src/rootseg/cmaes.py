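"""Covariance Matrix Adaptation Evolution Strategy (CMA-ES).

A compact implementation of the standard (mu/mu_w, lambda) CMA-ES for
unconstrained continuous minimization, following Hansen's tutorial
formulation: rank-based recombination with log-decreasing weights,
cumulative step-size adaptation, and rank-one plus rank-mu covariance
updates. Suitable for the low-dimensional black-box objectives this package
tunes (a handful of filter parameters); deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CMAResult", "minimize"]


@dataclass(frozen=True)
class CMAResult:
    x: np.ndarray
    fun: float
    n_evaluations: int


def minimize(
    f,
    x0,
    sigma0: float,
    max_evaluations: int,
    seed: int = 0,
    popsize: int | None = None,
) -> CMAResult:
    """Minimize ``f`` starting from ``x0`` with initial step size ``sigma0``.

    Runs until ``max_evaluations`` objective calls are spent (the incumbent
    best is always returned, never an error). ``x0`` itself is evaluated
    first so the result can never be worse than the starting point.
    """
    if max_evaluations < 1:
        raise ValueError("max_evaluations must be >= 1")
    x0 = np.asarray(x0, dtype=np.float64)
    n = x0.size
    rng = np.random.default_rng(seed)

    lam = popsize or 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log((lam + 1) / 2.0) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / (w**2).sum()

    cs = (mueff + 2) / (n + mueff + 5)
    ds = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    mean = x0.copy()
    sigma = float(sigma0)
    C = np.eye(n)
    ps = np.zeros(n)
    pc = np.zeros(n)

    best_x = x0.copy()
    best_f = float(f(x0))
    nev = 1
    gen = 0
    while nev < max_evaluations:
        gen += 1
        # eigendecomposition each generation (n is small)
        evals, B = np.linalg.eigh(C)
        evals = np.maximum(evals, 1e-20)
        D = np.sqrt(evals)
        k = min(lam, max_evaluations - nev)
        z = rng.standard_normal((lam, n))[:k]
        y = z * D @ B.T
        xs = mean + sigma * y
        fs = np.array([float(f(x)) for x in xs])
        nev += k
        i_best = int(fs.argmin())
        if fs[i_best] < best_f:
            best_f = float(fs[i_best])
            best_x = xs[i_best].copy()
        if k < mu:
            break  # not enough evaluations left for a proper update
        order = np.argsort(fs)
        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        mean = mean + sigma * y_w

        c_inv_sqrt_yw = B @ ((B.T @ y_w) / D)
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * c_inv_sqrt_yw
        h_sig = float(
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * gen)) / chi_n
            < 1.4 + 2 / (n + 1)
        )
        pc = (1 - cc) * pc + h_sig * np.sqrt(cc * (2 - cc) * mueff) * y_w
        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1 - h_sig) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        sigma *= np.exp((cs / ds) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = float(min(sigma, 1e8))
    return CMAResult(x=best_x, fun=best_f, n_evaluations=nev)
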