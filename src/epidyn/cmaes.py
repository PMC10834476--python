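"""Covariance matrix adaptation evolution strategy (CMA-ES), minimization.

A compact (mu/mu_w, lambda)-CMA-ES with cumulative step-size adaptation
and rank-one plus rank-mu covariance updates, following the standard
strategy-parameter settings. Dimensionality here is small (7), so the
covariance eigendecomposition is performed every generation.
"""
from __future__ import annotations

import numpy as np


class CMAES:
    """Ask/tell interface: ``ask`` samples a population, ``tell`` ranks it."""

    def __init__(self, x0: np.ndarray, sigma0: float, seed: int | None = None,
                 popsize: int | None = None):
        self.mean = np.asarray(x0, dtype=float).copy()
        self.n = len(self.mean)
        self.sigma = float(sigma0)
        self.rng = np.random.default_rng(seed)

        n = self.n
        self.lam = popsize if popsize is not None else 4 + int(3 * np.log(n))
        self.mu = self.lam // 2
        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / (self.weights**2).sum()

        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(
            1 - self.c1,
            2 * (self.mueff - 2 + 1 / self.mueff) / ((n + 2) ** 2 + self.mueff),
        )
        self.damps = 1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.cs
        self.chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self._decompose()
        self.generation = 0

    def _decompose(self) -> None:
        self.C = (self.C + self.C.T) / 2
        vals, vecs = np.linalg.eigh(self.C)
        vals = np.clip(vals, 1e-20, None)
        self.B = vecs
        self.D = np.sqrt(vals)
        self.inv_sqrt_C = vecs @ np.diag(1.0 / self.D) @ vecs.T

    def ask(self) -> np.ndarray:
        """Sample a lambda x n population from N(mean, sigma^2 C)."""
        z = self.rng.standard_normal((self.lam, self.n))
        self._last_y = z @ np.diag(self.D) @ self.B.T
        return self.mean + self.sigma * self._last_y

    def tell(self, solutions: np.ndarray, fitness: np.ndarray) -> None:
        """Update distribution from evaluated solutions (lower fitness is better)."""
        order = np.argsort(fitness, kind="stable")
        sel = np.asarray(solutions)[order[: self.mu]]
        old_mean = self.mean.copy()
        self.mean = self.weights @ sel

        y_mean = (self.mean - old_mean) / self.sigma
        self.ps = (1 - self.cs) * self.ps + np.sqrt(
            self.cs * (2 - self.cs) * self.mueff
        ) * (self.inv_sqrt_C @ y_mean)
        hsig = (
            np.linalg.norm(self.ps)
            / np.sqrt(1 - (1 - self.cs) ** (2 * (self.generation + 1)))
            / self.chi_n
            < 1.4 + 2 / (self.n + 1)
        )
        self.pc = (1 - self.cc) * self.pc + hsig * np.sqrt(
            self.cc * (2 - self.cc) * self.mueff
        ) * y_mean

        ys = (sel - old_mean) / self.sigma
        rank_mu = ys.T @ np.diag(self.weights) @ ys
        delta = (1 - hsig) * self.cc * (2 - self.cc)
        self.C = (
            (1 - self.c1 - self.cmu) * self.C
            + self.c1 * (np.outer(self.pc, self.pc) + delta * self.C)
            + self.cmu * rank_mu
        )
        self.sigma *= np.exp(
            (self.cs / self.damps) * (np.linalg.norm(self.ps) / self.chi_n - 1)
        )
        self.sigma = float(np.clip(self.sigma, 1e-12, 1e4))
        self.generation += 1
        self._decompose()
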