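"""Covariance matrix adaptation evolution strategy (minimization).

A self-contained (mu/mu_w, lambda)-CMA-ES with cumulative step-size
adaptation and rank-1 + rank-mu covariance updates, following the standard
formulation (Hansen's tutorial parameterization).  The search space is
unbounded; any box constraints of the problem are handled on the phenotype
side by the caller (state clipping at genome compilation).

Only the pieces needed by the neuroevolution driver are implemented:
``ask`` samples a population, ``tell`` consumes (solutions, values) and
updates mean, paths, covariance and step size.  Values are minimized;
callers maximizing a fitness pass its negation.
"""

from __future__ import annotations

import numpy as np


class CMAES:
    def __init__(
        self,
        x0: np.ndarray,
        sigma0: float,
        popsize: int | None = None,
        rng: np.random.Generator | int | None = None,
    ):
        self.mean = np.array(x0, dtype=float).ravel()
        self.sigma = float(sigma0)
        if self.sigma <= 0:
            raise ValueError("sigma0 must be positive")
        n = self.mean.size
        self.n = n
        self.lam = int(popsize) if popsize else 4 + int(3 * np.log(n))
        if self.lam < 2:
            raise ValueError("population size must be >= 2")
        self.rng = (
            rng
            if isinstance(rng, np.random.Generator)
            else np.random.default_rng(rng)
        )

        self.mu = self.lam // 2
        w = np.log((self.lam + 1) / 2.0) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights**2)

        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(
            1 - self.c1,
            2 * (self.mueff - 2 + 1 / self.mueff) / ((n + 2) ** 2 + self.mueff),
        )
        self.damps = (
            1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.cs
        )
        self.chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self._decompose()
        self.generation = 0
        self._pending: np.ndarray | None = None

    def _decompose(self) -> None:
        self.C = (self.C + self.C.T) / 2.0
        eigvals, self.B = np.linalg.eigh(self.C)
        self.D = np.sqrt(np.maximum(eigvals, 1e-20))
        self.inv_sqrt_C = (self.B / self.D) @ self.B.T

    def ask(self) -> np.ndarray:
        """Sample a (lam, n) population around the current mean."""
        z = self.rng.standard_normal((self.lam, self.n))
        y = z @ (self.B * self.D).T  # y_k = B D z_k
        x = self.mean + self.sigma * y
        self._pending = x
        return x

    def tell(self, solutions: np.ndarray, values) -> None:
        """Update the distribution from evaluated solutions (minimization)."""
        solutions = np.asarray(solutions, dtype=float)
        values = np.asarray(values, dtype=float)
        if solutions.shape != (self.lam, self.n) or values.shape != (self.lam,):
            raise ValueError("tell() expects the population returned by ask()")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite objective values passed to CMA-ES")
        order = np.argsort(values, kind="stable")
        elite = solutions[order[: self.mu]]

        old_mean = self.mean
        y_elite = (elite - old_mean) / self.sigma
        yw = self.weights @ y_elite
        self.mean = old_mean + self.sigma * yw

        self.ps = (1 - self.cs) * self.ps + np.sqrt(
            self.cs * (2 - self.cs) * self.mueff
        ) * (self.inv_sqrt_C @ yw)
        self.generation += 1
        ps_norm = np.linalg.norm(self.ps)
        denom = np.sqrt(1 - (1 - self.cs) ** (2 * self.generation))
        hsig = ps_norm / denom / self.chi_n < 1.4 + 2 / (self.n + 1)

        self.pc = (1 - self.cc) * self.pc + hsig * np.sqrt(
            self.cc * (2 - self.cc) * self.mueff
        ) * yw

        rank_mu = np.einsum("k,ki,kj->ij", self.weights, y_elite, y_elite)
        self.C = (
            (1 - self.c1 - self.cmu) * self.C
            + self.c1
            * (
                np.outer(self.pc, self.pc)
                + (1 - hsig) * self.cc * (2 - self.cc) * self.C
            )
            + self.cmu * rank_mu
        )
        self.sigma *= float(np.exp((self.cs / self.damps) * (ps_norm / self.chi_n - 1)))
        self._decompose()
        self._pending = None
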