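"""Free-energy estimators over reduced-potential sample matrices.

Implements exponential averaging (EXP), the Bennett acceptance ratio for a
pair of states (BAR), and the multistate Bennett acceptance ratio (MBAR),
together with the two-trial uncertainty protocol: each window's samples are
split in half by time, the endpoint free-energy difference is estimated
independently on each half, and the reported value and error bar are the
mean and sample standard deviation of the two trials.

All estimators work in reduced units (u = beta*U, dimensionless); conversion
to kJ/mol happens only at the :class:`FreeEnergyResult` boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .core import InvalidSpecError, IonsolvError, ThermoState


class NonOverlapError(IonsolvError):
    """Raised when two states share no phase-space overlap."""


class ConvergenceError(IonsolvError):
    """Raised when the MBAR self-consistency loop fails to converge."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class CannotSplitError(IonsolvError):
    """Raised when a state has too few samples for the two-trial split."""


@dataclass
class ReducedEnergyMatrix:
    """Samples-by-states matrix of reduced potentials u_k(x_n).

    Rows are samples grouped by origin state (state 0's samples first, then
    state 1's, ...); within a state, rows are in time order.  Column k holds
    the reduced potential of every sample re-evaluated at state k, which is
    exactly what multistate estimators need.
    """

    u: np.ndarray              # (N_total, K) float
    n_k: np.ndarray            # (K,) int, samples drawn from each state
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.n_k = np.asarray(self.n_k, dtype=int)
        if self.u.ndim != 2:
            raise InvalidSpecError("u must be 2-D (samples x states)")
        n, k = self.u.shape
        if k < 2:
            raise InvalidSpecError("need at least 2 states")
        if self.n_k.shape != (k,):
            raise InvalidSpecError("n_k length must equal the number of states")
        if (self.n_k < 0).any():
            raise InvalidSpecError("n_k must be non-negative")
        if self.n_k.sum() != n:
            raise InvalidSpecError(
                f"sum(n_k) = {self.n_k.sum()} does not match row count {n}"
            )
        if not np.isfinite(self.u).all():
            raise InvalidSpecError("reduced energies must all be finite")
        if self.labels is None:
            self.labels = [f"state{i}" for i in range(k)]
        elif len(self.labels) != k:
            raise InvalidSpecError("label count must equal the number of states")

    @property
    def n_states(self) -> int:
        return self.u.shape[1]

    def _bounds(self, k: int) -> tuple[int, int]:
        start = int(self.n_k[:k].sum())
        return start, start + int(self.n_k[k])

    def rows_from(self, k: int) -> np.ndarray:
        """The (N_k, K) block of samples drawn from state k."""
        a, b = self._bounds(k)
        return self.u[a:b]


@dataclass
class FreeEnergyResult:
    """Relative free energies of all states plus endpoint summary.

    ``f`` holds reduced free energies with the gauge f[0] = 0; ``delta_g``
    is the endpoint difference converted to kJ/mol when a thermodynamic
    state is available.  Under the two-trial protocol ``delta_g`` is the
    trial mean and ``uncertainty`` the trial sample standard deviation.
    """

    f: np.ndarray
    estimator: str
    iterations: int = 0
    residual: float = 0.0
    delta_g: Optional[float] = None            # kJ/mol
    trial_delta_g: Optional[tuple[float, float]] = None
    uncertainty: Optional[float] = None        # kJ/mol
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.uncertainty is not None and self.uncertainty < 0:
            raise InvalidSpecError("uncertainty must be >= 0")

    @property
    def delta_f(self) -> float:
        """Reduced endpoint free-energy difference f[-1] - f[0]."""
        return float(self.f[-1] - self.f[0])

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "f": [float(v) for v in self.f],
            "labels": self.labels,
            "delta_g_kJ_per_mol": self.delta_g,
            "trial_delta_g_kJ_per_mol": list(self.trial_delta_g)
            if self.trial_delta_g is not None else None,
            "uncertainty_kJ_per_mol": self.uncertainty,
            "iterations": self.iterations,
            "residual": self.residual,
        }


def exp_averaging(u: ReducedEnergyMatrix, from_state: int, to_state: int) -> float:
    """One-sided exponential-averaging (Zwanzig) estimate of f_to - f_from.

    delta_f = -ln < exp(-(u_to - u_from)) > over samples drawn from
    ``from_state``, evaluated with a log-sum-exp guard.
    """
    block = u.rows_from(from_state)
    if block.shape[0] == 0:
        raise InvalidSpecError(f"state {from_state} has no samples")
    w = block[:, to_state] - block[:, from_state]
    return float(-(logsumexp(-w) - np.log(len(w))))


def _bar_residual(delta_f: float, d_a: np.ndarray, d_b: np.ndarray, m: float) -> float:
    # Bennett self-consistency: sum of Fermi functions over both ensembles.
    lhs = expit(-(m + d_a - delta_f)).sum()
    rhs = expit(m + d_b - delta_f).sum()
    return lhs - rhs


def bar_pair(
    u: ReducedEnergyMatrix,
    state_a: int,
    state_b: int,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Bennett acceptance ratio estimate of f_b - f_a (reduced units).

    Solves the Bennett self-consistency equation by bracketed root finding,
    starting from an expanding bracket around the mean forward/reverse work.
    """
    block_a = u.rows_from(state_a)
    block_b = u.rows_from(state_b)
    if block_a.shape[0] == 0 or block_b.shape[0] == 0:
        raise InvalidSpecError("both states need samples for BAR")
    # d = u_b - u_a evaluated in each ensemble
    d_a = block_a[:, state_b] - block_a[:, state_a]
    d_b = block_b[:, state_b] - block_b[:, state_a]
    # forward work d_a and reverse work -d_b; both one-sided beyond 50
    # reduced units means the Fermi sums are numerically degenerate
    if d_a.min() > 50.0 and (-d_b).min() > 50.0:
        raise NonOverlapError(
            f"states {state_a} and {state_b} share no overlap "
            f"(min forward work {d_a.min():.1f}, max reverse work {(-d_b).max():.1f})"
        )
    m = np.log(len(d_a) / len(d_b))
    f = lambda x: _bar_residual(x, d_a, d_b, m)
    lo = min(d_a.mean(), d_b.mean()) - 1.0
    hi = max(d_a.mean(), d_b.mean()) + 1.0
    # residual is monotonically increasing in delta_f; expand until bracketed
    for _ in range(100):
        if f(lo) < 0 < f(hi):
            break
        if f(lo) >= 0:
            lo -= 2 * (hi - lo)
        if f(hi) <= 0:
            hi += 2 * (hi - lo)
    else:
        raise NonOverlapError(
            f"could not bracket the BAR root for states {state_a}->{state_b}"
        )
    return float(brentq(f, lo, hi, xtol=tol, maxiter=max_iter))


def _mbar_log_denominator(u: np.ndarray, f: np.ndarray, n_k: np.ndarray) -> np.ndarray:
    sampled = n_k > 0
    log_n = np.log(n_k[sampled])
    # (N, K_sampled) -> logsumexp over sampled states
    return logsumexp(log_n[None, :] + f[sampled][None, :] - u[:, sampled], axis=1)


def _mbar_update(u: np.ndarray, f: np.ndarray, n_k: np.ndarray) -> np.ndarray:
    log_denom = _mbar_log_denominator(u, f, n_k)
    f_new = -logsumexp(-u - log_denom[:, None], axis=0)
    return f_new - f_new[0]


def _mbar_gradient_hessian(u, f, n_k):
    sampled = np.flatnonzero(n_k > 0)
    log_denom = _mbar_log_denominator(u, f, n_k)
    # weights W[n, i] = N_i exp(f_i - u_in) / denom_n for sampled i
    logw = (np.log(n_k[sampled])[None, :] + f[sampled][None, :]
            - u[:, sampled] - log_denom[:, None])
    w = np.exp(logw)
    grad = w.sum(axis=0) - n_k[sampled]
    hess = np.diag(w.sum(axis=0)) - w.T @ w
    return sampled, grad, hess


def mbar_solve(
    u: ReducedEnergyMatrix,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    thermo: Optional[ThermoState] = None,
) -> FreeEnergyResult:
    """Solve the MBAR self-consistency equations for all state free energies.

    Starts with self-consistent iteration (robust far from the solution) and
    switches to damped Newton-Raphson on the gradient of the MBAR objective
    once the residual is small.  States with zero samples participate only
    as evaluation states.  The gauge is f[0] = 0.
    """
    if (u.n_k > 0).sum() < 2:
        raise InvalidSpecError("MBAR needs at least two states with samples")
    mat = u.u
    n_k = u.n_k
    f = np.zeros(u.n_states)
    residual = np.inf
    it = 0
    while it < max_iter:
        f_new = _mbar_update(mat, f, n_k)
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        it += 1
        if residual < tol:
            break
        if residual < 1.0:
            # Newton refinement on the sampled-state subvector
            for _ in range(50):
                sampled, grad, hess = _mbar_gradient_hessian(mat, f, n_k)
                free = sampled[sampled != sampled[0]]  # gauge state fixed
                idx = [int(np.where(sampled == j)[0][0]) for j in free]
                h = hess[np.ix_(idx, idx)]
                g = grad[idx]
                try:
                    step = np.linalg.solve(h, g)
                except np.linalg.LinAlgError:
                    break
                f[free] -= step
                it += 1
                f_check = _mbar_update(mat, f, n_k)
                residual = float(np.max(np.abs(f_check - f)))
                f = f_check
                if residual < tol or it >= max_iter:
                    break
            if residual < tol:
                break
    if residual >= tol:
        raise ConvergenceError(
            f"MBAR did not converge in {it} iterations (residual {residual:.3e})",
            residual=residual,
            iterations=it,
        )
    # one final pass to populate unsampled evaluation states consistently
    f = _mbar_update(mat, f, n_k)
    delta_g = None
    if thermo is not None:
        delta_g = float((f[-1] - f[0]) / thermo.beta)
    return FreeEnergyResult(
        f=f, estimator="MBAR", iterations=it, residual=residual,
        delta_g=delta_g, labels=u.labels,
    )


def split_trials(u: ReducedEnergyMatrix) -> tuple[ReducedEnergyMatrix, ReducedEnergyMatrix]:
    """Split each state's time-ordered samples into two halves (trials).

    The first ceil(N_k/2) samples of every sampled state go to trial 1 and
    the remainder to trial 2, preserving order.
    """
    first_blocks, second_blocks = [], []
    n1, n2 = [], []
    for k in range(u.n_states):
        block = u.rows_from(k)
        nk = block.shape[0]
        if nk == 0:
            n1.append(0)
            n2.append(0)
            continue
        if nk < 2:
            raise CannotSplitError(f"state {k} has {nk} sample(s); need >= 2 to split")
        half = int(np.ceil(nk / 2))
        first_blocks.append(block[:half])
        second_blocks.append(block[half:])
        n1.append(half)
        n2.append(nk - half)
    first = ReducedEnergyMatrix(np.vstack(first_blocks), np.array(n1), list(u.labels))
    second = ReducedEnergyMatrix(np.vstack(second_blocks), np.array(n2), list(u.labels))
    return first, second


def estimate_with_uncertainty(
    u: ReducedEnergyMatrix,
    thermo: ThermoState,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> FreeEnergyResult:
    """MBAR endpoint free energy with the two-trial error protocol.

    The matrix is split in half by time per state; MBAR runs independently
    on each half.  delta_g is the mean of the two endpoint estimates and
    the uncertainty their sample standard deviation (divisor n-1), which
    for two trials equals \\|dG1 - dG2\\|/sqrt(2).
    """
    half1, half2 = split_trials(u)
    r1 = mbar_solve(half1, tol=tol, max_iter=max_iter, thermo=thermo)
    r2 = mbar_solve(half2, tol=tol, max_iter=max_iter, thermo=thermo)
    full = mbar_solve(u, tol=tol, max_iter=max_iter, thermo=thermo)
    g1, g2 = r1.delta_g, r2.delta_g
    mean = 0.5 * (g1 + g2)
    sd = float(np.std([g1, g2], ddof=1))
    return FreeEnergyResult(
        f=full.f,
        estimator="MBAR(two-trial)",
        iterations=full.iterations,
        residual=full.residual,
        delta_g=mean,
        trial_delta_g=(g1, g2),
        uncertainty=sd,
        labels=u.labels,
    )
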