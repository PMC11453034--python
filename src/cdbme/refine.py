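"""Bayesian maximum-entropy (BME) reweighting of conformational ensembles.

The posterior weights minimise, for a given entropy-scale theta > 0,

    L(w) = sum_k (M_k / 2) * chi2_k(w)  -  theta * S_rel(w, w0)

where chi2_k is the mean squared uncertainty-normalised deviation of the
scaled ensemble-average prediction from the measured observables of
type k,

    chi2_k = (1/M_k) * sum_i ((O_ki - alpha_k * Obar_ki) / sigma_ki)^2 ,

alpha_k is free and positive for SAXS (beam-intensity compensation) and
fixed to one for CD and chemical shifts, and S_rel is the relative
entropy of the weights against the prior.  Large theta keeps the weights
near the prior; small theta prioritises the data fit.

The minimisation uses an unconstrained softmax parameterisation
w = exp(z)/sum(exp(z)) so iterates stay strictly on the simplex, with
quasi-Newton (L-BFGS) steps.  For free-scale blocks, alpha_k is profiled
out: its closed-form optimum is recomputed at every loss evaluation, and
by the envelope theorem the gradient in w is unaffected.

A theta scan runs independent refinements over a grid (default
{0.1, 1, 2, 5, 10, 20, 50, 100, 200}); the selection rule keeps the
largest theta that still achieves a significant fraction (default half)
of the maximum attainable total-chi2 reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from scipy.optimize import minimize

from .core import (
    ObservableBlock,
    RefinementResult,
    ScaleMode,
    WeightedEnsemble,
    normalize_weights,
    relative_entropy,
)
from .forward import ensemble_average

__all__ = [
    "DEFAULT_THETA_GRID",
    "ThetaScan",
    "DegenerateScaleError",
    "ConvergenceError",
    "optimal_scale",
    "chi2_block",
    "bme_loss",
    "bme_refine",
    "theta_scan",
    "select_theta",
]

#: default entropy-scale grid for the theta scan
DEFAULT_THETA_GRID = (0.1, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0)

_ALPHA_FLOOR = 1e-12


class DegenerateScaleError(ValueError):
    """Optimal scaling factor is undefined (all predictions zero)."""


class ConvergenceError(RuntimeError):
    """Minimisation did not converge; carries the best iterate found."""

    def __init__(self, message: str, result: RefinementResult):
        super().__init__(message)
        self.result = result


def optimal_scale(block: ObservableBlock, w: npt.ArrayLike) -> float:
    """Closed-form alpha minimising chi2_k, clipped to (0, inf).

    alpha* = [sum_i O_i*Obar_i/sigma_i^2] / [sum_i Obar_i^2/sigma_i^2].
    """
    obar = ensemble_average(w, block.P)
    inv_var = 1.0 / block.sigma**2
    denom = float(np.sum(obar**2 * inv_var))
    if denom <= 0:
        raise DegenerateScaleError(
            "all ensemble-average predictions are zero; alpha undefined"
        )
    alpha = float(np.sum(block.O * obar * inv_var)) / denom
    return max(alpha, _ALPHA_FLOOR)


def _resolve_alpha(block: ObservableBlock, w: npt.ArrayLike) -> float:
    if block.scale_mode is ScaleMode.FREE_POSITIVE:
        return optimal_scale(block, w)
    return 1.0


def chi2_block(
    block: ObservableBlock, w: npt.ArrayLike, alpha: float | None = None
) -> float:
    """Reduced chi^2 of one block at weights w.

    ``alpha=None`` resolves the scale from the block's mode (closed-form
    optimum for free blocks, one otherwise).
    """
    if alpha is None:
        alpha = _resolve_alpha(block, w)
    obar = ensemble_average(w, block.P)
    resid = (block.O - alpha * obar) / block.sigma
    return float(np.mean(resid**2))


def bme_loss(
    blocks: list[ObservableBlock],
    w: npt.ArrayLike,
    w0: npt.ArrayLike,
    theta: float,
) -> float:
    """The BME objective L = sum_k (M_k/2) chi2_k - theta * S_rel."""
    chi_term = sum(0.5 * b.M * chi2_block(b, w) for b in blocks)
    return float(chi_term - theta * relative_entropy(w, w0))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _loss_and_grad(z, blocks, w0, theta):
    w = _softmax(z)
    # data term and its gradient in w (alpha profiled for free blocks)
    loss = 0.0
    g = np.zeros_like(w)
    for b in blocks:
        alpha = _resolve_alpha(b, w)
        obar = w @ b.P
        r = (b.O - alpha * obar) / b.sigma
        loss += 0.5 * float(r @ r)
        g -= alpha * (b.P @ (r / b.sigma))
    # entropy penalty: -theta * S_rel = theta * sum w ln(w/w0)
    logratio = np.log(w / w0)
    loss += theta * float(w @ logratio)
    g += theta * (logratio + 1.0)
    # chain rule through softmax
    gz = w * (g - float(w @ g))
    return loss, gz


def bme_refine(
    blocks: list[ObservableBlock],
    w0: npt.ArrayLike | WeightedEnsemble,
    theta: float,
    tol: float = 1e-9,
    max_iter: int = 5000,
) -> RefinementResult:
    """Minimise the BME objective at fixed theta.

    Parameters
    ----------
    blocks
        Observable blocks entering the fit (at least one).
    w0
        Prior weights on the simplex (or a :class:`WeightedEnsemble`
        whose prior is used).
    theta
        Entropy-scale parameter, > 0.
    tol
        Relative loss-change convergence threshold.
    max_iter
        Iteration cap; exceeding it raises :class:`ConvergenceError`
        carrying the best iterate.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if not blocks:
        raise ValueError("at least one observable block is required")
    if isinstance(w0, WeightedEnsemble):
        ids = w0.conformer_ids
        w0 = np.asarray(w0.w0, float)
    else:
        w0 = normalize_weights(w0)
        ids = tuple(range(len(w0)))
    for b in blocks:
        if b.n_conformers != len(w0):
            raise ValueError(
                f"block {b.kind.value} has {b.n_conformers} conformer rows, "
                f"prior has {len(w0)}"
            )

    z0 = np.log(w0)
    res = minimize(
        _loss_and_grad,
        z0,
        args=(blocks, w0, theta),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
    )
    w_star = _softmax(res.x)
    _, gz = _loss_and_grad(res.x, blocks, w0, theta)
    result = _pack_result(blocks, ids, w_star, w0, theta, res.nit, res.success)
    if not res.success and np.max(np.abs(gz)) > 1e-5:
        if res.nit >= max_iter:
            raise ConvergenceError(
                f"BME minimisation hit max_iter={max_iter} "
                f"(|grad|_inf={np.max(np.abs(gz)):.2e})",
                result,
            )
        warnings.warn(
            f"BME minimiser stopped early ({res.message}); "
            f"|grad|_inf={np.max(np.abs(gz)):.2e}",
            RuntimeWarning,
            stacklevel=2,
        )
    return result


def _pack_result(blocks, ids, w, w0, theta, n_iter, converged):
    alphas = tuple(_resolve_alpha(b, w) for b in blocks)
    chi2s = tuple(chi2_block(b, w, a) for b, a in zip(blocks, alphas))
    s_rel = relative_entropy(w, w0)
    loss = sum(0.5 * b.M * c for b, c in zip(blocks, chi2s)) - theta * s_rel
    ensemble = WeightedEnsemble(ids, w, w0)
    return RefinementResult(
        weights=ensemble,
        theta=float(theta),
        chi2_per_block=chi2s,
        alpha_per_block=alphas,
        s_rel=s_rel,
        loss=float(loss),
        n_iter=int(n_iter),
        converged=bool(converged),
    )


@dataclass(frozen=True)
class ThetaScan:
    """Refinements over a theta grid, reported from largest to smallest."""

    thetas: tuple
    results: tuple
    prior_chi2_per_block: tuple
    block_M: tuple

    def delta_chi2(self) -> np.ndarray:
        """Total-chi2 reduction Delta(theta) relative to the prior weights."""
        prior_total = sum(m * c for m, c in zip(self.block_M, self.prior_chi2_per_block))
        return np.array(
            [
                prior_total - sum(m * c for m, c in zip(self.block_M, r.chi2_per_block))
                for r in self.results
            ]
        )


def theta_scan(
    blocks: list[ObservableBlock],
    w0: npt.ArrayLike | WeightedEnsemble,
    thetas=DEFAULT_THETA_GRID,
) -> ThetaScan:
    """Run independent refinements (each initialised at the prior) per theta."""
    thetas = tuple(float(t) for t in thetas)
    if not thetas or any(t <= 0 for t in thetas):
        raise ValueError("thetas must be nonempty and all > 0")
    order = sorted(thetas, reverse=True)
    if isinstance(w0, WeightedEnsemble):
        w0_vec = np.asarray(w0.w0, float)
    else:
        w0_vec = normalize_weights(w0)
    prior_chi2 = tuple(chi2_block(b, w0_vec) for b in blocks)
    results = tuple(bme_refine(blocks, w0, t) for t in order)
    return ThetaScan(
        thetas=tuple(order),
        results=results,
        prior_chi2_per_block=prior_chi2,
        block_M=tuple(b.M for b in blocks),
    )


def select_theta(scan: ThetaScan, frac: float = 0.5) -> float:
    """Pick the largest theta retaining a significant chi2 improvement.

    "Significant" means the total-chi2 reduction from the prior reaches
    at least ``frac`` of the best reduction anywhere on the grid.  The
    grid is scanned from largest to smallest theta and the first theta
    meeting the criterion wins.
    """
    if len(scan.thetas) < 2:
        raise ValueError("theta scan must cover at least two theta values")
    if not 0 < frac < 1:
        raise ValueError("frac must lie in (0, 1)")
    delta = scan.delta_chi2()
    best = delta.max()
    if best <= 0:
        warnings.warn(
            "no theta improves the total chi2 over the prior; "
            "returning the largest theta",
            RuntimeWarning,
            stacklevel=2,
        )
        return scan.thetas[0]
    for theta, d in zip(scan.thetas, delta):
        if d >= frac * best:
            return theta
    return scan.thetas[-1]  # unreachable: the argmax itself qualifies
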