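"""Core domain types and simplex/entropy primitives.

A conformational ensemble is a set of conformers with weights on the
probability simplex.  Refinement redistributes weights away from a prior
(usually uniform) to better fit measured observables, paying an entropic
cost quantified by the relative entropy

    S_rel(w, w0) = -sum_j w_j * ln(w_j / w0_j)   (nats, <= 0)

Observables are grouped into blocks by type (CD, SAXS, chemical shifts);
each block carries the measured values, their uncertainties and a
per-conformer prediction matrix so that ensemble averages are linear in
the weights.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

__all__ = [
    "ObservableKind",
    "ScaleMode",
    "WeightedEnsemble",
    "ObservableBlock",
    "RefinementResult",
    "InvalidWeightsError",
    "normalize_weights",
    "relative_entropy",
]

#: absolute tolerance for weight / simplex comparisons
WEIGHT_ATOL = 1e-9


class InvalidWeightsError(ValueError):
    """Raised for weight vectors that cannot lie on the simplex."""


class ObservableKind(str, enum.Enum):
    CD = "CD"
    SAXS = "SAXS"
    CS = "CS"


class ScaleMode(str, enum.Enum):
    """How the uniform per-block scaling factor alpha_k is treated.

    SAXS intensities carry an arbitrary beam/concentration normalisation,
    so alpha is a free positive parameter; CD intensities and chemical
    shifts are on absolute scales and alpha is fixed to one.
    """

    FREE_POSITIVE = "free_positive"
    FIXED_ONE = "fixed_one"


def normalize_weights(raw: npt.ArrayLike) -> np.ndarray:
    """Project a nonnegative vector onto the simplex by rescaling.

    Raises
    ------
    InvalidWeightsError
        If any entry is negative or the vector sums to zero.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise InvalidWeightsError("weights must be a nonempty 1-D vector")
    if np.any(raw < 0):
        raise InvalidWeightsError("weights must be nonnegative")
    total = raw.sum()
    if total <= 0:
        raise InvalidWeightsError("weights must not be all zero")
    return raw / total


def relative_entropy(w: npt.ArrayLike, w0: npt.ArrayLike) -> float:
    """Relative entropy S_rel = -sum_j w_j ln(w_j/w0_j), in nats.

    Nonpositive, and zero exactly when ``w == w0``.  The convention
    0*ln(0) = 0 lets refined weights sit on the simplex boundary.
    """
    w = np.asarray(w, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    if w.shape != w0.shape:
        raise ValueError(f"length mismatch: {w.shape} vs {w0.shape}")
    if np.any(w0 <= 0):
        raise InvalidWeightsError("prior weights must be strictly positive")
    mask = w > 0
    return -float(np.sum(w[mask] * np.log(w[mask] / w0[mask])))


@dataclass(frozen=True)
class WeightedEnsemble:
    """Conformer labels with current and prior weights on the simplex."""

    conformer_ids: tuple
    w: np.ndarray
    w0: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        w0 = np.asarray(self.w0, dtype=float)
        object.__setattr__(self, "conformer_ids", tuple(self.conformer_ids))
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "w0", w0)
        n = len(self.conformer_ids)
        if w.shape != (n,) or w0.shape != (n,):
            raise InvalidWeightsError("conformer_ids, w and w0 must agree in length")
        if np.any(w < 0):
            raise InvalidWeightsError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > WEIGHT_ATOL:
            raise InvalidWeightsError(f"weights sum to {w.sum()!r}, not 1")
        if np.any(w0 <= 0):
            raise InvalidWeightsError("prior weights must be strictly positive")
        if abs(w0.sum() - 1.0) > WEIGHT_ATOL:
            raise InvalidWeightsError(f"prior weights sum to {w0.sum()!r}, not 1")

    @classmethod
    def uniform(cls, conformer_ids) -> "WeightedEnsemble":
        ids = tuple(conformer_ids)
        u = np.full(len(ids), 1.0 / len(ids))
        return cls(ids, u, u.copy())

    @property
    def n_conformers(self) -> int:
        return len(self.conformer_ids)

    def s_rel(self) -> float:
        return relative_entropy(self.w, self.w0)

    def with_weights(self, w: npt.ArrayLike) -> "WeightedEnsemble":
        return WeightedEnsemble(self.conformer_ids, np.asarray(w, float), self.w0)


@dataclass
class ObservableBlock:
    """One observable type: measured values, uncertainties, predictions.

    Parameters
    ----------
    kind
        Observable type (CD, SAXS or CS).
    O
        Measured values O_ki, length M (kMRE, intensity a.u., or ppm).
    sigma
        Uncertainties sigma_ki, same length and units, strictly positive.
    P
        Per-conformer prediction matrix O_kij, shape (n_conformers, M).
    scale_mode
        Treatment of the uniform scaling factor alpha_k; defaults to the
        convention for the kind (free for SAXS, fixed to 1 otherwise).
    """

    kind: ObservableKind
    O: np.ndarray
    sigma: np.ndarray
    P: np.ndarray
    scale_mode: ScaleMode | None = None
    alpha: float = 1.0
    labels: tuple | None = field(default=None, repr=False)

    def __post_init__(self):
        self.kind = ObservableKind(self.kind)
        self.O = np.asarray(self.O, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        if self.scale_mode is None:
            self.scale_mode = (
                ScaleMode.FREE_POSITIVE
                if self.kind is ObservableKind.SAXS
                else ScaleMode.FIXED_ONE
            )
        else:
            self.scale_mode = ScaleMode(self.scale_mode)
        m = self.O.size
        if self.sigma.shape != (m,):
            raise ValueError("sigma must match O in length")
        if self.P.shape[1] != m:
            raise ValueError(
                f"P has {self.P.shape[1]} columns but {m} observables measured"
            )
        if np.any(self.sigma <= 0):
            raise ValueError("uncertainties must be strictly positive")
        if self.labels is not None:
            self.labels = tuple(self.labels)

    @property
    def M(self) -> int:
        """Number of fitted observables M_k."""
        return self.O.size

    @property
    def n_conformers(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class RefinementResult:
    """Outcome of one BME minimisation at a fixed theta."""

    weights: WeightedEnsemble
    theta: float
    chi2_per_block: tuple
    alpha_per_block: tuple
    s_rel: float
    loss: float
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self):
        if self.s_rel > 1e-12:
            raise ValueError(f"relative entropy must be <= 0, got {self.s_rel}")

    def total_chi2(self, blocks) -> float:
        """M_k-weighted total chi^2 over the given blocks."""
        return float(
            sum(b.M * c for b, c in zip(blocks, self.chi2_per_block, strict=True))
        )
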