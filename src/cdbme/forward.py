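"""Linear forward models: basis-set CD prediction and ensemble averaging.

The CD spectrum of a conformation (or ensemble) is modelled as a linear
combination of "pure" basis spectra, one per secondary-structure class:
I(lambda) = sum_k F_k * B_k(lambda).  Ensemble observables are weighted
means of per-conformer predictions, so every forward model here is linear
in the weights.

Uncertainty models for the refinement:

* CD: sigma = delta*|O| + sigma0 with delta = 0.2 (intensity-normalisation
  uncertainty from concentration/path-length determination) and
  sigma0 = 0.75 kMRE (machine error).
* Chemical shifts: fixed per-atom-type sigma reflecting predictor accuracy
  (0.95 / 1.03 / 1.13 ppm for CA / CB / CO).
* SAXS: per-point sigma supplied with the measured curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from .core import normalize_weights

__all__ = [
    "BasisSet",
    "SSComposition",
    "predict_spectrum",
    "ensemble_average",
    "ensemble_ss",
    "cd_sigma",
    "cs_sigma",
    "CD_DELTA",
    "CD_SIGMA0",
    "CS_SIGMA_PPM",
]

#: default fractional CD intensity-normalisation uncertainty
CD_DELTA = 0.2
#: default CD machine error floor, kMRE
CD_SIGMA0 = 0.75
#: chemical-shift uncertainties (ppm) per backbone carbon atom type
CS_SIGMA_PPM = {"CA": 0.95, "CB": 1.03, "CO": 1.13}


class SchemeMismatchError(ValueError):
    """Class schemes of two objects that must share one do not."""


@dataclass(frozen=True)
class BasisSet:
    """Pure-component CD basis spectra on a common wavelength grid.

    ``B[k, l]`` is the intensity (kMRE per unit fraction) of class ``k``
    at ``wavelengths[l]``; wavelengths are in nm, strictly increasing.
    """

    class_names: tuple
    wavelengths: np.ndarray
    B: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "class_names", tuple(self.class_names))
        wl = np.asarray(self.wavelengths, dtype=float)
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "B", B)
        if B.shape != (len(self.class_names), wl.size):
            raise ValueError("B must be (n_classes, n_wavelengths)")
        if wl.size >= 2 and np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass(frozen=True)
class SSComposition:
    """Secondary-structure fractions under a named classification scheme.

    Pure-SS fractions must sum to one; optional side-chain correction
    channels (flagged through ``side_chain_mask``) are exempt from the
    sum constraint since they scale with composition, not structure.
    """

    scheme: str
    class_names: tuple
    F: np.ndarray
    side_chain_mask: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "class_names", tuple(self.class_names))
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "F", F)
        if F.shape != (len(self.class_names),):
            raise ValueError("F must match class_names in length")
        if np.any(F < -1e-12):
            raise ValueError("fractions must be nonnegative")
        if self.side_chain_mask is not None:
            mask = np.asarray(self.side_chain_mask, dtype=bool)
            object.__setattr__(self, "side_chain_mask", mask)
            if mask.shape != F.shape:
                raise ValueError("side_chain_mask must match F in length")
            ss_sum = F[~mask].sum()
        else:
            ss_sum = F.sum()
        if abs(ss_sum - 1.0) > 1e-6:
            raise ValueError(
                f"pure-SS fractions sum to {ss_sum!r}, expected 1 (scheme "
                f"{self.scheme!r})"
            )

    def as_dict(self) -> dict:
        return dict(zip(self.class_names, self.F.tolist()))


def predict_spectrum(comp: SSComposition, basis: BasisSet):
    """Predict a CD spectrum as the composition-weighted sum of basis spectra.

    Returns a :class:`cdbme.metrics.Spectrum` with role ``"calc"`` on the
    basis wavelength grid.
    """
    from .metrics import Spectrum  # deferred: metrics imports this module

    if tuple(comp.class_names) != tuple(basis.class_names):
        raise SchemeMismatchError(
            f"composition classes {comp.class_names} do not match basis "
            f"classes {basis.class_names}"
        )
    intensities = comp.F @ basis.B
    return Spectrum(basis.wavelengths.copy(), intensities, role="calc")


def ensemble_average(w: npt.ArrayLike, P: npt.ArrayLike) -> np.ndarray:
    """Weighted column mean sum_j w_j * P[j, :] of per-conformer predictions."""
    w = np.asarray(w, dtype=float)
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape[0] != w.size:
        raise ValueError(
            f"P has {P.shape[0]} conformer rows but {w.size} weights given"
        )
    return w @ P


def ensemble_ss(w: npt.ArrayLike, comps: list[SSComposition]) -> SSComposition:
    """Ensemble-average secondary-structure composition.

    All per-conformer compositions must share one scheme; the result is
    their convex combination and hence itself a valid composition.
    """
    if not comps:
        raise ValueError("need at least one composition")
    scheme = comps[0].scheme
    names = comps[0].class_names
    for c in comps[1:]:
        if c.scheme != scheme or c.class_names != names:
            raise SchemeMismatchError(
                f"composition scheme {c.scheme!r} != {scheme!r}"
            )
    w = normalize_weights(w)
    if w.size != len(comps):
        raise ValueError("one weight per composition required")
    F = w @ np.vstack([c.F for c in comps])
    return SSComposition(scheme, names, F, side_chain_mask=comps[0].side_chain_mask)


def cd_sigma(
    O: npt.ArrayLike, delta: float = CD_DELTA, sigma0: float = CD_SIGMA0
) -> np.ndarray:
    """CD uncertainty model sigma = delta*|O| + sigma0 (kMRE).

    The magnitude |O| is used because CD intensities are signed and a
    negative uncertainty would be meaningless.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be > 0")
    return delta * np.abs(np.asarray(O, dtype=float)) + sigma0


def cs_sigma(atom_type: str) -> float:
    """Fixed chemical-shift uncertainty (ppm) for a backbone carbon type."""
    try:
        return CS_SIGMA_PPM[atom_type.upper()]
    except KeyError:
        raise ValueError(
            f"unknown atom type {atom_type!r}; expected one of "
            f"{sorted(CS_SIGMA_PPM)}"
        ) from None
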