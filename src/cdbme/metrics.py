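"""Accuracy metrics for CD prediction and secondary-structure estimation.

Two headline deviations quantify accuracy:

* RMSD of CD intensities (kMRE) between a measured and a predicted
  spectrum over their overlapping wavelengths,

      RMSD_CD = sqrt( (1/N) * sum_lambda (alpha * I_exp - I_calc)^2 ),

  where the optional scaling factor alpha is applied to the
  *experimental* spectrum and chosen to minimise the RMSD, absorbing
  intensity-normalisation errors (concentration, path length).

* RMSD of secondary-structure fractions between an estimated and a
  reference composition over the M classes of a scheme,

      RMSD_SS = sqrt( (1/M) * sum_k (F_est_k - F_ref_k)^2 ),

  complemented by a scale-free chi^2 when per-class uncertainties are
  available.

SAXS model quality is quoted as chi = sqrt(chi2) with the scale factor
at its optimum, which makes it insensitive to any rescaling of the
predicted curve.  Group statistics are reported as mean +/- SEM (sample
standard deviation over sqrt(n)), with half-up rounding for printed
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from .core import ObservableBlock, ScaleMode
from .forward import SSComposition

__all__ = [
    "Spectrum",
    "ClassMap",
    "GroupSummary",
    "regrid_spectrum",
    "rmsd_cd",
    "rmsd_ss",
    "chi2_ss",
    "group_classes",
    "saxs_chi",
    "summarize",
    "round_half_up",
]


@dataclass(frozen=True)
class Spectrum:
    """A CD spectrum: wavelength grid (nm) with intensities (kMRE)."""

    wavelengths: np.ndarray
    I: np.ndarray
    role: str = "exp"  # "exp" (measured) or "calc" (predicted)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.I, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "I", inten)
        if wl.shape != inten.shape or wl.ndim != 1:
            raise ValueError("wavelengths and intensities must be equal-length 1-D")
        if wl.size >= 2 and np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")
        if self.role not in ("exp", "calc"):
            raise ValueError("role must be 'exp' or 'calc'")


def regrid_spectrum(s: Spectrum, grid: npt.ArrayLike) -> Spectrum:
    """Linearly interpolate a spectrum onto the grid points it covers.

    Grid points outside the spectrum's wavelength span are dropped (they
    cannot be compared); an empty overlap is an error.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.wavelengths[0], s.wavelengths[-1]
    keep = (grid >= lo) & (grid <= hi)
    if not keep.any():
        raise ValueError("no overlap between requested grid and spectrum span")
    sub = grid[keep]
    return Spectrum(sub, np.interp(sub, s.wavelengths, s.I), role=s.role)


def rmsd_cd(
    I_exp: Spectrum, I_calc: Spectrum, scale: bool = True
) -> tuple[float, float]:
    """RMSD (kMRE) between measured and predicted CD spectra.

    The predicted spectrum is interpolated onto the measured grid over
    the overlapping wavelength range.  With ``scale=True`` the
    experimental intensities are rescaled by the least-squares
    alpha = sum(I_exp*I_calc)/sum(I_exp^2) before the comparison;
    otherwise alpha = 1.

    Returns ``(rmsd, alpha)``.
    """
    calc = regrid_spectrum(I_calc, I_exp.wavelengths)
    exp = regrid_spectrum(I_exp, calc.wavelengths)
    if exp.wavelengths.size < 2:
        raise ValueError("need at least two overlapping wavelengths")
    e, c = exp.I, calc.I
    if scale:
        denom = float(e @ e)
        if denom == 0:
            raise ValueError("experimental spectrum is all zero; alpha undefined")
        alpha = float(e @ c) / denom
    else:
        alpha = 1.0
    return float(np.sqrt(np.mean((alpha * e - c) ** 2))), alpha


def rmsd_ss(F_est: SSComposition, F_ref: SSComposition) -> float:
    """Root-mean-square deviation between two compositions on one scheme."""
    if F_est.scheme != F_ref.scheme or F_est.class_names != F_ref.class_names:
        raise ValueError(
            f"scheme mismatch: {F_est.scheme!r} vs {F_ref.scheme!r}"
        )
    return float(np.sqrt(np.mean((F_est.F - F_ref.F) ** 2)))


def chi2_ss(
    F_est: SSComposition, F_ref: SSComposition, sigma_est: npt.ArrayLike
) -> float:
    """Scale-free reduced chi^2 of estimated vs reference SS fractions."""
    if F_est.scheme != F_ref.scheme or F_est.class_names != F_ref.class_names:
        raise ValueError(
            f"scheme mismatch: {F_est.scheme!r} vs {F_ref.scheme!r}"
        )
    sigma = np.asarray(sigma_est, dtype=float)
    if sigma.shape != F_est.F.shape:
        raise ValueError("one uncertainty per class required")
    if np.any(sigma <= 0):
        raise ValueError("uncertainties must be strictly positive")
    return float(np.mean(((F_ref.F - F_est.F) / sigma) ** 2))


@dataclass(frozen=True)
class ClassMap:
    """Surjective grouping of one SS scheme's classes into another's.

    ``assignment`` maps every source class to a target class; grouped
    fractions are sums of their source fractions, so total fraction mass
    is conserved.  An optional ``completion`` names a target class whose
    fraction is recomputed last as one minus the sum of the others
    (e.g. a three-class scheme reporting only helix and sheet, with
    coil completed as the remainder).
    """

    source_scheme: str
    target_scheme: str
    target_names: tuple
    assignment: dict
    completion: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "target_names", tuple(self.target_names))
        object.__setattr__(self, "assignment", dict(self.assignment))
        unknown = set(self.assignment.values()) - set(self.target_names)
        if unknown:
            raise ValueError(f"assignment targets not in target_names: {unknown}")
        if self.completion is not None and self.completion not in self.target_names:
            raise ValueError(f"completion class {self.completion!r} unknown")


def group_classes(F: SSComposition, cmap: ClassMap) -> SSComposition:
    """Regroup a composition into a coarser scheme via a ClassMap."""
    if F.scheme != cmap.source_scheme:
        raise ValueError(
            f"composition scheme {F.scheme!r} != map source {cmap.source_scheme!r}"
        )
    out = dict.fromkeys(cmap.target_names, 0.0)
    for name, frac in zip(F.class_names, F.F):
        if name not in cmap.assignment:
            raise ValueError(f"source class {name!r} has no mapping")
        out[cmap.assignment[name]] += float(frac)
    if cmap.completion is not None:
        rest = sum(v for k, v in out.items() if k != cmap.completion)
        out[cmap.completion] = 1.0 - rest
    return SSComposition(
        cmap.target_scheme,
        cmap.target_names,
        np.array([out[k] for k in cmap.target_names]),
    )


def saxs_chi(block: ObservableBlock, w: npt.ArrayLike) -> float:
    """SAXS goodness-of-fit chi = sqrt(chi2) with the scale at its optimum.

    Because alpha is profiled out, multiplying all predictions by any
    positive constant leaves chi unchanged.
    """
    from .refine import chi2_block  # local import to avoid a cycle

    if block.scale_mode is not ScaleMode.FREE_POSITIVE:
        raise ValueError("saxs_chi requires a free-scale block")
    return float(math.sqrt(chi2_block(block, w)))


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero, as printed tables are rounded."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SEM of a metric over a group of ensembles."""

    values: tuple
    mean: float
    sem: float | None
    n: int

    def rounded(self, decimals: int) -> tuple[float, float | None]:
        sem = None if self.sem is None else round_half_up(self.sem, decimals)
        return round_half_up(self.mean, decimals), sem


def summarize(values, round_to: int | None = None) -> GroupSummary:
    """Mean and standard error of a metric list; NA/None values excluded.

    With fewer than two valid values the SEM is undefined (None).
    ``round_to`` only affects the convenience fields returned by
    :meth:`GroupSummary.rounded`; stored mean/sem stay unrounded.
    """
    clean = [float(v) for v in values if v is not None and not np.isnan(v)]
    if not clean:
        raise ValueError("no non-NA values to summarise")
    n = len(clean)
    mean = float(np.mean(clean))
    sem = float(np.std(clean, ddof=1) / math.sqrt(n)) if n >= 2 else None
    return GroupSummary(values=tuple(clean), mean=mean, sem=sem, n=n)
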