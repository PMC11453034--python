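"""Plain-text readers and writers and the run configuration.

All formats are columnar TSV with ``#`` comment lines, matching the
ecosystem of CD/SAXS deposition files (PCDDB/SASBDB dumps are columnar
text):

* spectrum: two columns, wavelength (nm) and intensity (kMRE);
* SAXS curve: three columns, q (1/A), intensity, sigma;
* chemical shifts: residue, atom type (CA/CB/CO), shift (ppm);
* prediction matrix: first column conformer id, header names the
  observables, ``NA`` marks missing entries;
* weights: conformer id and weight;
* SS composition: class name and fraction;
* basis set: header of class names, then wavelength + one column per
  class;
* sub-ensemble members: conformer id and multiplicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import WeightedEnsemble
from .forward import CD_DELTA, CD_SIGMA0, BasisSet, SSComposition
from .metrics import Spectrum
from .refine import DEFAULT_THETA_GRID, ThetaScan
from .subsample import DEFAULT_REPLICAS, DEFAULT_SIZES, SizeTable, SubEnsemble

__all__ = [
    "FormatError",
    "RunConfig",
    "read_spectrum",
    "write_spectrum",
    "read_saxs",
    "write_saxs",
    "read_shifts",
    "write_shifts",
    "read_matrix",
    "write_matrix",
    "read_weights",
    "write_weights",
    "read_composition",
    "write_composition",
    "read_basis",
    "write_basis",
    "write_scan_report",
    "write_size_table",
    "write_members",
    "read_members",
]


class FormatError(ValueError):
    """A file does not conform to its documented format."""


def _read_numeric(path, n_cols: int, what: str) -> np.ndarray:
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric {what} data ({exc})") from exc
    if data.size == 0:
        raise FormatError(f"{path}: empty {what} file")
    if data.shape[1] != n_cols:
        raise FormatError(
            f"{path}: expected {n_cols} columns for {what}, got {data.shape[1]}"
        )
    return data


def read_spectrum(path) -> Spectrum:
    """Read a two-column spectrum; descending input is sorted (warning)."""
    data = _read_numeric(path, 2, "spectrum")
    if data.shape[0] < 2:
        raise FormatError(f"{path}: a spectrum needs at least 2 points")
    wl, inten = data[:, 0], data[:, 1]
    if np.any(np.diff(wl) <= 0):
        if np.unique(wl).size != wl.size:
            raise FormatError(f"{path}: duplicate wavelengths")
        warnings.warn(
            f"{path}: wavelengths not ascending; sorting", stacklevel=2
        )
        order = np.argsort(wl)
        wl, inten = wl[order], inten[order]
    return Spectrum(wl, inten, role="exp")


def write_spectrum(path, spectrum: Spectrum, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("# wavelength_nm\tintensity_kMRE\n")
        for wl, inten in zip(spectrum.wavelengths, spectrum.I):
            fh.write(f"{wl:.6g}\t{inten:.10g}\n")


def read_saxs(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a three-column SAXS curve (q, I, sigma)."""
    data = _read_numeric(path, 3, "SAXS")
    q, inten, sigma = data.T
    if np.any(sigma <= 0):
        raise FormatError(f"{path}: SAXS sigmas must be > 0")
    return q, inten, sigma


def write_saxs(path, q, I, sigma) -> None:
    with open(path, "w") as fh:
        fh.write("# q_invA\tintensity\tsigma\n")
        for row in zip(q, I, sigma):
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_shifts(path) -> pd.DataFrame:
    """Read chemical shifts: residue, atom type, shift (ppm)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["residue", "atom", "shift_ppm"],
        dtype={"residue": str, "atom": str, "shift_ppm": float},
    )
    if df.empty:
        raise FormatError(f"{path}: empty chemical-shift file")
    return df


def write_shifts(path, residues, atoms, shifts) -> None:
    with open(path, "w") as fh:
        fh.write("# residue\tatom\tshift_ppm\n")
        for res, atom, val in zip(residues, atoms, shifts):
            fh.write(f"{res}\t{atom}\t{val:.10g}\n")


def read_matrix(path) -> pd.DataFrame:
    """Read a per-conformer prediction matrix.

    First column holds conformer ids, header names the observables,
    ``NA`` marks missing entries (NaN in the frame, to be masked out of
    the fitted observable count).
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate conformer ids {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from exc
    return df


def write_matrix(path, df: pd.DataFrame) -> None:
    df.to_csv(
        path, sep="\t", na_rep="NA", index_label="conformer_id",
        float_format="%.10g",
    )


def read_weights(path) -> tuple[tuple, np.ndarray]:
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["conformer_id", "weight"],
        dtype={"conformer_id": str, "weight": float},
    )
    if df.empty:
        raise FormatError(f"{path}: empty weights file")
    if df["conformer_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate conformer ids")
    return tuple(df["conformer_id"]), df["weight"].to_numpy()


def write_weights(path, ensemble_or_ids, w=None) -> None:
    if isinstance(ensemble_or_ids, WeightedEnsemble):
        ids, w = ensemble_or_ids.conformer_ids, ensemble_or_ids.w
    else:
        ids = ensemble_or_ids
    with open(path, "w") as fh:
        fh.write("# conformer_id\tweight\n")
        for cid, wj in zip(ids, w):
            fh.write(f"{cid}\t{wj:.12g}\n")


def read_composition(path, scheme: str) -> SSComposition:
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["cls", "fraction"],
        dtype={"cls": str, "fraction": float},
    )
    if df.empty:
        raise FormatError(f"{path}: empty composition file")
    return SSComposition(scheme, tuple(df["cls"]), df["fraction"].to_numpy())


def write_composition(path, comp: SSComposition) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scheme: {comp.scheme}\n# class\tfraction\n")
        for name, frac in zip(comp.class_names, comp.F):
            fh.write(f"{name}\t{frac:.10g}\n")


def read_basis(path) -> BasisSet:
    """Read a basis set: header of class names, wavelength + class columns."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty basis file")
    wl = df.index.to_numpy(dtype=float)
    return BasisSet(tuple(df.columns), wl, df.to_numpy(dtype=float).T)


def write_basis(path, basis: BasisSet) -> None:
    df = pd.DataFrame(
        basis.B.T, index=basis.wavelengths, columns=list(basis.class_names)
    )
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index_label="wavelength_nm", float_format="%.10g")


def write_scan_report(path, scan: ThetaScan, block_names) -> None:
    """Tabular scan report: theta, per-block chi2 and alpha, S_rel, loss."""
    cols = ["theta"]
    for name in block_names:
        cols += [f"chi2_{name}", f"alpha_{name}"]
    cols += ["s_rel", "loss"]
    with open(path, "w") as fh:
        fh.write("# BME theta scan (prior row: theta=inf)\n")
        fh.write("\t".join(cols) + "\n")
        prior = ["inf"]
        for c in scan.prior_chi2_per_block:
            prior += [f"{c:.8g}", "1"]
        prior += ["0", "-"]
        fh.write("\t".join(prior) + "\n")
        for theta, res in zip(scan.thetas, scan.results):
            row = [f"{theta:g}"]
            for c, a in zip(res.chi2_per_block, res.alpha_per_block):
                row += [f"{c:.8g}", f"{a:.8g}"]
            row += [f"{res.s_rel:.8g}", f"{res.loss:.8g}"]
            fh.write("\t".join(row) + "\n")


def write_size_table(path, table: SizeTable, block_names) -> None:
    with open(path, "w") as fh:
        cols = ["size"]
        for name in block_names:
            cols += [f"mean_chi2_{name}", f"sem_chi2_{name}", f"concat_chi2_{name}"]
        fh.write("\t".join(cols) + "\n")
        for si, size in enumerate(table.sizes):
            row = [str(size)]
            for k in range(len(block_names)):
                row += [
                    f"{table.mean_chi2[si, k]:.8g}",
                    f"{table.sem_chi2[si, k]:.8g}",
                    f"{table.concat_chi2[si, k]:.8g}",
                ]
            fh.write("\t".join(row) + "\n")


def write_members(path, sub: SubEnsemble, conformer_ids) -> None:
    with open(path, "w") as fh:
        fh.write(f"# size={sub.size} replica={sub.replica_id} seed={sub.seed}\n")
        fh.write("# conformer_id\tmultiplicity\n")
        for idx, mult in sub.members:
            fh.write(f"{conformer_ids[idx]}\t{mult}\n")


def read_members(path, conformer_ids) -> SubEnsemble:
    index = {cid: j for j, cid in enumerate(conformer_ids)}
    members = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cid, mult = line.split("\t")
            members.append((index[cid], int(mult)))
    members = tuple(sorted(members))
    size = sum(m for _, m in members)
    return SubEnsemble(size=size, members=members, replica_id=0, seed=0)


@dataclass
class RunConfig:
    """Pipeline configuration with the study's default parameters."""

    outdir: str = "cdbme_out"
    seed: int = 0
    theta_grid: tuple = DEFAULT_THETA_GRID
    frac: float = 0.5
    cd_delta: float = CD_DELTA
    cd_sigma0: float = CD_SIGMA0
    sizes: tuple = DEFAULT_SIZES
    replicas: int = DEFAULT_REPLICAS
    improve_tol: float = 0.05
    agree_tol: float = 1.0
    cd_measured: str | None = None
    cd_predictions: str | None = None
    saxs_measured: str | None = None
    saxs_predictions: str | None = None
    cs_measured: str | None = None
    cs_predictions: str | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs, extra=extra)
        for t in ("theta_grid", "sizes"):
            setattr(cfg, t, tuple(getattr(cfg, t)))
        if any(t <= 0 for t in cfg.theta_grid):
            raise FormatError(f"{path}: theta grid must be positive")
        base = Path(path).parent
        for f in (
            "cd_measured", "cd_predictions", "saxs_measured",
            "saxs_predictions", "cs_measured", "cs_predictions",
        ):
            val = getattr(cfg, f)
            if val is not None:
                p = Path(val)
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise FormatError(f"{path}: referenced file missing: {p}")
                setattr(cfg, f, str(p))
        return cfg

    def dump(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "extra" and v is not None
        }
        data.update(self.extra)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
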