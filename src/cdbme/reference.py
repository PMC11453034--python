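"""Shipped assessment tables for the IDP8 reference set.

The package ships the per-ensemble deviation tables for the IDP8
reference set of disordered-protein ensembles -- SAXS chi, backbone
chemical-shift RMSDs and CD-intensity RMSDs -- as plain TSV data.  They
serve as worked inputs for the group-summary layer: recomputing the
published group statistics (mean +/- SEM over the ensembles of a group)
exercises ``metrics.summarize`` end to end on real numbers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .metrics import GroupSummary, summarize

__all__ = [
    "load_assessment",
    "load_cd_rmsd",
    "group_summary",
    "refinement_basis_summary",
]


def _load(name: str) -> pd.DataFrame:
    path = resources.files("cdbme").joinpath("data", name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#", na_values=["NA", "-"])


def load_assessment() -> pd.DataFrame:
    """Per-ensemble SAXS chi, chemical-shift RMSDs and CD RMSD."""
    df = _load("idp8_assessment.tsv")
    df["group"] = df["group"].astype(str)
    return df


def load_cd_rmsd() -> pd.DataFrame:
    """Per-ensemble CD-prediction RMSD per method / basis set."""
    df = _load("idp8_cd_rmsd.tsv")
    df["group"] = df["group"].astype(str)
    return df


def group_summary(df: pd.DataFrame, group, columns) -> GroupSummary:
    """Mean +/- SEM of one or more metric columns within a group.

    ``group`` may be a single label or a list; ``columns`` likewise.
    All selected values are pooled into one summary (NA cells dropped).
    """
    groups = [group] if isinstance(group, str) else list(group)
    cols = [columns] if isinstance(columns, str) else list(columns)
    sel = df[df["group"].isin(groups)]
    values = sel[cols].to_numpy().ravel()
    return summarize(values[~pd.isna(values)])


def refinement_basis_summary(df: pd.DataFrame | None = None) -> GroupSummary:
    """CD RMSD of CD-refined ensembles evaluated with their own basis set.

    For each Group B ensemble, picks the RMSD column of the basis set
    that was used during its refinement and summarises those values.
    """
    if df is None:
        df = load_cd_rmsd()
    rows = df[df["refinement_basis"].notna()]
    values = [row[row["refinement_basis"]] for _, row in rows.iterrows()]
    return summarize(values)
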