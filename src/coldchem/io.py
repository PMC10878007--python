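"""Delimited-text readers and writers for panel inputs and outputs.

All formats are tab-separated text: metadata (one row per biological
sample), peak tables in long form (sample_id, fa_label, area), spectra
in wide form (first column ``wavenumber``, one column per spectrum) with
a sidecar table mapping spectrum columns to samples and technical
replicates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ftir import SpectrumSet
from .gc_quant import DEFAULT_IS_MASS_MG, PeakTable

__all__ = [
    "read_metadata", "write_metadata",
    "read_peak_tables", "write_peak_tables",
    "read_spectra", "write_spectra",
    "spectrum_column_name",
]


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata must have a sample_id column")
    return df


def write_peak_tables(tables: list[PeakTable], path) -> None:
    rows = [
        {"sample_id": pt.sample_id, "fa_label": label, "area": area}
        for pt in tables
        for label, area in pt.areas.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_peak_tables(
    path,
    metadata: pd.DataFrame,
    is_label: str = "C19:0",
    is_mass_mg: float = DEFAULT_IS_MASS_MG,
    biomass_column: str = "biomass_dry_mg",
) -> list[PeakTable]:
    """Read long-form peak areas; biomass comes from the metadata table."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "fa_label", "area"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if biomass_column not in metadata.columns:
        raise ValueError(
            f"metadata lacks the {biomass_column!r} column needed for "
            "quantification"
        )
    biomass = metadata.set_index("sample_id")[biomass_column]
    tables = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        if sample_id not in biomass.index:
            raise KeyError(
                f"sample {sample_id!r} has peaks but no metadata row"
            )
        tables.append(PeakTable(
            sample_id=str(sample_id),
            areas=dict(zip(grp["fa_label"], grp["area"].astype(float))),
            biomass_dry_mg=float(biomass.loc[sample_id]),
            is_label=is_label,
            is_mass_mg=is_mass_mg,
        ))
    return tables


def spectrum_column_name(sample_id: str, replicate: int) -> str:
    return f"{sample_id}_t{replicate + 1}"


def write_spectra(sset: SpectrumSet, path, meta_path=None) -> None:
    """Wide spectra table plus an optional spectrum->sample sidecar."""
    columns = {
        spectrum_column_name(
            str(row.sample_id), int(row.replicate)
        ): sset.matrix[i]
        for i, row in enumerate(sset.metadata.itertuples(index=False))
    }
    wide = pd.DataFrame({"wavenumber": sset.wavenumbers, **columns})
    wide.to_csv(path, sep="\t", index=False)
    if meta_path is not None:
        meta = sset.metadata.copy()
        meta.insert(0, "spectrum_id", [
            spectrum_column_name(str(r.sample_id), int(r.replicate))
            for r in sset.metadata.itertuples(index=False)
        ])
        meta.to_csv(meta_path, sep="\t", index=False)


def read_spectra(path, meta_path=None) -> SpectrumSet:
    wide = pd.read_csv(path, sep="\t")
    if "wavenumber" not in wide.columns:
        raise ValueError(f"{path}: first column must be 'wavenumber'")
    wavenumbers = wide["wavenumber"].to_numpy(float)
    spectrum_ids = [c for c in wide.columns if c != "wavenumber"]
    if not spectrum_ids:
        raise ValueError(f"{path}: no spectrum columns found")
    matrix = wide[spectrum_ids].to_numpy(float).T

    if meta_path is not None and Path(meta_path).exists():
        meta = pd.read_csv(meta_path, sep="\t")
        meta = meta.set_index("spectrum_id").loc[spectrum_ids].reset_index()
    else:
        # Fall back to parsing the "<sample>_t<k>" column convention.
        sample_ids, reps = [], []
        for sid in spectrum_ids:
            stem, _, tail = sid.rpartition("_t")
            if stem and tail.isdigit():
                sample_ids.append(stem)
                reps.append(int(tail) - 1)
            else:
                sample_ids.append(sid)
                reps.append(0)
        meta = pd.DataFrame({
            "spectrum_id": spectrum_ids,
            "sample_id": sample_ids,
            "replicate": reps,
        })
    return SpectrumSet(wavenumbers, matrix, meta)
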