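"""Band-ratio compositional estimates from preprocessed FTIR spectra.

The amide I band near 1656 cm-1 (protein alpha-helix C=O stretch) is a
relatively temperature-stable reference. Two ratios against it estimate
relative composition:

* L/P — ester C=O stretch at 1742 cm-1 over amide I: relative total
  lipid content;
* P/P — P-O-C symmetric stretch at 1083 cm-1 (phospholipids, teichoic
  acids, nucleic acids) over amide I: relative phosphorus-compound
  content.

Reported band positions for these peaks vary by a few cm-1 between
instruments and studies (1742/1743/1734; 1656/1654), so the default
mode searches for the local extremum within +-8 cm-1 of the nominal
center, which absorbs such discrepancies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ftir import Spectrum, SpectrumSet

__all__ = [
    "BandDefinition",
    "BandRatioResult",
    "band_value",
    "compute_ratios",
]


@dataclass(frozen=True)
class BandDefinition:
    """A band position and the rule for reading its height."""

    name: str
    center: float
    search_halfwidth: float = 8.0
    mode: str = "local_extremum_in_window"

    def __post_init__(self) -> None:
        if self.mode not in ("height_at_center",
                             "local_extremum_in_window"):
            raise ValueError(f"unknown band mode {self.mode!r}")
        if self.search_halfwidth <= 0:
            raise ValueError("search_halfwidth must be positive")


@dataclass
class BandRatioResult:
    """Per-spectrum band ratios with the band readings actually used."""

    sample_id: str
    replicate: int
    L_over_P: float
    P_over_P: float
    lp_numerator: float
    pp_numerator: float
    denominator: float
    lp_wavenumber: float
    pp_wavenumber: float
    denom_wavenumber: float
    valid: bool = True


def band_value(
    spectrum: Spectrum,
    band: BandDefinition,
    magnitude: bool = False,
) -> tuple[float, float]:
    """Read one band height; returns (value, selected wavenumber).

    ``height_at_center`` reads the value at the grid point nearest the
    nominal center; ``local_extremum_in_window`` the maximum (of the
    absolute value when ``magnitude`` is set, as appropriate for
    second-derivative spectra) within +-``search_halfwidth``.
    """
    w = spectrum.wavenumbers
    v = spectrum.values
    lo, hi = band.center - band.search_halfwidth, \
        band.center + band.search_halfwidth
    if hi < w.min() or lo > w.max():
        raise ValueError(
            f"band {band.name!r} window [{lo}, {hi}] lies outside the "
            f"spectrum span [{w.min()}, {w.max()}]"
        )
    if band.mode == "height_at_center":
        idx = int(np.argmin(np.abs(w - band.center)))
    else:
        window = np.flatnonzero((w >= lo) & (w <= hi))
        values = np.abs(v[window]) if magnitude else v[window]
        idx = int(window[np.argmax(values)])
    value = float(abs(v[idx])) if magnitude else float(v[idx])
    return value, float(w[idx])


def compute_ratios(
    sset: SpectrumSet,
    lp_bands: tuple[float, float] = (1742.0, 1656.0),
    pp_bands: tuple[float, float] = (1083.0, 1656.0),
    mode: str = "local_extremum_in_window",
    search_halfwidth: float = 8.0,
    magnitude: bool = False,
    denom_tol: float = 1e-12,
) -> list[BandRatioResult]:
    """Compute L/P and P/P for every spectrum in the set.

    A denominator at or below ``denom_tol`` flags the spectrum invalid
    (ratios NaN) rather than dropping it. Set ``magnitude=True`` when the
    ratio path ran in second-derivative mode.
    """
    lp_num = BandDefinition("lp_numerator", lp_bands[0],
                            search_halfwidth, mode)
    pp_num = BandDefinition("pp_numerator", pp_bands[0],
                            search_halfwidth, mode)
    if lp_bands[1] != pp_bands[1]:
        raise ValueError("L/P and P/P must share the protein reference "
                         "band")
    denom = BandDefinition("protein_reference", lp_bands[1],
                           search_halfwidth, mode)

    results: list[BandRatioResult] = []
    for spectrum in sset.spectra():
        lp_v, lp_w = band_value(spectrum, lp_num, magnitude=magnitude)
        pp_v, pp_w = band_value(spectrum, pp_num, magnitude=magnitude)
        d_v, d_w = band_value(spectrum, denom, magnitude=magnitude)
        valid = d_v > denom_tol
        results.append(
            BandRatioResult(
                sample_id=spectrum.sample_id,
                replicate=spectrum.replicate,
                L_over_P=lp_v / d_v if valid else float("nan"),
                P_over_P=pp_v / d_v if valid else float("nan"),
                lp_numerator=lp_v,
                pp_numerator=pp_v,
                denominator=d_v,
                lp_wavenumber=lp_w,
                pp_wavenumber=pp_w,
                denom_wavenumber=d_w,
                valid=valid,
            )
        )
    return results


def ratios_frame(results: list[BandRatioResult]) -> pd.DataFrame:
    """Tidy one-row-per-spectrum frame of band-ratio results."""
    return pd.DataFrame([r.__dict__ for r in results])


def average_technical_replicates(frame: pd.DataFrame) -> pd.DataFrame:
    """Average ratios over technical replicates per sample.

    Ratios are computed per spectrum first and averaged after (the ratio
    of a mean spectrum is not the mean of ratios); invalid spectra are
    excluded from the mean and counted.
    """
    valid = frame[frame["valid"]]
    grouped = valid.groupby("sample_id", sort=True).agg(
        L_over_P=("L_over_P", "mean"),
        P_over_P=("P_over_P", "mean"),
        n_replicates=("L_over_P", "size"),
    )
    n_invalid = (
        frame[~frame["valid"]].groupby("sample_id").size()
        .reindex(grouped.index, fill_value=0)
    )
    grouped["n_invalid"] = n_invalid
    return grouped.reset_index()
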