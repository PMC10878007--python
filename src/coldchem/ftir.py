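"""FTIR spectral preprocessing: Savitzky-Golay, region cutting, EMSC.

Two preprocessing paths are supported, mirroring common practice for
high-throughput transmission FTIR of dried microbial films:

* multivariate (PCA) path — Savitzky-Golay second derivative (order 2,
  window 11), removal of the uninformative regions 4000-3100, 2800-1800
  and 900-400 cm-1, then extended multiplicative signal correction
  (EMSC) against the set mean to separate chemical signal from
  scatter/thickness artifacts;
* univariate (band-ratio) path — Savitzky-Golay smoothing and selection
  of the informative 1900-900 cm-1 region.

Wavenumber grids are stored in descending (spectroscopic) order; all
interval notation is (high, low) cm-1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "EMSCModel",
    "NonUniformGridError",
    "DEFAULT_REMOVE_REGIONS",
    "DEFAULT_RATIO_REGION",
    "savgol",
    "cut_regions",
    "select_region",
    "emsc_fit",
    "emsc_correct",
    "pipeline_pca",
    "pipeline_ratio",
]

DEFAULT_REMOVE_REGIONS: tuple[tuple[float, float], ...] = (
    (4000.0, 3100.0),
    (2800.0, 1800.0),
    (900.0, 400.0),
)
DEFAULT_RATIO_REGION: tuple[float, float] = (1900.0, 900.0)


class NonUniformGridError(ValueError):
    """The wavenumber grid is not uniform; resample before filtering."""


def _normalize_grid(wavenumbers: np.ndarray, values: np.ndarray):
    w = np.asarray(wavenumbers, dtype=float)
    v = np.asarray(values, dtype=float)
    if w.ndim != 1:
        raise ValueError("wavenumbers must be one-dimensional")
    if v.shape[-1] != w.shape[0]:
        raise ValueError("values and wavenumbers lengths differ")
    dw = np.diff(w)
    if w.size >= 2 and np.all(dw > 0):
        w = w[::-1].copy()
        v = v[..., ::-1].copy()
    elif w.size >= 2 and not np.all(dw < 0):
        raise ValueError("wavenumber grid must be strictly monotonic")
    return w, v


@dataclass
class Spectrum:
    """A single spectrum on a strictly monotonic wavenumber grid."""

    wavenumbers: np.ndarray
    values: np.ndarray
    sample_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.wavenumbers, self.values = _normalize_grid(
            self.wavenumbers, self.values
        )


@dataclass
class SpectrumSet:
    """Spectra sharing one grid: matrix rows are samples.

    ``metadata`` carries one row per spectrum (at minimum ``sample_id``
    and ``replicate``) and stays positionally aligned with ``matrix``.
    """

    wavenumbers: np.ndarray
    matrix: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavenumbers, self.matrix = _normalize_grid(
            self.wavenumbers, np.atleast_2d(np.asarray(self.matrix, float))
        )
        if len(self.metadata) != self.matrix.shape[0]:
            raise ValueError("metadata rows must match matrix rows")
        self.metadata = self.metadata.reset_index(drop=True)

    @classmethod
    def from_spectra(cls, spectra: list[Spectrum]) -> "SpectrumSet":
        if not spectra:
            raise ValueError("empty spectrum list")
        grid = spectra[0].wavenumbers
        for s in spectra[1:]:
            if not np.array_equal(s.wavenumbers, grid):
                raise ValueError("all spectra must share one grid")
        meta = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in spectra],
                "replicate": [s.replicate for s in spectra],
            }
        )
        return cls(grid.copy(), np.vstack([s.values for s in spectra]), meta)

    def spectra(self) -> list[Spectrum]:
        return [
            Spectrum(
                self.wavenumbers.copy(),
                self.matrix[i].copy(),
                sample_id=str(self.metadata.iloc[i].get("sample_id", "")),
                replicate=int(self.metadata.iloc[i].get("replicate", 0)),
            )
            for i in range(self.matrix.shape[0])
        ]

    def copy_with(self, wavenumbers=None, matrix=None, metadata=None):
        return SpectrumSet(
            self.wavenumbers if wavenumbers is None else wavenumbers,
            self.matrix if matrix is None else matrix,
            self.metadata if metadata is None else metadata,
        )


def _grid_spacing(w: np.ndarray, rtol: float = 1e-4) -> float:
    dw = np.diff(w)
    spacing = float(np.abs(dw).mean())
    if spacing == 0 or np.any(np.abs(np.abs(dw) - spacing) > rtol * spacing):
        raise NonUniformGridError(
            "wavenumber grid is not uniform; resample onto a uniform "
            "grid before Savitzky-Golay filtering"
        )
    return spacing


def savgol(
    spectrum: Spectrum | SpectrumSet,
    window: int = 11,
    poly_order: int = 2,
    deriv_order: int = 0,
) -> Spectrum | SpectrumSet:
    """Savitzky-Golay filtering (smoothing or second derivative).

    Local least-squares polynomial of degree ``poly_order`` over an odd
    ``window``; ``deriv_order=2`` returns the second derivative in
    absorbance per (cm-1)^2 units, i.e. scaled by the grid spacing.
    Edge points are evaluated from the one-sided end-window polynomial
    fit (the standard interpolating edge mode), so the output length
    equals the input length.
    """
    if window % 2 == 0 or window <= poly_order:
        raise ValueError("window must be odd and exceed poly_order")
    if deriv_order not in (0, 2):
        raise ValueError("deriv_order must be 0 or 2")
    if isinstance(spectrum, SpectrumSet):
        spacing = _grid_spacing(spectrum.wavenumbers)
        out = savgol_filter(
            spectrum.matrix, window, poly_order,
            deriv=deriv_order, delta=spacing, axis=-1, mode="interp",
        )
        return spectrum.copy_with(matrix=out)
    spacing = _grid_spacing(spectrum.wavenumbers)
    out = savgol_filter(
        spectrum.values, window, poly_order,
        deriv=deriv_order, delta=spacing, mode="interp",
    )
    return replace(spectrum, values=out)


def _normalize_interval(interval) -> tuple[float, float]:
    hi, lo = float(interval[0]), float(interval[1])
    if hi < lo:
        hi, lo = lo, hi
    return hi, lo


def cut_regions(
    spectrum: Spectrum | SpectrumSet,
    remove=DEFAULT_REMOVE_REGIONS,
) -> Spectrum | SpectrumSet:
    """Drop grid points inside the removal intervals.

    Intervals are (high, low) cm-1 and closed: a point exactly on an
    interval boundary is removed (removal takes precedence at shared
    endpoints, so the span edges 4000 and 400 cm-1 are dropped with
    their regions).
    """
    w = spectrum.wavenumbers
    keep = np.ones(w.shape, dtype=bool)
    for interval in remove:
        hi, lo = _normalize_interval(interval)
        keep &= ~((w >= lo) & (w <= hi))
    if not keep.any():
        raise ValueError("region cutting removed every grid point")
    if isinstance(spectrum, SpectrumSet):
        return spectrum.copy_with(
            wavenumbers=w[keep], matrix=spectrum.matrix[:, keep]
        )
    return replace(
        spectrum, wavenumbers=w[keep], values=spectrum.values[keep]
    )


def select_region(
    spectrum: Spectrum | SpectrumSet, region=DEFAULT_RATIO_REGION
) -> Spectrum | SpectrumSet:
    """Keep only the closed interval [low, high] cm-1."""
    hi, lo = _normalize_interval(region)
    w = spectrum.wavenumbers
    keep = (w >= lo) & (w <= hi)
    if not keep.any():
        raise ValueError(f"no grid points inside [{lo}, {hi}] cm-1")
    if isinstance(spectrum, SpectrumSet):
        return spectrum.copy_with(
            wavenumbers=w[keep], matrix=spectrum.matrix[:, keep]
        )
    return replace(
        spectrum, wavenumbers=w[keep], values=spectrum.values[keep]
    )


@dataclass
class EMSCModel:
    """Fitted EMSC parameters for a set of spectra.

    Each spectrum y is regressed on {P_0(x), .., P_d(x), reference},
    where x is the wavenumber grid affinely mapped to [-1, 1] and P_k are
    Legendre polynomials (a well-conditioned basis for the baseline).
    ``coefficients`` holds one row per spectrum: [a_0, .., a_d, b] with b
    the multiplicative gain. ``uncorrectable`` flags spectra whose |b|
    fell below tolerance.
    """

    wavenumbers: np.ndarray
    reference: np.ndarray
    poly_degree: int
    coefficients: np.ndarray
    residual_norm: np.ndarray
    b_tol: float = 1e-6

    @property
    def gains(self) -> np.ndarray:
        return self.coefficients[:, -1]

    @property
    def baseline_coefficients(self) -> np.ndarray:
        return self.coefficients[:, :-1]

    @property
    def uncorrectable(self) -> np.ndarray:
        return np.abs(self.gains) < self.b_tol

    def design_matrix(self) -> np.ndarray:
        return _emsc_design(self.wavenumbers, self.reference,
                            self.poly_degree)


def _mapped_x(w: np.ndarray) -> np.ndarray:
    lo, hi = float(w.min()), float(w.max())
    if hi == lo:
        raise ValueError("degenerate wavenumber grid")
    return 2.0 * (w - lo) / (hi - lo) - 1.0


def _emsc_design(
    w: np.ndarray, reference: np.ndarray, poly_degree: int
) -> np.ndarray:
    x = _mapped_x(w)
    poly = np.polynomial.legendre.legvander(x, poly_degree)
    return np.column_stack([poly, reference])


def emsc_fit(
    sset: SpectrumSet,
    reference: Spectrum | np.ndarray | str = "mean",
    poly_degree: int = 2,
    b_tol: float = 1e-6,
) -> EMSCModel:
    """Fit the EMSC model to every spectrum in the set.

    ``reference`` is either an explicit spectrum on the same grid or
    ``"mean"`` (arithmetic mean of the set, the default). Raises on a
    singular design, e.g. a reference collinear with the polynomial
    baseline.
    """
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError("reference must be a spectrum or 'mean'")
        ref = sset.matrix.mean(axis=0)
    elif isinstance(reference, Spectrum):
        if not np.array_equal(reference.wavenumbers, sset.wavenumbers):
            raise ValueError("reference grid differs from the set grid")
        ref = reference.values
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != sset.wavenumbers.shape:
            raise ValueError("reference length differs from the grid")

    design = _emsc_design(sset.wavenumbers, ref, poly_degree)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            "singular EMSC design: reference is collinear with the "
            "polynomial baseline"
        )
    coeffs, _, _, _ = np.linalg.lstsq(design, sset.matrix.T, rcond=None)
    residuals = sset.matrix.T - design @ coeffs
    model = EMSCModel(
        wavenumbers=sset.wavenumbers.copy(),
        reference=ref.copy(),
        poly_degree=poly_degree,
        coefficients=coeffs.T,
        residual_norm=np.linalg.norm(residuals, axis=0),
        b_tol=b_tol,
    )
    n_bad = int(model.uncorrectable.sum())
    if n_bad:
        logger.warning("EMSC: %d spectra have |b| < %.1e and are flagged "
                       "uncorrectable", n_bad, b_tol)
    return model


def emsc_correct(
    sset: SpectrumSet,
    model: EMSCModel,
    drop_uncorrectable: bool = False,
) -> SpectrumSet:
    """Apply the fitted correction: (y - baseline) / b per spectrum.

    Re-fitting a corrected spectrum against the same reference yields
    b ~ 1 and a ~ 0. Uncorrectable spectra (|b| below tolerance) are
    flagged in the metadata column ``emsc_uncorrectable`` and, with
    ``drop_uncorrectable=True``, excluded with a logged count.
    """
    if not np.array_equal(sset.wavenumbers, model.wavenumbers):
        raise ValueError("model grid differs from the set grid")
    design = model.design_matrix()
    baseline = design[:, :-1] @ model.baseline_coefficients.T
    bad = model.uncorrectable
    gains = np.where(bad, 1.0, model.gains)
    corrected = (sset.matrix - baseline.T) / gains[:, None]
    meta = sset.metadata.copy()
    meta["emsc_uncorrectable"] = bad
    out = sset.copy_with(matrix=corrected, metadata=meta)
    if drop_uncorrectable and bad.any():
        logger.warning("EMSC: excluding %d uncorrectable spectra",
                       int(bad.sum()))
        out = out.copy_with(
            matrix=out.matrix[~bad], metadata=out.metadata.loc[~bad]
        )
    return out


def pipeline_pca(
    sset: SpectrumSet,
    window: int = 11,
    poly_order: int = 2,
    remove=DEFAULT_REMOVE_REGIONS,
    reference: Spectrum | np.ndarray | str = "mean",
    poly_degree: int = 2,
    drop_uncorrectable: bool = True,
    return_model: bool = False,
):
    """Multivariate path: SG 2nd derivative -> cut regions -> EMSC."""
    deriv = savgol(sset, window=window, poly_order=poly_order,
                   deriv_order=2)
    cut = cut_regions(deriv, remove=remove)
    model = emsc_fit(cut, reference=reference, poly_degree=poly_degree)
    corrected = emsc_correct(cut, model,
                             drop_uncorrectable=drop_uncorrectable)
    return (corrected, model) if return_model else corrected


def pipeline_ratio(
    sset: SpectrumSet,
    window: int = 11,
    poly_order: int = 2,
    deriv_order: int = 0,
    region=DEFAULT_RATIO_REGION,
) -> SpectrumSet:
    """Univariate path: SG smoothing -> select the 1900-900 cm-1 region.

    ``deriv_order=2`` switches the path to second-derivative band
    magnitudes for downstream ratio analysis.
    """
    smoothed = savgol(sset, window=window, poly_order=poly_order,
                      deriv_order=deriv_order)
    return select_region(smoothed, region=region)
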