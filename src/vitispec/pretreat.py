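"""The nine spectral pre-treatment pipelines ("spectral sources").

Each source maps the raw reflectance matrix to a feature matrix, composing
up to three primitives: the pseudo-absorbance transform A = log10(1/R),
Savitzky-Golay derivatives (polynomial order 3, window 5 points on the
decimated ~10 nm grid), the per-spectrum Standard Normal Variate transform,
and continuum removal against the upper convex hull.  All primitives act on
one spectrum at a time -- no cross-sample statistics -- so features can be
computed once up front without leaking information between CV folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .io import Spectrum, SpectralLibrary, WavelengthGrid

#: the legal source names, in canonical order
SOURCES = (
    "REF",
    "ABS",
    "ABS_SG1",
    "ABS_SNV",
    "ABS_SG1_SNV",
    "ABS_SG2_SNV",
    "REF_SG1",
    "REF_SNV",
    "CR",
)


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay filter parameters.

    Derivatives are expressed per index step of the (decimated) grid; with
    the default factor-10 decimation one step is ~10 nm and the 5-point
    window spans ~50 nm.
    """

    poly_order: int = 3
    window_points: int = 5
    deriv_order: int = 1

    def __post_init__(self) -> None:
        if self.window_points % 2 == 0:
            raise ValueError("window_points must be odd")
        if self.window_points <= self.poly_order:
            raise ValueError("window_points must exceed poly_order")
        if self.deriv_order not in (0, 1, 2):
            raise ValueError("deriv_order must be 0, 1 or 2")


def _as_2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    if x.ndim == 2:
        return x, False
    raise ValueError("expected a vector or a (samples, wavelengths) matrix")


def pseudo_absorbance(r: np.ndarray | Spectrum):
    """A = log10(1/R), the Beer-Lambert-style absorbance proxy.

    Strictly decreasing in R; R=1 maps to 0 and R=10^-k to k.
    """
    if isinstance(r, Spectrum):
        return Spectrum(r.grid, pseudo_absorbance(r.reflectance))
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pseudo-absorbance requires strictly positive reflectance")
    return -np.log10(r)


def snv(x: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: per-spectrum (x - mean) / sd.

    Uses the population standard deviation (divide by n, the chemometrics
    convention), removing additive baseline and multiplicative scatter.
    Idempotent, and invariant to affine maps a*x + b with a > 0.
    """
    arr, was_1d = _as_2d(x)
    if arr.shape[1] < 2:
        raise ValueError("SNV needs at least 2 points per spectrum")
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # population (ddof=0)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for a constant spectrum")
    out = (arr - mean) / sd
    return out[0] if was_1d else out


def savgol(x: np.ndarray, params: SGParams = SGParams()) -> np.ndarray:
    """Savitzky-Golay smoothed derivative, same length as the input.

    Edges are handled by evaluating the local polynomial fit (scipy's
    ``interp`` mode), keeping the feature width fixed.  Derivatives are per
    index step (unit spacing), not per nm.
    """
    arr, was_1d = _as_2d(x)
    if arr.shape[1] < params.window_points:
        raise ValueError(
            f"window of {params.window_points} points exceeds spectrum "
            f"length {arr.shape[1]}"
        )
    out = savgol_filter(
        arr,
        window_length=params.window_points,
        polyorder=params.poly_order,
        deriv=params.deriv_order,
        delta=1.0,
        axis=1,
        mode="interp",
    )
    return out[0] if was_1d else out


def _upper_hull_envelope(wl: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Upper convex hull of the (wl, r) point set, linearly interpolated.

    Monotone-chain over points already sorted by wavelength; collinear and
    constant spectra degenerate to the chord between the endpoints, which is
    the correct continuum for them.
    """
    hull: list[int] = []
    for i in range(len(wl)):
        while len(hull) >= 2:
            x1, y1 = wl[hull[-2]], r[hull[-2]]
            x2, y2 = wl[hull[-1]], r[hull[-1]]
            # drop the middle point if it is at or below the chord
            if (x2 - x1) * (r[i] - y1) - (wl[i] - x1) * (y2 - y1) >= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(wl, wl[hull], r[hull])


def continuum_removal(s: Spectrum | np.ndarray, grid: WavelengthGrid | None = None):
    """Divide reflectance by its upper convex hull.

    The result lies in (0, 1] and equals 1 at every hull vertex, in
    particular at both grid endpoints.
    """
    if isinstance(s, Spectrum):
        return Spectrum(s.grid, continuum_removal(s.reflectance, s.grid))
    if grid is None:
        raise ValueError("continuum_removal on arrays requires the grid")
    arr, was_1d = _as_2d(s)
    if arr.shape[1] < 2:
        raise ValueError("continuum removal needs at least 2 points")
    if np.any(arr <= 0):
        raise ValueError("continuum removal requires positive reflectance")
    wl = grid.values
    out = np.empty_like(arr)
    for i in range(arr.shape[0]):
        out[i] = arr[i] / _upper_hull_envelope(wl, arr[i])
    return out[0] if was_1d else out


def apply_source(
    lib: SpectralLibrary,
    source: str,
    params: SGParams | None = None,
) -> np.ndarray:
    """Compute the (samples, wavelengths) feature matrix for one source.

    Composition is left to right in the name after the base transform, e.g.
    ABS_SG1_SNV = snv(savgol(pseudo_absorbance(R), deriv=1)).
    """
    name = source.upper().replace("+", "_")
    if name not in SOURCES:
        raise ValueError(f"unknown spectral source {source!r}; expected one of {SOURCES}")
    sg1 = SGParams(deriv_order=1) if params is None else params
    sg2 = SGParams(sg1.poly_order, sg1.window_points, deriv_order=2)
    r = lib.reflectance_matrix()
    if name == "REF":
        return r
    if name == "ABS":
        return pseudo_absorbance(r)
    if name == "ABS_SG1":
        return savgol(pseudo_absorbance(r), sg1)
    if name == "ABS_SNV":
        return snv(pseudo_absorbance(r))
    if name == "ABS_SG1_SNV":
        return snv(savgol(pseudo_absorbance(r), sg1))
    if name == "ABS_SG2_SNV":
        return snv(savgol(pseudo_absorbance(r), sg2))
    if name == "REF_SG1":
        return savgol(r, sg1)
    if name == "REF_SNV":
        return snv(r)
    # CR
    return continuum_removal(r, lib.grid)
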