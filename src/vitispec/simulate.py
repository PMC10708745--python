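"""Synthetic VNIR-SWIR grape spectra with maturity-linked structure.

The field data behind this problem domain (in-situ berry spectra with
wet-chemistry Brix/pH/TA) are not publicly deposited, so this module
generates libraries with the same statistical skeleton, giving every stage
of the pipeline a testable ground truth:

* **Targets.** A single latent ripeness factor drives all three indicators
  through a Gaussian copula: Brix and pH load positively, TA negatively,
  reproducing the inverse sugar/acidity relationship.  Latent correlations
  are calibrated (rho = 2 sin(pi r / 6)) so that after mapping through the
  per-variety value envelopes the Pearson magnitudes approach |r(Brix,TA)|
  = 0.8 and |r(pH,TA)| = 0.72 at large n.  Values stay inside the
  per-variety min/max envelopes (default: the Syrah 2023 campaign ranges,
  e.g. Brix in [4.70, 26.50]).
* **Sampling dates.** Seven field visits; a sample's date is the quantile
  bin of its latent ripeness, so ripeness increases with date index and
  date-stratified CV folds span the full maturation trajectory.
* **Spectra.** Pseudo-absorbance = smooth baseline + Gaussian absorption
  bands.  Maturity-linked bands sit at 730 nm (sugar O-H overtone),
  1510 nm (carboxylic-acid C=O overtone), 2120 and 2320 nm (O-H/C-O
  combination bands); water bands at 1450/1940 nm are target-independent.
  A chlorophyll term at 680 nm fades as ripeness rises while a broad
  pigment term at 550 nm deepens, so visible reflectance is higher for
  unripe (low-Brix) berries.  Reflectance = 10^(-A) x multiplicative
  scatter + additive noise, clipped to (0, 1] on the native 350-2500 nm
  1 nm grid (2151 points).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import (
    MaturityTargets,
    SampleRecord,
    SpectralLibrary,
    Spectrum,
    WavelengthGrid,
)

#: native instrument grid
GRID_NM = np.arange(350.0, 2501.0, 1.0)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    Band depth (in pseudo-absorbance units) is ``base_depth`` plus the dot
    product of ``depths`` with the envelope-normalized (Brix, pH, TA)
    triple, so a band can deepen or fade with any indicator.
    """

    center: float  # nm
    width: float  # Gaussian sigma, nm
    depths: tuple[float, float, float] = (0.0, 0.0, 0.0)
    base_depth: float = 0.0

    def __post_init__(self) -> None:
        if not 350.0 <= self.center <= 2500.0:
            raise ValueError("band center outside [350, 2500] nm")
        if self.width <= 0:
            raise ValueError("band width must be positive")


#: maturity-linked bands (plus water, chlorophyll and pigment terms)
DEFAULT_BANDS = (
    BandSpec(730.0, 25.0, depths=(0.35, 0.0, 0.0)),
    BandSpec(1510.0, 30.0, depths=(0.0, 0.05, 0.30)),
    BandSpec(2120.0, 30.0, depths=(0.08, 0.12, 0.0)),
    BandSpec(2320.0, 25.0, depths=(0.25, 0.0, 0.0)),
    BandSpec(1450.0, 35.0, base_depth=0.35),
    BandSpec(1940.0, 45.0, base_depth=0.55),
    BandSpec(680.0, 30.0, depths=(-0.12, 0.0, 0.0), base_depth=0.12),
    BandSpec(550.0, 90.0, depths=(0.45, 0.0, 0.0)),
)

#: planted maturity-band centers, the ground truth for importance recovery
PLANTED_BAND_CENTERS = (730.0, 1510.0, 2120.0, 2320.0)

#: Syrah 2023 campaign value envelopes (min, max) per indicator
SYRAH_ENVELOPES = {
    "brix": (4.70, 26.50),
    "ph": (2.56, 3.83),
    "ta": (3.9, 35.6),
}


def _latent_rho(r: float) -> float:
    """Latent normal correlation whose rank-preserving uniform transform
    has Pearson correlation r (inverse of r = (6/pi) asin(rho/2))."""
    return 2.0 * np.sin(np.pi * r / 6.0)


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults emulate the 2023 Syrah campaign."""

    n: int = 260
    variety: str = "Syrah"
    seed: int = 0
    envelopes: dict = field(default_factory=lambda: dict(SYRAH_ENVELOPES))
    #: target Pearson magnitudes; signs fixed Brix-TA < 0, pH-TA < 0
    corr_brix_ta: float = 0.8
    corr_ph_ta: float = 0.72
    #: loading of Brix on the latent ripeness factor
    brix_loading: float = 0.95
    n_dates: int = 7
    first_date: datetime.date = datetime.date(2023, 7, 6)
    date_step_days: int = 12
    additive_noise_sd: float = 0.002
    scatter_range: tuple[float, float] = (0.9, 1.1)
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.additive_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 < self.scatter_range[0] <= self.scatter_range[1]:
            raise ValueError("scatter range must be ordered and positive")
        for lo, hi in self.envelopes.values():
            if lo >= hi:
                raise ValueError("envelopes must be ordered (min < max)")
        a_b = self.brix_loading
        a_t = _latent_rho(self.corr_brix_ta) / a_b
        a_p = _latent_rho(self.corr_ph_ta) / a_t
        if not (0 < a_t < 1 and 0 < a_p < 1 and 0 < a_b < 1):
            raise ValueError(
                "infeasible correlation triple for a single-factor copula"
            )

    @property
    def loadings(self) -> tuple[float, float, float]:
        """(Brix, pH, TA) loadings on latent ripeness; TA sign is negative."""
        a_b = self.brix_loading
        a_t = _latent_rho(self.corr_brix_ta) / a_b
        a_p = _latent_rho(self.corr_ph_ta) / a_t
        return (a_b, a_p, -a_t)


def _norm_cdf(z: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr

    return ndtr(z)


def sample_targets(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[MaturityTargets], list[datetime.date]]:
    """Draw maturity triples and their sampling dates.

    Ripeness u ~ N(0,1); each indicator is u scaled by its loading plus
    independent noise, pushed through the normal CDF and the variety
    envelope.  Dates are the n_dates quantile bins of u.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    u = rng.standard_normal(cfg.n)
    targets = []
    z = {}
    for name, loading in zip(("brix", "ph", "ta"), cfg.loadings):
        eps = rng.standard_normal(cfg.n)
        z[name] = loading * u + np.sqrt(1.0 - loading**2) * eps
    for i in range(cfg.n):
        vals = {}
        for name in ("brix", "ph", "ta"):
            lo, hi = cfg.envelopes[name]
            vals[name] = lo + (hi - lo) * _norm_cdf(z[name][i])
        targets.append(MaturityTargets(**vals))
    # date = quantile bin of ripeness (later visits = riper berries)
    ranks = np.argsort(np.argsort(u))
    bins = (ranks * cfg.n_dates) // max(cfg.n, 1)
    bins = np.clip(bins, 0, cfg.n_dates - 1)
    dates = [
        cfg.first_date + datetime.timedelta(days=int(b) * cfg.date_step_days)
        for b in bins
    ]
    return targets, dates


def _normalized_targets(t: MaturityTargets, cfg: SimConfig) -> np.ndarray:
    out = []
    for name, v in zip(("brix", "ph", "ta"), t.as_array()):
        lo, hi = cfg.envelopes[name]
        out.append((v - lo) / (hi - lo))
    return np.array(out)


def render_spectrum(
    t: MaturityTargets,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    bands: Sequence[BandSpec] | None = None,
) -> Spectrum:
    """Render one reflectance spectrum for a maturity triple."""
    cfg = cfg or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    bands = cfg.bands if bands is None else tuple(bands)
    frac = _normalized_targets(t, cfg)
    wl = GRID_NM
    absorb = 0.25 + 0.15 * (wl - wl[0]) / (wl[-1] - wl[0])
    for band in bands:
        depth = band.base_depth + float(np.dot(band.depths, frac))
        if depth <= 0:
            continue
        absorb = absorb + depth * np.exp(
            -0.5 * ((wl - band.center) / band.width) ** 2
        )
    reflectance = 10.0 ** (-absorb)
    lo, hi = cfg.scatter_range
    reflectance = reflectance * rng.uniform(lo, hi)
    if cfg.additive_noise_sd > 0:
        reflectance = reflectance + cfg.additive_noise_sd * rng.standard_normal(
            wl.size
        )
    reflectance = np.clip(reflectance, 1e-6, 1.0)
    return Spectrum(WavelengthGrid(wl), reflectance)


def generate_library(cfg: SimConfig | None = None, **overrides) -> SpectralLibrary:
    """Generate a full library on the native 1 nm grid, reproducibly.

    Keyword overrides are forwarded to :class:`SimConfig`, e.g.
    ``generate_library(n=300, seed=7)``.
    """
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a SimConfig or keyword overrides, not both")
    rng = np.random.default_rng(cfg.seed)
    targets, dates = sample_targets(cfg, rng)
    width = len(str(cfg.n))
    records = []
    grid = None
    for i, (t, d) in enumerate(zip(targets, dates)):
        s = render_spectrum(t, cfg, rng)
        grid = grid or s.grid
        records.append(
            SampleRecord(
                sample_id=f"{cfg.variety[:3].upper()}{i + 1:0{width}d}",
                variety=cfg.variety,
                sampling_date=d,
                spectrum=s,
                targets=t,
            )
        )
    return SpectralLibrary(records, grid)
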