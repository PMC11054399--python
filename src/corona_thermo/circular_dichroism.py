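"""Circular-dichroism analysis: mean residue ellipticity, helicity, melting.

The observed far-UV ellipticity (mdeg) is normalized to mean residue
ellipticity

    MRE = obs / (10 · Cp · n · l)      [deg cm^2 dmol^-1]

with Cp the molar protein concentration, n the residue count (585 for HSA)
and l the cell path in cm, and the α-helix content follows from the 208 nm
value by linear interpolation between the pure-helix (−33,000) and
coil/β (−4,000) reference ellipticities:

    helix % = (−MRE208 − 4000) / 29000 · 100

Thermal melts at 222 nm are fitted with a two-state sigmoid with
temperature-independent baselines; sloped baselines are available behind a
flag.  The default cell path is 0.1 cm, the value tied to the helicity
formula; it is configurable because instrument records sometimes carry a
different nominal path, and the choice is logged with every call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .io_formats import SpectrumTable

logger = logging.getLogger("corona_thermo")

MRE_HELIX_208 = -33000.0  # deg cm^2 dmol^-1, pure alpha-helix at 208 nm
MRE_COIL_208 = -4000.0    # beta-sheet / random coil reference at 208 nm

__all__ = [
    "CDParams",
    "HelicityResult",
    "MeltFit",
    "mre_at",
    "mre_at_208",
    "helix_fraction",
    "fit_melting",
    "MRE_HELIX_208",
    "MRE_COIL_208",
]


@dataclass
class CDParams:
    """Cell/sample parameters entering the MRE normalization."""

    cp_molar: float          # protein concentration, M
    n_res: int = 585         # residues (585 for HSA)
    path_cm: float = 0.1

    def __post_init__(self):
        if self.cp_molar <= 0 or self.n_res <= 0 or self.path_cm <= 0:
            raise ValueError("Cp, n_res and path length must all be positive")


@dataclass
class HelicityResult:
    mre208: float
    helix_pct: float
    clamped: bool = False


@dataclass
class MeltFit:
    t_m: float               # °C
    width: float             # °C
    theta_folded: float      # mdeg
    theta_unfolded: float    # mdeg
    se_t_m: float
    boundary: bool = False   # T_M at the edge of the scanned range


def mre_at(spectrum: SpectrumTable, wavelength_nm: float,
           params: CDParams) -> float:
    """MRE at a wavelength, linearly interpolating the observed mdeg."""
    x, y = spectrum.x, spectrum.y
    lo, hi = min(x[0], x[-1]), max(x[0], x[-1])
    if not (lo <= wavelength_nm <= hi):
        raise ValueError(
            f"{wavelength_nm} nm outside the recorded range {lo}-{hi} nm")
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    obs = float(np.interp(wavelength_nm, x, y))
    denom = 10.0 * params.cp_molar * params.n_res * params.path_cm
    mre = obs / denom
    logger.info("MRE(%g nm) = %.6g deg cm^2/dmol (obs %.4g mdeg, path %g cm)",
                wavelength_nm, mre, obs, params.path_cm)
    return mre


def mre_at_208(spectrum: SpectrumTable, params: CDParams) -> float:
    """Mean residue ellipticity at the 208 nm π-π* helix band."""
    return mre_at(spectrum, 208.0, params)


def helix_fraction(mre208: float) -> HelicityResult:
    """α-helix percentage from MRE208, clamped to [0, 100] with a flag."""
    pct = (-mre208 - (-MRE_COIL_208)) / (-MRE_HELIX_208 - (-MRE_COIL_208)) * 100.0
    clamped = pct < 0.0 or pct > 100.0
    return HelicityResult(mre208=float(mre208),
                          helix_pct=float(np.clip(pct, 0.0, 100.0)),
                          clamped=clamped)


def _sigmoid(t, theta_f, theta_u, t_m, width):
    return theta_f + (theta_u - theta_f) / (1.0 + np.exp((t_m - t) / width))


def _sigmoid_sloped(t, theta_f, theta_u, t_m, width, slope_f, slope_u):
    frac = 1.0 / (1.0 + np.exp((t_m - t) / width))
    return (theta_f + slope_f * t) * (1 - frac) + (theta_u + slope_u * t) * frac


def fit_melting(melt: SpectrumTable, sloped_baselines: bool = False) -> MeltFit:
    """Two-state melting fit θ(T) = θ_F + (θ_U − θ_F)/(1 + exp((T_M − T)/w)).

    T_M is initialized at the maximum of |dθ/dT| (finite differences) and the
    baselines from the first/last 10 % of points; raises if no interior
    inflection is detectable.
    """
    t = np.asarray(melt.x, dtype=float)
    y = np.asarray(melt.y, dtype=float)
    if len(t) < 10:
        raise RuntimeError("need >= 10 temperature points for a melting fit")
    deriv = np.gradient(y, t)
    i_max = int(np.argmax(np.abs(deriv)))
    if i_max in (0, len(t) - 1):
        raise RuntimeError("no transition: |dθ/dT| maximal at the scan edge")
    k = max(1, len(t) // 10)
    theta_f0 = float(y[:k].mean())
    theta_u0 = float(y[-k:].mean())
    t_m0 = float(t[i_max])
    p0 = [theta_f0, theta_u0, t_m0, 2.0]
    model = _sigmoid
    if sloped_baselines:
        p0 += [0.0, 0.0]
        model = _sigmoid_sloped
    popt, pcov = optimize.curve_fit(model, t, y, p0=p0, maxfev=20000)
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    t_m = float(popt[2])
    boundary = not (t.min() <= t_m <= t.max())
    logger.info("melting fit: T_M=%.3f C (se %.3g), width=%.3g C", t_m, se[2],
                abs(popt[3]))
    return MeltFit(t_m=t_m, width=float(abs(popt[3])),
                   theta_folded=float(popt[0]), theta_unfolded=float(popt[1]),
                   se_t_m=float(se[2]), boundary=boundary)
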