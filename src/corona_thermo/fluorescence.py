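"""Tryptophan-quenching analysis: Stern–Volmer fits and EEM peak location.

The intrinsic W214 fluorescence of serum albumin is quenched by the titrant;
the classic Stern–Volmer plot F0/F vs [Q] yields the quenching constant K_SV
from its slope, and the double-logarithmic modified Stern–Volmer plot

    log10((F0 − F)/F)  vs  log10([AD] − (F0 − F)·[HSA]/F0)

yields the dissociation constant K_D from its intercept (K_D = 10^(−b)); the
second logarithm is the free-titrant concentration, so the expected slope is
one and the fitted slope is reported as a diagnostic.  Base-10 logarithms
throughout, matching the conventional double-log plot.  No inner-filter
correction is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import TitrationTable

logger = logging.getLogger("corona_thermo")

__all__ = [
    "SternVolmerFit",
    "DissociationFit",
    "EEMPeak",
    "fit_stern_volmer",
    "fit_modified_stern_volmer",
    "locate_eem_peaks",
]


@dataclass
class SternVolmerFit:
    k_sv: float          # M^-1
    intercept: float     # dimensionless (≈1 expected, not constrained)
    r_squared: float
    se_k_sv: float
    no_quenching: bool = False  # set when the data carry no quenching signal


@dataclass
class DissociationFit:
    k_d: float       # M
    se_k_d: float
    r_squared: float
    slope: float     # diagnostic; ≈1 for ideal single-site quenching
    n_excluded: int = 0


@dataclass(frozen=True)
class EEMPeak:
    lambda_ex: float  # nm
    lambda_em: float  # nm
    intensity: float


def _f0_from_table(t: TitrationTable, f0: float | None) -> float:
    """Zero-quencher row supplies F0 when present, else it must be given."""
    if t.quencher_conc[0] == 0.0:
        return float(t.intensity[0])
    if f0 is None:
        raise ValueError("no zero-quencher row; supply F0 explicitly")
    return float(f0)


def fit_stern_volmer(t: TitrationTable, f0: float | None = None) -> SternVolmerFit:
    """Ordinary least squares of F0/F on [Q]; slope is K_SV."""
    f0 = _f0_from_table(t, f0)
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    q = t.quencher_conc
    y = f0 / t.intensity
    if len(q) < 3:
        raise RuntimeError("need >= 3 points for a Stern-Volmer fit")
    if np.allclose(y, y[0]):
        # no quenching: slope 0, undefined correlation reported as 0
        return SternVolmerFit(k_sv=0.0, intercept=float(y[0]), r_squared=0.0,
                              se_k_sv=0.0, no_quenching=True)
    res = stats.linregress(q, y)
    flag = res.slope < 0
    if flag:
        warnings.warn("negative fitted K_SV: no quenching signal", stacklevel=2)
    logger.info("Stern-Volmer fit: K_SV=%.4g M^-1 (se %.2g), R2=%.5f",
                res.slope, res.stderr, res.rvalue ** 2)
    return SternVolmerFit(k_sv=float(res.slope), intercept=float(res.intercept),
                          r_squared=float(res.rvalue ** 2),
                          se_k_sv=float(res.stderr), no_quenching=flag)


def fit_modified_stern_volmer(t: TitrationTable, f0: float | None = None,
                              hsa_conc: float | None = None) -> DissociationFit:
    """Double-log regression for the dissociation constant K_D.

    Points where F >= F0 or where the free-titrant term
    [AD] − (F0 − F)·[HSA]/F0 is non-positive cannot enter the logarithms and
    are excluded with a warning.
    """
    f0 = _f0_from_table(t, f0)
    if hsa_conc is None:
        hsa_conc = t.fixed_species_conc
    if hsa_conc <= 0:
        raise ValueError("fixed protein concentration must be positive")
    ad = t.quencher_conc
    f = t.intensity
    dfrac = (f0 - f) / f0                       # fraction quenched
    free = ad - dfrac * hsa_conc                # free titrant, M
    usable = (f0 > f) & (free > 0) & (ad > 0)
    n_excl = int(np.sum(~usable))
    if n_excl:
        warnings.warn(
            f"{n_excl} point(s) excluded from modified Stern-Volmer fit "
            "(non-positive log argument)", stacklevel=2)
    if usable.sum() < 3:
        raise RuntimeError("fewer than 3 usable points for the double-log fit")
    y = np.log10((f0 - f[usable]) / f[usable])
    x = np.log10(free[usable])
    res = stats.linregress(x, y)
    k_d = 10.0 ** (-res.intercept)
    se_k_d = k_d * np.log(10.0) * res.intercept_stderr
    logger.info("modified SV fit: K_D=%.4g M (se %.2g), slope=%.4f, R2=%.5f",
                k_d, se_k_d, res.slope, res.rvalue ** 2)
    return DissociationFit(k_d=float(k_d), se_k_d=float(se_k_d),
                           r_squared=float(res.rvalue ** 2),
                           slope=float(res.slope), n_excluded=n_excl)


def locate_eem_peaks(intensity: np.ndarray, lambda_ex: np.ndarray,
                     lambda_em: np.ndarray,
                     rayleigh_halfwidth: float = 10.0) -> list[EEMPeak]:
    """Local maxima of an excitation–emission matrix off the scatter diagonal.

    The band |λ_em − λ_ex| <= rayleigh_halfwidth (first-order Rayleigh
    scattering) is masked; surviving local maxima above mean + 3·SD of the
    unmasked cells are returned sorted by intensity, descending.
    """
    z = np.asarray(intensity, dtype=float)
    ex = np.asarray(lambda_ex, dtype=float)
    em = np.asarray(lambda_em, dtype=float)
    if z.shape != (len(ex), len(em)):
        raise ValueError("intensity must be shaped (n_ex, n_em)")
    mask = np.abs(em[None, :] - ex[:, None]) <= rayleigh_halfwidth
    if mask.all():
        return []
    vals = z[~mask]
    thresh = vals.mean() + 3.0 * vals.std()
    peaks = []
    for i in range(z.shape[0]):
        for j in range(z.shape[1]):
            if mask[i, j] or z[i, j] <= thresh:
                continue
            window = z[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
            if z[i, j] >= window.max():
                peaks.append(EEMPeak(float(ex[i]), float(em[j]), float(z[i, j])))
    peaks.sort(key=lambda p: -p.intensity)
    return peaks
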