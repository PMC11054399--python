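"""One-set-of-sites ITC analysis with micelle mass conservation.

The titrant is an amphiphilic dendrimer that self-assembles into nanomicelles
of ``n_agg`` monomers above the critical micellar concentration (CMC).  Total
amphiphile obeys the mass-conservation relation

    [AD_tot] = [AD_mon] + N_agg · [AD_mic]

so above the CMC the monomer pool is pinned at the CMC and the remainder is
micellar.  The micelle is treated as the macromolecular species carrying
``n_sites`` independent identical protein sites; the enthalpy is per mole of
protein bound.  Per-injection heats follow the Wiseman one-site isotherm under
the overflow (perfusion) dilution convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .io_formats import InjectionTable

logger = logging.getLogger("corona_thermo")

R_KCAL = 1.9872e-3  # gas constant, kcal mol^-1 K^-1

__all__ = [
    "MicelleState",
    "BindingParams",
    "ThermoTriplet",
    "OneSiteFitResult",
    "micelle_concentration",
    "simulate_isotherm",
    "fit_one_site",
    "derive_thermodynamics",
]


@dataclass(frozen=True)
class MicelleState:
    """Partition of total amphiphile into monomer and micellar pools."""

    ad_total: float   # M
    ad_monomer: float # M
    ad_micelle: float # M (concentration of whole micelles)
    n_agg: int

    def __post_init__(self):
        residual = self.ad_monomer + self.n_agg * self.ad_micelle - self.ad_total
        assert abs(residual) <= 1e-12 * max(1.0, self.ad_total), residual


@dataclass
class BindingParams:
    """One-set-of-sites parameters: K_d (M), ΔH (kcal/mol of protein bound),
    n_sites (proteins per micelle), temperature (K)."""

    k_d: float
    delta_h: float
    n_sites: float = 6.0
    temperature_k: float = 298.15

    def __post_init__(self):
        if self.k_d <= 0:
            raise ValueError("K_d must be positive")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")


@dataclass(frozen=True)
class ThermoTriplet:
    """ΔG = ΔH + (−TΔS), all in kcal/mol."""

    delta_g: float
    delta_h: float
    minus_t_delta_s: float

    def __post_init__(self):
        assert abs(self.delta_g - (self.delta_h + self.minus_t_delta_s)) < 1e-9


@dataclass
class OneSiteFitResult:
    params: BindingParams
    thermo: ThermoTriplet
    se_k_d: float
    se_delta_h: float
    se_n_sites: float
    reduced_chi2: float
    n_discarded_injections: int = 0
    at_bound: bool = False
    offset_ucal: float = 0.0


def micelle_concentration(ad_total: float, n_agg: int, cmc: float) -> MicelleState:
    """Split a total amphiphile concentration into monomer and micelle pools.

    Below the CMC everything is monomeric; above it the monomer pool stays at
    the CMC and the excess forms micelles of ``n_agg`` monomers.
    """
    if ad_total < 0 or cmc < 0:
        raise ValueError("concentrations must be non-negative")
    if n_agg < 1:
        raise ValueError("n_agg must be >= 1")
    if ad_total <= cmc:
        return MicelleState(ad_total, ad_total, 0.0, n_agg)
    return MicelleState(ad_total, cmc, (ad_total - cmc) / n_agg, n_agg)


def _bound_complex(h: np.ndarray, s: np.ndarray, k_d: float) -> np.ndarray:
    """1:1 mass-action bound concentration from the quadratic root.

    h, s are total protein and total site concentrations (M).
    """
    b = h + s + k_d
    disc = b * b - 4.0 * h * s
    assert np.all(disc >= -1e-30)
    return 0.5 * (b - np.sqrt(np.maximum(disc, 0.0)))


def simulate_isotherm(
    design: InjectionTable,
    params: BindingParams,
    n_agg: int = 17,
    cmc: float = 4.5e-6,
    offset_ucal: float = 0.0,
) -> np.ndarray:
    """Noiseless per-injection heats (µcal) for the one-set-of-sites model.

    The syringe amphiphile concentration is converted to a micelle
    concentration once (the syringe is far above the CMC); per injection i of
    volume dV into the overflow cell of volume V0, previously present species
    are diluted by (1 − dV/V0) and the fresh aliquot contributes
    dV·c_syr/V0 undiluted.  Heats are differences of the cell heat content
    Q_i = [HS]_i·ΔH·V0 with the standard displaced-volume correction.
    """
    v0 = design.cell_volume_ul
    mic_syr = micelle_concentration(design.syringe_conc, n_agg, cmc).ad_micelle
    h = design.cell_conc          # protein in cell, M
    mic = 0.0                     # micelles in cell, M
    q_prev = 0.0
    heats = np.empty(len(design))
    for i, dv in enumerate(design.volumes_ul):
        f = dv / v0
        h *= (1.0 - f)
        mic = mic * (1.0 - f) + f * mic_syr
        s = params.n_sites * mic
        hs = _bound_complex(np.asarray(h), np.asarray(s), params.k_d)
        # µcal = M · kcal/mol · µL · 1e3
        q = float(hs) * params.delta_h * v0 * 1e3
        heats[i] = q - q_prev + f * (q + q_prev) / 2.0 + offset_ucal
        q_prev = q
    return heats


def molar_ratio_axis(design: InjectionTable, n_agg: int = 17,
                     cmc: float = 4.5e-6) -> np.ndarray:
    """Reporting x-axis: [protein]/[micelle] in the cell after each injection."""
    v0 = design.cell_volume_ul
    mic_syr = micelle_concentration(design.syringe_conc, n_agg, cmc).ad_micelle
    h = design.cell_conc
    mic = 0.0
    out = np.empty(len(design))
    for i, dv in enumerate(design.volumes_ul):
        f = dv / v0
        h *= (1.0 - f)
        mic = mic * (1.0 - f) + f * mic_syr
        out[i] = h / mic
    return out


def derive_thermodynamics(k_d: float, delta_h: float,
                          temperature_k: float = 298.15) -> ThermoTriplet:
    """ΔG = R·T·ln(K_d) (standard state 1 M) and −TΔS = ΔG − ΔH."""
    if k_d <= 0 or temperature_k <= 0:
        raise ValueError("K_d and T must be positive")
    delta_g = R_KCAL * temperature_k * np.log(k_d)
    return ThermoTriplet(delta_g, delta_h, delta_g - delta_h)


def fit_one_site(
    exp: InjectionTable,
    n_agg: int = 17,
    cmc: float = 4.5e-6,
    fit_n: bool = True,
    fixed_n: float = 6.0,
    discard_first: bool = False,
    fit_offset: bool = False,
    n_starts: int = 8,
) -> OneSiteFitResult:
    """Weighted nonlinear least squares of the forward isotherm.

    Multi-start over log-spaced K_d (1e-9 … 1e-3 M); the best fit by SSE
    wins.  ΔG/ΔH/−TΔS are derived at the design temperature.
    """
    heats = exp.heats_ucal.copy()
    n_discarded = 0
    mask = np.ones(len(heats), dtype=bool)
    if discard_first:
        mask[0] = False
        n_discarded = 1
    if mask.sum() < 5:
        raise RuntimeError("fewer than 5 usable injections")

    design = exp

    def residuals(theta):
        log_kd, dh = theta[0], theta[1]
        n = theta[2] if fit_n else fixed_n
        off = theta[3 if fit_n else 2] if fit_offset else 0.0
        p = BindingParams(10.0 ** log_kd, dh, max(n, 1e-6), exp.temperature_k)
        model = simulate_isotherm(design, p, n_agg, cmc, offset_ucal=off)
        return model[mask] - heats[mask]

    dh0 = heats[mask][0] / (
        design.volumes_ul[0] / design.cell_volume_ul
        * micelle_concentration(design.syringe_conc, n_agg, cmc).ad_micelle
        * fixed_n * design.cell_volume_ul * 1e3
    )
    if not np.isfinite(dh0) or dh0 == 0:
        dh0 = -1.0

    lo = [-9.0, -1e3] + ([1e-3] if fit_n else []) + ([-1e3] if fit_offset else [])
    hi = [-3.0, 1e3] + ([1e3] if fit_n else []) + ([1e3] if fit_offset else [])

    best = None
    for log_kd0 in np.linspace(-9.0, -3.0, n_starts):
        x0 = [log_kd0, dh0] + ([fixed_n] if fit_n else []) + ([0.0] if fit_offset else [])
        try:
            sol = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                         method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("one-site fit failed to converge from every start")

    x = best.x
    k_d = 10.0 ** x[0]
    dh = x[1]
    n = x[2] if fit_n else fixed_n
    off = x[3 if fit_n else 2] if fit_offset else 0.0
    n_par = len(x)
    n_pts = int(mask.sum())
    sse = 2.0 * best.cost
    red_chi2 = sse / max(n_pts - n_par, 1)

    # covariance from the Gauss-Newton approximation
    se = np.full(n_par, np.nan)
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * red_chi2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        pass
    se_kd = k_d * np.log(10.0) * se[0]
    se_dh = se[1]
    se_n = se[2] if fit_n else 0.0

    at_bound = bool(np.any(np.isclose(x, lo, atol=1e-6))
                    or np.any(np.isclose(x, hi, atol=1e-6)))
    if at_bound:
        warnings.warn("one-site fit parameter at search bound", stacklevel=2)

    params = BindingParams(k_d, dh, n, exp.temperature_k)
    thermo = derive_thermodynamics(k_d, dh, exp.temperature_k)
    logger.info(
        "one-site fit: K_d=%.4g M (se %.2g), dH=%.4g kcal/mol (se %.2g), "
        "n=%.3g, red_chi2=%.3g", k_d, se_kd, dh, se_dh, n, red_chi2)
    return OneSiteFitResult(
        params=params, thermo=thermo,
        se_k_d=float(se_kd), se_delta_h=float(se_dh), se_n_sites=float(se_n),
        reduced_chi2=float(red_chi2),
        n_discarded_injections=n_discarded,
        at_bound=at_bound, offset_ucal=float(off),
    )
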