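"""13C mass-balance model of the CO2 -> butane back flux.

During net anaerobic oxidation of butane in a closed incubation, a small
reverse flux (f-) returns carbon from the labelled dissolved-inorganic-
carbon (DIC) pool into the butane pool, progressively enriching residual
butane in 13C.  The extent of the back flux is

    mu = f- / (n * f_net),

with n the carbons per alkane (4 for butane) and f_net the net oxidation
rate.  The pipeline approximates the butane pool by a three-parameter
first-order decay and the butane d13C trajectory by a four-parameter
logistic, then evaluates mu(t) from the closed-form isotope balance: the
rate of 13C change of the alkane pool equals label gain from the back flux
(alpha- * F_CO2 per carbon) minus label loss through the forward flux
(alpha+ * F_Alk per carbon), where F are fractional 13C abundances.

Also provided: the Rayleigh estimator of the forward fractionation factor
from natural-abundance data, and flux-force diagnostics linking back-flux
ratios to the overall free energy of the process.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import N_BUTANE, R_VPDB, SULFATE_PER_BUTANE, T_STANDARD, rt

__all__ = [
    "IsotopeConstants",
    "LabelingSetup",
    "FirstOrderFit",
    "LogisticFit",
    "BackFluxTrajectory",
    "delta_to_ratio",
    "ratio_to_delta",
    "ratio_to_fraction",
    "fraction_to_ratio",
    "delta_to_fraction",
    "fraction_to_delta",
    "fit_first_order",
    "fit_logistic",
    "net_rate",
    "alkane_13c_amount",
    "d13c_alkane_dt",
    "co2_13fraction",
    "back_flux_extent",
    "rayleigh_alpha",
    "flux_force",
    "overall_delta_g",
]

#: Points where |denominator| of the explicit mu expression falls below
#: this value (mmol C L^-1 d^-1) are masked rather than extrapolated.
DENOMINATOR_TOL = 1e-6


# ---------------------------------------------------------------------------
# delta / ratio / fractional-abundance conversions (VPDB scale)

def delta_to_ratio(delta, r_std: float = R_VPDB):
    """13C/12C ratio from a d13C value in permil."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise ValueError("d13C must exceed -1000 permil")
    return r_std * (1.0 + delta / 1000.0)


def ratio_to_delta(ratio, r_std: float = R_VPDB):
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("isotope ratio must be positive")
    return (ratio / r_std - 1.0) * 1000.0


def ratio_to_fraction(ratio):
    """Fractional 13C abundance F = R / (1 + R)."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("isotope ratio must be positive")
    return ratio / (1.0 + ratio)


def fraction_to_ratio(fraction):
    fraction = np.asarray(fraction, dtype=float)
    if np.any((fraction <= 0) | (fraction >= 1)):
        raise ValueError("fractional abundance must lie in (0, 1)")
    return fraction / (1.0 - fraction)


def delta_to_fraction(delta, r_std: float = R_VPDB):
    return ratio_to_fraction(delta_to_ratio(delta, r_std))


def fraction_to_delta(fraction, r_std: float = R_VPDB):
    return ratio_to_delta(fraction_to_ratio(fraction), r_std)


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class IsotopeConstants:
    """Fractionation factors and isotope-scale constants.

    ``alpha_plus`` is the kinetic fractionation factor of the forward
    (oxidative) flux, ``alpha_minus`` of the reverse flux; ``n`` the
    carbons per alkane.
    """

    r_std: float = R_VPDB
    alpha_plus: float = 0.9975
    alpha_minus: float = 1.0
    n: int = N_BUTANE
    temperature: float = T_STANDARD

    def __post_init__(self) -> None:
        if not 0.9 <= self.alpha_minus <= 1.0:
            raise ValueError("alpha_minus outside [0.9, 1]")
        if not 0.99 <= self.alpha_plus <= 1.0:
            raise ValueError("alpha_plus outside [0.99, 1]")
        if self.n < 2:
            raise ValueError("n must be an integer >= 2")


@dataclass(frozen=True)
class LabelingSetup:
    """Initial pools of a closed labeling incubation.

    ``alk0`` and ``dic0`` in mmol L^-1, ``atom13_dic0`` the fractional 13C
    abundance of the initial DIC, ``delta0_alk`` the initial alkane d13C in
    permil.  Total carbon and total 13C are conserved throughout.
    """

    alk0: float = 6.0
    dic0: float = 18.0
    atom13_dic0: float = 0.98
    delta0_alk: float = -25.0
    n: int = N_BUTANE

    def __post_init__(self) -> None:
        if self.alk0 <= 0 or self.dic0 <= 0:
            raise ValueError("initial pools must be positive")
        if not 0.0112 <= self.atom13_dic0 <= 0.98:
            raise ValueError("atom13_dic0 outside [0.0112, 0.98]")

    @property
    def c_total(self) -> float:
        """Total carbon atoms, mmol C L^-1 (conserved)."""
        return self.dic0 + self.n * self.alk0

    @property
    def c13_total(self) -> float:
        """Total 13C atoms, mmol 13C L^-1 (conserved)."""
        f_alk0 = float(delta_to_fraction(self.delta0_alk))
        return self.atom13_dic0 * self.dic0 + self.n * f_alk0 * self.alk0


@dataclass(frozen=True)
class FirstOrderFit:
    """Exponential decay of the alkane pool toward a floor c0."""

    c0: float
    c1: float
    lam: float
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.c1 > self.c0 >= 0):
            raise ValueError("first-order fit requires c1 > c0 >= 0")
        if self.lam <= 0:
            raise ValueError("decay constant must be positive")

    def alkane(self, t):
        t = np.asarray(t, dtype=float)
        return self.c0 + (self.c1 - self.c0) * np.exp(-self.lam * t)


@dataclass(frozen=True)
class LogisticFit:
    """S-shaped d13C trajectory of the alkane pool."""

    d0: float
    d1: float
    d2: float
    k: float
    cov: np.ndarray | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("logistic rate k must be positive")

    def delta(self, t):
        t = np.asarray(t, dtype=float)
        return self.d0 + (self.d1 - self.d0) / (1.0 + np.exp(-self.k * (t - self.d2)))


@dataclass(frozen=True)
class BackFluxTrajectory:
    """mu(t) with component fluxes.

    Units: ``f_minus`` in mmol C L^-1 d^-1; ``f_plus``, ``f_net`` and ``v``
    in mmol alkane L^-1 d^-1 (so that f_plus - f_minus/n = v).  ``mask`` is
    True where mu is identifiable.  Optional 95% bands are attached by the
    posterior propagation layer.
    """

    t: np.ndarray
    mu: np.ndarray
    f_minus: np.ndarray
    f_plus: np.ndarray
    f_net: np.ndarray
    v: np.ndarray
    mask: np.ndarray
    dg: np.ndarray | None = None
    mu_lo95: np.ndarray | None = None
    mu_hi95: np.ndarray | None = None
    converged: bool | None = None

    @property
    def mu_peak(self) -> float:
        """Maximum of mu over identifiable points."""
        if not self.mask.any():
            raise ValueError("no identifiable back flux window")
        return float(np.nanmax(self.mu[self.mask]))

    @property
    def t_peak(self) -> float:
        valid = np.where(self.mask)[0]
        return float(self.t[valid[int(np.nanargmax(self.mu[self.mask]))]])


# ---------------------------------------------------------------------------
# empirical fits

def _first_order(t, c0, c1, lam):
    return c0 + (c1 - c0) * np.exp(-lam * t)


def _first_order_jac(t, c0, c1, lam):
    e = np.exp(-lam * t)
    return np.column_stack([1.0 - e, e, -(c1 - c0) * t * e])


def fit_first_order(t, alk) -> FirstOrderFit:
    """Least-squares fit of the three-parameter first-order decay model."""
    t = np.asarray(t, dtype=float)
    alk = np.asarray(alk, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(alk))):
        raise ValueError("time series contains non-finite values")
    if np.any(alk <= 0):
        raise ValueError("alkane concentrations must be positive")
    c1_guess = float(alk[0])
    c0_guess = float(alk[-1])
    span = c1_guess - c0_guess
    if span <= 0 or span < 1e-12 * max(c1_guess, 1.0):
        raise ValueError(
            "series shows no decay (constant or rising); the first-order "
            "model is degenerate on such data"
        )
    # log-linear regression on the decaying part for the rate guess
    resid = alk - 0.95 * c0_guess
    ok = resid > 0
    slope = np.polyfit(t[ok], np.log(resid[ok]), 1)[0]
    lam_guess = max(-slope, 1e-4)
    try:
        popt, pcov = curve_fit(
            _first_order, t, alk,
            p0=[max(c0_guess, 1e-9), c1_guess, lam_guess],
            jac=_first_order_jac, xtol=1e-12, ftol=1e-12, maxfev=20000,
        )
    except RuntimeError as err:
        raise ValueError(f"first-order fit did not converge: {err}") from err
    c0, c1, lam = popt
    if lam <= 0:
        raise ValueError("fitted decay constant non-positive; series may be constant")
    return FirstOrderFit(c0=float(c0), c1=float(c1), lam=float(lam), cov=pcov)


def net_rate(fit: FirstOrderFit, t):
    """Net oxidation rate v = lam * ([Alk](t) - c0), mmol alkane L^-1 d^-1."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return fit.lam * (fit.c1 - fit.c0) * np.exp(-fit.lam * t)


def _logistic(t, d0, d1, d2, k):
    return d0 + (d1 - d0) / (1.0 + np.exp(-k * (t - d2)))


def _logistic_jac(t, d0, d1, d2, k):
    e = np.exp(-k * (t - d2))
    s = 1.0 / (1.0 + e)
    ds = e * s * s
    return np.column_stack([1.0 - s, s, -(d1 - d0) * k * ds, (d1 - d0) * (t - d2) * ds])


def fit_logistic(t, delta) -> LogisticFit:
    """Least-squares fit of the four-parameter logistic d13C model.

    A flat series cannot identify (d2, k); the returned fit is then flagged
    ``degenerate`` with d1 ~ d0.
    """
    t = np.asarray(t, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 time points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(delta))):
        raise ValueError("time series contains non-finite values")
    d0_guess, d1_guess = float(delta[0]), float(delta[-1])
    rise = d1_guess - d0_guess
    if abs(rise) < 1e-6 * max(1.0, abs(d0_guess)) or np.ptp(delta) < 1e-9:
        return LogisticFit(d0=d0_guess, d1=d0_guess + 1e-9, d2=float(np.median(t)),
                           k=1e-3, degenerate=True)
    mid = d0_guess + 0.5 * rise
    d2_guess = float(np.interp(mid, delta, t)) if rise > 0 else float(np.median(t))
    grad = np.gradient(delta, t)
    k_guess = max(abs(4.0 * grad[np.argmax(np.abs(grad))] / rise), 1e-3)
    try:
        popt, pcov = curve_fit(
            _logistic, t, delta, p0=[d0_guess, d1_guess, d2_guess, k_guess],
            jac=_logistic_jac, xtol=1e-12, ftol=1e-12, maxfev=20000,
        )
    except RuntimeError as err:
        raise ValueError(
            "logistic fit did not converge; data span "
            f"[{delta.min():.3g}, {delta.max():.3g}] permil over "
            f"[{t.min():.3g}, {t.max():.3g}] d"
        ) from err
    d0, d1, d2, k = popt
    if k < 0:  # mirrored parameterization; normalize
        d0, d1, k = d1, d0, -k
    return LogisticFit(d0=float(d0), d1=float(d1), d2=float(d2), k=float(k), cov=pcov)


# ---------------------------------------------------------------------------
# isotope balance pipeline

def alkane_13c_amount(fit: FirstOrderFit, lfit: LogisticFit,
                      const: IsotopeConstants, t):
    """13C in the alkane pool, mmol 13C L^-1: n * F_Alk(t) * [Alk](t)."""
    ratio = delta_to_ratio(lfit.delta(t), const.r_std)
    return const.n * ratio / (1.0 + ratio) * fit.alkane(t)


def d13c_alkane_dt(fit: FirstOrderFit, lfit: LogisticFit,
                   const: IsotopeConstants, t):
    """Time derivative of the alkane-pool 13C amount (closed form).

    First term: label change through the moving d13C trajectory; second
    term: 13C carried away by net alkane consumption.
    """
    t = np.asarray(t, dtype=float)
    ratio = delta_to_ratio(lfit.delta(t), const.r_std)
    e = np.exp(-lfit.k * (t - lfit.d2))
    label_gain = (
        const.n * fit.alkane(t) / (1.0 + ratio) ** 2
        * const.r_std / 1000.0
        * (lfit.d1 - lfit.d0) * lfit.k * e / (1.0 + e) ** 2
    )
    net_loss = const.n * ratio / (1.0 + ratio) * net_rate(fit, t)
    return label_gain - net_loss


def co2_13fraction(setup: LabelingSetup, fit: FirstOrderFit, lfit: LogisticFit,
                   const: IsotopeConstants, t):
    """Fractional 13C abundance of the DIC pool from carbon conservation."""
    t = np.asarray(t, dtype=float)
    alk = fit.alkane(t)
    denom = setup.c_total - const.n * alk
    if np.any(denom <= 1e-12):
        raise ValueError("DIC pool empty: c_total must exceed n*[Alk](t)")
    return (setup.c13_total - alkane_13c_amount(fit, lfit, const, t)) / denom


def back_flux_extent(setup: LabelingSetup, fit: FirstOrderFit, lfit: LogisticFit,
                     const: IsotopeConstants, t,
                     denominator_tol: float = DENOMINATOR_TOL) -> BackFluxTrajectory:
    """Evaluate the back-flux extent mu(t) and the component fluxes.

    mu is undefined where the net rate vanishes or the isotopic contrast
    between the DIC and alkane pools is exhausted; such points are masked.
    Raises if no point is identifiable.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(net_rate(fit, t), dtype=float)
    f_alk = ratio_to_fraction(delta_to_ratio(lfit.delta(t), const.r_std))
    f_co2 = co2_13fraction(setup, fit, lfit, const, t)
    d13 = d13c_alkane_dt(fit, lfit, const, t)
    denom = const.n * v * (const.alpha_minus * f_co2 - const.alpha_plus * f_alk)
    mask = np.abs(denom) >= denominator_tol
    if not mask.any():
        raise ValueError("no identifiable back flux window")
    mu = np.full_like(v, np.nan)
    mu[mask] = (d13[mask] + const.n * v[mask] * const.alpha_plus * f_alk[mask]) / denom[mask]
    f_minus = mu * const.n * v
    f_plus = (1.0 + mu) * v
    return BackFluxTrajectory(
        t=t, mu=mu, f_minus=f_minus, f_plus=f_plus, f_net=v.copy(), v=v, mask=mask
    )


# ---------------------------------------------------------------------------
# Rayleigh fractionation and flux-force diagnostics

def rayleigh_alpha(t, alk, delta) -> tuple[float, float]:
    """Forward fractionation factor from the logarithmic Rayleigh regression.

    Regresses ln((d13C + 1000)/(d13C_0 + 1000)) of the residual alkane on
    ln of the fraction remaining; the slope is alpha+ - 1 and epsilon =
    slope * 1000 permil.  Intended for natural-abundance series.
    """
    t = np.asarray(t, dtype=float)
    alk = np.asarray(alk, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if alk.size < 3:
        raise ValueError("need at least 3 points")
    f = alk / alk[0]
    if np.any(f <= 0) or np.any(f > 1.0 + 1e-12):
        raise ValueError("fraction remaining must lie in (0, 1]")
    y = np.log((delta + 1000.0) / (delta[0] + 1000.0))
    x = np.log(f)
    slope = float(np.polyfit(x, y, 1)[0])
    return 1.0 + slope, slope * 1000.0


def flux_force(dg: float, temperature: float = T_STANDARD) -> tuple[float, float]:
    """Flux-force relation: (f-/f+, f-/f_net) at overall free energy ``dg``.

    f-/f+ = exp(dG/RT); f-/f_net = 1/(exp(-dG/RT) - 1).  dG must not be
    positive (net direction undefined); at dG = 0 the net rate vanishes and
    f-/f_net is infinite.
    """
    if dg > 0:
        raise ValueError("dG must be negative for a defined net direction")
    rt_ = rt(temperature)
    ratio = math.exp(dg / rt_)
    if dg == 0:
        return 1.0, math.inf
    return ratio, 1.0 / (math.exp(-dg / rt_) - 1.0)


def overall_delta_g(butane, sulfate, sulfide, dic, dg0_overall: float,
                    temperature: float = T_STANDARD):
    """Free energy of the overall AOB process along a concentration series.

    C4H10 + 3.25 SO4^2- -> 4 HCO3- + 3.25 HS- (+ 0.75 H+ + H2O), with the
    H+ term absorbed in ``dg0_overall`` at pH 7.  Inputs in mmol L^-1
    (converted to activities relative to 1 mol L^-1); ``dg0_overall`` must
    be supplied by configuration.  Non-positive concentrations yield masked
    (NaN) points.
    """
    rt_ = rt(temperature)
    arrays = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, dtype=float)) / 1000.0
          for a in (butane, sulfate, sulfide, dic))
    )
    but, so4, hs, hco3 = (a.copy() for a in arrays)
    ok = (but > 0) & (so4 > 0) & (hs > 0) & (hco3 > 0)
    out = np.full(but.shape, np.nan)
    lnq = (4.0 * np.log(hco3, where=ok, out=np.zeros_like(hco3))
           + SULFATE_PER_BUTANE * np.log(hs, where=ok, out=np.zeros_like(hs))
           - np.log(but, where=ok, out=np.zeros_like(but))
           - SULFATE_PER_BUTANE * np.log(so4, where=ok, out=np.zeros_like(so4)))
    out[ok] = dg0_overall + rt_ * lnq[ok]
    return out
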