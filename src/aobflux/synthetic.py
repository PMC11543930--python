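"""Generators emulating the 13C-DIC labeling incubations.

Two modes:

* ``parametric_generate`` draws the butane and d13C trajectories directly
  from the empirical first-order and logistic models — the statistical
  structure the analysis pipeline assumes.
* ``mechanistic_simulate`` integrates the two-pool isotope exchange ODE
  with an imposed true back-flux profile mu*(t).  It tracks both isotopes
  explicitly, with kinetic fractionation applied to instantaneous isotope
  ratios, and serves as the independent oracle for the analytic pipeline.

The default truth parameters reproduce the anchor points of the study
conditions: 6 mmol L^-1 butane consumed to < 2% within ~120 d, sulfide at
3.25 mol per mol butane, and a d13C rise from -25 permil to ~ +80 permil
under 98 atom% 13C-DIC (to ~ -15 permil at natural abundance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import N_BUTANE, SULFATE_PER_BUTANE
from .isotope import (
    FirstOrderFit,
    LabelingSetup,
    LogisticFit,
    delta_to_fraction,
    fraction_to_delta,
)

__all__ = [
    "ExperimentConfig",
    "TruthRecord",
    "IsotopeTimeSeries",
    "default_d1",
    "parametric_generate",
    "mechanistic_simulate",
    "sulfide_series",
]

#: Default truth parameters of the 98 atom% labeling experiment:
#: (c0, c1 [mmol/L], lambda [1/d], d0, d1 [permil], d2 [d], k [1/d]).
DEFAULT_TRUTH = (0.1, 6.0, 0.04, -25.0, 80.0, 80.0, 0.08)

#: Plateau d13C anchors: -15 permil at natural abundance, +80 at 98 atom%.
_D1_ANCHORS = ((0.0112, -15.0), (0.98, 80.0))


def default_d1(atom13_dic0: float) -> float:
    """Plateau d13C of residual butane, interpolated linearly in the
    initial 13C abundance of the DIC pool between the observed anchors."""
    (x0, y0), (x1, y1) = _D1_ANCHORS
    return y0 + (atom13_dic0 - x0) * (y1 - y0) / (x1 - x0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Conditions of one labeling incubation.

    Defaults mirror the study design: 6 mmol L^-1 butane, 18 mmol L^-1 DIC
    at one of five 13C levels, 28 mmol L^-1 sulfate, sampling every 10 d
    over 160 d, 5% relative noise on concentrations and 1 permil on d13C.
    """

    alk0: float = 6.0
    dic0: float = 18.0
    atom13_dic0: float = 0.98
    delta0_alk: float = -25.0
    sulfate0: float = 28.0
    schedule: tuple[float, ...] = tuple(float(x) for x in range(0, 161, 10))
    noise_conc: float = 0.05
    noise_delta: float = 1.0
    noise_sulfide: float = 0.05
    n_technical: int = 3
    seed: int = 0
    assimilation_fraction: float = 0.0
    coupling_factor: float = 1.0
    mode: str = "parametric"

    def __post_init__(self) -> None:
        if min(self.alk0, self.dic0, self.sulfate0) <= 0:
            raise ValueError("concentrations must be positive")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size < 2 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing")

    def setup(self) -> LabelingSetup:
        return LabelingSetup(
            alk0=self.alk0, dic0=self.dic0, atom13_dic0=self.atom13_dic0,
            delta0_alk=self.delta0_alk,
        )

    def truth_params(self) -> tuple[float, ...]:
        c0, c1, lam, d0, _, d2, k = DEFAULT_TRUTH
        return (
            c0 * self.alk0 / 6.0, self.alk0, lam,
            self.delta0_alk, default_d1(self.atom13_dic0), d2, k,
        )


@dataclass(frozen=True)
class TruthRecord:
    """Generator ground truth emitted alongside every dataset."""

    mode: str
    params: dict[str, float]
    alphas: dict[str, float] = field(default_factory=dict)
    mu_true: tuple[float, ...] | None = None
    config: dict | None = None

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)

    @classmethod
    def read(cls, path: str | Path) -> "TruthRecord":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        if d.get("mu_true") is not None:
            d["mu_true"] = tuple(d["mu_true"])
        return cls(**d)


@dataclass
class IsotopeTimeSeries:
    """One incubation's measurements plus its labeling setup.

    ``data`` columns: time_d, butane_mmol_l, sulfide_mmol_l,
    d13c_butane_permil, replicate.  d13C technical replicates share the
    concentration measurement of their time point.
    """

    data: pd.DataFrame
    setup: LabelingSetup

    REQUIRED = ("time_d", "butane_mmol_l", "sulfide_mmol_l",
                "d13c_butane_permil", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")

    def averaged(self) -> pd.DataFrame:
        """Technical replicates averaged per time point, sorted by time."""
        out = (self.data.groupby("time_d", as_index=False)
               [["butane_mmol_l", "sulfide_mmol_l", "d13c_butane_permil"]]
               .mean())
        return out.sort_values("time_d").reset_index(drop=True)


def sulfide_series(butane, sulfate0: float = 28.0,
                   coupling_factor: float = 1.0):
    """Sulfide produced by sulfate reduction coupled to butane oxidation.

    3.25 mol sulfate per mol butane (26 e- released / 8 e- per sulfate),
    scaled by ``coupling_factor`` (measured electron-balance ratio), and
    capped once sulfate is exhausted.
    """
    butane = np.asarray(butane, dtype=float)
    consumed = butane[0] - butane
    if np.any(np.diff(consumed) < -1e-9):
        raise ValueError("butane series must be non-increasing before noise")
    sulfide = SULFATE_PER_BUTANE * consumed * coupling_factor
    return np.minimum(sulfide, sulfate0)


def _apply_noise(config: ExperimentConfig, t, butane, sulfide, delta,
                 rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for j, tt in enumerate(t):
        b = butane[j]
        s = sulfide[j]
        if config.noise_conc > 0:
            b = max(b * (1.0 + config.noise_conc * rng.standard_normal()), 0.0)
        if config.noise_sulfide > 0:
            s = max(s * (1.0 + config.noise_sulfide * rng.standard_normal()), 0.0)
        for rep in range(1, config.n_technical + 1):
            d = delta[j]
            if config.noise_delta > 0:
                d = d + config.noise_delta * rng.standard_normal()
            rows.append((tt, b, s, d, rep))
    return pd.DataFrame(
        rows, columns=list(IsotopeTimeSeries.REQUIRED)
    )


def parametric_generate(
    config: ExperimentConfig,
    params: tuple[float, ...] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[IsotopeTimeSeries, TruthRecord]:
    """Draw a dataset from the empirical trajectory models.

    ``params`` = (c0, c1, lam, d0, d1, d2, k); defaults are the study-
    condition truth for the configured label level.
    """
    if params is None:
        params = config.truth_params()
    c0, c1, lam, d0, d1, d2, k = params
    fit = FirstOrderFit(c0=c0, c1=c1, lam=lam)
    lfit = LogisticFit(d0=d0, d1=d1, d2=d2, k=k)
    t = np.asarray(config.schedule, dtype=float)
    butane = fit.alkane(t)
    delta = lfit.delta(t)
    sulfide = sulfide_series(butane, config.sulfate0, config.coupling_factor)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    data = _apply_noise(config, t, butane, sulfide, delta, rng)
    truth = TruthRecord(
        mode="parametric",
        params=dict(zip(("c0", "c1", "lam", "d0", "d1", "d2", "k"), params)),
        config=asdict(config),
    )
    return IsotopeTimeSeries(data=data, setup=config.setup()), truth


def mechanistic_simulate(
    config: ExperimentConfig,
    mu_true=2e-3,
    alpha_plus: float = 0.9975,
    alpha_minus: float = 1.0,
    decay: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
    rtol: float = 1e-9,
) -> tuple[IsotopeTimeSeries, TruthRecord]:
    """Integrate the two-pool isotope-exchange ODE (the oracle mode).

    The total alkane pool decays first-order at net rate v = lam*(Alk-c0)
    (``decay`` = (c0, lam), defaulting to the study-condition truth); the
    forward flux f+ = (1+mu)v and back flux f- = mu*n*v exchange carbon
    with the DIC pool.  Isotope fluxes are split by instantaneous isotope
    ratios with kinetic fractionation factors alpha+/alpha- applied
    ratio-wise, so the mu* = 0, natural-abundance limit reproduces closed-
    form Rayleigh distillation.  An optional assimilation fraction diverts
    net oxidized carbon from the DIC pool into biomass.

    ``mu_true`` may be a constant or a callable mu(t) >= 0.
    """
    if callable(mu_true):
        mu_fn = mu_true
    else:
        if mu_true < 0:
            raise ValueError("mu_true must be non-negative")
        mu_fn = lambda t: mu_true  # noqa: E731
    setup = config.setup()
    n = setup.n
    if decay is None:
        c0, _, lam, *_ = config.truth_params()
    else:
        c0, lam = decay
    a_frac = config.assimilation_fraction
    c_tot, c13_tot = setup.c_total, setup.c13_total
    f0 = float(delta_to_fraction(config.delta0_alk))

    def h(frac, alpha):
        # 13C share of a flux drawn from a pool at abundance `frac`,
        # fractionating on the isotope ratio
        r = alpha * frac / (1.0 - frac)
        return r / (1.0 + r)

    def rhs(t, y):
        alk, a13, bio, bio13 = y
        v = lam * max(alk - c0, 0.0)
        mu = mu_fn(t)
        f_minus_c = mu * n * v          # carbon units
        f_plus_c = (1.0 + mu) * n * v
        dic = c_tot - n * alk - bio
        dic13 = c13_tot - a13 - bio13
        if dic <= 0:
            raise ValueError("DIC pool underflow during integration")
        f_alk = a13 / (n * alk) if alk > 0 else 0.0
        f_dic = dic13 / dic
        d_alk = -v
        d_a13 = f_minus_c * h(f_dic, alpha_minus) - f_plus_c * h(f_alk, alpha_plus)
        d_bio = a_frac * n * v
        d_bio13 = a_frac * n * v * h(f_alk, alpha_plus)
        return [d_alk, d_a13, d_bio, d_bio13]

    t = np.asarray(config.schedule, dtype=float)
    y0 = [setup.alk0, n * f0 * setup.alk0, 0.0, 0.0]
    sol = solve_ivp(rhs, (t[0], t[-1]), y0, t_eval=t, method="LSODA",
                    rtol=rtol, atol=1e-14)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    alk, a13 = sol.y[0], sol.y[1]
    frac = a13 / (n * alk)
    delta = fraction_to_delta(frac)
    sulfide = sulfide_series(alk, config.sulfate0, config.coupling_factor)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    data = _apply_noise(config, t, alk, sulfide, delta, rng)
    truth = TruthRecord(
        mode="mechanistic",
        params={"c0": c0, "lam": lam, "alk0": setup.alk0},
        alphas={"alpha_plus": alpha_plus, "alpha_minus": alpha_minus},
        mu_true=tuple(float(mu_fn(tt)) for tt in t),
        config=asdict(config),
    )
    return IsotopeTimeSeries(data=data, setup=setup), truth
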