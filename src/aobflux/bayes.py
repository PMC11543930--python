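"""Ensemble-MCMC inference of the empirical fit parameters.

The seven parameters — (c0, c1, lam) of the first-order butane model and
(d0, d1, d2, k) of the logistic d13C model — are sampled as two
independent blocks with affine-invariant ensemble MCMC (emcee), uniform
priors and a Gaussian likelihood whose scale is 5% of the mean observed
concentration for the butane series and 1 permil for d13C.  Posterior
draws are propagated through the isotope balance to pointwise credible
bands on the back-flux extent mu(t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd

from .isotope import (
    BackFluxTrajectory,
    FirstOrderFit,
    IsotopeConstants,
    LabelingSetup,
    LogisticFit,
    _first_order,
    _logistic,
    back_flux_extent,
)

__all__ = [
    "PriorSpec",
    "LikelihoodSpec",
    "PosteriorEnsemble",
    "default_priors",
    "log_likelihood",
    "sample_posterior",
    "infer_experiment",
    "posterior_backflux",
]

FIRST_ORDER_PARAMS = ("c0", "c1", "lam")
LOGISTIC_PARAMS = ("d0", "d1", "d2", "k")

#: Convergence thresholds: integrated autocorrelation time must fit this
#: many times into the chain, and split-chain R-hat must stay below 1.1.
TAU_FACTOR = 50.0
RHAT_MAX = 1.1


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one (low, high) pair per parameter."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name}: low must be < high")

    def names(self) -> tuple[str, ...]:
        return tuple(self.bounds)

    def contains(self, theta: np.ndarray) -> np.ndarray:
        lo = np.array([b[0] for b in self.bounds.values()])
        hi = np.array([b[1] for b in self.bounds.values()])
        theta = np.atleast_2d(theta)
        return np.all((theta >= lo) & (theta <= hi), axis=1)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        lo = np.array([b[0] for b in self.bounds.values()])
        hi = np.array([b[1] for b in self.bounds.values()])
        return rng.uniform(lo, hi, size=(size, len(self.bounds)))

    def widened(self, factor: float) -> "PriorSpec":
        """Bounds stretched about their midpoint (positivity preserved)."""
        out = {}
        for name, (lo, hi) in self.bounds.items():
            mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo) * factor
            new_lo = mid - half
            if lo >= 0:
                new_lo = max(new_lo, 0.0 if lo == 0 else lo / factor)
            out[name] = (new_lo, mid + half)
        return PriorSpec(out)


@dataclass(frozen=True)
class LikelihoodSpec:
    """Gaussian error scales: relative on concentrations, permil on d13C."""

    sigma_conc: float = 0.05
    sigma_delta: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_conc <= 0 or self.sigma_delta <= 0:
            raise ValueError("likelihood scales must be positive")


@dataclass
class PosteriorEnsemble:
    """Retained posterior draws with convergence diagnostics.

    ``draws`` holds the subsampled draws used for posterior propagation;
    ``posterior_mean`` / ``posterior_sd`` summarize the full post-burn-in
    chain (much smaller Monte-Carlo error than the subsample).
    """

    draws: pd.DataFrame
    n_chains: int
    n_steps: int
    burn_in: int
    seed: int
    tau: dict[str, float]
    rhat: dict[str, float]
    posterior_mean: dict[str, float] = field(default_factory=dict)
    posterior_sd: dict[str, float] = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        tau_ok = all((self.n_steps - self.burn_in) >= TAU_FACTOR * t
                     for t in self.tau.values())
        rhat_ok = all(r < RHAT_MAX for r in self.rhat.values())
        return tau_ok and rhat_ok

    def diagnostics_report(self) -> str:
        lines = [
            f"chains: {self.n_chains}  steps: {self.n_steps}  "
            f"burn-in: {self.burn_in}  retained draws: {len(self.draws)}",
            f"converged: {self.converged}",
        ]
        for name in self.draws.columns:
            mean = self.posterior_mean.get(name, self.draws[name].mean())
            sd = self.posterior_sd.get(name, self.draws[name].std())
            lines.append(
                f"{name}: tau={self.tau[name]:.1f}  rhat={self.rhat[name]:.4f}  "
                f"mean={mean:.6g}  sd={sd:.3g}"
            )
        return "\n".join(lines)


def default_priors(model: str, alk0: float = 6.0, t_max: float = 160.0) -> PriorSpec:
    """Wide positivity-respecting uniform bounds scaled to the experiment."""
    if model == "first_order":
        return PriorSpec({
            "c0": (0.0, alk0),
            "c1": (0.5 * alk0, 2.0 * alk0),
            "lam": (1e-4, 1.0),
        })
    if model == "logistic":
        return PriorSpec({
            "d0": (-60.0, 20.0),
            "d1": (-60.0, 1000.0),
            "d2": (0.0, 2.0 * t_max),
            "k": (1e-3, 1.0),
        })
    raise ValueError(f"unknown model {model!r}")


def _model_fn(model: str):
    if model == "first_order":
        return _first_order
    if model == "logistic":
        return _logistic
    raise ValueError(f"unknown model {model!r}")


def _sigma(model: str, y: np.ndarray, spec: LikelihoodSpec) -> float:
    if model == "first_order":
        return spec.sigma_conc * float(np.mean(y))
    return spec.sigma_delta


def log_likelihood(theta, t, y, model: str, spec: LikelihoodSpec,
                   priors: PriorSpec | None = None):
    """Gaussian log-likelihood of one parameter block (vectorized).

    ``theta`` may be a single parameter vector or a (walkers, ndim) array.
    Parameters outside the prior support score -inf.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    single = theta.ndim == 1
    th = np.atleast_2d(theta)
    sigma = _sigma(model, y, spec)
    fn = _model_fn(model)
    pred = fn(t[None, :], *(th[:, j:j + 1] for j in range(th.shape[1])))
    sse = np.sum((y[None, :] - pred) ** 2, axis=1)
    out = -0.5 * sse / sigma**2 - y.size * np.log(np.sqrt(2.0 * np.pi) * sigma)
    if priors is not None:
        out = np.where(priors.contains(th), out, -np.inf)
    return float(out[0]) if single else out


def _ball_init(t, y, model: str, priors: PriorSpec,
               rng: np.random.Generator, n_chains: int) -> np.ndarray:
    """Walkers in a small relative ball around the least-squares estimate,
    clipped into the prior support (the standard ensemble-MCMC workflow
    for unimodal curve-fit posteriors)."""
    from .isotope import fit_first_order, fit_logistic

    if model == "first_order":
        f = fit_first_order(t, y)
        est = np.array([f.c0, f.c1, f.lam])
    else:
        f = fit_logistic(t, y)
        est = np.array([f.d0, f.d1, f.d2, f.k])
    lo = np.array([b[0] for b in priors.bounds.values()])
    hi = np.array([b[1] for b in priors.bounds.values()])
    scale = np.maximum(0.02 * np.abs(est), 1e-4 * (hi - lo))
    p0 = est + scale * rng.standard_normal((n_chains, est.size))
    eps = 1e-9 * (hi - lo)
    return np.clip(p0, lo + eps, hi - eps)


def sample_posterior(
    t, y, model: str,
    priors: PriorSpec | None = None,
    spec: LikelihoodSpec | None = None,
    seed: int = 0,
    n_chains: int = 128,
    n_steps: int = 5000,
    burn_in: int = 2000,
    n_final: int = 1000,
    init: str = "ball",
) -> PosteriorEnsemble:
    """Affine-invariant ensemble sampling of one parameter block.

    Walkers start from a tight ball around the least-squares estimate
    (``init="ball"``, default) or from uniform prior draws
    (``init="prior"``); the ball start is preferred because prior-wide
    starts leave straggling walkers that survive the fixed burn-in.  After
    discarding ``burn_in`` steps, ``n_final`` draws are retained by
    evenly-spaced subsampling of the flattened chain.  Fully reproducible
    under ``seed``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if priors is None:
        priors = default_priors(model, alk0=float(np.max(y)) if model == "first_order" else 6.0,
                                t_max=float(np.max(t)))
    spec = spec or LikelihoodSpec()
    names = priors.names()
    ndim = len(names)
    rng = np.random.default_rng(seed)
    if init == "ball":
        try:
            p0 = _ball_init(t, y, model, priors, rng, n_chains)
        except ValueError:
            p0 = priors.sample(rng, n_chains)
    elif init == "prior":
        p0 = priors.sample(rng, n_chains)
    else:
        raise ValueError(f"unknown init {init!r}")
    lp0 = log_likelihood(p0, t, y, model, spec, priors)
    if not np.any(np.isfinite(lp0)):
        raise ValueError(
            "likelihood is non-finite at every initial position; "
            "check prior bounds against the data scale"
        )
    # replace non-finite starters with finite ones (prior draws, retried)
    bad = ~np.isfinite(lp0)
    for _ in range(100):
        if not bad.any():
            break
        p0[bad] = priors.sample(rng, int(bad.sum()))
        lp0 = log_likelihood(p0, t, y, model, spec, priors)
        bad = ~np.isfinite(lp0)

    sampler = emcee.EnsembleSampler(
        n_chains, ndim,
        log_likelihood, args=(t, y, model, spec, priors),
        vectorize=True,
    )
    state = np.random.RandomState(rng.integers(2**31 - 1))
    sampler.random_state = state.get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)

    chain = sampler.get_chain()  # (steps, walkers, ndim)
    post = chain[burn_in:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tau_arr = sampler.get_autocorr_time(discard=burn_in, tol=0, quiet=True)
    tau = {n: float(tau_arr[j]) for j, n in enumerate(names)}
    rhat = {
        n: float(az.rhat(np.ascontiguousarray(post[:, :, j].T)))
        for j, n in enumerate(names)
    }
    flat = post.reshape(-1, ndim)
    idx = np.linspace(0, flat.shape[0] - 1, n_final).astype(int)
    draws = pd.DataFrame(flat[idx], columns=list(names))
    return PosteriorEnsemble(
        draws=draws, n_chains=n_chains, n_steps=n_steps, burn_in=burn_in,
        seed=seed, tau=tau, rhat=rhat,
        posterior_mean={n: float(flat[:, j].mean()) for j, n in enumerate(names)},
        posterior_sd={n: float(flat[:, j].std()) for j, n in enumerate(names)},
    )


def infer_experiment(
    timeseries, spec: LikelihoodSpec | None = None, seed: int = 0,
    priors_conc: PriorSpec | None = None,
    priors_delta: PriorSpec | None = None,
    **mcmc_kwargs,
) -> tuple[PosteriorEnsemble, PosteriorEnsemble]:
    """Sample both parameter blocks of one incubation.

    Technical d13C replicates are averaged per time point before fitting.
    Returns the (concentration, d13C) ensembles, sampled independently
    with seeds derived from ``seed``.
    """
    df = timeseries.averaged()
    t = df["time_d"].to_numpy()
    alk0 = timeseries.setup.alk0
    ens_c = sample_posterior(
        t, df["butane_mmol_l"].to_numpy(), "first_order",
        priors=priors_conc or default_priors("first_order", alk0=alk0),
        spec=spec, seed=seed * 2 + 1, **mcmc_kwargs,
    )
    ens_d = sample_posterior(
        t, df["d13c_butane_permil"].to_numpy(), "logistic",
        priors=priors_delta or default_priors("logistic", t_max=float(t.max())),
        spec=spec, seed=seed * 2 + 2, **mcmc_kwargs,
    )
    return ens_c, ens_d


def posterior_backflux(
    ensembles: tuple[PosteriorEnsemble, PosteriorEnsemble],
    setup: LabelingSetup,
    const: IsotopeConstants,
    t,
) -> BackFluxTrajectory:
    """Propagate paired posterior draws to 95% bands on mu(t).

    Draws of the two blocks are paired by index (they are independent
    posteriors).  Reports the pointwise median and the 2.5/97.5
    percentiles over draws; a point is masked when identifiable in fewer
    than half of the draws.  An unconverged ensemble attaches a warning.
    """
    ens_c, ens_d = ensembles
    t = np.asarray(t, dtype=float)
    n_draws = min(len(ens_c.draws), len(ens_d.draws))
    mus = np.full((n_draws, t.size), np.nan)
    vs = np.full((n_draws, t.size), np.nan)
    for i in range(n_draws):
        c = ens_c.draws.iloc[i]
        d = ens_d.draws.iloc[i]
        try:
            fit = FirstOrderFit(c0=c["c0"], c1=c["c1"], lam=c["lam"])
            lfit = LogisticFit(d0=d["d0"], d1=d["d1"], d2=d["d2"], k=d["k"])
            traj = back_flux_extent(setup, fit, lfit, const, t)
        except ValueError:
            continue
        mus[i] = traj.mu
        vs[i] = traj.v
    n_valid = np.sum(np.isfinite(mus), axis=0)
    mask = n_valid >= max(1, n_draws // 2)
    if not mask.any():
        raise ValueError("no identifiable back flux window in any draw")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mu_med = np.nanmedian(mus, axis=0)
        lo, hi = np.nanpercentile(mus, [2.5, 97.5], axis=0)
        v_med = np.nanmedian(vs, axis=0)
    converged = ens_c.converged and ens_d.converged
    if not converged:
        warnings.warn("posterior ensemble not converged; bands may be unreliable",
                      stacklevel=2)
    n = const.n
    return BackFluxTrajectory(
        t=t, mu=mu_med, f_minus=mu_med * n * v_med,
        f_plus=(1.0 + mu_med) * v_med, f_net=v_med, v=v_med,
        mask=mask, mu_lo95=lo, mu_hi95=hi, converged=converged,
    )
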