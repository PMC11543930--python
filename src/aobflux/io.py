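"""CSV / YAML input-output for time series, trajectories and ensembles.

Fixed unit system, validated at parse time: time in days, concentrations
in mmol L^-1, d13C in permil VPDB, energies in kJ mol^-1.  All CSV output
uses comma separation, UTF-8 and 9 significant digits.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import PosteriorEnsemble
from .isotope import BackFluxTrajectory, LabelingSetup
from .quasieq import QuasiEquilibriumSolution
from .synthetic import ExperimentConfig, IsotopeTimeSeries

__all__ = [
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "write_trajectory",
    "write_solution",
    "write_ensemble",
]

_FLOAT_FMT = "%.9g"


@dataclass(frozen=True)
class RunConfig:
    """Whole-pipeline configuration; round-trips losslessly through YAML."""

    experiment: dict = field(default_factory=lambda: asdict(ExperimentConfig()))
    isotope: dict = field(default_factory=lambda: {
        "alpha_plus": 0.9975, "alpha_minus": 1.0, "n": 4})
    inference: dict = field(default_factory=lambda: {
        "n_chains": 128, "n_steps": 5000, "burn_in": 2000, "n_final": 1000})
    thermo: dict = field(default_factory=lambda: {
        "direction": "AOB", "ex": -0.220, "xh2_x_ratio": 4.0})
    dg0_overall: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    def write(self, path: str | Path) -> None:
        d = asdict(self)
        d["experiment"]["schedule"] = list(d["experiment"]["schedule"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if "experiment" in d and "schedule" in d["experiment"]:
            d["experiment"]["schedule"] = tuple(d["experiment"]["schedule"])
        return cls(**d)

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(**self.experiment)


def read_timeseries(path: str | Path,
                    setup: LabelingSetup | None = None) -> IsotopeTimeSeries:
    """Read an incubation time series CSV.

    Requires columns time_d, butane_mmol_l, sulfide_mmol_l,
    d13c_butane_permil, replicate (unit suffixes are part of the
    contract).  Rows are sorted by time; replicates stay grouped.
    """
    df = pd.read_csv(path)
    missing = [c for c in IsotopeTimeSeries.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("butane_mmol_l", "sulfide_mmol_l"):
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative concentration in {col}")
    if (df["time_d"] < 0).any():
        raise ValueError(f"{path}: negative time")
    df = df.sort_values(["time_d", "replicate"], kind="stable").reset_index(drop=True)
    times = df["time_d"].unique()
    if not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}: time points not strictly increasing")
    return IsotopeTimeSeries(data=df, setup=setup or LabelingSetup())


def write_timeseries(ts: IsotopeTimeSeries, path: str | Path) -> None:
    ts.data.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_trajectory(traj: BackFluxTrajectory, path: str | Path) -> None:
    """Back-flux trajectory CSV with deterministic column order."""
    cols = {
        "time_d": traj.t,
        "mu": traj.mu,
        "mu_lo95": traj.mu_lo95 if traj.mu_lo95 is not None else np.full_like(traj.t, np.nan),
        "mu_hi95": traj.mu_hi95 if traj.mu_hi95 is not None else np.full_like(traj.t, np.nan),
        "f_minus": traj.f_minus,
        "f_plus": traj.f_plus,
        "v": traj.v,
        "dg": traj.dg if traj.dg is not None else np.full_like(traj.t, np.nan),
        "valid": traj.mask.astype(int),
    }
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_solution(sol: QuasiEquilibriumSolution, path: str | Path) -> None:
    """Quasi-equilibrium solution as YAML (activities, dG, verdict)."""
    d = {
        "feasible": bool(sol.feasible),
        "residual_norm": float(sol.residual_norm),
        "dissipation_dg_kj_mol": float(sol.dissipation_dg),
        "catabolic_dg_kj_mol": float(sol.catabolic_dg),
        "activities_mol_l": {k: float(np.exp(v)) for k, v in sol.log_activities.items()},
        "ln_redox_ratios": {k: float(v) for k, v in sol.redox_ratios.items()},
        "per_reaction_dg_kj_mol": {int(k): float(v) for k, v in sol.per_reaction_dg.items()},
        "violations": {k: float(v) for k, v in sol.report.violations.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def write_ensemble(ens: PosteriorEnsemble, path: str | Path) -> None:
    """Posterior draws CSV plus a '# ' commented diagnostics block header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in ens.diagnostics_report().splitlines():
            fh.write(f"# {line}\n")
        ens.draws.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_ensemble_draws(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
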