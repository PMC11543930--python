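"""Quasi-equilibrium solver for pathway intermediate concentrations.

Each non-dissipating reaction j pins its free energy at a target (0 for
equilibrium steps, ``n_H * proton_quantum`` for PMF-coupled steps), giving
one linear equation in the log-activities of the internal metabolites and
the log-ratios of the cytoplasmic redox couples:

    sum_i s_ij ln a_i = (dG_target_j - dG0'_j) / RT  - boundary terms.

The single dissipation reaction is excluded from the system; its free
energy is recovered afterwards as the slack that closes the pathway energy
balance (dG_dis).  A scheme is feasible when every solved metabolite
activity lies inside a physiological window (1 uM - 10 mM by default) and
the dissipated energy is non-positive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .pathway import CouplingScheme, PathwayModel

__all__ = [
    "QuasiEquilibriumSolution",
    "FeasibilityReport",
    "quasi_equilibrium_solve",
    "feasibility",
    "net_proton_search",
    "FEASIBLE_LOW",
    "FEASIBLE_HIGH",
]

#: Physiological concentration window for solved intermediates, mol L^-1.
FEASIBLE_LOW = 1e-6
FEASIBLE_HIGH = 1e-2

#: Relative residual above which the linear system is declared inconsistent.
RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class FeasibilityReport:
    feasible: bool
    low: float
    high: float
    violations: dict[str, float] = field(default_factory=dict)
    dissipation_positive: bool = False


@dataclass(frozen=True)
class QuasiEquilibriumSolution:
    """Solved log-activities, per-reaction free energies and diagnostics."""

    log_activities: dict[str, float]
    redox_ratios: dict[str, float]  # couple -> ln(reduced/oxidized)
    per_reaction_dg: dict[int, float]
    dissipation_dg: float
    catabolic_dg: float
    residual_norm: float
    feasible: bool
    report: FeasibilityReport

    @property
    def activities(self) -> dict[str, float]:
        return {sp: math.exp(v) for sp, v in self.log_activities.items()}


def _reaction_dg(model: PathwayModel, reaction, log_act, log_ratio) -> float:
    """dG = dG0' + RT * sum_i s_i ln a_i with couples as ratio terms."""
    red_by_couple = {red: c for c, (red, ox) in model.couples.items()}
    ox_by_couple = {ox: c for c, (red, ox) in model.couples.items()}
    s = 0.0
    for sp, c in reaction.stoich.items():
        c = float(c)
        if sp == "H+":
            continue
        if sp in red_by_couple:
            s += c * log_ratio[red_by_couple[sp]]
        elif sp in ox_by_couple:
            pass  # paired with the reduced form; net contribution is the ratio
        elif sp in model.boundary:
            s += c * math.log(model.boundary[sp])
        else:
            s += c * log_act[sp]
    return reaction.dg0_prime(model.ex) + model.rt * s


def quasi_equilibrium_solve(
    model: PathwayModel,
    scheme: CouplingScheme,
    low: float = FEASIBLE_LOW,
    high: float = FEASIBLE_HIGH,
) -> QuasiEquilibriumSolution:
    """Solve the log-linear concentration system for one coupling scheme.

    Raises ``ValueError`` if the system is rank-deficient (naming the
    undetermined species).  An inconsistent (over-determined) system is
    returned flagged infeasible with its residual as diagnostic.
    """
    internals = model.internal_species()
    solved_couples = [c for c in model.couples if c != "X"]
    unknowns = internals + [f"ratio:{c}" for c in solved_couples]
    n = len(unknowns)
    col = {u: k for k, u in enumerate(unknowns)}

    red_by_couple = {red: c for c, (red, ox) in model.couples.items()}
    ox_by_couple = {ox: c for c, (red, ox) in model.couples.items()}

    rows, rhs = [], []
    constrained = [r for r in model.reactions if scheme.role(r.index) != "dissipation"]
    if len([r for r in model.reactions if scheme.role(r.index) == "dissipation"]) > 1:
        raise ValueError("scheme may designate at most one dissipation reaction")
    for r in constrained:
        a = np.zeros(n)
        b = (scheme.pmf_sites.get(r.index, 0) * model.proton_quantum
             - r.dg0_prime(model.ex)) / model.rt
        for sp, c in r.stoich.items():
            c = float(c)
            if sp == "H+":
                continue
            if sp in red_by_couple:
                couple = red_by_couple[sp]
                if couple == "X":
                    b -= c * math.log(model.xh2_x_ratio)
                else:
                    a[col[f"ratio:{couple}"]] += c
            elif sp in ox_by_couple:
                continue
            elif sp in model.boundary:
                b -= c * math.log(model.boundary[sp])
            else:
                a[col[sp]] += c
        rows.append(a)
        rhs.append(b)

    amat = np.array(rows) if rows else np.zeros((0, n))
    bvec = np.array(rhs)
    if n:
        rank = np.linalg.matrix_rank(amat) if rows else 0
        if rank < n:
            # name the species spanning the null space
            _, sv, vt = np.linalg.svd(amat) if rows else (None, np.zeros(0), np.eye(n))
            null = vt[rank:] if rows else np.eye(n)
            loose = sorted(
                {unknowns[k] for vec in null for k in np.nonzero(np.abs(vec) > 1e-10)[0]}
            )
            raise ValueError(f"rank-deficient system; undetermined species: {loose}")
        x, *_ = np.linalg.lstsq(amat, bvec, rcond=None)
    else:
        x = np.zeros(0)
    resid = float(np.linalg.norm(amat @ x - bvec)) if rows else 0.0
    scale = max(1.0, float(np.linalg.norm(bvec))) if rows else 1.0
    consistent = resid / scale <= RESIDUAL_TOL

    log_act = {sp: float(x[col[sp]]) for sp in internals}
    log_ratio = {c: float(x[col[f"ratio:{c}"]]) for c in solved_couples}
    log_ratio["X"] = math.log(model.xh2_x_ratio)

    per_dg = {
        r.index: _reaction_dg(model, r, log_act, log_ratio) for r in model.reactions
    }
    if scheme.dissipation_site is not None:
        dis_dg = per_dg[scheme.dissipation_site]
    else:
        dis_dg = 0.0
    catabolic = sum(r.multiplicity * per_dg[r.index] for r in model.reactions)

    report = feasibility_from_logs(log_act, dis_dg, low, high,
                                   has_dissipation=scheme.dissipation_site is not None)
    return QuasiEquilibriumSolution(
        log_activities=log_act,
        redox_ratios=log_ratio,
        per_reaction_dg=per_dg,
        dissipation_dg=dis_dg,
        catabolic_dg=catabolic,
        residual_norm=resid,
        feasible=consistent and report.feasible,
        report=report,
    )


def feasibility_from_logs(
    log_act: dict[str, float],
    dissipation_dg: float,
    low: float = FEASIBLE_LOW,
    high: float = FEASIBLE_HIGH,
    has_dissipation: bool = True,
) -> FeasibilityReport:
    if not (0 < low < high):
        raise ValueError("thresholds must satisfy 0 < low < high")
    violations = {}
    for sp, la in log_act.items():
        a = math.exp(la)
        if not (low <= a <= high):
            violations[sp] = a
    dis_bad = has_dissipation and dissipation_dg > 1e-9
    return FeasibilityReport(
        feasible=not violations and not dis_bad,
        low=low,
        high=high,
        violations=violations,
        dissipation_positive=dis_bad,
    )


def feasibility(
    solution: QuasiEquilibriumSolution,
    low: float = FEASIBLE_LOW,
    high: float = FEASIBLE_HIGH,
) -> FeasibilityReport:
    """Re-assess a solution against a concentration window.

    Redox ratios are dimensionless and exempt from the bounds.
    """
    return feasibility_from_logs(solution.log_activities, solution.dissipation_dg,
                                 low, high)


def net_proton_search(
    model: PathwayModel,
    max_per_site: int = 4,
    pmf_sites: tuple[int, ...] | None = None,
    dissipation_site: int | None | str = "auto",
    feasible_only: bool = True,
) -> list[tuple[CouplingScheme, int, bool]]:
    """Enumerate integer proton stoichiometries over the PMF sites.

    Every assignment with each |n_H| <= ``max_per_site`` is solved; results
    are sorted by net protons conserved (descending) with a deterministic
    tie-break on the per-site assignment.  Returns ``(scheme, net_protons,
    feasible)`` triples, restricted to feasible schemes by default.
    ``dissipation_site="auto"`` places dissipation at the shipped default
    for the model's direction; ``None`` solves without a dissipation step.
    """
    if max_per_site < 1:
        raise ValueError("max_per_site must be >= 1")
    if pmf_sites is None:
        pmf_sites = (3, 15, 16, 17)
    if dissipation_site == "auto":
        dissipation_site = 11 if model.direction == "AOB" else 9
    results = []
    choices = range(-max_per_site, max_per_site + 1)
    for assignment in itertools.product(choices, repeat=len(pmf_sites)):
        scheme = CouplingScheme(
            pmf_sites=dict(zip(pmf_sites, assignment)),
            dissipation_site=dissipation_site,
        )
        sol = quasi_equilibrium_solve(model, scheme)
        if sol.feasible or not feasible_only:
            results.append((scheme, scheme.net_protons(model), sol.feasible))
    results.sort(
        key=lambda t: (-t[1], tuple(sorted(t[0].pmf_sites.items())))
    )
    return results
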