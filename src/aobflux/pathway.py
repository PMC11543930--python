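"""Pathway-level bookkeeping: net stoichiometry, electron ledger, reversal,
and the catabolic free energy of the overall AOB / rAOB conversion.

The oxidative pathway sums to ``C4H10 + 8 H2O + 13 X -> 4 CO2 + 13 XH2``;
the reductive direction (rAOB, archaeal butane formation from CO2) is the
exact mirror, obtained by negating every reaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

from .constants import PROTON_QUANTUM, T_STANDARD, rt
from .reactions import (
    DEFAULT_BOUNDARY,
    REDOX_COUPLES,
    Reaction,
    load_reaction_table,
)

__all__ = [
    "PathwayModel",
    "CouplingScheme",
    "CarrierLedger",
    "delta_g0_prime",
    "net_reaction",
    "electron_ledger",
    "reverse_model",
    "catabolic_delta_g",
    "default_aob_model",
    "default_raob_model",
    "default_aob_scheme",
    "default_raob_scheme",
]

#: Reactions that only shuttle electrons between carriers and the
#: membrane-bound MQ/X pool (NDH, Fqo, Nuo, terminal MHCs).  They are
#: excluded when counting how many reduced carriers the pathway generates.
MEMBRANE_TRANSFER_REACTIONS = frozenset({8, 15, 16, 17})

#: Electrons per reduced carrier.  XH2, NADH and F420H2 are two-electron
#: carriers; ferredoxin is counted as a one-electron carrier, consistent
#: with a 26-electron total for full butane oxidation.
ELECTRONS_PER_CARRIER = {"XH2": 2, "NADH": 2, "F420H2": 2, "Fd_red": 1}

_EX_SHIPPED_RANGE = (-0.414, -0.220)


@dataclass(frozen=True)
class CarrierLedger:
    """Reduced electron carriers generated per mol butane oxidized."""

    counts: dict[str, int]
    electrons_total: int


@dataclass(frozen=True)
class CouplingScheme:
    """Energy-transduction assignment for the quasi-equilibrium solve.

    ``pmf_sites`` maps reaction index -> signed proton count n_H; the step's
    free energy is pinned at ``n_H * proton_quantum`` (positive n_H =
    protons conserved, negative = invested).  ``dissipation_site`` (at most
    one) is the step whose free energy is left free and recovered as the
    slack closing the pathway energy balance.  All other reactions are held
    at thermodynamic equilibrium (dG = 0).
    """

    pmf_sites: dict[int, int] = field(default_factory=dict)
    dissipation_site: int | None = None

    def __post_init__(self) -> None:
        if self.dissipation_site is not None and self.dissipation_site in self.pmf_sites:
            raise ValueError("dissipation site cannot also be a pmf site")

    def role(self, index: int) -> str:
        if index == self.dissipation_site:
            return "dissipation"
        if self.pmf_sites.get(index, 0) != 0:
            return "pmf"
        return "equilibrium"

    def net_protons(self, model: "PathwayModel") -> int:
        """Net protons conserved per mol butane (conserved minus invested)."""
        mult = {r.index: r.multiplicity for r in model.reactions}
        return sum(n * mult[i] for i, n in self.pmf_sites.items())


@dataclass(frozen=True)
class PathwayModel:
    """A directed pathway with boundary conditions.

    Boundary species have fixed activities; the four cytoplasmic redox
    couples (NAD, F420, Fd, MQ) are solved as single reduced/oxidized
    ratios; the syntrophic couple X/XH2 is an imposed ratio
    (``xh2_x_ratio``).  Everything else is a solved internal metabolite.
    """

    reactions: tuple[Reaction, ...]
    direction: str = "AOB"
    ex: float = -0.220
    temperature: float = T_STANDARD
    proton_quantum: float = PROTON_QUANTUM
    boundary: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BOUNDARY))
    xh2_x_ratio: float = 4.0
    couples: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(REDOX_COUPLES)
    )

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.xh2_x_ratio <= 0:
            raise ValueError("xh2_x_ratio must be positive")
        if any(a <= 0 for a in self.boundary.values()):
            raise ValueError("boundary activities must be positive")

    @property
    def rt(self) -> float:
        return rt(self.temperature)

    @property
    def couple_species(self) -> set[str]:
        return {sp for pair in self.couples.values() for sp in pair}

    def internal_species(self) -> list[str]:
        """Solved metabolites: everything not boundary and not a redox form."""
        seen: list[str] = []
        skip = self.couple_species
        for r in self.reactions:
            for sp in r.stoich:
                if sp in self.boundary or sp in skip or sp in seen:
                    continue
                seen.append(sp)
        return seen

    def reaction(self, index: int) -> Reaction:
        for r in self.reactions:
            if r.index == index:
                return r
        raise KeyError(f"no reaction with index {index}")


def delta_g0_prime(reaction: Reaction, ex: float) -> float:
    """Standard transformed free energy of one reaction at carrier potential ``ex``.

    Constant reactions ignore ``ex``; the two Ex-linear steps (butyl-CoM
    conversion and terminal electron transfer) evaluate ``a*Ex + b``.
    """
    return reaction.dg0_prime(ex)


def net_reaction(model: PathwayModel) -> dict[str, Fraction]:
    """Multiplicity-weighted sum of all reactions.

    Internal metabolites and redox-couple species must cancel exactly;
    a non-cancelling internal species raises ``ValueError`` naming it.
    H+ is excluded (absorbed in dG0' at pH 7).
    """
    total: dict[str, Fraction] = {}
    for r in model.reactions:
        for sp, c in r.stoich.items():
            total[sp] = total.get(sp, Fraction(0)) + c * r.multiplicity
    total = {sp: c for sp, c in total.items() if c != 0 and sp != "H+"}
    internal = set(model.internal_species())
    bad = sorted(sp for sp in total if sp in internal)
    if bad:
        raise ValueError(f"internal species do not cancel in net reaction: {bad}")
    return total


def electron_ledger(model: PathwayModel) -> CarrierLedger:
    """Count reduced carriers generated per mol butane.

    Net production of XH2, NADH, F420H2 and Fd_red is summed over all
    reactions except the membrane electron-transfer steps (NDH, Fqo, Nuo
    and the terminal MHCs), i.e. over the steps that actually strip
    electrons from the substrate.  For the full oxidative table this gives
    2 XH2 + 5 NADH + 4 F420H2 + 4 Fd_red = 26 electrons.  Carriers with a
    negative net count (possible for truncated tables) carry no electrons
    toward the total.
    """
    counts: dict[str, int] = {}
    for r in model.reactions:
        if r.index in MEMBRANE_TRANSFER_REACTIONS:
            continue
        for sp, c in r.stoich.items():
            if sp in ELECTRONS_PER_CARRIER:
                counts[sp] = counts.get(sp, 0) + int(c * r.multiplicity)
    counts = {sp: c for sp, c in counts.items() if c != 0}
    electrons = sum(
        max(c, 0) * ELECTRONS_PER_CARRIER[sp] for sp, c in counts.items()
    )
    return CarrierLedger(counts=counts, electrons_total=electrons)


def reverse_model(model: PathwayModel) -> PathwayModel:
    """The pathway run in the opposite direction (every reaction negated)."""
    return replace(
        model,
        reactions=tuple(r.reversed() for r in model.reactions),
        direction="rAOB" if model.direction == "AOB" else "AOB",
    )


def catabolic_delta_g(model: PathwayModel) -> float:
    """Free energy of the overall conversion per mol butane (dG_cat).

    Multiplicity-weighted sum of standard free energies plus the RT ln Q
    term over the net boundary species and the imposed XH2/X ratio.
    """
    total = sum(r.multiplicity * r.dg0_prime(model.ex) for r in model.reactions)
    net = net_reaction(model)
    red_x, ox_x = model.couples["X"]
    lnq = 0.0
    for sp, c in net.items():
        if sp == red_x:
            lnq += float(c) * math.log(model.xh2_x_ratio)
        elif sp == ox_x:
            pass  # folded into the ratio term
        else:
            a = model.boundary.get(sp)
            if a is None:
                raise ValueError(f"net species {sp} has no boundary activity")
            lnq += float(c) * math.log(a)
    # the couple must appear as red/ox in equal and opposite amounts
    if net.get(red_x, Fraction(0)) != -net.get(ox_x, Fraction(0)):
        raise ValueError("X couple does not appear as a balanced ratio")
    return total + model.rt * lnq


def default_aob_model(
    ex: float = -0.220, xh2_x_ratio: float = 4.0, **kwargs
) -> PathwayModel:
    """The shipped oxidative model at carrier potential ``ex``."""
    if not (_EX_SHIPPED_RANGE[0] <= ex <= _EX_SHIPPED_RANGE[1]):
        import warnings

        warnings.warn(
            f"Ex={ex} V outside the shipped scenario range {_EX_SHIPPED_RANGE}",
            stacklevel=2,
        )
    return PathwayModel(
        reactions=tuple(load_reaction_table()),
        direction="AOB",
        ex=ex,
        xh2_x_ratio=xh2_x_ratio,
        **kwargs,
    )


def default_raob_model(
    ex: float = -0.220, xh2_x_ratio: float = 2000.0, **kwargs
) -> PathwayModel:
    """The shipped reductive (butane-forming) model."""
    return reverse_model(default_aob_model(ex=ex, xh2_x_ratio=xh2_x_ratio, **kwargs))


def default_aob_scheme(
    n3: int = -1, n15: int = 2, n16: int = 4, n17: int = -1
) -> CouplingScheme:
    """Default oxidative coupling: PMF investment at the butyl-CoM
    conversion (3) and terminal electron transfer (17), conservation at
    F420H2 (15) and ferredoxin (16) oxidation, dissipation at
    methylene-H4MPT oxidation (11)."""
    return CouplingScheme(
        pmf_sites={3: n3, 15: n15, 16: n16, 17: n17}, dissipation_site=11
    )


def default_raob_scheme(
    n3: int = 1, n15: int = -2, n16: int = -4, n17: int = 1
) -> CouplingScheme:
    """Default reductive coupling: the oxidative sites with signs flipped,
    dissipation at acetyl-CoA synthesis (reverse of step 9)."""
    return CouplingScheme(
        pmf_sites={3: n3, 15: n15, 16: n16, 17: n17}, dissipation_site=9
    )
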