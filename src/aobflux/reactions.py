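"""The shipped reaction table of the anaerobic butane oxidation (AOB) pathway.

The pathway is described as 17 elementary transformations converting one
butane to four CO2 while transferring 26 electrons, via a generic
two-electron carrier X/XH2, to a syntrophic sulfate reducer.  Two steps
(butyl-CoM conversion, reaction 3, and terminal electron transfer to X,
reaction 17) have standard free energies that depend linearly on the
standard redox potential ``Ex`` of the X/XH2 couple.

Reactions are parsed from a plain-text TSV shipped with the package and can
be round-tripped through :func:`write_reaction_table`.
"""

from __future__ import annotations

import csv
import importlib.resources
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

__all__ = [
    "Reaction",
    "load_reaction_table",
    "write_reaction_table",
    "REDOX_COUPLES",
    "DEFAULT_BOUNDARY",
    "SKELETON_CARBONS",
]

#: Redox couples handled as single ratio unknowns: couple -> (reduced, oxidized).
REDOX_COUPLES: dict[str, tuple[str, str]] = {
    "X": ("XH2", "X"),
    "NAD": ("NADH", "NAD+"),
    "F420": ("F420H2", "F420"),
    "Fd": ("Fd_red", "Fd_ox"),
    "MQ": ("MQH2", "MQ"),
}

#: Default fixed activities.  Gas-phase butane and CO2 and water at unit
#: activity; free carrier forms held at a 1 mM reference level.
DEFAULT_BOUNDARY: dict[str, float] = {
    "C4H10": 1.0,
    "CO2": 1.0,
    "H2O": 1.0,
    "H+": 1.0,  # absorbed in dG0' at pH 7
    "HS-CoM": 1e-3,
    "HS-CoB": 1e-3,
    "CoA": 1e-3,
    "H4MPT": 1e-3,
    "MF": 1e-3,
}

#: Substrate-derived (butane-skeleton) carbon atoms per species, used to
#: check that carbon balances within each reaction.  Carrier backbones
#: (CoA, CoM, H4MPT, MF, NAD, F420, MQ) appear on both sides and are not
#: counted.
SKELETON_CARBONS: dict[str, int] = {
    "C4H10": 4,
    "C4H9-S-CoM": 4,
    "Butyryl-CoA": 4,
    "Crotonyl-CoA": 4,
    "3-Hydroxybutyryl-CoA": 4,
    "Acetoacetyl-CoA": 4,
    "Acetyl-CoA": 2,
    "CH3-H4MPT": 1,
    "CH2-H4MPT": 1,
    "CH-H4MPT+": 1,
    "CHO-H4MPT": 1,
    "CHO-MF": 1,
    "CO2": 1,
}

_TERM_RE = re.compile(r"^(\d+)\s+(\S.*)$")


def _parse_side(side: str, sign: int) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            continue
        m = _TERM_RE.match(term)
        if m:
            coeff, species = int(m.group(1)), m.group(2).strip()
        else:
            coeff, species = 1, term
        out[species] = out.get(species, Fraction(0)) + sign * Fraction(coeff)
    return {k: v for k, v in out.items() if v != 0}


def parse_equation(equation: str) -> dict[str, Fraction]:
    """Parse ``A + 2 B = C`` into signed stoichiometric coefficients.

    Reactants are negative, products positive.  Coefficients are separated
    from species names by whitespace, so names such as ``3-Hydroxybutyryl-CoA``
    are unambiguous.
    """
    parts = equation.split(" = ")
    if len(parts) != 2:
        raise ValueError(f"equation must contain exactly one ' = ': {equation!r}")
    stoich = _parse_side(parts[0], -1)
    for sp, c in _parse_side(parts[1], +1).items():
        stoich[sp] = stoich.get(sp, Fraction(0)) + c
    return {k: v for k, v in stoich.items() if v != 0}


def format_equation(stoich: dict[str, Fraction]) -> str:
    """Inverse of :func:`parse_equation` (species in insertion order)."""

    def side(items):
        terms = []
        for sp, c in items:
            c = abs(c)
            terms.append(sp if c == 1 else f"{c} {sp}")
        return " + ".join(terms)

    lhs = [(s, c) for s, c in stoich.items() if c < 0]
    rhs = [(s, c) for s, c in stoich.items() if c > 0]
    return f"{side(lhs)} = {side(rhs)}"


@dataclass(frozen=True)
class Reaction:
    """One step of the pathway.

    ``dg0`` is either a constant standard free energy (kJ mol^-1) or, when
    ``dg0_linear`` is set, the pair ``(a, b)`` of the linear form
    ``a*Ex + b`` with ``Ex`` in volt.
    """

    index: int
    name: str
    enzyme: str
    stoich: dict[str, Fraction]
    multiplicity: int
    dg0_const: float | None = None
    dg0_linear: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if (self.dg0_const is None) == (self.dg0_linear is None):
            raise ValueError(
                f"reaction {self.index}: exactly one of dg0_const/dg0_linear required"
            )
        if self.multiplicity < 1:
            raise ValueError(f"reaction {self.index}: multiplicity must be positive")
        # substrate-skeleton carbon must balance within the reaction
        carbon = sum(
            c * SKELETON_CARBONS.get(sp, 0) for sp, c in self.stoich.items()
        )
        if carbon != 0:
            raise ValueError(f"reaction {self.index}: carbon imbalance of {carbon}")

    @property
    def ex_dependent(self) -> bool:
        return self.dg0_linear is not None

    def dg0_prime(self, ex: float) -> float:
        """Standard transformed free energy at carrier redox potential ``ex`` (V)."""
        if not (ex == ex and abs(ex) != float("inf")):
            raise ValueError("Ex must be finite")
        if self.dg0_linear is not None:
            a, b = self.dg0_linear
            return a * ex + b
        assert self.dg0_const is not None
        return self.dg0_const

    def reversed(self) -> "Reaction":
        """The same transformation written in the opposite direction."""
        return Reaction(
            index=self.index,
            name=self.name,
            enzyme=self.enzyme,
            stoich={sp: -c for sp, c in self.stoich.items()},
            multiplicity=self.multiplicity,
            dg0_const=None if self.dg0_const is None else -self.dg0_const,
            dg0_linear=None
            if self.dg0_linear is None
            else (-self.dg0_linear[0], -self.dg0_linear[1]),
        )


def _table_path() -> Path:
    return Path(str(importlib.resources.files("aobflux") / "data" / "aob_reactions.tsv"))


def load_reaction_table(path: str | Path | None = None) -> list[Reaction]:
    """Load the shipped 17-reaction AOB table (or a user table at ``path``)."""
    path = _table_path() if path is None else Path(path)
    reactions: list[Reaction] = []
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in fh if not r.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    for row in reader:
        const = row.get("dg0_const", "").strip()
        a = row.get("dg0_a", "").strip() if row.get("dg0_a") else ""
        b = row.get("dg0_b", "").strip() if row.get("dg0_b") else ""
        reactions.append(
            Reaction(
                index=int(row["index"]),
                name=row["name"],
                enzyme=row["enzyme"],
                stoich=parse_equation(row["equation"]),
                multiplicity=int(row["multiplicity"]),
                dg0_const=float(const) if const else None,
                dg0_linear=(float(a), float(b)) if a and b else None,
            )
        )
    return reactions


def write_reaction_table(reactions: list[Reaction], path: str | Path) -> None:
    """Write a reaction list back to TSV (round-trips with the loader)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["index", "name", "enzyme", "equation", "multiplicity",
             "dg0_const", "dg0_a", "dg0_b"]
        )
        for r in reactions:
            if r.dg0_linear is not None:
                const, a, b = "", repr(r.dg0_linear[0]), repr(r.dg0_linear[1])
            else:
                const, a, b = repr(r.dg0_const), "", ""
            writer.writerow(
                [r.index, r.name, r.enzyme, format_equation(r.stoich),
                 r.multiplicity, const, a, b]
            )
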