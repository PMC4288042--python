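"""Thermodynamics of sulfide oxidation: ΔG° and pH-corrected ΔG°′.

Sulfide can be oxidized completely to sulfate or incompletely to
zero-valent sulfur, S(0), with oxygen or nitrate (reduced to N2, ammonium
or nitrite) as electron acceptor.  Eight canonical reactions cover the
pairings; this module checks their element/charge balance, repairs
unbalanced typeset stoichiometries by an exact rational linear solve with
H2O and H+ as free species (the sulfide coefficient pinned at 1), and
evaluates

    ΔG°  = Σ ν_i ΔGf°(i)
    ΔG°′ = ΔG° + ν_H+ · (−R·T·ln(10)·pH)

per mole of reaction, with all species except the proton at unit activity.
At pH 7 and 298.15 K the proton term is −39.96 kJ per mol of product H+.

The default formation-energy table (kJ/mol, 25 °C, aqueous standard
state) is a conventional literature compilation; it is a swappable input
with its provenance carried along, not a fitted quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd
import sympy

__all__ = [
    "Species",
    "Reaction",
    "ThermoTable",
    "DEFAULT_THERMO_TABLE",
    "PRINTED_REACTIONS",
    "CORRECTED_EQ2",
    "R_KJ",
    "balance_check",
    "is_balanced",
    "rebalance",
    "delta_g_standard",
    "delta_g_prime",
    "equations_table",
]

R_KJ = 8.31446261815324e-3  # gas constant, kJ mol^-1 K^-1


@dataclass(frozen=True)
class Species:
    name: str
    elements: dict  # element symbol -> count per formula unit
    charge: int
    dgf0: float  # standard Gibbs free energy of formation, kJ/mol

    def __post_init__(self):
        if any(v < 0 for v in self.elements.values()):
            raise ValueError(f"{self.name}: negative element count")
        if not math.isfinite(self.dgf0):
            raise ValueError(f"{self.name}: dgf0 must be finite")


@dataclass(frozen=True)
class Reaction:
    """Signed stoichiometry: reactants negative, products positive."""

    label: str
    stoichiometry: dict  # species name -> signed coefficient
    notes: str = ""

    def __post_init__(self):
        coeffs = self.stoichiometry.values()
        if not any(c < 0 for c in coeffs) or not any(c > 0 for c in coeffs):
            raise ValueError(f"{self.label}: need at least one reactant and one product")
        if any(c == 0 for c in coeffs):
            raise ValueError(f"{self.label}: zero coefficients are not allowed")

    def scaled(self, factor: float) -> "Reaction":
        return Reaction(self.label, {s: c * factor for s, c in self.stoichiometry.items()}, self.notes)

    def reversed(self) -> "Reaction":
        return self.scaled(-1)

    def equation(self) -> str:
        def fmt(side):
            parts = []
            for s, c in side:
                c = abs(c)
                parts.append(s if c == 1 else f"{float(c):g} {s}")
            return " + ".join(parts)

        lhs = [(s, c) for s, c in self.stoichiometry.items() if c < 0]
        rhs = [(s, c) for s, c in self.stoichiometry.items() if c > 0]
        return f"{fmt(lhs)} -> {fmt(rhs)}"


@dataclass
class ThermoTable:
    species: dict  # name -> Species
    provenance: str = ""

    def __getitem__(self, name: str) -> Species:
        try:
            return self.species[name]
        except KeyError:
            raise KeyError(f"species {name!r} not in thermo table ({self.provenance})") from None

    def resolve(self, reaction: Reaction) -> list[Species]:
        return [self[name] for name in reaction.stoichiometry]


def _sp(name, elements, charge, dgf0):
    return name, Species(name, elements, charge, dgf0)


DEFAULT_THERMO_TABLE = ThermoTable(
    species=dict(
        [
            _sp("H2S", {"H": 2, "S": 1}, 0, -27.9),
            _sp("O2", {"O": 2}, 0, 0.0),
            _sp("SO4-2", {"S": 1, "O": 4}, -2, -744.6),
            _sp("H+", {"H": 1}, +1, 0.0),
            _sp("S0", {"S": 1}, 0, 0.0),
            _sp("NO3-", {"N": 1, "O": 3}, -1, -111.3),
            _sp("NO2-", {"N": 1, "O": 2}, -1, -37.2),
            _sp("N2", {"N": 2}, 0, 0.0),
            _sp("NH4+", {"N": 1, "H": 4}, +1, -79.4),
            _sp("H2O", {"H": 2, "O": 1}, 0, -237.2),
            _sp("H2", {"H": 2}, 0, 0.0),
        ]
    ),
    provenance="conventional aqueous standard-state compilation, 25 C",
)


def _f(x) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(x).limit_denominator(10**6)


# The eight sulfide-oxidation reactions as conventionally typeset.  Three
# are not element/charge balanced as printed (eq2: oxygen has no sink;
# eq3/eq4/eq6: fractional coefficients rounded or protons omitted) and are
# repaired by rebalance() before any free-energy evaluation.
PRINTED_REACTIONS: list[Reaction] = [
    Reaction("eq1", {"H2S": -1, "O2": -2, "SO4-2": 1, "H+": 2},
             "complete aerobic oxidation"),
    Reaction("eq2", {"H2S": -1, "O2": Fraction(-1, 2), "S0": 1, "H2": 1},
             "incomplete aerobic oxidation; unbalanced as typeset (O unaccounted)"),
    Reaction("eq3", {"H2S": -1, "NO3-": Fraction(-8, 5), "SO4-2": 1, "N2": Fraction(4, 5), "H2O": 1},
             "complete oxidation, denitrification to N2"),
    Reaction("eq4", {"H2S": -1, "NO3-": Fraction(-33, 100), "S0": 1, "N2": Fraction(16, 100), "H2O": 1},
             "incomplete oxidation, denitrification to N2; coefficients rounded as typeset"),
    Reaction("eq5", {"H2S": -1, "NO3-": -1, "H2O": -1, "SO4-2": 1, "NH4+": 1},
             "complete oxidation, nitrate to ammonium"),
    Reaction("eq6", {"H2S": -1, "NO3-": -1, "H+": -8, "S0": 1, "NH4+": 1, "H2O": 3},
             "incomplete oxidation, nitrate to ammonium; charge-unbalanced as typeset"),
    Reaction("eq7", {"H2S": -1, "NO3-": -4, "SO4-2": 1, "NO2-": 4, "H+": 2},
             "complete oxidation, nitrate to nitrite"),
    Reaction("eq8", {"H2S": -1, "NO3-": -1, "S0": 1, "NO2-": 1, "H2O": 1},
             "incomplete oxidation, nitrate to nitrite"),
]

# eq2 with the spurious H2 dropped: the usual incomplete-aerobic reaction.
CORRECTED_EQ2 = Reaction(
    "eq2_corrected", {"H2S": -1, "O2": Fraction(-1, 2), "S0": 1, "H2O": 1},
    "incomplete aerobic oxidation, repaired"
)


def balance_check(reaction: Reaction, table: ThermoTable = DEFAULT_THERMO_TABLE) -> dict:
    """Per-element and charge residuals, Σ ν_i·count; all ~0 iff balanced."""
    residuals: dict[str, float] = {}
    charge = 0.0
    for name, coeff in reaction.stoichiometry.items():
        sp = table[name]
        for el, cnt in sp.elements.items():
            residuals[el] = residuals.get(el, 0.0) + float(coeff) * cnt
        charge += float(coeff) * sp.charge
    residuals["charge"] = charge
    return residuals


def is_balanced(reaction: Reaction, table: ThermoTable = DEFAULT_THERMO_TABLE, tol: float = 1e-9) -> bool:
    return all(abs(v) <= tol for v in balance_check(reaction, table).values())


def rebalance(
    reaction: Reaction,
    table: ThermoTable = DEFAULT_THERMO_TABLE,
    donor: str = "H2S",
    free_species: tuple[str, ...] = ("H2O", "H+"),
) -> Reaction:
    """Repair a typeset stoichiometry by an exact rational linear solve.

    The species set is the reaction's own plus ``free_species``; the
    electron donor's coefficient is pinned at its printed value (−1 by
    convention) and all other coefficients are solved from the element and
    charge balance.  With several solutions the minimal-Euclidean-norm one
    (rational pseudoinverse) is returned; species that come back with a
    zero coefficient are dropped.  Raises if the system is inconsistent.
    """
    if donor not in reaction.stoichiometry:
        raise ValueError(f"donor {donor!r} not in reaction {reaction.label}")
    names = list(reaction.stoichiometry)
    for fs in free_species:
        if fs not in names:
            names.append(fs)
    unknowns = [n for n in names if n != donor]
    donor_coeff = _f(reaction.stoichiometry[donor])

    elements = sorted({el for n in names for el in table[n].elements})
    rows_keys = elements + ["charge"]

    def count(name, key):
        sp = table[name]
        return sp.charge if key == "charge" else sp.elements.get(key, 0)

    a = sympy.Matrix([[sympy.Rational(count(n, key)) for n in unknowns] for key in rows_keys])
    b = sympy.Matrix([[-sympy.Rational(donor_coeff.numerator, donor_coeff.denominator) * count(donor, key)]
                      for key in rows_keys])

    aug_rank = a.row_join(b).rank()
    if aug_rank > a.rank():
        raise ValueError(
            f"{reaction.label}: no balanced solution exists "
            f"(rank A = {a.rank()}, rank [A|b] = {aug_rank})"
        )
    x = a.pinv() * b  # exact min-norm solution over the rationals

    stoich: dict[str, Fraction] = {donor: donor_coeff}
    for name, val in zip(unknowns, x):
        frac = Fraction(int(val.p), int(val.q)) if val != 0 else Fraction(0)
        if frac != 0:
            stoich[name] = frac
    out = Reaction(reaction.label, stoich, reaction.notes)
    assert is_balanced(out, table), "rebalance produced an unbalanced reaction"
    return out


def delta_g_standard(
    reaction: Reaction,
    table: ThermoTable = DEFAULT_THERMO_TABLE,
    allow_unbalanced: bool = False,
) -> float:
    """ΔG° in kJ per mole of reaction as written."""
    if not allow_unbalanced and not is_balanced(reaction, table):
        res = balance_check(reaction, table)
        bad = {k: v for k, v in res.items() if abs(v) > 1e-9}
        raise ValueError(f"{reaction.label} is not balanced ({bad}); rebalance first or override")
    return sum(float(c) * table[s].dgf0 for s, c in reaction.stoichiometry.items())


def delta_g_prime(
    reaction: Reaction,
    table: ThermoTable = DEFAULT_THERMO_TABLE,
    pH: float = 7.0,
    temperature: float = 298.15,
    allow_unbalanced: bool = False,
) -> float:
    """ΔG°′ in kJ per mole of reaction: ΔG° shifted to proton activity 10^−pH."""
    dg0 = delta_g_standard(reaction, table, allow_unbalanced=allow_unbalanced)
    nu_h = float(reaction.stoichiometry.get("H+", 0))
    return dg0 + nu_h * (-R_KJ * temperature * math.log(10.0) * pH)


def equations_table(
    table: ThermoTable = DEFAULT_THERMO_TABLE,
    pH: float = 7.0,
    temperature: float = 298.15,
) -> pd.DataFrame:
    """The eight sulfide-oxidation reactions with balance status and ΔG°′.

    Unbalanced typeset stoichiometries are rebalanced before evaluation;
    the table reports both the printed and the evaluated equation.
    """
    rows = []
    for rxn in PRINTED_REACTIONS:
        balanced = is_balanced(rxn, table)
        if balanced:
            used = rxn
        elif rxn.label == "eq2":
            # the typeset H2 product has no oxygen sink; the conventional
            # repair drops it rather than solving over the full species set
            used = CORRECTED_EQ2
        else:
            used = rebalance(rxn, table)
        rows.append(
            {
                "label": rxn.label,
                "printed_equation": rxn.equation(),
                "balanced_as_printed": balanced,
                "evaluated_equation": used.equation(),
                "delta_g0_kj": delta_g_standard(used, table),
                "delta_g_prime_kj": delta_g_prime(used, table, pH=pH, temperature=temperature),
                "notes": rxn.notes,
            }
        )
    return pd.DataFrame(rows)
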