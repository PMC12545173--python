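"""Gibbs free energy of iron(III)-oxide-dependent sulfur oxidation.

This module computes standard (ΔGr°) and actual (ΔGr) reaction free energies
for redox couples in which reduced sulfur compounds (sulfide, thiosulfate) or
formate donate electrons to solid-phase ferric (oxyhydr)oxide, modelled
compositionally as Fe(OH)3.  The actual free energy follows

    ΔGr = ΔGr° + R·T·ln(Qr),        Qr = Π aᵢ^νᵢ

with activities aᵢ = γᵢ·Cᵢ/C° for dissolved ions (C° = 1 M), a(H⁺) = 10^−pH,
and unit activity for the solvent and for solid phases (ferrihydrite, FeS,
elemental sulfur).  Dissolved sulfide is speciated between H2S, HS⁻ and S²⁻
from pH and the two acidity constants of hydrogen sulfide; reactions are
written with HS⁻ and receive the HS⁻ fraction of the total sulfide pool.

Activity coefficients default to the Davies equation, which is adequate up to
roughly seawater ionic strength (I ≈ 0.7 M); tabulated coefficients may be
supplied to override the closed form.

ΔGf° values ship in a pinned table (``misokit/data/species_dg0.tsv``) drawn
from standard thermochemical compilations; any species table with the same
columns can be substituted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

#: Universal gas constant, J K^-1 mol^-1.
R_J = 8.314
R_KJ = R_J / 1000.0
#: Default temperature, K (25 C).
T_STANDARD = 298.15
#: Debye-Hueckel A parameter at 25 C for the Davies equation.
DAVIES_A = 0.509
#: Acidity constants of hydrogen sulfide.
PKA1_H2S = 7.04
PKA2_H2S = 11.96

PHASES = frozenset({"aqueous", "solid", "water", "gas"})

_ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Na": 22.990, "K": 39.098, "Fe": 55.845,
}

# Names under which a reaction may reference the dissolved sulfide pool; the
# concentration used is total sulfide times the pH-dependent fraction.
_SULFIDE_POOL = {"H2S", "HS-", "S2-"}


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a chemical formula such as ``Fe(OH)3`` into element counts."""
    stack: list[dict[str, int]] = [{}]
    i = 0
    while i < len(formula):
        ch = formula[i]
        if ch == "(":
            stack.append({})
            i += 1
        elif ch == ")":
            if len(stack) == 1:
                raise ValueError(f"unbalanced ')' in formula {formula!r}")
            i += 1
            m = re.match(r"\d+", formula[i:])
            mult = int(m.group()) if m else 1
            i += m.end() if m else 0
            group = stack.pop()
            for el, n in group.items():
                stack[-1][el] = stack[-1].get(el, 0) + n * mult
        else:
            m = re.match(r"([A-Z][a-z]?)(\d*)", formula[i:])
            if not m:
                raise ValueError(f"cannot parse formula {formula!r} at position {i}")
            el = m.group(1)
            if el not in _ATOMIC_MASS:
                raise ValueError(f"unknown element {el!r} in formula {formula!r}")
            stack[-1][el] = stack[-1].get(el, 0) + int(m.group(2) or 1)
            i += m.end()
    if len(stack) != 1:
        raise ValueError(f"unbalanced '(' in formula {formula!r}")
    return stack[0]


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol of a formula string."""
    return sum(_ATOMIC_MASS[el] * n for el, n in parse_formula(formula).items())


def mineral_molarity(mass_g: float, volume_ml: float, formula: str = "Fe(OH)3") -> float:
    """Molar concentration (mol/L) of ``mass_g`` of a mineral in ``volume_ml``.

    The default formula treats ferrihydrite as Fe(OH)3, so the result is the
    nominal Fe(III) concentration of a ferrihydrite suspension.
    """
    if mass_g <= 0 or volume_ml <= 0:
        raise ValueError("mass and volume must be positive")
    return (mass_g / molar_mass(formula)) / (volume_ml / 1000.0)


@dataclass(frozen=True)
class ChemicalSpecies:
    """A chemical species with its standard free energy of formation."""

    name: str
    formula: Mapping[str, int]
    charge: int
    phase: str
    dgf0: float  # kJ/mol

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"{self.name}: phase must be one of {sorted(PHASES)}")
        if any(n < 0 for n in self.formula.values()):
            raise ValueError(f"{self.name}: negative element count")
        if not math.isfinite(self.dgf0):
            raise ValueError(f"{self.name}: dGf0 must be finite")


def load_species_table(path=None) -> dict[str, ChemicalSpecies]:
    """Load a species table (TSV: name, formula, charge, phase, dGf0_kJ_mol).

    With no argument, the pinned table shipped with the package is used.
    Lines starting with ``#`` are comments.
    """
    if path is None:
        text = resources.files("misokit.data").joinpath("species_dg0.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, ChemicalSpecies] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        sp = ChemicalSpecies(
            name=row["name"],
            formula=parse_formula(row["formula"]),
            charge=int(row["charge"]),
            phase=row["phase"],
            dgf0=float(row["dGf0_kJ_mol"]),
        )
        table[sp.name] = sp
    return table


_TERM_RE = re.compile(r"^(\d+(?:\.\d+)?)\s+(\S+)$")


@dataclass(frozen=True)
class Reaction:
    """A balanced reaction: signed stoichiometry over species names.

    Reactants carry negative coefficients, products positive.  ``n_electrons``
    is the number of electrons transferred per formula unit of the reaction as
    written (e.g. 8 for complete sulfide oxidation to sulfate).
    """

    stoichiometry: Mapping[str, float]
    n_electrons: float
    label: str = "custom"

    @classmethod
    def parse(cls, text: str, n_electrons: float, label: str = "custom") -> "Reaction":
        """Parse ``"HS- + 8 Fe(OH)3 + 15 H+ -> SO4-2 + 8 Fe2+ + 20 H2O"``.

        Terms are separated by `` + `` (space-plus-space); a leading number is
        the coefficient, the rest of the term is the species name.
        """
        if "->" not in text:
            raise ValueError(f"reaction {text!r} lacks '->'")
        left, right = text.split("->", 1)
        stoich: dict[str, float] = {}

        def add(side: str, sign: float) -> None:
            for term in side.split(" + "):
                term = term.strip()
                if not term:
                    continue
                m = _TERM_RE.match(term)
                if m:
                    coeff, name = float(m.group(1)), m.group(2)
                else:
                    coeff, name = 1.0, term
                stoich[name] = stoich.get(name, 0.0) + sign * coeff

        add(left, -1.0)
        add(right, +1.0)
        return cls(stoichiometry=stoich, n_electrons=n_electrons, label=label)


#: Balanced forms of the three iron(III)-oxide-coupled sulfur oxidation
#: reactions and the formate couple (ferrihydrite as Fe(OH)3).
PRESET_REACTIONS: dict[str, Reaction] = {
    "reaction1": Reaction.parse(
        "HS- + 8 Fe(OH)3 + 15 H+ -> SO4-2 + 8 Fe2+ + 20 H2O", 8, "reaction1"),
    "reaction2": Reaction.parse(
        "HS- + 2 Fe(OH)3 + 5 H+ -> S0 + 2 Fe2+ + 6 H2O", 2, "reaction2"),
    "reaction3": Reaction.parse(
        "S2O3-2 + 8 Fe(OH)3 + 14 H+ -> 2 SO4-2 + 8 Fe2+ + 19 H2O", 8, "reaction3"),
    "formate": Reaction.parse(
        "HCOO- + 2 Fe(OH)3 + 5 H+ -> CO2 + 2 Fe2+ + 6 H2O", 2, "formate"),
    # The dissolved-iron(III) form of the formate couple.
    "formate_aq": Reaction.parse(
        "HCOO- + 2 Fe3+ -> CO2 + 2 Fe2+ + H+", 2, "formate_aq"),
}


@dataclass(frozen=True)
class BalanceReport:
    """Element and charge residuals of a reaction (products minus reactants)."""

    element_residuals: Mapping[str, float]
    charge_residual: float

    @property
    def balanced(self) -> bool:
        tol = 1e-9
        return (abs(self.charge_residual) < tol
                and all(abs(v) < tol for v in self.element_residuals.values()))


def check_balance(reaction: Reaction,
                  species_table: Mapping[str, ChemicalSpecies] | None = None) -> BalanceReport:
    """Verify element and charge conservation of a reaction."""
    if species_table is None:
        species_table = load_species_table()
    missing = [n for n in reaction.stoichiometry if n not in species_table]
    if missing:
        raise KeyError(f"species not in table: {', '.join(sorted(missing))}")
    elements: dict[str, float] = {}
    charge = 0.0
    for name, coeff in reaction.stoichiometry.items():
        sp = species_table[name]
        for el, n in sp.formula.items():
            elements[el] = elements.get(el, 0.0) + coeff * n
        charge += coeff * sp.charge
    return BalanceReport(element_residuals=elements, charge_residual=charge)


def standard_gibbs(reaction: Reaction,
                   species_table: Mapping[str, ChemicalSpecies] | None = None) -> float:
    """ΔGr° = Σ νᵢ·ΔGf°ᵢ in kJ/mol."""
    if species_table is None:
        species_table = load_species_table()
    missing = [n for n in reaction.stoichiometry if n not in species_table]
    if missing:
        raise KeyError(f"species lacking dGf0: {', '.join(sorted(missing))}")
    return sum(coeff * species_table[name].dgf0
               for name, coeff in reaction.stoichiometry.items())


@dataclass(frozen=True)
class SpeciationState:
    """Equilibrium fractions of the dissolved sulfide pool at a given pH."""

    fractions: Mapping[str, float]  # keys: H2S, HS-, S2-
    pka1: float = PKA1_H2S
    pka2: float = PKA2_H2S

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"speciation fractions sum to {total}, not 1")


def sulfide_speciation(pH: float, pka1: float = PKA1_H2S,
                       pka2: float = PKA2_H2S) -> SpeciationState:
    """Diprotic-acid speciation of dissolved sulfide at a given pH.

    f(H2S) = 1 / (1 + 10^(pH-pKa1) + 10^(2pH-pKa1-pKa2)); the HS⁻ and S²⁻
    fractions follow by successive factors of 10^(pH-pKa).
    """
    if not math.isfinite(pH):
        raise ValueError("pH must be finite")
    r1 = 10.0 ** (pH - pka1)
    r2 = 10.0 ** (2 * pH - pka1 - pka2)
    denom = 1.0 + r1 + r2
    return SpeciationState(
        fractions={"H2S": 1.0 / denom, "HS-": r1 / denom, "S2-": r2 / denom},
        pka1=pka1, pka2=pka2)


def activity_coefficient(charge: int, ionic_strength: float,
                         model: str = "davies",
                         override_table: Mapping[tuple[int, float], float] | None = None,
                         ) -> float:
    """Single-ion activity coefficient γ.

    An override table keyed by (charge, ionic strength) takes precedence and
    allows tabulated coefficients to replace the closed form.  Otherwise the
    Davies equation is evaluated:

        log10 γ = -A·z²·( √I/(1+√I) − 0.3·I ),   A = 0.509 at 25 C.

    γ = 1 at infinite dilution (I = 0) and for neutral species.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if override_table is not None:
        key = (charge, ionic_strength)
        if key in override_table:
            return float(override_table[key])
    if model != "davies":
        raise ValueError(f"unknown activity model {model!r}")
    if charge == 0 or ionic_strength == 0:
        return 1.0
    sqrt_i = math.sqrt(ionic_strength)
    log_g = -DAVIES_A * charge ** 2 * (sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength)
    return 10.0 ** log_g


#: Environmental condition presets.  Concentrations in mol/L; the
#: dissolved sulfide pool is keyed "sulfide_total" and speciated at run time.
SCENARIOS: dict[str, dict] = {
    "marine": dict(ionic_strength=0.7,
                   concentrations={"sulfide_total": 100e-6, "SO4-2": 28e-3,
                                   "S2O3-2": 1e-6, "Fe2+": 10e-6}),
    "freshwater": dict(ionic_strength=0.001,
                       concentrations={"sulfide_total": 100e-6, "SO4-2": 100e-6,
                                       "S2O3-2": 1e-6, "Fe2+": 10e-6}),
}


@dataclass(frozen=True)
class EnvConditions:
    """Environmental setting defining the reaction quotient."""

    temperature: float = T_STANDARD   # K
    ionic_strength: float = 0.0       # mol/L
    pH: float = 7.0
    concentrations: Mapping[str, float] = field(default_factory=dict)  # mol/L
    scenario: str = "custom"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError("pH must lie in [0, 14]")
        if any(c <= 0 for c in self.concentrations.values()):
            raise ValueError("all concentrations must be positive")

    @classmethod
    def preset(cls, scenario: str, pH: float = 7.0,
               temperature: float = T_STANDARD) -> "EnvConditions":
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}; "
                             f"choose from {sorted(SCENARIOS)} or build custom conditions")
        cfg = SCENARIOS[scenario]
        return cls(temperature=temperature, ionic_strength=cfg["ionic_strength"],
                   pH=pH, concentrations=dict(cfg["concentrations"]), scenario=scenario)


def _activity(name: str, sp: ChemicalSpecies, conditions: EnvConditions,
              gamma_override=None) -> float:
    """Activity of one species under the given conditions."""
    if sp.phase in ("water", "solid"):
        return 1.0
    if name == "H+":
        return 10.0 ** (-conditions.pH)
    if name == "OH-":
        return 10.0 ** (conditions.pH - 14.0)
    if name in _SULFIDE_POOL:
        if "sulfide_total" not in conditions.concentrations:
            raise ValueError(f"no total-sulfide concentration available for {name}")
        frac = sulfide_speciation(conditions.pH).fractions[name]
        conc = conditions.concentrations["sulfide_total"] * frac
    else:
        if name not in conditions.concentrations:
            raise ValueError(f"no concentration supplied for aqueous species {name!r}")
        conc = conditions.concentrations[name]
    if conc <= 0:
        raise ValueError(f"non-positive concentration for {name!r}")
    gamma = activity_coefficient(sp.charge, conditions.ionic_strength,
                                 override_table=gamma_override)
    return gamma * conc  # / C0 with C0 = 1 M


def reaction_quotient(reaction: Reaction, conditions: EnvConditions,
                      species_table: Mapping[str, ChemicalSpecies] | None = None,
                      gamma_override=None) -> float:
    """Reaction quotient Qr = Π aᵢ^νᵢ (dimensionless, > 0)."""
    return math.exp(ln_reaction_quotient(reaction, conditions, species_table,
                                         gamma_override))


def ln_reaction_quotient(reaction: Reaction, conditions: EnvConditions,
                         species_table: Mapping[str, ChemicalSpecies] | None = None,
                         gamma_override=None) -> float:
    """ln Qr computed as Σ νᵢ·ln aᵢ (numerically robust for extreme Qr)."""
    if species_table is None:
        species_table = load_species_table()
    missing = [n for n in reaction.stoichiometry if n not in species_table]
    if missing:
        raise KeyError(f"species not in table: {', '.join(sorted(missing))}")
    total = 0.0
    for name, coeff in reaction.stoichiometry.items():
        a = _activity(name, species_table[name], conditions, gamma_override)
        total += coeff * math.log(a)
    return total


@dataclass(frozen=True)
class GibbsResult:
    """Actual reaction free energy under stated conditions."""

    dgr: float               # kJ/mol reaction
    dgr_per_electron: float  # kJ/(mol e-)
    dgr0: float              # kJ/mol, standard
    ln_qr: float
    temperature: float


def gibbs_actual(reaction: Reaction, conditions: EnvConditions,
                 species_table: Mapping[str, ChemicalSpecies] | None = None,
                 gamma_override=None) -> GibbsResult:
    """ΔGr = ΔGr° + R·T·ln Qr, with the per-electron normalisation."""
    if species_table is None:
        species_table = load_species_table()
    dgr0 = standard_gibbs(reaction, species_table)
    ln_qr = ln_reaction_quotient(reaction, conditions, species_table, gamma_override)
    dgr = dgr0 + R_KJ * conditions.temperature * ln_qr
    per_e = dgr / reaction.n_electrons if reaction.n_electrons else math.nan
    return GibbsResult(dgr=dgr, dgr_per_electron=per_e, dgr0=dgr0,
                       ln_qr=ln_qr, temperature=conditions.temperature)


@dataclass(frozen=True)
class EnergyProfile:
    """ΔGr (and per-electron ΔGr) across a pH grid for one scenario."""

    pH_grid: np.ndarray
    dgr: np.ndarray
    dgr_per_electron: np.ndarray
    reaction_label: str
    scenario: str

    def __post_init__(self) -> None:
        if not (len(self.pH_grid) == len(self.dgr) == len(self.dgr_per_electron)):
            raise ValueError("profile grids must have equal length")


def ph_sweep(reaction: Reaction, scenario: str | EnvConditions,
             ph_min: float = 5.0, ph_max: float = 10.0, n_points: int = 201,
             species_table: Mapping[str, ChemicalSpecies] | None = None,
             gamma_override=None) -> EnergyProfile:
    """Sweep ΔGr across a uniform pH grid under a preset or custom setting."""
    if not ph_min < ph_max:
        raise ValueError("require ph_min < ph_max")
    if n_points < 2:
        raise ValueError("require n_points >= 2")
    if isinstance(scenario, EnvConditions):
        base = scenario
    else:
        base = EnvConditions.preset(scenario)
    if species_table is None:
        species_table = load_species_table()
    grid = np.linspace(ph_min, ph_max, n_points)
    dgr = np.empty_like(grid)
    per_e = np.empty_like(grid)
    for i, p in enumerate(grid):
        res = gibbs_actual(reaction, replace(base, pH=float(p)),
                           species_table, gamma_override)
        dgr[i] = res.dgr
        per_e[i] = res.dgr_per_electron
    return EnergyProfile(pH_grid=grid, dgr=dgr, dgr_per_electron=per_e,
                         reaction_label=reaction.label, scenario=base.scenario)
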