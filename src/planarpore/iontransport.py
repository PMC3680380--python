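"""Electrodiffusion mathematics for bilayer permeation analysis.

Nernst and Goldman-Hodgkin-Katz (GHK) reversal potentials, closed-form
inversion of the monovalent GHK voltage equation for a cation:anion
permeability ratio, the numeric zero-current root of the GHK flux sum for
mixtures containing divalents, and ionic-activity models.

Sign convention throughout: the trans chamber is grounded and potentials are
V = V_cis - V_trans, in mV. A positive reversal potential therefore means the
cis side had to be held positive to null the current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "R",
    "F",
    "thermal_voltage",
    "IonSpecies",
    "SolutionPair",
    "PermeabilityResult",
    "activity",
    "nernst",
    "ghk_voltage_monovalent",
    "permeability_ratio_from_erev",
    "ghk_current_reversal",
]

R = 8.31446261815324  # gas constant, J mol^-1 K^-1
F = 96485.33212331001  # Faraday constant, C mol^-1

ACTIVITY_MODELS = ("concentration", "debye_huckel", "table")


def thermal_voltage(temperature: float) -> float:
    """RT/F in mV at the given absolute temperature (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return 1000.0 * R * temperature / F


class InfeasibleErevError(ValueError):
    """Measured reversal potential lies outside the Nernst bracket."""


# ---------------------------------------------------------------------------
# activity models
# ---------------------------------------------------------------------------

# Mean molal activity coefficients at 25 C (Robinson & Stokes), indexed by
# salt molality in mol/kg; treated as per-molar for the dilute-to-1 M range
# used here. No extrapolation beyond the tabulated range.
_GAMMA_TABLES = {
    "KCl": (
        np.array([0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
                  0.6, 0.7, 0.8, 0.9, 1.0]),
        np.array([0.965, 0.927, 0.902, 0.815, 0.770, 0.718, 0.688, 0.666,
                  0.649, 0.637, 0.626, 0.618, 0.610, 0.604]),
    ),
    "CaCl2": (
        np.array([0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0]),
        np.array([0.888, 0.789, 0.732, 0.584, 0.518, 0.472, 0.455, 0.448,
                  0.460, 0.500]),
    ),
}


def _davies_a(temperature: float) -> float:
    """Debye-Huckel A coefficient (mol^-1/2 L^1/2) from the water dielectric."""
    t = temperature - 273.15
    eps = 87.740 - 0.40008 * t + 9.398e-4 * t * t - 1.410e-6 * t**3
    return 1.8248e6 / (eps * temperature) ** 1.5


def activity(
    conc: float,
    species_charge: int,
    ionic_strength: float,
    model: str = "concentration",
    temperature: float = 295.15,
    salt: str | None = None,
) -> float:
    """Effective (activity-scaled) concentration in mM.

    ``ionic_strength`` is the chamber ionic strength in mM. Under the
    ``debye_huckel`` model the Davies form of the extended Debye-Huckel
    equation is applied; under ``table`` a packaged mean-activity-coefficient
    table (KCl for monovalents, CaCl2 for divalents unless ``salt`` says
    otherwise) is interpolated, with no extrapolation beyond its range.
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if model not in ACTIVITY_MODELS:
        raise ValueError(f"unknown activity model {model!r}")
    if conc == 0 or model == "concentration":
        return conc
    i_molar = ionic_strength / 1000.0
    if model == "debye_huckel":
        a_coef = _davies_a(temperature)
        z2 = species_charge * species_charge
        sqrt_i = math.sqrt(i_molar)
        log10_gamma = -a_coef * z2 * (sqrt_i / (1.0 + sqrt_i) - 0.3 * i_molar)
        return conc * 10.0**log10_gamma
    # table model
    if salt is None:
        salt = "CaCl2" if abs(species_charge) == 2 else "KCl"
    if salt not in _GAMMA_TABLES:
        raise ValueError(f"no packaged activity table for salt {salt!r}")
    grid, gamma = _GAMMA_TABLES[salt]
    # convert chamber ionic strength back to the salt molality the table uses
    molality = i_molar / (3.0 if salt == "CaCl2" else 1.0)
    if molality < grid[0] or molality > grid[-1]:
        raise ValueError(
            f"ionic strength {ionic_strength:g} mM outside the {salt} table "
            f"range [{grid[0] * 1000:g}, {grid[-1] * 1000:g}] mM salt; "
            "refusing to extrapolate"
        )
    return conc * float(np.interp(molality, grid, gamma))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species with per-chamber concentrations (mM) and a relative
    permeability (dimensionless; fix one species at 1)."""

    name: str
    valence: int
    conc_cis: float
    conc_trans: float
    permeability: float = 1.0

    def __post_init__(self) -> None:
        if self.valence not in (-2, -1, 1, 2):
            raise ValueError("valence must be one of -2, -1, +1, +2")
        if self.conc_cis < 0 or self.conc_trans < 0:
            raise ValueError("concentrations must be non-negative")
        if self.permeability < 0:
            raise ValueError("permeability must be non-negative")


@dataclass(frozen=True)
class SolutionPair:
    """cis/trans solution composition with temperature and activity model.

    ``junction_potential`` (mV) is a user-supplied electrode correction; it
    is subtracted from measured reversal potentials before any inversion.
    Each chamber must be electroneutral.
    """

    species: tuple[IonSpecies, ...]
    temperature: float = 295.15  # 22 C
    activity_model: str = "concentration"
    junction_potential: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.activity_model not in ACTIVITY_MODELS:
            raise ValueError(f"unknown activity model {self.activity_model!r}")
        for side in ("cis", "trans"):
            net = sum(s.valence * getattr(s, f"conc_{side}") for s in self.species)
            scale = sum(abs(s.valence) * getattr(s, f"conc_{side}") for s in self.species)
            if scale > 0 and abs(net) > 1e-9 * scale:
                raise ValueError(f"{side} chamber is not electroneutral (net {net:g} mM)")

    def ionic_strength(self, side: str) -> float:
        """Chamber ionic strength in mM: I = 0.5 * sum(c_i z_i^2)."""
        return 0.5 * sum(
            getattr(s, f"conc_{side}") * s.valence**2 for s in self.species
        )

    def activity_of(self, sp: IonSpecies, side: str) -> float:
        return activity(
            getattr(sp, f"conc_{side}"),
            sp.valence,
            self.ionic_strength(side),
            self.activity_model,
            self.temperature,
        )

    def get(self, name: str) -> IonSpecies:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(f"no species named {name!r}")

    def with_permeabilities(self, perms: dict[str, float]) -> "SolutionPair":
        new = tuple(
            replace(s, permeability=perms.get(s.name, s.permeability))
            for s in self.species
        )
        return replace(self, species=new)


@dataclass(frozen=True)
class PermeabilityResult:
    """Permeability ratio P_numerator / P_denominator inferred from Erev."""

    ratio: float
    numerator_species: str
    denominator_species: str
    erev_used: float  # mV, after junction correction; V = V_cis - V_trans
    activity_model: str

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("permeability ratio must be positive")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def nernst(
    species: IonSpecies,
    temperature: float = 295.15,
    activity_model: str = "concentration",
) -> float:
    """Nernst equilibrium potential (mV) of one species.

    E = (RT/zF) ln(a_trans / a_cis), with V = V_cis - V_trans. When called
    standalone, the chamber ionic strength used by the activity model is
    approximated from the species' own salt stoichiometry.
    """
    if species.valence == 0:
        raise ValueError("Nernst potential undefined for uncharged species")
    factor = 1.0 if abs(species.valence) == 1 else 3.0
    a_cis = activity(species.conc_cis, species.valence,
                     factor * species.conc_cis, activity_model, temperature)
    a_trans = activity(species.conc_trans, species.valence,
                       factor * species.conc_trans, activity_model, temperature)
    if a_cis <= 0 or a_trans <= 0:
        raise ValueError("Nernst potential requires positive activities on both sides")
    return thermal_voltage(temperature) / species.valence * math.log(a_trans / a_cis)


def ghk_voltage_monovalent(pair: SolutionPair) -> float:
    """GHK reversal potential (mV) for a mixture of monovalent ions.

    Erev = (RT/F) ln[(sum_cat P a_trans + sum_an P a_cis) /
                     (sum_cat P a_cis + sum_an P a_trans)].
    Reduces to the Nernst potential when only one permeability is nonzero.
    """
    if any(abs(s.valence) != 1 for s in pair.species):
        raise ValueError(
            "ghk_voltage_monovalent handles monovalent ions only; "
            "use ghk_current_reversal for mixtures with divalents"
        )
    num = den = 0.0
    for s in pair.species:
        a_cis = pair.activity_of(s, "cis")
        a_trans = pair.activity_of(s, "trans")
        if s.valence == 1:
            num += s.permeability * a_trans
            den += s.permeability * a_cis
        else:
            num += s.permeability * a_cis
            den += s.permeability * a_trans
    if num <= 0 or den <= 0:
        raise ValueError("no permeant species with positive activity")
    return thermal_voltage(pair.temperature) * math.log(num / den)


def permeability_ratio_from_erev(
    erev: float,
    pair: SolutionPair,
    numerator: str | None = None,
    denominator: str | None = None,
) -> PermeabilityResult:
    """Invert the two-ion monovalent GHK voltage equation for P_num/P_den.

    ``erev`` is the measured reversal potential in mV (cis minus trans); the
    pair's junction potential is subtracted before inversion. The corrected
    Erev must lie strictly between the two species' Nernst potentials, else
    the implied ratio would be negative and an InfeasibleErevError is raised.
    Round-trips with ghk_voltage_monovalent to better than 1e-9 mV.
    """
    if len(pair.species) != 2:
        raise ValueError("inversion requires exactly two species")
    s0, s1 = pair.species
    if {s0.valence, s1.valence} != {1, -1}:
        raise ValueError("inversion requires one monovalent cation and one anion")
    cation = s0 if s0.valence == 1 else s1
    anion = s1 if cation is s0 else s0
    if numerator is None:
        numerator, denominator = cation.name, anion.name
    if {numerator, denominator} != {cation.name, anion.name}:
        raise ValueError("numerator/denominator must name the pair's two species")

    erev_corr = erev - pair.junction_potential
    x = math.exp(erev_corr / thermal_voltage(pair.temperature))
    a_cat_cis = pair.activity_of(cation, "cis")
    a_cat_trans = pair.activity_of(cation, "trans")
    a_an_cis = pair.activity_of(anion, "cis")
    a_an_trans = pair.activity_of(anion, "trans")
    num = a_an_cis - x * a_an_trans
    den = x * a_cat_cis - a_cat_trans
    # feasible iff the implied ratio is positive: num and den share a sign
    if num * den <= 0:
        e_cat = nernst(cation, pair.temperature, pair.activity_model)
        e_an = nernst(anion, pair.temperature, pair.activity_model)
        raise InfeasibleErevError(
            f"Erev {erev_corr:g} mV lies outside the Nernst bracket "
            f"[{min(e_cat, e_an):g}, {max(e_cat, e_an):g}] mV; "
            "the implied permeability ratio would be negative"
        )
    ratio_cat_over_an = num / den
    ratio = ratio_cat_over_an if numerator == cation.name else 1.0 / ratio_cat_over_an
    return PermeabilityResult(
        ratio=ratio,
        numerator_species=numerator,
        denominator_species=denominator,
        erev_used=erev_corr,
        activity_model=pair.activity_model,
    )


def _ghk_flux_term(v_mv: float, z: int, p: float, a_cis: float, a_trans: float,
                   vt_mv: float) -> float:
    # GHK constant-field flux, in arbitrary common units:
    #   I_i ∝ P z^2 V (a_cis - a_trans e^{-zV/Vt}) / (1 - e^{-zV/Vt})
    # with the removable singularity at V=0 handled by its series limit.
    if p == 0.0:
        return 0.0
    x = z * v_mv / vt_mv
    if abs(x) < 1e-6:
        # V (a_c - a_t e^{-x})/(1-e^{-x}) -> Vt/z (a_c - a_t) + V (a_c + a_t)/2
        return p * z * z * (
            vt_mv / z * (a_cis - a_trans) + v_mv * (a_cis + a_trans) / 2.0
        )
    em = math.exp(-x)
    return p * z * z * v_mv * (a_cis - a_trans * em) / (1.0 - em)


def ghk_current_reversal(pair: SolutionPair, bracket: float = 200.0) -> float:
    """Zero-current GHK reversal potential (mV) for arbitrary valence mixes.

    Finds the root of the summed GHK constant-field fluxes over all permeant
    species, bracketed within +/-``bracket`` mV and refined to <=1e-6 mV.
    Agrees with ghk_voltage_monovalent on all-monovalent mixtures.
    """
    if not any(s.permeability > 0 for s in pair.species):
        raise ValueError("at least one species must be permeant")
    vt = thermal_voltage(pair.temperature)
    acts = [
        (s.valence, s.permeability, pair.activity_of(s, "cis"),
         pair.activity_of(s, "trans"))
        for s in pair.species
    ]

    def total(v: float) -> float:
        return sum(_ghk_flux_term(v, z, p, ac, at, vt) for z, p, ac, at in acts)

    lo, hi = -bracket, bracket
    f_lo, f_hi = total(lo), total(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no zero-current crossing in [{lo:g}, {hi:g}] mV "
            f"(I({lo:g})={f_lo:.3g}, I({hi:g})={f_hi:.3g})"
        )
    return float(brentq(total, lo, hi, xtol=1e-9, rtol=8.9e-16))
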