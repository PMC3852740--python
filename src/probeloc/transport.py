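"""Steady-state subcellular distribution model for small ionizable cations.

A compound with a fixed +1 charge and up to two additional basic groups is
distributed across a nested compartment topology

    extracellular  ⊃  cytosol  ⊃  {mitochondria, lysosome}

by passive transmembrane diffusion.  Each ionization state (species) of the
compound permeates independently; the net flux of a species of charge ``z``
across a membrane follows the Nernst-Planck (Goldman) form

    J = P · N · (a_out − a_in · e^N) / (e^N − 1),      N = zFE/RT,

where ``a = γ·f·c`` is the free aqueous activity of the species (γ the
activity coefficient from lipid sorption, f the Henderson-Hasselbalch
fraction, c the total compound concentration in the compartment), ``P`` the
species permeability and ``E`` the membrane potential (interior minus
exterior).  As N → 0 this reduces to Fick's law, J = P·(a_out − a_in).
With a constant extracellular reservoir the steady state of each compartment
is the unique interior concentration at which the summed species flux
vanishes; lysosomes and mitochondria equilibrate against the cytosolic
steady state.

Species lipophilicity sets both sorption and permeability:

* γ = 1 / (water_fraction + lipid_fraction · 10^logP_species)
* log10 P(cm/s) = logP_species − 6.7
* logP of an ion with k extra unit charges = logP(+1 species) − 3.7·k

The model reports the mass in mitochondria, in lysosomes, and in cytoplasmic
(or plasma) membranes — by default the lipid-sorbed mass of the cytosolic
compartment — as fractions of the three-compartment total.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .library import Compound

#: RT/F at 310 K, in millivolts.
RT_OVER_F_MV = 26.73

#: log10 permeability offset: log10 P(cm/s) = logP_species + this.
LOGP_TO_LOG_PERM = -6.7

#: logP penalty per additional unit of charge beyond the fixed +1.
CHARGE_LOGP_PENALTY = 3.7


@dataclass(frozen=True)
class CompartmentParams:
    """Geometry and physiology of one compartment.

    ``membrane_potential_mV`` is the potential of the compartment interior
    minus its immediate exterior; a negative interior attracts cations.
    ``lipid_fraction`` is the volume fraction occupied by membrane lipid.
    """

    name: str
    volume_L: float
    pH: float
    membrane_potential_mV: float = 0.0
    lipid_fraction: float = 0.0
    water_fraction: float = 1.0
    membrane_area_cm2: float = 1.0

    def __post_init__(self):
        if self.volume_L <= 0:
            raise ValueError("volume must be positive")
        if self.lipid_fraction + self.water_fraction > 1 + 1e-12:
            raise ValueError("lipid_fraction + water_fraction must be <= 1")
        if not 0 < self.water_fraction <= 1:
            raise ValueError("water_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SpeciesState:
    """One ionization state of the compound within one compartment."""

    charge: int
    fraction: float  # Henderson-Hasselbalch fraction at the local pH
    activity_coefficient: float
    permeability_cm_s: float
    nernst_n: float  # N = zFE/RT for this species across the bounding membrane


@dataclass
class DistributionResult:
    compound_id: str
    mass_mito: float
    mass_lyso: float
    mass_membranes: float
    frac_mito: float
    frac_lyso: float
    frac_membranes: float
    concentrations: dict = field(default_factory=dict)  # compartment -> mol/L


def ionization_fractions(
    extra_pkas, pH: float, fixed_charge: int = 1
) -> list[tuple[int, float]]:
    """Species charges and Henderson-Hasselbalch fractions at a given pH.

    Extra groups are basic: group k is protonated (adding +1) with fraction
    1 / (1 + 10^(pH − pKa_k)), independently of the others.  With no extra
    groups the compound is a single permanent cation.
    """
    extra_pkas = tuple(extra_pkas)
    if len(extra_pkas) > 2:
        raise ValueError("at most 2 additional ionizable groups are supported")
    species = {fixed_charge: 1.0}
    for pka in extra_pkas:
        f_prot = 1.0 / (1.0 + 10.0 ** (pH - pka))
        new: dict[int, float] = {}
        for z, f in species.items():
            new[z + 1] = new.get(z + 1, 0.0) + f * f_prot
            new[z] = new.get(z, 0.0) + f * (1.0 - f_prot)
        species = new
    return sorted(species.items())


def activity_coefficient(logp_species: float, compartment: CompartmentParams) -> float:
    """Aqueous-activity coefficient under linear lipid sorption.

    γ = 1 / (water_fraction + lipid_fraction · 10^logP); the free aqueous
    activity of a species present at total concentration c is γ·c.
    """
    return 1.0 / (
        compartment.water_fraction
        + compartment.lipid_fraction * 10.0 ** logp_species
    )


def _species_states(
    compound: Compound, compartment: CompartmentParams, potential_mV: float
) -> list[SpeciesState]:
    states = []
    for z, f in ionization_fractions(
        compound.extra_pkas, compartment.pH, compound.fixed_charge
    ):
        logp_z = compound.logp - CHARGE_LOGP_PENALTY * (z - compound.fixed_charge)
        states.append(
            SpeciesState(
                charge=z,
                fraction=f,
                activity_coefficient=activity_coefficient(logp_z, compartment),
                permeability_cm_s=10.0 ** (logp_z + LOGP_TO_LOG_PERM),
                nernst_n=z * potential_mV / RT_OVER_F_MV,
            )
        )
    return states


def _species_flux(p: float, n: float, a_out: float, a_in: float) -> float:
    """Nernst-Planck net inward flux per unit area for one species."""
    if abs(n) < 1e-6:  # Fick limit, avoids 0/0
        return p * (a_out - a_in)
    return p * n * (a_out - a_in * math.exp(n)) / (math.expm1(n))


def membrane_flux(
    c_out: float,
    c_in: float,
    species_out: list[SpeciesState],
    species_in: list[SpeciesState],
    area_cm2: float = 1.0,
) -> float:
    """Net inward molar flux across a membrane, summed over species.

    ``species_in`` carries the Nernst factors N (computed from the membrane
    potential); matched charges are paired across the two sides.  The flux
    is strictly decreasing in ``c_in``.
    """
    out_by_z = {s.charge: s for s in species_out}
    flux = 0.0
    for s_in in species_in:
        s_out = out_by_z.get(s_in.charge)
        if s_out is None:
            raise ValueError(f"species charge {s_in.charge} missing on outer side")
        a_out = s_out.activity_coefficient * s_out.fraction * c_out
        a_in = s_in.activity_coefficient * s_in.fraction * c_in
        flux += _species_flux(s_in.permeability_cm_s, s_in.nernst_n, a_out, a_in)
    return area_cm2 * flux


def steady_state_concentration(
    compartment: CompartmentParams,
    outer: CompartmentParams,
    outer_concentration: float,
    compound: Compound,
) -> float:
    """Total interior concentration at which net transmembrane flux is zero.

    The summed species flux is strictly decreasing in the interior
    concentration, so the zero is unique; it is found by bracketed root
    finding (bracket expanded geometrically from the outer concentration).
    """
    if outer_concentration < 0:
        raise ValueError("outer concentration must be >= 0")
    if outer_concentration == 0:
        return 0.0
    species_in = _species_states(
        compound, compartment, compartment.membrane_potential_mV
    )
    # the outer side sees the same membrane; N only enters via species_in
    species_out = _species_states(compound, outer, compartment.membrane_potential_mV)

    def net_flux(ratio):
        # solved in the dimensionless ratio c_in / c_out for conditioning
        return membrane_flux(
            outer_concentration, ratio * outer_concentration, species_out, species_in
        )

    hi = 1.0
    for _ in range(64):
        if net_flux(hi) <= 0:
            break
        hi *= 4.0
    else:
        raise RuntimeError(
            f"bracket expansion failed for {compound.compound_id} in "
            f"{compartment.name}: flux still inward at c_in/c_out = {hi:g}"
        )
    ratio = brentq(net_flux, 0.0, hi, xtol=1e-30, rtol=1e-14, maxiter=300)
    return float(ratio * outer_concentration)


def _lipid_sorbed_fraction(compound: Compound, compartment: CompartmentParams) -> float:
    """Fraction of the compartment's compound mass sorbed to membrane lipid."""
    sorbed = 0.0
    for z, f in ionization_fractions(
        compound.extra_pkas, compartment.pH, compound.fixed_charge
    ):
        logp_z = compound.logp - CHARGE_LOGP_PENALTY * (z - compound.fixed_charge)
        kl = compartment.lipid_fraction * 10.0 ** logp_z
        sorbed += f * kl / (compartment.water_fraction + kl)
    return sorbed


def fractional_masses(
    compound: Compound,
    cell: dict[str, CompartmentParams],
    c_ext: float = 1e-6,
    include_aqueous_cytosol: bool = False,
) -> DistributionResult:
    """Steady-state fractional mass in mitochondria, lysosomes and membranes.

    The cytosol equilibrates against the constant extracellular reservoir;
    mitochondria and lysosomes then equilibrate against the cytosolic steady
    state.  "Membranes" is the lipid-sorbed mass of the cytosol/plasma-
    membrane compartment (set ``include_aqueous_cytosol`` to count the
    aqueous cytosolic mass there as well).  Fractions are normalized over
    the three compartments only.
    """
    for name in ("extracellular", "cytosol", "mitochondria", "lysosome"):
        if name not in cell:
            raise KeyError(f"cell parameter table missing compartment {name!r}")
    ext, cyt = cell["extracellular"], cell["cytosol"]
    mito, lyso = cell["mitochondria"], cell["lysosome"]

    c_cyt = steady_state_concentration(cyt, ext, c_ext, compound)
    c_mito = steady_state_concentration(mito, cyt, c_cyt, compound)
    c_lyso = steady_state_concentration(lyso, cyt, c_cyt, compound)

    mass_mito = c_mito * mito.volume_L
    mass_lyso = c_lyso * lyso.volume_L
    cyto_mass = c_cyt * cyt.volume_L
    if include_aqueous_cytosol:
        mass_mem = cyto_mass
    else:
        mass_mem = cyto_mass * _lipid_sorbed_fraction(compound, cyt)

    total = mass_mito + mass_lyso + mass_mem
    if total <= 0:
        raise ValueError("no compound mass in the three reporting compartments")
    return DistributionResult(
        compound_id=compound.compound_id,
        mass_mito=mass_mito,
        mass_lyso=mass_lyso,
        mass_membranes=mass_mem,
        frac_mito=mass_mito / total,
        frac_lyso=mass_lyso / total,
        frac_membranes=mass_mem / total,
        concentrations={
            "extracellular": c_ext,
            "cytosol": c_cyt,
            "mitochondria": c_mito,
            "lysosome": c_lyso,
        },
    )


def predict_library(
    library: list[Compound],
    cell: dict[str, CompartmentParams] | None = None,
    c_ext: float = 1e-6,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the distribution model over a library.

    Compounds with two or more additional ionizable groups are excluded
    (the model is parameterized for 0 or 1) and reported in the exclusion
    table.  Returns ``(predictions, exclusions)`` data frames; prediction
    fractions are in percent.
    """
    if cell is None:
        cell = default_cell()
    rows, excluded = [], []
    for compound in library:
        if compound.n_extra_ionizable >= 2:
            excluded.append(
                {
                    "compound_id": compound.compound_id,
                    "reason": "more than one additional ionizable group",
                }
            )
            continue
        res = fractional_masses(compound, cell, c_ext=c_ext, **kwargs)
        rows.append(
            {
                "compound_id": compound.compound_id,
                "head": compound.head.index,
                "aldehyde": compound.aldehyde.index,
                "frac_mito": 100.0 * res.frac_mito,
                "frac_lyso": 100.0 * res.frac_lyso,
                "frac_membranes": 100.0 * res.frac_membranes,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(excluded, columns=["compound_id", "reason"])


def load_cell_params(path=None) -> dict[str, CompartmentParams]:
    """Load a compartment parameter table from a TOML file.

    With no path, the packaged baseline "average mammalian cell" table is
    used (cytosol pH 7.2 at −60 mV, mitochondria pH 8.0 at −160 mV and 10%
    of cell volume, lysosomes pH 5.0 at +10 mV and 1%, 5% lipid throughout).
    """
    if path is None:
        text = (
            resources.files("probeloc").joinpath("data/cell_baseline.toml").read_text()
        )
        raw = tomllib.loads(text)
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    return {
        name: CompartmentParams(
            name=name,
            volume_L=sec["volume_L"],
            pH=sec["pH"],
            membrane_potential_mV=sec.get("membrane_potential_mV", 0.0),
            lipid_fraction=sec.get("lipid_fraction", 0.0),
            water_fraction=sec.get("water_fraction", 1.0 - sec.get("lipid_fraction", 0.0)),
            membrane_area_cm2=sec.get("membrane_area_cm2", 1.0),
        )
        for name, sec in raw.items()
    }


def default_cell() -> dict[str, CompartmentParams]:
    """The packaged baseline cell parameter table."""
    return load_cell_params(None)
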