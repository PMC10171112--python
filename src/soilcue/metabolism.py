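"""Microbial metabolic efficiency from ¹⁸O-H₂O incubations.

Derives the seven per-site quantities — C_respiration, C_growth, C_uptake,
CUE, MBC, qCO₂ and biomass turnover time τ — from raw vial measurements:
headspace CO₂ mixing ratios, DNA mass and oxygen content, ¹⁸O atom percent
of DNA and of the vial water, and chloroform-fumigation extractable carbon.

The growth calculation follows the substrate-independent ¹⁸O-water method:
new DNA is quantified from the excess ¹⁸O incorporated into DNA oxygen
relative to the enrichment of the vial water, and converted to biomass
carbon through the per-sample MBC:DNA mass ratio.

Conventions
-----------
* Carbon fluxes are µg C g⁻¹ dry soil h⁻¹; MBC is µg C g⁻¹ dry soil;
  qCO₂ is µg CO₂-C (µg MBC)⁻¹ h⁻¹; τ is hours.
* Physically impossible negative differences arising from measurement
  noise (ΔCO₂ < 0, atom-percent excess < 0, fumigation flush < 0) are
  clamped to zero with a logged warning; sites are never silently dropped.
* Undefined ratios (CUE with zero uptake, qCO₂ with zero MBC, τ with zero
  growth) return NaN with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ideal gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314462618
#: Molar mass of carbon, g mol⁻¹.
MOLAR_MASS_C = 12.011
#: Natural ¹⁸O abundance of water and biomolecules, atom percent.
NATURAL_18O_ATOM_PCT = 0.2005
#: Oxygen mass fraction of DNA.
F_O_DNA = 0.31
#: Fumigation-extraction efficiency factor for MBC.
K_EC_DEFAULT = 0.45


@dataclass
class IncubationMeasurement:
    """Raw measurements for one site's incubation (replicates pre-averaged).

    Attributes
    ----------
    co2_labeled_ppm, co2_control_ppm:
        Headspace CO₂ mixing ratio (ppm) after incubation in the labeled
        vial and in the ambient-air control vial.
    headspace_volume:
        Vial headspace, liters.
    temperature : kelvin
    pressure : pascal
    dry_mass:
        Dry soil per vial, g.
    duration : hours
    dna_total:
        Total DNA extracted per vial, µg.
    o_total:
        Oxygen in the DNA extract, µg.
    atom_pct_labeled, atom_pct_natural:
        ¹⁸O atom percent of DNA in labeled and natural-abundance vials.
    label_volume:
        Added ¹⁸O water, µL (density 1 g mL⁻¹ assumed).
    label_atom_pct:
        Atom percent ¹⁸O of the label water.
    soil_water_mass:
        Native soil water in the vial, g.
    ec_fumigated, ec_unfumigated:
        Extractable organic C after/without chloroform fumigation,
        µg C g⁻¹ dry soil.
    """

    co2_labeled_ppm: float
    co2_control_ppm: float
    headspace_volume: float
    temperature: float
    pressure: float
    dry_mass: float
    duration: float
    dna_total: float
    o_total: float
    atom_pct_labeled: float
    atom_pct_natural: float
    label_volume: float
    label_atom_pct: float
    soil_water_mass: float
    ec_fumigated: float
    ec_unfumigated: float

    def __post_init__(self) -> None:
        for name in ("headspace_volume", "dry_mass", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("atom_pct_labeled", "atom_pct_natural", "label_atom_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100] atom percent")


@dataclass
class MetabolicEfficiency:
    """Derived per-site metabolic quantities (see module docstring units)."""

    c_respiration: float
    c_growth: float
    c_uptake: float
    cue: float
    mbc: float
    qco2: float
    tau: float


def compute_respiration(m: IncubationMeasurement) -> float:
    """Basal respiration rate from the headspace CO₂ increase.

    The CO₂ mole increment is obtained from the mixing-ratio difference and
    the ideal-gas molar content of the headspace, converted to µg CO₂-C and
    normalized by dry mass and duration.
    """
    delta_ppm = m.co2_labeled_ppm - m.co2_control_ppm
    if delta_ppm < 0:
        logger.warning(
            "negative headspace CO2 increment (%.3f ppm); clamped to 0", delta_ppm
        )
        delta_ppm = 0.0
    headspace_m3 = m.headspace_volume * 1e-3
    mol_air = m.pressure * headspace_m3 / (R_GAS * m.temperature)
    mol_co2 = mol_air * delta_ppm * 1e-6
    ug_c = mol_co2 * MOLAR_MASS_C * 1e6
    return ug_c / m.dry_mass / m.duration


def compute_water_enrichment(
    m: IncubationMeasurement, natural_atom_pct: float = NATURAL_18O_ATOM_PCT
) -> float:
    """Atom percent ¹⁸O of the vial water after adding the label.

    Mass-weighted two-pool mixture of label water (``label_volume`` µL at
    ``label_atom_pct``) and native soil water at natural abundance.
    """
    m_label = m.label_volume * 1e-3  # µL -> g at density 1 g/mL
    total = m_label + m.soil_water_mass
    if total <= 0:
        raise ValueError("no water in vial: label_volume and soil_water_mass both zero")
    return (m_label * m.label_atom_pct + m.soil_water_mass * natural_atom_pct) / total


def compute_growth(
    m: IncubationMeasurement,
    mbc: float,
    f_o_dna: float = F_O_DNA,
    natural_atom_pct: float = NATURAL_18O_ATOM_PCT,
) -> float:
    """Microbial growth rate (µg C g⁻¹ h⁻¹) from ¹⁸O incorporation into DNA.

    Chain: atom-percent excess of DNA over the natural-abundance control,
    scaled by the water enrichment excess, gives the mass of *new* DNA
    oxygen; dividing by the DNA oxygen mass fraction gives new DNA, which
    the per-sample MBC:DNA mass ratio converts to biomass carbon.

    Parameters
    ----------
    mbc:
        Microbial biomass carbon of the same sample, µg C g⁻¹ dry soil
        (from :func:`compute_mbc`); sets the DNA→biomass-C conversion.
    """
    if m.dna_total <= 0:
        raise ValueError("dna_total must be positive")
    ape_dna = m.atom_pct_labeled - m.atom_pct_natural
    if ape_dna < 0:
        logger.warning("negative DNA atom percent excess (%.4f); clamped to 0", ape_dna)
        ape_dna = 0.0
    ape_water = compute_water_enrichment(m, natural_atom_pct) - natural_atom_pct
    if ape_water <= 0:
        raise ValueError("water atom percent excess is non-positive: no label present")
    o_new = m.o_total * ape_dna / ape_water
    dna_produced = o_new / f_o_dna
    mbc_per_dna = mbc * m.dry_mass / m.dna_total
    return dna_produced * mbc_per_dna / m.dry_mass / m.duration


def compute_mbc(
    ec_fumigated: float, ec_unfumigated: float, k_ec: float = K_EC_DEFAULT
) -> float:
    """Microbial biomass carbon by chloroform-fumigation extraction.

    MBC = (EC_fumigated − EC_unfumigated) / k_EC, with the flush clamped to
    zero (warning) when noise makes it negative.
    """
    if not 0 < k_ec <= 1:
        raise ValueError(f"k_ec={k_ec} outside (0, 1]")
    flush = ec_fumigated - ec_unfumigated
    if flush < 0:
        logger.warning("negative fumigation flush (%.3f); clamped to 0", flush)
        flush = 0.0
    return flush / k_ec


def compute_cue(c_growth: float, c_respiration: float) -> tuple[float, float]:
    """Carbon uptake and carbon use efficiency.

    C_uptake = C_growth + C_respiration; CUE = C_growth / C_uptake.
    Returns ``(c_uptake, cue)``; CUE is NaN when both fluxes are zero.
    """
    if c_growth < 0 or c_respiration < 0:
        raise ValueError("carbon fluxes must be non-negative")
    c_uptake = c_growth + c_respiration
    if c_uptake == 0:
        logger.warning("zero uptake: CUE undefined, returning NaN")
        return 0.0, float("nan")
    return c_uptake, c_growth / c_uptake


def compute_qco2(c_respiration: float, mbc: float) -> float:
    """Metabolic quotient qCO₂ = C_respiration / MBC; NaN when MBC ≤ 0."""
    if mbc <= 0:
        logger.warning("non-positive MBC (%.3f): qCO2 undefined, returning NaN", mbc)
        return float("nan")
    return c_respiration / mbc


def compute_turnover(mbc: float, c_growth: float) -> float:
    """Biomass turnover time τ = MBC / C_growth (hours); NaN when growth ≤ 0."""
    if c_growth <= 0:
        logger.warning("non-positive growth (%.3g): tau undefined, returning NaN", c_growth)
        return float("nan")
    return mbc / c_growth


def derive_efficiency(
    m: IncubationMeasurement,
    k_ec: float = K_EC_DEFAULT,
    f_o_dna: float = F_O_DNA,
) -> MetabolicEfficiency:
    """Run the full chain for one site's (replicate-averaged) measurements."""
    c_resp = compute_respiration(m)
    mbc = compute_mbc(m.ec_fumigated, m.ec_unfumigated, k_ec)
    c_growth = compute_growth(m, mbc, f_o_dna)
    c_uptake, cue = compute_cue(c_growth, c_resp)
    return MetabolicEfficiency(
        c_respiration=c_resp,
        c_growth=c_growth,
        c_uptake=c_uptake,
        cue=cue,
        mbc=mbc,
        qco2=compute_qco2(c_resp, mbc),
        tau=compute_turnover(mbc, c_growth),
    )


#: Replicate-triple column stems averaged before the APE computation.
_REPLICATE_STEMS = ("co2_labeled_ppm", "atom_pct_labeled", "atom_pct_natural")

_SCALAR_COLUMNS = (
    "co2_control_ppm",
    "headspace_volume",
    "temperature",
    "pressure",
    "dry_mass",
    "duration",
    "dna_total",
    "o_total",
    "label_volume",
    "label_atom_pct",
    "soil_water_mass",
    "ec_fumigated",
    "ec_unfumigated",
)


def measurement_from_row(row: pd.Series) -> IncubationMeasurement:
    """Build an :class:`IncubationMeasurement` from one incubation-table row.

    Replicate triples (``<stem>_1 .. <stem>_3``) are averaged; plain
    ``<stem>`` columns are accepted as already averaged.
    """
    values: dict[str, float] = {}
    for stem in _REPLICATE_STEMS:
        reps = [c for c in row.index if c == stem or c.startswith(stem + "_")]
        if not reps:
            raise KeyError(f"incubation table is missing column '{stem}' (or replicates)")
        values[stem] = float(np.mean([row[c] for c in reps]))
    for col in _SCALAR_COLUMNS:
        if col not in row.index:
            raise KeyError(f"incubation table is missing column '{col}'")
        values[col] = float(row[col])
    return IncubationMeasurement(**values)


def process_incubation_table(
    table: pd.DataFrame,
    k_ec: float = K_EC_DEFAULT,
    f_o_dna: float = F_O_DNA,
) -> pd.DataFrame:
    """Derive all seven metabolic quantities for every row of ``table``.

    The index of ``table`` (site identifiers) is preserved in the output,
    which has columns ``c_respiration, c_growth, c_uptake, cue, mbc, qco2,
    tau``.
    """
    records = []
    for site, row in table.iterrows():
        eff = derive_efficiency(measurement_from_row(row), k_ec=k_ec, f_o_dna=f_o_dna)
        records.append(
            {
                "site": site,
                "c_respiration": eff.c_respiration,
                "c_growth": eff.c_growth,
                "c_uptake": eff.c_uptake,
                "cue": eff.cue,
                "mbc": eff.mbc,
                "qco2": eff.qco2,
                "tau": eff.tau,
            }
        )
    return pd.DataFrame.from_records(records).set_index("site")
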