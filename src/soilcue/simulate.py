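"""Synthetic riparian study generator.

Produces complete, seed-deterministic study datasets with the statistical
structure the downstream analysis assumes, so every stage is testable
without any field or sequencing data:

* site tables over three river zones with zone-graded physicochemistry;
* raw ¹⁸O-incubation measurements obtained by *inverting* the metabolic
  chain from planted per-site CUE/MBC/qCO₂ truths and then adding
  measurement noise — so the forward pipeline is an exact recovery oracle
  at ``noise_sd = 0``;
* seven-enzyme activity panels driven by a latent enzyme factor that
  carries a configurable standardized path to metabolic efficiency;
* two ASV count tables (bacterial 16S, fungal ITS scale) with planted
  block-correlation modules and taxonomy strings from the dominant
  riparian phyla;
* random rooted trees over the ASVs for phylogenetic diversity.

All randomness is driven by named substreams of the master seed, so each
stage is reproducible in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metabolism
from .config import SimulationConfig

# fixed substream tags so stages decouple
_STREAM_SITES = 1
_STREAM_LATENTS = 2
_STREAM_INCUBATION = 3
_STREAM_ENZYMES = 4
_STREAM_ASV_BACTERIA = 5
_STREAM_ASV_FUNGI = 6
_STREAM_TREE_BACTERIA = 7
_STREAM_TREE_FUNGI = 8

#: Zone means for the physicochemical table (upstream, midstream, downstream).
PHYSICOCHEM_ZONE_MEANS = {
    "pH": (7.9, 7.6, 7.3),
    "SWC": (22.0, 25.0, 28.0),       # %
    "TC": (14.0, 17.0, 20.0),        # g kg-1
    "TN": (1.2, 1.5, 1.8),           # g kg-1
    "TP": (0.65, 0.75, 0.85),        # g kg-1
    "SOC": (8.0, 11.0, 14.0),        # g kg-1
    "Cond": (180.0, 150.0, 120.0),   # µS cm-1
}

#: Baseline enzyme activities, nmol h⁻¹ g⁻¹ soil (mildly P-limited profile).
ENZYME_BASELINES = {
    "BG": 120.0, "BX": 60.0, "CBH": 45.0, "PPO": 30.0,
    "NAG": 80.0, "LAP": 70.0, "ACP": 120.0,
}

#: Taxonomy pools: (phylum, sampling weight). Dominant riparian soil phyla.
BACTERIAL_PHYLA = (
    ("Actinobacteriota", 0.24), ("Proteobacteria", 0.22), ("Chloroflexi", 0.18),
    ("Acidobacteriota", 0.14), ("Desulfobacterota", 0.08), ("Nitrospirota", 0.07),
    ("Myxococcota", 0.07),
)
FUNGAL_PHYLA = (
    ("Ascomycota", 0.45), ("unclassified_k_Fungi", 0.20), ("Basidiomycota", 0.15),
    ("Mortierellomycota", 0.10), ("Calcarisporiellomycota", 0.05),
    ("Rozellomycota", 0.05),
)

# fixed incubation protocol constants (physically plausible vial setup)
VIAL = dict(
    headspace_volume=0.05,   # L
    temperature=293.15,      # K (20 °C)
    pressure=101325.0,       # Pa
    dry_mass=0.5,            # g dry soil
    duration=48.0,           # h
    co2_control_ppm=450.0,   # ambient lab air
    label_volume=100.0,      # µL 18O water
    label_atom_pct=20.0,     # atom% 18O of the label
    soil_water_mass=0.15,    # g native water (0.5 g soil at ~60% WHC)
    ec_unfumigated=80.0,     # µg C g-1 baseline extractable C
    mbc_to_dna=12.0,         # MBC : DNA mass ratio used to set DNA yields
)

#: Default standardized latent path coefficients (soil→…→efficiency chain).
DEFAULT_LATENT_BETAS = {
    ("soil", "diversity"): 0.5,
    ("soil", "enzymes"): 0.3,
    ("soil", "efficiency"): 0.2,
    ("diversity", "enzymes"): 0.45,
    ("diversity", "efficiency"): -0.1,
    # ("enzymes", "efficiency") comes from config.enzyme_efficiency_beta
}


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream])


def _site_ids(config: SimulationConfig) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(config.n_sites)]


def _zone_labels(config: SimulationConfig) -> list[str]:
    labels: list[str] = []
    for zone, n in zip(config.zones, config.n_sites_per_zone):
        labels += [zone] * n
    return labels


# ---------------------------------------------------------------------------
# latent chain
# ---------------------------------------------------------------------------

def generate_latent_chain(
    n: int,
    betas: dict[tuple[str, str], float],
    rng: np.random.Generator,
    order: tuple[str, ...] = ("soil", "diversity", "enzymes", "efficiency"),
) -> pd.DataFrame:
    """Standardized latent variables from a recursive linear chain.

    The first variable in ``order`` is exogenous standard normal; each
    later variable is the β-weighted sum of its parents plus a residual
    scaled so its theoretical variance is exactly 1. Hence every β is a
    standardized path coefficient by construction.
    """
    cols: dict[str, np.ndarray] = {}
    cov = pd.DataFrame(0.0, index=order, columns=order)
    for i, name in enumerate(order):
        if i == 0:
            cols[name] = rng.standard_normal(n)
            cov.loc[name, name] = 1.0
            continue
        parents = [a for (a, b), v in betas.items() if b == name and v != 0.0]
        if not parents:
            cols[name] = rng.standard_normal(n)
            cov.loc[name, name] = 1.0
            continue
        beta = np.array([betas[(a, name)] for a in parents])
        cpp = cov.loc[parents, parents].to_numpy()
        lin_var = float(beta @ cpp @ beta)
        if lin_var >= 1.0:
            raise ValueError(f"latent path coefficients into '{name}' imply variance ≥ 1")
        lin = np.column_stack([cols[a] for a in parents]) @ beta
        cols[name] = lin + math.sqrt(1.0 - lin_var) * rng.standard_normal(n)
        for other in order[: i]:
            c = float(beta @ cov.loc[parents, other].to_numpy())
            cov.loc[name, other] = cov.loc[other, name] = c
        cov.loc[name, name] = 1.0
    return pd.DataFrame(cols)


def generate_path_dataset(
    n: int,
    betas: dict[tuple[str, str], float] | None = None,
    n_indicators: int = 4,
    loading: float = 0.9,
    seed: int = 0,
) -> dict:
    """Latent chain plus observed indicator groups for path-model tests.

    Each latent variable gets ``n_indicators`` observed variables
    ``loading·latent + sqrt(1−loading²)·noise``, emulating the correlated
    variable groups that PCA composites summarize. Returns a dict with
    ``latents`` (DataFrame) and ``groups`` (name → indicator DataFrame).
    """
    if betas is None:
        betas = dict(DEFAULT_LATENT_BETAS)
        betas[("enzymes", "efficiency")] = -0.65
    rng = np.random.default_rng([seed, 91])
    latents = generate_latent_chain(n, betas, rng)
    resid = math.sqrt(1.0 - loading**2)
    groups = {}
    for name in latents.columns:
        base = latents[name].to_numpy()
        data = {
            f"{name}_{k + 1}": loading * base + resid * rng.standard_normal(n)
            for k in range(n_indicators)
        }
        groups[name] = pd.DataFrame(data)
    return {"latents": latents, "groups": groups, "betas": betas}


# ---------------------------------------------------------------------------
# sites / incubation / enzymes
# ---------------------------------------------------------------------------

def generate_sites(config: SimulationConfig) -> pd.DataFrame:
    """Site table: zone label plus physicochemical variables.

    Each variable is its zone mean scaled by multiplicative Gaussian
    noise of relative SD ``noise_sd``, with a mild dependence on the
    site's latent soil factor so the physicochemical block is internally
    correlated (as real soil panels are).
    """
    rng = _rng(config.seed, _STREAM_SITES)
    latents = _study_latents(config)
    zone_idx = {z: i for i, z in enumerate(config.zones)}
    zones = _zone_labels(config)
    rows = {}
    for var, means in PHYSICOCHEM_ZONE_MEANS.items():
        mean = np.array([means[zone_idx[z]] for z in zones])
        values = mean * np.exp(
            0.08 * latents["soil"].to_numpy()
            + config.noise_sd * rng.standard_normal(len(zones))
        )
        rows[var] = values
    df = pd.DataFrame(rows, index=_site_ids(config))
    df.insert(0, "zone", zones)
    df.index.name = "site"
    return df


def _study_latents(config: SimulationConfig) -> pd.DataFrame:
    """Per-site latent chain shared by all study stages (own substream)."""
    betas = dict(DEFAULT_LATENT_BETAS)
    betas[("enzymes", "efficiency")] = config.enzyme_efficiency_beta
    rng = _rng(config.seed, _STREAM_LATENTS)
    df = generate_latent_chain(config.n_sites, betas, rng)
    df.index = _site_ids(config)
    return df


def planted_truth(config: SimulationConfig) -> pd.DataFrame:
    """Planted per-site metabolic truths (CUE, MBC, qCO₂ and derived fluxes).

    CUE is the zone mean plus ``site_sd`` times the site's latent
    efficiency factor (clipped to (0.01, 0.99)); qCO₂ and MBC are zone
    means log-modulated by efficiency and soil factors. C_respiration,
    C_growth and τ follow from the definitions.
    """
    latents = _study_latents(config)
    zone_idx = {z: i for i, z in enumerate(config.zones)}
    zones = _zone_labels(config)
    eff = latents["efficiency"].to_numpy()
    soil = latents["soil"].to_numpy()
    cue = np.clip(
        np.array([config.cue_gradient[zone_idx[z]] for z in zones])
        + config.site_sd * eff,
        0.01, 0.99,
    )
    qco2 = np.array([config.qco2_gradient[zone_idx[z]] for z in zones]) * np.exp(
        -0.2 * eff
    )
    mbc = np.array([config.mbc_gradient[zone_idx[z]] for z in zones]) * np.exp(
        0.1 * soil
    )
    c_resp = qco2 * mbc
    c_growth = c_resp * cue / (1.0 - cue)
    tau = mbc / c_growth
    return pd.DataFrame(
        {"zone": zones, "cue": cue, "mbc": mbc, "qco2": qco2,
         "c_respiration": c_resp, "c_growth": c_growth, "tau": tau},
        index=_site_ids(config),
    )


def generate_incubation(
    sites: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Raw incubation table obtained by inverting the metabolic chain.

    From each site's planted (CUE, MBC, qCO₂) the implied fluxes are
    back-solved into headspace CO₂ mixing ratios, fumigation extract C,
    DNA mass/oxygen and ¹⁸O atom percents, under the fixed vial protocol
    in :data:`VIAL`. Labeled CO₂ and atom-percent measurements come as
    replicate triples; multiplicative measurement noise of relative SD
    ``noise_sd`` is applied per replicate (none at ``noise_sd = 0``, in
    which case re-deriving the quantities reproduces the truth exactly).
    """
    truth = planted_truth(config)
    rng = _rng(config.seed, _STREAM_INCUBATION)
    v = VIAL
    mol_air = v["pressure"] * (v["headspace_volume"] * 1e-3) / (
        metabolism.R_GAS * v["temperature"]
    )
    m_label = v["label_volume"] * 1e-3
    water_atom_pct = (
        m_label * v["label_atom_pct"]
        + v["soil_water_mass"] * metabolism.NATURAL_18O_ATOM_PCT
    ) / (m_label + v["soil_water_mass"])
    ape_water = water_atom_pct - metabolism.NATURAL_18O_ATOM_PCT

    def jitter(value, size=None):
        eps = rng.standard_normal(size if size is not None else 1)
        out = value * (1.0 + config.noise_sd * eps)
        return out if size is not None else float(out[0])

    records = []
    for site, t in truth.iterrows():
        c_resp, c_growth, mbc = t["c_respiration"], t["c_growth"], t["mbc"]
        delta_ppm = (
            c_resp * v["dry_mass"] * v["duration"]
            / (metabolism.MOLAR_MASS_C * 1e6) / mol_air / 1e-6
        )
        dna_total = mbc * v["dry_mass"] / v["mbc_to_dna"]
        o_total = dna_total * metabolism.F_O_DNA
        dna_produced = c_growth * v["duration"] * dna_total / mbc
        ape_dna = dna_produced * metabolism.F_O_DNA * ape_water / o_total
        ec_fum = v["ec_unfumigated"] + mbc * metabolism.K_EC_DEFAULT

        co2_reps = v["co2_control_ppm"] + jitter(delta_ppm, 3)
        nat_reps = jitter(metabolism.NATURAL_18O_ATOM_PCT, 3)
        lab_reps = jitter(metabolism.NATURAL_18O_ATOM_PCT + ape_dna, 3)
        rec = {
            "site": site,
            "co2_labeled_ppm_1": co2_reps[0],
            "co2_labeled_ppm_2": co2_reps[1],
            "co2_labeled_ppm_3": co2_reps[2],
            "co2_control_ppm": v["co2_control_ppm"],
            "headspace_volume": v["headspace_volume"],
            "temperature": v["temperature"],
            "pressure": v["pressure"],
            "dry_mass": v["dry_mass"],
            "duration": v["duration"],
            "dna_total": jitter(dna_total),
            "o_total": jitter(o_total),
            "atom_pct_labeled_1": lab_reps[0],
            "atom_pct_labeled_2": lab_reps[1],
            "atom_pct_labeled_3": lab_reps[2],
            "atom_pct_natural_1": nat_reps[0],
            "atom_pct_natural_2": nat_reps[1],
            "atom_pct_natural_3": nat_reps[2],
            "label_volume": v["label_volume"],
            "label_atom_pct": v["label_atom_pct"],
            "soil_water_mass": v["soil_water_mass"],
            "ec_fumigated": jitter(ec_fum),
            "ec_unfumigated": jitter(v["ec_unfumigated"]),
        }
        records.append(rec)
    df = pd.DataFrame.from_records(records).set_index("site")
    if config.noise_sd == 0:
        return df
    # labeled vials must stay at or above natural abundance
    for k in (1, 2, 3):
        lab, nat = f"atom_pct_labeled_{k}", f"atom_pct_natural_{k}"
        df[lab] = np.maximum(df[lab], df[nat])
    return df


def generate_enzymes(config: SimulationConfig) -> pd.DataFrame:
    """Seven-enzyme activity panel per site, nmol h⁻¹ g⁻¹ soil.

    Activities are log-normal around field-typical baselines, driven by
    the site's latent enzyme factor (loading 0.4 on the log scale) plus
    relative measurement noise — so the panel's composite index tracks
    the latent factor that carries the planted path to efficiency.
    """
    latents = _study_latents(config)
    rng = _rng(config.seed, _STREAM_ENZYMES)
    enz = latents["enzymes"].to_numpy()
    data = {}
    for name, base in ENZYME_BASELINES.items():
        data[name] = base * np.exp(
            0.4 * enz + config.noise_sd * rng.standard_normal(config.n_sites)
        )
    df = pd.DataFrame(data, index=_site_ids(config))
    df.index.name = "site"
    return df


# ---------------------------------------------------------------------------
# ASV tables and trees
# ---------------------------------------------------------------------------

def generate_asv_table(
    config: SimulationConfig,
    kingdom: str = "bacteria",
    depth_factors: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Count matrix with planted correlation modules plus taxonomy and truth.

    ASVs are split into ``n_planted_modules`` blocks; members of a block
    share a latent per-site factor mixed so the within-block Spearman
    correlation targets ``within_module_rho`` (the Pearson latent
    correlation is 2·sin(π·ρ/6), the Gaussian-copula inverse of the
    Spearman map). Latent log-abundances become counts by Poisson
    thinning (deterministic rounding at ``noise_sd = 0``).

    Returns ``(counts, taxonomy, truth_partition)``; the partition maps
    every ASV id to ``"Truth#k"``.
    """
    if kingdom == "bacteria":
        n_asvs, stream, phyla, prefix = (
            config.n_asvs_bacteria, _STREAM_ASV_BACTERIA, BACTERIAL_PHYLA, "B_ASV")
        domain = "k__Bacteria"
    elif kingdom == "fungi":
        n_asvs, stream, phyla, prefix = (
            config.n_asvs_fungi, _STREAM_ASV_FUNGI, FUNGAL_PHYLA, "F_ASV")
        domain = "k__Fungi"
    else:
        raise ValueError("kingdom must be 'bacteria' or 'fungi'")
    rng = _rng(config.seed, stream)
    n_sites = config.n_sites
    asv_ids = [f"{prefix}{j + 1:04d}" for j in range(n_asvs)]

    blocks = np.array_split(np.arange(n_asvs), config.n_planted_modules)
    truth = {}
    for k, block in enumerate(blocks):
        for j in block:
            truth[asv_ids[j]] = f"Truth#{k}"

    rho_pearson = 2.0 * math.sin(math.pi * config.within_module_rho / 6.0)
    shared = rng.standard_normal((n_sites, config.n_planted_modules))
    # log-uniform mean abundances down to a few counts, so rare ASVs
    # produce the absences/singletons real amplicon tables have
    mu = rng.uniform(math.log(5.0), math.log(300.0), n_asvs)
    latent = np.empty((n_sites, n_asvs))
    for k, block in enumerate(blocks):
        eps = rng.standard_normal((n_sites, len(block)))
        latent[:, block] = (
            math.sqrt(rho_pearson) * shared[:, [k]]
            + math.sqrt(1.0 - rho_pearson) * eps
        )
    abundance = np.exp(mu[None, :] + latent)
    if depth_factors is not None:
        abundance = abundance * np.asarray(depth_factors)[:, None]
    if config.noise_sd == 0:
        counts = np.round(abundance).astype(int)
    else:
        counts = rng.poisson(abundance)
    table = pd.DataFrame(counts, index=_site_ids(config), columns=asv_ids)
    table.index.name = "site"

    names = [p for p, _ in phyla]
    weights = np.array([w for _, w in phyla])
    assigned = rng.choice(names, size=n_asvs, p=weights / weights.sum())
    taxonomy = pd.Series(
        [f"{domain};p__{ph};g__{ph}_genus{j % 17 + 1}"
         for j, ph in enumerate(assigned)],
        index=asv_ids, name="lineage",
    )
    return table, taxonomy, truth


def generate_tree(asv_ids: list[str], seed: int) -> str:
    """Random rooted bifurcating tree over ``asv_ids``, as a newick string.

    Built by repeated random joins of subtrees with exponential branch
    lengths; deterministic in ``seed``. Requires at least two leaves.
    """
    if len(asv_ids) < 2:
        raise ValueError("need at least 2 ASV ids for a tree")
    rng = np.random.default_rng(seed)
    subtrees = [f"{a}:{rng.exponential(0.1) + 0.01:.6f}" for a in asv_ids]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        if len(subtrees) == 0:
            subtrees.append(f"({left},{right}):0.0")
        else:
            subtrees.append(f"({left},{right}):{rng.exponential(0.1) + 0.01:.6f}")
    return subtrees[0] + ";"


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """A complete generated dataset plus its planted ground truth."""

    config: SimulationConfig
    sites: pd.DataFrame
    incubation: pd.DataFrame
    enzymes: pd.DataFrame
    asv_bacteria: pd.DataFrame
    asv_fungi: pd.DataFrame
    taxonomy: pd.Series
    tree_bacteria: str
    tree_fungi: str
    truth: dict


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate every study table from one configuration.

    ASV sequencing depth is mildly tilted by the latent diversity factor
    (exp(0.3·diversity)), so observed alpha diversity carries the latent
    diversity signal used in the path model.
    """
    latents = _study_latents(config)
    truth_metab = planted_truth(config)
    depth = np.exp(0.3 * latents["diversity"].to_numpy())
    asv_b, tax_b, part_b = generate_asv_table(config, "bacteria", depth_factors=depth)
    asv_f, tax_f, part_f = generate_asv_table(config, "fungi", depth_factors=depth)
    tree_b = generate_tree(
        list(asv_b.columns), int(_rng(config.seed, _STREAM_TREE_BACTERIA).integers(2**31 - 1))
    )
    tree_f = generate_tree(
        list(asv_f.columns), int(_rng(config.seed, _STREAM_TREE_FUNGI).integers(2**31 - 1))
    )
    betas = dict(DEFAULT_LATENT_BETAS)
    betas[("enzymes", "efficiency")] = config.enzyme_efficiency_beta
    truth = {
        "metabolic": truth_metab,
        "partition_bacteria": part_b,
        "partition_fungi": part_f,
        "latents": latents,
        "path_betas": betas,
    }
    return SyntheticStudy(
        config=config,
        sites=generate_sites(config),
        incubation=generate_incubation(None, config),
        enzymes=generate_enzymes(config),
        asv_bacteria=asv_b,
        asv_fungi=asv_f,
        taxonomy=pd.concat([tax_b, tax_f]),
        tree_bacteria=tree_b,
        tree_fungi=tree_f,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write all study tables as TSV/newick/JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.sites.to_csv(outdir / "sites.tsv", sep="\t")
    study.incubation.to_csv(outdir / "incubation.tsv", sep="\t")
    study.enzymes.to_csv(outdir / "enzymes.tsv", sep="\t")
    study.asv_bacteria.to_csv(outdir / "asv_bacteria.tsv", sep="\t")
    study.asv_fungi.to_csv(outdir / "asv_fungi.tsv", sep="\t")
    study.taxonomy.rename_axis("asv_id").to_csv(outdir / "taxonomy.tsv", sep="\t")
    (outdir / "tree_bacteria.nwk").write_text(study.tree_bacteria + "\n")
    (outdir / "tree_fungi.nwk").write_text(study.tree_fungi + "\n")
    truth = {
        "config": study.config.to_dict(),
        "metabolic": study.truth["metabolic"].reset_index()
        .rename(columns={"index": "site"}).to_dict(orient="list"),
        "partition_bacteria": study.truth["partition_bacteria"],
        "partition_fungi": study.truth["partition_fungi"],
        "path_betas": {f"{a}->{b}": v for (a, b), v in study.truth["path_betas"].items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
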