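# soilcue

Analysis pipeline for **soil microbial metabolic efficiency** and its
drivers, built for riparian-zone soil studies that combine ¹⁸O-water
incubations, enzyme assays and amplicon sequencing. It links four stages
that are usually scattered across ad-hoc spreadsheets and scripts:

1. **Metabolic efficiency** — from raw incubation measurements it derives
   respiration (headspace CO₂ + ideal gas law), growth (¹⁸O incorporation
   into DNA), carbon uptake and **CUE = C_growth/(C_growth+C_respiration)**,
   plus MBC (chloroform-fumigation flush / k_EC), the metabolic quotient
   **qCO₂ = C_respiration/MBC** and turnover time **τ = MBC/C_growth**.
2. **Ecoenzymatic stoichiometry** — the vector model
   Length = √(x²+y²), Angle = degrees(atan2(x, y)) with
   x = (BG+CBH)/(BG+CBH+ACP) and y = (BG+CBH)/(BG+CBH+LAP+NAG);
   Angle > 45° flags P limitation, < 45° N limitation; plus MBC-normalized
   specific activities and a z-score composite enzyme activity index.
3. **Community structure** — alpha diversity (Chao1, Shannon, rooted
   Faith's PD) with zone ANOVA, and Spearman co-occurrence networks
   (|r| > 0.8, p < 0.05) with greedy-modularity modules and Zi/Pi node
   roles (module hubs, connectors, network hubs).
4. **Driver analysis** — permutation random-forest importance (%IncMSE
   with response-permutation p-values), Spearman correlation screens, and
   a recursive path model over PCA composite variables
   (soil → diversity → enzymes → efficiency) with standardized
   coefficients, χ² and RMSEA.

A first-class **synthetic study generator** plants known truths (per-site
CUE/MBC/qCO₂, correlation modules in ASV tables, a latent
enzymes→efficiency path) and back-solves raw measurements from them, so
the entire chain is testable end-to-end with no field data; at zero noise
the pipeline recovers the planted values to floating-point precision.

## Worked example

```python
import soilcue as sc

cfg = sc.SimulationConfig(seed=42)        # 20 sites, zones 2/8/10
study = sc.generate_study(cfg)
eff = sc.process_incubation_table(study.incubation)
print(eff.head(3).round(4))
```

```
      c_respiration  c_growth  c_uptake     cue       mbc    qco2        tau
site
S01          0.3831    0.0988    0.4819  0.2050  200.7865  0.0019  2032.8892
S02          0.2591    0.0704    0.3295  0.2136  156.3588  0.0017  2221.3479
S03          0.5162    0.2619    0.7781  0.3366  389.5386  0.0013  1487.2297
```

Each row is one site: carbon fluxes in µg C g⁻¹ dry soil h⁻¹, MBC in
µg C g⁻¹, qCO₂ in µg CO₂-C (µg MBC)⁻¹ h⁻¹, τ in hours. CUE near 0.2 means
only ~20 % of absorbed carbon goes to biomass. Testing the downstream
gradient:

```python
res = sc.zone_anova(eff["cue"], study.sites["zone"])
print(f"F={res['F']:.2f} p={res['p']:.2e}", res["means"])
# F=42.59 p=2.39e-07 {'upstream': 0.209, 'midstream': 0.344, 'downstream': 0.488}
```

CUE rises significantly downstream, and the enzyme vector model classifies
the sites as P-limited (Angle ≈ 47–48°):

```python
print(sc.enzymes.vector_table(study.enzymes).head(3).round(3))
#           x      y  length   angle limitation_class
# site
# S01   0.537  0.506   0.737  46.722        P-limited
```

The same analyses run from the shell; `run-all` chains every stage from
one config:

```bash
soilcue simulate --outdir data --seed 42
soilcue cue --incubation data/incubation.tsv --out efficiency.tsv
soilcue network --table data/asv_bacteria.tsv --metadata data/sites.tsv --out net/
soilcue run-all --outdir results --seed 42
```

All interchange is plain TSV (sites as rows), newick trees and JSON model
objects, so every stage output is diffable.

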