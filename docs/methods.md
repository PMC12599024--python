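# Methods

## The model and its refinement

The starting network is the *E. coli* K-12 MG1655 core reconstruction
(BIGG id `e_coli_core`, 72 metabolites × 95 reactions), bundled as a JSON
fixture so no download is needed. The fixture was exported from the core-model
copy distributed with COBRApy; its biomass reaction id is aligned to BIGG's
current `BIOMASS_Ecoli_core_w_GAM` and its provenance is recorded in the
fixture's `notes` block (the upstream BIGG snapshot date is not recorded by
the source — the one piece of provenance we cannot supply).

The M4-lineage strain edit set (`strain_editor.builtin_m4_edits`) encodes the
engineered genotype as network surgery:

| edit | reason |
| --- | --- |
| add `EX_glyc_e`, `GLYCt`, `GLYK`, `G3PD2` | glycerol assimilation via GlpF/GlpK/GlpD-type route; BIGG-standard stoichiometries (GLYK: glyc_c + atp_c → glyc3p_c + adp_c + h_c; G3PD2 NADP-linked) |
| add `ALDD2x` (acald + H₂O + NAD → ac + 2H + NADH) | with `ACKr`/`PTAr` deleted the core network has **no** acetate-producing route, yet the strains secrete acetate and the published flux panel reports ALDD2x; it is the only consistent acetate source |
| remove `EX_glc__D_e` | no glucose in the medium |
| remove `ACKr`, `PTAr`, `SUCDi` | the Δ*ackA-pta* and Δ*sdhA* knockouts |
| remove `PPC`; make `PPCK` reversible | anaplerosis runs through overexpressed Pck in the carboxylating, ATP-producing direction (PEP + CO₂ + ADP → OAA + ATP). With PPC present, parsimonious FBA routes all carboxylation through PPC and PPCK carries zero flux in every scenario, contradicting the reported nonzero Pck fluxes and the reported strictly positive PPCK flux-variability minimum in the parental strain. The published panel lists PPCK under ATP-producing reactions, which fixes the direction. |
| make `MALt2_2` reversible | the core malate/H⁺ symporter is uptake-only; the engineered strains export L-malate, and malate-secreting scenarios are LP-infeasible without this edit |

Removals are true deletions (a knockout-by-bounds mode exists for sensitivity
checks). All additions are elementally balanced; the glyoxylate-shunt
reactions stay present with default bounds, since the Δ*iclR* derepression
enters through the measured rates, not the topology. All three strains share
the structural edit set; they differ only via their measured exchange-rate
constraints.

## From measurements to constraints

Specific rates over a sampling interval (t₁, t₂):

    q_i = 1000 (C_i(t₂) − C_i(t₁)) / (MW_i (t₂−t₁) X̄),   μ = ΔX / (Δt X̄)

with X̄ the arithmetic mean of the endpoint biomass (a log-mean option is
provided; for the 24 h intervals used here the choice moves rates by a few
percent and is absorbed by the normalization). All rates are then scaled so
glycerol uptake equals −20 mmol/gCDW·h, which preserves every flux ratio.

Carbon closure counts 3 C per glycerol, 4 per L-malate/succinate, 2 per
acetate, and a biomass carbon coefficient computed from the model's own
biomass stoichiometry (42.56 mmol C/gCDW for the bundled core — within the
40–45 band expected for *E. coli*), rather than a literature constant; this
keeps the closure self-consistent with the network the fluxes constrain. The
compensating CO₂ flux is c_in − c_out (negative = net uptake) and the CO₂
exchange is **fixed to that computed value**, not to the published rounded
value: with all other carbon exchanges fixed, carbon must balance exactly
through the stoichiometry, and fixing the published value (which embeds a
slightly different biomass-carbon coefficient) makes the optimized scenario
infeasible. The published values are recovered within 0.2 mmol/gCDW·h.

O₂ is left free by default and treated as a model prediction: dissolved
oxygen was a controlled setpoint in the experiments, not a measured specific
rate. A `fix_o2` mode exists for sensitivity analysis, as does the ATPM
(maintenance ATP) bound, left at the fixture default of 8.39 mmol/gCDW·h.

## pFBA and FVA

FBA/pFBA/FVA run on scipy's HiGHS solver behind a one-function LP contract
(feasibility tolerance 1e-9, comparison tolerance 1e-6). pFBA splits
v = p − q (p, q ≥ 0, coupled by v − p + q = 0 so fixed negative bounds
survive) and minimizes Σ(p+q); with an objective present it is first fixed at
its FBA optimum as an *equality* — the scenario fluxes are measurements, so
no optimality slack is implied. In the fully constrained scenarios there is
nothing left to maximize (biomass is fixed), and Σ|v| is minimized directly;
this interpretation of "parsimonious FBA on fixed measured fluxes" is the one
that reproduces the published panel.

FVA reports per-reaction (min, max) over the region with objective ≥
fraction × z*; the optional `pfba_factor` additionally caps Σ|v| at that
multiple of its minimum. The published flux-range statements (PPCK range
1.27–3.48 in the parental strain, width 0 in Pck-overexpressing strains) are
statements about the parsimonious face: plain FVA reproduces the 1.27 lower
end but gives wide upper ends and non-zero widths everywhere. At the
parsimonious face we obtain [1.27, 4.48] for the parental strain (upper end
~1 above the published value — a residual discrepancy we note but cannot
close) and exactly zero width in all four Pck strains.

Alternate optima: the parsimonious solution can be degenerate, and a handful
of internal fluxes (notably PYK vs the PPCK/MDH/malic-enzyme cycle, and the
PDH/NADTRHD split in the parental column) depend on the vertex the solver
returns. Tests and the acceptance report therefore compare the reaction
fluxes the study itself highlights. Equivalence with COBRApy on identical
inputs (objective, panel fluxes, FVA ranges, total |flux|) is asserted to
1e-4 in the test suite.

## Factorial screening statistics

2³ factorial plus 3 center replicates (11 runs). Effects are factorial
contrasts; the error term is the pure-error variance of the center replicates
only (df = 2), not pooled higher-order interactions — the standard choice for
an unreplicated screening factorial, and the third-order interaction is
estimated and reported rather than pooled. Var(effect) = 4s²/N (N = 8),
significance at the two-sided 95% t cut. Under the null this t-statistic is
exactly t(2)-distributed, which the Monte-Carlo calibration confirms
(type-I rate 0.05 ± 0.02 over 500 simulated designs). Curvature
(center mean − factorial mean) is reported, not formally tested. Ties in the
Pareto ordering break stably by term name.

The published per-run responses are not printed, so the screening module is
validated on properties (exact recovery of planted noiseless effects,
calibrated type-I error) plus the qualitative finding: on designs with the
planted crude-glycerol pattern (biomass +, glycerol +, DO null), DO ranks
last among main effects and is flagged non-significant at the nominal rate.

## Synthetic fermentations

`gen_fermentation` draws logistic biomass X(t) (closed form, as is its time
integral), routes glycerol to growth (ΔX / Y_xs) and to a Luedeking–Piret
product stream (α ΔX + β ∫X dt), splits the product stream across species by
their yield coefficients, floors glycerol at zero by clipping cumulative
consumption at the initial pool, and adds independent Gaussian observation
noise (clipped at zero) per sampled concentration. Yield sets are validated
on a carbon basis at construction (product carbon per g glycerol ≤ glycerol
carbon content), so noiseless courses conserve carbon at every time point.

What the generator emulates: the shapes of the study's batch courses
(~12.5 g/L glycerol exhausted between 24 and 72 h, L-malate peaking at
8–11 g/L, logistic biomass from OD₅₇₀ 0.1 or 1.1 inocula) with observation
noise of the magnitude of the published ±SD bars (σ = 0.25 g/L). What it does
not: mechanistic pH/DO dynamics (the pH channel is cosmetic), substrate
inhibition, lag phases, or the continued slow biomass drift after substrate
exhaustion. Passing round-trip tests therefore shows the estimators are
algebraically correct on data of the assumed structure, not that the study's
kinetics are Luedeking–Piret.

Default presets (`flask_pure`, `bioreactor_pure`, `bioreactor_crude`) use
12.5 g/L initial glycerol, inocula of 0.033/0.363 g CDW/L, μ = 0.25–0.30 1/h,
and malate yields of 0.72–0.80 g/g chosen to land the published product
bands; they are fixed study conditions, not fitting knobs.

## Quantitation conventions

Molecular weights: glycerol 92.09, L-malate 134.09, succinate 118.09, acetate
60.05 g/mol. OD₅₇₀ → CDW at 0.33 g/L per unit; photon-flux conversion factor
0.22 W·m⁻² per µmol·m⁻²·s⁻¹, valid only in [0.20, 0.23]. Headspace H₂
assumes ideal-gas behaviour at 303.15 K with no water-vapour correction.
The "C2–C4 consumed" denominator of the H₂ yield includes glycerol. The
volumetric productivity is exposed for both candidate time bases (92 h and
96 h appear in the source data's sampling grid); 92 h is the default.
Consumption-table totals are computed from the printed per-species initial
and final concentrations; summing the printed columns gives a total consumed
of 36.46 mM, 0.01 below the published total row (a rounding residue of the
original table). Report formatting uses 2 decimals for concentrations and
fluxes and 1 for percentages; underlying TSVs keep full precision.

## Known limitations

* The parental-column NADH panel cannot be reproduced: the published
  NADTRHD/PDH values for that column are LP-infeasible under the column's own
  printed constraints (and that column's printed ALDD2x contradicts its fixed
  acetate rate), so we report the parsimonious solution of the stated
  constraints instead (NADTRHD 42.5 vs 51.9 published).
* SBML support is read-only and covers the Level 3 + FBC flux-bounds dialect.
* No gene–protein–reaction rules, loopless FBA, or dynamic FBA.
* Problem sizes: the core network (95 reactions) solves in milliseconds; the
  Monte-Carlo calibration uses 500 designs; vertex-enumeration oracles are
  restricted to ≤6-reaction toys.
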