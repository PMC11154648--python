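# Methods

This note documents the models, the parameter choices that matter, what
the synthetic world does and does not emulate, and the numerical and
design decisions a maintainer should know about.

## Food-web bioaccumulation model

The contaminant (SCCPs, treated as a single compound) is propagated from
dissolved water and sediment into tissue with a steady-state kinetic mass
balance per species; all species are solved simultaneously as one linear
system, so cyclic predator–prey structures are legal whenever the system
is nonsingular.  At build time a web must be either acyclic or diagonally
dominant, otherwise construction fails naming a cycle.

Rate constants follow the standard allometric kinetic formulation:

- gill uptake efficiency `E_W = 1/(1.85 + 155/Kow)`, ventilation
  `G_V = 1400·BW^0.65 / DO` (DO = 8 mg·L⁻¹), `k1 = E_W·G_V/BW`
  (L·kg⁻¹·d⁻¹), overridable per species;
- elimination via lipid partitioning, `k2 = k1/(L·Kow)`;
- dietary assimilation `E_D = 1/(3·10⁻⁷·Kow + 2)`, feeding rate
  `G_D = 0.022·BW^0.85·e^(0.06T)` kg·d⁻¹, `kD = E_D·G_D/BW`;
- egestion as a fixed fraction of dietary uptake, `kE = 0.125·kD`
  (`egestion_ratio`, per species);
- growth dilution `kG` and metabolism `kM` given per species.

Base compartments are at equilibrium with the abiotic environment:
phytoplankton and zooplankton at `C = L·Kow·C_wd` with sorbing-phase
fractions 0.005 and 0.008, and sediment pore water at
`C_pw = C_sed/(f_oc·K_oc)` with `K_oc = 0.35·Kow`.  The plankton lipid
fractions are deliberately below the 1–2% often quoted for biomass: they
represent the effective sorbing phase and keep planktivorous fish below
the benthos, consistent with the field observation that filter-feeding
bivalves carry the highest chlorinated-paraffin burdens.

One representative `logKow = 6.2` is used (mid-range of the 4.01–8.67
span reported for commercial SCCP mixtures); homolog-specific chemistry is
out of scope.  Temperature enters only through the feeding allometry.

**Species presets.**  Eight taxa — hairtail, large and small yellow
croaker, sea bass, pomfret (fish); prawn, clam, oyster (benthic) — with an
acyclic predation matrix (hairtail, croakers and sea bass eating small
yellow croaker and prawn).  Benthic taxa respire 50–90% pore water and
ingest 40–50% sediment/detritus.  Fish carry `kM = 0.02 d⁻¹` and
invertebrates `0.002 d⁻¹`: chlorinated paraffins are biotransformed much
faster in fish than in bivalves, and without this contrast a piscivorous
chain would biomagnify above the benthos, contrary to observation.  The
steady-state choice itself (rather than a time-resolved model) reflects
multi-year environmental loading against biological response times of
weeks to months.

## Synthetic world

The generator emulates the statistical structure the analysis needs, not
any real geography:

- **Contaminant field**: per coastal region, a lognormal median
  (geometric SD 2.5 across regions, geometric mean 1 ng·L⁻¹) with cells
  decaying offshore by a factor 0.7 per rank and multiplicative lognormal
  cell noise (GSD 1.8).  Sediment sits a factor 3 above water-column
  equilibrium (`sediment_enrichment`), representing the historical
  integration of loading by sediments.
- **Provinces**: 31 provinces, 11 coastal, placed in a 2500 km box with
  the coastal ones along one edge; Euclidean distances (only relative
  deterrence matters to the gravity and LP models).  Populations are
  lognormal around 45 M (GSD 1.8).
- **Consumption**: per-capita intake lognormal around 15 g·day⁻¹, doubled
  in coastal provinces (coastal seafood intake rates run 1.5–2.6× the
  national mean), split over species by jittered national shares in which
  clams (0.32) and oysters (0.26) dominate; rates are rescaled once so
  national demand is exactly 11,000 kt·yr⁻¹ against a supply of
  13,742.9 kt·yr⁻¹ — the system is supply-surplus by construction, and
  demand ≡ rate × population × 365 × 10⁻⁹ holds to 1e-9 relative.
- **Observed flows**: gravity flows at `β = 1` perturbed by multiplicative
  lognormal noise (default GSD 1.3) and IPF-rebalanced to the margins, for
  deterrence-exponent recovery experiments.
- **Measurements**: tissue concentrations times lognormal noise (GSD 2),
  for the model-evaluation metrics.

All noise is multiplicative lognormal, matching the strictly positive,
right-skewed uncertainty of environmental concentration data.  Randomness
flows from one root seed through named per-stage substreams, so stages
rerun individually reproduce the full-pipeline outputs.

What the generator does **not** emulate: real Chinese geography, emission
inventories or atmospheric transport (environmental concentrations are
inputs here), seasonal dynamics, age- or sex-stratified intake,
international trade, and any correlation between province wealth and
consumption.  Tests passing on this world show the machinery is correct
and the qualitative structure (coastal excess, benthic excess,
trade-embodied redistribution, optimization head-room) emerges under the
stated conditions — not that the numeric outputs transfer to real data.

## Gravity model

Doubly constrained (production- and attraction-constrained) variant of
the Leontief–Strout family, since both provincial supply and demand are
fixed.  Power-law deterrence `d^-β` with `β = 1` by default; the
exponential form is retained as an option.  Intra-provincial distance is
`d_ii = ½·min_j d_ij` (configurable): intercapital distances leave the
diagonal undefined, yet local consumption clearly exists.  The national
surplus is absorbed by a virtual slack destination with uniform (no
distance preference) weight.  IPF runs to a margin tolerance of 1e-10
(max 5000 iterations), errors on structural infeasibility (a demand node
reachable from no positive-supply origin), and is exactly invariant to a
global rescaling of distances under the power form.  `β` is recovered
from observed flows by bounded 1-D least squares on log flows over
positive entries; at least three distinct distances are required for
identifiability.

## Exposure layer

`EDI = C·I/W` with `W = 63 kg` (standard adult consumer, configurable).
EDI is reported in ng·kg⁻¹·day⁻¹ throughout.  Consumed concentration is
the origin-share-weighted mix; attribution over origins is exact by
construction (checked to 1e-12).  Under a flow scenario, intake is scaled
by the delivered fraction of demand, so the no-trade counterfactual
exposes a province only to what its own fishery supplies (inland
provinces: nothing).  Scenario differencing reports `EDI_DF = EDI_T −
EDI_NT` with the relative change divided by the **trade-scenario** EDI —
the published provincial pairs are mutually consistent only under that
denominator, so it is fixed here and documented.  The trade-embodied
share is population-weighted (a consumer-weighted alternative would need
consumer counts the data do not provide).  Uncertainty intervals are
multiplicative, `(EDI/uf, EDI·uf)` with `uf = 10` by default, matching
the ×/÷10 pattern of published EDI intervals; a seeded lognormal
Monte-Carlo interval is available as an alternative.  Evaluation metrics:
`MB = mean(model−obs)`, `NMB = Σ(model−obs)/Σobs·100`, R² of the
least-squares fit of model on observation, and inclusive factor-k
coverage for k ∈ {2, 5}.

## Optimizer

Per-species transportation LP: minimize
`w_cost·Σc_ij T_ij / C₀ + w_health·Σh_ij T_ij / H₀` subject to row sums
≤ supply, column sums = demand, `T ≥ 0`, where `c_ij` is unit cost ×
distance and `h_ij` the origin tissue concentration — `Σh·T` is then
exactly proportional to the national mass of contaminant delivered and
eaten, keeping the health objective linear.  Both terms are normalized by
their gravity-baseline values `C₀, H₀`, making the weights dimensionless
(at the baseline each term equals 1).  The weighted sum is the primary
scalarization; an ε-constraint mode (minimize cost s.t. `Σh·T ≤ ε`) is
provided since only the existence of separate cost and risk weighting is
known.  One LP per species (no cross-species substitution).  Solved with
the HiGHS dual simplex, which returns an optimal vertex deterministically;
a brute-force vertex enumeration (all candidate bases of the balanced
transportation polytope, batched linear solves) serves as the optimality
oracle for instances up to 5×5.  Unit transport cost is a single scalar
(default 1 yuan·kt⁻¹·km⁻¹); only its ratio to the health weight matters.

## Numerical choices and degenerate inputs

- Steady-state linear solves require a relative residual < 1e-10 and
  non-negative concentrations; singular systems raise with the offending
  cycle.
- IPF margin errors are measured relative to the largest margin; zero
  rows/columns with zero margins are tolerated, with positive margins they
  raise infeasibility.
- A 1×1 world gets `d_intra = 1` (the deterrence weight cancels in IPF).
- Zero-demand destinations get zero share columns, flagged in
  `shares.attrs["zero_demand"]`; zero-current-EDI provinces get NaN
  relative changes, flagged rather than silently dropped.
- LP ties are broken deterministically by the solver's fixed pivoting;
  flows, manifests and all CSVs are byte-reproducible under a fixed seed.
- Problem sizes in the test and acceptance runs (31-province world,
  200 random IPF instances, 50 recovery worlds, LP oracles to 5×5) were
  chosen so the full check executes in well under a minute each while
  still covering the dimensionalities the pipeline uses.

## Known limitations

Single representative logKow; no temperature correction of partitioning;
steady-state only; no age-stratified intake; no international trade; the
health objective prices exposure only through delivered contaminant mass,
not toxicological dose-response; and the synthetic world's parametric
realism is qualitative, as described above.
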