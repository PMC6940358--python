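# Methods

## Scope and model

`secrecon` treats protein secretion as two coupled layers:

1. **A scalar bioenergetic cost** per protein molecule, in ATP equivalents
   (GTP hydrolysis counted 1:1 with ATP). This is a bookkeeping model, not a
   kinetic one: it sums the nucleotide hydrolysis events of translation, ER
   import and vesicular transport, assuming no proofreading and no
   misfolding/retranslation cycles.
2. **A stoichiometric pathway** — the same events written as reactions over
   currency metabolites and protein intermediates — which can be spliced
   into a genome-scale metabolic model so that linear programming sees the
   full material demand (amino acids, redox equivalents, glycan precursors)
   of making the product, in competition with biomass formation.

The two layers are kept numerically consistent by construction: the summed
ATP+GTP consumption of a generated pathway at unit flux equals the cost
engine's raw total to machine precision, and this is asserted in the test
suite over hundreds of random feature vectors.

## Cost parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| translation cost | 4 per residue | ATP eq. | 2L for tRNA charging (ATP→AMP), 2 for initiation+termination, L−1 peptide-bond GTPs, L−1 ribosomal translocation GTPs |
| signal-peptide degradation | 22 | ATP | mean signal peptide is ~22 residues; one ATP per peptide bond hydrolyzed |
| translocon activation | 2 | GTP | SRP/SR GTPase cycle on ER targeting |
| BiP-assisted import | 1 per 40 residues | GTP | one BiP nucleotide cycle per ~40 residues threaded |
| COPII vesicle | 192 | GTP | coat + Rab GTPases per ER→Golgi vesicle |
| secretory vesicle | 44 | GTP | clathrin-coated carrier, Golgi→surface |
| vesicle diameters | 50 / 100 | nm | COPII / secretory; sets the per-vesicle cargo capacity |
| cargo occupancy | 0.7 | — | fraction of vesicle volume usable by cargo |
| specific volume | 0.00121 | nm³/Da | globular-protein approximation V_P = MW × 0.00121 |

Vesicle costs are shared continuously over the fractional number of cargo
molecules per vesicle (no integer flooring): each leg costs
`gtp_per_vesicle · V_P / (V_vesicle · 0.7)`. The translocation term is kept
as an exact real; only the final per-protein total is rounded, **half-up**,
to an integer. A `rounding_sensitivity` helper reports the half-even, floor
and ceiling alternatives so users can see which totals are within ±1 of the
convention choice.

Conventions worth making explicit:

- **Multimers.** Length and MW of an assembled product (an IgG tetramer, a
  receptor-Fc dimer) refer to the assembled molecule, and the
  signal-peptide and translocon-activation terms are charged once per
  molecule, not per chain. This single-event convention is what the
  per-protein integer totals in the test suite assume.
- **PTMs carry no ATP line-item.** Disulfide bonds consume oxidizing
  equivalents, glycosylation consumes core-glycan precursor units, GPI
  attachment consumes one precursor — all as metabolite stoichiometry in
  the pathway layer, not as ATP in the scalar cost. The scalar cost of a
  secreted protein is therefore a function of L, MW and the signal-peptide
  flag only.
- **Membrane proteins** (TMD > 0, GPI-anchored, or membrane-located) incur
  the same two vesicle legs as secreted proteins and are routed to a
  membrane compartment by the terminal demand.
- **Basal cost** is the translation-only 4L, the comparator used when
  asking how much the secretory machinery adds beyond amino-acid and glycan
  costs (glycan precursor costs are identical in both accountings and
  cancel).

## Pathway templates

Templates are model-agnostic: stoichiometry is written over species ids and
a `CurrencyMap` binds currency/precursor names to the ids of the host model
at expansion time. Protein intermediates are `<id>_<stage>_<compartment>`
over compartments c/r/g/m/e; every processing reaction converts exactly one
unit of the upstream species to one unit of the downstream species, so the
protein moiety is conserved and pathway flux is well-defined. Reaction
emission is gated on the PSIM flags — a signal-peptide-only protein yields
translation + translocation + SP degradation + COPII + secretory vesicle +
demand; a cytosolic construct yields translation + demand. Core O-glycan
attachment is emitted in the ER-lumen stage of the chain before COPII
transport — a lumping choice (O-glycosylation initiates in the Golgi) that
does not affect mass or energy balances because the precursor is a single
pseudo-metabolite. ERAD/proteasomal templates are generated only on request
and are zero-bounded, since no per-protein misfolding fraction is modeled.

## Constraint-based analyses

- FBA uses cobrapy with its GLPK backend; objective values are compared at
  1e-6 absolute in tests, and the test suite cross-checks optima against an
  independent `scipy.optimize.linprog` (HiGHS) oracle built directly from
  the stoichiometric matrix.
- Growth-at-fixed-productivity converts q_p (pg/cell/day) to a demand flux
  via `1000·q_p/(DW·MW·24)` and pins the demand to it. Infeasibility is
  diagnosed as product-limited (requested flux above the feasible product
  maximum) or media-limited.
- Pareto frontiers sweep the product demand over an even grid (default 50
  points) from 0 to its single-objective maximum, maximizing growth at each
  point; solver jitter is clamped so the non-increasing invariant holds
  exactly. The frontier endpoints are therefore the two single-objective
  optima by construction.
- The trade-off statistic Δ compares frontier arc lengths after normalizing
  both axes by the wild-type curve's maxima (a shared normalization so the
  two curves are commensurable): Δ = (L_KO − L_WT)/L_WT, with arc length
  the sum of Euclidean segment lengths. The normalization convention is a
  declared design choice, isolated behind `tradeoff_delta` and unit-tested
  (identical curves give 0; a uniformly ×s scaled curve gives exactly s−1).
- Competitor coupling (e.g. a highly expressed selection marker) is the LP
  equality row v_competitor = ratio · v_product with
  ratio = RPKM_competitor / (2·(RPKM_light + RPKM_heavy)) for a two-chain
  product; the equality form holds at every point of a Pareto sweep, and a
  fixed-bound form is available through ordinary constraints. Knockout
  simulation compares the coupled product maximum with the
  competitor-zeroed maximum; by LP feasible-set inclusion the knockout
  optimum can never be lower.
- Biomass rescaling for recombinant lines multiplies the biomass reaction's
  amino-acid coefficients by a factor (0.8 when the product is 20 % of cell
  protein), leaving all other coefficients untouched.
- The feature-productivity regression is ordinary least squares with an
  intercept (statsmodels), with explicit rejection of constant and
  collinear predictor columns.

## Culture rates

μ, q_p and exchange rates are per-cell derivatives of VCD, titer and
concentration. The default estimators are regressions over a user-declared
exponential window: ln(VCD) on time for μ, and titer (or concentration) on
trapezoidal cumulative cell-hours for q_p and v_x — these reduce to the
pointwise derivative definitions for exact exponential growth and are more
robust to noise. Pointwise (central-difference, one-sided at endpoints)
variants are provided. q_p is reported per day (the unit productivity is
quoted in practice) with the per-hour conversion explicit; consumption is
negative and production positive. Unit conversions use a fixed cell dry
weight of 456.3 pg/cell. Window selection is a required user input: real
cultures leave the exponential regime, and no automatic changepoint
detection is attempted.

## Statistics

Spearman correlation (average-rank ties, two-sided p) via scipy after a
1-RPKM low-expression cutoff; ids are matched exactly with no ortholog
mapping. Feature enrichment uses the upper-tail hypergeometric p-value per
binary feature; raw p-values are the externally comparable quantity and
Benjamini–Hochberg adjusted values are reported alongside. The
ribosomal-load ranking reports cumulative expression shares of secreted
genes sorted descending.

## Synthetic data

The generators define the test conditions and are first-class, seeded code:

- **Toy host model**: glucose uptake ≤ 5 with 2 ATP per glucose, aggregate
  amino-acid uptake ≤ 3 (or 20 individual pools), nucleotide recycling
  (NDK/ADK), free stubs for core N-/O-glycan, GPI and oxidizing-equivalent
  precursors, and a biomass reaction consuming 1 amino acid + 1 ATP. The
  unconstrained biomass optimum has a closed form (here 3) and is asserted
  at build time. The precursor stubs are energy-neutral by default, so the
  pathway's ATP accounting matches the scalar cost engine exactly; binding
  to a real host model may map them to dolichol/FAD/O2 chemistry instead.
- **Synthetic PSIM**: lengths log-uniform in [50, 3000]; MW ≈ 110 Da/residue
  with 5 % lognormal jitter clipped to [95, 135]; sparse Poisson PTM counts
  (disulfides mean 2, N-glycans 1.2, O-glycans 0.6, TMD 0.4, GPI 5 %);
  80 % of entries carry a signal peptide with a location drawn consistently.
- **Synthetic cultures**: exponential VCD at μ = 0.03/h from 3×10⁵
  cells/mL; titer = q_p (default 16 pg/cell/day) times trapezoidal
  cumulative cell-hours on the sampling grid; metabolite concentrations
  linear in cumulative biomass at configured mmol/gDW/h rates;
  multiplicative lognormal noise (σ default 0.05) on every observed series.
  Using the grid-trapezoid integral (rather than the continuous exponential
  integral) makes noiseless estimator recovery exact by construction; the
  residual discretization question is exercised separately by the noisy
  recovery tests.
- **Synthetic expression**: a Gaussian copula against the normal scores of
  cost ranks, with the Pearson parameter calibrated as
  ρ = 2·sin(π·ρ_s/6) to hit a target Spearman ρ_s, mapped through a
  lognormal marginal to positive RPKM.

What passing tests on these generators do **not** show: real secretomes
have correlated features (large proteins carry more glycans), real cultures
have death phases and fed-batch volume changes, and real expression tables
carry mapping ambiguity — none of which is emulated.

## Problem sizes and numerics

The test suite and the acceptance script use deliberately small problems —
toy models with ~20 reactions, Pareto grids of 10–50 points, 200-entry
synthetic secretomes, 5000-gene expression tables — chosen so every check
is an exact or tightly-toleranced comparison rather than a statistical
impression. LP objective comparisons use 1e-6 absolute; cross-module energy
bookkeeping 1e-9 absolute; rank statistics 1e-12 against brute-force
oracles.

## Known limitations

- One published per-protein total (erythropoietin) is not reproducible from
  the stated cost formulas, which give ≈801 ATP for its feature row; the
  package reports the formula value and the discrepancy is flagged in the
  tests rather than reconciled.
- No machinery capacity constraints (translocon counts, chaperone
  abundances), no glycoform heterogeneity (single core N-/O-glycans only),
  no unfolded-protein-response coupling, no per-chain assembly kinetics for
  multimers.
- Signal-peptide degradation is a standalone reaction, not coupled to the
  proteasome subsystem's machinery.
- Gene-protein-reaction rules are not evaluated; `component_genes` style
  annotations are out of scope.
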