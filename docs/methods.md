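# Methods

This note documents the models implemented in `lipoflux`, the parameters
that matter, the synthetic data the tests run on, and the design decisions
taken where more than one reasonable choice existed. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Constraint-based model construction

The core object is a metabolic network in the schema of genome-scale
reconstructions such as Recon3D: metabolites with compartments, reactions
with stoichiometry (columns of S), flux bounds in mmol·gDW⁻¹·h⁻¹,
subsystem labels, boolean gene–protein–reaction (GPR) rules, and optional
per-reaction annotations — enzyme turnover numbers kcat (s⁻¹) and standard
transformed Gibbs free energies ΔG′° (kJ·mol⁻¹). Exchange reactions are
written `1 m ↔ ∅` with coefficient −1 (COBRA community convention), so
negative exchange flux is uptake and medium composition reduces to
exchange lower bounds.

Three bound-tightening operations specialize a network to a condition and
replicate. All are pure (they return a new network), idempotent, and never
widen a bound — properties the test suite checks on randomized networks.

**Enzyme capacity.** The reaction-level enzyme abundance *a* is aggregated
from transcript abundances over the GPR: AND → minimum (an enzyme complex
is limited by its scarcest subunit), OR → sum (isoenzymes add), missing
genes contribute 0, and an empty rule yields no information rather than
zero. The capacity bound is |v| ≤ σ·kcat·a, applied to the upper bound
and, for reversible reactions, symmetrically to the lower bound. The
scale σ (`capacity_scale`, default 1) absorbs the unknown
transcript-to-enzyme proportionality; enzyme abundance is taken directly
proportional to normalized transcript abundance because expression data
are the only quantitative input available at this stage. Reactions
without kcat or without a GPR are left untouched: annotation coverage in
resources like BRENDA is partial, and treating a missing kcat as zero
would silence most of the network.

**Thermodynamic directionality.** A reaction with ΔG′° < −τ is made
forward-only (lb ← max(lb, 0)); ΔG′° > +τ reverse-only; values inside the
±τ dead band leave bounds unchanged. The dead band (`thermo_threshold`,
default τ = 10 kJ·mol⁻¹) prevents over-constraining near-equilibrium
reactions whose in-vivo direction depends on metabolite concentrations we
do not model. A directionality that contradicts pre-existing bounds
collapses the reaction to [0, 0] with a warning rather than producing an
infeasible bound pair. Only standard transformed energies are used; no
concentration adjustment is attempted.

**Medium.** Exchange reactions of metabolites present in the medium table
get lb = −(max uptake); all other exchanges get lb = 0; secretion (upper
bounds) is never restricted. Serum-like supplements are represented
simply as additional medium entries — the shipped example media are toys,
not a literal culture-medium formulation.

## FBA, pFBA and the replicate flux matrix

FBA maximizes the biomass objective c·v subject to S·v = 0 and bounds; the
LP is solved with HiGHS (via `scipy.optimize.linprog`) with feasibility
tolerance 1e−9 and optimality tolerance 1e−7, deterministic settings. A
bound pair with lb > ub reports `infeasible` status instead of raising.

Because the FBA optimum is generally degenerate, per-replicate point
estimates come from parsimonious FBA: split v = p − n with p, n ≥ 0,
constrain biomass to ≥ fraction × FBA optimum (default fraction 1.0,
within 1e−9) and minimize Σ(p + n). Per-reaction inequality rows preserve
original intervals that exclude zero. pFBA is the standard way to obtain
one well-defined flux vector per model, which the downstream t-tests
require; whether an alternative scheme (sampling, FVA midpoints) would
change the differential calls is untested and out of scope. Residual ties
in Σ|v| beyond the pFBA objective are resolved by the solver's
deterministic pivoting; outputs are reproducible for fixed inputs.

`replicate_flux_matrix` applies medium → thermodynamic directions →
per-replicate capacity bounds, then pFBA, and assembles a reaction ×
(condition, replicate) matrix, condition-major in input order.
Non-optimal replicates are excluded from the matrix and listed in a side
report.

## Differential statistics and enrichment

Per feature (reaction, or metabolite production turnover), groups are
compared with a pooled-variance two-tailed Student's t (df = n₁ + n₂ − 2).
Zero pooled variance — common on deterministic toy fixtures — resolves
deterministically: equal means give p = 1, unequal means p = 0, flagged
`degenerate_variance`. Fold changes are computed on magnitudes with a
pseudo-count, log2((|m_t| + ε)/(|m_c| + ε)), ε default 1e−6, because
fluxes can be zero or negative; a `sign_flip` flag records means of
opposite sign. Benjamini–Hochberg adjustment is the standard step-up,
applied separately within three families — reactions, metabolites,
subsystems — since the three tables answer different questions.

The metabolite-level score is the production turnover
Σ_j max(S_mj·v_j, 0), the total production flux of metabolite m (equal to
total consumption at steady state). This is this package's normative
definition of "predicted metabolite change"; other mappings from fluxes
to metabolite scores exist, and numeric agreement with analyses that used
an unspecified mapping is not claimed.

Subsystem enrichment takes the reactions with p_adj < α (default 0.05),
forms the 2×2 table of significance × subsystem membership over the whole
network as background, and computes a one-sided (greater) Fisher's exact
p (two-sided available); subsystem p-values are BH-adjusted. One-sided
"greater" is the natural alternative for enrichment; the 2×2 counts always
sum to the number of background reactions.

## Chromatin integration

Coordinates are 0-based half-open throughout (BED convention; GTF input
is converted on read). Genes are classified Up/Down/Unchanged with
inclusive thresholds |log2FC| ≥ 0.58 (fold change 1.5) and p ≤ 0.05.
DAR region classes, strand-aware per gene: promoter = 3 kb upstream of
the TSS, gene body = the gene span, downstream = 3 kb past the gene end
(the downstream extent is this package's choice, configurable), distal =
no qualifying gene; within one gene the precedence is promoter >
gene_body > downstream; overlap means ≥ 1 shared base. A DAR may link to
several genes — no nearest-gene restriction is imposed.

The stratified association table reports, for each gene class × region ×
DAR direction, the percentage of genes in the class with at least one
such DAR (each gene counted once per cell; Up and Down DARs tabulated
independently; empty classes give missing values). Only the three
gene-linked regions appear in the table: under this region model a distal
DAR is linked to no gene, so a per-class distal percentage would be
identically zero. The distal class is still produced by per-DAR
annotation.

## Radial profiling and PNPR

Each cytoplasmic pixel gets a normalized radial coordinate
d = d_nuc/(d_nuc + d_cell), where d_nuc and d_cell are Euclidean
distance transforms to the nucleus edge and the cell edge; this stays
meaningful for non-circular cells. Intensities are binned into 20
equal-width bins over [0, 1] (d = 1 joins the last bin; bin counts
partition the cytoplasm exactly). PNPR is the count-weighted mean signal
over the inner band (d < 0.25) divided by the outer band (d ≥ 0.75) —
the band edges are this package's convention, configurable — and is
invariant to global intensity scaling. Conditions are compared with a
two-tailed Welch t-test on per-cell PNPR values; fold change is the ratio
of group means.

Segmentation of the bundled synthetic images uses Otsu thresholds
(nucleus from the DNA channel, cell from the signal channel with closing
and hole-filling), largest connected component, and enforces nucleus ⊆
cell. Ground-truth masks can always be supplied to bypass segmentation.
Otsu is a deliberately simple default: on cells whose perinuclear band is
much brighter than the periphery (ratio ≳ 4) a bimodal threshold can land
inside the cell, so strongly enriched synthetic cells are quantified on
their generator ground-truth masks.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of parameters and seed
(`numpy.random.default_rng`), reproducible bit-for-bit.

* **Toy networks** — one exchange + linear conversion chain per
  subsystem, all chains feeding a shared biomass precursor consumed by
  the biomass objective, so each chain contributes additively to growth
  and responds independently to its own enzymes. Every internal reaction
  carries a unique gene and a kcat sampled uniformly from (1, 5) s⁻¹; a
  configurable fraction (default 0.5) carries a forward-consistent ΔG′°
  in (−40, −15) kJ·mol⁻¹. The default medium allows generous uptake
  (100 mmol·gDW⁻¹·h⁻¹) so that enzyme capacity, not uptake, is limiting —
  the regime in which expression changes propagate to flux changes.
* **Expression replicates** — per gene and replicate, abundance =
  1.0 × lognormal(0, noise_sd); treated-condition target genes are
  multiplied by the planted effect size. Defaults: 3 replicates per
  condition (a typical bulk RNA-seq design), effect size 4, noise_sd 0.2
  (CV ≈ 20%, the order of biological replicate variability for
  well-expressed genes). Lognormal multiplicative noise keeps abundances
  positive and matches the right-skew of TPM-like data. The generator
  does not emulate count noise, gene–gene correlation, library-size
  artifacts or isoform structure — so passing tests show the pipeline
  recovers planted capacity effects under idealized noise, not that it is
  robust to every artifact of real RNA-seq.
* **Genomic fixtures** — genes tiled on one synthetic chromosome with
  ≥ 9 kb spacing so neighboring 3 kb windows never collide, giving every
  planted DAR an unambiguous ground-truth (gene, region) assignment; DE
  classes hit requested proportions (defaults 25% Up, 15% Down); DAR
  direction is drawn with up-fraction 0.84, mirroring the skew of
  accessibility gains over losses typical of activating stimuli; distal
  filler DARs sit ≥ 3 kb from every gene. Real genomes — overlapping
  genes, nested windows, multi-chromosome structure — are not emulated,
  which is exactly why the analysis path is also checked against a
  brute-force oracle on these fixtures rather than trusted on layout
  alone.
* **Cell images** — concentric disk nucleus and annular cytoplasm; the
  planted perinuclear ratio multiplies the signal in the inner 25% of
  normalized cytoplasmic distance, computed with the same
  distance-transform definition the profiling uses, so on ground-truth
  masks a noiseless image recovers the ratio exactly; optional
  multiplicative lognormal noise. Irregular cell shapes, background
  fluorescence, off-center nuclei and imaging artifacts are not emulated.

## Numerical and testing choices

* LP tolerances as above; solution feasibility (S·v = 0, bounds) is
  asserted to 1e−6 in tests on every optimal solution.
* BH and Fisher are verified against independent brute-force
  implementations (literal step-up; direct hypergeometric summation) to
  1e−12; the FBA solver against exhaustive vertex enumeration of the flux
  polytope on small integer-bounded networks to 1e−6; the association
  table against a double-loop re-implementation.
* Problem sizes in the default test run and acceptance script (toy
  networks of 4×4 reactions, 100-run recovery sweeps, fixtures up to a
  few hundred genes/DARs, 96×96 images) were chosen so the whole suite
  completes in a few minutes on one CPU while still exercising every
  stage end to end.
* End-to-end recovery of a planted 4-fold subsystem effect with the 3+3
  design succeeds in 95 of 100 fixed-seed runs; the residue is the honest
  power limit of a pooled t at n = 3 with CV ≈ 20% noise (runs where the
  effect misses the BH cutoff) plus occasional chance co-significance of
  an unperturbed chain that ties the planted subsystem's Fisher p.

## Known limitations

* Enzyme capacity uses transcript abundance as a proxy for enzyme
  abundance; no translation/degradation model.
* pFBA is the single normative flux estimator; no FVA, sampling, MOMA or
  dynamic extensions.
* The metabolite score is a flux-derived turnover, not a concentration
  prediction.
* SBML support is read-only interop via cobrapy; the native JSON/TSV
  dialects are the normative formats.
* The chromatin stage consumes externally computed DARs and DE tables; it
  performs no peak calling or differential accessibility testing.
* PNPR band definitions and segmentation are package conventions; numeric
  agreement with measurements made under other shell definitions is not
  claimed.
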