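# Methods

## The metabolic network

The packaged model (`src/fluxqtl/data/yeast_ccm_synthetic.tsv`) is a
reduced network of *S. cerevisiae* central carbon metabolism under
anaerobic wine-fermentation conditions: 68 reactions over 61 metabolites
in cytosol and mitochondria, with extracellular excretion represented as
pure drain reactions (`_t`) and mitochondrial transport as `_tm`
reactions. The TCA pathway is split into an oxidative branch
(pyruvate → acetyl-CoA → citrate → α-ketoglutarate → succinyl-CoA →
succinate) and a reductive branch (oxaloacetate → malate → fumarate →
succinate) that do not close into a cycle, as appropriate without
respiration. The biomass reaction drains precursors (G6P, R5P, E4P,
GAP, 3PG, PEP, OAA, pyruvate, acetyl-CoA, α-ketoglutarate, glutamate) and
115 mmol cytosolic ATP per gram dry weight — the ATP figure consistent
with anaerobic growth yields — and is a net NADH producer, which is what
ties glycerol formation to growth in the model. The 20
pathway-representative reactions and the biomass composition are fixed
reference points of the network; the surrounding reactions are a
reconstruction from standard yeast biochemistry (the file and loader
docstring label it synthetic), validated at the network level: the
model admits steady-state flux distributions reproducing realistic
exponential-phase fermentation yields.

Reversibilities follow standard assignments, with two deliberate
exceptions kept as the reference panel prints them: the
glucose-6-phosphate dehydrogenase step (`G6p_6pgl`) and the CO₂ drain
are reversible. Elemental balancing of individual reactions is not
validated (the model carries no formulas); only network-level steady
state is enforced.

## Flux estimation

Measurements enter as yields at the sampling point (mmol/L; dry mass
g/L), not as rates — every constraint and result is per litre of
culture, and final fluxes are normalised to glucose input = 100, so
absolute time never enters. Each measured drain y is boxed to
[y·(1−m), y·(1+m)] with m = 0.025 by default; dry biomass boxes the
biomass flux with the same margin (separately configurable via
`biomass_margin`); consumed hexose (glucose + fructose, "fructose
treated as glucose") boxes the single glucose-uptake reaction.
Non-positive dry mass or hexose means "not measured" and leaves the
reaction free. Succinate bounds can be replaced by a fixed range
(`succinate_bounds` in the pipeline config) for datasets where
succinate determinations suffer batch effects; no default range is
shipped because any such range is dataset-specific — the default is to
use the measurement-derived box.

The LP minimises glucose input subject to S·v = 0 and the bounds
(HiGHS via `scipy.optimize.linprog`). The glucose minimum need not pin
every internal flux (e.g. futile transport cycles), so a second stage
fixes the optimal glucose input (to within 1e−9) and minimises Σ|vᵢ|,
making the reported distribution deterministic; `tie_break_applied`
records whether the second stage moved anything by more than 1e−6.
Feasibility uses the solver default tolerances; reported solutions are
checked against ‖S·v‖∞ < 1e−6. Because all constraints are homogeneous,
the parsimonious optimum typically sits at the (1−m) scaling of the
measured state, so the modelled-vs-measured sugar-uptake divergence is
bounded by (and often attains) the margin.

## Flux structure

φ is the cosine similarity of null-space basis rows (SVD basis, singular
values below 1e−10·σ_max treated as zero); it is invariant to the basis
choice, which the tests verify with an independently mixed QR basis.
Reactions with zero kernel rows are blocked (no steady state admits flux
through them) and are excluded from the coupled groups rather than
forming singletons. Coefficients of variation use the sample (n−1)
standard deviation because parent groups can be as small as two strains;
zero-mean columns are reported as undefined (NaN), never infinity.

Representative-flux selection is rule-based per pathway tag: `first`
and `last` refer to model (file) order within the pathway, `explicit`
lists ids, and parallel routes to the same product are all retained.
The packaged default configuration resolves to a 20-flux panel covering
upper/lower glycolysis, PPP entry, ethanol synthesis (both
compartments), acetate and acetyl-CoA metabolism, both TCA branches,
the measured excretion fluxes and biomass.

## QTL mapping

The cross is haploid and biallelic, so the scan algebra is that of a
backcross with two genotype classes, regardless of the "F2" label such
segregant panels carry. Genotype probabilities come from a two-state
forward–backward HMM per chromosome with Haldane transition fractions
(no interference — the standard default when nothing is known about
interference) and a symmetric genotyping error rate (default 1e−4);
missing genotypes are handled inside the HMM, never by dropping
individuals. Pseudomarkers are placed on a regular grid (default
2.5 cM) from the first marker of each chromosome; the HMM is hand-rolled
because the position-specific transition matrices of a genetic map do
not fit the homogeneous-chain API of general HMM libraries.

Haley–Knott: y is regressed on P(A) at each position;
LOD = (n/2)·log₁₀(RSS₀/RSS₁) with RSS₀ from the intercept-only model.
At a fully informative marker this equals the closed-form
(n/2)·log₁₀(1/(1−R²)) of the marker regression (tested to 1e−9).

Non-parametric: phenotypes are replaced by ranks (ties averaged) and a
Kruskal–Wallis statistic is generalised to genotype probabilities with
weights pᵢ = P(A): n_A = Σpᵢ, r̄_A = Σpᵢrᵢ/n_A (and the complements for
B), H = 12/(n(n+1))·[n_A(r̄_A−r̄)² + n_B(r̄_B−r̄)²]/C_ties, and
LOD = H/(2·ln 10). At a fully informative marker this is exactly the
two-group Kruskal–Wallis statistic, including the tie correction.

Significance is a genome-wide permutation threshold: phenotype labels
are permuted (default 1000 times), the per-permutation maximum LOD is
recorded, and the empirical (1−α) quantile (upper-value method, so
α = 0 returns the maximum) is the per-trait threshold. This controls
the genome-wide error rate per trait; no multiplicity adjustment is
made across traits, matching standard practice for scan panels of
correlated fluxes. Peaks are per-chromosome maxima above threshold
(leftmost position on ties). Support intervals extend from the peak to
the outermost contiguous positions with LOD ≥ peak − 1 (boundary
included) and are converted to bp using the nearest flanking physical
marker on each side; bp and cM must both be supplied in the map — no
physical↔genetic inference is performed. When both phenotype models
detect the same locus (peaks within the grouping distance), the
higher-LOD version is kept. fQTL grouping is single-linkage clustering
of peaks per chromosome at 10 cM, with union borders, maximum member
LOD, and `chr<N>@<peak cM>` names.

Variance explained by a locus is 1 − 10^(−2·LOD/n), the standard
likelihood-ratio identity for a single-QTL model.

## Synthetic data

The generator emulates the target study design: 125 haploid segregants
(default), duplicate phenotyping, multi-chromosome marker map (default
four chromosomes of 100 cM with 41 evenly spaced markers, physical
scale 3 kb/cM), and exponential-phase sampling of a synthetic must with
100 g/L each of glucose and fructose. Default base yields (ethanol
225 mmol/L, CO₂ 228, glycerol 8, acetate 2.2, succinate 1.2, pyruvate
0.6, α-ketoglutarate 0.35, dry mass 0.8 g/L) were chosen once as a
redox- and ATP-consistent exponential-phase state of the packaged
model; replicate noise is multiplicative lognormal with CV 0.02,
matching good HPLC repeatability and sitting below the 2.5% constraint
margin so that generated strains remain feasible for the estimator.

Planted allelic effects are multiplicative on target yields (fractions
of base per A allele), the way allelic effects on fluxes are reported
in practice. Because the network couples yields (NADH balance above
all), an arbitrary single-yield scaling is usually not attainable in
any steady state; per-segregant expected yields are therefore projected
onto the feasible set with a weighted-L1 LP (weights 1/target, so
relative deviations compare across metabolites of very different
magnitude), followed by a glucose-minimisation and L1 tie-break stage
so the reference flux vector is the same canonical representative the
estimator would return. Ground truth records the realised
(post-projection) yields: a nominal +8% glycerol effect realises as
roughly +5% with a compensating biomass co-effect, which is the
biologically coherent outcome, and detection/recovery tests are stated
against realised effects. Effects on yields with internal slack
(acetate, via the NADP branch) project essentially unchanged.

What the generator does **not** emulate: crossover interference,
segregation distortion, genotyping errors in the written files,
strain-specific biomass composition, block/batch effects in the
measurements, and real linkage-disequilibrium structure. Passing tests
therefore demonstrate correctness of the estimation and mapping
machinery under the stated model, not robustness to every artefact of
real fermentation data.

## Numerical and design choices

- LP solver: HiGHS; variable caps at ±1e6 for open bounds so stage-2
  L1 problems stay bounded.
- Degenerate all-zero solutions (zero sugar uptake) are reported as
  optimal with undefined normalised fluxes rather than as errors.
- Kernel cutoff 1e−10·σ_max; coupling tolerance |φ| ≥ 1 − 1e−9;
  blocked-row tolerance 1e−9 relative.
- Permutation quantile uses the "higher" method (conservative,
  exact at α = 0).
- Equal-LOD peak ties resolve to the smallest cM.
- Per-strain solver failures are warnings (strain excluded from the
  flux matrix); structural errors (unknown reactions, malformed files)
  abort.
- Pipeline problem sizes in tests and examples (60–125 segregants,
  2–4 chromosomes, 150–1000 permutations) were chosen to keep the demo
  and suite fast while preserving the statistical behaviour being
  checked; all thresholds and defaults are the standard settings listed
  above.

## Known limitations

- Single-QTL scans only: no multiple-QTL models, epistasis or
  covariates.
- No flux variability analysis; the L1 tie-break reports one canonical
  distribution among alternate optima and `tie_break_applied` is the
  only degeneracy diagnostic.
- The reconstructed portion of the network is structurally but not
  bibliographically validated; swap in your own reaction TSV via the
  `model` config key if you have a curated network.
- The "FDR 0.05" language often used for 1000-permutation max-LOD
  thresholds is, strictly, a genome-wide (family-wise) error rate per
  trait; this package implements and documents it as such.
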