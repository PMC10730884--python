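# Methods

This note documents the models, conventions and numerical choices behind
`d2bscreen`, and what the synthetic-data generator does and does not
emulate.

## Reaction transforms and mass bookkeeping

The three isocyanide multicomponent reactions are modeled as formula
arithmetic: product = Σ parents − H₂O, with the Ugi-tetrazole reaction
additionally gaining HN₃, which is accounted by giving the azide building
block the formula HN₃ outright (the trimethylsilyl group of TMSN₃ is lost
during workup and never reaches the product). Monoisotopic and average
masses come from the RDKit periodic table; the formula-vs-mass consistency
contract is 10⁻⁴ Da.

2-D product structures are generated opportunistically from reaction SMARTS
(α-acylamino amide for the Ugi schemes, 1,5-disubstituted tetrazole for the
azide scheme) and may be absent for substrates the SMARTS cannot sanitize;
the enumeration contract is formula/mass, not depiction, because downstream
hit calling needs masses only. Blocks carrying several copies of their
role's functional group react once, at the first matching site in RDKit's
canonical atom order, and the product is flagged `multi_reactive:<id>`.
Deduplication is on (scheme, sorted parent-id multiset); stereochemistry is
ignored.

Eligibility is enforced by SMARTS per role: primary amine
`[NX3;H2;!$(NC=[O,S,N])]` (anilines eligible, amides not), aldehyde/ketone,
carboxylic acid, isocyanide `[N+]#[C-]`. A secondary amine supplied in the
amine role raises an eligibility error rather than silently enumerating.

## Plate design

Well ranges are interpreted as inclusive row-major contiguous spans, which
makes the three zones exactly 128 wells each and tile the 384-well plate.
The sparse-matrix sampler is seeded uniform sampling without replacement;
the balanced mode is a greedy round-robin that, at each step, picks a
product minimizing the maximum (then total) usage count of its
variable-role parents, with ties broken by the seeded generator — this
guarantees every building block appears once before any appears twice
whenever arithmetically feasible. Reagents common to an entire zone
(isocyanide, formaldehyde, azide) are excluded from balancing since they
carry no coverage information.

Stock dosing: amine/oxo/acid 0.5 M × 125 nL, isocyanide 0.25 M × 250 nL
(all 62.5 nmol = 1 eq), azide 0.6 M × 250 nL (150 nmol = 2.4 eq).
Formaldehyde, supplied as 37% w/w aqueous solution in practice, is dosed at
volume parity and modeled with a configurable effective molarity defaulting
to 0.5 M. Equivalents are always recomputed from conc × volume / 62.5 nmol
so the transfer table is self-consistent by construction.

## Hit calling

A peak matches an adduct when |m/z − (M + δ)| ≤ tol, with monoisotopic
cation deltas 1.00728 / 22.98922 / 38.96316 Da and default tol = 0.3 Da
(direct-injection, unit-resolution data; configurable). The verdict is
green when a matched peak ties or exceeds the base peak (optimistic
tie-break), blue when nothing matches, yellow otherwise. The base peak is
determined after discarding m/z < 100 by default, so dominant low-mass
solvent/matrix ions do not demote genuine product wells to yellow; if a
spectrum contains only sub-cutoff peaks the cutoff is waived rather than
erroring. The normalized well value is best-matched intensity over
base-peak intensity, which makes green ≡ 1 by definition.

## Viability triage

Normalization divides by the untreated-well mean (idempotent by
construction). Strong inhibition is viability strictly below 0.5;
`beats_controls` compares against the smaller of the per-plate mean
pomalidomide and lenalidomide viabilities — the comparator had to be chosen
here, and the per-plate mean is the least assumption-laden option. Crude
wells attribute activity to the intended product with no purity correction;
this mirrors the D2B screening premise and is the main caveat when
interpreting triage output. Diverse picking is greedy MaxMin
(farthest-point) on 2048-bit RDKit substructure-fingerprint Tanimoto
distance, seeded at the lowest-viability hit; the greedy rule carries the
standard factor-2 guarantee on the minimum pairwise distance, which the
test suite asserts against brute force on small pools.

## Dose–response

The 4PL curve is fit by bounded least squares on a log₁₀(EC₅₀)
parameterization, multi-started over a 7 × 3 grid of midpoints (dose range
± 1 log) and Hill slopes (0.5, 1, 2); the best RSS wins. Series flatter
than 0.05 response units are declared degenerate with undefined midpoint
instead of returning an arbitrary extrapolation; midpoints outside
[min dose/10, max dose×10] are flagged extrapolated. Replicates are pooled
as raw points. The CRBN-dependence rule — knockout range < 0.2 or midpoint
shift > 100× — is an operational definition chosen here to binarize what is
qualitatively an abolished curve; both thresholds are exposed as module
constants.

## Proteomics statistics

The pipeline follows the Perseus/limma conventions: log₂; keep proteins
quantified in strictly more than 70% of samples (3/4 passes); per-sample
median centering; imputation per sample from
Normal(mean − 1.8·SD, (0.3·SD)²) computed on that sample's observed values
(a global-statistics mode is available by computing on the pooled matrix).
The moderated t squeezes gene-wise pooled variances (d_g = n₁+n₂−2) toward
a prior (d₀, s₀²) estimated by method-of-moments on log variances with
digamma/trigamma inversion; the trigamma inverse is Newton iteration on
1/trigamma from the asymptotic start 0.5 + 1/x. When the log-variance
spread does not exceed its sampling expectation the prior df is infinite
and the prior scale is the arithmetic mean of the variances, so the
statistic reduces exactly to the pooled-common-variance t (and with d₀ = 0,
to the ordinary per-gene Student t). The test suite pins this
implementation against limma's `lmFit`/`eBayes` on a shared matrix.
Benjamini–Hochberg is the standard step-up with monotonicity enforcement;
significance is p_adj < 0.05.

The volcano table's y-axis is −log₁₀ of the *adjusted* p-value; the raw
p-value column is retained for an unadjusted plot.

**Known limitation — imputation under MNAR.** Downshifted-normal imputation
deliberately fabricates low values with a narrow width (0.3 SD). When
missingness is intensity-dependent and happens to be asymmetric between
groups, this deflates within-group variance and can produce false
positives beyond the nominal FDR. The statistical-performance simulations
(type-I error, spike-in power) therefore run the generator in its
complete-matrix mode, isolating the moderated-t/BH machinery from this
imputation artifact; the artifact itself is real, documented behavior of
the method, not a bug.

## Synthetic-data generator

All stages draw from named substreams of one root seed
(`default_rng([seed, stage])`), so regenerating one stage never perturbs
another and the full chain is byte-reproducible.

Defaults encode the campaign the pipeline emulates: 28/28/28 variable
blocks plus fixed isocyanide, formaldehyde and azide (87 starting
materials; 23,520 products); per-scheme success probabilities 0.51 / 0.67 /
0.61 (Ugi / Ugi-formaldehyde / Ugi-tetrazole); conditional on success, the
three adduct peaks get Dirichlet-weighted intensities and the top adduct is
the base peak with probability 0.8 (otherwise a dominant contaminant peak
forces a yellow call); Poisson(5) background peaks are drawn uniformly on
m/z 100–1200, excluding the ±0.5 Da adduct windows — background ions
coinciding exactly with the product adduct are not part of what the
generator emulates, which keeps generated verdicts interpretable as ground
truth. The fixed isocyanide defaults to a synthetic stand-in with a
glutarimide–phthalimide (IMiD-like) head group.

Viability: MS-positive wells are hits with probability 0.73; hit
viabilities are uniform on [0.05, 0.45], non-hits on [0.55, 1.1], plus
Gaussian noise (SD 0.02); control wells (untreated, pomalidomide at 0.50,
lenalidomide at 0.55, vehicle) are placed on reaction-failed (blue) wells
of the screening copy, which are compound-free by construction.

Proteomics: protein baselines ~ Normal(20, 2) in log₂; replicate noise
SD 0.5; the first k = 5 proteins shift −2 log₂ units in the treated group;
missingness follows P(missing|x) = 0.6·expit((16.5 − x)/0.8), i.e. low
intensities censor preferentially (MNAR), giving ~5% overall missingness at
the defaults.

What the generator does **not** emulate: isotope envelopes and in-source
fragmentation; adducts beyond H/Na/K; plate-position (edge) effects and
spatial drift in viability; purity/yield coupling between MS intensity and
phenotype; peptide-level quantification and protein rollup; correlated
protein co-regulation. Passing tests therefore demonstrate correctness of
the computations under the stated statistical structure, not robustness to
those real-data effects.

## Problem sizes

The test suite and acceptance script run the full 23,520-product
enumeration and 384-well designs directly (sub-second), 100-seed viability
and 4PL simulations, 50-seed proteomics power runs and a 1000-protein
type-I simulation; these sizes give stable estimates (binomial/SE bands
quoted in the tests) while keeping a full run in seconds.
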