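# Methods

## The relative limb size index

Adaptation to habitual bipedalism enlarges the load-bearing joints of the
lower limb relative to those of the upper limb; climbing and suspension do
the opposite. For one individual preserving upper-limb joint dimensions
U = {u_i} and lower-limb dimensions L = {l_j} (all in mm), the package
computes

    RLSI = ln( GM(U) / GM(L) ),    GM(x) = exp(mean(ln x)),

a dimensionless log-ratio. The geometric mean equalises the weight of
measurements with different absolute ranges, and logging the ratio puts the
index on a symmetric additive scale (ratios of normally distributed
measurements are themselves not normal). Natural logs are used throughout,
so differences read as proportional contrasts; 0 means equal upper and
lower geometric mean joint size, negative values are the human direction.

Ten composite elements enter the index — G, H, B, U, R (upper) and F, Sub,
A, T, Sac (lower); G, H, Sub and Sac are geometric means of two calipers
and are formed only when both calipers are present. Fossil partial
skeletons preserve different subsets, so the ratio spec is truncated per
specimen to its preserved elements (`preserved_spec`); nothing is imputed.
Values flagged as estimated in the source compilation (e.g. a talar width
estimated from tibial plafond width) are used as printed and carry a
provenance flag. Readers warn on calipers outside 1–200 mm rather than
rejecting them.

Useful identities, all property-tested: the index is invariant to uniform
scaling of a specimen and to element order, and exactly negates when the
two sides of the spec are swapped.

## Synthetic extant samples

The extant comparative data (humans n=67, *Pan*, *Gorilla*, *Pongo*,
pooled hylobatids) are published only as per-element mean ± SD with N, so
specimen-level samples are synthesised. Marginals are log-normal,
moment-matched per element (σ² = ln(1+cv²), μ = ln(mean) − σ²/2);
dimensions within a specimen are equicorrelated on the log scale with
ρ = 0.8 by default, realised through a single shared standard-normal size
factor. ρ = 0.8 encodes that joint sizes co-vary strongly through body
size; the published tables carry no covariance information, so this is a
modelling choice, exposed in `SyntheticConfig`. A truncated-normal option
(raw-scale normal with whole-specimen rejection of non-positive draws)
exists as a sensitivity switch; its moments are approximate at large cv.
Generation is deterministic per seed, with per-taxon child streams spawned
in sorted order so one taxon's sample does not depend on which others are
requested.

What the generator does **not** emulate: sexual dimorphism, ontogeny,
genus structure inside pooled taxa, per-element missingness, heavy tails
or outliers, and — critically — any correlation structure richer than a
single shared size factor. Tests passing on these samples show the
pipeline's logic is correct under the stated model, not that real museum
samples behave identically (see "Known limitations").

One published value deserves note: the *Pan* talar width dispersion is
printed as 18.1 ± 34.1 mm (cv ≈ 1.9), which is not a credible linear
measurement SD (all other rows have cv ≈ 0.07–0.22) and is treated as a
transcription artifact of the source table. It is nevertheless used as
printed, with a loader warning; consequences: synthetic *Pan* RLSI ranges
under any T-bearing spec are vacuously wide, and the raw-scale SD of that
one column converges too slowly for a 1%-at-n=10⁵ recovery check (the SD
estimator of so heavy-tailed a log-normal has ≈4% sampling error at that
n), so for implausibly dispersed rows (cv > 0.5) moment-recovery tests
check the matched log-scale parameters instead, which converge at the
normal rate.

## Classification

For each fossil the extant per-specimen RLSI distributions are computed
under the fossil's own preserved spec and summarised by observed extremes
and quartiles (inclusive linear interpolation — the {1,2,3,4,5} → 2/3/4
convention); membership bounds are inclusive, ties resolve toward
"within". Calls are graded: within the IQR, within the observed min–max
range, outside.

"Human-like" is directional: a fossil is called human-like when its RLSI
is at or below the human sample maximum — i.e. within the human range, or
beyond it on the low side. The strict within-range call is reported
alongside. The directional rule matters for exactly one specimen:
KNM-WT 15000 has an even lower relative upper-limb index than the sampled
humans, which is more extreme in the human direction, not ape-like; a pure
min–max rule would absurdly exclude it for being "too human".

Because the comparative samples are synthetic, classifications are
replicated over a seed sweep (default 25 seeds) and reported as the modal
call with its frequency.

Under the default generator the modal human-like set has **four** members
(A.L. 288-1, DIK-1-1, KNM-WT 15000, LES 1). KSD-VP-1/1, the fifth skeleton
one would expect on the real data, computes to RLSI = +0.054 under its
preserved {G,B}:{A,Sac} spec while the synthetic human distribution under
that spec is (exactly, in log space) normal with mean ≈ −0.063 and
SD ≈ 0.037 — a 3.1σ gap that the maximum of 67 draws clears in only ~5% of
seeds. The discrepancy is a limitation of uniform ρ = 0.8 equicorrelation:
in real skeletons shoulder and pelvic dimensions are less than fully
size-correlated, which widens the human RLSI spread for small mixed-girdle
specs. The package reports this honestly rather than re-tuning ρ after the
fact.

## Element profile (how a low RLSI is achieved)

For the three elements F (femoral head), Sac (sacral body) and B
(biepicondylar breadth), each specimen's values are closed over their
geometric mean, logged, and contrasted with the human reference
(per-element geometric mean of the same composition over the human
sample):

    index_e = ln(e / GM3) − mean_human[ ln(e / GM3) ].

The three indices of any specimen sum to zero and are invariant to uniform
scaling. Extant-taxon profiles get percentile-bootstrap 95% CIs (default
10⁴ resamples) resampling *both* the subject and the reference specimens,
since the reference is itself an estimate; simulation shows ≈95% coverage.
This reproduces the reversed femur/sacrum pattern of the two low-RLSI
lineages: KNM-WT 15000 pairs a relatively large femoral head with a small
sacrum, A.L. 288-1 the opposite ordering. The exact index construction
behind the published figure is not specified; the closed three-element
composition is this package's choice, made because that analysis restricts
itself to exactly those three elements.

## Allometry

`fit_scaling` fits ln(y) on ln(x) across specimens. Default estimator is
reduced major axis — slope = sign(r)·sd(ln y)/sd(ln x) — standard when
both variables carry measurement error and symmetric in x and y up to
reciprocal; OLS is available for sensitivity. CIs are percentile
bootstraps over specimens (default 10⁴ resamples, seeded); bootstrap
rather than analytic to avoid normality assumptions on log sizes. A fit is
isometric when its CI contains 1, otherwise the sign of m − 1 decides.
Fits warn when |r| < 0.1 (RMA slopes are then unstable) and refuse n < 3
or zero x-variance.

The published hylobatid slopes (glenoid m = 0.75, biepicondylar m = 0.76
on femoral head) live in the raw museum file, which is not redistributed
here; given that file as a specimen CSV the same fit applies directly.
Without it the suite validates the estimator by simulation: data generated
with a true RMA slope of 0.75 at n = 69 (bivariate log-normal, r = 0.9)
are covered by the 95% bootstrap CI in ≥ 93% of 500 replicates. Synthetic
within-taxon slopes from the equicorrelated generator hover near 1 by
construction (a single shared size factor induces near-isometry) and are
not evidence about real hylobatid scaling.

## Parsimony

The RLSI is coded binary (high = ape-like, low = human-like), exactly as
the cross-topology comparison frames it; no squared-change/continuous
treatment is attempted. Ancestral states are reconstructed by unit-cost
Sankoff dynamic programming (valid on polytomies; equals Fitch on binary
trees — property-tested against exhaustive enumeration), and *all*
most-parsimonious reconstructions are enumerated by DP backtracking (trees
over 25 internal nodes are refused and fall back to count-only). No
ACCTRAN/DELTRAN tie-breaking is applied silently; every MPR is reported
with its change decomposition.

The ancestral hominoid condition is high, implemented as a virtual
high-state stem ancestor above the root: an MPR that reconstructs the root
as low pays for, and reports, a gain on the stem branch. With that prior,
each change is classified as a gain of low (high→low: an independent
origin of human-like proportions) or a reversal to high (low→high). The
question asked of each topology: does any MPR achieve a single gain of low
with zero reversals? The standalone `fitch_min_changes` keeps the classic
unconstrained semantics (minimum over all labelings, no stem edge); on the
hominin data both agree because optimal roots are high anyway.

The six topology fixtures are Newick reconstructions of the published
hypothesis panels (two from formal cladistic analyses; three published but
never recovered hypotheses — *A. garhi* ancestral to *Homo*, *A. sediba*
ancestral to *Homo*, polyphyletic *Paranthropus*; and one hypothetical
tree placing *A. afarensis* sister to later *Homo*). The panels are
published graphically, so the fixtures are editable data, not code —
substitute exact published trees freely. *A. garhi*'s position among the
high-state taxa is arbitrary where the source hypothesis does not fix it;
it cannot affect change counts. Result, stable across fixtures A–E: two
changes minimum, achieved only by two independent gains of low (one on the
*A. afarensis* branch, one in later *Homo*); only the hypothetical tree F
admits a single origin without reversals.

## Problem sizes and numerical choices

Default run: 25-seed sweep at published Ns (~480 synthetic specimens per
seed), 10⁴ bootstrap resamples for CIs; the full pipeline completes in
seconds. Test-suite simulations use 500 replicates with 800–2000 bootstrap
resamples, chosen as the smallest sizes at which coverage assertions are
stable. Floating-point tolerances in tests: 1e-12 for algebraic
identities, 1e-9 for identities involving a multiplicative rescaling.

## Known limitations

* ρ is a single free parameter standing in for a full covariance matrix;
  it cannot be validated against published values and demonstrably
  understates the human RLSI spread for small mixed-girdle specs (the
  KSD-VP-1/1 case above).
* The exact element subsets behind each published per-fossil comparison
  are derived here from preservation; the original panels may have chosen
  differently.
* The glenoid's second caliper is described inconsistently in the source
  (ML width vs AP width); it is modelled as a single generic width field.
* Whether "within the range" in the source means whisker extent or
  observed extremes is unstated; observed extremes are used.
* No phylogenetically independent contrasts for the scaling fits (the
  published scaling aside is non-phylogenetic), and no body-mass or limb
  length estimation anywhere.
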