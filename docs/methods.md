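# Methods

`rnamod` profiles the modification status of single RNA molecules from
nanopore signal. A direct-RNA read is a sequence of segmented *events*, each
summarized by its mean current (pA) and attributable to one pore-occupying
kmer (k = 5 by default). Annotated modified positions (pseudouridine,
2′-O-methyls, ac4C, ...) are each given a private character in an extended
alphabet, so that every kmer overlapping a modified position has two versions
— canonical and modified — with separate emission Gaussians. Aligning a
read's events against this branchable kmer space and decoding the posterior
over branch choices yields, per molecule, a probability of modification at
every annotated site. Downstream layers quantify per-site frequencies and
their changes between conditions, concerted (correlated) modification,
molecule subpopulations, and modified-site locations from comparative
signal.

## The variable-order signal HMM

**State space.** For a read mapped to reference interval `[start, end]`, one
state pair per (kmer slot, variant): a *Match* state emitting from the
variant kmer's Gaussian `N(μ, σ)` and an *Insert* state emitting from a broad
background Gaussian (mean of the window's canonical levels, 3× their spread)
for spurious events. A slot covering *b* annotated sites has 2^b variants
(capped at 4 sites per slot; yeast's densest annotated run, 25S
2921–2923, needs 3).

**Variable-order coupling.** Transitions between slots are admissible only
when the two variants agree on every shared site, and each site *entering*
the window contributes a factor ½ (a uniform per-site prior applied exactly
once). Consequently the posterior mass over variants is generated by a single
per-site character choice along each path — overlapping slots can never vote
independently about the same site.

**Transitions.** Fixed, not re-estimated: stay 0.30 (re-emit the same kmer),
step 0.55, skip 0.10 (jump one slot), insert 0.05; moves unavailable at the
reference edge are renormalized away. Initial mass covers the first three
slots (geometric in the skip probability) and their insert twins, because the
first measured event may belong to a slot reached after a skip or be
spurious; without this, a skipped first slot can underflow the first event's
emission and spuriously fail the alignment.

**Recursions.** Forward/backward run in probability space with per-step
rescaling plus a per-step max-shift of the log-emission row; the total
log-likelihood is reassembled from the accumulated scales and shifts. This is
numerically equivalent to log-space recursion for any per-step dynamic range
the data can produce, roughly 20× faster in the compiled kernels, and is
verified against literal path enumeration to < 1e-9 log units on randomized
small instances (the enumeration reference lives in `rnamod._enumerate` and
never calls the kernels). A read whose events admit no monotone path with
positive mass raises an alignment failure rather than crashing.

**Decoding.** Site probability = posterior mass on *match* states whose
variant carries the modified character, over all match-state mass covering
the site. Insert emissions are variant-independent, so including insert
occupancy would only dilute every probability toward ½; excluding it keeps
the single-slot case exactly equal to the two-hypothesis Bayes ratio. Sites
with no covering mass are reported missing, never 0. The maximum-expected-
accuracy (MEA) path maximizes summed posterior mass over admissible monotone
state sequences; ties resolve to the smallest slot, then variant, then
match-over-insert.

## Per-read normalization

Two stages. First, shift and scale are chosen so the median and MAD of the
read's event means match those of the canonical model levels across its
mapped slots — exact under any affine signal distortion, which makes decoded
probabilities invariant to per-read gain/offset. Second, after a first
alignment, the affine fit is refined by regressing event means on their
MEA-assigned model levels (OLS slope, median-residual intercept, one
trimming pass at 4 MAD). The refinement exists because the MAD-ratio scale
estimator is biased high by event noise and spurious events (~2–3%), which
otherwise compresses all trained levels toward the window mean; regression
with the noise in the response removes the bias, and the robust intercept
resists the few percent of misassigned pairs.

## Supervised training

Labels are dataset-wide: wild-type-like reads are treated as modified at
every callable site, IVT-like reads as canonical everywhere — accepting that
not every wild-type molecule is truly fully modified, which is why the
default wild-type simulation template is 0.95 rather than 1. Each round aligns every
read with its labels fixed, pools event means per kmer, and re-estimates
mean = median, sd = MAD for every kmer touching a modification branch point
(canonical and modified versions both), carrying parameters forward when a
pool has fewer than 10 effective events. Defaults: 30 rounds, 500 reads per
class, raw (unscaled) MAD; the Gaussian-consistent scaling (×1.4826) is an
opt-in flag because raw MAD materially narrows the Gaussians (MAD ≈ 0.67σ).

Pooling is posterior-weighted by default (`pooling="posterior"`): each event
joins a kmer's pool with its posterior occupancy, and weighted medians/MADs
are used. Hard assignment along the MEA path (`pooling="mea"`) is available
but measurably biased: when two adjacent slots have nearly equal levels, the
path must attribute their shared boundary events to one side, and the
step-favoring transition set censors each pool asymmetrically.

**Known limitation.** Under the default study conditions (300-nt contig, 12
sites, +3 pA shift at σ = 1 pA, 500 reads/class, 30 rounds), recovered
modified-kmer means have median error ≈ 0.09 pA, but kmers whose neighbouring
slot level lies within ~1 pA (typically 3–5 per 60 at these settings) settle
0.3–0.45 pA low. The raw-MAD sd (~0.64 for unit-σ pools) sharpens boundary
attribution each round and amplifies the censoring into that equilibrium;
with the consistent MAD scaling the worst error drops to ≈ 0.26 pA. The
corresponding acceptance check is left failing rather than papering over it,
since both the sd estimator and the study conditions are fixed by design.

## Calling, metrics, statistics

Calling composes normalization → alignment → decode per read, records
per-read provenance (shift, scale, log-likelihood, full-length status), and
drops alignment failures with a logged reason. Full-coverage filtering (only
reads with a probability at every site) is explicit and is enforced
internally before clustering and correlation. Frequencies use a strict 0.5
cutoff (P = 0.5 counts as unmodified). Classification metrics: midrank
AUROC (equal to the normalized Mann–Whitney U), PR curve, equal-width
calibration bins, confusion at the cutoff, and balanced accuracy
(sensitivity + specificity)/2, optionally per position. Calibration quality
is summarized as the occupancy-weighted expected calibration error; an
unweighted mean over near-empty probability bins would measure binomial
noise, not calibration.

Frequency change between an experiment and three wild-type replicates: per
site, a 2×2 chi-square for every (WT × experiment) pairing — continuity
correction auto-applied when an expected count is below 5, proportional
tables short-circuit to p = 1 — keeping the *highest* p (worst case over
batches), Benjamini–Hochberg across sites per contig, and two effect-size
gates: a global 10% minimum change and the maximum frequency spread among
the WT replicates (batch control). Concerted modification: Spearman
correlation between the continuous probability columns of full-coverage
reads (midrank ties), p from the t approximation with df = n−2, BH over
pairs. Correlation changes between conditions: Fisher z-transform two-sample
test, reporting per pair the minimum |Δρ| and the highest p over repeat
pairings; a pair is starred only when the corrected comparison is
significant *and* the focal correlation is itself significantly nonzero.
Aggregation of dependent tests uses the Empirical Brown's method: per-read
quantities are transformed through their empirical right-tail probabilities
(w = −2 ln P(X ≥ x)), the covariance of the transformed columns rescales
Fisher's χ² (f = 2E²/Var, c = Var/2E, E = 2m); with zero covariance it
reduces exactly to Fisher's method, with duplicated columns to the halved-df
limit. The per-read quantity fed to the covariance is the probability rather
than the binarized call; the caller can pass either.

## Clustering

Profiles are clustered with Ward's method on Euclidean distance after
full-coverage filtering; cutting at N branches and counting reads per branch
per sample quantifies subpopulations (fractions per sample sum to 1; cluster
ids are stabilized by dendrogram leaf order). Linkage heights are verified
against an O(n³) Lance–Williams agglomeration reference on small instances.
Determinism relies on scipy's nearest-neighbor-chain implementation; inputs
with exact distance ties (measure-zero for continuous profiles) may permute
cluster ids but not the partition structure.

As a model-free cross-check, standardized event means over a slot region are
clustered the same way: per read, whole-read z-standardization (location and
scale estimated from MEA match-assigned events, so a random number of
spurious events cannot inflate the scale), MEA assignment to slots,
multi-event slots averaged, reads missing a region slot dropped, columns
standardized. On synthetic data where modification fully determines a +3σ
level shift, this recovers the planted classes and agrees with profile
clustering. When reads were already affine-normalized against the model,
`read_standardize=False` skips the per-read z: re-estimating an
already-applied correction from ~T events adds ~sd/√(2T) scale jitter, which
at 3 pA effect sizes is the difference between a clean and a noisy
separation.

## Comparative site detection

The detector assumes no trained modified model: reads from two samples are
aligned against the canonical reference only, each MEA match event is
attributed to the *center* position of its kmer (so a modification perturbs
positions within ±k//2 = ±2 of itself), and per position the two samples'
event-mean distributions are scored with the exact two-sample
Kolmogorov–Smirnov D (positions with < 10 events in either sample are
masked). The reported statistic is the 3-position windowed mean
w_i = (d_{i−1} + d_i + d_{i+1})/3. Evaluation offers the strict per-position
AUROC and the relaxed window-peak protocol: each modified position is scored
by the maximum w over the 5 positions centred on it, and the 2 flanking
positions on each side of every modification are excluded from the negative
set (overlapping exclusion zones are unioned). Because signal bleeds into
neighbouring kmers, the relaxed protocol never scores below the strict one
when the true peak lies within ±2 of the annotation.

## Synthetic data generator

The generator emulates the event-level output of a direct-RNA run and is the
package's ground truth. Per read: a subpopulation template is drawn from the
sample's mixture; per-site binary states are drawn from the template
frequencies, with optional pairwise dependence planted through a Gaussian
copula whose latent correlation is calibrated (bivariate-normal orthant
probability, bisection) so the realized correlation of the *binary states*
hits the requested Spearman target; the read walks slots 5′→3′, skipping a
slot with p = 0.10, emitting 1 + Geometric(0.3) events per visited slot from
the kmer's Gaussian, and appending a background event with p = 0.05; a
per-read affine distortion (scale U(0.95, 1.05), shift U(−5, 5) pA) is
applied; reads are stored 3′→5′ as sequenced. Defaults: one 300-nt contig,
12 well-separated sites, canonical kmer levels i.i.d. N(100, 10) pA with
σ = 1 pA, modified kmers offset +3 pA — separations where calling is
reliable but not trivial; 90% of reads are full length, the rest start past
the 5′ dead zone (nanopore RNA reads proceed 3′→5′, so truncation hits the
5′ end). A profile-level generator draws state-conditional Beta cells
(modified → Beta(8, 2), canonical → Beta(2, 8), or exact 0/1 point masses)
to exercise the statistics and clustering layers without the signal stack.

What it does *not* emulate: raw (pre-segmentation) squiggle, dwell-time
physics, sequence-dependent level correlation between neighbouring kmers
(real adjacent 5-mers share 4 bases and have correlated levels; i.i.d.
levels make neighbour collisions rarer but more abrupt), homopolymer
segmentation pathology, carrier/adapter sequence, and basecalling or mapping
errors. Passing tests therefore demonstrate correctness of the algorithms
under a faithful event-level abstraction, not performance on real flow-cell
data.

## Fixed constants and degenerate inputs

5′ dead zone 15 nt (sites there are flagged uncallable); probability cutoff
0.5 (strict >); frequency-change cutoff 10%; α = 0.05; BH families per
(statistic × contig × comparison); ks minimum coverage 10; branch cap 4
sites/slot; modification characters drawn deterministically (lowercase,
digits, spare uppercase, fixed punctuation) in (contig, position) order.
Degenerate inputs have defined behaviour: constant event means and
constant probability columns are rejected/flagged, |ρ| = 1 pairs are marked
non-comparable, p = 0 is clipped to the machine minimum with a warning,
zero-MAD pools keep their previous sd, and empty kmer event samples are
allowed.

## Bundled fixture

The yeast-like annotation (37 sites on 18S, 73 on 25S) and reference are a
*synthetic stand-in*: positions and guides named in published text appear at
their real coordinates (e.g. the 25S peptidyl-transfer-center run
2921/2922/2923 and the U24-guided triad 1437/1449/1450); the remaining
positions and the reference sequence itself are generated deterministically.
Files carry "synthetic" in their names.
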