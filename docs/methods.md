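# Methods

This note documents the models implemented in `tetflank`, the choices
made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Substrate library and oxidation model

A library molecule is a fixed-length duplex: 20-nt invariant primer arms
around a 22-nt core of ten randomized bases, the target C, the +0' base X
(G for CpG libraries; drawn 1:3 CpG:CpH for CpN libraries, i.e. each of
G/A/C/T with probability 1/4), and ten more randomized bases. Only the
upper strand carries the modification (hemimodified design); the lower
strand is fully unmodified. Flank bases are i.i.d. uniform unless a
composition-bias vector is supplied. Coordinates are upper-strand 5'→3':
target C = 0, −10..−1 on its 5' side, +0' the base 3' of the C,
+1..+10 beyond it.

Oxidation follows the linear chain 5mC → 5hmC → 5fC → 5caC with rate
constants k1, k2, k3 and a processive branch 5mC → 5fC with rate k12
that models consecutive oxidation without enzyme release. Each molecule
is simulated exactly as a continuous-time Markov jump process with
exponential waiting times (Gillespie sampling, not time discretization),
so the library's marginal species fractions converge to the deterministic
solution of the rate equations as the library grows; this is tested
against the matrix-exponential solution. Rates may depend on the
molecule's full flank context through an arbitrary `rate_fn`, which is
how context preferences are planted in tests.

Bisulfite chemistry is applied per strand: C in state {unmodified, 5fC,
5caC} reads T (except with probability `conv_failure_rate`), C in state
{5mC, 5hmC} reads C (except with probability `over_conversion_rate`),
then uniform substitution noise at `seq_error_rate`. The hairpin that
physically links the two strands of one molecule in the wet-lab protocol
is abstracted as a linked read *pair* (upper read, lower read, shared
molecule ID); this preserves all information the reconstruction needs. A
concatenated single-record dialect (upper + configurable spacer + lower)
is available for realism; the exact hairpin/spacer sequence of the
original protocol is not fixed here and is therefore configurable.

All stochastic operations take an explicit seed, and the `simulate` CLI
writes a JSON run manifest.

## Readout

Reads are frame-anchored by the invariant arms (conversion-aware Hamming
match, default tolerance 2 mismatches per arm; mate orientation is
auto-detected, making the reconstruction symmetric under swapping the two
reads) rather than aligned — the library is a fixed-length design with no
indels, so an aligner would only add failure modes. The Q20 filter is
implemented as *mean* read quality ≥ 20 on both mates, the simplest
contract consistent with a per-read quality threshold; a length window is
available separately.

Duplex reconstitution resolves each position from the (upper, lower)
base pair: (C,G) → protected C; (T,G) → converted C; (T,A) → T; (A,T) →
A; (G,C) → G; (G,T) → G with the lower-strand C converted. Any other
combination is conversion-inconsistent and marks the position ambiguous.
Molecules with ambiguous flank positions are kept with `call=ambiguous`
and excluded from all statistics but counted in the QC report — the
handling of such molecules is a free choice, and rejection with
accounting was preferred over guessing. Molecules whose site class
contradicts the declared library type are routed to the QC report, not
dropped.

At the target, C means 5mC-or-5hmC and T means 5fC-or-5caC. On a 5mC
library an oxidized call therefore requires at least two oxidation steps,
on a 5hmC library at least one; downstream interpretation carries this
asymmetry.

## Flank statistics

Expected base frequencies in the obs/exp table default to the *empirical*
per-position frequencies of all retained molecules of the same sample.
This corrects synthesis/sequencing composition bias and reduces to 0.25
for unbiased libraries; a `uniform` mode is provided since either
convention is defensible. The conservation identity
Σ_b expected(b)·obsexp(b) = 1 holds by construction and is asserted to
1e−12.

Context profiles average the oxidized indicator over all molecules of
each NNCXNN context (4^(2k) contexts; k = 2 by default). Contexts with
fewer than 20 molecules are flagged low-coverage and propagate as nulls
into the kinetic fit (their residuals are dropped, never imputed). Ranks
are descending with min-rank ties. Extreme subsets default to the 10 most
preferred and 10 most disfavored contexts — the subset size is not a
measured quantity and is configurable — and are exported as per-position
base-probability matrices (rows sum to 1), the direct input to any
sequence-logo renderer; no plotting is done in the package.

The CpX summary assumes all site classes come from one competitive
reaction, so class activities share a scale and are reported relative to
the best class (100%). Classes below 200 molecules or below a mean
oxidation of 0.03 are excluded from profile analysis (the practical fate
of mCpT, whose product counts are too low for stable profiles); the
relative-activity histogram uses 20-percentage-point bins.

## Joint competitive kinetics

In a competitive reaction the relative turnover of all 256 contexts at a
given sampling point is precisely known even though the effective time
axis is not. Product fractions are modeled as z_i = 1 − exp(−k_i t_j) and
the objective Σ_j Σ_i (y_ij − z_ij)² is minimized jointly over k_i ≥ 0
and latent times t_j ≥ 0 with the gauge t_1 = 1 (rates are in units of
1/t_1). Initialization is k_i = 1, t_j = 0.5, with a budget of 100,000
evaluations. The optimizer is a bounded trust-region least-squares solver
with the analytic Jacobian (∂z/∂k = t·e^(−kt), ∂z/∂t = k·e^(−kt)) —
the same objective as a generic constrained minimizer, but much better
conditioned; bounds are k ≤ 10³ and t ≤ 10², wide enough never to bind
on realistic data, and no ordering constraint is imposed on the latent
times. With a single time point the closed form k = −ln(1 − y) is
returned directly. An optional jittered multi-start flag exists as a
ruggedness check; the default single start from the prescribed
initialization converges to machine precision on noiseless data, and
under binomial counting noise (10⁴ molecules/context/time, 4 time
points) recovers a planted 50-fold rate span to within ~1%. Residual
weighting by per-context counts is available behind a flag but off by
default: the objective as written is unweighted.

## Four-species ODE fitting

Two integrators are provided. Forward Euler at dt = 0.01 min mirrors the
spreadsheet-style procedure commonly used for such data and preserves
the linear conservation law exactly up to round-off; a stability guard
rejects dt·(max exit rate) ≥ 1. The matrix exponential of the 4×4 rate
matrix is the exact solution of the linear chain and serves both as the
accuracy oracle for Euler (agreement < 1e−3 sup-norm at the default step
over 60 min for per-minute rates ≤ ~0.2, the measured range for TET
catalysis) and as the model evaluation inside fits, where it is ~100×
faster than stepping.

Measured signals are mapped to concentrations via per-species
multiplicative intensities (bounds [0.1, 10], 5mC pinned at 1 as the
identifiability gauge) and additive baselines (bounds [−0.05, 0.05]); the
exact nuisance structure is our choice. Raw LC-MS ingestion starts from a
per-species signal table: each signal is divided by the internal
cytosine reference, calibrated, and each time point's modified-cytosine
vector normalized to sum 1. Fitting minimizes RMSD with seeded jittered
multi-starts (default 5). For model selection the four-rate fit is
additionally seeded from the three-rate optimum: the models are nested,
so this guarantees the RMSD ordering reflects the processive branch and
not optimizer luck. 5hmC-substrate reactions fix k1 = k12 = 0. Curves for
5mC and 5hmC substrates are fitted separately by default; a joint mode
(`fit_progress_shared`) shares k2 and k3 across the two reactions in one
least-squares problem, for when the same enzyme preparation and
conditions justify it. Simulated measurement noise in the
model-selection checks is Gaussian with sigma = 0.01 on species
fractions, a typical relative precision for calibrated, normalized LC-MS
species quantification.

Rate-ratio summaries between preferred and disfavored substrates divide
each rate by the enzyme concentration of its reaction before taking the
ratio, since disfavored substrates are typically measured with more
enzyme.

## Genomic analyses

Per-CpG tracks are bedGraph-style TSVs (0-based half-open; + strand CpGs
only), filtered at coverage ≥ 10; malformed rows are rejected with line
numbers. Contexts are extracted from an indexed FASTA and validated to be
CG at the site. The hydroxymethylome is BS − oxBS clamped at 0 (sampling
noise can make the difference negative); the methylome is the oxBS level.

The mixture prediction min-max normalizes the TET preference, 5mC and
5hmC context profiles to [0, 1] and scans α ∈ {0, 0.01, …, 1} for the
mixture α·TET + (1−α)·5mC maximizing Pearson correlation with the 5hmC
profile. Normalization-plus-grid-search is our documented choice for an
operation whose original normalization is underdetermined; recovery of a
noiseless construction is exact to the grid step. When two enzymes'
preference profiles must be combined, they are averaged after min-max
normalization.

Sliding-window correlations use runs of consecutive retained CpGs in
coordinate order ("consecutive" is defined on retained sites; an optional
max-gap in bases splits runs, default unlimited). Each 18-site window
contributes the Pearson R between its 5hmC levels and the TET preference
looked up per site context; zero-variance windows are skipped and
counted, and the histogram reports the positive and negative window
fractions and their ratio per |R| bin of width 0.1.

The knock-out analysis intersects wild-type and KO tables on (chrom,
pos), computes Δm = m(KO) − m(wt) per site, and measures obs/exp base
enrichment at the −1/+1 positions in the top-10,000 gain sites against
the all-shared-sites background (ties in Δm break by coordinate).

## Synthetic genome generator

The generator produces a seeded uniform-random reference (default 2 Mb;
tests and the acceptance script use 200–500 kb, which already gives
~9,000–22,000 CpGs — ample for the statistics while keeping runs in
seconds), beta-distributed 5mC levels (optionally context-modulated to
emulate DNMT flank preferences), 5hmC levels coupled to a TET preference
table with weight `coupling` plus Beta(2, 2) noise and scale
`hmc_scale = 0.3` of the local 5mC, Poisson coverage (mean 30), and
binomial observed levels for BS and oxBS. The KO generator adds a
methylation gain proportional to the TET preference of each context.
What this emulates: context-dependent level structure, counting noise,
coverage variation, the BS/oxBS difference construction. What it does
not: CpG islands and domain structure, strand asymmetries, mapping
artifacts, or any real-genome sequence composition — so passing tests
demonstrate correctness of the statistics and estimators on data of the
assumed generative form, not biological conclusions about real genomes.

The built-in `synthetic_tet_preferences` table is a multiplicative
per-position weight model (A strongly preferred and G strongly disfavored
at −1, C disfavored and T preferred at +1, milder effects at ±2),
qualitatively matching measured TET preference profiles; it is a
synthetic stand-in, not measured data.

## Numerical conventions and limitations

Ties in ranking use min-rank; context tables are always emitted in
lexicographic order for stable output. All-zero observation matrices are
unidentifiable and return zero rates with a warning rather than raising.
Convergence tolerances are 1e−12 on cost change for both fitters.

Known limitations: no PCR bias, demultiplexing or base-caller error
profiles in the read simulator; no indel handling in the readout (the
design is fixed-length); no bootstrap error bars on fitted rate
constants; the joint fit assumes first-order kinetics throughout and
offers no alternative rate law.
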