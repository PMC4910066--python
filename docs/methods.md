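# Methods

## The repeat-divergence clock

A gene containing an intramolecular direct repeat began as a tandem
duplication. At that moment — the earliest ancestral gene (EA-gene) — the
two repeat copies were identical. Afterwards the copies accumulate
substitutions independently, so the pairwise evolutionary distance
between them inside one present-day gene,

    d_DR = d(repeat_1, repeat_2),

estimates twice the per-copy divergence accumulated since the
duplication: if each copy has accumulated mu*t substitutions/site,
E[d_DR] = 2*mu*t. Unlike a conventional between-gene distance, d_DR
needs no outer group: its zero point (the EA-gene) is internal to every
gene in the family. Ranking genes by d_DR ranks them by similarity to
the common ancestor.

The interpretation rests on two preconditions, implemented as explicit,
reportable criteria rather than silent assumptions:

* **Criterion 1 — single duplication.** All family members must inherit
  their repeat from one duplication event; a later re-duplication resets
  the clock for that lineage and breaks comparability. Following the
  paralog-rooting argument, the joint neighbor-joining tree of all
  first+second repeat sequences must contain an edge whose bipartition
  is exactly {first repeats} | {second repeats}. We report a
  `separation_score` — the best fraction of leaves on their correct side
  over all edges and both orientations (always >= 0.5) — and the
  misplaced leaves when it is < 1. The test is run on the NJ tree of the
  chosen distance model; no likelihood re-estimation is attempted, which
  matches the distance-based workflow the rest of the package uses.
* **Criterion 2 — conservation ratio.** Two i.i.d. unbiased random
  nucleotide sequences agree at ~25% of sites, so repeat identity close
  to that floor carries no signal. The default cutoff is identity >= 30%:
  above the floor with margin, while still admitting every family both
  reference tables contain (their minima are 32.6% and 39.9%). The cutoff
  is configurable in (25, 100]; a permutation mode (shuffle one repeat's
  comparable columns, pass iff observed identity exceeds the 99th
  percentile of the null) is available for borderline or
  compositionally biased pairs.

Genes failing either criterion, or with saturated distances, are kept in
the report flagged and excluded from rankings — never silently dropped.

## Distance models

All comparisons use **pairwise deletion**: a column counts only when
both sequences carry an unambiguous base (gaps, N and X are excluded).
This is why "compared bases" can differ between genes of one alignment.
Identity percent is rounded half-up to one decimal, matching the
convention of printed tables.

Closed forms (p = fraction of differing compared sites; P, Q =
transition/transversion proportions; g_X = pooled base frequencies):

* `p`: 1 − identical/compared.
* `jc69`: −(3/4) ln(1 − 4p/3).
* `k2p`: −(1/2) ln(1 − 2P − Q) − (1/4) ln(1 − 2Q).
* `tn93`: the standard Tamura–Nei estimator with purine/pyrimidine
  transitions separated and observed base frequencies. Verified against
  an independent implementation (ape's `dist.dna`) to 1e-12 on a frozen
  input; undefined when a base is entirely absent from the compared
  sites.
* `mcl_composite` (default): a Tamura–Nei-form distance whose *shared*
  rate parameters are estimated once per alignment set by maximizing the
  composite likelihood — the sum over sequence pairs of each pair's
  multinomial log-likelihood sum_ij F_ij log(pi_i P_ij(d)), with base
  frequencies fixed at pooled empirical values, each pair's branch
  length d profiled out at its own maximum (vectorized golden-section
  on [1e-9, 10]), and the two transition/transversion rate ratios
  (kappa1, kappa2) optimized by Nelder–Mead. This emulates the
  documented default behaviour of MEGA's "maximum composite likelihood"
  distance; it is not a bit-exact clone — MEGA's exact internal
  iteration is not fully published, so this package states its own
  likelihood precisely instead.

Saturation (a log argument <= 0, or a composite-likelihood optimum at
the branch-length bound) yields `inf` plus a flag, never NaN and never a
capped value. Gamma rate variation is deliberately not offered: the
distance defaults being emulated assume uniform rates.

## Trees

Neighbor joining, Newick I/O and Robinson–Foulds comparison are
delegated to scikit-bio; NJ's small negative branch lengths are clamped
to zero (standard practice, and what keeps the additive-matrix
exactness tests meaningful: path lengths on the NJ tree of an additive
matrix reproduce the input to <= 1e-9). Trees are unrooted throughout —
rooting is precisely what the method avoids. An optional ladderization
keyed on per-gene d_DR reorders children for display only.

## Downstream statistics

* **Correlation/regression** (`correlate`): Pearson r with the standard
  two-sided t test (df = n − 2) and the OLS line of y on x. The p-value
  convention is documented because published figures typically report
  only "p < 0.01" without naming the test.
* **EA-protein extrapolation** (`extrapolate_ea`): with residue counts
  regressed on d_DR, the intercept is the predicted count at d_DR = 0,
  i.e. in the EA-protein — valid under the explicit assumption that the
  count varies linearly with d_DR throughout evolution. Negative
  intercepts are reported raw and clamped at 0 (a count cannot be
  negative; a strongly negative intercept reads as "none of this
  residue"). Counts are taken over a user-specified core region by
  default, with full-length mode available; per-residue correlations are
  reported raw, with no multiple-testing correction across the 20
  residues.
* **Emergence order** (`infer_emergence_order`): regress family B's
  d_DR on family A's across shared species. Under the two stated
  assumptions (cross-family comparability of d_DR; linearity), a slope
  within a configured band around 1 (default 0.8–1.2) means both genes
  accumulate mutations at a similar rate, and then a significantly
  positive intercept (one-sided t test on the intercept, default alpha
  0.05; on an exact fit any nonzero intercept counts) means family B had
  already diverged when family A was created — B emerged first. The
  verdict bands are configuration, not claims: the underlying argument
  is qualitative ("slope approximately 1, intercept positive"), so the
  defaults simply make it reproducible.

## The simulator

`simulate_family` draws a prototype sequence from the model's stationary
distribution, duplicates it at time 0, and evolves both copies
independently along a species tree whose branch lengths are expected
substitutions/site per copy. Substitution is simulated *exactly* by
per-site Poisson event counts under uniformization: events arrive at
rate lambda = max leaving rate of the generator Q, each applying the
jump kernel K = I + Q/lambda (self-transitions allowed) — no time
discretization, valid for any of the three generators (JC69,
K2P(kappa), TN93(kappa1, kappa2, pi), all scaled to one expected
substitution per site per unit time). Output is bit-reproducible given
the config, and every run carries a truth table of expected d_DR per
species.

Key defaults, chosen once as the study conditions the package is
validated under:

* `repeat_length = 282` sites — the repeat comparison size of the larger
  packaged family table.
* `stem_offset = 0.1` substitutions/site per copy between duplication
  and the species-tree root. The single-duplication test is only
  meaningful when the duplication predates the radiation: the stem is
  exactly the internal edge separating the two repeat clades, and with
  a zero stem the joint tree is a star and criterion 1 is undecidable.
  Set to 0 to model duplication at the radiation itself (used by the
  estimator-calibration tests, which need E[d_DR] = 2*mu_t with mu_t
  the root-to-tip depth alone).
* species trees: a user Newick, a star tree (`n_species` tips at depth
  `mu_t`, default 8 x 0.25), or a seeded pure-birth (Yule) generator.
* `second_duplication`: overwrite one tip's second copy with its first
  at the start of its terminal branch — the engineered criterion-1
  violation; that lineage's true d_DR restarts from the reset point.
* two-family mode: family B gets an extra stem divergence delta, so its
  true d_DR exceeds family A's by 2*delta on every species with equal
  rates thereafter — the slope ~ 1, positive-intercept regime the
  emergence-order analysis is designed to detect.

What the generator deliberately does not emulate: indels (inputs are
assumed pre-aligned; gap handling is exercised through hand-built
alignments instead), codon structure and selection (the criteria operate
on nucleotides), and rate heterogeneity across lineages beyond the
family offset. Passing tests therefore demonstrate correctness of the
estimators and decision rules under the stated substitution models —
they do not certify behaviour on real alignments with alignment error or
selection, which is why criterion checks and saturation flags are
surfaced rather than auto-resolved.

## Numerical choices and test scale

* Half-up rounding for printed identities (floor(10x + 0.5)/10).
* Golden-section profiling of composite-likelihood branch lengths on
  [1e-9, 10] (70 iterations, bracket < 1e-12); distances within 1% of
  the upper bound are reported saturated.
* The kappa search is bounded in log-space at e^±6; the eigendecomposition
  of the reversible generator is done once per candidate kappa via the
  pi^(1/2) symmetrization.
* NJ tie-breaking is the deterministic order of the underlying library,
  so identical inputs give identical trees.
* Monte-Carlo test sizes (50 replicates of 10 kb pairs for estimator
  bias; 20 replicates for criterion-1 power; 10 x 100 kb pairs for the
  random floor) were sized to keep Monte-Carlo error well inside the
  asserted bands, with assertions stated in standard errors where the
  quantity is stochastic.

## Input conventions and limitations

Inputs are coding-strand nucleotide FASTA (U mapped to T, case-folded);
ambiguity codes beyond N are rejected at parse time rather than
partially matched. Codon back-threading (`thread_codons`) maps an
unaligned CDS onto a given amino-acid alignment (residue -> source
codon, gap -> `---`), verifying translation under the standard code with
a configurable mismatch tolerance (default 0); producing the amino-acid
alignment itself is out of scope — curated alignments are accepted as
input, and published per-family d_DR values are shipped as a versioned
reference table rather than re-derived, since the manually curated
alignments behind them are not reproducible algorithmically. Absolute
time calibration (years since duplication) is likewise out of scope:
d_DR is a distance, and rate constancy across billions of years is an
assumption the method's own cross-checks (reference-gene distances,
cross-family slopes) can support but not prove.
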