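# Methods

## The question and the approach

Natural protein sequences are a thin, selected slice of sequence space.
To ask whether intrinsically disordered residues are *preferred* or
*avoided* — overall, and specifically near the N and C termini — the
package compares a proteome against randomized versions of itself that
preserve composition but destroy residue order. Any systematic difference
between real and shuffled sequences is then attributable to the
arrangement of residues, not to amino-acid (or nucleotide) content.

Three null models are implemented, each preserving per-protein length
exactly:

1. **Length-conserved**: a uniform permutation of each protein's residues;
   preserves the protein's full amino-acid composition. Used for
   proteome-wide disorder-content comparisons.
2. **Terminal-conserved**: independent permutations of the first and last
   200 residues, middle untouched (sequences with L ≤ 400 are split at the
   midpoint into two blocks); preserves terminal-region composition. Used
   for position-wise profiles near the termini.
3. **Column-wise**: proteins are anchored from both ends (residue *i*
   belongs to N-column *i* when *i* ≤ ⌈L/2⌉, else to C-column L−i+1) and
   residues are permuted across proteins within each column; preserves the
   proteome's per-position composition exactly.

The midpoint split in models 2 and 3 is a design choice: it assigns every
residue to exactly one block/column and preserves lengths; for dual-end
anchoring it is the only partition with that property.

Each model has a codon-level analogue that shuffles the codons of the
matched CDS (one token per residue; a terminal stop codon stays in place so
records remain valid). Under the codon-level length-conserved model every
sequence's genic GC is preserved *exactly*, which makes it the appropriate
null for asking whether GC, rather than amino-acid arrangement, drives a
positional signal.

## Scoring and consensus

External per-residue disorder predictors are consumed as score tracks
(three-column TSV: position, residue, score in [0, 1]); the package never
re-implements them. For self-contained runs a deliberately simple baseline
scorer is provided: the sliding-window mean (default window 21, truncated
at the ends) of a packaged per-residue disorder propensity scale — a
published order/disorder discriminating ranking rescaled linearly to
[0, 1], with polar/charged residues (P, E, K, S, Q, G, R) high and
aromatic/hydrophobic residues (W, F, Y, I, L, V, C) low. The baseline is a
stand-in with the same interface as a real predictor, not a competitor to
one; window 21 is the conventional smoothing width for profile-style
disorder scores, and the default call threshold is 0.5.

Binary calls from several predictors combine through a k-of-n agreement
rule. Two presets mirror common practice: *strict* (all n predictors must
agree) and *majority* (⌊n/2⌋+1). Per-protein disorder content is reported
as the percentage of all called residues (Dis_all) and the percentage of
called residues inside maximal runs of ≥ 30 consecutive calls (Dis_30);
runs are never merged across gaps — a single uncalled residue splits a
region.

## The positional Z statistic

For a per-residue quantity (score, call, per-codon GC, any ingested
track), the profile at position *p* (1…150 from either terminus, proteins
longer than 200 residues) is the mean over contributing proteins. The real
proteome's profile is compared with R = 10 independent replicate null
proteomes.

At each position, with replicate means m₁…m_R, the package reports:

- `z_ratio` = (real − mean(m)) / sd(m): the deviation in units of the
  replicate standard deviation;
- `p_value`: exact under the null, from Student's t with R−1 degrees of
  freedom applied to t = z_ratio / √(1 + 1/R);
- `z`: the signed standard-normal quantile of that p-value (a calibrated
  deviate).

The t construction is not optional polish. Under *any* of the
composition-preserving shuffles, the real profile mean is exchangeable
with the replicate means (conditional on composition, the real arrangement
is itself a uniform draw), so z_ratio is distributed as √(1+1/R)·t_{R−1}
— at R = 10 its |z_ratio| > 1.96 rate is ≈ 9.4%, nearly double the nominal
5%. The calibrated `z` restores the usual reading: |z| > 1.96 ⇔ p < 0.05
at any replicate count. Because the map from z_ratio to z is strictly
monotone, rank-based downstream analyses (Spearman correlation of paired
Z-profiles, heatmap orderings) are identical under either column.

Degenerate positions: zero replicate spread with real = null gives z = 0,
p = 1; zero spread otherwise gives a signed infinity sentinel with p = 0.
A `dispersion="pooled"` switch replaces the replicate-mean spread with the
across-protein dispersion pooled over replicates (normal p-values); an
empirical rank-based p is available when R is large (≥ 100).

### What the terminal-conserved null can and cannot show

A composition-preserving shuffle conserves mass. If real proteins carry a
disorder-promoting block in positions 1–30, the terminal-conserved shuffle
spreads those residues over the whole 200-position window: the null is
*elevated* above background at positions 31–200, so the real proteome
shows strongly *negative* z there — a necessary mirror image of the
positive terminal signal, growing with sample size, not an artifact. Users
should read mid-window negative z values accompanying a terminal peak as
the same enrichment seen from the other side. For this reason no
"flat far from the signal" behavior should be expected (or is asserted)
for block-injected proteomes; flatness at all positions is expected — and
verified — only when no signal is injected.

### Column-wise null and linear scorers

The expected profile mean of a *linear* window-mean score is invariant
under column-wise shuffling (the mean of a window average is the average
of column means). Hence the column-wise null detects contiguity only
through nonlinear statistics — e.g. the frequency of thresholded calls —
exactly as real disorder predictors (nonlinear in local composition) do.
The test suite demonstrates both facts: window-1 score profiles of a
constant-length proteome give z ≡ 0 against the column-wise null, while
call-frequency tracks with randomized block offsets give consistently
positive z.

## Cohort statistics

Mann–Whitney U uses midranks; p-values are exact (full enumeration of
label assignments, correct under ties) when n_x + n_y ≤ 12, otherwise the
tie-corrected, continuity-corrected normal approximation. The two
implementations are compared against each other and against scipy in the
tests; the normal approximation is accurate from roughly n_x, n_y ≥ 3 but
is intrinsically poor for the smallest samples (n_x + n_y ≤ ~6), where the
exact path is always used in practice. Spearman's ρ is the product-moment
correlation of midranks with the t approximation for p. Significance stars
follow the 0.05 / 1e−4 / 1e−6 convention.

Stratifications: genic-GC bins (default five equal-width bins over the
observed range; edges configurable), GO-term groups (a term qualifies with
strictly more than 100 proteins of strictly more than 200 residues;
proteins with several terms join every group), expression quantiles
(default top/bottom quartiles; ties and the all-equal degenerate case
resolve deterministically with a warning), and the splice-junction-free
subset (single-exon proteins, or first *and* last exon strictly longer
than 300 bp). For stratified Z-profiles the null replicates are
regenerated within each stratum, never sliced from proteome-wide
replicates.

## The synthetic generator

`synthetic.generate_proteome` emulates the structure the analysis assumes:
lengths log-normal (median 400, σ = 0.35, minimum 250 — long enough for
150-position profiles at the 200-residue inclusion cutoff), residues
i.i.d. from a Swiss-Prot-like background composition, and optional
30-residue blocks drawn from a composition with 84% of its mass on
G, R, Q, S, E, K injected at the N and/or C terminus with configurable
probability. Because every null preserves composition, the *contiguity and
placement* of blocks is the only recoverable signal; the `scattered`
dispersion mode (same residues, random positions within the first/last
200) exists precisely to show the signal vanish. Back-translation samples
synonymous codons of the standard genetic code with a single global
exponential tilt on codon G+C fitted by bisection to a target coding GC
(warning and clamping when the target is infeasible); a TAA stop is
appended.

What the generator does *not* emulate: inter-protein homology and
phylogenetic correlation, domain architecture, position-dependent
composition gradients beyond the injected blocks, codon-usage structure
beyond the GC tilt, and real predictor nonlinearity. Passing recovery
tests therefore show the statistical machinery is correct and calibrated —
not that any particular organism shows the biological effect.

## Problem sizes and numerical choices

Desk-scale defaults used by the test suite and the acceptance script (the
package's own choices for fast, reproducible runs): calibration uses 400
proteins per seed over 10 seeds (5 in the script); parameter recovery uses
2000 proteins (1000 in the script) at injection probabilities
{0, 0.25, 0.5, 1}; GC calibration uses 300 proteins per seed. All
randomness flows through numpy `default_rng` seeded from user-visible
integers; replicate r of a randomization uses the substream
`(seed, r)`, so replicates are order-independent. Shuffle exactness is
asserted as exact multiset equality, never approximately. Reports are TSV
with a header recording package version, seed, and a configuration hash;
identical configurations produce byte-identical outputs.

## Known limitations

- The baseline scorer is linear in local composition; against the
  column-wise null it is blind to contiguity by construction (see above).
  Ingest real predictor tracks for that comparison.
- Column-wise exactness holds per *column*; when protein lengths vary, a
  profile position past half the shortest included protein mixes N- and
  C-anchored columns, so profile-level z under the column-wise null is
  exactly zero only for constant-length proteomes (and a window-1 track).
- The normal approximation for Mann–Whitney is poor below n ≈ 3 per group;
  the exact path covers that regime.
- Proteins with 200 < L < 300 contribute residues to both the N and C
  profiles; the two anchored profiles are therefore not independent.
- GC profiles are codon-anchored and exclude a terminal stop codon, so
  codon position p aligns with residue position p.
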