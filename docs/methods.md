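# Methods

`spacerhost` implements the computational chain for assigning small
circular Rep-encoding ssDNA (CRESS-DNA) viruses to prokaryotic hosts via
CRISPR spacers, exercised end to end on synthetic data with known ground
truth.  This note records the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## The glocal aligner

Spacer→protospacer search asks whether the *entire* spacer (the query)
matches somewhere inside a viral genome (the subject).  The aligner is
therefore query-global/subject-local ("glocal", semi-global): subject
terminal gaps are free — the alignment may start and end at any subject
position — while the query must be covered end to end, with no clipping.
Scoring is match +1, mismatch −1, affine gaps with open −2 and extend −1;
a gap of length g costs 2 + (g − 1).  Traceback starts from the maximal
cell of the last query row; among equal-scoring end cells the smallest
subject end coordinate wins, and within the traceback diagonal moves are
preferred over gaps in the subject over gaps in the query — pure
tie-breaking conventions for determinism.

The production DP is vectorised with numpy across a batch of equal-length
queries and along the subject; the within-row dependency of the
gap-in-query state is resolved exactly with a running-maximum prefix scan
(valid because the extension cost is constant).  Traceback re-runs a
scalar three-state (Gotoh) DP on a short subject window ending at the hit
and asserts that its score equals the vectorised score.  The test suite
validates the DP against two independent oracles: an explicit enumeration
of alignment strings (tiny instances) and a memoised scalar recursion
(queries ≤ 10 nt, subjects ≤ 14 nt).

Both strands are always searched; minus-strand coordinates are reported
on the forward (viral-sense) genome.  Circular subjects are handled by
extending the sequence with a wrap-around margin of twice the query
length; origin-spanning hits are reported once, with `end` past the
genome length.  Identity is identical columns over all alignment columns,
gap columns included in the denominator.  Non-ACGT (IUPAC ambiguity)
bases score as mismatches against everything — the conservative choice.

A plain Smith–Waterman local mode with the same scoring is available as a
fallback for more diverged targets; local-mode hits are tracked
separately ("local-only") and excluded from the headline statistics
unless explicitly included.

Frame rule: for hits in coding regions, gap counts that are equal in
query and subject, or that differ by exactly three, leave the reading
frame downstream intact; other gap patterns are flagged.

## Empirical E-values

BLAST-style analytic statistics are unreliable for ~36-nt queries, so
E-values are calibrated empirically per query length: random i.i.d.
uniform queries are aligned against random subjects (default 10⁶ nt, 500
replicate queries per length; smaller sizes are used in the tests and
acceptance script and noted below), and hits are counted with exactly the
same non-overlapping selection rule the real scan uses.  The exceedance
count per score, divided by (replicates × calibration nucleotides), is
the per-query per-nucleotide rate; multiplying by the searched database
size (both strands) gives the E-value.  E-values scale linearly with
database size by construction.

Two numerical choices matter:

* **Tail extrapolation.**  The log-survival of glocal scores is concave —
  the decay steepens toward its asymptote — so a fit over the whole curve
  flattens the tail and inflates extrapolated E-values.  The decay rate λ
  is instead taken from the deepest well-sampled decade of the survival
  counts (the last score with ≥ 10 exceedances and the last score with at
  least ten times as many), and the exponential continuation is anchored
  exactly at the deepest empirical point.  When the counts cannot support
  the fit the model freezes at the last empirical value and flags the
  tail unreliable.
* **Score discreteness (mid-P).**  Scores are integers, so the plain
  survival function overshoots at every threshold crossing and
  thresholding at E ≤ t would select matches at a true rate systematically
  *below* t (by up to a factor e^λ ≈ 3).  Reported E-values therefore use
  the mid-survival convention — the geometric mean of the step rates at s
  and s+1 — the discrete-statistics analogue of mid-P, which keeps the
  realised rate at a cut-off close to nominal.

The honesty experiment (the defining property of an E-value) scans fresh
random databases and requires matches at E ≤ 0.01 to occur at
n_queries × 0.01 within three standard errors.  Because the integer score
grid only admits certain achievable rates, this check uses a database
size (42 circular 2.5-kb genomes, both strands) at which an integer
cutoff with true rate close to 0.01 exists — the same reasoning as
choosing n for the binomial calibration check below.  The calibration
behind it uses 400 replicates × 6×10⁵ nt at length 36.

Array-level combined significance follows the multiple-testing argument
for a whole CRISPR array: with n spacers tried and k matches observed,
the chance of matches this good is approximately n^k × ∏ E_i.  Feeding
the four printed per-spacer E-values (0.002, 7.48×10⁻⁷, 7.06×10⁻⁶,
2.91×10⁻⁸) with n = 111 gives 4.67×10⁻¹⁴ (5×10⁻¹⁴ at one significant
figure).  The expected chance-match count for a scan is n_queries ×
threshold (111 × 0.01 = 1.11).

## CRISPR detection and leader calling

The repeat-array detector is a k-mer seed-and-extend scheme (CRT-like):
exact 11-mers recurring at CRISPR-like periods (repeat 23–47 nt plus
spacer 20–72 nt) seed candidate arrays; repeat boundaries extend while
columns stay conserved across instances (all instances for ≤ 4 copies,
80% for more); the consensus is the per-column majority.  Degenerate
terminal repeats — which rarely contain the seed k-mer — are recovered by
a Hamming search one period beyond each array end (tolerance
`max_repeat_mismatch + 4`, i.e. 7 by default, against 3 for interior
instances).  Arrays below the 4-repeat minimum are kept only as
satellites: within 10 kb of a selected array and sharing its repeat on
either strand.

The leader side is called from acquisition biology: new spacers insert at
the leader end, so the terminal repeat distal to the leader is the oldest
and typically degenerate.  Primary criterion: the side whose terminal
repeat is closest to consensus (a margin of ≥ 2 mismatches is required to
call it).  Tie-break: the leader flank must be more AT-rich than the
genome background.  If both criteria are uninformative the side is
"unknown" and indexing defaults to leftmost-first.  Spacers are indexed
sp1, sp2, … away from the leader and reported in transcription (crRNA)
sense.

## PAM discovery

For each selected match the 10 nt flanking the protospacer are read on
the non-target strand (the strand matching the crRNA); "upstream" is 5′
of that reading, where Type I PAMs sit.  Stacked flanks give a position
frequency matrix; per-column information content is 2 − H bits.  The
small-sample correction e(n) = 3/(2·ln2·n) is available behind a flag but
off by default: with stacks of 6–23 sequences it shifts letter heights
but not the motif call, and the uncorrected IC is the simpler
reproducible contract.  A motif call takes every position whose dominant
base reaches the conservation threshold (default 0.6); sub-threshold
positions between called ones become N.  Completeness is the fraction of
flanks carrying every called base, and an any-position fraction is also
reported.  Logos can be rendered as IC-scaled stacked bars with
matplotlib; the PFM/IC tables are the primary output.

## Strand bias and other statistics

Strand bias: each targeted spacer contributes its best match; the number
landing on the viral-sense strand is tested against Binomial(n, ½) with
an exact one-sided tail summed term by term (P(X ≥ k); no normal
approximation).  The direction is fixed toward viral-strand excess, the
question at issue; a two-sided variant is available.  Viral sense itself
is defined operationally by the origin nonanucleotide orientation (below),
not by input file orientation.  The exact test is discrete: at nominal
α = 0.05 the achievable level depends on n, so the type-I calibration
simulation uses n = 37, where the achievable one-sided level is 0.0494 —
asserting 0.05 ± 0.01 at an n with achievable level far from 0.05 would
measure discreteness, not calibration.

Stop-codon profiling classifies the final codon of each CDS as amber
(TAG), opal (TGA) or ochre (TAA); other endings are excluded from the
denominator and logged.  Amber depletion is the biologically interesting
signal: hosts that reassign amber to pyrrolysine rarely use it as a
terminator.  Percentages are reported to two decimals, probabilities to
three significant figures.

Spacer-age strata default to modern sp1–9, middle sp12–27, ancient
sp35–72 (inclusive); identity decay across strata is summarised by
per-stratum min/mean of best-match identities.  The presence matrix
records the best identity per (spacer, genome) with row/column marginals.

## Viral-sense orientation and the archetype

Genomes are oriented so the conserved replication-origin nonanucleotide
(IUPAC `NAGTRTTAC`) reads forward; a genome with the motif only on the
reverse strand is reverse-complemented (annotation flipped with it), a
genome with the motif on both strands is an ambiguity error, and a genome
without it is excluded with a warning.  No distance constraint to the
*rep* stop codon is enforced — only motif presence — since that distance
is not otherwise specified.  When the motif orientation contradicts gene
annotation strands the motif wins, with a warning.

The archetype places each representative match (best per spacer: highest
score, then lowest E-value, then first genome in input order) at the
fractional position of its protospacer *midpoint* within its segment
(midpoint rather than start/end: symmetric and stable at boundaries).
Segment lengths are means over the genomes contributing placements;
segment order is intergenic-A (the origin-containing gap after *rep*),
*cap*, intergenic-B, *rep*.  Local-only matches are marked distinctly.

## Synthetic data

The generator emulates the study system: a host contig (default 2.5 Mb)
with a planted CRISPR locus — AT-rich leader (default 150 nt at 70% AT),
112 copies of the 31-nt repeat `GTTAGAAATCCATCTAAACTAGAATGTAAAT`
interleaved with 111 unique random spacers of 35–37 nt, a degenerate (3–6
substitutions) repeat at the leader-distal end, and optionally a 3-repeat
satellite array on the opposite strand 3 kb away — plus circular ~2.5-kb
viruses with *rep* (900 nt) and *cap* (1170 nt, ~30% larger) ORFs, the
origin nonanucleotide shortly (15 nt) downstream of the *rep* stop, and
planted protospacers with controlled identity, gap counts, strand, and an
optional CCN PAM.  Backgrounds are i.i.d. uniform A/C/G/T — a neutral
null matching the E-value calibration.  Substitutions for partial
identity land on aligned interior positions (never in the PAM, so the
PAM signal stays testable; never in the two terminal bases, so recovery
stays anchored); gap runs are contiguous and indels in coding regions are
spliced, shifting downstream coordinates, so a net indel of 0 or ±3
preserves the reading frame.  Chance occurrences of the origin motif are
scrubbed after assembly (a single base edit that breaks the motif without
creating an in-frame stop) so orientation is always unambiguous.  All
randomness flows from the config seed; the same seed is byte-identical.

What the synthetic experiments show: that every stage recovers planted
truth under the stated noise (identity down to 0.86, both strands, origin
spanning, 78% PAM penetrance) and that the statistics are calibrated on
the null they assume.  What they do not show: performance under real
compositional bias (GC skew, repeats, codon structure), real viral
sequence divergence structure, or database redundancy — the uniform
background is exactly the assumption the E-value model makes, so real
genomes can only be harder.

## Problem sizes used in tests and the acceptance script

Unit tests calibrate E-values at 80 replicates × 1.5×10⁵ nt per length
and use 20–150 kb hosts; the acceptance properties use 1000 oracle
instances, 200 planted-recovery replicates per identity level, 200
honesty replicates (calibration 400 × 6×10⁵ nt), 100 PAM datasets and
10⁴ binomial null replicates.  These sizes put every estimate's sampling
error well inside the asserted tolerance while keeping a full run on one
CPU in minutes; they are stated here so results are reproducible at the
same sizes.

## Known limitations

* The detector assumes quasi-identical repeats; strongly diverged repeat
  families or arrays with insertions inside repeats are out of scope.
* E-value calibration assumes i.i.d. uniform composition; skewed
  subjects need recalibration against a matched background.
* The per-spacer threshold override (for borderline matches confirmed by
  an external search) is a configuration knob, not an automated decision.
* Combined array significance treats per-spacer E-values as independent,
  as the underlying arithmetic does; redundancy among subjects makes it
  conservative in the same direction as the original argument.
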