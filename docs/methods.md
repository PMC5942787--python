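# Methods

## Melodic proxy: the highest-pitch line

Polyphonic keyboard scores have no unambiguous "melody"; the package uses
the topmost sounding pitch as the melodic proxy.  Operationally, at every
onset where at least one non-grace note begins, the maximum pitch among
all notes sounding at that instant (started and not yet ended) is
emitted.  Consequences of this literal reading:

* a sustained high note suppresses the emission of lower notes that
  start underneath it, and is itself emitted only once;
* tied notes count as one tone, as do slurred repetitions of the *same*
  pitch; slurred notes of different pitches are kept separate, because
  merging them would delete melodic intervals (this is the one place the
  slur rule is genuinely ambiguous; the package resolves it in favour of
  preserving intervals);
* grace notes are excluded entirely — they neither emit nor trigger an
  emission;
* rests do not break a sequence (n-gram windows may span them), but
  movement boundaries do: windows never cross movements.

MusicXML reading is a purpose-built partwise parser on lxml covering
pitched notes, chords, rests, grace notes, ties, slurs,
`backup`/`forward` and mid-part `divisions` changes.  Onsets and
durations are exact rationals (quarter-note units), so no floating-point
timing artifacts can reorder events.  Compressed `.mxl`, MEI, ABC and
MIDI input are out of scope.

## Transition statistics

For order *n*, every window of n+1 consecutive tones contributes one
count.  The window is stored relative to its first pitch (first offset
0), the first *n* offsets forming the context and the last the outcome.
Probabilities are raw maximum-likelihood ratios
`count(context, outcome) / count(context)` with no smoothing or
pseudo-counts: an unobserved context is *absent* (returned as `None`),
never 0/0, and an observed context with an unseen outcome has
probability 0.  Because contexts are stored in relative form, a context
is shared by all of its transpositions — this is what makes the whole
analysis a relative-pitch analysis.

**Pooling.**  Movement-level tables are pooled into a piece-level table
by summing counts.  This equals a weighted average of per-movement
probabilities with weights proportional to per-movement context counts;
it was chosen over an unweighted average of probabilities because it
makes the piece-level table the maximum-likelihood estimate for the
piece and is invariant to how a piece happens to be split into
movements.

**Universality.**  A pattern enters the regression only if its full
(context + outcome) count is ≥ 1 in every piece's pooled table.
Universality is assessed at piece level (after pooling), not per
movement.  The corpus matrix built from universal patterns is therefore
strictly positive in every cell.

## Trend regression

The regressand is the piece serial number 1..N (publication order); the
candidates are the universal-pattern probabilities.  Selection is
forward stepwise: at each step the candidate with the smallest partial
p-value enters if p < `p_enter`; afterwards any included predictor with
p > `p_remove` is removed, worst first; every accepted model is recorded
on the path.  Defaults are `p_enter = 0.05` (the stated significance
level) and `p_remove = 0.10` (the common statistical-package default;
both are configurable).  Ties on partial p-value go to the
lexicographically smaller pattern, for determinism.  A forward step is
not attempted when it would leave fewer residual degrees of freedom than
an intercept model requires (n ≤ k + 1).

Diagnostics follow the conventions of the SPSS-style collinearity
output the report layout mirrors:

* standardized coefficients `beta_j = B_j · sd(x_j) / sd(y)` with sample
  standard deviations;
* `VIF_j = 1 / (1 − R²_j)` from regressing column j on the remaining
  columns plus an intercept (exactly 1 for a single predictor; infinite,
  not an exception, under exact collinearity);
* condition indices from the singular values of the *uncentered* design
  including the intercept column, every column scaled to unit Euclidean
  norm: `CI_j = s_max / s_j`, reported ascending.  Verified numerically:
  this convention reproduces the published per-model CI values for the
  packaged matrices to two decimals.

The adopted ("final") model is the path model with the most predictors
among those in which every VIF < 2 and every CI < 20; ties break toward
higher R².  If no path model passes, the screening error names the
violated criterion.  The CSV report attaches the model's largest
condition index to each coefficient row (the per-dimension indices are
in the JSON report); which index belongs to which row is a presentation
convention, not a model quantity.

Identities `adj R² = 1 − (1 − R²)(n−1)/(n−k−1)` and
`F = (R²/k) / ((1−R²)/(n−k−1))` hold to 1e-10 by construction and are
used in reverse (`adj_r2_from_f`) to cross-check reported F statistics
against reported adjusted R² values.

## Packaged datasets

`datasets/beethoven_sonatas/order{1..5}.csv` hold the 32-sonata
transitional-probability matrices (20, 37, 12, 3 and 1 universal
patterns at orders 1–5), transcribed verbatim at their printed 3-decimal
precision, column order preserved.  Two known quirks of the source are
reproduced verbatim rather than corrected: the order-1 rows for pieces
1 and 29 are identical, as are the order-4 rows for pieces 1 and 11.
Regressions on these matrices reproduce the source statistics within
tolerances that absorb the 3-decimal input rounding (|Δadj R²| ≤ 0.03,
|ΔF| ≤ 0.4, coefficients within 5%).

## Synthetic corpus generator

The generator emulates the study geometry, not real music: an ordered
corpus whose movements are realizations of an order-n interval Markov
chain, with one designated pattern's probability drifting linearly in
the piece serial number, `p_t = clamp(p_0 + slope·(t−1), 0.01, 0.99)`.
Sibling outcomes within the drifted context are rescaled proportionally
so every context remains a proper distribution at every t; when the
target is the context's only outcome there is no sibling to exchange
mass with and its probability stays 1 (this keeps a degenerate
single-outcome chain strictly periodic).  The clamp bounds keep every
outcome observable, so universality remains plausible at the default
lengths.

Defaults (chosen once, as the conditions under which the pipeline is
validated): 32 pieces × 3 movements × 2000 notes, order 1, an 8-interval
base distribution dominated by small steps, target pattern `[0,2]` at
base probability 0.20, slope +0.012 per piece-index step (reaching 0.57
by piece 32).  At this effect size the full pipeline recovers the target
in ≥ 90% of replicates; with slope 0 the target is selected in ≤ 15% of
replicates (empirically ≈ 0 at 200 replicates).  Sequences are
pitch-realized from C4 by cumulative offsets and are reproducible
bit-for-bit from (spec, seed): each movement's stream is keyed by
(seed, piece index, movement index).

What the generator does **not** emulate: meter, tonality, phrase
structure, voice leading, movement-length variation, or any
higher-order dependence beyond the specified chain.  Passing recovery
tests therefore demonstrate that the estimator chain is correct under
its own model assumptions, not that real corpora satisfy them.

## Numerical and interface choices

* Pitch representation: integer semitones, MIDI convention (C4 = 60).
* Matrix CSVs round-trip exactly: written at repr precision, read with
  pandas' `round_trip` float parser.
* TP-table exports round to 3 decimals on output only; full precision is
  retained internally.
* Diatonic decoding realizes a pattern from each degree of a 7-tone
  scale, octave-reduced, keeping it iff every realized pitch class is in
  the scale; spelling uses the scale's own natural note names, with no
  enharmonic inference.
* The acceptance script runs 200 replicates per recovery experiment;
  the reported rates are Monte-Carlo estimates with binomial standard
  error ≤ 0.035.

## Known limitations

* The highest-pitch proxy misattributes melodies carried in inner or
  bass voices.
* Universality filtering discards patterns absent from any piece, so the
  analysis says nothing about patterns that appear or vanish mid-career.
* No multiple-testing correction is applied across Markov orders; the
  stepwise procedure's selection inflates the nominal α across
  candidates (measured against a permutation oracle in the tests).
* Variable-order / back-off models, smoothing, and information-content
  measures are out of scope.
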