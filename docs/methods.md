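# Methods

This note documents the models and procedures implemented in `aggrevar`,
the defaults that matter, and the design decisions taken where the
conventions were genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## APR calling and gatekeeper flanks

A per-residue aggregation-propensity track assigns each residue a score on
a percent scale, `s_i ∈ [0, 100]`. An aggregation-prone region (APR) is a
maximal run of at least 5 consecutive residues with `s_i > 5` (strictly
greater; a residue at exactly 5.0 terminates a run). Runs are maximal by
construction: extending any called APR by one residue violates the
threshold or the track bounds. Two qualifying runs separated by even a
single sub-threshold residue are distinct regions; no merge rule is
applied.

The **region score** is the *sum* of the per-residue percent scores over
the span. Whether a per-region scalar should be a sum, mean or maximum is
a convention; the sum is adopted here because the downstream "strong APR"
cut of 70 is only meaningfully reachable on a percent scale by summation
(a 5-residue region averaging > 14%/residue crosses it). The convention is
isolated in `aprs.region_score_from_track` so it can be swapped without
touching callers.

The three positions before and three after an APR are its gatekeeping
flanks, clipped at the sequence termini rather than discarded. Flank
residues in {P, R, K, E, D} are gatekeepers; N- and C-side gatekeepers are
not distinguished. Charged gatekeepers oppose aggregation by charge
repulsion, arginine/lysine additionally by bulk and flexibility, and
proline by β-incompatibility.

## Stand-in propensity scorer

Every downstream rule consumes only the track, so the pipeline is
predictor-agnostic: externally computed tracks imported from TSV always
take precedence. The shipped scorer exists so the package runs end to end
without an external predictor. It is deliberately simple and is not a
reimplementation of any published statistical-mechanics method:

```
raw_i  = w_h · ⟨hyd⟩_w(i) + w_b · ⟨beta⟩_w(i) − w_c · |Σ charge|_w(i) / w(i)
s_i    = 100 / (1 + exp(−(raw_i − m) / τ))
```

where `⟨·⟩_w(i)` averages over a centered window (default 7 residues;
windows at the termini are truncated and renormalized by their actual
width — no padding residues are invented), `hyd` is the Kyte–Doolittle
hydropathy index and `beta` the Chou–Fasman β-sheet preference, each
min-max normalized over the 20 residues, and the charge term penalizes net
window charge (D/E = −1, K/R = +1, histidine treated as neutral). Each
window is summed independently (direct convolution), which makes the
scorer's locality exact: a single substitution changes scores only within
one window radius, bit for bit.

Defaults `w_h = w_b = w_c = 1`, `m = 1.5`, `τ = 0.15` were calibrated once
and frozen so that (i) fully hydrophobic stretches score near the top of
the scale, (ii) charged or proline-rich stretches (e.g. poly-glutamate)
score below the 5% APR threshold, and (iii) a random sequence of natural
residue composition has roughly one residue in ten inside a called APR.
Ambiguity codes (B, Z, X) are rejected at parse time because the scorer
has no parameters for them.

## Variant classification

Intrinsic effect, with precedence `DE_NOVO_APR > IN_APR > GATEKEEPER >
OUTSIDE`:

* `DE_NOVO_APR` — some mutant APR shares no position with any wild-type
  APR. A variant that both creates a new APR and lies inside an existing
  one counts as de novo, because de-novo creation is reported as a
  separate, additive category.
* `IN_APR` — the position lies inside a wild-type APR. Wild-type
  boundaries are authoritative for membership; the mutant track enters
  only through the de-novo test and the score delta.
* `GATEKEEPER` — the position is a wild-type flank position *and* the
  wild-type residue is in {P, R, K, E, D}.
* `OUTSIDE` — everything else.

The direction of change follows the sign of
`Δ = Σ region scores(mut) − Σ region scores(wt)`; `|Δ| ≤ ε` (default
ε = 1.0 percent-sum units) is neutral, absorbing floating-point noise from
rescoring. A de-novo APR is always an increase. When the wild-type track
was supplied externally, the intrinsic delta still compares stand-in
wild-type against stand-in mutant tracks, since an external predictor
cannot be re-run on arbitrary mutants and mixing scales would make Δ
meaningless; APR membership and domain signatures use the supplied track.

Stability classes from ΔΔG (kcal/mol, positive destabilizes):
stabilizing `< −0.5`, neutral `[−0.5, 0.5]`, destabilizing `> 0.5`,
strongly destabilizing `≥ 2` (a refinement of destabilizing).

The **combined rule** flags a variant as aggregation-increasing iff
`ΔΔG ≥ 2` (inclusive) and the strongest APR region score of the variant's
domain exceeds 70 (strict), matching the stated inequality forms. The rule
uses the *wild-type* domain signature — the mechanism modeled is
destabilization exposing a pre-existing buried APR, not a mutant-sequence
property. Variants without a ΔΔG value or not covered by any annotated
domain receive NA (distinct from False) and are excluded from rule
denominators; exclusion counts are reported in the run summary.
Inter-domain (linker) variants are assigned no domain and therefore fall
into this NA class. The disorder flag is `disorder score ≥ 0.5`
(inclusive) at the variant position, NA without a track.

## Domain signatures

A variant belongs to the unique domain covering its position (domain
annotations may not overlap; overlapping input is rejected rather than
resolved by a guessed precedence). An APR is assigned to every domain with
which it shares at least one residue; an APR straddling a boundary
contributes its full region score to both domains — the simplest reading
of the one-residue membership rule, again isolated for swapping. The
signature of a domain is (i) total track score over the domain divided by
domain length, using all residues, not only APR residues; (ii) the number
of assigned APRs; (iii) the strongest assigned APR region score (0 when
none).

## Structural metrics

Minimal variant-to-APR distance is the minimum Euclidean distance over all
atom pairs between the variant residue and any APR residue, 0 by
definition when the variant lies inside the APR span, NA (with a warning)
when either side is unresolved in the structure. Residue numbering in the
structure must match sequence numbering identically; no re-alignment is
attempted.

Solvent-accessible surface area uses a deterministic Shrake–Rupley
implementation: a 960-point golden-spiral unit sphere per atom, probe
radius 1.4 Å, and standard van der Waals radii (C 1.70, N 1.55, O 1.52,
S 1.80, H 1.20 Å). Burial is computed separately over sidechain and
mainchain atom sets (backbone = N, CA, C, O, OXT) as
`1 − ASA_observed / ASA_reference`, clipped to [0, 1]. The reference is
the ASA of the *same atom set evaluated in isolation with the same
sampler*, rather than a fixed per-residue maximal-ASA table: published
maximal-ASA tables are whole-residue values and cannot be split into
sidechain and mainchain components, while the self-reference yields
burial = 0 for an isolated residue and ≈ 1 for a fully enclosed one for
any residue chemistry, by construction. Glycine has no sidechain atoms and
reports NA for the sidechain component. Burial is exactly invariant under
translation; under rotation it is invariant when the sampling point set is
co-rotated (the API accepts an explicit point set for this), and agrees
within sampling granularity (~1/960) otherwise. These metrics reproduce
the *quantity class* of a force-field-internal burial, not any particular
program's numbers. Per-residue stability contributions (dG, kcal/mol,
negative = stabilizing) are consumed as input and averaged over APR spans;
they are never computed here.

## Statistics

* Chi-square: plain Pearson on the 2×2 table, df = 1, no continuity
  correction (the common default at the cohort sizes involved); a zero
  marginal raises an error advising an exact test rather than returning a
  misleading value.
* Mann–Whitney U: two-sided; the exact enumerated null is used when both
  samples have n ≤ 12 and the pooled data are tie-free, otherwise the
  normal approximation with tie correction (no continuity correction).
  U is reported as `min(U_x, U_y)`.
* Proportions carry Wilson 95% score intervals.
* Enrichment curves bin a scalar (ΔΔG or strongest-APR score) into
  half-open `[lo, hi)` bins, last bin closed; out-of-range values are
  clamped into the end bins and counted. Per-cohort relative frequencies
  each sum to 1, so the pathogenic − neutral differences sum to 0.
  Defaults: ΔΔG bins of width 0.5 kcal/mol over [−5, 10]; APR-score bins
  of width 10 over [0, 300]. Both are declared defaults, not inferred from
  any source.
* No multiple-testing correction is applied; p-values are reported raw.

## Synthetic data generator

The generator emulates a two-cohort variant study — a proteome with
domain annotations, aggregation and disorder tracks, labeled variants and
per-variant ΔΔG — with planted contrasts, so the whole pipeline is
testable with no external data. All randomness flows from one integer
seed through a single `numpy.random.Generator`.

Sequences are sampled residue-by-residue from a background distribution
with hydrophobic residues down-weighted (so spontaneous APRs are rare),
then overwritten: each domain receives, with configurable probabilities
(defaults 0.35/0.35/0.30), a strong APR core (6–9 hydrophobic residues
from {I, V, L, F}, flanks overwritten with gatekeepers at probability 0.5
per position), a weak APR core (a mildly aggregation-prone 5-mer such as
`AVAVA` in a neutralized context), or nothing. Because tracks are then
computed by the stand-in scorer, sequences and tracks are mutually
consistent by construction. A charged flank would suppress a weak core
below the call threshold under the windowed scorer, which is why weak
cores get neutral context instead of gatekeepers. After scoring, APRs are
re-called and the protein is rejected and resampled until every planted
region verifiably satisfies its intent at the domain level (strong:
strongest assigned APR score > 70; weak: an APR present with strongest
≤ 70); ground-truth flags are recorded from the realized data, never from
the sampling intent.

Cohort defaults mirror the contrast magnitudes the pipeline is designed to
detect: 5000 pathogenic / 1000 neutral variants; planted
aggregation-increasing prevalences 0.225 / 0.075; site-category mixes
(APR hit, gatekeeper hit, disordered site) of 15.4% / 12% / 12% for
pathogenic and 11.3% / 8% / 24% for neutral; pathogenic ΔΔG mixture
`0.6·N(3.0, 1.5) + 0.4·N(0.5, 1.0)` versus neutral `N(0.3, 1.0)` kcal/mol
— invented, configurable defaults shaped so that pathogenic variants are
generally more destabilizing. Planted variants are placed in a domain
whose strongest APR exceeds 70 and draw ΔΔG from `N(3.5, 1.0)` truncated
at 2; non-planted variants are placed in non-strong domains, or in a
strong domain with ΔΔG truncated below 2 when only strong domains offer
the requested site category, so the realized rule flag always equals the
planted one (asserted during generation). The planted Bernoulli flag is
drawn once per variant, before placement, so position collisions cannot
bias the realized prevalence. A correlation knob couples non-planted ΔΔG
to domain APR strength; it defaults to 0 (independence), since the real
within-cohort covariance is unknown. `generate_null` draws both cohorts
from one shared process (neutral ΔΔG mixture, common prevalence, default
0.15) for calibration studies.

What the generator does **not** emulate: realistic domain architectures or
residue covariation, structure (structural metrics are tested on
hand-built coordinate fixtures), evolutionary processes, annotation error,
or predictor noise — external tracks from a real predictor will be rougher
than the stand-in's. Passing recovery tests therefore shows the pipeline's
bookkeeping and statistics are correct under known ground truth, not that
any particular biological effect size is real. Disordered segments are
planted inside domains as well as linkers, a simplification that keeps
every variant inside a domain so rule denominators stay full; realized
disorder-site fractions sit somewhat above their category targets because
"other" placements can land in disordered segments by chance (the
pathogenic < neutral ordering is preserved).

## Problem sizes and numerical choices

The test suite exercises the APR caller against a quadratic brute-force
run finder on 1000 random tracks of lengths 5–500; the intrinsic
classifier against an independent re-derivation on all 19×30 substitutions
of a 30-residue fixture; parameter recovery on the full default cohorts
(5000/1000, fixed seed), requiring the Wilson 95% CI of each recovered
fraction to cover the planted value and the 2×2 chi-square to reject at
p < 1e-5; and chi-square size under 1000 null replicates (150 + 150
variants, 10 proteins each), requiring a rejection rate of 5% ± 1.5% at
α = 0.05 — the null replicates use the generator's realized ground-truth
flags, with one replicate verified in full against the classification
pipeline (the two are identical by the generator's construction).
Mann–Whitney exact mode is checked against full enumeration for every
sample-size pair with n ≤ 8. Degenerate inputs are errors, not silent
defaults: empty tracks, non-contiguous positions, out-of-range scores,
overlapping domains, wild-type mismatches and synonymous substitutions are
all rejected at validation time with the offending records named.
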