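# Methods

This note documents the statistical models, the defaults and their
rationale, the numerical choices, what the synthetic data do and do not
emulate, and the known limitations.

## Clone identity and frequency

A T cell clone is the exact triple (V gene label, J gene label, nucleotide
CDR3). Nucleotide rather than amino-acid junctions are used because the
nucleotide recombination distribution has higher entropy, so collapsing to
protein level would conflate distinct recombination events (which may carry
different, unobserved α chains). Gene labels are compared as exact strings;
allele-suffix stripping (`TRBV2*01 → TRBV2`) exists but is off by default,
since upstream platforms already provide a deterministic V/J assignment.
Clones with identical CDR3 but unresolved or differing V calls remain
distinct keys.

Sample totals N count productive (in-frame, stop-free) rearrangements only,
as judged by the file's own productive/frame flag — no independent
translation check is attempted, because the upstream platform has already
made that call on the raw reads. Fractional counts are rejected rather than
rounded. Frequencies are f_x = n_x/N. For display, an unobserved clone (or
clone set) is drawn at the pseudo-frequency 1/(3N) — using the largest N
across the plotted samples — and flagged as a detection floor, never fed
into any test.

## The adapted expansion test

To test for at least twofold expansion between baseline (n_x of N) and a
later sample (m_x of M), the baseline is rescaled by half: the clone's own
count is preserved and the non-clone cells become round(N/2) − n_x (clamped
at 0), giving the 2×2 table [[n_x, round(N/2)−n_x], [m_x, M−m_x]]. Under
this rescaling, equal row proportions correspond exactly to a doubling of
frequency, so the hypergeometric null tests "≥ 2-fold" rather than "any
change". Clones with observed fold change below 2 are assigned P = 1
outright (with n_x = 0 the fold is +∞ when m_x > 0 — the dominant case for
vaccine-response candidates, which must be absent at baseline — and 0 when
m_x = 0).

Numerical choices:

* **Two-sided P definition.** P is the sum of the probabilities of all
  tables with the observed margins whose probability does not exceed the
  observed table's. We compute it with exact big-integer arithmetic
  (binomial-coefficient numerators over the common denominator C(n, c₁)),
  so ties are resolved exactly and no floating-point epsilon enters the
  definition. This agrees with the common library convention to ~1e-9
  except exactly at float near-ties, where the exact answer is the
  defensible one. Values are cached on the (n_x, N, m_x, M) tuple;
  repeated screens at fixed depth reuse almost all entries.
* **N/2 rounding.** Banker's rounding (round-half-even) to keep the table
  integral without directional bias; configurable in the sense that the
  table constructor is a public function.
* **Bonferroni.** P_adjusted = P × |N ∪ M| (unique clones in the union of
  the two samples), capped at 1 so adjusted values remain probabilities.
* **Monotonicity caveat.** The tie-inclusive two-sided P is not exactly
  monotone in m_x: it can tick up by a few percent when a far-tail table
  crosses the observed probability. The expansion-supporting one-sided
  tail is strictly monotone; the tests assert both facts explicitly.

## Response procedures

Dose-day ties: a sample collected on a dose day belongs to the pre-dose
side ("on the day of but before"). When several samples fall in a baseline
window, the latest one (closest to treatment start) is the anchor.

* **Checkpoint response.** Latest sample on/before the checkpoint dose vs
  the latest sample before the first vaccine dose. Every union clone is
  tested; responder iff any P_adjusted < 0.001.
* **Vaccine priming response.** Candidates must pass QC (≥ 3 reads in ≥ 2
  samples, guarding against sequencing artefacts) and have zero reads in
  every sample up to the first vaccine dose. Baseline is the
  post-checkpoint pre-vaccine sample; candidate windows run from the first
  vaccine dose to the first chemotherapy dose (or booster, when no
  chemotherapy is recorded). Per clone the minimum union-adjusted P over
  candidate samples is further multiplied by the number of candidate
  samples (the second Bonferroni counts the post samples actually tested),
  capped at 1. Responder iff any final P < 0.001. Because candidates must
  be absent pre-vaccine, a clone detected as checkpoint-expanded can never
  also be vaccine-expanded — the two sets are disjoint by construction.
* **Booster response.** For previously primed clones only: standard
  two-sided Fisher on the unrescaled table between the sample immediately
  before the booster and the first follow-up after it, at P < 0.01 with no
  multiplicity adjustment (each clone was already individually
  identified). We additionally require the later frequency to exceed the
  earlier one: a two-sided P is also small under contraction, which is not
  a boost response. This direction filter is an interpretive choice and is
  documented as such.

Null behaviour: comparing two independent multinomial draws from the same
clone distribution (10,000 clones, 50,000 reads) flags zero clones at the
0.001 screen-wide threshold in ≥ 99% of comparisons — the conservative
regime the correction is designed for.

## Peptide specificity from sorted fractions

After peptide restimulation and CD107a sorting, each clone's reads split
between the positive and negative fractions. The call is a one-tailed exact
binomial test of the CD107a⁺ read fraction against p₀ = 0.2, Bonferroni-
corrected by the number of clones tested in the same condition (the screen
is the natural hypothesis family), significant at P_adjusted < 0.001.
Clones reaching significance in the DMSO vehicle control are non-specific
and excluded from every peptide condition. Read counts stand in for cell
counts since the sorted cells are gDNA-sequenced; no minimum read depth is
imposed beyond one read, so single-read clones are testable but can never
survive the correction.

## Neoantigen quality

Cross-reactivity between 9-mer epitopes is modelled with an
independent-site approximation: d_C(p^A, p^B) = Σᵢ₌₁⁹ dᵢ·M[p^A_i, p^B_i],
with M a 20×20 substitution-distance matrix (zero diagonal) and dᵢ
positional weights. Quality of a mutant 9-mer is distance from self minus
distance to the nearest known epitope, Q = d_C(MT, WT) − min_IEDB d_C(MT, ·):
high-quality neoantigens are far from the germline peptide but resemble
epitopes the immune system is known to recognize. Q may be negative, and it
is monotone non-decreasing as the epitope set grows (a min over a superset
can only shrink).

A neopeptide's quality averages the two highest-quality 9-mer windows that
contain the substituted residue and are predicted to bind **any** patient
HLA allele at Kd ≤ 4,000 nM (a deliberately permissive cut-off: vaccination
can drive presentation well above endogenous levels, so differential-
presentation terms are dropped). A single qualifying window is used alone;
with none the neoantigen is excluded (quality undefined) rather than given
an arbitrary score. Ties among window qualities break to the leftmost
start; the allele achieving the minimum Kd is recorded for provenance.
Frameshift/indel neoantigens have no aligned wild-type window and pass
through as undefined.

**Model parameters are inputs.** The fitted matrix and positional weights
of the published cross-reactivity model are not redistributable here; the
shipped default (BLOSUM62-derived dissimilarity M[a,b] = S[a,a] − S[a,b],
uniform weights) is a toy stand-in with the right structural properties
(zero diagonal, non-negativity) for testing, and must not be mistaken for a
fitted model. The immunogenicity comparison is a two-sided Mann–Whitney
rank-sum test between immunogenic and non-immunogenic quality scores.

## Tumour clonality

Subclone trees (consumed as structured input; inference is external) carry
cellular cancer fractions X^α obeying the pigeonhole constraint
X^α ≥ Σ children (tolerance 1e-6; worse violations are errors naming the
node). Exclusive frequencies x^α = X^α − Σ_{β∈D(α)} X^β clamp negatives
within tolerance to zero and sum to the root's CCF. Entropy is
−Σ x^α ln x^α with 0·ln 0 = 0 — natural log, a scale choice only —
averaged arithmetically over the top-5 trees by likelihood (all trees if
fewer; boundary ties break by input order).

## ELISpot

Spot counts are averaged over duplicate wells, scaled to 300,000 effector
cells, and background-subtracted with the medium control. Positive iff the
subtracted value is ≥ 7 ("exceeded a minimum threshold of 7" is read
inclusively; the threshold is a parameter). A patient is a responder iff
any vaccine neoantigen is positive. The inter-individual anti-CD3
normalization and distribution-free resampling tests used in the trial
literature are intentionally not implemented — their formulas live in the
cited references — so outputs are labelled as plain threshold calls.
Concordance between ELISpot and clone-tracking responder calls is reported
as a 2×2 table with an agreement fraction.

## Synthetic data

The generators draw background clone frequencies from a heavy-tailed law
(log-normal with σ = 2 by default; Pareto power-law alternative), sample
every timepoint as an independent multinomial, and plant expansions as
clones with probability zero before their appearance day and a fixed target
frequency afterwards. Defaults — 10,000 background clones, 50,000 reads per
sample, 20 spikes with per-clone post frequencies log-uniform in
[5e-4, 5e-3] (aggregate ≈ 1–5%) over a protocol-like schedule (checkpoint
day 42, vaccine day 63, chemotherapy day 147, booster day 365) — put the
simulations in the regime where the method operates, with recovery checks
run at 100,000-read depth where the smallest spikes carry ≥ 40 reads.
Sorted-fraction screens use true CD107a⁺ probabilities of 0.8 (specific)
vs 0.05 (non-specific) with ≥ 30 reads per clone. The neoantigen cohort
labels exactly 22 of 80 peptides immunogenic by weighted sampling with
weight exp(2·z(Q)), so label probability rises with true quality at a
strength chosen a priori to represent clear enrichment. The ELISpot cohort
plants 8 responders among 16 patients.

What the synthetic data do **not** emulate: PCR/sequencing error at the
sequence level (collapsed upstream in the real platform), template-count
calibration, clone-frequency autocorrelation between timepoints beyond the
shared law, repertoire turnover, batch effects, or HLA-restricted binding
structure (affinities are i.i.d. log-uniform). Passing recovery tests
therefore demonstrate the statistics behave correctly under the stated
sampling model — not that real-data error modes are handled.

## Problem sizes in the shipped checks

The test suite and the acceptance script run at desk scale: ~10⁴-table
oracle grids with totals ≤ 500, 100–200 null comparisons at 10⁴ clones ×
5×10⁴ reads, 25–50 spike-recovery replicates at 10⁵ reads, exhaustive
binomial checks to totals of 150–200, and a 3,000-clone end-to-end
pipeline determinism run. These sizes were chosen so the whole battery
completes in minutes while every statistic is exercised in its operating
regime.

## Known limitations

* The adapted test treats reads as cells; template-level overdispersion
  (PCR jackpots) is assumed handled upstream.
* The booster direction filter and the "latest sample in window" anchor
  rule are documented interpretive choices.
* The quality model's shipped parameters are a toy default (above).
* ELISpot significance testing beyond the threshold rule is out of scope.
* Survival analysis, diversity indices, V/J usage statistics, and any
  upstream inference (variant calling, tree reconstruction, MHC binding
  prediction, single-cell processing) are out of scope by design.
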