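"""Expansion statistics for longitudinal clone tracking.

The central test asks whether a clone at least doubled in frequency between
a baseline sample (n_x of N productive reads) and a later sample (m_x of M).
It is an adapted two-tailed Fisher's exact test: the baseline repertoire
size is rescaled by half — the clone's own count n_x is preserved while the
cells not belonging to the clone are reduced to round(N/2) - n_x — so that
the null hypothesis of equal odds in the resulting 2x2 table corresponds to
a twofold frequency increase rather than no change.  Clones whose observed
fold change (m_x/M)/(n_x/N) is below 2 are assigned P = 1 outright, making
the procedure one-directional despite the two-tailed tail definition.

P values are Bonferroni-adjusted by the number of unique clones in the union
of the two samples compared.  Three response procedures are layered on top:

* checkpoint-inhibitor (atezolizumab) response — one baseline/post pair,
  every union clone tested, responder iff any adjusted P < 0.001;
* vaccine priming response — candidate clones must have >= 3 reads in >= 2
  samples and zero reads in every pre-vaccine sample; the per-clone P is the
  minimum adjusted P over the candidate post samples, further multiplied by
  the number of candidate samples; responder iff any final P < 0.001;
* booster response — previously primed clones only, a standard (unadapted)
  Fisher's exact test with no fold gate and no multiplicity adjustment at
  P < 0.01, requiring the later frequency to exceed the earlier one.

All exact-test probabilities are computed with exact big-integer
hypergeometric enumeration (two-sided P = sum of the probabilities of all
tables with the same margins that are no more probable than the observed
table, ties compared exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Sequence

from .repertoire_io import (
    CloneKey,
    ConfigurationError,
    LongitudinalRepertoire,
    RepertoireSample,
    ValidationError,
    DisplayFrequency,
    display_frequency,
)

__all__ = [
    "ContingencyTable2x2",
    "ExpansionResult",
    "ResponseCall",
    "fisher_two_sided",
    "expansion_p_adapted",
    "standard_fisher_p",
    "fold_change",
    "bonferroni_clones",
    "qc_pass",
    "pairwise_expansion",
    "atezolizumab_response",
    "vaccine_response",
    "booster_response",
    "aggregate_trajectory",
]

#: Default significance threshold for priming/checkpoint expansion calls.
DEFAULT_ALPHA = 0.001
#: Default threshold for booster re-expansion (unadjusted standard test).
DEFAULT_BOOSTER_ALPHA = 0.01
#: Minimum fold change gating the adapted test.
FOLD_GATE = 2.0
#: Quality control: minimum reads in minimum number of samples.
QC_MIN_READS = 3
QC_MIN_SAMPLES = 2


@dataclass(frozen=True, slots=True)
class ContingencyTable2x2:
    """2x2 table; row 1 is the (rescaled) baseline, row 2 the later sample."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError(f"negative cell in table {self}")
        if self.a + self.b <= 0 or self.c + self.d <= 0:
            raise ValidationError(f"empty row in table {self}")


@dataclass(frozen=True, slots=True)
class ExpansionResult:
    """Outcome of one clone's expansion test between two samples."""

    clone: CloneKey
    baseline_sample_id: str
    later_sample_id: str
    n_x: int
    N: int
    m_x: int
    M: int
    fold_change: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(slots=True)
class ResponseCall:
    """Per-patient treatment response: the significantly expanded clones."""

    patient_id: str
    treatment: str
    expanded_clones: dict[CloneKey, ExpansionResult]
    responder: bool

    def __post_init__(self) -> None:
        if self.responder != bool(self.expanded_clones):
            raise ValidationError(
                "responder flag must equal non-emptiness of expanded_clones"
            )


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test P for the table [[a, b], [c, d]].

    The two-sided P is the sum of hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed that of the
    observed table.  Probabilities are compared as exact integers (common
    denominator C(n, a+c)), so ties are handled exactly and the result is
    deterministic to the last bit.
    """
    r1, r2, c1 = a + b, c + d, a + c
    if r1 < 0 or r2 < 0 or min(a, b, c, d) < 0:
        raise ValidationError(f"invalid table {(a, b, c, d)}")
    if c1 == 0 or a + b == 0 or c + d == 0 or b + d == 0:
        return 1.0
    n = r1 + r2
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    num_obs = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for k in range(k_min, k_max + 1):
        nk = math.comb(r1, k) * math.comb(r2, c1 - k)
        if nk <= num_obs:
            total += nk
    return float(Fraction(total, math.comb(n, c1)))


def fold_change(n_x: int, N: int, m_x: int, M: int) -> float:
    """Fold change (m_x/M)/(n_x/N); +inf for de novo clones, 0 if absent in
    both samples."""
    if n_x == 0:
        return math.inf if m_x > 0 else 0.0
    return (m_x / M) / (n_x / N)


def _check_pair(n_x: int, N: int, m_x: int, M: int) -> None:
    if N <= 0 or M <= 0:
        raise ValidationError(f"totals must be positive, got N={N}, M={M}")
    if not (0 <= n_x <= N) or not (0 <= m_x <= M):
        raise ValidationError(
            f"counts out of range: n_x={n_x}, N={N}, m_x={m_x}, M={M}"
        )


def rescaled_table(n_x: int, N: int, m_x: int, M: int) -> ContingencyTable2x2:
    """The adapted test's table: baseline non-clone cells rescaled to
    round(N/2) - n_x (banker's rounding, clamped at zero); later row kept."""
    half = round(N / 2)  # N/2 is exactly representable; round() is half-even
    return ContingencyTable2x2(n_x, max(half - n_x, 0), m_x, M - m_x)


def expansion_p_adapted(
    n_x: int, N: int, m_x: int, M: int, fold_gate: float = FOLD_GATE
) -> float:
    """Adapted exact test P value for a >= ``fold_gate`` clonal expansion.

    Returns exactly 1 when the observed fold change is below the gate;
    otherwise the two-sided exact P on the half-rescaled baseline table.
    """
    _check_pair(n_x, N, m_x, M)
    if fold_change(n_x, N, m_x, M) < fold_gate:
        return 1.0
    t = rescaled_table(n_x, N, m_x, M)
    return fisher_two_sided(t.a, t.b, t.c, t.d)


def standard_fisher_p(n_x: int, N: int, m_x: int, M: int) -> float:
    """Standard two-sided exact test on [[n_x, N-n_x], [m_x, M-m_x]] (no
    rescaling, no fold gate); used for booster re-expansion."""
    _check_pair(n_x, N, m_x, M)
    return fisher_two_sided(n_x, N - n_x, m_x, M - m_x)


def bonferroni_clones(p_raw: float, n_unique_clones: int) -> float:
    """Bonferroni adjustment P x (number of clones screened), capped at 1."""
    if n_unique_clones < 1:
        raise ValidationError("n_unique_clones must be >= 1")
    return min(1.0, p_raw * n_unique_clones)


def qc_pass(
    clone: CloneKey,
    rep: LongitudinalRepertoire,
    min_reads: int = QC_MIN_READS,
    min_samples: int = QC_MIN_SAMPLES,
) -> bool:
    """True iff the clone has >= min_reads reads in >= min_samples samples."""
    hits = sum(1 for s in rep.samples if s.counts.get(clone, 0) >= min_reads)
    return hits >= min_samples


# ---------------------------------------------------------------------------
# Pairwise comparison and anchor selection
# ---------------------------------------------------------------------------


def pairwise_expansion(
    baseline: RepertoireSample,
    later: RepertoireSample,
    alpha: float = DEFAULT_ALPHA,
    clones: Iterable[CloneKey] | None = None,
) -> list[ExpansionResult]:
    """Adapted expansion test for every clone in the union of two samples.

    The Bonferroni factor is the number of unique clones in the union of the
    two samples regardless of any ``clones`` restriction, matching the
    screen-wide correction.
    """
    union = set(baseline.counts) | set(later.counts)
    n_union = len(union)
    tested = union if clones is None else set(clones)
    N, M = baseline.total_productive, later.total_productive
    out = []
    for clone in tested:
        n_x = baseline.counts.get(clone, 0)
        m_x = later.counts.get(clone, 0)
        fc = fold_change(n_x, N, m_x, M)
        p = expansion_p_adapted(n_x, N, m_x, M)
        p_adj = bonferroni_clones(p, n_union) if n_union else 1.0
        out.append(
            ExpansionResult(
                clone, baseline.sample_id, later.sample_id,
                n_x, N, m_x, M, fc, p, p_adj, p_adj < alpha,
            )
        )
    return out


def _latest_at_or_before(
    rep: LongitudinalRepertoire, day: int, after: int | None = None
) -> RepertoireSample | None:
    """Latest sample with collection_day <= day (dose-day ties go to the
    pre-dose side), optionally restricted to days strictly after ``after``."""
    candidates = [
        s
        for s in rep.samples
        if s.collection_day <= day
        and (after is None or s.collection_day > after)
    ]
    return candidates[-1] if candidates else None


def atezolizumab_response(
    rep: LongitudinalRepertoire, alpha: float = DEFAULT_ALPHA
) -> ResponseCall:
    """Checkpoint-inhibitor response call.

    Baseline: latest sample on/before the atezolizumab dose day.  Later:
    latest sample on/before the first vaccine dose (and after atezolizumab).
    Every clone in the union is tested; responder iff any adjusted P < alpha.
    """
    w = rep.windows
    if w.atezolizumab_day is None or w.first_vaccine_day is None:
        raise ConfigurationError(
            "atezolizumab_day and first_vaccine_day are required"
        )
    baseline = _latest_at_or_before(rep, w.atezolizumab_day)
    later = _latest_at_or_before(
        rep, w.first_vaccine_day, after=w.atezolizumab_day
    )
    if baseline is None or later is None:
        raise ConfigurationError(
            f"patient {rep.patient_id}: missing anchor sample for the "
            "atezolizumab comparison"
        )
    results = pairwise_expansion(baseline, later, alpha)
    expanded = {r.clone: r for r in results if r.significant}
    return ResponseCall(rep.patient_id, "atezolizumab", expanded, bool(expanded))


def _vaccine_anchors(
    rep: LongitudinalRepertoire,
) -> tuple[RepertoireSample, list[RepertoireSample], list[RepertoireSample]]:
    w = rep.windows
    if w.first_vaccine_day is None:
        raise ConfigurationError("first_vaccine_day is required")
    baseline = _latest_at_or_before(
        rep, w.first_vaccine_day, after=w.atezolizumab_day
    )
    if baseline is None:
        raise ConfigurationError(
            f"patient {rep.patient_id}: no post-atezolizumab pre-vaccine "
            "baseline sample"
        )
    pre_vaccine = [
        s for s in rep.samples if s.collection_day <= w.first_vaccine_day
    ]
    upper = w.first_chemo_day
    if upper is None:
        upper = w.booster_day
    candidates = [
        s
        for s in rep.samples
        if s.collection_day > w.first_vaccine_day
        and (upper is None or s.collection_day <= upper)
    ]
    if not candidates:
        raise ConfigurationError(
            f"patient {rep.patient_id}: no post-vaccine candidate samples"
        )
    return baseline, pre_vaccine, candidates


def vaccine_response(
    rep: LongitudinalRepertoire,
    alpha: float = DEFAULT_ALPHA,
    min_reads: int = QC_MIN_READS,
    min_samples: int = QC_MIN_SAMPLES,
) -> ResponseCall:
    """Vaccine priming response call.

    Candidate clones must pass QC (>= 3 reads in >= 2 samples) and be
    unobserved (0 reads) in every sample up to the day of the first vaccine
    dose.  The baseline is the post-atezolizumab pre-vaccine sample; the
    candidate windows run until the day of the first chemotherapy dose.  Per
    clone, the final P is the minimum over candidate samples of the
    union-size-adjusted P, further multiplied by the number of candidate
    samples (capped at 1); responder iff any final P < alpha.
    """
    baseline, pre_vaccine, candidates = _vaccine_anchors(rep)
    post_union: set[CloneKey] = set()
    for s in candidates:
        post_union |= set(s.counts)
    eligible = [
        c
        for c in post_union
        if all(s.counts.get(c, 0) == 0 for s in pre_vaccine)
        and qc_pass(c, rep, min_reads, min_samples)
    ]
    n_cand = len(candidates)
    best: dict[CloneKey, ExpansionResult] = {}
    for s in candidates:
        n_union = len(set(baseline.counts) | set(s.counts))
        N, M = baseline.total_productive, s.total_productive
        for clone in eligible:
            n_x = baseline.counts.get(clone, 0)
            m_x = s.counts.get(clone, 0)
            p = expansion_p_adapted(n_x, N, m_x, M)
            p_adj = bonferroni_clones(p, n_union)
            prev = best.get(clone)
            if prev is None or p_adj < prev.p_adjusted:
                best[clone] = ExpansionResult(
                    clone, baseline.sample_id, s.sample_id,
                    n_x, N, m_x, M, fold_change(n_x, N, m_x, M),
                    p, p_adj, False,
                )
    expanded = {}
    for clone, r in best.items():
        p_final = min(1.0, r.p_adjusted * n_cand)
        r_final = ExpansionResult(
            r.clone, r.baseline_sample_id, r.later_sample_id,
            r.n_x, r.N, r.m_x, r.M, r.fold_change,
            r.p_raw, p_final, p_final < alpha,
        )
        if r_final.significant:
            expanded[clone] = r_final
    return ResponseCall(rep.patient_id, "vaccine_priming", expanded,
                        bool(expanded))


def booster_response(
    rep: LongitudinalRepertoire,
    primed_clones: Iterable[CloneKey],
    alpha: float = DEFAULT_BOOSTER_ALPHA,
) -> ResponseCall:
    """Booster re-expansion call for previously primed clones.

    Standard two-sided exact test between the sample immediately before the
    booster and the first follow-up after it; no fold gate, no multiplicity
    adjustment.  A clone re-expands iff P < alpha and its later frequency
    exceeds its earlier frequency (two-sided P is also small under
    contraction, which is not a boost response).
    """
    primed = set(primed_clones)
    if not primed:
        return ResponseCall(rep.patient_id, "booster", {}, False)
    w = rep.windows
    if w.booster_day is None:
        raise ConfigurationError("booster_day is required")
    before = _latest_at_or_before(rep, w.booster_day)
    after_samples = [
        s for s in rep.samples if s.collection_day > w.booster_day
    ]
    if before is None or not after_samples:
        raise ConfigurationError(
            f"patient {rep.patient_id}: missing pre- or post-booster sample"
        )
    after = after_samples[0]
    N, M = before.total_productive, after.total_productive
    expanded = {}
    for clone in primed:
        n_x = before.counts.get(clone, 0)
        m_x = after.counts.get(clone, 0)
        p = standard_fisher_p(n_x, N, m_x, M)
        grew = (m_x / M) > (n_x / N)
        sig = p < alpha and grew
        if sig:
            expanded[clone] = ExpansionResult(
                clone, before.sample_id, after.sample_id,
                n_x, N, m_x, M, fold_change(n_x, N, m_x, M), p, p, True,
            )
    return ResponseCall(rep.patient_id, "booster", expanded, bool(expanded))


def aggregate_trajectory(
    rep: LongitudinalRepertoire, clone_set: Iterable[CloneKey]
) -> list[DisplayFrequency]:
    """Longitudinal aggregate frequency of a clone set over all samples in
    time order (pseudo-floor convention of :func:`display_frequency`)."""
    return display_frequency(rep.samples, clone_set, mode="aggregate")
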