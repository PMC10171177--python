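"""Seeded generators for every input the analysis modules consume.

The generators emulate the statistical structure of the real assays —
heavy-tailed clone-frequency distributions sampled multinomially at several
timepoints with spiked fold-change expansions, sorted CD107a fractions with
known specific clones, random clone trees with valid cellular-cancer-
fraction ordering, random peptide cohorts with assigned binding affinities,
and ELISpot plates with planted responders — and return ground-truth labels
for recovery testing.  All randomness flows through ``numpy``'s PCG64
generator seeded from the spec, so outputs are reproducible bit-for-bit
across platforms.

Default scale mirrors the regime the clone-tracking method operates in:
~10^4 unique background clones, 5x10^4 productive reads per sample, and 20
spiked expansions with per-clone post frequencies log-uniform in
[5e-4, 5e-3] (an aggregate of roughly 1-5% of the repertoire).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .neoantigen_quality import (
    AMINO_ACIDS,
    BindingTable,
    EpitopeSet,
    NeoantigenRecord,
    SubstitutionModel,
    neoantigen_quality,
)
from .repertoire_io import (
    CloneKey,
    LongitudinalRepertoire,
    Phase,
    RepertoireSample,
    TreatmentWindows,
    ValidationError,
)
from .response_calls import ElispotMeasurement
from .specificity import SortedFractionCounts
from .tumor_clonality import CloneTree, TreeEnsemble

__all__ = [
    "SamplePlan",
    "SimulationSpec",
    "RepertoireTruth",
    "simulate_longitudinal_repertoire",
    "simulate_sorted_fractions",
    "simulate_tree_ensemble",
    "simulate_neoantigen_cohort",
    "simulate_elispot_cohort",
]

_V_GENES = tuple(f"TRBV{i}" for i in range(2, 31))
_J_GENES = tuple(f"TRBJ{a}-{b}" for a in (1, 2) for b in range(1, 7))
_NT = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True, slots=True)
class SamplePlan:
    """One planned blood draw: day, phase label and sequencing depth."""

    collection_day: int
    phase: Phase
    depth: int


def default_schedule(depth: int = 50_000) -> tuple[SamplePlan, ...]:
    """A protocol-like draw schedule (days from surgery): checkpoint dose at
    day 42, first vaccine dose day 63, chemotherapy start day 147, booster
    day 365."""
    return (
        SamplePlan(42, Phase.PRE_ATEZOLIZUMAB, depth),
        SamplePlan(63, Phase.POST_ATEZOLIZUMAB_PRE_VACCINE, depth),
        SamplePlan(98, Phase.POST_PRIMING, depth),
        SamplePlan(126, Phase.POST_PRIMING, depth),
        SamplePlan(147, Phase.POST_PRIMING, depth),
        SamplePlan(365, Phase.PRE_BOOSTER, depth),
        SamplePlan(393, Phase.POST_BOOSTER, depth),
    )


DEFAULT_WINDOWS = TreatmentWindows(
    atezolizumab_day=42, first_vaccine_day=63, first_chemo_day=147,
    booster_day=365,
)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters for all generators; fields unused by a generator are
    ignored by it.  Override individual fields with ``dataclasses.replace``.
    """

    seed: int = 0
    # Longitudinal repertoire
    n_clones: int = 10_000
    frequency_law: str = "lognormal"  # or "powerlaw"
    lognormal_sigma: float = 2.0
    powerlaw_alpha: float = 1.5
    schedule: tuple[SamplePlan, ...] = field(default_factory=default_schedule)
    windows: TreatmentWindows = DEFAULT_WINDOWS
    n_spikes: int = 20
    spike_freq_range: tuple[float, float] = (5e-4, 5e-3)
    spike_after_day: int | None = None  # default: first vaccine day
    booster_boost_fold: float = 1.0
    patient_id: str = "SIM-01"
    # Sorted fractions
    sort_n_clones: int = 200
    sort_n_specific: int = 20
    p_cd107a_specific: float = 0.8
    p_cd107a_nonspecific: float = 0.05
    sort_min_reads: int = 30
    sort_mean_extra_reads: float = 30.0
    sort_condition: str = "poolA"
    # Clone trees
    n_trees: int = 10
    n_tree_nodes: int = 6
    # Neoantigen cohort
    n_neoantigens: int = 80
    n_immunogenic: int = 22
    neoantigen_length: int = 15
    n_iedb_epitopes: int = 50
    n_alleles_per_patient: int = 2
    kd_log10_range: tuple[float, float] = (1.0, 4.7)
    immunogenicity_tilt: float = 2.0
    # ELISpot cohort
    n_patients: int = 16
    n_responders: int = 8
    n_targets_per_patient: int = 5
    elispot_background_rate: float = 1.0
    elispot_response_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.n_clones < 1 or any(p.depth < 1 for p in self.schedule):
            raise ValidationError("n_clones and depths must be >= 1")
        for p in (self.p_cd107a_specific, self.p_cd107a_nonspecific):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        lo, hi = self.spike_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("spike_freq_range must be within (0, 1)")


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    # Independent stream per generator so one spec can feed all of them.
    return np.random.default_rng([spec.seed, stream])


def _random_clone_keys(
    rng: np.random.Generator, n: int, cdr3_length: int = 39
) -> list[CloneKey]:
    keys: list[CloneKey] = []
    seen: set[str] = set()
    while len(keys) < n:
        need = n - len(keys)
        codes = rng.integers(0, 4, size=(need, cdr3_length))
        v_idx = rng.integers(0, len(_V_GENES), size=need)
        j_idx = rng.integers(0, len(_J_GENES), size=need)
        for row, vi, ji in zip(codes, v_idx, j_idx):
            cdr3 = _NT[row].tobytes().decode()
            if cdr3 in seen:
                continue
            seen.add(cdr3)
            keys.append(CloneKey(_V_GENES[vi], _J_GENES[ji], cdr3))
    return keys


def _baseline_probs(spec: SimulationSpec, rng: np.random.Generator
                    ) -> np.ndarray:
    if spec.frequency_law == "lognormal":
        w = np.exp(rng.normal(0.0, spec.lognormal_sigma, spec.n_clones))
    elif spec.frequency_law == "powerlaw":
        w = rng.pareto(spec.powerlaw_alpha, spec.n_clones) + 1.0
    else:
        raise ValidationError(f"unknown frequency law {spec.frequency_law!r}")
    return w / w.sum()


@dataclass(frozen=True)
class RepertoireTruth:
    """Ground truth of a simulated repertoire: the genuinely expanded
    (spiked) clones, their target post frequencies, and the background law's
    per-clone probabilities."""

    spiked_clones: frozenset[CloneKey]
    spike_frequencies: dict[CloneKey, float]
    background_probs: np.ndarray


def simulate_longitudinal_repertoire(
    spec: SimulationSpec,
) -> tuple[LongitudinalRepertoire, RepertoireTruth]:
    """Simulate one patient's longitudinal repertoire with spiked expansions.

    Background clone frequencies are drawn once from the heavy-tailed law
    and every sample is an independent multinomial draw at its depth.
    Spiked clones are absent (probability zero) in all samples up to and
    including ``spike_after_day`` (default: the first vaccine day) and
    present at their target frequency afterwards; samples after the booster
    day multiply spike frequencies by ``booster_boost_fold``.
    """
    rng = _rng(spec, 1)
    keys = _random_clone_keys(rng, spec.n_clones + spec.n_spikes)
    bg_keys = keys[: spec.n_clones]
    spike_keys = keys[spec.n_clones :]
    bg_probs = _baseline_probs(spec, rng)
    lo, hi = spec.spike_freq_range
    spike_freqs = np.exp(
        rng.uniform(np.log(lo), np.log(hi), spec.n_spikes)
    )
    after_day = spec.spike_after_day
    if after_day is None:
        after_day = spec.windows.first_vaccine_day
        if after_day is None:
            after_day = 0

    samples = []
    for i, plan in enumerate(spec.schedule):
        boosted = (
            spec.windows.booster_day is not None
            and plan.collection_day > spec.windows.booster_day
        )
        active = plan.collection_day > after_day and spec.n_spikes > 0
        if active:
            freqs = spike_freqs * (spec.booster_boost_fold if boosted else 1.0)
            mass = float(freqs.sum())
            if mass >= 1.0:
                raise ValidationError(
                    f"total spike mass {mass} must stay below 1"
                )
            probs = np.concatenate([bg_probs * (1.0 - mass), freqs])
            draw_keys = bg_keys + spike_keys
        else:
            probs = bg_probs
            draw_keys = bg_keys
        counts = rng.multinomial(plan.depth, probs)
        nonzero = np.flatnonzero(counts)
        samples.append(
            RepertoireSample(
                sample_id=f"{spec.patient_id}-d{plan.collection_day:03d}",
                patient_id=spec.patient_id,
                collection_day=plan.collection_day,
                phase=plan.phase,
                counts={draw_keys[j]: int(counts[j]) for j in nonzero},
            )
        )
    rep = LongitudinalRepertoire(spec.patient_id, samples, spec.windows)
    truth = RepertoireTruth(
        frozenset(spike_keys),
        dict(zip(spike_keys, map(float, spike_freqs))),
        bg_probs,
    )
    return rep, truth


def simulate_sorted_fractions(
    spec: SimulationSpec,
) -> tuple[list[SortedFractionCounts], frozenset[CloneKey]]:
    """Simulate a sorted CD107a screen for one peptide condition.

    Each clone's reads split binomially between the positive and negative
    fractions at its true degranulation probability (0.8 for truly specific
    clones, 0.05 for non-specific ones by default); read depth per clone is
    ``sort_min_reads`` plus a Poisson excess.
    """
    rng = _rng(spec, 2)
    keys = _random_clone_keys(rng, spec.sort_n_clones)
    specific = frozenset(keys[: spec.sort_n_specific])
    counts = []
    for key in keys:
        reads = spec.sort_min_reads + int(
            rng.poisson(spec.sort_mean_extra_reads)
        )
        p_true = (
            spec.p_cd107a_specific
            if key in specific
            else spec.p_cd107a_nonspecific
        )
        k_pos = int(rng.binomial(reads, p_true))
        counts.append(
            SortedFractionCounts(key, k_pos, reads - k_pos,
                                 spec.sort_condition)
        )
    return counts, specific


def simulate_tree_ensemble(spec: SimulationSpec) -> TreeEnsemble:
    """Random rooted clone trees with CCFs valid by construction.

    Each non-root node attaches to a uniformly chosen earlier node and
    receives a uniform fraction of its parent's remaining (unallocated)
    cellular cancer fraction, so the pigeonhole constraint holds exactly.
    """
    rng = _rng(spec, 3)
    trees = []
    for t in range(spec.n_trees):
        nodes = tuple(str(i) for i in range(spec.n_tree_nodes))
        parent: dict[str, str] = {}
        ccf = {"0": 1.0}
        remaining = {"0": 1.0}
        for i in range(1, spec.n_tree_nodes):
            par = str(int(rng.integers(0, i)))
            parent[str(i)] = par
            x = remaining[par] * float(rng.uniform(0.2, 0.9))
            remaining[par] -= x
            ccf[str(i)] = x
            remaining[str(i)] = x
        trees.append(
            CloneTree(nodes, parent, ccf,
                      likelihood=float(rng.normal(-5000.0, 100.0)),
                      tree_id=f"tree{t}")
        )
    return TreeEnsemble(tuple(trees))


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(
        AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)
    )


def simulate_neoantigen_cohort(
    spec: SimulationSpec,
) -> tuple[
    list[NeoantigenRecord],
    EpitopeSet,
    BindingTable,
    dict[str, bool],
    dict[str, float],
]:
    """Random neoantigen cohort with qualities and immunogenicity labels.

    Wild-type peptides are random proteome-like sequences with a single
    random substitution; affinities are log-uniform over the configured Kd
    range for every (mutant 9-mer, patient allele) pair.  Exactly
    ``n_immunogenic`` of the scoreable neoantigens are labelled immunogenic
    by weighted sampling without replacement with weight exp(tilt * z(Q))
    under the toy substitution model, so the label probability increases
    with true quality.

    Returns (records, epitope set, binding table, labels, qualities); the
    label and quality maps cover neoantigens with defined quality only.
    """
    rng = _rng(spec, 4)
    allele_pool = tuple(
        f"HLA-A*{i:02d}:01" for i in (1, 2, 3, 11, 24, 26)
    )
    iedb = EpitopeSet.from_epitopes(
        _random_peptide(rng, int(rng.integers(9, 16)))
        for _ in range(spec.n_iedb_epitopes)
    )
    model = SubstitutionModel.blosum62_toy()

    records = []
    kd: dict[tuple[str, str], float] = {}
    lo, hi = spec.kd_log10_range
    for i in range(spec.n_neoantigens):
        wt = _random_peptide(rng, spec.neoantigen_length)
        pos = int(rng.integers(1, spec.neoantigen_length + 1))
        old = wt[pos - 1]
        new = AMINO_ACIDS[
            int(rng.choice([j for j in range(20) if AMINO_ACIDS[j] != old]))
        ]
        mt = wt[: pos - 1] + new + wt[pos:]
        alleles = tuple(
            rng.choice(allele_pool, size=spec.n_alleles_per_patient,
                       replace=False)
        )
        rec = NeoantigenRecord(f"neo{i:03d}", mt, wt, pos, alleles)
        records.append(rec)
        for start in range(len(mt) - 8):
            mer = mt[start : start + 9]
            for allele in alleles:
                kd.setdefault(
                    (mer, allele), float(10 ** rng.uniform(lo, hi))
                )
    binding = BindingTable(kd)

    qualities: dict[str, float] = {}
    for rec in records:
        res = neoantigen_quality(rec, iedb, model, binding)
        if res.quality is not None:
            qualities[rec.neoantigen_id] = res.quality
    ids = sorted(qualities)
    q = np.array([qualities[i] for i in ids])
    z = (q - q.mean()) / (q.std() if q.std() > 0 else 1.0)
    w = np.exp(spec.immunogenicity_tilt * z)
    n_imm = min(spec.n_immunogenic, len(ids))
    chosen = set(
        rng.choice(len(ids), size=n_imm, replace=False, p=w / w.sum())
    )
    labels = {nid: (j in chosen) for j, nid in enumerate(ids)}
    return records, iedb, binding, labels, qualities


def simulate_elispot_cohort(
    spec: SimulationSpec,
) -> tuple[
    dict[str, dict[str, ElispotMeasurement]],
    dict[str, ElispotMeasurement],
    dict[str, bool],
]:
    """Simulate an ELISpot screen with planted responders.

    Every patient gets duplicate wells per target plus a medium control;
    planted responders have one to three targets with Poisson spot counts at
    the response rate, everything else at the background rate.

    Returns (per-patient target measurements, per-patient medium controls,
    true responder labels).
    """
    rng = _rng(spec, 5)
    measurements: dict[str, dict[str, ElispotMeasurement]] = {}
    medium: dict[str, ElispotMeasurement] = {}
    truth: dict[str, bool] = {}
    responder_ids = set(range(spec.n_responders))
    for p in range(spec.n_patients):
        pid = f"PT{p + 1:02d}"
        is_responder = p in responder_ids
        n_hot = int(rng.integers(1, 4)) if is_responder else 0
        hot = set(rng.choice(spec.n_targets_per_patient, size=n_hot,
                             replace=False)) if n_hot else set()
        targets = {}
        for t in range(spec.n_targets_per_patient):
            rate = (
                spec.elispot_response_rate
                if t in hot
                else spec.elispot_background_rate
            )
            spots = tuple(float(rng.poisson(rate)) for _ in range(2))
            targets[f"neo{t}"] = ElispotMeasurement(pid, f"neo{t}", spots)
        measurements[pid] = targets
        medium[pid] = ElispotMeasurement(
            pid, "medium",
            tuple(float(rng.poisson(spec.elispot_background_rate))
                  for _ in range(2)),
        )
        truth[pid] = is_responder
    return measurements, medium, truth
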