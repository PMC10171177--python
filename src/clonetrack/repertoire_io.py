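"""Reading, validating and writing longitudinal TCR-beta repertoire samples.

A T cell clone is identified by its V gene segment, J gene segment and the
nucleotide CDR3 (junction) sequence of the rearranged beta chain.  Nucleotide
rather than amino-acid CDR3s are used so that distinct recombination events
encoding the same protein sequence are not conflated.  Sample-level totals
count productive (in-frame, stop-codon-free) rearrangements only; the clone
frequency is the read count divided by that productive total.

Input tables may use either Adaptive immunoSEQ-style column names or AIRR
Rearrangement names; the internal model is dialect-free.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import yaml

__all__ = [
    "CloneTrackError",
    "FormatError",
    "ValidationError",
    "ConfigurationError",
    "Phase",
    "CloneKey",
    "RepertoireSample",
    "TreatmentWindows",
    "LongitudinalRepertoire",
    "DisplayFrequency",
    "parse_rearrangements",
    "parse_cohort",
    "read_metadata",
    "read_windows",
    "clone_frequency",
    "display_frequency",
    "write_samples",
    "write_metadata",
]


class CloneTrackError(Exception):
    """Base class for all package errors."""


class FormatError(CloneTrackError):
    """An input file does not conform to a supported format."""


class ValidationError(CloneTrackError):
    """Input values violate a documented invariant."""


class ConfigurationError(CloneTrackError):
    """A required sample, anchor or configuration entry is missing."""


class Phase(str, enum.Enum):
    """Treatment-schedule label for a blood sample."""

    PRE_ATEZOLIZUMAB = "pre_atezolizumab"
    POST_ATEZOLIZUMAB_PRE_VACCINE = "post_atezolizumab_pre_vaccine"
    POST_PRIMING = "post_priming"
    PRE_BOOSTER = "pre_booster"
    POST_BOOSTER = "post_booster"
    POST_CHEMO_START = "post_chemo_start"
    OTHER = "other"


_DNA = frozenset("ACGT")


@dataclass(frozen=True, slots=True)
class CloneKey:
    """Identity of a T cell clone: V gene, J gene and nucleotide CDR3.

    Equality and hashing are exact on the triple; there is no collapsing to
    the amino-acid level and, by default, no trimming of allele suffixes.
    """

    v_gene: str
    j_gene: str
    cdr3_nt: str

    def __post_init__(self) -> None:
        if not self.cdr3_nt:
            raise ValidationError("cdr3_nt must be non-empty")
        if not set(self.cdr3_nt) <= _DNA:
            raise ValidationError(
                f"cdr3_nt must be uppercase A/C/G/T only, got {self.cdr3_nt!r}"
            )

    def strip_alleles(self) -> "CloneKey":
        """Return a key with ``*NN`` allele suffixes removed from V and J."""
        return CloneKey(
            self.v_gene.split("*")[0], self.j_gene.split("*")[0], self.cdr3_nt
        )


@dataclass(slots=True)
class RepertoireSample:
    """One timepoint's clone -> productive read count table.

    ``total_productive`` (N) equals the sum of counts; frequencies n_x / N
    therefore sum to one over the observed clones.
    """

    sample_id: str
    patient_id: str
    collection_day: int
    phase: Phase
    counts: dict[CloneKey, int]
    total_productive: int = field(default=-1)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if self.total_productive == -1:
            self.total_productive = total
        elif self.total_productive != total:
            raise ValidationError(
                f"sample {self.sample_id}: total_productive "
                f"{self.total_productive} != sum of counts {total}"
            )
        for clone, n in self.counts.items():
            if not isinstance(n, int) or isinstance(n, bool) or n <= 0:
                raise ValidationError(
                    f"sample {self.sample_id}: clone {clone} has invalid "
                    f"count {n!r} (positive integers required)"
                )


@dataclass(frozen=True, slots=True)
class TreatmentWindows:
    """Dosing-day anchors (days from surgery); any may be absent.

    A sample collected on a dose day is, by the package's convention,
    assigned to the pre-dose side ("on the day of but before" the dose).
    """

    atezolizumab_day: int | None = None
    first_vaccine_day: int | None = None
    first_chemo_day: int | None = None
    booster_day: int | None = None

    def __post_init__(self) -> None:
        days = [
            self.atezolizumab_day,
            self.first_vaccine_day,
            self.first_chemo_day,
            self.booster_day,
        ]
        present = [d for d in days if d is not None]
        if present != sorted(present):
            raise ValidationError(
                "treatment windows must be ordered: atezolizumab <= first "
                f"vaccine <= first chemo <= booster, got {days}"
            )


@dataclass(slots=True)
class LongitudinalRepertoire:
    """All repertoire samples for one patient, ordered by collection day."""

    patient_id: str
    samples: list[RepertoireSample]
    windows: TreatmentWindows = field(default_factory=TreatmentWindows)

    def __post_init__(self) -> None:
        self.samples = sorted(self.samples, key=lambda s: s.collection_day)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate sample_ids: {ids}")
        days = [s.collection_day for s in self.samples]
        if len(set(days)) != len(days):
            raise ValidationError(
                f"collection days must be strictly ordered, got {days}"
            )

    def sample(self, sample_id: str) -> RepertoireSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


# ---------------------------------------------------------------------------
# Column-name dialects
# ---------------------------------------------------------------------------

#: Aliases accepted for each canonical column (canonical name first).
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "sample_id": ("sample_id", "sample_name", "repertoire_id"),
    "v_gene": ("v_gene", "v_call", "v_resolved", "vGeneName", "v_gene_name"),
    "j_gene": ("j_gene", "j_call", "j_resolved", "jGeneName", "j_gene_name"),
    "cdr3_nt": ("cdr3_nt", "junction", "cdr3_rearrangement", "nucleotide",
                "rearrangement"),
    "productive": ("productive", "frame_type"),
    "count": ("count", "duplicate_count", "templates", "reads",
              "count_templates_reads"),
}

_PRODUCTIVE_TRUE = {"t", "true", "1", "yes", "y", "in", "in-frame", "productive"}
_PRODUCTIVE_FALSE = {"f", "false", "0", "no", "n", "out", "stop",
                     "out-of-frame", "nonproductive", "non-productive"}


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    lowered = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias.lower() in lowered:
                resolved[canonical] = lowered[alias.lower()]
                break
        else:
            if canonical != "productive":  # productive may default to true
                raise FormatError(
                    f"required column {canonical!r} not found; accepted "
                    f"names: {aliases}; file has {list(columns)}"
                )
    return resolved


def _is_productive(value: object) -> bool:
    text = str(value).strip().lower()
    if text in _PRODUCTIVE_TRUE:
        return True
    if text in _PRODUCTIVE_FALSE:
        return False
    raise FormatError(f"cannot interpret productive flag {value!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, patient_id, collection_day, phase).

    Accepts TSV/CSV, YAML or JSON; YAML/JSON hold a list of records.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml", ".json"}:
        with open(path) as fh:
            records = yaml.safe_load(fh)
        frame = pd.DataFrame(records)
    else:
        frame = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "patient_id", "collection_day", "phase"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    return frame


def read_windows(path: str | Path) -> dict[str, TreatmentWindows]:
    """Read per-patient treatment windows from YAML/JSON.

    The file maps patient_id -> {atezolizumab_day, first_vaccine_day,
    first_chemo_day, booster_day}; absent keys mean the dose was not given.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for patient_id, days in raw.items():
        out[str(patient_id)] = TreatmentWindows(**{k: v for k, v in days.items()})
    return out


def _coerce_count(value: object) -> int:
    """Counts are read/template integers; fractional counts are rejected."""
    if isinstance(value, bool):
        raise ValidationError(f"invalid count {value!r}")
    if isinstance(value, int):
        n = value
    elif isinstance(value, float):
        if not value.is_integer():
            raise ValidationError(f"fractional count {value!r} rejected")
        n = int(value)
    else:
        text = str(value).strip()
        try:
            n = int(text)
        except ValueError:
            try:
                f = float(text)
            except ValueError:
                raise ValidationError(f"non-numeric count {value!r}") from None
            if not f.is_integer():
                raise ValidationError(f"fractional count {value!r} rejected")
            n = int(f)
    if n < 0:
        raise ValidationError(f"negative count {n}")
    return n


def parse_cohort(
    path: str | Path,
    metadata: pd.DataFrame | str | Path,
    windows: Mapping[str, TreatmentWindows] | str | Path | None = None,
    strip_alleles: bool = False,
) -> dict[str, LongitudinalRepertoire]:
    """Parse a rearrangement file into per-patient longitudinal repertoires.

    Non-productive rows are excluded from both the clone counts and the
    productive total N; rows sharing a (v_gene, j_gene, cdr3_nt) key within a
    sample are summed.  Every sample in the file must appear in the metadata.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    if windows is not None and not isinstance(windows, Mapping):
        windows = read_windows(windows)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(frame.columns)

    meta_by_sample = {
        str(rec["sample_id"]): rec
        for rec in metadata.to_dict(orient="records")
    }
    pos = {k: frame.columns.get_loc(v) for k, v in cols.items()}
    per_sample: dict[str, dict[CloneKey, int]] = {}
    for row in frame.itertuples(index=False, name=None):
        sample_id = str(row[pos["sample_id"]])
        if sample_id not in meta_by_sample:
            raise ValidationError(
                f"sample {sample_id!r} in rearrangement file has no "
                "metadata entry"
            )
        if "productive" in pos and not _is_productive(row[pos["productive"]]):
            continue
        count = _coerce_count(row[pos["count"]])
        if count == 0:
            continue
        key = CloneKey(
            str(row[pos["v_gene"]]),
            str(row[pos["j_gene"]]),
            str(row[pos["cdr3_nt"]]).upper(),
        )
        if strip_alleles:
            key = key.strip_alleles()
        bucket = per_sample.setdefault(sample_id, {})
        bucket[key] = bucket.get(key, 0) + count

    by_patient: dict[str, list[RepertoireSample]] = {}
    for sample_id, counts in per_sample.items():
        meta = meta_by_sample[sample_id]
        sample = RepertoireSample(
            sample_id=sample_id,
            patient_id=str(meta["patient_id"]),
            collection_day=int(meta["collection_day"]),
            phase=Phase(str(meta["phase"])),
            counts=counts,
        )
        by_patient.setdefault(sample.patient_id, []).append(sample)

    out = {}
    for patient_id, samples in by_patient.items():
        win = TreatmentWindows()
        if windows is not None and patient_id in windows:
            win = windows[patient_id]
        out[patient_id] = LongitudinalRepertoire(patient_id, samples, win)
    return out


def parse_rearrangements(
    path: str | Path,
    metadata: pd.DataFrame | str | Path,
    windows: Mapping[str, TreatmentWindows] | str | Path | None = None,
    strip_alleles: bool = False,
) -> LongitudinalRepertoire:
    """Parse a single-patient rearrangement file.

    See :func:`parse_cohort`; raises if the file spans multiple patients.
    """
    cohort = parse_cohort(path, metadata, windows, strip_alleles)
    if len(cohort) != 1:
        raise ValidationError(
            f"expected a single patient, found {sorted(cohort)}; use "
            "parse_cohort for multi-patient files"
        )
    return next(iter(cohort.values()))


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------


def clone_frequency(sample: RepertoireSample, clone: CloneKey) -> float:
    """Observed clone frequency f_x = n_x / N; 0 when the clone is absent."""
    n = sample.counts.get(clone, 0)
    if n == 0:
        return 0.0
    return n / sample.total_productive


class DisplayFrequency(NamedTuple):
    """A per-sample (aggregate) frequency; ``is_pseudo`` marks the 1/(3N)
    detection floor reported for unobserved clones, which is a display
    convention and not an observation."""

    sample_id: str
    frequency: float
    is_pseudo: bool


def display_frequency(
    samples: Sequence[RepertoireSample],
    clone_set: Iterable[CloneKey],
    mode: str = "aggregate",
) -> list[DisplayFrequency]:
    """Per-sample frequency of a clone set with a pseudo-frequency floor.

    The aggregate count is n_X = sum over the set of n_x.  When n_X = 0 in a
    sample the value reported is 1/(3 * N_max) where N_max is the largest
    productive total across the supplied samples, flagged as a floor.
    In ``single`` mode the set must contain exactly one clone.
    """
    clones = list(clone_set)
    if not clones:
        raise ValidationError("clone_set must be non-empty")
    if mode not in {"single", "aggregate"}:
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "single" and len(clones) != 1:
        raise ValidationError("single mode requires exactly one clone")
    if not samples:
        return []
    n_max = max(s.total_productive for s in samples)
    out = []
    for s in samples:
        n_agg = sum(s.counts.get(c, 0) for c in clones)
        if n_agg == 0:
            out.append(DisplayFrequency(s.sample_id, 1.0 / (3.0 * n_max), True))
        else:
            out.append(
                DisplayFrequency(s.sample_id, n_agg / s.total_productive, False)
            )
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_CANONICAL_COLUMNS = ["sample_id", "v_gene", "j_gene", "cdr3_nt", "count"]


def write_samples(rep: LongitudinalRepertoire, path: str | Path) -> None:
    """Write the canonical TSV (sample_id, v_gene, j_gene, cdr3_nt, count).

    Lossless for clone keys and counts: parsing the output with the sample
    metadata reproduces identical count maps and productive totals.
    """
    rows = []
    for s in rep.samples:
        for key in sorted(
            s.counts, key=lambda k: (k.v_gene, k.j_gene, k.cdr3_nt)
        ):
            rows.append(
                (s.sample_id, key.v_gene, key.j_gene, key.cdr3_nt,
                 s.counts[key])
            )
    pd.DataFrame(rows, columns=_CANONICAL_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_metadata(rep: LongitudinalRepertoire, path: str | Path) -> None:
    """Write sample metadata as TSV alongside the canonical rearrangements."""
    rows = [
        (s.sample_id, s.patient_id, s.collection_day, s.phase.value)
        for s in rep.samples
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "collection_day", "phase"]
    ).to_csv(path, sep="\t", index=False)


def windows_to_json(windows: Mapping[str, TreatmentWindows], path: str | Path
                    ) -> None:
    payload = {
        pid: {
            k: v
            for k, v in {
                "atezolizumab_day": w.atezolizumab_day,
                "first_vaccine_day": w.first_vaccine_day,
                "first_chemo_day": w.first_chemo_day,
                "booster_day": w.booster_day,
            }.items()
            if v is not None
        }
        for pid, w in windows.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
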