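"""ELISpot positivity calls and patient-level responder classification.

A target (neoantigen) is ELISpot-positive when its mean spot count across
duplicate wells, after subtracting the non-stimulated (medium) control and
scaling to 300,000 effector cells per well, reaches a minimum of 7 spots.
A patient is a vaccine responder when at least one vaccine neoantigen is
positive.  The boundary is read as >= 7 after subtraction; it is
configurable.  The inter-individual anti-CD3 normalisation and
distribution-free resampling significance tests used alongside this
threshold in the trial literature are deliberately not implemented here —
outputs are plain threshold calls only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .repertoire_io import FormatError, ValidationError

__all__ = [
    "ElispotMeasurement",
    "ConcordanceTable",
    "elispot_positive",
    "classify_responder",
    "concordance",
    "read_elispot",
    "write_elispot",
    "MEDIUM_TARGET",
]

#: Target label recognised as the non-stimulated (medium) control.
MEDIUM_TARGET = "medium"

#: Positivity threshold: spots per reference cell number.
DEFAULT_SPOT_THRESHOLD = 7.0
REFERENCE_CELLS = 300_000


@dataclass(frozen=True, slots=True)
class ElispotMeasurement:
    """Spot counts of duplicate wells for one target in one patient."""

    patient_id: str
    target: str
    spots: tuple[float, ...]
    cells_per_well: int = REFERENCE_CELLS

    def __post_init__(self) -> None:
        if len(self.spots) < 1:
            raise ValidationError(
                f"{self.patient_id}/{self.target}: at least one well required"
            )
        if any(s < 0 for s in self.spots):
            raise ValidationError("spot counts must be non-negative")
        if self.cells_per_well <= 0:
            raise ValidationError("cells_per_well must be positive")

    @property
    def mean_spots_per_reference(self) -> float:
        """Mean spot count scaled to the 300,000-cell reference."""
        mean = sum(self.spots) / len(self.spots)
        return mean * REFERENCE_CELLS / self.cells_per_well


def elispot_positive(
    meas: ElispotMeasurement,
    medium_control: ElispotMeasurement,
    threshold: float = DEFAULT_SPOT_THRESHOLD,
    scale: bool = True,
) -> bool:
    """Positivity call: background-subtracted mean count >= threshold per
    300,000 cells (which also guarantees the target exceeds the control).

    With ``scale=False``, differing cells_per_well raises instead of being
    rescaled to the reference.
    """
    if not scale and meas.cells_per_well != medium_control.cells_per_well:
        raise ValidationError(
            "cells_per_well differ and scaling is disabled: "
            f"{meas.cells_per_well} vs {medium_control.cells_per_well}"
        )
    subtracted = (
        meas.mean_spots_per_reference
        - medium_control.mean_spots_per_reference
    )
    return subtracted >= threshold


def classify_responder(calls: Iterable[bool] | Mapping[str, bool]) -> bool:
    """Responder iff any tested neoantigen is positive (logical OR)."""
    if isinstance(calls, Mapping):
        calls = calls.values()
    values = list(calls)
    if not values:
        raise ValidationError("at least one neoantigen call is required")
    return any(values)


@dataclass(frozen=True, slots=True)
class ConcordanceTable:
    """2x2 agreement between ELISpot and clone-tracking responder calls."""

    both_positive: int
    elispot_only: int
    clonetrack_only: int
    both_negative: int

    @property
    def n(self) -> int:
        return (self.both_positive + self.elispot_only
                + self.clonetrack_only + self.both_negative)

    @property
    def agreement(self) -> float:
        return (self.both_positive + self.both_negative) / self.n


def concordance(
    elispot_calls: Mapping[str, bool],
    clonetrack_calls: Mapping[str, bool],
) -> ConcordanceTable:
    """Cross-tabulate per-patient responder calls from the two assays.

    Patients must be present in both mappings.
    """
    patients = set(elispot_calls)
    if patients != set(clonetrack_calls):
        raise ValidationError(
            "patient sets differ between the two call mappings"
        )
    if not patients:
        raise ValidationError("no patients to cross-tabulate")
    cells = [0, 0, 0, 0]
    for p in patients:
        e, c = elispot_calls[p], clonetrack_calls[p]
        if e and c:
            cells[0] += 1
        elif e:
            cells[1] += 1
        elif c:
            cells[2] += 1
        else:
            cells[3] += 1
    return ConcordanceTable(*cells)


def read_elispot(
    path: str | Path,
) -> tuple[dict[str, dict[str, ElispotMeasurement]],
           dict[str, ElispotMeasurement]]:
    """Read the ELISpot TSV (patient, target, well, spots, cells_per_well).

    Wells of the same (patient, target) are collected as duplicates; the
    target labelled ``medium`` is returned separately as the per-patient
    non-stimulated control.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"patient", "target", "well", "spots", "cells_per_well"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"ELISpot table missing columns: {sorted(missing)}")
    grouped: dict[tuple[str, str], list[tuple[int, float, int]]] = {}
    for r in frame.itertuples(index=False):
        grouped.setdefault((str(r.patient), str(r.target)), []).append(
            (int(r.well), float(r.spots), int(r.cells_per_well))
        )
    targets: dict[str, dict[str, ElispotMeasurement]] = {}
    medium: dict[str, ElispotMeasurement] = {}
    for (patient, target), wells in grouped.items():
        wells.sort()
        cells = {w[2] for w in wells}
        if len(cells) != 1:
            raise ValidationError(
                f"{patient}/{target}: wells disagree on cells_per_well"
            )
        meas = ElispotMeasurement(
            patient, target, tuple(w[1] for w in wells), cells.pop()
        )
        if target == MEDIUM_TARGET:
            medium[patient] = meas
        else:
            targets.setdefault(patient, {})[target] = meas
    return targets, medium


def write_elispot(
    targets: Mapping[str, Mapping[str, ElispotMeasurement]],
    medium: Mapping[str, ElispotMeasurement],
    path: str | Path,
) -> None:
    rows = []
    for patient in sorted(targets):
        for meas in list(targets[patient].values()) + [medium[patient]]:
            for well, spots in enumerate(meas.spots, start=1):
                rows.append(
                    (meas.patient_id, meas.target, well, spots,
                     meas.cells_per_well)
                )
    pd.DataFrame(
        rows, columns=["patient", "target", "well", "spots", "cells_per_well"]
    ).to_csv(path, sep="\t", index=False)
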