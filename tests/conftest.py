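from __future__ import annotations

import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from clonetrack.repertoire_io import (
    CloneKey,
    LongitudinalRepertoire,
    Phase,
    RepertoireSample,
    TreatmentWindows,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_BASES = "ACGT"


def clone(i: int) -> CloneKey:
    """Deterministic distinct clone keys for hand-built fixtures."""
    cdr3 = "".join(_BASES[(i >> (2 * j)) & 3] for j in range(12))
    return CloneKey(f"TRBV{i % 7 + 2}", f"TRBJ1-{i % 6 + 1}", cdr3)


def make_sample(
    counts: dict[CloneKey, int],
    sample_id: str = "S1",
    day: int = 0,
    phase: Phase = Phase.OTHER,
    patient_id: str = "PT01",
) -> RepertoireSample:
    return RepertoireSample(sample_id, patient_id, day, phase, dict(counts))


def make_repertoire(
    samples: list[RepertoireSample],
    windows: TreatmentWindows | None = None,
    patient_id: str = "PT01",
) -> LongitudinalRepertoire:
    return LongitudinalRepertoire(
        patient_id, samples, windows or TreatmentWindows()
    )


@pytest.fixture
def hamming_model():
    from clonetrack.neoantigen_quality import SubstitutionModel

    return SubstitutionModel.hamming()


@pytest.fixture
def toy_model():
    from clonetrack.neoantigen_quality import SubstitutionModel

    return SubstitutionModel.blosum62_toy()
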