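"""Peptide-specificity calls from sorted CD107a fractions.

After in vitro peptide restimulation, T cells are sorted into degranulating
(CD107a+) and non-degranulating (CD107a-) fractions and both fractions are
TCR-beta sequenced.  A clone is called specifically stimulated when
significantly more than 20% of its reads fall in the CD107a+ fraction
(one-tailed exact binomial test, Bonferroni-adjusted by the number of clones
tested in the same condition, adjusted P < 0.001).  Clones that reach
significance in the DMSO vehicle control are non-specifically stimulated and
are excluded from every peptide condition's specific set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import binomtest

from .repertoire_io import CloneKey, FormatError, ValidationError

__all__ = [
    "SortedFractionCounts",
    "SpecificityResult",
    "specificity_p",
    "call_specific_clones",
    "specificity_results",
    "read_sorted_fractions",
    "write_sorted_fractions",
    "write_specificity_results",
    "DMSO_CONDITION",
]

#: Condition label recognised as the vehicle (non-specific) control.
DMSO_CONDITION = "DMSO"
#: Null CD107a+ read fraction under non-specific stimulation.
DEFAULT_P0 = 0.2
DEFAULT_ALPHA = 0.001


@dataclass(frozen=True, slots=True)
class SortedFractionCounts:
    """Read counts of one clone in the CD107a+/- fractions of one condition."""

    clone: CloneKey
    k_pos: int
    k_neg: int
    condition: str

    def __post_init__(self) -> None:
        if self.k_pos < 0 or self.k_neg < 0:
            raise ValidationError("fraction counts must be non-negative")
        if self.k_pos + self.k_neg < 1:
            raise ValidationError(
                f"clone {self.clone} has zero reads in condition "
                f"{self.condition!r}"
            )


@dataclass(frozen=True, slots=True)
class SpecificityResult:
    clone: CloneKey
    condition: str
    k_pos: int
    k_neg: int
    p_raw: float
    p_adjusted: float
    specific: bool
    dmso_excluded: bool = False


def specificity_p(k_pos: int, k_neg: int, p0: float = DEFAULT_P0) -> float:
    """Upper-tail exact binomial P of >= k_pos successes in k_pos + k_neg
    trials at success probability p0."""
    if k_pos < 0 or k_neg < 0 or k_pos + k_neg < 1:
        raise ValidationError(
            f"need k_pos + k_neg >= 1, got k_pos={k_pos}, k_neg={k_neg}"
        )
    return binomtest(k_pos, k_pos + k_neg, p0, alternative="greater").pvalue


def specificity_results(
    counts: Iterable[SortedFractionCounts],
    alpha: float = DEFAULT_ALPHA,
    p0: float = DEFAULT_P0,
    dmso_condition: str = DMSO_CONDITION,
) -> list[SpecificityResult]:
    """Per-clone, per-condition specificity tests with DMSO exclusion.

    The Bonferroni factor is the number of clones tested within the same
    condition.  A clone significant in the DMSO control is flagged
    ``dmso_excluded`` and is never ``specific`` in any peptide condition.
    """
    counts = list(counts)
    by_condition: dict[str, list[SortedFractionCounts]] = {}
    for c in counts:
        by_condition.setdefault(c.condition, []).append(c)

    raw: dict[tuple[str, CloneKey], tuple[float, float]] = {}
    for condition, group in by_condition.items():
        n_tested = len(group)
        for c in group:
            p = specificity_p(c.k_pos, c.k_neg, p0)
            raw[(condition, c.clone)] = (p, min(1.0, p * n_tested))

    dmso_nonspecific = {
        clone
        for (condition, clone), (_, p_adj) in raw.items()
        if condition == dmso_condition and p_adj < alpha
    }

    out = []
    for c in counts:
        p, p_adj = raw[(c.condition, c.clone)]
        excluded = c.clone in dmso_nonspecific
        specific = (
            p_adj < alpha and c.condition != dmso_condition and not excluded
        )
        out.append(
            SpecificityResult(
                c.clone, c.condition, c.k_pos, c.k_neg, p, p_adj, specific,
                excluded,
            )
        )
    return out


def call_specific_clones(
    counts: Iterable[SortedFractionCounts],
    alpha: float = DEFAULT_ALPHA,
    p0: float = DEFAULT_P0,
    dmso_condition: str = DMSO_CONDITION,
) -> dict[str, set[CloneKey]]:
    """Specific clone sets per peptide condition (DMSO never a key)."""
    results = specificity_results(counts, alpha, p0, dmso_condition)
    out: dict[str, set[CloneKey]] = {}
    for r in results:
        if r.condition == dmso_condition:
            continue
        out.setdefault(r.condition, set())
        if r.specific:
            out[r.condition].add(r.clone)
    return out


_COLUMNS = ["condition", "v_gene", "j_gene", "cdr3_nt", "count_pos",
            "count_neg"]


def read_sorted_fractions(path: str | Path) -> list[SortedFractionCounts]:
    """Read the sorted-fraction TSV (condition, v_gene, j_gene, cdr3_nt,
    count_pos, count_neg)."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(
            f"sorted-fraction table missing columns: {sorted(missing)}"
        )
    return [
        SortedFractionCounts(
            CloneKey(str(r.v_gene), str(r.j_gene), str(r.cdr3_nt)),
            int(r.count_pos), int(r.count_neg), str(r.condition),
        )
        for r in frame.itertuples(index=False)
    ]


def write_sorted_fractions(
    counts: Sequence[SortedFractionCounts], path: str | Path
) -> None:
    rows = [
        (c.condition, c.clone.v_gene, c.clone.j_gene, c.clone.cdr3_nt,
         c.k_pos, c.k_neg)
        for c in counts
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def write_specificity_results(
    results: Sequence[SpecificityResult], path: str | Path
) -> None:
    rows = [
        (r.condition, r.clone.v_gene, r.clone.j_gene, r.clone.cdr3_nt,
         r.k_pos, r.k_neg, r.p_raw, r.p_adjusted, r.specific,
         r.dmso_excluded)
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=_COLUMNS + ["p_raw", "p_adjusted", "specific",
                            "dmso_excluded"],
    ).to_csv(path, sep="\t", index=False)
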