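"""Neoantigen quality via a positional-weighted cross-reactivity distance.

The cross-reactivity distance between two MHC class I minimal epitopes
(9-mers) p^A and p^B is modelled under an independent-site approximation as

    d_C(p^A, p^B) = sum_{i=1..9} d_i * M[p^A_i, p^B_i]

where M is a 20x20 amino-acid substitution-distance matrix (zero diagonal)
and d_1..d_9 are positional scaling weights.  The quality of a mutant 9-mer
is its distance from the germline (wild-type) 9-mer minus its minimum
distance to the set of all 9-mer subsequences of known antigenic epitopes
(IEDB):

    Q(p^MT) = d_C(p^MT, p^WT) - min_{p^a in P_IEDB} d_C(p^MT, p^a)

A high-quality neoantigen is therefore far from self but close to a known
immunogenic epitope.  A long neopeptide's quality is the average of the two
highest-quality 9-mer windows that (a) contain the substituted residue and
(b) are predicted binders (Kd <= 4,000 nM) to any of the patient's MHC I
alleles; neoantigens with no predicted minimal-epitope binder are excluded
(quality undefined) rather than scored.

The fitted matrix M and weights d_i are inputs loaded from a parameter
file.  The shipped defaults — a BLOSUM62-derived dissimilarity with uniform
positional weights — are a documented toy stand-in for testing, not a
published fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Align import substitution_matrices
from scipy.stats import mannwhitneyu

from .repertoire_io import ValidationError

__all__ = [
    "AMINO_ACIDS",
    "SubstitutionModel",
    "NeoantigenRecord",
    "BindingTable",
    "EpitopeSet",
    "MutantWindow",
    "QualityResult",
    "cross_reactivity_distance",
    "enumerate_mutant_9mers",
    "quality_9mer",
    "neoantigen_quality",
    "compare_quality_by_immunogenicity",
    "read_neoantigens",
    "write_neoantigens",
    "write_quality_results",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
DEFAULT_KD_THRESHOLD_NM = 4000.0
EPITOPE_LENGTH = 9


def _encode(peptide: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[aa] for aa in peptide], dtype=np.intp)
    except KeyError as exc:
        raise ValidationError(
            f"non-standard residue {exc.args[0]!r} in peptide {peptide!r}"
        ) from None


@dataclass(frozen=True)
class SubstitutionModel:
    """Substitution-distance matrix M (20x20, zero diagonal) and positional
    weights d_1..d_9."""

    matrix: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        d = np.asarray(self.weights, dtype=float)
        if m.shape != (20, 20):
            raise ValidationError(f"matrix must be 20x20, got {m.shape}")
        if d.shape != (EPITOPE_LENGTH,):
            raise ValidationError(f"weights must have length 9, got {d.shape}")
        if not np.all(np.isfinite(m)) or not np.all(np.isfinite(d)):
            raise ValidationError("model parameters must be finite")
        if np.any(m < 0) or np.any(d < 0):
            raise ValidationError("model parameters must be non-negative")
        if np.any(np.diag(m) != 0):
            raise ValidationError("matrix diagonal must be zero")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "weights", d)

    @classmethod
    def hamming(cls) -> "SubstitutionModel":
        """Indicator model: d_C reduces to the Hamming distance."""
        m = 1.0 - np.eye(20)
        return cls(m, np.ones(EPITOPE_LENGTH))

    @classmethod
    def blosum62_toy(cls) -> "SubstitutionModel":
        """Toy default for testing: BLOSUM62-derived dissimilarity
        M[a, b] = S[a, a] - S[a, b] with uniform positional weights.

        This is a stand-in with sensible metric-like behaviour (zero
        diagonal, non-negative), not a fitted cross-reactivity model.
        """
        blosum = substitution_matrices.load("BLOSUM62")
        m = np.zeros((20, 20))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                m[i, j] = blosum[a, a] - blosum[a, b]
        return cls(m, np.ones(EPITOPE_LENGTH))

    @classmethod
    def from_file(cls, path: str | Path) -> "SubstitutionModel":
        """Load model parameters from a YAML/JSON file with keys
        ``alphabet`` (20-letter order), ``matrix`` (20 rows of 20) and
        ``weights`` (9 values)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        alphabet = raw.get("alphabet", AMINO_ACIDS)
        if sorted(alphabet) != sorted(AMINO_ACIDS):
            raise ValidationError(
                "alphabet must be a permutation of the 20 standard residues"
            )
        perm = [alphabet.index(aa) for aa in AMINO_ACIDS]
        m = np.asarray(raw["matrix"], dtype=float)[np.ix_(perm, perm)]
        d = np.asarray(raw["weights"], dtype=float)
        return cls(m, d)

    def to_file(self, path: str | Path) -> None:
        payload = {
            "alphabet": AMINO_ACIDS,
            "matrix": self.matrix.tolist(),
            "weights": self.weights.tolist(),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass(frozen=True, slots=True)
class NeoantigenRecord:
    """A point-substituted neopeptide with its wild-type counterpart.

    ``mut_pos`` is 1-based; the two peptides must be equal length and differ
    exactly there.  Frameshift/indel neoantigens have no aligned wild-type
    and are outside this model's domain.
    """

    neoantigen_id: str
    mt_peptide: str
    wt_peptide: str
    mut_pos: int
    patient_hla: tuple[str, ...]

    def __post_init__(self) -> None:
        mt, wt = self.mt_peptide, self.wt_peptide
        if len(mt) != len(wt):
            raise ValidationError(
                f"{self.neoantigen_id}: MT and WT peptides differ in length"
            )
        for pep in (mt, wt):
            if not set(pep) <= set(AMINO_ACIDS):
                raise ValidationError(
                    f"{self.neoantigen_id}: non-standard residue in {pep!r}"
                )
        if not 1 <= self.mut_pos <= len(mt):
            raise ValidationError(
                f"{self.neoantigen_id}: mut_pos {self.mut_pos} outside "
                f"peptide of length {len(mt)}"
            )
        diff = [i + 1 for i, (a, b) in enumerate(zip(mt, wt)) if a != b]
        if diff != [self.mut_pos]:
            raise ValidationError(
                f"{self.neoantigen_id}: peptides must differ exactly at "
                f"mut_pos {self.mut_pos}, differ at {diff}"
            )


class BindingTable:
    """Predicted peptide-MHC dissociation constants, (9-mer, allele) -> nM.

    Binding prediction itself is external; this table consumes its output.
    A missing entry means no predicted binding for that pair.
    """

    def __init__(self, kd_nm: Mapping[tuple[str, str], float]):
        for (pep, allele), kd in kd_nm.items():
            if kd <= 0:
                raise ValidationError(
                    f"Kd must be positive, got {kd} for ({pep}, {allele})"
                )
        self._kd = dict(kd_nm)

    def __len__(self) -> int:
        return len(self._kd)

    def kd(self, peptide: str, allele: str) -> float | None:
        return self._kd.get((peptide, allele))

    def best_binder(
        self, peptide: str, alleles: Sequence[str],
        threshold: float = DEFAULT_KD_THRESHOLD_NM,
    ) -> tuple[str, float] | None:
        """Strongest allele with Kd <= threshold, or None if no binder."""
        best = None
        for allele in alleles:
            kd = self._kd.get((peptide, allele))
            if kd is not None and kd <= threshold:
                if best is None or kd < best[1]:
                    best = (allele, kd)
        return best

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BindingTable":
        frame = pd.read_csv(path, sep="\t")
        required = {"peptide", "allele", "kd_nm"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(
                f"binding table missing columns: {sorted(missing)}"
            )
        return cls(
            {
                (str(r.peptide), str(r.allele)): float(r.kd_nm)
                for r in frame.itertuples(index=False)
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [(p, a, kd) for (p, a), kd in sorted(self._kd.items())]
        pd.DataFrame(rows, columns=["peptide", "allele", "kd_nm"]).to_csv(
            path, sep="\t", index=False
        )


class EpitopeSet:
    """All 9-mer subsequences of a collection of known epitopes (P_IEDB)."""

    def __init__(self, nine_mers: Iterable[str]):
        mers = sorted(set(nine_mers))
        if any(len(p) != EPITOPE_LENGTH for p in mers):
            raise ValidationError("all epitope set members must be 9-mers")
        self.nine_mers: tuple[str, ...] = tuple(mers)
        self._encoded = (
            np.stack([_encode(p) for p in mers])
            if mers
            else np.empty((0, EPITOPE_LENGTH), dtype=np.intp)
        )

    def __len__(self) -> int:
        return len(self.nine_mers)

    def __contains__(self, peptide: str) -> bool:
        return len(peptide) == EPITOPE_LENGTH and peptide in set(self.nine_mers)

    @classmethod
    def from_epitopes(cls, epitopes: Iterable[str]) -> "EpitopeSet":
        mers = []
        for epi in epitopes:
            for start in range(len(epi) - EPITOPE_LENGTH + 1):
                mers.append(epi[start : start + EPITOPE_LENGTH])
        return cls(mers)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "EpitopeSet":
        return cls.from_epitopes(
            str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        )

    @classmethod
    def from_text(cls, path: str | Path) -> "EpitopeSet":
        """One epitope per line; blank lines and ``#`` comments ignored."""
        lines = Path(path).read_text().splitlines()
        return cls.from_epitopes(
            ln.strip().upper()
            for ln in lines
            if ln.strip() and not ln.startswith("#")
        )

    def min_distance(self, peptide: str, model: SubstitutionModel) -> float:
        """min over the set of d_C(peptide, member); vectorised."""
        if len(self) == 0:
            raise ValidationError("epitope set is empty")
        enc = _encode(peptide)
        if enc.shape[0] != EPITOPE_LENGTH:
            raise ValidationError("peptide must be a 9-mer")
        dists = model.matrix[enc[None, :], self._encoded] @ model.weights
        return float(dists.min())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def cross_reactivity_distance(
    p_a: str, p_b: str, model: SubstitutionModel
) -> float:
    """d_C(p^A, p^B) = sum_i d_i * M[p^A_i, p^B_i] over the nine positions."""
    if len(p_a) != EPITOPE_LENGTH or len(p_b) != EPITOPE_LENGTH:
        raise ValidationError("both peptides must be 9-mers")
    ia, ib = _encode(p_a), _encode(p_b)
    return float(model.matrix[ia, ib] @ model.weights)


class MutantWindow(NamedTuple):
    """One mutant 9-mer window with its aligned wild-type window;
    ``start`` is 1-based in the source peptide."""

    mt: str
    wt: str
    start: int


def enumerate_mutant_9mers(rec: NeoantigenRecord) -> list[MutantWindow]:
    """All 9-mer windows of the mutant peptide covering the substituted
    residue, each paired with the same-coordinate wild-type window."""
    length = len(rec.mt_peptide)
    if length < EPITOPE_LENGTH:
        raise ValidationError(
            f"{rec.neoantigen_id}: peptide shorter than 9 residues"
        )
    first = max(1, rec.mut_pos - EPITOPE_LENGTH + 1)
    last = min(length - EPITOPE_LENGTH + 1, rec.mut_pos)
    return [
        MutantWindow(
            rec.mt_peptide[s - 1 : s - 1 + EPITOPE_LENGTH],
            rec.wt_peptide[s - 1 : s - 1 + EPITOPE_LENGTH],
            s,
        )
        for s in range(first, last + 1)
    ]


def quality_9mer(
    p_mt: str, p_wt: str, iedb: EpitopeSet, model: SubstitutionModel
) -> float:
    """Q(p^MT) = d_C(p^MT, p^WT) - min over P_IEDB of d_C(p^MT, .);
    may be negative (closer to a known epitope than to self)."""
    if len(iedb) == 0:
        raise ValidationError("epitope set is empty")
    return cross_reactivity_distance(p_mt, p_wt, model) - iedb.min_distance(
        p_mt, model
    )


class WindowQuality(NamedTuple):
    window: MutantWindow
    quality: float
    best_allele: str
    kd_nm: float


@dataclass(frozen=True)
class QualityResult:
    """Quality of a neopeptide, or None with an exclusion reason."""

    neoantigen_id: str
    quality: float | None
    windows: tuple[WindowQuality, ...] = ()
    selected: tuple[WindowQuality, ...] = ()
    exclusion_reason: str | None = None


def neoantigen_quality(
    rec: NeoantigenRecord,
    iedb: EpitopeSet,
    model: SubstitutionModel,
    binding: BindingTable,
    kd_threshold: float = DEFAULT_KD_THRESHOLD_NM,
) -> QualityResult:
    """Neopeptide quality: mean of the two highest-quality mutant 9-mer
    windows that are predicted binders (Kd <= threshold) to any patient
    allele.  A single qualifying binder is used alone; with no binder the
    quality is undefined and the neoantigen is flagged excluded.
    """
    scored = []
    for window in enumerate_mutant_9mers(rec):
        binder = binding.best_binder(window.mt, rec.patient_hla, kd_threshold)
        if binder is None:
            continue
        q = quality_9mer(window.mt, window.wt, iedb, model)
        scored.append(WindowQuality(window, q, binder[0], binder[1]))
    if not scored:
        return QualityResult(
            rec.neoantigen_id, None, (), (), "no_predicted_binder"
        )
    # Stable top-2 by quality, ties broken by leftmost window start.
    ranked = sorted(scored, key=lambda wq: (-wq.quality, wq.window.start))
    selected = tuple(ranked[:2])
    value = sum(wq.quality for wq in selected) / len(selected)
    return QualityResult(rec.neoantigen_id, value, tuple(scored), selected)


def compare_quality_by_immunogenicity(
    qualities: Sequence[float], immunogenic: Sequence[bool]
) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney U) comparison of quality scores
    between immunogenic and non-immunogenic neoantigens.

    Returns (U statistic, two-sided P).  Both labels must be present.
    """
    q = np.asarray(qualities, dtype=float)
    lab = np.asarray(immunogenic, dtype=bool)
    if q.shape != lab.shape:
        raise ValidationError("qualities and labels must align")
    pos, neg = q[lab], q[~lab]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both immunogenic and non-immunogenic scores "
                              "are required")
    res = mannwhitneyu(pos, neg, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def read_neoantigens(path: str | Path) -> list[NeoantigenRecord]:
    """Read the neoantigen TSV (neoantigen_id, mt_peptide, wt_peptide,
    mut_pos, alleles with ``;``-separated allele labels)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"neoantigen_id", "mt_peptide", "wt_peptide", "mut_pos",
                "alleles"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(
            f"neoantigen table missing columns: {sorted(missing)}"
        )
    return [
        NeoantigenRecord(
            str(r.neoantigen_id), str(r.mt_peptide), str(r.wt_peptide),
            int(r.mut_pos), tuple(str(r.alleles).split(";")),
        )
        for r in frame.itertuples(index=False)
    ]


def write_neoantigens(
    records: Sequence[NeoantigenRecord], path: str | Path
) -> None:
    rows = [
        (r.neoantigen_id, r.mt_peptide, r.wt_peptide, r.mut_pos,
         ";".join(r.patient_hla))
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["neoantigen_id", "mt_peptide", "wt_peptide", "mut_pos",
                 "alleles"],
    ).to_csv(path, sep="\t", index=False)


def write_quality_results(
    results: Sequence[QualityResult], path: str | Path
) -> None:
    """Per-neoantigen TSV with the selected windows and final quality."""
    rows = []
    for res in results:
        rows.append(
            (
                res.neoantigen_id,
                res.quality if res.quality is not None else "",
                ";".join(str(wq.window.start) for wq in res.selected),
                ";".join(f"{wq.quality:.6g}" for wq in res.windows),
                res.exclusion_reason or "",
            )
        )
    pd.DataFrame(
        rows,
        columns=["neoantigen_id", "quality", "selected_window_starts",
                 "window_qualities", "exclusion_reason"],
    ).to_csv(path, sep="\t", index=False)
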