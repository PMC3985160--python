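"""n-gram and exchange-group feature extraction for protein sequences.

A protein sequence over the 20-letter amino-acid alphabet is summarised by a
56-dimensional composition vector: the 36 normalized 2-gram frequencies of its
6-letter exchange-group recoding concatenated with the 20 normalized residue
1-gram frequencies.  The exchange groups partition the amino acids into six
biochemical equivalence classes, so the 2-gram half captures coarse local
order while the 1-gram half captures raw composition.

Counts of a length-``n`` gram are normalized by ``l - n + 1`` (the number of
gram positions in a length-``l`` sequence), so each half of the vector sums
to one.  For classifier input the columns are additionally min-max scaled to
``[-1, 1]`` with statistics learned from the training split only.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Exchange groups: biochemical equivalence classes of the amino acids.
EXCHANGE_GROUPS: dict[str, str] = {
    "A": "HRK",
    "B": "DENQ",
    "C": "C",
    "D": "STPAG",
    "E": "MILV",
    "F": "FYW",
}

RESIDUE_TO_GROUP: dict[str, str] = {
    residue: group for group, members in EXCHANGE_GROUPS.items() for residue in members
}

GROUP_LABELS = "ABCDEF"

#: Fixed lexicographic layout of the 36 exchange-group 2-gram slots.
E2_GRAMS: tuple[str, ...] = tuple(a + b for a in GROUP_LABELS for b in GROUP_LABELS)
#: Fixed alphabetic layout of the 20 residue 1-gram slots.
A1_GRAMS: tuple[str, ...] = tuple(AMINO_ACIDS)

#: Column names of the combined feature vector, e2 block first.
FEATURE_NAMES: tuple[str, ...] = tuple(f"e2_{g}" for g in E2_GRAMS) + tuple(
    f"a1_{r}" for r in A1_GRAMS
)

N_FEATURES = len(FEATURE_NAMES)  # 36 + 20 = 56

_E2_INDEX = {g: i for i, g in enumerate(E2_GRAMS)}
_A1_INDEX = {r: i for i, r in enumerate(A1_GRAMS)}


class FastaError(ValueError):
    """Raised for malformed FASTA input."""


class SequenceError(ValueError):
    """Raised when a sequence violates the amino-acid alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified protein sequence over the 20-letter alphabet."""

    id: str
    residues: str


@dataclass(frozen=True)
class ExchangeString:
    """A protein sequence recoded into the 6 exchange-group labels."""

    groups: str


@dataclass(frozen=True)
class NGramCounts:
    """Counts of every contiguous length-``n`` substring of a sequence."""

    n: int
    counts: dict[str, int]
    seq_length: int


@dataclass(frozen=True)
class FeatureVector:
    """The 56-dimensional normalized composition representation."""

    e2: np.ndarray  # 36 exchange-group 2-gram frequencies
    a1: np.ndarray  # 20 residue 1-gram frequencies

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.e2, self.a1])


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The record id is the first whitespace-delimited token of the header;
    residues are uppercased with internal whitespace removed.  Sequence data
    appearing before any ``>`` header is a parse error naming the line.
    """
    records: list[ProteinRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            break
        handle.seek(0)
        for header, sequence in SimpleFastaParser(handle):
            seq_id = header.split()[0] if header.split() else header
            residues = "".join(sequence.split()).upper()
            records.append(ProteinRecord(id=seq_id, residues=residues))
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    """Write records as plain FASTA, 70 residues per line."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for start in range(0, len(rec.residues), 70):
                handle.write(rec.residues[start : start + 70] + "\n")


def validate_sequence(record: ProteinRecord, policy: str = "strict") -> ProteinRecord:
    """Enforce the 20-letter alphabet on a record.

    ``strict`` raises :class:`SequenceError` at the first out-of-alphabet
    character (1-based position reported); ``drop-unknown`` silently removes
    such characters (B/Z/X ambiguity codes, U/O, gap symbols) with a warning.
    """
    if policy not in ("strict", "drop-unknown"):
        raise ValueError(f"unknown validation policy {policy!r}")
    residues = record.residues
    if policy == "strict":
        for pos, ch in enumerate(residues, start=1):
            if ch not in RESIDUE_TO_GROUP:
                raise SequenceError(
                    f"sequence {record.id!r}: invalid residue {ch!r} at position {pos}"
                )
        return record
    kept = "".join(ch for ch in residues if ch in RESIDUE_TO_GROUP)
    if len(kept) != len(residues):
        logger.warning(
            "sequence %r: dropped %d non-standard residue(s)",
            record.id,
            len(residues) - len(kept),
        )
    return ProteinRecord(id=record.id, residues=kept)


def to_exchange_string(record: ProteinRecord) -> ExchangeString:
    """Recode each residue into its exchange-group label (length preserved)."""
    try:
        return ExchangeString(groups="".join(RESIDUE_TO_GROUP[r] for r in record.residues))
    except KeyError as exc:
        raise SequenceError(
            f"sequence {record.id!r}: residue {exc.args[0]!r} outside the amino-acid alphabet"
        ) from exc


def count_ngrams(sequence: str, n: int) -> NGramCounts:
    """Count every contiguous length-``n`` substring of ``sequence``.

    Grams with zero count are omitted.  When ``n`` exceeds the sequence
    length the count map is empty (no gram positions exist) — not an error.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    length = len(sequence)
    counts = Counter(sequence[i : i + n] for i in range(length - n + 1))
    return NGramCounts(n=n, counts=dict(counts), seq_length=length)


def normalize_counts(counts: NGramCounts) -> dict[str, float]:
    """Divide each gram count by ``l - n + 1`` so the map sums to one."""
    denom = counts.seq_length - counts.n + 1
    if denom < 1:
        raise ValueError(
            f"cannot normalize: sequence length {counts.seq_length} < n {counts.n}"
        )
    return {gram: c / denom for gram, c in counts.counts.items()}


def build_feature_vector(record: ProteinRecord) -> FeatureVector:
    """Build the 56-dimensional feature vector of a validated record.

    Exchange-group 2-gram frequencies fill the fixed 36-slot lexicographic
    layout; residue 1-gram frequencies fill the fixed 20-slot alphabetic
    layout; absent grams are zero.  Sequences shorter than two residues have
    no 2-gram representation and are rejected.
    """
    if len(record.residues) < 2:
        raise ValueError(
            f"sequence {record.id!r}: length {len(record.residues)} < 2, "
            "exchange-group 2-grams undefined"
        )
    exchange = to_exchange_string(record)
    e2 = np.zeros(len(E2_GRAMS))
    for gram, value in normalize_counts(count_ngrams(exchange.groups, 2)).items():
        e2[_E2_INDEX[gram]] = value
    a1 = np.zeros(len(A1_GRAMS))
    for gram, value in normalize_counts(count_ngrams(record.residues, 1)).items():
        a1[_A1_INDEX[gram]] = value
    return FeatureVector(e2=e2, a1=a1)


def feature_matrix(records: list[ProteinRecord]) -> np.ndarray:
    """Stack feature vectors of ``records`` into an ``N x 56`` matrix."""
    if not records:
        return np.empty((0, N_FEATURES))
    return np.vstack([build_feature_vector(rec).combined for rec in records])


def features_to_csv(matrix: np.ndarray, ids: list[str], path) -> None:
    """Write a feature matrix as CSV with the fixed 56-column header."""
    frame = pd.DataFrame(matrix, columns=list(FEATURE_NAMES))
    frame.insert(0, "id", ids)
    frame.to_csv(path, index=False)


def features_from_csv(path) -> tuple[np.ndarray, list[str]]:
    """Read a feature CSV written by :func:`features_to_csv`."""
    frame = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing feature columns {missing[:3]}...")
    ids = frame["id"].astype(str).tolist() if "id" in frame.columns else [
        str(i) for i in range(len(frame))
    ]
    return frame[list(FEATURE_NAMES)].to_numpy(dtype=float), ids


def read_labels(path) -> dict[str, str]:
    """Read a two-column delimited label file (id, class), header optional."""
    frame = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (id, label)")
    first = frame.iloc[0]
    if first.iloc[0].lower() in ("id", "sequence", "name") or first.iloc[1].lower() in (
        "label",
        "class",
        "superfamily",
    ):
        frame = frame.iloc[1:]
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


@dataclass
class FeatureScaler:
    """Per-dimension affine map of training range onto ``[-1, 1]``.

    Fitted on the training matrix only; test data transformed with training
    statistics may fall outside the interval.  Constant dimensions map to 0.
    """

    minimum: np.ndarray = field(default=None)
    maximum: np.ndarray = field(default=None)

    def fit(self, matrix: np.ndarray) -> "FeatureScaler":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] < 1:
            raise ValueError("scaler requires a non-empty 2-D training matrix")
        self.minimum = matrix.min(axis=0)
        self.maximum = matrix.max(axis=0)
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.minimum is None:
            raise ValueError("scaler not fitted")
        matrix = np.asarray(matrix, dtype=float)
        span = self.maximum - self.minimum
        safe = np.where(span > 0, span, 1.0)
        scaled = 2.0 * (matrix - self.minimum) / safe - 1.0
        return np.where(span > 0, scaled, 0.0)

    def fit_transform(self, matrix: np.ndarray) -> np.ndarray:
        return self.fit(matrix).transform(matrix)


def fit_scaler(train_matrix: np.ndarray) -> FeatureScaler:
    """Fit a ``[-1, 1]`` min-max scaler on the training matrix."""
    return FeatureScaler().fit(train_matrix)


def apply_scaler(scaler: FeatureScaler, matrix: np.ndarray) -> np.ndarray:
    """Transform ``matrix`` with training statistics held by ``scaler``."""
    return scaler.transform(matrix)
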