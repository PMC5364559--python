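"""Reading, validating and writing protein sequence data.

A :class:`ProteinRecord` is the unit of all downstream encoding: an
identifier plus a residue string over the 20-letter standard amino-acid
alphabet.  FASTA input is parsed with Biopython; records are uppercased
before validation so mixed-case files lose no information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Standard residues, fixed alphabetical order used by every encoder.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
#: Residue letter -> column index in AMINO_ACIDS order.
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class ResidueVerdict:
    """Outcome of residue validation.

    ``position`` is 1-based and refers to the first offending character;
    both extra fields are ``None`` for valid or empty sequences.
    """

    valid: bool
    position: int | None = None
    character: str | None = None


def validate_residues(sequence: str) -> ResidueVerdict:
    """Check that every (uppercased) character is a standard residue.

    The empty string is invalid: it encodes no protein.
    """
    if not sequence:
        return ResidueVerdict(valid=False)
    for pos, ch in enumerate(sequence.upper(), start=1):
        if ch not in _AA_SET:
            return ResidueVerdict(valid=False, position=pos, character=ch)
    return ResidueVerdict(valid=True)


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the standard alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus a validated residue string.

    The sequence is uppercased on construction; construction fails if the
    result contains a non-standard residue or is empty.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        verdict = validate_residues(self.sequence)
        if not verdict.valid:
            if verdict.position is None:
                raise InvalidResidueError(f"record {self.id!r}: empty sequence")
            raise InvalidResidueError(
                f"record {self.id!r}: non-standard residue "
                f"{verdict.character!r} at position {verdict.position}"
            )

    @property
    def length(self) -> int:
        """Number of residues (the L of every encoder denominator)."""
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Ordered records with one label in {+1, -1} per record.

    +1 is the positive class, -1 the negative class.
    Prediction-mode datasets may carry a single class or be empty.
    """

    records: list[ProteinRecord]
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.records) != self.labels.size:
            raise ValueError(
                f"{len(self.records)} records but {self.labels.size} labels"
            )
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be +1/-1, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, indices: Sequence[int] | np.ndarray) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            records=[self.records[i] for i in idx], labels=self.labels[idx]
        )

    @classmethod
    def from_classes(
        cls,
        positives: Iterable[ProteinRecord],
        negatives: Iterable[ProteinRecord],
    ) -> "LabeledDataset":
        pos, neg = list(positives), list(negatives)
        labels = np.concatenate(
            [np.ones(len(pos), dtype=int), -np.ones(len(neg), dtype=int)]
        )
        return cls(records=pos + neg, labels=labels)


def read_fasta(path: str | Path, policy: str = "strict") -> list[ProteinRecord]:
    """Parse a FASTA file into validated :class:`ProteinRecord` objects.

    Parameters
    ----------
    path:
        FASTA file (multi-line records allowed).
    policy:
        ``"strict"`` aborts on any record with a non-standard residue or a
        duplicate id.  ``"skip-invalid"`` drops invalid records (counted in
        the log) and disambiguates duplicate ids with a numeric suffix.
    """
    if policy not in ("strict", "skip-invalid"):
        raise ValueError(f"unknown policy {policy!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    n_skipped = 0
    for raw in SeqIO.parse(str(path), "fasta"):
        rid = raw.id
        seq = str(raw.seq).upper()
        verdict = validate_residues(seq)
        if not verdict.valid:
            if policy == "strict":
                if verdict.position is None:
                    raise InvalidResidueError(f"record {rid!r}: empty sequence")
                raise InvalidResidueError(
                    f"record {rid!r}: non-standard residue "
                    f"{verdict.character!r} at position {verdict.position}"
                )
            n_skipped += 1
            continue
        if rid in seen:
            if policy == "strict":
                raise ValueError(f"duplicate identifier {rid!r}")
            seen[rid] += 1
            new_id = f"{rid}_{seen[rid]}"
            logger.warning("duplicate id %r renamed to %r", rid, new_id)
            rid = new_id
        seen.setdefault(rid, 1)
        records.append(ProteinRecord(id=rid, sequence=seq))

    if n_skipped:
        logger.info("read_fasta: skipped %d invalid record(s)", n_skipped)
    if not records and n_skipped == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with fixed line width (deterministic output)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


@dataclass(frozen=True)
class PredictionRow:
    """One output row of the prediction table.

    ``predicted_label``/``probability`` are ``None`` for sequences that
    could not be scored (e.g. shorter than the scheme's minimum length).
    """

    sequence_id: str
    predicted_label: int | None
    probability: float | None


def write_predictions(rows: Iterable[PredictionRow], path: str | Path) -> None:
    """Write a tab-separated prediction table.

    Columns: sequence_id, predicted_label, probability (4 decimals).
    Unscorable rows print ``NA`` in the last two columns.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sequence_id\tpredicted_label\tprobability\n")
        for row in rows:
            if row.predicted_label is None:
                fh.write(f"{row.sequence_id}\tNA\tNA\n")
                continue
            if row.probability is None:
                prob = "NA"
            else:
                if not 0.0 <= row.probability <= 1.0:
                    raise ValueError(
                        f"probability {row.probability} outside [0, 1] "
                        f"for {row.sequence_id!r}"
                    )
                prob = f"{row.probability:.4f}"
            fh.write(f"{row.sequence_id}\t{row.predicted_label:+d}\t{prob}\n")
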