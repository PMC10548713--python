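"""Protein input, peptide-window extraction and dataset assembly.

Candidate arginine methylation sites are represented as fixed-length peptide
windows ``P(-gamma) ... P(-1) R P(1) ... P(gamma)`` of length ``2*gamma + 1``
centered on an arginine (R).  A window is a positive sample when its central R
is an annotated methylation site and a negative sample otherwise.  Windows
that would run past a protein terminus are padded with ``'X'``, which every
downstream feature encoder treats as inert, so all windows share one length.

Annotations are 1-based (position of the R in the protein); windows report a
1-based ``center_position``.  Input proteins are assumed to be pre-deduplicated
(redundancy removal, e.g. CD-HIT clustering, is upstream of this package).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: ambiguity / non-standard codes accepted on input and normalized to 'X'
AMBIGUOUS_AA = "BZUO"
PAD = "X"

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"

SITE_CLASSES = ("mono", "di")


class SequenceError(ValueError):
    """Malformed FASTA/annotation input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein chain: an identifier and an upper-case residue string."""

    id: str
    sequence: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideWindow:
    """A ``2*gamma + 1`` residue window centered on an arginine.

    ``residues[gamma]`` is always ``'R'``; positions falling outside the
    source protein hold the pad character ``'X'``.
    """

    residues: str
    gamma: int
    center_position: int  # 1-based index of the central R in the source protein
    source_id: str
    label: str = UNLABELED

    def __post_init__(self) -> None:
        if self.gamma < 1:
            raise ValueError(f"gamma must be >= 1, got {self.gamma}")
        if len(self.residues) != 2 * self.gamma + 1:
            raise ValueError(
                f"window length {len(self.residues)} != 2*gamma+1 = {2 * self.gamma + 1}"
            )
        if self.residues[self.gamma] != "R":
            raise ValueError(f"window center is {self.residues[self.gamma]!r}, expected 'R'")
        if self.label not in (POSITIVE, NEGATIVE, UNLABELED):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def window_id(self) -> str:
        return f"{self.source_id}:{self.center_position}"


@dataclass
class LabeledDataset:
    """An ordered collection of labeled peptide windows."""

    windows: list[PeptideWindow] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for w in self.windows:
            counts[w.label] = counts.get(w.label, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def subset(self, labels: Iterable[str]) -> list[PeptideWindow]:
        wanted = set(labels)
        return [w for w in self.windows if w.label in wanted]


def _normalize_sequence(record_id: str, raw: str) -> str:
    seq = raw.upper()
    out = []
    for i, ch in enumerate(seq):
        if ch in STANDARD_AA or ch == PAD:
            out.append(ch)
        elif ch in AMBIGUOUS_AA:
            logger.warning(
                "record %s: ambiguity code %r at position %d normalized to 'X'",
                record_id, ch, i + 1,
            )
            out.append(PAD)
        else:
            raise SequenceError(
                f"record {record_id!r}: illegal residue character {ch!r} at position {i + 1}"
            )
    return "".join(out)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased; ambiguity codes B/Z/U/O are normalized to 'X'
    with a warning; any other non-standard character is an error naming the
    record and 1-based offset.  Duplicate identifiers and empty files are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _normalize_sequence(rec.id, str(rec.seq))
        if not seq:
            raise SequenceError(f"record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def extract_windows(protein: ProteinRecord, gamma: int = 5) -> list[PeptideWindow]:
    """Extract one window per arginine in *protein*, padding termini with 'X'."""
    if gamma < 1:
        raise ValueError(f"gamma must be >= 1, got {gamma}")
    seq = protein.sequence
    padded = PAD * gamma + seq + PAD * gamma
    windows = []
    for i, ch in enumerate(seq):
        if ch == "R":
            windows.append(
                PeptideWindow(
                    residues=padded[i : i + 2 * gamma + 1],
                    gamma=gamma,
                    center_position=i + 1,
                    source_id=protein.id,
                )
            )
    return windows


def read_annotations(path: str | Path) -> list[tuple[str, int, str]]:
    """Read a site-annotation table (TSV or CSV).

    Expected header columns: ``protein_id``, ``position`` (1-based),
    ``label`` in {mono, di}.  Lines starting with '#' are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise SequenceError(f"no annotation rows in {path}")
    delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.DictReader(lines, delimiter=delimiter)
    required = {"protein_id", "position", "label"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise SequenceError(
            f"annotation table {path} must have columns {sorted(required)}, "
            f"got {reader.fieldnames}"
        )
    rows = []
    for i, row in enumerate(reader, start=2):
        label = row["label"].strip()
        if label not in SITE_CLASSES:
            raise SequenceError(
                f"{path} line {i}: label {label!r} not in {SITE_CLASSES}"
            )
        try:
            pos = int(row["position"])
        except ValueError as exc:
            raise SequenceError(f"{path} line {i}: non-integer position") from exc
        rows.append((row["protein_id"].strip(), pos, label))
    return rows


def build_dataset(
    proteins: Sequence[ProteinRecord],
    annotations: Iterable[tuple[str, int, str]],
    gamma: int = 5,
    site_class: str = "mono",
) -> LabeledDataset:
    """Assemble the labeled benchmark for one methylation class.

    Positives are windows whose central R is annotated with *site_class*.
    Negatives are the remaining R-centered windows of the same proteins,
    excluding (a) R sites annotated with any methylation class and (b) windows
    whose residue string is identical to some positive's (to avoid planting
    label contradictions).  Duplicate negatives are otherwise retained.
    """
    if site_class not in SITE_CLASSES:
        raise ValueError(f"site_class must be one of {SITE_CLASSES}, got {site_class!r}")
    by_id = {p.id: p for p in proteins}
    annotated: dict[tuple[str, int], str] = {}
    for pid, pos, label in annotations:
        if pid not in by_id:
            raise SequenceError(f"annotation references unknown protein id {pid!r}")
        seq = by_id[pid].sequence
        if not (1 <= pos <= len(seq)):
            raise SequenceError(
                f"annotation ({pid!r}, {pos}) outside protein of length {len(seq)}"
            )
        if seq[pos - 1] != "R":
            raise SequenceError(
                f"annotation ({pid!r}, {pos}) points at {seq[pos - 1]!r}, not 'R'"
            )
        annotated[(pid, pos)] = label

    positives: list[PeptideWindow] = []
    candidates: list[PeptideWindow] = []
    for protein in proteins:
        for w in extract_windows(protein, gamma):
            key = (w.source_id, w.center_position)
            if annotated.get(key) == site_class:
                positives.append(replace(w, label=POSITIVE))
            elif key not in annotated:
                candidates.append(w)
    positive_strings = {w.residues for w in positives}
    negatives = [
        replace(w, label=NEGATIVE)
        for w in candidates
        if w.residues not in positive_strings
    ]
    return LabeledDataset(windows=positives + negatives)


def undersample(dataset: LabeledDataset, seed: int) -> LabeledDataset:
    """Balance classes by uniform random down-sampling of the majority class.

    The minority class is untouched; window order within the output follows
    the input order.  Deterministic for a given seed.
    """
    pos = [w for w in dataset if w.label == POSITIVE]
    neg = [w for w in dataset if w.label == NEGATIVE]
    if not pos or not neg:
        raise ValueError(
            f"undersample needs both classes, got counts {dataset.class_counts}"
        )
    if len(pos) == len(neg):
        return LabeledDataset(windows=list(dataset.windows))
    rng = np.random.default_rng(seed)
    major, minor = (neg, pos) if len(neg) > len(pos) else (pos, neg)
    keep = set(rng.choice(len(major), size=len(minor), replace=False).tolist())
    major_kept = {id(w) for i, w in enumerate(major) if i in keep}
    minor_ids = {id(w) for w in minor}
    kept = [w for w in dataset if id(w) in major_kept or id(w) in minor_ids]
    return LabeledDataset(windows=kept)


def write_windows_tsv(dataset: LabeledDataset, path: str | Path) -> None:
    """Serialize a window dataset as TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["window_id", "source_id", "center_position", "residues", "label"])
        for w in dataset:
            writer.writerow([w.window_id, w.source_id, w.center_position, w.residues, w.label])


def read_windows_tsv(path: str | Path) -> LabeledDataset:
    """Read a window dataset written by :func:`write_windows_tsv`."""
    path = Path(path)
    windows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            residues = row["residues"]
            gamma = (len(residues) - 1) // 2
            if len(residues) != 2 * gamma + 1 or residues[gamma] != "R":
                raise SequenceError(
                    f"{path} line {i}: {residues!r} is not an odd-length R-centered window"
                )
            windows.append(
                PeptideWindow(
                    residues=residues,
                    gamma=gamma,
                    center_position=int(row["center_position"]),
                    source_id=row["source_id"],
                    label=row["label"],
                )
            )
    return LabeledDataset(windows=windows)
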