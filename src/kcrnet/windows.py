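"""FASTA I/O and lysine-centered peptide window extraction.

Kcr-site predictors operate on fixed-length peptide windows (default 29
residues) centered on a candidate lysine.  Windows overrunning a protein
terminus are padded with ``-``; non-canonical residues (B, J, O, U, Z) are
collapsed to the unknown symbol ``X`` at load time so the downstream
vocabulary stays at 22 tokens (20 amino acids + pad + unknown).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD_SYMBOL = "-"
UNKNOWN_SYMBOL = "X"
DEFAULT_WINDOW_LENGTH = 29

_NONCANONICAL = set("BJOUZ")
_VALID = set(AMINO_ACIDS) | {PAD_SYMBOL, UNKNOWN_SYMBOL}

Label = Literal["positive", "negative", "unlabeled"]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass
class SequenceRecord:
    """A named amino-acid sequence (upper-cased, non-canonicals mapped to X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)} after normalization"
            )


@dataclass
class PeptideWindow:
    """A fixed-length peptide window centered on a lysine.

    ``source_position`` is the 1-based index of the central K in the parent
    sequence (biologist convention); ``center_index`` is 0-based internal.
    """

    residues: str
    label: Label = "unlabeled"
    source_id: str = ""
    source_position: int | None = None

    @property
    def center_index(self) -> int:
        return len(self.residues) // 2

    @property
    def center_residue(self) -> str:
        return self.residues[self.center_index]


@dataclass
class LabeledDataset:
    """An ordered collection of labeled peptide windows."""

    windows: list[PeptideWindow] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int]:
        n_pos = sum(1 for w in self.windows if w.label == "positive")
        n_neg = sum(1 for w in self.windows if w.label == "negative")
        return n_pos, n_neg

    @property
    def labels(self) -> list[int]:
        return [1 if w.label == "positive" else 0 for w in self.windows]

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


def normalize_residues(raw: str) -> str:
    """Upper-case and map non-canonical residues (B/J/O/U/Z) to ``X``."""
    up = "".join(raw.split()).upper()
    return "".join(UNKNOWN_SYMBOL if c in _NONCANONICAL else c for c in up)


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving file order.

    Multi-line and single-line dialects are both accepted.  A non-blank
    sequence line appearing before any ``>`` header is a parse error that
    names the offending line number; an empty file is an error.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    # SeqIO silently skips content before the first header, so pre-check.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(SequenceRecord(id=rec.id, residues=normalize_residues(str(rec.seq))))
    if not records:
        raise FastaParseError(f"{path}: no records parsed")
    return records


def write_fasta(windows: Iterable[PeptideWindow | SequenceRecord], path: str | os.PathLike) -> None:
    """Write records single-line so that read_fasta round-trips (id, residues)."""
    recs = []
    for i, w in enumerate(windows):
        rid = getattr(w, "source_id", "") or getattr(w, "id", "") or f"w{i}"
        recs.append(SeqRecord(Seq(w.residues), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(recs)


def extract_windows(
    record: SequenceRecord,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    pad_symbol: str = PAD_SYMBOL,
) -> list[PeptideWindow]:
    """Cut one window per lysine in ``record``, padding past either terminus.

    Window length must be odd so the K sits exactly at the center; the flank
    on each side is ``(window_length - 1) // 2``.
    """
    if window_length < 3 or window_length % 2 == 0:
        raise ValueError(f"window_length must be odd and >= 3, got {window_length}")
    flank = (window_length - 1) // 2
    seq = record.residues
    padded = pad_symbol * flank + seq + pad_symbol * flank
    out = []
    for i, aa in enumerate(seq):
        if aa == "K":
            out.append(
                PeptideWindow(
                    residues=padded[i : i + window_length],
                    label="unlabeled",
                    source_id=record.id,
                    source_position=i + 1,
                )
            )
    return out


def _check_window(
    rec: SequenceRecord, window_length: int, on_non_k_center: str
) -> PeptideWindow | None:
    if len(rec.residues) != window_length:
        raise ValueError(
            f"record {rec.id!r}: window length {len(rec.residues)} != expected {window_length}"
        )
    w = PeptideWindow(residues=rec.residues, source_id=rec.id)
    if w.center_residue != "K":
        if on_non_k_center == "reject":
            raise ValueError(
                f"record {rec.id!r}: center residue {w.center_residue!r} is not K"
            )
        if on_non_k_center == "drop":
            return None
        import warnings

        warnings.warn(f"record {rec.id!r}: center residue is not K; keeping")
    return w


def load_labeled_pair(
    pos_path: str | os.PathLike,
    neg_path: str | os.PathLike,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    on_non_k_center: str = "warn",
) -> LabeledDataset:
    """Load a positive/negative FASTA pair of pre-cut windows.

    Every record is length-checked against ``window_length``; a wrong-length
    record is rejected with its id in the message.  ``on_non_k_center`` is
    one of ``warn`` (keep), ``reject`` (error), ``drop``.
    """
    ds = LabeledDataset()
    for path, label in ((pos_path, "positive"), (neg_path, "negative")):
        for rec in read_fasta(path):
            w = _check_window(rec, window_length, on_non_k_center)
            if w is not None:
                w.label = label
                ds.windows.append(w)
    return ds
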