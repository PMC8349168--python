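"""Reading protein sequences and extracting lysine-centred peptide windows.

Every candidate sumoylation site is represented as a 41-residue window: the
target lysine (K) at 1-based position 21, flanked by 20 residues upstream and
20 downstream. Positions that fall outside the protein are padded with the
virtual residue ``X``. Residues are encoded as integers 1-20 following the
alphabetical order of the full amino-acid *names* (Alanine=1 ... Valine=20),
with 21 reserved for ``X`` and any ambiguity letter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 41
#: 1-based position of the target lysine inside a window.
CENTER_POSITION = 21

#: Residue -> integer code, by alphabetical order of the amino-acid names:
#: Alanine, Arginine, Asparagine, Aspartate, Cysteine, Glutamate, Glutamine,
#: Glycine, Histidine, Isoleucine, Leucine, Lysine, Methionine, Phenylalanine,
#: Proline, Serine, Threonine, Tryptophan, Tyrosine, Valine; 21 is the
#: virtual residue X.
RESIDUE_CODES: Mapping[str, int] = {
    "A": 1, "R": 2, "N": 3, "D": 4, "C": 5,
    "E": 6, "Q": 7, "G": 8, "H": 9, "I": 10,
    "L": 11, "K": 12, "M": 13, "F": 14, "P": 15,
    "S": 16, "T": 17, "W": 18, "Y": 19, "V": 20,
    "X": 21,
}

X_CODE = 21
K_CODE = RESIDUE_CODES["K"]
N_CODES = 21

#: code -> residue letter (code 21 decodes to 'X').
CODE_RESIDUES: Mapping[int, str] = {v: k for k, v in RESIDUE_CODES.items()}

#: Record counts of the published benchmark dataset, usable to verify a local
#: copy of the supplementary peptide files.
EXPECTED_BENCHMARK_COUNTS: Mapping[str, int] = {
    "positive": 4987,
    "negative": 5000,
    "total": 9987,
    "train_positive": 3487,
    "train_negative": 3500,
    "test_positive": 1500,
    "test_negative": 1500,
}


@dataclass
class ProteinRecord:
    """A named protein (or bare peptide) sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.strip().upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")


@dataclass
class PeptideWindow:
    """A 41-residue site window centred on a target lysine.

    ``center_position`` is the 1-based index of the K in the source sequence
    (for windows read directly from peptide-lines files it is 21, the centre
    of the window itself).
    """

    source_id: str
    center_position: int
    residues: str
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.residues) != WINDOW_LENGTH:
            raise ValueError(
                f"window from {self.source_id!r}: length {len(self.residues)} != {WINDOW_LENGTH}"
            )
        if self.residues[CENTER_POSITION - 1] != "K":
            raise ValueError(
                f"window from {self.source_id!r}: centre residue "
                f"{self.residues[CENTER_POSITION - 1]!r} is not K"
            )


def read_sequences(
    path: str | Path,
    format: str = "fasta",
    strict: bool = False,
) -> list[ProteinRecord]:
    """Read protein records from FASTA or a one-peptide-per-line text file.

    In ``peptide-lines`` mode each non-empty line is one record whose sequence
    is the raw line (trailing whitespace tolerated); with ``strict=True``
    lines whose length differs from 41 raise a ``ValueError`` naming the line.
    """
    path = Path(path)
    if format == "fasta":
        records = [
            ProteinRecord(id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    elif format == "peptide-lines":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                seq = line.strip()
                if not seq:
                    continue
                if strict and len(seq) != WINDOW_LENGTH:
                    raise ValueError(
                        f"{path}:{lineno}: peptide line has length {len(seq)}, "
                        f"expected {WINDOW_LENGTH}"
                    )
                records.append(ProteinRecord(id=f"{path.name}:{lineno}", sequence=seq))
    else:
        raise ValueError(f"unknown format {format!r} (expected 'fasta' or 'peptide-lines')")
    if not records:
        logger.warning("no records read from %s", path)
    return records


def extract_windows(record: ProteinRecord) -> list[PeptideWindow]:
    """Cut one 41-mer window per lysine in the sequence, X-padded at termini."""
    seq = record.sequence
    flank = CENTER_POSITION - 1
    padded = "X" * flank + seq + "X" * flank
    windows = []
    for i, residue in enumerate(seq):
        if residue != "K":
            continue
        # i is 0-based in seq; the padded string shifts it by `flank`.
        windows.append(
            PeptideWindow(
                source_id=record.id,
                center_position=i + 1,
                residues=padded[i : i + WINDOW_LENGTH],
            )
        )
    return windows


def windows_from_records(
    records: Iterable[ProteinRecord], label: int | None = None
) -> list[PeptideWindow]:
    """Interpret peptide-lines records as ready-made windows (no re-centring)."""
    return [
        PeptideWindow(source_id=r.id, center_position=CENTER_POSITION,
                      residues=r.sequence, label=label)
        for r in records
    ]


def encode(sequence: str) -> np.ndarray:
    """Encode a residue string into integer codes 1-21.

    Ambiguity letters (B, J, O, U, Z) and anything else outside the 20
    standard letters map to 21 (virtual X) with a logged warning.
    """
    codes = np.empty(len(sequence), dtype=np.int64)
    for i, letter in enumerate(sequence.upper()):
        code = RESIDUE_CODES.get(letter)
        if code is None:
            logger.warning("unknown residue %r mapped to virtual X (code 21)", letter)
            code = X_CODE
        codes[i] = code
    return codes


def encode_window(window: PeptideWindow) -> np.ndarray:
    """Encode a window; the result has length 41 and code 12 (K) at index 20."""
    return encode(window.residues)


def decode(codes: Sequence[int] | np.ndarray) -> str:
    """Inverse of :func:`encode` on the 21-symbol alphabet."""
    return "".join(CODE_RESIDUES[int(c)] for c in codes)


def write_windows_tsv(windows: Sequence[PeptideWindow], path: str | Path) -> None:
    """Write windows as TSV: source_id, center_position, window, label."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "source_id": [w.source_id for w in windows],
            "center_position": [w.center_position for w in windows],
            "window": [w.residues for w in windows],
            "label": [("" if w.label is None else w.label) for w in windows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_windows_tsv(path: str | Path) -> list[PeptideWindow]:
    """Read a windows table written by :func:`write_windows_tsv`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"source_id": str, "window": str})
    windows = []
    for row in df.itertuples(index=False):
        label = None
        if "label" in df.columns and not pd.isna(row.label) and row.label != "":
            label = int(row.label)
        windows.append(
            PeptideWindow(
                source_id=row.source_id,
                center_position=int(row.center_position),
                residues=row.window,
                label=label,
            )
        )
    return windows


def verify_benchmark_counts(
    files: Mapping[str, str | Path],
    expected: Mapping[str, int] = EXPECTED_BENCHMARK_COUNTS,
) -> dict:
    """Count records in peptide-lines files and compare with expected counts.

    ``files`` maps dataset-part names (e.g. ``positive``, ``train_negative``)
    to peptide-lines paths. Returns ``{part: {"count", "expected", "ok"}}``
    plus a ``total`` entry when ``positive`` and ``negative`` are both given.
    """
    report: dict = {}
    counts: dict[str, int] = {}
    for part, path in files.items():
        n = len(read_sequences(path, format="peptide-lines"))
        counts[part] = n
        exp = expected.get(part)
        report[part] = {"count": n, "expected": exp, "ok": (exp is None or n == exp)}
    if "positive" in counts and "negative" in counts:
        total = counts["positive"] + counts["negative"]
        exp = expected.get("total")
        report["total"] = {"count": total, "expected": exp, "ok": (exp is None or total == exp)}
    return report
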