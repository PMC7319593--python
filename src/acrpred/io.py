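"""Sequence and PSSM input/output.

Reads multi-record FASTA files, parses and writes PSI-BLAST ASCII PSSM
files (the BLAST+ ``-out_ascii_pssm`` dialect), applies the dataset
filters used for anti-CRISPR training data (length 50-350, standard
20-letter alphabet), and optionally drives an external PSI-BLAST binary
to generate PSSMs against a user-supplied database.

A position-specific scoring matrix (PSSM) for a protein of length L is
an L x 20 integer matrix P[i, j] of log-odds conservation scores, one
row per sequence position and one column per standard amino-acid type.
Row indices are 1-based in documentation; storage is 0-based.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AA_ORDER",
    "BLAST_COLUMN_ORDER",
    "ProteinRecord",
    "PSSMatrix",
    "PsiBlastConfig",
    "AcrPredError",
    "InputError",
    "PssmParseError",
    "ExternalToolError",
    "read_fasta",
    "write_fasta",
    "validate_record",
    "length_filter",
    "parse_psiblast_pssm",
    "format_psiblast_pssm",
    "read_pssm_file",
    "write_pssm_file",
    "load_pssm_dir",
    "run_psiblast",
]

#: Canonical amino-acid ordering used for all feature vectors (alphabetical
#: one-letter codes). Encoder outputs are always reported in this order.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Column ordering printed by PSI-BLAST in its ASCII PSSM output.
BLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

_STANDARD_AA = frozenset(AA_ORDER)

# Default length filter bounds: anti-CRISPRs are small proteins, and the
# training data was restricted to this closed interval.
MIN_LENGTH = 50
MAX_LENGTH = 350


class AcrPredError(Exception):
    """Base class for all package errors."""


class InputError(AcrPredError):
    """Invalid user input (bad FASTA, bad sequence, bad configuration)."""


class PssmParseError(InputError):
    """Malformed PSI-BLAST ASCII PSSM file."""


class ExternalToolError(AcrPredError):
    """An external tool (PSI-BLAST) failed or produced no usable output."""


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: identifier, free-text description, and sequence."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("protein record has an empty id")
        if not self.sequence:
            raise InputError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PSSMatrix:
    """Position-specific scoring matrix for one protein.

    Parameters
    ----------
    protein_id:
        Token matching the paired :class:`ProteinRecord`.
    scores:
        L x 20 integer array of log-odds scores, columns ordered as in
        ``column_order`` (the file order, by default the PSI-BLAST one).
    row_residues:
        Length-L string of the query residues as printed in the file.
    column_order:
        The residue ordering of the 20 score columns.
    pseudo:
        True when the matrix is a substitution-matrix fallback rather
        than a genuine PSI-BLAST profile (no-hit queries, opt-in).
    """

    protein_id: str
    scores: np.ndarray
    row_residues: str
    column_order: str = BLAST_COLUMN_ORDER
    pseudo: bool = False

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise InputError(
                f"PSSM for {self.protein_id!r} must be L x 20, got shape {scores.shape}"
            )
        if scores.shape[0] != len(self.row_residues):
            raise InputError(
                f"PSSM for {self.protein_id!r}: {scores.shape[0]} rows but "
                f"{len(self.row_residues)} row residues"
            )
        if sorted(self.column_order) != sorted(AA_ORDER):
            raise InputError(
                f"PSSM for {self.protein_id!r}: column_order is not a "
                f"permutation of the 20 standard residues"
            )
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return self.scores.shape[0]

    def canonical_scores(self) -> np.ndarray:
        """Scores with columns reordered to :data:`AA_ORDER`, as float64."""
        idx = [self.column_order.index(a) for a in AA_ORDER]
        return self.scores[:, idx].astype(np.float64)

    def check_pairing(self, record: ProteinRecord) -> None:
        """Assert this matrix belongs to ``record`` (id and sequence match)."""
        if self.protein_id != record.id:
            raise InputError(
                f"PSSM id {self.protein_id!r} does not match record id {record.id!r}"
            )
        if self.row_residues != record.sequence:
            raise InputError(
                f"PSSM row residues for {self.protein_id!r} disagree with the "
                f"paired FASTA sequence"
            )


@dataclass(frozen=True)
class PsiBlastConfig:
    """Settings for external PSSM generation with PSI-BLAST.

    Defaults follow standard practice for profile construction: three
    search iterations against the database with an inclusion e-value of
    0.001.
    """

    database_path: str
    iterations: int = 3
    evalue: float = 0.001
    binary_path: str = "psiblast"
    no_hit_policy: str = "error"  # "error" | "fallback"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise InputError("PSI-BLAST iterations must be >= 1")
        if self.evalue <= 0:
            raise InputError("PSI-BLAST e-value must be > 0")
        if self.no_hit_policy not in ("error", "fallback"):
            raise InputError(f"unknown no-hit policy {self.no_hit_policy!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; record order is preserved. Raises
    :class:`InputError` for a missing or empty file, duplicate ids, or
    an entry with an empty sequence.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise InputError(f"FASTA entry {entry.id!r} has an empty sequence")
        if entry.id in seen:
            raise InputError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(ProteinRecord(entry.id, entry.description, seq))
    if not records:
        raise InputError(f"FASTA file contains no records: {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to ``path`` in FASTA format (wrapped at ``width``)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def validate_record(record: ProteinRecord, policy: str = "reject") -> ProteinRecord:
    """Validate a record's sequence against the 20-letter standard alphabet.

    ``policy="reject"`` (default) raises :class:`InputError` at the first
    nonstandard letter, naming its 1-based position. ``policy="mask"``
    replaces every nonstandard letter with ``X``; downstream encoders
    treat ``X`` as a 21st type that contributes to no amino-acid bin.
    Lowercase input is uppercased in both policies.
    """
    if policy not in ("reject", "mask"):
        raise InputError(f"unknown nonstandard-residue policy {policy!r}")
    seq = record.sequence.upper()
    if policy == "reject":
        for pos, letter in enumerate(seq, start=1):
            if letter not in _STANDARD_AA:
                raise InputError(
                    f"protein {record.id!r}: nonstandard residue {letter!r} "
                    f"at position {pos}"
                )
    else:
        seq = "".join(c if c in _STANDARD_AA else "X" for c in seq)
    if seq == record.sequence:
        return record
    return ProteinRecord(record.id, record.description, seq)


def length_filter(
    records: Sequence[ProteinRecord],
    min_len: int = MIN_LENGTH,
    max_len: int = MAX_LENGTH,
) -> list[ProteinRecord]:
    """Keep records whose length lies in the closed interval [min_len, max_len].

    Order is preserved and the bounds are inclusive.
    """
    if min_len > max_len:
        raise InputError(f"min_len ({min_len}) exceeds max_len ({max_len})")
    return [r for r in records if min_len <= len(r) <= max_len]


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM parsing / writing

_PSSM_HEADER_HINT = "position-specific scoring matrix"


def parse_psiblast_pssm(text: str, protein_id: str = "") -> PSSMatrix:
    """Parse the contents of a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first block of 20 integer columns (the log-odds scores) is
    consumed; the weighted-percentage block and the trailing statistics
    lines are ignored. The column ordering is taken from the header line.
    """
    lines = text.splitlines()
    header_idx = None
    column_order = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 20 and all(len(t) == 1 and t in _STANDARD_AA for t in tokens[:20]):
            header_idx = i
            column_order = "".join(tokens[:20])
            break
    if header_idx is None:
        raise PssmParseError("no PSSM column header line found")
    if len(set(column_order)) != 20:
        raise PssmParseError(f"PSSM header columns are not 20 distinct residues: {column_order}")

    rows: list[list[int]] = []
    residues: list[str] = []
    expected_index = 1
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            break
        if not tokens[0].isdigit():
            break
        if int(tokens[0]) != expected_index:
            raise PssmParseError(
                f"line {lineno}: expected row index {expected_index}, got {tokens[0]}"
            )
        if len(tokens) < 22:
            raise PssmParseError(
                f"line {lineno}: truncated PSSM row ({len(tokens)} tokens, need >= 22)"
            )
        residue = tokens[1]
        if len(residue) != 1:
            raise PssmParseError(f"line {lineno}: bad residue token {residue!r}")
        try:
            scores = [int(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise PssmParseError(f"line {lineno}: non-integer score token ({exc})") from None
        residues.append(residue)
        rows.append(scores)
        expected_index += 1
    if not rows:
        raise PssmParseError("PSSM contains no score rows")
    return PSSMatrix(
        protein_id=protein_id,
        scores=np.array(rows, dtype=np.int64),
        row_residues="".join(residues),
        column_order=column_order,
    )


def format_psiblast_pssm(pssm: PSSMatrix) -> str:
    """Serialize a matrix to the ASCII dialect read by :func:`parse_psiblast_pssm`.

    The percentage block is filled with zeros (it is never consumed);
    ``parse(format(m))`` round-trips the scores, residues and column
    order exactly.
    """
    out = ["", "Last position-specific scoring matrix computed"]
    cols = "  ".join(pssm.column_order)
    out.append("           " + cols + "   " + cols)
    for i in range(len(pssm)):
        scores = " ".join(f"{int(v):3d}" for v in pssm.scores[i])
        zeros = " ".join(["  0"] * 20)
        out.append(f"{i + 1:5d} {pssm.row_residues[i]}  {scores}  {zeros}  0.00 0.00")
    out.append("")
    return "\n".join(out) + "\n"


def read_pssm_file(path: str | Path, protein_id: str = "") -> PSSMatrix:
    path = Path(path)
    if not path.exists():
        raise InputError(f"PSSM file not found: {path}")
    if not protein_id:
        protein_id = path.stem
    return parse_psiblast_pssm(path.read_text(), protein_id=protein_id)


def write_pssm_file(pssm: PSSMatrix, path: str | Path) -> None:
    Path(path).write_text(format_psiblast_pssm(pssm))


def load_pssm_dir(
    records: Sequence[ProteinRecord], pssm_dir: str | Path
) -> dict[str, PSSMatrix]:
    """Load ``<pssm_dir>/<id>.pssm`` for every record and verify pairing.

    Raises :class:`InputError` listing every record without a matching
    PSSM file, and verifies row residues against each paired sequence.
    """
    pssm_dir = Path(pssm_dir)
    missing = [r.id for r in records if not (pssm_dir / f"{r.id}.pssm").exists()]
    if missing:
        raise InputError(f"missing PSSM files for: {', '.join(missing)}")
    out: dict[str, PSSMatrix] = {}
    for rec in records:
        pssm = read_pssm_file(pssm_dir / f"{rec.id}.pssm", protein_id=rec.id)
        pssm.check_pairing(rec)
        out[rec.id] = pssm
    return out


# ---------------------------------------------------------------------------
# External PSI-BLAST wrapper


def _blosum62_pseudo_pssm(record: ProteinRecord) -> PSSMatrix:
    """Fallback profile for no-hit queries: one BLOSUM62 row per residue."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    rows = np.zeros((len(record), 20), dtype=np.int64)
    for i, res in enumerate(record.sequence):
        query = res if res in blosum.alphabet else "X"
        for j, col in enumerate(BLAST_COLUMN_ORDER):
            rows[i, j] = int(blosum[query][col])
    return PSSMatrix(
        protein_id=record.id,
        scores=rows,
        row_residues=record.sequence,
        column_order=BLAST_COLUMN_ORDER,
        pseudo=True,
    )


def run_psiblast(
    record: ProteinRecord, config: PsiBlastConfig, out_dir: str | Path
) -> PSSMatrix:
    """Generate a PSSM for ``record`` by running the configured PSI-BLAST.

    Writes ``<out_dir>/<id>.pssm`` and parses it. For queries with no
    database hits PSI-BLAST may emit no matrix; the configured no-hit
    policy then either raises (default) or substitutes a BLOSUM62-based
    pseudo-profile flagged ``pseudo=True``.
    """
    binary = shutil.which(config.binary_path)
    if binary is None:
        raise ExternalToolError(f"PSI-BLAST binary not found: {config.binary_path!r}")
    db = Path(config.database_path)
    if not db.parent.exists() or not any(
        db.parent.glob(db.name + ".p*")
    ) and not db.exists():
        raise ExternalToolError(f"BLAST database not found: {config.database_path!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pssm_path = out_dir / f"{record.id}.pssm"
    with tempfile.TemporaryDirectory() as tmp:
        query = Path(tmp) / "query.fasta"
        write_fasta([record], query)
        cmd = [
            binary,
            "-query", str(query),
            "-db", str(config.database_path),
            "-num_iterations", str(config.iterations),
            "-evalue", str(config.evalue),
            "-inclusion_ethresh", str(config.evalue),
            "-out_ascii_pssm", str(pssm_path),
            "-out", str(Path(tmp) / "report.txt"),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise ExternalToolError(
            f"PSI-BLAST failed for {record.id!r} (exit {proc.returncode}): "
            f"{proc.stderr.strip()[:500]}"
        )
    if not pssm_path.exists() or not pssm_path.read_text().strip():
        if config.no_hit_policy == "fallback":
            pssm = _blosum62_pseudo_pssm(record)
            write_pssm_file(pssm, pssm_path)
            return pssm
        raise ExternalToolError(
            f"PSI-BLAST produced no PSSM for {record.id!r} (no database hits); "
            f"use no_hit_policy='fallback' to substitute a BLOSUM62 pseudo-profile"
        )
    pssm = read_pssm_file(pssm_path, protein_id=record.id)
    pssm.check_pairing(record)
    return pssm
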