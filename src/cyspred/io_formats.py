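"""Readers and writers for the external file formats used by the toolkit.

Formats handled: multi-record FASTA, site annotation TSV
(``protein_id<TAB>position<TAB>label``), the AAindex1 flat file,
PSI-BLAST ASCII PSSM profiles, and per-residue track TSVs
(``protein_id<TAB>position<TAB>value``) for solvent accessibility (ASA)
and secondary structure (SS).

Conventions:

* Residue letters outside the 20 standard one-letter codes are
  normalized to ``X`` at read time, so every downstream stage works on a
  single 21-symbol alphabet.
* Site and track positions are 1-based (UniProt convention).
* ASA tracks are stored in raw percent; scaling to [0, 1] happens in the
  encoder, keeping readers lossless.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

#: Alphabetical one-letter order of the 20 standard amino acids.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
#: 21-symbol alphabet: the 20 standard residues plus the padding/unknown symbol.
ALPHABET21 = AA_ORDER + "X"

#: Column order of the PSI-BLAST ASCII PSSM header.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWVY"

#: Residue order of the two value rows in an AAindex1 ``I`` block.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWVY"

_VALID_SS = frozenset("HEC")


class FormatError(ValueError):
    """Raised when an input file violates its expected dialect."""


def normalize_sequence(seq: str) -> str:
    """Uppercase *seq* and map any non-standard letter to ``X``."""
    seq = seq.upper()
    return "".join(c if c in AA_ORDER else "X" for c in seq)


@dataclass(frozen=True)
class ProteinRecord:
    """A full-length protein sequence over the 21-symbol alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET21)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-normalized letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteRecord:
    """One annotated cysteine: protein, 1-based position, and class label."""

    protein_id: str
    position: int
    label: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")
        if self.label not in (1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")


@dataclass(frozen=True)
class AAIndexEntry:
    """One physicochemical index: a numeric value per standard residue."""

    accession: str
    description: str
    values: Mapping[str, float]
    has_na: bool = False

    def __post_init__(self) -> None:
        if not self.has_na and len(self.values) != 20:
            raise ValueError(
                f"{self.accession}: expected 20 values, got {len(self.values)}"
            )

    def vector(self, order: str = AA_ORDER) -> np.ndarray:
        """Values as an array in *order*; requires a complete entry."""
        if self.has_na:
            raise ValueError(f"{self.accession}: entry has NA values")
        return np.array([self.values[a] for a in order], dtype=float)


@dataclass(frozen=True)
class PSSMProfile:
    """Per-protein position-specific scoring matrix (L x 20).

    ``column_order`` records the residue letter of each score column as
    declared by the file header (PSI-BLAST order by default).
    """

    protein_id: str
    scores: np.ndarray
    column_order: str = PSIBLAST_ORDER

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(
                f"profile {self.protein_id!r}: expected L x 20 matrix, "
                f"got shape {scores.shape}"
            )
        if len(self.column_order) != 20:
            raise ValueError("column_order must list 20 residues")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return self.scores.shape[0]

    def reordered(self, order: str = AA_ORDER) -> np.ndarray:
        """Score matrix with columns permuted into *order*."""
        idx = [self.column_order.index(a) for a in order]
        return self.scores[:, idx]


@dataclass(frozen=True)
class ResidueTrack:
    """Per-residue annotation track: ASA percentages or SS symbols."""

    protein_id: str
    kind: str  # "ASA" | "SS"
    values: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("ASA", "SS"):
            raise ValueError(f"track kind must be ASA or SS, got {self.kind!r}")
        if self.kind == "ASA":
            vals = tuple(float(v) for v in self.values)
            if any(v < 0 for v in vals):
                raise ValueError(
                    f"track {self.protein_id!r}: negative ASA value"
                )
        else:
            vals = tuple(str(v) for v in self.values)
            bad = set(vals) - _VALID_SS
            if bad:
                raise ValueError(
                    f"track {self.protein_id!r}: invalid SS symbols {sorted(bad)}"
                )
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file, normalizing residues to the
    21-symbol alphabet. Duplicate IDs and empty files are errors."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, normalize_sequence(str(rec.seq))))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Site TSV


def read_sites(path, proteins: Sequence[ProteinRecord] | None = None) -> list[SiteRecord]:
    """Read a site TSV. If *proteins* is given, positions are validated
    to fall inside the sequence and to point at a cysteine."""
    by_id = {p.id: p for p in proteins} if proteins is not None else None
    sites: list[SiteRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            pid, pos_s, label_s = parts
            try:
                pos = int(pos_s)
                label = int(label_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if label not in (1, -1):
                raise FormatError(
                    f"{path}:{lineno}: label must be +1 or -1, got {label_s}"
                )
            if by_id is not None:
                if pid not in by_id:
                    raise FormatError(f"{path}:{lineno}: unknown protein {pid!r}")
                seq = by_id[pid].sequence
                if not 1 <= pos <= len(seq):
                    raise FormatError(
                        f"{path}:{lineno}: position {pos} outside protein "
                        f"{pid!r} (length {len(seq)})"
                    )
                if seq[pos - 1] != "C":
                    raise FormatError(
                        f"{pid!r} position {pos}: residue {seq[pos - 1]!r} "
                        "is not a cysteine"
                    )
            sites.append(SiteRecord(pid, pos, label))
    return sites


def write_sites(sites: Iterable[SiteRecord], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.label:+d}\n")


# ---------------------------------------------------------------------------
# AAindex1


def read_aaindex(path) -> list[AAIndexEntry]:
    """Parse an AAindex1 flat file into entries.

    Every ``H`` block yields one entry; entries whose ``I`` block
    contains ``NA`` are flagged ``has_na`` (use :func:`filter_aaindex`
    to drop them).
    """
    entries: list[AAIndexEntry] = []
    accession = ""
    description = ""
    value_tokens: list[str] = []
    in_values = False

    def flush() -> None:
        nonlocal accession, description, value_tokens, in_values
        if not accession:
            return
        if len(value_tokens) != 20:
            raise FormatError(
                f"AAindex entry {accession}: expected 20 values, "
                f"got {len(value_tokens)}"
            )
        residues = _AAINDEX_ROW1 + _AAINDEX_ROW2
        values: dict[str, float] = {}
        has_na = False
        for aa, tok in zip(residues, value_tokens):
            if tok.upper() == "NA":
                has_na = True
            else:
                values[aa] = float(tok)
        entries.append(AAIndexEntry(accession, description.strip(), values, has_na))
        accession = ""
        description = ""
        value_tokens = []
        in_values = False

    with open(path) as fh:
        for line in fh:
            if line.startswith("//"):
                flush()
            elif line.startswith("H "):
                accession = line[2:].strip()
                in_values = False
            elif line.startswith("D "):
                description = line[2:].strip()
                in_values = False
            elif line.startswith("I "):
                in_values = True
            elif line[:1] in (" ", "\t") and in_values:
                value_tokens.extend(line.split())
            else:
                in_values = False
    flush()
    return entries


def filter_aaindex(entries: Iterable[AAIndexEntry]) -> list[AAIndexEntry]:
    """Drop entries flagged with NA values."""
    return [e for e in entries if not e.has_na]


def write_aaindex(entries: Iterable[AAIndexEntry], path) -> None:
    """Write entries in the AAindex1 flat-file dialect (round-trips
    through :func:`read_aaindex`)."""
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f"H {e.accession}\n")
            fh.write(f"D {e.description}\n")
            fh.write("I    A/L     R/K     N/M     D/F     C/P     "
                     "Q/S     E/T     G/W     H/Y     I/V\n")
            row1 = " ".join(
                _fmt_aaindex_value(e.values.get(a)) for a in _AAINDEX_ROW1
            )
            row2 = " ".join(
                _fmt_aaindex_value(e.values.get(a)) for a in _AAINDEX_ROW2
            )
            fh.write(f"   {row1}\n   {row2}\n//\n")


def _fmt_aaindex_value(v) -> str:
    return "NA" if v is None else f"{v:.4f}"


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM

_PSSM_ROW_RE = re.compile(r"^\s*(\d+)\s+([A-Za-z])\s+(-?\d)")


def read_pssm(path, protein_id: str | None = None,
              expected_length: int | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first 20 score columns are used; the trailing frequency
    columns of the full dialect are ignored.
    """
    header: str | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if header is None:
                if len(tokens) >= 20 and all(
                    len(t) == 1 and t.isalpha() for t in tokens[:20]
                ):
                    header = "".join(tokens[:20]).upper()
                continue
            if _PSSM_ROW_RE.match(line):
                idx = int(tokens[0])
                if idx != len(rows) + 1:
                    raise FormatError(
                        f"{path}: row index {idx} out of order "
                        f"(expected {len(rows) + 1})"
                    )
                numeric = tokens[2:]
                if len(numeric) < 20:
                    raise FormatError(
                        f"{path}: row {idx} has fewer than 20 score columns"
                    )
                rows.append([float(v) for v in numeric[:20]])
    if header is None or not rows:
        raise FormatError(f"{path}: not a PSI-BLAST ASCII PSSM file")
    if expected_length is not None and len(rows) != expected_length:
        raise FormatError(
            f"{path}: profile has {len(rows)} rows, expected {expected_length}"
        )
    pid = protein_id if protein_id is not None else Path(path).stem
    return PSSMProfile(pid, np.array(rows, dtype=float), header)


def write_pssm(profile: PSSMProfile, path, sequence: str | None = None) -> None:
    """Write a profile in a minimal PSI-BLAST ASCII dialect."""
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(profile.column_order) + "\n")
        for i, row in enumerate(profile.scores):
            res = sequence[i] if sequence is not None else "X"
            cells = " ".join(f"{v:4.0f}" for v in row)
            fh.write(f"{i + 1:5d} {res}  {cells}\n")


# ---------------------------------------------------------------------------
# Residue tracks


def read_tracks(path, kind: str) -> dict[str, ResidueTrack]:
    """Read a track TSV possibly covering several proteins.

    Positions must be contiguous from 1 for each protein; gaps are
    errors.
    """
    if kind not in ("ASA", "SS"):
        raise ValueError(f"track kind must be ASA or SS, got {kind!r}")
    per_protein: dict[str, dict[int, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            pid, pos_s, value = parts
            pos = int(pos_s)
            per_protein.setdefault(pid, {})
            if pos in per_protein[pid]:
                raise FormatError(
                    f"{path}:{lineno}: duplicate position {pos} for {pid!r}"
                )
            per_protein[pid][pos] = value
    tracks: dict[str, ResidueTrack] = {}
    for pid, by_pos in per_protein.items():
        length = max(by_pos)
        missing = [p for p in range(1, length + 1) if p not in by_pos]
        if missing:
            raise FormatError(
                f"{path}: protein {pid!r} missing positions {missing[:5]}"
            )
        raw = [by_pos[p] for p in range(1, length + 1)]
        if kind == "ASA":
            values: tuple = tuple(float(v) for v in raw)
        else:
            values = tuple(raw)
        tracks[pid] = ResidueTrack(pid, kind, values)
    return tracks


def read_track(path, kind: str) -> ResidueTrack:
    """Read a track TSV that must describe exactly one protein."""
    tracks = read_tracks(path, kind)
    if len(tracks) != 1:
        raise FormatError(
            f"{path}: expected a single protein, found {len(tracks)}"
        )
    return next(iter(tracks.values()))


def write_tracks(tracks: Iterable[ResidueTrack], path) -> None:
    with open(path, "w") as fh:
        for track in tracks:
            for pos, value in enumerate(track.values, 1):
                if track.kind == "ASA":
                    fh.write(f"{track.protein_id}\t{pos}\t{value:.2f}\n")
                else:
                    fh.write(f"{track.protein_id}\t{pos}\t{value}\n")
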