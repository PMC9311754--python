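"""Readers and writers for the standard formats the pipeline touches.

Three on-disk formats are supported: multi-record FASTA for protein
sequences, the PSI-BLAST ``-out_ascii_pssm`` dialect for per-protein
position-specific scoring matrices, and a three-column TSV for labeled
protein pairs.  Only the log-odds block of a PSSM file is consumed; the
percentage block is parsed for validation and discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

#: Canonical amino-acid column order of the PSI-BLAST ASCII PSSM header.
#: All score matrices in this package index their 20 columns in this order.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Ambiguity / non-standard residue codes tolerated in FASTA sequences.
AMBIGUOUS_RESIDUES = "BZXUO*"

_VALID_RESIDUES = frozenset(AA_ORDER + AMBIGUOUS_RESIDUES)


class ParseError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (labels, ids, lengths)."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence over the 20 standard letters plus
    tolerated ambiguity codes (B, Z, X, U, O)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein id must be nonempty")
        if len(self.residues) < 1:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: invalid residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PSSM:
    """One protein's N x 20 position-specific score matrix.

    Rows follow sequence position order; columns follow :data:`AA_ORDER`.
    Entries are PSI-BLAST style log-odds scores (integers in real files,
    real-valued accepted).
    """

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValidationError(
                f"PSSM {self.protein_id!r}: expected N x 20 matrix, "
                f"got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValidationError(f"PSSM {self.protein_id!r}: zero rows")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError(f"PSSM {self.protein_id!r}: non-finite scores")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class PairRecord:
    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValidationError(
                f"pair ({self.id_a}, {self.id_b}): label must be 0 or 1, "
                f"got {self.label!r}"
            )


@dataclass
class PairList:
    """Ordered list of labeled protein pairs (1 = interacting)."""

    records: list[PairRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def ids(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out.add(r.id_a)
            out.add(r.id_b)
        return out

    def validate_against(self, known_ids: Iterable[str]) -> None:
        known = set(known_ids)
        for r in self.records:
            for pid in (r.id_a, r.id_b):
                if pid not in known:
                    raise ValidationError(f"pair list references unknown id {pid!r}")


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a multi-record FASTA file into :class:`ProteinSequence` objects.

    Residues are upper-cased and surrounding whitespace stripped.  Duplicate
    ids or empty sequences raise :class:`ValidationError` naming the record.
    """
    path = Path(path)
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id.strip()
        if not pid:
            raise ParseError(f"{path}: FASTA record with empty id")
        if pid in seen:
            raise ValidationError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        residues = str(rec.seq).strip().upper()
        if not residues:
            raise ParseError(f"{path}: record {pid!r} has an empty sequence")
        out.append(ProteinSequence(id=pid, residues=residues))
    return out


def write_fasta(path: str | Path, proteins: Sequence[ProteinSequence]) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.residues), 60):
                fh.write(p.residues[i : i + 60] + "\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return math.isfinite(float(tok))


def read_ascii_pssm(path: str | Path, protein_id: str | None = None) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a :class:`PSSM`.

    The file layout is two header lines, a column-header line, one row per
    residue (position index, residue letter, 20 log-odds columns, 20
    weighted-percentage columns, optionally two trailing statistics), and a
    trailer.  Only the first 20 numeric columns (the log-odds block) are
    returned; row order equals residue order.

    ``protein_id`` defaults to the file stem.
    """
    path = Path(path)
    pid = protein_id if protein_id is not None else path.stem
    rows: list[list[float]] = []
    expected_index = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            # data rows start with the 1-based position index then a residue
            if len(toks) < 2 or not toks[0].isdigit():
                continue
            if len(toks[1]) != 1 or not toks[1].isalpha():
                continue
            numeric = toks[2:]
            n_num = len(numeric)
            if n_num not in (40, 42):
                raise ParseError(
                    f"{path}: line {lineno} (position {toks[0]}): expected 40 "
                    f"numeric fields (20 log-odds + 20 percentages), found {n_num}"
                )
            for tok in numeric[:40]:
                if not _is_number(tok):
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric score {tok!r}"
                    )
            if int(toks[0]) != expected_index:
                raise ParseError(
                    f"{path}: line {lineno}: position index {toks[0]} out of "
                    f"order (expected {expected_index})"
                )
            expected_index += 1
            rows.append([float(t) for t in numeric[:20]])
    if not rows:
        raise ParseError(f"{path}: no PSSM score rows found (truncated file?)")
    return PSSM(protein_id=pid, scores=np.array(rows, dtype=float))


def write_ascii_pssm(
    path: str | Path,
    pssm: PSSM,
    residues: str | None = None,
) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect that :func:`read_ascii_pssm`
    parses.

    Integer-valued scores are written as integers so a read/write cycle is
    bit-exact on them.  The percentage block is filled with zeros (it is not
    consumed downstream).  ``residues`` defaults to the per-row argmax column
    letter.
    """
    path = Path(path)
    scores = pssm.scores
    if residues is None:
        residues = "".join(AA_ORDER[j] for j in np.argmax(scores, axis=1))
    if len(residues) != pssm.length:
        raise ValidationError(
            f"PSSM {pssm.protein_id!r}: residue string length {len(residues)} "
            f"!= matrix rows {pssm.length}"
        )

    def fmt(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else repr(float(x))

    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down\n"
        )
        header = "            " + "   ".join(AA_ORDER) + "   " + "   ".join(AA_ORDER)
        fh.write(header + "\n")
        for i in range(pssm.length):
            cells = [fmt(v) for v in scores[i]] + ["0"] * 20
            fh.write(f"{i + 1:>5} {residues[i]}  " + "  ".join(cells) + "\n")
        fh.write("\n")


def read_pair_list(
    path: str | Path,
    known_ids: Iterable[str] | None = None,
) -> PairList:
    """Read a labeled pair list from a 3-column TSV (id_a, id_b, label).

    Lines starting with ``#`` are comments.  Labels must be 0 or 1.  When
    ``known_ids`` is supplied every id must resolve against it.
    """
    path = Path(path)
    records: list[PairRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, "
                    f"found {len(parts)}"
                )
            id_a, id_b, label_s = (p.strip() for p in parts)
            try:
                label = int(label_s)
            except ValueError:
                raise ValidationError(
                    f"{path}: line {lineno}: label {label_s!r} is not an integer"
                ) from None
            if label not in (0, 1):
                raise ValidationError(
                    f"{path}: line {lineno}: label must be 0 or 1, got {label}"
                )
            records.append(PairRecord(id_a=id_a, id_b=id_b, label=label))
    pairs = PairList(records=records)
    if known_ids is not None:
        pairs.validate_against(known_ids)
    return pairs


def write_pair_list(path: str | Path, pairs: PairList) -> None:
    with open(path, "w") as fh:
        fh.write("# id_a\tid_b\tlabel\n")
        for r in pairs:
            fh.write(f"{r.id_a}\t{r.id_b}\t{r.label}\n")


def filter_by_length(
    proteins: Sequence[ProteinSequence], min_length: int = 50
) -> list[ProteinSequence]:
    """Drop proteins shorter than ``min_length`` residues.

    This mirrors the usual benchmark-construction rule of discarding very
    short chains; sequence-identity clustering is out of scope here and must
    be done upstream.
    """
    return [p for p in proteins if len(p) >= min_length]


def read_pssm_dir(
    directory: str | Path, suffix: str = ".pssm"
) -> dict[str, PSSM]:
    """Read every ``*.pssm`` file in a directory, keyed by protein id."""
    directory = Path(directory)
    out: dict[str, PSSM] = {}
    for f in sorted(directory.glob(f"*{suffix}")):
        p = read_ascii_pssm(f)
        if p.protein_id in out:
            raise ValidationError(f"duplicate PSSM id {p.protein_id!r} in {directory}")
        out[p.protein_id] = p
    return out
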