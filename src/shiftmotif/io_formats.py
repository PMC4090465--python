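"""Readers and writers for the files the tool touches.

Four surfaces:

* chemical-shift tables — either the in-house TSV dialect (header
  ``protein_id  chain_id  residue_number  residue_type  nucleus  shift_ppm``,
  tab-separated, ``.`` decimal) or the assigned-chemical-shift loop of an
  NMR-STAR file (``_Atom_chem_shift.*`` tags; all other frames are ignored);
* motif segment definitions — TSV with columns
  ``protein_id  chain_id  start  end  [label]``;
* FASTA sequences (via Biopython);
* fitted models — versioned JSON text.

Residue numbering is taken as given (author numbering, 1-based); segment
ranges are inclusive on both ends and never span chains.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_1to3
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from shiftmotif.defs import NUCLEI, normalize_nucleus, validate_class

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "shiftmotif-model/1"

SHIFT_TSV_HEADER = (
    "protein_id",
    "chain_id",
    "residue_number",
    "residue_type",
    "nucleus",
    "shift_ppm",
)
SEGMENT_TSV_HEADER = ("protein_id", "chain_id", "start", "end", "label")

_AA_1TO3 = {aa: code.upper() for aa, code in protein_letters_1to3.items()}
_AA_3TO1 = {v: k for k, v in _AA_1TO3.items()}


class ParseError(ValueError):
    """A file does not parse under the named dialect (message names the line)."""


class IntegrityError(ValueError):
    """Parsed content violates a data invariant (e.g. duplicate assignment)."""


class ModelFormatError(ValueError):
    """A serialized model is truncated, corrupt, or of an unsupported version."""


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned chemical shift for one residue and nucleus.

    ``nucleus`` is normalized to the canonical token on construction;
    ``shift_ppm`` must be finite.
    """

    protein_id: str
    chain_id: str
    residue_number: int
    residue_type: str
    nucleus: str
    shift_ppm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "nucleus", normalize_nucleus(self.nucleus))
        object.__setattr__(self, "shift_ppm", float(self.shift_ppm))
        if not np.isfinite(self.shift_ppm):
            raise ValueError(
                f"non-finite shift for {self.protein_id}/{self.chain_id}"
                f" residue {self.residue_number} {self.nucleus}"
            )

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.protein_id, self.chain_id, self.residue_number, self.nucleus)


class ShiftTable:
    """Collection of :class:`ShiftRecord` indexed by (protein, chain, residue, nucleus).

    At most one record per key; adding a duplicate raises :class:`IntegrityError`.
    """

    def __init__(self, records: Iterable[ShiftRecord] = ()) -> None:
        self._records: dict[tuple[str, str, int, str], ShiftRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: ShiftRecord) -> None:
        if rec.key in self._records:
            raise IntegrityError(
                f"duplicate assignment for {rec.protein_id}/{rec.chain_id}"
                f" residue {rec.residue_number} nucleus {rec.nucleus}"
            )
        self._records[rec.key] = rec

    def get(
        self, protein_id: str, chain_id: str, residue_number: int, nucleus: str
    ) -> ShiftRecord | None:
        key = (protein_id, chain_id, residue_number, normalize_nucleus(nucleus))
        return self._records.get(key)

    def residue_records(
        self, protein_id: str, chain_id: str, residue_number: int
    ) -> list[ShiftRecord]:
        return [
            r
            for r in self._records.values()
            if r.protein_id == protein_id
            and r.chain_id == chain_id
            and r.residue_number == residue_number
        ]

    def __iter__(self) -> Iterator[ShiftRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShiftTable):
            return NotImplemented
        return self._records == other._records


@dataclass(frozen=True)
class Segment:
    """One motif instance: an inclusive residue range on one chain.

    ``label``, when present, is one of HH, EH, HE, EE; ``sequence`` is the
    optional one-letter amino-acid string of the segment (needed only for the
    amino-acid-composition baseline).
    """

    protein_id: str
    chain_id: str
    start_residue: int
    end_residue: int
    label: str | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise ValueError(
                f"segment {self.protein_id}/{self.chain_id}"
                f" {self.start_residue}-{self.end_residue}: start > end"
            )
        if self.label is not None:
            object.__setattr__(self, "label", validate_class(self.label))

    @property
    def length(self) -> int:
        return self.end_residue - self.start_residue + 1

    @property
    def residues(self) -> range:
        return range(self.start_residue, self.end_residue + 1)

    def describe(self) -> str:
        return f"{self.protein_id}/{self.chain_id}:{self.start_residue}-{self.end_residue}"


# ---------------------------------------------------------------------------
# chemical-shift tables


def read_shift_table(path: str | Path, dialect: str = "tsv") -> ShiftTable:
    """Read a chemical-shift table.

    ``dialect`` is ``"tsv"`` (in-house dialect) or ``"nmrstar"`` (BMRB-style
    file; only the ``_Atom_chem_shift`` loop is consulted).  Nucleus aliases
    are normalized; atoms outside the six supported nuclei are skipped with a
    logged count; a duplicate (residue, nucleus) assignment raises
    :class:`IntegrityError`.
    """
    path = Path(path)
    if dialect == "tsv":
        rows = _read_shift_tsv_rows(path)
    elif dialect == "nmrstar":
        rows = _read_shift_star_rows(path)
    else:
        raise ValueError(f"unknown shift-table dialect {dialect!r}")

    table = ShiftTable()
    skipped = 0
    for lineno, (pid, chain, resnum, restype, nucleus, value) in rows:
        try:
            nuc = normalize_nucleus(nucleus)
        except ValueError:
            skipped += 1
            continue
        try:
            rec = ShiftRecord(pid, chain, resnum, restype, nuc, value)
        except ValueError as exc:
            raise ParseError(f"{path} line {lineno}: {exc}") from exc
        table.add(rec)
    if skipped:
        logger.info("%s: skipped %d records with unsupported nuclei", path, skipped)
    return table


def _read_shift_tsv_rows(path: Path):
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SHIFT_TSV_HEADER:
            raise ParseError(f"{path} line 1: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path} line {lineno}: expected 6 fields, got {len(fields)}")
            pid, chain, resnum, restype, nucleus, value = fields
            try:
                yield lineno, (pid, chain, int(resnum), restype, nucleus, float(value))
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc


def write_shift_table(table: ShiftTable, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    records = sorted(table, key=lambda r: (r.protein_id, r.chain_id, r.residue_number, NUCLEI.index(r.nucleus)))
    if dialect == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(SHIFT_TSV_HEADER) + "\n")
            for r in records:
                fh.write(
                    f"{r.protein_id}\t{r.chain_id}\t{r.residue_number}\t"
                    f"{r.residue_type}\t{r.nucleus}\t{r.shift_ppm!r}\n"
                )
    elif dialect == "nmrstar":
        _write_shift_star(records, path)
    else:
        raise ValueError(f"unknown shift-table dialect {dialect!r}")


_STAR_TAGS = (
    "_Atom_chem_shift.ID",
    "_Atom_chem_shift.Entry_ID",
    "_Atom_chem_shift.Auth_asym_ID",
    "_Atom_chem_shift.Comp_index_ID",
    "_Atom_chem_shift.Comp_ID",
    "_Atom_chem_shift.Atom_ID",
    "_Atom_chem_shift.Val",
)


def _write_shift_star(records: list[ShiftRecord], path: Path) -> None:
    lines = [
        "data_shiftmotif",
        "",
        "save_assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts",
        "",
        "   loop_",
    ]
    lines += [f"      {tag}" for tag in _STAR_TAGS]
    lines.append("")
    for i, r in enumerate(records, start=1):
        comp = _AA_1TO3.get(r.residue_type.upper(), "UNK")
        lines.append(
            f"      {i} {r.protein_id} {r.chain_id} {r.residue_number}"
            f" {comp} {r.nucleus} {r.shift_ppm!r}"
        )
    lines += ["   stop_", "save_", ""]
    path.write_text("\n".join(lines), encoding="utf-8")


def _star_tokens(path: Path):
    """Whitespace tokenizer for STAR files: yields (lineno, token), skipping comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("#"):
                continue
            for tok in stripped.split():
                yield lineno, tok


def _read_shift_star_rows(path: Path):
    """Extract rows from the first loop carrying ``_Atom_chem_shift`` tags.

    Minimal STAR handling: whitespace-separated tokens, ``loop_``/``stop_``
    framing, ``.``/``?`` as nulls.  Quoted values and multi-line text blocks
    are not needed for assigned-shift loops and are not supported.
    """
    tokens = _star_tokens(path)
    tags: list[str] = []
    in_loop = False
    for lineno, tok in tokens:
        if tok == "loop_":
            in_loop = True
            tags = []
            continue
        if in_loop and tok.startswith("_"):
            tags.append(tok)
            continue
        if in_loop and tags:
            if any(t.startswith("_Atom_chem_shift.") for t in tags):
                yield from _parse_shift_loop(path, tags, lineno, tok, tokens)
                return
            in_loop = False  # some other loop; skip its values
    raise ParseError(f"{path}: no _Atom_chem_shift loop found")


def _parse_shift_loop(path, tags, first_lineno, first_tok, tokens):
    idx = {}
    for want, names in {
        "protein": ("_Atom_chem_shift.Entry_ID",),
        "chain": ("_Atom_chem_shift.Auth_asym_ID", "_Atom_chem_shift.Entity_ID"),
        "resnum": ("_Atom_chem_shift.Comp_index_ID", "_Atom_chem_shift.Seq_ID"),
        "comp": ("_Atom_chem_shift.Comp_ID",),
        "atom": ("_Atom_chem_shift.Atom_ID",),
        "val": ("_Atom_chem_shift.Val",),
    }.items():
        for name in names:
            if name in tags:
                idx[want] = tags.index(name)
                break
        else:
            raise ParseError(f"{path}: shift loop lacks any of tags {names}")

    row: list[str] = [first_tok]
    lineno = first_lineno
    ncol = len(tags)

    def emit(row, lineno):
        pid = row[idx["protein"]]
        chain = row[idx["chain"]]
        comp = row[idx["comp"]].upper()
        restype = _AA_3TO1.get(comp, comp if len(comp) == 1 else "X")
        try:
            resnum = int(row[idx["resnum"]])
            value = float(row[idx["val"]])
        except ValueError as exc:
            raise ParseError(f"{path} line {lineno}: {exc}") from exc
        return lineno, (pid, chain, resnum, restype, row[idx["atom"]], value)

    for lineno, tok in tokens:
        if tok == "stop_":
            break
        row.append(tok)
        if len(row) == ncol:
            if "." in (row[idx["val"]], row[idx["resnum"]]) or "?" in row:
                row = []
                continue
            yield emit(row, lineno)
            row = []
    if row and len(row) == ncol:
        yield emit(row, lineno)
    elif row:
        raise ParseError(f"{path} line {lineno}: truncated shift loop row {row!r}")


# ---------------------------------------------------------------------------
# segments


def read_segments(path: str | Path) -> list[Segment]:
    """Read motif segment definitions from TSV.

    Columns ``protein_id  chain_id  start  end  [label]``; the label column
    may be empty or absent (prediction mode).
    """
    path = Path(path)
    segments: list[Segment] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:4]) != SEGMENT_TSV_HEADER[:4]:
            raise ParseError(f"{path} line 1: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path} line {lineno}: expected >= 4 fields")
            pid, chain, start, end = fields[:4]
            label = fields[4] if len(fields) > 4 and fields[4] else None
            try:
                segments.append(
                    Segment(pid, chain, int(start), int(end), label=label)
                )
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
    return segments


def write_segments(segments: Iterable[Segment], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SEGMENT_TSV_HEADER) + "\n")
        for s in segments:
            fh.write(
                f"{s.protein_id}\t{s.chain_id}\t{s.start_residue}\t"
                f"{s.end_residue}\t{s.label or ''}\n"
            )


def attach_sequences(
    segments: Iterable[Segment], sequences: Mapping[str, str]
) -> list[Segment]:
    """Fill each segment's ``sequence`` by slicing its protein's FASTA sequence.

    Residue *i* maps to sequence position *i* (1-based); a segment whose
    protein is absent or whose range falls outside the sequence is an error.
    """
    out: list[Segment] = []
    for seg in segments:
        seq = sequences.get(seg.protein_id)
        if seq is None:
            raise IntegrityError(f"no sequence for protein {seg.protein_id!r}")
        if seg.end_residue > len(seq):
            raise IntegrityError(
                f"segment {seg.describe()} extends past sequence of"
                f" length {len(seq)}"
            )
        out.append(replace(seg, sequence=seq[seg.start_residue - 1 : seg.end_residue]))
    return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{protein_id: sequence}`` (upper-cased).

    Duplicate IDs and empty files are errors; non-standard residue letters
    are retained and flagged with a logged count.
    """
    path = Path(path)
    out: dict[str, str] = {}
    nonstandard = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise IntegrityError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        nonstandard += sum(1 for c in seq if c not in _AA_1TO3)
        out[rec.id] = seq
    if not out:
        raise ParseError(f"{path}: empty FASTA file")
    if nonstandard:
        logger.info("%s: %d non-standard residue letters retained", path, nonstandard)
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# model serialization (versioned JSON)


def write_model(model, path: str | Path) -> None:
    """Serialize a fitted :class:`~shiftmotif.qda.QDModel` as versioned JSON text."""
    payload = {
        "format": MODEL_FORMAT_VERSION,
        "feature_names": list(model.feature_names),
        "prior_mode": model.prior_mode,
        "regularization": model.regularization,
        "classes": [
            {
                "label": cm.label,
                "sample_count": cm.sample_count,
                "mean": cm.mean.tolist(),
                "covariance": cm.covariance.tolist(),
                "regularized": cm.regularized,
            }
            for cm in model.classes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_model(path: str | Path):
    from shiftmotif.qda import ClassModel, QDModel  # deferred: avoid import cycle

    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not a valid model file ({exc})") from exc
    version = payload.get("format")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format {version!r}"
            f" (expected {MODEL_FORMAT_VERSION})"
        )
    try:
        classes = tuple(
            ClassModel.from_moments(
                label=c["label"],
                sample_count=c["sample_count"],
                mean=np.asarray(c["mean"], dtype=float),
                covariance=np.asarray(c["covariance"], dtype=float),
                regularized=c["regularized"],
            )
            for c in payload["classes"]
        )
        return QDModel(
            classes=classes,
            feature_names=tuple(payload["feature_names"]),
            prior_mode=payload["prior_mode"],
            regularization=float(payload["regularization"]),
        )
    except KeyError as exc:
        raise ModelFormatError(f"{path}: missing field {exc}") from exc
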