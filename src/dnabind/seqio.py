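"""Reading, validating, filtering and writing protein sequence sets.

Sequences are kept in the canonical 20-letter amino-acid alphabet.  The six
letters B, J, O, U, X and Z (ambiguity codes and non-standard residues) are
either stripped in place or cause rejection of the whole record, depending on
policy.  Length limits default to the 50–6000 residue window commonly used to
exclude fragments and unwieldy multi-domain giants.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = frozenset(AMINO_ACIDS)
AMBIGUOUS_LETTERS = frozenset("BJOUXZ")

DEFAULT_MIN_LEN = 50
DEFAULT_MAX_LEN = 6000


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with a unique id and free-text description."""

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class Rejection:
    """A record dropped by validation, with a machine-readable reason code."""

    id: str
    reason: str
    detail: str = ""


class FastaFormatError(ValueError):
    pass


class DuplicateIdError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into a list of ``ProteinRecord``, order preserved.

    Sequences are uppercased but not otherwise validated; run
    :func:`validate_and_filter` afterwards.  Raises on a missing file, on
    sequence data appearing before the first header, and on duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: sequence data before first '>' header"
                )
            break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, desc, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, sequences wrapped at ``width`` columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def validate_and_filter(
    records: Iterable[ProteinRecord],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    ambiguous_policy: str = "strip",
) -> tuple[list[ProteinRecord], list[Rejection]]:
    """Apply the alphabet and length filters.

    ``ambiguous_policy="strip"`` deletes the letters B/J/O/U/X/Z in place and
    re-checks length on the shortened sequence; ``"reject"`` drops any record
    containing them.  Letters outside the 26 recognised ones (20 canonical + 6
    ambiguous) always cause rejection.  Nothing raises: every dropped record
    is returned in the rejection log with a reason code.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    if ambiguous_policy not in ("strip", "reject"):
        raise ValueError(f"unknown ambiguous_policy: {ambiguous_policy!r}")

    kept: list[ProteinRecord] = []
    log: list[Rejection] = []
    for rec in records:
        seq = rec.sequence.upper()
        letters = set(seq)
        invalid = letters - AMINO_ACID_SET - AMBIGUOUS_LETTERS
        if invalid:
            log.append(Rejection(rec.id, "invalid_letter", "".join(sorted(invalid))))
            continue
        ambiguous = letters & AMBIGUOUS_LETTERS
        if ambiguous:
            if ambiguous_policy == "reject":
                log.append(
                    Rejection(rec.id, "ambiguous_letters", "".join(sorted(ambiguous)))
                )
                continue
            seq = "".join(c for c in seq if c not in AMBIGUOUS_LETTERS)
        if len(seq) < min_len:
            log.append(Rejection(rec.id, "too_short", str(len(seq))))
            continue
        if len(seq) > max_len:
            log.append(Rejection(rec.id, "too_long", str(len(seq))))
            continue
        kept.append(ProteinRecord(rec.id, rec.description, seq))
    return kept, log


def dereplicate_by_family(
    records: Sequence[ProteinRecord],
    families: Mapping[str, frozenset[str] | set[str]],
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Keep the longest member of every family.

    ``families`` maps record id to the set of family ids it belongs to (one
    or two in practice).  Returns the representative records (deduplicated —
    a record representing two families appears once) plus the family →
    representative-id map.  Length ties break to the lexicographically
    smallest id.
    """
    by_id = {r.id: r for r in records}
    for rec in records:
        if rec.id not in families:
            raise KeyError(f"record {rec.id!r} missing from family table")
    best: dict[str, str] = {}
    for rec in records:
        for fam in families[rec.id]:
            cur = best.get(fam)
            if cur is None:
                best[fam] = rec.id
                continue
            cur_rec = by_id[cur]
            if len(rec) > len(cur_rec) or (
                len(rec) == len(cur_rec) and rec.id < cur
            ):
                best[fam] = rec.id
    reps: list[ProteinRecord] = []
    seen: set[str] = set()
    for fam in sorted(best):
        rid = best[fam]
        if rid not in seen:
            seen.add(rid)
            reps.append(by_id[rid])
    return reps, best


def build_negative_pool(
    records: Sequence[ProteinRecord],
    families: Mapping[str, frozenset[str] | set[str]],
    excluded_family_ids: set[str] | frozenset[str],
) -> list[ProteinRecord]:
    """Records whose family memberships avoid ``excluded_family_ids`` entirely.

    Used to build a negative set that shares no family with the positives.
    """
    excluded = frozenset(excluded_family_ids)
    out = []
    for rec in records:
        if rec.id not in families:
            raise KeyError(f"record {rec.id!r} missing from family table")
        if not (frozenset(families[rec.id]) & excluded):
            out.append(rec)
    return out


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column ``id<TAB>label`` table; labels must be 0 or 1.

    A first row whose second field is not 0/1 is treated as a header.
    """
    labels: dict[str, int] = {}
    with open(path) as handle:
        for i, line in enumerate(handle):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{i + 1}: expected 2 tab-separated fields")
            rid, lab = parts
            if lab not in ("0", "1"):
                if i == 0:
                    continue  # header line
                raise ValueError(f"{path}:{i + 1}: label must be 0 or 1, got {lab!r}")
            if rid in labels:
                raise ValueError(f"{path}: duplicate id {rid!r}")
            labels[rid] = int(lab)
    return labels


def write_labels(labels: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("id\tlabel\n")
        for rid, lab in labels.items():
            if lab not in (0, 1):
                raise ValueError(f"label for {rid!r} must be 0 or 1, got {lab!r}")
            handle.write(f"{rid}\t{lab}\n")


def read_families(path: str | Path) -> dict[str, set[str]]:
    """Read a ``record_id<TAB>family_id`` table, one row per membership."""
    fams: dict[str, set[str]] = {}
    with open(path) as handle:
        for i, line in enumerate(handle):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{i + 1}: expected 2 tab-separated fields")
            if i == 0 and parts == ["id", "family"]:
                continue
            fams.setdefault(parts[0], set()).add(parts[1])
    return fams


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature matrix (rows = records, columns = named features) as TSV."""
    matrix.to_csv(path, sep="\t", index_label="id", float_format="%.8g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
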