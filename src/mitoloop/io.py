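"""Readers and writers for the plain-text interchange formats.

Formats: BED (intervals / motif sites, with the retention category in an
optional seventh column), BEDPE (paired-mate fragments), a minimal 5-column
pairs-like dialect for contacts (``chrom1 pos1 chrom2 pos2 [count]``),
upper-triangle triplet text for binned matrices, and headered CSV for
karyotype and compaction tables.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    CompactionRecord,
    ContactList,
    Fragment,
    GenomicInterval,
    KaryotypeRecord,
    MotifSite,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


def _parse_int(token: str, path: PathLike, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer {what}: {token!r}") from None


# ---------------------------------------------------------------------------
# BED intervals / motif sites


def read_intervals(path: PathLike, format: str = "bed"):
    """Read a BED file into GenomicInterval or MotifSite objects.

    Columns: chrom, start, end[, name, score, strand[, category]].  When a
    category column is present the records are returned as
    :class:`~mitoloop.core.MotifSite`.
    """
    if format.lower() != "bed":
        raise ValueError(f"unsupported interval format: {format!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            start = _parse_int(fields[1], path, lineno, "start")
            end = _parse_int(fields[2], path, lineno, "end")
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                interval = GenomicInterval(chrom, start, end, strand)
                if len(fields) >= 7:
                    out.append(MotifSite(interval, category=fields[6]))
                else:
                    out.append(interval)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return out


def write_intervals(path: PathLike, records: Sequence) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, MotifSite):
                iv = rec.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\t{rec.category}\n"
                )
            else:
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t.\t0\t{rec.strand}\n")


# ---------------------------------------------------------------------------
# pairs-like contact text


def read_contacts(path: PathLike) -> ContactList:
    """Read whitespace-separated ``chrom1 pos1 chrom2 pos2 [count]`` records.

    Header lines start with ``#``.  Intra-chromosomal records are normalized
    to ``pos1 <= pos2``; a missing count column defaults to 1.
    """
    c1, p1, c2, p2, ct = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (4, 5):
                raise ParseError(f"{path}:{lineno}: expected 4 or 5 columns")
            c1.append(fields[0])
            p1.append(_parse_int(fields[1], path, lineno, "pos1"))
            c2.append(fields[2])
            p2.append(_parse_int(fields[3], path, lineno, "pos2"))
            ct.append(_parse_int(fields[4], path, lineno, "count") if len(fields) == 5 else 1)
    return ContactList(c1, p1, c2, p2, ct)


def write_contacts(path: PathLike, contacts: ContactList) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom1 pos1 chrom2 pos2 count\n")
        for i in range(len(contacts)):
            fh.write(
                f"{contacts.chrom1[i]} {contacts.pos1[i]} "
                f"{contacts.chrom2[i]} {contacts.pos2[i]} {contacts.count[i]}\n"
            )


# ---------------------------------------------------------------------------
# fragments: BED or BEDPE


def read_fragments(path: PathLike, format: str = "bed") -> list[Fragment]:
    """Read ATAC fragments from BED (direct spans) or BEDPE (mate pairs).

    BEDPE mates are collapsed to ``[min(starts), max(ends))``; mate pairs on
    different chromosomes are skipped with a logged warning.
    """
    fmt = format.lower()
    if fmt not in ("bed", "bedpe"):
        raise ValueError(f"unsupported fragment format: {format!r}")
    out: list[Fragment] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fmt == "bed":
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
                out.append(
                    Fragment(
                        fields[0],
                        _parse_int(fields[1], path, lineno, "start"),
                        _parse_int(fields[2], path, lineno, "end"),
                    )
                )
            else:
                if len(fields) < 6:
                    raise ParseError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
                chrom1, chrom2 = fields[0], fields[3]
                if chrom1 != chrom2:
                    skipped += 1
                    logger.warning(
                        "%s:%d: BEDPE mates on different chromosomes (%s, %s); skipped",
                        path, lineno, chrom1, chrom2,
                    )
                    continue
                s1 = _parse_int(fields[1], path, lineno, "start1")
                e1 = _parse_int(fields[2], path, lineno, "end1")
                s2 = _parse_int(fields[4], path, lineno, "start2")
                e2 = _parse_int(fields[5], path, lineno, "end2")
                out.append(Fragment(chrom1, min(s1, s2), max(e1, e2)))
    if skipped:
        logger.warning("%s: skipped %d inter-chromosomal BEDPE records", path, skipped)
    return out


def write_fragments(path: PathLike, fragments: Sequence[Fragment]) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


# ---------------------------------------------------------------------------
# triplet text for binned matrices (upper triangle only)


def write_triplet(path: PathLike, matrix) -> None:
    """Write a BinnedMatrix's counts as ``bin_i bin_j value`` triplet text.

    A header comment carries chrom, bin size and bin count so the matrix can
    be reconstructed without a sidecar.
    """
    coo = matrix.counts.tocoo()
    with open(path, "w") as fh:
        fh.write(f"# chrom={matrix.chrom} bin_size={matrix.bin_size} n_bins={matrix.n_bins}\n")
        order = np.lexsort((coo.col, coo.row))
        for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
            fh.write(f"{i}\t{j}\t{v:g}\n")


def read_triplet(path: PathLike):
    """Read triplet text written by :func:`write_triplet` back into a BinnedMatrix."""
    from scipy import sparse

    from .matrix import BinnedMatrix

    meta: dict[str, str] = {}
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 triplet columns")
            rows.append(_parse_int(fields[0], path, lineno, "bin_i"))
            cols.append(_parse_int(fields[1], path, lineno, "bin_j"))
            vals.append(float(fields[2]))
    if "n_bins" not in meta or "bin_size" not in meta:
        raise ParseError(f"{path}: missing matrix header (chrom/bin_size/n_bins)")
    n = int(meta["n_bins"])
    counts = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return BinnedMatrix(
        chrom=meta.get("chrom", "."),
        bin_size=int(meta["bin_size"]),
        n_bins=n,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# CSV tables


def read_karyotype(path: PathLike) -> list[KaryotypeRecord]:
    """CSV with header columns chrom,length_bp,centromere_bp."""
    df = pd.read_csv(path)
    required = {"chrom", "length_bp", "centromere_bp"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: karyotype CSV requires columns {sorted(required)}")
    return [
        KaryotypeRecord(str(r.chrom), int(r.length_bp), int(r.centromere_bp))
        for r in df.itertuples()
    ]


def read_compaction(path: PathLike) -> list[CompactionRecord]:
    """CSV with header columns group,chromatid_length_um,qarm_mb."""
    df = pd.read_csv(path)
    required = {"group", "chromatid_length_um", "qarm_mb"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: compaction CSV requires columns {sorted(required)}")
    return [
        CompactionRecord(str(r.group), float(r.chromatid_length_um), float(r.qarm_mb))
        for r in df.itertuples()
    ]


def convert_one_based(records: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Shift 1-based inclusive intervals to 0-based half-open (start -= 1)."""
    return [
        GenomicInterval(r.chrom, r.start - 1, r.end, r.strand) for r in records
    ]
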