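"""Domain types and genomic-interval I/O.

All coordinates are 0-based half-open (BED convention) throughout the
package.  The atoms here — :class:`Fragment`, :class:`GenomeSequence`,
:class:`CoverageTrack` — are consumed by every analysis module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

_BASES = "ACGT"
_UMI_RE = re.compile(r"^[ACGTN]+$")


class ParseError(ValueError):
    """Raised when a text record cannot be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True, slots=True)
class Fragment:
    """One sequenced cfDNA molecule as a genomic interval.

    ``start``/``end`` are 0-based half-open.  ``strand`` is '+', '-' or '.'
    (unknown).  ``umi`` carries the molecular tag when present.
    """

    contig: str
    start: int
    end: int
    strand: str = "."
    umi: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Deterministic midpoint, floor((start+end)/2)."""
        return (self.start + self.end) // 2


@dataclass(slots=True)
class GenomeSequence:
    """A named contig with its sequence over {A,C,G,T,N}."""

    contig: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    def __getitem__(self, key) -> str:
        return self.sequence[key]


@dataclass(slots=True)
class ReadRecord:
    """A minimal sequencing-read record with optional mapping information.

    ``mapped`` is ``(contig, start, end, strand)`` when the read aligns.
    """

    identifier: str
    sequence: str
    qualities: np.ndarray
    mate_of: Optional[str] = None
    mapped: Optional[tuple[str, int, int, str]] = None
    proper_pair: bool = False

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int32)
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities differ in length")


@dataclass(slots=True)
class CoverageTrack:
    """Per-base fragment coverage for one contig."""

    contig: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("negative depth")


@dataclass(slots=True)
class SiteAnnotation:
    """Annotated genomic sites (e.g. TF binding sites, TSSs).

    ``anchor`` selects how each interval is collapsed to a single anchor
    position: the interval midpoint, or the strand-respecting start (5'
    end: ``start`` on '+', ``end - 1`` on '-').
    """

    intervals: list[tuple[str, int, int, str, str]]  # contig,start,end,strand,label
    anchor: str = "midpoint"

    def __post_init__(self) -> None:
        if self.anchor not in ("midpoint", "start"):
            raise ValueError(f"unknown anchor mode {self.anchor!r}")
        self.intervals = sorted(self.intervals, key=lambda r: (r[0], r[1], r[2]))

    def anchors(self) -> list[tuple[str, int, str, str]]:
        """(contig, anchor position, strand, label) per interval."""
        out = []
        for contig, start, end, strand, label in self.intervals:
            if self.anchor == "midpoint":
                pos = (start + end) // 2
            else:
                pos = start if strand != "-" else end - 1
            out.append((contig, pos, strand, label))
        return out


# ---------------------------------------------------------------------------
# Fragment ingestion


def read_fragments(
    path: str | Path,
    length_filter: Optional[tuple[int, int]] = None,
) -> tuple[list[Fragment], dict]:
    """Read fragments from a 6-column BED or 10-column BEDPE file.

    BEDPE mates are merged to the outermost interval.  Records whose length
    falls outside ``length_filter`` (inclusive bounds) are dropped.  Returns
    the fragments ordered by (contig, start, end) plus a stats dict with
    counts of rejected/filtered records.
    """
    frags: list[Fragment] = []
    stats = {"rejected": 0, "length_filtered": 0}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) >= 10:
                frag = _parse_bedpe(fields, lineno)
            elif len(fields) >= 6:
                frag = _parse_bed6(fields, lineno)
            else:
                raise ParseError(
                    f"expected 6 (BED) or 10 (BEDPE) columns, got {len(fields)}",
                    lineno,
                )
            if frag is None:
                stats["rejected"] += 1
                continue
            if length_filter is not None:
                lo, hi = length_filter
                if not (lo <= frag.length <= hi):
                    stats["length_filtered"] += 1
                    continue
            frags.append(frag)
    frags.sort(key=lambda f: (f.contig, f.start, f.end))
    return frags, stats


def _parse_int(text: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"non-integer coordinate {text!r}", lineno) from None


def _parse_bed6(fields: Sequence[str], lineno: int) -> Optional[Fragment]:
    contig = fields[0]
    start = _parse_int(fields[1], lineno)
    end = _parse_int(fields[2], lineno)
    strand = fields[5] if fields[5] in "+-" else "."
    if start >= end or start < 0:
        return None
    umi = _umi_from_name(fields[3])
    return Fragment(contig, start, end, strand, umi)


def _parse_bedpe(fields: Sequence[str], lineno: int) -> Optional[Fragment]:
    c1, c2 = fields[0], fields[3]
    if c1 != c2:
        raise ParseError(f"BEDPE mates on different contigs {c1!r}/{c2!r}", lineno)
    s1 = _parse_int(fields[1], lineno)
    e1 = _parse_int(fields[2], lineno)
    s2 = _parse_int(fields[4], lineno)
    e2 = _parse_int(fields[5], lineno)
    start, end = min(s1, s2), max(e1, e2)
    if start >= end or start < 0:
        return None
    strand = fields[8] if len(fields) > 8 and fields[8] in "+-" else "."
    umi = _umi_from_name(fields[6]) if len(fields) > 6 else None
    return Fragment(c1, start, end, strand, umi)


def _umi_from_name(name: str) -> Optional[str]:
    """UMI convention: read/fragment name suffix after the last '_'."""
    if "_" in name:
        tail = name.rsplit("_", 1)[1]
        if len(tail) >= 4 and _UMI_RE.match(tail):
            return tail
    return None


def fragments_from_pairs(records: Iterable[ReadRecord]) -> tuple[list[Fragment], dict]:
    """Build fragments from properly paired alignment records.

    Records sharing an identifier form a pair; only proper pairs mapped to
    the same contig yield a fragment spanning the outermost coordinates.
    """
    stats = {"mate_missing": 0, "different_contigs": 0, "not_proper": 0}
    by_id: dict[str, list[ReadRecord]] = {}
    for rec in records:
        by_id.setdefault(rec.identifier, []).append(rec)
    frags: list[Fragment] = []
    for ident, pair in by_id.items():
        if len(pair) != 2 or any(r.mapped is None for r in pair):
            stats["mate_missing"] += 1
            continue
        if not all(r.proper_pair for r in pair):
            stats["not_proper"] += 1
            continue
        (c1, s1, e1, strand1), (c2, s2, e2, _) = pair[0].mapped, pair[1].mapped
        if c1 != c2:
            stats["different_contigs"] += 1
            continue
        frags.append(
            Fragment(c1, min(s1, s2), max(e1, e2), strand1, _umi_from_name(ident))
        )
    frags.sort(key=lambda f: (f.contig, f.start, f.end))
    return frags, stats


_PROPER_PAIR_FLAGS = {83, 99, 147, 163}


def read_alignment_records(path: str | Path) -> Iterator[ReadRecord]:
    """Minimal tab-delimited alignment-record reader (SAM-like columns).

    Accepts the proper-pair flag subset {83, 99, 147, 163}; headers ('@'
    lines) are skipped.  The aligned interval is taken as POS..POS+len(SEQ)
    (1-based input converted to 0-based half-open); this is an adapter seam,
    not a full SAM implementation.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise ParseError("expected >= 11 alignment columns", lineno)
            qname, flag_s, rname, pos_s = fields[0], fields[1], fields[2], fields[3]
            seq, qual = fields[9], fields[10]
            flag = _parse_int(flag_s, lineno)
            pos = _parse_int(pos_s, lineno) - 1
            strand = "-" if flag & 16 else "+"
            mapped = None if rname == "*" else (rname, pos, pos + len(seq), strand)
            quals = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int32) - 33
            yield ReadRecord(
                identifier=qname,
                sequence=seq,
                qualities=quals,
                mapped=mapped,
                proper_pair=flag in _PROPER_PAIR_FLAGS,
            )


# ---------------------------------------------------------------------------
# Coverage


def coverage_from_fragments(
    fragments: Iterable[Fragment],
    genome_lengths: dict[str, int],
) -> tuple[dict[str, CoverageTrack], int]:
    """Per-base fragment coverage for each contig.

    depth[i] counts fragments whose interval contains i (each fragment
    counted once; overlapping mates are not double-counted).  Fragments
    extending beyond the contig end are clipped and counted.  Returns
    (tracks, number of clipped fragments).
    """
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in genome_lengths.items()}
    clipped = 0
    for frag in fragments:
        if frag.contig not in diffs:
            raise KeyError(f"fragment on unknown contig {frag.contig!r}")
        n = genome_lengths[frag.contig]
        end = frag.end
        if end > n:
            end = n
            clipped += 1
        if frag.start >= n:
            continue
        diffs[frag.contig][frag.start] += 1
        diffs[frag.contig][end] -= 1
    tracks = {
        c: CoverageTrack(c, np.cumsum(d[:-1])) for c, d in diffs.items()
    }
    return tracks, clipped


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(
    path: str | Path, contig: str, values: np.ndarray, start: int = 0
) -> None:
    """Write a per-position track as run-length-merged bedGraph."""
    values = np.asarray(values)
    if values.ndim != 1:
        raise ValueError("track values must be 1-D")
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        boundaries = np.nonzero(np.diff(values))[0] + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(values)]))
        for s, e in zip(starts, ends):
            v = values[s]
            v_repr = int(v) if float(v).is_integer() else repr(float(v))
            fh.write(f"{contig}\t{start + s}\t{start + e}\t{v_repr}\n")


def read_bedgraph(path: str | Path) -> dict[str, tuple[int, np.ndarray]]:
    """Read a bedGraph into per-contig (start offset, dense value array)."""
    rows: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError("expected 4 bedGraph columns", lineno)
            contig = fields[0]
            s, e = _parse_int(fields[1], lineno), _parse_int(fields[2], lineno)
            rows.setdefault(contig, []).append((s, e, float(fields[3])))
    out = {}
    for contig, ivs in rows.items():
        if any(b[0] < a[0] for a, b in zip(ivs, ivs[1:])):
            raise ParseError(f"unsorted bedGraph intervals on {contig}")
        start = ivs[0][0]
        values = np.zeros(ivs[-1][1] - start)
        for s, e, v in ivs:
            values[s - start : e - start] = v
        out[contig] = (start, values)
    return out


# ---------------------------------------------------------------------------
# FASTA (sequential reader via Biopython; genomes here are desk-scale)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    from Bio import SeqIO

    seqs = [
        GenomeSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    names = [s.contig for s in seqs]
    if len(set(names)) != len(names):
        raise ParseError("duplicate contig names in FASTA")
    return seqs


def write_fasta(path: str | Path, seqs: Iterable[GenomeSequence], width: int = 70) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s.sequence), id=s.contig, description="") for s in seqs
    ]
    seqio_write(records, str(path), "fasta")


def write_fragments_bed(path: str | Path, fragments: Iterable[Fragment]) -> None:
    with open(path, "w") as fh:
        for i, f in enumerate(fragments):
            name = f"frag{i}" + (f"_{f.umi}" if f.umi else "")
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_runs(sequence: str, min_length: int = 2) -> list[tuple[int, int, str]]:
    """Mononucleotide runs of at least ``min_length``: (start, length, base)."""
    runs = []
    for m in re.finditer(r"(A+|C+|G+|T+)", sequence):
        length = m.end() - m.start()
        if length >= min_length:
            runs.append((m.start(), length, m.group()[0]))
    return runs
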