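"""Sequence and alignment I/O: FASTA/FASTQ/SAM ingest, record routing.

This module owns the package's domain types (contigs, read pairs, mapping
records) and the "convert" stage: turning a report-all SAM file into
internal mapping records, routing each pair into one of four categories
(both ends co-placed / one end mapped / neither mapped / ends on different
scaffolds).

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open on the forward strand of a
contig; SAM's 1-based positions are converted on ingest.  Per-end edits are
expressed in *machine-cycle* read coordinates: position 0 is the first
sequenced base of that end regardless of which genome strand the end aligns
to, because sequencing error rates vary with cycle number, not with genome
position.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pysam
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")
# uppercased input: U->T, anything outside {A,C,G,T,N} -> N
_NORMALIZE = {}
for _c in range(256):
    _ch = chr(_c).upper()
    if _ch == "U":
        _NORMALIZE[_c] = "T"
    elif _ch in "ACGTN":
        _NORMALIZE[_c] = _ch
    else:
        _NORMALIZE[_c] = "N"
_NORMALIZE = str.maketrans({chr(c): v for c, v in _NORMALIZE.items()})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U to T and anything outside {A,C,G,T,N} to N."""
    return seq.translate(_NORMALIZE)


class Edit(NamedTuple):
    """One difference between a read end and the reference it aligns to.

    ``read_pos`` is the 0-based machine-cycle position: for substitutions
    the substituted base, for insertions the first inserted base, for
    deletions the read position immediately following the deleted
    reference bases.  ``ref``/``read`` carry the reference and read bases
    involved ("-" or "" where one side is gapped).
    """

    read_pos: int
    kind: str  # "sub" | "ins" | "del"
    ref: str
    read: str
    length: int


@dataclass(frozen=True)
class Contig:
    name: str
    sequence: str

    def __post_init__(self):
        if not self.name:
            raise ValueError("contig name must be nonempty")

    @property
    def length(self) -> int:
        return len(self.sequence)


class AssemblyIndex:
    """An assembly: named contigs plus derived totals.

    Supplies the sequence context for every mapping and the denominator of
    the uniform start-site model (total number of positions where a
    fragment of a given length fits).
    """

    def __init__(self, contigs: Iterable[Contig]):
        self.contigs: list[Contig] = list(contigs)
        if not self.contigs:
            raise ValueError("no contigs")
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names")
        self._by_name = {c.name: c for c in self.contigs}
        self.total_length = sum(c.length for c in self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def __getitem__(self, name: str) -> Contig:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.contigs]


@dataclass(frozen=True)
class ReadPair:
    id: str
    end1_sequence: str
    end2_sequence: str

    def __post_init__(self):
        if not self.end1_sequence or not self.end2_sequence:
            raise ValueError(f"read pair {self.id}: empty end sequence")


@dataclass(frozen=True)
class MappingRecord:
    """One candidate co-placement of a read pair on a contig.

    ``start_site`` is the 0-based leftmost base of the fragment on the
    contig's forward strand; ``fragment_length`` spans from there to the
    rightmost aligned base of the downstream end.  ``end1_strand`` is the
    genome strand end 1 aligns to ("+" forward).  ``end*_ref`` hold, for
    each machine-cycle position of that end, the reference base it aligns
    to ("-" at inserted positions), already complemented for ends on the
    reverse strand, so the error model never needs the assembly sequence.
    """

    pair_id: str
    contig_name: str
    start_site: int
    fragment_length: int
    orientation: str  # "FR" | "RF"
    end1_strand: str  # "+" | "-"
    end1_edits: tuple[Edit, ...]
    end2_edits: tuple[Edit, ...]
    end1_ref: str
    end2_ref: str

    @property
    def n_edits(self) -> int:
        return sum(e.length for e in self.end1_edits) + sum(e.length for e in self.end2_edits)

    def placement_key(self):
        return (self.contig_name, self.start_site, self.fragment_length, self.end1_strand)


@dataclass
class RoutedReadSet:
    """Partition of input pairs after the convert stage."""

    both_mapped: dict[str, list[MappingRecord]] = field(default_factory=dict)
    one_end_mapped: list[str] = field(default_factory=list)
    neither_mapped: list[str] = field(default_factory=list)
    cross_scaffold: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return (
            len(self.both_mapped)
            + len(self.one_end_mapped)
            + len(self.neither_mapped)
            + len(self.cross_scaffold)
        )

    @property
    def non_mapped_ids(self) -> list[str]:
        return sorted(set(self.one_end_mapped) | set(self.neither_mapped) | set(self.cross_scaffold))

    def unique_mappings(self) -> list[MappingRecord]:
        """Records of pairs with exactly one mapping (used for learning)."""
        return [recs[0] for recs in self.both_mapped.values() if len(recs) == 1]


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> AssemblyIndex:
    """Read an assembly; sequences are uppercased, U->T, other IUPAC -> N."""
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs.append(Contig(rec.id, normalize_sequence(str(rec.seq))))
    if not contigs:
        raise ValueError(f"no contigs in {path}")
    return AssemblyIndex(contigs)


def write_fasta(assembly: AssemblyIndex, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in assembly.contigs:
            fh.write(f">{c.name}\n")
            for i in range(0, c.length, width):
                fh.write(c.sequence[i : i + width] + "\n")


_END_SUFFIX = re.compile(r"/[12]$")


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Read two mate FASTQ files in lockstep; /1 and /2 id suffixes stripped.

    Base qualities are parsed by the FASTQ reader but ignored: the error
    model is learned from the data, not taken from quality strings.
    """
    pairs = []
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in zip(it1, it2, strict=True):
        id1 = _END_SUFFIX.sub("", r1.id)
        id2 = _END_SUFFIX.sub("", r2.id)
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {r1.id} vs {r2.id}")
        pairs.append(
            ReadPair(id1, normalize_sequence(str(r1.seq)), normalize_sequence(str(r2.seq)))
        )
    return pairs


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2, quality_char: str = "I") -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.end1_sequence}\n+\n{quality_char * len(p.end1_sequence)}\n")
            f2.write(f"@{p.id}/2\n{p.end2_sequence}\n+\n{quality_char * len(p.end2_sequence)}\n")


# ---------------------------------------------------------------------------
# Scaffold splitting


def split_scaffolds(assembly: AssemblyIndex, min_n_run: int = 25) -> AssemblyIndex:
    """Split scaffolds at runs of >= ``min_n_run`` N's into contigs.

    Shorter N runs are retained inside contigs.  Output names carry a
    ``.<ordinal>`` suffix when a scaffold was split; scaffolds that are
    entirely removed yield zero contigs (with a warning).
    """
    if min_n_run < 1:
        raise ValueError("min_n_run must be >= 1")
    pattern = re.compile("N{%d,}" % min_n_run)
    out = []
    for c in assembly.contigs:
        parts = [p for p in pattern.split(c.sequence) if p]
        if not parts:
            warnings.warn(f"scaffold {c.name} is entirely N; dropped")
            continue
        if len(parts) == 1 and pattern.search(c.sequence) is None:
            out.append(c)
        else:
            for i, p in enumerate(parts):
                out.append(Contig(f"{c.name}.{i}", p))
    return AssemblyIndex(out)


# ---------------------------------------------------------------------------
# Alignment columns -> edits


def gapless_columns(read_seq: str, ref_seq: str) -> list[tuple[str, str]]:
    if len(read_seq) != len(ref_seq):
        raise ValueError("gapless alignment requires equal lengths")
    return list(zip(read_seq, ref_seq))


def columns_to_edits(columns: list[tuple[str | None, str | None]]) -> tuple[tuple[Edit, ...], str]:
    """Turn machine-orientation alignment columns into (edits, aligned_ref).

    Each column is (read_base or None, ref_base or None).  Returns the edit
    list plus the aligned-reference string: one character per read
    position, "-" at inserted positions, the aligned reference base
    elsewhere.  A deletion is attached to the read position that follows
    the deleted reference bases; a deletion with no following read base
    (trailing) is dropped, as local alignments never end in a gap that the
    model could observe.
    """
    edits: list[Edit] = []
    aligned_ref: list[str] = []
    j = 0
    i = 0
    n = len(columns)
    while i < n:
        rb, xb = columns[i]
        if rb is None:
            run = []
            while i < n and columns[i][0] is None:
                run.append(columns[i][1] or "N")
                i += 1
            edits.append(Edit(j, "del", "".join(run), "", len(run)))
            continue
        if xb is None:
            run = []
            while i < n and columns[i][0] is not None and columns[i][1] is None:
                run.append(columns[i][0])
                aligned_ref.append("-")
                i += 1
            edits.append(Edit(j, "ins", "-", "".join(run), len(run)))
            j += len(run)
            continue
        aligned_ref.append(xb)
        if rb != xb and xb in "ACGTN" and rb in "ACGTN":
            if not (rb == "N" and xb == "N"):
                if xb != "N":  # ref N columns are uninformative, not edits
                    edits.append(Edit(j, "sub", xb, rb, 1))
        j += 1
        i += 1
    edits = [e for e in edits if not (e.kind == "del" and e.read_pos >= j)]
    return tuple(edits), "".join(aligned_ref)


def flip_columns(columns: list[tuple[str | None, str | None]]) -> list[tuple[str | None, str | None]]:
    """Reverse-complement alignment columns (reference-order -> machine order
    for a reverse-strand alignment)."""
    out = []
    for rb, xb in reversed(columns):
        out.append(
            (
                rb.translate(_COMPLEMENT) if rb is not None else None,
                xb.translate(_COMPLEMENT) if xb is not None else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# SAM conversion

_QUERY_CONSUMING = {0, 1, 4, 7, 8}  # M, I, S, =, X
_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X


class _EndAlignment(NamedTuple):
    contig: str
    ref_start: int
    ref_end: int  # half-open
    strand: str
    edits: tuple[Edit, ...]
    aligned_ref: str
    n_edits: int


def _alignment_columns(aln: pysam.AlignedSegment, assembly: AssemblyIndex, query: str):
    """Build reference-order columns for one SAM alignment from its CIGAR
    and the assembly sequence (no MD tag needed).  Returns None if the
    alignment is clipped (clipping hides bases the model must explain)."""
    contig = assembly[aln.reference_name]
    cig = aln.cigartuples
    if cig is None:
        raise ValueError(f"alignment {aln.query_name}: missing CIGAR")
    if any(op in (4, 5) for op, _ in cig):
        return None  # soft/hard clipped
    columns: list[tuple[str | None, str | None]] = []
    q = 0
    r = aln.reference_start
    for op, length in cig:
        if op in (0, 7, 8):  # M, =, X
            for k in range(length):
                columns.append((query[q + k], contig.sequence[r + k]))
            q += length
            r += length
        elif op == 1:  # I
            for k in range(length):
                columns.append((query[q + k], None))
            q += length
        elif op == 2:  # D
            for k in range(length):
                columns.append((None, contig.sequence[r + k]))
            r += length
        elif op == 3:  # N (reference skip)
            r += length
        elif op == 6:  # P
            continue
        else:
            raise ValueError(f"alignment {aln.query_name}: unsupported CIGAR op {op}")
    if q != len(query) or r > contig.length:
        raise ValueError(f"alignment {aln.query_name}: CIGAR inconsistent with sequence")
    return columns, aln.reference_start, r


def convert_sam(sam_path, assembly: AssemblyIndex, max_edits: int = 5, orientation: str = "FR") -> RoutedReadSet:
    """Convert a report-all SAM file into routed mapping records.

    Every co-placement of a pair's two ends on the same contig, on opposite
    strands in the configured orientation, with total edits <= ``max_edits``
    becomes one :class:`MappingRecord`.  Pairs with no such co-placement are
    routed to ``one_end_mapped`` / ``neither_mapped`` / ``cross_scaffold``.
    Clipped alignments are treated as if that end were unmapped.
    """
    if orientation not in ("FR", "RF"):
        raise ValueError("orientation must be FR or RF")
    # per pair id: [end1 alignments, end2 alignments], seen-end flags
    alns: dict[str, tuple[list[_EndAlignment], list[_EndAlignment]]] = {}
    primary_seq: dict[tuple[str, int], str] = {}
    order: list[str] = []

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        records = list(fh)

    # first pass: remember primary sequences (secondary records may omit SEQ)
    for aln in records:
        if aln.query_sequence and not aln.is_secondary and not aln.is_supplementary:
            end = 1 if aln.is_read2 else 0
            primary_seq[(aln.query_name, end)] = aln.query_sequence

    for aln in records:
        name = aln.query_name
        end = 1 if aln.is_read2 else 0
        if name not in alns:
            alns[name] = ([], [])
            order.append(name)
        if aln.is_unmapped:
            continue
        if aln.reference_name not in assembly:
            raise ValueError(f"alignment {name}: unknown contig {aln.reference_name}")
        query = aln.query_sequence or primary_seq.get((name, end))
        if query is None:
            raise ValueError(f"alignment {name}: no sequence available")
        query = normalize_sequence(query)
        built = _alignment_columns(aln, assembly, query)
        if built is None:
            continue  # clipped: route as if unmapped
        columns, ref_start, ref_end = built
        strand = "-" if aln.is_reverse else "+"
        machine_cols = flip_columns(columns) if strand == "-" else columns
        edits, aligned_ref = columns_to_edits(machine_cols)
        n_edits = sum(e.length for e in edits)
        alns[name][end].append(
            _EndAlignment(aln.reference_name, ref_start, ref_end, strand, edits, aligned_ref, n_edits)
        )

    routed = RoutedReadSet()
    for name in order:
        a1, a2 = alns[name]
        if not a1 and not a2:
            routed.neither_mapped.append(name)
            continue
        if not a1 or not a2:
            routed.one_end_mapped.append(name)
            continue
        recs = _pair_alignments(name, a1, a2, max_edits, orientation, assembly)
        if recs:
            routed.both_mapped[name] = recs
        else:
            routed.cross_scaffold.append(name)
    return routed


def _pair_alignments(
    name: str,
    a1: list[_EndAlignment],
    a2: list[_EndAlignment],
    max_edits: int,
    orientation: str,
    assembly: AssemblyIndex,
) -> list[MappingRecord]:
    recs = []
    seen = set()
    for e1 in a1:
        for e2 in a2:
            if e1.contig != e2.contig or e1.strand == e2.strand:
                continue
            upstream, downstream = (e1, e2) if e1.ref_start <= e2.ref_start else (e2, e1)
            want_up = "+" if orientation == "FR" else "-"
            if upstream.strand != want_up:
                continue
            start = upstream.ref_start
            frag = downstream.ref_end - upstream.ref_start
            if frag < max(e1.ref_end - e1.ref_start, e2.ref_end - e2.ref_start):
                continue
            if start + frag > assembly[e1.contig].length:
                continue
            if e1.n_edits + e2.n_edits > max_edits:
                continue
            rec = MappingRecord(
                pair_id=name,
                contig_name=e1.contig,
                start_site=start,
                fragment_length=frag,
                orientation=orientation,
                end1_strand=e1.strand,
                end1_edits=e1.edits,
                end2_edits=e2.edits,
                end1_ref=e1.aligned_ref,
                end2_ref=e2.aligned_ref,
            )
            key = rec.placement_key() + (rec.end1_edits, rec.end2_edits)
            if key not in seen:
                seen.add(key)
                recs.append(rec)
    recs.sort(key=lambda r: (r.contig_name, r.start_site, r.fragment_length, r.end1_strand))
    return recs


# ---------------------------------------------------------------------------
# Routed-record serialization (tab-separated, bit-exact across runs)

_MAPPINGS_HEADER = (
    "pair_id\tcontig\tstart\tfragment_length\torientation\tend1_strand\t"
    "end1_edits\tend1_ref\tend2_edits\tend2_ref"
)


def _encode_edits(edits: tuple[Edit, ...]) -> str:
    if not edits:
        return "."
    return ";".join(f"{e.read_pos},{e.kind},{e.ref},{e.read},{e.length}" for e in edits)


def _decode_edits(text: str) -> tuple[Edit, ...]:
    if text == ".":
        return ()
    out = []
    for part in text.split(";"):
        pos, kind, ref, read, length = part.split(",")
        out.append(Edit(int(pos), kind, ref, read, int(length)))
    return tuple(out)


def write_routed(routed: RoutedReadSet, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "mappings.tsv", "w") as fh:
        fh.write(_MAPPINGS_HEADER + "\n")
        for pair_id in sorted(routed.both_mapped):
            for r in routed.both_mapped[pair_id]:
                fh.write(
                    f"{r.pair_id}\t{r.contig_name}\t{r.start_site}\t{r.fragment_length}\t"
                    f"{r.orientation}\t{r.end1_strand}\t{_encode_edits(r.end1_edits)}\t"
                    f"{r.end1_ref}\t{_encode_edits(r.end2_edits)}\t{r.end2_ref}\n"
                )
    for fname, ids in (
        ("one_end_mapped.txt", routed.one_end_mapped),
        ("neither_mapped.txt", routed.neither_mapped),
        ("cross_scaffold.txt", routed.cross_scaffold),
    ):
        with open(outdir / fname, "w") as fh:
            for pid in sorted(ids):
                fh.write(pid + "\n")
    counts = {
        "both_mapped": len(routed.both_mapped),
        "one_end_mapped": len(routed.one_end_mapped),
        "neither_mapped": len(routed.neither_mapped),
        "cross_scaffold": len(routed.cross_scaffold),
        "n_pairs": routed.n_pairs,
    }
    with open(outdir / "convert_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_routed(outdir) -> RoutedReadSet:
    outdir = Path(outdir)
    routed = RoutedReadSet()
    with open(outdir / "mappings.tsv") as fh:
        header = fh.readline().rstrip("\n")
        if header != _MAPPINGS_HEADER:
            raise ValueError(f"unexpected mappings header in {outdir}")
        for line in fh:
            (pair_id, contig, start, frag, orient, strand, ed1, ref1, ed2, ref2) = line.rstrip(
                "\n"
            ).split("\t")
            rec = MappingRecord(
                pair_id,
                contig,
                int(start),
                int(frag),
                orient,
                strand,
                _decode_edits(ed1),
                _decode_edits(ed2),
                ref1,
                ref2,
            )
            routed.both_mapped.setdefault(pair_id, []).append(rec)
    for attr, fname in (
        ("one_end_mapped", "one_end_mapped.txt"),
        ("neither_mapped", "neither_mapped.txt"),
        ("cross_scaffold", "cross_scaffold.txt"),
    ):
        with open(outdir / fname) as fh:
            getattr(routed, attr).extend(line.strip() for line in fh if line.strip())
    return routed
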