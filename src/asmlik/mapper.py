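"""Built-in read mappers: exhaustive (toy scale) and seeded (pipeline scale).

Production mapping is expected to come from an external report-all mapper
via SAM.  For self-contained validation the package ships two mappers of
its own: an exhaustive enumerator that reports *every* gapless co-placement
of a pair within a fragment-length window and an edit budget (the ground
truth for oracle comparisons, usable only on tiny genomes), and a
k-mer-seeded mapper fast enough for ~100 kb genomes.  The seeded mapper
verifies each candidate gaplessly first and falls back to a banded
edit-distance alignment around the candidate, so reads containing indels
are still placed.  Both mappers emit report-all SAM so the convert stage
can be exercised end to end.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple

import edlib

from .io_formats import (
    AssemblyIndex,
    MappingRecord,
    ReadPair,
    RoutedReadSet,
    columns_to_edits,
    flip_columns,
    gapless_columns,
    reverse_complement,
)


def _record_from_gapless(
    pair_id: str,
    contig_name: str,
    contig_seq: str,
    pos1: int,
    strand1: str,
    end1: str,
    pos2: int,
    strand2: str,
    end2: str,
    orientation: str,
) -> MappingRecord:
    """Build a MappingRecord from two gapless end placements (forward-strand
    positions; an end on "-" had its reverse complement matched there)."""
    win1 = contig_seq[pos1 : pos1 + len(end1)]
    win2 = contig_seq[pos2 : pos2 + len(end2)]
    ref1 = win1 if strand1 == "+" else reverse_complement(win1)
    ref2 = win2 if strand2 == "+" else reverse_complement(win2)
    ed1, ar1 = columns_to_edits(gapless_columns(end1, ref1))
    ed2, ar2 = columns_to_edits(gapless_columns(end2, ref2))
    start = min(pos1, pos2)
    frag = max(pos1 + len(end1), pos2 + len(end2)) - start
    return MappingRecord(
        pair_id=pair_id,
        contig_name=contig_name,
        start_site=start,
        fragment_length=frag,
        orientation=orientation,
        end1_strand=strand1,
        end1_edits=ed1,
        end2_edits=ed2,
        end1_ref=ar1,
        end2_ref=ar2,
    )


def _mismatches(a: str, b: str) -> int:
    # N columns are uninformative, not edits
    return sum(1 for x, y in zip(a, b) if x != y and x != "N" and y != "N")


def exhaustive_pair_mappings(
    assembly: AssemblyIndex,
    pair: ReadPair,
    max_edits: int,
    frag_min: int,
    frag_max: int,
    orientation: str = "FR",
) -> list[MappingRecord]:
    """Every gapless co-placement of ``pair`` with total mismatches <=
    ``max_edits`` and fragment length in [frag_min, frag_max].

    Enumerates all (contig, fragment length, start, strand) combinations;
    quadratic in genome size, intended for toy genomes only.
    """
    len1, len2 = len(pair.end1_sequence), len(pair.end2_sequence)
    rc1 = reverse_complement(pair.end1_sequence)
    rc2 = reverse_complement(pair.end2_sequence)
    out = []
    for contig in assembly.contigs:
        seq = contig.sequence
        n = contig.length
        for l in range(max(frag_min, max(len1, len2)), min(frag_max, n) + 1):
            for s in range(0, n - l + 1):
                # fragment strand "+": end1 forward at s, end2 reverse at s+l-len2
                m1 = _mismatches(pair.end1_sequence, seq[s : s + len1])
                m2 = _mismatches(rc2, seq[s + l - len2 : s + l])
                if m1 + m2 <= max_edits:
                    rec = _record_from_gapless(
                        pair.id, contig.name, seq, s, "+", pair.end1_sequence,
                        s + l - len2, "-", pair.end2_sequence, orientation,
                    )
                    out.append(_with_fragment(rec, s, l))
                # fragment strand "-": end2 forward at s, end1 reverse at s+l-len1
                m1 = _mismatches(rc1, seq[s + l - len1 : s + l])
                m2 = _mismatches(pair.end2_sequence, seq[s : s + len2])
                if m1 + m2 <= max_edits:
                    rec = _record_from_gapless(
                        pair.id, contig.name, seq, s + l - len1, "-", pair.end1_sequence,
                        s, "+", pair.end2_sequence, orientation,
                    )
                    out.append(_with_fragment(rec, s, l))
    return out


def _with_fragment(rec: MappingRecord, start: int, fragment_length: int) -> MappingRecord:
    if rec.start_site == start and rec.fragment_length == fragment_length:
        return rec
    return MappingRecord(
        rec.pair_id, rec.contig_name, start, fragment_length, rec.orientation,
        rec.end1_strand, rec.end1_edits, rec.end2_edits, rec.end1_ref, rec.end2_ref,
    )


class _Placement(NamedTuple):
    contig_index: int
    ref_start: int
    ref_end: int  # half-open
    strand: str
    columns: tuple  # target-order (query_base | None, ref_base | None)
    n_edits: int


def _columns_from_cigar(q: str, target: str, t0: int, cigar: str) -> tuple[tuple, int, int]:
    """Expand an edlib path ('=', 'X', 'I' consumes query, 'D' consumes
    target) into alignment columns; returns (columns, ref_start, ref_end)."""
    cols = []
    qi, ti = 0, t0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            for _ in range(n):
                cols.append((q[qi], target[ti]))
                qi += 1
                ti += 1
        elif ch == "I":
            for _ in range(n):
                cols.append((q[qi], None))
                qi += 1
        elif ch == "D":
            for _ in range(n):
                cols.append((None, target[ti]))
                ti += 1
        else:  # pragma: no cover
            raise ValueError(f"unexpected edlib cigar op {ch!r}")
    return tuple(cols), t0, ti


class SeedMapper:
    """Seed-and-extend mapper with a k-mer hash index.

    Three spaced seeds per end guarantee (pigeonhole) that any placement
    with at most two edits is found.  Candidates are verified gaplessly
    first; if that fails, a banded edit-distance alignment around the
    candidate recovers placements containing indels, mirroring the
    indel-capable external mappers the convert stage is designed for.
    """

    def __init__(self, assembly: AssemblyIndex, k: int = 11, max_mismatch_per_end: int = 3):
        self.assembly = assembly
        self.k = k
        self.max_mismatch_per_end = max_mismatch_per_end
        self._index: dict[str, list[tuple[int, int]]] = {}
        for ci, contig in enumerate(assembly.contigs):
            seq = contig.sequence
            for p in range(0, len(seq) - k + 1):
                kmer = seq[p : p + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((ci, p))

    def map_end(self, seq: str) -> list[_Placement]:
        """All distinct placements of one end, both strands, with at most
        ``max_mismatch_per_end`` edits."""
        k = self.k
        budget = self.max_mismatch_per_end
        pad = budget + 2
        placements: dict[tuple[int, int, str], _Placement] = {}
        for strand, q in (("+", seq), ("-", reverse_complement(seq))):
            L = len(q)
            if L < k:
                continue
            tried: set[tuple[int, int]] = set()
            for o in sorted({0, (L - k) // 2, L - k}):
                for ci, p in self._index.get(q[o : o + k], ()):
                    c = p - o
                    if (ci, c) in tried:
                        continue
                    tried.add((ci, c))
                    contig = self.assembly.contigs[ci]
                    n = contig.length
                    placed = None
                    if 0 <= c and c + L <= n:
                        mm = _mismatches(q, contig.sequence[c : c + L])
                        if mm <= budget:
                            cols = tuple(gapless_columns(q, contig.sequence[c : c + L]))
                            placed = _Placement(ci, c, c + L, strand, cols, mm)
                    if placed is None:
                        w0 = max(0, c - pad)
                        w1 = min(n, c + L + pad)
                        if w1 - w0 >= k:
                            res = edlib.align(
                                q, contig.sequence[w0:w1], mode="HW", task="path", k=budget
                            )
                            if res["editDistance"] >= 0 and res["locations"]:
                                t0 = w0 + (res["locations"][0][0] or 0)
                                cols, rs, re_ = _columns_from_cigar(
                                    q, contig.sequence, t0, res["cigar"]
                                )
                                placed = _Placement(ci, rs, re_, strand, cols, res["editDistance"])
                    if placed is None:
                        continue
                    key = (placed.contig_index, placed.ref_start, placed.strand)
                    old = placements.get(key)
                    if old is None or placed.n_edits < old.n_edits:
                        placements[key] = placed
        return [placements[k2] for k2 in sorted(placements)]

    def map_pair(
        self,
        pair: ReadPair,
        frag_min: int,
        frag_max: int,
        max_edits: int,
        orientation: str = "FR",
    ) -> tuple[list[MappingRecord], bool, bool]:
        m1 = self.map_end(pair.end1_sequence)
        m2 = self.map_end(pair.end2_sequence)
        recs = []
        want_up = "+" if orientation == "FR" else "-"
        for p1 in m1:
            for p2 in m2:
                if (
                    p1.contig_index != p2.contig_index
                    or p1.strand == p2.strand
                    or p1.n_edits + p2.n_edits > max_edits
                ):
                    continue
                up = p1 if p1.ref_start <= p2.ref_start else p2
                down = p2 if up is p1 else p1
                if up.strand != want_up:
                    continue
                frag = max(p1.ref_end, p2.ref_end) - up.ref_start
                if not (frag_min <= frag <= frag_max):
                    continue
                mc1 = p1.columns if p1.strand == "+" else tuple(flip_columns(list(p1.columns)))
                mc2 = p2.columns if p2.strand == "+" else tuple(flip_columns(list(p2.columns)))
                ed1, ar1 = columns_to_edits(list(mc1))
                ed2, ar2 = columns_to_edits(list(mc2))
                recs.append(
                    MappingRecord(
                        pair_id=pair.id,
                        contig_name=self.assembly.contigs[p1.contig_index].name,
                        start_site=up.ref_start,
                        fragment_length=frag,
                        orientation=orientation,
                        end1_strand=p1.strand,
                        end1_edits=ed1,
                        end2_edits=ed2,
                        end1_ref=ar1,
                        end2_ref=ar2,
                    )
                )
        recs.sort(key=lambda r: (r.contig_name, r.start_site, r.fragment_length, r.end1_strand))
        return recs, bool(m1), bool(m2)

    def route_pairs(
        self,
        pairs: Iterable[ReadPair],
        frag_min: int,
        frag_max: int,
        max_edits: int = 5,
        orientation: str = "FR",
    ) -> RoutedReadSet:
        routed = RoutedReadSet()
        for pair in pairs:
            recs, any1, any2 = self.map_pair(pair, frag_min, frag_max, max_edits, orientation)
            if recs:
                routed.both_mapped[pair.id] = recs
            elif any1 and any2:
                routed.cross_scaffold.append(pair.id)
            elif any1 or any2:
                routed.one_end_mapped.append(pair.id)
            else:
                routed.neither_mapped.append(pair.id)
        return routed

    def write_sam(self, pairs: Iterable[ReadPair], path) -> None:
        """Report-all SAM with every end placement (unpaired report; pairing
        and orientation filters are applied by the convert stage)."""

        def cigar_of(cols) -> str:
            parts = []
            for qb, rb in cols:
                op = "M" if qb is not None and rb is not None else ("I" if rb is None else "D")
                if parts and parts[-1][1] == op:
                    parts[-1][0] += 1
                else:
                    parts.append([1, op])
            return "".join(f"{n}{op}" for n, op in parts)

        path = Path(path)
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for c in self.assembly.contigs:
                fh.write(f"@SQ\tSN:{c.name}\tLN:{c.length}\n")
            for pair in pairs:
                for end_idx, seq in ((0, pair.end1_sequence), (1, pair.end2_sequence)):
                    placements = self.map_end(seq)
                    endflag = 0x40 if end_idx == 0 else 0x80
                    if not placements:
                        fh.write(
                            f"{pair.id}\t{0x1 | 0x4 | endflag}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n"
                        )
                        continue
                    for i, pl in enumerate(placements):
                        flag = 0x1 | endflag
                        if pl.strand == "-":
                            flag |= 0x10
                        if i > 0:
                            flag |= 0x100
                        out_seq = seq if pl.strand == "+" else reverse_complement(seq)
                        fh.write(
                            f"{pair.id}\t{flag}\t{self.assembly.contigs[pl.contig_index].name}\t"
                            f"{pl.ref_start + 1}\t255\t{cigar_of(pl.columns)}\t*\t0\t0\t{out_seq}\t*\n"
                        )
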