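"""Position-specific sequencing error model.

Error rates differ across machine cycles (positions within a read), across
reference bases and across substitution types, so the model keeps, for
every read position j: a substitution rate for each ordered (ref base,
read base) pair, an insertion-opening rate and a deletion-opening rate,
plus pmfs over insertion and deletion lengths.  At each read position
exactly one event occurs - match, substitution, insertion opening or
deletion opening - so the four event probabilities sum to one; an opened
indel's length is drawn from the corresponding length pmf.  A deletion is
indexed by the read position immediately following the deleted reference
bases and consumes that position's event slot (the read base there then
copies the reference).

All rates are learned from uniquely mapped reads; base-quality strings are
ignored.  Columns where the reference (or read) base is N contribute a
fixed uninformative factor of 1/4, which keeps the probability well
defined across scaffold gaps.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable

import numpy as np

from .io_formats import AssemblyIndex, Edit, MappingRecord

BASES = "ACGT"
_BI = {b: i for i, b in enumerate(BASES)}
LOG_QUARTER = math.log(0.25)
_NEG_INF = float("-inf")


class ErrorModel:
    """Per-position substitution/indel rates and indel-length pmfs.

    Parameters
    ----------
    sub:
        Array of shape (read_length, 4, 4); ``sub[j, b, b']`` is the
        probability that reference base ``b`` is read as ``b' != b`` at
        position j.  The diagonal is ignored (forced to zero).
    ins, dele:
        Arrays of shape (read_length,): probability of opening an
        insertion / deletion at position j.
    ins_len_pmf, del_len_pmf:
        Maps length -> probability; each sums to 1.
    """

    def __init__(
        self,
        sub: np.ndarray,
        ins: np.ndarray,
        dele: np.ndarray,
        ins_len_pmf: dict[int, float],
        del_len_pmf: dict[int, float],
    ):
        sub = np.asarray(sub, dtype=float).copy()
        if sub.ndim != 3 or sub.shape[1:] != (4, 4):
            raise ValueError("sub must have shape (read_length, 4, 4)")
        R = sub.shape[0]
        for b in range(4):
            sub[:, b, b] = 0.0
        ins = np.asarray(ins, dtype=float).copy()
        dele = np.asarray(dele, dtype=float).copy()
        if ins.shape != (R,) or dele.shape != (R,):
            raise ValueError("ins/del rate arrays must have shape (read_length,)")
        self.read_length = R
        self.sub = sub
        self.ins = ins
        self.dele = dele
        self.ins_len_pmf = _normalize_pmf(ins_len_pmf)
        self.del_len_pmf = _normalize_pmf(del_len_pmf)
        # match probability: the remainder of each (position, ref base) slot
        self.match = 1.0 - sub.sum(axis=2) - ins[:, None] - dele[:, None]
        if np.any(self.match <= 0.0):
            raise ValueError("event rates sum to >= 1 at some (position, ref base)")
        self._build_log_tables()

    def _build_log_tables(self):
        R = self.read_length
        with np.errstate(divide="ignore"):
            lm = np.log(self.match)
            ls = np.where(self.sub > 0, np.log(np.maximum(self.sub, 1e-320)), _NEG_INF)
            li = np.where(self.ins > 0, np.log(np.maximum(self.ins, 1e-320)), _NEG_INF)
            ld = np.where(self.dele > 0, np.log(np.maximum(self.dele, 1e-320)), _NEG_INF)
        self._log_ins = li.tolist()
        self._log_del = ld.tolist()
        self._log_sub = ls.tolist()
        self._log_match_by_char = [
            {"A": lm[j, 0], "C": lm[j, 1], "G": lm[j, 2], "T": lm[j, 3], "N": LOG_QUARTER}
            for j in range(R)
        ]
        self._log_ins_len = {k: math.log(v) for k, v in self.ins_len_pmf.items() if v > 0}
        self._log_del_len = {k: math.log(v) for k, v in self.del_len_pmf.items() if v > 0}

    def match_prob(self, position: int, ref_base: str) -> float:
        return float(self.match[position, _BI[ref_base]])

    def sub_rate(self, position: int, ref_base: str, read_base: str) -> float:
        return float(self.sub[position, _BI[ref_base], _BI[read_base]])

    @classmethod
    def uniform(
        cls,
        read_length: int,
        sub_rate: float = 0.01,
        ins_rate: float = 0.0005,
        del_rate: float = 0.0005,
        ins_len_pmf: dict[int, float] | None = None,
        del_len_pmf: dict[int, float] | None = None,
    ) -> "ErrorModel":
        """Scalar-shortcut model: same rates at every position, substitution
        mass split evenly over the three alternative bases."""
        sub = np.full((read_length, 4, 4), sub_rate / 3.0)
        for b in range(4):
            sub[:, b, b] = 0.0
        ins = np.full(read_length, ins_rate)
        dele = np.full(read_length, del_rate)
        if ins_len_pmf is None:
            ins_len_pmf = {1: 0.9, 2: 0.09, 3: 0.01}
        if del_len_pmf is None:
            del_len_pmf = {1: 0.9, 2: 0.09, 3: 0.01}
        return cls(sub, ins, dele, ins_len_pmf, del_len_pmf)

    # -- serialization ------------------------------------------------------

    def to_table(self, path) -> None:
        """Plain-text table, one row per position x event, for inspection."""
        with open(path, "w") as fh:
            fh.write(f"read_length\t{self.read_length}\n")
            for j in range(self.read_length):
                for b in BASES:
                    for b2 in BASES:
                        if b != b2:
                            fh.write(f"sub\t{j}\t{b}\t{b2}\t{float(self.sub[j, _BI[b], _BI[b2]])!r}\n")
                fh.write(f"ins\t{j}\t.\t.\t{float(self.ins[j])!r}\n")
                fh.write(f"del\t{j}\t.\t.\t{float(self.dele[j])!r}\n")
            for k, v in sorted(self.ins_len_pmf.items()):
                fh.write(f"ins_len\t{k}\t.\t.\t{v!r}\n")
            for k, v in sorted(self.del_len_pmf.items()):
                fh.write(f"del_len\t{k}\t.\t.\t{v!r}\n")

    @classmethod
    def from_table(cls, path) -> "ErrorModel":
        with open(path) as fh:
            tag, val = fh.readline().split()
            if tag != "read_length":
                raise ValueError("malformed error-model table")
            R = int(val)
            sub = np.zeros((R, 4, 4))
            ins = np.zeros(R)
            dele = np.zeros(R)
            ins_len: dict[int, float] = {}
            del_len: dict[int, float] = {}
            for line in fh:
                kind, a, b, c, v = line.split()
                v = float(v)
                if kind == "sub":
                    sub[int(a), _BI[b], _BI[c]] = v
                elif kind == "ins":
                    ins[int(a)] = v
                elif kind == "del":
                    dele[int(a)] = v
                elif kind == "ins_len":
                    ins_len[int(a)] = v
                elif kind == "del_len":
                    del_len[int(a)] = v
        return cls(sub, ins, dele, ins_len or {1: 1.0}, del_len or {1: 1.0})


def _normalize_pmf(pmf: dict[int, float]) -> dict[int, float]:
    pmf = {int(k): float(v) for k, v in pmf.items() if v > 0}
    if not pmf:
        raise ValueError("empty length pmf")
    total = math.fsum(pmf.values())
    return {k: v / total for k, v in pmf.items()}


# ---------------------------------------------------------------------------
# Evaluation


def p_error(model: ErrorModel, edits: Iterable[Edit], aligned_ref: str) -> float:
    """Natural-log probability of one read end given its aligned reference.

    ``aligned_ref`` has one character per machine-cycle position of the
    end: the aligned reference base, "-" at inserted positions, or "N" for
    uninformative columns (scaffold gaps, unaligned tails of a local
    alignment).  Each position contributes exactly one factor: its match
    probability, a substitution rate, or - for positions consumed by an
    indel event - the indel-opening rate times its length pmf.
    """
    R = model.read_length
    L = len(aligned_ref)
    if L > R:
        raise ValueError(f"aligned read length {L} exceeds model read length {R}")
    tables = model._log_match_by_char
    if not edits:
        lp = 0.0
        for j in range(L):
            lp += tables[j][aligned_ref[j]]
        return lp

    lp = 0.0
    skip = bytearray(L)
    for e in edits:
        if e.read_pos >= R or e.read_pos > L:
            raise ValueError(f"edit at position {e.read_pos} >= read length {R}")
        if e.kind == "ins":
            lg = model._log_ins_len.get(e.length)
            li = model._log_ins[e.read_pos]
            if lg is None or li == _NEG_INF:
                return _NEG_INF
            lp += li + lg
            for k in range(e.read_pos, min(e.read_pos + e.length, L)):
                skip[k] = 1
        elif e.kind == "del":
            lg = model._log_del_len.get(e.length)
            ld = model._log_del[e.read_pos] if e.read_pos < R else _NEG_INF
            if lg is None or ld == _NEG_INF:
                return _NEG_INF
            lp += ld + lg
            if e.read_pos < L:
                skip[e.read_pos] = 1  # slot consumed: the read base copies the reference
        elif e.kind == "sub":
            if e.ref in BASES and e.read in BASES:
                ls = model._log_sub[e.read_pos][_BI[e.ref]][_BI[e.read]]
                if ls == _NEG_INF:
                    return _NEG_INF
                lp += ls
            else:
                lp += LOG_QUARTER
            if e.read_pos < L:
                skip[e.read_pos] = 1
        else:
            raise ValueError(f"unknown edit kind {e.kind!r}")
    for j in range(L):
        if not skip[j]:
            lp += tables[j][aligned_ref[j]]
    return lp


def p_error_pair(model: ErrorModel, record: MappingRecord) -> float:
    """Log probability of both ends of one mapping."""
    return p_error(model, record.end1_edits, record.end1_ref) + p_error(
        model, record.end2_edits, record.end2_ref
    )


# ---------------------------------------------------------------------------
# Learning


def learn_error_model(
    unique_mappings: Iterable[MappingRecord],
    assembly: AssemblyIndex | None = None,
    read_length: int | None = None,
    pseudocount: float = 1.0,
) -> ErrorModel:
    """Learn per-position error rates from uniquely mapped pairs.

    Substitution rates are Laplace estimates conditioned on the reference
    base observed at each position, ``(count + a) / (ref-base count + 4a)``;
    indel-opening rates use the per-position coverage as the opportunity
    count, ``(count + a) / (coverage + 2a)``.  Indel-length pmfs are
    smoothed counts over lengths 1..max observed (minimum support {1}).
    The ``assembly`` argument is accepted for interface symmetry; mapping
    records already carry their aligned reference bases.
    """
    records = list(unique_mappings)
    if not records:
        raise ValueError("no uniquely mapped pairs; cannot learn error model")
    ends: list[tuple[tuple[Edit, ...], str]] = []
    for r in records:
        ends.append((r.end1_edits, r.end1_ref))
        ends.append((r.end2_edits, r.end2_ref))
    max_len = max(len(ref) for _, ref in ends)
    if read_length is None:
        read_length = max_len
    elif max_len > read_length:
        raise ValueError(f"observed read length {max_len} exceeds declared {read_length}")
    R = read_length

    den = np.zeros((R, 4))  # ref-base b observed at position j (match or sub column)
    sub_counts = np.zeros((R, 4, 4))
    cov = np.zeros(R)  # indel opportunities
    ins_counts = np.zeros(R)
    del_counts = np.zeros(R)
    ins_len_counts: dict[int, int] = {}
    del_len_counts: dict[int, int] = {}

    for edits, ref in ends:
        L = len(ref)
        cov[:L] += 1
        consumed = bytearray(L)
        for e in edits:
            if e.kind == "sub":
                consumed[e.read_pos] = 1
                if e.ref in BASES and e.read in BASES:
                    bi, qi = _BI[e.ref], _BI[e.read]
                    sub_counts[e.read_pos, bi, qi] += 1
                    den[e.read_pos, bi] += 1
            elif e.kind == "ins":
                ins_counts[e.read_pos] += 1
                ins_len_counts[e.length] = ins_len_counts.get(e.length, 0) + 1
                for k in range(e.read_pos, min(e.read_pos + e.length, L)):
                    consumed[k] = 1
            elif e.kind == "del":
                if e.read_pos < R:
                    del_counts[e.read_pos] += 1
                del_len_counts[e.length] = del_len_counts.get(e.length, 0) + 1
                if e.read_pos < L:
                    consumed[e.read_pos] = 1
        for j in range(L):
            if not consumed[j]:
                b = ref[j]
                if b in BASES:
                    den[j, _BI[b]] += 1

    a = float(pseudocount)
    if a > 0 and np.any(cov == 0):
        warnings.warn("some read positions never observed; rates there are pure pseudocount")

    with np.errstate(divide="ignore", invalid="ignore"):
        sub = np.where(
            (den[:, :, None] + 4 * a) > 0,
            (sub_counts + a) / (den[:, :, None] + 4 * a),
            0.0,
        )
    for b in range(4):
        sub[:, b, b] = 0.0
    ins = (ins_counts + a) / (cov + 2 * a) if a > 0 or cov.min() > 0 else np.zeros(R)
    dele = (del_counts + a) / (cov + 2 * a) if a > 0 or cov.min() > 0 else np.zeros(R)
    if a == 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            ins = np.where(cov > 0, ins_counts / np.maximum(cov, 1), 0.0)
            dele = np.where(cov > 0, del_counts / np.maximum(cov, 1), 0.0)

    # validity guard: at sparse positions the Laplace estimates can sum to
    # >= 1; rescale that position's event mass to 0.95 and warn.
    tot = sub.sum(axis=2).max(axis=1) + ins + dele
    bad = tot >= 0.95
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} position(s) with near-degenerate event mass; rescaled to 0.95"
        )
        factor = np.where(bad, 0.95 / tot, 1.0)
        sub *= factor[:, None, None]
        ins *= factor
        dele *= factor

    def _len_pmf(counts: dict[int, int]) -> dict[int, float]:
        hi = max(counts) if counts else 1
        raw = {k: counts.get(k, 0) + a for k in range(1, hi + 1)}
        if all(v == 0 for v in raw.values()):
            return {1: 1.0}
        return raw

    return ErrorModel(sub, ins, dele, _len_pmf(ins_len_counts), _len_pmf(del_len_counts))
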