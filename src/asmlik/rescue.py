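"""Rescue of read pairs the mapper could not place.

A random subsample of the non-mapped pairs is aligned directly to the
assembly with exact affine-gap Smith-Waterman (candidate windows located
first with an infix edit-distance search so only a short stretch of the
assembly enters the quadratic DP).  Each sampled pair gets a log
probability on the same scale as mapped pairs; the arithmetic mean of the
sampled log probabilities (a geometric-mean imputation, robust to one
near-zero sample) is assigned to every non-sampled non-mapped pair.
"""

from __future__ import annotations

import json
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable

import edlib
import numpy as np

from .error_model import ErrorModel, p_error
from .fragment_model import FragmentLengthDistribution, StartSiteModel
from .io_formats import ReadPair, columns_to_edits, flip_columns, reverse_complement
from .likelihood import LOG_HALF

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class SWScores:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2  # cost of a length-1 gap
    gap_extend: int = -1  # additional cost per extra gapped base

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")


@dataclass(frozen=True)
class SWAlignment:
    score: int
    read_start: int
    read_end: int  # half-open, in the query as passed in
    target_start: int
    target_end: int
    columns: tuple  # ((read_base | None, target_base | None), ...)


def smith_waterman(read: str, target: str, scores: SWScores = SWScores()) -> SWAlignment:
    """Highest-scoring local alignment with affine gaps (length-k gap costs
    gap_open + (k-1) * gap_extend).  Ties are broken by smallest target
    start, then smallest read start; within the traceback, diagonal moves
    are preferred over gaps.  Quadratic time and memory."""
    if not read or not target:
        raise ValueError("smith_waterman requires nonempty sequences")
    m, n = len(read), len(target)
    ms, xs, go, ge = scores.match, scores.mismatch, scores.gap_open, scores.gap_extend
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in read (consumes target)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in target (consumes read)
    for i in range(1, m + 1):
        ri = read[i - 1]
        Hi, Hp = H[i], H[i - 1]
        Ei, Fi, Fp = E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            e = max(Hi[j - 1] + go, Ei[j - 1] + ge)
            f = max(Hp[j] + go, Fp[j] + ge)
            d = Hp[j - 1] + (ms if ri == target[j - 1] else xs)
            h = d
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
    best = int(H.max())
    if best == 0:
        return SWAlignment(0, 0, 0, 0, 0, ())
    ends = np.argwhere(H == best)
    candidates = []
    for i, j in ends:
        aln = _traceback(read, target, H, E, F, int(i), int(j), scores)
        candidates.append(aln)
    candidates.sort(key=lambda a: (a.target_start, a.read_start, a.target_end, a.read_end))
    return candidates[0]


def _traceback(read, target, H, E, F, i, j, scores) -> SWAlignment:
    ms, xs, go, ge = scores.match, scores.mismatch, scores.gap_open, scores.gap_extend
    cols = []
    end_i, end_j = i, j
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            d = H[i - 1][j - 1] + (ms if read[i - 1] == target[j - 1] else xs)
            if h == d:
                cols.append((read[i - 1], target[j - 1]))
                i -= 1
                j -= 1
            elif h == E[i][j]:
                state = "E"
            elif h == F[i][j]:
                state = "F"
            else:  # pragma: no cover - DP consistency
                raise AssertionError("inconsistent traceback")
        elif state == "E":
            cols.append((None, target[j - 1]))
            if E[i][j] == H[i][j - 1] + go:
                state = "H"
            j -= 1
        else:  # "F"
            cols.append((read[i - 1], None))
            if F[i][j] == H[i - 1][j] + go:
                state = "H"
            i -= 1
    cols.reverse()
    return SWAlignment(int(H[end_i][end_j]), i, end_i, j, end_j, tuple(cols))


@dataclass(frozen=True)
class EndPlacement:
    contig_index: int
    strand: str
    alignment: SWAlignment  # target coords are contig coords
    aligned: bool


def best_local_alignment(
    read_end: str, assembly, scores: SWScores = SWScores(), window_pad: int = 15
) -> EndPlacement:
    """Best local alignment of one end against all contigs, both strands.

    An infix edit-distance scan shortlists one window per (contig, strand);
    exact Smith-Waterman then scores the window.  Deterministic: ties go to
    the lowest contig index, "+" before "-", then smallest target start."""
    best = None
    for ci, contig in enumerate(assembly.contigs):
        for sidx, (strand, q) in enumerate((("+", read_end), ("-", reverse_complement(read_end)))):
            res = edlib.align(q, contig.sequence, mode="HW", task="locations")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            loc = min((s if s is not None else 0, e) for s, e in res["locations"])
            w0 = max(0, loc[0] - window_pad)
            w1 = min(contig.length, loc[1] + 1 + window_pad)
            if w1 <= w0:
                continue
            aln = smith_waterman(q, contig.sequence[w0:w1], scores)
            if aln.score <= 0:
                continue
            shifted = SWAlignment(
                aln.score, aln.read_start, aln.read_end,
                aln.target_start + w0, aln.target_end + w0, aln.columns,
            )
            key = (-shifted.score, ci, sidx, shifted.target_start, shifted.read_start)
            if best is None or key < best[0]:
                best = (key, EndPlacement(ci, strand, shifted, True))
    if best is None:
        return EndPlacement(-1, "+", SWAlignment(0, 0, 0, 0, 0, ()), False)
    return best[1]


def _end_log_probability(placement: EndPlacement, read_end: str, em: ErrorModel) -> float:
    """p_E of one rescued end: unaligned head/tail positions contribute the
    uninformative 1/4 factor (same rule as N columns)."""
    L = len(read_end)
    if not placement.aligned:
        return p_error(em, (), "N" * L)
    q = read_end if placement.strand == "+" else reverse_complement(read_end)
    aln = placement.alignment
    cols = (
        [(q[i], "N") for i in range(aln.read_start)]
        + list(aln.columns)
        + [(q[i], "N") for i in range(aln.read_end, L)]
    )
    if placement.strand == "-":
        cols = flip_columns(cols)
    edits, aligned_ref = columns_to_edits(cols)
    lp = p_error(em, edits, aligned_ref)
    if lp == _NEG_INF:
        # the learned model assigns this alignment zero probability (e.g. an
        # indel length never seen in the mapped data); fall back to the
        # fully-uninformative floor so the rescued value stays finite
        return p_error(em, (), "N" * L)
    return lp


@dataclass
class RescueResult:
    sampled_pair_ids: list[str]
    per_pair_log_probability: dict[str, float]
    imputed_log_probability: float
    sample_size: int
    seed: int
    audit: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "sampled_pair_ids": self.sampled_pair_ids,
                    "per_pair_log_probability": self.per_pair_log_probability,
                    "imputed_log_probability": self.imputed_log_probability,
                    "sample_size": self.sample_size,
                    "seed": self.seed,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RescueResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["sampled_pair_ids"],
            d["per_pair_log_probability"],
            d["imputed_log_probability"],
            d["sample_size"],
            d["seed"],
        )


def rescue_pair_log_probability(
    pair: ReadPair,
    assembly,
    p_F: FragmentLengthDistribution,
    p_S: StartSiteModel,
    p_E: ErrorModel,
    scores: SWScores = SWScores(),
    orientation: str = "FR",
) -> tuple[float, dict]:
    """Log probability of one rescued pair.

    If the two best end alignments co-place compatibly (same contig,
    opposite strands, proper orientation, fragment length inside the
    learned support) the pair is scored exactly like a single mapping.
    Otherwise each end's best alignment contributes its p_E and the
    placement term is bounded by the modal fragment probability."""
    b1 = best_local_alignment(pair.end1_sequence, assembly, scores)
    b2 = best_local_alignment(pair.end2_sequence, assembly, scores)
    pe1 = _end_log_probability(b1, pair.end1_sequence, p_E)
    pe2 = _end_log_probability(b2, pair.end2_sequence, p_E)
    detail = {
        "end1": (b1.contig_index, b1.strand, b1.alignment.target_start, b1.alignment.score),
        "end2": (b2.contig_index, b2.strand, b2.alignment.target_start, b2.alignment.score),
    }
    if b1.aligned and b2.aligned and b1.contig_index == b2.contig_index and b1.strand != b2.strand:
        up, down = (b1, b2) if b1.alignment.target_start <= b2.alignment.target_start else (b2, b1)
        want_up = "+" if orientation == "FR" else "-"
        if up.strand == want_up:
            frag = down.alignment.target_end - up.alignment.target_start
            lf = p_F.log_pmf(frag)
            ls = p_S.log_p_start(frag)
            if lf != _NEG_INF and ls != _NEG_INF:
                detail["co_placed"] = True
                return lf + ls + LOG_HALF + pe1 + pe2, detail
    mode = p_F.mode()
    ls = p_S.log_p_start(mode)
    if ls == _NEG_INF:
        ls = -math.log(max(p_S.assembly.total_length, 2))
    detail["co_placed"] = False
    return p_F.log_pmf(mode) + ls + LOG_HALF + pe1 + pe2, detail


def rescue_sample(
    non_mapped_pairs: Iterable[ReadPair],
    assembly,
    p_F: FragmentLengthDistribution,
    p_S: StartSiteModel,
    p_E: ErrorModel,
    sample_size: int = 500,
    seed: int = 0,
    threads: int = 1,
    scores: SWScores = SWScores(),
    orientation: str = "FR",
) -> RescueResult:
    """Sample ``sample_size`` pairs without replacement and align them.

    Reproducible given (seed, sample_size); the thread count affects only
    wall time, never which alignment wins (results are merged in sampled
    order and all tie-breaking is deterministic)."""
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    pool = sorted(non_mapped_pairs, key=lambda p: p.id)
    if not pool:
        return RescueResult([], {}, math.nan, 0, seed)
    rng = np.random.default_rng(seed)
    if len(pool) <= sample_size:
        sampled = pool
    else:
        idx = rng.choice(len(pool), size=sample_size, replace=False)
        sampled = [pool[i] for i in sorted(idx)]

    def work(pair: ReadPair):
        return rescue_pair_log_probability(pair, assembly, p_F, p_S, p_E, scores, orientation)

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as ex:
            results = list(ex.map(work, sampled))
    else:
        results = [work(p) for p in sampled]
    per_pair = {p.id: lp for p, (lp, _) in zip(sampled, results)}
    audit = {p.id: det for p, (_, det) in zip(sampled, results)}
    imputed = math.fsum(per_pair.values()) / len(per_pair)
    return RescueResult(
        sampled_pair_ids=[p.id for p in sampled],
        per_pair_log_probability=per_pair,
        imputed_log_probability=imputed,
        sample_size=len(sampled),
        seed=seed,
        audit=audit,
    )
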