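"""Paired-end read simulator under the generative sequencing model.

Fragments are drawn with rounded-Gaussian lengths (truncated to lengths
that fit the genome), placed uniformly over all valid start sites on either
strand, and the two ends are read through the position-specific error
model's event grammar (match / substitution / insertion / deletion at each
machine cycle).  The simulator emits FASTQ plus a truth log from which
every injected edit can be reconstructed, and the exact "true parameter"
distributions needed to score the genome the reads came from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.stats import norm

from .error_model import BASES, ErrorModel
from .fragment_model import FragmentLengthDistribution, StartSiteModel
from .io_formats import (
    AssemblyIndex,
    Edit,
    MappingRecord,
    ReadPair,
    RoutedReadSet,
    _decode_edits,
    _encode_edits,
    write_fastq_pairs,
)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
_COMP_ASCII = np.arange(256, dtype=np.uint8)
for _a, _b in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")):
    _COMP_ASCII[ord(_a)] = ord(_b)
_BASE_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_STR = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SimulationConfig:
    """Study conditions for a simulation run.

    Defaults emulate a short-insert Illumina library: 35 bp ends, 200 bp
    mean fragment length with 20 bp spread, 1% substitution rate and
    5e-4 insertion/deletion opening rates per cycle.
    """

    n_pairs: int
    read_length: int = 35
    fragment_mean: float = 200.0
    fragment_sd: float = 20.0
    sub_rate: float = 0.01
    ins_rate: float = 0.0005
    del_rate: float = 0.0005
    seed: int = 0
    error_model: ErrorModel | None = None

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed fragment_mean")
        if self.error_model is None:
            self.error_model = ErrorModel.uniform(
                self.read_length, self.sub_rate, self.ins_rate, self.del_rate
            )
        elif self.error_model.read_length != self.read_length:
            raise ValueError("error_model read_length differs from config read_length")


@dataclass(frozen=True)
class TruthRecord:
    """Where a simulated pair came from and which edits were injected."""

    pair_id: str
    contig: str
    start_site: int
    fragment_length: int
    strand: str
    end1_edits: tuple[Edit, ...]
    end2_edits: tuple[Edit, ...]
    end1_ref: str
    end2_ref: str

    def to_mapping_record(self, orientation: str = "FR") -> MappingRecord:
        return MappingRecord(
            pair_id=self.pair_id,
            contig_name=self.contig,
            start_site=self.start_site,
            fragment_length=self.fragment_length,
            orientation=orientation,
            end1_strand=self.strand,
            end1_edits=self.end1_edits,
            end2_edits=self.end2_edits,
            end1_ref=self.end1_ref,
            end2_ref=self.end2_ref,
        )


def true_fragment_distribution(config: SimulationConfig, genome: AssemblyIndex) -> FragmentLengthDistribution:
    """Discretized truncated Gaussian: mass of Normal(mean, sd) on
    [l - 0.5, l + 0.5], renormalized over the truncation window
    [read_length, longest contig].  Lengths beyond eight standard
    deviations carry no representable mass and are omitted."""
    max_len = max(c.length for c in genome.contigs)
    lo = max(config.read_length, int(math.floor(config.fragment_mean - 8 * config.fragment_sd)))
    hi = min(max_len, int(math.ceil(config.fragment_mean + 8 * config.fragment_sd)))
    if lo > hi:
        raise ValueError("no admissible fragment length in the truncation window")
    ls = np.arange(lo, hi + 1)
    mass = norm.cdf(ls + 0.5, config.fragment_mean, config.fragment_sd) - norm.cdf(
        ls - 0.5, config.fragment_mean, config.fragment_sd
    )
    pmf = {int(l): float(m) for l, m in zip(ls, mass) if m > 0}
    return FragmentLengthDistribution(pmf)


def _draw_length(pmf: dict[int, float], x: float) -> int:
    acc = 0.0
    last = 1
    for k in sorted(pmf):
        acc += pmf[k]
        last = k
        if x < acc:
            return k
    return last


class _RetryPair(Exception):
    pass


def _simulate_end_with_indels(seq, start_g, direction, comp, u_row, v_row, em, R, rng):
    """Walk one end through the event grammar, allowing indels.

    Raises _RetryPair if the walk runs off the contig."""
    n = len(seq)
    read: list[str] = []
    aligned_ref: list[str] = []
    edits: list[Edit] = []
    g = start_g
    j = 0

    def ref_char(pos: int) -> str:
        if pos < 0 or pos >= n:
            raise _RetryPair()
        c = seq[pos]
        return c.translate(_COMP_STR) if comp else c

    while j < R:
        uu = u_row[j]
        dele = em.dele[j]
        ins = em.ins[j]
        if uu < dele:
            if j == 0:  # a deletion cannot precede the first cycle: match
                c = ref_char(g)
                if c == "N":
                    read.append(BASES[int(rng.integers(0, 4))])
                    aligned_ref.append("N")
                else:
                    read.append(c)
                    aligned_ref.append(c)
                g += direction
                j += 1
                continue
            k = _draw_length(em.del_len_pmf, v_row[j])
            deleted = "".join(ref_char(g + t * direction) for t in range(k))
            g += k * direction
            c = ref_char(g)  # the slot's read base copies the next reference base
            read.append(c)
            aligned_ref.append(c)
            edits.append(Edit(j, "del", deleted, "", k))
            g += direction
            j += 1
        elif uu < dele + ins:
            k = min(_draw_length(em.ins_len_pmf, v_row[j]), R - j)
            bases = "".join(BASES[i] for i in rng.integers(0, 4, size=k))
            read.append(bases)
            aligned_ref.append("-" * k)
            edits.append(Edit(j, "ins", "-", bases, k))
            j += k
        else:
            b = ref_char(g)
            if b == "N":
                read.append(BASES[int(rng.integers(0, 4))])
                aligned_ref.append("N")
            else:
                bi = _CODE[ord(b)]
                row = em.sub[j, bi]
                stot = float(row.sum())
                if uu < dele + ins + stot:
                    cdf = np.cumsum(row) / stot
                    choice = int(np.searchsorted(cdf, v_row[j], side="right"))
                    choice = min(choice, 3)
                    b2 = BASES[choice]
                    read.append(b2)
                    aligned_ref.append(b)
                    edits.append(Edit(j, "sub", b, b2, 1))
                else:
                    read.append(b)
                    aligned_ref.append(b)
            g += direction
            j += 1
    return "".join(read), "".join(aligned_ref), tuple(edits)


def simulate_reads(
    genome: AssemblyIndex, config: SimulationConfig
) -> tuple[list[ReadPair], list[TruthRecord]]:
    """Simulate ``config.n_pairs`` paired-end reads from ``genome``.

    Reproducible given ``config.seed``.  End 1 reads the fragment's 5' end
    on the fragment strand; end 2 reads the 3' end on the opposite strand
    (forward-reverse layout).
    """
    rng = np.random.default_rng(config.seed)
    em = config.error_model
    R = config.read_length
    n = config.n_pairs
    clens = np.array([c.length for c in genome.contigs], dtype=np.int64)
    max_len = int(clens.max())
    if max_len < R:
        raise ValueError("no contig admits even the minimum fragment length")
    offsets = np.concatenate([[0], np.cumsum(clens)[:-1]])
    G = np.frombuffer("".join(c.sequence for c in genome.contigs).encode(), dtype=np.uint8)

    # fragment lengths: rounded Gaussian truncated to [R, longest contig]
    l = np.rint(rng.normal(config.fragment_mean, config.fragment_sd, n)).astype(np.int64)
    for _ in range(1000):
        bad = (l < R) | (l > max_len)
        if not bad.any():
            break
        l[bad] = np.rint(
            rng.normal(config.fragment_mean, config.fragment_sd, int(bad.sum()))
        ).astype(np.int64)
    else:
        raise ValueError("could not draw admissible fragment lengths")

    # uniform (contig, start) over valid sites for each length
    tv = np.maximum(clens[None, :] - l[:, None] + 1, 0)
    tot = tv.sum(axis=1)
    u_site = rng.integers(0, tot)
    cum = np.cumsum(tv, axis=1)
    ci = (u_site[:, None] >= cum).sum(axis=1)
    prev = cum[np.arange(n), ci] - tv[np.arange(n), ci]
    s = u_site - prev
    strand = rng.integers(0, 2, n)  # 0 -> "+", 1 -> "-"

    u = rng.random((n, 2, R))
    v = rng.random((n, 2, R))
    # event bands: [0, del) deletion, [del, del+ins) insertion, then
    # substitution / match.  A deletion cannot precede the first cycle; its
    # band at position 0 falls through to match.
    ev_del = u < em.dele[None, None, :]
    ev_del[:, :, 0] = False
    ev_ins = (u >= em.dele[None, None, :]) & (u < (em.dele + em.ins)[None, None, :])
    has_indel = ev_del.any(axis=(1, 2)) | ev_ins.any(axis=(1, 2))

    # ---- vectorized path: pairs without indel events -----------------------
    idx0 = np.nonzero(~has_indel)[0]
    reads = np.empty((n, 2, R), dtype=np.uint8)
    refs = np.empty((n, 2, R), dtype=np.uint8)
    if idx0.size:
        ar = np.arange(R)
        for e in (0, 1):
            # end1 is on the fragment strand; end2 on the opposite strand
            fwd = (strand[idx0] == 0) if e == 0 else (strand[idx0] == 1)
            base = offsets[ci[idx0]]
            gidx = np.where(
                fwd[:, None],
                (base + s[idx0])[:, None] + ar[None, :],
                (base + s[idx0] + l[idx0] - 1)[:, None] - ar[None, :],
            )
            r = G[gidx]
            r = np.where(fwd[:, None], r, _COMP_ASCII[r])
            refs[idx0, e, :] = r
        sub_tot = em.sub.sum(axis=2)  # (R, 4)
        codes = _CODE[refs[idx0]]  # (m, 2, R); 4 == N
        is_n = codes == 4
        st = np.where(is_n, 0.0, sub_tot[np.arange(R)[None, None, :], np.minimum(codes, 3)])
        thr = (em.dele + em.ins)[None, None, :] + st
        ev_sub = (u[idx0] >= (em.dele + em.ins)[None, None, :]) & (u[idx0] < thr)
        reads[idx0] = refs[idx0]
        if ev_sub.any():
            w = np.nonzero(ev_sub)
            jj = w[2]
            bb = np.minimum(codes[w], 3)
            rows = em.sub[jj, bb, :]
            cdf = np.cumsum(rows, axis=1) / rows.sum(axis=1, keepdims=True)
            vv = v[idx0][w]
            choice = (vv[:, None] >= cdf).sum(axis=1)
            choice = np.minimum(choice, 3)
            reads[idx0[w[0]], w[1], jj] = _BASE_ASCII[choice]
        if is_n.any():
            wn = np.nonzero(is_n)
            reads[idx0[wn[0]], wn[1], wn[2]] = _BASE_ASCII[rng.integers(0, 4, size=wn[0].size)]

    pairs: list[ReadPair] = []
    truths: list[TruthRecord] = []
    width = max(6, len(str(n)))
    for i in range(n):
        pid = f"sim_{i:0{width}d}"
        contig = genome.contigs[int(ci[i])]
        st_char = "+" if strand[i] == 0 else "-"
        if not has_indel[i]:
            e_reads, e_refs, e_edits = [], [], []
            for e in (0, 1):
                rd = bytes(reads[i, e]).decode()
                rf = bytes(refs[i, e]).decode()
                edits = tuple(
                    Edit(int(j), "sub", rf[j], rd[j], 1)
                    for j in range(R)
                    if rd[j] != rf[j] and rf[j] != "N"
                )
                e_reads.append(rd)
                e_refs.append(rf)
                e_edits.append(edits)
            pairs.append(ReadPair(pid, e_reads[0], e_reads[1]))
            truths.append(
                TruthRecord(
                    pid, contig.name, int(s[i]), int(l[i]), st_char,
                    e_edits[0], e_edits[1], e_refs[0], e_refs[1],
                )
            )
            continue
        # ---- indel path: per-read walk with bounded retries ----------------
        li, si, ciL, stL = int(l[i]), int(s[i]), int(ci[i]), st_char
        u1, v1, u2, v2 = u[i, 0], v[i, 0], u[i, 1], v[i, 1]
        for attempt in range(100):
            contig = genome.contigs[ciL]
            seq = contig.sequence
            try:
                if stL == "+":
                    r1, f1, ed1 = _simulate_end_with_indels(seq, si, +1, False, u1, v1, em, R, rng)
                    r2, f2, ed2 = _simulate_end_with_indels(
                        seq, si + li - 1, -1, True, u2, v2, em, R, rng
                    )
                else:
                    r1, f1, ed1 = _simulate_end_with_indels(
                        seq, si + li - 1, -1, True, u1, v1, em, R, rng
                    )
                    r2, f2, ed2 = _simulate_end_with_indels(seq, si, +1, False, u2, v2, em, R, rng)
                break
            except _RetryPair:
                li = int(np.rint(rng.normal(config.fragment_mean, config.fragment_sd)))
                li = min(max(li, R), max_len)
                tvr = np.maximum(clens - li + 1, 0)
                ur = int(rng.integers(0, int(tvr.sum())))
                cumr = np.cumsum(tvr)
                ciL = int((ur >= cumr).sum())
                si = ur - (int(cumr[ciL]) - int(tvr[ciL]))
                stL = "+" if int(rng.integers(0, 2)) == 0 else "-"
                u1, v1 = rng.random(R), rng.random(R)
                u2, v2 = rng.random(R), rng.random(R)
        else:
            raise ValueError("simulation could not place a fragment after 100 retries")
        pairs.append(ReadPair(pid, r1, r2))
        truths.append(
            TruthRecord(pid, genome.contigs[ciL].name, si, li, stL, ed1, ed2, f1, f2)
        )
    return pairs, truths


# ---------------------------------------------------------------------------
# Truth log I/O

_TRUTH_HEADER = (
    "pair_id\tcontig\tstart\tfragment_length\tstrand\tend1_edits\tend1_ref\tend2_edits\tend2_ref"
)


def write_truth(truths: Iterable[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for t in truths:
            fh.write(
                f"{t.pair_id}\t{t.contig}\t{t.start_site}\t{t.fragment_length}\t{t.strand}\t"
                f"{_encode_edits(t.end1_edits)}\t{t.end1_ref}\t"
                f"{_encode_edits(t.end2_edits)}\t{t.end2_ref}\n"
            )


def read_truth(path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TRUTH_HEADER:
            raise ValueError("unexpected truth log header")
        for line in fh:
            pid, contig, start, frag, strand, ed1, ref1, ed2, ref2 = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    pid, contig, int(start), int(frag), strand,
                    _decode_edits(ed1), _decode_edits(ed2), ref1, ref2,
                )
            )
    return out


def write_simulation(pairs, truths, outdir, config: SimulationConfig) -> None:
    """FASTQ pair + truth log + run manifest under one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fastq_pairs(pairs, outdir / "reads_1.fastq", outdir / "reads_2.fastq")
    write_truth(truths, outdir / "truth.tsv")
    manifest = {
        "n_pairs": config.n_pairs,
        "read_length": config.read_length,
        "fragment_mean": config.fragment_mean,
        "fragment_sd": config.fragment_sd,
        "sub_rate": config.sub_rate,
        "ins_rate": config.ins_rate,
        "del_rate": config.del_rate,
        "seed": config.seed,
    }
    import json

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def truths_to_routed(truths: Iterable[TruthRecord]) -> RoutedReadSet:
    """Treat each pair's true placement as its single mapping."""
    routed = RoutedReadSet()
    for t in truths:
        routed.both_mapped[t.pair_id] = [t.to_mapping_record()]
    return routed


def true_parameter_log_likelihood(
    genome: AssemblyIndex,
    routed: RoutedReadSet,
    config: SimulationConfig,
    rescue_result=None,
):
    """Total log likelihood evaluated with the simulator's own parameters:
    the discretized truncated-Gaussian fragment pmf, the uniform start-site
    model on ``genome`` and the configured error model."""
    from .likelihood import total_log_likelihood

    p_F = true_fragment_distribution(config, genome)
    p_S = StartSiteModel(genome)
    return total_log_likelihood(routed, p_F, p_S, config.error_model, rescue_result)
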