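"""Brute-force reference computation of the per-read probability.

Independent of the mapping-based engine: enumerates every (fragment
length, start site, strand) placement of a pair on the assembly directly
and accumulates probabilities in linear space with exact summation.  Used
to validate the mapping-based approximation at toy scale; cost is
O(genome^2), so only run this on genomes of a few hundred bases.
"""

from __future__ import annotations

import math

from .error_model import _BI, ErrorModel
from .fragment_model import FragmentLengthDistribution
from .io_formats import AssemblyIndex, ReadPair, reverse_complement


def _end_probability_and_edits(read: str, ref: str, em: ErrorModel) -> tuple[float, int]:
    """Linear-space probability of a gapless end alignment and its mismatch
    count (N columns contribute 1/4 and are not mismatches)."""
    p = 1.0
    mm = 0
    for j, (rb, xb) in enumerate(zip(read, ref)):
        if rb == "N" or xb == "N":
            p *= 0.25
        elif rb == xb:
            p *= float(em.match[j, _BI[xb]])
        else:
            p *= float(em.sub[j, _BI[xb], _BI[rb]])
            mm += 1
    return p, mm


def brute_force_log_probability(
    assembly: AssemblyIndex,
    pair: ReadPair,
    p_F: FragmentLengthDistribution,
    em: ErrorModel,
    max_edits: int,
) -> float:
    """log of the triple sum over (l, s, strand) of
    p_F(l) * p_S(s|l) * 1/2 * p_E, keeping only gapless placements with at
    most ``max_edits`` mismatches (indel placements carry probability zero
    when the model's indel rates are zero, which is the regime this oracle
    is exact in)."""
    end1, end2 = pair.end1_sequence, pair.end2_sequence
    len1, len2 = len(end1), len(end2)
    contig_lengths = [c.length for c in assembly.contigs]
    terms: list[float] = []
    for l in p_F.support:
        if l < max(len1, len2):
            continue  # a fragment cannot be shorter than either of its ends
        valid = sum(max(0, n - l + 1) for n in contig_lengths)
        if valid == 0:
            continue
        base = p_F.pmf(l) * (1.0 / valid) * 0.5
        for contig in assembly.contigs:
            seq = contig.sequence
            for s in range(0, contig.length - l + 1):
                # Error rates are indexed by machine cycle, so each end is
                # compared against its reference window in read orientation
                # (window reverse-complemented for reverse-strand ends).
                # fragment on "+": end1 forward at s, end2 on the reverse
                # strand at the fragment's right edge
                p1, m1 = _end_probability_and_edits(end1, seq[s : s + len1], em)
                p2, m2 = _end_probability_and_edits(
                    end2, reverse_complement(seq[s + l - len2 : s + l]), em
                )
                if m1 + m2 <= max_edits:
                    terms.append(base * p1 * p2)
                # fragment on "-": mirrored
                p1, m1 = _end_probability_and_edits(
                    end1, reverse_complement(seq[s + l - len1 : s + l]), em
                )
                p2, m2 = _end_probability_and_edits(end2, seq[s : s + len2], em)
                if m1 + m2 <= max_edits:
                    terms.append(base * p1 * p2)
    total = math.fsum(terms)
    if total <= 0.0:
        return float("-inf")
    return math.log(total)
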