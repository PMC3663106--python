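"""Fragment-length distribution (empirical) and uniform start-site model.

Insert-size distributions depend on library size selection and are often
not well approximated by standard parametric families, so the fragment
length pmf p_F is learned as the (optionally Laplace-smoothed) empirical
distribution over uniquely mapped pairs.  Fragment start sites are modelled
as uniform over every position, on every contig, where a fragment of the
given length fits; the number of such positions shrinks as total assembly
length grows, which is the mechanism that penalises inflated assemblies.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .io_formats import AssemblyIndex, MappingRecord

_NEG_INF = float("-inf")


class FragmentLengthDistribution:
    """Probability mass function over fragment lengths (bases)."""

    def __init__(self, pmf: dict[int, float]):
        pmf = {int(l): float(p) for l, p in pmf.items() if p > 0.0}
        if not pmf:
            raise ValueError("empty fragment length pmf")
        total = math.fsum(pmf.values())
        if abs(total - 1.0) > 1e-9:
            pmf = {l: p / total for l, p in pmf.items()}
        self._pmf = pmf
        self._log = {l: math.log(p) for l, p in pmf.items()}
        self.support_min = min(pmf)
        self.support_max = max(pmf)

    def pmf(self, length: int) -> float:
        return self._pmf.get(length, 0.0)

    def log_pmf(self, length: int) -> float:
        return self._log.get(length, _NEG_INF)

    @property
    def support(self) -> list[int]:
        return sorted(self._pmf)

    def items(self):
        return sorted(self._pmf.items())

    def mean(self) -> float:
        return math.fsum(l * p for l, p in self._pmf.items())

    def sd(self) -> float:
        m = self.mean()
        return math.sqrt(math.fsum((l - m) ** 2 * p for l, p in self._pmf.items()))

    def mode(self) -> int:
        # deterministic tie-break: smallest length among maxima
        best = max(self._pmf.values())
        return min(l for l, p in self._pmf.items() if p == best)

    def to_table(self, path) -> None:
        """Two-column text table (length, probability) for inspection/reuse."""
        with open(path, "w") as fh:
            fh.write("length\tprobability\n")
            for l, p in self.items():
                fh.write(f"{l}\t{p!r}\n")

    @classmethod
    def from_table(cls, path) -> "FragmentLengthDistribution":
        pmf = {}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                l, p = line.split()
                pmf[int(l)] = float(p)
        return cls(pmf)

    @classmethod
    def from_lengths(cls, lengths: Iterable[int], pseudocount: float = 1.0) -> "FragmentLengthDistribution":
        lengths = list(lengths)
        if not lengths:
            raise ValueError("no fragment lengths")
        lo, hi = min(lengths), max(lengths)
        window = hi - lo + 1
        n = len(lengths)
        counts: dict[int, int] = {}
        for l in lengths:
            counts[l] = counts.get(l, 0) + 1
        denom = n + pseudocount * window
        pmf = {
            l: (counts.get(l, 0) + pseudocount) / denom
            for l in range(lo, hi + 1)
            if counts.get(l, 0) + pseudocount > 0
        }
        return cls(pmf)


def learn_fragment_lengths(
    unique_mappings: Iterable[MappingRecord], pseudocount: float = 1.0
) -> FragmentLengthDistribution:
    """Empirical fragment-length pmf from uniquely mapped pairs.

    Laplace smoothing with ``pseudocount`` spreads mass over the whole
    observed [min, max] window so no observed-range fragment length gets
    probability zero.
    """
    lengths = [r.fragment_length for r in unique_mappings]
    if not lengths:
        raise ValueError("no uniquely mapped pairs; cannot learn p_F")
    return FragmentLengthDistribution.from_lengths(lengths, pseudocount)


class StartSiteModel:
    """Uniform fragment-start distribution conditioned on fragment length.

    For a fragment of length l the admissible forward-strand start sites
    number max(0, length - l + 1) on each contig; p_S(s | l) is uniform
    over their total.  Strand choice is handled separately (a fair 1/2
    factor per placement in the likelihood engine).
    """

    def __init__(self, assembly: AssemblyIndex):
        self.assembly = assembly
        self._lengths = np.array([c.length for c in assembly.contigs], dtype=np.int64)
        self._cache: dict[int, int] = {}

    def valid_sites(self, fragment_length: int) -> int:
        if fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        v = self._cache.get(fragment_length)
        if v is None:
            v = int(np.maximum(self._lengths - fragment_length + 1, 0).sum())
            self._cache[fragment_length] = v
        return v

    def p_start(self, fragment_length: int) -> float:
        v = self.valid_sites(fragment_length)
        return 1.0 / v if v > 0 else 0.0

    def log_p_start(self, fragment_length: int) -> float:
        v = self.valid_sites(fragment_length)
        return -math.log(v) if v > 0 else _NEG_INF


def p_start(model: StartSiteModel, fragment_length: int) -> float:
    """Probability of any single admissible start site for this length."""
    return model.p_start(fragment_length)
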