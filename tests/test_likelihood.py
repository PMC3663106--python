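"""Per-read probabilities (sum over mappings) and total log likelihood."""

import math

import numpy as np
import pytest

from asmlik.error_model import ErrorModel
from asmlik.fragment_model import FragmentLengthDistribution, StartSiteModel
from asmlik.io_formats import AssemblyIndex, Contig, MappingRecord, RoutedReadSet
from asmlik.likelihood import (
    mapping_log_term,
    per_read_probability,
    total_log_likelihood,
)
from asmlik.mapper import exhaustive_pair_mappings
from asmlik.oracle import brute_force_log_probability
from asmlik.simulator import SimulationConfig, simulate_reads, truths_to_routed

from conftest import random_genome


def _one_base_record(pid="p", frag=41, contig="a"):
    return MappingRecord(pid, contig, 0, frag, "FR", "+", (), (), "A", "A")


@pytest.fixture
def simple_models():
    asm = AssemblyIndex([Contig("a", "A" * 100), Contig("b", "A" * 50)])
    p_F = FragmentLengthDistribution({41: 0.5, 42: 0.5})
    p_S = StartSiteModel(asm)
    p_E = ErrorModel.uniform(1, 0.01, 0.0, 0.0)  # 1 bp ends, match prob 0.99
    return asm, p_F, p_S, p_E


class TestPerReadProbability:
    def test_single_mapping_product(self, simple_models):
        _, p_F, p_S, p_E = simple_models
        prl = per_read_probability([_one_base_record()], p_F, p_S, p_E)
        # p_F = 0.5, p_S = 1/70, strand 1/2, p_E = 0.99^2 = 0.9801
        assert prl.log_probability == pytest.approx(math.log(0.5 * (1 / 70) * 0.5 * 0.9801))
        assert prl.log_probability == pytest.approx(-5.65489, abs=1e-5)
        assert prl.n_mappings == 1 and prl.category == "mapped"

    def test_two_identical_mappings_add(self, simple_models):
        _, p_F, p_S, p_E = simple_models
        one = per_read_probability([_one_base_record()], p_F, p_S, p_E)
        two = per_read_probability([_one_base_record(), _one_base_record()], p_F, p_S, p_E)
        assert two.log_probability == pytest.approx(one.log_probability + math.log(2))

    def test_unsupported_fragment_length_skipped(self, simple_models):
        _, p_F, p_S, p_E = simple_models
        good = _one_base_record(frag=41)
        bad = _one_base_record(frag=60)  # outside p_F support
        both = per_read_probability([good, bad], p_F, p_S, p_E)
        only = per_read_probability([good], p_F, p_S, p_E)
        assert both.log_probability == pytest.approx(only.log_probability)
        assert per_read_probability([bad], p_F, p_S, p_E) is None  # -> rescue

    def test_log_sum_exp_extremes(self, simple_models):
        """Terms spanning the full double range combine without under- or
        overflow."""
        asm, _, p_S, p_E = simple_models
        p_F = FragmentLengthDistribution({41: 1e-300, 42: 1.0 - 1e-300})
        tiny = _one_base_record(frag=41)
        big = _one_base_record(frag=42)
        t_tiny = mapping_log_term(tiny, p_F, p_S, p_E)
        t_big = mapping_log_term(big, p_F, p_S, p_E)
        assert t_tiny < -690 and math.isfinite(t_tiny)
        prl = per_read_probability([tiny, big], p_F, p_S, p_E)
        assert math.isfinite(prl.log_probability)
        assert prl.log_probability == pytest.approx(np.logaddexp(t_tiny, t_big))

    def test_matches_brute_force_oracle(self, rng):
        """Mapping-based per-read value equals exhaustive enumeration of the
        generative sum truncated at the same edit budget."""
        genome = random_genome(rng, [70, 60])
        cfg = SimulationConfig(n_pairs=8, read_length=8, fragment_mean=30, fragment_sd=4,
                               sub_rate=0.03, ins_rate=0.0, del_rate=0.0, seed=21)
        pairs, _ = simulate_reads(genome, cfg)
        p_F = FragmentLengthDistribution(
            {l: math.exp(-((l - 30.0) ** 2) / 32.0) for l in range(16, 45)}
        )
        p_S = StartSiteModel(genome)
        em = ErrorModel.uniform(8, 0.02, 0.0, 0.0)
        p_E_checked = 0
        for d in (0, 1, 2):
            for pair in pairs:
                recs = exhaustive_pair_mappings(genome, pair, d, p_F.support_min, p_F.support_max)
                oracle = brute_force_log_probability(genome, pair, p_F, em, d)
                if not recs:
                    assert oracle == float("-inf")
                    continue
                prl = per_read_probability(recs, p_F, p_S, em)
                assert abs(math.exp(prl.log_probability - oracle) - 1.0) < 1e-10
                p_E_checked += 1
        assert p_E_checked > 10


class TestTotalLogLikelihood:
    def _routed(self, n, frag=41):
        routed = RoutedReadSet()
        for i in range(n):
            routed.both_mapped[f"p{i}"] = [_one_base_record(f"p{i}", frag)]
        return routed

    def test_total_is_sum_of_per_read(self, simple_models):
        _, p_F, p_S, p_E = simple_models
        routed = self._routed(3)
        per = per_read_probability(routed.both_mapped["p0"], p_F, p_S, p_E)
        report = total_log_likelihood(routed, p_F, p_S, p_E)
        assert report.total_log_likelihood == pytest.approx(3 * per.log_probability)
        assert report.n_reads == 3

    def test_duplicating_reads_doubles_total(self, rng):
        genome = random_genome(rng, [800])
        cfg = SimulationConfig(n_pairs=25, read_length=20, fragment_mean=100, fragment_sd=10, seed=31)
        _, truths = simulate_reads(genome, cfg)
        routed = truths_to_routed(truths)
        doubled = RoutedReadSet()
        for pid, recs in routed.both_mapped.items():
            doubled.both_mapped[pid + "a"] = recs
            doubled.both_mapped[pid + "b"] = recs
        p_F = FragmentLengthDistribution.from_lengths([t.fragment_length for t in truths])
        p_S = StartSiteModel(genome)
        em = ErrorModel.uniform(20)
        r1 = total_log_likelihood(routed, p_F, p_S, em)
        r2 = total_log_likelihood(doubled, p_F, p_S, em)
        assert r2.total_log_likelihood == pytest.approx(2 * r1.total_log_likelihood, rel=1e-12)

    def test_contig_order_invariance(self, rng):
        genome = random_genome(rng, [300, 200])
        cfg = SimulationConfig(n_pairs=20, read_length=20, fragment_mean=90, fragment_sd=8, seed=32)
        _, truths = simulate_reads(genome, cfg)
        routed = truths_to_routed(truths)
        p_F = FragmentLengthDistribution.from_lengths([t.fragment_length for t in truths])
        em = ErrorModel.uniform(20)
        permuted = AssemblyIndex(list(reversed(genome.contigs)))
        r1 = total_log_likelihood(routed, p_F, StartSiteModel(genome), em)
        r2 = total_log_likelihood(routed, p_F, StartSiteModel(permuted), em)
        assert r1.total_log_likelihood == pytest.approx(r2.total_log_likelihood, rel=1e-14)

    def test_junk_contig_strictly_lowers_likelihood(self, rng):
        """Appending an unused contig shrinks every placement's start-site
        probability, so the total drops for any read set."""
        genome = random_genome(rng, [1000])
        cfg = SimulationConfig(n_pairs=30, read_length=20, fragment_mean=100, fragment_sd=10, seed=33)
        _, truths = simulate_reads(genome, cfg)
        routed = truths_to_routed(truths)
        p_F = FragmentLengthDistribution.from_lengths([t.fragment_length for t in truths])
        em = ErrorModel.uniform(20)
        inflated = AssemblyIndex(
            list(genome.contigs) + [Contig("junk", random_genome(rng, [400]).contigs[0].sequence)]
        )
        r1 = total_log_likelihood(routed, p_F, StartSiteModel(genome), em)
        r2 = total_log_likelihood(routed, p_F, StartSiteModel(inflated), em)
        assert r2.total_log_likelihood < r1.total_log_likelihood

    def test_missing_rescue_errors(self, simple_models):
        _, p_F, p_S, p_E = simple_models
        routed = self._routed(1)
        routed.neither_mapped.append("lost")
        with pytest.raises(ValueError, match="rescue"):
            total_log_likelihood(routed, p_F, p_S, p_E)
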