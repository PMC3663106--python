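"""Learning and evaluating the position-specific error model."""

import math

import numpy as np
import pytest

from asmlik.error_model import ErrorModel, learn_error_model, p_error, p_error_pair
from asmlik.io_formats import Edit, MappingRecord
from asmlik.simulator import SimulationConfig, simulate_reads, truths_to_routed

from conftest import random_genome


def _rec(pid, ed1, ref1, ed2, ref2):
    return MappingRecord(pid, "c", 0, 100, "FR", "+", tuple(ed1), tuple(ed2), ref1, ref2)


class TestLearning:
    def test_single_substitution_counting(self):
        # 100 gapless reads of length 4, one A->G substitution at position 3
        recs = []
        for i in range(100):
            if i == 0:
                recs.append(_rec(f"p{i}", [Edit(3, "sub", "A", "G", 1)], "CCTA", [], "CCTA"))
            else:
                recs.append(_rec(f"p{i}", [], "CCTA", [], "CCTA"))
        em = learn_error_model(recs, pseudocount=0)
        n_a_at_3 = 200  # both ends of every record show ref A at position 3
        assert em.sub_rate(3, "A", "G") == pytest.approx(1 / n_a_at_3)
        assert em.sub_rate(3, "A", "C") == 0.0
        assert em.sub_rate(2, "T", "G") == 0.0

    def test_no_indels_observed(self):
        recs = [_rec("p", [], "ACGT", [], "ACGT")]
        em = learn_error_model(recs, pseudocount=0)
        assert np.all(em.ins == 0) and np.all(em.dele == 0)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="cannot learn"):
            learn_error_model([])

    def test_local_normalization(self, rng):
        genome = random_genome(rng, [3000])
        cfg = SimulationConfig(n_pairs=300, read_length=30, fragment_mean=100, fragment_sd=10, seed=8)
        _, truths = simulate_reads(genome, cfg)
        em = learn_error_model(truths_to_routed(truths).unique_mappings())
        total = em.match + em.sub.sum(axis=2) + em.ins[:, None] + em.dele[:, None]
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_parameter_recovery_within_binomial_error(self, rng):
        """Per-position substitution rates learned from simulated reads sit
        within 3 binomial standard errors of the simulator's true rate."""
        genome = random_genome(rng, [20000])
        true_sub = 0.01
        cfg = SimulationConfig(n_pairs=8000, read_length=30, fragment_mean=120, fragment_sd=10,
                               sub_rate=true_sub, ins_rate=0.0, del_rate=0.0, seed=9)
        _, truths = simulate_reads(genome, cfg)
        em = learn_error_model(truths_to_routed(truths).unique_mappings(), pseudocount=0)
        assert np.all(em.ins == 0) and np.all(em.dele == 0)
        # ref-base observation counts per position, from the truth log
        bi = {b: i for i, b in enumerate("ACGT")}
        den = np.zeros((cfg.read_length, 4))
        for t in truths:
            for ref in (t.end1_ref, t.end2_ref):
                for j, ch in enumerate(ref):
                    den[j, bi[ch]] += 1
        per_base = em.sub.sum(axis=2)  # (R, 4): total sub rate given ref base
        pooled = (per_base * den).sum(axis=1) / den.sum(axis=1)
        n_j = den.sum(axis=1)
        se = np.sqrt(true_sub * (1 - true_sub) / n_j)
        assert np.all(np.abs(pooled - true_sub) < 3 * se)

    def test_table_round_trip(self, tmp_path):
        em = ErrorModel.uniform(5, 0.01, 0.001, 0.002)
        em.to_table(tmp_path / "em.tsv")
        back = ErrorModel.from_table(tmp_path / "em.tsv")
        assert np.allclose(back.sub, em.sub)
        assert np.allclose(back.ins, em.ins)
        assert back.del_len_pmf == em.del_len_pmf


class TestPError:
    def test_error_free_product(self):
        # uniform total error 0.01/position, no indels, 2 bp per end
        em = ErrorModel.uniform(2, 0.01, 0.0, 0.0)
        rec = _rec("p", [], "AC", [], "GT")
        assert math.exp(p_error_pair(em, rec)) == pytest.approx(0.99**4)

    def test_single_substitution_value(self):
        sub = np.zeros((3, 4, 4))
        sub[:, :, :] = 0.01 / 3
        sub[0, 0, 2] = 0.002  # A->G at position 0
        for b in range(4):
            sub[:, b, b] = 0
        em = ErrorModel(sub, np.zeros(3), np.zeros(3), {1: 1.0}, {1: 1.0})
        edits = [Edit(0, "sub", "A", "G", 1)]
        lp = p_error(em, edits, "ATT")
        m1 = em.match_prob(1, "T")
        m2 = em.match_prob(2, "T")
        assert math.exp(lp) == pytest.approx(0.002 * m1 * m2)

    def test_extra_mismatch_never_raises_probability(self, rng):
        em = ErrorModel.uniform(10, 0.01, 0.0005, 0.0005)
        ref = "ACGTACGTAC"
        clean = p_error(em, (), ref)
        worse = p_error(em, (Edit(4, "sub", "A", "T", 1),), ref)
        assert worse < clean

    def test_indel_factors(self):
        em = ErrorModel.uniform(6, 0.01, 0.002, 0.003, {1: 0.8, 2: 0.2}, {1: 0.7, 2: 0.3})
        lp = p_error(em, (Edit(2, "ins", "-", "TT", 2),), "AC--GT")
        expect = (
            em.match_prob(0, "A") * em.match_prob(1, "C") * (0.002 * 0.2)
            * em.match_prob(4, "G") * em.match_prob(5, "T")
        )
        assert math.exp(lp) == pytest.approx(expect)
        lp = p_error(em, (Edit(3, "del", "AA", "", 2),), "ACGT")
        expect = (
            em.match_prob(0, "A") * em.match_prob(1, "C") * em.match_prob(2, "G")
            * (0.003 * 0.3)  # deletion consumes position 3's slot
        )
        assert math.exp(lp) == pytest.approx(expect)

    def test_n_columns_contribute_quarter(self):
        em = ErrorModel.uniform(3, 0.01, 0.0, 0.0)
        lp = p_error(em, (), "ANG")
        assert math.exp(lp) == pytest.approx(em.match_prob(0, "A") * 0.25 * em.match_prob(2, "G"))

    def test_edit_beyond_read_length_errors(self):
        em = ErrorModel.uniform(4, 0.01, 0.001, 0.001)
        with pytest.raises(ValueError, match="read length"):
            p_error(em, (Edit(7, "sub", "A", "C", 1),), "ACGT")

    def test_global_normalization_one_base(self):
        """For a 1-base reference and 1-base read with no indels, summing
        p_E over the four possible read bases gives exactly 1."""
        em = ErrorModel.uniform(1, 0.013, 0.0, 0.0)
        total = 0.0
        for b in "ACGT":
            if b == "A":
                total += math.exp(p_error(em, (), "A"))
            else:
                total += math.exp(p_error(em, (Edit(0, "sub", "A", b, 1),), "A"))
        assert total == pytest.approx(1.0, abs=1e-15)

    def test_position_independence_factorization(self):
        """Moving the same edit between positions changes the value only
        through the position-indexed rates."""
        sub = np.zeros((4, 4, 4))
        rates = [0.004, 0.008, 0.012, 0.016]
        for j, r in enumerate(rates):
            sub[j, :, :] = r / 3
            for b in range(4):
                sub[j, b, b] = 0
        em = ErrorModel(sub, np.zeros(4), np.zeros(4), {1: 1.0}, {1: 1.0})
        ref = "AAAA"
        for j in range(4):
            lp = p_error(em, (Edit(j, "sub", "A", "C", 1),), ref)
            expect = math.fsum(
                math.log(em.match_prob(k, "A")) for k in range(4) if k != j
            ) + math.log(rates[j] / 3)
            assert lp == pytest.approx(expect)
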