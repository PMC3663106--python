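"""Smith-Waterman alignment and rescue of unmapped pairs."""

import math
from functools import lru_cache

import numpy as np
import pytest

from asmlik.error_model import ErrorModel
from asmlik.fragment_model import FragmentLengthDistribution, StartSiteModel
from asmlik.io_formats import ReadPair, reverse_complement
from asmlik.likelihood import per_read_probability
from asmlik.mapper import exhaustive_pair_mappings
from asmlik.rescue import (
    SWScores,
    best_local_alignment,
    rescue_pair_log_probability,
    rescue_sample,
    smith_waterman,
)

from conftest import random_genome, random_sequence


def sw_score_oracle(read: str, target: str, scores: SWScores) -> int:
    """Independent affine-gap local alignment score by memoized recursion
    over (i, j, state); exponential-free but quadratic, for tiny inputs."""

    @lru_cache(maxsize=None)
    def best(i, j, state):  # best score of an alignment ENDING at (i, j) in state
        if state == "M":
            s = scores.match if read[i] == target[j] else scores.mismatch
            prev = 0
            if i > 0 and j > 0:
                prev = max(0, best(i - 1, j - 1, "M"), best(i - 1, j - 1, "E"), best(i - 1, j - 1, "F"))
            return prev + s
        if state == "E":  # gap in read, consumes target[j]
            cands = []
            if j > 0:
                cands.append(best(i, j - 1, "E") + scores.gap_extend)
                if i >= 0:
                    cands.append(best(i, j - 1, "M") + scores.gap_open)
            return max(cands, default=-(10**9))
        # "F": gap in target, consumes read[i]
        cands = []
        if i > 0:
            cands.append(best(i - 1, j, "F") + scores.gap_extend)
            cands.append(best(i - 1, j, "M") + scores.gap_open)
        return max(cands, default=-(10**9))

    m = 0
    for i in range(len(read)):
        for j in range(len(target)):
            m = max(m, best(i, j, "M"), best(i, j, "E"), best(i, j, "F"))
    return m


class TestSmithWaterman:
    def test_exact_substring(self):
        aln = smith_waterman("ACGT", "TTACGTTT")
        assert aln.score == 4
        assert aln.target_start == 2 and aln.read_start == 0
        assert all(a == b for a, b in aln.columns)

    def test_single_mismatch_vs_shorter_run(self):
        aln = smith_waterman("ACGT", "TTAGGTTT")
        assert aln.score == 2  # A c/g G T with one mismatch: 1 - 1 + 1 + 1

    def test_affine_gap_scoring(self):
        # read spans a 2-base deletion in the target: 8 matches - (open+extend)
        aln = smith_waterman("AAAATTTT", "AAAACGTTTT")
        assert aln.score == 8 + (-2) + (-1)
        kinds = [(a is None, b is None) for a, b in aln.columns]
        assert (True, False) in kinds  # gap in read

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT")

    def test_tie_breaks_to_smallest_target_start(self):
        aln = smith_waterman("ACG", "ACGTTACG")
        assert aln.score == 3 and aln.target_start == 0

    def test_matches_dp_oracle_on_random_inputs(self, rng):
        scores = SWScores()
        for _ in range(40):
            read = random_sequence(rng, int(rng.integers(3, 10)))
            target = random_sequence(rng, int(rng.integers(3, 16)))
            assert smith_waterman(read, target, scores).score == sw_score_oracle(
                read, target, scores
            )

    def test_reverse_strand_found_via_search(self, rng):
        genome = random_genome(rng, [200])
        read = reverse_complement(genome.contigs[0].sequence[50:75])
        hit = best_local_alignment(read, genome)
        assert hit.aligned and hit.strand == "-"
        assert hit.alignment.target_start == 50
        assert hit.alignment.score == 25


@pytest.fixture
def rescue_setup(rng):
    genome = random_genome(rng, [2000])
    p_F = FragmentLengthDistribution.from_lengths(
        list(np.rint(rng.normal(100, 8, 400)).astype(int))
    )
    p_S = StartSiteModel(genome)
    p_E = ErrorModel.uniform(20, 0.01, 0.001, 0.001)
    return genome, p_F, p_S, p_E


def _pairs_from(genome, starts, frag=100, rlen=20):
    seq = genome.contigs[0].sequence
    return [
        ReadPair(f"u{i:03d}", seq[s : s + rlen], reverse_complement(seq[s + frag - rlen : s + frag]))
        for i, s in enumerate(starts)
    ]


class TestRescueSample:
    def test_identical_pairs_impute_their_common_value(self, rescue_setup):
        genome, p_F, p_S, p_E = rescue_setup
        base = _pairs_from(genome, [100])[0]
        pool = [ReadPair(f"dup{i}", base.end1_sequence, base.end2_sequence) for i in range(6)]
        res = rescue_sample(pool, genome, p_F, p_S, p_E, sample_size=3, seed=1)
        vals = list(res.per_pair_log_probability.values())
        assert all(v == pytest.approx(vals[0]) for v in vals)
        assert res.imputed_log_probability == pytest.approx(vals[0])

    def test_full_sample_gives_exact_mean(self, rescue_setup):
        genome, p_F, p_S, p_E = rescue_setup
        pool = _pairs_from(genome, [50, 300, 700, 1200])
        res = rescue_sample(pool, genome, p_F, p_S, p_E, sample_size=10, seed=2)
        assert res.sample_size == 4
        mean = math.fsum(res.per_pair_log_probability.values()) / 4
        assert res.imputed_log_probability == pytest.approx(mean)

    def test_bit_identical_given_seed_and_threads(self, rescue_setup):
        genome, p_F, p_S, p_E = rescue_setup
        pool = _pairs_from(genome, list(range(40, 1500, 60)))
        a = rescue_sample(pool, genome, p_F, p_S, p_E, sample_size=8, seed=7, threads=1)
        b = rescue_sample(pool, genome, p_F, p_S, p_E, sample_size=8, seed=7, threads=3)
        assert a.sampled_pair_ids == b.sampled_pair_ids
        assert a.per_pair_log_probability == b.per_pair_log_probability
        assert a.imputed_log_probability == b.imputed_log_probability

    def test_seed_changes_sample_but_mean_is_stable(self, rescue_setup):
        genome, p_F, p_S, p_E = rescue_setup
        pool = _pairs_from(genome, list(range(30, 1700, 35)))
        a = rescue_sample(pool, genome, p_F, p_S, p_E, sample_size=12, seed=1)
        b = rescue_sample(pool, genome, p_F, p_S, p_E, sample_size=12, seed=2)
        vals = list(a.per_pair_log_probability.values())
        sem = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert a.sampled_pair_ids != b.sampled_pair_ids
        assert abs(a.imputed_log_probability - b.imputed_log_probability) < max(3 * 2 * sem, 1e-9)

    def test_rescue_never_beats_mapping(self, rescue_setup):
        """A pair scored through rescue gets at most the probability the
        mapping path would have assigned it."""
        genome, p_F, p_S, p_E = rescue_setup
        for pair in _pairs_from(genome, [200, 900]):
            lp, detail = rescue_pair_log_probability(pair, genome, p_F, p_S, p_E)
            recs = exhaustive_pair_mappings(
                genome, pair, 4, p_F.support_min, p_F.support_max
            )
            mapped = per_read_probability(recs, p_F, p_S, p_E)
            assert detail["co_placed"]
            assert lp <= mapped.log_probability + 1e-9

    def test_empty_pool(self, rescue_setup):
        genome, p_F, p_S, p_E = rescue_setup
        res = rescue_sample([], genome, p_F, p_S, p_E, sample_size=5, seed=0)
        assert res.sample_size == 0 and res.sampled_pair_ids == []
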