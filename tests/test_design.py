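"""Designer: biased initialization, refinement, batches, statistics."""

import math

import numpy as np
import pytest

from pzfold.alphabet import CANONICAL_DNA, DNA_PZ
from pzfold.design import (
    DesignConfig,
    SelectionBias,
    design_batch,
    initialize_sequence,
    paired_comparison,
    refine,
)
from pzfold.energy import SecondaryStructure
from pzfold.folding import ned, partition_function
from pzfold.structio import parse_dotbracket


def hairpin_target(stem=10, loop=4):
    return parse_dotbracket("(" * stem + "." * loop + ")" * stem)


class TestSelectionBias:
    def test_defaults(self):
        pz = SelectionBias.default(DNA_PZ)
        assert pz.pair_weights == {"PZ": 0.20, "GC": 0.50, "AT": 0.30}
        assert pz.loop_weights == {"A": 0.60, "C": 0.10, "G": 0.10, "T": 0.20}
        dna = SelectionBias.default(CANONICAL_DNA)
        assert dna.pair_weights == {"GC": 0.50, "AT": 0.50}

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SelectionBias({"GC": 0.6, "AT": 0.6},
                          {"A": 0.6, "C": 0.1, "G": 0.1, "T": 0.2})

    def test_pz_never_in_loops(self):
        with pytest.raises(ValueError, match="never selected for loops"):
            SelectionBias({"GC": 1.0}, {"P": 1.0})


class TestInitialization:
    def test_loop_frequencies_match_weights(self):
        target = SecondaryStructure(10_000, frozenset())
        bias = SelectionBias.default(DNA_PZ)
        rng = np.random.default_rng(0)
        seq = initialize_sequence(target, bias, rng)
        counts = {b: str(seq).count(b) for b in "ACGT"}
        n = len(seq)
        for b, w in bias.loop_weights.items():
            sigma = math.sqrt(n * w * (1 - w))
            assert abs(counts[b] - n * w) < 3 * sigma
        assert "P" not in str(seq) and "Z" not in str(seq)

    def test_pair_frequencies_match_weights(self):
        stem = 5000
        target = parse_dotbracket("(" * stem + "...." + ")" * stem)
        bias = SelectionBias.default(DNA_PZ)
        rng = np.random.default_rng(1)
        seq = initialize_sequence(target, bias, rng)
        kinds = {"PZ": 0, "GC": 0, "AT": 0}
        for i in range(stem):
            j = target.length - 1 - i
            pair = frozenset((seq[i], seq[j]))
            if pair == frozenset("PZ"):
                kinds["PZ"] += 1
            elif pair == frozenset("GC"):
                kinds["GC"] += 1
            elif pair == frozenset("AT"):
                kinds["AT"] += 1
        for k, w in (("PZ", 0.20), ("GC", 0.50), ("AT", 0.30)):
            sigma = math.sqrt(stem * w * (1 - w))
            assert abs(kinds[k] - stem * w) < 3 * sigma

    def test_same_seed_same_sequence(self):
        target = hairpin_target()
        bias = SelectionBias.default(DNA_PZ)
        s1 = initialize_sequence(target, bias, np.random.default_rng(5))
        s2 = initialize_sequence(target, bias, np.random.default_rng(5))
        assert str(s1) == str(s2)

    def test_degenerate_bias_all_gc(self):
        target = hairpin_target()
        bias = SelectionBias({"GC": 1.0},
                             {"A": 0.6, "C": 0.1, "G": 0.1, "T": 0.2})
        seq = initialize_sequence(target, bias, np.random.default_rng(2))
        for i, j in target.pairs:
            assert frozenset((seq[i], seq[j])) == frozenset("GC")


class TestRefine:
    def test_hairpin_reaches_threshold(self, em_pz):
        target = parse_dotbracket("((((((((((....))))))))))")
        cfg = DesignConfig(seed=11, ned_threshold=0.05, max_iterations=500)
        rng = np.random.default_rng(11)
        seq0 = initialize_sequence(target, SelectionBias.default(DNA_PZ), rng)
        res = refine(seq0, target, cfg, em_pz, rng=rng, seed_used=11)
        assert res.ned <= 0.05
        assert res.iterations_used <= 500

    def test_reported_ned_matches_independent_recomputation(self, em_pz):
        target = hairpin_target(6)
        cfg = DesignConfig(seed=12, ned_threshold=0.05, max_iterations=100)
        rng = np.random.default_rng(12)
        seq0 = initialize_sequence(target, SelectionBias.default(DNA_PZ), rng)
        res = refine(seq0, target, cfg, em_pz, rng=rng, seed_used=12)
        again = ned(str(res.sequence), target, params=em_pz)
        assert res.ned == pytest.approx(again.ned, abs=1e-12)

    def test_threshold_one_returns_after_initialization(self, em_pz):
        target = hairpin_target(6)
        cfg = DesignConfig(seed=13, ned_threshold=1.0)
        rng = np.random.default_rng(13)
        seq0 = initialize_sequence(target, SelectionBias.default(DNA_PZ), rng)
        res = refine(seq0, target, cfg, em_pz, rng=rng, seed_used=13)
        assert res.iterations_used == 0

    def test_trajectory_non_increasing(self, em_pz):
        target = hairpin_target(8)
        cfg = DesignConfig(seed=14, ned_threshold=0.001, max_iterations=60)
        rng = np.random.default_rng(14)
        seq0 = initialize_sequence(target, SelectionBias.default(DNA_PZ), rng)
        res = refine(seq0, target, cfg, em_pz, rng=rng, seed_used=14)
        assert all(b <= a + 1e-12 for a, b in zip(res.trajectory,
                                                  res.trajectory[1:]))

    def test_structure_consistency_enforced(self, em_pz):
        target = hairpin_target(4)
        from pzfold.alphabet import parse_sequence

        bad = parse_sequence("GGGGAAAATCCC")  # G-T at an intended pair
        with pytest.raises(ValueError, match="inconsistent"):
            refine(bad, target, DesignConfig(seed=1), em_pz)

    def test_isolated_pair_gate(self, em_pz):
        target = parse_dotbracket("(....)")
        cfg = DesignConfig(seed=1, allow_isolated_pairs=False)
        rng = np.random.default_rng(1)
        seq0 = initialize_sequence(target, SelectionBias.default(DNA_PZ), rng)
        with pytest.raises(ValueError, match="isolated"):
            refine(seq0, target, cfg, em_pz, rng=rng)


class TestBatch:
    def test_batch_summary_and_determinism(self, em_pz):
        target = hairpin_target(6)
        cfg = DesignConfig(seed=21, ned_threshold=0.05, max_iterations=40)
        b1 = design_batch(target, cfg, 3, em_pz)
        b2 = design_batch(target, cfg, 3, em_pz, seeds=b1["seeds"])
        assert len(b1["results"]) == 3
        assert b1["best_ned"] <= b1["mean_ned"]
        assert [str(r.sequence) for r in b1["results"]] == [
            str(r.sequence) for r in b2["results"]]
        assert [r.ned for r in b1["results"]] == [r.ned for r in b2["results"]]


class TestPairedComparison:
    def test_identical_paired_samples(self):
        a = [0.1, 0.2, 0.3, 0.4]
        rep = paired_comparison(a, list(a), kind="paired", alternative="less")
        assert math.isnan(rep["t"]) or rep["t"] == 0.0
        # scipy returns nan for zero variance; a tiny jitter gives t ~ 0
        rep = paired_comparison([0.1, 0.2, 0.3], [0.1001, 0.1999, 0.3],
                                kind="paired", alternative="less")
        assert 0.05 < rep["p"] < 0.95

    def test_welch_matches_closed_form(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 5.0, 6.0, 4.0])
        rep = paired_comparison(a, b, kind="welch", alternative="less")
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        assert rep["t"] == pytest.approx(t)
        assert rep["df"] == pytest.approx(df)

    def test_planted_shift_is_detected(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0.10, 0.01, size=20)
        a = b - 0.05
        rep = paired_comparison(a, b, kind="paired", alternative="less")
        assert rep["p"] < 1e-6
        assert rep["significant"]

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least two"):
            paired_comparison([1.0], [2.0])
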