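"""LLR/ORLLR statistics, per-read calling, consensus voting."""

import math

import numpy as np
import pytest
from scipy.stats import binom, norm

from xnacall.basecall import (
    OrllrParams,
    call_position,
    candidates_for,
    consensus_call,
    focal_xna_position,
    llr,
    orllr,
    sequence_log10_likelihood,
    statistic_scores,
)
from xnacall.kmer_model import CoverageError, decompose
from xnacall.levels_io import ReadLevelRecord
from xnacall.simulate import SimConfig, simulate_code, theoretical_recall

from conftest import build_heptamer_model, separated_pg_model


def pg_record(levels7, read_id="r1"):
    return ReadLevelRecord(read_id, "ref", "AAAPAAA", np.asarray(levels7, float), 12.0, 1.0)


def random_pg_setup(seed):
    """Random mus for the AAA(P|G)AAA kmers plus a random record."""
    rng = np.random.default_rng(seed)
    p_kmers = ["AAAP", "AAPA", "APAA", "PAAA"]
    g_kmers = ["AAAG", "AAGA", "AGAA", "GAAA"]
    mus = {k: rng.uniform(-2, 2) for k in p_kmers + g_kmers}
    model = build_heptamer_model(mus, sigma=0.4)
    levels = np.zeros(7)
    levels[1:5] = rng.uniform(-2, 2, size=4)
    return model, pg_record(levels), mus


# ------------------------------------------------------------- likelihood
class TestSequenceLikelihood:
    def test_levels_at_model_means_maximize(self):
        model, record, mus = random_pg_setup(0)
        peak_levels = np.zeros(7)
        for off, kmer in decompose("AAAPAAA", 3):
            peak_levels[3 - off] = mus[kmer]
        rec = pg_record(peak_levels)
        win = (0, 7)
        ll_p = sequence_log10_likelihood(rec, "AAAPAAA", model, win)
        ll_g = sequence_log10_likelihood(rec, "AAAGAAA", model, win)
        peak = 4 * math.log10(1 / (0.4 * math.sqrt(2 * math.pi)))
        assert ll_p == pytest.approx(peak)
        assert ll_p > ll_g

    def test_translation_invariance(self):
        model, record, mus = random_pg_setup(1)
        shifted_model = build_heptamer_model({k: mu + 1.5 for k, mu in mus.items()}, 0.4)
        shifted_rec = pg_record(record.levels + 1.5)
        a = sequence_log10_likelihood(record, "AAAPAAA", model, (0, 7))
        b = sequence_log10_likelihood(shifted_rec, "AAAPAAA", shifted_model, (0, 7))
        assert a == pytest.approx(b)

    def test_equals_per_kmer_product_in_log_space(self):
        """Independent oracle: the product of per-kmer normal densities,
        taken in log10."""
        model, record, mus = random_pg_setup(2)
        got = sequence_log10_likelihood(record, "AAAPAAA", model, (0, 7))
        expected = 0.0
        for off, kmer in decompose("AAAPAAA", 3):
            level = record.levels[3 - off]
            dens = norm.pdf(level, mus[kmer], 0.4)
            expected += math.log10(dens)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_missing_kmer_reported(self):
        model, record, _ = random_pg_setup(3)
        with pytest.raises(CoverageError, match="AAAT"):
            sequence_log10_likelihood(record, "AAATAAA", model, (0, 7))


# ------------------------------------------------------------- llr
class TestLlr:
    def test_antisymmetry(self):
        model, record, _ = random_pg_setup(4)
        assert llr(record, 3, "P", "G", model) == pytest.approx(
            -llr(record, 3, "G", "P", model), rel=1e-12
        )

    def test_levels_at_own_model_favor_it(self):
        model = separated_pg_model([0.5, 0.5, 0.5, 0.5])
        levels = np.zeros(7)
        levels[1:5] = 0.5  # exactly at the P-model means
        assert llr(pg_record(levels), 3, "P", "G", model) > 0

    def test_single_kmer_closed_form(self):
        """One discriminating kmer: LLR equals
        ((I-mu_j)^2 - (I-mu_i)^2) * log10(e) / (2 sigma^2)."""
        model = separated_pg_model([0.8, 0.0, 0.0, 0.0], sigma=0.4)
        levels = np.zeros(7)
        levels[1] = 0.3  # level of the +2 kmer AAAP; others at shared mean 0
        got = llr(pg_record(levels), 3, "P", "G", model)
        mu_i, mu_j, level = 0.8, 0.0, 0.3
        expected = ((level - mu_j) ** 2 - (level - mu_i) ** 2) * math.log10(math.e) / (2 * 0.4**2)
        assert got == pytest.approx(expected, rel=1e-12)


# ------------------------------------------------------------- orllr
def oracle_orllr(levels, mu_i, mu_j, sigma, params: OrllrParams):
    """Literal step-by-step evaluation of the printed formula, written
    independently of the implementation."""
    total = 0.0
    for I, mi, mj in zip(levels, mu_i, mu_j):
        p_i = 1.0 / (sigma * math.sqrt(2 * math.pi)) * math.exp(-((I - mi) ** 2) / (2 * sigma**2))
        p_j = 1.0 / (sigma * math.sqrt(2 * math.pi)) * math.exp(-((I - mj) ** 2) / (2 * sigma**2))
        llr_term = math.log10(p_i) - math.log10(p_j)
        sc_diff = I - (mi + mj) / 2.0
        mu_diff = abs(mi - mj)
        if mu_diff == 0:
            continue
        total += (
            math.exp(-(sc_diff**2) / (params.sf * sigma**2))
            * llr_term
            / (sigma**2 * mu_diff**params.sp * params.sf2)
        )
    return total


class TestOrllr:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_evaluation(self, seed):
        """Implementation agrees with a literal evaluation of the formula
        (Sf=4, Sf2=3, Sp=0.3) to 1e-12 on randomized inputs."""
        model, record, mus = random_pg_setup(seed)
        params = OrllrParams()
        got = orllr(record, 3, "P", "G", model, params)
        mu_i = [mus[k] for _, k in decompose("AAAPAAA", 3)]
        mu_j = [mus[k] for _, k in decompose("AAAGAAA", 3)]
        levels = [record.levels[3 - off] for off, _ in decompose("AAAPAAA", 3)]
        expected = oracle_orllr(levels, mu_i, mu_j, model.global_sigma, params)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_worked_single_kmer_value(self):
        """sigma=0.4, mu_i=0.5, mu_j=0.9, I=0.5: value agrees with the
        hand-evaluated formula."""
        model = build_heptamer_model(
            {"AAAP": 0.5, "AAPA": 0.0, "APAA": 0.0, "PAAA": 0.0,
             "AAAG": 0.9, "AAGA": 0.0, "AGAA": 0.0, "GAAA": 0.0},
            sigma=0.4,
        )
        levels = np.zeros(7)
        levels[1] = 0.5
        got = orllr(pg_record(levels), 3, "P", "G", model)
        expected = oracle_orllr([0.5], [0.5], [0.9], 0.4, OrllrParams())
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_per_kmer_sign_agrees_with_llr(self, seed):
        """All ORLLR scale factors are positive, so each kmer's ORLLR term
        has the sign of its LLR term; with a single active kmer the
        aggregate signs must agree."""
        rng = np.random.default_rng(100 + seed)
        mu_i, mu_j, level = rng.uniform(-2, 2, size=3)
        model = build_heptamer_model(
            {"AAAP": mu_i, "AAPA": 0.0, "APAA": 0.0, "PAAA": 0.0,
             "AAAG": mu_j, "AAGA": 0.0, "AGAA": 0.0, "GAAA": 0.0},
            sigma=0.4,
        )
        levels = np.zeros(7)
        levels[1] = level
        rec = pg_record(levels)
        assert np.sign(orllr(rec, 3, "P", "G", model)) == np.sign(llr(rec, 3, "P", "G", model))

    def test_midpoint_gives_zero(self):
        model = separated_pg_model([0.6, 0.6, 0.6, 0.6])
        levels = np.zeros(7)
        levels[1:5] = 0.3  # midpoint of the two models at every kmer
        assert orllr(pg_record(levels), 3, "P", "G", model) == pytest.approx(0.0, abs=1e-15)

    def test_degenerate_equal_means_contribute_zero(self):
        model = separated_pg_model([0.0, 0.0, 0.0, 0.0])  # mu_i == mu_j everywhere
        levels = np.zeros(7)
        levels[1:5] = 1.0
        assert orllr(pg_record(levels), 3, "P", "G", model) == 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            OrllrParams(sf=0)


# ------------------------------------------------------------- calling
class TestCallPosition:
    def test_levels_at_null_keep_null(self):
        model = separated_pg_model([1.5, 1.5, 1.5, 1.5])
        levels = np.zeros(7)
        levels[1:5] = 1.5
        res = call_position(pg_record(levels), 3, "P", ["G"], model)
        assert res.called_base == "P"

    def test_levels_at_candidate_call_candidate(self):
        model = separated_pg_model([1.5, 1.5, 1.5, 1.5])
        levels = np.zeros(7)  # exactly at the G-model means
        res = call_position(pg_record(levels), 3, "P", ["G"], model)
        assert res.called_base == "G"
        assert res.statistic_values["G"] > 0

    def test_decision_equals_argmax_likelihood(self):
        """With statistic=llr and threshold 0 the two-candidate decision
        coincides with the total-likelihood argmax."""
        for seed in range(25):
            model, record, _ = random_pg_setup(200 + seed)
            res = call_position(record, 3, "P", ["G"], model, statistic="llr")
            best = max(res.total_log10, key=lambda b: (res.total_log10[b], b))
            assert res.called_base == best

    def test_candidate_equal_null_skipped(self):
        model, record, _ = random_pg_setup(5)
        res = call_position(record, 3, "P", ["P", "G"], model)
        assert "P" not in res.statistic_values

    def test_threshold_raises_null_retention(self):
        model = separated_pg_model([0.3, 0.3, 0.3, 0.3])
        levels = np.zeros(7)
        res_default = call_position(pg_record(levels), 3, "P", ["G"], model)
        res_strict = call_position(pg_record(levels), 3, "P", ["G"], model, threshold=1e6)
        assert res_default.called_base == "G"
        assert res_strict.called_base == "P"

    def test_candidates_for_modes(self):
        assert candidates_for("P", "standard") == ["G"]
        assert candidates_for("B", "standard") == ["A"]
        assert set(candidates_for("P", "canonical")) == set("ATGC")
        assert len(candidates_for("P", "all")) == 11

    def test_focal_xna_position(self):
        assert focal_xna_position("AAAPAAA") == 3
        assert focal_xna_position("AAAGAAA") is None
        with pytest.raises(ValueError):
            focal_xna_position("APAPA")


class TestRecallOracle:
    def test_simulated_recall_matches_gaussian_oracle(self):
        """Per-read recall over 10^4 simulated reads agrees with
        Phi(sqrt(sum Delta^2)/(2 sigma)) within 3 binomial SEs."""
        deltas = [0.35, 0.35, 0.35, 0.35]
        model = separated_pg_model(deltas, sigma=0.4)
        n = 10_000
        table = simulate_code(model, "P", SimConfig(n_reads_per_heptamer=n, seed=13),
                              heptamers=["AAAPAAA"])
        scores = statistic_scores(table, 3, "P", "G", model)
        empirical = float(np.mean(scores > 0))
        expected = theoretical_recall(model, "AAAPAAA", "P", "G")
        assert expected == pytest.approx(norm.cdf(0.7 / 0.8))
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(empirical - expected) < 3 * se

    def test_vectorized_scores_match_per_read_llr(self, pz_model):
        table = simulate_code(pz_model, "P", SimConfig(n_reads_per_heptamer=5, seed=3),
                              heptamers=["ACGPTCA", "TTTPGGG"])
        scores = statistic_scores(table, 3, "P", "G", pz_model)
        manual = [llr(rec, 3, "P", "G", pz_model) for rec in table]
        assert np.allclose(scores, manual)
        scores_o = statistic_scores(table, 3, "P", "G", pz_model, statistic="orllr")
        manual_o = [orllr(rec, 3, "P", "G", pz_model) for rec in table]
        assert np.allclose(scores_o, manual_o)


# ------------------------------------------------------------- consensus
class TestConsensus:
    def make_calls(self, bases, name="ref", pos=3):
        from xnacall.basecall import CallResult

        return [
            CallResult(f"r{i}", name, pos, "P", b, "llr", {"G": 0.0}, {})
            for i, b in enumerate(bases)
        ]

    def test_unanimous(self):
        cc = consensus_call(self.make_calls(["P"] * 10))
        assert cc.called_base == "P" and cc.n_reads == 10

    def test_majority(self):
        cc = consensus_call(self.make_calls(["P"] * 6 + ["G"] * 4))
        assert cc.called_base == "P"

    def test_below_min_reads_no_call(self):
        cc = consensus_call(self.make_calls(["P"] * 9))
        assert cc.called_base is None

    def test_tie_no_call(self):
        cc = consensus_call(self.make_calls(["P"] * 5 + ["G"] * 5))
        assert cc.called_base is None

    def test_order_invariance(self):
        calls = self.make_calls(["P", "G", "P", "G", "P"] * 3)
        assert consensus_call(calls).called_base == consensus_call(calls[::-1]).called_base

    def test_consensus_recall_follows_binomial_majority(self):
        """For per-read recall r > 0.5 and odd n, consensus recall equals
        the exact binomial majority probability (and so exceeds r)."""
        deltas = [0.2, 0.2, 0.2, 0.2]
        model = separated_pg_model(deltas, sigma=0.4)
        r = theoretical_recall(model, "AAAPAAA", "P", "G")
        assert r > 0.5
        n_group, n_groups = 11, 1500
        table = simulate_code(
            model, "P", SimConfig(n_reads_per_heptamer=n_group * n_groups, seed=21),
            heptamers=["AAAPAAA"],
        )
        per_read = (statistic_scores(table, 3, "P", "G", model) > 0).reshape(n_groups, n_group)
        consensus_correct = (per_read.sum(axis=1) > n_group // 2).mean()
        exact = float(1 - binom.cdf(n_group // 2, n_group, r))
        assert exact >= r
        se = math.sqrt(exact * (1 - exact) / n_groups)
        assert abs(consensus_correct - exact) < 3 * se
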