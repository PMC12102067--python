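"""Engine correctness: forward/backward/Viterbi against exhaustive path
enumeration, log-space robustness, and Baum-Welch behaviour."""

import numpy as np
import pytest

from fibrilhmm.alphabet import NonCanonicalResidueError
from fibrilhmm.hmm import (
    NEG_INF,
    DegenerateCorpusError,
    HmmSpec,
    StateKind,
    backward,
    baum_welch,
    corpus_log_likelihood,
    forward,
    forward_batch,
    sample,
    viterbi,
)
from fibrilhmm.template import HmmBuildParams, build_initial_hmm

from helpers import (
    enumerate_paths,
    random_oracle_sequence,
    random_small_hmm,
    single_match_model,
    toy_three_state_model,
)


class TestForwardBackward:
    def test_certain_emission_has_probability_one(self):
        m = single_match_model("A")
        assert forward(m, "A") == pytest.approx(0.0, abs=1e-12)
        assert backward(m, "A") == pytest.approx(0.0, abs=1e-12)

    def test_impossible_emission_is_neg_inf_sentinel(self):
        m = single_match_model("A")
        assert forward(m, "C") == NEG_INF
        assert backward(m, "C") == NEG_INF
        assert viterbi(m, "C") == ([], NEG_INF)

    def test_toy_model_matches_enumeration(self):
        m = toy_three_state_model()
        for seq in ["AC", "AGC", "AGGW", "AAAC"]:
            log_total, _, _ = enumerate_paths(m, seq)
            assert forward(m, seq) == pytest.approx(log_total, abs=1e-10)
            assert backward(m, seq) == pytest.approx(log_total, abs=1e-10)

    def test_rejects_non_canonical_residue_with_position(self):
        m = single_match_model("A")
        with pytest.raises(NonCanonicalResidueError, match=r"'X' at position 2"):
            forward(m, "AX")
        with pytest.raises(ValueError):
            forward(m, "")

    def test_forward_batch_agrees_with_forward(self):
        m = toy_three_state_model()
        seqs = ["AGC", "AAC", "GGC", "AWW"]
        batched = forward_batch(m, seqs)
        singles = [forward(m, s) for s in seqs]
        assert np.allclose(batched, singles, atol=1e-10)

    def test_no_underflow_on_long_sequences(self, small_fixture):
        """A 300-residue query against a template model keeps a finite
        log-likelihood whenever a nonzero path exists."""
        model = build_initial_hmm(small_fixture.template)
        rng = np.random.default_rng(0)
        core = small_fixture.consensus_query
        pad = 300 - len(core)
        seq = core + "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, pad)
        )
        ll = forward(m := model, seq)
        assert np.isfinite(ll)
        assert backward(m, seq) == pytest.approx(ll, abs=1e-6)


class TestOracleEquivalence:
    def test_random_models_match_enumeration(self):
        """forward, backward and Viterbi agree with exhaustive enumeration on
        a battery of random small models and short sequences."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 60:
            m = random_small_hmm(rng)
            seq = random_oracle_sequence(rng)
            log_total, log_best, best_paths = enumerate_paths(m, seq)
            f = forward(m, seq)
            b = backward(m, seq)
            path, v = viterbi(m, seq)
            if log_total == NEG_INF:
                assert f == NEG_INF and b == NEG_INF and v == NEG_INF
            else:
                assert f == pytest.approx(log_total, abs=1e-8)
                assert b == pytest.approx(f, abs=1e-6)
                assert v == pytest.approx(log_best, abs=1e-8)
                assert path in best_paths
            checked += 1

    def test_viterbi_never_exceeds_forward(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = random_small_hmm(rng)
            seq = random_oracle_sequence(rng)
            _, v = viterbi(m, seq)
            f = forward(m, seq)
            assert v <= f + 1e-9


class TestViterbiDecoding:
    def test_consensus_decodes_to_all_match_path(self, clean_fixture):
        """With no noise, the gap-filled consensus query follows the match
        chain (plus missing-segment absorbers) in template order."""
        tdef = clean_fixture.template
        model = build_initial_hmm(tdef, HmmBuildParams())
        path, lp = viterbi(model, clean_fixture.consensus_query)
        match_positions = [
            model.state(s).template_position
            for s in path
            if model.state(s).kind is StateKind.MATCH
        ]
        assert match_positions == list(range(1, len(tdef.consensus) + 1))
        assert np.isfinite(lp)

    def test_deletion_detour_beats_mismatched_match(self):
        """When the middle residue fits the emitting-deletion state far
        better than the match state, the best path takes the detour."""
        m = toy_three_state_model()
        log_total, log_best, best_paths = enumerate_paths(m, "AGC")
        path, v = viterbi(m, "AGC")
        assert v == pytest.approx(log_best, abs=1e-10)
        assert path in best_paths
        assert "D1" in path


class TestBaumWelch:
    def test_inertia_one_is_identity(self, small_fixture):
        model = build_initial_hmm(small_fixture.template)
        seqs = list(small_fixture.corpus.values())[:5]
        out = baum_welch(model, seqs, inertia=1.0, stop_threshold=1e-3,
                         max_iterations=5)
        for s_old, s_new in zip(model.states, out.states):
            assert s_old.transitions == s_new.transitions
            assert s_old.emissions == s_new.emissions

    def test_training_recovers_perturbed_emissions(self, small_fixture):
        """Sequences sampled from the generating model pull a mismatched
        initial model's match emissions closer to the truth (L1)."""
        truth = small_fixture.truth_model  # match_emit 0.9
        start = build_initial_hmm(small_fixture.template,
                                  HmmBuildParams(match_emit=0.7,
                                                 mismatch_total=0.3))
        seqs = list(small_fixture.corpus.values())
        trained = baum_welch(start, seqs, inertia=0.5, stop_threshold=1e-2,
                             max_iterations=30)

        def match_l1(a: HmmSpec, b: HmmSpec) -> float:
            total, count = 0.0, 0
            for s in a.states:
                if s.kind is StateKind.MATCH:
                    other = b.state(s.id)
                    total += sum(
                        abs(s.emissions[aa] - other.emissions[aa])
                        for aa in s.emissions
                    )
                    count += 1
            return total / count

        assert match_l1(trained, truth) < match_l1(start, truth)

    def test_log_likelihood_never_decreases(self, small_fixture):
        """Accepted iterations are monotone in corpus log-likelihood even
        with the inertia term (the EM objective is concave in the rows)."""
        model = build_initial_hmm(small_fixture.template)
        seqs = list(small_fixture.corpus.values())[:10]
        lls = []
        cur = model
        for _ in range(5):
            lls.append(corpus_log_likelihood(cur, seqs))
            cur = baum_welch(cur, seqs, inertia=0.8, stop_threshold=1e-12,
                             max_iterations=1)
        lls.append(corpus_log_likelihood(cur, seqs))
        for a, b in zip(lls, lls[1:]):
            assert b >= a - 1e-6

    def test_degenerate_corpus_raises(self):
        model = single_match_model("A")
        with pytest.raises(DegenerateCorpusError, match="mismatch"):
            baum_welch(model, ["C", "CC"], inertia=0.5, stop_threshold=1.0)

    def test_update_preserves_probability_invariants(self, small_fixture):
        model = build_initial_hmm(small_fixture.template)
        seqs = list(small_fixture.corpus.values())[:8]
        out = baum_welch(model, seqs, inertia=0.9, stop_threshold=1e-9,
                         max_iterations=3)
        out.validate()


def test_sampled_sequences_have_finite_likelihood(small_fixture):
    rng = np.random.default_rng(5)
    seq, path = sample(small_fixture.truth_model, rng)
    assert len(seq) == len(path)
    assert np.isfinite(forward(small_fixture.truth_model, seq))
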