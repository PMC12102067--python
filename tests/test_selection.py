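"""Alignment decoding, gapless coverage, and the modelability rule."""

import numpy as np
import pytest

from fibrilhmm.fixtures import FixtureSpec, generate_fixture
from fibrilhmm.scoring import fit_calibrator
from fibrilhmm.selection import (
    COVERAGE_THRESHOLD,
    SCORE_THRESHOLD,
    TemplateModel,
    align_to_template,
    apply_modelability_rule,
    export_score_matrix,
    select_template,
)
from fibrilhmm.template import HmmBuildParams, TemplateDefinition, build_initial_hmm


@pytest.fixture(scope="module")
def flat_template():
    """100-position template, no CDRs, no missing segments."""
    rng = np.random.default_rng(31)
    consensus = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                        for i in rng.integers(0, 20, 100))
    return TemplateDefinition("FLAT", consensus, segments=[(1, 100)])


@pytest.fixture(scope="module")
def flat_model(flat_template):
    return build_initial_hmm(flat_template)


class TestAlignmentAndCoverage:
    def test_consensus_query_full_coverage_no_indels(self, flat_template,
                                                     flat_model):
        aln, rep = align_to_template(
            flat_model, None, flat_template, flat_template.consensus,
            n_shuffles=5, rng_seed=0,
        )
        assert aln.coverage == 1.0
        assert aln.cdr_indels == []
        assert aln.flank_lengths == (0, 0)
        assert len(aln.pairs) == 100
        assert not rep.degenerate

    def test_mutated_nterm_absorbed_by_flank_gives_080(self, flat_template,
                                                       flat_model):
        """Replace the first 20 consensus positions with residues that align
        nowhere: the flank absorbs them and coverage drops to 0.8."""
        consensus = flat_template.consensus
        rng = np.random.default_rng(7)
        prefix = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[(ord(c) + int(rng.integers(3, 9))) % 20]
            for c in consensus[:20]
        )
        query = prefix + consensus[20:]
        aln, _ = align_to_template(flat_model, None, flat_template, query,
                                   n_shuffles=5, rng_seed=0)
        matched = {t for t, _ in aln.pairs}
        assert matched == set(range(21, 101)) or len(matched) <= 80
        assert aln.coverage <= 0.8
        assert aln.coverage >= 0.75  # flank path, not wholesale misalignment

    def test_cdr_insertion_recorded_without_breaking_constant_pairs(
        self, tmp_path
    ):
        fx = generate_fixture(
            FixtureSpec(template_length=40, cdr_intervals=((15, 24),),
                        missing_segments=(), mutation_rate=0.0,
                        cdr_indel_rate=0.0, corpus_size=1, rng_seed=37),
            tmp_path,
        )
        model = build_initial_hmm(fx.template)
        consensus = fx.template.consensus
        query = consensus[:20] + "W" + consensus[20:]  # insert inside CDR
        aln, _ = align_to_template(model, None, fx.template, query,
                                   n_shuffles=5, rng_seed=0)
        assert any(e.kind == "insertion" for e in aln.cdr_indels)
        # constant-region positions still pair 1:1
        constant = [p for p in aln.pairs if p[0] <= 14]
        assert constant == [(i, i) for i in range(1, 15)]

    def test_appending_unalignable_termini_never_raises_coverage(
        self, flat_template, flat_model
    ):
        base = flat_template.consensus
        aln0, _ = align_to_template(flat_model, None, flat_template, base,
                                    n_shuffles=5, rng_seed=0)
        grown, _ = align_to_template(
            flat_model, None, flat_template, "W" * 7 + base + "W" * 7,
            n_shuffles=5, rng_seed=0,
        )
        assert grown.coverage <= aln0.coverage
        assert grown.flank_lengths >= (1, 1)

    def test_degenerate_query_empty_alignment(self):
        from helpers import single_match_model

        strict = single_match_model("A")
        tdef = TemplateDefinition("MINI", "A", segments=[(1, 1)])
        aln, rep = align_to_template(strict, None, tdef, "C",
                                     n_shuffles=3, rng_seed=0)
        assert rep.degenerate
        assert aln.pairs == []
        assert aln.coverage == 0.0


class TestModelabilityRule:
    @pytest.mark.parametrize(
        "score,coverage,expected,failing",
        [
            (0.14, 1.00, False, "score"),   # best template far below threshold
            (0.51, 0.85, True, None),
            (0.51, 0.79, False, "coverage"),
            (0.50, 0.85, False, "score"),   # strict: exactly 0.5 fails
            (0.51, 0.80, True, None),       # non-strict: exactly 0.8 passes
        ],
    )
    def test_threshold_boundary_behaviour(self, score, coverage, expected,
                                          failing):
        verdict, reasons = apply_modelability_rule(score, coverage)
        assert verdict is expected
        if failing == "score":
            assert not reasons["score_ok"]
        elif failing == "coverage":
            assert not reasons["coverage_ok"]

    def test_default_thresholds(self):
        assert SCORE_THRESHOLD == 0.5
        assert COVERAGE_THRESHOLD == 0.8

    def test_single_template_registry_reduces_to_two_rule_check(
        self, small_fixture
    ):
        model = build_initial_hmm(small_fixture.template)
        scores = [1.0, 2.0, 3.0, 4.0, 5.0]
        tm = TemplateModel(small_fixture.template, model,
                           fit_calibrator(scores))
        res = select_template([tm], small_fixture.consensus_query,
                              n_shuffles=10, rng_seed=3)
        assert res.best_template == small_fixture.template.template_id
        expected, _ = apply_modelability_rule(
            res.reasons["best_score"], res.reasons["best_coverage"])
        assert res.modelable is expected


@pytest.fixture(scope="module")
def registry(small_fixture, tmp_path_factory):
    out = tmp_path_factory.mktemp("fx2")
    other = generate_fixture(
        FixtureSpec(template_length=50, cdr_intervals=((20, 28),),
                    missing_segments=(), corpus_size=1, rng_seed=41),
        out,
    )
    reg = []
    for fx in (small_fixture, other):
        model = build_initial_hmm(fx.template)
        reg.append(TemplateModel(fx.template, model,
                                 fit_calibrator([0.0, 5.0, 10.0])))
    return reg


class TestScoreMatrixExport:
    def test_matrix_shape_and_score_range(self, registry, small_fixture):
        queries = dict(list(small_fixture.corpus.items())[:3])
        table = export_score_matrix(registry, queries, n_shuffles=5,
                                    rng_seed=2)
        score_cols = [c for c in table.columns if c.startswith("score_")]
        assert table.shape[0] == 3
        assert len(score_cols) == 2
        vals = table[score_cols].to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_query_degenerate_on_one_template_flagged_excluded(self, registry):
        """A query the noise-free model cannot emit at all (a residue absent
        from its consensus) is flagged and marks the row for exclusion."""
        from helpers import single_match_model

        strict = TemplateModel(
            TemplateDefinition("MINI", "A", segments=[(1, 1)]),
            single_match_model("A"),
            fit_calibrator([0.0, 1.0, 2.0]),
        )
        queries = {"impossible": "C" * 30}
        table = export_score_matrix(registry + [strict], queries,
                                    n_shuffles=3, rng_seed=2)
        assert bool(table.loc[0, "excluded"]) is True
        assert bool(table.loc[0, "degenerate_MINI"]) is True
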