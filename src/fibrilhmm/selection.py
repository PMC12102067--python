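"""Query scoring against the template registry, alignment decoding, and the
modelability rule.

A query is reliably modelable by homology only when its best calibrated
template score *exceeds* ``SCORE_THRESHOLD`` (strict, i.e. above the median
of the reference corpus) and *at least* ``COVERAGE_THRESHOLD`` of the
template consensus aligns through match states (non-strict).  Both rules are
deliberately conservative: backbone coordinates are copied from the
template, so misalignments are unrecoverable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import NEG_INF, HmmSpec, StateKind, viterbi
from .scoring import (
    DEFAULT_N_SHUFFLES,
    QuantileCalibrator,
    ScoreReport,
    calibrated_score,
    raw_score,
)
from .template import TemplateDefinition

SCORE_THRESHOLD = 0.5
COVERAGE_THRESHOLD = 0.8


@dataclass
class IndelEvent:
    """One maximal run of insert or emitting-delete states inside a CDR."""

    kind: str  # "insertion" | "deletion"
    cdr_position: int  # consensus position the event is anchored to
    length: int


@dataclass
class AlignmentResult:
    template_id: str
    pairs: list[tuple[int, int]]  # (template consensus pos, query pos), 1-based
    cdr_indels: list[IndelEvent] = field(default_factory=list)
    flank_lengths: tuple[int, int] = (0, 0)
    coverage: float = 0.0


@dataclass
class SelectionResult:
    query_id: str
    score_vector: dict[str, float]
    degenerate_templates: list[str]
    best_template: str | None
    modelable: bool
    reasons: dict


@dataclass
class TemplateModel:
    """One registered template: its definition, (trained) HMM, calibrator."""

    template: TemplateDefinition
    model: HmmSpec
    calibrator: QuantileCalibrator | None = None

    @property
    def template_id(self) -> str:
        return self.template.template_id


def _decode_path(
    model: HmmSpec, template: TemplateDefinition, path: list[str]
) -> tuple[list[tuple[int, int]], list[IndelEvent], tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    indels: list[IndelEvent] = []
    n_flank = c_flank = 0
    run_kind: str | None = None
    run_anchor = 0
    run_len = 0
    last_tpos = 0

    def close_run():
        nonlocal run_kind, run_len
        if run_kind is not None:
            indels.append(IndelEvent(run_kind, run_anchor, run_len))
        run_kind, run_len = None, 0

    for qpos, sid in enumerate(path, start=1):
        st = model.state(sid)
        if st.kind is StateKind.MATCH:
            close_run()
            pairs.append((st.template_position, qpos))
            last_tpos = st.template_position
        elif st.kind is StateKind.FLANK:
            close_run()
            if pairs:
                c_flank += 1
            else:
                n_flank += 1
        elif st.kind is StateKind.INSERT:
            if run_kind != "insertion":
                close_run()
                run_kind, run_anchor = "insertion", last_tpos
            run_len += 1
        elif st.kind is StateKind.DELETE_EMIT:
            # only CDR deletions are indel events; inter-segment gap states
            # absorb residues over structurally unresolved stretches
            if sid.startswith("D"):
                if run_kind != "deletion":
                    close_run()
                    run_kind, run_anchor = "deletion", last_tpos + 1
                run_len += 1
            else:
                close_run()
    close_run()
    return pairs, indels, (n_flank, c_flank)


def compute_coverage(
    pairs: list[tuple[int, int]],
    template: TemplateDefinition,
    seq_len: int,
    denominator: str = "template",
) -> float:
    """Fraction of positions aligned gap-free through match states.

    The denominator is the template consensus length by default (what
    homology modeling of the backbone needs); ``denominator="sequence"``
    switches to the query-length convention.
    """
    if denominator == "template":
        denom = len(template.consensus)
    elif denominator == "sequence":
        denom = seq_len
    else:
        raise ValueError(f"unknown coverage denominator {denominator!r}")
    return len(pairs) / denom if denom else 0.0


def align_to_template(
    model: HmmSpec,
    calibrator: QuantileCalibrator | None,
    template: TemplateDefinition,
    seq: str,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng_seed: int = 0,
    coverage_denominator: str = "template",
) -> tuple[AlignmentResult, ScoreReport]:
    """Viterbi-align a query to one template and score it.

    A degenerate query (zero likelihood) yields an empty alignment with
    coverage 0 and a flagged score.
    """
    report = raw_score(
        model, seq, n_shuffles=n_shuffles, rng_seed=rng_seed,
        template_id=template.template_id,
    )
    if calibrator is not None:
        report = calibrated_score(calibrator, report)
    path, logp = viterbi(model, seq)
    if logp == NEG_INF:
        return AlignmentResult(template.template_id, pairs=[]), report
    pairs, indels, flanks = _decode_path(model, template, path)
    cov = compute_coverage(pairs, template, len(seq), coverage_denominator)
    return (
        AlignmentResult(template.template_id, pairs, indels, flanks, cov),
        report,
    )


def apply_modelability_rule(
    best_score: float,
    best_coverage: float,
    score_threshold: float = SCORE_THRESHOLD,
    coverage_threshold: float = COVERAGE_THRESHOLD,
) -> tuple[bool, dict]:
    """The two-rule verdict: score strictly above threshold ("exceeds"),
    coverage at or above threshold ("at least")."""
    score_ok = best_score > score_threshold
    cov_ok = best_coverage >= coverage_threshold
    return score_ok and cov_ok, {
        "score_ok": score_ok,
        "coverage_ok": cov_ok,
        "best_score": best_score,
        "best_coverage": best_coverage,
        "score_threshold": score_threshold,
        "coverage_threshold": coverage_threshold,
    }


def select_template(
    registry: list[TemplateModel],
    seq: str,
    query_id: str = "query",
    score_threshold: float = SCORE_THRESHOLD,
    coverage_threshold: float = COVERAGE_THRESHOLD,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng_seed: int = 0,
    coverage_denominator: str = "template",
) -> SelectionResult:
    """Score a query against every registered template and apply the rule:
    modelable iff best calibrated score > score_threshold (strict) and its
    alignment coverage >= coverage_threshold (non-strict).
    """
    if not registry:
        raise ValueError("template registry is empty")
    scores: dict[str, float] = {}
    coverages: dict[str, float] = {}
    degenerate: list[str] = []
    for tm in registry:
        aln, report = align_to_template(
            tm.model, tm.calibrator, tm.template, seq,
            n_shuffles=n_shuffles, rng_seed=rng_seed,
            coverage_denominator=coverage_denominator,
        )
        if report.degenerate:
            degenerate.append(tm.template_id)
            scores[tm.template_id] = 0.0
        else:
            scores[tm.template_id] = (
                report.calibrated_score
                if report.calibrated_score is not None
                else report.raw_score
            )
        coverages[tm.template_id] = aln.coverage
    # argmax by score; ties go to the lexicographically smaller template id
    best = min(scores, key=lambda t: (-scores[t], t))
    modelable, reasons = apply_modelability_rule(
        scores[best], coverages[best], score_threshold, coverage_threshold
    )
    return SelectionResult(
        query_id=query_id,
        score_vector=scores,
        degenerate_templates=degenerate,
        best_template=best,
        modelable=modelable,
        reasons=reasons,
    )


def export_score_matrix(
    registry: list[TemplateModel],
    seqs: dict[str, str],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng_seed: int = 0,
    **select_kwargs,
) -> pd.DataFrame:
    """Per-query score vector over all templates, one row per query.

    Calibrated scores become the landscape feature vector (one column per
    template).  Queries degenerate on at least one template are flagged for
    exclusion from downstream embedding analyses.
    """
    rows = []
    ss = np.random.SeedSequence(rng_seed).spawn(max(len(seqs), 1))
    for (qid, seq), child in zip(seqs.items(), ss):
        res = select_template(
            registry, seq, query_id=qid, n_shuffles=n_shuffles,
            rng_seed=int(child.generate_state(1)[0] % (2**31)), **select_kwargs,
        )
        row = {"query_id": qid}
        for tm in registry:
            row[f"score_{tm.template_id}"] = res.score_vector[tm.template_id]
        for tm in registry:
            row[f"degenerate_{tm.template_id}"] = (
                tm.template_id in res.degenerate_templates
            )
        row["excluded"] = bool(res.degenerate_templates)
        row["best_template"] = res.best_template
        row["modelable"] = res.modelable
        rows.append(row)
    return pd.DataFrame(rows)
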