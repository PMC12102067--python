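"""Iterative retraining of a template model on an amyloid sequence corpus.

Training proceeds in rounds of shrinking corpus fractions (30%, 20%, 10% by
default): each round scores the whole corpus with the current model, keeps
the top-scoring fraction and refines the model on it with Baum-Welch under
inertia.  After the last round the whole corpus is rescored with the final
model and the quantile calibrator is fitted on those raw scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hmm import HmmSpec, baum_welch, corpus_log_likelihood
from .scoring import (
    DEFAULT_N_SHUFFLES,
    QuantileCalibrator,
    fit_calibrator,
    raw_score_many,
)

#: sequences shorter than this are fragments, not full-length light chains
FULL_LENGTH_MIN = 211


@dataclass
class TrainingConfig:
    fractions: tuple[float, ...] = (0.30, 0.20, 0.10)
    inertia: float = 0.9
    stop_threshold: float = 50.0
    max_iterations: int = 500
    n_shuffles: int = DEFAULT_N_SHUFFLES
    rng_seed: int = 0

    def validate(self) -> None:
        prev = None
        for f in self.fractions:
            if not (0.0 < f <= 1.0):
                raise ValueError(f"fraction {f} outside (0, 1]")
            if prev is not None and f >= prev:
                raise ValueError("fractions must be strictly decreasing")
            prev = f
        if not (0.0 <= self.inertia <= 1.0):
            raise ValueError("inertia must lie in [0, 1]")
        if self.stop_threshold <= 0:
            raise ValueError("stop_threshold must be positive")


@dataclass
class TrainingLog:
    """Per-round record of scores, selections, and corpus log-likelihood."""

    rows: list[dict] = field(default_factory=list)

    def record_round(self, round_no, ids, scores, selected, loglik):
        sel = set(selected)
        for sid, sc in zip(ids, scores):
            self.rows.append({
                "round": round_no, "sequence_id": sid, "raw_score": sc,
                "selected": sid in sel, "corpus_log_likelihood": loglik,
            })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["round", "sequence_id", "raw_score", "selected",
                     "corpus_log_likelihood"],
        )

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_full_length(
    seqs: dict[str, str] | list[str], min_length: int = FULL_LENGTH_MIN
):
    """Keep only full-length light chains (>= 211 residues, inclusive)."""
    if isinstance(seqs, dict):
        return {k: v for k, v in seqs.items() if len(v) >= min_length}
    return [s for s in seqs if len(s) >= min_length]


def select_top_fraction(
    ids: list[str], scores: list[float], fraction: float
) -> list[str]:
    """Ids of the ceil(fraction * N) best finite scores.

    Degenerate (-inf) sequences never enter the pool.  Ties at the selection
    boundary are broken by input order (stable sort).
    """
    finite = [(i, sid) for i, (sid, sc) in enumerate(zip(ids, scores))
              if np.isfinite(sc)]
    k = math.ceil(fraction * len(ids))
    order = sorted(finite, key=lambda t: (-scores[t[0]], t[0]))
    chosen = [sid for _, sid in order[:k]]
    if not chosen:
        raise ValueError(
            f"selection of the top {fraction:.0%} picked zero sequences "
            "(corpus empty or fully degenerate)"
        )
    return chosen


def iterative_retrain(
    initial: HmmSpec,
    corpus: dict[str, str],
    cfg: TrainingConfig | None = None,
    template_id: str = "",
) -> tuple[HmmSpec, QuantileCalibrator, TrainingLog]:
    """Three-round top-fraction retraining plus final score calibration.

    Selection uses raw (pre-calibration) scores; the calibrator is fitted
    once, on the final model's scores over the full corpus, with degenerate
    sequences excluded.  Deterministic for a fixed (corpus order, seed,
    config).
    """
    cfg = cfg or TrainingConfig()
    cfg.validate()
    if not corpus:
        raise ValueError("training corpus is empty")
    ids = list(corpus)
    seqs = [corpus[i] for i in ids]
    log = TrainingLog()
    model = initial
    for round_no, fraction in enumerate(cfg.fractions, start=1):
        reports = raw_score_many(
            model, seqs, n_shuffles=cfg.n_shuffles,
            rng_seed=cfg.rng_seed, template_id=template_id,
        )
        scores = [r.raw_score for r in reports]
        chosen = select_top_fraction(ids, scores, fraction)
        train_seqs = [corpus[c] for c in chosen]
        model = baum_welch(
            model, train_seqs, inertia=cfg.inertia,
            stop_threshold=cfg.stop_threshold,
            max_iterations=cfg.max_iterations,
        )
        log.record_round(round_no, ids, scores, chosen,
                         corpus_log_likelihood(model, train_seqs))
    final_reports = raw_score_many(
        model, seqs, n_shuffles=cfg.n_shuffles,
        rng_seed=cfg.rng_seed, template_id=template_id,
    )
    final_scores = [r.raw_score for r in final_reports]
    calibrator = fit_calibrator(final_scores)
    log.record_round(len(cfg.fractions) + 1, ids, final_scores, [], float("nan"))
    return model, calibrator, log
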