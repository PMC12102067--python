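"""Shuffle-normalized similarity scores and their quantile calibration.

The raw score of a sequence against a template model is the log-ratio
between the sequence's likelihood and the average likelihood of random
shuffles of the same sequence (average taken in probability space).  This
normalizes away sequence length and residue composition: a model that is
indifferent to residue order scores exactly 0.  Raw scores are mapped to
[0, 1] by an empirical-quantile calibrator fitted on a reference corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hmm import NEG_INF, HmmSpec, backward, forward_batch

DEFAULT_N_SHUFFLES = 100


@dataclass
class ScoreReport:
    """Raw and calibrated similarity of one sequence to one template model."""

    template_id: str
    raw_score: float
    calibrated_score: float | None = None
    degenerate: bool = False

    def __post_init__(self):
        if self.calibrated_score is not None and not (
            0.0 <= self.calibrated_score <= 1.0
        ):
            raise ValueError("calibrated_score must lie in [0, 1]")


def shuffle_sequence(seq: str, rng_seed: int | np.random.Generator) -> str:
    """Uniform random permutation of the residues; reproducible under a seed."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return "".join(rng.permutation(list(seq)))


def raw_score(
    hmm: HmmSpec,
    seq: str,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng_seed: int | np.random.SeedSequence = 0,
    template_id: str = "",
) -> ScoreReport:
    """log P(seq) minus the log of the mean shuffle likelihood.

    The mean over shuffles is arithmetic in probability space, computed with
    log-sum-exp.  Per-shuffle RNG streams are spawned deterministically from
    the master seed, so the result is reproducible and invariant to shuffle
    order.  A sequence the model cannot emit gets the -inf sentinel and the
    degenerate flag.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    ll = backward(hmm, seq)
    if ll == NEG_INF:
        return ScoreReport(template_id=template_id, raw_score=NEG_INF, degenerate=True)
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    streams = ss.spawn(n_shuffles)
    shuffles = [
        shuffle_sequence(seq, np.random.default_rng(s)) for s in streams
    ]
    lls = forward_batch(hmm, shuffles)
    finite = lls[np.isfinite(lls)]
    if len(finite) == 0:
        # all shuffles impossible while the sequence itself is not: the
        # normalizer is zero, the ratio unbounded
        return ScoreReport(template_id=template_id, raw_score=float("inf"))
    m = float(np.max(finite))
    log_mean = m + float(np.log(np.sum(np.exp(finite - m)))) - float(np.log(n_shuffles))
    return ScoreReport(template_id=template_id, raw_score=ll - log_mean)


def raw_score_many(
    hmm: HmmSpec,
    seqs: list[str],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng_seed: int = 0,
    template_id: str = "",
) -> list[ScoreReport]:
    """Score a corpus; each sequence gets its own child seed so the result
    does not depend on corpus order."""
    children = np.random.SeedSequence(rng_seed).spawn(len(seqs))
    return [
        raw_score(hmm, s, n_shuffles=n_shuffles,
                  rng_seed=child, template_id=template_id)
        for s, child in zip(seqs, children)
    ]


class QuantileCalibrator:
    """Monotone map from raw scores to their empirical quantiles in [0, 1].

    Linear interpolation between sorted reference scores (uniform quantile
    grid), clamped at the extremes: the reference minimum maps to 0 and the
    maximum to 1.
    """

    def __init__(self, reference_scores: np.ndarray):
        ref = np.sort(np.asarray(reference_scores, dtype=float))
        if len(ref) < 2:
            raise ValueError("need at least two finite reference scores")
        if not np.all(np.isfinite(ref)):
            raise ValueError("reference scores must be finite")
        self.reference = ref
        self.quantiles = np.linspace(0.0, 1.0, len(ref))

    def transform(self, raw: float | np.ndarray) -> float | np.ndarray:
        out = np.interp(raw, self.reference, self.quantiles)
        return float(out) if np.isscalar(raw) else out

    def to_json(self) -> str:
        return json.dumps(
            {"format": "fibrilhmm-calibrator", "version": 1,
             "reference_scores": self.reference.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "QuantileCalibrator":
        data = json.loads(text)
        if data.get("version", 0) != 1:
            raise ValueError(f"unsupported calibrator version {data.get('version')}")
        return cls(np.array(data["reference_scores"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "QuantileCalibrator":
        return cls.from_json(Path(path).read_text())


def fit_calibrator(raw_scores: list[float]) -> QuantileCalibrator:
    """Fit the empirical-quantile map on finite reference scores.

    -inf (degenerate) entries are excluded before fitting; an all-degenerate
    input is an error.
    """
    finite = [s for s in raw_scores if np.isfinite(s)]
    if len(finite) < 2:
        raise ValueError(
            "cannot fit calibrator: fewer than two finite reference scores "
            f"({len(finite)} of {len(raw_scores)} usable)"
        )
    return QuantileCalibrator(np.array(finite))


def calibrated_score(
    calibrator: QuantileCalibrator, report: ScoreReport
) -> ScoreReport:
    """Fill in the calibrated score; degenerate reports calibrate to 0."""
    if report.degenerate:
        return ScoreReport(report.template_id, report.raw_score,
                           calibrated_score=0.0, degenerate=True)
    return ScoreReport(
        report.template_id, report.raw_score,
        calibrated_score=float(calibrator.transform(report.raw_score)),
    )
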