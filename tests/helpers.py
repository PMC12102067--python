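"""Independent oracles and generators used across the test suite.

The path-enumeration oracle is deliberately written in plain probability
space over Python dicts — no shared code with the log-space engine it
checks.
"""

from __future__ import annotations

import math

import numpy as np

from fibrilhmm.hmm import HmmSpec, StateKind, StateSpec

NEG_INF = float("-inf")


def enumerate_paths(hmm: HmmSpec, seq: str):
    """Exhaustive sum/max over all state paths emitting ``seq``.

    Returns (log total probability, log best-path probability, best paths)
    where best paths is the list of all maximum-probability state-id paths.
    Only usable for tiny models/sequences.
    """
    results: list[tuple[float, tuple[str, ...]]] = []

    def rec(state_id: str, pos: int, prob: float, path: list[str]):
        st = hmm.state(state_id)
        for tgt, p in st.transitions.items():
            if p <= 0.0:
                continue
            if tgt == hmm.end_state:
                if pos == len(seq):
                    results.append((prob * p, tuple(path)))
                continue
            if pos < len(seq):
                ep = hmm.state(tgt).emissions.get(seq[pos], 0.0)
                if p * ep > 0.0:
                    rec(tgt, pos + 1, prob * p * ep, path + [tgt])

    rec(hmm.start_state, 0, 1.0, [])
    if not results:
        return NEG_INF, NEG_INF, []
    total = math.fsum(pr for pr, _ in results)
    best = max(pr for pr, _ in results)
    best_paths = [list(p) for pr, p in results if pr == best]
    return math.log(total), math.log(best), best_paths


def single_match_model(residue: str = "A") -> HmmSpec:
    """START -> M -> END, the match emitting one residue with probability 1."""
    return HmmSpec(
        [
            StateSpec("START", StateKind.START, transitions={"M1": 1.0}),
            StateSpec("M1", StateKind.MATCH, transitions={"END": 1.0},
                      emissions={residue: 1.0}, template_position=1),
            StateSpec("END", StateKind.END),
        ],
        start_state="START",
        end_state="END",
    )


def toy_three_state_model() -> HmmSpec:
    """Small mixed-emission model with loops, for oracle comparisons."""
    return HmmSpec(
        [
            StateSpec("START", StateKind.START,
                      transitions={"M1": 0.7, "F": 0.3}),
            StateSpec("F", StateKind.FLANK,
                      emissions={"A": 0.25, "C": 0.25, "G": 0.25, "W": 0.25},
                      transitions={"F": 0.5, "M1": 0.5}),
            StateSpec("M1", StateKind.MATCH, template_position=1,
                      emissions={"A": 0.8, "C": 0.1, "G": 0.1},
                      transitions={"M2": 0.6, "D1": 0.4}),
            StateSpec("D1", StateKind.DELETE_EMIT,
                      emissions={"A": 0.05, "C": 0.05, "G": 0.45, "W": 0.45},
                      transitions={"D1": 0.3, "M2": 0.7}),
            StateSpec("M2", StateKind.MATCH, template_position=2,
                      emissions={"C": 0.9, "W": 0.1},
                      transitions={"END": 1.0}),
            StateSpec("END", StateKind.END),
        ],
        start_state="START",
        end_state="END",
    )


_KINDS = [StateKind.MATCH, StateKind.INSERT, StateKind.DELETE_EMIT, StateKind.FLANK]
_ORACLE_ALPHABET = "ACGW"


def random_small_hmm(rng: np.random.Generator, max_states: int = 10) -> HmmSpec:
    """Random valid model with a guaranteed START -> ... -> END backbone plus
    random extra edges, sparse emissions over a 4-letter sub-alphabet."""
    n = int(rng.integers(2, max_states + 1))
    ids = [f"s{i}" for i in range(n)]
    states = []
    tpos = 1
    for i, sid in enumerate(ids):
        kind = _KINDS[rng.integers(0, len(_KINDS))]
        emissions_support = rng.choice(list(_ORACLE_ALPHABET),
                                       size=int(rng.integers(2, 5)), replace=False)
        weights = rng.dirichlet(np.ones(len(emissions_support)))
        emissions = {aa: float(w) for aa, w in zip(emissions_support, weights)}
        targets = {ids[i + 1] if i + 1 < n else "END"}
        n_extra = int(rng.integers(0, 3))
        pool = ids + ["END"]
        for _ in range(n_extra):
            targets.add(pool[rng.integers(0, len(pool))])
        targets = sorted(targets)
        tw = rng.dirichlet(np.ones(len(targets)))
        transitions = {t: float(w) for t, w in zip(targets, tw)}
        states.append(StateSpec(
            sid, kind, transitions=transitions, emissions=emissions,
            template_position=tpos if kind is StateKind.MATCH else None,
        ))
        if kind is StateKind.MATCH:
            tpos += 1
    start_targets = sorted({ids[0], ids[int(rng.integers(0, n))]})
    sw = rng.dirichlet(np.ones(len(start_targets)))
    states.insert(0, StateSpec(
        "START", StateKind.START,
        transitions={t: float(w) for t, w in zip(start_targets, sw)},
    ))
    states.append(StateSpec("END", StateKind.END))
    hmm = HmmSpec(states, "START", "END")
    hmm.validate()
    return hmm


def random_oracle_sequence(rng: np.random.Generator, max_len: int = 8) -> str:
    length = int(rng.integers(1, max_len + 1))
    return "".join(rng.choice(list(_ORACLE_ALPHABET), size=length))
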