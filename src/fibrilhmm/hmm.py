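"""Generic hidden-Markov-model inference and learning in natural-log space.

The engine is agnostic to the constrained light-chain topology built in
:mod:`fibrilhmm.template`: it works on any :class:`HmmSpec` whose states are
all *emitting* except for the silent START and END bookends.  Deletion states
are emitting by design here (they absorb query residues spanning structurally
unresolved template segments), so the dynamic programs never need silent-state
elimination.

All probabilities are handled as natural logarithms; an impossible event is
the ``-inf`` sentinel, which propagates through ``logsumexp`` without raising.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import AMINO_ACIDS, N_AA, encode_sequence

NEG_INF = float("-inf")

_SUM_TOL = 1e-9


class StateKind(enum.Enum):
    MATCH = "MATCH"
    INSERT = "INSERT"
    DELETE_EMIT = "DELETE_EMIT"
    FLANK = "FLANK"
    START = "START"
    END = "END"


#: Viterbi tie-break order: prefer MATCH, then emitting deletions, then
#: insertions, then flanks; final ties go to the lower state index.  The rule
#: is deterministic and favors maximal template coverage.
_KIND_PRIORITY = {
    StateKind.MATCH: 0,
    StateKind.DELETE_EMIT: 1,
    StateKind.INSERT: 2,
    StateKind.FLANK: 3,
    StateKind.START: 4,
    StateKind.END: 4,
}


@dataclass
class StateSpec:
    """One HMM state: emissions over the 20 canonical residues and outgoing
    transitions keyed by target state id.

    ``template_position`` is the 1-based consensus coordinate carried by MATCH
    states only; it is what turns a decoded state path into an alignment.
    """

    id: str
    kind: StateKind
    transitions: dict[str, float] = field(default_factory=dict)
    emissions: dict[str, float] | None = None
    template_position: int | None = None

    @property
    def silent(self) -> bool:
        return self.kind in (StateKind.START, StateKind.END)


class InvalidHmmError(ValueError):
    pass


class DegenerateCorpusError(ValueError):
    """Every training sequence has -inf likelihood: the topology cannot emit
    the corpus (wrong template, or sequences shorter than the forced path)."""


@dataclass
class HmmSpec:
    """An HMM as an ordered list of states plus silent START/END bookends."""

    states: list[StateSpec]
    start_state: str
    end_state: str

    def __post_init__(self):
        self._by_id = {s.id: s for s in self.states}
        if len(self._by_id) != len(self.states):
            raise InvalidHmmError("duplicate state ids")
        self._compiled: _CompiledHmm | None = None

    def state(self, state_id: str) -> StateSpec:
        return self._by_id[state_id]

    @property
    def emitting_states(self) -> list[StateSpec]:
        return [s for s in self.states if not s.silent]

    def validate(self) -> None:
        """Check probability-sum, uniqueness and reachability invariants."""
        if self.start_state not in self._by_id or self.end_state not in self._by_id:
            raise InvalidHmmError("start/end state id not present")
        seen_positions: set[int] = set()
        for s in self.states:
            if s.kind is StateKind.END:
                if s.transitions:
                    raise InvalidHmmError("END state must have no transitions")
                continue
            total = sum(s.transitions.values())
            if abs(total - 1.0) > _SUM_TOL:
                raise InvalidHmmError(
                    f"transitions of state {s.id!r} sum to {total!r}, not 1"
                )
            for tgt, p in s.transitions.items():
                if tgt not in self._by_id:
                    raise InvalidHmmError(f"{s.id!r} -> unknown state {tgt!r}")
                if not (0.0 <= p <= 1.0):
                    raise InvalidHmmError(f"transition {s.id!r}->{tgt!r} = {p}")
            if s.silent:
                if s.emissions:
                    raise InvalidHmmError(f"silent state {s.id!r} has emissions")
            else:
                if s.emissions is None:
                    raise InvalidHmmError(f"emitting state {s.id!r} lacks emissions")
                if set(s.emissions) - set(AMINO_ACIDS):
                    raise InvalidHmmError(
                        f"state {s.id!r} emits non-canonical residues"
                    )
                etot = sum(s.emissions.values())
                if abs(etot - 1.0) > _SUM_TOL:
                    raise InvalidHmmError(
                        f"emissions of state {s.id!r} sum to {etot!r}, not 1"
                    )
            if s.kind is StateKind.MATCH:
                if s.template_position is None:
                    raise InvalidHmmError(f"MATCH state {s.id!r} lacks template_position")
                if s.template_position in seen_positions:
                    raise InvalidHmmError(
                        f"template_position {s.template_position} used twice"
                    )
                seen_positions.add(s.template_position)
            elif s.template_position is not None:
                raise InvalidHmmError(
                    f"non-MATCH state {s.id!r} carries a template_position"
                )
        # reachability: END reachable from START over positive-probability edges
        frontier = [self.start_state]
        reached = {self.start_state}
        while frontier:
            cur = frontier.pop()
            for tgt, p in self._by_id[cur].transitions.items():
                if p > 0.0 and tgt not in reached:
                    reached.add(tgt)
                    frontier.append(tgt)
        if self.end_state not in reached:
            raise InvalidHmmError("END state unreachable from START")

    # -- compiled form -----------------------------------------------------

    def compiled(self) -> "_CompiledHmm":
        if self._compiled is None:
            self._compiled = _CompiledHmm(self)
        return self._compiled

    def copy(self) -> "HmmSpec":
        states = [
            replace(
                s,
                transitions=dict(s.transitions),
                emissions=dict(s.emissions) if s.emissions is not None else None,
            )
            for s in self.states
        ]
        return HmmSpec(states, self.start_state, self.end_state)


def _log(p: float) -> float:
    return math.log(p) if p > 0.0 else NEG_INF


class _CompiledHmm:
    """Array form of an HmmSpec for vectorized dynamic programming.

    Emitting states are indexed in list order.  Transitions between emitting
    states are stored as edge arrays grouped by destination (forward pass)
    and by source (backward pass); grouping uses ``np.ufunc.reduceat`` over
    contiguous segments.  Within a destination group, edges are ordered by
    the Viterbi predecessor priority so the first maximal entry implements
    the tie-break.
    """

    def __init__(self, spec: HmmSpec):
        self.spec = spec
        emitting = spec.emitting_states
        self.n = len(emitting)
        self.ids = [s.id for s in emitting]
        self.index = {s.id: i for i, s in enumerate(emitting)}
        self.kinds = [s.kind for s in emitting]
        self.priority = np.array(
            [(_KIND_PRIORITY[s.kind], i) for i, s in enumerate(emitting)],
            dtype=np.int64,
        )
        prio_rank = np.lexsort((self.priority[:, 1], self.priority[:, 0]))
        # rank[i] = position of state i in priority order (lower = preferred)
        self.rank = np.empty(self.n, dtype=np.int64)
        self.rank[prio_rank] = np.arange(self.n)

        self.log_e = np.full((self.n, N_AA), NEG_INF)
        for i, s in enumerate(emitting):
            for aa, p in s.emissions.items():
                self.log_e[i, AMINO_ACIDS.index(aa)] = _log(p)

        start = spec.state(spec.start_state)
        self.log_pi = np.full(self.n, NEG_INF)
        for tgt, p in start.transitions.items():
            if tgt == spec.end_state:
                continue
            self.log_pi[self.index[tgt]] = _log(p)
        self.log_end = np.full(self.n, NEG_INF)

        src_l, dst_l, lw_l = [], [], []
        for s in emitting:
            i = self.index[s.id]
            for tgt, p in s.transitions.items():
                if tgt == spec.end_state:
                    self.log_end[i] = _log(p)
                elif tgt == spec.start_state:
                    raise InvalidHmmError("transition back into START")
                else:
                    src_l.append(i)
                    dst_l.append(self.index[tgt])
                    lw_l.append(_log(p))
        src = np.array(src_l, dtype=np.intp)
        dst = np.array(dst_l, dtype=np.intp)
        lw = np.array(lw_l, dtype=float)

        # forward/Viterbi layout: edges sorted by (dst, src priority rank)
        order = np.lexsort((self.rank[src], dst)) if len(src) else np.array([], np.intp)
        self.f_src, self.f_dst, self.f_lw = src[order], dst[order], lw[order]
        self.f_groups, self.f_starts = _segments(self.f_dst, self.n)
        # backward layout: edges sorted by src
        order_b = np.argsort(src, kind="stable") if len(src) else np.array([], np.intp)
        self.b_src, self.b_dst, self.b_lw = src[order_b], dst[order_b], lw[order_b]
        self.b_groups, self.b_starts = _segments(self.b_src, self.n)


def _segments(keys: np.ndarray, n: int):
    """Unique group keys and reduceat start offsets for a sorted key array."""
    if len(keys) == 0:
        return np.array([], dtype=np.intp), np.array([], dtype=np.intp)
    uniq, starts = np.unique(keys, return_index=True)
    return uniq, starts


def _segment_logsumexp(vals: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """logsumexp over contiguous segments; -inf-safe.  vals: (..., E)."""
    m = np.maximum.reduceat(vals, starts, axis=-1)
    lengths = np.diff(np.append(starts, vals.shape[-1]))
    m_rep = np.repeat(m, lengths, axis=-1)
    with np.errstate(invalid="ignore"):
        terms = np.where(np.isneginf(m_rep), 0.0, np.exp(vals - m_rep))
    s = np.add.reduceat(terms, starts, axis=-1)
    with np.errstate(divide="ignore"):
        out = m + np.log(s)
    return np.where(np.isneginf(m), NEG_INF, out)


def _logsumexp(vals: np.ndarray) -> float:
    m = np.max(vals) if len(vals) else NEG_INF
    if m == NEG_INF:
        return NEG_INF
    return float(m + np.log(np.sum(np.exp(vals - m))))


# ---------------------------------------------------------------------------
# forward / backward


def _forward_table(ch: _CompiledHmm, obs: np.ndarray) -> np.ndarray:
    """alpha[t, s] = log P(x[0..t], state_t = s).  obs may be (L,) or (B, L)."""
    batch = obs.ndim == 2
    L = obs.shape[-1]
    shape = (obs.shape[0], L, ch.n) if batch else (L, ch.n)
    alpha = np.full(shape, NEG_INF)
    e0 = ch.log_e[:, obs[..., 0]]  # (n,) or (n, B)
    alpha[..., 0, :] = ch.log_pi + np.moveaxis(e0, 0, -1)
    for t in range(1, L):
        prev = alpha[..., t - 1, :]
        vals = prev[..., ch.f_src] + ch.f_lw
        red = _segment_logsumexp(vals, ch.f_starts)
        nxt = np.full(prev.shape, NEG_INF)
        nxt[..., ch.f_groups] = red
        et = np.moveaxis(ch.log_e[:, obs[..., t]], 0, -1)
        alpha[..., t, :] = nxt + et
    return alpha


def _backward_table(ch: _CompiledHmm, obs: np.ndarray) -> np.ndarray:
    """beta[t, s] = log P(x[t+1..L-1] and reach END | state_t = s)."""
    L = obs.shape[-1]
    beta = np.full((L, ch.n), NEG_INF)
    beta[L - 1] = ch.log_end
    for t in range(L - 2, -1, -1):
        nxt = beta[t + 1, ch.b_dst] + ch.b_lw + ch.log_e[ch.b_dst, obs[t + 1]]
        red = _segment_logsumexp(nxt, ch.b_starts)
        row = np.full(ch.n, NEG_INF)
        row[ch.b_groups] = red
        beta[t] = row
    return beta


def forward(hmm: HmmSpec, seq: str) -> float:
    """Total log probability log P(seq | hmm) summed over all state paths.

    Returns the ``-inf`` sentinel when no path can emit the sequence.
    """
    obs = encode_sequence(seq)
    ch = hmm.compiled()
    alpha = _forward_table(ch, obs)
    return _logsumexp(alpha[-1] + ch.log_end)


def forward_batch(hmm: HmmSpec, seqs: list[str]) -> np.ndarray:
    """Vectorized :func:`forward` over equal-length sequences."""
    if not seqs:
        return np.array([])
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("forward_batch requires equal-length sequences")
    obs = np.stack([encode_sequence(s) for s in seqs])
    ch = hmm.compiled()
    alpha = _forward_table(ch, obs)
    last = alpha[:, -1, :] + ch.log_end
    m = np.max(last, axis=1)
    with np.errstate(invalid="ignore"):
        out = m + np.log(np.sum(np.exp(last - m[:, None]), axis=1))
    return np.where(np.isneginf(m), NEG_INF, out)


def backward(hmm: HmmSpec, seq: str) -> float:
    """log P(seq | hmm) by the backward recursion; equals :func:`forward`."""
    obs = encode_sequence(seq)
    ch = hmm.compiled()
    beta = _backward_table(ch, obs)
    return _logsumexp(ch.log_pi + ch.log_e[:, obs[0]] + beta[0])


# ---------------------------------------------------------------------------
# Viterbi


def viterbi(hmm: HmmSpec, seq: str) -> tuple[list[str], float]:
    """Maximum-probability state path and its log probability.

    Ties are broken deterministically: among equally scoring predecessors the
    MATCH > DELETE_EMIT > INSERT > FLANK order wins, then the lower state
    index.  If no path has positive probability, returns ``([], -inf)``.
    """
    obs = encode_sequence(seq)
    ch = hmm.compiled()
    L = len(obs)
    delta = np.full((L, ch.n), NEG_INF)
    back = np.full((L, ch.n), -1, dtype=np.intp)
    delta[0] = ch.log_pi + ch.log_e[:, obs[0]]
    E = len(ch.f_src)
    if E:
        seg_len = np.diff(np.append(ch.f_starts, E))
        pos_in_seg = np.arange(E) - np.repeat(ch.f_starts, seg_len)
    for t in range(1, L):
        if E:
            vals = delta[t - 1, ch.f_src] + ch.f_lw
            seg_max = np.maximum.reduceat(vals, ch.f_starts)
            max_rep = np.repeat(seg_max, seg_len)
            # first (priority-ordered) edge attaining the segment max
            cand = np.where(vals == max_rep, pos_in_seg, E)
            first = np.minimum.reduceat(cand, ch.f_starts)
            best_edge = ch.f_starts + first
            row = np.full(ch.n, NEG_INF)
            ptr = np.full(ch.n, -1, dtype=np.intp)
            ok = np.isfinite(seg_max)
            row[ch.f_groups[ok]] = seg_max[ok]
            ptr[ch.f_groups[ok]] = ch.f_src[best_edge[ok]]
            delta[t] = row + ch.log_e[:, obs[t]]
            back[t] = ptr
        else:
            delta[t] = NEG_INF
    final = delta[-1] + ch.log_end
    if np.all(np.isneginf(final)):
        return [], NEG_INF
    # final-state tie-break by priority rank
    best = np.max(final)
    tied = np.flatnonzero(final == best)
    last = int(tied[np.argmin(ch.rank[tied])])
    path_idx = [last]
    for t in range(L - 1, 0, -1):
        last = int(back[t, last])
        path_idx.append(last)
    path_idx.reverse()
    return [ch.ids[i] for i in path_idx], float(np.max(final))


# ---------------------------------------------------------------------------
# sampling


def sample(hmm: HmmSpec, rng: np.random.Generator) -> tuple[str, list[str]]:
    """Draw one (sequence, emitting-state path) from the model."""
    seq: list[str] = []
    path: list[str] = []
    cur = hmm.start_state
    while True:
        st = hmm.state(cur)
        targets = list(st.transitions)
        probs = np.array([st.transitions[t] for t in targets])
        cur = targets[rng.choice(len(targets), p=probs / probs.sum())]
        if cur == hmm.end_state:
            break
        nxt = hmm.state(cur)
        aas = list(nxt.emissions)
        ps = np.array([nxt.emissions[a] for a in aas])
        seq.append(aas[rng.choice(len(aas), p=ps / ps.sum())])
        path.append(cur)
    return "".join(seq), path


# ---------------------------------------------------------------------------
# Baum-Welch with inertia


def corpus_log_likelihood(hmm: HmmSpec, seqs: list[str]) -> float:
    return float(sum(forward(hmm, s) for s in seqs))


def baum_welch(
    hmm: HmmSpec,
    seqs: list[str],
    inertia: float = 0.9,
    stop_threshold: float = 50.0,
    max_iterations: int = 500,
    floor: float = 1e-10,
) -> HmmSpec:
    """Expectation-maximization with an inertia term.

    Each accepted iteration replaces every emission row and transition row by
    ``inertia * old + (1 - inertia) * estimate`` where the estimate is the
    normalized expected count from the forward-backward pass, floored at
    ``floor`` and renormalized (only over events the topology allows, so
    structural zeros stay zero).  Iteration stops once the corpus
    log-likelihood improves by less than ``stop_threshold`` (absolute change
    over the whole corpus) or after ``max_iterations``.

    Inertia 1.0 returns an identical model.  Raises
    :class:`DegenerateCorpusError` if every sequence has -inf likelihood.
    """
    if not seqs:
        raise ValueError("training corpus must be non-empty")
    if not (0.0 <= inertia <= 1.0):
        raise ValueError("inertia must lie in [0, 1]")
    cur = hmm.copy()
    prev_ll: float | None = None
    for _ in range(max_iterations):
        stats, ll = _expected_counts(cur, seqs)
        if stats is None:
            raise DegenerateCorpusError(
                "every training sequence has zero likelihood under the model; "
                "the topology cannot emit this corpus (template/corpus mismatch "
                "or sequences shorter than the forced state path)"
            )
        if prev_ll is not None and ll - prev_ll < stop_threshold:
            break
        prev_ll = ll
        if inertia == 1.0:
            break
        cur = _apply_update(cur, stats, inertia, floor)
    return cur


def _expected_counts(hmm: HmmSpec, seqs: list[str]):
    ch = hmm.compiled()
    E = len(ch.b_src)
    e_counts = np.zeros((ch.n, N_AA))
    t_counts = np.zeros(E)  # ordered as ch.b_* (by source)
    pi_counts = np.zeros(ch.n)
    end_counts = np.zeros(ch.n)
    total_ll = 0.0
    used = 0
    for seq in seqs:
        obs = encode_sequence(seq)
        alpha = _forward_table(ch, obs)
        ll = _logsumexp(alpha[-1] + ch.log_end)
        if ll == NEG_INF:
            continue
        used += 1
        total_ll += ll
        beta = _backward_table(ch, obs)
        gamma = np.exp(alpha + beta - ll)  # (L, n) posterior state occupancy
        for a in range(N_AA):
            mask = obs == a
            if mask.any():
                e_counts[:, a] += gamma[mask].sum(axis=0)
        pi_counts += gamma[0]
        end_counts += np.exp(alpha[-1] + ch.log_end - ll)
        if E and len(obs) > 1:
            with np.errstate(invalid="ignore"):
                xi = np.exp(
                    alpha[:-1, ch.b_src]
                    + ch.b_lw
                    + ch.log_e[ch.b_dst, :][:, obs[1:]].T
                    + beta[1:, ch.b_dst]
                    - ll
                )
            t_counts += np.nan_to_num(xi, nan=0.0, posinf=0.0).sum(axis=0)
    if used == 0:
        return None, NEG_INF
    return (e_counts, t_counts, pi_counts, end_counts, ch), total_ll


def _mix_row(old: np.ndarray, counts: np.ndarray, inertia: float, floor: float):
    total = counts.sum()
    if total <= 0.0:
        return old  # state never visited: keep old parameters
    est = counts / total
    est = np.maximum(est, floor)
    est /= est.sum()
    return inertia * old + (1.0 - inertia) * est


def _apply_update(hmm: HmmSpec, stats, inertia: float, floor: float) -> HmmSpec:
    e_counts, t_counts, pi_counts, end_counts, ch = stats
    new = hmm.copy()
    # emissions
    for i, sid in enumerate(ch.ids):
        st = new.state(sid)
        old = np.array([st.emissions.get(a, 0.0) for a in AMINO_ACIDS])
        mixed = _mix_row(old, e_counts[i], inertia, floor)
        st.emissions = {a: float(p) for a, p in zip(AMINO_ACIDS, mixed)}
    # transitions out of each emitting state (edges grouped by source + END)
    for i, sid in enumerate(ch.ids):
        st = new.state(sid)
        targets: list[str] = []
        old_p: list[float] = []
        cnt: list[float] = []
        for e in range(len(ch.b_src)):
            if ch.b_src[e] == i:
                tgt = ch.ids[ch.b_dst[e]]
                targets.append(tgt)
                old_p.append(st.transitions[tgt])
                cnt.append(t_counts[e])
        if hmm.end_state in st.transitions:
            targets.append(hmm.end_state)
            old_p.append(st.transitions[hmm.end_state])
            cnt.append(end_counts[i])
        if not targets:
            continue
        mixed = _mix_row(np.array(old_p), np.array(cnt), inertia, floor)
        st.transitions = {t: float(p) for t, p in zip(targets, mixed)}
    # START transitions
    start = new.state(new.start_state)
    targets = [t for t in start.transitions if t != new.end_state]
    if targets:
        old = np.array([start.transitions[t] for t in targets])
        cnt = np.array([pi_counts[ch.index[t]] for t in targets])
        mixed = _mix_row(old, cnt, inertia, floor)
        for t, p in zip(targets, mixed):
            start.transitions[t] = float(p)
    return new
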