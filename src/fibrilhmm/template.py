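"""Fibril template ingestion and the constrained initial profile HMM.

A template is one chain of one layer of an experimentally solved light-chain
amyloid fibril.  Its structurally resolved residues define a consensus
sequence; jumps in author residue numbering define missing segments; CDR
intervals come from a user-supplied annotation (never inferred, since no
single numbering scheme is assumed).

The initial HMM is deliberately rigid: within constant regions match states
chain directly with no insert/delete neighbours, unresolved segments are
bridged by a single self-looping emitting deletion state (geometric length),
CDRs get full match/insert/delete profile wiring, and uniform-emission flank
states absorb unaligned termini.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser

from .alphabet import AMINO_ACIDS, N_AA
from .hmm import HmmSpec, StateKind, StateSpec

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}

#: probability that an alignment starts in the match chain directly (versus
#: entering the N-terminal flank first); likewise for ending at the last
#: position versus the C-terminal flank.
DIRECT_ENTRY_PROB = 0.5

#: terminal-exit probability of each non-final match state.  Alignment is
#: semi-global: a query may leave leading or trailing template positions
#: unmatched (terminal gaps), so entry is spread uniformly over all match
#: states and every match state can exit to the C-terminal flank / end.
#: Kept small so interior matches still pass essentially all their mass
#: down the chain.
TERMINAL_EXIT_PROB = 0.01


@dataclass
class MissingSegment:
    """A structurally unresolved stretch between two resolved segments.

    ``after_consensus_position`` is the consensus coordinate of the last
    resolved residue before the gap; ``length`` is the number of unresolved
    residues implied by the author-numbering jump, or ``None`` if unknown.
    """

    after_consensus_position: int
    length: int | None = None


@dataclass
class TemplateDefinition:
    template_id: str
    consensus: str
    segments: list[tuple[int, int]]  # author residue-number intervals, inclusive
    missing_segments: list[MissingSegment] = field(default_factory=list)
    cdr_intervals: list[tuple[int, int]] = field(default_factory=list)  # consensus coords
    structure_path: str | None = None
    chain: str = "A"

    def validate(self) -> None:
        n = len(self.consensus)
        total = 0
        prev_end = None
        for start, end in self.segments:
            if end < start:
                raise ValueError(f"segment ({start}, {end}) reversed")
            if prev_end is not None and start <= prev_end:
                raise ValueError("segments must be disjoint and ordered")
            total += end - start + 1
            prev_end = end
        if total != n:
            raise ValueError(
                f"segments cover {total} residues but consensus has {n}"
            )
        prev = None
        for a, b in self.cdr_intervals:
            if not (1 <= a <= b <= n):
                raise ValueError(f"CDR interval ({a}, {b}) outside consensus bounds")
            if prev is not None and a <= prev:
                raise ValueError("CDR intervals must be ordered and non-overlapping")
            prev = b

    @property
    def segment_break_positions(self) -> list[int]:
        """Consensus positions after which a missing segment opens."""
        breaks = []
        cum = 0
        for start, end in self.segments[:-1]:
            cum += end - start + 1
            breaks.append(cum)
        return breaks

    def author_number(self, consensus_position: int) -> int:
        """Author residue number of a 1-based consensus position."""
        if not (1 <= consensus_position <= len(self.consensus)):
            raise ValueError(f"consensus position {consensus_position} out of range")
        offset = consensus_position - 1
        for start, end in self.segments:
            length = end - start + 1
            if offset < length:
                return start + offset
            offset -= length
        raise AssertionError("unreachable: segments cover consensus")


class ChainNotFoundError(ValueError):
    pass


def parse_template_structure(
    structure_path: str | Path, chain_selector: str, template_id: str | None = None
) -> TemplateDefinition:
    """Read one chain of a fibril PDB file into a :class:`TemplateDefinition`.

    The consensus is the one-letter sequence of residues carrying backbone
    (CA) coordinates, in author numbering order.  A jump greater than one in
    author numbering opens a missing segment whose length is the numbering
    gap.  CDR intervals are *not* inferred here; supply them from the
    template annotation config.
    """
    structure_path = Path(structure_path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(template_id or structure_path.stem, structure_path)
    model = next(structure.get_models())
    chain_ids = [c.id for c in model]
    if chain_selector not in chain_ids:
        raise ChainNotFoundError(
            f"chain {chain_selector!r} not present in {structure_path} "
            f"(available: {', '.join(chain_ids)})"
        )
    chain = model[chain_selector]
    residues = []
    unknown = []
    for res in chain:
        if res.id[0] != " " or "CA" not in res:
            continue
        one = _3TO1.get(res.get_resname().upper())
        if one is None or one not in AMINO_ACIDS:
            unknown.append(f"{res.get_resname()}{res.id[1]}")
            continue
        residues.append((res.id[1], one))
    if unknown:
        raise ValueError(
            "non-standard residues without a canonical mapping: " + ", ".join(unknown)
        )
    if not residues:
        raise ValueError(f"chain {chain_selector!r} has no resolved residues")
    consensus = []
    segments: list[tuple[int, int]] = []
    missing: list[MissingSegment] = []
    seg_start = residues[0][0]
    prev_num = None
    for num, aa in residues:
        if prev_num is not None:
            if num <= prev_num:
                raise ValueError(
                    f"non-increasing author numbering at residue {num} "
                    f"in chain {chain_selector!r}"
                )
            if num - prev_num > 1:
                segments.append((seg_start, prev_num))
                missing.append(
                    MissingSegment(
                        after_consensus_position=len(consensus),
                        length=num - prev_num - 1,
                    )
                )
                seg_start = num
        consensus.append(aa)
        prev_num = num
    segments.append((seg_start, prev_num))
    tdef = TemplateDefinition(
        template_id=template_id or structure_path.stem,
        consensus="".join(consensus),
        segments=segments,
        missing_segments=missing,
        structure_path=str(structure_path),
        chain=chain_selector,
    )
    tdef.validate()
    return tdef


def load_template_annotation(config_path: str | Path) -> TemplateDefinition:
    """Build a TemplateDefinition from a JSON annotation config.

    Required fields: ``template_id``, ``structure_path``, ``chain``,
    ``cdr_intervals`` (1-based inclusive, consensus coordinates).  Relative
    structure paths resolve against the config file's directory.  Optional
    ``segments`` overrides the numbering-derived segmentation.
    """
    config_path = Path(config_path)
    cfg = json.loads(config_path.read_text())
    spath = Path(cfg["structure_path"])
    if not spath.is_absolute():
        spath = config_path.parent / spath
    tdef = parse_template_structure(spath, cfg["chain"], cfg["template_id"])
    tdef.cdr_intervals = [tuple(iv) for iv in cfg.get("cdr_intervals", [])]
    if "segments" in cfg:
        tdef.segments = [tuple(iv) for iv in cfg["segments"]]
    tdef.validate()
    return tdef


@dataclass
class HmmBuildParams:
    """Initial ("dummy") parameterization of a template HMM before training.

    match_emit
        Probability a match state emits the template residue (0.8); the
        remaining ``mismatch_total`` (0.2) is spread evenly over the other
        19 amino acids.
    skip_emit
        Per-residue emission of emitting deletion / insertion / flank states
        (0.05 each, uniform over the 20 residues).
    cdr_gap_open
        Total gap-open probability inside a CDR (0.1), split evenly between
        match-to-delete and match-to-insert.
    gap_extend
        Extension probability of CDR indel states and inter-segment deletion
        states (0.9; the complementary 0.1 terminates the gap).
    flank_self
        Self-transition of the terminal flank states (0.9).
    """

    match_emit: float = 0.8
    mismatch_total: float = 0.2
    skip_emit: float = 0.05
    cdr_gap_open: float = 0.1
    gap_extend: float = 0.9
    flank_self: float = 0.9

    def validate(self) -> None:
        for name in ("match_emit", "mismatch_total", "skip_emit",
                     "cdr_gap_open", "gap_extend", "flank_self"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.match_emit + self.mismatch_total - 1.0) > 1e-9:
            raise ValueError("match_emit + mismatch_total must equal 1")
        if abs(self.skip_emit * N_AA - 1.0) > 1e-9:
            raise ValueError("skip_emit must be uniform over the 20 residues (1/20)")


def _uniform_emissions(p: float) -> dict[str, float]:
    return {aa: p for aa in AMINO_ACIDS}


def build_initial_hmm(
    template: TemplateDefinition,
    params: HmmBuildParams | None = None,
    semi_global: bool = True,
) -> HmmSpec:
    """Wire the constrained profile HMM for one template.

    Topology: one MATCH state per consensus position; constant-region matches
    chain directly (M->M, no indel neighbours); each missing segment is a
    single self-looping emitting deletion state; each CDR interval gets full
    M/D/I profile wiring; uniform-emission flank states with self-loops
    absorb unaligned N/C termini.  Alignment is semi-global: entry is spread
    over all match states and every non-final match carries a small terminal
    exit, so a query may leave template termini unmatched (lowering coverage)
    but can never open an internal constant-region gap.  With
    ``semi_global=False`` entry and exit are pinned to the first and last
    template positions (global traversal) — the form used when *sampling*
    full-length sequences rather than scoring arbitrary queries.
    """
    params = params or HmmBuildParams()
    params.validate()
    template.validate()
    n = len(template.consensus)
    breaks = set(template.segment_break_positions)
    cdr_of: dict[int, tuple[int, int]] = {}
    for a, b in template.cdr_intervals:
        for brk in breaks:
            if a <= brk < b:
                raise ValueError(
                    f"CDR interval ({a}, {b}) overlaps a missing-segment boundary "
                    f"after consensus position {brk}: wiring would be ambiguous"
                )
        for i in range(a, b + 1):
            cdr_of[i] = (a, b)

    gap_after = {}
    for k, pos in enumerate(sorted(breaks)):
        gap_after[pos] = f"G{k + 1}"

    def next_after(i: int) -> dict[str, float]:
        """Transition mass after consuming consensus position i."""
        if i in gap_after:
            return {gap_after[i]: 1.0}
        if i == n:
            return {"FLANK_C": 1.0 - DIRECT_ENTRY_PROB, "END": DIRECT_ENTRY_PROB}
        return {f"M{i + 1}": 1.0}

    def scaled(dist: dict[str, float], mass: float) -> dict[str, float]:
        return {k: v * mass for k, v in dist.items()}

    def entries(mass: float) -> dict[str, float]:
        # semi-global: the alignment may begin at any template position
        if not semi_global:
            return {"M1": mass}
        return {f"M{k}": mass / n for k in range(1, n + 1)}

    terminal_exit = TERMINAL_EXIT_PROB if semi_global else 0.0
    exit_dist = {"FLANK_C": terminal_exit / 2, "END": terminal_exit / 2}

    states: list[StateSpec] = []
    states.append(StateSpec(
        id="START", kind=StateKind.START,
        transitions={"FLANK_N": 1.0 - DIRECT_ENTRY_PROB,
                     **entries(DIRECT_ENTRY_PROB)},
    ))
    states.append(StateSpec(
        id="FLANK_N", kind=StateKind.FLANK,
        emissions=_uniform_emissions(params.skip_emit),
        transitions={"FLANK_N": params.flank_self,
                     **entries(1.0 - params.flank_self)},
    ))

    half_open = params.cdr_gap_open / 2.0
    for i in range(1, n + 1):
        res = template.consensus[i - 1]
        emissions = {
            aa: params.match_emit if aa == res else params.mismatch_total / (N_AA - 1)
            for aa in AMINO_ACIDS
        }
        if i in cdr_of:
            a, b = cdr_of[i]
            trans: dict[str, float] = {f"I{i}": half_open}
            open_mass = half_open
            if i < b:
                trans[f"D{i + 1}"] = half_open
                open_mass += half_open
            if i < n and terminal_exit:
                trans.update(exit_dist)
                trans.update(scaled(next_after(i),
                                    1.0 - open_mass - terminal_exit))
            else:
                trans.update(scaled(next_after(i), 1.0 - open_mass))
            states.append(StateSpec(
                id=f"M{i}", kind=StateKind.MATCH, emissions=emissions,
                transitions=trans, template_position=i,
            ))
            itrans = {f"I{i}": params.gap_extend}
            itrans.update(scaled(next_after(i), 1.0 - params.gap_extend))
            states.append(StateSpec(
                id=f"I{i}", kind=StateKind.INSERT,
                emissions=_uniform_emissions(params.skip_emit), transitions=itrans,
            ))
            if i > a:
                # D_i skips consensus position i; chains forward while the
                # gap extends, re-enters the match chain when it terminates
                if i < b:
                    dtrans = {f"D{i + 1}": params.gap_extend}
                    dtrans.update(scaled(next_after(i), 1.0 - params.gap_extend))
                else:
                    dtrans = dict(next_after(i))
                states.append(StateSpec(
                    id=f"D{i}", kind=StateKind.DELETE_EMIT,
                    emissions=_uniform_emissions(params.skip_emit), transitions=dtrans,
                ))
        else:
            if i < n and terminal_exit:
                trans = dict(exit_dist)
                trans.update(scaled(next_after(i), 1.0 - terminal_exit))
            else:
                trans = dict(next_after(i))
            states.append(StateSpec(
                id=f"M{i}", kind=StateKind.MATCH, emissions=emissions,
                transitions=trans, template_position=i,
            ))
        if i in gap_after:
            gid = gap_after[i]
            gtrans = {gid: params.gap_extend}
            gtrans.update(scaled(
                {f"M{i + 1}": 1.0} if i < n else
                {"FLANK_C": 1.0 - DIRECT_ENTRY_PROB, "END": DIRECT_ENTRY_PROB},
                1.0 - params.gap_extend,
            ))
            states.append(StateSpec(
                id=gid, kind=StateKind.DELETE_EMIT,
                emissions=_uniform_emissions(params.skip_emit), transitions=gtrans,
            ))

    states.append(StateSpec(
        id="FLANK_C", kind=StateKind.FLANK,
        emissions=_uniform_emissions(params.skip_emit),
        transitions={"FLANK_C": params.flank_self, "END": 1.0 - params.flank_self},
    ))
    states.append(StateSpec(id="END", kind=StateKind.END))

    hmm = HmmSpec(states, start_state="START", end_state="END")
    hmm.validate()
    return hmm
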