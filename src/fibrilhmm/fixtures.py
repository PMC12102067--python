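"""Synthetic template + corpus generator.

Everything downstream (training, selection, structure pruning) is testable
offline from fixtures built here: a random template consensus with declared
CDR intervals and missing segments, a minimal multi-chain backbone PDB file
consistent with the segment numbering (extended poly-backbone geometry,
fibril layers stacked 4.8 Å apart), and a corpus of sequences sampled from
the template's own HMM at controlled mutation and CDR-indel rates, each with
its ground-truth alignment recorded at sampling time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from .alphabet import AMINO_ACIDS
from .hmm import HmmSpec, StateKind, sample
from .template import (
    HmmBuildParams,
    MissingSegment,
    TemplateDefinition,
    build_initial_hmm,
)

_1TO3 = {k: v.upper() for k, v in protein_letters_1to3.items()}

#: inter-layer spacing of stacked fibril chains, Å
LAYER_RISE = 4.8


@dataclass
class FixtureSpec:
    """Parameters of one synthetic template + corpus.

    ``missing_segments`` lists (after_consensus_position, gap_length) pairs;
    ``mutation_rate`` is the per-position probability that a constant-region
    or CDR match emits a non-template residue; ``cdr_indel_rate`` is the
    total gap-open probability inside CDRs.
    """

    template_length: int = 60
    cdr_intervals: tuple[tuple[int, int], ...] = ((25, 34),)
    missing_segments: tuple[tuple[int, int], ...] = ((45, 6),)
    mutation_rate: float = 0.1
    cdr_indel_rate: float = 0.1
    corpus_size: int = 50
    n_chains: int = 2
    rng_seed: int = 0

    def validate(self) -> None:
        if self.template_length < 1:
            raise ValueError("template_length must be >= 1")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate outside [0, 1]")
        if not (0.0 <= self.cdr_indel_rate <= 1.0):
            raise ValueError("cdr_indel_rate outside [0, 1]")
        if self.corpus_size < 1:
            raise ValueError("corpus_size must be >= 1")
        for pos, length in self.missing_segments:
            if not (1 <= pos < self.template_length) or length < 1:
                raise ValueError(f"bad missing segment ({pos}, {length})")


@dataclass
class Fixture:
    template: TemplateDefinition
    structure_path: str
    corpus: dict[str, str]
    alignments: dict[str, list[tuple[int, int]]]
    truth_model: HmmSpec
    #: consensus with every missing segment filled by sampled residues — the
    #: shape of a real full-length query, whose unresolved stretches the
    #: template cannot see but the model must still absorb
    consensus_query: str = ""
    spec: FixtureSpec = field(repr=False, default=None)


def _segments_from_breaks(
    length: int, missing: tuple[tuple[int, int], ...]
) -> tuple[list[tuple[int, int]], list[MissingSegment]]:
    """Author-numbered segments implied by gap positions and lengths."""
    breaks = sorted(missing)
    segments = []
    missing_out = []
    author = 1
    prev = 0
    for pos, gap_len in breaks:
        segments.append((author, author + (pos - prev) - 1))
        author += (pos - prev) + gap_len
        missing_out.append(MissingSegment(pos, gap_len))
        prev = pos
    segments.append((author, author + (length - prev) - 1))
    return segments, missing_out


def write_synthetic_structure(
    template: TemplateDefinition, path: str | Path, n_chains: int = 2
) -> None:
    """Minimal backbone-only PDB for the template: N/CA/C/O per resolved
    residue, extended geometry, chains stacked as fibril layers."""
    sb = StructureBuilder()
    sb.init_structure(template.template_id)
    sb.init_model(0)
    offsets = {"N": (-0.5, 0.4), "CA": (0.0, 0.0), "C": (0.5, 0.4), "O": (0.7, 1.5)}
    for c in range(n_chains):
        cid = chr(ord("A") + c)
        sb.init_chain(cid)
        sb.init_seg("    ")
        for pos in range(1, len(template.consensus) + 1):
            num = template.author_number(pos)
            res3 = _1TO3[template.consensus[pos - 1]]
            sb.init_residue(res3, " ", num, " ")
            for name, (dx, dy) in offsets.items():
                coord = np.array([num * 3.8 + dx, dy, c * LAYER_RISE], dtype="f")
                sb.init_atom(name, coord, 0.0, 1.0, " ", name.center(4), element=name[0])
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


def truth_model_params(spec: FixtureSpec) -> HmmBuildParams:
    """Build parameters of the generating model implied by the fixture rates."""
    return HmmBuildParams(
        match_emit=1.0 - spec.mutation_rate,
        mismatch_total=spec.mutation_rate,
        cdr_gap_open=spec.cdr_indel_rate,
    )


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> Fixture:
    """Random template + synthetic PDB + sampled corpus with ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    consensus = "".join(
        AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), spec.template_length)
    )
    segments, missing = _segments_from_breaks(
        spec.template_length, spec.missing_segments
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structure_path = out_dir / "template_synthetic.pdb"
    template = TemplateDefinition(
        template_id=f"SYN{spec.rng_seed}",
        consensus=consensus,
        segments=segments,
        missing_segments=missing,
        cdr_intervals=list(spec.cdr_intervals),
        structure_path=str(structure_path),
        chain="A",
    )
    template.validate()
    write_synthetic_structure(template, structure_path, n_chains=spec.n_chains)
    # sampling uses the global-traversal form: corpus sequences emulate
    # full-length chains spanning the whole template, not fragments
    truth = build_initial_hmm(template, truth_model_params(spec),
                              semi_global=False)
    corpus: dict[str, str] = {}
    alignments: dict[str, list[tuple[int, int]]] = {}
    for k in range(spec.corpus_size):
        seq, path = sample(truth, rng)
        sid = f"seq{k:04d}"
        corpus[sid] = seq
        pairs = []
        for qpos, state_id in enumerate(path, start=1):
            st = truth.state(state_id)
            if st.kind is StateKind.MATCH:
                pairs.append((st.template_position, qpos))
        alignments[sid] = pairs
    query_parts = []
    cursor = 0
    for m in missing:
        query_parts.append(consensus[cursor:m.after_consensus_position])
        query_parts.append("".join(
            AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), m.length)
        ))
        cursor = m.after_consensus_position
    query_parts.append(consensus[cursor:])
    return Fixture(
        template=template,
        structure_path=str(structure_path),
        corpus=corpus,
        alignments=alignments,
        truth_model=truth,
        consensus_query="".join(query_parts),
        spec=spec,
    )
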