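"""FASTA and model/template JSON serialization.

The FASTA layer is deliberately permissive: residue validation happens when a
model consumes a sequence, not at parse time, so arbitrary corpora can be
loaded and filtered first.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hmm import HmmSpec, StateKind, StateSpec
from .template import MissingSegment, TemplateDefinition

MODEL_FORMAT_VERSION = 1


class FastaFormatError(ValueError):
    pass


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-FASTA file -> ordered {id: sequence} mapping."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}:{lineno}: expected a '>' header before sequence data"
                )
            break
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FastaFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns, preserving identifiers."""
    records = [
        SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# model / template serialization


def hmm_to_dict(hmm: HmmSpec) -> dict:
    return {
        "start_state": hmm.start_state,
        "end_state": hmm.end_state,
        "states": [
            {
                "id": s.id,
                "kind": s.kind.value,
                "transitions": s.transitions,
                "emissions": s.emissions,
                "template_position": s.template_position,
            }
            for s in hmm.states
        ],
    }


def hmm_from_dict(data: dict) -> HmmSpec:
    states = [
        StateSpec(
            id=d["id"],
            kind=StateKind(d["kind"]),
            transitions=dict(d["transitions"]),
            emissions=dict(d["emissions"]) if d["emissions"] is not None else None,
            template_position=d["template_position"],
        )
        for d in data["states"]
    ]
    return HmmSpec(states, data["start_state"], data["end_state"])


def template_to_dict(tdef: TemplateDefinition) -> dict:
    return {
        "template_id": tdef.template_id,
        "consensus": tdef.consensus,
        "segments": [list(s) for s in tdef.segments],
        "missing_segments": [
            {"after_consensus_position": m.after_consensus_position,
             "length": m.length}
            for m in tdef.missing_segments
        ],
        "cdr_intervals": [list(c) for c in tdef.cdr_intervals],
        "structure_path": tdef.structure_path,
        "chain": tdef.chain,
    }


def template_from_dict(data: dict) -> TemplateDefinition:
    return TemplateDefinition(
        template_id=data["template_id"],
        consensus=data["consensus"],
        segments=[tuple(s) for s in data["segments"]],
        missing_segments=[
            MissingSegment(m["after_consensus_position"], m["length"])
            for m in data["missing_segments"]
        ],
        cdr_intervals=[tuple(c) for c in data["cdr_intervals"]],
        structure_path=data.get("structure_path"),
        chain=data.get("chain", "A"),
    )


def save_model(
    hmm: HmmSpec,
    template: TemplateDefinition,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Versioned JSON bundle: template definition + HMM + provenance."""
    payload = {
        "format": "fibrilhmm-model",
        "version": MODEL_FORMAT_VERSION,
        "template": template_to_dict(template),
        "hmm": hmm_to_dict(hmm),
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[HmmSpec, TemplateDefinition, dict]:
    data = json.loads(Path(path).read_text())
    version = data.get("version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model file {path} has format version {version}; "
            f"this build reads version {MODEL_FORMAT_VERSION}"
        )
    hmm = hmm_from_dict(data["hmm"])
    hmm.validate()
    return hmm, template_from_dict(data["template"]), data.get("metadata", {})
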