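"""Backbone pruning and side-chain job emission for homology modeling.

Once a query is deemed modelable, its structural model reuses the template
backbone verbatim: template residues not covered by the alignment are pruned
(whole residues, symmetrically on every chain of the fibril stack), and the
remaining positions where the query differs from the template are written as
a mutation list for an external side-chain optimization force field (the
``buildmodel``-style individual-list dialect: semicolon-terminated lines of
comma-separated ``<wt><chain><number><mutant>`` tokens).  Backbone
coordinates are never touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio.PDB import PDBIO, PDBParser

from .alphabet import AMINO_ACIDS
from .selection import AlignmentResult
from .template import TemplateDefinition


@dataclass
class PrunedStructure:
    """Template coordinates restricted to alignment-covered residues."""

    structure: object  # Bio.PDB Structure
    template_id: str
    chains: list[str]
    #: consensus position -> (author residue number, query sequence position)
    residue_map: dict[int, tuple[int, int]]


@dataclass
class Mutation:
    chain: str
    residue_number: int
    template_residue: str
    query_residue: str

    def token(self) -> str:
        return (
            f"{self.template_residue}{self.chain}"
            f"{self.residue_number}{self.query_residue}"
        )


@dataclass
class SideChainJob:
    pruned_pdb: str
    mutation_list: str
    manifest: str
    mutations: list[Mutation] = field(default_factory=list)


class PruningError(ValueError):
    pass


def prune_backbone(
    template_structure: str | Path,
    template: TemplateDefinition,
    alignment: AlignmentResult,
    chains: list[str] | None = None,
) -> PrunedStructure:
    """Remove every residue not covered by the alignment, on all chains.

    Residues are matched across chains by author number (fibril layers share
    numbering), and removed whole; retained coordinates are not modified.
    A degenerate (empty) alignment is an error — there is nothing to model.
    """
    if not alignment.pairs:
        raise PruningError("alignment is degenerate (no matched positions)")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(template.template_id, str(template_structure))
    model = next(structure.get_models())
    keep_numbers = {}
    residue_map = {}
    for tpos, qpos in alignment.pairs:
        num = template.author_number(tpos)
        keep_numbers[num] = tpos
        residue_map[tpos] = (num, qpos)
    selected = chains or [c.id for c in model]
    for cid in selected:
        if cid not in [c.id for c in model]:
            raise PruningError(f"chain {cid!r} absent from template structure")
    present = {
        res.id[1]
        for cid in selected
        for res in model[cid]
        if res.id[0] == " "
    }
    missing = sorted(set(keep_numbers) - present)
    if missing:
        raise PruningError(
            "alignment references consensus positions absent from the "
            f"structure (author numbers {missing})"
        )
    for chain in list(model):
        if chain.id not in selected:
            model.detach_child(chain.id)
            continue
        for res in list(chain):
            if res.id[0] != " " or res.id[1] not in keep_numbers:
                chain.detach_child(res.id)
    return PrunedStructure(
        structure=structure,
        template_id=template.template_id,
        chains=selected,
        residue_map=residue_map,
    )


def write_pruned_pdb(pruned: PrunedStructure, path: str | Path) -> None:
    io = PDBIO()
    io.set_structure(pruned.structure)
    io.save(str(path))


def build_mutation_list(
    pruned: PrunedStructure,
    template: TemplateDefinition,
    query_seq: str,
) -> list[Mutation]:
    """Substitutions needed to turn the retained template residues into the
    query, applied symmetrically to every retained chain.  Identity positions
    are omitted."""
    mutations = []
    for tpos in sorted(pruned.residue_map):
        num, qpos = pruned.residue_map[tpos]
        wt = template.consensus[tpos - 1]
        mut = query_seq[qpos - 1]
        if mut not in AMINO_ACIDS:
            raise ValueError(
                f"query residue {mut!r} at position {qpos} is not canonical"
            )
        if wt == mut:
            continue
        for cid in pruned.chains:
            mutations.append(Mutation(cid, num, wt, mut))
    return mutations


def emit_sidechain_job(
    pruned: PrunedStructure,
    template: TemplateDefinition,
    query_seq: str,
    out_dir: str | Path,
    query_id: str = "query",
) -> SideChainJob:
    """Write the pruned backbone, the individual-style mutation list, and a
    JSON manifest describing the side-chain modeling job."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_path = out_dir / f"{query_id}_pruned.pdb"
    list_path = out_dir / "individual_list.txt"
    manifest_path = out_dir / "job_manifest.json"
    write_pruned_pdb(pruned, pdb_path)
    mutations = build_mutation_list(pruned, template, query_seq)
    line = ",".join(m.token() for m in mutations) + ";" if mutations else ";"
    list_path.write_text(line + "\n")
    manifest_path.write_text(json.dumps({
        "job_type": "sidechain-buildmodel",
        "template_id": pruned.template_id,
        "query_id": query_id,
        "pruned_pdb": pdb_path.name,
        "mutation_list": list_path.name,
        "chains": pruned.chains,
        "n_mutations": len(mutations),
        "backbone_frozen": True,
    }, indent=2))
    return SideChainJob(
        pruned_pdb=str(pdb_path),
        mutation_list=str(list_path),
        manifest=str(manifest_path),
        mutations=mutations,
    )


def read_mutation_list(path: str | Path) -> list[Mutation]:
    """Parse an individual-list mutation file back into Mutation records."""
    mutations = []
    for line in Path(path).read_text().splitlines():
        line = line.strip().rstrip(";")
        if not line:
            continue
        for token in line.split(","):
            token = token.strip()
            if not token:
                continue
            wt, cid, rest = token[0], token[1], token[2:]
            mutations.append(Mutation(cid, int(rest[:-1]), wt, rest[-1]))
    return mutations
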