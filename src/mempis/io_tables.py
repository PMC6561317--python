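"""TSV/JSON readers and writers for evidence files, solutions and run reports.

Evidence TSV: columns ``condition``, ``kind`` (compound|ec), ``id``.
Solution TSV: columns ``condition``, ``node_id``, ``node_kind``
(reaction|compound), ``role``:

* ``forced`` — active reaction carrying an over-expressed EC,
* ``covering`` — active reaction incident to a measured compound (and the
  measured compounds themselves),
* ``connector`` — everything kept purely for connectivity.

The JSON run report records objective, status, solver, seed, mode and the
unmapped-evidence report; wall-clock timing goes to the structured logs so
report files are byte-stable across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

from .mempis_core import ActiveSubnetwork, UnmappedEvidence
from .reaction_db import MetabolicNetwork

__all__ = [
    "read_evidence_table",
    "write_evidence_table",
    "write_solution",
    "read_solution",
    "write_run_report",
]


def read_evidence_table(path: str | Path) -> dict[str, dict[str, list[str]]]:
    """Parse an evidence TSV into {condition: {"compounds": [...], "ecs": [...]}}."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:3] != ["condition", "kind", "id"]:
        raise ValueError(f"{path}: expected header 'condition\\tkind\\tid'")
    out: dict[str, dict[str, list[str]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        condition, kind, ident = (p.strip() for p in parts[:3])
        if kind not in ("compound", "ec"):
            raise ValueError(f"{path}:{lineno}: kind must be compound|ec, got {kind!r}")
        bucket = out.setdefault(condition, {"compounds": [], "ecs": []})
        bucket["compounds" if kind == "compound" else "ecs"].append(ident)
    return out


def write_evidence_table(
    evidence: dict[str, dict[str, list[str]]], path: str | Path
) -> None:
    rows = ["condition\tkind\tid"]
    for condition in sorted(evidence):
        for cid in sorted(evidence[condition].get("compounds", [])):
            rows.append(f"{condition}\tcompound\t{cid}")
        for ec in sorted(evidence[condition].get("ecs", [])):
            rows.append(f"{condition}\tec\t{ec}")
    Path(path).write_text("\n".join(rows) + "\n")


def _reaction_role(rid: str, net: MetabolicNetwork, sol: ActiveSubnetwork) -> str:
    if any(ec in sol.forced_ecs for ec in net.reactions[rid].ecs):
        return "forced"
    if net.reactions[rid].participants & sol.measured_compounds:
        return "covering"
    return "connector"


def write_solution(
    sol: ActiveSubnetwork, net: MetabolicNetwork, path: str | Path
) -> None:
    rows = ["condition\tnode_id\tnode_kind\trole"]
    for rid in sorted(sol.active_reactions):
        rows.append(f"{sol.condition}\t{rid}\treaction\t{_reaction_role(rid, net, sol)}")
    for cid in sorted(sol.connector_compounds):
        role = "covering" if cid in sol.measured_compounds else "connector"
        rows.append(f"{sol.condition}\t{cid}\tcompound\t{role}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_solution(path: str | Path) -> ActiveSubnetwork:
    """Reconstruct an :class:`ActiveSubnetwork` from a solution TSV (status is
    assumed optimal; evidence roles are recovered from the role column)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:4] != [
        "condition",
        "node_id",
        "node_kind",
        "role",
    ]:
        raise ValueError(f"{path}: bad solution header")
    condition = ""
    reactions, compounds, measured = set(), set(), set()
    for line in lines[1:]:
        if not line.strip():
            continue
        condition, node_id, node_kind, role = line.split("\t")[:4]
        if node_kind == "reaction":
            reactions.add(node_id)
        else:
            compounds.add(node_id)
            if role == "covering":
                measured.add(node_id)
    return ActiveSubnetwork(
        condition=condition,
        active_reactions=frozenset(reactions),
        connector_compounds=frozenset(compounds),
        objective=len(reactions),
        status="optimal",
        measured_compounds=frozenset(measured),
    )


def write_run_report(
    sol: ActiveSubnetwork,
    path: str | Path,
    seed: int | None = None,
    unmapped: UnmappedEvidence | None = None,
    forcing_mode: str = "at_least_one",
) -> None:
    report = {
        "condition": sol.condition,
        "objective": sol.objective,
        "status": sol.status,
        "solver": "scipy-highs",
        "seed": seed,
        "forcing_mode": forcing_mode,
        "n_active_reactions": len(sol.active_reactions),
        "n_connector_compounds": len(sol.connector_compounds),
        "infeasible_items": list(sol.infeasible_items),
        "unmapped_evidence": unmapped.as_dict() if unmapped else None,
    }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
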