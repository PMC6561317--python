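"""Module-level classification and comparison of solved subnetworks.

Active reactions are binned by their reaction-module annotations; a reaction
annotated to several modules counts once per module, and unannotated
reactions accumulate under the reserved ``"unassigned"`` key.  Per-condition
module distributions are compared by correlating fraction vectors over the
union of module keys, and condition-tagged bipartite graphs are exported as
GraphML or GEXF for downstream visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .mempis_core import ActiveSubnetwork
from .reaction_db import MetabolicNetwork

__all__ = [
    "UNASSIGNED",
    "ModuleDistribution",
    "ConditionComparison",
    "classify",
    "distribution_correlation",
    "compare_conditions",
    "tag_across_networks",
    "export_graph",
    "write_distribution",
    "read_distribution",
]

UNASSIGNED = "unassigned"


@dataclass
class ModuleDistribution:
    """Counts (and fractions summing to 1) of active reactions per module."""

    condition: str
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.counts


@dataclass
class ConditionComparison:
    """Set-algebra tags and a distribution correlation for two conditions."""

    first: str
    second: str
    tags: dict[str, str]  # reaction id -> "first-only" | "second-only" | "both"
    correlation: float  # NaN when undefined


def classify(sol: ActiveSubnetwork, net: MetabolicNetwork) -> ModuleDistribution:
    """Bin a solved subnetwork's active reactions into reaction modules."""
    counts: dict[str, int] = {}
    for rid in sol.active_reactions:
        modules = net.reactions[rid].modules or frozenset({UNASSIGNED})
        for mod in modules:
            counts[mod] = counts.get(mod, 0) + 1
    total = sum(counts.values())
    fractions = {m: c / total for m, c in counts.items()} if total else {}
    return ModuleDistribution(condition=sol.condition, counts=counts, fractions=fractions)


def distribution_correlation(
    a: ModuleDistribution,
    b: ModuleDistribution,
    method: str = "pearson",
    use: str = "fractions",
) -> float:
    """Correlation of two module distributions over the union of their keys.

    Absent keys contribute 0.  Returns NaN (with a warning) when either
    vector is constant over the union — a 1-module union, or an empty
    distribution — where the coefficient is undefined.
    """
    if use not in ("fractions", "counts"):
        raise ValueError(f"use must be 'fractions' or 'counts', got {use!r}")
    keys = sorted(set(a.counts) | set(b.counts))
    src_a = a.fractions if use == "fractions" else a.counts
    src_b = b.fractions if use == "fractions" else b.counts
    va = np.array([src_a.get(k, 0.0) for k in keys], dtype=float)
    vb = np.array([src_b.get(k, 0.0) for k in keys], dtype=float)
    if len(keys) < 2 or np.ptp(va) == 0 or np.ptp(vb) == 0:
        warnings.warn(
            "module-distribution correlation undefined (constant vector); "
            "returning NaN",
            stacklevel=2,
        )
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(va, vb).statistic)
    if method == "spearman":
        return float(stats.spearmanr(va, vb).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def compare_conditions(
    sol1: ActiveSubnetwork,
    sol2: ActiveSubnetwork,
    net: MetabolicNetwork,
    method: str = "pearson",
) -> ConditionComparison:
    """Tag each active reaction by condition membership and correlate the
    module distributions of the two solutions."""
    tags: dict[str, str] = {}
    for rid in sorted(sol1.active_reactions | sol2.active_reactions):
        in1 = rid in sol1.active_reactions
        in2 = rid in sol2.active_reactions
        tags[rid] = "both" if (in1 and in2) else ("first-only" if in1 else "second-only")
    d1, d2 = classify(sol1, net), classify(sol2, net)
    if d1.is_empty or d2.is_empty:
        corr = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = distribution_correlation(d1, d2, method=method)
    return ConditionComparison(
        first=sol1.condition, second=sol2.condition, tags=tags, correlation=corr
    )


def tag_across_networks(
    sols_a: Sequence[ActiveSubnetwork], sols_b: Sequence[ActiveSubnetwork]
) -> dict[str, str]:
    """Tag reactions as ``common`` (predicted in both network/soil solution
    groups) or ``unique``; drives the node-size attribute on export."""
    set_a = frozenset().union(*(s.active_reactions for s in sols_a)) if sols_a else frozenset()
    set_b = frozenset().union(*(s.active_reactions for s in sols_b)) if sols_b else frozenset()
    return {
        rid: ("common" if rid in set_a and rid in set_b else "unique")
        for rid in sorted(set_a | set_b)
    }


def export_graph(
    sols: ActiveSubnetwork | Sequence[ActiveSubnetwork],
    net: MetabolicNetwork,
    path: str | Path,
    fmt: str = "graphml",
    cross_tags: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Write the union of one or more solved subnetworks as a bipartite graph.

    Node attributes: ``kind`` (reaction|compound), ``condition`` tag
    (first|second|both for two solutions, the condition label for one),
    ``modules`` (semicolon-joined), and — when ``cross_tags`` is given —
    ``cross`` (common|unique) plus a numeric ``size`` attribute (2 for common,
    1 for unique).  Edges are the incidences between exported reactions and
    compounds.  Nodes are inserted in sorted order so output bytes are stable.
    """
    if isinstance(sols, ActiveSubnetwork):
        sols = [sols]
    if fmt not in ("graphml", "gexf"):
        raise ValueError(f"unknown graph format {fmt!r}")

    r_members = [s.active_reactions for s in sols]
    c_members = [s.connector_compounds for s in sols]
    all_r = sorted(frozenset().union(*r_members)) if sols else []
    all_c = sorted(frozenset().union(*c_members)) if sols else []

    g = nx.Graph()
    for cid in all_c:
        g.add_node(
            cid,
            kind="compound",
            condition=_tag_for(cid, c_members, sols),
            modules="",
        )
    for rid in all_r:
        attrs = {
            "kind": "reaction",
            "condition": _tag_for(rid, r_members, sols),
            "modules": ";".join(sorted(net.reactions[rid].modules)),
        }
        if cross_tags is not None:
            cross = cross_tags.get(rid, "unique")
            attrs["cross"] = cross
            attrs["size"] = 2 if cross == "common" else 1
        g.add_node(rid, **attrs)
        for cid in sorted(net.reactions[rid].participants):
            if cid in g:
                g.add_edge(rid, cid)

    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    else:
        nx.write_gexf(g, path)
    return g


def _tag_for(
    node_id: str, memberships: list[frozenset[str]], sols: Sequence[ActiveSubnetwork]
) -> str:
    present = [i for i, members in enumerate(memberships) if node_id in members]
    if len(sols) == 1:
        return sols[0].condition
    if len(present) >= len(sols):
        return "both"
    if present == [0]:
        return "first"
    if present == [1]:
        return "second"
    return "+".join(sols[i].condition for i in present)


def write_distribution(dists: Iterable[ModuleDistribution], path: str | Path) -> None:
    """Module distribution TSV: condition, module, count, fraction."""
    rows = ["condition\tmodule\tcount\tfraction"]
    for dist in dists:
        for mod in sorted(dist.counts):
            rows.append(
                f"{dist.condition}\t{mod}\t{dist.counts[mod]}\t"
                f"{dist.fractions.get(mod, 0.0):.10g}"
            )
    Path(path).write_text("\n".join(rows) + "\n")


def read_distribution(path: str | Path) -> list[ModuleDistribution]:
    lines = Path(path).read_text().splitlines()
    dists: dict[str, ModuleDistribution] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        condition, mod, count, fraction = line.split("\t")
        dist = dists.setdefault(condition, ModuleDistribution(condition=condition))
        dist.counts[mod] = int(count)
        dist.fractions[mod] = float(fraction)
    return list(dists.values())
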