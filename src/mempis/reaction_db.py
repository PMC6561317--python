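"""Bipartite compound-reaction networks from KEGG-style reaction tables.

The network model is deliberately *binary*: after parsing, stoichiometric
coefficients are discarded and only participation (which compounds take part
in which reactions) is kept, so the graph is a complete description of
connectivity between metabolites and reactions.  Directionality is likewise
discarded; the reversibility marker of the source equation is preserved as
metadata only.

Input format
------------
Reaction table: TSV with a header row and columns

    reaction_id  equation  ecs  modules  pathways

where ``equation`` uses KEGG-equation syntax (``C00031 + C00002 <=> C00092 +
C00008``, coefficients as leading integers) and the last three columns are
semicolon-separated lists (may be empty).  An optional compound table
(``compound_id``, ``name``) supplies display names.  Glycan (G-number) and
generic polymer ("n") entries are not understood and must be filtered out of
the table before loading; the parser rejects non-integer coefficients.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "DEFAULT_CURRENCY",
    "Compound",
    "Reaction",
    "MetabolicNetwork",
    "EquationParseError",
    "NetworkFormatError",
    "parse_equation",
    "load_network",
    "build_network",
    "write_network",
    "network_stats",
]

#: Ubiquitous cofactors whose hub connectivity would trivialize minimal
#: subnetworks: water, ATP, NAD(+/H), NADP(+/H), O2, ADP, orthophosphate,
#: CO2 and H+.  Overridable (including to the empty set) in load_network.
DEFAULT_CURRENCY: frozenset[str] = frozenset(
    {
        "C00001",  # H2O
        "C00002",  # ATP
        "C00003",  # NAD+
        "C00004",  # NADH
        "C00005",  # NADPH
        "C00006",  # NADP+
        "C00007",  # O2
        "C00008",  # ADP
        "C00009",  # orthophosphate
        "C00011",  # CO2
        "C00080",  # H+
    }
)


class EquationParseError(ValueError):
    """Raised for malformed reaction equations; names the offending token."""


class NetworkFormatError(ValueError):
    """Raised for structural problems in a reaction/compound table."""


@dataclass(frozen=True)
class Compound:
    """A metabolite node.

    ``is_currency`` is derived from the loader's blacklist, never read from
    input files.
    """

    id: str
    name: str = ""
    is_currency: bool = False


@dataclass(frozen=True)
class Reaction:
    """A reaction node with its (binary-converted) participants.

    ``substrates``/``products`` retain the parsed coefficients for
    round-tripping, but everything downstream of the loader uses only
    ``participants`` — the union of both sides.
    """

    id: str
    substrates: Mapping[str, int]
    products: Mapping[str, int]
    ecs: frozenset[str] = frozenset()
    modules: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()
    reversible: bool = True

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise NetworkFormatError(
                f"reaction {self.id!r}: both equation sides must be nonempty"
            )
        overlap = set(self.substrates) & set(self.products)
        if overlap:
            raise NetworkFormatError(
                f"reaction {self.id!r}: compounds on both sides: {sorted(overlap)}"
            )
        for cid, k in list(self.substrates.items()) + list(self.products.items()):
            if not isinstance(k, int) or k < 1:
                raise NetworkFormatError(
                    f"reaction {self.id!r}: coefficient of {cid!r} must be a positive integer"
                )

    @property
    def participants(self) -> frozenset[str]:
        return frozenset(self.substrates) | frozenset(self.products)


@dataclass
class MetabolicNetwork:
    """Bipartite compound-reaction graph with EC and module indexes."""

    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    graph: nx.Graph = field(default_factory=nx.Graph)
    ec_index: dict[str, frozenset[str]] = field(default_factory=dict)
    module_index: dict[str, frozenset[str]] = field(default_factory=dict)

    def incident_reactions(self, compound_id: str) -> frozenset[str]:
        """Reactions in which ``compound_id`` participates (either side)."""
        if compound_id not in self.compounds:
            return frozenset()
        return frozenset(n[1] for n in self.graph.neighbors(("c", compound_id)))

    @property
    def currency_compounds(self) -> frozenset[str]:
        return frozenset(c.id for c in self.compounds.values() if c.is_currency)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


_TERM_RE = re.compile(r"^(?:(\d+)\s+)?(\S+)$")


def _parse_side(side: str, *, line: str) -> dict[str, int]:
    coeffs: dict[str, int] = {}
    terms = [t.strip() for t in side.split("+")]
    if any(not t for t in terms):
        raise EquationParseError(f"empty term in equation side {side!r} (line {line!r})")
    for term in terms:
        m = _TERM_RE.match(term)
        if m is None:
            raise EquationParseError(f"malformed term {term!r} (line {line!r})")
        k = int(m.group(1)) if m.group(1) else 1
        cid = m.group(2)
        if k < 1:
            raise EquationParseError(f"nonpositive coefficient in {term!r} (line {line!r})")
        if cid in coeffs:
            raise EquationParseError(
                f"duplicate compound {cid!r} on one side (line {line!r})"
            )
        coeffs[cid] = k
    return coeffs


def parse_equation(text: str) -> tuple[dict[str, int], dict[str, int]]:
    """Parse a KEGG-style equation into (substrates, products) coefficient maps.

    Exactly one of the separators ``<=>``, ``=>``, ``<=`` must occur; ``<=``
    swaps sides so that substrates are always the consumed set reading left to
    right.  Directionality is otherwise discarded by the binary representation.
    """
    text = text.strip()
    if "<=>" in text:
        lhs, rhs = text.split("<=>", 1)
        swap = False
    elif "=>" in text:
        lhs, rhs = text.split("=>", 1)
        swap = False
    elif "<=" in text:
        lhs, rhs = text.split("<=", 1)
        swap = True
    else:
        raise EquationParseError(f"no reaction separator in {text!r}")
    for side, which in ((lhs, "left"), (rhs, "right")):
        if not side.strip():
            raise EquationParseError(f"empty {which} side in {text!r}")
    subs = _parse_side(lhs, line=text)
    prods = _parse_side(rhs, line=text)
    if swap:
        subs, prods = prods, subs
    return subs, prods


def _split_list(cell: str) -> frozenset[str]:
    return frozenset(x.strip() for x in cell.split(";") if x.strip())


def build_network(
    reactions: Iterable[Reaction],
    compound_names: Mapping[str, str] | None = None,
    currency_blacklist: Iterable[str] = DEFAULT_CURRENCY,
) -> MetabolicNetwork:
    """Assemble a :class:`MetabolicNetwork` from parsed reactions.

    Compounds referenced by equations but absent from ``compound_names`` are
    created with empty names.  ``is_currency`` comes solely from the blacklist.
    """
    names = dict(compound_names or {})
    blacklist = frozenset(currency_blacklist)
    net = MetabolicNetwork()
    ec_index: dict[str, set[str]] = {}
    mod_index: dict[str, set[str]] = {}
    for rxn in reactions:
        if rxn.id in net.reactions:
            raise NetworkFormatError(f"duplicate reaction id {rxn.id!r}")
        net.reactions[rxn.id] = rxn
        net.graph.add_node(("r", rxn.id), kind="reaction")
        for cid in sorted(rxn.participants):
            if cid not in net.compounds:
                net.compounds[cid] = Compound(
                    id=cid, name=names.get(cid, ""), is_currency=cid in blacklist
                )
                net.graph.add_node(("c", cid), kind="compound")
            net.graph.add_edge(("r", rxn.id), ("c", cid))
        for ec in rxn.ecs:
            ec_index.setdefault(ec, set()).add(rxn.id)
        for mod in rxn.modules:
            mod_index.setdefault(mod, set()).add(rxn.id)
    net.ec_index = {ec: frozenset(v) for ec, v in ec_index.items()}
    net.module_index = {m: frozenset(v) for m, v in mod_index.items()}
    return net


_REACTION_COLUMNS = ["reaction_id", "equation", "ecs", "modules", "pathways"]


def load_network(
    reaction_table: str | Path,
    compound_table: str | Path | None = None,
    currency_blacklist: Iterable[str] = DEFAULT_CURRENCY,
) -> MetabolicNetwork:
    """Load the master network from a reaction TSV (and optional compound TSV)."""
    path = Path(reaction_table)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise OSError(f"cannot read reaction table {path}: {exc}") from exc

    names: dict[str, str] = {}
    if compound_table is not None:
        cpath = Path(compound_table)
        try:
            clines = cpath.read_text().splitlines()
        except OSError as exc:
            raise OSError(f"cannot read compound table {cpath}: {exc}") from exc
        for i, line in enumerate(clines):
            if i == 0 or not line.strip():
                continue
            parts = line.split("\t")
            names[parts[0].strip()] = parts[1].strip() if len(parts) > 1 else ""

    reactions: list[Reaction] = []
    if lines:
        header = lines[0].rstrip("\n").split("\t")
        if [h.strip() for h in header[: len(_REACTION_COLUMNS)]] != _REACTION_COLUMNS:
            raise NetworkFormatError(
                f"{path}: expected header columns {_REACTION_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise NetworkFormatError(f"{path}:{lineno}: expected >=2 columns")
            parts += [""] * (5 - len(parts))
            rid, equation, ecs, modules, pathways = parts[:5]
            subs, prods = parse_equation(equation)
            reactions.append(
                Reaction(
                    id=rid.strip(),
                    substrates=subs,
                    products=prods,
                    ecs=_split_list(ecs),
                    modules=_split_list(modules),
                    pathways=_split_list(pathways),
                    reversible="<=>" in equation,
                )
            )
    return build_network(reactions, names, currency_blacklist)


def _format_side(coeffs: Mapping[str, int]) -> str:
    return " + ".join(
        (f"{k} {cid}" if k != 1 else cid) for cid, k in sorted(coeffs.items())
    )


def write_network(net: MetabolicNetwork, reaction_table: str | Path) -> None:
    """Write the reaction table back out in the canonical TSV dialect.

    Reloading the written table yields an isomorphic network (same ids, edges
    and annotations); compound display names live in the separate compound
    table and are not round-tripped here.
    """
    rows = ["\t".join(_REACTION_COLUMNS)]
    for rid in sorted(net.reactions):
        rxn = net.reactions[rid]
        sep = "<=>" if rxn.reversible else "=>"
        eq = f"{_format_side(rxn.substrates)} {sep} {_format_side(rxn.products)}"
        rows.append(
            "\t".join(
                [
                    rid,
                    eq,
                    ";".join(sorted(rxn.ecs)),
                    ";".join(sorted(rxn.modules)),
                    ";".join(sorted(rxn.pathways)),
                ]
            )
        )
    Path(reaction_table).write_text("\n".join(rows) + "\n")


def network_stats(net: MetabolicNetwork) -> dict[str, int]:
    """Summary counts: reactions, compounds, incidence edges, ECs, modules."""
    return {
        "reactions": len(net.reactions),
        "compounds": len(net.compounds),
        "edges": net.graph.number_of_edges(),
        "ecs": len(net.ec_index),
        "modules": len(net.module_index),
    }


def stats_json(net: MetabolicNetwork) -> str:
    return json.dumps(network_stats(net), sort_keys=True)
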