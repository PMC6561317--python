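"""Minimal active-subnetwork selection by mixed-integer linear programming.

Given a bipartite compound-reaction network, a set of measured metabolites and
a set of over-expressed enzyme classes (EC numbers), find the smallest set of
reactions that

* covers every measured metabolite (at least one incident reaction active,
  whether producing or consuming it),
* activates the reactions associated with each over-expressed EC (at least
  one carrier by default, or all carriers in ``"all"`` mode), and
* connects all of these evidence terminals through shared non-currency
  metabolites — a Steiner-style connectivity requirement on the bipartite
  graph, encoded with single-commodity flow.

Currency metabolites (water, ATP, ...) never act as connectors; a *measured*
currency compound is still a terminal, attached to the connected subnetwork
through exactly one selected witness reaction.  Over-expressed ECs with many
carrier reactions are handled the same way: an auxiliary terminal per EC whose
flow is confined to a single chosen witness, so "connect the evidence" never
leaks connectivity through an enzyme class or a cofactor pool.

The MILP is solved exactly with HiGHS branch and bound via
:func:`scipy.optimize.milp`.  ``brute_force_minimal`` is an independent
exhaustive oracle for small networks, and ``verify_solution`` re-checks any
solution by plain graph traversal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .reaction_db import MetabolicNetwork

__all__ = [
    "EvidenceSet",
    "ActiveSubnetwork",
    "SolverOptions",
    "BruteForceResult",
    "SolverUnavailableError",
    "map_evidence",
    "solve_minimal_subnetwork",
    "brute_force_minimal",
    "verify_solution",
    "enumerate_alternates",
]


class SolverUnavailableError(RuntimeError):
    """The configured MILP backend cannot be used."""


@dataclass(frozen=True)
class EvidenceSet:
    """Per-condition constraints: measured compounds and over-expressed ECs."""

    condition: str
    measured_compounds: frozenset[str] = frozenset()
    overexpressed_ecs: frozenset[str] = frozenset()


@dataclass(frozen=True)
class UnmappedEvidence:
    """Evidence items that could not be matched to the network, with reasons."""

    compounds: tuple[tuple[str, str], ...] = ()
    ecs: tuple[tuple[str, str], ...] = ()

    def as_dict(self) -> dict[str, list[dict[str, str]]]:
        return {
            "compounds": [{"id": i, "reason": r} for i, r in self.compounds],
            "ecs": [{"id": i, "reason": r} for i, r in self.ecs],
        }


@dataclass
class ActiveSubnetwork:
    """A solved condition-specific subnetwork."""

    condition: str
    active_reactions: frozenset[str]
    connector_compounds: frozenset[str]
    objective: int
    status: str  # "optimal" | "infeasible" | "within-gap"
    measured_compounds: frozenset[str] = frozenset()
    forced_ecs: frozenset[str] = frozenset()
    infeasible_items: tuple[str, ...] = ()
    alternates: list[frozenset[str]] | None = None


@dataclass(frozen=True)
class SolverOptions:
    """Knobs for the MILP.

    forcing_mode
        ``"at_least_one"`` (default): each over-expressed EC activates at
        least one of its carrier reactions.  ``"all"``: every carrier.
    epsilon_compounds
        Include the tiny compound-parsimony term in the objective so the
        connector set is minimal among reaction-count optima.
    deterministic
        Add an even tinier per-reaction rank weight so the reported optimum
        is reproducible across runs when alternates exist.
    time_limit
        Seconds per solve; hitting it yields status "within-gap" with the
        incumbent, never silently "optimal".
    """

    forcing_mode: str = "at_least_one"
    epsilon_compounds: bool = True
    deterministic: bool = True
    time_limit: float = 300.0

    def __post_init__(self) -> None:
        if self.forcing_mode not in ("at_least_one", "all"):
            raise ValueError(f"unknown forcing mode {self.forcing_mode!r}")


def map_evidence(
    net: MetabolicNetwork,
    condition: str,
    compounds: Iterable[str] = (),
    ecs: Iterable[str] = (),
) -> tuple[EvidenceSet, UnmappedEvidence]:
    """Partition raw evidence into mapped constraints and an unmapped report.

    Nothing is dropped silently: compounds missing from the network and ECs
    carried by no reaction are listed with reasons.
    """
    mapped_c, bad_c = set(), []
    for cid in sorted(set(compounds)):
        if cid in net.compounds:
            mapped_c.add(cid)
        else:
            bad_c.append((cid, "compound not in network"))
    mapped_e, bad_e = set(), []
    for ec in sorted(set(ecs)):
        if ec in net.ec_index and net.ec_index[ec]:
            mapped_e.add(ec)
        else:
            bad_e.append((ec, "EC carried by no reaction"))
    ev = EvidenceSet(
        condition=condition,
        measured_compounds=frozenset(mapped_c),
        overexpressed_ecs=frozenset(mapped_e),
    )
    return ev, UnmappedEvidence(compounds=tuple(bad_c), ecs=tuple(bad_e))


# ---------------------------------------------------------------------------
# shared feasibility semantics (used by the oracle and by verify_solution)
# ---------------------------------------------------------------------------


def _terminal_structure(
    net: MetabolicNetwork, ev: EvidenceSet, forcing_mode: str
) -> tuple[list[str], list[tuple[str, frozenset[str]]]]:
    """Split terminals into fixed graph nodes and witness groups.

    Fixed terminals are measured non-currency compounds (plus, in ``"all"``
    mode, every carrier reaction of each forced EC).  Witness groups are
    terminals attached through exactly one active incident reaction: measured
    currency compounds always, and each forced EC in ``"at_least_one"`` mode.
    Returns (fixed compound ids + fixed reaction ids tagged, witness groups as
    (label, candidate reaction ids)).
    """
    currency = net.currency_compounds
    fixed: list[str] = []
    groups: list[tuple[str, frozenset[str]]] = []
    for cid in sorted(ev.measured_compounds):
        if cid in currency:
            groups.append((f"compound:{cid}", net.incident_reactions(cid)))
        else:
            fixed.append(f"compound:{cid}")
    for ec in sorted(ev.overexpressed_ecs):
        carriers = net.ec_index.get(ec, frozenset())
        if forcing_mode == "all":
            fixed.extend(f"reaction:{r}" for r in sorted(carriers))
        else:
            groups.append((f"ec:{ec}", carriers))
    return fixed, groups


def _induced_graph(net: MetabolicNetwork, active: frozenset[str]) -> nx.Graph:
    """Active reactions plus their non-currency participants; incidence edges."""
    currency = net.currency_compounds
    g = nx.Graph()
    for rid in active:
        g.add_node(("r", rid))
        for cid in net.reactions[rid].participants:
            if cid not in currency:
                g.add_edge(("r", rid), ("c", cid))
    return g


def _feasible(
    net: MetabolicNetwork,
    ev: EvidenceSet,
    active: frozenset[str],
    forcing_mode: str,
) -> tuple[bool, list[str]]:
    """Check coverage + forcing + terminal connectivity for a reaction set."""
    violations: list[str] = []
    for cid in sorted(ev.measured_compounds):
        if not (net.incident_reactions(cid) & active):
            violations.append(f"measured compound {cid} not covered")
    for ec in sorted(ev.overexpressed_ecs):
        carriers = net.ec_index.get(ec, frozenset())
        if forcing_mode == "all":
            missing = carriers - active
            if missing:
                violations.append(
                    f"EC {ec}: forced reactions inactive: {sorted(missing)}"
                )
        elif not (carriers & active):
            violations.append(f"EC {ec}: no carrier reaction active")
    if violations:
        return False, violations

    fixed, groups = _terminal_structure(net, ev, forcing_mode)
    if not fixed and not groups:
        return True, []
    g = _induced_graph(net, active)

    fixed_nodes = []
    for term in fixed:
        kind, ident = term.split(":", 1)
        node = ("c", ident) if kind == "compound" else ("r", ident)
        if node not in g:
            violations.append(f"terminal {term} not in active subgraph")
        else:
            fixed_nodes.append((term, node))
    if violations:
        return False, violations

    components = list(nx.connected_components(g)) if g.number_of_nodes() else []

    def group_ok(comp: set, carriers: frozenset[str]) -> bool:
        return any(("r", r) in comp for r in carriers & active)

    if fixed_nodes:
        comp = next(c for c in components if fixed_nodes[0][1] in c)
        for term, node in fixed_nodes[1:]:
            if node not in comp:
                violations.append(
                    f"terminal {term} disconnected from {fixed_nodes[0][0]}"
                )
        for label, carriers in groups:
            if not group_ok(comp, carriers):
                violations.append(f"terminal {label} has no witness in the "
                                  "terminal component")
        return not violations, violations

    # only witness groups: some single component must host a witness for each
    for comp in components:
        if all(group_ok(comp, carriers) for _, carriers in groups):
            return True, []
    violations.append(
        "witness terminals cannot be hosted by one connected component: "
        + ", ".join(label for label, _ in groups)
    )
    return False, violations


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------


@dataclass
class BruteForceResult:
    feasible: bool
    minimum: int | None
    optima: list[frozenset[str]] = field(default_factory=list)


def brute_force_minimal(
    net: MetabolicNetwork,
    ev: EvidenceSet,
    max_reactions: int = 15,
    forcing_mode: str = "at_least_one",
) -> BruteForceResult:
    """Exhaustively enumerate reaction subsets in increasing size.

    Test oracle only: refuses networks with more than ``max_reactions``
    reactions.  Returns the minimal feasible cardinality and *all* optimal
    reaction sets, or ``feasible=False`` when no subset works.
    """
    rids = sorted(net.reactions)
    if len(rids) > max_reactions:
        raise ValueError(
            f"brute force refused: {len(rids)} reactions > max_reactions={max_reactions}"
        )
    for size in range(len(rids) + 1):
        optima = [
            frozenset(sub)
            for sub in itertools.combinations(rids, size)
            if _feasible(net, ev, frozenset(sub), forcing_mode)[0]
        ]
        if optima:
            return BruteForceResult(feasible=True, minimum=size, optima=optima)
    return BruteForceResult(feasible=False, minimum=None)


def verify_solution(
    net: MetabolicNetwork,
    ev: EvidenceSet,
    sol: ActiveSubnetwork,
    forcing_mode: str = "at_least_one",
) -> tuple[bool, list[str]]:
    """Independent re-check of a solution by graph traversal.

    Validates coverage, forcing, terminal connectivity and the objective
    bookkeeping; never consults the solver.
    """
    if sol.status == "infeasible":
        return False, ["solution is marked infeasible"]
    ok, violations = _feasible(net, ev, sol.active_reactions, forcing_mode)
    if sol.objective != len(sol.active_reactions):
        violations.append(
            f"objective {sol.objective} != |active_reactions| "
            f"{len(sol.active_reactions)}"
        )
        ok = False
    return ok, violations


# ---------------------------------------------------------------------------
# MILP
# ---------------------------------------------------------------------------


def _build_and_solve(
    net: MetabolicNetwork,
    ev: EvidenceSet,
    opts: SolverOptions,
    forbidden_sets: Sequence[frozenset[str]] = (),
    cardinality: int | None = None,
) -> tuple[str, frozenset[str], frozenset[str]]:
    """One MILP solve.  Returns (status, active reactions, connector compounds).

    ``forbidden_sets`` adds no-good cuts excluding previously found optima;
    ``cardinality`` pins the reaction count (used when enumerating alternates).
    """
    currency = net.currency_compounds
    rids = sorted(net.reactions)
    r_pos = {r: i for i, r in enumerate(rids)}
    cids = sorted(c for c in net.compounds if c not in currency)
    c_pos = {c: i for i, c in enumerate(cids)}
    nR, nC = len(rids), len(cids)

    fixed, groups = _terminal_structure(net, ev, opts.forcing_mode)
    n_terms = len(fixed) + len(groups)

    # flow nodes: reactions, non-currency compounds, one aux node per group
    nodes: list[tuple[str, str]] = [("r", r) for r in rids]
    nodes += [("c", c) for c in cids]
    nodes += [("g", label) for label, _ in groups]
    node_pos = {n: i for i, n in enumerate(nodes)}

    # arcs (directed, both orientations of every usable undirected edge)
    arcs: list[tuple[int, int, str, int]] = []  # (u, v, cap_kind, cap_index)
    for r in rids:
        for c in sorted(net.reactions[r].participants):
            if c in currency:
                continue
            u, v = node_pos[("r", r)], node_pos[("c", c)]
            arcs.append((u, v, "rc", r_pos[r]))
            arcs.append((v, u, "rc", r_pos[r]))
            # the same two arcs are also capped by z_c; handled below

    w_pairs: list[tuple[int, str]] = []  # (group index, reaction id)
    for gi, (label, carriers) in enumerate(groups):
        for r in sorted(carriers):
            w_pairs.append((gi, r))
    w_pos = {pair: i for i, pair in enumerate(w_pairs)}
    for gi, (label, carriers) in enumerate(groups):
        a = node_pos[("g", label)]
        for r in sorted(carriers):
            u = node_pos[("r", r)]
            arcs.append((a, u, "w", w_pos[(gi, r)]))
            arcs.append((u, a, "w", w_pos[(gi, r)]))

    nW = len(w_pairs)
    use_flow = n_terms > 1
    nF = len(arcs) if use_flow else 0

    # variable layout: y (nR) | z (nC) | w (nW) | f (nF)
    off_z, off_w, off_f = nR, nR + nC, nR + nC + nW
    n_vars = nR + nC + nW + nF
    K = float(n_terms) if n_terms else 1.0

    lb = np.zeros(n_vars)
    ub = np.ones(n_vars)
    if use_flow:
        ub[off_f:] = K
    integrality = np.zeros(n_vars)
    integrality[: off_f if use_flow else n_vars] = 1

    measured_noncur = {c for c in ev.measured_compounds if c not in currency}
    for c in measured_noncur:
        i = off_z + c_pos[c]
        lb[i] = ub[i] = 1.0
    if opts.forcing_mode == "all":
        for ec in ev.overexpressed_ecs:
            for r in net.ec_index.get(ec, frozenset()):
                lb[r_pos[r]] = 1.0

    rows_i: list[int] = []
    cols_i: list[int] = []
    vals: list[float] = []
    con_lb: list[float] = []
    con_ub: list[float] = []
    row = 0

    def add_entry(r: int, c: int, v: float) -> None:
        rows_i.append(r)
        cols_i.append(c)
        vals.append(v)

    # coverage for measured non-currency compounds
    for c in sorted(measured_noncur):
        for r in net.incident_reactions(c):
            add_entry(row, r_pos[r], 1.0)
        con_lb.append(1.0)
        con_ub.append(np.inf)
        row += 1

    # witness selection: sum_r w = 1 and w <= y
    for gi, (label, carriers) in enumerate(groups):
        for r in sorted(carriers):
            add_entry(row, off_w + w_pos[(gi, r)], 1.0)
        con_lb.append(1.0)
        con_ub.append(1.0)
        row += 1
    for (gi, r), wi in w_pos.items():
        add_entry(row, off_w + wi, 1.0)
        add_entry(row, r_pos[r], -1.0)
        con_lb.append(-np.inf)
        con_ub.append(0.0)
        row += 1

    if use_flow:
        # pick the root: prefer fixed (real) terminals, lexicographic
        term_nodes: list[tuple[str, str]] = []
        for term in fixed:
            kind, ident = term.split(":", 1)
            term_nodes.append(("c", ident) if kind == "compound" else ("r", ident))
        term_nodes.sort(key=lambda n: n[1])
        group_nodes = sorted((("g", label) for label, _ in groups), key=lambda n: n[1])
        ordered_terms = term_nodes + group_nodes
        root = ordered_terms[0]
        demand = {node_pos[n]: 1.0 for n in ordered_terms}
        demand[node_pos[root]] = -(n_terms - 1.0)

        in_arcs: dict[int, list[int]] = {}
        out_arcs: dict[int, list[int]] = {}
        for ai, (u, v, _, _) in enumerate(arcs):
            out_arcs.setdefault(u, []).append(ai)
            in_arcs.setdefault(v, []).append(ai)

        for ni in range(len(nodes)):
            ins = in_arcs.get(ni, [])
            outs = out_arcs.get(ni, [])
            if not ins and not outs and ni not in demand:
                continue
            for ai in ins:
                add_entry(row, off_f + ai, 1.0)
            for ai in outs:
                add_entry(row, off_f + ai, -1.0)
            d = demand.get(ni, 0.0)
            con_lb.append(d)
            con_ub.append(d)
            row += 1

        # capacities: f <= K * (gating binary); rc arcs gated by y_r and z_c
        for ai, (u, v, kind, idx) in enumerate(arcs):
            if kind == "rc":
                add_entry(row, off_f + ai, 1.0)
                add_entry(row, idx, -K)  # y_r
                con_lb.append(-np.inf)
                con_ub.append(0.0)
                row += 1
                cnode = nodes[v] if nodes[v][0] == "c" else nodes[u]
                add_entry(row, off_f + ai, 1.0)
                add_entry(row, off_z + c_pos[cnode[1]], -K)
                con_lb.append(-np.inf)
                con_ub.append(0.0)
                row += 1
            else:  # aux witness arc
                add_entry(row, off_f + ai, 1.0)
                add_entry(row, off_w + idx, -K)
                con_lb.append(-np.inf)
                con_ub.append(0.0)
                row += 1

    # no-good cuts on previously found optima
    for s in forbidden_sets:
        for r in s:
            add_entry(row, r_pos[r], 1.0)
        con_lb.append(-np.inf)
        con_ub.append(float(len(s) - 1))
        row += 1
    if cardinality is not None:
        for r in rids:
            add_entry(row, r_pos[r], 1.0)
        con_lb.append(float(cardinality))
        con_ub.append(float(cardinality))
        row += 1

    # objective: reactions >> connector compounds >> deterministic rank
    eps = 1.0 / (2.0 * (nC + 1)) if opts.epsilon_compounds else 0.0
    obj = np.zeros(n_vars)
    obj[:nR] = 1.0
    obj[off_z : off_z + nC] = eps
    if opts.deterministic and nR:
        delta = (eps if eps > 0 else 1.0 / (2.0 * (nC + 1))) / (2.0 * nR * nR)
        obj[:nR] += delta * np.arange(nR)

    if row:
        a_mat = sparse.coo_matrix(
            (vals, (rows_i, cols_i)), shape=(row, n_vars)
        ).tocsc()
        constraints = [LinearConstraint(a_mat, con_lb, con_ub)]
    else:
        constraints = []

    res = milp(
        c=obj,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"time_limit": opts.time_limit, "presolve": True},
    )
    if res.status == 0:
        status = "optimal"
    elif res.status == 2:
        return "infeasible", frozenset(), frozenset()
    elif res.status == 1 and res.x is not None:
        status = "within-gap"
    else:  # pragma: no cover - unexpected backend state
        raise SolverUnavailableError(f"MILP backend failed: {res.message}")

    x = res.x
    active = frozenset(r for r in rids if x[r_pos[r]] > 0.5)
    connectors = frozenset(c for i, c in enumerate(cids) if x[off_z + i] > 0.5)
    return status, active, connectors


def solve_minimal_subnetwork(
    net: MetabolicNetwork,
    ev: EvidenceSet,
    opts: SolverOptions = SolverOptions(),
) -> ActiveSubnetwork:
    """Solve the minimal connected active subnetwork MILP for one condition.

    The objective minimizes the number of active reactions; a tiny
    compound-parsimony term (and, in deterministic mode, a tinier rank term)
    breaks ties without ever changing the reaction count.  Infeasible
    evidence is reported with the violating items named, never raised.
    """
    # pre-checks that give better diagnostics than a bare infeasible LP
    bad: list[str] = []
    for cid in sorted(ev.measured_compounds):
        if cid not in net.compounds:
            bad.append(f"measured compound {cid} not in network")
        elif not net.incident_reactions(cid):
            bad.append(f"measured compound {cid} has no incident reactions")
    for ec in sorted(ev.overexpressed_ecs):
        if not net.ec_index.get(ec, frozenset()):
            bad.append(f"over-expressed EC {ec} carried by no reaction")
    if bad:
        return ActiveSubnetwork(
            condition=ev.condition,
            active_reactions=frozenset(),
            connector_compounds=frozenset(),
            objective=0,
            status="infeasible",
            measured_compounds=ev.measured_compounds,
            forced_ecs=ev.overexpressed_ecs,
            infeasible_items=tuple(bad),
        )
    if not ev.measured_compounds and not ev.overexpressed_ecs:
        return ActiveSubnetwork(
            condition=ev.condition,
            active_reactions=frozenset(),
            connector_compounds=frozenset(),
            objective=0,
            status="optimal",
        )

    status, active, connectors = _build_and_solve(net, ev, opts)
    if status == "infeasible":
        return ActiveSubnetwork(
            condition=ev.condition,
            active_reactions=frozenset(),
            connector_compounds=frozenset(),
            objective=0,
            status="infeasible",
            measured_compounds=ev.measured_compounds,
            forced_ecs=ev.overexpressed_ecs,
            infeasible_items=("terminals cannot be connected",),
        )
    measured_in_net = frozenset(
        c for c in ev.measured_compounds if c in net.compounds
    )
    return ActiveSubnetwork(
        condition=ev.condition,
        active_reactions=active,
        connector_compounds=connectors | measured_in_net,
        objective=len(active),
        status=status,
        measured_compounds=ev.measured_compounds,
        forced_ecs=ev.overexpressed_ecs,
    )


def enumerate_alternates(
    net: MetabolicNetwork,
    ev: EvidenceSet,
    k: int,
    opts: SolverOptions = SolverOptions(),
) -> list[frozenset[str]]:
    """Up to ``k`` distinct optimal reaction sets, via no-good cuts at the
    fixed optimal cardinality.  Deterministic order under deterministic mode."""
    if k < 1:
        return []
    first = solve_minimal_subnetwork(net, ev, opts)
    if first.status != "optimal":
        return []
    found = [first.active_reactions]
    m = first.objective
    while len(found) < k:
        status, active, _ = _build_and_solve(
            net, ev, opts, forbidden_sets=found, cardinality=m
        )
        if status != "optimal":
            break
        found.append(active)
    return found
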