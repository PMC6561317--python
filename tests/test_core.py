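import pytest

from mempis.mempis_core import (
    EvidenceSet,
    SolverOptions,
    brute_force_minimal,
    enumerate_alternates,
    map_evidence,
    solve_minimal_subnetwork,
    verify_solution,
)
from mempis.reaction_db import Reaction, build_network, load_network
from mempis.synth import random_small_instance


def ev(condition="t", compounds=(), ecs=()):
    return EvidenceSet(
        condition=condition,
        measured_compounds=frozenset(compounds),
        overexpressed_ecs=frozenset(ecs),
    )


class TestMapEvidence:
    def test_unmapped_ec_reported(self, toy_net):
        mapped, unmapped = map_evidence(toy_net, "t", ecs=["9.9.9.9"])
        assert mapped.overexpressed_ecs == frozenset()
        assert unmapped.ecs == (("9.9.9.9", "EC carried by no reaction"),)

    def test_empty_input(self, toy_net):
        mapped, unmapped = map_evidence(toy_net, "t")
        assert mapped.measured_compounds == frozenset()
        assert mapped.overexpressed_ecs == frozenset()
        assert unmapped.compounds == () and unmapped.ecs == ()

    def test_present_items_mapped(self, toy_net):
        mapped, unmapped = map_evidence(
            toy_net, "t", compounds=["A", "Z"], ecs=["1.1.1.1"]
        )
        assert mapped.measured_compounds == {"A"}
        assert mapped.overexpressed_ecs == {"1.1.1.1"}
        assert unmapped.compounds == (("Z", "compound not in network"),)


class TestToyCases:
    def test_measured_endpoints_single_shortcut(self, toy_net):
        sol = solve_minimal_subnetwork(toy_net, ev(compounds={"A", "C"}))
        assert sol.status == "optimal"
        assert sol.objective == 1
        assert sol.active_reactions == {"R3"}
        ok, violations = verify_solution(toy_net, ev(compounds={"A", "C"}), sol)
        assert ok, violations

    def test_forced_ec_with_measured_end(self, toy_net):
        evidence = ev(compounds={"C"}, ecs={"1.1.1.1"})
        sol = solve_minimal_subnetwork(toy_net, evidence)
        assert sol.status == "optimal"
        assert sol.objective == 2
        assert sol.active_reactions in ({"R1", "R2"}, {"R1", "R3"})
        alts = enumerate_alternates(toy_net, evidence, k=5)
        assert {frozenset(a) for a in alts} == {
            frozenset({"R1", "R2"}),
            frozenset({"R1", "R3"}),
        }

    def test_empty_evidence_empty_solution(self, toy_net):
        sol = solve_minimal_subnetwork(toy_net, ev())
        assert sol.status == "optimal"
        assert sol.objective == 0
        assert sol.active_reactions == frozenset()

    def test_brute_force_agrees_on_toys(self, toy_net):
        bf1 = brute_force_minimal(toy_net, ev(compounds={"A", "C"}))
        assert bf1.minimum == 1 and bf1.optima == [frozenset({"R3"})]
        bf2 = brute_force_minimal(toy_net, ev(compounds={"C"}, ecs={"1.1.1.1"}))
        assert bf2.minimum == 2
        assert set(bf2.optima) == {
            frozenset({"R1", "R2"}),
            frozenset({"R1", "R3"}),
        }


class TestInfeasibility:
    def test_isolated_measured_compound_named(self, toy_net):
        sol = solve_minimal_subnetwork(toy_net, ev(compounds={"QQQ"}))
        assert sol.status == "infeasible"
        assert any("QQQ" in item for item in sol.infeasible_items)

    def test_disconnected_terminals(self):
        # two disjoint components; measured compounds in both cannot connect
        net = build_network(
            [
                Reaction("R1", {"A": 1}, {"B": 1}),
                Reaction("R2", {"X": 1}, {"Y": 1}),
            ]
        )
        evidence = ev(compounds={"A", "Y"})
        sol = solve_minimal_subnetwork(net, evidence)
        assert sol.status == "infeasible"
        bf = brute_force_minimal(net, evidence)
        assert not bf.feasible

    def test_brute_force_reports_infeasible(self, toy_net):
        bf = brute_force_minimal(toy_net, ev(compounds={"A", "C", "ZZZ"}))
        assert not bf.feasible


class TestCurrencySemantics:
    def make_currency_net(self):
        # R1 and R2 share only water (C00001); R3 bridges via real compound M
        return build_network(
            [
                Reaction("R1", {"A": 1}, {"C00001": 1, "M": 1}),
                Reaction("R2", {"C00001": 1, "X": 1}, {"B": 1}),
                Reaction("R3", {"M": 1}, {"X": 1}),
            ]
        )

    def test_currency_never_connects(self):
        net = self.make_currency_net()
        evidence = ev(compounds={"A", "B"})
        sol = solve_minimal_subnetwork(net, evidence)
        # connecting A and B must route through M and X, not through water
        assert sol.objective == 3
        bf = brute_force_minimal(net, evidence)
        assert bf.minimum == 3

    def test_measured_currency_is_terminal_via_witness(self):
        net = self.make_currency_net()
        evidence = ev(compounds={"A", "C00001"})
        sol = solve_minimal_subnetwork(net, evidence)
        assert sol.status == "optimal"
        # R1 produces water and consumes A: one reaction covers both
        assert sol.objective == 1 and sol.active_reactions == {"R1"}
        ok, violations = verify_solution(net, evidence, sol)
        assert ok, violations


class TestForcingModes:
    def make_shared_ec_net(self):
        return build_network(
            [
                Reaction("R1", {"A": 1}, {"B": 1}, ecs=frozenset({"1.1.1.1"})),
                Reaction("R2", {"B": 1}, {"C": 1}, ecs=frozenset({"1.1.1.1"})),
                Reaction("R3", {"C": 1}, {"D": 1}),
            ]
        )

    def test_at_least_one_picks_single_witness(self):
        net = self.make_shared_ec_net()
        sol = solve_minimal_subnetwork(net, ev(ecs={"1.1.1.1"}))
        assert sol.objective == 1
        assert sol.active_reactions < {"R1", "R2"}

    def test_all_mode_forces_every_carrier(self):
        net = self.make_shared_ec_net()
        sol = solve_minimal_subnetwork(
            net, ev(ecs={"1.1.1.1"}), SolverOptions(forcing_mode="all")
        )
        assert sol.status == "optimal"
        assert {"R1", "R2"} <= sol.active_reactions
        assert sol.objective == 2
        ok, violations = verify_solution(
            net, ev(ecs={"1.1.1.1"}), sol, forcing_mode="all"
        )
        assert ok, violations

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="forcing mode"):
            SolverOptions(forcing_mode="some")


class TestVerifySolution:
    def test_missing_forced_reaction_named(self, toy_net):
        from mempis.mempis_core import ActiveSubnetwork

        fake = ActiveSubnetwork(
            condition="t",
            active_reactions=frozenset({"R2"}),
            connector_compounds=frozenset({"B", "C"}),
            objective=1,
            status="optimal",
        )
        ok, violations = verify_solution(toy_net, ev(ecs={"1.1.1.1"}), fake)
        assert not ok
        assert any("1.1.1.1" in v for v in violations)

    def test_disconnected_solution_named(self):
        from mempis.mempis_core import ActiveSubnetwork

        net = build_network(
            [
                Reaction("R1", {"A": 1}, {"B": 1}),
                Reaction("R2", {"X": 1}, {"Y": 1}),
            ]
        )
        fake = ActiveSubnetwork(
            condition="t",
            active_reactions=frozenset({"R1", "R2"}),
            connector_compounds=frozenset({"A", "Y"}),
            objective=2,
            status="optimal",
        )
        ok, violations = verify_solution(net, ev(compounds={"A", "Y"}), fake)
        assert not ok
        assert any("disconnected" in v for v in violations)

    def test_objective_bookkeeping_checked(self, toy_net):
        from mempis.mempis_core import ActiveSubnetwork

        fake = ActiveSubnetwork(
            condition="t",
            active_reactions=frozenset({"R3"}),
            connector_compounds=frozenset({"A", "C"}),
            objective=7,
            status="optimal",
        )
        ok, violations = verify_solution(toy_net, ev(compounds={"A", "C"}), fake)
        assert not ok and any("objective" in v for v in violations)


class TestEnumerateAlternates:
    def test_k_one_returns_one(self, toy_net):
        alts = enumerate_alternates(toy_net, ev(compounds={"C"}, ecs={"1.1.1.1"}), k=1)
        assert len(alts) == 1

    def test_unique_optimum_single_set(self, toy_net):
        alts = enumerate_alternates(toy_net, ev(compounds={"A", "C"}), k=10)
        assert alts == [frozenset({"R3"})]

    def test_all_alternates_verify(self, toy_net):
        from mempis.mempis_core import ActiveSubnetwork

        evidence = ev(compounds={"C"}, ecs={"1.1.1.1"})
        for s in enumerate_alternates(toy_net, evidence, k=5):
            sol = ActiveSubnetwork(
                condition="t",
                active_reactions=s,
                connector_compounds=frozenset(),
                objective=len(s),
                status="optimal",
            )
            ok, violations = verify_solution(toy_net, evidence, sol)
            assert ok, violations

    def test_deterministic_first_solution(self, toy_net):
        evidence = ev(compounds={"C"}, ecs={"1.1.1.1"})
        runs = [
            enumerate_alternates(toy_net, evidence, k=5) for _ in range(3)
        ]
        assert runs[0] == runs[1] == runs[2]


class TestOracleEquivalence:
    """MILP vs exhaustive enumeration on seeded random instances."""

    @pytest.mark.parametrize("block", range(4))
    def test_objective_and_feasibility_agree(self, block):
        for seed in range(block * 25, (block + 1) * 25):
            net, compounds, ecs = random_small_instance(seed)
            evidence, _ = map_evidence(net, f"s{seed}", compounds, ecs)
            # deliberately include unmapped evidence sometimes via raw ids
            sol = solve_minimal_subnetwork(net, evidence)
            bf = brute_force_minimal(net, evidence)
            assert bf.feasible == (sol.status == "optimal"), seed
            if bf.feasible:
                assert sol.objective == bf.minimum, seed
                assert sol.active_reactions in set(bf.optima) or len(
                    sol.active_reactions
                ) == bf.minimum
                ok, violations = verify_solution(net, evidence, sol)
                assert ok, (seed, violations)

    def test_monotonicity_under_added_compound(self):
        for seed in range(30):
            net, compounds, ecs = random_small_instance(seed)
            evidence, _ = map_evidence(net, "m", compounds, ecs)
            sol = solve_minimal_subnetwork(net, evidence)
            if sol.status != "optimal":
                continue
            extra = sorted(set(net.compounds) - evidence.measured_compounds)
            if not extra:
                continue
            bigger, _ = map_evidence(
                net, "m", list(evidence.measured_compounds) + [extra[0]],
                evidence.overexpressed_ecs,
            )
            sol2 = solve_minimal_subnetwork(net, bigger)
            if sol2.status == "optimal":
                assert sol2.objective >= sol.objective

    def test_epsilon_term_never_changes_reaction_count(self):
        for seed in range(40):
            net, compounds, ecs = random_small_instance(seed)
            evidence, _ = map_evidence(net, "e", compounds, ecs)
            with_eps = solve_minimal_subnetwork(net, evidence)
            without = solve_minimal_subnetwork(
                net, evidence, SolverOptions(epsilon_compounds=False)
            )
            assert with_eps.status == without.status
            if with_eps.status == "optimal":
                assert with_eps.objective == without.objective
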