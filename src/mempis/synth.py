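"""Synthetic networks, count matrices and metabolite evidence with known truth.

The generator emulates the statistical structure the integration method
assumes: a bipartite compound-reaction network with hub compounds (wired by
preferential attachment, mimicking currency-metabolite hubs), a planted
connected chain of reactions whose enzymes are over-expressed in one
treatment, negative-binomial transcript counts per EC, and a partially
covered list of "measured" metabolites along the planted chain.  Every stage
of the pipeline can then be scored against the planted ground truth.

All randomness flows from one explicit integer seed; there is no global
generator state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .reaction_db import (
    DEFAULT_CURRENCY,
    MetabolicNetwork,
    Reaction,
    build_network,
)
from .mempis_core import ActiveSubnetwork

__all__ = [
    "NetworkSpec",
    "random_small_instance",
    "SyntheticTruth",
    "generate_network",
    "make_design",
    "simulate_counts",
    "make_evidence",
    "recovery_score",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Shape of a synthetic network.

    n_reactions counts planted chain reactions plus random background
    reactions; background wiring is preferential-attachment (weight
    degree + 1) so hub compounds arise.  Background reactions never touch
    two planted-chain compounds at once, keeping the planted chain the
    unique cheapest connector of its own metabolites.  ``n_currency_hubs``
    compounds take ids from the standard currency blacklist and are attached
    to many reactions, stressing the currency filter.
    """

    n_compounds: int = 45
    n_reactions: int = 60
    planted_len: int = 8
    n_currency_hubs: int = 2
    currency_rate: float = 0.3
    ec_share_prob: float = 0.1
    module_prob: float = 0.7
    n_modules: int = 5

    def __post_init__(self) -> None:
        if self.planted_len < 0 or self.n_reactions < self.planted_len:
            raise ValueError("need n_reactions >= planted_len >= 0")
        if self.n_compounds < self.planted_len + 1:
            raise ValueError("need n_compounds >= planted_len + 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth accompanying a generated network."""

    seed: int
    spec: NetworkSpec
    planted_path: tuple[str, ...]  # ordered reaction ids forming the chain
    planted_compounds: tuple[str, ...]  # chain compounds, in order
    planted_ecs: tuple[str, ...]  # 1:1 with planted_path
    planted_log2fc: float = 2.0
    dispersion: float = 0.1
    treatment: str = "dry"
    coverage: float = 1.0


_CURRENCY_POOL = sorted(DEFAULT_CURRENCY)


def generate_network(
    spec: NetworkSpec = NetworkSpec(),
    seed: int = 0,
    planted_log2fc: float = 2.0,
    dispersion: float = 0.1,
) -> tuple[MetabolicNetwork, SyntheticTruth]:
    """Generate a reproducible synthetic network with a planted reaction chain.

    The chain reaction i converts chain compound i into chain compound i+1
    and carries a unique planted EC appearing nowhere else.  With
    ``planted_len=0`` a plain random network is returned (empty truth).
    """
    rng = np.random.default_rng(seed)
    L = spec.planted_len
    chain_compounds = [f"C{10001 + i:05d}" for i in range(L + 1)] if L else []
    n_free = spec.n_compounds - len(chain_compounds) - spec.n_currency_hubs
    free_compounds = [f"C{20001 + i:05d}" for i in range(max(n_free, 0))]
    hubs = _CURRENCY_POOL[: spec.n_currency_hubs]
    noncur_pool = chain_compounds + free_compounds

    reactions: list[Reaction] = []
    planted_rids, planted_ecs = [], []
    for i in range(L):
        rid = f"R{1 + i:05d}"
        ec = f"9.1.1.{i + 1}"
        subs = {chain_compounds[i]: 1}
        prods = {chain_compounds[i + 1]: 1}
        if hubs and rng.random() < spec.currency_rate:
            prods[hubs[int(rng.integers(len(hubs)))]] = 1
        mods = frozenset({"M90001"})
        reactions.append(
            Reaction(rid, subs, prods, ecs=frozenset({ec}), modules=mods,
                     pathways=frozenset({"map90001"}))
        )
        planted_rids.append(rid)
        planted_ecs.append(ec)

    # preferential-attachment background wiring
    degree = {c: 1 for c in noncur_pool}
    chain_set = set(chain_compounds)
    ec_counter = 0
    last_ec: str | None = None
    for j in range(spec.n_reactions - L):
        rid = f"R{10001 + j:05d}"
        for _attempt in range(50):
            k = int(rng.integers(2, 5))  # 2-4 non-currency participants
            weights = np.array([degree[c] for c in noncur_pool], dtype=float)
            weights /= weights.sum()
            picks = list(
                rng.choice(noncur_pool, size=min(k, len(noncur_pool)),
                           replace=False, p=weights)
            )
            if sum(c in chain_set for c in picks) <= 1:
                break
        else:
            picks = [c for c in noncur_pool if c not in chain_set][:2]
        n_sub = max(1, int(rng.integers(1, len(picks))))
        subs = {c: 1 for c in picks[:n_sub]}
        prods = {c: 1 for c in picks[n_sub:]} or {free_compounds[0]: 1}
        if set(subs) & set(prods):  # pragma: no cover - picks are unique
            continue
        if hubs and rng.random() < spec.currency_rate:
            hub = hubs[int(rng.integers(len(hubs)))]
            if hub not in subs:
                prods[hub] = 1
        if last_ec is not None and rng.random() < spec.ec_share_prob:
            ec = last_ec
        else:
            ec_counter += 1
            ec = f"2.1.1.{ec_counter}"
        last_ec = ec
        mods = (
            frozenset({f"M{1 + int(rng.integers(spec.n_modules)):05d}"})
            if rng.random() < spec.module_prob
            else frozenset()
        )
        reactions.append(
            Reaction(rid, subs, prods, ecs=frozenset({ec}), modules=mods)
        )
        for c in picks:
            degree[c] += 1

    net = build_network(reactions, currency_blacklist=DEFAULT_CURRENCY)
    truth = SyntheticTruth(
        seed=seed,
        spec=spec,
        planted_path=tuple(planted_rids),
        planted_compounds=tuple(chain_compounds),
        planted_ecs=tuple(planted_ecs),
        planted_log2fc=planted_log2fc,
        dispersion=dispersion,
    )
    return net, truth


def make_design(
    sites: Sequence[str] = ("A",),
    treatments: Sequence[str] = ("control", "dry"),
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Sample design table (site x treatment x replicate)."""
    rows = [
        {
            "sample": f"{site}-{trt}-{rep}",
            "site": site,
            "treatment": trt,
            "replicate": rep,
        }
        for site in sites
        for trt in treatments
        for rep in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def simulate_counts(
    net: MetabolicNetwork,
    truth: SyntheticTruth,
    design: pd.DataFrame,
    seed: int = 0,
    base_mean_log: float = 4.5,
    base_mean_sd: float = 1.0,
) -> pd.DataFrame:
    """Negative-binomial EC-level counts; planted ECs are shifted by
    2**planted_log2fc in ``truth.treatment`` samples.

    Per-EC baseline means are log-normal (median ~ 90 counts); the NB
    variance is mu + dispersion * mu^2.  Reproducible under the seed.
    """
    rng = np.random.default_rng(seed)
    ecs = sorted(net.ec_index)
    planted = set(truth.planted_ecs)
    mu0 = rng.lognormal(mean=base_mean_log, sigma=base_mean_sd, size=len(ecs))
    disp = truth.dispersion
    samples = list(design["sample"])
    trt = dict(zip(design["sample"], design["treatment"]))
    mat = np.zeros((len(ecs), len(samples)), dtype=int)
    for i, ec in enumerate(ecs):
        for j, s in enumerate(samples):
            mu = mu0[i]
            if ec in planted and trt[s] == truth.treatment:
                mu *= 2.0 ** truth.planted_log2fc
            if disp > 0:
                n_param = 1.0 / disp
                p_param = n_param / (n_param + mu)
                mat[i, j] = rng.negative_binomial(n_param, p_param)
            else:
                mat[i, j] = rng.poisson(mu)
    return pd.DataFrame(mat, index=ecs, columns=samples)


def make_evidence(
    truth: SyntheticTruth, coverage: float = 1.0, seed: int = 0
) -> list[str]:
    """Sample a fraction of the planted-chain compounds as "measured".

    The number sampled is round-half-up of coverage * n; emulates partial
    identification of metabolites against reference databases.
    """
    if not 0 <= coverage <= 1:
        raise ValueError("coverage must be in [0, 1]")
    pool = sorted(truth.planted_compounds)
    k = int(np.floor(coverage * len(pool) + 0.5))
    if k == 0:
        return []
    rng = np.random.default_rng(seed)
    return sorted(str(c) for c in rng.choice(pool, size=k, replace=False))


def random_small_instance(
    seed: int,
    max_reactions: int = 12,
    max_compounds: int = 15,
) -> tuple[MetabolicNetwork, list[str], list[str]]:
    """A small random network plus sampled evidence, for oracle comparisons.

    Networks have 2..max_reactions reactions over 4..max_compounds compounds
    (ids drawn from C00001.. so some land on the currency blacklist), 0-3
    measured compounds and 0-2 over-expressed ECs.  Instances may be
    infeasible by construction; that is intentional.
    """
    rng = np.random.default_rng(seed)
    n_c = int(rng.integers(4, max_compounds + 1))
    n_r = int(rng.integers(2, max_reactions + 1))
    cids = [f"C{i:05d}" for i in rng.choice(range(1, 120), size=n_c, replace=False)]
    rxns = []
    for j in range(n_r):
        k = int(rng.integers(2, min(5, n_c) + 1))
        picks = list(rng.choice(cids, size=k, replace=False))
        n_sub = int(rng.integers(1, k))
        subs = {c: int(rng.integers(1, 3)) for c in picks[:n_sub]}
        prods = {c: 1 for c in picks[n_sub:]}
        ecs = (
            frozenset({f"1.1.1.{int(rng.integers(1, 6))}"})
            if rng.random() < 0.6
            else frozenset()
        )
        rxns.append(Reaction(f"R{j:05d}", subs, prods, ecs=ecs))
    net = build_network(rxns, currency_blacklist=DEFAULT_CURRENCY)
    comp_pool = sorted(net.compounds)
    n_meas = int(rng.integers(0, 4))
    compounds = [
        str(c)
        for c in rng.choice(comp_pool, size=min(n_meas, len(comp_pool)), replace=False)
    ]
    ec_pool = sorted(net.ec_index)
    n_ec = int(rng.integers(0, 3))
    ecs = (
        [str(e) for e in rng.choice(ec_pool, size=min(n_ec, len(ec_pool)), replace=False)]
        if ec_pool
        else []
    )
    return net, compounds, ecs


def recovery_score(sol: ActiveSubnetwork, truth: SyntheticTruth) -> float:
    """Jaccard index between the active reactions and the planted chain."""
    a = set(sol.active_reactions)
    p = set(truth.planted_path)
    if not a and not p:
        return 1.0
    union = a | p
    return len(a & p) / len(union)
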