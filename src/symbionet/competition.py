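"""Seed sets, effective metabolic overlap, and source-metabolite dependencies.

The *seed set* of a network is a purely topological prediction of the
compounds an organism must acquire from its surroundings: build the directed
compound graph (substrate -> product for every reaction), condense it into
strongly connected components, and take every compound belonging to a
component with no incoming edge from outside. Seed SCCs of size > 1
contribute all their members, unweighted.

The *competition score* of an ordered pair (row, column) is the fraction of
the row organism's producible essential metabolites it loses when the source
metabolites it shares with the column organism are withheld — the effective
metabolic overlap, in [0, 1], asymmetric by construction. The "optimal"
environment for the row species is its own seed set.

The *dependency scan* asks a finer question in an explicit environment:
remove one source metabolite at a time and count the essential metabolites
that can no longer be produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import pandas as pd

from .expansion import expand
from .reaction_universe import Environment, MetabolicNetwork, TargetSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedSet:
    """Topology-predicted exogenously required compounds of one network."""

    organism_id: str
    seeds: frozenset[str]
    seed_components: tuple[frozenset[str], ...]


def compound_graph(network: MetabolicNetwork) -> nx.DiGraph:
    """Directed compound graph: an edge substrate -> product per reaction."""
    g = nx.DiGraph()
    for r in network.reactions:
        g.add_nodes_from(r.substrates | r.products)
        for s in r.substrates:
            for p in r.products:
                g.add_edge(s, p)
    return g


def seed_set(network: MetabolicNetwork) -> SeedSet:
    """Source-SCC members of the compound graph.

    Empty networks yield an empty seed set with a warning rather than an
    error, so community-wide sweeps do not abort on a degenerate genome.
    """
    if not network.reactions:
        logger.warning("%s: empty network, empty seed set", network.organism_id)
        return SeedSet(network.organism_id, frozenset(), ())
    g = compound_graph(network)
    condensation = nx.condensation(g)
    components = []
    for node in condensation.nodes:
        if condensation.in_degree(node) == 0:
            components.append(frozenset(condensation.nodes[node]["members"]))
    components.sort(key=lambda c: min(c))
    seeds = frozenset().union(*components) if components else frozenset()
    return SeedSet(network.organism_id, seeds, tuple(components))


def competition_score(
    row: MetabolicNetwork,
    col: MetabolicNetwork,
    targets: TargetSet,
    seed_fn: Callable[[MetabolicNetwork], SeedSet] = seed_set,
) -> float:
    """Effect of the column species on the row species, in [0, 1].

    T_opt counts the row's producible targets with all of its own seeds
    available; T_red counts them after removing the seeds shared with the
    column. Score = (T_opt - T_red) / T_opt, and 0 when T_opt = 0 (a
    species producing nothing cannot be outcompeted in this metric).
    """
    row_seeds = seed_fn(row).seeds
    col_seeds = seed_fn(col).seeds
    if not row_seeds:
        return 0.0
    t_opt = len(expand(row_seeds, row).scope & targets.targets)
    if t_opt == 0:
        return 0.0
    reduced = row_seeds - (row_seeds & col_seeds)
    t_red = len(expand(reduced, row).scope & targets.targets)
    return (t_opt - t_red) / t_opt


@dataclass
class CompetitionMatrix:
    """All ordered-pair effective-metabolic-overlap scores.

    ``scores.loc[row, col]`` is the effect of the column species on the row
    species. The diagonal is NaN by convention: self-pairs are excluded
    from every summary.
    """

    scores: pd.DataFrame

    @property
    def organism_ids(self) -> list[str]:
        return list(self.scores.index)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return float(self.scores.loc[pair[0], pair[1]])


def competition_matrix(
    networks: Sequence[MetabolicNetwork], targets: TargetSet
) -> CompetitionMatrix:
    """Scores for all ordered pairs of *networks* (asymmetry preserved)."""
    if len(networks) < 2:
        raise ValueError("competition_matrix requires at least 2 networks")
    ids = [n.organism_id for n in networks]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate organism ids in competition_matrix input")
    seed_cache = {n.organism_id: seed_set(n) for n in networks}
    lookup = lambda net: seed_cache[net.organism_id]  # noqa: E731
    df = pd.DataFrame(index=ids, columns=ids, dtype=float)
    for a in networks:
        for b in networks:
            if a.organism_id == b.organism_id:
                continue
            df.loc[a.organism_id, b.organism_id] = competition_score(
                a, b, targets, seed_fn=lookup
            )
    return CompetitionMatrix(scores=df)


def dependency_scan(
    network: MetabolicNetwork, env: Environment, targets: TargetSet
) -> pd.Series:
    """Targets lost upon removing each single source metabolite from *env*.

    Returns a Series indexed by source-metabolite id whose values are
    ``n_produced(env) - n_produced(env minus that source)`` — non-negative
    by expansion monotonicity. Sources no reaction of the network consumes
    score 0. Only single removals are scanned.
    """
    baseline = len(expand(env, network).scope & targets.targets)
    consumed: set[str] = set()
    for r in network.reactions:
        consumed |= r.substrates
    cells = {}
    for s in sorted(env.source_metabolites):
        if s not in consumed:
            cells[s] = 0
            continue
        reduced = env.source_metabolites - {s}
        n = len(expand(reduced, network).scope & targets.targets) if reduced else 0
        cells[s] = baseline - n
    return pd.Series(cells, name=network.organism_id, dtype=int)


def dependency_table(
    networks: Sequence[MetabolicNetwork], env: Environment, targets: TargetSet
) -> pd.DataFrame:
    """Organism x source-metabolite dependency counts (one scan per row)."""
    rows = [dependency_scan(n, env, targets) for n in networks]
    return pd.DataFrame(rows)
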