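"""Network expansion: the reachable-metabolite fixed point ("scope").

Starting from a set of source metabolites, iteratively fire every reaction
whose substrates are all available, adding its products, until no further
reaction becomes feasible. The result — the scope — is the unique least
fixed point of that rule, independent of the order in which reactions are
considered. The model is purely qualitative: no stoichiometry, no flux, no
quantities; a compound is either producible or it is not.

Growth capacity in an environment is then proxied by how many members of a
predefined essential-metabolite panel (amino acids, nucleotides, cofactors)
fall inside the scope.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable

from .reaction_universe import (
    Environment,
    MetabolicNetwork,
    ReactionUniverse,
    TargetSet,
)


@dataclass(frozen=True)
class ExpansionResult:
    """Scope (reachable compounds, seeds included) plus activated reactions."""

    scope: frozenset[str]
    active_reactions: frozenset[str]
    organism_id: str = ""
    environment_name: str = ""


@dataclass(frozen=True)
class GrowthAssessment:
    """Target-panel coverage of an expansion result."""

    produced_targets: frozenset[str]
    environment_name: str = ""

    @property
    def n_produced(self) -> int:
        return len(self.produced_targets)


def expand(
    seeds: Iterable[str] | Environment,
    network: MetabolicNetwork,
    universe: ReactionUniverse | None = None,
    environment_name: str = "",
) -> ExpansionResult:
    """Compute the scope of *seeds* under *network*.

    Uses a worklist keyed by per-reaction unmet-substrate counts, so each
    reaction is examined once per newly available substrate (near-linear in
    network size). A reaction producing one of its own substrates needs no
    special-casing: the fixed-point semantics handle autocatalysis.

    Passing a :class:`ReactionUniverse` validates the seeds against it and
    raises listing any unknown compound ids.
    """
    if isinstance(seeds, Environment):
        if not environment_name:
            environment_name = seeds.name
        seeds = seeds.source_metabolites
    seed_set = frozenset(seeds)
    if universe is not None:
        universe.validate_compounds(seed_set, "seed")

    reactions = list(network.reactions)
    unmet = [len(r.substrates) for r in reactions]
    needs: dict[str, list[int]] = {}
    for i, r in enumerate(reactions):
        for s in r.substrates:
            needs.setdefault(s, []).append(i)

    scope: set[str] = set(seed_set)
    active: set[str] = set()
    queue: deque[str] = deque(scope)
    # zero-substrate reactions cannot occur (substrates are non-empty by
    # construction), so every firing is triggered by a compound arrival
    while queue:
        compound = queue.popleft()
        for i in needs.get(compound, ()):
            unmet[i] -= 1
            if unmet[i] == 0:
                r = reactions[i]
                active.add(r.id)
                for p in r.products:
                    if p not in scope:
                        scope.add(p)
                        queue.append(p)
    return ExpansionResult(
        scope=frozenset(scope),
        active_reactions=frozenset(active),
        organism_id=network.organism_id,
        environment_name=environment_name,
    )


def assess_growth(result: ExpansionResult, targets: TargetSet) -> GrowthAssessment:
    """Which essential metabolites the expanded network produces."""
    return GrowthAssessment(
        produced_targets=result.scope & targets.targets,
        environment_name=result.environment_name,
    )


def expand_bruteforce(
    seeds: Iterable[str],
    network: MetabolicNetwork,
    order: list | None = None,
) -> ExpansionResult:
    """Reference fixed-point computation: sweep all reactions until no change.

    Quadratic and deliberately naive; serves as the independent oracle the
    worklist implementation is checked against, optionally under an
    arbitrary reaction ordering to demonstrate order independence.
    """
    reactions = list(network.reactions) if order is None else list(order)
    scope = set(seeds)
    active: set[str] = set()
    changed = True
    while changed:
        changed = False
        for r in reactions:
            if r.substrates <= scope:
                if r.id not in active:
                    active.add(r.id)
                    changed = True
                new = r.products - scope
                if new:
                    scope |= new
                    changed = True
    return ExpansionResult(
        scope=frozenset(scope),
        active_reactions=frozenset(active),
        organism_id=network.organism_id,
    )
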