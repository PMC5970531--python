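"""Synthetic universes, genomes and environments with planted ground truth.

Every pipeline stage is testable without any download: linear biosynthetic
chains split across genomes plant known complementary metabolites, shared
limiting seeds plant closed-form competition scores, and random universes
feed the brute-force expansion oracle. Generators are pure functions of
their parameters and RNG seed.

Also included are small hand-built "toy" communities whose structure mirrors
well-documented whitefly-symbiont biology (lysine hand-off, tryptophan
precursor dependency, thiamine activation) and a five-genome demo community
over the packaged 49-compound bacteriocyte medium.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .environments import load_host_environment
from .reaction_universe import (
    Compound,
    DirectedReaction,
    Environment,
    FORWARD_SUFFIX,
    GenomeAnnotation,
    MetabolicNetwork,
    REVERSE_SUFFIX,
    ReactionUniverse,
    TargetSet,
    network_from_ecs,
)


def _synthetic_ec(index: int, salt: str = "") -> str:
    """A syntactically valid, collision-resistant synthetic EC number."""
    h = zlib.crc32(salt.encode()) if salt else 0
    return f"{1 + h % 6}.{1 + (h // 6) % 80}.{1 + (h // 480) % 80}.{index + 1}"


# ---------------------------------------------------------------------------
# Linear / split pathways
# ---------------------------------------------------------------------------


def make_linear_pathway(length: int, id_prefix: str = "P") -> ReactionUniverse:
    """A linear chain ``c0 -> c1 -> ... -> cL`` of irreversible reactions.

    Compounds are named ``{prefix}_c{i}`` and reaction i converts c{i} to
    c{i+1} under its own distinct synthetic EC. Emulates unbranched
    biosynthetic chains (lysine, BCA-style pathways).
    """
    if length < 1:
        raise ValueError("pathway length must be >= 1")
    universe = ReactionUniverse()
    for i in range(length):
        universe.add_reaction(
            DirectedReaction(
                id=f"{id_prefix}_r{i}",
                ec_numbers=frozenset({_synthetic_ec(i, id_prefix)}),
                substrates=frozenset({f"{id_prefix}_c{i}"}),
                products=frozenset({f"{id_prefix}_c{i + 1}"}),
            )
        )
    return universe


@dataclass(frozen=True)
class SplitPathwayFixture:
    """A pathway partitioned across genomes plus its planted ground truth."""

    universe: ReactionUniverse
    annotations: tuple[GenomeAnnotation, ...]
    environment: Environment
    #: expected combination-specific complementary sets, keyed by the tuple
    #: of member organism ids in annotation order
    expected: Mapping[tuple[str, ...], frozenset[str]]


def plant_split_pathway(
    universe: ReactionUniverse,
    cut_points: Sequence[int],
    genomes: Sequence[str],
    id_prefix: str = "P",
) -> SplitPathwayFixture:
    """Partition a linear pathway's reactions among genomes.

    ``cut_points`` are strictly increasing reaction indices splitting the
    chain into ``len(genomes)`` consecutive non-overlapping segments (an
    overlapping or empty segment would destroy the planted signal and is
    rejected). Genome g receives the ECs of segment g.

    The planted truth, with the chain head as sole source: a combination S
    has a non-empty combination-specific complementary set exactly when S is
    a prefix run of segments {g1..gj}, and that set is the compounds of the
    last segment in the run (for j >= 2).
    """
    length = len(universe.reactions)
    cuts = [0, *cut_points, length]
    if len(genomes) != len(cuts) - 1:
        raise ValueError("need len(cut_points) == len(genomes) - 1")
    if any(cuts[i] >= cuts[i + 1] for i in range(len(cuts) - 1)):
        raise ValueError("cut points must be strictly increasing within the chain")
    segments = [list(range(cuts[i], cuts[i + 1])) for i in range(len(genomes))]
    annotations = tuple(
        GenomeAnnotation(
            organism_id=g,
            ec_set=frozenset(_synthetic_ec(i, id_prefix) for i in seg),
        )
        for g, seg in zip(genomes, segments)
    )
    expected: dict[tuple[str, ...], frozenset[str]] = {}
    import itertools

    for k in range(2, len(genomes) + 1):
        for combo in itertools.combinations(range(len(genomes)), k):
            key = tuple(genomes[i] for i in combo)
            if combo == tuple(range(k)):
                seg = segments[k - 1]
                expected[key] = frozenset(
                    f"{id_prefix}_c{i + 1}" for i in seg
                )
            else:
                expected[key] = frozenset()
    env = Environment("chain-head", frozenset({f"{id_prefix}_c0"}))
    return SplitPathwayFixture(universe, annotations, env, expected)


# ---------------------------------------------------------------------------
# Shared limiting seeds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SharedSeedFixture:
    """Genomes with known shared/private seeds and closed-form scores."""

    universe: ReactionUniverse
    annotations: tuple[GenomeAnnotation, ...]
    targets: TargetSet
    expected_scores: pd.DataFrame


def plant_shared_seeds(
    genomes: int,
    shared: int,
    private_per_genome: int,
    targets_per_genome: int,
    seed: int = 0,
) -> SharedSeedFixture:
    """Each genome's targets depend on a known mix of shared/private seeds.

    The first ``min(shared, targets_per_genome)`` targets of every genome
    are produced from shared seeds (round-robin); the rest from that
    genome's private seeds. The expected pairwise competition score is
    therefore ``n_shared_dependent / targets_per_genome`` for every ordered
    cross pair, in closed form from the construction.
    """
    if genomes < 1 or shared < 0 or private_per_genome < 0 or targets_per_genome < 0:
        raise ValueError("counts must be non-negative (>=1 genome)")
    n_shared_dep = min(shared, targets_per_genome)
    if targets_per_genome > n_shared_dep and private_per_genome == 0:
        raise ValueError(
            "private seeds required when targets outnumber shared-fed targets"
        )
    rng = np.random.default_rng(seed)
    universe = ReactionUniverse()
    org_ids = [f"G{g}" for g in range(genomes)]
    shared_seeds = [f"S{j}" for j in range(shared)]
    all_targets: set[str] = set()
    annotations = []
    ec_counter = 0
    for g, org in enumerate(org_ids):
        ecs = set()
        private = [f"{org}_p{j}" for j in range(private_per_genome)]
        for t in range(targets_per_genome):
            target = f"{org}_t{t}"
            all_targets.add(target)
            if t < n_shared_dep:
                substrate = shared_seeds[t % shared]
            else:
                substrate = private[t % private_per_genome]
            ec = _synthetic_ec(ec_counter, "shared-seed")
            ec_counter += 1
            ecs.add(ec)
            universe.add_reaction(
                DirectedReaction(
                    id=f"{org}_r{t}",
                    ec_numbers=frozenset({ec}),
                    substrates=frozenset({substrate}),
                    products=frozenset({target}),
                )
            )
        annotations.append(GenomeAnnotation(org, frozenset(ecs)))
    score = n_shared_dep / targets_per_genome if targets_per_genome else 0.0
    expected = pd.DataFrame(
        np.full((genomes, genomes), score if shared else 0.0),
        index=org_ids,
        columns=org_ids,
    )
    np.fill_diagonal(expected.values, np.nan)
    # RNG reserved for future jitter; draw once so the seed is part of the contract
    rng.random()
    return SharedSeedFixture(
        universe=universe,
        annotations=tuple(annotations),
        targets=TargetSet(frozenset(all_targets)),
        expected_scores=expected,
    )


# ---------------------------------------------------------------------------
# Random universes
# ---------------------------------------------------------------------------


def make_random_universe(
    n_compounds: int,
    n_reactions: int,
    reversible_fraction: float = 0.3,
    seed: int = 0,
) -> ReactionUniverse:
    """A uniformly sampled universe for oracle testing.

    Substrate and product sets have sizes 1-3 (products may overlap
    substrates: autocatalytic loops are legal). A ``reversible_fraction``
    of reactions is stored as split direction pairs, exactly as the loader
    would produce. Reproducible from the seed.
    """
    if n_compounds < 2:
        raise ValueError("need at least 2 compounds")
    rng = np.random.default_rng(seed)
    compounds = [f"M{i}" for i in range(n_compounds)]
    universe = ReactionUniverse(compounds=[Compound(c) for c in compounds])
    for i in range(n_reactions):
        ns = int(rng.integers(1, 4))
        npd = int(rng.integers(1, 4))
        subs = frozenset(rng.choice(n_compounds, size=ns, replace=False))
        prods = frozenset(rng.choice(n_compounds, size=npd, replace=False))
        subs_ids = frozenset(compounds[j] for j in subs)
        prods_ids = frozenset(compounds[j] for j in prods)
        ec = frozenset({_synthetic_ec(i, "random")})
        rid = f"R{i}"
        if rng.random() < reversible_fraction:
            universe.add_reaction(DirectedReaction(
                rid + FORWARD_SUFFIX, ec, subs_ids, prods_ids,
                from_reversible=True, parent_id=rid))
            universe.add_reaction(DirectedReaction(
                rid + REVERSE_SUFFIX, ec, prods_ids, subs_ids,
                from_reversible=True, parent_id=rid))
        else:
            universe.add_reaction(DirectedReaction(rid, ec, subs_ids, prods_ids))
    return universe


# ---------------------------------------------------------------------------
# Hand-built toy communities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyCommunity:
    """A small community fixture: universe, member networks, media, targets."""

    universe: ReactionUniverse
    networks: Mapping[str, MetabolicNetwork]
    env_host: Environment
    targets: TargetSet
    annotations: Mapping[str, GenomeAnnotation] = None  # type: ignore[assignment]


def _community(
    reactions: Sequence[tuple[str, str, Sequence[str], Sequence[str]]],
    genomes: Mapping[str, Sequence[str]],
    env: Sequence[str],
    targets: Sequence[str],
    env_name: str = "host",
    extra_compounds: Sequence[Compound] = (),
) -> ToyCommunity:
    universe = ReactionUniverse(compounds=list(extra_compounds))
    for rid, ec, subs, prods in reactions:
        universe.add_reaction(
            DirectedReaction(rid, frozenset({ec}), frozenset(subs), frozenset(prods))
        )
    for cid in list(env) + list(targets):
        if cid not in universe:
            universe.add_compound(Compound(cid))
    annotations = {
        org: GenomeAnnotation(org, frozenset(ecs), genus_label=org.split("_")[0])
        for org, ecs in genomes.items()
    }
    networks = {
        org: network_from_ecs(universe, ann) for org, ann in annotations.items()
    }
    return ToyCommunity(
        universe=universe,
        networks=networks,
        env_host=Environment(env_name, frozenset(env)),
        targets=TargetSet(frozenset(targets)),
        annotations=annotations,
    )


def lysine_toy() -> ToyCommunity:
    """Lysine hand-off between facultative symbionts.

    A *Wolbachia*-like genome runs the diaminopimelate route from aspartate
    to M-DAP but lacks the terminal diaminopimelate decarboxylase
    (EC 4.1.1.20); a *Hamiltonella*-like genome carries exactly that
    enzyme. An obligate (*Portiera*-like) genome also reaches M-DAP, so
    enriching the medium with its products lets the decarboxylase carrier
    finish lysine alone — masking the pairwise complementation.
    """
    return _community(
        reactions=[
            ("ask", "2.7.2.4", ["ASP"], ["ASA"]),
            ("dap", "1.2.1.11", ["ASA"], ["MDAP"]),
            ("lysA", "4.1.1.20", ["MDAP"], ["LYS"]),
        ],
        genomes={
            "Wolbachia": ["2.7.2.4", "1.2.1.11"],
            "Hamiltonella": ["4.1.1.20"],
            "Portiera": ["2.7.2.4", "1.2.1.11"],
        },
        env=["ASP"],
        targets=["LYS"],
    )


def tryptophan_toy() -> ToyCommunity:
    """An obligate-symbiont genome with narrow precursor dependencies.

    Tryptophan requires all three of D-erythrose 4-phosphate,
    phosphoenolpyruvate (via chorismate) and D-ribose 5-phosphate (via
    PRPP); methionine requires L-homocysteine; threonine requires
    aspartate. Removing any one tryptophan precursor costs exactly that
    one target.
    """
    return _community(
        reactions=[
            ("aro", "2.5.1.54", ["E4P", "PEP"], ["CHOR"]),
            ("prs", "2.7.6.1", ["R5P"], ["PRPP"]),
            ("trp", "4.2.1.20", ["CHOR", "PRPP"], ["TRP"]),
            ("met", "2.1.1.14", ["HCY"], ["MET"]),
            ("hom", "1.1.1.3", ["ASP"], ["HSER"]),
            ("thr", "4.2.3.1", ["HSER"], ["THR"]),
        ],
        genomes={
            "Portiera": ["2.5.1.54", "2.7.6.1", "4.2.1.20", "2.1.1.14",
                         "1.1.1.3", "4.2.3.1"],
        },
        env=["E4P", "PEP", "R5P", "HCY", "ASP"],
        targets=["TRP", "MET", "THR"],
    )


def thiamine_toy() -> ToyCommunity:
    """Thiamine activation restricted to a kinase-bearing genome.

    Only the *Wolbachia*-like network carries thiamine diphosphokinase
    (EC 2.7.6.2) converting thiamine to thiamine diphosphate; the
    *Rickettsia*-like network produces its targets independently of
    thiamine, so thiamine removal hurts only the kinase carrier.
    """
    return _community(
        reactions=[
            ("tdk", "2.7.6.2", ["THI", "ATP"], ["THDP", "AMP"]),
            ("ggc", "6.3.2.2", ["CYS", "GLU", "ATP"], ["GGC"]),
        ],
        genomes={
            "Wolbachia": ["2.7.6.2"],
            "Rickettsia": ["6.3.2.2"],
        },
        env=["THI", "ATP", "CYS", "GLU"],
        targets=["THDP", "GGC"],
    )


# ---------------------------------------------------------------------------
# Five-genome demo community over the packaged bacteriocyte medium
# ---------------------------------------------------------------------------

#: demo reactions: (id, EC, substrates, products), KEGG-style compound ids
_DEMO_REACTIONS: list[tuple[str, str, list[str], list[str]]] = [
    # aromatic amino acids (obligate): chorismate from E4P + PEP, PRPP from R5P
    ("aroA", "2.5.1.54", ["C00279", "C00074"], ["C00251"]),
    ("prsA", "2.7.6.1", ["C00117", "C00002"], ["C00119", "C00008"]),
    ("trpB", "4.2.1.20", ["C00251", "C00119"], ["C00078"]),
    ("pheA", "4.2.1.51", ["C00251"], ["C00079"]),
    # methionine from homocysteine; threonine from aspartate
    ("metE", "2.1.1.13", ["C00155"], ["C00073"]),
    ("hom", "1.1.1.3", ["C00049"], ["C00263"]),
    ("thrC", "4.2.3.1", ["C00263"], ["C00188"]),
    # alanine and glutamine (obligate)
    ("alaC", "2.6.1.2", ["C00022", "C00025"], ["C00041", "C00026"]),
    ("glnA", "6.3.1.2", ["C00025", "C00014", "C00002"], ["C00064", "C00008"]),
    # branched-chain amino acids: intermediates by the obligate, the
    # terminal aminotransferase (ilvE) only in the Rickettsia-like genome
    ("ilvB", "2.2.1.6", ["C00022"], ["C00141"]),
    ("leuA", "2.3.3.13", ["C00141"], ["C00233"]),
    ("ilvA", "4.3.1.19", ["C00188"], ["C00671"]),
    ("ilvE_val", "2.6.1.42", ["C00141", "C00025"], ["C00183", "C00026"]),
    ("ilvE_leu", "2.6.1.42", ["C00233", "C00025"], ["C00123", "C00026"]),
    ("ilvE_ile", "2.6.1.42", ["C00671", "C00025"], ["C00407", "C00026"]),
    # lysine: diaminopimelate route to M-DAP, terminal decarboxylase apart
    ("ask", "2.7.2.4", ["C00049", "C00002"], ["C00441", "C00008"]),
    ("dapB", "1.2.1.11", ["C00441"], ["C00680"]),
    ("lysA", "4.1.1.20", ["C00680"], ["C00047"]),
    # asparagine (ATP-dependent)
    ("asnB", "6.3.5.4", ["C00049", "C00014", "C00002"], ["C00152", "C00008"]),
    # thiamine activation
    ("thiN", "2.7.6.2", ["C00378", "C00002"], ["C00068", "C00020"]),
    # serine-consuming one-carbon step (methylene-THF target)
    ("glyA", "2.1.2.1", ["C00065", "C00101"], ["C00037", "C00143"]),
    # cysteine-consuming glutathione precursor (ATP-dependent)
    ("gshA", "6.3.2.2", ["C00097", "C00025", "C00002"], ["C00669", "C00008"]),
    # NAD+-dependent malate dehydrogenase
    ("mdh", "1.1.1.37", ["C00149", "C00003"], ["C00036", "C00004"]),
    # pyruvate kinase: ATP regeneration from PEP (glycolytic genomes only)
    ("pyk", "2.7.1.40", ["C00074", "C00008"], ["C00022", "C00002"]),
]

_DEMO_GENOMES: dict[str, list[str]] = {
    "Portiera": ["2.5.1.54", "2.7.6.1", "4.2.1.20", "4.2.1.51", "2.1.1.13",
                 "1.1.1.3", "4.2.3.1", "2.6.1.2", "6.3.1.2", "2.2.1.6",
                 "2.3.3.13", "4.3.1.19", "2.7.2.4", "1.2.1.11"],
    "Rickettsia": ["2.6.1.42", "6.3.2.2", "1.1.1.37"],
    "Hamiltonella": ["4.1.1.20", "6.3.5.4", "2.1.2.1", "2.7.1.40"],
    "Cardinium": ["6.3.5.4"],
    "Wolbachia": ["2.7.2.4", "1.2.1.11", "2.7.6.2", "2.1.2.1", "6.3.2.2",
                  "1.1.1.37", "6.3.5.4", "2.7.1.40"],
}

#: essential-metabolite panel of the demo community (non-source compounds)
_DEMO_TARGETS = [
    "C00078",  # L-tryptophan
    "C00079",  # L-phenylalanine
    "C00073",  # L-methionine
    "C00188",  # L-threonine
    "C00041",  # L-alanine
    "C00064",  # L-glutamine
    "C00183",  # L-valine
    "C00123",  # L-leucine
    "C00407",  # L-isoleucine
    "C00047",  # L-lysine
    "C00152",  # L-asparagine
    "C00068",  # thiamine diphosphate
    "C00004",  # NADH
    "C00669",  # gamma-glutamylcysteine
    "C00143",  # 5,10-methylene-THF
]


def bacteriocyte_demo() -> ToyCommunity:
    """Five-genome demo community in the packaged 49-compound medium.

    Hand-built so that the documented whitefly-symbiont interaction motifs
    are all present: the obligate genome synthesizes Gln, Ala, Thr, Met
    (from homocysteine), Trp and Phe; lysine requires the M-DAP producer
    plus the decarboxylase carrier; BCA synthesis requires the obligate's
    intermediates plus the *Rickettsia*-like aminotransferase; thiamine
    diphosphate is exclusive to the kinase-bearing genome; and NAD+/ATP/
    cysteine/serine dependencies split across genomes according to which
    carry glycolytic ATP regeneration.
    """
    universe = ReactionUniverse()
    for rid, ec, subs, prods in _DEMO_REACTIONS:
        universe.add_reaction(
            DirectedReaction(rid, frozenset({ec}), frozenset(subs), frozenset(prods))
        )
    env = load_host_environment()
    for cid in env.source_metabolites:
        if cid not in universe:
            universe.add_compound(Compound(cid))
    annotations = {
        org: GenomeAnnotation(org, frozenset(ecs), genus_label=org)
        for org, ecs in _DEMO_GENOMES.items()
    }
    networks = {
        org: network_from_ecs(universe, ann) for org, ann in annotations.items()
    }
    return ToyCommunity(
        universe=universe,
        networks=networks,
        env_host=env,
        targets=TargetSet(frozenset(_DEMO_TARGETS)),
        annotations=annotations,
    )
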