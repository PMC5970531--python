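"""Compounds, reactions, organisms and their file formats.

The analysis operates on a *reaction universe*: a catalogue of compounds and
directed reactions indexed by EC number. Per-organism metabolic networks are
the subset of universe reactions whose EC annotations appear in the genome's
enzyme list. The bacteriocyte is modeled as one well-mixed compound pool, so
compound identity is a single flat namespace with no compartments.

File dialects (all plain text, tab-separated):

* reaction table — one reaction per line::

      reaction_id<TAB>ec1;ec2<TAB>substrate1;substrate2<TAB>product1<TAB>direction

  with ``direction`` one of ``>`` (forward), ``<`` (reverse) or ``=``
  (reversible, split into two directed reactions at load time);
* compound table — ``id<TAB>name<TAB>pathway_class``;
* EC list — one EC per line, ``#`` comments allowed;
* environment / target list — one compound id per line.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

EC_PATTERN = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")

#: suffixes appended to a reversible reaction id for its two directions
FORWARD_SUFFIX = "__f"
REVERSE_SUFFIX = "__r"


class UniverseFormatError(ValueError):
    """Malformed reaction/compound file (carries the offending line number)."""


class UniverseValidationError(ValueError):
    """Structurally valid file whose contents violate universe invariants."""


def is_valid_ec(ec: str) -> bool:
    """True if *ec* matches ``d.d.d.d`` where trailing fields may be ``-``."""
    return bool(EC_PATTERN.match(ec))


def ec_matches(annotation_ec: str, universe_ec: str, strict: bool = False) -> bool:
    """Whether an annotated EC selects a universe EC.

    Partial ECs (trailing ``-`` fields, e.g. ``1.1.1.-``) match any universe
    EC they prefix, because annotation pipelines routinely emit partial ECs
    and silently dropping them would understate metabolic capability. With
    ``strict=True`` only exact string equality matches.
    """
    if annotation_ec == universe_ec:
        return True
    if strict:
        return False
    ann = annotation_ec.split(".")
    uni = universe_ec.split(".")
    if len(ann) != 4 or len(uni) != 4:
        return False
    for a, u in zip(ann, uni):
        if a == "-":
            return True
        if a != u:
            return False
    return True


@dataclass(frozen=True)
class Compound:
    """A metabolite. ``pathway_class`` is an optional super-pathway tag."""

    id: str
    name: str = ""
    pathway_class: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise UniverseValidationError("compound id must be non-empty")


@dataclass(frozen=True)
class DirectedReaction:
    """One direction of a biochemical reaction.

    Reversible catalogue entries are split into two ``DirectedReaction``
    records sharing a ``parent_id``; feasibility downstream is then purely
    "all substrates available".
    """

    id: str
    ec_numbers: frozenset[str]
    substrates: frozenset[str]
    products: frozenset[str]
    from_reversible: bool = False
    parent_id: str = ""

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise UniverseValidationError(
                f"reaction {self.id!r}: substrates and products must be non-empty"
            )
        for ec in self.ec_numbers:
            if not is_valid_ec(ec):
                raise UniverseValidationError(
                    f"reaction {self.id!r}: invalid EC number {ec!r}"
                )
        if not self.parent_id:
            object.__setattr__(self, "parent_id", self.id)


class ReactionUniverse:
    """The global catalogue of compounds and directed reactions.

    Maintains an EC index (EC string -> set of directed-reaction ids)
    covering exactly the ECs that appear on reactions.
    """

    def __init__(
        self,
        compounds: Iterable[Compound] = (),
        reactions: Iterable[DirectedReaction] = (),
    ) -> None:
        self.compounds: dict[str, Compound] = {}
        self.reactions: dict[str, DirectedReaction] = {}
        self.ec_index: dict[str, set[str]] = {}
        for c in compounds:
            self.add_compound(c)
        for r in reactions:
            self.add_reaction(r)

    # -- construction -----------------------------------------------------

    def add_compound(self, compound: Compound) -> None:
        existing = self.compounds.get(compound.id)
        if existing is not None and existing != compound:
            raise UniverseValidationError(f"duplicate compound id {compound.id!r}")
        self.compounds[compound.id] = compound

    def add_reaction(
        self, reaction: DirectedReaction, create_compounds: bool = True
    ) -> None:
        if reaction.id in self.reactions:
            raise UniverseValidationError(f"duplicate reaction id {reaction.id!r}")
        for cid in reaction.substrates | reaction.products:
            if cid not in self.compounds:
                if create_compounds:
                    self.add_compound(Compound(cid))
                else:
                    raise UniverseValidationError(
                        f"reaction {reaction.id!r} references unknown compound {cid!r}"
                    )
        self.reactions[reaction.id] = reaction
        for ec in reaction.ec_numbers:
            self.ec_index.setdefault(ec, set()).add(reaction.id)

    # -- queries -----------------------------------------------------------

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.compounds

    @property
    def compound_ids(self) -> frozenset[str]:
        return frozenset(self.compounds)

    def reactions_for_ec(self, ec: str, strict: bool = False) -> set[str]:
        """Directed-reaction ids selected by an (possibly partial) EC."""
        if strict or "-" not in ec:
            return set(self.ec_index.get(ec, ()))
        hits: set[str] = set()
        for uni_ec, rids in self.ec_index.items():
            if ec_matches(ec, uni_ec):
                hits |= rids
        return hits

    def validate_compounds(self, ids: Iterable[str], what: str = "compound") -> None:
        unknown = sorted(set(ids) - set(self.compounds))
        if unknown:
            raise UniverseValidationError(
                f"unknown {what} id(s): {', '.join(unknown)}"
            )


@dataclass(frozen=True)
class GenomeAnnotation:
    """An organism's enzyme content: its genome-derived EC numbers."""

    organism_id: str
    ec_set: frozenset[str]
    genus_label: str = ""

    def __post_init__(self) -> None:
        if not self.organism_id:
            raise UniverseValidationError("organism_id must be non-empty")
        bad = sorted(ec for ec in self.ec_set if not is_valid_ec(ec))
        if bad:
            raise UniverseValidationError(
                f"{self.organism_id}: invalid EC number(s): {', '.join(bad)}"
            )


@dataclass(frozen=True)
class MetabolicNetwork:
    """One organism's reaction subset, drawn from a shared universe."""

    organism_id: str
    reactions: frozenset[DirectedReaction]
    unmapped_ecs: frozenset[str] = frozenset()

    @property
    def reaction_ids(self) -> frozenset[str]:
        return frozenset(r.id for r in self.reactions)

    @property
    def compound_ids(self) -> frozenset[str]:
        ids: set[str] = set()
        for r in self.reactions:
            ids |= r.substrates | r.products
        return frozenset(ids)


@dataclass(frozen=True)
class Environment:
    """A named set of source metabolites seeding network expansion."""

    name: str
    source_metabolites: frozenset[str]

    def __post_init__(self) -> None:
        if not self.source_metabolites:
            raise UniverseValidationError(
                f"environment {self.name!r} must contain at least one source metabolite"
            )

    def __len__(self) -> int:
        return len(self.source_metabolites)

    def without(self, compound_id: str) -> "Environment":
        """The environment with one source metabolite removed."""
        reduced = self.source_metabolites - {compound_id}
        return Environment(f"{self.name}-minus-{compound_id}", frozenset(reduced))


@dataclass(frozen=True)
class TargetSet:
    """The panel of essential metabolites whose producibility proxies growth."""

    targets: frozenset[str]

    def __len__(self) -> int:
        return len(self.targets)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _data_lines(path: Path) -> list[tuple[int, str]]:
    lines = []
    for i, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        lines.append((i, line))
    return lines


def load_compound_table(path: str | Path) -> list[Compound]:
    """Read a ``id<TAB>name<TAB>pathway_class`` compound table."""
    path = Path(path)
    compounds = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if not parts[0]:
            raise UniverseFormatError(f"{path}:{lineno}: empty compound id")
        name = parts[1] if len(parts) > 1 else ""
        pclass = parts[2] if len(parts) > 2 else ""
        compounds.append(Compound(parts[0], name, pclass))
    return compounds


def load_universe(
    path: str | Path, compounds_path: str | Path | None = None
) -> ReactionUniverse:
    """Read a reaction table (and optional compound table) into a universe.

    Reversible records (direction ``=``) are split into two directed
    reactions (suffixes ``__f``/``__r``) both indexed under the parent's EC
    numbers. With a compound table, any reaction referencing a compound
    absent from the table is a validation error; without one, compounds are
    inferred from the reactions.
    """
    path = Path(path)
    universe = ReactionUniverse()
    strict_compounds = compounds_path is not None
    if strict_compounds:
        for c in load_compound_table(Path(compounds_path)):
            universe.add_compound(c)
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 5:
            raise UniverseFormatError(
                f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}"
            )
        rid, ec_field, sub_field, prod_field, direction = parts
        if not rid:
            raise UniverseFormatError(f"{path}:{lineno}: empty reaction id")
        if direction not in (">", "<", "="):
            raise UniverseFormatError(
                f"{path}:{lineno}: direction must be one of > < =, got {direction!r}"
            )
        ecs = frozenset(e for e in ec_field.split(";") if e)
        subs = frozenset(s for s in sub_field.split(";") if s)
        prods = frozenset(p for p in prod_field.split(";") if p)
        try:
            if direction == "=":
                records = [
                    DirectedReaction(rid + FORWARD_SUFFIX, ecs, subs, prods,
                                     from_reversible=True, parent_id=rid),
                    DirectedReaction(rid + REVERSE_SUFFIX, ecs, prods, subs,
                                     from_reversible=True, parent_id=rid),
                ]
            elif direction == "<":
                records = [DirectedReaction(rid, ecs, prods, subs)]
            else:
                records = [DirectedReaction(rid, ecs, subs, prods)]
            for rec in records:
                universe.add_reaction(rec, create_compounds=not strict_compounds)
        except UniverseValidationError as exc:
            raise UniverseValidationError(f"{path}:{lineno}: {exc}") from exc
    return universe


def write_universe(
    universe: ReactionUniverse,
    path: str | Path,
    compounds_path: str | Path | None = None,
) -> None:
    """Write a universe back to the reaction-table dialect.

    Reversible direction pairs are re-merged into single ``=`` records, so
    ``load_universe`` after ``write_universe`` reproduces the universe
    exactly (up to record order).
    """
    path = Path(path)
    lines = []
    seen_parents: set[str] = set()
    for rid in sorted(universe.reactions):
        r = universe.reactions[rid]
        if r.from_reversible:
            if r.parent_id in seen_parents:
                continue
            seen_parents.add(r.parent_id)
            if rid.endswith(REVERSE_SUFFIX):
                # emit from the forward member for a stable orientation
                r = universe.reactions[r.parent_id + FORWARD_SUFFIX]
            lines.append(_format_reaction(r.parent_id, r, "="))
        else:
            lines.append(_format_reaction(r.id, r, ">"))
    path.write_text("\n".join(lines) + "\n")
    if compounds_path is not None:
        rows = [
            f"{c.id}\t{c.name}\t{c.pathway_class}"
            for c in (universe.compounds[i] for i in sorted(universe.compounds))
        ]
        Path(compounds_path).write_text("\n".join(rows) + "\n")


def _format_reaction(rid: str, r: DirectedReaction, direction: str) -> str:
    return "\t".join(
        [
            rid,
            ";".join(sorted(r.ec_numbers)),
            ";".join(sorted(r.substrates)),
            ";".join(sorted(r.products)),
            direction,
        ]
    )


def load_ec_list(path: str | Path, organism_id: str | None = None,
                 genus_label: str = "") -> GenomeAnnotation:
    """Read a one-EC-per-line genome annotation file."""
    path = Path(path)
    ecs = []
    for lineno, line in _data_lines(path):
        ec = line.split()[0]
        if not is_valid_ec(ec):
            raise UniverseFormatError(f"{path}:{lineno}: invalid EC number {ec!r}")
        ecs.append(ec)
    if organism_id is None:
        organism_id = path.stem
    return GenomeAnnotation(organism_id, frozenset(ecs), genus_label)


def write_ec_list(annotation: GenomeAnnotation, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(annotation.ec_set)) + "\n")


def load_compound_list(path: str | Path) -> frozenset[str]:
    """Read a one-compound-id-per-line file (environment/target dialect)."""
    return frozenset(line for _, line in _data_lines(Path(path)))


def write_compound_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n")


def load_targets(path: str | Path, universe: ReactionUniverse | None = None) -> TargetSet:
    ids = load_compound_list(path)
    if universe is not None:
        universe.validate_compounds(ids, "target")
    return TargetSet(ids)


# ---------------------------------------------------------------------------
# Network reconstruction
# ---------------------------------------------------------------------------


def network_from_ecs(
    universe: ReactionUniverse,
    annotation: GenomeAnnotation,
    strict_ec: bool = False,
) -> MetabolicNetwork:
    """Reconstruct an organism's metabolic network from its EC content.

    Every directed reaction whose EC annotations intersect the genome's EC
    set is included — one EC may map to many reactions and all are kept,
    since the reconstruction is driven by enzyme content alone. ECs with no
    counterpart in the universe are recorded on the returned network (and
    logged), never fatal: genome annotations routinely outpace any reaction
    catalogue.
    """
    reaction_ids: set[str] = set()
    unmapped: set[str] = set()
    for ec in annotation.ec_set:
        hits = universe.reactions_for_ec(ec, strict=strict_ec)
        if hits:
            reaction_ids |= hits
        else:
            unmapped.add(ec)
    if unmapped:
        logger.info(
            "%s: %d EC(s) not mapped to any catalogue reaction: %s",
            annotation.organism_id, len(unmapped), ", ".join(sorted(unmapped)),
        )
    if not reaction_ids and annotation.ec_set:
        logger.warning(
            "%s: no catalogue reaction matched any of its %d ECs",
            annotation.organism_id, len(annotation.ec_set),
        )
    return MetabolicNetwork(
        organism_id=annotation.organism_id,
        reactions=frozenset(universe.reactions[r] for r in reaction_ids),
        unmapped_ecs=frozenset(unmapped),
    )


def merge_networks(networks: Sequence[MetabolicNetwork]) -> MetabolicNetwork:
    """Pool the reaction sets of several organisms into one combined network.

    The combined network models co-growth of the member organisms: its
    reactions are the set union and its id the ordered concatenation of the
    member ids.
    """
    if not networks:
        raise ValueError("merge_networks requires at least one network")
    reactions: frozenset[DirectedReaction] = frozenset()
    for n in networks:
        reactions |= n.reactions
    organism_id = "+".join(n.organism_id for n in networks)
    return MetabolicNetwork(organism_id=organism_id, reactions=reactions)
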