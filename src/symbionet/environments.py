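"""Bacteriocyte environments: host-only sources and obligate-enriched media.

The host is represented solely by the metabolites it provides (source
metabolites); its own enzymes are never modeled. A second, enriched
environment is derived by letting the obligate symbiont (*Portiera*-like)
expand in the host-only environment and adding everything it can make. The
two environments are kept apart by name in every downstream result so
host-only and host+obligate outputs cannot be silently mixed.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .expansion import expand
from .reaction_universe import (
    Environment,
    MetabolicNetwork,
    ReactionUniverse,
    UniverseValidationError,
    load_compound_list,
    write_compound_list,
)

logger = logging.getLogger(__name__)

#: packaged synthetic reconstruction of the 49-compound host-only medium
BUNDLED_HOST_ENVIRONMENT = Path(__file__).parent / "data" / "bacteriocyte_sources_synthetic.txt"


def load_environment(
    path: str | Path,
    universe: ReactionUniverse | None = None,
    name: str | None = None,
) -> Environment:
    """Read a one-compound-per-line environment file.

    Duplicate lines collapse (set semantics). An empty file is an error —
    an environment must provide at least one source metabolite. With a
    universe, every id must resolve in it.
    """
    path = Path(path)
    ids = load_compound_list(path)
    if not ids:
        raise UniverseValidationError(f"environment file {path} is empty")
    if universe is not None:
        universe.validate_compounds(ids, "source metabolite")
    env = Environment(name or path.stem, ids)
    logger.info("environment %s: %d source metabolites", env.name, len(env))
    return env


def write_environment(env: Environment, path: str | Path) -> None:
    write_compound_list(env.source_metabolites, path)


def load_host_environment(universe: ReactionUniverse | None = None) -> Environment:
    """The packaged synthetic 49-compound bacteriocyte source list.

    A stand-in assembled from published descriptions of phloem and
    bacteriocyte content: ATP, NAD+ and other cofactors and vitamins (heme,
    thiamine), six non-essential amino acids, sugars, and pathway precursors
    such as D-ribose 5-phosphate, D-erythrose 4-phosphate and
    phosphoenolpyruvate.
    """
    return load_environment(BUNDLED_HOST_ENVIRONMENT, universe, name="host")


def derive_host_portiera(
    host_env: Environment, portiera: MetabolicNetwork
) -> Environment:
    """Enrich the host environment with the obligate symbiont's products.

    The derived source set is the obligate's full scope in the host
    environment — host metabolites plus everything the symbiont can make
    from them (seeds are part of scope, so this is equivalent to adding
    only the "new" compounds). Re-applying with the same network is a
    no-op (idempotent).
    """
    scope = expand(host_env, portiera).scope
    name = f"{host_env.name}+{portiera.organism_id}"
    if host_env.name.endswith(f"+{portiera.organism_id}"):
        name = host_env.name
    return Environment(name, scope)
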