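"""Metabolic complementation: metabolites only genome combinations can make.

A metabolite is *complementary* (synergistic) for a combination of genomes
in a given environment when the pooled reaction set produces it but no
proper sub-combination does. For pairs this is the classic three-stage
procedure: pool the two EC-derived reaction sets, expand the pooled network
in the environment, and subtract everything either member produces alone.

Complementary metabolites detected in the host-only environment but not
once the medium is enriched by the obligate symbiont are *masked*: an
alternative route through the obligate exists.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from sklearn.decomposition import PCA

from .expansion import expand
from .reaction_universe import Environment, MetabolicNetwork, merge_networks

logger = logging.getLogger(__name__)

MASK_BOTH = "both_envs"
MASK_HOST_ONLY = "host_only"
MASK_HP_ONLY = "host_portiera_only"


@dataclass(frozen=True)
class ComplementationResult:
    """Complementary metabolites of one genome combination in one medium."""

    member_ids: tuple[str, ...]
    environment_name: str
    complementary: frozenset[str]

    @property
    def label(self) -> str:
        return "+".join(self.member_ids)


def complementary_metabolites(
    a: MetabolicNetwork, b: MetabolicNetwork, env: Environment
) -> ComplementationResult:
    """Pairwise complementary metabolites of *a* and *b* in *env*.

    ``scope(a ∪ b) \\ (scope(a) ∪ scope(b))`` — symmetric in the pair.
    """
    if a.organism_id == b.organism_id:
        raise ValueError("complementation requires two distinct organisms")
    return kwise_complementary([a, b], env)


def kwise_complementary(
    members: Sequence[MetabolicNetwork], env: Environment
) -> ComplementationResult:
    """Combination-specific complementary metabolites for k >= 2 genomes.

    Metabolites in the scope of the full pooled network that no proper
    non-empty sub-combination (including singletons) can reach. For k = 2
    this reduces exactly to the pairwise definition.
    """
    if len(members) < 2:
        raise ValueError("kwise_complementary requires at least 2 networks")
    full_scope = expand(env, merge_networks(list(members))).scope
    covered: set[str] = set()
    for size in range(1, len(members)):
        for sub in itertools.combinations(members, size):
            net = sub[0] if size == 1 else merge_networks(list(sub))
            covered |= expand(env, net).scope
    return ComplementationResult(
        member_ids=tuple(m.organism_id for m in members),
        environment_name=env.name,
        complementary=frozenset(full_scope - covered),
    )


def masking_classify(
    pair: Sequence[MetabolicNetwork],
    env_host: Environment,
    env_hp: Environment,
) -> dict[str, str]:
    """Label each complementary metabolite of *pair* by environment.

    ``both_envs`` — complementary in the host-only and the enriched medium;
    ``host_only`` — complementary only in the host-only medium (masked by
    the obligate symbiont's contribution); ``host_portiera_only`` — the
    reverse.
    """
    comp_host = kwise_complementary(pair, env_host).complementary
    comp_hp = kwise_complementary(pair, env_hp).complementary
    labels: dict[str, str] = {}
    for m in comp_host | comp_hp:
        if m in comp_host and m in comp_hp:
            labels[m] = MASK_BOTH
        elif m in comp_host:
            labels[m] = MASK_HOST_ONLY
        else:
            labels[m] = MASK_HP_ONLY
    return labels


@dataclass
class ComplementationProfile:
    """Combination x metabolite binary incidence, optionally with masking.

    ``incidence`` rows are combination labels (one per combination per
    environment), columns are compound ids in lexicographic order, entries
    in {0, 1}. ``masking`` holds per-(combination, metabolite) labels where
    defined.
    """

    incidence: pd.DataFrame
    masking: dict[tuple[str, str], str]

    @property
    def row_labels(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.incidence.columns)


def build_profile(
    results: Iterable[ComplementationResult],
    masking: dict[tuple[str, str], str] | None = None,
) -> ComplementationProfile:
    """Assemble complementation results into a binary incidence matrix.

    One row per result, labelled ``members@environment``; columns are the
    lexicographically sorted union of all observed complementary compounds.
    Row sums therefore equal the per-combination complementary counts.
    """
    results = list(results)
    columns = sorted(set().union(*(r.complementary for r in results))) if results else []
    rows = {}
    for r in results:
        label = f"{r.label}@{r.environment_name}"
        rows[label] = [1 if c in r.complementary else 0 for c in columns]
    incidence = pd.DataFrame.from_dict(rows, orient="index", columns=columns, dtype=int)
    return ComplementationProfile(incidence=incidence, masking=dict(masking or {}))


def pca_cluster_profiles(
    profile: ComplementationProfile,
    n_components: int = 2,
    n_clusters: int = 2,
    linkage: str = "average",
) -> tuple[pd.DataFrame, pd.Series]:
    """PCA coordinates and hierarchical cluster labels for profile rows.

    PCA is computed on the centered raw binary incidence (no scaling); the
    sign of each component is fixed so its largest-magnitude loading is
    positive, making coordinates deterministic. Clustering is agglomerative
    on Euclidean row distances (linkage method selectable, default
    average), cut into ``n_clusters`` flat clusters.
    """
    X = profile.incidence.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 profile rows for PCA/clustering")
    n_components = min(n_components, X.shape[0] - 1, max(X.shape[1], 1))
    if np.allclose(X.var(axis=0), 0):
        warnings.warn("all profile rows identical: zero variance, coordinates are 0")
        coords = np.zeros((X.shape[0], n_components))
        components = np.zeros((n_components, X.shape[1]))
    else:
        pca = PCA(n_components=n_components)
        coords = pca.fit_transform(X)
        components = pca.components_
        for k in range(components.shape[0]):
            j = int(np.argmax(np.abs(components[k])))
            if components[k, j] < 0:
                components[k] *= -1
                coords[:, k] *= -1
    coord_df = pd.DataFrame(
        coords,
        index=profile.incidence.index,
        columns=[f"PC{k + 1}" for k in range(coords.shape[1])],
    )
    if X.shape[0] == n_clusters:
        labels = np.arange(1, X.shape[0] + 1)
    else:
        Z = scipy_linkage(X, method=linkage, metric="euclidean")
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    cluster = pd.Series(labels, index=profile.incidence.index, name="cluster")
    return coord_df, cluster
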