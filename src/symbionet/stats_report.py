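"""Summary statistics and tab-separated report emission.

Covers the community-level summaries: the mean effective metabolic overlap
across cross-genus ordered pairs, the Welch two-sample t-test asking
whether metabolic overlap differs between field-observed (occurring) and
unobserved symbiont pairings, and deterministic TSV reports for every
pipeline product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .competition import CompetitionMatrix
from .complementation import ComplementationProfile, ComplementationResult
from .expansion import ExpansionResult
from .reaction_universe import TargetSet

#: packaged transcription of the published pairwise-interaction table
BUNDLED_PAIRWISE_TABLE = Path(__file__).parent / "data" / "pairwise_interactions.tsv"


@dataclass(frozen=True)
class OccurrenceTable:
    """Which unordered organism pairs co-occur in field surveys."""

    occurring: Mapping[frozenset, bool]

    def __contains__(self, pair: Iterable[str]) -> bool:
        return frozenset(pair) in self.occurring

    def is_occurring(self, a: str, b: str) -> bool:
        return bool(self.occurring[frozenset((a, b))])


@dataclass(frozen=True)
class PairwiseStudyTable:
    """A published-style pairwise table: counts, overlap scores, occurrence."""

    matrix: CompetitionMatrix
    genus_of: Mapping[str, str]
    comp_host: pd.DataFrame
    comp_hp: pd.DataFrame
    occurrence: OccurrenceTable


def load_pairwise_table(path: str | Path = BUNDLED_PAIRWISE_TABLE) -> PairwiseStudyTable:
    """Load a long-format pairwise table (see the packaged fixture header)."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    orgs = list(dict.fromkeys(df["row_organism"]))
    genus_of = {}
    for _, r in df.iterrows():
        genus_of[r["row_organism"]] = r["row_genus"]
        genus_of[r["col_organism"]] = r["col_genus"]
    scores = pd.DataFrame(index=orgs, columns=orgs, dtype=float)
    host = pd.DataFrame(index=orgs, columns=orgs, dtype=float)
    hp = pd.DataFrame(index=orgs, columns=orgs, dtype=float)
    occurring: dict[frozenset, bool] = {}
    for _, r in df.iterrows():
        a, b = r["row_organism"], r["col_organism"]
        scores.loc[a, b] = r["competition"]
        host.loc[a, b] = r["comp_host"]
        hp.loc[a, b] = r["comp_hp"]
        if not pd.isna(r["occurring"]):
            occurring[frozenset((a, b))] = bool(int(r["occurring"]))
    return PairwiseStudyTable(
        matrix=CompetitionMatrix(scores=scores),
        genus_of=genus_of,
        comp_host=host,
        comp_hp=hp,
        occurrence=OccurrenceTable(occurring),
    )


def mean_cross_genus_score(
    matrix: CompetitionMatrix, genus_of: Mapping[str, str]
) -> float:
    """Mean overlap over ordered pairs whose members differ in genus.

    Self pairs and same-genus pairs (duplicate genome reconstructions of
    one genus) are excluded; the result is invariant to row/column order.
    """
    values = []
    for a in matrix.organism_ids:
        for b in matrix.scores.columns:
            if a == b or genus_of[a] == genus_of[b]:
                continue
            v = matrix.scores.loc[a, b]
            if not pd.isna(v):
                values.append(float(v))
    if not values:
        raise ValueError("no cross-genus pairs with scores")
    return float(np.mean(values))


def occurrence_association_test(
    matrix: CompetitionMatrix,
    occ: OccurrenceTable,
    genus_of: Mapping[str, str] | None = None,
) -> tuple[float, float, float]:
    """Welch two-sample t-test of overlap scores by pair occurrence.

    Every ordered cross-genus cell whose unordered pair has an occurrence
    flag contributes its score to the occurring or non-occurring group.
    Returns (t statistic, Welch-Satterthwaite df, two-sided p).
    """
    groups: dict[bool, list[float]] = {True: [], False: []}
    for a in matrix.organism_ids:
        for b in matrix.scores.columns:
            if a == b:
                continue
            if genus_of is not None and genus_of[a] == genus_of[b]:
                continue
            if (a, b) not in occ and frozenset((a, b)) not in occ.occurring:
                continue
            v = matrix.scores.loc[a, b]
            if not pd.isna(v):
                groups[occ.is_occurring(a, b)].append(float(v))
    if len(groups[True]) < 2 or len(groups[False]) < 2:
        raise ValueError("both occurrence groups need at least 2 scores")
    res = stats.ttest_ind(groups[True], groups[False], equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_ttest_closed_form(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Textbook Welch t-test (independent oracle for the scipy route)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


# ---------------------------------------------------------------------------
# Report emission
# ---------------------------------------------------------------------------


def format_pair_cell(comp_host: int, comp_hp: int | None, score: float) -> str:
    """Render one pairwise cell as ``m1/m2 (score)`` (or ``m1 (score)``)."""
    score_s = f"{score:.2f}"
    if comp_hp is None:
        return f"{comp_host} ({score_s})"
    return f"{comp_host}/{comp_hp} ({score_s})"


def emit_pairwise_table(
    path: str | Path,
    matrix: CompetitionMatrix,
    comp_host: Mapping[tuple[str, str], int],
    comp_hp: Mapping[tuple[str, str], int] | None = None,
) -> None:
    """Pairwise table: complementary counts per environment + overlap score.

    Cells follow the ``m1/m2 (score)`` convention; combinations with no
    complementary metabolites print explicit zero counts, never blanks.
    """
    ids = matrix.organism_ids
    rows = []
    for a in ids:
        cells = []
        for b in ids:
            if a == b:
                cells.append("-")
                continue
            ch = int(comp_host.get((a, b), 0))
            hp = None if comp_hp is None else int(comp_hp.get((a, b), 0))
            cells.append(format_pair_cell(ch, hp, float(matrix.scores.loc[a, b])))
        rows.append([a] + cells)
    df = pd.DataFrame(rows, columns=["organism"] + ids)
    df.to_csv(path, sep="\t", index=False)


def emit_production_matrix(
    path: str | Path,
    results: Sequence[ExpansionResult],
    targets: TargetSet,
) -> None:
    """Organism x target binary production matrix for one environment."""
    cols = sorted(targets.targets)
    rows = {
        r.organism_id: [1 if t in r.scope else 0 for t in cols] for r in results
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols, dtype=int)
    df.index.name = "organism"
    df.sort_index().to_csv(path, sep="\t")


def emit_dependency_table(path: str | Path, table: pd.DataFrame) -> None:
    out = table.sort_index()
    out = out[sorted(out.columns)]
    out.index.name = "organism"
    out.to_csv(path, sep="\t")


def emit_profile(
    path_coords: str | Path,
    coords: pd.DataFrame,
    clusters: pd.Series,
) -> None:
    out = coords.copy()
    out["cluster"] = clusters
    out.index.name = "combination"
    out.to_csv(path_coords, sep="\t")


def emit_complementation_list(
    path: str | Path, results: Sequence[ComplementationResult]
) -> None:
    rows = []
    for r in sorted(results, key=lambda r: (r.environment_name, r.member_ids)):
        rows.append(
            {
                "combination": r.label,
                "environment": r.environment_name,
                "n_complementary": len(r.complementary),
                "complementary": ";".join(sorted(r.complementary)),
            }
        )
    pd.DataFrame(rows, columns=["combination", "environment", "n_complementary",
                                "complementary"]).to_csv(path, sep="\t", index=False)
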