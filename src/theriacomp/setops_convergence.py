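"""Stage-partition enrichment and presence/absence convergence screens.

Two families of analysis live here. First, the early/late stage-partition
test: given reference-species placenta-specific gene programs split into an
early and a late developmental set, count how many of each are expressed in
the query species' placenta and test the 2x2 table for enrichment with a
Pearson chi-square. Second, the four-way set-logic screens for convergent
gene co-option: genes expressed in both species' placentas and the query
species' mammary gland but silenced in the reference mammary gland (and the
complementary "reference-placenta-only" variant), with control organs
(liver, testis) run through the identical formula to gauge how many genes
such a screen yields by chance.

Namespace convention: screen outputs are reported in species-A (query)
identifiers. Genes lacking an ortholog are excluded from cross-species
screens and tallied as ``unmappable`` — a missing mapping is not evidence
of absent expression.

A generic one-sided hypergeometric over-representation test is provided for
annotating screen outputs against gene-set libraries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential_expression import adjust_bh
from .io_formats import GeneSet, OrthologMap


class ScreenError(ValueError):
    """Raised on invalid tables or set inputs."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for {early, late} programs x {expressed, not expressed}.

    a = early & expressed, b = early & not, c = late & expressed, d = late & not.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ScreenError(f"cell {name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class ConvergenceScreenResult:
    """Outcome of one presence/absence screen, in species-A namespace."""

    name: str
    genes: frozenset
    inputs: dict
    unmappable: int = 0
    control_counts: tuple = ()

    def __len__(self) -> int:
        return len(self.genes)

    def to_gene_set(self) -> GeneSet:
        roles = ", ".join(f"{k}={v}" for k, v in self.inputs.items())
        return GeneSet(name=self.name, genes=self.genes, description=roles)


def stage_partition_counts(
    early_program: GeneSet,
    late_program: GeneSet,
    query_expressed: Iterable[str],
    orthologs: OrthologMap,
) -> ContingencyTable2x2:
    """Cross the early/late programs with query-placenta expression.

    Programs are in the reference (species-B) namespace; ``query_expressed``
    is the query (species-A) expressed set and is mapped through the
    ortholog table before intersecting.
    """
    if early_program.genes & late_program.genes:
        overlap = sorted(early_program.genes & late_program.genes)[:5]
        raise ScreenError(f"early and late programs overlap: {overlap}")
    query_in_b = orthologs.to_b(query_expressed)
    a = len(early_program.genes & query_in_b)
    c = len(late_program.genes & query_in_b)
    return ContingencyTable2x2(
        a=a, b=len(early_program) - a, c=c, d=len(late_program) - c
    )


def chi_square_independence(table: ContingencyTable2x2, yates: bool = False) -> tuple:
    """Pearson chi-square test of independence on a 2x2 table, 1 df.

    Expected counts from the marginals; optional Yates continuity
    correction (|O-E| reduced by 0.5, not past zero). The uncorrected form
    is the default. Returns ``(statistic, p_value)``.
    """
    observed = table.as_array
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    total = observed.sum()
    if (row == 0).any() or (col == 0).any():
        raise ScreenError("zero marginal in contingency table")
    expected = np.outer(row, col) / total
    if (expected <= 0).any():
        raise ScreenError("expected cell count of zero")
    diff = np.abs(observed - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    p_value = float(stats.chi2.sf(statistic, df=1))
    return statistic, p_value


def shared_coopted(
    placenta_a: Iterable[str],
    placenta_b: Iterable[str],
    organ_a: Iterable[str],
    organ_b: Iterable[str],
    orthologs: OrthologMap,
    name: str = "shared_coopted",
    organ: str = "mammary",
) -> ConvergenceScreenResult:
    """Genes in both placentas and the species-A organ, absent from the B organ.

    Set formula (species-A namespace): (placenta_A n placenta_B n organ_A)
    \\ organ_B. Species-B sets are mapped through the ortholog table;
    species-A genes without an ortholog cannot be evaluated against the B
    sets and are tallied as unmappable.
    """
    placenta_a = set(placenta_a)
    organ_a = set(organ_a)
    placenta_b_in_a = orthologs.to_a(placenta_b)
    organ_b_in_a = orthologs.to_a(organ_b)
    candidates = placenta_a & organ_a
    unmappable = len(orthologs.unmappable_a(candidates))
    genes = (candidates & placenta_b_in_a) - organ_b_in_a
    return ConvergenceScreenResult(
        name=name,
        genes=frozenset(genes),
        inputs={
            "shared_in": f"placenta_A, placenta_B, {organ}_A",
            "excluded_from": f"{organ}_B",
        },
        unmappable=unmappable,
    )


def eutherian_only_shared(
    placenta_b: Iterable[str],
    organ_a: Iterable[str],
    placenta_a: Iterable[str],
    organ_b: Iterable[str],
    orthologs: OrthologMap,
    name: str = "eutherian_only_shared",
    organ: str = "mammary",
) -> ConvergenceScreenResult:
    """Genes in the B placenta and A organ but absent from A placenta and B organ.

    Set formula (species-A namespace): (placenta_B n organ_A) \\
    (placenta_A u organ_B).
    """
    placenta_a = set(placenta_a)
    organ_a = set(organ_a)
    placenta_b_in_a = orthologs.to_a(placenta_b)
    organ_b_in_a = orthologs.to_a(organ_b)
    unmappable = len(orthologs.unmappable_a(organ_a))
    genes = (placenta_b_in_a & organ_a) - (placenta_a | organ_b_in_a)
    return ConvergenceScreenResult(
        name=name,
        genes=frozenset(genes),
        inputs={
            "shared_in": f"placenta_B, {organ}_A",
            "excluded_from": f"placenta_A, {organ}_B",
        },
        unmappable=unmappable,
    )


SCREEN_KINDS = {"shared_coopted", "eutherian_only_shared"}


def control_screens(
    kind: str,
    placenta_a: Iterable[str],
    placenta_b: Iterable[str],
    control_organ_pairs: Sequence[tuple],
    orthologs: OrthologMap,
) -> list:
    """Re-run a screen formula with control organs in the organ slots.

    ``control_organ_pairs`` is a sequence of ``(tissue, organ_a_set,
    organ_b_set)``. Returns ``[(tissue, count), ...]`` with counts from the
    identical set formula — the chance-level yardstick for the primary
    screen.
    """
    if kind not in SCREEN_KINDS:
        raise ScreenError(f"unknown screen kind {kind!r}")
    out = []
    for tissue, organ_a, organ_b in control_organ_pairs:
        if kind == "shared_coopted":
            res = shared_coopted(
                placenta_a, placenta_b, organ_a, organ_b, orthologs,
                name=f"shared_coopted[{tissue}]", organ=tissue,
            )
        else:
            res = eutherian_only_shared(
                placenta_b, organ_a, placenta_a, organ_b, orthologs,
                name=f"eutherian_only_shared[{tissue}]", organ=tissue,
            )
        out.append((tissue, len(res)))
    return out


def ora_fisher(
    query: GeneSet,
    annotations: Sequence[GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query gene list.

    For each annotation set: overlap k of the query (size n) with the
    annotation restricted to the universe (size K of N); p = P(X >= k) under
    Hypergeom(N, K, n); BH across annotations. The query must lie within
    the universe.
    """
    universe = set(universe)
    if not universe:
        raise ScreenError("empty universe")
    outside = set(query.genes) - universe
    if outside:
        raise ScreenError(f"query genes outside universe: {sorted(outside)[:5]}")
    n = len(query.genes)
    big_n = len(universe)
    rows = []
    for ann in annotations:
        restricted = ann.genes & universe
        k = len(query.genes & restricted)
        big_k = len(restricted)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        # odds ratio of the 2x2 (query x annotation) split of the universe
        other = big_n - big_k - n + k
        denom = (big_k - k) * (n - k)
        odds = (k * other / denom) if denom > 0 else np.inf
        rows.append(
            {
                "annotation": ann.name,
                "overlap": k,
                "set_size": big_k,
                "query_size": n,
                "universe_size": big_n,
                "odds_ratio": odds,
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "annotation", "overlap", "set_size", "query_size",
            "universe_size", "odds_ratio", "p_value",
        ],
    )
    if len(result):
        result["q_value"] = adjust_bh(result["p_value"].to_numpy())
    else:
        result["q_value"] = []
    return result
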