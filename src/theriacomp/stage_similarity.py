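"""Rank-based developmental stage mapping across species and platforms.

The query organ (tag-count data in one species) is compared against a
reference developmental series (microarray intensities in the other
species) by: (1) reducing to the orthologous genes expressed in *every*
dataset entering the comparison, (2) ranking each profile from highest to
lowest expression, and (3) computing pairwise Spearman correlations between
every query timepoint and every reference stage. Ranking first is the whole
point: any strictly monotone distortion of one platform's scale leaves the
correlation grid untouched, so tag counts and array intensities become
directly comparable.

A control organ (e.g. adult heart of the reference species) is carried as
extra columns. If the reference series beats the control for every query
row, the signal is organ-specific conservation rather than generic
species-level similarity.

The common gene universe is computed once for the whole grid — per-cell
universes would make the correlations incomparable across cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression_calling import ExpressionCallSet, ExpressionProfile
from .io_formats import OrthologMap


class StageMapError(ValueError):
    """Raised on empty universes or degenerate profiles."""


@dataclass(frozen=True)
class OrthologUniverse:
    """Aligned ortholog pairs expressed in every contributing dataset.

    ``genes_a[i]`` and ``genes_b[i]`` are the same gene in the two species'
    namespaces; order is deterministic (sorted by the A identifier).
    """

    genes_a: tuple
    genes_b: tuple

    def __post_init__(self) -> None:
        if len(self.genes_a) != len(self.genes_b):
            raise StageMapError("misaligned ortholog universe")

    def __len__(self) -> int:
        return len(self.genes_a)


@dataclass(frozen=True)
class RankedProfile:
    """Descending ranks (1 = highest expression, average ranks on ties)."""

    gene_ids: tuple
    ranks: np.ndarray
    label: str

    def __post_init__(self) -> None:
        ranks = np.asarray(self.ranks, dtype=float)
        object.__setattr__(self, "ranks", ranks)
        n = len(ranks)
        if n != len(self.gene_ids):
            raise StageMapError("one rank per gene required")
        # tie-averaged ranks always sum to n(n+1)/2
        if n and not np.isclose(ranks.sum(), n * (n + 1) / 2):
            raise StageMapError("ranks are not a tie-averaged permutation of 1..n")


@dataclass(frozen=True)
class StageCorrelationMatrix:
    """Spearman rho for every query x (reference + control) pair.

    ``rho`` is a complete DataFrame (query rows, reference-then-control
    columns); ``control_labels`` names the columns that belong to the
    control organ; ``n_genes`` is the size of the shared universe.
    """

    rho: pd.DataFrame
    control_labels: tuple
    n_genes: int

    def __post_init__(self) -> None:
        if self.rho.isna().any().any():
            raise StageMapError("correlation matrix has missing cells")
        if (self.rho.abs() > 1 + 1e-12).any().any():
            raise StageMapError("|rho| > 1")
        missing = [c for c in self.control_labels if c not in self.rho.columns]
        if missing:
            raise StageMapError(f"control columns absent from matrix: {missing}")

    @property
    def reference_labels(self) -> tuple:
        return tuple(c for c in self.rho.columns if c not in set(self.control_labels))

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        controls = set(self.control_labels)
        for query in self.rho.index:
            for col in self.rho.columns:
                rows.append(
                    {
                        "query": query,
                        "reference": col,
                        "rho": self.rho.at[query, col],
                        "is_control": col in controls,
                        "n_genes": self.n_genes,
                    }
                )
        return pd.DataFrame(rows)


def intersect_expressed(
    call_sets_a: Sequence[ExpressionCallSet],
    call_sets_b: Sequence[ExpressionCallSet],
    orthologs: OrthologMap,
) -> OrthologUniverse:
    """Orthologs expressed in every species-A and every species-B call set.

    Raises with per-dataset sizes if the intersection is empty.
    """
    if len(call_sets_a) + len(call_sets_b) < 2:
        raise StageMapError("need at least two call sets to intersect")
    expressed_a: set = None
    for cs in call_sets_a:
        expressed_a = set(cs.expressed) if expressed_a is None else expressed_a & cs.expressed
    expressed_b: set = None
    for cs in call_sets_b:
        expressed_b = set(cs.expressed) if expressed_b is None else expressed_b & cs.expressed
    pairs = [
        (a, b)
        for a, b in orthologs.a_to_b.items()
        if (expressed_a is None or a in expressed_a)
        and (expressed_b is None or b in expressed_b)
    ]
    if not pairs:
        sizes = {cs.label: len(cs.expressed) for cs in [*call_sets_a, *call_sets_b]}
        raise StageMapError(f"empty expressed-ortholog intersection; set sizes {sizes}")
    pairs.sort(key=lambda ab: ab[0])
    genes_a, genes_b = zip(*pairs)
    return OrthologUniverse(genes_a=tuple(genes_a), genes_b=tuple(genes_b))


def rank_profile(profile: ExpressionProfile, universe: Sequence[str]) -> RankedProfile:
    """Rank ``universe`` genes of a profile from highest (rank 1) to lowest.

    Ties receive the average of the ranks they span — with tag counts, tied
    zeros are guaranteed, so the tie convention matters.
    """
    index = {g: i for i, g in enumerate(profile.gene_ids)}
    missing = [g for g in universe if g not in index]
    if missing:
        raise StageMapError(f"universe genes absent from profile: {missing[:5]}")
    values = profile.values[[index[g] for g in universe]]
    ranks = rankdata(-values, method="average")
    return RankedProfile(gene_ids=tuple(universe), ranks=ranks, label=profile.label)


def spearman_rho(x: RankedProfile, y: RankedProfile) -> float:
    """Tie-safe Spearman: Pearson correlation of the two rank vectors.

    The classic 6*sum(d^2) shortcut is biased under ties, so it is not used
    here (except as an oracle in tests on tie-free data).
    """
    if x.gene_ids != y.gene_ids:
        raise StageMapError("profiles ranked on different universes")
    n = len(x.gene_ids)
    if n < 3:
        raise StageMapError("need at least 3 genes for a rank correlation")
    rx = x.ranks - x.ranks.mean()
    ry = y.ranks - y.ranks.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise StageMapError("degenerate profile: zero rank variance (all values tied)")
    return float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))


def similarity_matrix(
    query_profiles: Sequence[ExpressionProfile],
    reference_profiles: Sequence[ExpressionProfile],
    control_profiles: Sequence[ExpressionProfile],
    universe: OrthologUniverse,
) -> StageCorrelationMatrix:
    """Complete Spearman grid: query rows vs reference + control columns.

    Query profiles live in the species-A namespace; reference and control
    profiles in species-B. All are ranked once on the shared universe.
    """
    if not query_profiles or not reference_profiles:
        raise StageMapError("need at least one query and one reference profile")

    def rank_b(profile: ExpressionProfile) -> RankedProfile:
        # rank in the B namespace, then report positions under the aligned
        # A identifiers so ortholog pairs compare slot-for-slot
        ranked = rank_profile(profile, universe.genes_b)
        return RankedProfile(
            gene_ids=universe.genes_a, ranks=ranked.ranks, label=ranked.label
        )

    ranked_q = [rank_profile(p, universe.genes_a) for p in query_profiles]
    ranked_r = [rank_b(p) for p in reference_profiles]
    ranked_c = [rank_b(p) for p in control_profiles]
    columns = [*ranked_r, *ranked_c]
    col_labels = [p.label for p in columns]
    if len(set(col_labels)) != len(col_labels):
        raise StageMapError(f"duplicate column labels: {col_labels}")
    rho = pd.DataFrame(
        [[spearman_rho(q, c) for c in columns] for q in ranked_q],
        index=pd.Index([q.label for q in ranked_q], name="query"),
        columns=col_labels,
    )
    return StageCorrelationMatrix(
        rho=rho,
        control_labels=tuple(p.label for p in ranked_c),
        n_genes=len(universe),
    )


def best_matching_stage(matrix: StageCorrelationMatrix, query_label: str) -> tuple:
    """Reference (non-control) column with maximal rho for one query row.

    Ties break toward the earliest reference column (input order is assumed
    chronological); the tie is reported. Returns ``(label, tied)``.
    """
    if query_label not in matrix.rho.index:
        raise StageMapError(f"query {query_label!r} not in matrix")
    refs = list(matrix.reference_labels)
    row = matrix.rho.loc[query_label, refs]
    best = float(row.max())
    winners = [c for c in refs if row[c] == best]
    return winners[0], len(winners) > 1


def control_contrast(matrix: StageCorrelationMatrix) -> pd.DataFrame:
    """Does the reference series beat the control organ for every query?

    For each query row: margin = min(reference rho) - max(control rho);
    the contrast passes only on a strictly positive margin (an exact tie
    fails).
    """
    if not matrix.control_labels:
        raise StageMapError("no control columns in matrix")
    refs = list(matrix.reference_labels)
    controls = list(matrix.control_labels)
    min_ref = matrix.rho[refs].min(axis=1)
    max_ctrl = matrix.rho[controls].max(axis=1)
    margin = min_ref - max_ctrl
    return pd.DataFrame(
        {
            "min_reference_rho": min_ref,
            "max_control_rho": max_ctrl,
            "margin": margin,
            "reference_exceeds_control": margin > 0,
        }
    )
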