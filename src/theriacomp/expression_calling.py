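"""Presence/absence expression calling with the 1%-of-mean rule.

A dataset (one species/organ/timepoint, possibly several replicates) is
reduced to a per-gene mean profile; a gene is called *expressed* when its
mean is at least ``fraction`` (default 1%) of the grand mean over all genes
of that profile, and *not expressed* otherwise. The threshold scales with
the profile mean, so the partition is invariant to global rescaling — which
is what makes the rule usable across libraries of very different depths.

Conventions (fixed here because the rule alone does not pin them down):

* "the mean" is the grand mean of the per-gene replicate averages, computed
  per dataset, not globally across datasets;
* a value exactly equal to the threshold counts as expressed (only values
  strictly below are excluded);
* an all-zero profile calls every gene not expressed — a 0 >= 0 comparison
  would declare everything expressed on zero evidence;
* cell fractions (e.g. basal + luminal mammary) are combined by the per-gene
  mean, keeping the combined profile on the scale of a single fraction.
  Because calling is scale-invariant, mean versus sum changes nothing
  downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, GeneSet


class CallingError(ValueError):
    """Raised on invalid selections or mismatched profiles."""


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene mean expression of one dataset."""

    gene_ids: tuple
    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.gene_ids):
            raise CallingError("profile needs exactly one value per gene")
        if (values < 0).any() or np.isnan(values).any():
            raise CallingError("profile values must be non-negative and finite")

    def value_of(self, gene: str) -> float:
        return float(self.values[self.gene_ids.index(gene)])


@dataclass(frozen=True)
class ExpressionCallSet:
    """Expressed / not-expressed partition of one dataset's gene universe."""

    label: str
    expressed: frozenset
    not_expressed: frozenset
    threshold: float
    fraction: float

    def __post_init__(self) -> None:
        if self.expressed & self.not_expressed:
            raise CallingError("expressed and not_expressed overlap")

    @property
    def universe(self) -> frozenset:
        return self.expressed | self.not_expressed


def average_replicates(matrix: CountMatrix, metadata: pd.DataFrame, selector) -> ExpressionProfile:
    """Average the samples picked by ``selector`` into one profile.

    Parameters
    ----------
    selector : mapping or sequence
        Either a mapping of metadata column -> required value (rows matching
        all entries are selected), or an explicit sequence of sample ids.
    """
    if isinstance(selector, Mapping):
        mask = pd.Series(True, index=metadata.index)
        for column, value in selector.items():
            if column not in metadata.columns:
                raise CallingError(f"selector column {column!r} not in metadata")
            mask &= metadata[column].astype("object") == value
        sample_ids = [
            s for s in metadata.loc[mask, "sample_id"] if s in matrix.sample_ids
        ]
        label = ",".join(f"{k}={v}" for k, v in selector.items())
    else:
        sample_ids = list(selector)
        label = ",".join(sample_ids)
    if not sample_ids:
        raise CallingError(f"selector {label!r} selects no samples")
    sub = matrix.select_samples(sample_ids)
    return ExpressionProfile(
        gene_ids=matrix.gene_ids,
        values=sub.values.mean(axis=1),
        label=label,
    )


def combine_cell_fractions(profiles: Sequence[ExpressionProfile]) -> ExpressionProfile:
    """Per-gene mean of profiles measured on the same gene universe.

    Used to merge cell-fraction datasets (basal and luminal mammary cells)
    into a single whole-organ representation. Profiles whose genes agree as
    a set but differ in order are aligned to the first profile's order.
    """
    profiles = list(profiles)
    if not profiles:
        raise CallingError("no profiles to combine")
    first = profiles[0]
    stacked = [first.values]
    for prof in profiles[1:]:
        if prof.gene_ids == first.gene_ids:
            stacked.append(prof.values)
        elif set(prof.gene_ids) == set(first.gene_ids):
            order = {g: i for i, g in enumerate(prof.gene_ids)}
            stacked.append(prof.values[[order[g] for g in first.gene_ids]])
        else:
            raise CallingError(
                f"profile {prof.label!r} has a different gene universe than {first.label!r}"
            )
    return ExpressionProfile(
        gene_ids=first.gene_ids,
        values=np.mean(stacked, axis=0),
        label=" + ".join(p.label for p in profiles),
    )


def call_expressed(profile: ExpressionProfile, fraction: float = 0.01) -> ExpressionCallSet:
    """Partition genes into expressed / not expressed at ``fraction`` of the grand mean.

    threshold = fraction * mean_g(profile.values); genes with value >=
    threshold are expressed. An all-zero profile yields an empty expressed
    set with a warning.
    """
    if not 0 < fraction < 1:
        raise CallingError(f"fraction must be in (0, 1), got {fraction}")
    if len(profile.gene_ids) == 0:
        raise CallingError("empty profile")
    grand_mean = float(profile.values.mean())
    threshold = fraction * grand_mean
    if grand_mean == 0.0:
        warnings.warn(
            f"profile {profile.label!r} is all zero; calling every gene not expressed",
            stacklevel=2,
        )
        return ExpressionCallSet(
            label=profile.label,
            expressed=frozenset(),
            not_expressed=frozenset(profile.gene_ids),
            threshold=0.0,
            fraction=fraction,
        )
    mask = profile.values >= threshold
    genes = np.asarray(profile.gene_ids, dtype=object)
    return ExpressionCallSet(
        label=profile.label,
        expressed=frozenset(genes[mask]),
        not_expressed=frozenset(genes[~mask]),
        threshold=threshold,
        fraction=fraction,
    )


def calls_to_frame(calls: ExpressionCallSet) -> pd.DataFrame:
    """Two-column export: gene, expressed in {0, 1}; sorted by gene id."""
    genes = sorted(calls.universe)
    return pd.DataFrame(
        {"gene": genes, "expressed": [int(g in calls.expressed) for g in genes]}
    )


def calls_to_gene_set(calls: ExpressionCallSet) -> GeneSet:
    return GeneSet(
        name=calls.label,
        genes=frozenset(calls.expressed),
        description=f"expressed at >= {calls.fraction:g} of grand mean",
    )
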