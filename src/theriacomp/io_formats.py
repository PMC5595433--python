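"""Readers and writers for the tabular formats used throughout the pipeline.

All external representations are plain text: count matrices and sample
metadata are tab-separated tables, gene sets use the GMT dialect, and
ortholog maps are two-column TSV. Parsing is strict — a malformed value is a
hard error, never silently imputed, because every downstream statistic here
is presence- or rank-based and a quietly repaired cell would corrupt ranks.

Gene identifiers are opaque, case-sensitive strings. No symbol/accession
conversion is attempted; the ortholog map input carries that burden.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised measurement platforms for a count matrix. ``tag_count`` marks
#: 3'-tag sequencing style integer counts (one read per transcript, no
#: length normalisation); ``microarray`` marks continuous intensity values.
PLATFORMS = ("tag_count", "microarray")

REQUIRED_METADATA_COLUMNS = ("sample_id", "species", "organ", "replicate")
OPTIONAL_METADATA_COLUMNS = ("tissue_compartment", "timepoint")


class FormatError(ValueError):
    """An input file violates its format contract."""


@dataclass(frozen=True)
class CountMatrix:
    """A genes-by-samples matrix of non-negative expression values.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers, order preserved.
    sample_ids : sequence of str
        Unique column identifiers, order preserved.
    values : ndarray, shape (n_genes, n_samples)
        Non-negative expression values (counts or intensities).
    platform : {"tag_count", "microarray"}
    """

    gene_ids: tuple
    sample_ids: tuple
    values: np.ndarray
    platform: str = "tag_count"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.platform not in PLATFORMS:
            raise FormatError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        if values.ndim != 2 or values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise FormatError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id {dup!r}")
        if np.isnan(values).any():
            raise FormatError("missing expression value (NaN) — ragged or empty cell")
        if (values < 0).any():
            raise FormatError("negative expression value")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def frame(self) -> pd.DataFrame:
        """Return a genes-by-samples DataFrame view of the matrix."""
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, platform: str = "tag_count") -> "CountMatrix":
        return cls(
            gene_ids=tuple(frame.index.astype(str)),
            sample_ids=tuple(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
            platform=platform,
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        """Column subset, preserving the requested order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"sample ids not in matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(
            gene_ids=self.gene_ids,
            sample_ids=tuple(sample_ids),
            values=self.values[:, idx],
            platform=self.platform,
        )


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


@dataclass(frozen=True)
class OrthologMap:
    """A strictly one-to-one gene correspondence between two species.

    Each gene, on either side, appears in at most one pair. Genes absent
    from the map are simply unmappable — absence of orthology information is
    never treated as evidence about expression.
    """

    a_to_b: Mapping[str, str]
    b_to_a: Mapping[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        a_to_b = dict(self.a_to_b)
        object.__setattr__(self, "a_to_b", a_to_b)
        b_to_a = {b: a for a, b in a_to_b.items()}
        if len(b_to_a) != len(a_to_b):
            dup = _first_duplicate(list(a_to_b.values()))
            raise FormatError(f"non-unique mapping for {dup!r}")
        object.__setattr__(self, "b_to_a", b_to_a)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "OrthologMap":
        a_to_b: dict = {}
        seen_b: set = set()
        for a, b in pairs:
            a, b = str(a), str(b)
            if a in a_to_b:
                raise FormatError(f"non-unique mapping for {a!r}")
            if b in seen_b:
                raise FormatError(f"non-unique mapping for {b!r}")
            a_to_b[a] = b
            seen_b.add(b)
        return cls(a_to_b=a_to_b)

    def __len__(self) -> int:
        return len(self.a_to_b)

    def to_b(self, genes_a: Iterable[str]) -> set:
        """Map species-A genes to their B orthologs, dropping unmappables."""
        return {self.a_to_b[g] for g in genes_a if g in self.a_to_b}

    def to_a(self, genes_b: Iterable[str]) -> set:
        """Map species-B genes to their A orthologs, dropping unmappables."""
        return {self.b_to_a[g] for g in genes_b if g in self.b_to_a}

    def unmappable_a(self, genes_a: Iterable[str]) -> set:
        return {g for g in genes_a if g not in self.a_to_b}

    def unmappable_b(self, genes_b: Iterable[str]) -> set:
        return {g for g in genes_b if g not in self.b_to_a}


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (GMT line)."""

    name: str
    genes: frozenset
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_count_matrix(path, platform: str = "tag_count") -> CountMatrix:
    """Read a genes-by-samples TSV (first column gene id, header sample ids).

    Raises :class:`FormatError` on duplicate gene ids, negative values,
    missing cells (including ragged rows) or an empty table.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep="\t", index_col=0, header=0, dtype={0: str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"no genes parsed from {path}") from None
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise FormatError(f"no genes parsed from {path}")
    try:
        values = frame.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric expression value in {path}: {exc}") from None
    matrix = CountMatrix(
        gene_ids=tuple(frame.index.astype(str)),
        sample_ids=tuple(frame.columns.astype(str)),
        values=values,
        platform=platform,
    )
    logger.info(
        "read count matrix %s: %d genes x %d samples (%s)",
        path, matrix.n_genes, matrix.n_samples, platform,
    )
    return matrix


def _shortest_float(x: float) -> str:
    """Shortest decimal that round-trips to the same double."""
    return repr(float(x))


def write_count_matrix(matrix: CountMatrix, path) -> None:
    frame = matrix.frame()
    if np.all(np.mod(matrix.values, 1.0) == 0):
        frame = frame.astype(np.int64)  # tag counts stay integers on disk
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format=_shortest_float)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the sample-metadata TSV and validate required columns.

    Required columns: sample_id, species, organ, replicate (integer >= 1).
    Optional: tissue_compartment, timepoint. Returns a DataFrame indexed by
    row order with sample_id kept as a column.
    """
    path = Path(path)
    try:
        meta = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"no metadata rows parsed from {path}") from None
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata {path} missing required columns {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r} in metadata")
    try:
        meta["replicate"] = meta["replicate"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer replicate in metadata: {exc}") from None
    if (meta["replicate"] < 1).any():
        raise FormatError("replicate numbers must be >= 1")
    for col in OPTIONAL_METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = pd.NA
    return meta


def check_metadata_covers(matrix: CountMatrix, metadata: pd.DataFrame) -> None:
    """Every sample in the matrix must have exactly one metadata row."""
    counts = metadata["sample_id"].value_counts()
    problems = [s for s in matrix.sample_ids if counts.get(s, 0) != 1]
    if problems:
        raise FormatError(
            f"samples without exactly one metadata row: {problems[:10]}"
        )


def read_ortholog_map(path) -> OrthologMap:
    """Read a two-column TSV of (species_A_gene, species_B_gene) pairs."""
    path = Path(path)
    pairs = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            pairs.append((fields[0], fields[1]))
    if not pairs:
        warnings.warn(f"ortholog map {path} is empty", stacklevel=2)
    return OrthologMap.from_pairs(pairs)


def write_ortholog_map(orthologs: OrthologMap, path) -> None:
    with open(path, "w") as handle:
        for a in sorted(orthologs.a_to_b):
            handle.write(f"{a}\t{orthologs.a_to_b[a]}\n")


def read_gene_sets(path) -> list:
    """Read a GMT file: name <tab> description <tab> gene [<tab> gene ...].

    Duplicate genes within a line are collapsed with a warning; a line with
    fewer than three fields is a hard error.
    """
    path = Path(path)
    sets = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, description, genes = fields[0], fields[1], fields[2:]
            if len(set(genes)) != len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in set {name!r} collapsed",
                    stacklevel=2,
                )
            sets.append(GeneSet(name=name, genes=frozenset(genes), description=description))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as handle:
        for gs in sets:
            genes = "\t".join(sorted(gs.genes))
            handle.write(f"{gs.name}\t{gs.description}\t{genes}\n")


def write_result_table(rows, path, columns: Sequence[str] = None) -> None:
    """Write tabular records as TSV with a deterministic column order.

    ``rows`` may be a DataFrame or a list of dicts sharing a schema. Floats
    are written with full ``repr`` precision so a read-back reproduces them
    exactly; byte-identical output for identical input.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        if rows:
            if columns is None:
                columns = list(rows[0].keys())
            frame = pd.DataFrame(rows, columns=list(columns))
        else:
            frame = pd.DataFrame(columns=list(columns or []))
    if columns is not None:
        frame = frame[list(columns)]
    frame.to_csv(path, sep="\t", index=False, float_format=_shortest_float)


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
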