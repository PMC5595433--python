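"""Synthetic two-species, multi-organ expression data with planted truth.

The generator emulates the statistical structure of a cross-species
placenta/mammary comparison so that every downstream stage is testable
without any external download:

* two species — a marsupial-like query species A (3'-tag counts: placenta
  with avascular/vascular compartments at three gestational days, mammary
  gland at three lactation days, liver, testis) and a eutherian-like
  reference species B (term placenta, basal+luminal mammary, liver, testis,
  heart, plus a multi-stage placenta developmental series on a
  microarray-like intensity scale);
* a one-to-one ortholog map covering the shared gene universe;
* planted organ-specific programs, early/late placenta-specific stage
  programs, convergently co-opted gene sets, and per-gene fold-change truth
  for the compartment and stage contrasts;
* negative-binomial count noise with gene-wise dispersion, parameterised as
  variance = mu + alpha * mu^2 to match the DE module's model.

Expression model. Per gene g the log relative expression in dataset
(species s, organ o) is

    lambda = b_g + org_(g,o) + sp_(g,s,o) [+ w_g(stage)] [+ DE effects]

with a gene baseline b, an organ modulation shared between species (this is
what makes the same organ look alike across species), a smaller
species-by-organ term, and — for placental datasets — a per-gene random
walk w across the reference developmental stages, so adjacent stages stay
more rank-correlated than distant ones. Query placenta timepoints reuse the
walk value at the planted stage, which is what stage mapping must recover.
Silenced genes keep NB mean at ``silenced_ratio`` (default 0.1%) of their
active mean rather than structural zero, so the 1%-of-mean caller's
boundary behaviour stays exercised.

Counts: NB(mean = library_size x relative expression, gene dispersion).
The reference series is reported as intensities = scale * (log2(mean + 1) +
Gaussian noise) — an affine-log, strictly monotone distortion that forces
the rank-based pipeline to prove platform invariance.

Everything is deterministic given ``(config, seed)``; each sample column
draws from its own child RNG keyed by dataset labels and replicate index.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    CountMatrix,
    GeneSet,
    OrthologMap,
    write_count_matrix,
    write_gene_sets,
    write_ortholog_map,
    write_result_table,
)

ORGANS = ("placenta", "mammary", "liver", "testis", "heart")

#: Reference-species developmental placenta series (chronological order).
REFERENCE_STAGES = ("e8.0", "e9.5", "e10.5", "e12.5", "e15.0", "e17.0", "term")

#: Index of the early/late boundary: early-program genes are active at
#: stages strictly before this index, late-program genes from it onward.
STAGE_SWITCH_INDEX = REFERENCE_STAGES.index("e12.5")

QUERY_TIMEPOINTS = ("d21", "d23", "d25")
MAMMARY_TIMEPOINTS = ("d36", "d60", "d95")

#: Query placenta sample design: 4 avascular (BOM) + 6 vascular (TOM)
#: columns, giving 4-vs-6 for the compartment contrast and 4-vs-6
#: (d21+d23 vs d25) for the stage contrast.
PLACENTA_DESIGN = (
    ("d21", "BOM"), ("d21", "TOM"),
    ("d23", "BOM"), ("d23", "TOM"),
    ("d25", "BOM"), ("d25", "BOM"),
    ("d25", "TOM"), ("d25", "TOM"), ("d25", "TOM"), ("d25", "TOM"),
)


class SimulationError(ValueError):
    """Raised on infeasible configurations."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic datasets.

    Planted set sizes default to the scale of the real screens (organ
    programs of 300; early/late placenta programs of 340/70; 77 co-opted
    and 108 reference-only-shared genes); fold-change truth defaults to
    4-fold. Effect-size defaults (baseline spread, organ and species
    effects, stage decorrelation) are chosen so that organ identity
    dominates species identity and adjacent developmental stages remain
    distinguishable — the qualitative regime the analyses assume.
    """

    n_genes: int = 5000
    n_replicates: int = 3
    library_size: float = 4.0e5
    library_size_spread: float = 0.2
    dispersion_range: tuple = (0.05, 0.5)
    organ_program_size: int = 300
    early_program_size: int = 340
    late_program_size: int = 70
    coopted_size: int = 77
    eutherian_only_size: int = 108
    n_de_genes: int = 200
    de_log2_fold_change: float = 2.0
    early_in_query_fraction: float = 90.0 / 340.0
    late_in_query_fraction: float = 10.0 / 70.0
    stage_decorrelation_rate: float = 0.3
    planted_stage: str = "e10.5"
    baseline_sd: float = 0.5
    organ_effect_sd: float = 0.45
    species_effect_sd: float = 0.2
    silenced_ratio: float = 1.0e-3
    microarray_scale: float = 20.0
    microarray_noise_sd: float = 0.1
    species_a: str = "marsupial"
    species_b: str = "eutherian"
    seed: int = 0

    def planted_total(self) -> int:
        return (
            len(ORGANS) * self.organ_program_size
            + self.early_program_size
            + self.late_program_size
            + self.coopted_size
            + self.eutherian_only_size
            + 2 * self.n_de_genes
        )

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise SimulationError("n_genes must be positive")
        if self.planted_total() >= self.n_genes:
            raise SimulationError(
                f"planted sets ({self.planted_total()}) must leave room in "
                f"{self.n_genes} genes"
            )
        lo, hi = self.dispersion_range
        if not (0 < lo <= hi):
            raise SimulationError("dispersion_range must be positive and ordered")
        for name in (
            "library_size", "library_size_spread", "stage_decorrelation_rate",
            "baseline_sd", "organ_effect_sd", "species_effect_sd",
            "microarray_scale",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        if self.library_size <= 0:
            raise SimulationError("library_size must be positive")
        if not 0 < self.silenced_ratio < 1:
            raise SimulationError("silenced_ratio must be in (0, 1)")
        for name in ("early_in_query_fraction", "late_in_query_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.planted_stage not in REFERENCE_STAGES:
            raise SimulationError(
                f"planted_stage {self.planted_stage!r} not in {REFERENCE_STAGES}"
            )
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth plus the latent parameters that generated it."""

    config: SimulationConfig
    ortholog_map: OrthologMap
    organ_programs: dict
    stage_programs: dict
    coopted_set: GeneSet
    eutherian_only_set: GeneSet
    de_truth: pd.DataFrame
    seed: int
    # latent model state (consumed by the simulators)
    gene_ids_a: tuple = field(repr=False, default=())
    gene_ids_b: tuple = field(repr=False, default=())
    baseline: np.ndarray = field(repr=False, default=None)
    organ_effects: dict = field(repr=False, default_factory=dict)
    species_effects: dict = field(repr=False, default_factory=dict)
    stage_walk: np.ndarray = field(repr=False, default=None)
    dispersions: np.ndarray = field(repr=False, default=None)
    active: dict = field(repr=False, default_factory=dict)
    series_active: np.ndarray = field(repr=False, default=None)
    compartment_sign: np.ndarray = field(repr=False, default=None)
    stage_sign: np.ndarray = field(repr=False, default=None)
    early_in_query: tuple = field(repr=False, default=())
    late_in_query: tuple = field(repr=False, default=())


def _crc(token) -> int:
    return zlib.crc32(str(token).encode())


def _child_rng(seed: int, *tags) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *(_crc(t) for t in tags)])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) with variance mu + alpha*mu^2, elementwise."""
    size = 1.0 / np.maximum(alpha, 1e-12)
    p = size / (size + mu)
    return rng.negative_binomial(size, np.clip(p, 1e-12, 1.0))


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw the latent model state and planted gene sets for one seed."""
    config.validate()
    n = config.n_genes
    rng = _child_rng(config.seed, "truth")

    gene_ids_a = tuple(f"msp{i:05d}" for i in range(n))
    gene_ids_b = tuple(f"eut{i:05d}" for i in range(n))
    orthologs = OrthologMap.from_pairs(zip(gene_ids_a, gene_ids_b))

    perm = rng.permutation(n)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = perm[cursor:cursor + k]
        cursor += k
        return np.sort(out)

    organ_idx = {organ: take(config.organ_program_size) for organ in ORGANS}
    early_idx = take(config.early_program_size)
    late_idx = take(config.late_program_size)
    coopted_idx = take(config.coopted_size)
    eutherian_only_idx = take(config.eutherian_only_size)
    de_comp_idx = take(config.n_de_genes)
    de_stage_idx = take(config.n_de_genes)

    baseline = rng.normal(0.0, config.baseline_sd, n)
    organ_effects = {o: rng.normal(0.0, config.organ_effect_sd, n) for o in ORGANS}
    species_effects = {
        (sp, o): rng.normal(0.0, config.species_effect_sd, n)
        for sp in (config.species_a, config.species_b)
        for o in ORGANS
    }
    steps = rng.normal(0.0, config.stage_decorrelation_rate, (n, len(REFERENCE_STAGES) - 1))
    stage_walk = np.concatenate([np.zeros((n, 1)), np.cumsum(steps, axis=1)], axis=1)
    lo, hi = config.dispersion_range
    dispersions = rng.uniform(lo, hi, n)

    n_early_q = int(round(config.early_in_query_fraction * len(early_idx)))
    n_late_q = int(round(config.late_in_query_fraction * len(late_idx)))
    early_in_query = np.sort(rng.choice(early_idx, size=n_early_q, replace=False))
    late_in_query = np.sort(rng.choice(late_idx, size=n_late_q, replace=False))

    compartment_sign = np.zeros(n)
    compartment_sign[de_comp_idx] = rng.choice([-1.0, 1.0], size=len(de_comp_idx))
    stage_sign = np.zeros(n)
    stage_sign[de_stage_idx] = rng.choice([-1.0, 1.0], size=len(de_stage_idx))

    # presence/absence per dataset ------------------------------------------
    a, b = config.species_a, config.species_b
    datasets = [(a, o) for o in ("placenta", "mammary", "liver", "testis")] + [
        (b, o) for o in ORGANS
    ]
    planted = np.zeros(n, dtype=bool)
    for idx in (*organ_idx.values(), early_idx, late_idx, coopted_idx,
                eutherian_only_idx):
        planted[idx] = True
    # housekeeping and DE-truth genes are expressed in every dataset
    active = {ds: ~planted for ds in datasets}
    active = {ds: mask.copy() for ds, mask in active.items()}
    for organ, idx in organ_idx.items():
        for sp in (a, b):
            if (sp, organ) in active:
                active[(sp, organ)][idx] = True
    # stage-dependent activity across the reference placenta series
    series_active = np.repeat(active[(b, "placenta")][:, None], len(REFERENCE_STAGES), axis=1)
    early_stages = np.arange(len(REFERENCE_STAGES)) < STAGE_SWITCH_INDEX
    series_active[np.ix_(early_idx, ~early_stages)] = False
    series_active[np.ix_(early_idx, early_stages)] = True
    series_active[np.ix_(late_idx, early_stages)] = False
    series_active[np.ix_(late_idx, ~early_stages)] = True
    series_active[coopted_idx, :] = True
    series_active[eutherian_only_idx, :] = True
    # bulk reference placenta is a term sample
    active[(b, "placenta")] = series_active[:, -1].copy()
    # planted co-option pattern
    active[(a, "placenta")][coopted_idx] = True
    active[(a, "mammary")][coopted_idx] = True
    active[(b, "mammary")][coopted_idx] = False
    active[(a, "mammary")][eutherian_only_idx] = True
    active[(a, "placenta")][eutherian_only_idx] = False
    active[(b, "mammary")][eutherian_only_idx] = False
    # query placenta expresses planted subsets of the early/late programs
    active[(a, "placenta")][early_in_query] = True
    active[(a, "placenta")][late_in_query] = True

    lfc = config.de_log2_fold_change
    de_truth = pd.DataFrame(
        {
            "lfc_compartment": compartment_sign * lfc,
            "lfc_stage": stage_sign * lfc,
        },
        index=pd.Index(gene_ids_a, name="gene"),
    )

    def a_set(name, idx, description=""):
        return GeneSet(
            name=name,
            genes=frozenset(gene_ids_a[i] for i in idx),
            description=description,
        )

    def b_set(name, idx, description=""):
        return GeneSet(
            name=name,
            genes=frozenset(gene_ids_b[i] for i in idx),
            description=description,
        )

    return SyntheticTruth(
        config=config,
        ortholog_map=orthologs,
        organ_programs={
            o: a_set(f"organ:{o}", idx, f"{o}-specific program") for o, idx in organ_idx.items()
        },
        stage_programs={
            "early": b_set("early", early_idx, "placenta-specific, pre-boundary"),
            "late": b_set("late", late_idx, "placenta-specific, post-boundary"),
        },
        coopted_set=a_set(
            "planted_coopted", coopted_idx,
            "expressed in A placenta, B placenta, A mammary; silenced in B mammary",
        ),
        eutherian_only_set=a_set(
            "planted_eutherian_only", eutherian_only_idx,
            "expressed in B placenta, A mammary; silenced in A placenta, B mammary",
        ),
        de_truth=de_truth,
        seed=config.seed,
        gene_ids_a=gene_ids_a,
        gene_ids_b=gene_ids_b,
        baseline=baseline,
        organ_effects=organ_effects,
        species_effects=species_effects,
        stage_walk=stage_walk,
        dispersions=dispersions,
        active=active,
        series_active=series_active,
        compartment_sign=compartment_sign,
        stage_sign=stage_sign,
        early_in_query=tuple(int(i) for i in early_in_query),
        late_in_query=tuple(int(i) for i in late_in_query),
    )


def _log_mean(
    truth: SyntheticTruth,
    species: str,
    organ: str,
    stage_index: Optional[int] = None,
    compartment: Optional[str] = None,
    timepoint: Optional[str] = None,
) -> np.ndarray:
    """Latent log relative expression for one dataset's samples."""
    cfg = truth.config
    lam = (
        truth.baseline
        + truth.organ_effects[organ]
        + truth.species_effects[(species, organ)]
    )
    if organ == "placenta":
        if species == cfg.species_b:
            s = len(REFERENCE_STAGES) - 1 if stage_index is None else stage_index
            active = truth.series_active[:, s]
        else:
            s = REFERENCE_STAGES.index(cfg.planted_stage)
            active = truth.active[(species, organ)]
        lam = lam + truth.stage_walk[:, s]
    else:
        active = truth.active[(species, organ)]
    lam = lam + np.log(cfg.silenced_ratio) * (~active)
    if species == cfg.species_a and organ == "placenta":
        half = 0.5 * cfg.de_log2_fold_change * np.log(2.0)
        if compartment is not None:
            lam = lam + truth.compartment_sign * (half if compartment == "BOM" else -half)
        if timepoint is not None:
            early = timepoint in ("d21", "d23")
            lam = lam + truth.stage_sign * (half if early else -half)
    return lam


def _count_column(
    truth: SyntheticTruth,
    rng: np.random.Generator,
    lam: np.ndarray,
) -> np.ndarray:
    cfg = truth.config
    rel = np.exp(lam - lam.max())
    p = rel / rel.sum()
    library = cfg.library_size * rng.lognormal(0.0, cfg.library_size_spread)
    return _nb_draw(rng, library * p, truth.dispersions)


def simulate_count_dataset(
    truth: SyntheticTruth,
    species: str,
    organ: str,
    timepoint: Optional[str] = None,
    compartment: Optional[str] = None,
    n_replicates: Optional[int] = None,
    stage_index: Optional[int] = None,
) -> tuple:
    """One homogeneous block of tag-count replicates for a dataset.

    Returns ``(CountMatrix, metadata)``. Each replicate column is drawn
    from a child RNG keyed by (seed, species, organ, timepoint,
    compartment, replicate), so regenerating any column is reproducible and
    distinct replicate indices differ.
    """
    cfg = truth.config
    if (species, organ) not in truth.active and not (
        species == cfg.species_b and organ == "placenta"
    ):
        raise SimulationError(f"unknown dataset ({species}, {organ})")
    n_replicates = cfg.n_replicates if n_replicates is None else n_replicates
    lam = _log_mean(truth, species, organ, stage_index, compartment, timepoint)
    columns, ids, meta_rows = [], [], []
    for rep in range(1, n_replicates + 1):
        rng = _child_rng(cfg.seed, "counts", species, organ, timepoint, compartment, rep)
        columns.append(_count_column(truth, rng, lam))
        parts = [species, organ] + [p for p in (timepoint, compartment) if p]
        ids.append("_".join(parts) + f"_r{rep}")
        meta_rows.append(
            {
                "sample_id": ids[-1],
                "species": species,
                "organ": organ,
                "tissue_compartment": compartment or "",
                "timepoint": timepoint or "",
                "replicate": rep,
            }
        )
    gene_ids = truth.gene_ids_a if species == cfg.species_a else truth.gene_ids_b
    matrix = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=tuple(ids),
        values=np.column_stack(columns).astype(float),
        platform="tag_count",
    )
    return matrix, pd.DataFrame(meta_rows)


def _concat_datasets(parts: Sequence[tuple]) -> tuple:
    matrices, metas = zip(*parts)
    first = matrices[0]
    values = np.column_stack([m.values for m in matrices])
    sample_ids = tuple(s for m in matrices for s in m.sample_ids)
    matrix = CountMatrix(
        gene_ids=first.gene_ids,
        sample_ids=sample_ids,
        values=values,
        platform=first.platform,
    )
    return matrix, pd.concat(metas, ignore_index=True)


def simulate_query_placenta(truth: SyntheticTruth) -> tuple:
    """The 10-sample query placenta design (4 BOM + 6 TOM over 3 days)."""
    cfg = truth.config
    parts = []
    rep_counter: dict = {}
    for timepoint, compartment in PLACENTA_DESIGN:
        key = (timepoint, compartment)
        rep_counter[key] = rep_counter.get(key, 0) + 1
        lam = _log_mean(truth, cfg.species_a, "placenta", None, compartment, timepoint)
        rep = rep_counter[key]
        rng = _child_rng(
            cfg.seed, "counts", cfg.species_a, "placenta", timepoint, compartment, rep
        )
        column = _count_column(truth, rng, lam)
        sample_id = f"{cfg.species_a}_placenta_{timepoint}_{compartment}_r{rep}"
        matrix = CountMatrix(
            gene_ids=truth.gene_ids_a,
            sample_ids=(sample_id,),
            values=column[:, None].astype(float),
            platform="tag_count",
        )
        meta = pd.DataFrame(
            [
                {
                    "sample_id": sample_id,
                    "species": cfg.species_a,
                    "organ": "placenta",
                    "tissue_compartment": compartment,
                    "timepoint": timepoint,
                    "replicate": rep,
                }
            ]
        )
        parts.append((matrix, meta))
    return _concat_datasets(parts)


def simulate_query_mammary(truth: SyntheticTruth) -> tuple:
    """Query mammary gland: one sample per lactation day."""
    cfg = truth.config
    return _concat_datasets(
        [
            simulate_count_dataset(truth, cfg.species_a, "mammary", timepoint=tp, n_replicates=1)
            for tp in MAMMARY_TIMEPOINTS
        ]
    )


def simulate_reference_mammary(truth: SyntheticTruth) -> tuple:
    """Reference mammary gland as separate basal and luminal cell fractions."""
    cfg = truth.config
    return _concat_datasets(
        [
            simulate_count_dataset(truth, cfg.species_b, "mammary", compartment=frac)
            for frac in ("basal", "luminal")
        ]
    )


def simulate_reference_series(truth: SyntheticTruth) -> tuple:
    """Microarray-like intensity series across the reference placenta stages.

    Intensities are ``scale * (log2(NB-mean + 1) + N(0, noise_sd))``,
    clipped at zero: a strictly monotone (affine-log) distortion of the
    underlying means, deliberately not on the count scale.
    """
    cfg = truth.config
    columns, ids, meta_rows = [], [], []
    for s, stage in enumerate(REFERENCE_STAGES):
        lam = _log_mean(truth, cfg.species_b, "placenta", stage_index=s)
        rel = np.exp(lam - lam.max())
        mu = cfg.library_size * rel / rel.sum()
        for rep in range(1, cfg.n_replicates + 1):
            rng = _child_rng(cfg.seed, "array", stage, rep)
            noise = rng.normal(0.0, cfg.microarray_noise_sd, cfg.n_genes)
            intensity = cfg.microarray_scale * (np.log2(mu + 1.0) + noise)
            columns.append(np.maximum(intensity, 0.0))
            sample_id = f"{cfg.species_b}_placenta_series_{stage}_r{rep}"
            ids.append(sample_id)
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "species": cfg.species_b,
                    "organ": "placenta",
                    "tissue_compartment": "",
                    "timepoint": stage,
                    "replicate": rep,
                }
            )
    matrix = CountMatrix(
        gene_ids=truth.gene_ids_b,
        sample_ids=tuple(ids),
        values=np.column_stack(columns),
        platform="microarray",
    )
    return matrix, pd.DataFrame(meta_rows)


def simulate_all_datasets(truth: SyntheticTruth) -> dict:
    """Every dataset of the full study design, keyed by role."""
    cfg = truth.config
    b = cfg.species_b
    return {
        "query_placenta": simulate_query_placenta(truth),
        "query_mammary": simulate_query_mammary(truth),
        "query_liver": simulate_count_dataset(truth, cfg.species_a, "liver"),
        "query_testis": simulate_count_dataset(truth, cfg.species_a, "testis"),
        "reference_placenta": simulate_count_dataset(truth, b, "placenta"),
        "reference_placenta_series": simulate_reference_series(truth),
        "reference_mammary": simulate_reference_mammary(truth),
        "reference_liver": simulate_count_dataset(truth, b, "liver"),
        "reference_testis": simulate_count_dataset(truth, b, "testis"),
        "stage_control": simulate_count_dataset(truth, b, "heart"),
    }


def export_fixture(truth: SyntheticTruth, directory) -> Path:
    """Write the full fixture tree: counts, metadata, maps, programs, truth.

    The tree is loadable by the I/O module, drives the orchestrated
    pipeline via the emitted ``config.yaml``, and includes the planted
    truth (``truth.json``, ``de_truth.tsv``) for assertions. Re-export with
    the same seed is byte-identical.
    """
    cfg = truth.config
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    datasets = simulate_all_datasets(truth)

    metas = []
    for role, (matrix, meta) in sorted(datasets.items()):
        write_count_matrix(matrix, directory / f"{role}.tsv")
        metas.append(meta)
    metadata = pd.concat(metas, ignore_index=True)
    write_result_table(metadata, directory / "metadata.tsv")

    write_ortholog_map(truth.ortholog_map, directory / "orthologs.tsv")
    write_gene_sets(
        [truth.stage_programs["early"], truth.stage_programs["late"]],
        directory / "stage_programs.gmt",
    )
    write_gene_sets(
        [*truth.organ_programs.values(), truth.coopted_set, truth.eutherian_only_set],
        directory / "annotations.gmt",
    )
    write_result_table(
        truth.de_truth.reset_index(), directory / "de_truth.tsv"
    )

    truth_manifest = {
        "seed": cfg.seed,
        "n_genes": cfg.n_genes,
        "species": {"query": cfg.species_a, "reference": cfg.species_b},
        "planted_stage": cfg.planted_stage,
        "reference_stages": list(REFERENCE_STAGES),
        "coopted": sorted(truth.coopted_set.genes),
        "eutherian_only": sorted(truth.eutherian_only_set.genes),
        "early_program": sorted(truth.stage_programs["early"].genes),
        "late_program": sorted(truth.stage_programs["late"].genes),
        "early_in_query": sorted(truth.gene_ids_a[i] for i in truth.early_in_query),
        "late_in_query": sorted(truth.gene_ids_a[i] for i in truth.late_in_query),
        "organ_programs": {
            o: sorted(gs.genes) for o, gs in truth.organ_programs.items()
        },
    }
    with open(directory / "truth.json", "w") as handle:
        json.dump(truth_manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")

    pipeline_config = {
        "seed": cfg.seed,
        "species": {"query": cfg.species_a, "reference": cfg.species_b},
        "parameters": {
            "expression_fraction": 0.01,
            "de_alpha": 0.05,
            "chi_square_yates": False,
            "allow_missing_control": False,
        },
        "metadata": "metadata.tsv",
        "orthologs": "orthologs.tsv",
        "stage_programs": "stage_programs.gmt",
        "annotations": "annotations.gmt",
        "datasets": {
            "query_placenta": {"counts": "query_placenta.tsv", "platform": "tag_count"},
            "reference_placenta": {"counts": "reference_placenta.tsv", "platform": "tag_count"},
            "reference_placenta_series": {
                "counts": "reference_placenta_series.tsv",
                "platform": "microarray",
            },
            "stage_control": {"counts": "stage_control.tsv", "platform": "tag_count"},
            "query_mammary": {"counts": "query_mammary.tsv", "platform": "tag_count"},
            "reference_mammary": {"counts": "reference_mammary.tsv", "platform": "tag_count"},
        },
        "controls": [
            {"tissue": "liver", "query": "query_liver.tsv", "reference": "reference_liver.tsv"},
            {"tissue": "testis", "query": "query_testis.tsv", "reference": "reference_testis.tsv"},
        ],
    }
    with open(directory / "config.yaml", "w") as handle:
        yaml.safe_dump(pipeline_config, handle, sort_keys=True)
    return directory
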