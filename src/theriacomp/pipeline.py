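"""Config-driven orchestration of the full comparative analysis.

The analysis is linear, so there is no workflow engine: expression calling
feeds everything else, differential expression runs on the query placenta,
stage similarity maps query timepoints onto the reference developmental
series with a control organ, and the set-logic screens consume the call
sets. Each stage writes its tables under the output directory, a
machine-readable ``summary.json`` collects the headline numbers, and
``manifest.json`` records input hashes, parameters and the package version
for provenance. Two runs on identical inputs produce identical tables and
summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .differential_expression import run_de
from .expression_calling import (
    average_replicates,
    call_expressed,
    calls_to_frame,
    combine_cell_fractions,
)
from .io_formats import (
    CountMatrix,
    read_count_matrix,
    read_gene_sets,
    read_ortholog_map,
    read_sample_metadata,
    check_metadata_covers,
    write_result_table,
    PLATFORMS,
)
from .setops_convergence import (
    chi_square_independence,
    control_screens,
    eutherian_only_shared,
    ora_fisher,
    shared_coopted,
    stage_partition_counts,
)
from .stage_similarity import (
    best_matching_stage,
    control_contrast,
    intersect_expressed,
    similarity_matrix,
)

logger = logging.getLogger(__name__)

REQUIRED_ROLES = (
    "query_placenta",
    "reference_placenta",
    "reference_placenta_series",
    "query_mammary",
    "reference_mammary",
)


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    base_dir: Path
    seed: int
    species_query: str
    species_reference: str
    expression_fraction: float
    de_alpha: float
    chi_square_yates: bool
    allow_missing_control: bool
    metadata: Path
    orthologs: Path
    stage_programs: Optional[Path]
    annotations: Optional[Path]
    datasets: dict
    controls: list = field(default_factory=list)


def _as_role_mapping(raw, errors: list) -> dict:
    """Accept datasets as a mapping role->entry or a list of entries with a
    ``role`` field; a role claimed twice is an error naming both entries."""
    if isinstance(raw, dict):
        return {str(k): v for k, v in raw.items()}
    mapping: dict = {}
    if isinstance(raw, list):
        for entry in raw:
            role = str(entry.get("role", ""))
            if not role:
                errors.append(f"dataset entry without role: {entry}")
                continue
            if role in mapping:
                errors.append(
                    f"role {role!r} claimed by two datasets: "
                    f"{mapping[role]} and {entry}"
                )
                continue
            mapping[role] = entry
        return mapping
    errors.append("datasets must be a mapping or a list of role entries")
    return {}


def validate_config(path) -> PipelineConfig:
    """Parse and validate a pipeline config, reporting *all* problems at once."""
    path = Path(path)
    base = path.parent
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    errors: list = []

    params = raw.get("parameters", {}) or {}
    fraction = params.get("expression_fraction", 0.01)
    alpha = params.get("de_alpha", 0.05)
    if not 0 < fraction < 1:
        errors.append(f"expression_fraction {fraction} outside (0, 1)")
    if not 0 < alpha < 1:
        errors.append(f"de_alpha {alpha} outside (0, 1)")

    species = raw.get("species", {}) or {}
    if "query" not in species or "reference" not in species:
        errors.append("species.query and species.reference are required")

    def resolve(key, required=True):
        value = raw.get(key)
        if value is None:
            if required:
                errors.append(f"missing required path {key!r}")
            return None
        p = base / value
        if not p.exists():
            errors.append(f"{key}: file not found: {p}")
        return p

    metadata = resolve("metadata")
    orthologs = resolve("orthologs")
    stage_programs = resolve("stage_programs", required=False)
    annotations = resolve("annotations", required=False)

    datasets = _as_role_mapping(raw.get("datasets", {}), errors)
    resolved: dict = {}
    for role, entry in datasets.items():
        counts = entry.get("counts")
        platform = entry.get("platform", "tag_count")
        if platform not in PLATFORMS:
            errors.append(f"dataset {role}: unknown platform {platform!r}")
        if counts is None:
            errors.append(f"dataset {role}: missing counts path")
            continue
        counts_path = base / counts
        if not counts_path.exists():
            errors.append(f"dataset {role}: file not found: {counts_path}")
        resolved[role] = {"counts": counts_path, "platform": platform}
    for role in REQUIRED_ROLES:
        if role not in resolved:
            errors.append(f"missing required dataset role {role!r}")
    allow_missing = bool(params.get("allow_missing_control", False))
    if "stage_control" not in resolved and not allow_missing:
        errors.append(
            "missing dataset role 'stage_control' "
            "(set parameters.allow_missing_control to run without it)"
        )

    controls = []
    for entry in raw.get("controls", []) or []:
        tissue = entry.get("tissue")
        if not tissue:
            errors.append(f"control entry without tissue: {entry}")
            continue
        pair = {"tissue": str(tissue)}
        for side in ("query", "reference"):
            value = entry.get(side)
            if value is None:
                errors.append(f"control {tissue}: missing {side} counts path")
                continue
            p = base / value
            if not p.exists():
                errors.append(f"control {tissue}: file not found: {p}")
            pair[side] = p
        controls.append(pair)

    if errors:
        raise ConfigError(
            "invalid pipeline config:\n" + "\n".join(f"  - {e}" for e in errors)
        )
    return PipelineConfig(
        base_dir=base,
        seed=int(raw.get("seed", 0)),
        species_query=str(species["query"]),
        species_reference=str(species["reference"]),
        expression_fraction=float(fraction),
        de_alpha=float(alpha),
        chi_square_yates=bool(params.get("chi_square_yates", False)),
        allow_missing_control=allow_missing,
        metadata=metadata,
        orthologs=orthologs,
        stage_programs=stage_programs,
        annotations=annotations,
        datasets=resolved,
        controls=controls,
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def average_replicates_all(matrix: CountMatrix):
    """Mean across every column of a matrix as one profile."""
    from .expression_calling import ExpressionProfile

    return ExpressionProfile(
        gene_ids=matrix.gene_ids,
        values=matrix.values.mean(axis=1),
        label="pooled",
    )


def _relabel(profile, label: str):
    from .expression_calling import ExpressionProfile

    return ExpressionProfile(gene_ids=profile.gene_ids, values=profile.values, label=label)


def _timepoint_order(metadata: pd.DataFrame, sample_ids) -> list:
    sub = metadata[metadata["sample_id"].isin(set(sample_ids))]
    seen: list = []
    for tp in sub["timepoint"]:
        if isinstance(tp, str) and tp and tp not in seen:
            seen.append(tp)
    return seen


def run_full_analysis(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "calls").mkdir(exist_ok=True)
    (out / "screens").mkdir(exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed, "parameters": {
        "expression_fraction": config.expression_fraction,
        "de_alpha": config.de_alpha,
        "chi_square_yates": config.chi_square_yates,
    }}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # ---- load ------------------------------------------------------------
    def _load():
        metadata = read_sample_metadata(config.metadata)
        orthologs = read_ortholog_map(config.orthologs)
        matrices = {}
        for role, entry in config.datasets.items():
            matrix = read_count_matrix(entry["counts"], platform=entry["platform"])
            check_metadata_covers(matrix, metadata)
            matrices[role] = matrix
        return metadata, orthologs, matrices

    metadata, orthologs, matrices = stage("load")(_load)

    # ---- expression calling ---------------------------------------------
    def _calls():
        calls, profiles = {}, {}
        for role, matrix in matrices.items():
            if role == "reference_mammary":
                meta = metadata[metadata["sample_id"].isin(matrix.sample_ids)]
                fractions = [
                    f for f in meta["tissue_compartment"].dropna().unique() if f
                ]
                if len(fractions) > 1:
                    parts = [
                        average_replicates(
                            matrix, metadata, {"tissue_compartment": f}
                        )
                        for f in sorted(fractions)
                    ]
                    profile = _relabel(combine_cell_fractions(parts), role)
                else:
                    profile = _relabel(average_replicates_all(matrix), role)
            else:
                profile = _relabel(average_replicates_all(matrix), role)
            profiles[role] = profile
            calls[role] = call_expressed(profile, config.expression_fraction)
            write_result_table(calls_to_frame(calls[role]), out / "calls" / f"{role}.tsv")
        return calls, profiles

    calls, profiles = stage("expression_calling")(_calls)
    summary["expressed_counts"] = {
        role: len(cs.expressed) for role, cs in sorted(calls.items())
    }

    # ---- differential expression ----------------------------------------
    def _de():
        results = {}
        for contrast in ("compartment", "stage"):
            table = run_de(
                matrices["query_placenta"], metadata, contrast, alpha=config.de_alpha
            )
            write_result_table(
                table.reset_index(), out / f"de_{contrast}.tsv"
            )
            results[contrast] = table
        return results

    de_results = stage("differential_expression")(_de)
    summary["differential_expression"] = {
        contrast: {
            "n_significant": int((table["q_value"] <= config.de_alpha).sum()),
            "n_up_in_A": int((table["direction"] == "up_in_A").sum()),
            "n_up_in_B": int((table["direction"] == "up_in_B").sum()),
        }
        for contrast, table in de_results.items()
    }

    # ---- stage similarity ------------------------------------------------
    def _stagemap():
        series = matrices["reference_placenta_series"]
        q_placenta = matrices["query_placenta"]
        have_control = "stage_control" in matrices
        calls_b = [calls["reference_placenta_series"]]
        if have_control:
            calls_b.append(calls["stage_control"])
        universe = intersect_expressed([calls["query_placenta"]], calls_b, orthologs)
        query_profiles = [
            _relabel(average_replicates(q_placenta, metadata, {"timepoint": tp}), tp)
            for tp in _timepoint_order(metadata, q_placenta.sample_ids)
        ]
        reference_profiles = [
            _relabel(average_replicates(series, metadata, {"timepoint": tp}), tp)
            for tp in _timepoint_order(metadata, series.sample_ids)
        ]
        control_profiles = (
            [_relabel(average_replicates_all(matrices["stage_control"]), "stage_control")]
            if have_control
            else []
        )
        matrix = similarity_matrix(
            query_profiles, reference_profiles, control_profiles, universe
        )
        wide = matrix.rho.reset_index()
        write_result_table(wide, out / "stage_similarity.tsv")
        write_result_table(matrix.to_long_frame(), out / "stage_similarity_long.tsv")
        assignments = []
        for label in matrix.rho.index:
            best, tied = best_matching_stage(matrix, label)
            assignments.append(
                {"query": label, "best_stage": best, "tie": tied,
                 "rho": matrix.rho.at[label, best]}
            )
        write_result_table(assignments, out / "stage_assignments.tsv")
        contrast_frame = None
        if have_control:
            contrast_frame = control_contrast(matrix)
            write_result_table(
                contrast_frame.reset_index(names="query"), out / "control_contrast.tsv"
            )
        return matrix, assignments, contrast_frame

    stage_matrix, assignments, contrast_frame = stage("stage_similarity")(_stagemap)
    summary["stage_mapping"] = {
        "n_genes": stage_matrix.n_genes,
        "assignments": {
            row["query"]: {"best_stage": row["best_stage"], "tie": bool(row["tie"])}
            for row in assignments
        },
        "control_contrast": (
            {
                str(q): bool(v)
                for q, v in contrast_frame["reference_exceeds_control"].items()
            }
            if contrast_frame is not None
            else "skipped"
        ),
    }

    # ---- stage-partition enrichment -------------------------------------
    if config.stage_programs is not None:
        def _partition():
            programs = {gs.name: gs for gs in read_gene_sets(config.stage_programs)}
            if "early" not in programs or "late" not in programs:
                raise ValueError(
                    f"stage_programs must contain sets named 'early' and 'late', "
                    f"got {sorted(programs)}"
                )
            table = stage_partition_counts(
                programs["early"], programs["late"],
                calls["query_placenta"].expressed, orthologs,
            )
            stat, p = chi_square_independence(table, yates=config.chi_square_yates)
            stat_plain, p_plain = chi_square_independence(table, yates=False)
            stat_yates, p_yates = chi_square_independence(table, yates=True)
            return {
                "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
                "yates_configured": config.chi_square_yates,
                "statistic": stat,
                "p_value": p,
                "statistic_uncorrected": stat_plain,
                "p_value_uncorrected": p_plain,
                "statistic_yates": stat_yates,
                "p_value_yates": p_yates,
            }

        summary["stage_partition"] = stage("stage_partition")(_partition)

    # ---- convergence screens --------------------------------------------
    def _screens():
        expressed = {role: set(cs.expressed) for role, cs in calls.items()}
        shared = shared_coopted(
            expressed["query_placenta"], expressed["reference_placenta"],
            expressed["query_mammary"], expressed["reference_mammary"], orthologs,
        )
        eut_only = eutherian_only_shared(
            expressed["reference_placenta"], expressed["query_mammary"],
            expressed["query_placenta"], expressed["reference_mammary"], orthologs,
        )
        control_pairs = []
        for pair in config.controls:
            q = average_replicates_all(read_count_matrix(pair["query"]))
            r = average_replicates_all(read_count_matrix(pair["reference"]))
            control_pairs.append(
                (
                    pair["tissue"],
                    set(call_expressed(q, config.expression_fraction).expressed),
                    set(call_expressed(r, config.expression_fraction).expressed),
                )
            )
        controls = {
            "shared_coopted": control_screens(
                "shared_coopted", expressed["query_placenta"],
                expressed["reference_placenta"], control_pairs, orthologs,
            ),
            "eutherian_only_shared": control_screens(
                "eutherian_only_shared", expressed["query_placenta"],
                expressed["reference_placenta"], control_pairs, orthologs,
            ),
        }
        for res in (shared, eut_only):
            write_result_table(
                [{"gene": g} for g in sorted(res.genes)],
                out / "screens" / f"{res.name}.tsv",
                columns=["gene"],
            )
        return shared, eut_only, controls

    shared, eut_only, screen_controls = stage("convergence_screens")(_screens)
    summary["screens"] = {
        "shared_coopted": {
            "n_genes": len(shared),
            "unmappable": shared.unmappable,
            "controls": {t: c for t, c in screen_controls["shared_coopted"]},
        },
        "eutherian_only_shared": {
            "n_genes": len(eut_only),
            "unmappable": eut_only.unmappable,
            "controls": {t: c for t, c in screen_controls["eutherian_only_shared"]},
        },
    }

    # ---- over-representation --------------------------------------------
    if config.annotations is not None:
        def _ora():
            annotations = read_gene_sets(config.annotations)
            expressed_a = set(calls["query_placenta"].expressed) | set(
                calls["query_mammary"].expressed
            )
            expressed_b_in_a = orthologs.to_a(
                set(calls["reference_placenta"].expressed)
            ) | orthologs.to_a(set(calls["reference_mammary"].expressed))
            universe = expressed_a | expressed_b_in_a
            results = {}
            for res in (shared, eut_only):
                table = ora_fisher(res.to_gene_set(), annotations, universe | res.genes)
                write_result_table(table, out / f"ora_{res.name}.tsv")
                if len(table):
                    top = table.sort_values(["p_value", "annotation"]).iloc[0]
                    results[res.name] = {
                        "top_annotation": str(top["annotation"]),
                        "top_p_value": float(top["p_value"]),
                        "top_q_value": float(top["q_value"]),
                    }
            return results

        summary["ora"] = stage("ora")(_ora)

    # ---- provenance ------------------------------------------------------
    inputs = {str(config.metadata), str(config.orthologs)}
    inputs |= {str(entry["counts"]) for entry in config.datasets.values()}
    for pair in config.controls:
        inputs |= {str(pair["query"]), str(pair["reference"])}
    for optional in (config.stage_programs, config.annotations):
        if optional is not None:
            inputs.add(str(optional))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": summary["parameters"],
        "inputs": {p: _sha256(Path(p)) for p in sorted(inputs)},
    }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")
    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=1, sort_keys=True)
        handle.write("\n")
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
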