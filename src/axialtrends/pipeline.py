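"""End-to-end orchestration: indices → centroid tree → ancestral
states → trend battery → subclade skewness test.

The run report is a single JSON document carrying every stage's
results together with the decisions that were data-dependent (which
difference variant the variance gate selected, whether the negative-log
pre-transform fired), so a run is auditable from the report alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestral import branch_pairs, ml_ancestral_states
from .errors import AxialTrendsError, ValidationError
from .formulae import (
    FormulaTable,
    match_table_and_tree,
    read_formula_table,
    write_index_table,
)
from .indices import SpeciesProfile, compute_profile
from .skewness import interpret_partition, subclade_skew_test
from .trees import Phylogeny, centroid_tree, read_trees
from .trends import run_trend_battery

logger = logging.getLogger("axialtrends")

REPORT_SCHEMA_VERSION = 1

VALID_INDICES = SpeciesProfile.INDEX_NAMES


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    table_path: str
    tree_path: str
    output_dir: str
    indices: tuple[str, ...] = VALID_INDICES
    seed: int = 0
    alpha: float = 0.05
    include_tips: bool = False
    min_group_branches: int = 10
    variance_test: str = "f"
    force_variant: str | None = None
    skew_transform: str = "auto"
    allow_zero_counts: bool = False
    merge_root_edges: bool = True

    def __post_init__(self) -> None:
        if not self.indices:
            raise ValidationError("at least one index must be selected")
        unknown = set(self.indices) - set(VALID_INDICES)
        if unknown:
            raise ValidationError(f"unknown index selection: {sorted(unknown)}")
        for attr in ("table_path", "tree_path"):
            if not Path(getattr(self, attr)).exists():
                raise ValidationError(f"{attr} does not exist: {getattr(self, attr)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
        if "indices" in raw and isinstance(raw["indices"], list):
            raw["indices"] = tuple(raw["indices"])
        return cls(**raw)


def _branch_group_labels(
    tree: Phylogeny, pairs: pd.DataFrame, species_groups: dict[str, str]
) -> pd.Series:
    """Group label per branch: the descendant clade's group if all its
    tips belong to one group, else None (mixed branches are pooled only
    into the whole-tree battery)."""
    below = tree.clade_tips()
    by_id = {tree.node_id[i]: below[i] for i in range(tree.n_nodes)}
    labels = []
    for dec in pairs["descendant_id"]:
        groups = {species_groups.get(t) for t in by_id[dec]}
        labels.append(groups.pop() if len(groups) == 1 else None)
    return pd.Series(labels, index=pairs.index)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write per-stage outputs plus a
    JSON run report into ``config.output_dir``.  Returns the report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "stages": {},
    }
    try:
        table = read_formula_table(
            config.table_path, allow_zero=config.allow_zero_counts
        )
        trees = read_trees(config.tree_path)
        report["stages"]["input"] = {
            "n_species": len(table),
            "n_trees": len(trees),
        }

        if len(trees) > 1:
            idx, matrix = centroid_tree(trees, config.merge_root_edges)
            tree = trees[idx]
            np.savetxt(out / "bsd_matrix.tsv", matrix, delimiter="\t", fmt="%.9g")
            report["stages"]["centroid"] = {
                "chosen_index": idx,
                "column_sums": matrix.sum(axis=0).tolist(),
            }
        else:
            tree = trees[0]

        table, tree, match = match_table_and_tree(table, tree)
        report["stages"]["match"] = {
            "n_shared": match.n_shared,
            "dropped_tips": match.dropped_tips,
            "dropped_rows": match.dropped_rows,
        }

        profiles = [compute_profile(rec) for rec in table]
        write_index_table(profiles, out / "indices.tsv")
        species_groups = {p.species_id: p.group_label for p in profiles}
        report["stages"]["indices"] = {
            "path": str(out / "indices.tsv"),
            "indices_computed": list(config.indices),
        }

        per_index: dict = {}
        for index_name in config.indices:
            tip_values = {p.species_id: getattr(p, index_name) for p in profiles}
            estimates = ml_ancestral_states(tree, tip_values)
            pairs = branch_pairs(tree, estimates, include_tips=config.include_tips)
            groups = _branch_group_labels(tree, pairs, species_groups)
            summaries = run_trend_battery(
                pairs,
                estimates,
                groups=groups,
                alpha=config.alpha,
                min_group_branches=config.min_group_branches,
                variance_test=config.variance_test,
                force_variant=config.force_variant,
            )
            skew = subclade_skew_test(
                np.array([tip_values[s] for s in table.species_ids]),
                np.array([species_groups[s] for s in table.species_ids]),
                transform=config.skew_transform,
            )
            ancestor_frame = pd.DataFrame(
                {
                    "node_id": list(estimates.node_values),
                    "age": [
                        estimates.node_ages[n] for n in estimates.node_values
                    ],
                    "estimate": list(estimates.node_values.values()),
                }
            )
            ancestor_frame.to_csv(
                out / f"ancestors_{index_name}.tsv", sep="\t", index=False
            )
            pairs.to_csv(out / f"branches_{index_name}.tsv", sep="\t", index=False)
            per_index[index_name] = {
                "sigma2_hat": estimates.sigma2_hat,
                "n_branches": len(pairs),
                "trend_tests": [s.to_dict() for s in summaries],
                "skew_partition": {
                    **skew.to_dict(),
                    "verdict": interpret_partition(skew),
                },
            }
        report["stages"]["analysis"] = per_index
        report["status"] = "ok"
    except AxialTrendsError as exc:
        report["status"] = "error"
        report["error"] = {"stage": _last_stage(report), "message": str(exc)}
        _write_report(report, out)
        raise
    _write_report(report, out)
    return report


def _last_stage(report: dict) -> str:
    stages = list(report.get("stages", {}))
    return stages[-1] if stages else "input"


def _write_report(report: dict, out: Path) -> None:
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_from_yaml(path: str | Path) -> dict:
    return run_pipeline(RunConfig.from_yaml(path))


def profiles_from_table(table: FormulaTable) -> list[SpeciesProfile]:
    """Convenience: index profiles for every record in a table."""
    return [compute_profile(rec) for rec in table]
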