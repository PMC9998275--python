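"""Reading, validating and writing vertebral-formula tables.

A formula table has one row per species with its modal presacral
vertebral formula: cervical (C), thoracic (T) and lumbar (L) counts
plus a higher-level group label.  Intraspecific variation is resolved
upstream (one modal formula per species); duplicate species rows are a
validation error here, never silently aggregated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import MatchingError, SchemaError, ValidationError
from .indices import SpeciesProfile

__all__ = [
    "VertebralFormula",
    "FormulaTable",
    "read_formula_table",
    "match_table_and_tree",
    "write_index_table",
    "normalize_label",
]

# canonical column -> accepted header spellings (lower-cased)
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "species_id": ("species", "species_id", "taxon", "tip", "binomial"),
    "group_label": ("group", "group_label", "clade", "order"),
    "cervical_count": ("c", "cervical", "cervical_count"),
    "thoracic_count": ("t", "thoracic", "thoracic_count"),
    "lumbar_count": ("l", "lumbar", "lumbar_count"),
}


def normalize_label(label: str) -> str:
    """Canonical form for species labels: underscores and spaces are
    interchangeable, comparison is case-insensitive.  Originals are
    preserved everywhere labels are displayed."""
    return label.strip().replace(" ", "_").casefold()


@dataclass(frozen=True)
class VertebralFormula:
    """One species' modal presacral formula and group assignment."""

    species_id: str
    group_label: str
    cervical_count: int
    thoracic_count: int
    lumbar_count: int

    @property
    def ctl_count(self) -> int:
        return self.cervical_count + self.thoracic_count + self.lumbar_count

    @property
    def tl_count(self) -> int:
        return self.thoracic_count + self.lumbar_count

    def validate(self, allow_zero: bool = False) -> None:
        floor = 0 if allow_zero else 1
        for name in ("cervical_count", "thoracic_count", "lumbar_count"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool):
                raise ValidationError(
                    f"{self.species_id}: {name} must be an integer, got {value!r}"
                )
            if value < floor:
                raise ValidationError(
                    f"{self.species_id}: {name} = {value} below minimum {floor}"
                    + ("" if allow_zero else " (pass allow_zero to accept 0)")
                )


@dataclass
class FormulaTable:
    """Ordered collection of vertebral formulae with a group index."""

    records: list[VertebralFormula]
    group_index: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.species_id in seen:
                raise ValidationError(f"duplicate species_id {rec.species_id!r}")
            seen.add(rec.species_id)
        self.group_index = {}
        for rec in self.records:
            self.group_index.setdefault(rec.group_label, []).append(rec.species_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species_ids(self) -> list[str]:
        return [rec.species_id for rec in self.records]

    def subset(self, species_ids: Sequence[str]) -> "FormulaTable":
        """Restrict to ``species_ids``, reordered to match that sequence."""
        by_id = {rec.species_id: rec for rec in self.records}
        return FormulaTable([by_id[s] for s in species_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": [r.species_id for r in self.records],
                "group": [r.group_label for r in self.records],
                "C": [r.cervical_count for r in self.records],
                "T": [r.thoracic_count for r in self.records],
                "L": [r.lumbar_count for r in self.records],
            }
        )


def _resolve_columns(
    columns: Iterable[str], aliases: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    lowered = {c.strip().lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in lowered:
                resolved[canonical] = lowered[name]
                break
        else:
            raise SchemaError(
                f"missing required column {canonical!r} "
                f"(accepted headers: {', '.join(names)})"
            )
    return resolved


def _parse_count(raw, column: str, row_label: str) -> int:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row_label}: {column} = {raw!r} is not a number")
    if not value.is_integer():
        raise ValidationError(f"row {row_label}: {column} = {raw!r} is not an integer")
    if value < 0:
        raise ValidationError(f"row {row_label}: {column} = {raw!r} is negative")
    return int(value)


def read_formula_table(
    path: str | Path | io.TextIOBase,
    dialect: str | None = None,
    aliases: Mapping[str, tuple[str, ...]] | None = None,
    allow_zero: bool = False,
) -> FormulaTable:
    """Read a delimited vertebral-formula table.

    Parameters
    ----------
    path
        CSV/TSV file (UTF-8, header row required) or an open text handle.
    dialect
        Field delimiter; ``None`` sniffs between comma and tab.
    aliases
        Optional override of the accepted header spellings per canonical
        column (case-insensitive).
    allow_zero
        Accept zero region counts (the index math tolerates them via
        0! = 1); off by default since no sampled mammal lacks a region.
    """
    sep = dialect if dialect is not None else None
    frame = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    colmap = _resolve_columns(frame.columns, aliases or DEFAULT_ALIASES)
    records = []
    for i, row in frame.iterrows():
        species = str(row[colmap["species_id"]]).strip()
        rec = VertebralFormula(
            species_id=species,
            group_label=str(row[colmap["group_label"]]).strip(),
            cervical_count=_parse_count(row[colmap["cervical_count"]], "C", species),
            thoracic_count=_parse_count(row[colmap["thoracic_count"]], "T", species),
            lumbar_count=_parse_count(row[colmap["lumbar_count"]], "L", species),
        )
        rec.validate(allow_zero=allow_zero)
        records.append(rec)
    return FormulaTable(records)


@dataclass
class MatchReport:
    """What was dropped while reconciling a table with a tree."""

    n_shared: int
    dropped_tips: list[str]
    dropped_rows: list[str]


def match_table_and_tree(table: FormulaTable, tree):
    """Reconcile a formula table with a phylogeny.

    Labels are compared after normalization (spaces/underscores unified,
    case folded).  Returns the table restricted to shared species in
    tree tip order, the tree pruned to the shared species, and a report
    of dropped tips and rows.  Fewer than three shared labels is an
    error: no comparative analysis is possible.
    """
    table_by_norm = {normalize_label(r.species_id): r.species_id for r in table}
    tip_by_norm = {normalize_label(t): t for t in tree.tip_labels}
    shared_norm = [n for n in tip_by_norm if n in table_by_norm]
    if len(shared_norm) < 3:
        raise MatchingError(
            f"only {len(shared_norm)} species shared between table "
            f"({len(table)}) and tree ({len(tree.tip_labels)} tips); need >= 3"
        )
    keep_tips = [tip_by_norm[n] for n in shared_norm]
    pruned = tree.prune_to(keep_tips)
    # table rows in pruned-tree tip order
    ordered_species = [table_by_norm[normalize_label(t)] for t in pruned.tip_labels]
    matched = table.subset(ordered_species)
    report = MatchReport(
        n_shared=len(shared_norm),
        dropped_tips=[t for n, t in tip_by_norm.items() if n not in table_by_norm],
        dropped_rows=[
            r.species_id
            for r in table
            if normalize_label(r.species_id) not in tip_by_norm
        ],
    )
    return matched, pruned, report


INDEX_TABLE_COLUMNS = [
    "species_id",
    "group",
    "C",
    "T",
    "L",
    "CTL",
    "TL",
    "brillouin_CTL",
    "evenness_CTL",
    "brillouin_TL",
    "evenness_TL",
    "tl_ratio",
    "logit_tl",
]


def write_index_table(
    profiles: Iterable[SpeciesProfile],
    path: str | Path | io.TextIOBase,
    decimals: int = 6,
    sep: str = "\t",
) -> None:
    """Write per-species index records as delimited text (default TSV)."""
    rows = [
        {
            "species_id": p.species_id,
            "group": p.group_label,
            "C": p.cervical_count,
            "T": p.thoracic_count,
            "L": p.lumbar_count,
            "CTL": p.ctl_count,
            "TL": p.tl_count,
            "brillouin_CTL": p.brillouin_ctl,
            "evenness_CTL": p.evenness_ctl,
            "brillouin_TL": p.brillouin_tl,
            "evenness_TL": p.evenness_tl,
            "tl_ratio": p.tl_ratio,
            "logit_tl": p.logit_tl,
        }
        for p in profiles
    ]
    frame = pd.DataFrame(rows, columns=INDEX_TABLE_COLUMNS)
    frame.to_csv(path, sep=sep, index=False, float_format=f"%.{decimals}f")
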