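"""Taxonomic composition and per-group recording statistics.

Species are mapped to the UK recording community's *informal* groups
(moths, beetles, true bugs, ...) which nest inside *higher* groups
(birds, invertebrates, plants, amphibians & reptiles, fish,
fungi & lichens, mammals, others).  Unmapped species fall into
("other", "others").  Coverage compares the species recorded in a
dataset against a British checklist total per informal group.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "HIGHER_GROUPS",
    "load_mapping",
    "load_checklist",
    "default_checklist",
    "assign_groups",
    "composition",
    "group_stats",
]

HIGHER_GROUPS = [
    "birds",
    "invertebrates",
    "plants",
    "amphibians & reptiles",
    "fish",
    "fungi & lichens",
    "mammals",
    "others",
]

UNMAPPED = ("other", "others")


def _norm_name(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


def load_mapping(path_or_df) -> pd.DataFrame:
    """Load a species -> (informal_group, higher_group) mapping CSV.

    Columns: ``scientificName, informalGroup, higherGroup``.  Species
    names are matched after trimming and case-folding; a duplicated
    species or an informal group pointing at two higher groups is a
    load-time error.
    """
    df = (
        path_or_df.copy()
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df, dtype=str)
    )
    required = {"scientificName", "informalGroup", "higherGroup"}
    if not required <= set(df.columns):
        raise ValueError(f"mapping CSV needs columns {sorted(required)}")
    df["scientificName"] = df["scientificName"].map(_norm_name)
    dup = df["scientificName"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate species entries in mapping: {sorted(df.loc[dup, 'scientificName'])[:5]}"
        )
    fanout = df.groupby("informalGroup")["higherGroup"].nunique()
    bad = fanout[fanout > 1]
    if len(bad):
        raise ValueError(
            f"informal group(s) mapped to multiple higher groups: {list(bad.index)}"
        )
    return df.set_index("scientificName")


def load_checklist(path_or_df) -> pd.Series:
    """Checklist CSV (``informalGroup, britishSpeciesTotal``) -> Series."""
    df = (
        path_or_df.copy()
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df)
    )
    if not {"informalGroup", "britishSpeciesTotal"} <= set(df.columns):
        raise ValueError("checklist CSV needs informalGroup,britishSpeciesTotal")
    s = df.set_index("informalGroup")["britishSpeciesTotal"].astype(int)
    if (s <= 0).any():
        raise ValueError("checklist totals must be positive")
    return s


def default_checklist() -> pd.Series:
    """British-list species totals shipped with the package (editable)."""
    with resources.files("citrec").joinpath("data/british_checklist.csv").open() as fh:
        return load_checklist(pd.read_csv(fh))


def assign_groups(records: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Attach informal/higher group labels to every record.

    Unmapped species get ("other", "others") and are flagged via
    ``group_mapped``.
    """
    out = records.copy()
    keys = out["scientificName"].map(_norm_name)
    informal = keys.map(mapping["informalGroup"])
    higher = keys.map(mapping["higherGroup"])
    out["group_mapped"] = informal.notna()
    out["informal_group"] = informal.fillna(UNMAPPED[0])
    out["higher_group"] = higher.fillna(UNMAPPED[1])
    return out


def composition(records: pd.DataFrame, level: str = "higher") -> pd.DataFrame:
    """Percentage of records per taxonomic group.

    ``level="higher"`` tabulates the higher groups;
    ``level="invertebrates"`` tabulates informal groups within the
    invertebrates only (the usual follow-up breakdown).  Percentages
    sum to 100 before rounding.
    """
    if len(records) == 0:
        raise ValueError("no records to tabulate")
    if level == "higher":
        counts = records["higher_group"].value_counts()
    elif level == "invertebrates":
        sub = records[records["higher_group"] == "invertebrates"]
        if len(sub) == 0:
            raise ValueError("no invertebrate records")
        counts = sub["informal_group"].value_counts()
    else:
        raise ValueError(f"unknown composition level {level!r}")
    out = counts.to_frame("n_records")
    out["percent"] = 100.0 * out["n_records"] / out["n_records"].sum()
    out.index.name = "group"
    return out


def group_stats(
    records: pd.DataFrame,
    checklist: pd.Series | None = None,
    level: str = "informal_group",
) -> pd.DataFrame:
    """Per-group recorders, records, records/recorder and coverage.

    Coverage is 100 x (distinct species recorded) / (British-list
    total); groups absent from the checklist get NaN coverage but full
    recording statistics.
    """
    if level not in records.columns:
        raise KeyError(f"records lack a {level!r} column")
    g = records.groupby(level)
    out = pd.DataFrame(
        {
            "n_recorders": g["recorder_id"].nunique(),
            "n_records": g.size(),
            "n_species_recorded": g["scientificName"].apply(
                lambda s: s.map(_norm_name).nunique()
            ),
        }
    )
    out["records_per_recorder"] = out["n_records"] / out["n_recorders"]
    if checklist is not None:
        out["checklist_total"] = checklist.reindex(out.index)
        out["coverage_pct"] = (
            100.0 * out["n_species_recorded"] / out["checklist_total"]
        ).round(0)
    out.index.name = "group"
    return out.sort_values("n_records", ascending=False)
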