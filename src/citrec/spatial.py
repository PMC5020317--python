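"""1-km grid-cell (monad) recording statistics and hotspots.

Records admitted to spatial analyses (precision <= 1000 m) are
aggregated per monad: number of records, distinct volunteers, distinct
informal taxonomic groups, and volunteer productivity (records per
volunteer).  Cross-dataset and cross-metric agreement is measured by
Spearman rank correlation over a configurable cell pairing; hotspots
are the top-n cells for a metric with a deterministic tie-break.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .records_io import parse_grid_reference

__all__ = [
    "aggregate_cells",
    "cross_correlation",
    "hotspots",
    "taxon_surface",
    "cells_to_geojson",
]

CELL_METRICS = ["n_records", "n_volunteers", "n_informal_groups", "productivity"]


def aggregate_cells(records: pd.DataFrame, group_column: str = "informal_group") -> pd.DataFrame:
    """Per-monad recording statistics.

    Returns a DataFrame indexed by monad with ``n_records``,
    ``n_volunteers``, ``n_informal_groups`` and ``productivity``
    columns plus one ``records_<group>`` count column per informal
    group present.  Only occupied cells appear.  Records coarser than
    1 km must have been filtered upstream.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=CELL_METRICS, index=pd.Index([], name="monad"))
    if (records["precision_m"] > 1000).any():
        raise ValueError(
            "records coarser than 1 km present; filter precision upstream"
        )
    g = records.groupby("monad")
    out = pd.DataFrame(
        {
            "n_records": g.size(),
            "n_volunteers": g["recorder_id"].nunique(),
        }
    )
    if group_column in records.columns:
        out["n_informal_groups"] = g[group_column].nunique()
        per_group = (
            records.pivot_table(
                index="monad", columns=group_column, aggfunc="size", fill_value=0
            )
            .add_prefix("records_")
        )
        out = out.join(per_group)
    else:
        out["n_informal_groups"] = 0
    out["productivity"] = out["n_records"] / out["n_volunteers"]
    out.index.name = "monad"
    return out.sort_index()


def cross_correlation(
    a: pd.DataFrame,
    b: pd.DataFrame,
    metric: str = "productivity",
    pairing: str = "union",
) -> tuple[float, int, float]:
    """Spearman correlation of one cell metric between two cell tables.

    ``pairing="union"`` pairs every cell occupied by either table,
    treating absence as 0 (the default, which makes the reported pair
    count auditable); ``"intersection"`` restricts to cells occupied by
    both.  Returns ``(rho, n_pairs, p_value)``.
    """
    for t in (a, b):
        if metric not in t.columns:
            raise KeyError(f"metric {metric!r} missing from cell table")
    if pairing == "union":
        idx = a.index.union(b.index)
        x = a[metric].reindex(idx, fill_value=0).to_numpy(float)
        y = b[metric].reindex(idx, fill_value=0).to_numpy(float)
    elif pairing == "intersection":
        idx = a.index.intersection(b.index)
        x = a.loc[idx, metric].to_numpy(float)
        y = b.loc[idx, metric].to_numpy(float)
    else:
        raise ValueError(f"unknown pairing policy {pairing!r}")
    if len(idx) < 3:
        raise ValueError(f"only {len(idx)} paired cells; need at least 3")
    rho, p = spearmanr(x, y)
    return float(rho), int(len(idx)), float(p)


def hotspots(cells: pd.DataFrame, metric: str = "n_records", top_n: int = 10,
             attributes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Top cells for one metric, ties broken by monad id (ascending).

    ``attributes`` (indexed by monad, e.g. a bluespace flag) is joined
    onto the ranking when given.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if metric not in cells.columns:
        raise KeyError(f"metric {metric!r} missing from cell table")
    ranked = (
        cells[[metric]]
        .reset_index()
        .sort_values([metric, "monad"], ascending=[False, True], kind="stable")
        .head(top_n)
        .reset_index(drop=True)
    )
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    if attributes is not None:
        ranked = ranked.merge(
            attributes, left_on="monad", right_index=True, how="left"
        )
    return ranked


def taxon_surface(
    records: pd.DataFrame, group: str, group_column: str = "informal_group"
) -> pd.DataFrame:
    """Cell statistics restricted to one informal taxonomic group."""
    if group_column not in records.columns:
        raise KeyError(f"records lack a {group_column!r} column")
    if group not in set(records[group_column].unique()):
        raise KeyError(f"group {group!r} has no mapping in the records")
    return aggregate_cells(records[records[group_column] == group], group_column)


def cells_to_geojson(cells: pd.DataFrame, path=None) -> dict:
    """1-km square polygons (OSGB coordinates) with metric properties.

    Cell corners come straight from the monad grid reference; no datum
    transformation is applied.
    """
    features = []
    for monad, row in cells.iterrows():
        e, n, prec = parse_grid_reference(str(monad))
        ring = [
            [e, n],
            [e + 1000, n],
            [e + 1000, n + 1000],
            [e, n + 1000],
            [e, n],
        ]
        props = {"monad": str(monad)}
        for col in cells.columns:
            val = row[col]
            props[col] = float(val) if isinstance(val, (int, float, np.number)) else val
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh)
    return doc
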