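"""Ingestion and validation of raw occurrence-record tables.

Raw tables arrive as Darwin-Core-like CSV (recordedBy, eventDate,
gridReference, scientificName, datasetID).  This module parses OSGB
(British National Grid) alphanumeric grid references at mixed precision,
canonicalises recorder identities, applies the exact-date and spatial
precision filters, and returns a cleaned table plus an audit of every
rejection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "GridRefError",
    "FilterAudit",
    "IngestPolicy",
    "parse_grid_reference",
    "format_grid_reference",
    "monad_of",
    "normalize_recorder_id",
    "clean_records",
    "read_raw_csv",
]

# 100-km letter pairs use the standard 5x5 scheme with I omitted.
_LETTERS = "ABCDEFGHJKLMNOPQRSTUVWXYZ"  # 25 letters, index = row*5 + col

# Tetrad (2-km) suffix letters, "DINTY" system: A-Z omitting O,
# column-major from the SW corner of the 10-km square.
_TETRAD_LETTERS = "ABCDEFGHIJKLMNPQRSTUVWXYZ"

# OSGB coordinate bounds in metres.
EASTING_MAX = 700_000
NORTHING_MAX = 1_300_000

_GRIDREF_RE = re.compile(r"^([A-Z]{2})(\d*)([A-Z]?)$")


class GridRefError(ValueError):
    """Raised for malformed or out-of-range grid references."""


def _letter_index(letter: str) -> int:
    i = _LETTERS.find(letter)
    if i < 0:
        raise GridRefError(f"invalid OSGB grid letter {letter!r}")
    return i


def parse_grid_reference(gridref: str) -> tuple[int, int, int]:
    """Parse an OSGB grid reference into SW-corner coordinates.

    Parameters
    ----------
    gridref
        Two 100-km letters followed by an even number (0-10) of digits,
        e.g. ``"TQ3280"``; or a tetrad reference such as ``"TQ38A"``
        (10-km square plus a DINTY letter).

    Returns
    -------
    (easting, northing, precision_m)
        SW-corner coordinates in metres on OSGB36/BNG and the edge
        length of the referenced square: 0 digits -> 100000, 2 -> 10000,
        4 -> 1000, 6 -> 100, 8 -> 10, 10 -> 1; tetrads -> 2000.
    """
    if not isinstance(gridref, str):
        raise GridRefError(f"grid reference must be a string, got {gridref!r}")
    token = gridref.strip().upper().replace(" ", "")
    m = _GRIDREF_RE.match(token)
    if not m:
        raise GridRefError(f"malformed grid reference {gridref!r}")
    letters, digits, tetrad = m.groups()

    i1 = _letter_index(letters[0])
    i2 = _letter_index(letters[1])
    # First letter: 500-km blocks around the false origin.
    easting = (i1 % 5 - 2) * 500_000
    northing = (3 - i1 // 5) * 500_000
    # Second letter: 100-km square within the block.
    easting += (i2 % 5) * 100_000
    northing += (4 - i2 // 5) * 100_000

    if tetrad:
        if len(digits) != 2:
            raise GridRefError(
                f"tetrad reference {gridref!r} needs exactly 2 digits before "
                f"the suffix letter {tetrad!r}"
            )
        t = _TETRAD_LETTERS.find(tetrad)
        if t < 0:
            raise GridRefError(f"invalid tetrad (DINTY) letter {tetrad!r}")
        easting += int(digits[0]) * 10_000 + (t // 5) * 2_000
        northing += int(digits[1]) * 10_000 + (t % 5) * 2_000
        precision = 2_000
    else:
        if len(digits) % 2 or len(digits) > 10:
            raise GridRefError(
                f"grid reference {gridref!r} has an odd or overlong digit "
                f"count ({len(digits)})"
            )
        half = len(digits) // 2
        precision = 100_000 // (10**half)
        if half:
            easting += int(digits[:half]) * precision
            northing += int(digits[half:]) * precision

    if not (0 <= easting < EASTING_MAX and 0 <= northing < NORTHING_MAX):
        raise GridRefError(f"grid reference {gridref!r} is outside OSGB bounds")
    return easting, northing, precision


def format_grid_reference(easting: int, northing: int, precision_m: int) -> str:
    """Inverse of :func:`parse_grid_reference` for power-of-ten precisions."""
    if not (0 <= easting < EASTING_MAX and 0 <= northing < NORTHING_MAX):
        raise GridRefError(f"coordinates ({easting}, {northing}) outside OSGB bounds")
    if precision_m not in (1, 10, 100, 1_000, 10_000, 100_000):
        raise GridRefError(f"unsupported precision {precision_m} m")
    e, n = int(easting), int(northing)
    col1 = 2 + e // 500_000
    row1 = 3 - n // 500_000
    col2 = (e % 500_000) // 100_000
    row2 = 4 - (n % 500_000) // 100_000
    letters = _LETTERS[row1 * 5 + col1] + _LETTERS[row2 * 5 + col2]
    half = {1: 5, 10: 4, 100: 3, 1_000: 2, 10_000: 1, 100_000: 0}[precision_m]
    if half == 0:
        return letters
    de = (e % 100_000) // precision_m
    dn = (n % 100_000) // precision_m
    return f"{letters}{de:0{half}d}{dn:0{half}d}"


def monad_of(easting: float, northing: float) -> str:
    """Return the 1-km cell (monad) grid reference containing a point."""
    if not (0 <= easting < EASTING_MAX and 0 <= northing < NORTHING_MAX):
        raise GridRefError(f"coordinates ({easting}, {northing}) outside OSGB bounds")
    return format_grid_reference(
        int(easting) // 1000 * 1000, int(northing) // 1000 * 1000, 1000
    )


# ---------------------------------------------------------------------------
# Recorder identity
# ---------------------------------------------------------------------------

_DEFAULT_GROUP_KEYWORDS = ("group", "society", "team", "club", "survey")
_ANONYMOUS_TOKENS = {"", "anon", "anonymous", "unknown", "n/a", "na"}


def normalize_recorder_id(
    name: str,
    collapse_synonyms: bool = False,
    group_keywords: tuple[str, ...] = _DEFAULT_GROUP_KEYWORDS,
) -> tuple[str, bool, bool]:
    """Classify a free-text recorder name.

    Returns ``(recorder_id, is_group, is_anonymous)``.  With
    ``collapse_synonyms`` the id becomes lowercased surname plus first
    initial, so "A. Person" and "Albert Person" share the id
    ``person_a``; collisions between true namesakes are accepted as a
    documented limitation.  Names containing a group keyword (e.g. "Wren
    Group") are flagged as collective identities.
    """
    raw = "" if name is None or (isinstance(name, float) and np.isnan(name)) else str(name)
    stripped = raw.strip()
    lowered = stripped.lower()
    if lowered in _ANONYMOUS_TOKENS:
        return "", False, True
    if any(kw in lowered.split() or kw in lowered for kw in group_keywords):
        return re.sub(r"\s+", "_", lowered), True, False
    if not collapse_synonyms:
        return re.sub(r"\s+", "_", lowered), False, False
    tokens = [re.sub(r"[^\w]", "", t) for t in lowered.split()]
    tokens = [t for t in tokens if t]
    if not tokens:
        return "", False, True
    surname = tokens[-1]
    initial = tokens[0][0] if len(tokens) > 1 else ""
    return f"{surname}_{initial}" if initial else surname, False, False


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


@dataclass
class IngestPolicy:
    """Filtering policy for :func:`clean_records`."""

    max_precision_m: int = 1000
    collapse_synonyms: bool = False
    drop_anonymous: bool = False
    drop_groups: bool = False
    group_keywords: tuple[str, ...] = _DEFAULT_GROUP_KEYWORDS


@dataclass
class FilterAudit:
    """Counts of rows rejected at each (disjoint) filtering step.

    Rejection priority is date -> precision -> anonymous -> group, so
    ``n_output = n_input - sum(rejections)`` holds exactly.
    """

    n_input: int = 0
    n_rejected_date: int = 0
    n_rejected_precision: int = 0
    n_rejected_anonymous: int = 0
    n_rejected_group: int = 0
    n_output: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def reconciles(self) -> bool:
        return self.n_output == self.n_input - (
            self.n_rejected_date
            + self.n_rejected_precision
            + self.n_rejected_anonymous
            + self.n_rejected_group
        )


_RAW_COLUMNS = ["recordedBy", "eventDate", "gridReference", "scientificName", "datasetID"]


def read_raw_csv(path) -> pd.DataFrame:
    """Read a raw occurrence CSV, checking the expected header."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("recordedBy", "eventDate", "scientificName") if c not in df.columns]
    if missing:
        raise ValueError(f"raw CSV is missing required columns: {missing}")
    has_gridref = "gridReference" in df.columns
    has_en = {"easting", "northing", "coordinateUncertaintyInMeters"} <= set(df.columns)
    if not (has_gridref or has_en):
        raise ValueError(
            "raw CSV needs either a gridReference column or "
            "easting/northing/coordinateUncertaintyInMeters columns"
        )
    return df


def _parse_exact_date(text: str):
    """Return a Timestamp for an exact calendar day, else None."""
    s = (text or "").strip()
    if not re.match(r"^\d{4}-\d{2}-\d{2}$", s):
        return None
    try:
        return pd.Timestamp(s)
    except ValueError:
        return None


def clean_records(
    raw: pd.DataFrame, policy: IngestPolicy | None = None
) -> tuple[pd.DataFrame, FilterAudit]:
    """Validate and normalise a raw occurrence table.

    Rows failing the exact-day date filter or the spatial precision
    filter (default <= 1000 m) are rejected and counted, never silently
    dropped.  Anonymous and collective (group) recorders are flagged
    and, depending on policy, either retained for spatial/taxonomic use
    or dropped.  Returns the cleaned table and a :class:`FilterAudit`.
    """
    policy = policy or IngestPolicy()
    audit = FilterAudit(n_input=len(raw))

    rows = []
    for rec in raw.itertuples(index=False):
        date = _parse_exact_date(getattr(rec, "eventDate", ""))
        if date is None:
            audit.n_rejected_date += 1
            continue
        gridref = getattr(rec, "gridReference", None)
        try:
            if gridref is not None and str(gridref).strip():
                easting, northing, precision = parse_grid_reference(str(gridref))
            else:
                easting = float(getattr(rec, "easting"))
                northing = float(getattr(rec, "northing"))
                precision = int(float(getattr(rec, "coordinateUncertaintyInMeters")))
        except (GridRefError, ValueError, AttributeError, TypeError):
            audit.n_rejected_precision += 1
            continue
        if precision > policy.max_precision_m:
            audit.n_rejected_precision += 1
            continue
        recorder_id, is_group, is_anon = normalize_recorder_id(
            getattr(rec, "recordedBy", ""),
            collapse_synonyms=policy.collapse_synonyms,
            group_keywords=policy.group_keywords,
        )
        if is_anon and policy.drop_anonymous:
            audit.n_rejected_anonymous += 1
            continue
        if is_group and policy.drop_groups:
            audit.n_rejected_group += 1
            continue
        rows.append(
            {
                "recorder_id": recorder_id,
                "is_group": is_group,
                "is_anonymous": is_anon,
                "date": date,
                "easting": int(easting),
                "northing": int(northing),
                "precision_m": precision,
                "monad": monad_of(easting, northing),
                "scientificName": str(getattr(rec, "scientificName", "")).strip(),
                "datasetID": str(getattr(rec, "datasetID", "")).strip(),
            }
        )

    clean = pd.DataFrame(
        rows,
        columns=[
            "recorder_id",
            "is_group",
            "is_anonymous",
            "date",
            "easting",
            "northing",
            "precision_m",
            "monad",
            "scientificName",
            "datasetID",
        ],
    )
    audit.n_output = len(clean)
    return clean, audit
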