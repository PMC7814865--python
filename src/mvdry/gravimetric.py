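"""Gravimetric sublimation mapping: vial weights -> fraction sublimed by location.

The mapping protocol weighs every vial three times — empty (tare), after
filling (pre-drying gross) and after a full or partial drying run
(post-drying gross).  Water removed is the gross-weight difference (the
tare cancels), and dividing by the initial water mass gives the per-vial
fraction sublimed.  Tracing each vial back to its tray position then lets
the run be summarized by location class: *edge* vials on the tray
perimeter receive extra radiative/conductive heat and dry fastest;
*center* vials are interior; on the large rectangular lyophilizer tray an
intermediate *inner edge* ring (one vial in from the perimeter, not
surrounded by a full shell of 6 nested neighbors) is also resolved.
Microwave-dryer wedge trays are small enough that only edge/center are
distinguished.

Input records are plain delimited text with columns
``vial_id, tray_id, row, col, tare_g, pre_gross_g, post_gross_g, content``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["vial_id", "tray_id", "row", "col", "tare_g",
                  "pre_gross_g", "post_gross_g", "content"]
LOCATION_CLASSES = ("center", "inner_edge", "edge")
#: fraction above which a vial is flagged as exceeding full removal
OVERSHOOT_FLAG = 1.05


@dataclass(frozen=True)
class VialRecord:
    """One vial's weighing record and tray position."""

    vial_id: str
    tray_id: str
    row: int
    col: int
    tare_g: float
    pre_gross_g: float
    post_gross_g: float
    content: str = "active"

    def __post_init__(self) -> None:
        if self.pre_gross_g < self.tare_g or self.post_gross_g < self.tare_g:
            raise ValueError(f"vial {self.vial_id}: gross weight below tare")
        if self.post_gross_g > self.pre_gross_g:
            logger.warning("vial %s: post-drying weight exceeds pre-drying "
                           "(weighing noise?)", self.vial_id)
        if self.content not in ("active", "placebo", "thermocouple"):
            raise ValueError(f"unknown content {self.content!r}")


@dataclass(frozen=True)
class TrayLayout:
    """Tray geometry for location classification.

    ``tight_wedge`` / ``loose_wedge``: triangular microwave-tray wedges
    described by a tuple of row lengths (32 and 44 vials by default);
    hex-nested and rigidly spaced respectively, but for classification both
    use the perimeter rule with two classes (edge / center).
    ``lyo_rect``: rectangular lyophilizer tray (rows x cols) of nested
    vials with hexagonal adjacency and three classes; the default
    21 x 26 = 546-position grid approximates the 543-vial tray, whose exact
    row/column split is configurable because it is not standardized.
    """

    arrangement: str = "lyo_rect"
    wedge_rows: tuple[int, ...] = ()
    n_rows: int = 21
    n_cols: int = 26

    def __post_init__(self) -> None:
        if self.arrangement not in ("tight_wedge", "loose_wedge", "lyo_rect"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.arrangement.endswith("wedge") and not self.wedge_rows:
            rows = (3, 4, 5, 6, 7, 7) if self.arrangement == "tight_wedge" \
                else (5, 6, 7, 8, 9, 9)
            object.__setattr__(self, "wedge_rows", rows)

    @property
    def n_vials(self) -> int:
        if self.arrangement.endswith("wedge"):
            return sum(self.wedge_rows)
        return self.n_rows * self.n_cols

    @property
    def classes(self) -> tuple[str, ...]:
        if self.arrangement == "lyo_rect":
            return ("center", "inner_edge", "edge")
        return ("center", "edge")


TIGHT_WEDGE = TrayLayout("tight_wedge")      # 32 vials
LOOSE_WEDGE = TrayLayout("loose_wedge")      # 44 vials
LYO_RECT = TrayLayout("lyo_rect")


def water_removed(record: VialRecord, clamp_negative: bool = False) -> float:
    """Water removed by sublimation, g: pre-drying gross minus post-drying gross.

    Negative values (weighing noise) are kept and logged by default;
    ``clamp_negative`` clips them to zero.
    """
    removed = record.pre_gross_g - record.post_gross_g
    if removed < 0:
        logger.warning("vial %s: negative water removed (%.4f g)",
                       record.vial_id, removed)
        if clamp_negative:
            return 0.0
    return removed


def fraction_sublimed(record: VialRecord, initial_water_mass_g: float) -> float:
    """Fraction of the initial water load removed; flagged above 1.05."""
    if initial_water_mass_g <= 0:
        raise ValueError("initial water mass must be positive")
    frac = water_removed(record) / initial_water_mass_g
    if frac > OVERSHOOT_FLAG:
        logger.warning("vial %s: fraction sublimed %.3f exceeds %.2f",
                       record.vial_id, frac, OVERSHOOT_FLAG)
    return frac


def classify_location(layout: TrayLayout, row: int, col: int) -> str:
    """Location class of a grid position.

    Wedge trays: perimeter vials (first/last row, or first/last slot of a
    row) are *edge*; everything else *center*.  Rectangular lyophilizer
    tray: perimeter is *edge*; the next ring in — non-edge vials missing a
    full 6-neighbor shell of nested vials — is *inner_edge*; the rest
    *center*.
    """
    if layout.arrangement.endswith("wedge"):
        if not 0 <= row < len(layout.wedge_rows):
            raise ValueError(f"row {row} outside wedge")
        if not 0 <= col < layout.wedge_rows[row]:
            raise ValueError(f"col {col} outside wedge row {row}")
        if row in (0, len(layout.wedge_rows) - 1):
            return "edge"
        if col in (0, layout.wedge_rows[row] - 1):
            return "edge"
        return "center"
    # lyo_rect
    if not (0 <= row < layout.n_rows and 0 <= col < layout.n_cols):
        raise ValueError(f"position ({row}, {col}) outside "
                         f"{layout.n_rows}x{layout.n_cols} tray")
    ring = min(row, col, layout.n_rows - 1 - row, layout.n_cols - 1 - col)
    if ring == 0:
        return "edge"
    if ring == 1:
        return "inner_edge"
    return "center"


def summarize_by_group(frame: pd.DataFrame, initial_water_mass_g: float,
                       layout: TrayLayout | None = None) -> pd.DataFrame:
    """Per-location summary of fraction sublimed: n, mean, SD, RSD.

    ``frame`` holds vial records (see RECORD_COLUMNS).  If ``layout`` is
    given, locations are classified from (row, col); otherwise the frame
    must already carry a ``location_class`` column.  Returns one row per
    present class plus an ``all`` row; SD uses the n-1 sample formula and
    RSD = 100 SD / mean.  Empty classes are omitted with a warning.
    """
    df = frame.copy()
    if layout is not None:
        df["location_class"] = [classify_location(layout, r, c)
                                for r, c in zip(df["row"], df["col"])]
    elif "location_class" not in df.columns:
        raise ValueError("need a layout or a location_class column")
    if "fraction_sublimed" not in df.columns:
        df["fraction_sublimed"] = (df["pre_gross_g"] - df["post_gross_g"]) \
            / initial_water_mass_g

    rows = []

    def stats(label: str, values: pd.Series) -> None:
        n = len(values)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if n > 1 else 0.0
        rsd = 100.0 * sd / mean if mean > 0 else math.nan
        rows.append((label, n, mean, sd, rsd))

    stats("all", df["fraction_sublimed"])
    for cls in LOCATION_CLASSES:
        sub = df[df["location_class"] == cls]
        if len(sub) == 0:
            if layout is not None and cls in layout.classes:
                logger.warning("no vials in class %r; omitted from summary", cls)
            continue
        stats(cls, sub["fraction_sublimed"])
    return pd.DataFrame(rows, columns=["group", "n", "mean_fraction_sublimed",
                                       "sd", "rsd_pct"])


def read_vial_records(path: str | Path) -> pd.DataFrame:
    """Read vial weighing records from delimited text, validating the schema."""
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file {path} missing columns: {sorted(missing)}")
    for rec in df.itertuples():   # validates invariants row by row
        VialRecord(str(rec.vial_id), str(rec.tray_id), int(rec.row), int(rec.col),
                   rec.tare_g, rec.pre_gross_g, rec.post_gross_g, rec.content)
    return df
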