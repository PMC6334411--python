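"""Localization-table I/O, filtering and region-of-interest splitting.

The universal currency of the toolkit is the localization table: one row per
detected emitter, carrying its fitted position (x, y) in nanometers, the
localization precision sigma (nm), and optionally a channel index, the
acquisition frame and the detected photon count.  Tables are stored as a
:class:`pandas.DataFrame` wrapped in :class:`LocalizationTable`, which
enforces the field invariants (finite coordinates, strictly positive
precision, channel >= 1).

Coordinate convention: x to the right, y up, nanometer units, origin
arbitrary per file.  ROI membership is half-open, ``[min, max)``, so abutting
rectangles partition the plane without double counting.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for tables written by :func:`write_table`
CANONICAL_COLUMNS = ["x", "y", "precision", "channel", "frame", "photons"]

REQUIRED_COLUMNS = ["x", "y", "precision"]

#: header aliases for the ThunderSTORM CSV dialect (lower-cased, stripped)
THUNDERSTORM_ALIASES: dict[str, str] = {
    "x [nm]": "x",
    "y [nm]": "y",
    "uncertainty [nm]": "precision",
    "uncertainty_xy [nm]": "precision",
    "frame": "frame",
    "intensity [photon]": "photons",
    "intensity [photons]": "photons",
    "channel": "channel",
    # "sigma [nm]" is the fitted PSF width, not a position or precision: ignored
}


class LocalizationError(ValueError):
    """Raised for malformed localization inputs (missing columns, empty files)."""


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangular region of interest, bounds in nm.

    Membership is half-open: a localization belongs to the ROI iff
    ``x_min <= x < x_max`` and ``y_min <= y < y_max``.
    """

    name: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"ROI {self.name!r}: need x_min < x_max and y_min < y_max, "
                f"got ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x_min) & (x < self.x_max) & (y >= self.y_min) & (y < self.y_max)
        )


class LocalizationTable:
    """Immutable-by-convention table of single-molecule localizations.

    Parameters
    ----------
    df
        Frame with at least columns ``x``, ``y``, ``precision`` (nm).
        Optional columns: ``channel`` (int >= 1, default 1), ``frame``
        (int >= 0), ``photons`` (float >= 0), ``id`` (stable row identifier;
        generated 0..n-1 if absent).
    validate
        Check the field invariants and raise :class:`LocalizationError` on
        violation.  Internal call sites that construct from already-valid
        data pass False.
    """

    def __init__(self, df: pd.DataFrame, *, validate: bool = True):
        df = df.reset_index(drop=True).copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise LocalizationError(f"missing required column(s): {', '.join(missing)}")
        if "channel" not in df.columns:
            df["channel"] = 1
        if "id" not in df.columns:
            df["id"] = np.arange(len(df), dtype=np.int64)
        for col in ("x", "y", "precision"):
            df[col] = df[col].astype(float)
        df["channel"] = df["channel"].astype(np.int64)
        df["id"] = df["id"].astype(np.int64)
        if "frame" in df.columns:
            df["frame"] = df["frame"].astype(np.int64)
        if "photons" in df.columns:
            df["photons"] = df["photons"].astype(float)
        if validate:
            self._check(df)
        self._df = df

    @staticmethod
    def _check(df: pd.DataFrame) -> None:
        if not np.isfinite(df["x"]).all() or not np.isfinite(df["y"]).all():
            raise LocalizationError("non-finite coordinate")
        prec = df["precision"].to_numpy()
        if not (np.isfinite(prec).all() and (prec > 0).all()):
            raise LocalizationError("precision must be finite and > 0")
        if (df["channel"] < 1).any():
            raise LocalizationError("channel must be >= 1")
        if "frame" in df.columns and (df["frame"] < 0).any():
            raise LocalizationError("frame must be >= 0")
        if "photons" in df.columns and (df["photons"] < 0).any():
            raise LocalizationError("photons must be >= 0")

    # -- accessors -------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def x(self) -> np.ndarray:
        return self._df["x"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self._df["y"].to_numpy()

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return self._df[["x", "y"]].to_numpy()

    @property
    def precision(self) -> np.ndarray:
        return self._df["precision"].to_numpy()

    @property
    def channel(self) -> np.ndarray:
        return self._df["channel"].to_numpy()

    @property
    def photons(self) -> np.ndarray | None:
        if "photons" in self._df.columns:
            return self._df["photons"].to_numpy()
        return None

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:
        chans = sorted(int(c) for c in self._df["channel"].unique()) if len(self._df) else []
        return f"LocalizationTable(n={len(self)}, channels={chans})"

    # -- derived tables --------------------------------------------------
    def select(self, mask: np.ndarray) -> "LocalizationTable":
        """Row subset preserving order and ids (no re-validation needed)."""
        return LocalizationTable(self._df.loc[np.asarray(mask, bool)], validate=False)

    def with_xy(self, x: np.ndarray, y: np.ndarray) -> "LocalizationTable":
        """Copy with replaced coordinates (used by transforms/ROI shifts)."""
        df = self._df.copy()
        df["x"] = np.asarray(x, float)
        df["y"] = np.asarray(y, float)
        return LocalizationTable(df, validate=False)

    def concat(self, other: "LocalizationTable") -> "LocalizationTable":
        df = pd.concat([self._df, other._df], ignore_index=True)
        df["id"] = np.arange(len(df), dtype=np.int64)
        return LocalizationTable(df, validate=False)

    @classmethod
    def from_arrays(
        cls,
        x: Sequence[float],
        y: Sequence[float],
        precision: Sequence[float],
        *,
        channel: Sequence[int] | int = 1,
        frame: Sequence[int] | None = None,
        photons: Sequence[float] | None = None,
    ) -> "LocalizationTable":
        data: dict[str, object] = {
            "x": np.asarray(x, float),
            "y": np.asarray(y, float),
            "precision": np.asarray(precision, float),
        }
        n = len(data["x"])  # type: ignore[arg-type]
        data["channel"] = np.full(n, channel) if np.isscalar(channel) else np.asarray(channel)
        if frame is not None:
            data["frame"] = np.asarray(frame)
        if photons is not None:
            data["photons"] = np.asarray(photons, float)
        return cls(pd.DataFrame(data))

    @classmethod
    def empty(cls) -> "LocalizationTable":
        return cls.from_arrays([], [], [])


@dataclass
class ROICollection:
    """A list of ROIs with the per-ROI localization tables in local frames.

    ``tables[i]`` holds the localizations falling in ``rois[i]`` with
    coordinates re-expressed relative to the ROI origin ``(x_min, y_min)``,
    so every point satisfies ``0 <= x < width`` and ``0 <= y < height``.
    """

    rois: list[RectROI] = field(default_factory=list)
    tables: list[LocalizationTable] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(zip(self.rois, self.tables))


# ---------------------------------------------------------------------------
# reading / writing


def _sniff_delimiter(path: str | os.PathLike, flag: str | None) -> str:
    if flag:
        return flag
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in (".tsv", ".txt") else ","


def read_table(
    path: str | os.PathLike,
    *,
    dialect: str = "generic",
    column_map: Mapping[str, str] | None = None,
    unit_scale: float = 1.0,
    delimiter: str | None = None,
) -> LocalizationTable:
    """Read a delimited localization table.

    Parameters
    ----------
    path
        CSV/TSV file with a header line.
    dialect
        ``"thunderstorm"`` auto-maps ThunderSTORM headers (``"x [nm]"``,
        ``"uncertainty [nm]"``, ...) to the canonical fields; ``"generic"``
        expects canonical names or an explicit ``column_map``.
    column_map
        Mapping from file column name to canonical field name; applied on
        top of (and overriding) the dialect aliases.
    unit_scale
        Nanometers per input unit for x, y and precision (e.g. 1000 for
        micrometer tables).  Must be > 0.
    delimiter
        Field separator; autodetected from the extension when omitted
        (``.tsv``/``.txt`` → tab, else comma).

    Returns
    -------
    LocalizationTable
        With coordinates and precision in nm.  Rows that fail numeric
        parsing or violate a field invariant (non-finite position,
        non-positive precision, ...) are dropped; the count is logged and
        exposed as ``table.n_rejected``.

    Raises
    ------
    LocalizationError
        If a required column is missing after mapping, or the file has no
        data rows.
    """
    if unit_scale <= 0:
        raise ValueError("unit_scale must be > 0")
    raw = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter))
    if raw.shape[0] == 0 and raw.shape[1] <= 1:
        raise LocalizationError(f"empty input file: {path}")

    mapping: dict[str, str] = {}
    if dialect == "thunderstorm":
        for col in raw.columns:
            key = str(col).strip().lower().replace('"', "")
            if key in THUNDERSTORM_ALIASES:
                mapping[col] = THUNDERSTORM_ALIASES[key]
    elif dialect != "generic":
        raise ValueError(f"unknown dialect: {dialect!r}")
    for col in raw.columns:
        key = str(col).strip().lower()
        if key in CANONICAL_COLUMNS and col not in mapping:
            mapping[col] = key
    if column_map:
        mapping.update(column_map)

    df = raw.rename(columns=mapping)
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LocalizationError(
            f"missing required column(s) {', '.join(missing)} in {path} "
            f"(dialect={dialect!r}; provide a column_map?)"
        )
    if len(df) == 0:
        raise LocalizationError(f"no data rows in {path}")

    n_in = len(df)
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    # optional columns left blank by a writer are absent, not malformed
    for col in ("channel", "frame", "photons"):
        if col in df.columns and df[col].isna().all():
            df = df.drop(columns=[col])
    ok = np.isfinite(df["x"]) & np.isfinite(df["y"])
    ok &= np.isfinite(df["precision"]) & (df["precision"] > 0)
    if "channel" in df.columns:
        ok &= df["channel"].notna() & (df["channel"] >= 1)
    if "frame" in df.columns:
        ok &= df["frame"].notna() & (df["frame"] >= 0)
    if "photons" in df.columns:
        ok &= df["photons"].notna() & (df["photons"] >= 0)
    df = df.loc[ok].reset_index(drop=True)
    n_rejected = n_in - len(df)
    if n_rejected:
        logger.warning("%s: rejected %d malformed row(s) of %d", path, n_rejected, n_in)

    for col in ("x", "y", "precision"):
        df[col] = df[col] * unit_scale
    table = LocalizationTable(df)
    table.n_rejected = n_rejected  # type: ignore[attr-defined]
    return table


def write_table(
    table: LocalizationTable, path: str | os.PathLike, *, delimiter: str | None = None
) -> None:
    """Write a table as delimited text with the canonical header.

    Columns are ``x,y,precision,channel,frame,photons`` (optional columns
    left blank when absent).  ``read_table`` of the written file reproduces
    all field values, so write → read is the identity.
    """
    sep = _sniff_delimiter(path, delimiter)
    out = pd.DataFrame(index=table.df.index)
    for col in CANONICAL_COLUMNS:
        out[col] = table.df[col] if col in table.df.columns else pd.NA
    out.to_csv(path, sep=sep, index=False, float_format="%.9f")


def read_rois(path: str | os.PathLike, *, delimiter: str | None = None) -> list[RectROI]:
    """Read rectangle ROIs from a CSV with columns name,x_min,y_min,x_max,y_max (nm)."""
    df = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter))
    needed = {"name", "x_min", "y_min", "x_max", "y_max"}
    if not needed.issubset(df.columns):
        raise LocalizationError(
            f"ROI file {path} must have columns {sorted(needed)}, got {list(df.columns)}"
        )
    return [
        RectROI(str(r.name), float(r.x_min), float(r.y_min), float(r.x_max), float(r.y_max))
        for r in df.itertuples(index=False)
    ]


def write_rois(rois: Sequence[RectROI], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [(r.name, r.x_min, r.y_min, r.x_max, r.y_max) for r in rois],
        columns=["name", "x_min", "y_min", "x_max", "y_max"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# filtering / splitting


def filter_table(table: LocalizationTable, **bounds) -> LocalizationTable:
    """Select rows satisfying per-field bounds, preserving row order.

    Each keyword is a field name (``x``, ``y``, ``precision``, ``channel``,
    ``frame``, ``photons``) with either a scalar (exact equality) or a
    ``(lo, hi)`` pair giving a closed interval; ``None`` endpoints are open.

    >>> filter_table(t, precision=(None, 20), channel=2)   # doctest: +SKIP
    """
    mask = np.ones(len(table), dtype=bool)
    for name, bound in bounds.items():
        if name not in table.df.columns:
            raise LocalizationError(f"unknown field for filtering: {name!r}")
        vals = table.df[name].to_numpy()
        if isinstance(bound, (tuple, list)):
            lo, hi = bound
            if lo is not None:
                mask &= vals >= lo
            if hi is not None:
                mask &= vals <= hi
        else:
            mask &= vals == bound
    return table.select(mask)


def split_by_rois(table: LocalizationTable, rois: Sequence[RectROI]) -> ROICollection:
    """Split a table into per-ROI tables in ROI-local coordinates.

    A localization belongs to ROI *i* iff ``x_min <= x < x_max`` and
    ``y_min <= y < y_max``; overlapping ROIs duplicate shared localizations
    into each.  Coordinates are shifted so the ROI origin is (0, 0).
    """
    x, y = table.x, table.y
    tables = []
    for roi in rois:
        sub = table.select(roi.contains(x, y))
        tables.append(sub.with_xy(sub.x - roi.x_min, sub.y - roi.y_min))
    return ROICollection(rois=list(rois), tables=tables)
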