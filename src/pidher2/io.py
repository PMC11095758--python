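"""Raster and table IO shared by every pipeline stage.

Conventions used throughout the package: rasters are row-major with origin
at the top-left and 0-based pixel indices; all physical lengths are in
micrometres; DAB IHC categories are serialised exactly as ``"0"``, ``"1+"``,
``"2+"``, ``"3+"``. Tissue-microarray core positions are labelled by row
letter plus 1-based column number (``"A5"``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

DAB_CLASSES = ("0", "1+", "2+", "3+")
EXCLUSION_REASONS = ("none", "dcis", "fixation", "cytoplasmic", "no_cancer", "peeling")

_CORE_ID_RE = re.compile(r"^([A-Z])([1-9][0-9]*)$")


class FormatError(ValueError):
    """An input file does not have the expected layout."""


class IntegrityError(ValueError):
    """A table violates a structural constraint (e.g. duplicate core ids)."""


@dataclass
class CoreImage:
    """One TMA core's fluorescence raster with its physical pixel size."""

    intensities: np.ndarray  # 2-D, nonnegative, arbitrary fluorescence units
    pixel_size_um: float
    core_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2 or self.intensities.size == 0:
            raise FormatError(f"core image must be a non-empty 2-D raster, got shape {self.intensities.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if np.any(self.intensities < 0):
            raise ValueError("fluorescence intensities must be nonnegative")


@dataclass
class InvasiveMask:
    """Binary raster marking the pathologist-annotated invasive-cancer region."""

    mask: np.ndarray  # 2-D boolean
    core_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2 or self.mask.size == 0:
            raise FormatError(f"mask must be a non-empty 2-D raster, got shape {self.mask.shape}")


@dataclass
class CoreRecord:
    """Per-core metadata and computed quantities carried through the pipeline."""

    core_id: str
    case_id: int | None = None
    dab_score_p1: str | None = None
    dab_score_p2: str | None = None
    dab_consensus: str | None = None
    exclusion_reason: str = "none"
    is_negative_control: bool = False
    pid_value: float | None = None
    pid_score: str | None = None
    ultra_low_flag: bool | None = None
    n_tiles: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(
                f"unknown exclusion reason {self.exclusion_reason!r} for core {self.core_id}; "
                f"expected one of {EXCLUSION_REASONS}"
            )
        for name in ("dab_score_p1", "dab_score_p2", "dab_consensus", "pid_score"):
            val = getattr(self, name)
            if val is not None and val not in DAB_CLASSES:
                raise ValueError(f"{name}={val!r} for core {self.core_id}: expected one of {DAB_CLASSES}")
        if self.pid_score is not None and self.pid_value is None:
            raise ValueError(f"core {self.core_id}: pid_score present without pid_value")


def parse_core_id(label: str) -> tuple[int, int]:
    """Parse a TMA position label into 1-based (row, column).

    ``"A5" -> (1, 5)``; ``"M16" -> (13, 16)``.
    """
    m = _CORE_ID_RE.match(str(label).strip())
    if m is None:
        raise ValueError(f"malformed core id {label!r}: expected letter A-Z followed by a positive integer")
    return ord(m.group(1)) - ord("A") + 1, int(m.group(2))


def read_core_image(path: str | Path, pixel_size_um: float | None = None, core_id: str = "") -> CoreImage:
    """Read a single-channel grayscale TIFF core image.

    The pixel size is taken from the ``pixel_size_um`` argument when given,
    otherwise from the TIFF resolution tags; supplying neither is an error.
    Integer inputs are loaded losslessly.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        if pixel_size_um is None:
            pixel_size_um = _pixel_size_from_tags(page)
    if arr.ndim != 2 or arr.size == 0:
        raise FormatError(f"{path}: expected a non-empty single-channel grayscale raster, got shape {arr.shape}")
    if pixel_size_um is None:
        raise ValueError(f"{path}: no pixel size given and none found in the TIFF resolution tags")
    if not core_id:
        core_id = path.stem
    return CoreImage(intensities=arr, pixel_size_um=float(pixel_size_um), core_id=core_id)


def _pixel_size_from_tags(page) -> float | None:
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    num, den = xres if isinstance(xres, tuple) else (xres, 1)
    if num == 0:
        return None
    per_unit = num / den  # pixels per unit
    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))  # inch, centimetre
    if unit_um is None:
        return None
    return unit_um / per_unit


def write_core_image(path: str | Path, image: CoreImage) -> np.ndarray:
    """Write a core image as 16-bit unsigned grayscale TIFF.

    Intensities are rounded; values above 65535 saturate at the format
    maximum with a warning. Pixel size is embedded as resolution tags
    (pixels per centimetre). Returns the array actually written.
    """
    data = np.round(np.asarray(image.intensities, dtype=float))
    if np.any(data > 65535):
        warnings.warn(
            f"core {image.core_id or path}: {int(np.sum(data > 65535))} pixel(s) exceed 65535 "
            "and saturate at the 16-bit maximum",
            stacklevel=2,
        )
    data = np.clip(data, 0, 65535).astype(np.uint16)
    px_per_cm = 10000.0 / image.pixel_size_um
    tifffile.imwrite(path, data, resolution=(px_per_cm, px_per_cm), resolutionunit="CENTIMETER")
    return data


def read_mask(path: str | Path, core_id: str = "") -> InvasiveMask:
    """Read a binary mask from PNG or TIFF: any strictly positive pixel is true."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # palette/RGB export of a binary mask
        arr = arr.max(axis=2)
    if not core_id:
        core_id = path.stem
    return InvasiveMask(mask=arr > 0, core_id=core_id)


def write_mask(path: str | Path, mask: InvasiveMask) -> None:
    """Write a binary mask as 8-bit PNG or TIFF (true -> 255)."""
    path = Path(path)
    data = (mask.mask.astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        Image.fromarray(data).save(path)


_RECORD_COLUMNS = (
    "core_id",
    "case_id",
    "dab_score_p1",
    "dab_score_p2",
    "dab_consensus",
    "exclusion_reason",
    "is_negative_control",
    "pid_value",
    "pid_score",
    "ultra_low_flag",
    "n_tiles",
)

_RESULT_COLUMNS = (
    "core_id",
    "case_id",
    "dab_consensus",
    "exclusion_reason",
    "n_tiles",
    "pid_value",
    "pid_score",
    "ultra_low_flag",
)


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_cohort_table(path: str | Path) -> list[CoreRecord]:
    """Read a cohort table (CSV or XLSX) into :class:`CoreRecord` objects.

    Empty cells map to missing values, never to zero. Columns beyond the
    known schema are preserved in each record's ``extra`` dict so they can
    be written through unchanged.
    """
    path = Path(path)
    df = _read_table(path)
    df.columns = [str(c).strip() for c in df.columns]
    if "core_id" not in df.columns:
        raise FormatError(f"{path}: cohort table must contain a core_id column, found {list(df.columns)}")
    dupes = df["core_id"][df["core_id"].duplicated()].tolist()
    if dupes:
        raise IntegrityError(f"{path}: duplicate core_id values: {sorted(set(map(str, dupes)))}")
    records = []
    extra_cols = [c for c in df.columns if c not in _RECORD_COLUMNS]
    for _, row in df.iterrows():
        kwargs: dict = {"core_id": str(row["core_id"]).strip()}
        for col in _RECORD_COLUMNS[1:]:
            if col not in df.columns or pd.isna(row[col]):
                continue
            val = row[col]
            if col == "case_id":
                kwargs[col] = int(val)
            elif col in ("is_negative_control", "ultra_low_flag"):
                kwargs[col] = _parse_bool(val)
            elif col == "pid_value":
                kwargs[col] = float(val)
            elif col == "n_tiles":
                kwargs[col] = int(val)
            else:
                s = str(val).strip()
                if s.endswith(".0"):  # numeric "0" read as float by the table parser
                    s = s[:-2]
                kwargs[col] = s
        extra = {c: row[c] for c in extra_cols if not pd.isna(row[c])}
        records.append(CoreRecord(**kwargs, extra=extra))
    return records


def _parse_bool(val) -> bool:
    if isinstance(val, (bool, np.bool_)):
        return bool(val)
    s = str(val).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot interpret {val!r} as a boolean")


def records_to_frame(records: list[CoreRecord], columns=_RECORD_COLUMNS) -> pd.DataFrame:
    """Tabulate records in deterministic column order, rows in TMA-map order."""
    rows = []
    for rec in records:
        row = {col: getattr(rec, col) for col in columns}
        row.update(rec.extra)
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values("core_id", key=lambda s: s.map(parse_core_id)).reset_index(drop=True)
    return df


def write_cohort_table(path: str | Path, records: list[CoreRecord]) -> None:
    """Write the full cohort schema plus any extra columns as CSV."""
    records_to_frame(records).to_csv(path, index=False)


def write_results(path: str | Path, records: list[CoreRecord]) -> None:
    """Write the per-core results table (CSV).

    Columns: ``core_id,case_id,dab_consensus,exclusion_reason,n_tiles,
    pid_value,pid_score,ultra_low_flag`` plus preserved extras; rows sorted
    by TMA position (row-major A1, A2, ...).
    """
    records_to_frame(records, columns=_RESULT_COLUMNS).to_csv(path, index=False)
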