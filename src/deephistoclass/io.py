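"""Reading and writing images, annotation tables and prediction tables.

On-disk contracts
-----------------
Annotation table (wide, one row per image): columns ``image_id``, ``split``,
optional ``protein_id`` / ``antibody_id``, and per cell type
``<celltype>_intensity`` (integer 0..3: negative, weak, moderate, strong) and
``<celltype>_location`` (``+``-joined subset of cytoplasm/nucleus/membrane,
empty for none).  This mirrors the per-antibody manual scoring sheet.

Prediction table (long, one row per image x cell type): predictive mean,
plug-in and jackknife entropies, CPPD, raw and normalized DHC score, the
binarized call and the manual label when known.  Floats are written at full
round-trip precision with a ``.`` decimal separator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .config import CELL_TYPES, LOCATIONS
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

SPLITS = ("train", "validation", "test", "external")


@dataclass
class AnnotationEntry:
    """Manual annotation of one cell type in one image."""

    intensity: int                      # 0 negative, 1 weak, 2 moderate, 3 strong
    locations: frozenset = frozenset()  # subset of LOCATIONS

    def __post_init__(self) -> None:
        self.locations = frozenset(self.locations)
        if self.intensity not in (0, 1, 2, 3):
            raise ValidationError(f"intensity must be in 0..3, got {self.intensity}")
        bad = self.locations - set(LOCATIONS)
        if bad:
            raise ValidationError(f"unknown subcellular locations: {sorted(bad)}")
        if (self.intensity == 0) != (len(self.locations) == 0):
            raise ValidationError(
                "intensity 0 must have no locations and intensity >0 must have "
                f"at least one (intensity={self.intensity}, "
                f"locations={sorted(self.locations)})"
            )

    @property
    def positive(self) -> bool:
        return self.intensity > 0


@dataclass
class LabeledImage:
    """One IHC image with its per-cell-type manual annotation.

    ``pixels`` may be None for metadata-only records (table reads); call
    :func:`load_image` to populate it.
    """

    image_id: str
    pixels: np.ndarray | None = None
    protein_id: str | None = None
    antibody_id: str | None = None
    split: str = "train"
    annotations: dict = field(default_factory=dict)
    cell_types: tuple = CELL_TYPES

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ValidationError(f"split must be one of {SPLITS}, got {self.split!r}")
        if self.pixels is not None:
            self.pixels = validate_pixels(self.pixels)
        if self.annotations:
            missing = set(self.cell_types) - set(self.annotations)
            extra = set(self.annotations) - set(self.cell_types)
            if missing or extra:
                raise ValidationError(
                    f"annotations must cover exactly the configured cell types; "
                    f"missing={sorted(missing)}, unknown={sorted(extra)}"
                )

    def label_vector(self) -> np.ndarray:
        """Binary label vector: positive iff intensity >= 1, in vocabulary order."""
        return np.array(
            [int(self.annotations[c].positive) for c in self.cell_types], dtype=np.int8
        )

    def intensity_vector(self) -> np.ndarray:
        return np.array(
            [self.annotations[c].intensity for c in self.cell_types], dtype=np.int8
        )


def validate_pixels(pixels: np.ndarray) -> np.ndarray:
    """Coerce an image array to 8-bit RGB, enforcing the size invariant."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValidationError(f"expected HxWx3 RGB array, got shape {pixels.shape}")
    if pixels.shape[0] < 32 or pixels.shape[1] < 32:
        raise ValidationError(f"image sides must be >= 32, got {pixels.shape[:2]}")
    if pixels.dtype == np.uint8:
        return pixels
    if pixels.dtype == np.uint16:
        logger.warning("rescaling 16-bit image linearly to 8-bit")
        return (pixels.astype(np.float64) / 257.0).round().astype(np.uint8)
    if np.issubdtype(pixels.dtype, np.integer):
        return np.clip(pixels, 0, 255).astype(np.uint8)
    raise ValidationError(f"unsupported pixel dtype {pixels.dtype}")


# ---------------------------------------------------------------------------
# annotation tables

def _location_str(locations) -> str:
    # canonical order for determinism
    return "+".join(l for l in LOCATIONS if l in locations)


def _parse_locations(raw, row: int) -> frozenset:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return frozenset()
    raw = str(raw).strip()
    if not raw:
        return frozenset()
    parts = [p.strip() for p in raw.split("+") if p.strip()]
    bad = set(parts) - set(LOCATIONS)
    if bad:
        raise ValidationError(f"row {row}: unknown locations {sorted(bad)}")
    return frozenset(parts)


def read_annotation_table(path, dialect: str | None = None,
                          cell_types: tuple = CELL_TYPES) -> list[LabeledImage]:
    """Read a wide annotation table; returns metadata records (pixels unloaded).

    ``dialect`` is ``"csv"`` or ``"tsv"``; by default it is inferred from the
    file extension (``.csv`` -> comma, otherwise tab).
    """
    sep = {"csv": ",", "tsv": "\t"}.get(
        dialect or ("csv" if str(path).endswith(".csv") else "tsv"))
    if sep is None:
        raise FormatError(f"unknown table dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc

    required = ["image_id", "split"] + [f"{c}_intensity" for c in cell_types] \
        + [f"{c}_location" for c in cell_types]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    known_prefixes = set(cell_types)
    for col in df.columns:
        for suffix in ("_intensity", "_location"):
            if col.endswith(suffix) and col[: -len(suffix)] not in known_prefixes:
                raise FormatError(
                    f"{path}: column {col!r} names a cell type outside the "
                    f"configured vocabulary"
                )

    records: list[LabeledImage] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        annotations = {}
        for c in cell_types:
            raw_int = str(row[f"{c}_intensity"]).strip()
            try:
                intensity = int(raw_int)
            except ValueError:
                raise ValidationError(
                    f"row {i}: intensity {raw_int!r} for {c} is not an integer")
            if intensity not in (0, 1, 2, 3):
                raise ValidationError(
                    f"row {i}: intensity {intensity} for {c} outside 0..3")
            locations = _parse_locations(row[f"{c}_location"], i)
            try:
                annotations[c] = AnnotationEntry(intensity, locations)
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
        records.append(LabeledImage(
            image_id=row["image_id"],
            protein_id=row.get("protein_id") or None,
            antibody_id=row.get("antibody_id") or None,
            split=row["split"],
            annotations=annotations,
            cell_types=tuple(cell_types),
        ))
    return records


def write_annotation_table(records: list[LabeledImage], path,
                           dialect: str | None = None) -> None:
    """Write the wide annotation table (inverse of :func:`read_annotation_table`)."""
    sep = {"csv": ",", "tsv": "\t"}.get(
        dialect or ("csv" if str(path).endswith(".csv") else "tsv"))
    if sep is None:
        raise FormatError(f"unknown table dialect {dialect!r}")
    rows = []
    for rec in records:
        row = {"image_id": rec.image_id, "split": rec.split,
               "protein_id": rec.protein_id or "", "antibody_id": rec.antibody_id or ""}
        for c in rec.cell_types:
            a = rec.annotations[c]
            row[f"{c}_intensity"] = a.intensity
            row[f"{c}_location"] = _location_str(a.locations)
        rows.append(row)
    cols = ["image_id", "split", "protein_id", "antibody_id"]
    ct = records[0].cell_types if records else CELL_TYPES
    for c in ct:
        cols += [f"{c}_intensity", f"{c}_location"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# prediction tables

PREDICTION_COLUMNS = (
    "image_id", "cell_type", "mu", "H_plugin", "H_jackknife", "mi_jackknife",
    "mutual_info", "cppd", "dhc_raw", "dhc_normalized", "call", "manual_label",
)


def write_prediction_table(records: pd.DataFrame, path) -> None:
    """Write the long per-(image, cell type) prediction/uncertainty table.

    Floats use Python's shortest round-trip representation, so a read-back
    reproduces them bit-identically; the decimal separator is always ``.``.
    """
    df = records.copy()
    for col in PREDICTION_COLUMNS:
        if col not in df.columns:
            if col == "manual_label" or df.empty:
                df[col] = ""
            else:
                raise ValidationError(f"prediction table missing column {col!r}")
    df = df[list(PREDICTION_COLUMNS)]
    df.to_csv(path, sep="\t", index=False)


def read_prediction_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"image_id": str, "cell_type": str},
                     float_precision="round_trip")
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing prediction columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# images

def load_image(path) -> np.ndarray:
    """Decode an image file (JPEG/PNG/TIFF) into an 8-bit RGB array."""
    try:
        with Image.open(path) as img:
            img = img.convert("RGB")
            pixels = np.asarray(img)
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise FormatError(f"{path} is not a decodable image: {exc}") from exc
    return validate_pixels(pixels)


def save_image(pixels: np.ndarray, path) -> None:
    Image.fromarray(validate_pixels(pixels)).save(path)


def resize_image(pixels: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bicubic resize to ``target`` (side, side); identity when already there.

    Values are clipped to [0, 255] (cubic interpolation can overshoot) and
    returned as uint8.
    """
    pixels = validate_pixels(pixels)
    side_y, side_x = int(target[0]), int(target[1])
    if side_y < 32 or side_x < 32:
        raise ValidationError(f"resize target must be >= 32, got {target}")
    if pixels.shape[:2] == (side_y, side_x):
        return pixels.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anti-aliasing notices on upsampling
        out = _sk_resize(pixels.astype(np.float64), (side_y, side_x, 3),
                         order=3, mode="reflect", anti_aliasing=True,
                         preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
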