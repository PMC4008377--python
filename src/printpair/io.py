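"""Reading and writing prints, masks, annotations and examiner trial tables.

Conventions used throughout the package:

* images are 2-D ``uint8`` arrays, intensities in ``[0, 255]`` with 0 the
  darkest value — ridges are dark, valleys/background bright; images are
  never auto-inverted;
* coordinates are ``(row, col)``, 0-based;
* segmentation masks are boolean rasters of the same shape as the image,
  ``True`` inside the fingerprint region (on disk: PNG, nonzero = inside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

#: canonical column order of a trial table on disk
TRIAL_COLUMNS = [
    "pair_id",
    "expert_id",
    "is_match",
    "judged_match",
    "difficulty",
    "confidence",
    "response_time",
    "timed_out",
]


class MaskShapeError(ValueError):
    """Image and segmentation mask do not share a shape."""


class EmptyMaskError(ValueError):
    """A segmentation mask contains no in-print pixel."""


@dataclass
class PrintImage:
    """A single fingerprint raster with its role in a comparison pair."""

    pixels: np.ndarray  # uint8, (H, W)
    role: str  # "latent" or "known"
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(f"print {self.id!r}: pixels must be a nonempty 2-D array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError(f"print {self.id!r}: intensities outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.role not in ("latent", "known"):
            raise ValueError(f"print {self.id!r}: role must be 'latent' or 'known'")


@dataclass
class SegmentationMask:
    """Boolean in-print mask paired with a :class:`PrintImage`."""

    mask: np.ndarray  # bool, same shape as the image

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class GlobalFeatureAnnotation:
    """Presence of level-I singularities (core, delta) in one print."""

    core_present: bool = False
    delta_present: bool = False
    core_type: str | None = None

    _CORE_TYPES = ("arch", "tented-arch", "left-loop", "right-loop", "whorl")

    def __post_init__(self) -> None:
        if self.core_type is not None:
            if not self.core_present:
                raise ValueError("core_type set while core_present is False")
            if self.core_type not in self._CORE_TYPES:
                raise ValueError(f"unknown core_type {self.core_type!r}")


@dataclass
class TrialTable:
    """Long-format table of per-(pair, expert) comparison outcomes.

    ``correct`` is derived as ``judged_match == is_match``; difficulty and
    confidence are 1–6 Likert ratings and may be missing for trials where
    the decision was entered but time expired before the ratings.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.data
        if len(df):
            dup = df.duplicated(subset=["pair_id", "expert_id"])
            if dup.any():
                bad = df.loc[dup, ["pair_id", "expert_id"]].iloc[0]
                raise ValueError(
                    f"duplicate trial for pair {bad.pair_id!r}, expert {bad.expert_id!r}"
                )
            for col in ("difficulty", "confidence"):
                vals = df[col].dropna()
                if len(vals) and ((vals < 1) | (vals > 6)).any():
                    raise ValueError(f"{col} ratings must lie in 1–6")

    def __len__(self) -> int:
        return len(self.data)


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Cast an image array onto [0, 255].

    8-bit input is passed through untouched; wider integer or float input is
    linearly mapped so the array maximum lands on 255 (a blank image maps
    to 0).
    """
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    top = arr.max()
    if top <= 0:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.rint(arr * (255.0 / top)).astype(np.uint8)


def read_print(
    image_path: str | Path,
    mask_path: str | Path,
    role: str,
    id: str | None = None,
) -> tuple[PrintImage, SegmentationMask]:
    """Read a grayscale print image and its segmentation mask.

    Raises :class:`MaskShapeError` on a shape mismatch and
    :class:`EmptyMaskError` when the mask has no in-print pixel.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    print_id = id if id is not None else image_path.stem

    with Image.open(image_path) as im:
        if im.mode not in ("L", "I", "I;16", "F"):
            im = im.convert("L")
        pixels = _to_uint8(np.asarray(im))
    with Image.open(mask_path) as mm:
        mask = np.asarray(mm.convert("L")) > 0

    if mask.shape != pixels.shape:
        raise MaskShapeError(
            f"print {print_id!r}: image shape {pixels.shape} != mask shape {mask.shape}"
        )
    if not mask.any():
        raise EmptyMaskError(f"print {print_id!r}: segmentation mask is empty")
    return PrintImage(pixels, role=role, id=print_id), SegmentationMask(mask)


def write_print(
    image: PrintImage,
    mask: SegmentationMask,
    image_path: str | Path,
    mask_path: str | Path,
) -> None:
    """Write an image and mask as 8-bit grayscale PNGs (lossless round-trip)."""
    Image.fromarray(image.pixels, mode="L").save(image_path)
    Image.fromarray(np.where(mask.mask, 255, 0).astype(np.uint8), mode="L").save(mask_path)


def read_annotations(path: str | Path) -> dict[str, GlobalFeatureAnnotation]:
    """Read per-print core/delta annotations from a CSV (id, role, core_present, ...)."""
    df = pd.read_csv(path)
    out: dict[str, GlobalFeatureAnnotation] = {}
    for row in df.itertuples(index=False):
        core_type = getattr(row, "core_type", None)
        if isinstance(core_type, float) and np.isnan(core_type):
            core_type = None
        out[str(row.id)] = GlobalFeatureAnnotation(
            core_present=bool(row.core_present),
            delta_present=bool(row.delta_present),
            core_type=core_type,
        )
    return out


def write_annotations(ann: dict[str, GlobalFeatureAnnotation], path: str | Path) -> None:
    rows = [
        {
            "id": k,
            "core_present": a.core_present,
            "delta_present": a.delta_present,
            "core_type": a.core_type,
        }
        for k, a in ann.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trials(csv_path: str | Path) -> TrialTable:
    """Read an examiner response table, applying the trial-exclusion rule.

    A trial is retained iff the examiner entered a match/non-match decision
    before time expired; timed-out trials without a decision are dropped.
    Trials with a decision but missing difficulty/confidence ratings are
    retained with the ratings left missing. Counts of both are logged.
    """
    csv_path = Path(csv_path)
    try:
        df = pd.read_csv(csv_path)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=TRIAL_COLUMNS)
    if df.empty:
        logger.warning("trial table %s is empty", csv_path)
        df = df.reindex(columns=TRIAL_COLUMNS)

    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing trial columns {missing}")

    n_total = len(df)
    # no decision recorded before timeout -> excluded
    no_decision = df["judged_match"].isna()
    dropped = int(no_decision.sum())
    df = df.loc[~no_decision].copy()

    for col in ("is_match", "judged_match"):
        df[col] = df[col].astype(bool)
    for col in ("difficulty", "confidence"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["timed_out"] = df["timed_out"].fillna(False).astype(bool)
    df["correct"] = (df["judged_match"] == df["is_match"]).astype(int)

    n_norating = int(df[["difficulty", "confidence"]].isna().any(axis=1).sum())
    logger.info(
        "read %d trials from %s: %d excluded (no decision), %d retained, "
        "%d retained without full ratings",
        n_total, csv_path, dropped, len(df), n_norating,
    )
    return TrialTable(df.reset_index(drop=True))


def write_trials(table: TrialTable, csv_path: str | Path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in table.data.columns]
    table.data.to_csv(csv_path, index=False, columns=cols)
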