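"""Image-quality and information metrics for latent/known print pairs.

Single-print metrics
--------------------
* **total area** — number of segmented (in-mask) pixels;
* **image intensity** — mean and population SD of in-mask intensities;
* **block intensity SD** — SD of per-block mean intensities over 50×50
  blocks anchored at the mask bounding box;
* **DEAI** — deviation from expected average intensity,
  ``-(|mean - 127.5|)``; 0 is best (equal dark/bright balance);
* **Michelson contrast** — ``(Imax - Imin) / (Imax + Imin)`` over the
  segmented region;
* **block contrast** — mean and SD of per-block Michelson contrast;
* **ridge reliability** — fraction of analysis windows whose dominant ridge
  orientation is uniquely determined by an oriented (Gabor) filter bank.

Pair metrics
------------
* **area ratio** — latent area / known area (may exceed 1);
* **ridge reliability sum** — Euclidean norm ``sqrt(rL² + rK²)``;
* latent×known interaction terms built from standardized mains.

Blocks and windows are anchored at the top-left of the mask bounding box,
which makes every metric invariant to translating the print (with its mask)
within the canvas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

from .io import EmptyMaskError, GlobalFeatureAnnotation, PrintImage, SegmentationMask

logger = logging.getLogger(__name__)

EXPECTED_MEAN_INTENSITY = 127.5  # half of [0, 255]: ideal dark/bright balance


# ---------------------------------------------------------------------------
# elementary metrics


def total_area(mask: np.ndarray | SegmentationMask) -> int:
    """Number of pixels inside the segmented fingerprint region."""
    m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    n = int(m.sum())
    if n == 0:
        raise EmptyMaskError("segmentation mask is empty")
    return n


def area_ratio(latent_mask, known_mask) -> float:
    """Latent area divided by known area; legitimately may exceed 1."""
    return total_area(latent_mask) / total_area(known_mask)


def intensity_stats(image, mask) -> tuple[float, float]:
    """Population mean and SD of intensity over in-mask pixels."""
    px = _inmask_pixels(image, mask)
    return float(px.mean()), float(px.std())


def deai(image, mask) -> float:
    """Deviation from expected average intensity: ``-(|mean - 127.5|)``.

    Always nonpositive; the maximum 0 is attained when dark and bright
    pixels balance exactly.
    """
    mean, _ = intensity_stats(image, mask)
    return -abs(mean - EXPECTED_MEAN_INTENSITY)


def michelson(image, mask) -> float:
    """Michelson contrast ``(Imax - Imin) / (Imax + Imin)`` over in-mask pixels."""
    px = _inmask_pixels(image, mask)
    hi, lo = float(px.max()), float(px.min())
    if hi == 0.0:
        warnings.warn("all in-mask pixels are 0; Michelson contrast defined as 0")
        return 0.0
    return (hi - lo) / (hi + lo)


def ridge_sum(r_latent: float, r_known: float) -> float:
    """Euclidean sum of the latent and known ridge reliabilities."""
    return float(np.hypot(r_latent, r_known))


def _inmask_pixels(image, mask) -> np.ndarray:
    img = image.pixels if isinstance(image, PrintImage) else np.asarray(image)
    m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    if img.shape != m.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {m.shape}")
    px = img[m].astype(np.float64)
    if px.size == 0:
        raise EmptyMaskError("segmentation mask is empty")
    return px


# ---------------------------------------------------------------------------
# block statistics


def block_partition(
    mask, block_size: int = 50, min_coverage: float = 0.5
) -> list[tuple[slice, slice]]:
    """Tile the mask bounding box into ``block_size``² blocks.

    Blocks are anchored at the bounding-box top-left. A block is retained
    iff its in-mask pixel count is at least ``min_coverage`` of a *full*
    block (so edge slivers never dominate block statistics).
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise EmptyMaskError("segmentation mask is empty")
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1

    need = min_coverage * block_size * block_size
    blocks: list[tuple[slice, slice]] = []
    for br in range(r0, r1, block_size):
        for bc in range(c0, c1, block_size):
            rs = slice(br, min(br + block_size, m.shape[0]))
            cs = slice(bc, min(bc + block_size, m.shape[1]))
            if m[rs, cs].sum() >= need:
                blocks.append((rs, cs))
    if not blocks:
        raise EmptyMaskError(
            f"no block reaches {min_coverage:.0%} in-mask coverage "
            f"(mask area {rows.size}, block size {block_size})"
        )
    return blocks


def block_intensity_sd(image, mask, block_size: int = 50) -> float:
    """SD across per-block mean intensities; NaN (with a warning) below 2 blocks."""
    img = image.pixels if isinstance(image, PrintImage) else np.asarray(image)
    m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    blocks = block_partition(m, block_size)
    if len(blocks) < 2:
        warnings.warn("fewer than 2 blocks: block-intensity SD undefined")
        return float("nan")
    means = [img[rs, cs][m[rs, cs]].astype(np.float64).mean() for rs, cs in blocks]
    return float(np.std(means))


def block_contrast(image, mask, block_size: int = 50) -> tuple[float, float]:
    """Mean and SD of per-block Michelson contrast over retained blocks.

    The mean is defined from one block; the SD needs two and is NaN (with a
    warning) otherwise.
    """
    img = image.pixels if isinstance(image, PrintImage) else np.asarray(image)
    m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    blocks = block_partition(m, block_size)
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero blocks contribute contrast 0
        for rs, cs in blocks:
            vals.append(michelson(img[rs, cs], m[rs, cs]))
    mean = float(np.mean(vals))
    if len(vals) < 2:
        warnings.warn("fewer than 2 blocks: block-contrast SD undefined")
        return mean, float("nan")
    return mean, float(np.std(vals))


# ---------------------------------------------------------------------------
# ridge reliability


@dataclass(frozen=True)
class RidgeReliabilityParams:
    """Tunables of the oriented-filter reliability operator.

    ``wavelength`` is the expected ridge period in pixels; ``sigma`` the
    isotropic Gaussian envelope of the even-symmetric Gabor filters;
    ``n_orientations`` filters span [0, π). A window is *high reliability*
    when the top orientation energy is at least ``dominance_ratio`` times
    the strongest non-adjacent competitor and carries at least
    ``energy_fraction`` of the maximum energy an in-range image could
    produce in that window.
    """

    window: int = 16
    n_orientations: int = 8
    wavelength: float = 9.0
    sigma: float = 4.0
    dominance_ratio: float = 1.5
    energy_fraction: float = 0.01
    min_coverage: float = 0.5


def _gabor_bank(params: RidgeReliabilityParams) -> list[np.ndarray]:
    kernels = []
    for k in range(params.n_orientations):
        theta = k * np.pi / params.n_orientations
        g = np.real(
            gabor_kernel(
                frequency=1.0 / params.wavelength,
                theta=theta,
                sigma_x=params.sigma,
                sigma_y=params.sigma,
            )
        )
        g = g - g.mean()  # zero DC response
        kernels.append(g)
    return kernels


def ridge_reliability(
    image, mask, params: RidgeReliabilityParams | None = None
) -> float:
    """Proportion of analysis windows with uniquely specified ridge orientation.

    The image is filtered with a bank of even-symmetric oriented Gabor
    filters; per window the squared filter responses are summed into one
    energy per orientation. A window counts as high reliability when its
    dominant orientation is unique: the top energy exceeds the noise floor
    (``energy_fraction`` of the window's maximum attainable energy) and is
    ``dominance_ratio`` times the strongest orientation not adjacent to the
    winner. Adjacent-channel energy is excluded from the competition
    because a discrete bank necessarily splits a single ridge flow across
    neighbouring orientation channels.
    """
    if params is None:
        params = RidgeReliabilityParams()
    img = image.pixels if isinstance(image, PrintImage) else np.asarray(image)
    m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    if img.shape != m.shape:
        raise ValueError("image/mask shape mismatch")
    if not m.any():
        raise EmptyMaskError("segmentation mask is empty")

    windows = block_partition(m, params.window, params.min_coverage)

    # suppress mask-boundary edges: out-of-mask pixels take the in-mask mean
    signal = img.astype(np.float64)
    signal[~m] = signal[m].mean()

    kernels = _gabor_bank(params)
    responses = [fftconvolve(signal, k, mode="same") for k in kernels]

    n_orient = params.n_orientations
    win_area = params.window * params.window
    # energy bound for intensities within +-127.5 of the filter's DC-free mean
    gains = [np.abs(k).sum() for k in kernels]
    e_max = win_area * (EXPECTED_MEAN_INTENSITY * max(gains)) ** 2
    floor = params.energy_fraction * e_max

    n_high = 0
    for rs, cs in windows:
        energies = np.array([float((r[rs, cs] ** 2).sum()) for r in responses])
        top = int(energies.argmax())
        if energies[top] < floor:
            continue
        rivals = [
            energies[j]
            for j in range(n_orient)
            if j not in (top, (top - 1) % n_orient, (top + 1) % n_orient)
        ]
        if not rivals or energies[top] >= params.dominance_ratio * max(rivals):
            n_high += 1
    return n_high / len(windows)


# ---------------------------------------------------------------------------
# per-print bundle


@dataclass
class SinglePrintMetrics:
    """All single-print predictor variables for one segmented print."""

    total_area: int
    mean_intensity: float
    sd_intensity: float
    sd_block_intensity: float
    deai: float
    michelson: float
    mean_block_contrast: float
    sd_block_contrast: float
    ridge_reliability: float
    core_present: bool = False
    delta_present: bool = False


def compute_print_metrics(
    image,
    mask,
    annotation: GlobalFeatureAnnotation | None = None,
    block_size: int = 50,
    reliability_params: RidgeReliabilityParams | None = None,
) -> SinglePrintMetrics:
    """Compute every single-print metric on one segmented print."""
    mean, sd = intensity_stats(image, mask)
    bc_mean, bc_sd = block_contrast(image, mask, block_size)
    ann = annotation or GlobalFeatureAnnotation()
    return SinglePrintMetrics(
        total_area=total_area(mask),
        mean_intensity=mean,
        sd_intensity=sd,
        sd_block_intensity=block_intensity_sd(image, mask, block_size),
        deai=deai(image, mask),
        michelson=michelson(image, mask),
        mean_block_contrast=bc_mean,
        sd_block_contrast=bc_sd,
        ridge_reliability=ridge_reliability(image, mask, reliability_params),
        core_present=ann.core_present,
        delta_present=ann.delta_present,
    )


# ---------------------------------------------------------------------------
# pair feature assembly

#: continuous single-print metrics measured on both prints of a pair
PAIRED_CONTINUOUS = (
    "total_area",
    "mean_intensity",
    "sd_intensity",
    "sd_block_intensity",
    "deai",
    "michelson",
    "mean_block_contrast",
    "sd_block_contrast",
    "ridge_reliability",
)
PAIRED_BINARY = ("core", "delta")
RELATIONAL = ("area_ratio", "ridge_sum")


def pair_record(
    pair_id: str, latent: SinglePrintMetrics, known: SinglePrintMetrics
) -> dict:
    """Raw (unstandardized) feature row for one latent–known pair."""
    row: dict = {"pair_id": pair_id}
    for name, m in (("L", latent), ("K", known)):
        d = asdict(m)
        for col in PAIRED_CONTINUOUS:
            row[f"{col}_{name}"] = d[col]
        row[f"core_{name}"] = int(d["core_present"])
        row[f"delta_{name}"] = int(d["delta_present"])
    row["area_ratio"] = latent.total_area / known.total_area
    row["ridge_sum"] = ridge_sum(latent.ridge_reliability, known.ridge_reliability)
    return row


class FeatureStandardizer:
    """Per-column z-scoring with persisted training statistics.

    Fitted on the analysis cohort; held-out pairs are transformed with the
    training means/SDs so their features live on the training scale.
    """

    def __init__(self) -> None:
        self.means: pd.Series | None = None
        self.sds: pd.Series | None = None

    def fit(self, df: pd.DataFrame, columns: Sequence[str]) -> "FeatureStandardizer":
        self.means = df[list(columns)].mean()
        self.sds = df[list(columns)].std(ddof=0)
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.means is None:
            raise RuntimeError("standardizer not fitted")
        out = df.copy()
        for col in self.means.index:
            sd = self.sds[col]
            if sd > 0:
                out[col] = (df[col] - self.means[col]) / sd
        return out

    def to_dict(self) -> dict:
        return {
            "means": {k: float(v) for k, v in self.means.items()},
            "sds": {k: float(v) for k, v in self.sds.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureStandardizer":
        s = cls()
        s.means = pd.Series(d["means"], dtype=float)
        s.sds = pd.Series(d["sds"], dtype=float)
        return s


def continuous_columns(df: pd.DataFrame) -> list[str]:
    """Continuous main-effect columns of a feature table (no binaries/interactions)."""
    cols = [f"{c}_{s}" for c in PAIRED_CONTINUOUS for s in ("L", "K")]
    cols += list(RELATIONAL)
    return [c for c in cols if c in df.columns]


def interaction_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.endswith("_LxK")]


def assemble_features(
    records: Iterable[dict],
    standardizer: FeatureStandardizer | None = None,
) -> tuple[pd.DataFrame, FeatureStandardizer]:
    """Build the standardized modeling table from raw pair records.

    Continuous columns are z-scored across the cohort (or with the supplied
    fitted ``standardizer`` for held-out data); binary core/delta flags stay
    0/1; for every metric measured on both prints a latent×known interaction
    column (``*_LxK``) is the elementwise product of the standardized (or
    0/1) mains. Rows with any missing metric are dropped with a log entry.
    Zero-variance continuous columns are dropped with a warning.
    """
    df = pd.DataFrame(list(records)).set_index("pair_id")

    incomplete = df.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "excluding %d pair(s) with missing metrics: %s",
            int(incomplete.sum()),
            ", ".join(map(str, df.index[incomplete][:10])),
        )
        df = df.loc[~incomplete]

    cont = continuous_columns(df)
    if standardizer is None:
        standardizer = FeatureStandardizer().fit(df, cont)
    degenerate = [c for c in cont if standardizer.sds[c] == 0]
    if degenerate:
        warnings.warn(f"dropping zero-variance columns: {degenerate}")
        df = df.drop(columns=degenerate)
    df = standardizer.transform(df)

    for col in PAIRED_CONTINUOUS + PAIRED_BINARY:
        lcol, kcol = f"{col}_L", f"{col}_K"
        if lcol in df.columns and kcol in df.columns:
            df[f"{col}_LxK"] = df[lcol] * df[kcol]
    return df, standardizer


# ---------------------------------------------------------------------------
# collinearity screening


def variance_inflation_factors(df: pd.DataFrame, columns: Sequence[str]) -> pd.Series:
    """VIF of each column regressed on the remaining ones (with intercept)."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in columns])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vifs = [variance_inflation_factor(X, i + 1) for i in range(len(columns))]
    return pd.Series(vifs, index=list(columns))


def collinearity_filter(
    df: pd.DataFrame,
    r_threshold: float = 0.5,
    vif_limit: float = 5.0,
    columns: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Iteratively remove collinear continuous predictors.

    While any pairwise |Pearson r| among continuous mains exceeds
    ``r_threshold``, the member of the worst pair with the larger mean
    absolute correlation to all other mains is dropped (ties: the later
    column in canonical order). Survivors must then all have VIF below
    ``vif_limit``; otherwise the largest-VIF column is dropped and the
    screen repeats. Interaction columns built on a dropped main are removed
    with it. Returns the reduced table and a drop report.
    """
    cols = list(columns) if columns is not None else continuous_columns(df)
    if len(cols) < 2:
        raise ValueError("need at least 2 continuous columns to screen")
    if len(df) < 3:
        raise ValueError("need at least 3 rows to screen collinearity")

    report: list[dict] = []
    step = 0

    def drop(col: str, reason: str, value: float) -> None:
        nonlocal step
        step += 1
        cols.remove(col)
        report.append({"step": step, "dropped": col, "reason": reason, "value": float(value)})

    while len(cols) >= 2:
        corr = df[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = float(corr.values.max())
        if worst <= r_threshold:
            vifs = variance_inflation_factors(df, cols)
            if vifs.max() < vif_limit or len(cols) <= 2:
                break
            drop(str(vifs.idxmax()), "vif", float(vifs.max()))
            continue
        i, j = np.unravel_index(int(corr.values.argmax()), corr.shape)
        a, b = cols[i], cols[j]
        mean_r = corr.mean(axis=1)
        # larger mean |r| goes; ties resolved by canonical (listed) order
        victim = b if mean_r[b] >= mean_r[a] else a
        drop(victim, "pairwise_r", worst)

    if len(cols) < 2:
        raise ValueError("collinearity screen left fewer than 2 predictors")

    dropped = {r["dropped"] for r in report}
    dead_interactions = [
        c for c in interaction_columns(df)
        if any(c.replace("_LxK", f"_{s}") in dropped for s in ("L", "K"))
    ]
    keep = [c for c in df.columns if c not in dropped and c not in dead_interactions]
    for r in report:
        logger.info("collinearity screen step %d: dropped %s (%s = %.3f)",
                    r["step"], r["dropped"], r["reason"], r["value"])
    return df[keep], report
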