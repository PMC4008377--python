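"""Synthetic fingerprint pairs and simulated examiner panels.

The generator produces the statistical structure the analysis pipeline
assumes, with no external data:

* **known prints** — a smooth ridge-orientation field with the singularity
  layout of a pattern class (arch, tented arch, left/right loop, whorl),
  rendered as dark ridges by iterated oriented filtering of noise, inside
  an elliptical print boundary;
* **latents** — the known print degraded in a fixed order: sub-region
  crop, dark Gaussian-blob smudges, multiplicative contrast attenuation,
  global intensity bias, additive noise;
* **examiner panels** — per-trial correctness drawn from the crossed
  logistic model (pair- and examiner-level Gaussian intercepts), with
  difficulty/confidence ratings and response times linked monotonically to
  the linear predictor, and pairs administered in batches of 20 holding
  ten matches and ten non-matches.

Pair-level ground-truth difficulty is injected *through the images*:
degradation moves the image metrics, the metrics move the linear
predictor, and the print-level random intercept carries residual pair
difficulty beyond the features — so refitting the model on a generated
study exercises the full measurement chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve
from scipy.special import expit

from . import metrics as pm
from .io import (
    GlobalFeatureAnnotation,
    PrintImage,
    SegmentationMask,
    TrialTable,
    write_annotations,
    write_print,
    write_trials,
)

logger = logging.getLogger(__name__)

PATTERN_CLASSES = ("arch", "tented-arch", "left-loop", "right-loop", "whorl")

#: generating fixed effects of the default study: the published accuracy
#: model scale (intercept ~3.4 on the logit, slopes ~|0.3-0.8| on
#: standardized features, print-level variance ~2)
DEFAULT_BETA = {
    "delta_L": 0.798,
    "mean_block_contrast_K": 0.534,
    "area_ratio": -0.471,
    "sd_block_contrast_LxK": -0.451,
    "ridge_sum": 0.419,
    "deai_LxK": 0.334,
}
DEFAULT_BETA0 = 3.385
DEFAULT_VAR_PRINT = 2.154
DEFAULT_VAR_EXPERT = 0.1


@dataclass
class GenConfig:
    """Configuration of one synthetic print and its latent degradation.

    Degradation strengths at their zero defaults leave the known print
    untouched; ranges: ``crop_fraction`` in (0, 1], ``contrast_attenuation``
    in [0, 1), ``noise_sd`` >= 0 intensity units, ``intensity_bias`` in
    [-127, 127].
    """

    canvas: int = 256
    wavelength: float = 9.0
    pattern_class: str = "whorl"
    delta_present: bool = True
    crop_fraction: float = 1.0
    n_smudges: int = 0
    smudge_radius: float = 18.0
    contrast_attenuation: float = 0.0
    noise_sd: float = 0.0
    intensity_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern_class not in PATTERN_CLASSES:
            raise ValueError(
                f"unknown pattern class {self.pattern_class!r}; "
                f"expected one of {PATTERN_CLASSES}"
            )
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ValueError("crop_fraction must lie in (0, 1]")
        if not 0.0 <= self.contrast_attenuation < 1.0:
            raise ValueError("contrast_attenuation must lie in [0, 1)")
        if self.noise_sd < 0 or self.n_smudges < 0:
            raise ValueError("noise_sd and n_smudges must be nonnegative")


@dataclass
class PanelConfig:
    """Configuration of a simulated examiner panel.

    ``beta`` maps feature columns to generating fixed effects; variance
    defaults follow the published accuracy model (print-level variance
    ~2.15, examiner-level variance small). Rating-link parameters are a
    plain monotone discretization of the pair-level linear predictor.
    """

    experts_per_pair: int = 10
    batch_size: int = 20
    batches_per_expert: int = 2
    beta0: float = DEFAULT_BETA0
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    var_print: float = DEFAULT_VAR_PRINT
    var_expert: float = DEFAULT_VAR_EXPERT
    difficulty_center: float = 3.2
    difficulty_slope: float = 0.8  # rating units per logit of pair difficulty
    difficulty_noise: float = 0.7
    confidence_noise: float = 0.7
    rt_log_mean: float = 3.3  # log seconds at difficulty 0
    rt_difficulty_slope: float = 0.15
    rt_log_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.var_print < 0 or self.var_expert < 0:
            raise ValueError("variances must be nonnegative")
        if self.experts_per_pair < 1:
            raise ValueError("experts_per_pair must be >= 1")


# ---------------------------------------------------------------------------
# orientation fields and ridge rendering


def _singularities(cfg: GenConfig) -> tuple[list[complex], list[complex]]:
    """Core (loop) and delta singularity positions for a pattern class.

    Positions are in canvas coordinates as complex ``col + 1j*row``. A
    whorl counts its core twice (Poincaré index 1); suppressed deltas are
    pushed far below the canvas so they stay invisible while keeping the
    field topologically consistent.
    """
    n = cfg.canvas
    cx, cy = n / 2.0, n / 2.0
    far = 6.0 * n  # off-canvas
    cores: list[complex] = []
    deltas: list[complex] = []
    if cfg.pattern_class == "arch":
        pass
    elif cfg.pattern_class == "tented-arch":
        cores = [complex(cx, cy - 0.08 * n)]
        deltas = [complex(cx, cy + 0.22 * n)]
    elif cfg.pattern_class == "left-loop":
        cores = [complex(cx + 0.05 * n, cy - 0.08 * n)]
        deltas = [complex(cx + 0.28 * n, cy + 0.26 * n)]
    elif cfg.pattern_class == "right-loop":
        cores = [complex(cx - 0.05 * n, cy - 0.08 * n)]
        deltas = [complex(cx - 0.28 * n, cy + 0.26 * n)]
    else:  # whorl
        cores = [complex(cx, cy - 0.05 * n)] * 2
        deltas = [complex(cx - 0.3 * n, cy + 0.28 * n),
                  complex(cx + 0.3 * n, cy + 0.28 * n)]
    if not cfg.delta_present:
        deltas = [complex(d.real, far) for d in deltas]
    return cores, deltas


def orientation_field(cfg: GenConfig) -> np.ndarray:
    """Ridge orientation (radians, mod pi) at every canvas pixel.

    Loops and whorls use the classic zero-pole model: the orientation is
    half the argument sum over core singularities minus half the argument
    sum over deltas. Arches use a smooth singularity-free bump flow.
    """
    n = cfg.canvas
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    z = cols + 1j * rows
    if cfg.pattern_class == "arch":
        xh = (cols - n / 2.0) / (0.35 * n)
        yh = (rows - n / 2.0) / (0.35 * n)
        theta = 0.9 * (-xh) * np.exp(-(xh**2 + yh**2) / 2.0)
        return np.mod(theta, np.pi)
    cores, deltas = _singularities(cfg)
    theta = np.zeros((n, n))
    for c in cores:
        theta += 0.5 * np.angle(z - c)
    for d in deltas:
        theta -= 0.5 * np.angle(z - d)
    return np.mod(theta, np.pi)


def _oriented_kernel(theta: float, wavelength: float, sigma: float) -> np.ndarray:
    from skimage.filters import gabor_kernel

    g = np.real(gabor_kernel(frequency=1.0 / wavelength, theta=theta,
                             sigma_x=sigma, sigma_y=sigma))
    return g - g.mean()


def render_ridges(
    theta: np.ndarray,
    wavelength: float,
    rng: np.random.Generator,
    n_iter: int = 5,
    n_bins: int = 16,
) -> np.ndarray:
    """Render a ridge pattern following an orientation field.

    Noise is repeatedly filtered with oriented bandpass kernels selected
    per pixel by the local orientation; a few iterations lock the pattern
    onto the field at the requested ridge wavelength. Returns values in
    [-1, 1], positive on ridges.

    Kernels respond to *edges along* their orientation argument, so each
    pixel uses the kernel perpendicular to its ridge orientation.
    """
    n = theta.shape[0]
    img = rng.standard_normal(theta.shape)
    bins = np.rint(theta / np.pi * n_bins).astype(int) % n_bins
    sigma = wavelength / 2.2
    kernels = [
        _oriented_kernel(k * np.pi / n_bins + np.pi / 2.0, wavelength, sigma)
        for k in range(n_bins)
    ]
    for _ in range(n_iter):
        stack = np.empty((n_bins,) + img.shape)
        for k, kern in enumerate(kernels):
            stack[k] = fftconvolve(img, kern, mode="same")
        img = np.take_along_axis(stack, bins[None, :, :], axis=0)[0]
        img /= max(img.std(), 1e-12)
    return np.tanh(1.5 * img)


def _ellipse_mask(n: int, r_row: float = 0.42, r_col: float = 0.36) -> np.ndarray:
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    cy = cx = n / 2.0
    return ((rows - cy) / (r_row * n)) ** 2 + ((cols - cx) / (r_col * n)) ** 2 <= 1.0


def generate_known(
    cfg: GenConfig,
) -> tuple[PrintImage, SegmentationMask, GlobalFeatureAnnotation]:
    """Generate a clean known print for a pattern class.

    Same seed, same config — byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    theta = orientation_field(cfg)
    ridges = render_ridges(theta, cfg.wavelength, rng)
    mask = _ellipse_mask(cfg.canvas)
    # dark ridges on bright paper
    img = 127.5 - 110.0 * ridges
    img[~mask] = 255.0
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    has_core = cfg.pattern_class != "arch"
    ann = GlobalFeatureAnnotation(
        core_present=has_core,
        delta_present=bool(cfg.delta_present and cfg.pattern_class != "arch"),
        core_type=cfg.pattern_class if has_core else None,
    )
    return (
        PrintImage(pixels, role="known", id=f"{cfg.pattern_class}-{cfg.seed}"),
        SegmentationMask(mask),
        ann,
    )


# ---------------------------------------------------------------------------
# latent degradation


def _crop_mask(
    mask: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Intersect the mask with a disk holding ~``fraction`` of its area."""
    if fraction >= 1.0:
        return mask
    area = mask.sum()
    target = fraction * area
    rows, cols = np.nonzero(mask)
    i = rng.integers(len(rows))
    cy, cx = rows[i], cols[i]
    rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    d2 = (rr - cy) ** 2.0 + (cc - cx) ** 2.0
    lo, hi = 1.0, float(max(mask.shape)) * 1.5
    for _ in range(40):  # bisect the disk radius onto the target area
        mid = 0.5 * (lo + hi)
        got = (mask & (d2 <= mid * mid)).sum()
        if got < target:
            lo = mid
        else:
            hi = mid
    out = mask & (d2 <= hi * hi)
    if not out.any():
        raise ValueError("crop produced an empty latent mask")
    return out


def degrade_to_latent(
    image: PrintImage,
    mask: SegmentationMask,
    cfg: GenConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PrintImage, SegmentationMask]:
    """Degrade a known print into a latent-like impression.

    Applied in order: sub-region crop, dark smudges, multiplicative
    contrast attenuation, global intensity bias, additive Gaussian noise,
    clipping to [0, 255]. Zero-strength settings reproduce the input.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    m0 = mask.mask
    m = _crop_mask(m0, cfg.crop_fraction, rng)
    img = image.pixels.astype(np.float64)

    if cfg.n_smudges > 0:
        rows, cols = np.nonzero(m)
        rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        for _ in range(cfg.n_smudges):
            i = rng.integers(len(rows))
            d2 = (rr - rows[i]) ** 2.0 + (cc - cols[i]) ** 2.0
            w = np.exp(-d2 / (2.0 * cfg.smudge_radius**2))
            img = img * (1.0 - w) + 35.0 * w  # push toward near-black ink

    if cfg.contrast_attenuation > 0.0:
        fieldn = gaussian_filter(rng.standard_normal(img.shape), sigma=img.shape[0] / 8.0)
        span = fieldn.max() - fieldn.min()
        fieldn = (fieldn - fieldn.min()) / span if span > 0 else fieldn * 0.0
        c = cfg.contrast_attenuation * fieldn
        center = img[m].mean()
        img = center + (img - center) * (1.0 - c)

    img = img + cfg.intensity_bias
    if cfg.noise_sd > 0.0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    img = np.where(m, img, np.uint8(255))
    return PrintImage(img, role="latent", id=image.id + "-latent"), SegmentationMask(m)


# ---------------------------------------------------------------------------
# examiner panel simulation


def _check_standardized(features: pd.DataFrame, columns: list[str]) -> None:
    for col in columns:
        if col.endswith("_LxK"):
            continue  # interaction of z-scored mains: no unit-SD guarantee
        x = features[col].to_numpy(float)
        if set(np.unique(x)) <= {0.0, 1.0}:
            continue  # binary flag
        sd = x.std()
        if abs(x.mean()) > 0.5 or not 0.5 < sd < 2.0:
            raise ValueError(
                f"feature {col!r} does not look standardized "
                f"(mean {x.mean():.2f}, sd {sd:.2f}); z-score features first"
            )


def simulate_panel(
    features: pd.DataFrame,
    cfg: PanelConfig,
    is_match: pd.Series | None = None,
) -> TrialTable:
    """Simulate examiner judgments for a set of pairs from the crossed model.

    ``features`` must be standardized, indexed by pair_id, and contain every
    column of ``cfg.beta``. Pairs are administered in batches of
    ``batch_size`` (ten matches, ten non-matches when the mix allows), each
    batch seen by ~``experts_per_pair`` examiners, each examiner completing
    ``batches_per_expert`` batches — the paper-style panel design.
    """
    rng = np.random.default_rng(cfg.seed)
    cols = list(cfg.beta)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise KeyError(f"beta names missing from features: {missing}")
    _check_standardized(features, cols)

    pair_ids = list(features.index)
    n_pairs = len(pair_ids)
    if is_match is None:
        is_match = pd.Series(
            [i % 2 == 0 for i in range(n_pairs)], index=features.index
        )

    xb = features[cols].to_numpy(float) @ np.array([cfg.beta[c] for c in cols]) \
        if cols else np.zeros(n_pairs)
    print_eff = rng.normal(0.0, np.sqrt(cfg.var_print), size=n_pairs)
    eta_pair = cfg.beta0 + xb + print_eff

    # batches of ten matches + ten non-matches where the mix allows
    half = max(1, cfg.batch_size // 2)
    match_ids = [p for p in pair_ids if is_match[p]]
    nonmatch_ids = [p for p in pair_ids if not is_match[p]]
    rng.shuffle(match_ids)
    rng.shuffle(nonmatch_ids)
    batches: list[list] = []
    while match_ids or nonmatch_ids:
        batch = match_ids[:half] + nonmatch_ids[:half]
        match_ids, nonmatch_ids = match_ids[half:], nonmatch_ids[half:]
        if batch:
            batches.append(batch)

    n_slots = len(batches) * cfg.experts_per_pair
    n_experts = max(cfg.experts_per_pair,
                    int(np.ceil(n_slots / cfg.batches_per_expert)))
    expert_eff = rng.normal(0.0, np.sqrt(cfg.var_expert), size=n_experts)
    # fill expert-batch assignments round-robin over a shuffled expert order
    slots: list[int] = []
    order = rng.permutation(n_experts)
    while len(slots) < n_slots:
        slots.extend(order.tolist())
    assignment: list[tuple[int, int]] = []  # (batch, expert)
    k = 0
    for b in range(len(batches)):
        seen: set[int] = set()
        for _ in range(cfg.experts_per_pair):
            while slots[k % len(slots)] in seen:
                k += 1
            e = slots[k % len(slots)]
            seen.add(e)
            assignment.append((b, e))
            k += 1

    index = {p: i for i, p in enumerate(pair_ids)}
    rows = []
    for b, e in assignment:
        for p in batches[b]:
            i = index[p]
            eta = eta_pair[i] + expert_eff[e]
            correct = int(rng.random() < expit(eta))
            match = bool(is_match[p])
            judged = match if correct else not match
            diff_latent = cfg.difficulty_center - cfg.difficulty_slope * (
                eta_pair[i] - cfg.beta0
            ) + rng.normal(0.0, cfg.difficulty_noise)
            difficulty = int(np.clip(np.rint(diff_latent), 1, 6))
            conf_latent = 7.0 - difficulty + rng.normal(0.0, cfg.confidence_noise)
            confidence = int(np.clip(np.rint(conf_latent), 1, 6))
            rt = float(np.exp(
                cfg.rt_log_mean
                + cfg.rt_difficulty_slope * difficulty
                + rng.normal(0.0, cfg.rt_log_sd)
            ))
            rows.append(
                {
                    "pair_id": p,
                    "expert_id": f"E{e:03d}",
                    "is_match": match,
                    "judged_match": judged,
                    "difficulty": difficulty,
                    "confidence": confidence,
                    "response_time": rt,
                    "timed_out": False,
                    "correct": correct,
                }
            )
    return TrialTable(pd.DataFrame(rows))


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else x - x.mean()


def simulate_features(
    n_pairs: int,
    columns: list[str] | None = None,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Directly simulate a standardized feature table (no images).

    Continuous columns are independent standard normals re-centered to
    exact z-scores; names ending in ``_L``/``_K`` for core/delta become 0/1
    flags; ``*_LxK`` names are products of their mains. Useful for studies
    of the statistical machinery where image content is irrelevant.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if columns is None:
        columns = ["ridge_sum", "area_ratio", "mean_block_contrast_K",
                   "sd_block_contrast_L", "sd_block_contrast_K", "deai_L",
                   "deai_K", "delta_L"]
    idx = pd.Index([f"P{i:04d}" for i in range(n_pairs)], name="pair_id")
    df = pd.DataFrame(index=idx)
    for col in columns:
        if col.endswith("_LxK"):
            continue
        if col.startswith(("core_", "delta_")):
            df[col] = rng.random(n_pairs) < 0.5
            df[col] = df[col].astype(int)
        else:
            df[col] = _zscore(rng.standard_normal(n_pairs))
    for col in columns:
        if col.endswith("_LxK"):
            stem = col[: -len("_LxK")]
            for side in ("L", "K"):
                if f"{stem}_{side}" not in df.columns:
                    df[f"{stem}_{side}"] = _zscore(rng.standard_normal(n_pairs))
            df[col] = df[f"{stem}_L"] * df[f"{stem}_K"]
    return df


# ---------------------------------------------------------------------------
# full study bundle


@dataclass
class StudyBundle:
    """Everything one synthetic study produces."""

    features: pd.DataFrame  # standardized, indexed by pair_id
    trials: TrialTable
    is_match: pd.Series
    standardizer: pm.FeatureStandardizer
    prints: dict[str, tuple[PrintImage, SegmentationMask]] = field(default_factory=dict)
    annotations: dict[str, GlobalFeatureAnnotation] = field(default_factory=dict)


def build_study(
    n_pairs: int = 200,
    panel: PanelConfig | None = None,
    canvas: int = 256,
    seed: int = 0,
    out_dir: str | Path | None = None,
    keep_images: bool = False,
) -> StudyBundle:
    """Generate a full synthetic study: images, metrics, features, panel.

    Pattern classes cycle over the class list; degradation parameters are
    drawn over wide ranges so the feature columns spread over their
    attainable values. Half the pairs are matches; non-matches pair the
    latent with a same-class, different-seed known print (standing in for
    the close non-matches an AFIS search would return). With ``out_dir``
    the bundle is written to disk (PNG images/masks, CSV annotations,
    features and trials).
    """
    panel = panel or PanelConfig(seed=seed + 1)
    rng = np.random.default_rng(seed)
    records = []
    annotations: dict[str, GlobalFeatureAnnotation] = {}
    prints: dict[str, tuple[PrintImage, SegmentationMask]] = {}
    is_match_flags = {}

    for i in range(n_pairs):
        pair_id = f"P{i:04d}"
        match = i % 2 == 0
        cls = PATTERN_CLASSES[i % len(PATTERN_CLASSES)]
        base_seed = int(rng.integers(2**31 - 1))
        gen = GenConfig(
            canvas=canvas,
            pattern_class=cls,
            delta_present=bool(rng.random() < 0.7),
            crop_fraction=float(rng.uniform(0.35, 1.0)),
            n_smudges=int(rng.integers(0, 13)),
            smudge_radius=float(rng.uniform(canvas / 24, canvas / 9)),
            contrast_attenuation=float(rng.uniform(0.0, 0.8)),
            noise_sd=float(rng.uniform(1.0, 18.0)),
            intensity_bias=float(rng.uniform(-35.0, 35.0)),
            seed=base_seed,
        )
        source_img, source_mask, source_ann = generate_known(gen)
        latent_img, latent_mask = degrade_to_latent(source_img, source_mask, gen, rng)
        if match:
            known_img, known_mask, known_ann = source_img, source_mask, source_ann
        else:
            twin = GenConfig(canvas=canvas, pattern_class=cls,
                             delta_present=gen.delta_present,
                             seed=int(rng.integers(2**31 - 1)))
            known_img, known_mask, known_ann = generate_known(twin)

        latent_ann = GlobalFeatureAnnotation(
            core_present=source_ann.core_present,
            delta_present=source_ann.delta_present,
            core_type=source_ann.core_type,
        )
        lat = pm.compute_print_metrics(latent_img, latent_mask, latent_ann)
        kno = pm.compute_print_metrics(known_img, known_mask, known_ann)
        records.append(pm.pair_record(pair_id, lat, kno))
        is_match_flags[pair_id] = match
        annotations[f"{pair_id}-latent"] = latent_ann
        annotations[f"{pair_id}-known"] = known_ann
        if keep_images or out_dir is not None:
            prints[f"{pair_id}-latent"] = (latent_img, latent_mask)
            prints[f"{pair_id}-known"] = (known_img, known_mask)

    features, standardizer = pm.assemble_features(records)
    is_match = pd.Series(is_match_flags).reindex(features.index)
    missing = [c for c in panel.beta if c not in features.columns]
    if missing:
        # degenerate columns can drop out of tiny cohorts; their effects
        # cannot enter the generating model
        logger.warning("generating effects without feature columns ignored: %s",
                       missing)
        panel = replace(panel,
                        beta={k: v for k, v in panel.beta.items()
                              if k not in missing})
    trials = simulate_panel(features, panel, is_match=is_match)
    bundle = StudyBundle(
        features=features,
        trials=trials,
        is_match=is_match,
        standardizer=standardizer,
        prints=prints if keep_images or out_dir else {},
        annotations=annotations,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
        if not keep_images:
            bundle.prints = {}
    return bundle


def _write_bundle(bundle: StudyBundle, out_dir: Path) -> None:
    images = out_dir / "images"
    masks = out_dir / "masks"
    for d in (out_dir, images, masks):
        d.mkdir(parents=True, exist_ok=True)
    for name, (img, mask) in bundle.prints.items():
        write_print(img, mask, images / f"{name}.png", masks / f"{name}.png")
    write_annotations(bundle.annotations, out_dir / "annotations.csv")
    feats = bundle.features.copy()
    feats.insert(0, "is_match", bundle.is_match)
    feats.to_csv(out_dir / "features.csv")
    write_trials(bundle.trials, out_dir / "trials.csv")
    logger.info("study bundle written to %s (%d pairs, %d trials)",
                out_dir, len(bundle.features), len(bundle.trials))
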