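"""Synthetic spectra, tissue images and margin cohorts with known truth.

Every downstream stage of the screening analysis can be exercised without
instrument data: this module emulates

* a Förster–Hoffmann viscosity response over the ethanol→glycerol range
  (1.2–945 cP) whose default slope is anchored so the glycerol/ethanol
  intensity ratio is exactly 18-fold, matching the probe's contrast;
* a linear nitroreductase titration over 0–9.0 μg/mL with Gaussian blank
  noise (defaults k = 11166.424 intensity units per μg/mL, σ = 77.883);
* two-channel 8-bit specimen images with elliptical tissue "blobs" of known
  class and planted per-channel maxima;
* margin cohorts shaped like the clinical designs (paired training tissue,
  labelled test margins) with class-separated dual-channel maxima.

All generators draw from ``numpy.random.default_rng(seed)`` and are
bit-reproducible for a fixed seed.  Noise is Gaussian throughout — the
simplest model consistent with a single blank standard deviation.
Intensities are quantized to integers only at the image/cohort level
(mirroring an 8-bit camera); spectra stay real-valued.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from marginscreen.image_quant import (
    ChannelImage,
    SampleRecord,
    records_to_frame,
    write_channel_tiff,
)
from marginscreen.photophysics import EmissionSeries

__all__ = [
    "SpectraConfig", "ImageConfig", "CohortConfig",
    "BlobTruth", "MarginCohort",
    "gen_viscosity_series", "gen_ntr_titration",
    "gen_tissue_image", "gen_margin_cohort",
    "write_tissue_image", "write_cohort_csv",
    "ETHANOL_CP", "GLYCEROL_CP", "DEFAULT_SLOPE_X",
]

# Handbook dynamic viscosities at ~20 °C (cP). Implementation constants of
# the generator, overridable through SpectraConfig.viscosities.
ETHANOL_CP = 1.2
GLYCEROL_CP = 945.0

# Slope chosen so the noise-free series has exactly an 18-fold intensity
# enhancement from ethanol to glycerol: 18 = (945/1.2)**x.
DEFAULT_SLOPE_X = math.log10(18.0) / math.log10(GLYCEROL_CP / ETHANOL_CP)


def _default_viscosities() -> tuple[float, ...]:
    return tuple(float(v) for v in np.geomspace(ETHANOL_CP, GLYCEROL_CP, 8))


def _default_titration_concs() -> tuple[float, ...]:
    return (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0)


@dataclass(frozen=True)
class SpectraConfig:
    """Conditions for the viscosity series and the enzyme titration.

    ``viscosities`` in cP, ``titration_concs`` in μg/mL (the assay's 0–9.0
    working range), intensities in arbitrary spectrometer units.
    ``rel_noise`` is fractional multiplicative noise on the viscosity
    series; ``blank_sd`` is additive Gaussian noise on the titration and
    the spread of the ``n_blanks`` blank replicates.
    """

    viscosities: tuple[float, ...] = field(default_factory=_default_viscosities)
    slope_x: float = DEFAULT_SLOPE_X
    intercept_c: float = 2.0
    rel_noise: float = 0.0
    titration_concs: tuple[float, ...] = field(default_factory=_default_titration_concs)
    titration_slope_k: float = 11166.424
    titration_intercept: float = 0.0
    blank_sd: float = 77.883
    n_blanks: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.viscosities):
            raise ValueError("viscosities must be strictly positive")
        if any(c < 0 for c in self.titration_concs):
            raise ValueError("titration concentrations must be non-negative")
        if not (0.0 <= self.rel_noise < 1.0):
            raise ValueError("rel_noise must lie in [0, 1)")
        if self.blank_sd < 0:
            raise ValueError("blank_sd must be non-negative")
        if self.n_blanks < 2:
            raise ValueError("need at least 2 blank replicates")


def _default_class_means() -> dict[str, tuple[float, float]]:
    return {"pos": (200.0, 200.0), "neg": (120.0, 120.0), "one_high": (200.0, 120.0)}


@dataclass(frozen=True)
class ImageConfig:
    """Layout of a synthetic two-channel specimen image.

    Blobs are axis-aligned ellipses with semi-axes drawn from
    ``blob_radius_range`` (pixels), placed without overlap; classes cycle
    through ``class_means`` (per-channel mean gray-scale) so every class is
    represented.  Background and blob pixels are Gaussian, clipped to the
    8-bit range.
    """

    width: int = 256
    height: int = 256
    n_samples: int = 5
    blob_radius_range: tuple[float, float] = (8.0, 16.0)
    class_means: dict[str, tuple[float, float]] = field(default_factory=_default_class_means)
    class_sd: float = 5.0
    background_mean: float = 15.0
    background_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        lo, hi = self.blob_radius_range
        if not (0 < lo <= hi):
            raise ValueError("blob_radius_range must be 0 < lo <= hi")
        if self.class_sd < 0 or self.background_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not self.class_means:
            raise ValueError("class_means must not be empty")


@dataclass(frozen=True)
class CohortConfig:
    """Shape of a synthetic margin cohort.

    Defaults mimic the liver design: paired cancerous/noncancerous training
    tissue from several patients, and a labelled test set of resection
    margins (9 tumor-involved, 26 tumor-free).  ``pos_mean``/``neg_mean``
    are (ntr, vis) mean gray-scales; intensities are drawn per class,
    rounded to integers and clipped to [0, 255].
    """

    n_train_pairs: int = 9
    n_test_pos: int = 9
    n_test_neg: int = 26
    pos_mean: tuple[float, float] = (200.0, 200.0)
    neg_mean: tuple[float, float] = (120.0, 120.0)
    sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train_pairs < 1:
            raise ValueError("need at least one training pair")
        if self.n_test_pos < 0 or self.n_test_neg < 0:
            raise ValueError("test counts must be non-negative")
        for name, mean in (("pos_mean", self.pos_mean), ("neg_mean", self.neg_mean)):
            if not all(0.0 <= m <= 255.0 for m in mean):
                raise ValueError(f"{name} must lie within [0, 255]")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class BlobTruth:
    """Ground truth for one planted blob."""

    blob_id: int
    cls: str
    mask: frozenset[tuple[int, int]]
    max_ntr: int
    max_vis: int


@dataclass(frozen=True)
class MarginCohort:
    """Generated training and test tables.

    ``training`` records carry a parallel ``training_groups`` tag
    ("cancerous"/"noncancerous", alternating within patient pairs);
    ``test`` records carry H&E labels.
    """

    training: tuple[SampleRecord, ...]
    training_groups: tuple[str, ...]
    test: tuple[SampleRecord, ...]


# ---------------------------------------------------------------------------
# spectra

def gen_viscosity_series(cfg: SpectraConfig) -> EmissionSeries:
    """Emission intensities on the configured log-log line, with optional
    multiplicative Gaussian noise: I = 10^(c + x·log10 η) · (1 + ε)."""
    rng = np.random.default_rng(cfg.seed)
    eta = np.asarray(cfg.viscosities, dtype=float)
    ideal = 10.0 ** (cfg.intercept_c + cfg.slope_x * np.log10(eta))
    noise = rng.normal(0.0, cfg.rel_noise, size=eta.shape) if cfg.rel_noise > 0 else 0.0
    inten = np.maximum(ideal * (1.0 + noise), np.finfo(float).tiny)
    return EmissionSeries(kind="viscosity",
                          points=tuple(zip(eta.tolist(), inten.tolist())),
                          wavelength_nm=610.0)


def gen_ntr_titration(cfg: SpectraConfig) -> tuple[EmissionSeries, list[float]]:
    """Linear enzyme titration plus blank replicates.

    I(conc) = k·conc + intercept + Normal(0, blank_sd); blanks are draws
    from Normal(intercept, blank_sd).  Blanks are produced even when the
    concentration list is empty.
    """
    rng = np.random.default_rng(cfg.seed)
    concs = np.asarray(cfg.titration_concs, dtype=float)
    noise = rng.normal(0.0, cfg.blank_sd, size=concs.shape) if cfg.blank_sd > 0 else np.zeros_like(concs)
    inten = cfg.titration_slope_k * concs + cfg.titration_intercept + noise
    blanks = rng.normal(cfg.titration_intercept, cfg.blank_sd, size=cfg.n_blanks)
    series = EmissionSeries(kind="titration",
                            points=tuple(zip(concs.tolist(), inten.tolist())),
                            wavelength_nm=520.0)
    return series, [float(b) for b in blanks]


# ---------------------------------------------------------------------------
# images

class BlobPlacementError(RuntimeError):
    """Raised when a blob cannot be placed without overlap."""


def _place_blobs(cfg: ImageConfig, rng: np.random.Generator,
                 max_attempts: int = 1000) -> list[tuple[float, float, float, float]]:
    """Choose non-overlapping (row, col, semi_r, semi_c) ellipse parameters."""
    lo, hi = cfg.blob_radius_range
    placed: list[tuple[float, float, float, float]] = []
    for idx in range(cfg.n_samples):
        for _ in range(max_attempts):
            a = rng.uniform(lo, hi)  # semi-axis along rows
            b = rng.uniform(lo, hi)  # semi-axis along cols
            r0 = rng.uniform(a + 1, cfg.height - a - 1)
            c0 = rng.uniform(b + 1, cfg.width - b - 1)
            rad = max(a, b) + 2.0  # bounding circle + 2 px gap
            ok = all(
                math.hypot(r0 - pr, c0 - pc) > rad + max(pa, pb) + 2.0
                for pr, pc, pa, pb in placed
            )
            if ok:
                placed.append((r0, c0, a, b))
                break
        else:
            raise BlobPlacementError(
                f"could not place blob {idx} without overlap after {max_attempts} attempts"
            )
    return placed


def gen_tissue_image(cfg: ImageConfig) -> tuple[ChannelImage, ChannelImage, list[BlobTruth]]:
    """Two-channel 8-bit image with planted elliptical specimen blobs.

    Blob classes cycle through ``class_means`` in sorted key order; each
    blob's pixels are Normal(class mean, class_sd) per channel, replacing
    the Gaussian background, then rounded and clipped to [0, 255].  The
    truth list records every blob's class, pixel mask and the maximum
    planted intensity per channel (read back from the final images).
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.height, cfg.width)
    bg_ntr = rng.normal(cfg.background_mean, cfg.background_sd, size=shape)
    bg_vis = rng.normal(cfg.background_mean, cfg.background_sd, size=shape)
    img_ntr = np.clip(np.rint(bg_ntr), 0, 255).astype(np.uint8)
    img_vis = np.clip(np.rint(bg_vis), 0, 255).astype(np.uint8)

    classes = sorted(cfg.class_means)
    truths: list[BlobTruth] = []
    rows_grid, cols_grid = np.mgrid[0:cfg.height, 0:cfg.width]
    for idx, (r0, c0, a, b) in enumerate(_place_blobs(cfg, rng)):
        cls = classes[idx % len(classes)]
        mean_ntr, mean_vis = cfg.class_means[cls]
        inside = ((rows_grid - r0) / a) ** 2 + ((cols_grid - c0) / b) ** 2 <= 1.0
        n_px = int(inside.sum())
        vals_ntr = np.clip(np.rint(rng.normal(mean_ntr, cfg.class_sd, n_px)), 0, 255)
        vals_vis = np.clip(np.rint(rng.normal(mean_vis, cfg.class_sd, n_px)), 0, 255)
        img_ntr[inside] = vals_ntr.astype(np.uint8)
        img_vis[inside] = vals_vis.astype(np.uint8)
        mask = frozenset(zip(rows_grid[inside].tolist(), cols_grid[inside].tolist()))
        truths.append(BlobTruth(
            blob_id=idx + 1, cls=cls, mask=mask,
            max_ntr=int(img_ntr[inside].max()), max_vis=int(img_vis[inside].max()),
        ))
    return (ChannelImage(pixels=img_ntr, channel="ntr"),
            ChannelImage(pixels=img_vis, channel="vis"),
            truths)


# ---------------------------------------------------------------------------
# cohorts

def _draw_records(rng: np.random.Generator, n: int, mean: tuple[float, float],
                  sd: float, prefix: str, label: Optional[str]) -> list[SampleRecord]:
    vals = np.clip(np.rint(rng.normal(mean, sd, size=(n, 2))), 0, 255).astype(int)
    return [
        SampleRecord(sample_id=f"{prefix}{i + 1:02d}", i_ntr=int(v[0]), i_vis=int(v[1]),
                     he_label=label)
        for i, v in enumerate(vals)
    ]


def gen_margin_cohort(cfg: CohortConfig) -> MarginCohort:
    """Paired training records plus an H&E-labelled test set.

    Training rows alternate cancerous (``pos_mean``) and noncancerous
    (``neg_mean``) within each pair; test rows are labelled P/N.
    """
    rng = np.random.default_rng(cfg.seed)
    training: list[SampleRecord] = []
    groups: list[str] = []
    for i in range(cfg.n_train_pairs):
        for group, mean in (("cancerous", cfg.pos_mean), ("noncancerous", cfg.neg_mean)):
            v = np.clip(np.rint(rng.normal(mean, cfg.sd, size=2)), 0, 255).astype(int)
            training.append(SampleRecord(
                sample_id=f"train{i + 1:02d}_{group}", i_ntr=int(v[0]), i_vis=int(v[1])))
            groups.append(group)
    test = (_draw_records(rng, cfg.n_test_pos, cfg.pos_mean, cfg.sd, "pos", "P")
            + _draw_records(rng, cfg.n_test_neg, cfg.neg_mean, cfg.sd, "neg", "N"))
    return MarginCohort(training=tuple(training), training_groups=tuple(groups),
                        test=tuple(test))


# ---------------------------------------------------------------------------
# on-disk artifacts

def write_tissue_image(stem: str | Path, ntr: ChannelImage, vis: ChannelImage,
                       truths: Sequence[BlobTruth]) -> tuple[Path, Path, Path]:
    """Write `<stem>_ntr.tif`, `<stem>_vis.tif` and `<stem>_truth.csv`."""
    stem = Path(stem)
    p_ntr = stem.with_name(stem.name + "_ntr.tif")
    p_vis = stem.with_name(stem.name + "_vis.tif")
    p_truth = stem.with_name(stem.name + "_truth.csv")
    write_channel_tiff(ntr, p_ntr)
    write_channel_tiff(vis, p_vis)
    pd.DataFrame([
        {"blob_id": t.blob_id, "class": t.cls, "area": len(t.mask),
         "max_ntr": t.max_ntr, "max_vis": t.max_vis}
        for t in truths
    ]).to_csv(p_truth, index=False)
    return p_ntr, p_vis, p_truth


def write_cohort_csv(cohort: MarginCohort, train_path: str | Path,
                     test_path: str | Path) -> None:
    train_df = records_to_frame(cohort.training)
    train_df["group"] = list(cohort.training_groups)
    train_df.to_csv(train_path, index=False)
    records_to_frame(cohort.test).to_csv(test_path, index=False)
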