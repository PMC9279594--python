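"""Seeded generators for every input the senescence pipeline consumes.

Each generator emulates one class of wet-lab measurement — FPKM time series
over passages, colony-assay passage records, spot-bearing nuclei for
quantitative telomere FISH, and diffuse-staining cell images — and returns
the generated data together with a :class:`PlantedTruth` recording the
ground truth, so downstream modules can be tested for exact recovery (zero
noise) or calibrated recovery (known noise).

All randomness flows through ``numpy.random.default_rng(seed)``: the same
seed and configuration always give byte-identical outputs.

Default study conditions: four cultures sampled at three passages, with a
stably expressed housekeeping gene (GAPDH), 10% of features planted as
monotonically up-regulated and 10% as down-regulated with a two-fold change
per step, and multiplicative lognormal noise with a 10% coefficient of
variation. FPKM replicates' dispersion is not reported for this kind of
experiment; 10% is a conventional figure for well-measured bulk libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fpkm import ExpressionMatrix
from .imaging import RoiSpec
from .lifespan import PassageRecord

__all__ = [
    "FpkmSimConfig",
    "PlantedTruth",
    "gen_fpkm_dataset",
    "gen_colony_series",
    "gen_fish_image",
    "gen_diffuse_image",
]


@dataclass(frozen=True)
class FpkmSimConfig:
    """Parameters of the synthetic FPKM time-series experiment."""

    n_features: int = 1000
    n_cultures: int = 4
    n_timepoints: int = 3
    frac_up: float = 0.10
    frac_down: float = 0.10
    fold_per_step: float = 2.0
    noise_cv: float = 0.10
    housekeeping_id: str = "GAPDH"
    baseline_fpkm_range: tuple[float, float] = (5.0, 500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_cultures < 1:
            raise ValueError("n_features and n_cultures must be positive")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be at least 2")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must not exceed 1")
        if self.fold_per_step <= 1:
            raise ValueError("fold_per_step must exceed 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        lo, hi = self.baseline_fpkm_range
        if lo <= 0 or hi < lo:
            raise ValueError("baseline_fpkm_range must be a positive interval")


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator, for recovery tests.

    Only the fields relevant to the generating function are populated.
    """

    directions: dict[str, str] = field(default_factory=dict)
    baselines: dict[str, float] = field(default_factory=dict)
    cell_rtl: dict[str, float] = field(default_factory=dict)
    cell_spots: dict[str, list[tuple[float, int]]] = field(default_factory=dict)
    background: float | None = None
    exhaustion_passage: int | None = None
    per_passage_doublings: tuple[float, ...] = ()
    ctcf: float | None = None


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=shape)


def gen_fpkm_dataset(config: FpkmSimConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Simulate an FPKM matrix with planted monotone trends.

    Direction assignment is deterministic: the first ``round(frac_up * n)``
    features trend up (expected value baseline * fold_per_step**t), the next
    block trends down, the rest are flat. The housekeeping gene takes the
    place of the first flat feature and has a constant expected value in
    every culture. Multiplicative lognormal noise with unit mean and
    coefficient of variation ``noise_cv`` is applied independently per
    observation.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_up = round(cfg.frac_up * cfg.n_features)
    n_down = round(cfg.frac_down * cfg.n_features)
    n_flat = cfg.n_features - n_up - n_down
    if n_flat < 1:
        raise ValueError("no flat feature left to host the housekeeping gene")

    ids = [f"G{i:05d}" for i in range(cfg.n_features)]
    directions = ["up"] * n_up + ["down"] * n_down + ["flat"] * n_flat
    ids[n_up + n_down] = cfg.housekeeping_id  # first flat feature

    lo, hi = cfg.baseline_fpkm_range
    baselines = np.exp(rng.uniform(math.log(lo), math.log(hi), size=cfg.n_features))

    t = np.arange(cfg.n_timepoints)
    exponent = {"up": 1.0, "down": -1.0, "flat": 0.0}
    rows = []
    for c in range(cfg.n_cultures):
        culture = f"C{c}"
        trend = np.stack(
            [baselines[i] * cfg.fold_per_step ** (exponent[directions[i]] * t)
             for i in range(cfg.n_features)]
        )
        noisy = trend * _lognormal_factors(rng, cfg.noise_cv, trend.shape)
        for i, fid in enumerate(ids):
            rows.append(
                {"feature_id": fid, "culture_id": culture, "status": "ok",
                 **{f"t{k}": noisy[i, k] for k in range(cfg.n_timepoints)}}
            )
    data = pd.DataFrame(rows)
    truth = PlantedTruth(
        directions=dict(zip(ids, directions)),
        baselines=dict(zip(ids, baselines.tolist())),
    )
    return ExpressionMatrix(data), truth


def gen_colony_series(
    p_star: int,
    cfe0: float,
    decay: float,
    inoculum: float,
    seed: int = 0,
    culture_id: str = "C1",
    doublings_per_passage: float = 4.0,
    noise_cv: float = 0.0,
) -> tuple[list[PassageRecord], PlantedTruth]:
    """Simulate colony-assay passage records up to culture exhaustion.

    Expected CFE decays exponentially at ``decay`` per passage and is
    truncated to 0 at passage ``p_star`` (the planted exhaustion passage);
    the aborted-colony fraction ramps linearly from 0 to 1 over the
    lifespan. Cell yield realises ``doublings_per_passage`` doublings of the
    clonogenic cells. Optional multiplicative lognormal noise perturbs CFE
    and yield.
    """
    if not 0.0 < cfe0 <= 1.0:
        raise ValueError("cfe0 must be in (0, 1]")
    if p_star < 1:
        raise ValueError("p_star must be at least 1")
    if inoculum <= 0:
        raise ValueError("inoculum must be positive")
    if decay < 0:
        raise ValueError("decay must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[PassageRecord] = []
    planted: list[float] = []
    for p in range(1, p_star + 1):
        if p == p_star:
            expected_cfe = 0.0
        else:
            expected_cfe = cfe0 * math.exp(-decay * (p - 1))
        aborted = 1.0 if p_star == 1 else min(1.0, (p - 1) / (p_star - 1))
        cfe = float(np.clip(expected_cfe * _lognormal_factors(rng, noise_cv, ()), 0.0, 1.0))
        clonogenic = inoculum * cfe
        if cfe > 0:
            d = doublings_per_passage
            cell_yield = clonogenic * 2.0 ** d * float(_lognormal_factors(rng, noise_cv, ()))
            planted.append(d)
        else:
            cell_yield = 0.0
            planted.append(0.0)
        records.append(
            PassageRecord(
                culture_id=culture_id,
                passage=p,
                inoculum=float(inoculum),
                cfe=cfe,
                cell_yield=cell_yield,
                aborted_fraction=aborted,
            )
        )
    truth = PlantedTruth(
        exhaustion_passage=p_star, per_passage_doublings=tuple(planted)
    )
    return records, truth


def _spot_shape(area: int) -> tuple[int, int]:
    """Factor an integer area into the most square (h, w) rectangle."""
    best = (1, area)
    for h in range(1, int(math.isqrt(area)) + 1):
        if area % h == 0:
            best = (h, area // h)
    return best


def gen_fish_image(
    cells: int = 4,
    spots_per_cell: tuple[int, int] = (4, 8),
    spot_area: tuple[int, int] = (4, 16),
    spot_intensity: tuple[int, int] = (2000, 10000),
    background: int = 100,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    noise_sd: float = 0.0,
    max_retries: int = 500,
) -> tuple[np.ndarray, list[RoiSpec], PlantedTruth]:
    """Render a synthetic telomere-FISH field of nuclei with rectangular spots.

    Cells occupy a regular grid of rectangular ROIs. Each cell receives a
    random number of non-overlapping constant-intensity rectangular spots;
    spot amplitude is the intensity above the uniform background, so the
    planted per-cell RTL is the sum of amplitude x area over its spots.
    Optional additive Gaussian noise (sd ``noise_sd``) is applied before
    rounding to the 16-bit range.

    Raises a RuntimeError when a spot cannot be placed without overlap
    within ``max_retries`` attempts.
    """
    if cells < 1:
        raise ValueError("cells must be positive")
    if spot_intensity[0] <= 0:
        raise ValueError("spot intensity must exceed the background (amplitude > 0)")
    if background < 0 or background + spot_intensity[1] > 65535:
        raise ValueError("intensities must fit the 16-bit range")
    rng = np.random.default_rng(seed)
    h, w = size
    ncols = int(math.ceil(math.sqrt(cells)))
    nrows = int(math.ceil(cells / ncols))
    cell_h, cell_w = h // nrows, w // ncols
    if cell_h < 8 or cell_w < 8:
        raise ValueError("image too small for the requested number of cells")

    img = np.full(size, float(background))
    occupied = np.zeros(size, dtype=bool)
    rois: list[RoiSpec] = []
    truth = PlantedTruth(background=float(background))

    for idx in range(cells):
        gr, gc = divmod(idx, ncols)
        r0, c0 = gr * cell_h + 1, gc * cell_w + 1
        r1, c1 = (gr + 1) * cell_h - 1, (gc + 1) * cell_w - 1
        cell_id = f"cell_{idx:02d}"
        rois.append(RoiSpec(cell_id=cell_id, rect=(r0, c0, r1, c1)))
        n_spots = int(rng.integers(spots_per_cell[0], spots_per_cell[1] + 1))
        placed: list[tuple[float, int]] = []
        for _ in range(n_spots):
            ok = False
            for _attempt in range(max_retries):
                area = int(rng.integers(spot_area[0], spot_area[1] + 1))
                sh, sw = _spot_shape(area)
                if sh > r1 - r0 or sw > c1 - c0:
                    continue
                sr = int(rng.integers(r0, r1 - sh + 1))
                sc = int(rng.integers(c0, c1 - sw + 1))
                # require a 1-px free margin so spots stay 8-disconnected
                pr0, pc0 = max(sr - 1, 0), max(sc - 1, 0)
                if occupied[pr0 : sr + sh + 1, pc0 : sc + sw + 1].any():
                    continue
                amplitude = float(rng.integers(spot_intensity[0], spot_intensity[1] + 1))
                img[sr : sr + sh, sc : sc + sw] = background + amplitude
                occupied[sr : sr + sh, sc : sc + sw] = True
                placed.append((amplitude, area))
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"could not place spot {len(placed) + 1} of {n_spots} in {cell_id} "
                    f"after {max_retries} attempts"
                )
        truth.cell_spots[cell_id] = placed
        truth.cell_rtl[cell_id] = float(sum(a * s for a, s in placed))

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    out = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return out, rois, truth


def gen_diffuse_image(
    cell_mean: float = 1000.0,
    cell_area: int = 400,
    background_mean: float = 100.0,
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, dict[str, RoiSpec], PlantedTruth]:
    """Render a diffusely stained cell on a uniform background.

    The cell is a rectangle of exactly ``cell_area`` pixels at ``cell_mean``;
    everything else sits at ``background_mean``. Returns the image, ROIs for
    the cell and a disjoint background patch, and the planted
    CTCF = cell_area * (cell_mean - background_mean).
    """
    if cell_mean < background_mean or background_mean < 0:
        raise ValueError("require cell_mean >= background_mean >= 0")
    h, w = size
    ch, cw = _spot_shape(int(cell_area))
    if ch > h - 4 or cw > w // 2 - 4:
        raise ValueError("cell ROI does not fit in the image")
    rng = np.random.default_rng(seed)
    img = np.full(size, float(background_mean))
    r0, c0 = 2, 2
    img[r0 : r0 + ch, c0 : c0 + cw] = float(cell_mean)
    cell_roi = RoiSpec(cell_id="cell", rect=(r0, c0, r0 + ch, c0 + cw))
    bg_rect = (2, w // 2 + 2, min(h - 2, 2 + ch), w - 2)
    bg_roi = RoiSpec(cell_id="background", rect=bg_rect)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    out = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    truth = PlantedTruth(ctcf=float(cell_area) * (cell_mean - background_mean))
    return out, {"cell": cell_roi, "background": bg_roi}, truth
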