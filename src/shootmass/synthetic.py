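"""Synthetic growth datasets and rendered three-view plant images.

Two generators make the whole pipeline testable without any real data:

* :func:`simulate_growth_dataset` emulates a greenhouse harvest design:
  320 plants, five destructive harvests at 15/26/34/40/43 days, 64 plants
  per harvest, two salt treatments and two varieties.  Projected shoot
  area grows exponentially (optionally logistically) with per-plant
  variation; salt scales the growth rate down so that end-of-experiment
  biomass is reduced by a configured fraction (moderate salinity reduces
  cereal growth by roughly 10–30%).  Dry weight follows the plant-
  specific-weight mechanism SDW = A · (b0 + b1·age) plus additive
  Gaussian noise, floored at a small positive weight.  Because PSW
  depends on age only — not on treatment — an area-only model fitted to
  these data is biased across treatments exactly as in real salt trials,
  while the area-by-age model is not.

* :func:`render_plant_views` draws green curvilinear "leaves" on a blue
  background in three views with an exact, known plant-pixel count per
  view, so segmentation can be checked in closed loop.  With
  anti-aliasing off every pixel is purely plant or purely background;
  with anti-aliasing on the mask is softened by a Gaussian so boundary
  pixels take intermediate colours, as in real photographs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage, optimize
from skimage.draw import disk

from .errors import ConfigurationError, InputError
from .imaging import VIEW_NAMES, ViewTriplet, rgb_to_hsi

__all__ = [
    "GrowthSimConfig",
    "RenderSpec",
    "simulate_growth_dataset",
    "simulate_area_age_dataset",
    "render_plant_views",
    "make_fixture_suite",
]

DEFAULT_SEED = 20110201


@dataclasses.dataclass(frozen=True)
class GrowthSimConfig:
    """Parameters of the simulated harvest experiment.

    Defaults emulate a wheat salinity trial: 64 plants per harvest over
    five harvest days, balanced over two treatments and two varieties.
    ``area0_mm2``/``rgr_per_day`` give control plants ~24 mm² of projected
    area at day 15 growing to ~390 mm² at day 43; with the default PSW line
    that spans ~0.03 g to ~1.1 g of shoot dry weight.
    """

    n_plants: int = 320
    harvest_days: tuple[int, ...] = (15, 26, 34, 40, 43)
    plants_per_harvest: int = 64
    treatments: tuple[str, str] = ("control", "salt")
    salt_fraction: float = 0.5
    varieties: tuple[str, ...] = ("Krichauff", "Berkut")
    area0_mm2: float = 5.3
    rgr_per_day: float = 0.10
    area_cv: float = 0.20  # lognormal per-plant variation of initial area
    growth: str = "exponential"  # or "logistic"
    logistic_capacity_mm2: float = 800.0
    salt_growth_reduction: float = 0.25  # fractional final-biomass reduction
    psw_b0: float = 3.6e-4  # g/mm^2
    psw_b1: float = 5.9e-5  # g/(mm^2.day)
    noise_sd_g: float = 0.02
    sdw_floor_g: float = 0.001
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        days = self.harvest_days
        if len(days) == 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigurationError("harvest_days must be strictly increasing")
        if any(d <= 0 for d in days):
            raise ConfigurationError("harvest_days must be positive")
        if self.n_plants != self.plants_per_harvest * len(days):
            raise ConfigurationError(
                f"n_plants ({self.n_plants}) must equal plants_per_harvest "
                f"({self.plants_per_harvest}) x number of harvests ({len(days)})"
            )
        if not 0.0 <= self.salt_fraction <= 1.0:
            raise ConfigurationError("salt_fraction must lie in [0, 1]")
        if not 0.0 <= self.salt_growth_reduction < 1.0:
            raise ConfigurationError("salt_growth_reduction must lie in [0, 1)")
        if self.noise_sd_g < 0:
            raise ConfigurationError("noise_sd_g must be non-negative")
        if self.area0_mm2 <= 0 or self.rgr_per_day <= 0:
            raise ConfigurationError("area0_mm2 and rgr_per_day must be positive")
        if self.growth not in ("exponential", "logistic"):
            raise ConfigurationError("growth must be 'exponential' or 'logistic'")
        if not self.varieties:
            raise ConfigurationError("need at least one variety")


def _area_at(cfg: GrowthSimConfig, a0: float, rate: float, t: np.ndarray | float):
    t = np.asarray(t, dtype=float)
    if cfg.growth == "exponential":
        return a0 * np.exp(rate * t)
    k = cfg.logistic_capacity_mm2
    e = np.exp(rate * t)
    return k * a0 * e / (k + a0 * (e - 1.0))


def _salt_rate(cfg: GrowthSimConfig) -> float:
    """Growth rate for salt-stressed plants.

    Calibrated so that, at the final harvest day and mean initial area, the
    projected area (hence biomass, via the shared PSW line) is reduced by
    ``salt_growth_reduction`` relative to control.
    """
    t_end = float(cfg.harvest_days[-1])
    target = (1.0 - cfg.salt_growth_reduction) * _area_at(
        cfg, cfg.area0_mm2, cfg.rgr_per_day, t_end
    )
    if cfg.growth == "exponential":
        return cfg.rgr_per_day + np.log(1.0 - cfg.salt_growth_reduction) / t_end

    def gap(r):
        return _area_at(cfg, cfg.area0_mm2, r, t_end) - target

    return float(optimize.brentq(gap, 1e-6, cfg.rgr_per_day))


def simulate_growth_dataset(
    cfg: GrowthSimConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate one harvest experiment.

    Returns the phenotype table (columns ``plant_id, variety, treatment,
    age_days, area_mm2, sdw_g``; one row per plant, each harvested exactly
    once) and a ground-truth record with the generating parameters,
    including the implied area-by-age model coefficients
    (c0, c1, c2) = (0, b0, b1).
    """
    cfg = cfg or GrowthSimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rate_salt = _salt_rate(cfg)

    rows = []
    pid = 0
    for day in cfg.harvest_days:
        n_salt = int(round(cfg.plants_per_harvest * cfg.salt_fraction))
        treatments = np.array(
            ["salt"] * n_salt + ["control"] * (cfg.plants_per_harvest - n_salt)
        )
        rng.shuffle(treatments)
        varieties = np.resize(np.asarray(cfg.varieties), cfg.plants_per_harvest)
        rng.shuffle(varieties)
        for treat, var in zip(treatments, varieties):
            pid += 1
            a0 = cfg.area0_mm2 * rng.lognormal(mean=0.0, sigma=cfg.area_cv)
            rate = rate_salt if treat == "salt" else cfg.rgr_per_day
            area = float(_area_at(cfg, a0, rate, day))
            psw = cfg.psw_b0 + cfg.psw_b1 * day
            sdw = area * psw + rng.normal(0.0, cfg.noise_sd_g)
            sdw = max(sdw, cfg.sdw_floor_g)
            rows.append(
                {
                    "plant_id": f"P{pid:04d}",
                    "variety": var,
                    "treatment": treat,
                    "age_days": day,
                    "area_mm2": area,
                    "sdw_g": sdw,
                }
            )
    obs = pd.DataFrame(rows)
    truth = {
        "psw_b0": cfg.psw_b0,
        "psw_b1": cfg.psw_b1,
        "model_b_coefficients": {"c0": 0.0, "c1": cfg.psw_b0, "c2": cfg.psw_b1},
        "rgr_control": cfg.rgr_per_day,
        "rgr_salt": rate_salt,
        "salt_growth_reduction": cfg.salt_growth_reduction,
        "noise_sd_g": cfg.noise_sd_g,
        "growth": cfg.growth,
        "seed": int(cfg.seed if seed is None else seed),
    }
    return obs, truth


def simulate_area_age_dataset(
    coefficients: tuple[float, float, float],
    n: int = 320,
    noise_sd_g: float = 0.05,
    area_range: tuple[float, float] = (10.0, 400.0),
    harvest_days: tuple[int, ...] = (15, 26, 34, 40, 43),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate observations directly from an area-by-age model.

    SDW = c0 + c1·A + c2·A·HD + Gaussian(0, noise_sd_g), with areas uniform
    over ``area_range`` and ages allocated evenly over the harvest days —
    the design used for coefficient-recovery experiments, where a fitted
    model's published coefficients serve as generating truth.
    """
    if n % len(harvest_days) != 0:
        raise ConfigurationError("n must be a multiple of the number of harvest days")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    c0, c1, c2 = coefficients
    area = rng.uniform(*area_range, n)
    age = np.repeat(np.asarray(harvest_days, dtype=float), n // len(harvest_days))
    rng.shuffle(age)
    sdw = c0 + c1 * area + c2 * area * age + rng.normal(0.0, noise_sd_g, n)
    return pd.DataFrame(
        {
            "plant_id": [f"S{i:04d}" for i in range(1, n + 1)],
            "variety": "simulated",
            "treatment": "control",
            "age_days": age,
            "area_mm2": area,
            "sdw_g": sdw,
        }
    )


@dataclasses.dataclass(frozen=True)
class RenderSpec:
    """Geometry and colours of the rendered plant views.

    Plant and background colours must be well separated in hue (green
    ~120° vs. blue ~240° by default) so the default segmentation band
    recovers the drawn pixels exactly when anti-aliasing is off.
    """

    width: int = 1280
    height: int = 960
    plant_rgb: tuple[int, int, int] = (40, 200, 40)
    background_rgb: tuple[int, int, int] = (40, 40, 200)
    leaf_width_px: float = 4.0
    leaf_length_frac: tuple[float, float] = (0.18, 0.45)
    antialias: bool = False
    aa_sigma: float = 0.6
    max_fill: float = 0.5  # largest drawable fraction of the frame

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("image dimensions must be positive")
        hue_plant = float(rgb_to_hsi(np.array(self.plant_rgb, float).reshape(1, 1, 3)).hue[0, 0])
        hue_bg = float(rgb_to_hsi(np.array(self.background_rgb, float).reshape(1, 1, 3)).hue[0, 0])
        sep = abs(hue_plant - hue_bg)
        if min(sep, 360.0 - sep) < 30.0:
            raise ConfigurationError("plant and background hues must be well separated")
        if self.leaf_width_px < 1.0:
            raise ConfigurationError("leaf_width_px must be at least 1")


def _view_pixel_budgets(
    target_area_mm2: float, calibration: tuple[float, float, float]
) -> list[int]:
    """Integer pixel counts per view whose calibrated sum best matches the target.

    The target area is split equally over the three views, floored to whole
    pixels, then single pixels are added greedily (largest fractional
    remainder first) while that brings the calibrated total closer to the
    target.
    """
    if target_area_mm2 < 0:
        raise InputError("target area must be non-negative")
    exact = [target_area_mm2 / 3.0 / c for c in calibration]
    counts = [int(np.floor(p)) for p in exact]
    remainders = [p - n for p, n in zip(exact, counts)]
    order = np.argsort(remainders)[::-1]
    for j in order:
        total = sum(n * c for n, c in zip(counts, calibration))
        if abs((total + calibration[j]) - target_area_mm2) < abs(total - target_area_mm2):
            counts[j] += 1
    return counts


def _draw_view(
    budget: int, spec: RenderSpec, rng: np.random.Generator, view: str
) -> np.ndarray:
    """Draw leaf strokes into a boolean canvas containing exactly ``budget`` pixels."""
    h, w = spec.height, spec.width
    if budget > spec.max_fill * h * w:
        raise ConfigurationError(
            f"target area unreachable: needs {budget} px, frame allows "
            f"{int(spec.max_fill * h * w)}"
        )
    canvas = np.zeros((h, w), dtype=bool)
    if budget == 0:
        return canvas
    if view == "top":
        base = np.array([h / 2.0, w / 2.0])
    else:
        base = np.array([h - 1.0, w / 2.0])
    radius = spec.leaf_width_px / 2.0
    drawn = 0
    stale = 0
    while drawn < budget:
        # one quadratic bezier "leaf" from the base point
        if view == "top":
            ang = rng.uniform(0.0, 2.0 * np.pi)
        else:
            ang = rng.uniform(np.pi / 2.0 - 1.3, np.pi / 2.0 + 1.3)  # mostly upward
        length = rng.uniform(*spec.leaf_length_frac) * min(h, w)
        direction = np.array([-np.sin(ang), np.cos(ang)])
        perp = np.array([-direction[1], direction[0]])
        p0, p2 = base, base + length * direction
        p1 = base + 0.5 * length * direction + rng.uniform(-0.2, 0.2) * length * perp
        t = np.linspace(0.0, 1.0, max(int(length * 2), 4))[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
        progressed = False
        for r, c in pts:
            rr, cc = disk((r, c), radius, shape=(h, w))
            new = ~canvas[rr, cc]
            if not new.any():
                continue
            idx = np.nonzero(new)[0]
            need = budget - drawn
            if idx.size > need:
                idx = idx[:need]
            canvas[rr[idx], cc[idx]] = True
            drawn += idx.size
            progressed = True
            if drawn >= budget:
                break
        stale = 0 if progressed else stale + 1
        if stale > 200:
            raise ConfigurationError("target area unreachable with this render geometry")
    return canvas


def _composite(mask: np.ndarray, spec: RenderSpec) -> np.ndarray:
    plant = np.array(spec.plant_rgb, dtype=float)
    bg = np.array(spec.background_rgb, dtype=float)
    if spec.antialias:
        cov = ndimage.gaussian_filter(mask.astype(float), spec.aa_sigma)[..., None]
    else:
        cov = mask.astype(float)[..., None]
    img = plant * cov + bg * (1.0 - cov)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_plant_views(
    target_area_mm2: float,
    spec: RenderSpec | None = None,
    calibration: tuple[float, float, float] = (0.25, 0.25, 0.25),
    seed: int = 0,
) -> tuple[ViewTriplet, dict[str, int]]:
    """Render a three-view plant with a known total projected area.

    Returns the triplet and the exact drawn plant-pixel count per view
    (the renderer's ground truth; with anti-aliasing off the segmentation
    of the render recovers these counts exactly).
    """
    spec = spec or RenderSpec()
    spec.validate()
    if any(c <= 0 for c in calibration):
        raise ConfigurationError("calibration factors must be positive")
    budgets = _view_pixel_budgets(float(target_area_mm2), tuple(calibration))
    rng = np.random.default_rng(seed)
    images = {}
    counts = {}
    for name, budget in zip(VIEW_NAMES, budgets):
        mask = _draw_view(budget, spec, rng, name)
        images[name] = _composite(mask, spec)
        counts[name] = budget
    triplet = ViewTriplet(
        top=images["top"],
        side0=images["side0"],
        side90=images["side90"],
        calibration=tuple(calibration),
    )
    return triplet, counts


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_suite(
    out_dir,
    n_plants: int = 5,
    seed: int = DEFAULT_SEED,
    image_size: tuple[int, int] = (320, 240),
    calibration: tuple[float, float, float] = (0.25, 0.25, 0.25),
    antialias: bool = False,
) -> dict[str, str]:
    """Write a small, seeded, byte-stable fixture set to ``out_dir``.

    One rendered PNG triplet per plant (named ``{plant_id}_{view}.png``), a
    phenotype CSV whose ``area_mm2`` column holds the *rendered* calibrated
    area (so the imaging pipeline closes the loop on it exactly), a
    ground-truth JSON with per-view pixel counts, and a manifest mapping
    every written file to its SHA-256 checksum.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    days = (15, 26, 34, 40, 43)
    reps = int(np.ceil(n_plants / len(days)))
    cfg = GrowthSimConfig(
        n_plants=reps * len(days), plants_per_harvest=reps, seed=seed
    )
    obs, _ = simulate_growth_dataset(cfg)
    obs = obs.iloc[:n_plants].reset_index(drop=True)
    w, h = image_size
    spec = RenderSpec(width=w, height=h, antialias=antialias)
    truth: dict[str, dict] = {}
    files: list[Path] = []
    for i, row in obs.iterrows():
        triplet, counts = render_plant_views(
            row["area_mm2"], spec, calibration, seed=seed + i
        )
        rendered = {v: counts[v] * triplet.calibration_for(v) for v in VIEW_NAMES}
        obs.loc[i, "area_mm2"] = sum(rendered.values())
        truth[row["plant_id"]] = {
            "per_view_pixels": counts,
            "per_view_mm2": rendered,
            "total_mm2": sum(rendered.values()),
        }
        for view in VIEW_NAMES:
            path = out / f"{row['plant_id']}_{view}.png"
            Image.fromarray(triplet.view(view)).save(path)
            files.append(path)

    pheno = out / "phenotype.csv"
    obs.to_csv(pheno, index=False)
    files.append(pheno)
    gt = out / "ground_truth.json"
    gt.write_text(json.dumps(truth, indent=2, sort_keys=True))
    files.append(gt)

    manifest = {p.name: _sha256(p) for p in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
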