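"""File formats: phenotype CSV, PNG images and masks, fit reports, YAML config."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .errors import InputError
from .models import FitResult

__all__ = [
    "PHENOTYPE_COLUMNS",
    "read_phenotype_csv",
    "write_phenotype_csv",
    "read_image",
    "write_image",
    "write_mask_png",
    "read_mask_png",
    "fit_result_to_json",
    "write_fit_result",
    "load_config",
    "sha256_file",
]

#: Required phenotype CSV header (``sfw_g`` fresh weight is optional).
PHENOTYPE_COLUMNS = ("plant_id", "variety", "treatment", "age_days", "area_mm2", "sdw_g")


def read_phenotype_csv(path) -> pd.DataFrame:
    """Read and validate a phenotype table (comma-separated, UTF-8, '.' decimal)."""
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"phenotype CSV {path} is missing column(s): {', '.join(missing)}")
    for col in ("age_days", "area_mm2", "sdw_g"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise InputError(f"phenotype column {col!r} must be numeric")
    return df


def write_phenotype_csv(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False)


def read_image(path) -> np.ndarray:
    """Read a PNG (or any Pillow-supported raster) as an 8-bit RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_image(img: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(path)


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit PNG (plant = 255, background = 0)."""
    Image.fromarray((np.asarray(mask, dtype=bool) * np.uint8(255))).save(path)


def read_mask_png(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127


def fit_result_to_json(fit: FitResult) -> str:
    payload = {
        "form": fit.form,
        "nobs": fit.nobs,
        "df_resid": fit.df_resid,
        "rsquared": fit.rsquared,
        "coefficients": fit.summary_frame().to_dict(orient="records"),
    }
    if fit.scale_const is not None:
        payload["scale_const"] = fit.scale_const
    return json.dumps(payload, indent=2)


def write_fit_result(fit: FitResult, path) -> None:
    """Serialize a FitResult; format chosen from the suffix (.json or .csv)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(fit_result_to_json(fit))
    else:
        fit.summary_frame().to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise InputError(f"config {path} must be a mapping")
    return cfg


def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
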