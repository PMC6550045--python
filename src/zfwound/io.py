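"""File-format helpers: TIFF stacks, CSV/TSV tables, YAML configuration."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import WoundROI
from .simgen import CountSimConfig, SceneConfig


def save_stack(path, stack) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def load_stack(path) -> np.ndarray:
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def load_roi_yaml(path) -> WoundROI:
    with open(path) as fh:
        return WoundROI.from_dict(yaml.safe_load(fh))


def save_roi_yaml(path, roi: WoundROI) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(roi.to_dict(), fh)


def scene_config_from_yaml(path) -> SceneConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "wound" in raw and raw["wound"] is not None:
        raw["wound"] = WoundROI.from_dict(raw["wound"])
    for key in ("axis_ratio_range",):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SceneConfig(**raw)


def counts_config_from_yaml(path) -> CountSimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("lfc_amp_magnitude", "attenuation_factor_range",
                "lfc_beclo_magnitude"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return CountSimConfig(**raw)


def read_counts_tsv(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return counts


def read_meta_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path, df: pd.DataFrame, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_csv(path, df: pd.DataFrame, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
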