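"""File formats: OME-TIFF channel stacks, YAML specs, CSV tables.

All CSVs are UTF-8, comma-delimited, with a mandatory header row and
``NA`` for missing values.  Scene and cohort specifications round-trip
through YAML; channel stacks are written as single OME-TIFF files with
five named channels (dapi, ker, vim, pdl1, cd45mask).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .quantify import CHANNELS, ChannelStack
from .synthgen import (
    CellClassModel,
    CohortSimSpec,
    LogNormalIntensity,
    LogUniformRange,
    SceneSpec,
)

__all__ = [
    "STACK_CHANNEL_ORDER",
    "write_stack",
    "read_stack",
    "scene_spec_to_yaml",
    "scene_spec_from_yaml",
    "cohort_spec_from_yaml",
    "write_csv",
    "read_csv",
]

STACK_CHANNEL_ORDER = (*CHANNELS, "cd45mask")


def write_stack(stack: ChannelStack, path: str | Path) -> None:
    """Write a channel stack as one OME-TIFF with named channels."""
    arr = np.stack([stack.channel(c) for c in STACK_CHANNEL_ORDER]).astype(np.float32)
    tifffile.imwrite(
        str(path),
        arr,
        ome=True,
        metadata={"axes": "CYX", "Channel": {"Name": list(STACK_CHANNEL_ORDER)}},
    )


def _channel_names_from_ome(tif: tifffile.TiffFile) -> list[str] | None:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        names = [
            ch.get("Name")
            for ch in root.iter()
            if ch.tag.endswith("Channel") and ch.get("Name")
        ]
        return names or None
    except Exception:
        return None


def read_stack(path: str | Path, channel_map: dict | None = None) -> ChannelStack:
    """Read a channel stack from (OME-)TIFF.

    Channel identity comes from the OME channel names when present;
    otherwise from ``channel_map`` (name -> plane index, e.g.
    ``{"dapi": 0, "ker": 1, ...}``); otherwise the default plane order
    dapi, ker, vim, pdl1, cd45mask is assumed.
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        names = _channel_names_from_ome(tif) if tif.is_ome else None
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-D channel stack, got shape {arr.shape}")
    if channel_map is None:
        order = names if names is not None else list(STACK_CHANNEL_ORDER)
        channel_map = {name: i for i, name in enumerate(order)}
    missing = set(STACK_CHANNEL_ORDER) - set(channel_map)
    if missing:
        raise ValueError(f"channel map missing channels: {sorted(missing)}")
    planes = {name: np.asarray(arr[channel_map[name]], dtype=float) for name in STACK_CHANNEL_ORDER}
    planes["cd45mask"] = (planes["cd45mask"] > 0.5).astype(np.uint8)
    return ChannelStack(**planes)


# ---------------------------------------------------------------------------
# Scene / cohort specs in YAML
# ---------------------------------------------------------------------------

def _dist_to_dict(d) -> dict:
    if isinstance(d, LogNormalIntensity):
        return {"dist": "lognormal", "median": d.median, "gsd": d.gsd}
    if isinstance(d, LogUniformRange):
        return {"dist": "loguniform", "lo": d.lo, "hi": d.hi}
    raise TypeError(type(d))


def _dist_from_dict(d: dict):
    kind = d.get("dist")
    if kind == "lognormal":
        return LogNormalIntensity(median=float(d["median"]), gsd=float(d.get("gsd", 1.0)))
    if kind == "loguniform":
        return LogUniformRange(lo=float(d["lo"]), hi=float(d["hi"]))
    raise ValueError(f"unknown distribution kind {kind!r}")


def _class_model_to_dict(m: CellClassModel) -> dict:
    out = {
        "dapi": _dist_to_dict(m.dapi),
        "ker": _dist_to_dict(m.ker),
        "pdl1": _dist_to_dict(m.pdl1),
        "cd45_positive": m.cd45_positive,
    }
    if m.vim_ker_ratio is not None:
        out["vim_ker_ratio"] = _dist_to_dict(m.vim_ker_ratio)
    else:
        out["vim"] = _dist_to_dict(m.vim)
    return out


def _class_model_from_dict(d: dict) -> CellClassModel:
    known = {"dapi", "ker", "pdl1", "vim", "vim_ker_ratio", "cd45_positive"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown class-model keys: {sorted(unknown)}")
    kwargs = dict(
        dapi=_dist_from_dict(d["dapi"]),
        ker=_dist_from_dict(d["ker"]),
        pdl1=_dist_from_dict(d["pdl1"]),
        cd45_positive=bool(d.get("cd45_positive", False)),
    )
    if "vim_ker_ratio" in d:
        kwargs["vim_ker_ratio"] = _dist_from_dict(d["vim_ker_ratio"])
    if "vim" in d:
        kwargs["vim"] = _dist_from_dict(d["vim"])
    return CellClassModel(**kwargs)


_SCENE_SCALARS = (
    "image_height_px", "image_width_px", "nucleus_radius_px", "cell_radius_px",
    "psf_sigma_px", "gaussian_noise_sd", "use_poisson_noise", "seed",
)


def scene_spec_to_yaml(spec: SceneSpec, path: str | Path) -> None:
    out = {name: getattr(spec, name) for name in _SCENE_SCALARS}
    out["n_cells_per_class"] = dict(spec.n_cells_per_class)
    out["cluster_spec"] = [[cls, int(size)] for cls, size in spec.cluster_spec]
    out["background_level"] = dict(spec.background_level)
    out["classes"] = {
        name: _class_model_to_dict(model) for name, model in spec.intensity_model.items()
    }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


def scene_spec_from_yaml(path: str | Path, *, seed: int | None = None) -> SceneSpec:
    """Load a :class:`SceneSpec` from YAML; ``seed`` overrides the file's."""
    d = yaml.safe_load(Path(path).read_text())
    known = set(_SCENE_SCALARS) | {
        "n_cells_per_class", "cluster_spec", "background_level", "classes",
    }
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown scene spec keys: {sorted(unknown)}")
    kwargs = {name: d[name] for name in _SCENE_SCALARS if name in d}
    if "n_cells_per_class" in d:
        kwargs["n_cells_per_class"] = dict(d["n_cells_per_class"])
    if "cluster_spec" in d:
        kwargs["cluster_spec"] = tuple((cls, int(size)) for cls, size in d["cluster_spec"])
    if "background_level" in d:
        kwargs["background_level"] = {k: float(v) for k, v in d["background_level"].items()}
    if "classes" in d:
        kwargs["intensity_model"] = {
            name: _class_model_from_dict(m) for name, m in d["classes"].items()
        }
    if seed is not None:
        kwargs["seed"] = int(seed)
    return SceneSpec(**kwargs)


def cohort_spec_from_yaml(path: str | Path, *, seed: int | None = None) -> CohortSimSpec:
    d = yaml.safe_load(Path(path).read_text())
    known = {
        "n_patients", "prevalence", "baseline_hazard", "log_hazard_ratios",
        "censoring_rate", "followup_horizon_months", "seed", "endpoint",
    }
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown cohort spec keys: {sorted(unknown)}")
    if seed is not None:
        d["seed"] = int(seed)
    return CohortSimSpec(**d)


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 CSV with NA for missing values."""
    df.to_csv(path, index=False, na_rep="NA", encoding="utf-8")


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"], encoding="utf-8")
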