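"""Reading and writing the package's file formats.

Weather files are plain CSV with header
``date,tmax,tmin,rhum,wind,srad,precip`` (ISO-8601 dates) plus an
optional ``realization`` column; crop and soil parameter sets and the
experiment configuration are YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .crop_surrogate import CropParams, SoilParams
from .exceptions import DomainError
from .synthetic_weather import ClimateConfig, WeatherSeries

__all__ = [
    "WEATHER_COLUMNS",
    "read_weather_csv",
    "write_weather_csv",
    "load_crop_params",
    "load_soil_params",
    "load_climate_config",
    "bundled_crop",
    "bundled_soil",
]

WEATHER_COLUMNS = ["date", "tmax", "tmin", "rhum", "wind", "srad", "precip"]

_DATA_DIR = Path(__file__).parent / "data"


def write_weather_csv(series: WeatherSeries, path: str | Path) -> None:
    series.to_frame(include_realization=True).to_csv(path, index=False)


def read_weather_csv(
    path: str | Path,
    site_id: str = "unknown",
    latitude: float = 45.0,
    realization: str | None = None,
) -> WeatherSeries:
    """Read one realization's season from a weather CSV.

    The realization label is taken from the ``realization`` column when
    present (which must then be single-valued), else from the argument,
    else from the file name stem's last ``_``-separated token.
    """
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing weather columns {missing}")
    if "realization" in df.columns:
        labels = df["realization"].unique()
        if len(labels) != 1:
            raise DomainError(f"{path}: expected a single realization, got {list(labels)}")
        realization = str(labels[0])
    elif realization is None:
        realization = Path(path).stem.split("_")[-1]
    return WeatherSeries(
        site_id=site_id,
        realization=realization,
        latitude=latitude,
        dates=pd.DatetimeIndex(pd.to_datetime(df["date"])),
        tmax=df["tmax"].to_numpy(float),
        tmin=df["tmin"].to_numpy(float),
        rhum=df["rhum"].to_numpy(float),
        wind=df["wind"].to_numpy(float),
        srad=df["srad"].to_numpy(float),
        precip=df["precip"].to_numpy(float),
    )


def _load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise DomainError(f"{path}: expected a YAML mapping")
    return doc


def load_crop_params(path: str | Path) -> CropParams:
    doc = _load_yaml(path)
    doc.pop("description", None)
    doc["kcb_stages"] = tuple(doc["kcb_stages"])
    doc["stage_fractions"] = tuple(doc["stage_fractions"])
    return CropParams(**doc)


def load_soil_params(path: str | Path) -> SoilParams:
    doc = _load_yaml(path)
    doc.pop("description", None)
    doc.pop("site_id", None)
    doc.pop("latitude", None)
    return SoilParams(**doc)


def load_climate_config(path: str | Path) -> ClimateConfig:
    """Load a ClimateConfig from a YAML file with a ``climate:`` block
    (or a bare mapping of field names)."""
    doc = _load_yaml(path)
    block = doc.get("climate", doc)
    if "members_per_year" in block:
        block["members_per_year"] = {int(k): int(v) for k, v in block["members_per_year"].items()}
    return ClimateConfig(**block)


def bundled_crop(name: str) -> CropParams:
    """Load one of the bundled synthetic crop parameter sets
    (``maize``, ``spring_barley``, ``sunflower``)."""
    path = _DATA_DIR / "crops" / f"{name}.yaml"
    if not path.exists():
        available = sorted(p.stem for p in (_DATA_DIR / "crops").glob("*.yaml"))
        raise DomainError(f"no bundled crop {name!r}; available: {available}")
    return load_crop_params(path)


def bundled_soil(name: str) -> SoilParams:
    """Load one of the bundled synthetic soil parameter sets
    (``pannonia_south``, ``pannonia_north``)."""
    path = _DATA_DIR / "soils" / f"{name}.yaml"
    if not path.exists():
        available = sorted(p.stem for p in (_DATA_DIR / "soils").glob("*.yaml"))
        raise DomainError(f"no bundled soil {name!r}; available: {available}")
    return load_soil_params(path)
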