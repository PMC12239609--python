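"""CSV readers/writers with schema validation.

All tables are UTF-8 CSV with a header row, dates ISO-8601, units embedded
in column names where ambiguous (``dls_h``, ``tt_cd``).  Validation errors
carry the file name and 1-based line number of the offending row.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import pandas as pd

from .bvp import GenotypeDev
from .envirotyping import Environment
from .exceptions import SchemaError
from .reaction_norm import ControlGroup
from .thermal_time import WeatherSeries

__all__ = [
    "read_weather_csv",
    "read_environments_csv",
    "read_genotypes_csv",
    "read_phenotypes_csv",
    "read_controls_csv",
]


def _read_csv(path, required: set) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    return df


def _parse_date(value, path, line: int, col: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise SchemaError(f"{path}:{line}: invalid ISO date in {col!r}: {value!r}") from exc


def read_weather_csv(path, name: str | None = None) -> WeatherSeries:
    """Read one environment's daily weather: ``date, tmin, tmax[, tmean]``."""
    path = Path(path)
    df = _read_csv(path, {"date", "tmin", "tmax"})
    for i, row in enumerate(df.itertuples(index=False), start=2):
        _parse_date(row.date, path, i, "date")
        for col in ("tmin", "tmax"):
            try:
                float(getattr(row, col))
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{path}:{i}: non-numeric {col!r}: {getattr(row, col)!r}"
                ) from exc
    try:
        return WeatherSeries(df, name=name or path.stem)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_environments_csv(path, weather_dir=None) -> list[Environment]:
    """Read the environment table:
    ``env_id, latitude, longitude, sowing_date[, emergence_date][, weather_file]``.

    Weather files are resolved against ``weather_dir`` (default: directory of
    the environments file), falling back to ``<env_id>.csv``.
    """
    path = Path(path)
    df = _read_csv(path, {"env_id", "latitude", "longitude", "sowing_date"})
    weather_dir = Path(weather_dir) if weather_dir is not None else path.parent
    envs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sowing = _parse_date(row.sowing_date, path, i, "sowing_date")
        emergence = None
        if "emergence_date" in df.columns and pd.notna(row.emergence_date) and str(row.emergence_date):
            emergence = _parse_date(row.emergence_date, path, i, "emergence_date")
        wx_name = (
            str(row.weather_file)
            if "weather_file" in df.columns and pd.notna(row.weather_file)
            else f"{row.env_id}.csv"
        )
        wx_path = weather_dir / wx_name
        if not wx_path.exists():
            raise SchemaError(f"{path}:{i}: weather file not found: {wx_path}")
        weather = read_weather_csv(wx_path, name=str(row.env_id))
        envs.append(
            Environment(
                env_id=str(row.env_id),
                latitude=float(row.latitude),
                longitude=float(row.longitude),
                sowing_date=sowing,
                emergence_date=emergence,
                weather=weather,
            )
        )
    return envs


def read_genotypes_csv(path) -> list[GenotypeDev]:
    """Read genotype development parameters:
    ``genotype_id, phyllochron, final_leaf_number[, bvp]``.

    A supplied ``bvp`` overrides prediction from the other two columns."""
    path = Path(path)
    df = _read_csv(path, {"genotype_id"})
    if not ({"phyllochron", "final_leaf_number"} <= set(df.columns) or "bvp" in df.columns):
        raise SchemaError(
            f"{path}: need either (phyllochron, final_leaf_number) or bvp columns"
        )
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        kwargs = {}
        for col in ("phyllochron", "final_leaf_number", "bvp"):
            if col in df.columns and pd.notna(getattr(row, col, None)):
                try:
                    kwargs[col] = float(getattr(row, col))
                except (TypeError, ValueError) as exc:
                    raise SchemaError(
                        f"{path}:{i}: non-numeric {col!r}: {getattr(row, col)!r}"
                    ) from exc
        try:
            out.append(GenotypeDev(genotype_id=str(row.genotype_id), **kwargs))
        except Exception as exc:
            raise SchemaError(f"{path}:{i}: {exc}") from exc
    return out


def read_phenotypes_csv(path) -> pd.DataFrame:
    """Read MET phenotypes: ``genotype_id, env_id, days_to_anthesis`` (BLUEs)."""
    path = Path(path)
    df = _read_csv(path, {"genotype_id", "env_id", "days_to_anthesis"})
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            v = float(row.days_to_anthesis)
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"{path}:{i}: non-numeric days_to_anthesis: {row.days_to_anthesis!r}"
            ) from exc
        if v <= 0:
            raise SchemaError(f"{path}:{i}: days_to_anthesis must be positive, got {v}")
    df["genotype_id"] = df["genotype_id"].astype(str)
    df["env_id"] = df["env_id"].astype(str)
    return df


def read_controls_csv(path) -> list[ControlGroup]:
    """Read the control mapping: long format ``set_id, genotype_id, env_id``
    where each row links one control set to one genotype or environment
    (leave the other field blank)."""
    path = Path(path)
    df = _read_csv(path, {"set_id"})
    if not {"genotype_id", "env_id"} & set(df.columns):
        raise SchemaError(f"{path}: need genotype_id and/or env_id columns")
    groups: dict[str, ControlGroup] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row.set_id)
        cg = groups.setdefault(sid, ControlGroup(sid, [], []))
        g = getattr(row, "genotype_id", None)
        e = getattr(row, "env_id", None)
        has_g = pd.notna(g) and str(g) != ""
        has_e = pd.notna(e) and str(e) != ""
        if not has_g and not has_e:
            raise SchemaError(f"{path}:{i}: row assigns neither a genotype nor an environment")
        if has_g:
            cg.genotype_ids.append(str(g))
        if has_e:
            cg.env_ids.append(str(e))
    return list(groups.values())
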