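"""Delimited-text readers and writers (comma, header row, UTF-8, '.' decimal).

Floats are written with Python's shortest round-tripping representation,
so every table survives a write/read cycle bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .foodweb import SpeciesParams
from .synthetic_world import World, WorldConfig
from .trade import TradeMatrix


def write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, encoding="utf-8")
    return path


def read_csv(path: Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col, encoding="utf-8")


def write_world(world: World, outdir: Path) -> dict[str, Path]:
    """Write provinces/distances/environment/supply/demand/consumption tables."""
    outdir = Path(outdir)
    written = {
        "provinces": write_csv(world.provinces, outdir / "provinces.csv"),
        "distances": write_csv(world.distance, outdir / "distances.csv"),
        "consumption": write_csv(world.consumption, outdir / "consumption.csv"),
        "supply": write_csv(world.supply, outdir / "supply.csv"),
        "demand": write_csv(world.demand, outdir / "demand.csv"),
        "environment": write_csv(
            world.environment, outdir / "environment.csv", index=False
        ),
    }
    cfg = {k: v for k, v in vars(world.config).items()}
    (outdir / "world_config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
    written["world_config"] = outdir / "world_config.json"
    return written


def read_world(outdir: Path) -> World:
    """Rebuild a :class:`World` from the tables written by :func:`write_world`."""
    outdir = Path(outdir)
    cfg_path = outdir / "world_config.json"
    if not cfg_path.exists():
        raise ConfigError(f"missing {cfg_path}")
    config = WorldConfig(**json.loads(cfg_path.read_text()))
    provinces = read_csv(outdir / "provinces.csv")
    provinces["coastal"] = provinces["coastal"].astype(bool)
    return World(
        config=config,
        provinces=provinces,
        distance=read_csv(outdir / "distances.csv"),
        consumption=read_csv(outdir / "consumption.csv"),
        supply=read_csv(outdir / "supply.csv"),
        demand=read_csv(outdir / "demand.csv"),
        environment=read_csv(outdir / "environment.csv", index_col=None),
    )


def write_species(species: list[SpeciesParams], path: Path) -> Path:
    rows = []
    for s in species:
        row = {k: v for k, v in vars(s).items()}
        rows.append(row)
    return write_csv(pd.DataFrame(rows).set_index("name"), Path(path))


def read_species(path: Path) -> list[SpeciesParams]:
    df = read_csv(Path(path))
    out = []
    for name, row in df.iterrows():
        kwargs = row.to_dict()
        if "benthic" in kwargs:
            kwargs["benthic"] = bool(kwargs["benthic"])
        if "k1" in kwargs and pd.isna(kwargs["k1"]):
            kwargs["k1"] = None
        out.append(SpeciesParams(name=name, **kwargs))
    return out


def write_trade_matrix(t: TradeMatrix, path: Path) -> Path:
    df = t.flows.copy()
    df["_slack"] = t.slack
    return write_csv(df, Path(path))


def read_trade_matrix(path: Path, species: str | None = None) -> TradeMatrix:
    df = read_csv(Path(path))
    slack = df.pop("_slack")
    return TradeMatrix(flows=df, slack=slack, species=species)
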