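"""YAML run configuration: parsing, validation, seed fan-out.

A run config is a mapping of named blocks (``rates``, ``geometry``,
``sensors``, ``segmentation``, ``quantification``, ``synthesis``,
``output``) whose keys map one-to-one onto the dataclass fields of the
corresponding module.  Unknown keys are rejected with a field-level
message so typos fail before any compute; negative rates are caught by
the dataclass validators themselves.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Mapping

import numpy as np
import yaml

from .image_analysis import SegmentationParams
from .simulator import Geometry1D, Geometry2D, RateParams, Sensor
from .synthetic_data import StackSpec, TableSpec

__all__ = ["ConfigError", "load_config", "build_rates", "build_geometry_2d",
           "build_geometry_1d", "build_segmentation", "build_table_spec",
           "build_stack_spec", "substream_seed"]

KNOWN_BLOCKS = {"rates", "geometry", "sensors", "segmentation",
                "quantification", "synthesis", "output", "seed"}


class ConfigError(ValueError):
    """A config failed validation; message names the offending field."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ConfigError("config root must be a mapping of blocks")
    unknown = set(cfg) - KNOWN_BLOCKS
    if unknown:
        raise ConfigError(f"unknown config block(s): {sorted(unknown)}")
    return dict(cfg)


def _build(cls, block: Mapping[str, Any] | None, block_name: str, **extra):
    block = dict(block or {})
    block.update(extra)
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ConfigError(f"{block_name}: unknown key(s) {sorted(unknown)}; "
                          f"expected a subset of {sorted(fields)}")
    try:
        return cls(**block)
    except (ValueError, TypeError) as err:
        raise ConfigError(f"{block_name}: {err}") from err


def build_rates(cfg: Mapping, block: str = "rates") -> RateParams:
    return _build(RateParams, cfg.get(block), block)


def build_geometry_2d(cfg: Mapping) -> Geometry2D:
    geo = dict(cfg.get("geometry") or {})
    sensors_cfg = cfg.get("sensors")
    sensors: tuple[Sensor, ...] = ()
    if isinstance(sensors_cfg, list):
        built = []
        for i, s in enumerate(sensors_cfg):
            s = dict(s)
            params = _build(RateParams, s.pop("rates", None), f"sensors[{i}].rates")
            built.append(_build(Sensor, s, f"sensors[{i}]", params=params))
        sensors = tuple(built)
    geo.pop("grid_spacing", None)
    return _build(Geometry2D, geo, "geometry", sensors=sensors)


def build_geometry_1d(cfg: Mapping) -> Geometry1D:
    geo = dict(cfg.get("geometry") or {})
    for k in ("width", "mesh_spacing", "sensors"):
        geo.pop(k, None)
    return _build(Geometry1D, geo, "geometry")


def build_segmentation(cfg: Mapping) -> SegmentationParams:
    return _build(SegmentationParams, cfg.get("segmentation"), "segmentation")


def build_table_spec(cfg: Mapping, seed: int | None = None) -> TableSpec:
    block = dict(cfg.get("synthesis") or {})
    if seed is not None:
        block["seed"] = seed
    return _build(TableSpec, block, "synthesis")


def build_stack_spec(cfg: Mapping, seed: int | None = None) -> StackSpec:
    block = dict(cfg.get("synthesis") or {})
    grad = block.pop("gradient", None)
    if seed is not None:
        block["seed"] = seed
    if grad is not None:
        block["gradient"] = _build(TableSpec, grad, "synthesis.gradient")
    return _build(StackSpec, block, "synthesis")


def substream_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from one global seed, below 2**31.

    Stages re-run in isolation reproduce their stream exactly.
    """
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))
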