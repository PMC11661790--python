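"""TOML run configuration: models, competition, interactions, picking.

Example::

    [competition]
    emitting = ["membrane", "carbon"]
    absorbing = ["platform"]

    [[interactions]]
    child = "platform"
    parent = "membrane"
    kind = "avoid"
    threshold = 0.5
    radius_nm = 10.0

    [picking]
    threshold = 0.5
    min_volume_nm3 = 50.0
    min_spacing_nm = 20.0

    [phantom]
    shape = [96, 160, 160]
    n_vesicles = 3
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .interactions import CompetitionConfig, InteractionSpec
from .phantom import PhantomConfig
from .picking import PickConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    competition: CompetitionConfig | None = None
    interactions: list[InteractionSpec] = field(default_factory=list)
    picking: PickConfig | None = None
    phantom: PhantomConfig | None = None
    raw: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    raw = tomllib.loads(Path(path).read_text())
    cfg = RunConfig(raw=raw)
    if "competition" in raw:
        c = raw["competition"]
        cfg.competition = CompetitionConfig(
            emitting=frozenset(c.get("emitting", [])),
            absorbing=frozenset(c.get("absorbing", [])),
        )
    for item in raw.get("interactions", []):
        cfg.interactions.append(
            InteractionSpec(
                parent_feature=item["parent"],
                child_feature=item["child"],
                kind=item["kind"],
                parent_threshold=float(item.get("threshold", 0.5)),
                radius_nm=float(item.get("radius_nm", 0.0)),
            )
        )
    if "picking" in raw:
        p = raw["picking"]
        cfg.picking = PickConfig(
            threshold=float(p.get("threshold", 0.5)),
            min_volume_nm3=float(p.get("min_volume_nm3", 0.0)),
            min_spacing_nm=float(p.get("min_spacing_nm", 0.0)),
            pixel_size=float(p.get("pixel_size", 10.0)),
        )
    if "phantom" in raw:
        ph = dict(raw["phantom"])
        if "shape" in ph:
            ph["shape"] = tuple(ph["shape"])
        for key in ("vesicle_radius_range", "granule_radius_range", "filament_length_range"):
            if key in ph:
                ph[key] = tuple(ph[key])
        cfg.phantom = PhantomConfig(**ph)
    return cfg
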