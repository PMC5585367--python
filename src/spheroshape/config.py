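"""Flat run configuration shared by the CLI commands.

Keys mirror the tunables of the pipeline stages, dotted by stage name
(``segmentation.sigma_px`` etc.). Unknown keys are rejected rather than
ignored so a typo cannot silently fall back to a default, and the
effective configuration is echoed into every output directory for
provenance.
"""

from __future__ import annotations

import json
import os
import tomllib
from dataclasses import asdict, dataclass, fields

from .errors import ValidationError


@dataclass
class RunConfig:
    # segmentation
    segmentation_sigma_px: float = 2.0
    segmentation_closing_radius_px: int = 3
    segmentation_min_area_px: int = 200
    segmentation_satellite_ratio: float = 0.10
    segmentation_polarity: str = "dark_object"
    # morphometry
    morphometry_n_sectors: int = 32
    morphometry_sigma_mode: str = "set_mean"
    # imaging
    pixel_size_um: float | None = None
    # logging
    log_level: str = "INFO"

    @classmethod
    def key_map(cls) -> dict[str, str]:
        """TOML dotted key -> attribute name."""
        return {f.name.replace("_", ".", 1): f.name for f in fields(cls)}

    @classmethod
    def from_toml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        flat: dict[str, object] = {}

        def _flatten(prefix: str, obj) -> None:
            for k, v in obj.items():
                key = f"{prefix}.{k}" if prefix else k
                if isinstance(v, dict):
                    _flatten(key, v)
                else:
                    flat[key] = v

        _flatten("", data)
        keymap = cls.key_map()
        kwargs = {}
        for key, value in flat.items():
            attr = keymap.get(key) or keymap.get(key.replace("_", ".", 1))
            if attr is None and key in {f.name for f in fields(cls)}:
                attr = key
            if attr is None:
                raise ValidationError(f"unknown config key: {key!r}")
            kwargs[attr] = value
        return cls(**kwargs)

    def echo(self, outdir: str | os.PathLike) -> str:
        """Write the effective config as JSON into ``outdir``; return path."""
        os.makedirs(outdir, exist_ok=True)
        path = os.path.join(os.fspath(outdir), "effective_config.json")
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path

    def analyze_kwargs(self) -> dict:
        return dict(
            polarity=self.segmentation_polarity,
            min_area_px=self.segmentation_min_area_px,
            sigma_px=self.segmentation_sigma_px,
            closing_radius_px=self.segmentation_closing_radius_px,
            satellite_ratio=self.segmentation_satellite_ratio,
            n_sectors=self.morphometry_n_sectors,
            sigma_mode=self.morphometry_sigma_mode,
        )
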