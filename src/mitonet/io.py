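"""Image and table I/O plus run configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .segmentation import DEFAULT_PIXEL_SIZE_UM, BinaryImage, GrayImage, SegmentationParams


def read_image(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> GrayImage:
    """Read a single-channel TIFF or PNG image as a GrayImage."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        arr = imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an RGB(A) PNG to one channel
        arr = arr[..., :3].mean(axis=-1)
    return GrayImage(arr.astype(float), pixel_size_um)


def write_gray_tiff(path, image: GrayImage) -> None:
    arr = image.pixels
    scale = arr.max() if arr.max() > 0 else 1.0
    tifffile.imwrite(path, (255.0 * arr / scale).astype(np.uint8))


def write_mask_tiff(path, mask: BinaryImage) -> None:
    """Write a binary mask as 8-bit TIFF (0/255)."""
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255))


def read_mask_tiff(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> BinaryImage:
    return BinaryImage(tifffile.imread(path) > 0, pixel_size_um)


@dataclass
class RunConfig:
    """Configuration of one analysis run, serialized alongside outputs."""

    inputs: list[str] = field(default_factory=list)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    n_samples: int = 1000
    bin_width_um: float = 0.5
    max_length_um: float = 25.0
    max_area_fraction: float = 0.6
    seed: int | None = None
    output_dir: str = "."
    pool: bool = False

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        data = dict(data)
        seg = data.pop("segmentation", {})
        cfg = cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})
        if seg:
            cfg.segmentation = SegmentationParams(**seg)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def write_metadata(path, config: RunConfig, table_hash: str, extra: dict | None = None) -> None:
    meta = {
        "config": json.loads(config.to_json()),
        "interpretation_table": table_hash,
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
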