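"""Reading and writing the on-disk formats: PNG images/masks, YOLO-format
normalized bounding-box text files, and JSON sidecars carrying the full
phantom specification."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InvalidBoxError
from .phantom import PhantomSample, PhantomSpec
from .types import BoundingBox, as_mask


def read_image(path) -> np.ndarray:
    return iio.imread(path)


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    """Read a mask PNG; any nonzero pixel counts as foreground."""
    return as_mask(iio.imread(path))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    iio.imwrite(path, (as_mask(mask) * np.uint8(255)))


def write_yolo_bbox(path, box: BoundingBox, image_shape, class_id: int = 0) -> None:
    """Write one box as ``class x_center y_center width height`` (normalized)."""
    h, w = image_shape[:2]
    cx = (box.x_min + box.x_max) / 2.0 / w
    cy = (box.y_min + box.y_max) / 2.0 / h
    bw = box.width / w
    bh = box.height / h
    Path(path).write_text(f"{class_id} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}\n")


def read_yolo_bbox(path, image_shape) -> list[tuple[int, BoundingBox]]:
    """Read YOLO-format boxes back into pixel-coordinate half-open boxes."""
    h, w = image_shape[:2]
    out = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 5:
            raise InvalidBoxError(f"malformed YOLO line: {line!r}")
        cls, cx, cy, bw, bh = int(parts[0]), *map(float, parts[1:])
        x0 = (cx - bw / 2.0) * w
        y0 = (cy - bh / 2.0) * h
        out.append(
            (
                cls,
                BoundingBox(
                    int(round(x0)),
                    int(round(y0)),
                    int(round(x0 + bw * w)),
                    int(round(y0 + bh * h)),
                ),
            )
        )
    return out


def spec_to_json(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["image_size_px"] = list(d["image_size_px"])
    return d


def spec_from_json(d: dict) -> PhantomSpec:
    d = dict(d)
    d["image_size_px"] = tuple(d["image_size_px"])
    return PhantomSpec(**d)


def write_sample(out_dir, stem: str, sample: PhantomSample) -> None:
    """Write one phantom sample: image, mask, YOLO box and JSON sidecar."""
    out = Path(out_dir)
    for sub in ("images", "masks", "labels", "specs"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    write_image(out / "images" / f"{stem}.png", sample.image)
    write_mask(out / "masks" / f"{stem}.png", sample.mask)
    write_yolo_bbox(out / "labels" / f"{stem}.txt", sample.bbox, sample.image.shape)
    sidecar = {
        "gt_angle_deg": sample.gt_angle_deg,
        "spec": spec_to_json(sample.spec),
    }
    (out / "specs" / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
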