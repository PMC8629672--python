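"""Shared I/O: PNG image loading, model persistence, and run reports."""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from .config import NetworkConfig
from .model import FWNNetParameters

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".png",)


def load_images(directory, expected_side: Optional[int] = None
                ) -> Tuple[list, list]:
    """Load every PNG in a directory as 8-bit grayscale, sorted by filename.

    RGB images are converted by the standard luminance weights
    (0.299 R + 0.587 G + 0.114 B).  Unreadable files are logged and
    skipped; the call fails only if nothing loads.  With ``expected_side``
    set, any image of a different size raises an error naming the file.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in IMAGE_SUFFIXES)
    if not paths:
        raise FileNotFoundError(f"no PNG images in {directory}")
    images, names = [], []
    for path in paths:
        try:
            with Image.open(path) as im:
                arr = np.asarray(im.convert("L"), dtype=np.uint8)
        except Exception as exc:  # noqa: BLE001 - per-file resilience
            logger.error("could not read %s: %s", path.name, exc)
            continue
        if expected_side is not None and arr.shape != (expected_side,
                                                       expected_side):
            raise ValueError(
                f"{path.name}: size {arr.shape} != expected "
                f"({expected_side}, {expected_side})")
        images.append(arr)
        names.append(path.name)
    if not images:
        raise RuntimeError(f"no readable image in {directory}")
    return images, names


def save_image(array: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(array, dtype=np.uint8)).save(path)


def save_model(params: FWNNetParameters, config: NetworkConfig, path) -> None:
    Path(path).write_text(params.to_json(config))


def load_model(path) -> Tuple[FWNNetParameters, NetworkConfig]:
    return FWNNetParameters.from_json(Path(path).read_text())


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_report(config: dict, seed: int, metrics: dict,
               input_files: Sequence = (), extra: Optional[dict] = None
               ) -> dict:
    """Assemble the standard JSON run report (config echo, seed, metrics,
    input hashes)."""
    report = {
        "seed": int(seed),
        "config": _jsonable(config),
        "metrics": _jsonable(metrics),
        "input_hashes": {str(Path(p).name): file_sha256(p)
                         for p in input_files},
    }
    if extra:
        report.update(_jsonable(extra))
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return {f: _jsonable(getattr(obj, f))
                for f in obj.__dataclass_fields__}
    return obj
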