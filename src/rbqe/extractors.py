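"""Pluggable feature extraction.

Two families of extractors share one interface:

* Deep backends (``alexnet_fc6``, ``vgg19_fc1``, ``vgg19_fc2``, ``vgg16_fc1``)
  take activations of a fully connected layer of an ImageNet-pre-trained CNN
  as a 4096-dimensional descriptor.  They need the optional ``torch`` /
  ``torchvision`` dependency and downloadable weights, and raise a clear error
  when those are unavailable — never a silent fallback.
* ``toy_histogram`` — a small deterministic descriptor used for testing and
  demos without any downloads: an intensity histogram concatenated with a
  histogram of gradient magnitudes, each block L1-normalized.

Bulk extraction walks a ``<root>/<class_label>/<image>`` tree in sorted order,
so record order (and hence all downstream tie-breaking) is reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from .core import FeatureDatabase, ImageRecord

logger = logging.getLogger(__name__)

__all__ = ["ExtractorSpec", "extract_features", "extract_database", "load_image"]

DEEP_BACKENDS = {"alexnet_fc6", "vgg19_fc1", "vgg19_fc2", "vgg16_fc1"}
KNOWN_EXTRACTORS = DEEP_BACKENDS | {"toy_histogram"}

#: Native input size per CNN backbone.
_DEEP_INPUT = {"alexnet_fc6": 227, "vgg19_fc1": 224, "vgg19_fc2": 224, "vgg16_fc1": 224}

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".dcm"}


@dataclasses.dataclass(frozen=True)
class ExtractorSpec:
    """Configuration of one extractor.

    ``output_dim`` is fixed at 4096 for the deep backends; for the toy
    descriptor it must be even (half intensity bins, half gradient bins) and
    defaults to 32.
    """

    name: str = "toy_histogram"
    output_dim: int = 32

    def __post_init__(self) -> None:
        if self.name not in KNOWN_EXTRACTORS:
            raise ValueError(
                f"unknown extractor {self.name!r}; choose one of {sorted(KNOWN_EXTRACTORS)}"
            )
        if self.name in DEEP_BACKENDS:
            object.__setattr__(self, "output_dim", 4096)
        elif self.output_dim < 2 or self.output_dim % 2:
            raise ValueError(f"toy_histogram output_dim must be even and >= 2, got {self.output_dim}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractorSpec":
        return cls(**d)


def _to_gray(image: np.ndarray) -> np.ndarray:
    """Collapse an image to a 2-D float64 grayscale array in [0, 1]."""
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(arr.astype(np.float64))):
        raise ValueError("image contains non-finite pixels")
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D pixel array, got ndim={arr.ndim}")
    arr = arr.astype(np.float64)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        arr = arr / np.iinfo(np.asarray(image).dtype).max
    else:
        lo, hi = arr.min(), arr.max()
        if hi > 1.0 or lo < 0.0:
            arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    return np.clip(arr, 0.0, 1.0)


def toy_histogram(image: np.ndarray, output_dim: int = 32) -> np.ndarray:
    """Intensity histogram + gradient-magnitude histogram, L1-normalized blocks.

    Both histograms use fixed bin edges (intensities over [0, 1], gradient
    magnitudes over [0, sqrt(2)]), so the descriptor is deterministic and
    independent of the image's file format.
    """
    bins = output_dim // 2
    gray = _to_gray(image)
    intensity, _ = np.histogram(gray, bins=bins, range=(0.0, 1.0))
    gy, gx = np.gradient(gray)
    grad = np.hypot(gx, gy)
    grad_hist, _ = np.histogram(grad, bins=bins, range=(0.0, float(np.sqrt(2.0))))

    out = np.empty(output_dim, dtype=np.float64)
    for block, dest in ((intensity, out[:bins]), (grad_hist, out[bins:])):
        total = block.sum()
        dest[:] = block / total if total > 0 else 0.0
    return out


def extract_features(image: np.ndarray, spec: ExtractorSpec) -> np.ndarray:
    """Extract one feature vector of length ``spec.output_dim`` from an image."""
    if spec.name == "toy_histogram":
        return toy_histogram(image, spec.output_dim)
    return _deep_extract(image, spec)


def _deep_extract(image: np.ndarray, spec: ExtractorSpec) -> np.ndarray:
    try:
        import torch
        from torchvision import models
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            f"extractor {spec.name!r} needs the optional deep backend: "
            "install with `pip install rbqe[deep]` (torch + torchvision, plus "
            "pre-trained weights downloaded on first use), or use the "
            "'toy_histogram' extractor"
        ) from exc
    return _deep_forward(image, spec, torch, models)  # pragma: no cover


def _deep_forward(image, spec, torch, models):  # pragma: no cover - needs weights
    """Forward an image through the backbone and read one FC layer.

    Preprocessing: resize to the backbone's native input, replicate grayscale
    to 3 channels, standard ImageNet channel normalization.  CT/MR intensity
    ranges are min-max scaled to [0, 1] beforehand by :func:`_to_gray`.
    """
    from PIL import Image as PILImage

    side = _DEEP_INPUT[spec.name]
    gray = _to_gray(image)
    pil = PILImage.fromarray((gray * 255).astype(np.uint8)).resize((side, side), PILImage.BILINEAR)
    x = np.asarray(pil, dtype=np.float32) / 255.0
    x = np.stack([x] * 3, axis=0)
    mean = np.array([0.485, 0.456, 0.406], dtype=np.float32)[:, None, None]
    std = np.array([0.229, 0.224, 0.225], dtype=np.float32)[:, None, None]
    batch = torch.from_numpy((x - mean) / std).unsqueeze(0)

    if spec.name == "alexnet_fc6":
        net, fc_pos = models.alexnet(weights="IMAGENET1K_V1"), 0
    elif spec.name == "vgg16_fc1":
        net, fc_pos = models.vgg16(weights="IMAGENET1K_V1"), 0
    elif spec.name == "vgg19_fc1":
        net, fc_pos = models.vgg19(weights="IMAGENET1K_V1"), 0
    else:  # vgg19_fc2
        net, fc_pos = models.vgg19(weights="IMAGENET1K_V1"), 1
    net.eval()
    captured = {}
    layer = [m for m in net.classifier if isinstance(m, torch.nn.Linear)][fc_pos]
    layer.register_forward_hook(lambda m, i, o: captured.update(out=o))
    with torch.no_grad():
        net(batch)
    vec = captured["out"].squeeze(0).numpy().astype(np.float64)
    if vec.size != spec.output_dim:
        raise RuntimeError(f"backend produced {vec.size} features, expected {spec.output_dim}")
    return vec


def load_image(path: str | Path) -> np.ndarray:
    """Read PNG/JPEG/TIFF via imageio, DICOM via pydicom.

    DICOM pixel data gets rescale slope/intercept applied when present, then
    each slice is min-max scaled to [0, 1].
    """
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        lo, hi = arr.min(), arr.max()
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    import imageio.v3 as iio

    return iio.imread(path)


def extract_database(
    image_root: str | Path,
    spec: ExtractorSpec,
    strict: bool = False,
) -> FeatureDatabase:
    """Extract features for every image under ``<root>/<class>/<image>``.

    Record order is sorted (class, filename).  Unreadable images are skipped
    with a logged warning (counted), or abort the run under ``strict``.
    """
    root = Path(image_root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    records: list[ImageRecord] = []
    n_skipped = 0
    for cdir in class_dirs:
        files = sorted(p for p in cdir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"class directory {cdir} contains no images")
        for f in files:
            try:
                vec = extract_features(load_image(f), spec)
            except Exception as exc:
                if strict:
                    raise RuntimeError(f"failed to extract {f}: {exc}") from exc
                logger.warning("skipping unreadable image %s: %s", f, exc)
                n_skipped += 1
                continue
            records.append(
                ImageRecord(
                    id=f"{cdir.name}/{f.name}",
                    class_label=cdir.name,
                    features=vec,
                    source_path=str(f),
                )
            )
    if n_skipped:
        logger.info("extraction skipped %d unreadable image(s)", n_skipped)
    return FeatureDatabase(records)
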