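"""Synthetic fixtures: clustered feature databases and toy image trees.

Stands in for real CT/MR collections at desk scale.  Feature databases are
isotropic Gaussian clusters, one per class, with centers placed on scaled
orthogonal axes so that every pair of centers is exactly ``separation``
apart; ``separation / sigma`` is then the knob controlling how hard the
retrieval problem is.  Image trees assign each class a distinct texture
(mean intensity + oriented grating) plus pixel noise, so the toy histogram
descriptor separates classes without any downloads.

Also hosts a tiny worked numerical example of mean-pooled query expansion:
five 6-component feature vectors and their expected component-wise mean.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .core import FeatureDatabase, ImageRecord

__all__ = ["SyntheticSpec", "gen_feature_db", "gen_image_tree", "table1_fixture", "table1_database"]


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one reproducible Gaussian-cluster feature database.

    ``separation`` is the exact pairwise Euclidean distance between class
    centers; ``sigma`` the isotropic within-class standard deviation.  The
    same spec always yields an identical database.
    """

    n_classes: int = 4
    class_sizes: tuple[int, ...] = (75, 50, 58, 41)
    dim: int = 64
    separation: float = 50.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        if len(self.class_sizes) != self.n_classes:
            raise ValueError(
                f"{self.n_classes} classes but {len(self.class_sizes)} class sizes"
            )
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("every class size must be >= 1")
        if self.dim < self.n_classes:
            raise ValueError(
                f"orthogonal-axis center placement needs dim >= n_classes; "
                f"got dim={self.dim} < {self.n_classes} — increase dim"
            )
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_sizes"] = list(d["class_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["class_sizes"] = tuple(d["class_sizes"])
        return cls(**d)


def class_centers(spec: SyntheticSpec) -> np.ndarray:
    """(n_classes, dim) centers with exact pairwise distance ``separation``.

    Center c sits at (separation / sqrt(2)) * e_c, so for any two distinct
    axes the distance is separation exactly.
    """
    centers = np.zeros((spec.n_classes, spec.dim))
    scale = spec.separation / np.sqrt(2.0)
    for c in range(spec.n_classes):
        centers[c, c] = scale
    return centers


def gen_feature_db(spec: SyntheticSpec) -> FeatureDatabase:
    """Draw the database described by ``spec``.

    Each class uses its own counter-based substream of the global seed, so
    adding a class never perturbs the draws of earlier classes.  Record order
    is (class, index); labels are ``class_00``, ``class_01``, ...
    """
    centers = class_centers(spec)
    records = []
    for c, size in enumerate(spec.class_sizes):
        rng = np.random.default_rng([spec.seed, c])
        noise = rng.normal(0.0, spec.sigma, size=(size, spec.dim))
        label = f"class_{c:02d}"
        for i, row in enumerate(centers[c] + noise):
            records.append(ImageRecord(id=f"{label}/{i:03d}", class_label=label, features=row))
    return FeatureDatabase(records)


def gen_image_tree(
    n_classes: int,
    per_class: int,
    out_dir: str | Path,
    size: int = 64,
    noise: float = 0.02,
    seed: int = 0,
    force: bool = False,
) -> Path:
    """Write a ``<out>/<class>/<i>.png`` tree of class-specific textures.

    Class c's images share a mean intensity and an oriented sinusoidal grating
    (frequency and orientation step with c) plus i.i.d. Gaussian pixel noise.
    Refuses to write into an existing non-empty directory unless ``force``.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (pass force=True to overwrite)")
    yy, xx = np.mgrid[0:size, 0:size] / size
    means = np.linspace(0.25, 0.75, n_classes)
    for c in range(n_classes):
        label = f"class_{c:02d}"
        (out / label).mkdir(parents=True, exist_ok=True)
        theta = np.pi * c / max(n_classes, 1)
        freq = 2.0 + 3.0 * c
        pattern = means[c] + 0.2 * np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)))
        rng = np.random.default_rng([seed, c])
        for i in range(per_class):
            img = pattern + rng.normal(0.0, noise, size=pattern.shape)
            img8 = np.clip(img, 0.0, 1.0) * 255
            iio.imwrite(out / label / f"{i:03d}.png", img8.round().astype(np.uint8))
    return out


#: Worked 6-component expansion example: five member vectors and their mean.
_TABLE1_MEMBERS = {
    "Img1": (0.99, -15.05, -5.02, -41.11, -23.11, 6.76),
    "Img2": (2.21, -12.71, -3.55, -43.14, -23.29, 8.57),
    "Img3": (-1.29, -13.40, -7.85, -39.39, -28.45, 8.29),
    "Img4": (-1.48, -11.07, -3.12, -37.64, -23.31, 13.11),
    "Img5": (-6.69, -7.70, 1.03, -40.86, -22.97, 6.07),
}
_TABLE1_NQE = (-1.252, -11.986, -3.702, -40.428, -24.226, 8.56)


def table1_fixture() -> tuple[dict[str, np.ndarray], np.ndarray]:
    """The worked mean-expansion example: members and their expected mean.

    Five images' feature rows truncated to six components (F1..F5 and F4096),
    with the printed component-wise mean they expand to.
    """
    members = {k: np.array(v, dtype=np.float64) for k, v in _TABLE1_MEMBERS.items()}
    return members, np.array(_TABLE1_NQE, dtype=np.float64)


def table1_database(class_label: str = "ct") -> FeatureDatabase:
    """Single-class database built from the worked-example vectors."""
    members, _ = table1_fixture()
    return FeatureDatabase(
        ImageRecord(id=name, class_label=class_label, features=vec)
        for name, vec in members.items()
    )
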