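"""Core domain types and on-disk formats for dermoscopy segmentation data.

A dataset is a directory of RGB lesion images (PNG/JPEG), binary ground-truth
masks (PNG), and one metadata CSV whose header is ``id`` followed by the
schema-derived column names.  The default metadata schema encodes the
histological diagnosis plus the standard dermoscopic attributes (asymmetry,
pigment network, dots/globules, streaks, regression areas, blue-whitish veil,
border irregularity and six colour flags) as 29 one-hot/binary columns.

Conventions: images are H×W×3 floats in [0,1], masks H×W {0,1} arrays,
row-major with origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from skimage.transform import resize as _sk_resize


class MetadataError(ValueError):
    """Raised when a metadata vector violates its schema."""


class ShapeError(ValueError):
    """Raised when image and mask spatial dimensions disagree."""


# ---------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class AttributeGroup:
    """One named attribute: a one-hot block, or a single binary flag column."""

    name: str
    categories: tuple[str, ...]
    kind: str = "onehot"  # "onehot" | "flag"

    @property
    def width(self) -> int:
        return 1 if self.kind == "flag" else len(self.categories)

    @property
    def vocab(self) -> int:
        """Number of embedding rows (flags embed their two states)."""
        return 2 if self.kind == "flag" else len(self.categories)


@dataclass(frozen=True)
class MetadataSchema:
    """Ordered attribute groups whose one-hot widths define the vector layout."""

    groups: tuple[AttributeGroup, ...]

    def __post_init__(self):
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")

    @property
    def total_width(self) -> int:
        return sum(g.width for g in self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def column_names(self) -> list[str]:
        cols = []
        for g in self.groups:
            if g.kind == "flag":
                cols.append(g.name)
            else:
                cols.extend(f"{g.name}.{c}" for c in g.categories)
        return cols

    def column_map(self) -> list[tuple[str, str]]:
        """Column index -> (group, category)."""
        out = []
        for g in self.groups:
            if g.kind == "flag":
                out.append((g.name, "present"))
            else:
                out.extend((g.name, c) for c in g.categories)
        return out

    def slices(self) -> dict[str, slice]:
        out, off = {}, 0
        for g in self.groups:
            out[g.name] = slice(off, off + g.width)
            off += g.width
        return out

    # -- validation / encoding -----------------------------------------
    def validate(self, vector: np.ndarray) -> None:
        v = np.asarray(vector, dtype=float)
        if v.shape != (self.total_width,):
            raise MetadataError(
                f"metadata length {v.shape} does not match schema width {self.total_width}")
        for g, sl in zip(self.groups, self.slices().values()):
            block = v[sl]
            if not np.all(np.isin(block, (0.0, 1.0))):
                raise MetadataError(f"group '{g.name}' has non-binary entries {block}")
            if g.kind == "onehot" and block.sum() != 1:
                raise MetadataError(
                    f"one-hot group '{g.name}' must have exactly one active "
                    f"category, got {int(block.sum())}")

    def group_indices(self, vector: np.ndarray) -> np.ndarray:
        """Active category index per group (flags: the 0/1 value itself)."""
        self.validate(vector)
        v = np.asarray(vector, dtype=float)
        idx = []
        for g, sl in zip(self.groups, self.slices().values()):
            block = v[sl]
            idx.append(int(block[0]) if g.kind == "flag" else int(np.argmax(block)))
        return np.array(idx, dtype=np.intp)

    def encode(self, **choices) -> np.ndarray:
        """Build a vector from ``group=category`` / ``flag=0|1`` keywords."""
        v = np.zeros(self.total_width)
        for g, sl in zip(self.groups, self.slices().values()):
            choice = choices.get(g.name)
            if g.kind == "flag":
                v[sl] = float(bool(choice))
            else:
                if choice is None:
                    choice = g.categories[0]
                v[sl.start + g.categories.index(choice)] = 1.0
        return v

    # -- serialisation --------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = [{"name": g.name, "categories": list(g.categories), "kind": g.kind}
               for g in self.groups]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "MetadataSchema":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(tuple(AttributeGroup(d["name"], tuple(d["categories"]),
                                        d.get("kind", "onehot")) for d in doc))


def default_schema() -> MetadataSchema:
    """The 29-column dermoscopy schema used throughout the package."""
    groups = [
        AttributeGroup("diagnosis", ("common_nevus", "atypical_nevus", "melanoma")),
        AttributeGroup("asymmetry", ("none", "one_axis", "two_axes")),
        AttributeGroup("pigment_network", ("absent", "typical", "atypical")),
        AttributeGroup("dots_globules", ("absent", "typical", "atypical")),
        AttributeGroup("streaks", ("absent", "regular", "irregular")),
        AttributeGroup("regression", ("absent", "partial", "extensive")),
        AttributeGroup("blue_whitish_veil", ("absent", "present")),
        AttributeGroup("border_irregularity", ("low", "medium", "high")),
    ]
    for colour in ("white", "red", "light_brown", "dark_brown", "blue_gray", "black"):
        groups.append(AttributeGroup(f"color_{colour}", (colour,), kind="flag"))
    schema = MetadataSchema(tuple(groups))
    assert schema.total_width == 29
    return schema


# ---------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------

@dataclass
class LesionSample:
    """One dermoscopic image with its binary mask and 29-entry metadata vector."""

    id: str
    image: np.ndarray  # H×W×3 in [0,1]
    mask: np.ndarray   # H×W in {0,1}
    metadata: np.ndarray
    schema: MetadataSchema = field(default_factory=default_schema, repr=False)

    def validate(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ShapeError(f"image must be H×W×3, got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ShapeError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} "
                "spatial dimensions differ")
        if not np.all(np.isin(self.mask, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.schema.validate(self.metadata)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/val/test id lists produced by :func:`split_dataset`."""

    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]
    seed: int

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return {"train": self.train, "val": self.val, "test": self.test}


# ---------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------

def _load_raster(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im)


def read_sample(image_path, mask_path, metadata_row, schema: MetadataSchema) -> LesionSample:
    """Read one image/mask/metadata triple, rescaling to the canonical ranges.

    The image is scaled to [0,1] by its dtype range; the mask is normalised by
    its own maximum and thresholded at 0.5, which is robust to both 0/255 and
    0/1 encodings.
    """
    img = _load_raster(image_path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:
        img = img[:, :, :3]
    scale = 255.0 if img.dtype == np.uint8 else float(np.iinfo(img.dtype).max) \
        if np.issubdtype(img.dtype, np.integer) else 1.0
    image = img.astype(np.float64) / scale

    m = _load_raster(mask_path).astype(np.float64)
    if m.ndim == 3:
        m = m[:, :, 0]
    if m.max() > 0:
        m = m / m.max()
    mask = (m > 0.5).astype(np.uint8)

    if mask.shape != image.shape[:2]:
        raise ShapeError(
            f"image {image.shape[:2]} and mask {mask.shape} shapes differ "
            f"({image_path} vs {mask_path})")

    if isinstance(metadata_row, pd.Series):
        sample_id = str(metadata_row.get("id", Path(image_path).stem))
        vec = metadata_row[schema.column_names()].to_numpy(dtype=float)
    else:
        sample_id = Path(image_path).stem
        vec = np.asarray(metadata_row, dtype=float)
    schema.validate(vec)

    sample = LesionSample(sample_id, image, mask, vec, schema)
    sample.validate()
    return sample


def write_sample(sample: LesionSample, image_dir, mask_dir) -> tuple[Path, Path]:
    """Write image (8-bit PNG) and mask (0/255 PNG); returns the two paths."""
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    image_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    img8 = np.clip(np.round(sample.image * 255.0), 0, 255).astype(np.uint8)
    ipath = image_dir / f"{sample.id}.png"
    mpath = mask_dir / f"{sample.id}.png"
    Image.fromarray(img8).save(ipath)
    Image.fromarray((sample.mask * 255).astype(np.uint8)).save(mpath)
    return ipath, mpath


def read_dataset(root) -> list[LesionSample]:
    """Read a directory written by :func:`lesionseg.synthetic.generate_dataset`."""
    root = Path(root)
    schema = MetadataSchema.from_yaml(root / "schema.yaml") \
        if (root / "schema.yaml").exists() else default_schema()
    meta = pd.read_csv(root / "metadata.csv", dtype={"id": str})
    samples = []
    for _, row in meta.iterrows():
        sid = row["id"]
        samples.append(read_sample(root / "images" / f"{sid}.png",
                                   root / "masks" / f"{sid}.png", row, schema))
    return samples


def write_dataset(samples: list[LesionSample], root) -> Path:
    root = Path(root)
    for s in samples:
        write_sample(s, root / "images", root / "masks")
    schema = samples[0].schema
    rows = [{"id": s.id, **dict(zip(schema.column_names(), s.metadata.astype(int)))}
            for s in samples]
    pd.DataFrame(rows).to_csv(root / "metadata.csv", index=False)
    schema.to_yaml(root / "schema.yaml")
    return root


# ---------------------------------------------------------------------
# transforms & splitting
# ---------------------------------------------------------------------

def resize_sample(sample: LesionSample, size: int = 224) -> LesionSample:
    """Bilinear-resize the image, nearest-resize the mask (stays binary)."""
    if size < 16:
        raise ValueError("size must be >= 16")
    if sample.image.shape[:2] == (size, size):
        return LesionSample(sample.id, sample.image.copy(), sample.mask.copy(),
                            sample.metadata.copy(), sample.schema)
    image = _sk_resize(sample.image, (size, size), order=1, mode="reflect",
                       anti_aliasing=sample.image.shape[0] > size, preserve_range=True)
    mask = _sk_resize(sample.mask.astype(float), (size, size), order=0,
                      anti_aliasing=False, preserve_range=True).astype(np.uint8)
    return LesionSample(sample.id, np.clip(image, 0, 1), mask,
                        sample.metadata.copy(), sample.schema)


def stretch_contrast(sample: LesionSample) -> LesionSample:
    """Per-image min–max contrast normalization of the image to [0, 1].

    Standard preprocessing for low-contrast inputs: it rescales each image by
    its own intensity range so that faint lesion/background offsets occupy a
    usable fraction of the network's input range.  Mask and metadata are
    untouched.
    """
    img = sample.image
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        img = (img - lo) / (hi - lo)
    return LesionSample(sample.id, img, sample.mask.copy(),
                        sample.metadata.copy(), sample.schema)


def _largest_remainder(n: int, ratios) -> list[int]:
    exact = [n * r for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    remainders = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in remainders[:short]:
        base[i] += 1
    return base


def split_dataset(ids, ratios=(0.70, 0.10, 0.20), seed: int = 0) -> DatasetSplit:
    """Seeded shuffle then largest-remainder partition into train/val/test."""
    ids = [str(i) for i in ids]
    if len(ids) < len(ratios):
        raise ValueError(f"need at least {len(ratios)} ids, got {len(ids)}")
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    shuffled = [ids[i] for i in order]
    sizes = _largest_remainder(len(ids), ratios)
    train = tuple(shuffled[:sizes[0]])
    val = tuple(shuffled[sizes[0]:sizes[0] + sizes[1]])
    test = tuple(shuffled[sizes[0] + sizes[1]:])
    return DatasetSplit(train, val, test, seed)
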