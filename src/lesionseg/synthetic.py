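"""Seeded generator of dermoscopy-like images, masks and metadata.

The generator emulates the structure of dermoscopic segmentation datasets:
a single smooth lesion (an ellipse deformed by low-frequency radial noise)
on a skin-like textured background, a paired binary mask that is the exact
indicator of the lesion region *before* edge blurring, and a 29-column
metadata vector whose attributes are rendered into the image as localized
additive textures:

* pigment network  -> reticular grid inside the lesion
* dots/globules    -> dark disks inside the lesion
* streaks          -> radial spokes crossing the boundary
* regression       -> pale patches inside the lesion
* blue-whitish veil-> blue tint inside the lesion
* colour flags     -> small per-channel shifts inside the lesion
* asymmetry / border irregularity / diagnosis -> shape parameters

Each renderer draws from its own random substream, so toggling one metadata
attribute changes pixels only within that renderer's support — the property
that makes the metadata→pixels coupling unit-testable.

The "ambiguous" mode implements a task in which segmentation is unresolvable
from pixels alone: every image contains the lesion and a same-sized
distractor blob, and only the diagnosis metadata says which is which.
Under the default "side" rule the two blobs look identical and melanoma
lesions sit in the left image half; under the "sign" rule the lesion is
darker than background iff melanoma and the distractor takes the opposite
offset.  An image-only model must guess; a metadata-aware model can decide.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .data_model import (LesionSample, MetadataSchema, default_schema,
                         write_dataset)

_SKIN_TONE = np.array([0.75, 0.58, 0.48])
_LESION_PROFILE = np.array([1.0, 0.95, 0.85])  # brownish darkening per channel


def default_prevalence() -> dict:
    """Per-group category probabilities (PH2-like diagnosis mix)."""
    return {
        "diagnosis": (0.4, 0.4, 0.2),
        "asymmetry": (0.4, 0.3, 0.3),
        "pigment_network": (0.3, 0.4, 0.3),
        "dots_globules": (0.4, 0.3, 0.3),
        "streaks": (0.5, 0.25, 0.25),
        "regression": (0.6, 0.25, 0.15),
        "blue_whitish_veil": (0.7, 0.3),
        "border_irregularity": (0.4, 0.35, 0.25),
        "color_white": 0.15, "color_red": 0.2, "color_light_brown": 0.6,
        "color_dark_brown": 0.5, "color_blue_gray": 0.2, "color_black": 0.25,
    }


def default_amplitudes() -> dict:
    return {
        "pigment_network": 0.10,
        "dots_globules": 0.15,
        "streaks": 0.12,
        "regression": 0.12,
        "blue_whitish_veil": 0.10,
        "colors": 0.03,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    image_size: int = 224
    n_samples: int = 200
    lesion_frac: tuple[float, float] = (0.22, 0.42)  # radius / image size
    sigma_b: float = 1.0     # boundary blur, px
    contrast: float = 0.4    # lesion-background intensity offset
    noise_std: float = 0.03
    prevalence: dict = field(default_factory=default_prevalence)
    texture_amplitude: dict = field(default_factory=default_amplitudes)
    ambiguous: bool = False  # metadata-dependent rule + distractor blob
    ambiguity_rule: str = "side"  # "side" | "sign" (see make_ambiguous_task)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must be in (0, 1]")
        if self.sigma_b < 0 or self.noise_std < 0:
            raise ValueError("sigma_b and noise_std must be >= 0")
        if not (0 < self.lesion_frac[0] <= self.lesion_frac[1]):
            raise ValueError("lesion_frac range must be non-empty and positive")


class DegenerateLesionError(RuntimeError):
    pass


# ---------------------------------------------------------------------
# metadata sampling
# ---------------------------------------------------------------------

def sample_metadata(cfg: GeneratorConfig, schema: MetadataSchema,
                    rng: np.random.Generator) -> np.ndarray:
    v = np.zeros(schema.total_width)
    for g, sl in zip(schema.groups, schema.slices().values()):
        prev = cfg.prevalence.get(g.name)
        if g.kind == "flag":
            p = 0.3 if prev is None else float(prev)
            v[sl] = float(rng.random() < p)
        else:
            p = np.full(g.width, 1.0 / g.width) if prev is None else np.asarray(prev, float)
            p = p / p.sum()
            v[sl.start + rng.choice(g.width, p=p)] = 1.0
    return v


# ---------------------------------------------------------------------
# shape model
# ---------------------------------------------------------------------

def _radial_region(size, center, r0, rng, asym_level, irregular_level):
    """Indicator of an ellipse-like region deformed by radial cosine noise."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - center[0], xx - center[1]
    theta = np.arctan2(dy, dx)
    rr = np.hypot(dy, dx)
    r_of_theta = np.ones_like(theta)
    # low-frequency lobes; k=1 term controlled by asymmetry
    a1 = asym_level * 0.18
    phi1 = rng.uniform(0, 2 * np.pi)
    r_of_theta += a1 * np.cos(theta + phi1)
    for k in range(2, 6):
        a = rng.normal(0.0, 0.05)
        phi = rng.uniform(0, 2 * np.pi)
        r_of_theta += a * np.cos(k * theta + phi)
    # high-frequency boundary perturbation from border irregularity
    for k in range(9, 13):
        a = rng.normal(0.0, 0.02) * irregular_level
        phi = rng.uniform(0, 2 * np.pi)
        r_of_theta += a * np.cos(k * theta + phi)
    radius = np.clip(r_of_theta, 0.3, 2.0) * r0
    return (rr <= radius).astype(np.uint8), radius, theta, rr


# ---------------------------------------------------------------------
# attribute renderers (additive in intensity space, each localized)
# ---------------------------------------------------------------------

def _render_pigment_network(img, mask_soft, rng, amp, atypical, size):
    period = rng.uniform(6, 10)
    phix, phiy = rng.uniform(0, 2 * np.pi, size=2)
    yy, xx = np.mgrid[0:size, 0:size]
    if atypical:
        warp = gaussian_filter(rng.normal(0, 1, (size, size)), size / 12) * 4.0
        xx = xx + warp
        yy = yy + warp.T
    grid = np.sin(2 * np.pi * xx / period + phix) * np.sin(2 * np.pi * yy / period + phiy)
    lines = (grid > 0.55).astype(float)
    img -= (amp * lines * mask_soft)[:, :, None] * np.array([1.0, 0.9, 0.7])


def _render_dots(img, mask, rng, amp, atypical, size):
    n = rng.poisson(18)
    ys, xs = np.nonzero(mask)
    if len(ys) == 0 or n == 0:
        return
    picks = rng.integers(0, len(ys), size=n)
    yy, xx = np.mgrid[0:size, 0:size]
    for p in picks:
        cy, cx = ys[p], xs[p]
        r = rng.uniform(1.0, 2.0) * (1.8 if atypical else 1.0)
        disk = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r ** 2
        img[disk] -= amp * np.array([1.0, 0.95, 0.8])


def _render_streaks(img, radius, theta, rr, rng, amp, irregular):
    m = int(rng.integers(10, 16))
    phi = rng.uniform(0, 2 * np.pi)
    ang = np.cos(m * theta + phi)
    if irregular:
        ang = ang + 0.5 * np.cos((m + 3) * theta + rng.uniform(0, 2 * np.pi))
    spokes = ang > 0.6
    ring = (rr >= 0.72 * radius) & (rr <= 1.28 * radius)
    support = spokes & ring
    img[support] -= amp * np.array([1.0, 0.9, 0.75])
    return support


def _render_regression(img, mask, rng, amp, extensive, size):
    n = 3 if extensive else 1
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return
    field_ = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n):
        p = rng.integers(0, len(ys))
        s = rng.uniform(0.05, 0.12) * size
        field_ += np.exp(-(((yy - ys[p]) ** 2 + (xx - xs[p]) ** 2) / (2 * s * s)))
    img += (amp * np.clip(field_, 0, 1) * mask)[:, :, None]


def _render_veil(img, mask_soft, amp):
    img[:, :, 2] += amp * mask_soft
    img[:, :, 0] -= 0.5 * amp * mask_soft


_COLOR_SHIFTS = {
    "color_white": np.array([1.0, 1.0, 1.0]),
    "color_red": np.array([1.0, -0.3, -0.3]),
    "color_light_brown": np.array([0.3, 0.1, -0.2]),
    "color_dark_brown": np.array([-0.5, -0.6, -0.7]),
    "color_blue_gray": np.array([-0.3, -0.1, 0.6]),
    "color_black": np.array([-1.0, -1.0, -1.0]),
}


# ---------------------------------------------------------------------
# sample generation
# ---------------------------------------------------------------------

def generate_sample(cfg: GeneratorConfig, rng: np.random.Generator,
                    metadata: np.ndarray | None = None,
                    schema: MetadataSchema | None = None,
                    sample_id: str = "S0", return_debug: bool = False):
    """Generate one lesion sample.

    ``rng`` is split into fixed named substreams (metadata, shape, placement,
    background, one per attribute, noise) so that overriding ``metadata``
    re-renders only the affected overlays.
    """
    schema = schema or default_schema()
    size = cfg.image_size
    streams = rng.spawn(6)
    s_meta, s_shape, s_place, s_bg, s_attr_root, s_noise = streams
    s_attr = {g.name: s for g, s in zip(schema.groups, s_attr_root.spawn(schema.n_groups))}

    if metadata is None:
        metadata = sample_metadata(cfg, schema, s_meta)
    schema.validate(metadata)
    groups = dict(zip((g.name for g in schema.groups),
                      schema.group_indices(metadata)))

    asym_level = groups["asymmetry"] / 2.0 if "asymmetry" in groups else 0.0
    irr_level = groups.get("border_irregularity", 0)

    # --- lesion region (mask is the pre-blur indicator) ----------------
    mask = None
    melanoma = groups.get("diagnosis", 0) == 2
    for _ in range(10):
        if cfg.ambiguous:
            # symmetric off-center placement keeps lesion and distractor apart
            off = s_place.uniform(0.15, 0.25, size=2) * \
                s_place.choice([-1.0, 1.0], size=2)
            if cfg.ambiguity_rule == "side":
                # the lesion sits left iff melanoma; the distractor mirrors it
                off[1] = abs(off[1]) * (-1.0 if melanoma else 1.0)
            c_jit = (0.5 + off) * size
        else:
            c_jit = s_place.uniform(0.35, 0.65, size=2) * size
        r0 = s_place.uniform(*cfg.lesion_frac) * size
        mask, radius, theta, rr = _radial_region(
            size, c_jit, r0, s_shape, asym_level, irr_level)
        if mask.sum() >= 9:
            break
    if mask is None or mask.sum() < 9:
        raise DegenerateLesionError("lesion area below 9 px after 10 resamples")

    # --- background -----------------------------------------------------
    tex = gaussian_filter(s_bg.uniform(-1, 1, (size, size)), size / 16.0)
    if tex.std() > 0:
        tex = tex / tex.std() * 0.04
    img = _SKIN_TONE[None, None, :] + tex[:, :, None] * np.array([1.0, 0.8, 0.6])

    # --- lesion fill -----------------------------------------------------
    soft = gaussian_filter(mask.astype(float), cfg.sigma_b) if cfg.sigma_b > 0 \
        else mask.astype(float)
    if cfg.ambiguous:
        d_center = (size - c_jit[0], size - c_jit[1])  # mirrored placement
        d_mask, _, _, _ = _radial_region(size, d_center, r0, s_place,
                                         asym_level, irr_level)
        d_soft = gaussian_filter(d_mask.astype(float), cfg.sigma_b) \
            if cfg.sigma_b > 0 else d_mask.astype(float)
        if cfg.ambiguity_rule == "sign":
            # opposite intensity offsets; melanoma -> the lesion is darker
            sign = -1.0 if melanoma else 1.0
            img += (sign * cfg.contrast * soft)[:, :, None]
            img += (-sign * cfg.contrast * d_soft)[:, :, None]
        else:
            # identical appearance: only the diagnosis says which blob is
            # the lesion (left iff melanoma), enforced by placement above
            img -= (cfg.contrast * soft)[:, :, None]
            img -= (cfg.contrast * d_soft)[:, :, None]
    else:
        img -= (cfg.contrast * soft)[:, :, None] * _LESION_PROFILE[None, None, :]

    # --- attribute overlays ----------------------------------------------
    amps = cfg.texture_amplitude
    debug: dict = {"mask": mask}
    if groups.get("pigment_network", 0) > 0:
        _render_pigment_network(img, soft, s_attr["pigment_network"],
                                amps.get("pigment_network", 0.1),
                                groups["pigment_network"] == 2, size)
    if groups.get("dots_globules", 0) > 0:
        _render_dots(img, mask, s_attr["dots_globules"],
                     amps.get("dots_globules", 0.15),
                     groups["dots_globules"] == 2, size)
    if groups.get("streaks", 0) > 0:
        debug["streak_support"] = _render_streaks(
            img, radius, theta, rr, s_attr["streaks"],
            amps.get("streaks", 0.12), groups["streaks"] == 2)
    if groups.get("regression", 0) > 0:
        _render_regression(img, mask, s_attr["regression"],
                           amps.get("regression", 0.12),
                           groups["regression"] == 2, size)
    if groups.get("blue_whitish_veil", 0) > 0:
        _render_veil(img, soft, amps.get("blue_whitish_veil", 0.1))
    col_amp = amps.get("colors", 0.03)
    for name, shift in _COLOR_SHIFTS.items():
        if groups.get(name, 0) > 0:
            img += (col_amp * soft)[:, :, None] * shift[None, None, :]

    # --- sensor noise -----------------------------------------------------
    if cfg.noise_std > 0:
        img = img + s_noise.normal(0.0, cfg.noise_std, img.shape)
    img = np.clip(img, 0.0, 1.0)

    sample = LesionSample(sample_id, img, mask, np.asarray(metadata, float), schema)
    sample.validate()
    if return_debug:
        return sample, debug
    return sample


# ---------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------

def generate_dataset(cfg: GeneratorConfig, out_dir=None,
                     schema: MetadataSchema | None = None) -> list[LesionSample]:
    """Generate ``cfg.n_samples`` samples; optionally write them to disk.

    Per-sample RNGs are spawned from one root seed sequence, so each sample is
    reproducible independently of generation order.
    """
    schema = schema or default_schema()
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_samples)
    width = max(4, len(str(cfg.n_samples - 1)))
    samples = [
        generate_sample(cfg, np.random.Generator(np.random.PCG64(child)),
                        schema=schema, sample_id=f"S{i:0{width}d}")
        for i, child in enumerate(children)
    ]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_dataset(samples, out_dir)
        manifest = {"generator_config": _cfg_to_dict(cfg), "seed": cfg.seed,
                    "n_samples": cfg.n_samples}
        (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return samples


def _cfg_to_dict(cfg: GeneratorConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["lesion_frac"] = list(cfg.lesion_frac)
    return d


def config_from_manifest(path) -> GeneratorConfig:
    doc = yaml.safe_load(Path(path).read_text())
    d = doc["generator_config"]
    d["lesion_frac"] = tuple(d["lesion_frac"])
    return GeneratorConfig(**d)


def make_ambiguous_task(cfg: GeneratorConfig,
                        rule: str = "side") -> GeneratorConfig:
    """Derive a low-contrast, blurred-boundary task whose correct segmentation
    requires the diagnosis metadata (see module docstring).

    Two rules are available.  ``"side"`` (default): lesion and distractor
    look identical and the diagnosis decides which side of the image holds
    the lesion (melanoma → left); the metadata branch can express this as a
    spatial prior, so small networks learn it reliably.  ``"sign"``: the
    lesion is darker than background iff melanoma and the distractor takes
    the opposite offset; resolving it requires a global appearance–metadata
    interaction.

    All texture attributes are set to "absent" so that diagnosis is the only
    varying metadata entry — any overlay rendered solely on the true lesion
    would leak its identity to an image-only model and defeat the point of
    the task.
    """
    if rule not in ("side", "sign"):
        raise ValueError("rule must be 'side' or 'sign'")
    prevalence = dict(cfg.prevalence)
    prevalence["diagnosis"] = (0.25, 0.25, 0.5)  # balanced sign rule
    for group in ("asymmetry", "pigment_network", "dots_globules", "streaks",
                  "regression", "border_irregularity"):
        prevalence[group] = (1.0, 0.0, 0.0)
    prevalence["blue_whitish_veil"] = (1.0, 0.0)
    for flag in ("white", "red", "light_brown", "dark_brown", "blue_gray", "black"):
        prevalence[f"color_{flag}"] = 0.0
    return dataclasses.replace(
        cfg,
        contrast=min(cfg.contrast, 0.12),
        sigma_b=max(cfg.sigma_b, 2.0),
        lesion_frac=(0.12, 0.20),
        prevalence=prevalence,
        ambiguous=True,
        ambiguity_rule=rule,
    )
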