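"""Procedural generator of paired front/back flower-like images.

The generator emulates the situation that motivates two-view fusion: some
class pairs are identical on the front and distinguishable only on the back,
and vice versa.  Class identity is a discrete *cue vector* split across the
views — the front shows a radial petal rosette (petal count, petal hue,
center-disk radius), the back shows concentric calyx rings and bracts (ring
count, calyx hue, bract spokes).  The joint (front, back) cue vector is
unique per class by construction, so the theoretical accuracy of a
joint-view classifier is 1.0, while each single view is ambiguous exactly on
the constructed overlap pairs; :func:`bayes_separability` computes those
bounds by enumeration.

Rendering is cue-based rather than photorealistic so that ground truth
(bounding boxes, petal boundaries, separability bounds) is exactly
computable.  Nuisance variation (whole-flower rotation, brightness) is
seeded per (view-cue, sample-index), which makes the front renders of a
front-identical class pair pixel-identical up to noise — the single view
carries genuinely zero extra information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .datasets import DatasetManifest, SampleRecord

# distinct saturated petal hues (front) and leafy calyx hues (back)
FRONT_PALETTE = (
    (235, 235, 240),  # white
    (240, 210, 60),   # yellow
    (220, 120, 170),  # pink
    (200, 60, 50),    # red
    (150, 100, 200),  # violet
    (240, 150, 60),   # orange
)
BACK_PALETTE = (
    (110, 160, 70),
    (70, 130, 90),
    (150, 170, 60),
    (90, 110, 50),
    (130, 190, 120),
    (170, 150, 80),
)

_VIEW_CODE = {"front": 1, "back": 2}

#: plain background intensity (dark, like a studio backdrop)
BACKGROUND_GRAY = 30.0


@dataclass(frozen=True)
class FrontCues:
    petal_count: int
    hue_index: int
    radius_index: int

    def as_tuple(self):
        return (self.petal_count, self.hue_index, self.radius_index)


@dataclass(frozen=True)
class BackCues:
    ring_count: int
    hue_index: int
    bract_index: int

    def as_tuple(self):
        return (self.ring_count, self.hue_index, self.bract_index)


@dataclass
class SynthMetadata:
    """Ground truth for one rendered image."""

    bbox: tuple  # (row0, row1, col0, col1), inclusive
    petal_boundary: list  # [(row, col), ...]; empty for back views
    cues: tuple

    def to_dict(self):
        return {
            "bbox": list(self.bbox),
            "petal_boundary": [list(p) for p in self.petal_boundary],
            "cues": list(self.cues),
        }


@dataclass
class SynthSpec:
    """Study conditions for the synthetic two-view dataset.

    The defaults are the desk-scale conditions used throughout the test
    suite: 6 classes x 20 pairs at 64x64 with cue_overlap 2/3, which puts
    both single-view theoretical accuracy bounds at 2/3 while the joint
    bound stays 1.0.
    """

    n_classes: int = 6
    pairs_per_class: int = 20
    image_size: int = 64
    cue_overlap: float = 2.0 / 3.0
    noise_sigma: float = 8.0
    background_mode: str = "plain"
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.background_mode not in ("plain", "textured"):
            raise ValueError("background_mode must be 'plain' or 'textured'")
        k = self.n_overlap_pairs
        if 2 * k > self.n_classes:
            raise ValueError("cue_overlap too large for the class count")

    @property
    def n_overlap_pairs(self) -> int:
        """Number of front-identical class pairs (= back-identical pairs)."""
        return int(round(self.cue_overlap * self.n_classes / 2))

    def cue_groups(self):
        """Per-class front/back cue-group ids implementing the overlap plan.

        Front pairs: (0,1), (2,3), ...; back pairs shifted by one with
        wrap-around: (1,2), (3,4), ... — so no class pair shares both views
        and the joint cue vector stays unique.
        """
        n, k = self.n_classes, self.n_overlap_pairs
        front = np.arange(n)
        for i in range(k):
            front[2 * i + 1] = front[2 * i]
        back = np.arange(n) + 100  # distinct base ids
        for i in range(k):
            a, b = (2 * i + 1) % n, (2 * i + 2) % n
            back[b] = back[a]
        # renumber densely and offset so front/back palettes differ per class
        front = _dense(front)
        back = _dense(back)
        return front, back

    def class_cues(self):
        """List of (FrontCues, BackCues) per class; joint vector unique."""
        front_ids, back_ids = self.cue_groups()
        out = []
        for c in range(self.n_classes):
            g, h = int(front_ids[c]), int(back_ids[c])
            out.append((_front_cues(g), _back_cues(h)))
        joint = {(f.as_tuple(), b.as_tuple()) for f, b in out}
        assert len(joint) == self.n_classes, "joint cue vector must be unique per class"
        return out

    def class_labels(self):
        return [f"class{c:02d}" for c in range(self.n_classes)]

    def to_dict(self):
        return {
            "n_classes": self.n_classes,
            "pairs_per_class": self.pairs_per_class,
            "image_size": self.image_size,
            "cue_overlap": self.cue_overlap,
            "noise_sigma": self.noise_sigma,
            "background_mode": self.background_mode,
            "seed": self.seed,
        }


def _dense(ids: np.ndarray) -> np.ndarray:
    seen: dict[int, int] = {}
    out = np.empty_like(ids)
    for i, v in enumerate(ids):
        out[i] = seen.setdefault(int(v), len(seen))
    return out


def _front_cues(g: int) -> FrontCues:
    # (g % 8, g % 6) is injective for g < 24; radius extends the range
    return FrontCues(petal_count=5 + g % 8, hue_index=g % len(FRONT_PALETTE), radius_index=(g // 24) % 3)


def _back_cues(g: int) -> BackCues:
    return BackCues(ring_count=2 + g % 4, hue_index=g % len(BACK_PALETTE), bract_index=(g // 12) % 4)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_flower(view: str, cues, image_size: int, rng: np.random.Generator,
                  noise_sigma: float = 0.0, background_mode: str = "plain"):
    """Render one view; returns (uint8 RGB image, SynthMetadata).

    Deterministic given the rng state: nuisance parameters (whole-flower
    rotation, brightness) are drawn first, pixel noise last.
    """
    s = image_size
    theta0 = rng.uniform(0.0, 2 * np.pi)
    brightness = rng.uniform(0.92, 1.08)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cy = cx = (s - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    ang = np.arctan2(dy, dx)

    # dark studio background: strong luminance contrast for edge detection
    img = np.full((s, s, 3), BACKGROUND_GRAY)
    if background_mode == "textured":
        img += rng.normal(0.0, 6.0, size=(s, s, 1))

    petal_boundary: list = []
    if view == "front":
        flower_mask, petal_mask = _paint_front(img, cues, s, r, ang, theta0, brightness)
        eroded = ndimage.binary_erosion(petal_mask)
        rows, cols = np.nonzero(petal_mask & ~eroded)
        petal_boundary = list(zip(rows.tolist(), cols.tolist()))
    elif view == "back":
        flower_mask = _paint_back(img, cues, s, r, ang, theta0, brightness)
    else:
        raise ValueError(f"view must be 'front' or 'back', got {view!r}")

    rows, cols = np.nonzero(flower_mask)
    bbox = (int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max()))

    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, SynthMetadata(bbox=bbox, petal_boundary=petal_boundary, cues=cues.as_tuple())


def _paint(img, mask, color, brightness):
    img[mask] = np.clip(np.asarray(color, dtype=np.float64) * brightness, 0, 255)


def _paint_front(img, cues: FrontCues, s, r, ang, theta0, brightness):
    disk_r = (0.08 + 0.04 * cues.radius_index) * s
    petal_d = 0.30 * s                      # petal-center orbit radius
    a = 0.11 * s                            # radial semi-axis
    b = min(0.065 * s, 0.75 * np.pi * petal_d / cues.petal_count)  # keeps petals apart
    petal_mask = np.zeros(r.shape, dtype=bool)
    cy = cx = (s - 1) / 2.0
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    for i in range(cues.petal_count):
        phi = theta0 + 2 * np.pi * i / cues.petal_count
        pcy, pcx = cy + petal_d * np.sin(phi), cx + petal_d * np.cos(phi)
        u = (xx - pcx) * np.cos(phi) + (yy - pcy) * np.sin(phi)   # radial offset
        v = -(xx - pcx) * np.sin(phi) + (yy - pcy) * np.cos(phi)  # tangential offset
        petal_mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    _paint(img, petal_mask, FRONT_PALETTE[cues.hue_index], brightness)
    disk_mask = r <= disk_r
    _paint(img, disk_mask, (210, 160, 40), brightness)
    return petal_mask | disk_mask, petal_mask


def _paint_back(img, cues: BackCues, s, r, ang, theta0, brightness):
    base = np.asarray(BACK_PALETTE[cues.hue_index], dtype=np.float64)
    r_in, r_out = 0.08 * s, 0.32 * s
    n = cues.ring_count
    edges = np.linspace(r_in, r_out, 2 * n)  # alternating ring / gap bands
    mask_total = np.zeros(r.shape, dtype=bool)
    for i in range(n):
        lo = edges[2 * i]
        hi = edges[2 * i + 1] if 2 * i + 1 < len(edges) else r_out
        ring = (r >= lo) & (r <= hi)
        shade = 1.0 - 0.12 * (i % 2)
        _paint(img, ring, base * shade, brightness)
        mask_total |= ring
    # receptacle
    rec = r <= 0.05 * s
    _paint(img, rec, (120, 85, 50), brightness)
    mask_total |= rec
    # bract spokes just outside the rings
    n_spokes = 5 + 2 * cues.bract_index
    spoke_r = 0.38 * s
    cy = cx = (s - 1) / 2.0
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    for i in range(n_spokes):
        phi = theta0 + 2 * np.pi * i / n_spokes
        scy, scx = cy + spoke_r * np.sin(phi), cx + spoke_r * np.cos(phi)
        spot = (yy - scy) ** 2 + (xx - scx) ** 2 <= (0.03 * s) ** 2
        _paint(img, spot, base * 0.55, brightness)
        mask_total |= spot
    return mask_total


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _sample_rng(spec: SynthSpec, view: str, cue_group: int, class_idx: int, sample_idx: int):
    """Two rngs: nuisance seeded by (view, cue-group, sample) — shared by
    classes with identical cues on that view — and noise seeded per class."""
    nuisance = np.random.default_rng([spec.seed, _VIEW_CODE[view], cue_group, sample_idx])
    noise = np.random.default_rng([spec.seed, _VIEW_CODE[view], class_idx, sample_idx, 7919])
    return nuisance, noise


def render_pair(spec: SynthSpec, class_idx: int, sample_idx: int):
    """Render the (front, back) images + metadata for one specimen."""
    front_ids, back_ids = spec.cue_groups()
    cues = spec.class_cues()[class_idx]
    out = []
    for view, cue_obj, group in (
        ("front", cues[0], int(front_ids[class_idx])),
        ("back", cues[1], int(back_ids[class_idx])),
    ):
        nuisance_rng, noise_rng = _sample_rng(spec, view, group, class_idx, sample_idx)
        img, meta = render_flower(view, cue_obj, spec.image_size, nuisance_rng,
                                  noise_sigma=0.0, background_mode="plain")
        if spec.background_mode == "textured":
            img = img.astype(np.float64) + noise_rng.normal(0.0, 6.0, size=(spec.image_size, spec.image_size, 1))
        if spec.noise_sigma > 0:
            img = img.astype(np.float64) + noise_rng.normal(0.0, spec.noise_sigma, size=img.shape)
        img = np.clip(img, 0, 255).astype(np.uint8)
        out.append((img, meta))
    return out[0], out[1]


def generate_dataset(spec: SynthSpec, out_dir) -> DatasetManifest:
    """Write PNG pairs, per-image metadata JSON, and a manifest CSV.

    Returns the manifest (paths absolute); ``out_dir/manifest.csv``
    round-trips through :func:`duostream.datasets.read_manifest`.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    meta_dir = out_dir / "metadata"
    img_dir.mkdir(parents=True, exist_ok=True)
    meta_dir.mkdir(parents=True, exist_ok=True)
    labels = spec.class_labels()
    records = []
    rel_rows = []
    for c in range(spec.n_classes):
        origin = f"origin{c % 3}"
        for i in range(spec.pairs_per_class):
            pair_id = f"c{c:02d}_s{i:03d}"
            (front_img, front_meta), (back_img, back_meta) = render_pair(spec, c, i)
            fpath = img_dir / f"{pair_id}_front.png"
            bpath = img_dir / f"{pair_id}_back.png"
            Image.fromarray(front_img).save(fpath)
            Image.fromarray(back_img).save(bpath)
            with open(meta_dir / f"{pair_id}.json", "w") as fh:
                json.dump(
                    {"front": front_meta.to_dict(), "back": back_meta.to_dict()}, fh
                )
            records.append(
                SampleRecord(pair_id, str(fpath), str(bpath), labels[c], origin)
            )
            rel_rows.append(
                (pair_id, f"images/{pair_id}_front.png", f"images/{pair_id}_back.png", labels[c], origin)
            )
    import pandas as pd

    pd.DataFrame(
        rel_rows, columns=["pair_id", "front_path", "back_path", "class_label", "origin"]
    ).to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "synth_spec.json", "w") as fh:
        json.dump(spec.to_dict(), fh)
    return DatasetManifest(records=records, classes=sorted(set(labels)))


def load_metadata(out_dir, pair_id: str) -> dict:
    with open(Path(out_dir) / "metadata" / f"{pair_id}.json") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# separability bounds
# ---------------------------------------------------------------------------

def bayes_separability(spec: SynthSpec) -> dict:
    """Best achievable accuracy per view, by enumeration of cue assignments.

    With uniform class priors and deterministic (noiseless) cues, an optimal
    single-view classifier answers one class per cue group, so the bound is
    (#distinct cue vectors) / n_classes.  The joint bound is 1.0 because the
    joint cue vector is unique per class.
    """
    cues = spec.class_cues()
    n = spec.n_classes
    front_groups = {f.as_tuple() for f, _ in cues}
    back_groups = {b.as_tuple() for _, b in cues}
    joint_groups = {(f.as_tuple(), b.as_tuple()) for f, b in cues}
    return {
        "front": len(front_groups) / n,
        "back": len(back_groups) / n,
        "joint": len(joint_groups) / n,
    }
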