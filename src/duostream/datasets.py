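"""Manifest-driven handling of paired front/back specimen images.

A dataset is described by a CSV manifest with columns
``pair_id,front_path,back_path,class_label,origin``; the manifest is the
single source of pairing (no filename-convention inference, so a silent
mis-pairing cannot happen).  Splitting is stratified 6:2:2 per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

REQUIRED_COLUMNS = ("pair_id", "front_path", "back_path", "class_label", "origin")


class ManifestFormatError(ValueError):
    """Raised when a manifest file is structurally invalid."""


@dataclass(frozen=True)
class SampleRecord:
    """One specimen: its two view paths and its class label."""

    pair_id: str
    front_path: str
    back_path: str
    class_label: str
    origin: str = ""


@dataclass
class DatasetManifest:
    """Ordered records plus the (lexicographically sorted) label set."""

    records: list = field(default_factory=list)
    classes: list = field(default_factory=list)

    def __post_init__(self):
        ids = [r.pair_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ManifestFormatError("duplicate pair_id in manifest")
        labels = {r.class_label for r in self.records}
        missing = labels - set(self.classes)
        if missing:
            raise ManifestFormatError(f"labels not in class list: {sorted(missing)}")

    def __len__(self):
        return len(self.records)

    def by_class(self) -> dict:
        out: dict[str, list] = {c: [] for c in self.classes}
        for r in self.records:
            out[r.class_label].append(r)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records], columns=list(REQUIRED_COLUMNS))

    def write(self, path):
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SplitSpec:
    """6:2:2 stratified split specification."""

    train_fraction: float = 0.6
    val_fraction: float = 0.2
    test_fraction: float = 0.2
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions sum to {total}, not 1")


def read_manifest(path) -> DatasetManifest:
    """Parse a manifest CSV; record order follows file order, classes sorted."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestFormatError(f"manifest {path} missing columns: {missing}")
    base = path.parent
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                pair_id=row.pair_id,
                front_path=str(base / row.front_path),
                back_path=str(base / row.back_path),
                class_label=row.class_label,
                origin=row.origin,
            )
        )
    classes = sorted({r.class_label for r in records})
    return DatasetManifest(records=records, classes=classes)


def split_dataset(manifest: DatasetManifest, spec: SplitSpec):
    """Stratified split into (train, val, test) manifests.

    Per class: train gets floor(train_fraction * n), val gets
    floor(val_fraction * n), the remainder goes to test — deterministic and
    test never empties.  The same seed always yields the same split.
    """
    rng = np.random.default_rng(spec.seed)
    train, val, test = [], [], []
    groups = manifest.by_class() if spec.stratified else {"_all": list(manifest.records)}
    for label in sorted(groups):
        recs = list(groups[label])
        n = len(recs)
        if spec.stratified and n < 5:
            raise ValueError(
                f"class {label!r} has {n} records; need >= 5 for a stratified 6:2:2 split"
            )
        order = rng.permutation(n)
        n_train = int(np.floor(spec.train_fraction * n))
        n_val = int(np.floor(spec.val_fraction * n))
        for pos, idx in enumerate(order):
            if pos < n_train:
                train.append(recs[idx])
            elif pos < n_train + n_val:
                val.append(recs[idx])
            else:
                test.append(recs[idx])
    make = lambda rs: DatasetManifest(records=rs, classes=list(manifest.classes))
    return make(train), make(val), make(test)


def load_view_pair(record: SampleRecord):
    """Decode both views as uint8 RGB arrays (original resolution kept)."""
    return _load_rgb(record.front_path), _load_rgb(record.back_path)


def _load_rgb(path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")  # promotes grayscale by channel replication
            return np.asarray(im, dtype=np.uint8)
    except FileNotFoundError:
        raise FileNotFoundError(f"image not found: {path}")
    except Exception as exc:  # decode failure
        raise OSError(f"cannot decode image {path}: {exc}") from exc


def derive_repeat_seed(base_seed: int, repeat_index: int) -> int:
    """Run-level seed -> per-repeat seed (simple additive derivation)."""
    return int(base_seed) + int(repeat_index)
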