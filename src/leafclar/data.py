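"""Dataset manifests: class bookkeeping, amplification, splits, loading.

A manifest is an ordered table with columns ``path, label, condition, split,
provenance``.  Labels come from a closed six-class set (healthy plus five
diseases), condition tags describe acquisition conditions, split tags
partition the records once assigned.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

LABELS = ("normal", "huanglong", "corynespora", "fat_spot", "scab", "canker")
CONDITIONS = ("sunny", "cloudy", "foggy", "uneven")
SPLITS = ("train", "val", "test", "unassigned")
AUG_FAMILIES = ("rotate", "flip", "random_crop", "brightness")

MANIFEST_COLUMNS = ["path", "label", "condition", "split", "provenance"]


def largest_remainder_allocation(total: int, weights) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``.

    Floors the exact shares and hands the remaining units to the largest
    fractional parts (ties to the lower index), so the counts always sum to
    ``total`` exactly.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    exact = total * w / w.sum()
    counts = np.floor(exact).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        frac = exact - counts
        order = np.argsort(-frac, kind="stable")
        counts[order[:remainder]] += 1
    return counts


@dataclass
class DatasetManifest:
    """Ordered records; thin wrapper over a DataFrame with a fixed schema."""

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        bad = set(df["label"]) - set(LABELS)
        if bad:
            raise ValueError(f"unknown class labels {sorted(bad)}")
        self.records = df[MANIFEST_COLUMNS].reset_index(drop=True)

    def __len__(self):
        return len(self.records)

    @classmethod
    def from_rows(cls, rows) -> "DatasetManifest":
        return cls(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))

    @classmethod
    def read_csv(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path, dtype=str))

    def write_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(path, index=False)

    def to_csv_bytes(self) -> bytes:
        buf = io.StringIO()
        self.records.to_csv(buf, index=False)
        return buf.getvalue().encode()

    def subset(self, split: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split]


@dataclass
class AugmentationSpec:
    """Which augmentation families run and how amplification is seeded."""

    families: tuple = AUG_FAMILIES
    seed: int = 0

    def __post_init__(self):
        fams = tuple(self.families)
        if not fams:
            raise ValueError("at least one augmentation family is required")
        bad = set(fams) - set(AUG_FAMILIES)
        if bad:
            raise ValueError(f"unknown augmentation families {sorted(bad)}")
        self.families = fams


@dataclass
class SplitSpec:
    ratios: tuple = (0.6, 0.2, 0.2)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        r = np.asarray(self.ratios, dtype=np.float64)
        if len(r) != 3 or (r < 0).any() or r.sum() <= 0:
            raise ValueError("ratios must be three nonnegative reals with positive sum")
        self.ratios = tuple(r / r.sum())


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _aug_rng(seed: int, index: int, family: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(index, AUG_FAMILIES.index(family))))


def _augment_pixels(px: np.ndarray, family: str,
                    rng: np.random.Generator) -> np.ndarray:
    """One augmented variant; parameters drawn from the supplied rng."""
    if family == "rotate":
        k = int(rng.integers(1, 4))          # 90/180/270 degrees
        return np.rot90(px, k, axes=(0, 1)).copy()
    if family == "flip":
        axis = int(rng.integers(0, 2))
        return np.flip(px, axis=axis).copy()
    if family == "random_crop":
        frac = float(rng.uniform(0.8, 1.0))
        h, w = px.shape[:2]
        ch, cw = max(1, int(round(h * frac))), max(1, int(round(w * frac)))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        crop = px[top:top + ch, left:left + cw]
        im = Image.fromarray(np.clip(np.rint(crop * 255), 0, 255).astype(np.uint8))
        out = np.asarray(im.resize((w, h), Image.BILINEAR), dtype=np.float32) / 255.0
        return out
    if family == "brightness":
        factor = float(rng.uniform(0.7, 1.3))
        return np.clip(px * factor, 0.0, 1.0)
    raise ValueError(f"unknown augmentation family {family!r}")


def amplify(manifest: DatasetManifest, spec: AugmentationSpec,
            images_root=None, out_dir=None) -> DatasetManifest:
    """Amplify the source pool: one augmented record per family per source.

    Each source record is replaced by ``len(families)`` augmented records
    (the canonical four-family mode turns 2,525 sources into 10,100
    records), inheriting class and condition tags.  With ``images_root`` and
    ``out_dir`` set, the transformed images are actually written; otherwise
    only the manifest is produced (bookkeeping mode).
    """
    df = manifest.records
    if (df["provenance"] != "source").any():
        raise ValueError("amplify expects all records to have provenance 'source'")
    rows = []
    for idx, rec in enumerate(df.itertuples(index=False)):
        src = Path(rec.path)
        for family in spec.families:
            new_path = src.with_name(f"{src.stem}__{family}{src.suffix or '.png'}")
            rows.append((str(new_path), rec.label, rec.condition,
                         rec.split, "augmented"))
            if images_root is not None and out_dir is not None:
                px = np.asarray(Image.open(Path(images_root) / rec.path).convert("RGB"),
                                dtype=np.float32) / 255.0
                aug = _augment_pixels(px, family, _aug_rng(spec.seed, idx, family))
                out_path = Path(out_dir) / new_path.name
                out_path.parent.mkdir(parents=True, exist_ok=True)
                Image.fromarray(
                    np.clip(np.rint(aug * 255), 0, 255).astype(np.uint8)).save(out_path)
    return DatasetManifest.from_rows(rows)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_manifest(manifest: DatasetManifest, spec: SplitSpec) -> DatasetManifest:
    """Stratified random train/val/test assignment.

    Within each class the records are shuffled with the spec seed and cut at
    largest-remainder counts for the three ratios, so per-class and total
    split sizes are exact and reproducible.  Splits are disjoint and
    exhaustive.
    """
    df = manifest.records
    if (df["split"] != "unassigned").any():
        raise ValueError("split_manifest expects unassigned records")
    out = df.copy()
    rng = np.random.default_rng(spec.seed)
    group_keys = out["label"] if spec.stratified else np.zeros(len(out), dtype=int)
    for _, idx in out.groupby(group_keys, sort=True).groups.items():
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        counts = largest_remainder_allocation(len(idx), spec.ratios)
        tags = np.repeat(["train", "val", "test"], counts)
        out.loc[idx[perm], "split"] = tags
    return DatasetManifest(out)


def iterations_per_epoch(n_train: int, batch_size: int) -> int:
    """Optimizer steps per epoch: ``ceil(n_train / batch_size)``."""
    if n_train <= 0 or batch_size <= 0:
        raise ValueError("n_train and batch_size must be positive")
    return math.ceil(n_train / batch_size)


def class_summary(manifest: DatasetManifest) -> pd.DataFrame:
    """Counts and percentage share per class (percent rounded to 2 dp)."""
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    counts = manifest.records["label"].value_counts()
    counts = counts.reindex([l for l in LABELS if l in counts.index])
    total = int(counts.sum())
    return pd.DataFrame({
        "label": counts.index,
        "count": counts.values,
        "percent": np.round(100.0 * counts.values / total, 2),
    }).reset_index(drop=True)


def load_and_resize(path, size: tuple = (224, 224)) -> np.ndarray:
    """Load an image file, bilinearly resize, return float32 in [0, 1]."""
    try:
        with Image.open(path) as im:
            im = im.convert("RGB").resize((size[1], size[0]), Image.BILINEAR)
            return np.asarray(im, dtype=np.float32) / 255.0
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"cannot load manifest record {path!r}") from exc
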