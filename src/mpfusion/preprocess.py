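"""Image preprocessing, augmentation and patient-level data splitting.

Preprocessing standardises every slice to a 224 x 224, 3-channel, [0, 1]
image via center cropping and bilinear resizing.  Augmentation applies
random vertical/horizontal flips, a brightness (luminance) scale and a shear
("miscut") transform.  Splitting is always at the patient level — all slices
of a patient travel together — with a stratified 8:1:1 train/val/test rule
and a stratified k-fold splitter for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import transform as sktransform
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "center_crop_standardize", "augment", "stratified_patient_split",
    "kfold_split", "SplitManifest", "assign_slices", "to_unit_float",
]


def to_unit_float(image):
    """Cast to float64 in [0, 1]; integer images are scaled by their dtype."""
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        return image.astype(np.float64) / np.iinfo(image.dtype).max
    return image.astype(np.float64)


def center_crop_standardize(image, target=224):
    """Center-crop to a square of side min(H, W), resize bilinearly to
    ``target`` x ``target`` and replicate gray images to 3 channels."""
    image = to_unit_float(image)
    if image.ndim == 2:
        image = image[:, :, None]
    h, w = image.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("empty image")
    side = min(h, w)
    r0, c0 = (h - side) // 2, (w - side) // 2
    crop = image[r0:r0 + side, c0:c0 + side]
    if side != target:
        crop = sktransform.resize(crop, (target, target), order=1,
                                  preserve_range=True, anti_aliasing=False)
    if crop.shape[2] == 1:
        crop = np.repeat(crop, 3, axis=2)
    return np.clip(crop, 0.0, 1.0)


def augment(image, rng=None, *, flip_p=0.5, brightness_range=0.2,
            shear_deg=10.0, vflip=None, hflip=None, brightness_factor=None,
            shear=None):
    """Stochastic augmentation of one preprocessed image.

    Draws, from the seeded stream ``rng``: a vertical-flip coin, a
    horizontal-flip coin, a brightness factor in [1-b, 1+b] and a shear
    angle in [-s, s] degrees.  Any draw can be overridden by the
    corresponding keyword for deterministic use.  Shape and value range are
    preserved (brightness clips at 1.0).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    img = np.asarray(image, dtype=np.float64)
    if vflip is None:
        vflip = rng.random() < flip_p
    if hflip is None:
        hflip = rng.random() < flip_p
    if brightness_factor is None:
        brightness_factor = rng.uniform(1 - brightness_range,
                                        1 + brightness_range)
    if shear is None:
        shear = rng.uniform(-shear_deg, shear_deg)

    if vflip:
        img = img[::-1]
    if hflip:
        img = img[:, ::-1]
    img = np.clip(img * brightness_factor, 0.0, 1.0)
    if shear != 0.0:
        h, w = img.shape[:2]
        center = np.array([w, h]) / 2.0
        tf = (sktransform.AffineTransform(translation=center)
              + sktransform.AffineTransform(shear=np.deg2rad(shear))
              + sktransform.AffineTransform(translation=-center))
        img = sktransform.warp(img, tf.inverse, order=1, mode="edge",
                               preserve_range=True)
    return img


@dataclass
class SplitManifest:
    """Patient -> split assignment with bookkeeping.

    ``assignment`` maps patient id to 'train'/'val'/'test' (or to a fold
    role when produced by :func:`kfold_split`); splits partition the
    patient set.
    """

    assignment: dict
    ratios: tuple = (8, 1, 1)
    seed: int | None = None
    fold: int | None = None
    per_class_counts: dict = field(default_factory=dict)

    def patients(self, split):
        return sorted(p for p, s in self.assignment.items() if s == split)


def _as_label_map(patients):
    if isinstance(patients, pd.DataFrame):
        df = patients.drop_duplicates("patient_id")
        return dict(zip(df.patient_id, df.label))
    return dict(patients)


def stratified_patient_split(patients, ratios=(8, 1, 1), seed=0):
    """Stratified patient-level train/val/test split.

    Per class, ``val = round(n * r_val / sum(ratios))`` and likewise for
    test, with the train split taking the remainder — with the default
    8:1:1 ratios this reproduces 60/8/8 and 50/6/6 from a 76 + 62 cohort.
    Membership is randomised by ``seed``.
    """
    labels = _as_label_map(patients)
    rng = np.random.default_rng(seed)
    total = sum(ratios)
    assignment, counts = {}, {}
    for cls in sorted(set(labels.values())):
        pids = sorted(p for p, l in labels.items() if l == cls)
        if len(pids) < 3:
            raise ValueError(f"class {cls} has {len(pids)} patients; "
                             "cannot populate train/val/test")
        rng.shuffle(pids)
        n = len(pids)
        n_val = round(n * ratios[1] / total)
        n_test = round(n * ratios[2] / total)
        n_train = n - n_val - n_test
        for p in pids[:n_train]:
            assignment[p] = "train"
        for p in pids[n_train:n_train + n_val]:
            assignment[p] = "val"
        for p in pids[n_train + n_val:]:
            assignment[p] = "test"
        counts[cls] = {"train": n_train, "val": n_val, "test": n_test}
    return SplitManifest(assignment=assignment, ratios=tuple(ratios),
                         seed=seed, per_class_counts=counts)


def kfold_split(patients, k=10, seed=0):
    """Stratified patient-level k-fold splitter.

    Fold i uses subset i as the test set, subset i+1 (cyclically) as the
    validation set and the remaining k-2 subsets for training; every
    patient is tested exactly once across the k manifests.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    labels = _as_label_map(patients)
    pids = np.array(sorted(labels))
    if len(pids) < k:
        raise ValueError(f"{len(pids)} patients cannot fill {k} folds")
    y = np.array([labels[p] for p in pids])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    subsets = [pids[test_idx] for _, test_idx in skf.split(pids, y)]
    manifests = []
    for i in range(k):
        assignment = {}
        for j, subset in enumerate(subsets):
            role = ("test" if j == i
                    else "val" if j == (i + 1) % k
                    else "train")
            for p in subset:
                assignment[p] = role
        manifests.append(SplitManifest(assignment=assignment, ratios=(k - 2, 1, 1),
                                       seed=seed, fold=i))
    return manifests


def assign_slices(records, manifest: SplitManifest):
    """Stamp each slice record with its patient's split; all slices of a
    patient follow the patient."""
    for rec in records:
        rec.split = manifest.assignment[rec.patient_id]
    return records
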