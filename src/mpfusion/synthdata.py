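"""Synthetic paired-modality cohort generator with a computable Bayes bound.

Emulates a two-sequence MRI cohort for binary tumor-grade classification:
patients carry one of two labels (1 = high-grade, 0 = low-grade, imbalance
~55/45), each contributes 1-5 paired 2-D slices, and the class signal is
split complementarily across the two modalities:

* modality A ("T2WI-like") carries a *texture* cue — an oriented sinusoid
  added inside the lesion disk, with amplitude proportional to a latent cue
  strength ``u_A``;
* modality B ("DCE-like") carries an *intensity-ring* cue — a rim-contrast
  offset at the lesion boundary proportional to ``u_B``.

The latent cue strengths are class-conditional Gaussians,

    u_m | y  ~  Normal(effect_m * y, cue_noise^2),       m in {A, B},

independent between modalities given the class, shared within a patient up
to a small per-slice jitter.  Rendering adds i.i.d. Gaussian pixel noise.
Because the image depends on the class only through (u_A, u_B), the Bayes
error of the two-dimensional Gaussian cue model lower-bounds the error of
*any* classifier trained on the images — a numeric oracle that both upper-
bounds every trained network and certifies that fusing the modalities is
strictly better than either alone whenever both effects are positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "SynthConfig", "SliceRecord", "Cohort", "generate_cohort",
    "mirror_reference_manifest", "bayes_accuracy", "bayes_auc",
    "cue_features", "write_cohort",
]

# fraction of the total cue variance shared by all slices of a patient
_PATIENT_SHARE = 0.8
# rendered gray-level per unit of latent cue strength
_CUE_GAIN = 0.12
# stripe period of the texture cue, in pixels
_TEXTURE_PERIOD = 4.0


@dataclass
class SynthConfig:
    """Conditions of a synthetic cohort.

    ``n_patients_per_class`` is the balanced per-class count; the realised
    counts are ``n1 = round(2n * class_imbalance)`` high-grade and the rest
    low-grade (defaults mirror a 138-patient cohort: 76 + 62).
    ``effect_a``/``effect_b`` are the class-cue strengths of the texture and
    ring cue in units of the latent cue standard deviation ``cue_noise``.
    """

    n_patients_per_class: int = 69
    slices_per_patient_range: tuple = (1, 5)
    image_size: int = 256
    effect_a: float = 1.0
    effect_b: float = 1.0
    noise_sigma: float = 0.05
    cue_noise: float = 0.5
    class_imbalance: float = 0.551
    seed: int = 0

    def __post_init__(self):
        if self.n_patients_per_class <= 0:
            raise ValueError("n_patients_per_class must be positive")
        lo, hi = self.slices_per_patient_range
        if lo > hi or lo < 1:
            raise ValueError("degenerate slices_per_patient_range")
        if self.effect_a < 0 or self.effect_b < 0:
            raise ValueError("effects must be nonnegative")
        if self.noise_sigma <= 0 or self.cue_noise <= 0:
            raise ValueError("noise levels must be positive")
        if not 0.0 <= self.class_imbalance <= 1.0:
            raise ValueError("class_imbalance must lie in [0, 1]")

    @property
    def n_patients(self):
        return 2 * self.n_patients_per_class

    @property
    def n_high(self):
        return int(round(self.n_patients * self.class_imbalance))

    @property
    def n_low(self):
        return self.n_patients - self.n_high

    @classmethod
    def small_mode(cls, **overrides):
        """Fast test-scale conditions: 8+8 patients, 32x32 images."""
        base = dict(n_patients_per_class=8, image_size=32,
                    class_imbalance=0.5)
        base.update(overrides)
        return cls(**base)


@dataclass
class SliceRecord:
    """One paired slice: both modality references resolve to same-size
    images, every slice of a patient carries the patient's label, and a
    patient appears in exactly one split."""

    patient_id: str
    label: int
    modality_a_path: str
    modality_b_path: str
    split: str | int | None = None
    is_augmented: bool = False


@dataclass
class Cohort:
    config: SynthConfig
    records: list = field(default_factory=list)
    images: dict = field(default_factory=dict)   # path/key -> [S,S] float32
    latents: pd.DataFrame | None = None          # per-slice truth

    def manifest(self):
        return pd.DataFrame([vars(r) for r in self.records])

    def arrays(self, records=None):
        """Stack (X1, X2, y, patient_id) for the given records (all by
        default); images replicated to 3 channels, NHWC."""
        recs = self.records if records is None else records
        x1 = np.stack([self.images[r.modality_a_path] for r in recs])
        x2 = np.stack([self.images[r.modality_b_path] for r in recs])
        x1 = np.repeat(x1[..., None], 3, axis=3)
        x2 = np.repeat(x2[..., None], 3, axis=3)
        y = np.array([r.label for r in recs], dtype=int)
        pids = np.array([r.patient_id for r in recs])
        return x1, x2, y, pids


def _lesion_geometry(rng, size):
    cx = size / 2 + rng.uniform(-0.05, 0.05) * size
    cy = size / 2 + rng.uniform(-0.05, 0.05) * size
    radius = rng.uniform(0.22, 0.30) * size
    return cx, cy, radius


def _render_pair(rng, size, u_a, u_b, noise_sigma):
    """Render one paired slice from latent cue strengths (u_a, u_b)."""
    cx, cy, radius = _lesion_geometry(rng, size)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    rr = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    disk = rr <= radius
    ring = (rr >= 0.8 * radius) & (rr <= 1.1 * radius)

    base = 0.35 + 0.2 * disk
    stripes = np.sin(2.0 * np.pi * xx / _TEXTURE_PERIOD)
    img_a = base + _CUE_GAIN * u_a * stripes * disk
    img_b = base + _CUE_GAIN * u_b * ring

    img_a = img_a + rng.normal(0.0, noise_sigma, (size, size))
    img_b = img_b + rng.normal(0.0, noise_sigma, (size, size))
    geo = (cx, cy, radius)
    return (np.clip(img_a, 0, 1).astype(np.float32),
            np.clip(img_b, 0, 1).astype(np.float32), geo)


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate a paired two-modality cohort.

    Deterministic: the same config (including seed) yields a bit-identical
    image store.  Returns a :class:`Cohort` holding the slice records, the
    in-memory image store and a per-slice latent table (patient id, label,
    cue strengths, lesion geometry) for diagnostics and oracle checks.
    """
    rng = np.random.default_rng(config.seed)
    labels = np.array([1] * config.n_high + [0] * config.n_low)
    rng.shuffle(labels)

    tau = config.cue_noise
    tau_p = np.sqrt(_PATIENT_SHARE) * tau
    tau_s = np.sqrt(1.0 - _PATIENT_SHARE) * tau

    cohort = Cohort(config=config)
    rows = []
    lo, hi = config.slices_per_patient_range
    for i, y in enumerate(labels):
        pid = f"P{i:04d}"
        upa = config.effect_a * y + rng.normal(0.0, tau_p)
        upb = config.effect_b * y + rng.normal(0.0, tau_p)
        n_slices = int(rng.integers(lo, hi + 1))
        for s in range(n_slices):
            u_a = upa + rng.normal(0.0, tau_s)
            u_b = upb + rng.normal(0.0, tau_s)
            img_a, img_b, geo = _render_pair(rng, config.image_size,
                                             u_a, u_b, config.noise_sigma)
            key_a = f"{pid}_s{s}_a.png"
            key_b = f"{pid}_s{s}_b.png"
            cohort.images[key_a] = img_a
            cohort.images[key_b] = img_b
            cohort.records.append(SliceRecord(pid, int(y), key_a, key_b))
            rows.append(dict(patient_id=pid, label=int(y), slice=s,
                             u_a=u_a, u_b=u_b,
                             cx=geo[0], cy=geo[1], radius=geo[2]))
    cohort.latents = pd.DataFrame(rows)
    return cohort


def write_cohort(cohort: Cohort, out_dir):
    """Write the image store as 8-bit PNGs plus a CSV manifest."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, img in cohort.images.items():
        arr = np.round(img * 255).astype(np.uint8)
        Image.fromarray(arr).save(out / key)
    manifest = cohort.manifest()
    for col in ("modality_a_path", "modality_b_path"):
        manifest[col] = [str(Path(out_dir) / p) for p in manifest[col]]
    manifest.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"


# ---------------------------------------------------------------------------
# Bayes oracle on the latent cue model
# ---------------------------------------------------------------------------

def bayes_accuracy(effects, cue_noise=0.5, prior_high=0.551, numeric=False):
    """Bayes-optimal accuracy of the Gaussian cue model.

    ``effects`` is a sequence of per-modality cue strengths (use one entry
    for a marginal single-modality bound, two for the joint bound).  With
    equal-covariance Gaussian classes the likelihood-ratio statistic
    ``z = sum_m effect_m * u_m / tau^2`` is itself Gaussian, giving the
    closed form evaluated here; ``numeric=True`` instead integrates the
    pointwise max of the two class densities (same quantity, independent
    route).
    """
    eff = np.atleast_1d(np.asarray(effects, dtype=float))
    tau = float(cue_noise)
    pi1, pi0 = float(prior_high), 1.0 - float(prior_high)
    s2 = float(np.sum(eff**2)) / tau**2          # separation of z between classes
    if s2 == 0.0:
        return max(pi0, pi1)
    s = np.sqrt(s2)
    if not numeric:
        c = s2 / 2.0 + np.log(pi0 / pi1)         # decide high-grade if z > c
        return pi1 * norm.sf((c - s2) / s) + pi0 * norm.cdf(c / s)
    # numeric route: accuracy = integral of max(pi1 p1(z), pi0 p0(z)) dz
    f = lambda z: np.maximum(pi1 * norm.pdf(z, loc=s2, scale=s),
                             pi0 * norm.pdf(z, loc=0.0, scale=s))
    lo, hi = -10 * s, s2 + 10 * s
    val, _ = integrate.quad(f, lo, hi, limit=200)
    return float(val)


def bayes_auc(effects, cue_noise=0.5):
    """AUC of the Bayes-optimal score: Phi(s / sqrt(2)) with
    s = ||effects|| / cue_noise."""
    eff = np.atleast_1d(np.asarray(effects, dtype=float))
    s = float(np.linalg.norm(eff)) / float(cue_noise)
    return float(norm.cdf(s / np.sqrt(2.0)))


def cue_features(cohort: Cohort):
    """Matched-filter estimates of the latent cue strengths per slice.

    Projects each rendered image onto its known texture/ring template
    (using the stored lesion geometry), returning a DataFrame with columns
    ``t_a``, ``t_b`` and ``label``.  This is a generator diagnostic: it
    gives a fast, training-free "empirical fused classifier" feature space.
    """
    size = cohort.config.image_size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    rows = []
    lat = cohort.latents.set_index(["patient_id", "slice"])
    for rec in cohort.records:
        s = int(rec.modality_a_path.split("_s")[1].split("_")[0])
        meta = lat.loc[(rec.patient_id, s)]
        rr = np.sqrt((xx - meta.cx) ** 2 + (yy - meta.cy) ** 2)
        disk = rr <= meta.radius
        ring = (rr >= 0.8 * meta.radius) & (rr <= 1.1 * meta.radius)
        stripes = np.sin(2.0 * np.pi * xx / _TEXTURE_PERIOD) * disk
        img_a = cohort.images[rec.modality_a_path].astype(np.float64)
        img_b = cohort.images[rec.modality_b_path].astype(np.float64)
        denom_a = _CUE_GAIN * np.sum(stripes**2)
        denom_b = _CUE_GAIN * np.sum(ring)
        t_a = np.sum(img_a * stripes) / denom_a
        t_b = np.sum((img_b - (0.35 + 0.2 * disk)) * ring) / denom_b
        rows.append(dict(patient_id=rec.patient_id, label=rec.label,
                         t_a=t_a, t_b=t_b))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference split manifest (clinical-cohort slice counts)
# ---------------------------------------------------------------------------

# (split, label) -> (patients, original slices, augmented slices)
_REFERENCE_COUNTS = {
    ("train", 1): (60, 155, 743), ("train", 0): (50, 99, 665),
    ("val", 1): (8, 19, 94), ("val", 0): (6, 12, 82),
    ("test", 1): (8, 19, 94), ("test", 0): (6, 12, 82),
}


def mirror_reference_manifest() -> pd.DataFrame:
    """Reference manifest mirroring the clinical cohort's slice bookkeeping.

    Reproduces the reference per-split, per-class slice counts of a
    138-patient study cohort (316 original and 1760 augmented slices over an
    8:1:1 patient split) as a concrete manifest: slices are distributed as
    evenly as possible over the patients of each split/class cell, and each
    patient appears in exactly one split.  The expansion factors are copied
    verbatim — the augmentation multiplicity behind them was never stated.
    """
    rows = []
    pid_counter = 0
    for (split, label), (n_pat, n_orig, n_aug) in _REFERENCE_COUNTS.items():
        pids = [f"R{pid_counter + i:04d}" for i in range(n_pat)]
        pid_counter += n_pat
        for flag, total in ((False, n_orig), (True, n_aug)):
            base, extra = divmod(total, n_pat)
            for i, pid in enumerate(pids):
                n_slices = base + (1 if i < extra else 0)
                for s in range(n_slices):
                    tag = "aug" if flag else "orig"
                    rows.append(dict(
                        patient_id=pid, label=label,
                        modality_a_path=f"{pid}_{tag}{s}_a.png",
                        modality_b_path=f"{pid}_{tag}{s}_b.png",
                        split=split, is_augmented=flag))
    return pd.DataFrame(rows)
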