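"""Seeded generator of paired MRI-like volumes and expression profiles.

Emulates the statistical structure of a paired imaging-genomics cohort with
no download: each synthetic patient gets (a) a volume containing an
ellipsoidal "brain" filled with Gaussian-noise intensities and one
ellipsoidal lesion whose mean intensity and radius shift with the class
label, and (b) a block-correlated expression profile in which one gene
module's mean shifts with the class.  A cross-modal "xor" mode plants a
signal carried only by the image-gene interaction, for ablation tests.

Determinism: all randomness flows through one numpy PCG64 generator seeded
from the spec; class counts use largest-remainder allocation, not sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import (BrainMask, ExpressionProfile, VolumeImage,
                         save_mask, save_volume)

__all__ = ["SyntheticCohortSpec", "largest_remainder", "generate_volume",
           "generate_expression", "generate_cohort", "generate_cohort_arrays"]


@dataclass
class SyntheticCohortSpec:
    n_patients: int = 60
    n_classes: int = 3
    class_proportions: tuple = ()   # default mildly imbalanced, class 0 largest
    volume_side: int = 16
    n_genes: int = 50
    n_modules: int = 4
    effect_size: float = 2.0
    noise_sd: float = 0.3
    signal_mode: str = "additive"   # or "xor" (cross-modal interaction)
    seed: int = 0

    def __post_init__(self):
        if not self.class_proportions:
            if self.signal_mode == "xor":
                self.n_classes = 2
                self.class_proportions = (0.5, 0.5)
            else:
                base = np.array([0.45, 0.30, 0.25])
                if self.n_classes != 3:
                    base = np.linspace(2.0, 1.0, self.n_classes)
                    base /= base.sum()
                self.class_proportions = tuple(base)
        props = np.asarray(self.class_proportions, dtype=np.float64)
        if len(props) != self.n_classes or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1 and match "
                             "n_classes")
        if self.n_modules > self.n_genes:
            raise ValueError("n_modules cannot exceed n_genes")
        if self.signal_mode not in ("additive", "xor"):
            raise ValueError("signal_mode must be 'additive' or 'xor'")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def largest_remainder(n: int, proportions) -> list[int]:
    """Integer allocation of n items to proportions, exact by construction."""
    props = np.asarray(proportions, dtype=np.float64)
    quotas = n * props
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    return counts.tolist()


def _ellipsoid(shape: tuple, center: np.ndarray, radii: np.ndarray
               ) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    dist = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return dist <= 1.0


def generate_volume(class_id: int, spec: SyntheticCohortSpec,
                    rng: np.random.Generator, patient_id: str = "",
                    lesion_shift: float | None = None
                    ) -> tuple[VolumeImage, BrainMask]:
    """One synthetic volume + brain mask.

    Brain = centered ellipsoid (intensity 1 + noise); lesion = smaller
    ellipsoid at a random interior position with intensity raised by
    1 + class_id * effect_size (and radius growing mildly with class).
    """
    if class_id >= spec.n_classes or class_id < 0:
        raise ValueError(f"class_id {class_id} out of range")
    if spec.volume_side < 8:
        raise ValueError("volume_side must be >= 8")
    s = spec.volume_side
    shape = (s, s, s)
    center = np.full(3, (s - 1) / 2.0)
    brain_radii = np.full(3, 0.42 * s)
    brain = _ellipsoid(shape, center, brain_radii)
    data = np.zeros(shape)
    data[brain] = 1.0 + rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
    if lesion_shift is None:
        lesion_shift = class_id * spec.effect_size
    lesion_r = 0.12 * s * (1.0 + 0.05 * lesion_shift)
    max_off = max(0.42 * s - lesion_r - 1.0, 0.0)
    offset = rng.uniform(-max_off, max_off, size=3) * 0.5
    lesion = _ellipsoid(shape, center + offset, np.full(3, lesion_r)) & brain
    data[lesion] += 1.0 + lesion_shift
    return (VolumeImage(data=data, spacing=(1.0, 1.0, 1.0), id=patient_id),
            BrainMask(data=brain.astype(np.uint8)))


def _module_assignment(spec: SyntheticCohortSpec) -> np.ndarray:
    sizes = largest_remainder(spec.n_genes,
                              np.full(spec.n_modules, 1.0 / spec.n_modules))
    return np.repeat(np.arange(spec.n_modules), sizes)


def generate_expression(class_id: int, spec: SyntheticCohortSpec,
                        rng: np.random.Generator, patient_id: str = "",
                        module_shift: float | None = None
                        ) -> ExpressionProfile:
    """Block-correlated log-normal expression with a class-shifted module.

    Genes within a module share a latent factor (loading sqrt(0.6), so the
    expected within-module correlation is 0.6); module 0's mean shifts by
    class_id * effect_size on the log2 scale, then values are exponentiated.
    """
    if class_id >= spec.n_classes or class_id < 0:
        raise ValueError(f"class_id {class_id} out of range")
    modules = _module_assignment(spec)
    factors = rng.normal(size=spec.n_modules)
    rho = 0.6
    x = (np.sqrt(rho) * factors[modules]
         + np.sqrt(1 - rho) * rng.normal(size=spec.n_genes))
    x += 3.0  # baseline log2 expression level
    if module_shift is None:
        module_shift = class_id * spec.effect_size
    x[modules == 0] += module_shift
    values = np.exp2(x) - 1.0
    values = np.maximum(values, 0.0)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    return ExpressionProfile(values=pd.Series(values, index=genes),
                             patient_id=patient_id)


def _cohort_plan(spec: SyntheticCohortSpec, rng: np.random.Generator):
    """Per-patient (label, image_shift, module_shift) under the signal mode."""
    counts = largest_remainder(spec.n_patients, spec.class_proportions)
    labels = np.repeat(np.arange(spec.n_classes), counts)
    plan = []
    if spec.signal_mode == "additive":
        for lab in labels:
            shift = lab * spec.effect_size
            plan.append((int(lab), shift, shift))
    else:  # xor: label = u XOR v; each modality alone is uninformative
        for lab in labels:
            u = int(rng.integers(2))
            v = u ^ int(lab)
            plan.append((int(lab), u * spec.effect_size, v * spec.effect_size))
    return plan


def generate_cohort_arrays(spec: SyntheticCohortSpec) -> dict:
    """In-memory cohort: volumes, masks, profiles, labels, patient ids."""
    rng = np.random.default_rng(spec.seed)
    plan = _cohort_plan(spec, rng)
    out = {"volumes": [], "masks": [], "profiles": [], "labels": [],
           "patient_ids": []}
    for i, (lab, img_shift, mod_shift) in enumerate(plan):
        pid = f"P{i:04d}"
        vol, mask = generate_volume(lab, spec, rng, patient_id=pid,
                                    lesion_shift=img_shift)
        prof = generate_expression(lab, spec, rng, patient_id=pid,
                                   module_shift=mod_shift)
        out["volumes"].append(vol)
        out["masks"].append(mask)
        out["profiles"].append(prof)
        out["labels"].append(lab)
        out["patient_ids"].append(pid)
    return out


def generate_cohort(spec: SyntheticCohortSpec, out_dir: str) -> pd.DataFrame:
    """Write the cohort to disk (NIfTI volumes + masks, expression TSV,
    pairing manifest CSV); returns the manifest."""
    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort_arrays(spec)
    rows = []
    for vol, mask, pid, lab in zip(cohort["volumes"], cohort["masks"],
                                   cohort["patient_ids"], cohort["labels"]):
        vpath = out / "volumes" / f"{pid}.nii.gz"
        mpath = out / "masks" / f"{pid}_mask.nii.gz"
        save_volume(vol, str(vpath))
        save_mask(mask, str(mpath))
        rows.append({"patient_id": pid, "image_path": str(vpath),
                     "mask_path": str(mpath), "label": int(lab)})
    table = pd.DataFrame(
        {p.patient_id: p.values for p in cohort["profiles"]})
    table.index.name = "gene"
    table.to_csv(out / "expression.tsv", sep="\t", float_format="%.6f")
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
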