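"""Synthetic FDG-PET cohort generator.

Emulates the multiplicative structure the scaled-subprofile model assumes:
each subject's image is a smooth group mean profile, scaled by a per-subject
global scaling factor (GSF), modulated by a group-specific regional
deviation pattern, and corrupted by voxel-wise multiplicative log-normal
noise. The log transform downstream turns every one of these effects into
an additive one, which is exactly the generative regime the model is built
for.

Patterns are placed in ellipsoidal pseudo-anatomical regions of a synthetic
brain ellipsoid, with extents chosen to echo how spatially extensive the
real disease-related topographies are (whole cortical territories and the
cerebellum, not isolated nuclei). Parkinson's disease (PD) raises striatum
and cerebellum and lowers parieto-temporal cortex; multiple system atrophy
(MSA) lowers putamen and cerebellum (the cerebellum is shared with PD at
opposite sign, echoing the strong PD-MSA topography anti-correlation);
progressive supranuclear palsy (PSP) lowers caudate and mediofrontal
cortex with relatively raised cerebellum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import BrainVolume, write_manifest

__all__ = ["SyntheticCohortSpec", "LabeledCohort", "make_group_patterns", "simulate_cohort", "write_cohort"]

CLASSES = ("PD", "MSA", "PSP")

#: Intensity of voxels outside the brain ellipsoid, as a fraction of the
#: base profile's peak. Small but positive so percentage-of-maximum masking
#: has something to exclude and the log transform stays defined everywhere.
BACKGROUND_FRACTION = 0.01

#: Peak intensity of the noise-free group mean profile (arbitrary units).
BASE_PEAK = 100.0


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a simulated identification or validation cohort.

    pattern_amplitude is the fractional regional metabolic deviation
    (0.15 = 15% hyper-/hypometabolism); gsf_range bounds the per-subject
    global scaling factor; noise_sd is the standard deviation of the
    voxel-level log-normal noise (in log-intensity units).
    """

    grid_shape: tuple[int, int, int] = (20, 24, 20)
    n_per_group: int = 20
    pattern_amplitude: float = 0.15
    gsf_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(d < 8 for d in self.grid_shape):
            raise ValueError(f"grid_shape must be 3D with all dims >= 8, got {self.grid_shape}")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if self.pattern_amplitude < 0:
            raise ValueError("pattern_amplitude must be >= 0")
        lo, hi = self.gsf_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"gsf_range must satisfy 0 < lo <= hi, got {self.gsf_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class LabeledCohort:
    """Simulated volumes with class labels and the generating truth maps."""

    images: list[BrainVolume]
    labels: list[str]
    truth_patterns: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have the same length")


def _normalized_radius(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal radius normalized so the brain boundary is at r = 1."""
    center = [(d - 1) / 2.0 for d in grid_shape]
    semi = [0.42 * d for d in grid_shape]
    axes = np.ogrid[tuple(slice(0, d) for d in grid_shape)]
    r2 = sum(((ax - c) / s) ** 2 for ax, c, s in zip(axes, center, semi))
    return np.sqrt(r2)


def brain_support(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean map of the synthetic brain ellipsoid."""
    return _normalized_radius(grid_shape) <= 1.0


def base_profile(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Noise-free group mean profile: bright center falling to a dim rim.

    Inside the brain the intensity runs from BASE_PEAK at the center down
    to 25% of peak at the rim, so percentage-of-maximum thresholds in the
    15-45% band trim the rim progressively; outside, a small positive
    background (BACKGROUND_FRACTION of peak).
    """
    r = _normalized_radius(grid_shape)
    profile = np.full(grid_shape, BACKGROUND_FRACTION * BASE_PEAK)
    inside = r <= 1.0
    profile[inside] = BASE_PEAK * (1.0 - 0.75 * r[inside] ** 2)
    return profile


def _ellipsoid(grid_shape: tuple[int, int, int], center_frac, semi_frac) -> np.ndarray:
    """Boolean ellipsoidal region given fractional center and semi-axes."""
    dims = np.asarray(grid_shape, dtype=float)
    center = np.asarray(center_frac) * (dims - 1)
    semi = np.asarray(semi_frac) * dims
    if np.any(semi < 0.5) or np.any(2 * semi > dims):
        raise ValueError(
            f"pattern region with semi-axes {semi} does not fit grid {grid_shape}"
        )
    axes = np.ogrid[tuple(slice(0, d) for d in grid_shape)]
    r2 = sum(((ax - c) / s) ** 2 for ax, c, s in zip(axes, center, semi))
    return r2 <= 1.0


def make_group_patterns(spec: SyntheticCohortSpec) -> dict[str, np.ndarray]:
    """Build the three class-specific fractional deviation maps.

    Each map is +/- ``spec.pattern_amplitude`` inside its ellipsoidal
    regions (clipped to the brain ellipsoid) and exactly 0 elsewhere. The
    cerebellar region is shared by PD (+) and MSA (-) so the two class
    topographies are anti-correlated by construction.
    """
    g = spec.grid_shape
    brain = brain_support(g)
    regions = {
        "striatum": _ellipsoid(g, (0.50, 0.55, 0.45), (0.16, 0.13, 0.13)),
        "cerebellum": _ellipsoid(g, (0.50, 0.20, 0.30), (0.22, 0.12, 0.14)),
        "parietotemporal": _ellipsoid(g, (0.50, 0.38, 0.72), (0.22, 0.13, 0.13)),
        "putamen": _ellipsoid(g, (0.66, 0.55, 0.45), (0.14, 0.12, 0.13)),
        "caudate": _ellipsoid(g, (0.42, 0.66, 0.52), (0.10, 0.10, 0.11)),
        "mediofrontal": _ellipsoid(g, (0.50, 0.82, 0.60), (0.18, 0.11, 0.14)),
    }
    a = spec.pattern_amplitude
    patterns = {c: np.zeros(g) for c in CLASSES}
    patterns["PD"][regions["striatum"]] = a
    patterns["PD"][regions["cerebellum"]] = a
    patterns["PD"][regions["parietotemporal"]] = -a
    patterns["MSA"][regions["putamen"]] = -a
    patterns["MSA"][regions["cerebellum"]] = -a
    patterns["PSP"][regions["caudate"]] = -a
    patterns["PSP"][regions["mediofrontal"]] = -a
    patterns["PSP"][regions["cerebellum"]] = a
    for c in CLASSES:
        patterns[c][~brain] = 0.0
    return patterns


def simulate_cohort(spec: SyntheticCohortSpec) -> LabeledCohort:
    """Simulate a balanced labeled cohort under the multiplicative model.

    Each image is ``GSF_i * base_profile * (1 + pattern_class) * exp(eps)``
    with ``eps ~ Normal(0, noise_sd)`` i.i.d. per voxel and ``GSF_i``
    uniform on ``gsf_range``. Identical spec (including seed) yields a
    bit-identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    base = base_profile(spec.grid_shape)
    patterns = make_group_patterns(spec)
    images, labels = [], []
    for cls in CLASSES:
        modulated = base * (1.0 + patterns[cls])
        for i in range(spec.n_per_group):
            gsf = rng.uniform(*spec.gsf_range)
            if spec.noise_sd > 0:
                noise = np.exp(rng.normal(0.0, spec.noise_sd, size=spec.grid_shape))
            else:
                noise = 1.0
            data = gsf * modulated * noise
            images.append(
                BrainVolume(data=data, subject_id=f"{cls}{i:03d}", label=cls)
            )
            labels.append(cls)
    return LabeledCohort(images=images, labels=labels, truth_patterns=patterns)


def write_cohort(cohort: LabeledCohort, outdir: str | Path, split: str = "identification") -> Path:
    """Write a cohort as NIfTI-1 volumes plus a manifest CSV.

    Returns the manifest path; readable back via
    :func:`parkmlr.image_io.load_cohort_volumes`.
    """
    from .image_io import save_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for vol in cohort.images:
        fname = f"{vol.subject_id}.nii"
        save_volume(vol, outdir / fname)
        records.append(
            {"subject_id": vol.subject_id, "path": fname, "label": vol.label, "split": split}
        )
    manifest_path = outdir / "manifest.csv"
    write_manifest(pd.DataFrame(records), manifest_path)
    return manifest_path
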