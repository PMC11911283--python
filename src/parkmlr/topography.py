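"""Disease-specific metabolic topographies.

Each non-reference class's topography is the linear combination of the
selected GIS columns weighted by that class's regression coefficients
(the intercept is excluded: a constant offset has no spatial meaning under
a double-centered basis). The map shows which voxels' relative metabolism
drives the class log-odds against the UD reference — e.g. striatal and
cerebellar relative hypermetabolism for PD, putaminal/cerebellar
hypometabolism for MSA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .image_io import BrainVolume, unstack
from .mlr import CLASS_ORDER, MultinomialFit
from .ssm import SSMModel

__all__ = ["Topography", "compute_topographies", "topography_correlation"]


@dataclass
class Topography:
    """Voxel weight map of one class-vs-UD contrast."""

    label: str                      # "PD/UD", "MSA/UD" or "PSP/UD"
    weights: np.ndarray             # (N,) masked-voxel weights
    volume: BrainVolume             # weights re-embedded in brain space
    component_indices: tuple[int, ...]


def compute_topographies(ssm: SSMModel, fit: MultinomialFit) -> list[Topography]:
    """One topography per disease class, from the same frozen model.

    weights(class) = GIS[:, selected] @ B[1:, class]; reordering the
    selected components permutes both factors identically, so the product
    is order-invariant.
    """
    if any(c < 1 or c > ssm.n_components for c in fit.component_indices):
        raise ValueError(
            f"fit components {fit.component_indices} not all retained by the "
            f"SSM model ({ssm.n_components} components)"
        )
    cols = [c - 1 for c in fit.component_indices]
    basis = ssm.gis[:, cols]
    out = []
    for j, cls in enumerate(CLASS_ORDER[:3]):
        w = basis @ fit.coefficients[1:, j]
        out.append(
            Topography(
                label=f"{cls}/UD",
                weights=w,
                volume=unstack(w, ssm.mask, subject_id=f"{cls}_UD_topography"),
                component_indices=fit.component_indices,
            )
        )
    return out


def topography_correlation(a: Topography, b: Topography) -> float:
    """Voxel-wise Pearson correlation of two topographies on the same mask.

    Undefined (NaN, with a warning) when either map has zero variance.
    """
    if a.weights.shape != b.weights.shape:
        raise ValueError("topographies are on different masks")
    if np.std(a.weights) == 0 or np.std(b.weights) == 0:
        warnings.warn("zero-variance topography: correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a.weights, b.weights)[0, 1])


def correlation_table(topographies: list[Topography]) -> "np.ndarray":
    """Pairwise correlation matrix in the given topography order."""
    k = len(topographies)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r[i, j] = r[j, i] = topography_correlation(topographies[i], topographies[j])
    return r
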