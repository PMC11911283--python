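"""Scaled Subprofile Model / PCA core.

The subjects x voxels intensity matrix **P** is log-transformed and double
centered: subtracting each subject's own row mean removes the global
scaling factor (a multiplicative brightness becomes an additive offset in
log space), and subtracting the column means removes the group mean
profile. What remains is the subject residual profile (SRP), which is
decomposed by PCA of the small subjects x subjects covariance
``S_sub = SRP @ SRP.T``. The voxel-space principal components (group
invariant subprofiles, GIS) and the per-subject expression scores (subject
scores field, SSF) follow from the eigenvectors E and eigenvalues L:

    GIS = SRP.T @ E @ L^(-1/2)        (orthonormal voxel topographies)
    SSF = E @ L^(1/2)                 (subject scores)
    SRP = SSF @ GIS.T                 (exact reconstruction)

New subjects are projected into score space with the model frozen: their
own row mean is subtracted, but the *training* voxel mean profile is
reused, never recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .image_io import BrainVolume, VoxelMask, VoxelMatrix, stack

__all__ = ["SSMModel", "SubjectScores", "double_center", "eigendecompose", "fit_ssm", "project_subjects"]

#: Components with eigenvalue below this fraction of the largest are
#: numerical rank deficiencies (double centering removes one dimension)
#: and are dropped.
RANK_TOL = 1e-10


@dataclass
class SSMModel:
    """Frozen SSM/PCA state of an identification cohort.

    ``voxel_mean_profile`` holds the column means subtracted during double
    centering (the log-space group mean profile); ``gis`` columns are the
    orthonormal voxel-space components; ``ssf`` the training subjects'
    scores; ``vaf`` each component's fraction of total variance.
    """

    voxel_mean_profile: np.ndarray  # (N,)
    eigenvalues: np.ndarray         # (K,), descending
    subject_eigenvectors: np.ndarray  # (M, K)
    gis: np.ndarray                 # (N, K)
    ssf: np.ndarray                 # (M, K)
    vaf: np.ndarray                 # (K,)
    mask: VoxelMask
    subject_ids: list[str]
    labels: list[str]

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def save(self, path: str | Path) -> None:
        """Serialize all arrays plus the mask to one .npz archive."""
        np.savez(
            path,
            format_version=np.array(1),
            voxel_mean_profile=self.voxel_mean_profile,
            eigenvalues=self.eigenvalues,
            subject_eigenvectors=self.subject_eigenvectors,
            gis=self.gis,
            ssf=self.ssf,
            vaf=self.vaf,
            mask_included=self.mask.included,
            mask_threshold=np.array(self.mask.threshold_pct),
            subject_ids=np.array(self.subject_ids),
            labels=np.array(self.labels),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SSMModel":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                voxel_mean_profile=z["voxel_mean_profile"],
                eigenvalues=z["eigenvalues"],
                subject_eigenvectors=z["subject_eigenvectors"],
                gis=z["gis"],
                ssf=z["ssf"],
                vaf=z["vaf"],
                mask=VoxelMask(z["mask_included"], float(z["mask_threshold"])),
                subject_ids=[str(s) for s in z["subject_ids"]],
                labels=[str(s) for s in z["labels"]],
            )


@dataclass
class SubjectScores:
    """Per-subject expression scores on a subset of components.

    Component indices are 1-based (the field's convention for "1st, 2nd,
    ... principal component") and the score columns follow them in
    ascending order.
    """

    scores: np.ndarray            # (n_subjects, n_components)
    component_indices: tuple[int, ...]
    subject_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.component_indices)
        if list(idx) != sorted(idx):
            raise ValueError("component_indices must be ascending")
        self.component_indices = idx
        if self.scores.shape[1] != len(idx):
            raise ValueError("score columns must match component_indices")


def double_center(matrix: VoxelMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-transform and double center, returning (SRP, voxel_mean_profile).

    Row means of the log matrix are removed first (per-subject global
    scaling), then the column means of the row-centered matrix (the group
    mean profile); the subtracted column means are returned so new
    subjects can be centered identically.
    """
    values = matrix.values if isinstance(matrix, VoxelMatrix) else np.asarray(matrix, float)
    if np.any(values <= 0):
        i, j = np.unravel_index(int(np.argmax(values <= 0)), values.shape)
        raise ValueError(
            f"non-positive intensity at subject row {i}, voxel column {j}: "
            "log transform undefined"
        )
    q = np.log(values)
    q -= q.mean(axis=1, keepdims=True)
    voxel_mean_profile = q.mean(axis=0)
    srp = q - voxel_mean_profile
    return srp, voxel_mean_profile


def eigendecompose(
    srp: np.ndarray,
    voxel_mean_profile: np.ndarray,
    mask: VoxelMask,
    subject_ids: list[str],
    labels: list[str],
) -> SSMModel:
    """PCA of the subject covariance of a double-centered SRP.

    Components below RANK_TOL x largest eigenvalue are dropped (double
    centering always removes at least one dimension). Eigenvector sign is
    fixed by making the largest-magnitude entry of each GIS column
    positive, so topographies are reproducible; the paired sign flip of E
    leaves the reconstruction SSF @ GIS.T unchanged.
    """
    srp = np.asarray(srp, dtype=np.float64)
    s_sub = srp @ srp.T
    if not np.any(np.abs(s_sub) > 0):
        raise ValueError("SRP is identically zero: degenerate cohort")
    eigvals, eigvecs = np.linalg.eigh(s_sub)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > RANK_TOL * eigvals[0]
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]

    gis = srp.T @ eigvecs @ np.diag(eigvals ** -0.5)
    # deterministic sign: dominant GIS entry positive, E flipped in step
    flip = np.sign(gis[np.abs(gis).argmax(axis=0), np.arange(gis.shape[1])])
    flip[flip == 0] = 1.0
    gis *= flip
    eigvecs = eigvecs * flip
    ssf = eigvecs @ np.diag(eigvals ** 0.5)

    return SSMModel(
        voxel_mean_profile=np.asarray(voxel_mean_profile, float),
        eigenvalues=eigvals,
        subject_eigenvectors=eigvecs,
        gis=gis,
        ssf=ssf,
        vaf=eigvals / eigvals.sum(),
        mask=mask,
        subject_ids=list(subject_ids),
        labels=list(labels),
    )


def fit_ssm(matrix: VoxelMatrix) -> SSMModel:
    """Convenience: double-center a voxel matrix and eigendecompose it."""
    srp, vmp = double_center(matrix)
    return eigendecompose(srp, vmp, matrix.mask, matrix.subject_ids, matrix.labels)


def project_subjects(
    data: VoxelMatrix | list[BrainVolume],
    model: SSMModel,
    components: tuple[int, ...] | None = None,
) -> SubjectScores:
    """Score new subjects on the model's components (1-based indices).

    Each subject's log profile is centered by its own row mean, then by
    the frozen training voxel mean profile, and projected onto the GIS
    columns. Applied to the training matrix itself this reproduces the
    training SSF.
    """
    if isinstance(data, list):
        data = stack(data, model.mask)
    if data.mask.n_voxels != model.mask.n_voxels or not np.array_equal(
        data.mask.included, model.mask.included
    ):
        raise ValueError("subjects must be stacked with the model's training mask")
    if components is None:
        components = tuple(range(1, model.n_components + 1))
    components = tuple(sorted(int(c) for c in components))
    if components and (components[0] < 1 or components[-1] > model.n_components):
        raise ValueError(
            f"component indices {components} outside retained range "
            f"1..{model.n_components}"
        )
    q = np.log(data.values)
    q -= q.mean(axis=1, keepdims=True)
    srp_new = q - model.voxel_mean_profile
    cols = [c - 1 for c in components]
    scores = srp_new @ model.gis[:, cols]
    return SubjectScores(
        scores=scores,
        component_indices=components,
        subject_ids=data.subject_ids,
        labels=data.labels,
    )
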