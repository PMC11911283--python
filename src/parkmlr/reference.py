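"""Construction of the artificial "undetermined" (UD) reference group.

The multinomial model needs a reference category, but the whole point of
the approach is to work without healthy controls. The reference is built
instead from the identification cohort itself: each UD image is the
voxel-wise arithmetic mean of one PD, one MSA and one PSP image (in native
intensity space, before the log transform), and every patient image
contributes to at most one UD image so the references stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import BrainVolume

__all__ = ["TripletPlan", "plan_triplets", "build_ud_images", "augment_with_ud"]

_TRIPLET_CLASSES = ("PD", "MSA", "PSP")


@dataclass
class TripletPlan:
    """Disjoint (PD, MSA, PSP) subject triplets used to average UD images."""

    triplets: list[tuple[str, str, str]]
    seed: int

    def __post_init__(self) -> None:
        flat = [sid for t in self.triplets for sid in t]
        if len(flat) != len(set(flat)):
            raise ValueError("a subject id appears in more than one triplet")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.triplets, columns=["pd_id", "msa_id", "psp_id"]
        ).rename_axis("triplet").to_csv(path)


def plan_triplets(subject_ids: list[str], labels: list[str], seed: int = 0) -> TripletPlan:
    """Pair subjects into min-group-size disjoint triplets, one per class.

    The pairing itself is arbitrary (any disjoint assignment satisfies the
    independence requirement), so it is drawn as a seeded uniform shuffle
    per class; results downstream should be insensitive to it.
    """
    by_class: dict[str, list[str]] = {c: [] for c in _TRIPLET_CLASSES}
    for sid, lab in zip(subject_ids, labels):
        if lab in by_class:
            by_class[lab].append(sid)
    for c, ids in by_class.items():
        if not ids:
            raise ValueError(f"cannot build UD triplets: class {c} is empty")
    rng = np.random.default_rng(seed)
    shuffled = {c: list(rng.permutation(ids)) for c, ids in by_class.items()}
    n = min(len(ids) for ids in shuffled.values())
    triplets = [
        (shuffled["PD"][k], shuffled["MSA"][k], shuffled["PSP"][k]) for k in range(n)
    ]
    return TripletPlan(triplets=triplets, seed=seed)


def build_ud_images(volumes: list[BrainVolume], plan: TripletPlan) -> list[BrainVolume]:
    """Average each planned triplet into a UD-labeled volume.

    Averaging happens in native intensity space; UD images are strictly
    positive whenever the inputs are.
    """
    by_id = {v.subject_id: v for v in volumes}
    grid = volumes[0].shape if volumes else None
    ud = []
    for k, triplet in enumerate(plan.triplets):
        members = []
        for sid in triplet:
            if sid not in by_id:
                raise ValueError(f"triplet member {sid!r} not among the provided volumes")
            vol = by_id[sid]
            if vol.shape != grid:
                raise ValueError(f"volume {sid!r} grid {vol.shape} != {grid}")
            members.append(vol.data)
        ud.append(
            BrainVolume(
                data=np.mean(members, axis=0),
                affine=by_id[triplet[0]].affine,
                subject_id=f"UD{k:03d}",
                label="UD",
            )
        )
    return ud


def augment_with_ud(
    volumes: list[BrainVolume], seed: int = 0
) -> tuple[list[BrainVolume], TripletPlan]:
    """Append UD images to an identification cohort; returns (augmented, plan)."""
    plan = plan_triplets([v.subject_id for v in volumes], [v.label for v in volumes], seed)
    return volumes + build_ud_images(volumes, plan), plan
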