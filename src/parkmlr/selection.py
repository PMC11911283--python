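"""Exhaustive AIC model selection over mask thresholds and PC subsets.

For every masking threshold (15-45% of image maximum, step 5) the whole
upstream pipeline is re-run — the mask changes the voxel count, so the
SSM/PCA state is never shared across thresholds. The candidate component
pool at each threshold runs from 3 components up to the largest count
whose cumulative variance accounted for stays within the VAF cap (50%);
every subset of the pool with at least 3 members is fitted and scored by
AIC, and the global minimum is frozen into the final classifier.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import mlr
from .image_io import BrainVolume, build_mask, stack
from .mlr import MultinomialFit
from .reference import TripletPlan, augment_with_ud
from .ssm import SSMModel, SubjectScores, fit_ssm, project_subjects

__all__ = [
    "CandidateModel",
    "SelectionReport",
    "ClassifierModel",
    "pc_pool_size",
    "enumerate_subsets",
    "grid_search",
]

DEFAULT_THRESHOLDS = (15, 20, 25, 30, 35, 40, 45)
MIN_SUBSET = 3
VAF_CAP = 0.50


def pc_pool_size(vaf: np.ndarray, vaf_cap: float = VAF_CAP) -> int:
    """Largest component count whose cumulative VAF stays within the cap.

    Floored at 3 (the smallest subset ever fitted) and capped at the
    number of retained components.
    """
    vaf = np.asarray(vaf, dtype=float)
    cum = np.cumsum(vaf)
    p_max = int(np.searchsorted(cum, vaf_cap + 1e-12, side="right"))
    return max(MIN_SUBSET, min(p_max if p_max > 0 else 0, vaf.size)) if vaf.size >= MIN_SUBSET else vaf.size


def enumerate_subsets(p_max: int, min_size: int = MIN_SUBSET) -> list[tuple[int, ...]]:
    """All component subsets of {1..p_max} with at least ``min_size`` members.

    Deterministic order: by size ascending, then lexicographic. For a pool
    of 6 this is C(6,3)+C(6,4)+C(6,5)+C(6,6) = 42 subsets.
    """
    if p_max < min_size:
        raise ValueError(f"pool size {p_max} smaller than minimum subset size {min_size}")
    subsets: list[tuple[int, ...]] = []
    for size in range(min_size, p_max + 1):
        subsets.extend(combinations(range(1, p_max + 1), size))
    return subsets


@dataclass
class CandidateModel:
    """One grid cell's fitted model: threshold, component subset, AIC."""

    mask_threshold_pct: float
    pc_pool_size: int
    pc_subset: tuple[int, ...]
    aic: float
    fit: MultinomialFit | None
    ssm: SSMModel


@dataclass
class ClassifierModel:
    """The frozen end-to-end classifier: SSM/PCA state plus regression fit.

    Prediction stacks new subjects with the *training* mask, projects them
    onto the frozen components, and applies the fitted softmax.
    """

    ssm: SSMModel
    fit: MultinomialFit
    triplet_plan: TripletPlan | None = None

    @property
    def mask_threshold_pct(self) -> float:
        return self.ssm.mask.threshold_pct

    @property
    def component_indices(self) -> tuple[int, ...]:
        return self.fit.component_indices

    def score_volumes(self, volumes: list[BrainVolume]) -> SubjectScores:
        return project_subjects(volumes, self.ssm, self.fit.component_indices)

    def predict_volumes(self, volumes: list[BrainVolume]) -> pd.DataFrame:
        """Four class probabilities (PD, MSA, PSP, UD) per subject."""
        return mlr.predict(self.fit, self.score_volumes(volumes))

    def save(self, path: str | Path) -> None:
        """Single-archive serialization (SSM arrays + fit + metadata)."""
        path = Path(path)
        with zipfile.ZipFile(path, "w") as zf:
            import io as _io

            buf = _io.BytesIO()
            self.ssm.save(buf)
            zf.writestr("ssm.npz", buf.getvalue())
            zf.writestr(
                "fit.json",
                json.dumps(
                    {
                        "coefficients": self.fit.coefficients.tolist(),
                        "component_indices": list(self.fit.component_indices),
                        "log_likelihood": self.fit.log_likelihood,
                        "converged": self.fit.converged,
                        "separation_flag": self.fit.separation_flag,
                        "ridge": self.fit.ridge,
                        "format_version": 1,
                    }
                ),
            )
            if self.triplet_plan is not None:
                zf.writestr(
                    "triplets.json",
                    json.dumps({"seed": self.triplet_plan.seed, "triplets": self.triplet_plan.triplets}),
                )

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        import io as _io

        with zipfile.ZipFile(path) as zf:
            ssm = SSMModel.load(_io.BytesIO(zf.read("ssm.npz")))
            meta = json.loads(zf.read("fit.json"))
            fit = MultinomialFit(
                coefficients=np.asarray(meta["coefficients"], float),
                component_indices=tuple(meta["component_indices"]),
                log_likelihood=float(meta["log_likelihood"]),
                converged=bool(meta["converged"]),
                separation_flag=bool(meta["separation_flag"]),
                ridge=float(meta["ridge"]),
            )
            plan = None
            if "triplets.json" in zf.namelist():
                t = json.loads(zf.read("triplets.json"))
                plan = TripletPlan([tuple(x) for x in t["triplets"]], t["seed"])
        return cls(ssm=ssm, fit=fit, triplet_plan=plan)


@dataclass
class SelectionReport:
    """Full grid-search outcome: AIC surface, ranking, and the winner."""

    grid: pd.DataFrame                      # threshold x pool size, best AIC per cell
    ranked: list[CandidateModel]            # ascending AIC
    triplet_plan: TripletPlan

    @property
    def best(self) -> CandidateModel:
        return self.ranked[0]

    @property
    def runners_up(self) -> list[CandidateModel]:
        return self.ranked[1:3]

    @property
    def best_model(self) -> ClassifierModel:
        return ClassifierModel(ssm=self.best.ssm, fit=self.best.fit, triplet_plan=self.triplet_plan)

    def grid_to_csv(self, path: str | Path) -> None:
        self.grid.to_csv(path)

    def summary(self) -> dict:
        return {
            "best": {
                "mask_threshold_pct": self.best.mask_threshold_pct,
                "pc_subset": list(self.best.pc_subset),
                "aic": self.best.aic,
            },
            "runners_up": [
                {
                    "mask_threshold_pct": c.mask_threshold_pct,
                    "pc_subset": list(c.pc_subset),
                    "aic": c.aic,
                }
                for c in self.runners_up
            ],
        }


def grid_search(
    volumes: list[BrainVolume],
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
    vaf_cap: float = VAF_CAP,
    min_subset: int = MIN_SUBSET,
    seed: int = 0,
) -> SelectionReport:
    """Identify the classifier on a labeled PD/MSA/PSP cohort.

    One UD triplet plan is drawn up front (seeded) and shared across the
    whole grid, so AIC differences reflect threshold and subset choices
    only. Any cell whose fit fails records +inf AIC with a warning rather
    than aborting the search. Ties in AIC are broken by smaller subset,
    then lower threshold.
    """
    augmented, plan = augment_with_ud(volumes, seed=seed)
    labels = [v.label for v in augmented]

    candidates: list[CandidateModel] = []
    grid_cells: dict[float, dict[int, float]] = {}
    for t in thresholds:
        mask = build_mask(augmented, t)
        matrix = stack(augmented, mask)
        ssm = fit_ssm(matrix)
        p_max = pc_pool_size(ssm.vaf, vaf_cap)
        p_max = min(p_max, ssm.n_components)
        cells: dict[int, float] = {p: np.inf for p in range(min_subset, p_max + 1)}
        for subset in enumerate_subsets(p_max, min_subset):
            cols = [c - 1 for c in subset]
            scores = SubjectScores(
                scores=ssm.ssf[:, cols],
                component_indices=subset,
                subject_ids=ssm.subject_ids,
                labels=labels,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # separation is expected mid-grid
                    fit = mlr.fit(scores, labels)
                cand_aic = fit.aic
            except Exception as exc:  # noqa: BLE001 - grid must survive bad cells
                warnings.warn(
                    f"fit failed at threshold {t}%, subset {subset}: {exc}", stacklevel=2
                )
                fit, cand_aic = None, np.inf
            candidates.append(
                CandidateModel(
                    mask_threshold_pct=float(t),
                    pc_pool_size=p_max,
                    pc_subset=subset,
                    aic=cand_aic,
                    fit=fit,
                    ssm=ssm,
                )
            )
            for p in range(max(subset), p_max + 1):
                if p in cells:
                    cells[p] = min(cells[p], cand_aic)
        grid_cells[float(t)] = cells

    all_pools = sorted({p for cells in grid_cells.values() for p in cells})
    grid = pd.DataFrame(
        {p: {t: grid_cells[t].get(p, np.nan) for t in grid_cells} for p in all_pools}
    )
    grid.index.name = "mask_threshold_pct"
    grid.columns.name = "pc_pool_size"

    ranked = sorted(
        candidates,
        key=lambda c: (c.aic, len(c.pc_subset), c.mask_threshold_pct, c.pc_subset),
    )
    return SelectionReport(grid=grid, ranked=ranked, triplet_plan=plan)
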