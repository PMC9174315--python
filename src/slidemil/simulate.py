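"""Clinical tissue-limitation simulators.

Three scenarios re-score the cohort with progressively less tissue while
keeping the scoring formula fixed (only the patch pool shrinks):

* single-WSI — one randomly chosen slide per patient;
* k-WSI — k slides per patient, repeated (default 100 iterations) and
  summarized as mean +/- sd AUC;
* simulated needle biopsies — 1-3 disjoint contiguous strips of tumor
  patches from one slide, fed through the standard multi-magnification
  ensemble path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import roc_auc

PATCH_MM_AT_10X = 0.512  # 512 px at ~1 um/px


@dataclass
class BiopsyGeometry:
    """A contiguous strip of tumor patches approximating one needle core."""

    anchor: tuple[int, int]           # (grid_row, grid_col) of the first patch
    orientation: str                  # "horizontal" | "vertical"
    strip_length: int
    magnification: int = 10
    microns_per_pixel: float = 1.0

    def cells(self) -> list[tuple[int, int]]:
        r, c = self.anchor
        if self.orientation == "horizontal":
            return [(r, c + i) for i in range(self.strip_length)]
        return [(r + i, c) for i in range(self.strip_length)]

    @property
    def physical_area_mm2(self) -> float:
        side = 512 * self.microns_per_pixel / 1000.0
        return self.strip_length * side * side


@dataclass
class SimulationResult:
    scenario: str                     # single_wsi | k_wsi | biopsy
    aucs: np.ndarray
    auc_mean: float
    auc_sd: float
    k: int | None = None
    n_cores: int | None = None
    iterations: int = 1
    per_iteration_scores: list = field(default_factory=list)
    n_flagged: int = 0

    def summary(self) -> dict:
        out = {
            "scenario": self.scenario,
            "iterations": self.iterations,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
        }
        if self.k is not None:
            out["k"] = self.k
        if self.n_cores is not None:
            out["n_cores"] = self.n_cores
        if self.n_flagged:
            out["n_flagged"] = self.n_flagged
        return out


def _slide_scores(score_table: pd.DataFrame) -> pd.DataFrame:
    return score_table[["patient_id", "slide_id", "wsi_score"]]


def _auc_from_scores(per_patient: dict, labels) -> float:
    pids = sorted(per_patient)
    y = np.array([int(labels[p]) for p in pids])
    s = np.array([per_patient[p] for p in pids])
    return roc_auc(s, y).auc


def simulate_single_wsi(score_table, labels, seed: int = 0,
                        iterations: int = 1) -> SimulationResult:
    """One uniformly chosen slide per patient; patient score = its WSI score."""
    res = simulate_k_wsi(score_table, labels, k=1, iterations=iterations,
                         seed=seed)
    res.scenario = "single_wsi"
    return res


def simulate_k_wsi(score_table, labels, k: int, iterations: int = 100,
                   seed: int = 0) -> SimulationResult:
    """k slides without replacement per patient (all slides when a patient
    has fewer than k); patient score = mean of the sampled WSI scores."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    slides = _slide_scores(score_table)
    grouped = {
        pid: g["wsi_score"].to_numpy()
        for pid, g in slides.groupby("patient_id")
    }
    rng = np.random.default_rng(seed)
    aucs, all_scores = [], []
    for _ in range(iterations):
        per_patient = {}
        for pid, scores in grouped.items():
            kk = min(k, len(scores))
            sel = rng.choice(len(scores), size=kk, replace=False)
            per_patient[pid] = float(scores[sel].mean())
        aucs.append(_auc_from_scores(per_patient, labels))
        all_scores.append(per_patient)
    aucs = np.asarray(aucs)
    return SimulationResult(
        scenario="k_wsi", aucs=aucs, auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        k=k, iterations=iterations, per_iteration_scores=all_scores,
    )


# ---------------------------------------------------------------------------
# needle-biopsy geometry
# ---------------------------------------------------------------------------


def _feasible_anchors(cells: set, length: int, orientation: str,
                      used: set) -> list[tuple[int, int]]:
    anchors = []
    for (r, c) in cells:
        strip = ([(r, c + i) for i in range(length)]
                 if orientation == "horizontal"
                 else [(r + i, c) for i in range(length)])
        if all(p in cells and p not in used for p in strip):
            anchors.append((r, c))
    return sorted(anchors)


def place_cores(tumor_cells, n_cores: int, strip_length: int,
                rng: np.random.Generator, magnification: int = 10,
                microns_per_pixel: float = 1.0, max_attempts: int = 20):
    """Place pairwise-disjoint contiguous strips inside the tumor patch set.

    Retries with progressively shorter strips when a core cannot be placed;
    returns ``(geometries, flagged)`` with ``flagged=True`` when any core is
    shorter than requested or missing entirely.
    """
    if not 1 <= n_cores <= 3:
        raise ValueError("n_cores must be between 1 and 3")
    if strip_length < 1:
        raise ValueError("strip_length must be >= 1")
    cells = set(map(tuple, tumor_cells))
    used: set = set()
    cores, flagged = [], False
    for _ in range(n_cores):
        placed = None
        length = strip_length
        attempts = 0
        while placed is None and length >= 1:
            orientation = "horizontal" if rng.random() < 0.5 else "vertical"
            anchors = _feasible_anchors(cells, length, orientation, used)
            if not anchors:
                other = ("vertical" if orientation == "horizontal"
                         else "horizontal")
                anchors = _feasible_anchors(cells, length, other, used)
                orientation = other
            if anchors:
                anchor = anchors[rng.integers(len(anchors))]
                placed = BiopsyGeometry(tuple(anchor), orientation, length,
                                        magnification, microns_per_pixel)
            else:
                attempts += 1
                if attempts >= max_attempts or length == 1:
                    flagged = True
                    length -= 1
                    attempts = 0
        if placed is None:
            flagged = True
            continue
        if placed.strip_length < strip_length:
            flagged = True
        used.update(placed.cells())
        cores.append(placed)
    return cores, flagged


def strip_footprint(cells, from_mag: int, to_mag: int) -> set:
    """Map patch cells between magnification grids covering the same
    physical field (one 10x patch covers a 2x2 block of 20x patches)."""
    if to_mag == from_mag:
        return set(cells)
    out = set()
    if to_mag > from_mag:
        f = to_mag // from_mag
        for (r, c) in cells:
            for dr in range(f):
                for dc in range(f):
                    out.add((r * f + dr, c * f + dc))
    else:
        f = from_mag // to_mag
        for (r, c) in cells:
            out.add((r // f, c // f))
    return out


def simulate_biopsies(features, pipeline, patients, labels, n_cores: int,
                      strip_length: int = 30, iterations: int = 100,
                      seed: int = 0, magnification: int = 10,
                      microns_per_pixel: float = 1.0) -> SimulationResult:
    """Score each patient from 1-3 simulated cores of a random slide.

    Cores are placed on the tumor grid at ``magnification``; their physical
    footprint is mapped to every model magnification and bags are drawn
    only from tumor patches inside it. Patients whose selected slide cannot
    host the requested geometry are scored from the shrunken cores and
    counted in ``n_flagged``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not 1 <= n_cores <= 3:
        raise ValueError("n_cores must be between 1 and 3")
    man = features.manifest
    rng = np.random.default_rng(seed)
    aucs, all_scores = [], []
    n_flagged = 0
    # pre-index tumor grids and (r, c) -> thumb row lookup per slide/mag
    index: dict = {}
    for (sid, m), sf in features.slides.items():
        sub = sf.meta[sf.meta["tissue_class"] == "tumor"]
        index[(sid, m)] = {
            (int(r), int(c)): i
            for i, (r, c) in zip(sub.index, zip(sub["grid_row"],
                                                sub["grid_col"]))
        }
    for _ in range(iterations):
        per_patient = {}
        for pid in patients:
            slides = [
                s for s in man.slides_of(pid)
                if index.get((s, magnification))
            ]
            if not slides:
                n_flagged += 1
                continue
            sid = slides[rng.integers(len(slides))]
            tumor_cells = set(index[(sid, magnification)])
            cores, flagged = place_cores(
                tumor_cells, n_cores, strip_length, rng, magnification,
                microns_per_pixel,
            )
            if flagged or not cores:
                n_flagged += 1
            if not cores:
                continue
            core_cells = set()
            for g in cores:
                core_cells.update(g.cells())
            pools = {}
            for m in pipeline.magnifications:
                foot = strip_footprint(core_cells, magnification, m)
                idx = index.get((sid, m), {})
                rows = [idx[c] for c in foot if c in idx]
                if rows:
                    sf = features.get(sid, m)
                    pools[m] = sf.thumbs[rows]
            per_patient[pid] = pipeline.score_pools(pools)
        aucs.append(_auc_from_scores(per_patient, labels))
        all_scores.append(per_patient)
    aucs = np.asarray(aucs)
    return SimulationResult(
        scenario="biopsy", aucs=aucs, auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        n_cores=n_cores, iterations=iterations,
        per_iteration_scores=all_scores, n_flagged=n_flagged,
    )
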