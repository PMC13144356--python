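"""Unsupervised whistle categorization by adaptive resonance over DTW similarity.

Contours are presented one at a time to a growing set of categories, each
holding a *reference contour* — the running average frequency-modulation
pattern of its members.  A contour computes its DTW similarity to every
reference, considers categories in descending bias-adjusted activation
(similarity plus ``bias * reference_length``, the tiny length-proportional
tie-breaker of the ART "choice" convention), and joins the first whose raw
similarity reaches the vigilance threshold; otherwise it founds a new
category with itself as reference.  On joining, the member is warped onto
the reference path and every reference point moves ``learning_rate`` of the
way toward the mean aligned member frequency; the reference length moves
toward the member length at the same rate.

Defaults: vigilance 96.00, warp factor 3, bias 1e-6, learning rate 0.1, at
most 100 iterations.

Presentation order is ascending contour id on every pass, which makes the
procedure fully deterministic.  The first pass over the data initializes the
assignment (nothing to reassign yet) and is followed by counted refinement
passes; the run has converged when a refinement pass changes no assignment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .agreement import Partition
from .contours import (
    DEFAULT_DT_S,
    ContourSet,
    WhistleContour,
    dtw_align_arrays,
    resample_contour,
    similarity_arrays,
)
from .errors import InfeasibleAlignmentError, InvalidInputError, InvalidParameterError

log = logging.getLogger(__name__)


@dataclass
class CategorizerConfig:
    vigilance_pct: float = 96.00
    warp_factor: int = 3
    bias: float = 0.000001
    learning_rate: float = 0.100
    max_iterations: int = 100
    common_dt_s: float = DEFAULT_DT_S

    def __post_init__(self) -> None:
        if not 0 < self.vigilance_pct <= 100:
            raise InvalidParameterError("vigilance_pct must be in (0, 100]")
        if not 0 < self.learning_rate <= 1:
            raise InvalidParameterError("learning_rate must be in (0, 1]")
        if self.max_iterations < 1:
            raise InvalidParameterError("max_iterations must be >= 1")
        if self.warp_factor < 1:
            raise InvalidParameterError("warp_factor must be >= 1")


@dataclass
class CategoryModel:
    """An automatic category: reference contour plus member ids."""

    category_id: int
    reference: WhistleContour
    member_ids: set[str]


@dataclass
class CategorizationResult:
    partition: Partition
    categories: list[CategoryModel]
    n_iterations: int
    converged: bool
    unassigned_ids: list[str] = field(default_factory=list)
    similarities: dict[str, float] = field(default_factory=dict)  # id -> sim to ref


class _Category:
    __slots__ = ("cid", "ref", "members")

    def __init__(self, cid: int, ref: np.ndarray) -> None:
        self.cid = cid
        self.ref = ref.copy()
        self.members: set[str] = set()


def _resample_array(freqs: np.ndarray, n_new: int) -> np.ndarray:
    if n_new == freqs.size:
        return freqs
    x_old = np.linspace(0.0, 1.0, freqs.size)
    x_new = np.linspace(0.0, 1.0, max(2, n_new))
    return np.interp(x_new, x_old, freqs)


def _update_reference(
    cat: _Category, member: np.ndarray, cfg: CategorizerConfig
) -> None:
    """Warp-average the member onto the reference and learn toward it."""
    try:
        path, _ = dtw_align_arrays(cat.ref, member, cfg.warp_factor)
    except InfeasibleAlignmentError:  # cannot warp: average lengths only
        path = None
    if path is not None:
        sums = np.zeros(cat.ref.size)
        counts = np.zeros(cat.ref.size)
        np.add.at(sums, path[:, 0], member[path[:, 1]])
        np.add.at(counts, path[:, 0], 1.0)
        target = sums / np.maximum(counts, 1.0)
        new_ref = cat.ref + cfg.learning_rate * (target - cat.ref)
    else:
        new_ref = cat.ref
    n_new = int(round((1 - cfg.learning_rate) * cat.ref.size + cfg.learning_rate * member.size))
    cat.ref = _resample_array(new_ref, max(2, n_new))


def categorize(contours: ContourSet, cfg: CategorizerConfig | None = None) -> CategorizationResult:
    """Run the adaptive-resonance categorization over a contour set.

    Returns the final partition, the categories with their reference
    contours, the number of refinement passes used, and whether the run
    converged (a full pass with no reassignment) within ``max_iterations``.
    """
    cfg = cfg or CategorizerConfig()
    if len(contours) == 0:
        raise InvalidInputError("cannot categorize an empty contour set")
    order = contours.ids()
    traces = {
        cid: resample_contour(contours[cid], cfg.common_dt_s).freqs_khz
        for cid in order
    }

    categories: dict[int, _Category] = {}
    assignment: dict[str, int] = {}
    next_cid = 1

    def present(cid: str) -> bool:
        """Present one contour; returns True when its label changed."""
        nonlocal next_cid
        trace = traces[cid]
        scored = []
        for cat in categories.values():
            sim = similarity_arrays(trace, cat.ref, cfg.warp_factor)
            activation = sim + cfg.bias * cat.ref.size
            scored.append((activation, cat.cid, sim))
        # descending activation; deterministic tie-break on category id
        scored.sort(key=lambda s: (-s[0], s[1]))
        chosen: Optional[int] = None
        chosen_sim = 100.0
        for activation, cat_id, sim in scored:
            if sim >= cfg.vigilance_pct:
                chosen = cat_id
                chosen_sim = sim
                break
        previous = assignment.get(cid)
        if chosen is None:
            cat = _Category(next_cid, trace)
            categories[next_cid] = cat
            next_cid += 1
            chosen = cat.cid
        if previous is not None and previous in categories:
            categories[previous].members.discard(cid)
        categories[chosen].members.add(cid)
        assignment[cid] = chosen
        _update_reference(categories[chosen], trace, cfg)
        return previous is not None and previous != chosen

    # initialization pass (not a counted iteration: nothing to reassign yet)
    for cid in order:
        present(cid)
    for empty in [c for c, cat in categories.items() if not cat.members]:
        del categories[empty]

    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iterations + 1):
        changes = 0
        for cid in order:
            if present(cid):
                changes += 1
        for empty in [c for c, cat in categories.items() if not cat.members]:
            del categories[empty]
        if changes == 0:
            converged = True
            break
    log.info(
        "categorize: %d contours -> %d categories in %d iteration(s), converged=%s",
        len(order), len(categories), n_iter, converged,
    )

    sims = {
        cid: similarity_arrays(traces[cid], categories[assignment[cid]].ref, cfg.warp_factor)
        for cid in order
    }
    models = [
        CategoryModel(
            category_id=cat.cid,
            reference=WhistleContour(
                id=f"ref-{cat.cid}",
                recording_id="",
                day_label="",
                onset_s=0.0,
                dt_s=cfg.common_dt_s,
                freqs_khz=cat.ref,
                snr_class="high",
            ),
            member_ids=set(cat.members),
        )
        for cat in sorted(categories.values(), key=lambda c: c.cid)
    ]
    return CategorizationResult(
        partition=Partition({cid: assignment[cid] for cid in order}),
        categories=models,
        n_iterations=n_iter,
        converged=converged,
        similarities=sims,
    )


def run_sequenced(
    contours: ContourSet, visual: Partition, cfg: CategorizerConfig | None = None
) -> dict:
    """Independent categorization within each visual category.

    Every contour must carry a visual label; results are keyed by label
    (labels with no contours are simply absent)."""
    cfg = cfg or CategorizerConfig()
    missing = [cid for cid in contours.ids() if cid not in visual.assignment]
    if missing:
        raise InvalidInputError(f"contours missing a visual label: {missing[:5]}")
    groups: dict = {}
    for cid in contours.ids():
        groups.setdefault(visual[cid], []).append(cid)
    out = {}
    for label in sorted(groups, key=str):
        subset = ContourSet(contours[cid] for cid in groups[label])
        out[label] = categorize(subset, cfg)
    return out


def run_global(
    contours: ContourSet,
    cfg: CategorizerConfig | None = None,
    prune_singletons: bool = False,
) -> CategorizationResult:
    """Single categorization over all contours; optionally drop categories
    with a single member from the reported result (their contours are
    flagged unassigned)."""
    res = categorize(contours, cfg)
    if not prune_singletons:
        return res
    keep = [c for c in res.categories if len(c.member_ids) > 1]
    dropped = [c for c in res.categories if len(c.member_ids) <= 1]
    unassigned = sorted(cid for c in dropped for cid in c.member_ids)
    assignment = {
        cid: lab
        for cid, lab in res.partition.assignment.items()
        if cid not in set(unassigned)
    }
    return CategorizationResult(
        partition=Partition(assignment),
        categories=keep,
        n_iterations=res.n_iterations,
        converged=res.converged,
        unassigned_ids=unassigned,
        similarities=res.similarities,
    )


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def write_assignment_csv(res: CategorizationResult, path) -> None:
    rows = [
        (cid, res.partition[cid], res.similarities.get(cid, float("nan")))
        for cid in res.partition.ids
    ]
    rows += [(cid, "", float("nan")) for cid in res.unassigned_ids]
    pd.DataFrame(rows, columns=["id", "category_id", "similarity_pct"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_assignment_csv(path) -> Partition:
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=False, na_values=[])
    df = df[df["category_id"] != ""]
    return Partition(dict(zip(df["id"], df["category_id"].astype(str))))


def write_run_metadata(res: CategorizationResult, cfg: CategorizerConfig, path) -> None:
    meta = {
        "config": asdict(cfg),
        "n_iterations": res.n_iterations,
        "converged": res.converged,
        "n_categories": len(res.categories),
        "n_unassigned": len(res.unassigned_ids),
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
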