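"""Agreement between whistle categorizations (visual vs automatic, judge vs judge).

Partitions produced by independent observers or by the unsupervised
categorizer use arbitrary label vocabularies, so labels are first aligned by
a one-to-one maximum-overlap (Hungarian) matching on the confusion table;
agreement percentages and Cohen's kappa are then computed on the matched
tables.  Fleiss' kappa operates on a complete item x rater table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .errors import InvalidInputError, UndefinedStatisticError

Label = Hashable


@dataclass
class Partition:
    """An assignment of contour ids to category labels."""

    assignment: dict[str, Label]

    @property
    def ids(self) -> list[str]:
        return sorted(self.assignment)

    @property
    def label_set(self) -> set[Label]:
        return set(self.assignment.values())

    def __len__(self) -> int:
        return len(self.assignment)

    def __getitem__(self, cid: str) -> Label:
        return self.assignment[cid]

    def restrict(self, ids: Iterable[str]) -> "Partition":
        ids = set(ids)
        return Partition({i: l for i, l in self.assignment.items() if i in ids})

    def sizes(self) -> dict[Label, int]:
        out: dict[Label, int] = {}
        for l in self.assignment.values():
            out[l] = out.get(l, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "label": [self.assignment[i] for i in self.ids]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Partition":
        return cls(dict(zip(df["id"].astype(str), df["label"])))


@dataclass
class RatingTable:
    """Labels assigned to each item by each rater; complete for kappa use."""

    items: list[str]
    raters: list[str]
    labels: dict[tuple[str, str], Label]

    def is_complete(self) -> bool:
        return all((i, r) in self.labels for i in self.items for r in self.raters)

    def rater_partition(self, rater: str) -> Partition:
        return Partition({i: self.labels[(i, rater)] for i in self.items})

    @classmethod
    def from_partitions(cls, parts: Mapping[str, Partition]) -> "RatingTable":
        raters = sorted(parts)
        items = sorted(set().union(*(set(p.assignment) for p in parts.values())))
        labels = {
            (i, r): parts[r][i] for r in raters for i in items if i in parts[r].assignment
        }
        return cls(items=items, raters=raters, labels=labels)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def confusion_counts(a: Partition, b: Partition) -> pd.DataFrame:
    """Co-assignment counts; rows are labels of ``a``, columns labels of ``b``."""
    if set(a.assignment) != set(b.assignment):
        raise InvalidInputError("partitions cover different contour ids")
    ids = a.ids
    la = pd.Series([a[i] for i in ids], name="a")
    lb = pd.Series([b[i] for i in ids], name="b")
    return pd.crosstab(la, lb)


def dominant_agreement(visual_size: int, split_sizes: Sequence[int]) -> int:
    """Percent of a visual category captured by its dominant automatic category.

    ``100 * max(split_sizes) / visual_size`` rounded half away from zero to an
    integer percent, the convention under which the consistent published
    splits reproduce their printed values.
    """
    split_sizes = list(split_sizes)
    if len(split_sizes) == 0:
        raise InvalidInputError("split_sizes is empty")
    if visual_size <= 0:
        raise InvalidInputError("visual_size must be > 0")
    if sum(split_sizes) != visual_size:
        raise InvalidInputError(
            f"splits {split_sizes} do not sum to visual_size {visual_size}"
        )
    pct = 100.0 * max(split_sizes) / visual_size
    return int(math.floor(pct + 0.5))  # half away from zero (pct >= 0 here)


def heatmap_percentages(conf: pd.DataFrame) -> pd.DataFrame:
    """Normalize a confusion table per automatic category (columns sum to 100)."""
    conf = conf.copy()
    sums = conf.sum(axis=0)
    empty = sums[sums == 0].index.tolist()
    if empty:
        warnings.warn(f"dropping zero-size automatic categories: {empty}")
        conf = conf.drop(columns=empty)
        sums = sums.drop(empty)
    return 100.0 * conf / sums


def match_labels(a: Partition, b: Partition) -> dict[Label, Label]:
    """One-to-one maximum-overlap matching of b's labels onto a's labels."""
    conf = confusion_counts(a, b)
    rows, cols = linear_sum_assignment(conf.to_numpy(), maximize=True)
    return {conf.columns[c]: conf.index[r] for r, c in zip(rows, cols)}


def pairwise_agreement(a: Partition, b: Partition) -> float:
    """Percent of ids on which the partitions agree after optimal one-to-one
    label matching (free label vocabularies; permutation invariant)."""
    conf = confusion_counts(a, b)
    rows, cols = linear_sum_assignment(conf.to_numpy(), maximize=True)
    matched = conf.to_numpy()[rows, cols].sum()
    return 100.0 * float(matched) / len(a)


def _matched_sequences(a: Partition, b: Partition) -> tuple[list, list]:
    mapping = match_labels(a, b)
    ids = a.ids
    ya = [a[i] for i in ids]
    # unmatched b labels stay distinct categories
    yb = [mapping.get(b[i], ("unmatched", b[i])) for i in ids]
    return ya, yb


def cohen_kappa(a: Partition, b: Partition) -> float:
    """Cohen's kappa between two partitions on the matched-label tables.

    ``(p_o - p_e) / (1 - p_e)`` with chance agreement from the marginal
    products.  Raises :class:`UndefinedStatisticError` when ``p_e == 1``
    (both raters constant on the same single label).
    """
    ya, yb = _matched_sequences(a, b)
    labels = sorted({str(l) for l in ya} | {str(l) for l in yb})
    ya = [str(l) for l in ya]
    yb = [str(l) for l in yb]
    if len(set(ya)) == 1 and set(ya) == set(yb):
        raise UndefinedStatisticError("p_e == 1: single shared label")
    return float(cohen_kappa_score(ya, yb, labels=labels))


def fleiss_kappa(table: RatingTable) -> float:
    """Fleiss' kappa over a complete rating table (>= 2 raters)."""
    if len(table.raters) < 2:
        raise InvalidInputError("Fleiss' kappa needs >= 2 raters")
    if not table.is_complete():
        raise InvalidInputError("rating table is incomplete")
    cats = sorted({str(v) for v in table.labels.values()})
    counts = np.zeros((len(table.items), len(cats)), dtype=int)
    cat_ix = {c: k for k, c in enumerate(cats)}
    for ii, item in enumerate(table.items):
        for r in table.raters:
            counts[ii, cat_ix[str(table.labels[(item, r)])]] += 1
    return float(_sm_fleiss_kappa(counts, method="fleiss"))


def flag_outlier_raters(table: RatingTable, threshold: float = 2.0) -> list[str]:
    """Raters whose mean pairwise agreement with the others falls below
    ``group mean - threshold * group SD`` of those per-rater means."""
    if len(table.raters) < 3:
        raise InvalidInputError("need >= 3 raters to flag outliers")
    parts = {r: table.rater_partition(r) for r in table.raters}
    means = {}
    for r in table.raters:
        vals = [
            pairwise_agreement(parts[r], parts[s]) for s in table.raters if s != r
        ]
        means[r] = float(np.mean(vals))
    arr = np.array(list(means.values()))
    mu, sd = float(arr.mean()), float(arr.std())
    cut = mu - threshold * sd
    if not np.isfinite(cut):
        return []
    return [r for r in table.raters if means[r] < cut]
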