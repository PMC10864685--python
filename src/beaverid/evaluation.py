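"""Dataset splitting, confusion matrices and identification accuracy.

The labelled image collection is split into a database (70% by default) and
a held-out test set, stratified so every individual keeps at least one
database image while the overall split hits the requested fraction exactly
(largest-remainder apportionment of the per-individual quotas).  Evaluation
follows the study design: individuals are grouped into sample blocks (25 per
block by default) and each block is scored on its own, restricting both the
database and the queries to the block; one prediction is made per test
image.  A confusion matrix (columns = actual individual, rows = predicted)
collects the outcomes, from which overall accuracy (correct / total) and
per-individual accuracy derive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .matching import FeatureDatabase, MatchConfig, identify
from .sift import FeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetSplit",
    "SampleBlock",
    "ConfusionMatrix",
    "AccuracyReport",
    "split_dataset",
    "make_sample_blocks",
    "evaluate_sample",
    "accuracy",
    "aggregate_report",
    "round_half_up",
]

#: Label used for test images whose best score fell below min_match_count.
UNIDENTIFIED = "__none__"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for displayed
    percentages, so 97.95 -> 98.0)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DatasetSplit:
    """Disjoint database/test partition of a labelled image collection."""

    database_items: pd.DataFrame
    test_items: pd.DataFrame
    db_fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.database_items["image_id"]) & set(
            self.test_items["image_id"])
        if overlap:
            raise ValueError(f"database and test overlap: {sorted(overlap)[:5]}")


@dataclass(frozen=True)
class SampleBlock:
    """One evaluation block: a named subset of individuals within a group
    (the study used four blocks of 25 animals per acquisition group)."""

    sample_id: str
    individuals: tuple[str, ...]
    group: str


@dataclass
class ConfusionMatrix:
    """Actual-vs-predicted counts: ``counts[i, j]`` is the number of test
    images of actual individual ``labels[j]`` predicted as ``labels[i]``
    (columns = actual, rows = predicted).  Unidentified queries are tallied
    per actual individual in ``none_counts``."""

    labels: list[str]
    counts: np.ndarray
    none_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.none_counts is None:
            self.none_counts = np.zeros(n, dtype=int)
        self.none_counts = np.asarray(self.none_counts, dtype=int)

    @property
    def column_totals(self) -> np.ndarray:
        """Test images per actual individual (including unidentified)."""
        return self.counts.sum(axis=0) + self.none_counts

    @property
    def n_total(self) -> int:
        return int(self.column_totals.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.labels, columns=self.labels)
        if self.none_counts.any():
            df.loc[UNIDENTIFIED] = self.none_counts
        df.index.name = "predicted"
        df.columns.name = "actual"
        return df


@dataclass
class AccuracyReport:
    """Correct / total counts with overall and per-individual accuracy
    percentages (display values rounded half-up to one decimal)."""

    n_correct: int
    n_total: int
    accuracy_percent: float
    per_individual_percent: dict[str, float] = field(default_factory=dict)
    mean_per_individual_percent: float | None = None

    @property
    def accuracy_display(self) -> float:
        return round_half_up(self.accuracy_percent, 1)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_dataset(items: pd.DataFrame, db_fraction: float = 0.7,
                  seed: int = 0) -> DatasetSplit:
    """Stratified random database/test split.

    The overall database size is ``round(db_fraction * n_items)`` (half-up);
    per-individual quotas are apportioned by largest remainder so that every
    individual contributes at least one database image (e.g. 800 images at
    fraction 0.7 give exactly 560 database / 240 test).  An individual with
    a single image goes to the database only, with a warning.  Deterministic
    for a fixed seed.
    """
    if not 0.0 < db_fraction < 1.0:
        raise ValueError("db_fraction must lie in (0, 1)")
    df = items.reset_index(drop=True)
    if "image_id" not in df.columns:
        raise ValueError("items must carry an 'image_id' column")
    if df["image_id"].duplicated().any():
        raise ValueError("duplicate image_id in items")
    rng = np.random.default_rng(seed)

    groups = {ind: sub.index.to_numpy()
              for ind, sub in df.groupby("individual_id", sort=True)}
    singles = [ind for ind, idx in groups.items() if len(idx) == 1]
    for ind in singles:
        logger.warning("individual %r has a single image; database only", ind)

    n_total = len(df)
    target_db = int(np.floor(db_fraction * n_total + 0.5))
    # base quotas and remainders
    inds = sorted(groups)
    base = {}
    rem = {}
    for ind in inds:
        n_i = len(groups[ind])
        q = db_fraction * n_i
        b = int(np.floor(q))
        b = max(1, b)               # every individual keeps >= 1 db image
        b = min(b, n_i)
        base[ind] = b
        rem[ind] = q - np.floor(q)
    leftover = target_db - sum(base.values())
    if leftover > 0:
        # largest remainder first; ties broken by a seeded shuffle
        order = list(inds)
        rng.shuffle(order)
        order.sort(key=lambda ind: -rem[ind])
        for ind in order:
            if leftover == 0:
                break
            if base[ind] < len(groups[ind]):
                base[ind] += 1
                leftover -= 1
    elif leftover < 0:
        order = list(inds)
        rng.shuffle(order)
        order.sort(key=lambda ind: rem[ind])
        for ind in order:
            if leftover == 0:
                break
            if base[ind] > 1:
                base[ind] -= 1
                leftover += 1

    db_idx: list[int] = []
    test_idx: list[int] = []
    for ind in inds:
        idx = groups[ind].copy()
        rng.shuffle(idx)
        k = base[ind]
        db_idx.extend(idx[:k].tolist())
        test_idx.extend(idx[k:].tolist())
    if not test_idx:
        raise ValueError("split leaves no test images")
    return DatasetSplit(
        database_items=df.loc[sorted(db_idx)].reset_index(drop=True),
        test_items=df.loc[sorted(test_idx)].reset_index(drop=True),
        db_fraction=db_fraction, seed=seed)


def make_sample_blocks(individuals: list[str], group: str,
                       per_sample: int = 25) -> list[SampleBlock]:
    """Chunk a group's individuals into disjoint evaluation blocks of at
    most ``per_sample`` individuals each."""
    inds = sorted(individuals)
    blocks = []
    for i in range(0, len(inds), per_sample):
        chunk = tuple(inds[i:i + per_sample])
        blocks.append(SampleBlock(
            sample_id=f"{group}-s{i // per_sample + 1}",
            individuals=chunk, group=group))
    return blocks


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate_sample(block: SampleBlock, split: DatasetSplit,
                    features: dict[str, FeatureSet],
                    match_cfg: MatchConfig = MatchConfig()) -> ConfusionMatrix:
    """Identify every test image of one sample block.

    Both the database and the queries are restricted to the block's
    individuals and acquisition group; each test image yields exactly one
    prediction (or an explicit non-identification).
    """
    if not block.individuals:
        raise ValueError("empty sample block")
    sel = set(block.individuals)

    def in_block(df: pd.DataFrame) -> pd.DataFrame:
        m = df["individual_id"].isin(sel)
        if "group" in df.columns and block.group:
            m &= df["group"] == block.group
        return df[m]

    db_items = in_block(split.database_items)
    test_items = in_block(split.test_items)
    if db_items.empty:
        raise ValueError(f"block {block.sample_id}: no database images")
    db = FeatureDatabase(
        entries=[features[i] for i in db_items["image_id"]])

    labels = sorted(sel)
    pos = {ind: i for i, ind in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    none_counts = np.zeros(len(labels), dtype=int)
    for _, row in test_items.iterrows():
        res = identify(features[row["image_id"]], db, match_cfg)
        j = pos[row["individual_id"]]
        if res.predicted_individual is None:
            none_counts[j] += 1
        else:
            counts[pos[res.predicted_individual], j] += 1
    return ConfusionMatrix(labels=labels, counts=counts,
                           none_counts=none_counts)


def accuracy(cm: ConfusionMatrix) -> AccuracyReport:
    """Accuracy report from a confusion matrix: overall accuracy is
    correct predictions / total predictions; per-individual accuracy is the
    diagonal over the column total, averaged over individuals with at least
    one test image."""
    total = cm.n_total
    if total == 0:
        raise ValueError("confusion matrix has no predictions")
    correct = cm.n_correct
    col = cm.column_totals
    per = {}
    for j, lab in enumerate(cm.labels):
        if col[j] > 0:
            per[lab] = 100.0 * cm.counts[j, j] / col[j]
    mean_per = float(np.mean(list(per.values()))) if per else None
    return AccuracyReport(
        n_correct=correct, n_total=total,
        accuracy_percent=100.0 * correct / total,
        per_individual_percent=per,
        mean_per_individual_percent=mean_per)


def aggregate_report(samples: list[tuple[str, str, ConfusionMatrix]]
                     ) -> dict:
    """Pool per-sample confusion matrices into an overall report.

    ``samples`` is a list of (sample_id, group, matrix).  Returns a dict
    with pooled counts/accuracy plus per-group and per-sample breakdowns.
    """
    if not samples:
        raise ValueError("no samples to aggregate")
    per_sample = {}
    group_counts: dict[str, list[int]] = {}
    tot_c = tot_n = 0
    for sample_id, group, cm in samples:
        rep = accuracy(cm)
        per_sample[sample_id] = {
            "group": group,
            "n_correct": rep.n_correct,
            "n_total": rep.n_total,
            "accuracy_percent": rep.accuracy_display,
            "mean_per_individual_percent":
                None if rep.mean_per_individual_percent is None
                else round_half_up(rep.mean_per_individual_percent, 1),
        }
        g = group_counts.setdefault(group, [0, 0])
        g[0] += rep.n_correct
        g[1] += rep.n_total
        tot_c += rep.n_correct
        tot_n += rep.n_total
    per_group = {
        g: {"n_correct": c, "n_total": n,
            "accuracy_percent": round_half_up(100.0 * c / n, 1)}
        for g, (c, n) in group_counts.items()}
    return {
        "overall": {"n_correct": tot_c, "n_total": tot_n,
                    "accuracy_percent": round_half_up(100.0 * tot_c / tot_n, 1)},
        "per_group": per_group,
        "per_sample": per_sample,
    }
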