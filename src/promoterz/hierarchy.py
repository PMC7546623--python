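"""Quantile-threshold classification of promoters into positional classes.

Promoters are classified by whether their mean histone-variant signal in
the −1 and +1 nucleosome flank windows falls in the top quantile (default
top 25%) of each side:

* ``Two``       — top quantile on both sides (variant at −1 and +1);
* ``One``       — top quantile on the +1 side only;
* ``MinusOnly`` — top quantile on the −1 side only (rare under the
  +1-before-−1 installation hierarchy, kept as an explicit class);
* ``Zero``      — neither side.

The threshold is a nearest-rank quantile (k-th largest, ``k = ceil(q*n)``,
ties included), computed by default on the two sides' scores pooled
together — so the classification is invariant under any strictly
increasing rescaling of the signal, and because the −1 side runs lower
than the +1 side the −1-only class stays rare.  Per-side thresholds are
available as an option.  For
cross-condition comparisons the thresholds established in the reference
condition are reused unchanged for the alternate condition, and class
transitions are tabulated per promoter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "CHANGE_CATEGORIES",
    "QuantileThresholds",
    "Classification",
    "TransitionTable",
    "top_threshold",
    "compute_thresholds",
    "classify",
    "transitions",
    "partition_by_change",
]

CLASSES: tuple[str, ...] = ("Zero", "One", "Two", "MinusOnly")
CHANGE_CATEGORIES: tuple[str, ...] = ("IncreasedMinus1", "IncreasedPlus1", "Both", "Neither")


def top_threshold(values: np.ndarray, q: float) -> float:
    """The k-th largest value, k = ceil(q*n): the entry threshold of the top-q set.

    Membership everywhere is ``value >= threshold``, so with ties at the
    threshold the top set may exceed ``ceil(q*n)`` items.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must be in (0, 1), got {q}")
    if n < 1:
        raise ValueError("need at least one value")
    k = math.ceil(q * n)
    if k < 1 or k > n:
        raise ValueError(f"top-quantile rank k={k} out of range for n={n}")
    # k-th largest == (n-k)-th order statistic (ascending)
    return float(np.partition(values, n - k)[n - k])


@dataclass(frozen=True)
class QuantileThresholds:
    """Per-side top-quantile thresholds and the condition they came from.

    ``q_minus1`` and ``q_plus1`` are usually equal (one top fraction applied
    to both sides); they are kept separate so a classification can also be
    anchored to known per-side exceedance fractions.
    """

    q_minus1: float
    q_plus1: float
    minus1_threshold: float
    plus1_threshold: float
    source: str = ""
    pooled: bool = False

    @property
    def q(self) -> float:
        if self.q_minus1 != self.q_plus1:
            raise ValueError("per-side quantiles differ; no single q")
        return self.q_minus1


def compute_thresholds(
    signals: pd.DataFrame,
    q: float = 0.25,
    source: str = "",
    pooled: bool | None = None,
    q_minus1: float | None = None,
    q_plus1: float | None = None,
) -> QuantileThresholds:
    """Top-quantile thresholds from a flank-signal table.

    ``signals`` needs columns ``minus1_mean`` and ``plus1_mean``.  By
    default ("top q of all scores on both sides") a single threshold is
    computed on the two sides' values pooled together and applied to both:
    since the −1 side runs lower than the +1 side, more than ``q`` of
    promoters exceed it on the +1 side and fewer on the −1 side, which is
    what keeps the −1-only class rare.  With ``pooled=False`` (or when
    ``q_minus1`` / ``q_plus1`` per-side quantiles are given) each side gets
    its own top-quantile threshold, so exactly ``ceil(q*n)`` promoters per
    side reach it when values are distinct.
    """
    if len(signals) < 4:
        raise ValueError(f"need at least 4 promoters, got {len(signals)}")
    per_side = q_minus1 is not None or q_plus1 is not None
    if pooled is None:
        pooled = not per_side
    if pooled and per_side:
        raise ValueError("pooled thresholds are incompatible with per-side quantiles")
    qm = q if q_minus1 is None else q_minus1
    qp = q if q_plus1 is None else q_plus1
    minus = signals["minus1_mean"].to_numpy(dtype=float)
    plus = signals["plus1_mean"].to_numpy(dtype=float)
    if pooled:
        thr = top_threshold(np.concatenate([minus, plus]), q)
        tm = tp = thr
    else:
        tm = top_threshold(minus, qm)
        tp = top_threshold(plus, qp)
    return QuantileThresholds(
        q_minus1=qm, q_plus1=qp, minus1_threshold=tm, plus1_threshold=tp,
        source=source, pooled=pooled,
    )


@dataclass
class Classification:
    """Per-promoter positional classes plus the thresholds that produced them."""

    frame: pd.DataFrame  # gene_id, class, minus1_mean, plus1_mean
    thresholds: QuantileThresholds
    condition: str = ""

    def counts(self) -> pd.Series:
        return self.frame["class"].value_counts().reindex(CLASSES, fill_value=0)

    def fractions(self) -> pd.Series:
        return self.counts() / len(self.frame)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["minus1_threshold"] = self.thresholds.minus1_threshold
        out["plus1_threshold"] = self.thresholds.plus1_threshold
        out["condition"] = self.condition
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Classification":
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "class", "minus1_mean", "plus1_mean",
                    "minus1_threshold", "plus1_threshold", "condition"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        thr = QuantileThresholds(
            q_minus1=float("nan"),
            q_plus1=float("nan"),
            minus1_threshold=float(df["minus1_threshold"].iloc[0]),
            plus1_threshold=float(df["plus1_threshold"].iloc[0]),
            source=str(df["condition"].iloc[0]),
        )
        cond = str(df["condition"].iloc[0])
        frame = df[["gene_id", "class", "minus1_mean", "plus1_mean"]].copy()
        return cls(frame=frame, thresholds=thr, condition=cond)


def classify(
    signals: pd.DataFrame,
    thresholds: QuantileThresholds,
    condition: str = "",
) -> Classification:
    """Assign each promoter its positional class against fixed thresholds.

    For cross-condition comparisons ``thresholds`` must come from the
    designated reference condition; the alternate condition's signals are
    judged against those same values.
    """
    minus = signals["minus1_mean"].to_numpy(dtype=float)
    plus = signals["plus1_mean"].to_numpy(dtype=float)
    minus_top = minus >= thresholds.minus1_threshold
    plus_top = plus >= thresholds.plus1_threshold
    labels = np.select(
        [minus_top & plus_top, plus_top, minus_top],
        ["Two", "One", "MinusOnly"],
        default="Zero",
    )
    frame = pd.DataFrame(
        {
            "gene_id": signals["gene_id"].to_numpy(),
            "class": labels,
            "minus1_mean": minus,
            "plus1_mean": plus,
        }
    )
    return Classification(frame=frame, thresholds=thresholds, condition=condition)


@dataclass
class TransitionTable:
    """Cross-condition class transition counts with named gain/loss margins.

    ``counts`` is a 4x4 table indexed (reference class, alternate class).
    ``gain_one_to_two`` / ``loss_one_to_zero`` list the promoters that
    gained the variant at the −1 position (One -> Two) or lost it at the
    +1 position (One -> Zero).
    """

    counts: pd.DataFrame
    gain_one_to_two: list[str]
    loss_one_to_zero: list[str]

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_tsv(self, path: str | Path) -> None:
        long = (
            self.counts.rename_axis("ref_class")
            .reset_index()
            .melt(id_vars="ref_class", var_name="alt_class", value_name="count")
        )
        long.to_csv(path, sep="\t", index=False)


def transitions(ref: Classification, alt: Classification) -> TransitionTable:
    """Tabulate per-promoter class transitions between two conditions.

    Both classifications must cover exactly the same promoters, with the
    alternate condition classified against the reference thresholds.
    """
    ref_ids = set(ref.frame["gene_id"])
    alt_ids = set(alt.frame["gene_id"])
    if ref_ids != alt_ids:
        diff = len(ref_ids.symmetric_difference(alt_ids))
        raise ValueError(f"promoter sets differ between conditions ({diff} mismatched ids)")
    merged = ref.frame[["gene_id", "class"]].merge(
        alt.frame[["gene_id", "class"]], on="gene_id", suffixes=("_ref", "_alt")
    )
    counts = pd.crosstab(merged["class_ref"], merged["class_alt"]).reindex(
        index=CLASSES, columns=CLASSES, fill_value=0
    )
    counts.index.name = "ref_class"
    counts.columns.name = "alt_class"
    gain = merged.loc[
        (merged["class_ref"] == "One") & (merged["class_alt"] == "Two"), "gene_id"
    ].tolist()
    loss = merged.loc[
        (merged["class_ref"] == "One") & (merged["class_alt"] == "Zero"), "gene_id"
    ].tolist()
    return TransitionTable(counts=counts, gain_one_to_two=gain, loss_one_to_zero=loss)


def partition_by_change(
    fc: pd.DataFrame,
    q: float = 0.25,
) -> pd.DataFrame:
    """Partition promoters by where the signal increased between conditions.

    ``fc`` needs columns ``gene_id, fc_minus1, fc_plus1`` holding per-side
    log fold changes.  A promoter with a fold change in the top ``q`` on the
    −1 side but not on the +1 side is ``IncreasedMinus1`` (and vice versa);
    top on both is ``Both``, otherwise ``Neither``.  Returns columns
    ``gene_id, category``.
    """
    if len(fc) < 4:
        raise ValueError(f"need at least 4 promoters, got {len(fc)}")
    fm = fc["fc_minus1"].to_numpy(dtype=float)
    fp = fc["fc_plus1"].to_numpy(dtype=float)
    top_m = fm >= top_threshold(fm, q)
    top_p = fp >= top_threshold(fp, q)
    labels = np.select(
        [top_m & top_p, top_m, top_p],
        ["Both", "IncreasedMinus1", "IncreasedPlus1"],
        default="Neither",
    )
    return pd.DataFrame({"gene_id": fc["gene_id"].to_numpy(), "category": labels})
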