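"""End-to-end composition of the analysis stages.

These helpers chain the stages exactly as the analysis is meant to be run
on real data: extract flank signals per condition, establish thresholds in
the reference condition, classify every condition against those reference
thresholds, tabulate transitions, and compare non-nucleosomal
accessibility changes between the gain and loss promoter groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import rank_sum_pairwise
from .hierarchy import Classification, QuantileThresholds, classify, compute_thresholds, transitions
from .synthetic import ALTERNATE, CONDITIONS, REFERENCE, ExperimentBundle
from .window_signal import flank_signals, log2fc, nnf_promoter_signal

__all__ = [
    "classify_experiment",
    "truth_agreement",
    "loss_response",
    "LossResponse",
]


def classify_experiment(
    bundle: ExperimentBundle,
    q: float = 0.25,
    mode: str = "hierarchy",
    pooled: bool | None = None,
    reference: str = REFERENCE,
) -> tuple[dict[str, pd.DataFrame], dict[str, Classification], QuantileThresholds]:
    """Classify every condition against thresholds established in the reference.

    Returns ``(signals, classifications, thresholds)`` keyed by condition.
    """
    signals = {
        cond: flank_signals(track, bundle.sim.tss, mode=mode)
        for cond, track in bundle.chip.items()
    }
    thr = compute_thresholds(signals[reference], q=q, source=reference, pooled=pooled)
    classifications = {
        cond: classify(sig, thr, condition=cond) for cond, sig in signals.items()
    }
    return signals, classifications, thr


def truth_agreement(bundle: ExperimentBundle, condition: str = REFERENCE) -> float:
    """Fraction of promoters whose measured class matches the generator truth.

    The per-side quantiles are anchored to the true per-side exceedance
    fractions recorded in the ground truth (the occupancy cutoff is part of
    the truth table), so in the noise-free limit the quantile rule recovers
    the true classes exactly.
    """
    state = bundle.sim.states[condition]
    sig = flank_signals(bundle.chip[condition], bundle.sim.tss, mode="hierarchy")
    cutoff = bundle.sim.config.truth_cutoff
    n = len(state)
    q_minus = max((state["occ_minus1"] >= cutoff).mean(), 1.0 / n)
    q_plus = max((state["occ_plus1"] >= cutoff).mean(), 1.0 / n)
    thr = compute_thresholds(sig, q_minus1=q_minus, q_plus1=q_plus, source=condition)
    result = classify(sig, thr, condition=condition)
    merged = result.frame.merge(state[["gene_id", "true_class"]], on="gene_id")
    return float((merged["class"] == merged["true_class"]).mean())


@dataclass
class LossResponse:
    """Hierarchy response to chaperone loss, with accessibility follow-up."""

    classifications: dict[str, Classification]
    gain_one_to_two: list[str]
    loss_one_to_zero: list[str]
    nnf_fc: pd.Series                # per-promoter log2FC of NNF signal (alt vs ref)
    comparisons: pd.DataFrame        # gain-vs-loss rank-sum result


def loss_response(
    bundle: ExperimentBundle,
    q: float = 0.25,
    pseudocount: float = 0.01,
) -> LossResponse:
    """Run the full cross-condition comparison on a simulated experiment.

    Classifies both conditions against reference thresholds, extracts the
    One->Two gain and One->Zero loss promoter groups, and tests whether the
    non-nucleosomal accessibility fold change differs between them.
    """
    _, classifications, _ = classify_experiment(bundle, q=q)
    table = transitions(classifications[REFERENCE], classifications[ALTERNATE])
    nnf = {
        cond: nnf_promoter_signal(frags, bundle.sim.tss, bundle.sim.layout)
        .set_index("gene_id")["nnf_mean"]
        for cond, frags in bundle.atac.items()
    }
    common = nnf[REFERENCE].index
    fc = pd.Series(
        [log2fc(nnf[ALTERNATE][g], nnf[REFERENCE][g], pseudocount) for g in common],
        index=common,
        name="nnf_log2fc",
    )
    comparisons = rank_sum_pairwise(
        {
            "gain_one_to_two": fc.loc[table.gain_one_to_two].to_numpy(),
            "loss_one_to_zero": fc.loc[table.loss_one_to_zero].to_numpy(),
        }
    )
    return LossResponse(
        classifications=classifications,
        gain_one_to_two=table.gain_one_to_two,
        loss_one_to_zero=table.loss_one_to_zero,
        nnf_fc=fc,
        comparisons=comparisons,
    )
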