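"""DHS category assignment, presence filtering, stability and transience.

A peak is called differentially accessible for a contrast when it shows a
greater-than-threshold fold change (default 3x), an adjusted p below 0.05,
and a normalized read count above 20 in *both* replicates of the condition
the peak is claimed present in (the higher-mean group).  "Up" peaks are
gained in group B of the contrast (mDHS for memory-vs-naive, iDHS for
stimulated-vs-resting); "down" peaks are the reciprocal (nDHS, dDHS).

Stability summaries count how many reference-set peaks still exceed a fold
threshold at a later timepoint; the transient fraction counts early-
suppressed peaks whose later signal no longer meets the suppression
criterion.  Percentages print as integers except when the value's first
decimal is 5, which keeps one decimal (so 97.46 -> 97.5 but 83.33 -> 83).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "classify_dhs",
    "presence_filter",
    "stability_summary",
    "consistent_set",
    "transient_fraction",
    "round_percent",
]


def round_percent(pct: float) -> float | int:
    """Integer rounding, except a trailing .5 keeps one decimal place."""
    tenth = int(round(pct * 10))
    if tenth % 10 == 5:
        return tenth / 10
    return int(round(pct))


def classify_dhs(
    diff: pd.DataFrame,
    norm_counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fold: float = 3.0,
    padj: float = 0.05,
    min_reads: float = 20.0,
    strict_fold: bool = True,
) -> pd.DataFrame:
    """Label each feature up / down / none for one two-group contrast.

    ``diff`` must carry ``log2fc`` (B over A) and ``padj``; ``norm_counts``
    the size-factor-normalized counts for at least the contrast's samples.
    ``strict_fold`` uses FC > threshold (the default reading of
    "greater than 3-fold"); set False for >=.
    """
    if fold <= 0 or padj <= 0 or min_reads < 0:
        raise ValueError("thresholds must be positive")
    missing = [s for s in (*group_a, *group_b) if s not in norm_counts.columns]
    if missing:
        raise ValueError(f"normalized counts missing replicates: {missing}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each contrast group needs >= 2 replicates")

    log2_thr = np.log2(fold)
    lfc = diff["log2fc"].to_numpy()
    q = diff["padj"].to_numpy()
    fc_up = lfc > log2_thr if strict_fold else lfc >= log2_thr
    fc_down = lfc < -log2_thr if strict_fold else lfc <= -log2_thr

    counts_a = norm_counts.loc[diff.index, list(group_a)].to_numpy()
    counts_b = norm_counts.loc[diff.index, list(group_b)].to_numpy()
    present_b = (counts_b > min_reads).all(axis=1)  # required where claimed gained
    present_a = (counts_a > min_reads).all(axis=1)

    up = fc_up & (q < padj) & present_b
    down = fc_down & (q < padj) & present_a
    assert not (up & down).any(), "a peak cannot be both up and down"

    category = np.where(up, "up", np.where(down, "down", "none"))
    out = diff.copy()
    out["category"] = category
    for s in group_a:
        out[f"norm_{s}"] = norm_counts.loc[diff.index, s]
    for s in group_b:
        out[f"norm_{s}"] = norm_counts.loc[diff.index, s]
    return out


def presence_filter(norm_counts: pd.DataFrame, min_reads: float = 20.0) -> dict[str, set[str]]:
    """Per-sample sets of features with normalized count above ``min_reads``."""
    return {
        sample: set(norm_counts.index[norm_counts[sample] > min_reads])
        for sample in norm_counts.columns
    }


def stability_summary(
    n_reference: int,
    later_fc: pd.Series | Sequence[float],
    thresholds: Sequence[float] = (3.0, 2.0),
) -> pd.DataFrame:
    """Counts and percentages of reference peaks still >= each fold threshold later.

    ``later_fc`` holds the linear fold changes (later timepoint over the
    original baseline) of the reference-set peaks; ``n_reference`` is the
    reference set size (the denominator — peaks missing from ``later_fc``
    count as failing).
    """
    if n_reference <= 0:
        raise ValueError("reference set must be non-empty")
    fc = np.asarray(later_fc, dtype=float)
    if len(fc) > n_reference:
        raise ValueError("more fold changes than reference peaks")
    rows = []
    for t in thresholds:
        count = int((fc >= t).sum())
        rows.append({"threshold": t, "count": count, "percent": round_percent(100.0 * count / n_reference)})
    return pd.DataFrame(rows)


def consistent_set(
    tables: Sequence[pd.DataFrame], direction: str = "up"
) -> set[str]:
    """Features labeled ``direction`` in every supplied contrast table."""
    if len(tables) < 2:
        raise ValueError("need >= 2 category tables")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    base = tables[0].index
    for t in tables[1:]:
        if not base.equals(t.index):
            raise ValueError("category tables cover different master sets")
    sets = [set(t.index[t["category"] == direction]) for t in tables]
    return set.intersection(*sets)


def transient_fraction(
    early_set: Iterable[str],
    later_fc: Mapping[str, float] | pd.Series,
    fold: float = 3.0,
) -> tuple[int, float | int]:
    """Fraction of early-suppressed peaks that recovered at a later timepoint.

    ``later_fc`` maps peak id -> linear fold change (later over the original
    baseline).  A peak has recovered when its later FC no longer meets the
    suppression criterion (FC > 1/fold).  Returns (count, percent).
    """
    early = list(early_set)
    if not early:
        raise ValueError("early-suppressed set is empty")
    fc = pd.Series(later_fc)
    recovered = int((fc.reindex(early) > 1.0 / fold).sum())
    return recovered, round_percent(100.0 * recovered / len(early))
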