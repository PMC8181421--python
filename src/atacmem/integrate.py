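"""Peak-to-gene integration: category gene sets, expression summaries, overlaps.

Each categorized peak maps to its nearest gene; a gene's category set is
the union over its peaks, reduced to an exclusive class: a gene with both
an mDHS and an iDHS is "mDHS+iDHS" and never counted among the "-only"
classes, and "dDHS-only" requires the absence of mDHS/iDHS peaks.  Gene
sets are summarized by their mean expression log2 fold change with a
seeded percentile-bootstrap confidence interval.  Primed-inducible genes
are the antigen-inducible genes that were already elevated in resting
memory cells.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Peak
from .classify import round_percent

__all__ = [
    "assign_genes",
    "exclusive_class",
    "mean_expression_fc",
    "primed_inducible_genes",
    "overlap_counts",
    "overlap_counts_intervals",
]

EXCLUSIVE_CLASSES = ("mDHS-only", "iDHS-only", "mDHS+iDHS", "dDHS-only", "none")


def exclusive_class(categories: Iterable[str]) -> str:
    cats = set(categories)
    if "mDHS" in cats and "iDHS" in cats:
        return "mDHS+iDHS"
    if "mDHS" in cats:
        return "mDHS-only"
    if "iDHS" in cats:
        return "iDHS-only"
    if "dDHS" in cats:
        return "dDHS-only"
    return "none"


def assign_genes(
    peak_categories: Mapping[str, str | Iterable[str]],
    peak_gene: Mapping[str, str],
) -> pd.DataFrame:
    """Gene-level category sets and exclusive classes.

    ``peak_categories`` maps peak id -> DHS category (mDHS/nDHS/iDHS/dDHS or
    "none"), or an iterable of categories when a peak is categorized in
    several contrasts; ``peak_gene`` maps peak id -> nearest gene id and
    must cover every categorized peak.
    """
    norm: dict[str, set[str]] = {}
    for peak_id, val in peak_categories.items():
        cats = {val} if isinstance(val, str) else set(val)
        norm[peak_id] = cats - {"none"}
    missing = [p for p, cats in norm.items() if cats and p not in peak_gene]
    if missing:
        raise ValueError(f"categorized peaks without a nearest gene: {missing[:5]}")
    by_gene: dict[str, set[str]] = {}
    for peak_id, cats in norm.items():
        if cats:
            by_gene.setdefault(peak_gene[peak_id], set()).update(cats)
    rows = [
        {
            "gene_id": gid,
            "categories": ",".join(sorted(cats)),
            "exclusive_class": exclusive_class(cats),
        }
        for gid, cats in sorted(by_gene.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "categories", "exclusive_class"])


def mean_expression_fc(
    gene_sets: Mapping[str, Iterable[str]],
    expression_log2fc: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-set mean expression log2FC with a 95% percentile bootstrap CI.

    Genes absent from the expression table are dropped and counted in
    ``n_missing``; a set that loses all its genes raises, naming the set.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name in gene_sets:
        genes = list(gene_sets[name])
        vals = expression_log2fc.reindex(genes)
        n_missing = int(vals.isna().sum())
        vals = vals.dropna().to_numpy()
        if vals.size == 0:
            raise ValueError(f"gene set {name!r} has no gene in the expression table")
        boots = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {
                "set": name,
                "n": int(vals.size),
                "n_missing": n_missing,
                "mean_log2fc": float(vals.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def primed_inducible_genes(
    memory_vs_naive_log2fc: pd.Series,
    stimulated_vs_memory_log2fc: pd.Series,
    fold: float = 3.0,
) -> dict:
    """Inducible genes already elevated in resting memory (primed-inducible).

    Inducible: log2FC >= log2(fold) in the stimulated-vs-memory contrast.
    Primed-inducible: also >= log2(fold) up in memory-vs-naive.  Returns the
    gene set, the count/denominator and the integer percentage.
    """
    thr = np.log2(fold)
    common = memory_vs_naive_log2fc.index.intersection(stimulated_vs_memory_log2fc.index)
    stim = stimulated_vs_memory_log2fc.reindex(common)
    mem = memory_vs_naive_log2fc.reindex(common)
    inducible = set(common[stim >= thr])
    if not inducible:
        raise ValueError("no antigen-inducible gene at this threshold")
    primed = {g for g in inducible if mem[g] >= thr}
    pct = round_percent(100.0 * len(primed) / len(inducible))
    return {
        "genes": primed,
        "n_primed": len(primed),
        "n_inducible": len(inducible),
        "percent": pct,
    }


def overlap_counts(a: Iterable, b: Iterable) -> tuple[int, int, int]:
    """Exact set algebra: (|A & B|, |A - B|, |B - A|)."""
    sa, sb = set(a), set(b)
    return len(sa & sb), len(sa - sb), len(sb - sa)


def overlap_counts_intervals(
    a: Sequence[Peak], b: Sequence[Peak]
) -> tuple[int, int, int]:
    """Venn counts for peak sets in different coordinate systems.

    Membership in the intersection is >= 1 bp interval overlap; the shared
    count is taken from A's side, so ``n_shared + n_a_only == len(a)``.
    """
    from .intervals import intersect_peaks

    shared_a = len(intersect_peaks(list(a), list(b)))
    shared_b = len(intersect_peaks(list(b), list(a)))
    return shared_a, len(a) - shared_a, len(b) - shared_b
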