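"""Multiple-testing adjustment, significance filtering and the three-stressor
Venn classification of taxon shifts versus the control."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .amplicon_profiles import AbundanceTable


@dataclass(frozen=True)
class DifferentialResult:
    """One taxon's differential-abundance outcome (treatment vs control)."""

    taxon: str
    log2fc: float
    pvalue: float
    padj: float | None = None
    method: str = "external"

    def __post_init__(self) -> None:
        if not 0 <= self.pvalue <= 1:
            raise ValueError(f"{self.taxon}: p-value outside [0, 1]")
        if self.padj is not None and not 0 <= self.padj <= 1:
            raise ValueError(f"{self.taxon}: adjusted p-value outside [0, 1]")


@dataclass(frozen=True)
class ShiftEntry:
    """Significantly increased / decreased taxon sets for one (condition, day)."""

    increased: frozenset[str]
    decreased: frozenset[str]

    def __post_init__(self) -> None:
        if self.increased & self.decreased:
            raise ValueError("a taxon cannot be both increased and decreased")

    @property
    def significant(self) -> frozenset[str]:
        return self.increased | self.decreased


@dataclass
class VennRegion:
    """One region of the 3-set Venn: which conditions, how labeled, which taxa."""

    conditions: frozenset[str]
    label: str  # "increase" | "decrease" | "conflict"
    taxa: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.taxa)


@dataclass
class VennSummary:
    regions: list[VennRegion] = field(default_factory=list)

    @property
    def total_significant(self) -> int:
        return sum(r.count for r in self.regions)

    def counts(self) -> dict[tuple[frozenset[str], str], int]:
        return {(r.conditions, r.label): r.count for r in self.regions}

    def to_records(self) -> list[dict]:
        return [
            {
                "conditions": "&".join(sorted(r.conditions)),
                "label": r.label,
                "count": r.count,
                "taxa": ",".join(sorted(r.taxa)),
            }
            for r in sorted(self.regions, key=lambda r: (len(r.conditions), sorted(r.conditions), r.label))
        ]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def significant_shifts(
    results: Iterable[DifferentialResult], alpha: float = 0.05
) -> ShiftEntry:
    """Split taxa with ``padj`` strictly below ``alpha`` by fold-change sign.

    Taxa with zero fold change are never significant in either direction.
    """
    inc, dec = set(), set()
    for r in results:
        if r.padj is None:
            raise ValueError(f"{r.taxon}: adjusted p-value missing; run bh_adjust first")
        if r.padj < alpha:
            if r.log2fc > 0:
                inc.add(r.taxon)
            elif r.log2fc < 0:
                dec.add(r.taxon)
    return ShiftEntry(increased=frozenset(inc), decreased=frozenset(dec))


def venn_classify(shiftsets: Mapping[str, ShiftEntry]) -> VennSummary:
    """Assign each significant taxon to its 3-set Venn region.

    A region is labeled ``increase`` if the taxon increased under every
    condition where it was significant, ``decrease`` if it always decreased,
    and ``conflict`` when the direction disagrees across conditions.
    """
    if len(shiftsets) != 3:
        raise ValueError("expected exactly 3 stressor conditions")
    all_taxa = set()
    for entry in shiftsets.values():
        all_taxa |= entry.significant
    buckets: dict[tuple[frozenset[str], str], set[str]] = {}
    for taxon in all_taxa:
        members = frozenset(c for c, e in shiftsets.items() if taxon in e.significant)
        directions = {
            ("+" if taxon in shiftsets[c].increased else "-") for c in members
        }
        if directions == {"+"}:
            label = "increase"
        elif directions == {"-"}:
            label = "decrease"
        else:
            label = "conflict"
        buckets.setdefault((members, label), set()).add(taxon)
    summary = VennSummary(
        regions=[
            VennRegion(conditions=conds, label=label, taxa=frozenset(taxa))
            for (conds, label), taxa in buckets.items()
        ]
    )
    return summary


def _clr(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Centered log-ratio transform of count rows (pseudocount added)."""
    x = counts.astype(float) + pseudocount
    logx = np.log(x / x.sum(axis=1, keepdims=True))
    return logx - logx.mean(axis=1, keepdims=True)


def fallback_da_test(
    t: AbundanceTable,
    condition: str,
    control: str,
    day: int | None = None,
    alpha_pseudocount: float = 0.5,
) -> list[DifferentialResult]:
    """Simple per-taxon Welch test on CLR-transformed proportions.

    This is a clearly-labeled stand-in for an external negative-binomial
    differential-abundance tool, not a re-implementation of one. Requires
    at least 2 replicates per group; taxa absent from both groups get
    p = 1 by convention. Results carry BH-adjusted p-values.
    """
    if t.metadata is None:
        raise ValueError("abundance table has no sample metadata")
    meta = t.metadata
    mask_t = meta["condition"] == condition
    mask_c = meta["condition"] == control
    if day is not None:
        mask_t &= meta["day"] == day
        mask_c &= meta["day"] == day
    grp_t = t.counts.loc[meta.index[mask_t]]
    grp_c = t.counts.loc[meta.index[mask_c]]
    if len(grp_t) < 2 or len(grp_c) < 2:
        raise ValueError(
            f"insufficient replication: {len(grp_t)} vs {len(grp_c)} samples "
            f"for {condition!r} vs {control!r}"
        )
    clr_t = _clr(grp_t.to_numpy(), alpha_pseudocount)
    clr_c = _clr(grp_c.to_numpy(), alpha_pseudocount)
    results = []
    pvals = []
    for j, taxon in enumerate(t.taxon_ids):
        a, b = clr_t[:, j], clr_c[:, j]
        if grp_t.iloc[:, j].sum() == 0 and grp_c.iloc[:, j].sum() == 0:
            p, lfc = 1.0, 0.0
        else:
            lfc = float((a.mean() - b.mean()) / math.log(2))
            with warnings.catch_warnings():
                # near-identical groups trip a harmless precision warning
                warnings.simplefilter("ignore", RuntimeWarning)
                stat = stats.ttest_ind(a, b, equal_var=False)
            p = float(stat.pvalue)
            if math.isnan(p):
                p = 1.0
        pvals.append(p)
        results.append(
            DifferentialResult(
                taxon=taxon, log2fc=lfc, pvalue=p, method="clr-welch-fallback"
            )
        )
    padj = bh_adjust(pvals)
    return [
        DifferentialResult(
            taxon=r.taxon, log2fc=r.log2fc, pvalue=r.pvalue, padj=float(q), method=r.method
        )
        for r, q in zip(results, padj)
    ]


# ---------------------------------------------------------------------------
# I/O for external DA result tables (columns: taxon, log2fc, pvalue[, padj])


def read_da_table(path: str | Path) -> list[DifferentialResult]:
    df = pd.read_csv(path, sep="\t")
    required = {"taxon", "log2fc", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_padj = "padj" in df.columns
    padj = df["padj"].to_numpy() if has_padj else bh_adjust(df["pvalue"].to_numpy())
    return [
        DifferentialResult(
            taxon=str(row.taxon),
            log2fc=float(row.log2fc),
            pvalue=float(row.pvalue),
            padj=float(q),
        )
        for row, q in zip(df.itertuples(index=False), padj)
    ]


def write_da_table(results: Sequence[DifferentialResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "taxon": [r.taxon for r in results],
            "log2fc": [r.log2fc for r in results],
            "pvalue": [r.pvalue for r in results],
            "padj": [r.padj for r in results],
            "method": [r.method for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
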