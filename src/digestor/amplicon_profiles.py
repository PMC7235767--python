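"""Read QC and OTU-table summarization.

FASTQ length/quality filtering, relative abundances, lineage-rank
aggregation, top-N taxon selection, Bray-Curtis dissimilarity and
principal-coordinates ordination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy.spatial.distance import pdist, squareform

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: QIIME-style lineage prefixes, outermost rank first.
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the 0-based record index."""

    def __init__(self, index: int, message: str):
        super().__init__(f"record {index}: {message}")
        self.index = index


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"{self.id}: negative PHRED score")

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qualities)) if self.qualities else 0.0


def read_fastq(handle: IO[str] | str | Path) -> Iterator[ReadRecord]:
    """Stream PHRED+33 FASTQ records; malformed input raises :class:`FastqParseError`."""

    def _iter(fh: IO[str]) -> Iterator[ReadRecord]:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(index, str(exc)) from exc
            phred = tuple(ord(c) - 33 for c in qual)
            if any(q < 0 for q in phred):
                raise FastqParseError(index, "quality character below PHRED+33 offset")
            yield ReadRecord(id=title.split()[0], sequence=seq, qualities=phred)
            index += 1

    if isinstance(handle, (str, Path)):
        with open(handle) as fh:
            yield from _iter(fh)
    else:
        yield from _iter(handle)


@dataclass
class QCSummary:
    """Tally of retained reads and removal reasons (length checked first)."""

    total: int = 0
    retained: int = 0
    removed_length: int = 0
    removed_quality: int = 0

    @property
    def removed(self) -> int:
        return self.removed_length + self.removed_quality


def filter_reads(
    reads: Iterable[ReadRecord],
    min_length: int = 400,
    min_mean_q: float = 7.0,
) -> tuple[list[ReadRecord], QCSummary]:
    """Keep reads with length >= ``min_length`` and mean PHRED >= ``min_mean_q``.

    Both thresholds are inclusive: the removal rule drops reads strictly
    shorter than the length cutoff or with mean quality strictly below the
    quality cutoff.
    """
    kept: list[ReadRecord] = []
    summary = QCSummary()
    for rec in reads:
        summary.total += 1
        if len(rec.sequence) < min_length:
            summary.removed_length += 1
        elif rec.mean_quality < min_mean_q:
            summary.removed_quality += 1
        else:
            summary.retained += 1
            kept.append(rec)
    return kept, summary


# ---------------------------------------------------------------------------
# Abundance tables


@dataclass
class AbundanceTable:
    """Samples x taxa count matrix with lineages and sample metadata.

    ``counts`` is indexed by sample id with taxon-id columns; ``lineages``
    maps taxon id to a rank tuple (outermost first, <= 7 ranks);
    ``metadata`` is indexed by sample id with at least ``condition``,
    ``day`` and ``replicate`` columns when present.
    """

    counts: pd.DataFrame
    lineages: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        for taxon, lineage in self.lineages.items():
            if len(lineage) > len(RANKS):
                raise ValueError(f"{taxon}: lineage has more than {len(RANKS)} ranks")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, counts_path: str | Path, metadata_path: str | Path | None = None) -> None:
        """Write a taxa-rows TSV with a trailing QIIME-style lineage column."""
        out = self.counts.T.copy()
        out.index.name = "taxon_id"
        out["lineage"] = [format_lineage(self.lineages.get(t, ())) for t in out.index]
        out.to_csv(counts_path, sep="\t")
        if metadata_path is not None and self.metadata is not None:
            meta = self.metadata.copy()
            meta.index.name = "sample_id"
            meta.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, metadata_path: str | Path | None = None
    ) -> "AbundanceTable":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        lineages: dict[str, tuple[str, ...]] = {}
        if "lineage" in df.columns:
            lineages = {t: parse_lineage(s) for t, s in df["lineage"].items()}
            df = df.drop(columns=["lineage"])
        counts = df.T.astype(int)
        counts.index.name = None
        counts.columns.name = None
        metadata = None
        if metadata_path is not None:
            metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(counts=counts, lineages=lineages, metadata=metadata)

    @classmethod
    def from_biom_json(cls, path: str | Path) -> "AbundanceTable":
        """Read a minimal BIOM-format (v1, dense or sparse) JSON table."""
        with open(path) as fh:
            doc = json.load(fh)
        sample_ids = [s["id"] for s in doc["columns"]]
        taxon_ids = [r["id"] for r in doc["rows"]]
        mat = np.zeros((len(taxon_ids), len(sample_ids)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat = np.asarray(doc["data"], dtype=float)
        lineages = {}
        for r in doc["rows"]:
            taxonomy = (r.get("metadata") or {}).get("taxonomy")
            if taxonomy:
                if isinstance(taxonomy, str):
                    lineages[r["id"]] = parse_lineage(taxonomy)
                else:
                    lineages[r["id"]] = tuple(str(x).strip() for x in taxonomy)
        counts = pd.DataFrame(mat.T.astype(int), index=sample_ids, columns=taxon_ids)
        return cls(counts=counts, lineages=lineages)


def parse_lineage(s: str) -> tuple[str, ...]:
    """Parse a QIIME-style ``k__Bacteria;p__Firmicutes;...`` string."""
    if not isinstance(s, str) or not s.strip():
        return ()
    parts = [p.strip() for p in s.split(";")]
    out = []
    for p in parts:
        for prefix in _RANK_PREFIXES:
            if p.startswith(prefix):
                p = p[len(prefix):]
                break
        out.append(p)
    while out and out[-1] == "":
        out.pop()
    return tuple(out)


def format_lineage(lineage: Sequence[str]) -> str:
    return ";".join(f"{_RANK_PREFIXES[i]}{name}" for i, name in enumerate(lineage))


@dataclass
class RelativeProfile:
    """Per-sample proportions; zero-total samples are flagged, not divided."""

    proportions: pd.DataFrame
    empty_samples: frozenset[str] = frozenset()
    lineages: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    metadata: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.proportions.columns)


def relative_abundance(t: AbundanceTable) -> RelativeProfile:
    """Close each sample's counts to proportions summing to 1."""
    totals = t.counts.sum(axis=1)
    empty = frozenset(totals.index[totals == 0])
    safe = totals.replace(0, 1)
    props = t.counts.div(safe, axis=0).astype(float)
    props.loc[list(empty)] = np.nan
    return RelativeProfile(
        proportions=props, empty_samples=empty, lineages=t.lineages, metadata=t.metadata
    )


def aggregate_rank(t: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum counts over taxa sharing the label at ``rank``.

    Taxa whose lineage does not resolve to ``rank`` are grouped under
    ``unclassified-<deepest resolved parent>``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank)
    labels: dict[str, str] = {}
    for taxon in t.taxon_ids:
        lineage = t.lineages.get(taxon, ())
        if len(lineage) > depth and lineage[depth]:
            labels[taxon] = lineage[depth]
        else:
            parent = next((name for name in reversed(lineage[:depth]) if name), "root")
            labels[taxon] = f"unclassified-{parent}"
    grouped = t.counts.T.groupby([labels[t_] for t_ in t.counts.columns]).sum().T
    new_lineages: dict[str, tuple[str, ...]] = {}
    for taxon, label in labels.items():
        lineage = t.lineages.get(taxon, ())
        new_lineages.setdefault(label, tuple(lineage[: depth + 1]))
    return AbundanceTable(counts=grouped, lineages=new_lineages, metadata=t.metadata)


def top_taxa(p: RelativeProfile, n: int) -> list[str]:
    """Taxa ranked by summed proportions over all samples, descending.

    Ties break lexicographically on the taxon id. If ``n`` exceeds the taxon
    count all taxa are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    totals = p.proportions.sum(axis=0, skipna=True)
    order = sorted(totals.index, key=lambda t: (-totals[t], t))
    return order[: min(n, len(order))]


def intersect_top(
    profiles: Mapping[str, RelativeProfile], n: int = 10
) -> list[str]:
    """Taxa in every condition's top-``n``, ordered by overall abundance."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 conditions")
    tops = [set(top_taxa(p, n)) for p in profiles.values()]
    common = set.intersection(*tops)
    overall: dict[str, float] = {}
    for p in profiles.values():
        for taxon, total in p.proportions.sum(axis=0, skipna=True).items():
            overall[taxon] = overall.get(taxon, 0.0) + float(total)
    return sorted(common, key=lambda t: (-overall.get(t, 0.0), t))


def bray_curtis(p: RelativeProfile) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities, samples x samples.

    Entries involving a flagged-empty sample are masked as NaN.
    """
    if len(p.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    x = p.proportions.fillna(0.0).to_numpy(dtype=float)
    d = squareform(pdist(x, metric="braycurtis"))
    out = pd.DataFrame(d, index=p.sample_ids, columns=p.sample_ids)
    for s in p.empty_samples:
        out.loc[s, :] = np.nan
        out.loc[:, s] = np.nan
    return out


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding of a dissimilarity matrix.

    ``eigenvalues`` includes any negative values (non-Euclidean input is not
    silently truncated); ``proportion_explained`` is relative to the sum of
    positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def ordinate(d: pd.DataFrame, k: int = 2) -> OrdinationResult:
    """Classical metric scaling (PCoA) of a symmetric dissimilarity matrix."""
    mat = d.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10, equal_nan=True):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.nan_to_num(np.diag(mat)), 0.0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have zero diagonal")
    if np.isnan(mat).any():
        raise ValueError("masked (NaN) entries present; drop those samples first")
    m = mat.shape[0]
    b = -0.5 * (mat**2)
    j = np.eye(m) - np.ones((m, m)) / m
    b = j @ b @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_pos = int((eigvals > 1e-12).sum())
    k_eff = min(k, n_pos)
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    pos_sum = eigvals[eigvals > 0].sum()
    frac = eigvals[:k_eff] / pos_sum if pos_sum > 0 else np.zeros(k_eff)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=d.index, columns=[f"PCo{i + 1}" for i in range(k_eff)]
        ),
        eigenvalues=eigvals,
        proportion_explained=frac,
    )
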