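"""Pseudocount-corrected fold differences, ranking and the mode diagnostic.

The core statistic is deliberately simple: with pseudocount ``c`` (default
100), the corrected fold difference of a gene is ``(focal + c) / (ref + c)``.
A histogram of the log10 of this ratio over all genes serves as the
normalization diagnostic — a mode at zero means no global scaling factor is
needed.  The shorter-read dataset, when present, acts as a replicate to flag
genes whose large fold rests on few reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_PSEUDOCOUNT = 100.0
DEFAULT_THRESHOLDS = (5.0, 10.0, 15.0)

FLAG_OK = "ok"
FLAG_LOW_SUPPORT = "low-support"
FLAG_NO_REPLICATE = "no-replicate"


class CountError(ValueError):
    pass


@dataclass(frozen=True)
class GeneCountRecord:
    """Per-gene read counts; 39 bp columns are the optional replicate run."""

    gene: str
    focal_76: float
    ref_76: float
    focal_39: float | None = None
    ref_39: float | None = None

    def __post_init__(self):
        for name in ("focal_76", "ref_76", "focal_39", "ref_39"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise CountError(f"{self.gene}: negative count {name}={v}")


@dataclass(frozen=True)
class FoldChangeRecord:
    gene: str
    fold: float
    log10_ratio: float
    replicate_fold: float | None = None
    replicate_flag: str = FLAG_NO_REPLICATE


@dataclass
class NormalizationDiagnostic:
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    mode: float  # center of the maximal-count bin
    offset: float  # estimated global log10 offset (== mode)
    passed: bool

    def validate(self, n_genes: int) -> None:
        if int(self.bin_counts.sum()) != n_genes:
            raise ValueError("histogram counts do not sum to the number of genes")


def corrected_fold(
    focal: float, reference: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """``(focal + pseudocount) / (reference + pseudocount)``."""
    if focal < 0 or reference < 0:
        raise CountError(f"negative count: focal={focal}, reference={reference}")
    if pseudocount <= 0:
        raise CountError(f"pseudocount must be positive, got {pseudocount}")
    return (focal + pseudocount) / (reference + pseudocount)


def fold_table(
    records: Iterable[GeneCountRecord], pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-gene counts plus corrected fold and its log10."""
    rows = []
    for r in records:
        fold = corrected_fold(r.focal_76, r.ref_76, pseudocount)
        rows.append(
            {
                "gene": r.gene,
                "focal_76": r.focal_76,
                "ref_76": r.ref_76,
                "focal_39": r.focal_39,
                "ref_39": r.ref_39,
                "fold": fold,
                "log10_ratio": math.log10(fold),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "focal_76", "ref_76", "focal_39", "ref_39", "fold", "log10_ratio"],
    )


def log_ratio_histogram(
    records: Sequence[GeneCountRecord],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    bin_width: float = 0.25,
) -> NormalizationDiagnostic:
    """Histogram of log10 corrected folds with bins centered on multiples of
    *bin_width* (so an unbiased dataset peaks in the bin centered at 0).

    The mode is the center of the maximal-count bin, ties resolved toward 0;
    the diagnostic passes iff the mode sits in the zero-centered bin (mode
    centers are exact multiples of *bin_width*, so ``|mode| < bin_width``
    means the mode is 0 and no global scaling is indicated).
    """
    records = list(records)
    if not records:
        raise CountError("log_ratio_histogram requires at least one record")
    if bin_width <= 0:
        raise CountError("bin width must be positive")
    ratios = np.array(
        [math.log10(corrected_fold(r.focal_76, r.ref_76, pseudocount)) for r in records]
    )
    k = np.floor(ratios / bin_width + 0.5).astype(int)  # index of centered bin
    kmin, kmax = int(k.min()), int(k.max())
    edges = (np.arange(kmin, kmax + 2) - 0.5) * bin_width
    counts, _ = np.histogram(ratios, bins=edges)
    centers = (np.arange(kmin, kmax + 1)) * bin_width
    max_count = counts.max()
    candidates = centers[counts == max_count]
    mode = float(min(candidates, key=lambda c: (abs(c), c)))
    diag = NormalizationDiagnostic(
        bin_edges=edges,
        bin_counts=counts,
        mode=mode,
        offset=mode,
        passed=abs(mode) < bin_width,
    )
    diag.validate(len(records))
    return diag


def scale_reference(
    records: Iterable[GeneCountRecord], log10_offset: float
) -> list[GeneCountRecord]:
    """Rescale reference counts by ``10**log10_offset`` (optional correction
    applied only when the diagnostic fails and the caller opts in)."""
    factor = 10.0 ** log10_offset
    return [
        GeneCountRecord(r.gene, r.focal_76, r.ref_76 * factor, r.focal_39, r.ref_39)
        for r in records
    ]


def rank_and_threshold(
    records: Iterable[GeneCountRecord],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_total_reads: float = 1.0,
) -> tuple[pd.DataFrame, dict[float, int]]:
    """Rank genes by corrected fold (descending, ties by gene id) and count
    genes at or above each fold threshold.

    Genes with fewer than *min_total_reads* reads across both species are
    kept out of the ranked table (their fold is pure pseudocount).
    """
    table = fold_table(records, pseudocount)
    table = table[(table["focal_76"] + table["ref_76"]) >= min_total_reads]
    table = table.sort_values(
        ["fold", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.index = pd.RangeIndex(1, len(table) + 1, name="rank")
    counts = {float(t): int((table["fold"] >= t).sum()) for t in thresholds}
    return table, counts


def threshold_counts_from_folds(
    folds: Sequence[float], thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> dict[float, int]:
    """Threshold counts straight from precomputed fold values."""
    arr = np.asarray(folds, dtype=float)
    return {float(t): int((arr >= t).sum()) for t in thresholds}


def replicate_support(
    records: Iterable[GeneCountRecord],
    min_replicate_reads: float = 100.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[FoldChangeRecord]:
    """Flag genes whose replicate (39 bp) focal count is too low to trust.

    Genes without replicate counts are flagged ``no-replicate``; otherwise
    the replicate fold uses the same pseudocount statistic on 39 bp counts
    and the flag is ``low-support`` when the 39 bp focal count falls below
    *min_replicate_reads*.
    """
    out: list[FoldChangeRecord] = []
    for r in records:
        fold = corrected_fold(r.focal_76, r.ref_76, pseudocount)
        if r.focal_39 is None or r.ref_39 is None:
            out.append(FoldChangeRecord(r.gene, fold, math.log10(fold)))
            continue
        rep_fold = corrected_fold(r.focal_39, r.ref_39, pseudocount)
        flag = FLAG_LOW_SUPPORT if r.focal_39 < min_replicate_reads else FLAG_OK
        out.append(FoldChangeRecord(r.gene, fold, math.log10(fold), rep_fold, flag))
    return out


def records_from_counts(
    focal_counts: Mapping[str, float],
    ref_counts: Mapping[str, float],
    genes: Iterable[str] | None = None,
) -> list[GeneCountRecord]:
    """Join two count tables into records; absent genes count 0."""
    if genes is None:
        genes = sorted(set(focal_counts) | set(ref_counts))
    return [
        GeneCountRecord(g, float(focal_counts.get(g, 0)), float(ref_counts.get(g, 0)))
        for g in genes
    ]


def read_counts_table(path) -> list[GeneCountRecord]:
    """Read a counts TSV: gene, focal_76, ref_76[, focal_39, ref_39]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "focal_76", "ref_76"}
    if not required.issubset(df.columns):
        raise CountError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    has_rep = {"focal_39", "ref_39"}.issubset(df.columns)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GeneCountRecord(
                str(row.gene),
                float(row.focal_76),
                float(row.ref_76),
                float(row.focal_39) if has_rep and not pd.isna(row.focal_39) else None,
                float(row.ref_39) if has_rep and not pd.isna(row.ref_39) else None,
            )
        )
    return records
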