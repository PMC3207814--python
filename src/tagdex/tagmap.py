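"""Tag read placement on transcripts/contigs, retention rules and counting.

Alignments come either from a standard SAM file (external mapper) or from
the built-in exact-seed, ungapped desk-scale aligner.  Retention applies
the positive-mapping-score gate and, for reference cDNA libraries, the
3'-window rule: a read whose start lies more than ``window`` nt upstream of
the transcript end is discarded.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pysam

from .simulate import FastqRead


class SamParseError(ValueError):
    pass


class AlignmentInputError(ValueError):
    pass


@dataclass(frozen=True)
class TagAlignment:
    """One read's placement on a target; ``start`` is 0-based on the target."""

    read_id: str
    target: str
    start: int
    strand: str  # "+" or "-"
    score: float  # MAPQ when read from SAM; read_length - mismatches when built-in
    multimapped: bool = False


@dataclass
class CountFilterStats:
    """Bookkeeping for one filtering run; categories partition ``aligned``."""

    total: int
    aligned: int
    rejected_nonpositive_score: int = 0
    rejected_outside_window: int = 0
    rejected_multimap: int = 0
    assigned: int = 0

    def validate(self) -> None:
        parts = (
            self.rejected_nonpositive_score
            + self.rejected_outside_window
            + self.rejected_multimap
            + self.assigned
        )
        if parts != self.aligned:
            raise ValueError(
                f"filter stats do not add up: {parts} categorized vs {self.aligned} aligned"
            )


def read_sam(path) -> tuple[list[TagAlignment], int]:
    """Ingest primary mapped records from a SAM file.

    Returns (alignments, n_unmapped).  MAPQ becomes the mapping score;
    secondary and supplementary records are ignored.  Malformed input raises
    :class:`SamParseError` carrying the approximate line number.
    """
    alignments: list[TagAlignment] = []
    n_unmapped = 0
    with open(path) as fh:
        n_header = sum(1 for line in fh if line.startswith("@"))
    record_no = 0
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                record_no += 1
                if rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.is_unmapped:
                    n_unmapped += 1
                    continue
                alignments.append(
                    TagAlignment(
                        read_id=rec.query_name,
                        target=rec.reference_name,
                        start=rec.reference_start,
                        strand="-" if rec.is_reverse else "+",
                        score=float(rec.mapping_quality),
                    )
                )
    except (ValueError, OSError) as exc:  # htslib surfaces parse errors as OSError
        raise SamParseError(
            f"{path}: parse error near line {n_header + record_no + 1}: {exc}"
        ) from None
    return alignments, n_unmapped


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def build_kmer_index(targets: Mapping[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for tid, seq in targets.items():
        for pos in range(len(seq) - k + 1):
            index[seq[pos : pos + k]].append((tid, pos))
    return dict(index)


def _mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def align_builtin(
    reads: Sequence[FastqRead],
    targets: Mapping[str, str],
    k: int = 20,
    max_mismatch: int = 4,
    n_seeds: int = 3,
) -> tuple[list[TagAlignment], "AlignStats"]:
    """Exact-k-mer seeded, ungapped alignment of tag reads on both strands.

    For each read, up to *n_seeds* non-overlapping k-mers are looked up in
    the target index per orientation; candidate placements are extended
    without gaps and scored as ``read_length - mismatches``.  The single
    best placement wins; reads whose best placement is shared by more than
    one (target, offset, strand) are reported multimapped with score 0 and
    are meant to be dropped by the downstream score gate.  Reads must fit
    entirely on the target.  Deterministic given its inputs.
    """
    if not targets:
        raise AlignmentInputError("empty target set")
    for r in reads[:1]:
        if k > len(r.seq):
            raise AlignmentInputError(f"seed length {k} exceeds read length {len(r.seq)}")
    index = build_kmer_index(targets, k)
    lengths = {tid: len(seq) for tid, seq in targets.items()}

    alignments: list[TagAlignment] = []
    n_unaligned = 0
    n_multi = 0
    for read in reads:
        rl = len(read.seq)
        best_mm = max_mismatch + 1
        best: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int, str]] = set()
        for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
            max_seed_start = rl - k
            for si in range(n_seeds):
                spos = si * k
                if spos > max_seed_start:
                    break
                for tid, tpos in index.get(seq[spos : spos + k], ()):
                    start = tpos - spos
                    if start < 0 or start + rl > lengths[tid]:
                        continue
                    key = (tid, start, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    mm = _mismatches(seq, targets[tid][start : start + rl], best_mm)
                    if mm < best_mm:
                        best_mm = mm
                        best = [key]
                    elif mm == best_mm and mm <= max_mismatch:
                        best.append(key)
        if best_mm > max_mismatch or not best:
            n_unaligned += 1
            continue
        if len(best) > 1:
            n_multi += 1
            tid, start, strand = best[0]
            alignments.append(TagAlignment(read.id, tid, start, strand, 0.0, multimapped=True))
            continue
        tid, start, strand = best[0]
        alignments.append(TagAlignment(read.id, tid, start, strand, float(rl - best_mm)))
    stats = AlignStats(total=len(reads), aligned=len(alignments), unaligned=n_unaligned, multimapped=n_multi)
    return alignments, stats


@dataclass
class AlignStats:
    total: int
    aligned: int
    unaligned: int
    multimapped: int


def filter_3prime(
    alignments: Iterable[TagAlignment],
    target_lengths: Mapping[str, int],
    window: int | None = 1050,
    min_score: float = 1.0,
    total_reads: int | None = None,
) -> tuple[list[TagAlignment], CountFilterStats]:
    """Apply the score gate and the 3'-window retention rule.

    An alignment survives iff it is not multimapped, its score is at least
    *min_score* ("positive mapping score"), and its start lies within the
    final *window* nt of the target: ``start >= max(0, L - window)``.
    Pass ``window=None`` to skip the positional rule (contig targets, whose
    3' ends are unknown).  Idempotent on its own output.
    """
    alignments = list(alignments)
    stats = CountFilterStats(
        total=len(alignments) if total_reads is None else total_reads,
        aligned=len(alignments),
    )
    retained: list[TagAlignment] = []
    for aln in alignments:
        if aln.multimapped:
            stats.rejected_multimap += 1
            continue
        if aln.score < min_score:
            stats.rejected_nonpositive_score += 1
            continue
        if window is not None:
            if aln.target not in target_lengths:
                raise AlignmentInputError(f"unknown target id {aln.target!r}")
            L = target_lengths[aln.target]
            if aln.start < max(0, L - window):
                stats.rejected_outside_window += 1
                continue
        retained.append(aln)
    stats.assigned = len(retained)
    stats.validate()
    return retained, stats


def count_reads(alignments: Iterable[TagAlignment]) -> dict[str, int]:
    """Integer read counts per target; zero-count targets are simply absent."""
    return dict(Counter(aln.target for aln in alignments))


def aggregate_counts(
    counts: Mapping[str, int], target_to_gene: Mapping[str, str]
) -> dict[str, int]:
    """Sum per-target counts up to gene level; unmapped targets are dropped."""
    out: Counter = Counter()
    for target, c in counts.items():
        gene = target_to_gene.get(target)
        if gene is not None:
            out[gene] += c
    return dict(out)
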