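"""Seeded synthetic transcriptomes, contigs and 3'-tag read libraries.

The generator emulates the structural properties the downstream analysis
depends on: two annotated reference transcriptomes of unequal divergence
from the focal species, 1:1 / 1:many / missing orthology, incomplete and
fragmented contig coverage of the focal transcriptome, 3'-biased short tag
reads inside a fixed window, poly-A/poly-T artifact reads and a known
per-gene fold-change truth set.  Every draw flows from a single seed, so
identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .orthomap import (
    CARD_NONE,
    CARD_ONE2MANY,
    CARD_ONE2ONE,
    OrthologRow,
    OrthologTable,
)

# orthology truth classes
CLASS_ONE2ONE = "one2one"
CLASS_REFB_ONLY = "refB_only"
CLASS_PARALOG = "paralog"
CLASS_UNPAIRED = "unpaired"

QUALITY_CHAR = "I"  # constant Phred+33 quality; no stage consumes qualities

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class ExpressionError(ValueError):
    """Expression vector inconsistent with the supplied sequences."""


@dataclass
class SimConfig:
    """All knobs of the synthetic dataset; see module docstring for intent.

    Divergences are per-site substitution probabilities; ``div_focal_refB``
    is expected to be the smaller one (guinea-pig-like helper reference).
    ``tag_decay`` is the geometric parameter of the 3' positional bias and
    ``tag_window`` the window (in nt from the 3' end) that read starts are
    drawn from.
    """

    n_genes: int = 200
    transcript_len_range: tuple[int, int] = (600, 3000)
    div_focal_refA: float = 0.10
    div_focal_refB: float = 0.03
    frac_one_to_one: float = 0.7
    frac_refB_only: float = 0.1
    frac_paralog: float = 0.1
    contig_coverage: float = 0.8
    contig_fragmentation_rate: float = 0.5
    library_size_focal: int = 100_000
    library_size_ref: int = 100_000
    read_length: int = 76
    tag_window: int = 1050
    tag_decay: float = 0.005
    frac_artifact: float = 0.3
    error_rate: float = 0.005
    n_de_genes: int = 40
    de_log2fold_range: tuple[float, float] = (1.0, 6.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        lo, hi = self.transcript_len_range
        if not (0 < lo <= hi):
            raise ConfigError(f"bad transcript_len_range {self.transcript_len_range}")
        if lo < self.read_length:
            raise ConfigError("shortest transcript must be >= read_length")
        for name in ("div_focal_refA", "div_focal_refB", "frac_one_to_one",
                     "frac_refB_only", "frac_paralog", "contig_coverage",
                     "frac_artifact", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.frac_one_to_one + self.frac_refB_only + self.frac_paralog > 1.0 + 1e-12:
            raise ConfigError("orthology class fractions sum to more than 1")
        if not 0.0 < self.tag_decay < 1.0:
            raise ConfigError("tag_decay must lie in (0, 1)")
        if self.tag_window < self.read_length:
            raise ConfigError("tag_window must be >= read_length")
        if self.contig_fragmentation_rate < 0:
            raise ConfigError("contig_fragmentation_rate must be >= 0")
        if self.library_size_focal < 0 or self.library_size_ref < 0:
            raise ConfigError("library sizes must be >= 0")
        if self.read_length <= 0:
            raise ConfigError("read_length must be positive")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ConfigError("n_de_genes must lie in [0, n_genes]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transcript_len_range"] = list(self.transcript_len_range)
        d["de_log2fold_range"] = list(self.de_log2fold_range)
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("transcript_len_range", "de_log2fold_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class GeneTruth:
    gene: str
    expr_focal: float
    expr_ref: float
    log2_fold: float  # NaN when the gene is absent from the reference library
    ortho_class: str
    covered: bool = False


@dataclass(frozen=True)
class ContigTruth:
    contig: str
    gene: str
    start: int  # 0-based, half-open on the source transcript
    end: int


@dataclass
class TruthSet:
    """Ground truth: per-gene expression/fold plus contig origins."""

    genes: dict[str, GeneTruth]
    contigs: dict[str, ContigTruth] = field(default_factory=dict)

    def validate(self, transcripts: Mapping[str, str] | None = None) -> None:
        for attr in ("expr_focal", "expr_ref"):
            total = sum(getattr(g, attr) for g in self.genes.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{attr} fractions sum to {total}, not 1")
        if transcripts is not None:
            for ct in self.contigs.values():
                if not (0 <= ct.start < ct.end <= len(transcripts[ct.gene])):
                    raise ValueError(f"contig {ct.contig} interval outside {ct.gene}")

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(g) for g in self.genes.values()])

    def contig_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.contigs.values()],
                            columns=["contig", "gene", "start", "end"])

    def write_tsv(self, gene_path, contig_path) -> None:
        self.gene_frame().to_csv(gene_path, sep="\t", index=False)
        self.contig_frame().to_csv(contig_path, sep="\t", index=False)


@dataclass(frozen=True)
class FastqRead:
    """A simulated read; the id encodes its origin (``gene|start`` or ``*|polyX``)."""

    id: str
    seq: str

    @property
    def source_gene(self) -> str | None:
        gene = self.id.split("|")[1]
        return None if gene == "*" else gene

    @property
    def is_artifact(self) -> bool:
        return self.source_gene is None


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Independent deterministic stream per operation."""
    return np.random.default_rng([config.seed, zlib.crc32(stream.encode())])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def _mutate(seq: str, div: float, rng: np.random.Generator) -> str:
    """Substitution-only divergence: each site flips to another base w.p. *div*."""
    if div <= 0:
        return seq
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()
    mask = rng.random(len(codes)) < div
    n = int(mask.sum())
    if n:
        codes[mask] = (codes[mask] + rng.integers(1, 4, n).astype(np.uint8)) % 4
    return _BASES[codes].tobytes().decode()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((xa == xb).mean())


def simulate_transcriptomes(
    config: SimConfig,
) -> tuple[dict[str, str], dict[str, str], dict[str, str], OrthologTable, TruthSet]:
    """Generate (refA, refB, focal) transcriptomes, ortholog table and truth.

    Gene classes: ``one2one`` genes appear in both references with a 1:1
    table row; ``refB_only`` genes are absent from reference A and reachable
    only through their refB 1:1 partner; ``paralog`` genes carry a
    near-duplicate second refA copy (``<gene>_P``) recorded as 1:many;
    the remainder (``unpaired``) has a refB sequence with no refA ortholog
    in the table.  Reference-B transcript ids are ``<gene>_B``.
    """
    config.validate()
    rng = _rng(config, "transcriptomes")
    n = config.n_genes
    genes = [f"G{i:04d}" for i in range(n)]

    n11 = round(config.frac_one_to_one * n)
    nb = round(config.frac_refB_only * n)
    np_ = round(config.frac_paralog * n)
    while n11 + nb + np_ > n:  # rounding overflow by at most a couple
        np_ -= 1 if np_ > 0 else 0
        if n11 + nb + np_ > n and np_ == 0:
            nb -= 1
    order = rng.permutation(n)
    classes = [CLASS_UNPAIRED] * n
    for idx in order[:n11]:
        classes[idx] = CLASS_ONE2ONE
    for idx in order[n11 : n11 + nb]:
        classes[idx] = CLASS_REFB_ONLY
    for idx in order[n11 + nb : n11 + nb + np_]:
        classes[idx] = CLASS_PARALOG

    lo, hi = config.transcript_len_range
    lengths = rng.integers(lo, hi + 1, n)

    focal: dict[str, str] = {}
    refA: dict[str, str] = {}
    refB: dict[str, str] = {}
    rows: list[OrthologRow] = []
    for gene, cls, length in zip(genes, classes, lengths):
        seq = _random_seq(rng, int(length))
        focal[gene] = seq
        seq_a = _mutate(seq, config.div_focal_refA, rng)
        seq_b = _mutate(seq, config.div_focal_refB, rng)
        refB[f"{gene}_B"] = seq_b
        if cls == CLASS_REFB_ONLY:
            rows.append(OrthologRow(f"{gene}_B", gene, CARD_ONE2ONE))
            continue  # gene is not annotation-usable in reference A
        refA[gene] = seq_a
        if cls == CLASS_ONE2ONE:
            rows.append(OrthologRow(f"{gene}_B", gene, CARD_ONE2ONE))
        elif cls == CLASS_PARALOG:
            refA[f"{gene}_P"] = _mutate(seq_a, config.div_focal_refA, rng)
            rows.append(OrthologRow(f"{gene}_B", gene, CARD_ONE2MANY))
            rows.append(OrthologRow(f"{gene}_B", f"{gene}_P", CARD_ONE2MANY))
        else:  # unpaired
            rows.append(OrthologRow(f"{gene}_B", None, CARD_NONE))

    # log-normal expression baseline, DE genes scaled by a signed fold factor
    base_log2 = rng.normal(0.0, 1.5, n)
    lfc = np.zeros(n)
    if config.n_de_genes:
        de_idx = rng.choice(n, size=config.n_de_genes, replace=False)
        flo, fhi = config.de_log2fold_range
        lfc[de_idx] = rng.uniform(flo, fhi, config.n_de_genes) * rng.choice(
            [-1.0, 1.0], config.n_de_genes
        )
    focal_level = np.exp2(base_log2 + lfc)
    ref_level = np.exp2(base_log2)
    ref_present = np.array([c != CLASS_REFB_ONLY for c in classes])
    ref_level = np.where(ref_present, ref_level, 0.0)
    expr_focal = focal_level / focal_level.sum()
    expr_ref = ref_level / ref_level.sum()

    truth_genes: dict[str, GeneTruth] = {}
    for i, gene in enumerate(genes):
        with np.errstate(divide="ignore"):
            l2f = (
                float(np.log2(expr_focal[i] / expr_ref[i]))
                if expr_ref[i] > 0
                else float("nan")
            )
        truth_genes[gene] = GeneTruth(
            gene=gene,
            expr_focal=float(expr_focal[i]),
            expr_ref=float(expr_ref[i]),
            log2_fold=l2f,
            ortho_class=classes[i],
        )
    truth = TruthSet(genes=truth_genes)
    truth.validate()
    return refA, refB, focal, OrthologTable(rows), truth


def simulate_contigs(
    focal: Mapping[str, str],
    config: SimConfig,
    truth: TruthSet | None = None,
) -> tuple[dict[str, str], dict[str, ContigTruth]]:
    """De-novo-assembly stand-in: substring contigs for a fraction of genes.

    Each focal transcript is covered with probability ``contig_coverage``;
    a covered transcript is split into ``1 + Poisson(contig_fragmentation_rate)``
    disjoint pieces (cut points at least one read length apart, so every
    fragment stays alignable).  When *truth* is given, covered flags and the
    contig map are recorded on it.
    """
    config.validate()
    if not focal:
        raise ExpressionError("focal transcriptome is empty")
    rng = _rng(config, "contigs")
    contigs: dict[str, str] = {}
    contig_truth: dict[str, ContigTruth] = {}
    min_frag = config.read_length
    for gene, seq in focal.items():
        if rng.random() >= config.contig_coverage:
            continue
        L = len(seq)
        n_cuts = int(rng.poisson(config.contig_fragmentation_rate))
        cuts: list[int] = []
        if n_cuts:
            prev = 0
            for c in sorted(int(x) for x in rng.integers(1, L, n_cuts)):
                if c - prev >= min_frag and L - c >= min_frag:
                    cuts.append(c)
                    prev = c
        bounds = [0, *cuts, L]
        for i in range(len(bounds) - 1):
            a, b = bounds[i], bounds[i + 1]
            cid = f"{gene}_c{i}"
            contigs[cid] = seq[a:b]
            contig_truth[cid] = ContigTruth(cid, gene, a, b)
        if truth is not None and gene in truth.genes:
            truth.genes[gene].covered = True
    if truth is not None:
        truth.contigs.update(contig_truth)
    return contigs, contig_truth


def simulate_reads(
    source: Mapping[str, str],
    expression: Mapping[str, float],
    config: SimConfig,
    n_reads: int | None = None,
    stream: str = "reads",
) -> list[FastqRead]:
    """Draw a 3'-tag read library from *source* sequences.

    Per-gene read counts are multinomial in *expression* (which must sum
    to 1 over genes present in *source*).  Read starts sit inside the final
    ``tag_window`` nt of the transcript with a geometric bias toward the 3'
    end, truncated at the transcript start for short transcripts.  A
    ``frac_artifact`` fraction of the library is replaced by poly-A/poly-T
    junk; substitution errors strike every read at ``error_rate`` per base.
    Use *stream* to draw independent libraries under one seed.
    """
    config.validate()
    if n_reads is None:
        n_reads = config.library_size_focal
    genes = list(expression)
    missing = [g for g in genes if g not in source]
    if missing:
        raise ExpressionError(f"expression genes absent from sequences: {missing[:5]}")
    p = np.asarray([expression[g] for g in genes], dtype=float)
    if (p < 0).any():
        raise ExpressionError("negative expression fraction")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ExpressionError(f"expression fractions sum to {p.sum()}, not 1")
    R = config.read_length
    too_short = [g for g in genes if len(source[g]) < R and expression[g] > 0]
    if too_short:
        raise ExpressionError(f"sequences shorter than read_length: {too_short[:5]}")

    rng = _rng(config, stream)
    n_artifact = int(rng.binomial(n_reads, config.frac_artifact)) if config.frac_artifact else 0
    counts = rng.multinomial(n_reads - n_artifact, p) if n_reads > n_artifact else np.zeros(len(p), dtype=int)

    reads: list[FastqRead] = []
    serial = 0
    for gene, c in zip(genes, counts):
        c = int(c)
        if c == 0:
            continue
        seq = source[gene]
        L = len(seq)
        smin = max(0, L - config.tag_window)
        smax = L - R
        offs = rng.geometric(config.tag_decay, c) - 1
        starts = np.clip(L - R - offs, smin, smax)
        nerr = rng.binomial(R, config.error_rate, c) if config.error_rate > 0 else np.zeros(c, dtype=int)
        for j in range(c):
            s = int(starts[j])
            rseq = seq[s : s + R]
            if nerr[j]:
                rseq = _inject_errors(rseq, int(nerr[j]), rng)
            reads.append(FastqRead(f"r{serial:07d}|{gene}|{s}", rseq))
            serial += 1
    for _ in range(n_artifact):
        base = "A" if rng.random() < 0.5 else "T"
        rseq = base * R
        ne = int(rng.binomial(R, config.error_rate)) if config.error_rate > 0 else 0
        if ne:
            rseq = _inject_errors(rseq, ne, rng)
        reads.append(FastqRead(f"r{serial:07d}|*|poly{base}", rseq))
        serial += 1
    return reads


def _inject_errors(seq: str, n_errors: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(n_errors, len(chars)), replace=False)
    for pos in positions:
        old = chars[pos]
        idx = "ACGT".find(old)
        if idx < 0:
            idx = 0
        chars[pos] = "ACGT"[(idx + int(rng.integers(1, 4))) % 4]
    return "".join(chars)
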