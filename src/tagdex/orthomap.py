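"""Contig-to-gene assignment via e-value disambiguation across two references.

A focal-species contig is aligned (BLAST tabular input or the built-in
k-mer chaining substitute) against two annotated transcriptomes: reference A
(well annotated, more diverged) and reference B (closer, bridged to A by
1:1 orthology).  A contig is assigned to a single reference-A gene when its
best hit is either the sole significant one or clearly better than the
runner-up; hits reached through a reference-B gene without a usable 1:1
partner invalidate the assignment.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

REF_A = "refA"
REF_B = "refB"

CARD_ONE2ONE = "one2one"
CARD_ONE2MANY = "one2many"
CARD_NONE = "none"
CARDINALITIES = frozenset({CARD_ONE2ONE, CARD_ONE2MANY, CARD_NONE})

STATUS_UNIQUE = "UNIQUE"
STATUS_CLEAR_BEST = "CLEAR_BEST"
STATUS_AMBIGUOUS = "AMBIGUOUS"
STATUS_NO_SIGNIFICANT_HIT = "NO_SIGNIFICANT_HIT"
STATUS_ORTHOLOGY_FAIL = "ORTHOLOGY_FAIL"

ASSIGNED_STATUSES = frozenset({STATUS_UNIQUE, STATUS_CLEAR_BEST})

_EVALUE_FLOOR = 1e-300
_LOG10_2 = math.log10(2.0)


class OrthologyError(ValueError):
    """Ortholog table rows inconsistent with their cardinality labels."""


class BlastParseError(ValueError):
    """Malformed tabular BLAST input."""


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class OrthologRow:
    refB_gene: str
    refA_gene: str | None
    cardinality: str


class OrthologTable:
    """refB gene -> refA gene map with orthology cardinality labels.

    Validates that row multiplicity agrees with the labels: a ``one2one``
    refB gene has exactly one refA partner, ``one2many`` has more than one,
    and ``none`` has no partner.
    """

    def __init__(self, rows: Iterable[OrthologRow]):
        self.rows: list[OrthologRow] = list(rows)
        by_b: dict[str, list[OrthologRow]] = defaultdict(list)
        for row in self.rows:
            if row.cardinality not in CARDINALITIES:
                raise OrthologyError(
                    f"unknown cardinality {row.cardinality!r} for {row.refB_gene}"
                )
            by_b[row.refB_gene].append(row)
        self._map: dict[str, tuple[str, tuple[str, ...]]] = {}
        for gene_b, grp in by_b.items():
            cards = {r.cardinality for r in grp}
            if len(cards) != 1:
                raise OrthologyError(f"{gene_b}: mixed cardinality labels {cards}")
            card = cards.pop()
            partners = tuple(r.refA_gene for r in grp if r.refA_gene)
            if card == CARD_ONE2ONE and len(partners) != 1:
                raise OrthologyError(
                    f"{gene_b}: labeled one2one but has {len(partners)} refA partners"
                )
            if card == CARD_ONE2MANY and len(partners) < 2:
                raise OrthologyError(
                    f"{gene_b}: labeled one2many but has {len(partners)} refA partners"
                )
            if card == CARD_NONE and partners:
                raise OrthologyError(f"{gene_b}: labeled none but has refA partners")
            self._map[gene_b] = (card, partners)

    def lookup(self, refB_gene: str) -> tuple[str | None, tuple[str, ...]]:
        """Return (cardinality, refA partners); (None, ()) for unknown genes."""
        return self._map.get(refB_gene, (None, ()))

    def one2one_partner(self, refB_gene: str) -> str | None:
        card, partners = self.lookup(refB_gene)
        if card == CARD_ONE2ONE:
            return partners[0]
        return None

    def __len__(self) -> int:
        return len(self._map)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("refB_gene\trefA_gene\tcardinality\n")
            for row in self.rows:
                fh.write(f"{row.refB_gene}\t{row.refA_gene or ''}\t{row.cardinality}\n")

    @classmethod
    def read_tsv(cls, path) -> "OrthologTable":
        rows = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("refB_gene"):
                raise OrthologyError(f"{path}: missing header line")
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise OrthologyError(f"{path}: bad row {line!r}")
                rows.append(OrthologRow(parts[0], parts[1] or None, parts[2]))
        return cls(rows)


@dataclass(frozen=True)
class BlastHit:
    """One query/subject similarity hit (tabular BLAST semantics)."""

    query: str
    subject: str
    species: str | None
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.evalue < 0:
            raise InputError(f"negative e-value for {self.query}/{self.subject}")


@dataclass(frozen=True)
class ContigAssignment:
    contig: str
    gene: str | None
    status: str
    best_evalue: float | None = None

    def __post_init__(self):
        if (self.gene is not None) != (self.status in ASSIGNED_STATUSES):
            raise InputError(
                f"{self.contig}: gene presence inconsistent with status {self.status}"
            )


def load_blast_tab(path, species_of: Mapping[str, str]) -> list[BlastHit]:
    """Parse 12-column tabular BLAST output (outfmt-6 dialect).

    Column 11 is the e-value, column 12 the bit score.  Subject species are
    taken from *species_of*; a subject missing from the map is an error.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise BlastParseError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, got {len(parts)}"
                )
            query, subject = parts[0], parts[1]
            try:
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise BlastParseError(f"{path}:{lineno}: non-numeric field: {exc}") from None
            if subject not in species_of:
                raise InputError(f"subject {subject!r} absent from species map")
            hits.append(BlastHit(query, subject, species_of[subject], evalue, bitscore))
    return hits


def _pseudo_evalue(matched_bases: int, query_len: int, db_len: int) -> tuple[float, float]:
    """(e-value, bitscore) for an ungapped chain covering *matched_bases*."""
    score = 2.0 * matched_bases
    log10_e = math.log10(query_len) + math.log10(db_len) - score * _LOG10_2
    evalue = 10.0 ** log10_e if log10_e > -300 else _EVALUE_FLOOR
    return evalue, score


def hits_builtin(
    contigs: Mapping[str, str],
    cdnas: Mapping[str, str],
    k: int = 11,
    species_of: Mapping[str, str] | None = None,
) -> list[BlastHit]:
    """Desk-scale similarity search standing in for an external BLAST run.

    For each contig x cDNA pair, shared k-mers are binned by diagonal and the
    best diagonal's coverage of the contig gives the matched-base count; the
    pseudo-bitscore is ``2 * matched_bases`` and the pseudo-e-value
    ``m * n * 2**-S`` (query length m, database length n), floored at 1e-300.
    Deterministic; pairs sharing no k-mer emit no hit.
    """
    if k < 8:
        raise InputError(f"seed length k must be >= 8, got {k}")
    if not cdnas:
        return []
    db_len = sum(len(s) for s in cdnas.values())
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for sid, seq in cdnas.items():
        for pos in range(len(seq) - k + 1):
            index[seq[pos : pos + k]].append((sid, pos))

    hits: list[BlastHit] = []
    for qid, qseq in contigs.items():
        m = len(qseq)
        diag_matches: dict[tuple[str, int], list[int]] = defaultdict(list)
        for qpos in range(m - k + 1):
            for sid, spos in index.get(qseq[qpos : qpos + k], ()):
                diag_matches[(sid, spos - qpos)].append(qpos)
        best_per_subject: dict[str, int] = {}
        for (sid, _diag), qpositions in diag_matches.items():
            covered = _interval_cover(qpositions, k)
            if covered > best_per_subject.get(sid, 0):
                best_per_subject[sid] = covered
        for sid, matched in sorted(best_per_subject.items()):
            evalue, score = _pseudo_evalue(matched, m, db_len)
            species = species_of.get(sid) if species_of is not None else None
            hits.append(BlastHit(qid, sid, species, evalue, score))
    return hits


def _interval_cover(starts: Sequence[int], k: int) -> int:
    """Total bases covered by the union of [s, s+k) intervals."""
    total = 0
    prev_end = -1
    for s in sorted(starts):
        end = s + k
        if s >= prev_end:
            total += k
        elif end > prev_end:
            total += end - prev_end
        prev_end = max(prev_end, end)
    return total


def _classify_evalues(evalues: Sequence[float], e_max: float, clearance: float) -> str:
    """Disambiguation rule on sorted-or-not per-gene best e-values."""
    if not evalues:
        return STATUS_NO_SIGNIFICANT_HIT
    evs = sorted(evalues)
    best = evs[0]
    if len(evs) == 1:
        return STATUS_UNIQUE if best < e_max else STATUS_NO_SIGNIFICANT_HIT
    if best >= e_max:
        return STATUS_AMBIGUOUS
    second = evs[1]
    if best == 0.0:
        return STATUS_CLEAR_BEST if second > 0.0 else STATUS_AMBIGUOUS
    return STATUS_CLEAR_BEST if best * clearance <= second else STATUS_AMBIGUOUS


def classify_contig(
    hits: Sequence[BlastHit],
    e_max: float = 0.05,
    clearance: float = 100.0,
    gene_of: Callable[[str], str] | None = None,
) -> ContigAssignment:
    """Classify one contig's hits before any orthology combination.

    Hits are first collapsed to one best (minimum e-value) hit per subject
    gene so that multiple HSPs or transcripts of the same gene do not compete
    with each other.  The contig is UNIQUE when a single gene is hit below
    *e_max*, CLEAR_BEST when the best gene's e-value is below *e_max* and at
    least *clearance*-fold smaller than the runner-up's, AMBIGUOUS otherwise,
    and NO_SIGNIFICANT_HIT when nothing qualifies.
    """
    queries = {h.query for h in hits}
    if len(queries) > 1:
        raise InputError(f"hits span multiple queries: {sorted(queries)}")
    if not hits:
        raise InputError("classify_contig requires at least one hit; use "
                         "combine_dual_reference for hitless contigs")
    contig = next(iter(queries))
    per_gene: dict[str, float] = {}
    for h in hits:
        gene = gene_of(h.subject) if gene_of is not None else h.subject
        if gene not in per_gene or h.evalue < per_gene[gene]:
            per_gene[gene] = h.evalue
    status = _classify_evalues(list(per_gene.values()), e_max, clearance)
    if status in ASSIGNED_STATUSES:
        winner = min(per_gene, key=lambda g: (per_gene[g], g))
        return ContigAssignment(contig, winner, status, per_gene[winner])
    best = min(per_gene.values()) if per_gene else None
    return ContigAssignment(contig, None, status, best)


def combine_dual_reference(
    hits: Iterable[BlastHit],
    orthologs: OrthologTable,
    e_max: float = 0.05,
    clearance: float = 100.0,
    mode: str = "pooled",
    all_queries: Iterable[str] | None = None,
) -> dict[str, ContigAssignment]:
    """Assign contigs to reference-A genes using hits against both references.

    Pooled mode (default): refB subjects with a 1:1 refA ortholog are merged
    into that refA gene's ortholog group; refB subjects without a usable 1:1
    partner form their own group.  Groups keep their minimum e-value and the
    disambiguation rule runs at group level.  A winning group that exists
    only through a non-1:1 refB gene yields ORTHOLOGY_FAIL.

    Per-species mode: each reference is classified separately; the species
    holding the overall best e-value decides, with refB winners translated
    through 1:1 orthology (failing to ORTHOLOGY_FAIL when impossible).
    """
    if mode not in ("pooled", "per_species"):
        raise InputError(f"unknown mode {mode!r}")
    by_query: dict[str, list[BlastHit]] = defaultdict(list)
    for h in hits:
        if h.species not in (REF_A, REF_B):
            raise InputError(f"hit {h.query}/{h.subject} lacks a refA/refB species label")
        by_query[h.query].append(h)

    out: dict[str, ContigAssignment] = {}
    for contig, qhits in by_query.items():
        if mode == "pooled":
            out[contig] = _combine_pooled(contig, qhits, orthologs, e_max, clearance)
        else:
            out[contig] = _combine_per_species(contig, qhits, orthologs, e_max, clearance)
    if all_queries is not None:
        for contig in all_queries:
            if contig not in out:
                out[contig] = ContigAssignment(contig, None, STATUS_NO_SIGNIFICANT_HIT)
    return out


def _combine_pooled(contig, qhits, orthologs, e_max, clearance) -> ContigAssignment:
    # group key -> (min e-value, refA gene or None)
    groups: dict[tuple[str, str], tuple[float, str | None]] = {}
    for h in qhits:
        if h.species == REF_A:
            key, gene = (REF_A, h.subject), h.subject
        else:
            partner = orthologs.one2one_partner(h.subject)
            if partner is not None:
                key, gene = (REF_A, partner), partner
            else:
                key, gene = (REF_B, h.subject), None
        prev = groups.get(key)
        if prev is None or h.evalue < prev[0]:
            groups[key] = (h.evalue, gene)
    status = _classify_evalues([ev for ev, _ in groups.values()], e_max, clearance)
    best_key = min(groups, key=lambda kk: (groups[kk][0], kk))
    best_ev, best_gene = groups[best_key]
    if status in ASSIGNED_STATUSES:
        if best_gene is None:
            return ContigAssignment(contig, None, STATUS_ORTHOLOGY_FAIL, best_ev)
        return ContigAssignment(contig, best_gene, status, best_ev)
    return ContigAssignment(contig, None, status, best_ev)


def _combine_per_species(contig, qhits, orthologs, e_max, clearance) -> ContigAssignment:
    split = {REF_A: [], REF_B: []}
    for h in qhits:
        split[h.species].append(h)
    best_by_species = {
        sp: min(h.evalue for h in hh) for sp, hh in split.items() if hh
    }
    winner_species = min(best_by_species, key=lambda sp: (best_by_species[sp], sp))
    asg = classify_contig(split[winner_species], e_max=e_max, clearance=clearance)
    if asg.status not in ASSIGNED_STATUSES:
        return asg
    if winner_species == REF_A:
        return asg
    partner = orthologs.one2one_partner(asg.gene)
    if partner is None:
        return ContigAssignment(contig, None, STATUS_ORTHOLOGY_FAIL, asg.best_evalue)
    return ContigAssignment(contig, partner, asg.status, asg.best_evalue)


def background_genes(assignments: Iterable[ContigAssignment]) -> set[str]:
    """Distinct reference-A genes holding at least one assigned contig.

    This set doubles as the universe for over-representation testing.
    """
    return {a.gene for a in assignments if a.gene is not None}


def contig_gene_map(assignments: Iterable[ContigAssignment]) -> dict[str, str]:
    """contig -> assigned refA gene, assigned contigs only."""
    return {a.contig: a.gene for a in assignments if a.gene is not None}


def write_assignments_tsv(assignments: Iterable[ContigAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tgene\tstatus\tbest_evalue\n")
        for a in sorted(assignments, key=lambda x: x.contig):
            ev = "" if a.best_evalue is None else f"{a.best_evalue:.3g}"
            fh.write(f"{a.contig}\t{a.gene or ''}\t{a.status}\t{ev}\n")
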