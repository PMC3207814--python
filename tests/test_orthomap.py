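import itertools
import math

import numpy as np
import pytest

from tagdex.orthomap import (
    CARD_NONE,
    CARD_ONE2MANY,
    CARD_ONE2ONE,
    REF_A,
    REF_B,
    STATUS_AMBIGUOUS,
    STATUS_CLEAR_BEST,
    STATUS_NO_SIGNIFICANT_HIT,
    STATUS_ORTHOLOGY_FAIL,
    STATUS_UNIQUE,
    BlastHit,
    BlastParseError,
    ContigAssignment,
    InputError,
    OrthologRow,
    OrthologTable,
    OrthologyError,
    background_genes,
    classify_contig,
    combine_dual_reference,
    hits_builtin,
    load_blast_tab,
)
from tagdex.simulate import (
    CLASS_ONE2ONE,
    CLASS_PARALOG,
    CLASS_REFB_ONLY,
    SimConfig,
    simulate_contigs,
    simulate_transcriptomes,
)


def hit(query, subject, evalue, species=REF_A, bitscore=50.0):
    return BlastHit(query, subject, species, evalue, bitscore)


class TestOrthologTable:
    def test_roundtrip(self, tmp_path):
        rows = [
            OrthologRow("b1", "a1", CARD_ONE2ONE),
            OrthologRow("b2", "a2", CARD_ONE2MANY),
            OrthologRow("b2", "a3", CARD_ONE2MANY),
            OrthologRow("b3", None, CARD_NONE),
        ]
        table = OrthologTable(rows)
        path = tmp_path / "orth.tsv"
        table.write_tsv(path)
        again = OrthologTable.read_tsv(path)
        assert again.lookup("b1") == (CARD_ONE2ONE, ("a1",))
        assert again.lookup("b2") == (CARD_ONE2MANY, ("a2", "a3"))
        assert again.lookup("b3") == (CARD_NONE, ())
        assert again.lookup("nope") == (None, ())

    @pytest.mark.parametrize(
        "rows",
        [
            [OrthologRow("b", "a1", CARD_ONE2ONE), OrthologRow("b", "a2", CARD_ONE2ONE)],
            [OrthologRow("b", "a1", CARD_ONE2MANY)],
            [OrthologRow("b", "a1", CARD_NONE)],
            [OrthologRow("b", "a1", CARD_ONE2ONE), OrthologRow("b", "a2", CARD_ONE2MANY)],
            [OrthologRow("b", "a1", "weird")],
        ],
    )
    def test_inconsistent_rows_rejected(self, rows):
        with pytest.raises(OrthologyError):
            OrthologTable(rows)


class TestLoadBlastTab:
    LINE = "c1\ts1\t98.5\t100\t1\t0\t1\t100\t5\t104\t{e}\t180.3\n"

    def test_single_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.LINE.format(e="1e-50"))
        hits = load_blast_tab(p, {"s1": REF_A})
        assert len(hits) == 1
        h = hits[0]
        assert (h.query, h.subject, h.species) == ("c1", "s1", REF_A)
        assert h.evalue == 1e-50 and h.bitscore == 180.3

    def test_tiny_evalue_parsed(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.LINE.format(e="1e-180"))
        assert load_blast_tab(p, {"s1": REF_A})[0].evalue == 1e-180

    def test_unknown_subject_named(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.LINE.format(e="1e-10"))
        with pytest.raises(InputError, match="s1"):
            load_blast_tab(p, {"other": REF_A})

    def test_nonnumeric_evalue_line_number(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.LINE.format(e="1e-9") + self.LINE.format(e="oops"))
        with pytest.raises(BlastParseError, match=":2:"):
            load_blast_tab(p, {"s1": REF_A})

    def test_too_few_columns(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("c1\ts1\t1e-5\n")
        with pytest.raises(BlastParseError, match=":1:"):
            load_blast_tab(p, {"s1": REF_A})


class TestHitsBuiltin:
    def test_self_match_dominates(self, rng):
        seqs = {f"d{i}": "".join(rng.choice(list("ACGT"), 500)) for i in range(4)}
        contig = {"c0": seqs["d2"]}
        hits = hits_builtin(contig, seqs, k=11)
        best = min(hits, key=lambda h: h.evalue)
        assert best.subject == "d2"

    def test_no_shared_kmers_no_hit(self):
        hits = hits_builtin({"c": "A" * 100}, {"d": "C" * 100}, k=11)
        assert hits == []

    def test_double_matched_bases_smaller_evalue(self):
        # construct shared blocks of 22 vs 44 identical bases on fixed diagonals
        rng = np.random.default_rng(8)
        block = "".join(rng.choice(list("ACGT"), 44))
        contig = {"c": block + "".join(rng.choice(list("ACGT"), 100))}
        cdnas = {
            "half": block[:22] + "".join(rng.choice(list("ACGT"), 122)),
            "full": block + "".join(rng.choice(list("ACGT"), 100)),
        }
        hits = {h.subject: h for h in hits_builtin(contig, cdnas, k=11)}
        assert hits["full"].evalue < hits["half"].evalue
        # direct formula: e = m * n * 2**-S with S = 2 * matched bases
        m = len(contig["c"])
        n = sum(len(s) for s in cdnas.values())
        expected = m * n * 2.0 ** (-2 * 22)
        assert hits["half"].evalue == pytest.approx(expected, rel=1e-9)

    def test_k_too_small_rejected(self):
        with pytest.raises(InputError):
            hits_builtin({"c": "ACGT" * 10}, {"d": "ACGT" * 10}, k=4)


class TestClassifyContig:
    def test_single_significant_unique(self):
        asg = classify_contig([hit("c", "g1", 0.01)])
        assert asg.status == STATUS_UNIQUE and asg.gene == "g1"

    def test_three_orders_clear_best(self):
        asg = classify_contig([hit("c", "g1", 1e-8), hit("c", "g2", 1e-5)])
        assert asg.status == STATUS_CLEAR_BEST and asg.gene == "g1"

    def test_one_order_ambiguous(self):
        asg = classify_contig([hit("c", "g1", 1e-8), hit("c", "g2", 1e-7)])
        assert asg.status == STATUS_AMBIGUOUS and asg.gene is None

    def test_exactly_two_orders_inclusive(self):
        asg = classify_contig([hit("c", "g1", 1e-7), hit("c", "g2", 1e-5)])
        assert asg.status == STATUS_CLEAR_BEST

    def test_single_insignificant(self):
        asg = classify_contig([hit("c", "g1", 0.2)])
        assert asg.status == STATUS_NO_SIGNIFICANT_HIT

    def test_zero_evalue_handling(self):
        assert classify_contig([hit("c", "g1", 0.0), hit("c", "g2", 1e-200)]).status \
            == STATUS_CLEAR_BEST
        assert classify_contig([hit("c", "g1", 0.0), hit("c", "g2", 0.0)]).status \
            == STATUS_AMBIGUOUS

    def test_per_gene_collapse_no_self_competition(self):
        # two HSPs on the same gene must not make the contig ambiguous
        asg = classify_contig([hit("c", "g1", 1e-30), hit("c", "g1", 1e-28)])
        assert asg.status == STATUS_UNIQUE and asg.gene == "g1"

    def test_mixed_queries_rejected(self):
        with pytest.raises(InputError):
            classify_contig([hit("c1", "g1", 1e-5), hit("c2", "g2", 1e-5)])

    def test_clearance_monotonicity(self):
        """Raising clearance never converts AMBIGUOUS to CLEAR_BEST."""
        grid = [0.0, 1e-10, 1e-8, 1e-6, 1e-4, 1e-2, 1.0]
        for e1, e2 in itertools.product(grid, repeat=2):
            hits = [hit("c", "g1", e1), hit("c", "g2", e2)]
            prev_clear = None
            for clearance in (10.0, 100.0, 1000.0, 1e6):
                status = classify_contig(hits, clearance=clearance).status
                is_clear = status == STATUS_CLEAR_BEST
                if prev_clear is False:
                    assert not is_clear
                prev_clear = is_clear


def oracle_status(evalues, e_max=0.05, clearance=100.0):
    """Literal enumeration of the published disambiguation rule."""
    evs = sorted(evalues)
    if not evs:
        return STATUS_NO_SIGNIFICANT_HIT
    if len(evs) == 1:
        return STATUS_UNIQUE if evs[0] < e_max else STATUS_NO_SIGNIFICANT_HIT
    best, second = evs[0], evs[1]
    if best < e_max:
        if best == 0.0 and second > 0.0:
            return STATUS_CLEAR_BEST
        if best > 0.0 and best * clearance <= second:
            return STATUS_CLEAR_BEST
    return STATUS_AMBIGUOUS


def test_classify_agrees_with_enumeration_oracle():
    grid = [0.0] + [10.0 ** -e for e in range(10, -1, -1)]
    for size in (1, 2, 3, 4):
        for combo in itertools.combinations_with_replacement(grid, size):
            hits = [hit("c", f"g{i}", e) for i, e in enumerate(combo)]
            assert classify_contig(hits).status == oracle_status(combo)


class TestCombineDualReference:
    TABLE = OrthologTable([
        OrthologRow("gb1", "ga1", CARD_ONE2ONE),
        OrthologRow("gb2", "ga2", CARD_ONE2MANY),
        OrthologRow("gb2", "ga3", CARD_ONE2MANY),
        OrthologRow("gb3", None, CARD_NONE),
    ])

    def test_refb_one2one_translated(self):
        hits = [hit("c", "gb1", 1e-20, REF_B), hit("c", "ga9", 1e-5, REF_A)]
        asg = combine_dual_reference(hits, self.TABLE)["c"]
        assert asg.gene == "ga1" and asg.status == STATUS_CLEAR_BEST

    def test_refb_one2many_orthology_fail(self):
        hits = [hit("c", "gb2", 1e-20, REF_B), hit("c", "ga9", 1e-5, REF_A)]
        asg = combine_dual_reference(hits, self.TABLE)["c"]
        assert asg.status == STATUS_ORTHOLOGY_FAIL and asg.gene is None

    def test_refb_no_ortholog_orthology_fail(self):
        hits = [hit("c", "gb3", 1e-40, REF_B)]
        asg = combine_dual_reference(hits, self.TABLE)["c"]
        assert asg.status == STATUS_ORTHOLOGY_FAIL

    def test_group_collapse_gene_and_own_ortholog_unique(self):
        # refA gene and its own 1:1 refB partner are one group -> UNIQUE
        hits = [hit("c", "ga1", 1e-20, REF_A), hit("c", "gb1", 1e-19, REF_B)]
        asg = combine_dual_reference(hits, self.TABLE)["c"]
        assert asg.status == STATUS_UNIQUE and asg.gene == "ga1"

    def test_ambiguous_between_two_groups(self):
        hits = [hit("c", "ga1", 1e-8, REF_A), hit("c", "ga2", 1e-7, REF_A)]
        asg = combine_dual_reference(hits, self.TABLE)["c"]
        assert asg.status == STATUS_AMBIGUOUS

    def test_hitless_query_reported(self):
        out = combine_dual_reference([], self.TABLE, all_queries=["lonely"])
        assert out["lonely"].status == STATUS_NO_SIGNIFICANT_HIT

    def test_missing_species_rejected(self):
        with pytest.raises(InputError):
            combine_dual_reference([hit("c", "x", 1e-5, None)], self.TABLE)

    def test_per_species_mode_translates(self):
        hits = [hit("c", "gb1", 1e-20, REF_B), hit("c", "ga9", 1e-4, REF_A)]
        asg = combine_dual_reference(hits, self.TABLE, mode="per_species")["c"]
        assert asg.gene == "ga1"


class TestBackgroundGenes:
    def test_duplicates_collapse(self):
        asgs = [
            ContigAssignment("c1", "A", STATUS_UNIQUE),
            ContigAssignment("c2", "A", STATUS_CLEAR_BEST),
            ContigAssignment("c3", "B", STATUS_UNIQUE),
            ContigAssignment("c4", None, STATUS_AMBIGUOUS),
        ]
        assert background_genes(asgs) == {"A", "B"}

    def test_empty(self):
        assert background_genes([]) == set()


class TestSimulatedAssignment:
    def test_zero_divergence_background_equals_gene_set(self, clean_config):
        refA, refB, focal, orth, truth = simulate_transcriptomes(clean_config)
        contigs, _ = simulate_contigs(focal, clean_config, truth=truth)
        species_of = {s: REF_A for s in refA} | {s: REF_B for s in refB}
        hits = hits_builtin(contigs, {**refA, **refB}, k=11, species_of=species_of)
        asgs = combine_dual_reference(hits, orth, all_queries=contigs)
        assert background_genes(asgs.values()) == set(truth.genes)
        for cid, asg in asgs.items():
            assert asg.gene == truth.contigs[cid].gene

    def test_paralogs_ambiguous_at_zero_divergence(self):
        cfg = SimConfig(
            n_genes=30, div_focal_refA=0.0, div_focal_refB=0.0,
            frac_one_to_one=0.6, frac_refB_only=0.0, frac_paralog=0.4,
            contig_coverage=1.0, contig_fragmentation_rate=0.0,
            n_de_genes=0, seed=13,
        )
        refA, refB, focal, orth, truth = simulate_transcriptomes(cfg)
        contigs, _ = simulate_contigs(focal, cfg, truth=truth)
        species_of = {s: REF_A for s in refA} | {s: REF_B for s in refB}
        hits = hits_builtin(contigs, {**refA, **refB}, k=11, species_of=species_of)
        asgs = combine_dual_reference(hits, orth, all_queries=contigs)
        paralog_contigs = [
            cid for cid, ct in truth.contigs.items()
            if truth.genes[ct.gene].ortho_class == CLASS_PARALOG
        ]
        assert paralog_contigs
        for cid in paralog_contigs:
            assert asgs[cid].status == STATUS_AMBIGUOUS
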