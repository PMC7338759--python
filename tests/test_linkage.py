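"""Promoters, the three evidence types, the linkage score, and integration."""

import warnings
from types import SimpleNamespace

import pytest
from hypothesis import given
from hypothesis import strategies as st

from enhlink.catalog import Enhancer
from enhlink.core import ChromatinContact, GeneRecord, GenomicInterval, center
from enhlink.linkage import (
    Promoter,
    TargetLink,
    contact_evidence,
    derive_promoter,
    distance_evidence_mirna,
    distance_evidence_mrna,
    dual_target_enhancers,
    integrate_links,
    linkage_score,
    tad_evidence,
    validate_tads,
)
from enhlink.simulate import load_table1, make_table1_fixture, table1_links


def gene(gene_id, chrom, tss, biotype="protein_coding", strand="+"):
    body = (
        GenomicInterval(chrom, tss, tss + 1000, strand)
        if strand == "+"
        else GenomicInterval(chrom, tss - 999, tss + 1, strand)
    )
    return GeneRecord(gene_id, chrom, tss, strand, biotype, body)


def enhancer(chrom, start, end, name="E"):
    return Enhancer(GenomicInterval(chrom, start, end, name=name), "merged", 1.0)


def promoter_at(chrom, start, end, gene_id="g", tss=None):
    tss = start if tss is None else tss
    return Promoter(gene_id, GenomicInterval(chrom, start, end), tss, "+")


class TestDerivePromoter:
    def test_plus_strand_window(self):
        p = derive_promoter(gene("g", "chr1", 10_000, strand="+"))
        assert (p.interval.start, p.interval.end) == (9000, 10_500)

    def test_minus_strand_reflected(self):
        p = derive_promoter(gene("g", "chr1", 10_000, strand="-"))
        assert (p.interval.start, p.interval.end) == (9500, 11_000)

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("tss", [1500, 40_000, 999_999])
    def test_length_always_1500(self, strand, tss):
        p = derive_promoter(gene("g", "chr1", tss, strand=strand))
        assert p.interval.length == 1500

    def test_clipped_at_chromosome_start_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            p = derive_promoter(gene("g", "chr1", 600, strand="+"))
        assert p.interval.start == 0
        assert p.interval.length < 1500

    def test_unknown_strand_rejected(self):
        fake = SimpleNamespace(gene_id="g", chrom="chr1", tss=5000, strand=".")
        with pytest.raises(ValueError, match="strand"):
            derive_promoter(fake)


class TestTadEvidence:
    TADS = [GenomicInterval("chr1", 0, 1_000_000),
            GenomicInterval("chr1", 1_000_000, 2_000_000)]

    def test_same_tad_true(self):
        e = enhancer("chr1", 100_000, 100_600)
        p = promoter_at("chr1", 500_000, 501_500)
        assert tad_evidence(e, p, self.TADS) is True

    def test_adjacent_tads_false(self):
        e = enhancer("chr1", 100_000, 100_600)
        p = promoter_at("chr1", 1_500_000, 1_501_500)
        assert tad_evidence(e, p, self.TADS) is False

    def test_tss_outside_any_tad_false(self):
        e = enhancer("chr1", 100_000, 100_600)
        p = promoter_at("chr1", 2_500_000, 2_501_500)
        assert tad_evidence(e, p, self.TADS) is False

    def test_overlap_mode_accepts_boundary_straddler(self):
        # enhancer straddles the TAD border; center falls in the second TAD
        e = enhancer("chr1", 999_900, 1_000_300)
        p = promoter_at("chr1", 500_000, 501_500)
        assert tad_evidence(e, p, self.TADS, mode="point") is False
        assert tad_evidence(e, p, self.TADS, mode="overlap") is True

    def test_overlapping_tads_rejected(self):
        bad = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)]
        with pytest.raises(ValueError, match="overlapping TADs"):
            validate_tads(bad)


class TestContactEvidence:
    def test_exact_anchor_match(self):
        e = enhancer("chr1", 100, 700)
        p = promoter_at("chr1", 5000, 6500)
        c = ChromatinContact(GenomicInterval("chr1", 100, 700),
                             GenomicInterval("chr1", 5000, 6500))
        assert contact_evidence(e, p, [c]) is True
        swapped = ChromatinContact(c.anchor2, c.anchor1)
        assert contact_evidence(e, p, [swapped]) is True

    def test_empty_contact_list_false(self):
        assert contact_evidence(
            enhancer("chr1", 100, 700), promoter_at("chr1", 5000, 6500), []
        ) is False

    def test_agreement_with_per_base_oracle(self, rng):
        def rand_iv():
            s = int(rng.integers(0, 900))
            return GenomicInterval("chr1", s, s + int(rng.integers(1, 100)))

        def base_overlap(a, b):
            return a.chrom == b.chrom and bool(
                set(range(a.start, a.end)) & set(range(b.start, b.end))
            )

        for _ in range(20):
            s = int(rng.integers(0, 900))
            e = enhancer("chr1", s, s + int(rng.integers(1, 100)))
            s = int(rng.integers(0, 900))
            p = promoter_at("chr1", s, s + int(rng.integers(1, 100)))
            contacts = [ChromatinContact(rand_iv(), rand_iv()) for _ in range(50)]
            oracle = any(
                (base_overlap(c.anchor1, e.interval) and base_overlap(c.anchor2, p.interval))
                or (base_overlap(c.anchor2, e.interval) and base_overlap(c.anchor1, p.interval))
                for c in contacts
            )
            assert contact_evidence(e, p, contacts) is oracle


class TestLinkageScore:
    @pytest.mark.parametrize(
        "A, B, expected",
        [(5000, 5000, 0.0), (0, 7000, 1.0), (100_000, 150_000, 0.2), (7000, 0, -1.0)],
    )
    def test_examples(self, A, B, expected):
        assert linkage_score(A, B) == pytest.approx(expected)

    def test_degenerate_and_negative_rejected(self):
        with pytest.raises(ValueError):
            linkage_score(0, 0)
        with pytest.raises(ValueError):
            linkage_score(-1, 10)

    @given(st.integers(0, 10**7), st.integers(0, 10**7))
    def test_bounded_and_threshold_equivalence(self, A, B):
        if A + B == 0:
            return
        S = linkage_score(A, B)
        assert -1.0 <= S <= 1.0
        assert (S < 0.2) == (B < 1.5 * A)


class TestDistanceEvidenceMirna:
    def test_far_mirna_not_associated(self):
        # closest miRNA at 10 kb, closest other gene at 200 kb: S ~ 0.90
        e = enhancer("chr1", 499_700, 500_300)
        genes = [gene("m1", "chr1", 510_000, "miRNA"), gene("g1", "chr1", 700_000)]
        assert distance_evidence_mirna(e, genes) == []

    def test_exact_threshold_excluded(self):
        # A = 100 kb, B = 150 kb gives S = 0.2 exactly; "below" is strict
        e = enhancer("chr1", 499_700, 500_300)
        genes = [gene("m1", "chr1", 600_000, "miRNA"), gene("g1", "chr1", 650_000)]
        assert distance_evidence_mirna(e, genes) == []

    def test_association_reports_a_b_s(self):
        e = enhancer("chr1", 499_700, 500_300)
        genes = [gene("m1", "chr1", 502_000, "miRNA"), gene("g1", "chr1", 502_500)]
        [(mid, score)] = distance_evidence_mirna(e, genes)
        assert mid == "m1"
        assert (score.A, score.B) == (2000.0, 2500.0)
        assert score.S == pytest.approx(500 / 4500)

    def test_ties_return_all_closest_mirnas(self):
        e = enhancer("chr1", 499_700, 500_300)
        genes = [
            gene("m_b", "chr1", 502_000, "miRNA"),
            gene("m_a", "chr1", 498_000, "miRNA"),
            gene("g1", "chr1", 502_500),
        ]
        out = distance_evidence_mirna(e, genes)
        assert [mid for mid, _ in out] == ["m_a", "m_b"]  # gene_id order

    def test_variant_flag_requires_mirna_closer(self):
        # nearest other gene closer than nearest miRNA: S < 0 fires as printed
        e = enhancer("chr1", 499_700, 500_300)
        genes = [gene("m1", "chr1", 510_000, "miRNA"), gene("g1", "chr1", 501_000)]
        assert len(distance_evidence_mirna(e, genes)) == 1
        assert distance_evidence_mirna(e, genes, require_mirna_closer=True) == []

    def test_missing_biotype_warns_empty(self):
        e = enhancer("chr1", 499_700, 500_300)
        with pytest.warns(UserWarning, match="lacks"):
            assert distance_evidence_mirna(e, [gene("g1", "chr1", 501_000)]) == []

    def test_matches_brute_force_recomputation(self, rng):
        for _ in range(30):
            c = int(rng.integers(100_000, 900_000))
            e = enhancer("chr1", c - 300, c + 300)
            genes = []
            for i in range(int(rng.integers(2, 12))):
                biotype = "miRNA" if rng.random() < 0.4 else "protein_coding"
                genes.append(
                    gene(f"g{i}", "chr1", int(rng.integers(0, 10**6) + 1000), biotype)
                )
            mirna = [(abs(g.tss - c), g.gene_id) for g in genes if g.biotype == "miRNA"]
            other = [(abs(g.tss - c), g.gene_id) for g in genes if g.biotype != "miRNA"]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = distance_evidence_mirna(e, genes)
            if not mirna or not other:
                assert got == []
                continue
            A, B = min(mirna)[0], min(other)[0]
            S = (B - A) / (A + B)
            if S < 0.2:
                expect = sorted(g for d, g in mirna if d == A)
                assert [mid for mid, _ in got] == expect
                assert all(s.A == A and s.B == B for _, s in got)
            else:
                assert got == []


class TestDistanceEvidenceMrna:
    E = enhancer("chr1", 499_700, 500_300)

    def test_overlapping_promoter_true(self):
        assert distance_evidence_mrna(self.E, promoter_at("chr1", 500_000, 501_500))

    def test_boundary_inclusive(self):
        p = promoter_at("chr1", 600_300, 601_800)  # gap exactly 100,000
        assert distance_evidence_mrna(self.E, p) is True

    def test_one_bp_beyond_false(self):
        p = promoter_at("chr1", 600_301, 601_801)  # gap 100,001
        assert distance_evidence_mrna(self.E, p) is False

    def test_other_chromosome_false(self):
        assert distance_evidence_mrna(self.E, promoter_at("chr2", 500_000, 501_500)) is False


class ToyGenome:
    """Hand-built genome: one bound enhancer, four expected links."""

    TADS = [GenomicInterval("chrT", 0, 300_000),
            GenomicInterval("chrT", 300_000, 600_000),
            GenomicInterval("chrT", 600_000, 900_000)]
    E1 = enhancer("chrT", 99_700, 100_300, name="E1")  # center 100,000

    GENES = [
        gene("miR-a", "chrT", 102_000, "miRNA"),      # same TAD
        gene("miR-b", "chrT", 101_000, "miRNA"),      # closest miRNA: A=1000
        gene("geneY", "chrT", 101_300),               # closest other: B=1300
        gene("geneX", "chrT", 350_000),               # TAD2, contacted
        gene("geneZ", "chrT", 180_000),               # same TAD, within 100 kb
        gene("geneW", "chrT", 120_000),               # same TAD but NOT DE
        gene("miR-far", "chrT", 800_000, "miRNA"),    # DE but no evidence
    ]
    DE = {"miR-a": 2.5, "miR-b": -1.4, "geneX": 1.8, "geneZ": -2.2, "miR-far": 3.0}
    CONTACTS = [
        ChromatinContact(GenomicInterval("chrT", 99_700, 100_300),
                         GenomicInterval("chrT", 349_000, 350_500)),
        # hits miR-b's promoter [100000,101500) but stops short of miR-a's
        ChromatinContact(GenomicInterval("chrT", 99_700, 100_300),
                         GenomicInterval("chrT", 100_000, 100_900)),
    ]

    EXPECTED = {
        ("E1", "miR-a"): {"tad"},
        ("E1", "miR-b"): {"distance", "tad", "contact"},
        ("E1", "geneX"): {"contact"},
        ("E1", "geneZ"): {"distance", "tad"},
    }


class TestIntegrateLinks:
    def run(self, tads=None, contacts=None, de=None):
        g = ToyGenome
        return integrate_links(
            [g.E1], g.GENES, de if de is not None else g.DE,
            g.TADS if tads is None else tads,
            g.CONTACTS if contacts is None else contacts,
        )

    def test_toy_genome_links_and_evidence(self):
        links = {(l.enhancer_id, l.target_id): set(l.evidence) for l in self.run()}
        assert links == ToyGenome.EXPECTED

    def test_all_three_evidence_pair_present(self):
        links = {l.target_id: l for l in self.run()}
        assert links["miR-b"].evidence == frozenset({"distance", "tad", "contact"})
        assert links["miR-b"].target_type == "miRNA"

    def test_pair_without_evidence_absent(self):
        assert "miR-far" not in {l.target_id for l in self.run()}

    def test_no_leakage_of_non_de_targets(self):
        ids = {l.target_id for l in self.run()}
        assert ids <= set(ToyGenome.DE)
        assert "geneW" not in ids and "geneY" not in ids

    def test_union_superset_of_single_method_runs(self):
        full = {(l.enhancer_id, l.target_id) for l in self.run()}
        no_contacts = {(l.enhancer_id, l.target_id) for l in self.run(contacts=[])}
        far_tads = [GenomicInterval("chrOther", 0, 1000)]
        no_tads = {(l.enhancer_id, l.target_id) for l in self.run(tads=far_tads)}
        assert no_contacts <= full and no_tads <= full

    def test_evidence_monotone_in_contacts(self):
        sparse = {(l.enhancer_id, l.target_id) for l in self.run(contacts=[])}
        full = {(l.enhancer_id, l.target_id) for l in self.run()}
        assert sparse <= full

    def test_log2fc_carried_from_de_table(self):
        links = {l.target_id: l.log2fc for l in self.run()}
        assert links["geneZ"] == -2.2


class TestDualTargetEnhancers:
    def _link(self, eid, tid, ttype):
        return TargetLink(eid, tid, ttype, frozenset({"tad"}), 1.0)

    def test_mixed_targets_detected(self):
        links = [self._link("E1", "m1", "miRNA"), self._link("E1", "g1", "mRNA")]
        assert dual_target_enhancers(links) == [("E1", 1, 1)]

    def test_split_across_enhancers_empty(self):
        links = [self._link("E1", "m1", "miRNA"), self._link("E2", "g1", "mRNA")]
        assert dual_target_enhancers(links) == []


class TestPublishedLinkTable:
    def test_twenty_six_records(self):
        assert len(load_table1()) == 26

    def test_chr19_row_has_all_three_evidence_flags(self):
        df = load_table1(zero_based=False)
        row = df[(df.enhancer_chrom == "chr19") & (df.enhancer_start == 782_330)]
        assert len(row) == 1
        row = row.iloc[0]
        assert row.target_id == "hsa-miR-4745-5p"
        assert (row.evidence_distance, row.evidence_tad, row.evidence_contact) == (1, 1, 1)

    def test_mir16_row_values(self):
        df = load_table1(zero_based=False)
        row = df[(df.enhancer_chrom == "chr13") & (df.enhancer_start == 50_529_144)]
        assert set(row.target_id) == {"hsa-miR-16-5p", "hsa-miR-3613-5p"}
        assert float(row[row.target_id == "hsa-miR-16-5p"].log2fc.iloc[0]) == 3.12

    def test_every_row_carries_evidence(self):
        links = table1_links()
        assert len(links) == 26
        assert all(link.evidence for link in links)

    def test_reserialization_reproduces_26_records(self, tmp_path):
        out = tmp_path / "table1.tsv"
        df = make_table1_fixture(out)
        import pandas as pd

        reread = pd.read_csv(out, sep="\t", comment="#")
        assert len(reread) == 26
        assert reread.equals(df)

    def test_coordinate_conversion_is_one_based_to_zero_based(self):
        one = load_table1(zero_based=False)
        zero = load_table1(zero_based=True)
        assert (one.enhancer_start - zero.enhancer_start == 1).all()
        assert (one.enhancer_end == zero.enhancer_end).all()
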