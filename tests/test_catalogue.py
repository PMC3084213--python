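import random

import pytest

from cincat.catalogue import (
    CINCatalogue,
    CatalogueRecord,
    GeneMeta,
    ScreenHit,
    classify_confidence,
    integrate_screens,
    read_catalogue,
    read_gene_meta,
    read_screen_table,
    summarize,
    write_catalogue,
)
from cincat.errors import ParseError, ValidationError

from conftest import tsv


class TestReadScreenTable:
    def test_direct_field_mapping(self):
        hits = read_screen_table(
            tsv("gene\tassay\tstrength\tsource\nYPR175W\tCTF\tSTRONG\tthis_study\n")
        )
        assert hits == [ScreenHit("YPR175W", "CTF", "STRONG", "this_study")]

    def test_unknown_assay_names_line(self):
        with pytest.raises(ParseError, match="line 2.*XYZ"):
            read_screen_table(
                tsv("gene\tassay\tstrength\tsource\nY1\tXYZ\tSTRONG\ts\n")
            )

    def test_unknown_strength_rejected(self):
        with pytest.raises(ParseError, match="strength"):
            read_screen_table(
                tsv("gene\tassay\tstrength\tsource\nY1\tCTF\tMEDIUM\ts\n")
            )

    def test_header_only_gives_empty_list(self):
        assert read_screen_table(tsv("gene\tassay\tstrength\tsource\n")) == []

    def test_duplicate_key_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            read_screen_table(
                tsv(
                    "gene\tassay\tstrength\tsource\n"
                    "Y1\tCTF\tSTRONG\ts\nY1\tCTF\tWEAK\ts\n"
                )
            )

    def test_missing_column_rejected(self):
        with pytest.raises(ParseError, match="missing"):
            read_screen_table(tsv("gene\tassay\tsource\nY1\tCTF\ts\n"))

    def test_optional_fields_parsed(self):
        hits = read_screen_table(
            tsv(
                "gene\tassay\tstrength\tsource\tallele\ttemperature\n"
                "Y1\tCTF\tWEAK\ts\ty1-1\t30\n"
            )
        )
        assert hits[0].allele == "y1-1"
        assert hits[0].temperature == 30.0

    def test_assay_case_normalized(self):
        hits = read_screen_table(
            tsv("gene\tassay\tstrength\tsource\nY1\tBiM\tweak\ts\n")
        )
        assert hits[0].assay == "BIM"
        assert hits[0].strength == "WEAK"

    def test_order_preserved(self):
        hits = read_screen_table(
            tsv(
                "gene\tassay\tstrength\tsource\n"
                "Y2\tCTF\tWEAK\ts\nY1\tCTF\tWEAK\ts\n"
            )
        )
        assert [h.gene_id for h in hits] == ["Y2", "Y1"]


class TestIntegrateScreens:
    META = [GeneMeta(f"Y{i}", essential=False) for i in range(1, 11)]

    def test_union_semantics(self):
        a = [ScreenHit("Y1", "CTF", "WEAK", "A")]
        b = [ScreenHit("Y1", "GCR", "WEAK", "B")]
        cat = integrate_screens([a, b], self.META)
        assert len(cat) == 1
        assert cat["Y1"].assays == {"CTF", "GCR"}
        assert cat["Y1"].sources == {"A", "B"}

    def test_disjoint_union_counts(self):
        a = [ScreenHit(f"Y{i}", "CTF", "WEAK", "A") for i in (1, 2, 3)]
        b = [ScreenHit(f"Y{i}", "GCR", "WEAK", "B") for i in (4, 5, 6, 7)]
        assert len(integrate_screens([a, b], self.META)) == 7

    def test_planted_two_of_three_screens(self):
        # 10 genes, each reported by exactly 2 of 3 screens (round-robin skip)
        genes = [f"Y{i}" for i in range(1, 11)]
        tables = []
        for s, src in enumerate(["S0", "S1", "S2"]):
            tables.append(
                [
                    ScreenHit(g, "CTF", "WEAK", src)
                    for i, g in enumerate(genes)
                    if i % 3 != s
                ]
            )
        cat = integrate_screens(tables, self.META)
        assert len(cat) == 10
        for i, g in enumerate(genes):
            expected = {f"S{s}" for s in range(3) if i % 3 != s}
            assert cat[g].sources == expected
            assert len(cat[g].sources) == 2

    def test_empty_table_list_rejected(self):
        with pytest.raises(ValidationError):
            integrate_screens([], self.META)

    def test_missing_meta_warns_and_keeps_record(self):
        hits = [ScreenHit("YX999", "CTF", "WEAK", "A")]
        with pytest.warns(UserWarning, match="YX999"):
            cat = integrate_screens([hits], self.META)
        assert cat["YX999"].meta is None

    def test_idempotent_reintegration(self):
        a = [ScreenHit("Y1", "CTF", "STRONG", "A"), ScreenHit("Y2", "ALF", "WEAK", "B")]
        cat1 = integrate_screens([a], self.META)
        evidence_tables = [rec.evidence for rec in cat1]
        cat2 = integrate_screens([a] + evidence_tables, self.META)
        assert cat1.genes() == cat2.genes()
        for g in cat1.genes():
            assert cat1[g].evidence == cat2[g].evidence
            assert cat1[g].confidence == cat2[g].confidence

    def test_order_invariance(self):
        tables = [
            [ScreenHit("Y1", "CTF", "WEAK", "A")],
            [ScreenHit("Y2", "GCR", "STRONG", "B")],
            [ScreenHit("Y1", "ALF", "WEAK", "C")],
        ]
        for _ in range(5):
            shuffled = tables[:]
            random.Random(0).shuffle(shuffled)
            cat = integrate_screens(shuffled, self.META)
            assert cat.genes() == {"Y1", "Y2"}
            assert cat["Y1"].sources == {"A", "C"}


class TestClassifyConfidence:
    @pytest.mark.parametrize(
        "hits,expected",
        [
            ([("A", "WEAK")], "LOW"),
            ([("A", "STRONG")], "HIGH"),
            ([("A", "WEAK"), ("B", "WEAK")], "HIGH"),
            ([("A", "WEAK"), ("A", "WEAK")], "LOW"),  # same source twice
        ],
    )
    def test_rule(self, hits, expected):
        evidence = [
            ScreenHit("Y1", assay, strength, source)
            for (source, strength), assay in zip(hits, ["CTF", "GCR", "ALF", "LOH"])
        ]
        cat = CINCatalogue([CatalogueRecord("Y1", evidence=evidence)])
        assert classify_confidence(cat)["Y1"].confidence == expected

    def test_zero_evidence_rejected(self):
        cat = CINCatalogue([CatalogueRecord("Y1", evidence=[])])
        with pytest.raises(ValidationError):
            classify_confidence(cat)

    def test_monotone_adding_evidence_never_demotes(self):
        rng = random.Random(42)
        assays = ["CTF", "ALF", "GCR", "BIM", "LOH"]
        for _ in range(50):
            n = rng.randint(1, 4)
            evidence = [
                ScreenHit("Y1", assays[i], rng.choice(["STRONG", "WEAK"]),
                          f"S{rng.randint(0, 2)}")
                for i in range(n)
            ]
            base = classify_confidence(
                CINCatalogue([CatalogueRecord("Y1", evidence=list(evidence))])
            )["Y1"].confidence
            extra = ScreenHit("Y1", assays[4], rng.choice(["STRONG", "WEAK"]), "S9")
            grown = classify_confidence(
                CINCatalogue([CatalogueRecord("Y1", evidence=evidence + [extra])])
            )["Y1"].confidence
            assert not (base == "HIGH" and grown == "LOW")


def _catalogue_with_counts(essential_cin, essential_total, noness_cin, noness_total):
    meta = [
        GeneMeta(f"E{i}", essential=True) for i in range(essential_total)
    ] + [GeneMeta(f"N{i}", essential=False) for i in range(noness_total)]
    hits = [
        ScreenHit(f"E{i}", "CTF", "WEAK", "S") for i in range(essential_cin)
    ] + [ScreenHit(f"N{i}", "CTF", "WEAK", "S") for i in range(noness_cin)]
    return integrate_screens([hits], meta), meta


class TestSummarize:
    def test_essential_proportion_integer_rounding(self):
        cat, meta = _catalogue_with_counts(323, 1156, 0, 10)
        s = summarize(cat, meta)
        assert s.essential_cin == 323
        assert s.essential_universe == 1156
        assert s.essential_pct == 28

    def test_nonessential_proportion_one_decimal(self):
        cat, meta = _catalogue_with_counts(0, 10, 369, 4800)
        s = summarize(cat, meta)
        assert s.nonessential_pct == 7.7

    def test_empty_catalogue(self):
        meta = [GeneMeta("Y1", essential=True)]
        cat = CINCatalogue([])
        s = summarize(cat, meta)
        assert s.total_genes == 0
        assert s.essential_cin == 0
        assert s.high_confidence_fraction is None

    def test_zero_universe_reports_missing_not_zero(self):
        meta = [GeneMeta("N1", essential=False)]
        cat = integrate_screens([[ScreenHit("N1", "CTF", "WEAK", "S")]], meta)
        s = summarize(cat, meta)
        assert s.essential_universe == 0
        assert s.essential_pct is None

    def test_counts_reconcile(self):
        meta = [GeneMeta("Y1", essential=True), GeneMeta("Y2", essential=False)]
        hits = [
            ScreenHit("Y1", "CTF", "WEAK", "S"),
            ScreenHit("Y2", "GCR", "WEAK", "S"),
            ScreenHit("Y9", "ALF", "WEAK", "S"),  # not in meta
        ]
        with pytest.warns(UserWarning):
            cat = integrate_screens([hits], meta)
        s = summarize(cat, meta)
        assert s.essential_cin + s.nonessential_cin + s.unknown_essentiality == s.total_genes

    def test_high_confidence_fraction(self, small_catalogue):
        meta = [m.meta for m in small_catalogue if m.meta]
        s = summarize(small_catalogue, meta)
        # Y1: two sources -> HIGH; Y2: single WEAK -> LOW; Y3: single WEAK -> LOW
        assert s.high_confidence_fraction == pytest.approx(1 / 3)

    def test_per_assay_counts(self, small_catalogue):
        s = summarize(small_catalogue, [])
        assert s.per_assay_counts["CTF"] == 2
        assert s.per_assay_counts["GCR"] == 1
        assert s.per_assay_counts["BIM"] == 0


class TestRoundTrip:
    def test_catalogue_write_read(self, small_catalogue, tmp_path):
        path = tmp_path / "cat.tsv"
        with open(path, "w") as fh:
            write_catalogue(small_catalogue, fh)
        with open(path) as fh:
            back = read_catalogue(fh)
        assert back.genes() == small_catalogue.genes()
        for g in back.genes():
            assert back[g].assays == small_catalogue[g].assays
            assert back[g].sources == small_catalogue[g].sources
            assert back[g].confidence == small_catalogue[g].confidence

    def test_gene_meta_reader(self):
        meta = read_gene_meta(
            tsv(
                "gene\tessential\tnuclear\tverified_orf\tfunctional_group\n"
                "Y1\t1\t0\t1\tmitosis\nY2\t\tyes\t0\t\n"
            )
        )
        assert meta[0] == GeneMeta("Y1", True, False, True, "mitosis")
        assert meta[1].essential is None
        assert meta[1].nuclear is True
        assert meta[1].verified_orf is False

    def test_duplicate_meta_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            read_gene_meta(tsv("gene\tessential\nY1\t1\nY1\t0\n"))
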