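"""Gene-table I/O and PUL detection."""

import pytest
from hypothesis import given, settings, strategies as st

from pulscape.genome import (
    GeneRecord,
    GenomeAnnotation,
    classify_regulator,
    detect_puls,
    parse_functional_class,
    puls_to_table,
    read_gene_table,
    read_pul_report,
    write_gene_table,
    write_pul_report,
)
from conftest import make_annotation


@pytest.mark.parametrize(
    "label,expected",
    [("susC", "susC"), ("GH:43", "GH:43"), ("CBM:6", "CBM:6"),
     ("hypothetical", "other"), ("XY:1", "other"), ("other", "other")],
)
def test_functional_class_parsing(label, expected):
    assert parse_functional_class(label) == expected


def test_gene_record_invariants():
    with pytest.raises(ValueError):
        GeneRecord("a", "c", 10, 10, "+")
    with pytest.raises(ValueError):
        GeneRecord("a", "c", 0, 10, "?")


def test_duplicate_locus_tag_is_hard_error():
    genes = [GeneRecord("a", "c", 0, 10, "+"), GeneRecord("a", "c", 20, 30, "+")]
    with pytest.raises(ValueError, match="'a'"):
        GenomeAnnotation.from_records("g", genes)


def test_zero_genes_is_hard_error(tmp_path):
    with pytest.raises(ValueError):
        GenomeAnnotation("g", {})
    p = tmp_path / "empty.tsv"
    p.write_text("locus_tag\tcontig\tstart\tend\tstrand\tfunctional_class\n")
    with pytest.raises(ValueError):
        read_gene_table(p)


def test_malformed_coordinates_named_with_line(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(
        "locus_tag\tcontig\tstart\tend\tstrand\tfunctional_class\n"
        "g1\tc\t0\t100\t+\tsusC\n"
        "g2\tc\tzero\t200\t+\tsusD\n"
    )
    with pytest.raises(ValueError, match=":3"):
        read_gene_table(p)


def test_gff3_reading_sorts_and_converts_coordinates(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text(
        "##gff-version 3\n"
        "c1\tsrc\tgene\t201\t300\t.\t-\t.\tID=g2;pul_class=susD\n"
        "c1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1;pul_class=susC\n"
        "c1\tsrc\tgene\t401\t500\t.\t+\t.\tID=g3;pul_class=GH:43\n"
    )
    ann = read_gene_table(p, format="gff3")
    genes = list(ann.genes())
    assert [g.locus_tag for g in genes] == ["g1", "g2", "g3"]
    assert (genes[0].start, genes[0].end) == (0, 100)  # 1-based inclusive -> half-open


def test_tsv_round_trip_identity(tmp_path, planted_pair):
    ann, *_ = planted_pair
    path = tmp_path / "genome.tsv"
    write_gene_table(ann, path)
    back = read_gene_table(path, genome_id=ann.genome_id)
    assert list(back.genes()) == list(ann.genes())


def test_gff3_round_trip_identity(tmp_path, planted_pair):
    ann, *_ = planted_pair
    path = tmp_path / "genome.gff3"
    write_gene_table(ann, path, format="gff3")
    back = read_gene_table(path, format="gff3", genome_id=ann.genome_id)
    assert [(g.locus_tag, g.start, g.end, g.strand, g.functional_class) for g in back.genes()] == [
        (g.locus_tag, g.start, g.end, g.strand, g.functional_class) for g in ann.genes()
    ]


def test_no_suscd_genes_yields_empty_list():
    ann = make_annotation(["other", "GH:13", "HTCS", "other"])
    assert detect_puls(ann) == []


def test_pair_expands_over_flanking_cazymes():
    ann = make_annotation(["other", "GH:13", "susC", "susD", "GH:43", "other"])
    (pul,) = detect_puls(ann, max_gap=1)
    assert (pul.first_index, pul.last_index) == (1, 4)
    assert pul.n_genes == 4


def test_trailing_other_genes_not_included():
    ann = make_annotation(["other", "susC", "susD", "other", "other"])
    (pul,) = detect_puls(ann, max_gap=1)
    assert (pul.first_index, pul.last_index) == (1, 2)


def test_gap_crossing_respects_max_gap():
    classes = ["susC", "susD", "other", "other", "GH:2"]
    (narrow,) = detect_puls(make_annotation(classes), max_gap=1)
    assert narrow.last_index == 1
    (wide,) = detect_puls(make_annotation(classes), max_gap=2)
    assert wide.last_index == 4


def test_tandem_suscd_pairs_merge_into_one_pul():
    ann = make_annotation(["HTCS", "susC", "susD", "GH:43", "susC", "susD", "GH:51"])
    puls = detect_puls(ann, merge_within=5)
    assert len(puls) == 1
    assert len(puls[0].susCD_pairs) == 2


def test_detection_recovers_planted_spans(planted_pair):
    annA, annB, _, _, _, truth = planted_pair
    for ann in (annA, annB):
        planted = [p for p in truth.params["puls"] if p["genome"] == ann.genome_id]
        detected = detect_puls(ann)
        assert len(detected) == len(planted)
        spans = {
            (ann.contigs[p.contig][p.first_index].locus_tag,
             ann.contigs[p.contig][p.last_index].locus_tag)
            for p in detected
        }
        assert spans == {(p["first_locus_tag"], p["last_locus_tag"]) for p in planted}


def test_regulator_classification_matches_planting(planted_pair):
    annA, _, _, _, _, truth = planted_pair
    planted = {
        (p["first_locus_tag"], p["last_locus_tag"]): p["regulator_class"]
        for p in truth.params["puls"] if p["genome"] == annA.genome_id
    }
    for pul in detect_puls(annA):
        genes = annA.contigs[pul.contig]
        key = (genes[pul.first_index].locus_tag, genes[pul.last_index].locus_tag)
        assert pul.regulator_class == planted[key]


def test_regulator_priority_and_window():
    ann = make_annotation(["HTCS", "ECF_sigma", "susC", "susD"])
    (pul,) = detect_puls(ann)
    assert classify_regulator(pul, ann, window=3) == "HTCS"
    far = make_annotation(["HTCS", "other", "other", "other", "other", "susC", "susD"])
    (pul,) = detect_puls(far)
    assert classify_regulator(pul, ann=far, window=3) == "none"


def test_per_contig_detection_equals_union(planted_pair):
    annA, annB, *_ = planted_pair
    combined = GenomeAnnotation(
        "both", {**{c: list(g) for c, g in annA.contigs.items()},
                 **{c: list(g) for c, g in annB.contigs.items()}}
    )
    merged = detect_puls(combined)
    per_contig = []
    for contig in combined.contigs:
        per_contig.extend(detect_puls(combined.subset_contig(contig)))
    assert [(p.contig, p.first_index, p.last_index, p.susCD_pairs) for p in merged] == [
        (p.contig, p.first_index, p.last_index, p.susCD_pairs) for p in per_contig
    ]


@settings(max_examples=60, deadline=None)
@given(
    classes=st.lists(
        st.sampled_from(["susC", "susD", "GH:2", "HTCS", "other"]), min_size=2, max_size=25
    ),
    gap_small=st.integers(0, 2),
    gap_extra=st.integers(1, 3),
)
def test_max_gap_monotonicity(classes, gap_small, gap_extra):
    """Increasing max_gap never shrinks any PUL's member count."""
    ann = make_annotation(classes)
    small = detect_puls(ann, max_gap=gap_small)
    large = detect_puls(ann, max_gap=gap_small + gap_extra)
    # every small-gap PUL is contained in some large-gap PUL
    for p in small:
        assert any(q.first_index <= p.first_index and q.last_index >= p.last_index for q in large)
    assert sum(p.n_genes for p in large) >= sum(p.n_genes for p in small)


def test_pul_report_round_trip(tmp_path, planted_pair):
    annA, *_ = planted_pair
    puls = detect_puls(annA)
    path = tmp_path / "puls.tsv"
    write_pul_report(puls, annA, path)
    assert read_pul_report(path) == puls
    table = puls_to_table(puls, annA)
    assert list(table["n_genes"]) == [p.n_genes for p in puls]
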