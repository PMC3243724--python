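"""Reciprocal best hits, synteny, and PUL orthology tiering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulscape.genome import detect_puls
from pulscape.orthology import (
    HomologyHit,
    classify_pul_pair,
    compare_genomes,
    flanking_synteny,
    kmer_similarity_hits,
    longest_order_preserving_chain,
    match_candidate_pul,
    reciprocal_best_hits,
)
from pulscape.simulate import synth_genome_pair
from conftest import make_annotation


def brute_force_rbh(score, evalue, e_cutoff):
    """Exhaustive all-pairs scan: (i, j) is an RBH iff j is i's best subject
    and i is j's best subject, both passing the cutoff."""
    na, nb = score.shape
    pairs = set()
    for i in range(na):
        cands = [(-score[i, j], evalue[i, j], f"B{j:03d}", j) for j in range(nb) if evalue[i, j] <= e_cutoff]
        if not cands:
            continue
        j = min(cands)[3]
        back = [(-score[i2, j], evalue[i2, j], f"A{i2:03d}", i2) for i2 in range(na) if evalue[i2, j] <= e_cutoff]
        if back and min(back)[3] == i:
            pairs.add((f"A{i:03d}", f"B{j:03d}"))
    return pairs


@settings(max_examples=40, deadline=None)
@given(
    na=st.integers(1, 15),
    nb=st.integers(1, 15),
    seed=st.integers(0, 10_000),
)
def test_rbh_equals_brute_force_oracle(na, nb, seed):
    rng = np.random.default_rng(seed)
    score = np.round(rng.uniform(10, 500, size=(na, nb)), 1)
    evalue = 10.0 ** rng.uniform(-50, -5, size=(na, nb))
    hits_ab = [
        HomologyHit(f"A{i:03d}", f"B{j:03d}", score[i, j], evalue[i, j])
        for i in range(na) for j in range(nb)
    ]
    hits_ba = [HomologyHit(h.subject, h.query, h.score, h.evalue) for h in hits_ab]
    rbh = reciprocal_best_hits(hits_ab, hits_ba, e_cutoff=1e-10)
    got = {(a, b) for a, b in rbh.pairs.items() if a.startswith("A")}
    assert got == brute_force_rbh(score, evalue, 1e-10)


def test_evalue_above_cutoff_excluded():
    hits_ab = [HomologyHit("a1", "b1", 500.0, 1e-5)]
    hits_ba = [HomologyHit("b1", "a1", 500.0, 1e-5)]
    assert len(reciprocal_best_hits(hits_ab, hits_ba, e_cutoff=1e-10)) == 0
    assert len(reciprocal_best_hits(hits_ab, hits_ba, e_cutoff=1e-4)) == 1


def test_same_genome_hit_is_hard_error():
    hits = [HomologyHit("a1", "a2", 100.0, 1e-20)]
    with pytest.raises(ValueError, match="same-genome"):
        reciprocal_best_hits(hits, [], 1e-10, genome_a_tags={"a1", "a2"}, genome_b_tags={"b1"})


def test_deterministic_tie_break_by_subject_id():
    hits_ab = [HomologyHit("a1", "b2", 100.0, 1e-20), HomologyHit("a1", "b1", 100.0, 1e-20)]
    hits_ba = [HomologyHit("b1", "a1", 100.0, 1e-20), HomologyHit("b2", "a1", 100.0, 1e-20)]
    rbh = reciprocal_best_hits(hits_ab, hits_ba, 1e-10)
    assert rbh.partner("a1") == "b1"


def brute_force_chain(pairs):
    best = 0
    for r in range(1, len(pairs) + 1):
        for sub in itertools.combinations(sorted(pairs), r):
            bs = [b for _, b in sub]
            if all(x < y for x, y in zip(bs, bs[1:])):
                best = max(best, r)
    return best


@settings(max_examples=40, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(0, 10))
def test_order_preserving_chain_equals_exhaustive_search(seed, n):
    rng = np.random.default_rng(seed)
    pairs = [(int(a), int(b)) for a, b in zip(rng.permutation(n), rng.permutation(n))]
    assert longest_order_preserving_chain(pairs) == brute_force_chain(pairs)


def _two_locus_setup(b_flank_order=None):
    """Tiny two-genome setup: one PUL each, 5-gene flanks, configurable
    genome-B flank gene order."""
    n_flank = 5
    classes = ["other"] * n_flank + ["susC", "susD", "GH:2"] + ["other"] * n_flank
    annA = make_annotation(classes, genome_id="A", contig="cA")
    annB = make_annotation(classes, genome_id="B", contig="cB")
    (pulA,) = detect_puls(annA)
    (pulB,) = detect_puls(annB)
    tagsA = [g.locus_tag for g in annA.genes()]
    tagsB = [g.locus_tag for g in annB.genes()]
    mapping = dict(zip(tagsA, tagsB))
    if b_flank_order is not None:  # permute which B flank genes the A flanks map to
        flank_idx = list(range(n_flank)) + list(range(n_flank + 3, len(classes)))
        src = [tagsB[i] for i in flank_idx]
        dst = [src[j] for j in b_flank_order]
        for a_idx, b_tag in zip(flank_idx, dst):
            mapping[tagsA[a_idx]] = b_tag
    hits_ab = [HomologyHit(a, b, 500.0, 1e-50) for a, b in mapping.items()]
    hits_ba = [HomologyHit(b, a, 500.0, 1e-50) for a, b in mapping.items()]
    rbh = reciprocal_best_hits(hits_ab, hits_ba, 1e-10)
    return annA, annB, pulA, pulB, rbh, hits_ab, hits_ba


def test_identical_flanks_give_full_synteny():
    annA, annB, pulA, pulB, rbh, *_ = _two_locus_setup()
    assert flanking_synteny(pulA, pulB, rbh, annA, annB, window=5) == 10


def test_no_flank_homologs_give_zero_synteny():
    annA, annB, pulA, pulB, rbh, *_ = _two_locus_setup()
    core = {g.locus_tag for g in annA.genes()}
    pul_tags = set(pulA.member_locus_tags(annA))
    stripped_pairs = {a: b for a, b in rbh.pairs.items() if a in pul_tags or b in pul_tags}
    rbh.pairs = stripped_pairs
    assert flanking_synteny(pulA, pulB, rbh, annA, annB, window=5) == 0


def test_match_requires_susc_and_susd_in_same_locus():
    annA, annB, pulA, pulB, rbh, *_ = _two_locus_setup()
    assert match_candidate_pul(pulA, [pulB], rbh, annA, annB).pul_id == pulB.pul_id
    # break the susD partner: point it outside the B PUL
    genesA = annA.contigs[pulA.contig]
    ci, di = pulA.susCD_pairs[0]
    susd_tag = genesA[di].locus_tag
    old = rbh.pairs[susd_tag]
    outside = annB.contigs[pulB.contig][0].locus_tag
    rbh.pairs[susd_tag] = outside
    assert match_candidate_pul(pulA, [pulB], rbh, annA, annB) is None
    rbh.pairs[susd_tag] = old


def test_tier_homologous_and_probably_and_unique():
    annA, annB, pulA, pulB, rbh, *_ = _two_locus_setup()
    call = classify_pul_pair(pulA, pulB, rbh, annA, annB)
    assert call.tier == "homologous" and call.same_orientation
    assert call.n_syntenic_flanking >= 3
    # inverted locus: reversed member order in B -> probably homologous
    n_flank = 5
    classes = ["other"] * n_flank + ["susC", "susD", "GH:2"] + ["other"] * n_flank
    inv_classes = ["other"] * n_flank + ["GH:2", "susD", "susC"] + ["other"] * n_flank
    annI = make_annotation(inv_classes, genome_id="B", contig="cB",
                           strand=["+"] * n_flank + ["-"] * 3 + ["+"] * n_flank)
    (pulI,) = detect_puls(annI)
    tagsA = [g.locus_tag for g in annA.genes()]
    tagsI = [g.locus_tag for g in annI.genes()]
    mapping = dict(zip(tagsA[:n_flank], tagsI[:n_flank]))
    mapping.update(zip(tagsA[n_flank + 3:], tagsI[n_flank + 3:]))
    mapping.update({tagsA[n_flank]: tagsI[n_flank + 2],      # susC
                    tagsA[n_flank + 1]: tagsI[n_flank + 1],  # susD
                    tagsA[n_flank + 2]: tagsI[n_flank]})     # GH:2
    hits_ab = [HomologyHit(a, b, 500.0, 1e-50) for a, b in mapping.items()]
    hits_ba = [HomologyHit(b, a, 500.0, 1e-50) for a, b in mapping.items()]
    rbh_i = reciprocal_best_hits(hits_ab, hits_ba, 1e-10)
    call = classify_pul_pair(pulA, pulI, rbh_i, annA, annI)
    assert call.tier == "probably_homologous" and not call.same_orientation
    # no candidate -> unique
    assert classify_pul_pair(pulA, None, rbh, annA, annB).tier == "unique"


def test_self_comparison_all_homologous():
    annA, annB, _, _, _, hits_ab, hits_ba = _two_locus_setup()
    calls, summary = compare_genomes(
        annA, annB, detect_puls(annA), detect_puls(annB), hits_ab, hits_ba
    )
    assert summary["tiers_a"] == {"homologous": 1, "probably_homologous": 0, "unique": 0}


def test_zero_cross_hits_all_unique(planted_pair):
    annA, annB, *_ = planted_pair
    calls, summary = compare_genomes(
        annA, annB, detect_puls(annA), detect_puls(annB), [], []
    )
    assert summary["tiers_a"]["unique"] == len(detect_puls(annA))
    assert summary["tiers_a"]["homologous"] == 0


def test_planted_structure_recovered_exactly(planted_pair):
    annA, annB, _, hits_ab, hits_ba, truth = planted_pair
    calls, summary = compare_genomes(
        annA, annB, detect_puls(annA), detect_puls(annB), hits_ab, hits_ba
    )
    assert summary["tiers_a"] == {"homologous": 10, "probably_homologous": 5, "unique": 5}
    assert summary["tiers_b"] == {"homologous": 10, "probably_homologous": 5, "unique": 5}


def test_tier_symmetry_under_genome_swap(planted_pair):
    annA, annB, _, hits_ab, hits_ba, _ = planted_pair
    pa, pb = detect_puls(annA), detect_puls(annB)
    _, fwd = compare_genomes(annA, annB, pa, pb, hits_ab, hits_ba)
    _, rev = compare_genomes(annB, annA, pb, pa, hits_ba, hits_ab)
    assert fwd["tiers_a"] == rev["tiers_b"]
    assert fwd["tiers_b"] == rev["tiers_a"]


def test_fallback_kmer_scorer_supports_rbh(planted_pair):
    annA, annB, proteins, _, _, truth = planted_pair
    # restrict to two shared loci worth of genes to keep the all-pairs scan small
    shared = [p for p in truth.params["puls"] if p["role"] == "shared"][:2]
    keep_a = set()
    keep_b = set()
    for p in shared:
        ann = annA if p["genome"] == "genomeA" else annB
        keep = keep_a if p["genome"] == "genomeA" else keep_b
        contig, i0 = ann.position(p["first_locus_tag"])
        _, i1 = ann.position(p["last_locus_tag"])
        keep.update(g.locus_tag for g in ann.contigs[contig][i0:i1 + 1])
    # same loci exist in both genomes; collect both sides via pair_id
    pair_ids = {p["pair_id"] for p in shared}
    for p in truth.params["puls"]:
        if p["pair_id"] in pair_ids:
            ann = annA if p["genome"] == "genomeA" else annB
            keep = keep_a if p["genome"] == "genomeA" else keep_b
            contig, i0 = ann.position(p["first_locus_tag"])
            _, i1 = ann.position(p["last_locus_tag"])
            keep.update(g.locus_tag for g in ann.contigs[contig][i0:i1 + 1])
    prot_a = {t: proteins[t] for t in keep_a}
    prot_b = {t: proteins[t] for t in keep_b}
    hits_ab, hits_ba = kmer_similarity_hits(prot_a, prot_b)
    rbh = reciprocal_best_hits(hits_ab, hits_ba, 1e-10)
    assert len(rbh) == len(keep_a) == len(keep_b)


def test_homologous_count_degrades_with_flank_shuffle():
    """Median homologous count over seeds is non-increasing in the flank-
    shuffle (conserved-flank erosion) rate."""
    rates = [0.0, 0.4, 0.8]
    medians = []
    for rate in rates:
        counts = []
        for seed in range(8):
            annA, annB, _, hab, hba, _ = synth_genome_pair(
                n_puls_shared=6, n_puls_inverted=0, n_puls_unique_each=0,
                n_filler_genes=80, flank_shuffle_rate=rate, seed=seed,
            )
            _, s = compare_genomes(annA, annB, detect_puls(annA), detect_puls(annB), hab, hba)
            counts.append(s["tiers_a"]["homologous"])
        medians.append(float(np.median(counts)))
    assert medians[0] == 6.0
    assert all(x >= y for x, y in zip(medians, medians[1:]))
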