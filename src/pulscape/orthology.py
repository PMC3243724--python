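"""Cross-genome PUL matching and three-tier orthology classification.

The orthology primitive is the reciprocal best hit (RBH): a cross-genome
gene pair in which each member is the other's top-scoring homology hit at an
E-value cutoff (default 1e-10).  A PUL in genome A is matched to a candidate
in genome B by requiring the RBH partners of both members of one of its
susC/susD pairs to fall inside the same B locus.  Matched pairs are then
tiered:

* ``homologous`` -- equal numbers of homologous genes per locus, conserved
  orientation, and >=3 order-preserving (syntenic) RBH pairs in the regions
  flanking the two loci;
* ``probably_homologous`` -- similar (but not identical-and-co-oriented)
  homologous gene content with the same flanking-synteny requirement;
* ``unique`` -- everything else.

"Similar numbers" is operationalised as |nA - nB| <= ceil(f * max(nA, nB))
with f = 0.25 by default; the threshold is recorded in every report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome import PUL, GenomeAnnotation


@dataclass(frozen=True)
class HomologyHit:
    query: str
    subject: str
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0 or self.score < 0:
            raise ValueError(f"hit {self.query}->{self.subject}: negative score or e-value")


def read_blast_table(path: str | Path) -> list[HomologyHit]:
    """Parse a BLAST tabular (outfmt 6 dialect) hit file.

    Only qseqid, sseqid, evalue and bitscore (columns 1, 2, 11, 12) are
    consumed.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected >=12 tab-separated columns (outfmt 6)")
    return [
        HomologyHit(query=str(r[0]), subject=str(r[1]), score=float(r[11]), evalue=float(r[10]))
        for r in df.itertuples(index=False)
    ]


def write_blast_table(hits: Sequence[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t100.0\t100\t0\t0\t1\t100\t1\t100\t{h.evalue:.3g}\t{h.score:.1f}\n"
            )


@dataclass
class RBHMap:
    """Symmetric set of reciprocal-best-hit gene pairs."""

    pairs: dict[str, str]  # both directions
    e_cutoff: float

    def partner(self, locus_tag: str) -> str | None:
        return self.pairs.get(locus_tag)

    def __len__(self) -> int:
        return len(self.pairs) // 2

    def pair_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b in self.pairs.items()}  # type: ignore[misc]


def _best_hits(hits: Iterable[HomologyHit], e_cutoff: float) -> dict[str, str]:
    """Best subject per query: highest score, ties by lowest e-value then
    lexicographic subject id."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        if h.evalue > e_cutoff:
            continue
        cur = best.get(h.query)
        if cur is None or (-h.score, h.evalue, h.subject) < (-cur.score, cur.evalue, cur.subject):
            best[h.query] = h
    return {q: h.subject for q, h in best.items()}


def reciprocal_best_hits(
    hits_ab: Sequence[HomologyHit],
    hits_ba: Sequence[HomologyHit],
    e_cutoff: float = 1e-10,
    genome_a_tags: set[str] | None = None,
    genome_b_tags: set[str] | None = None,
) -> RBHMap:
    """Compute the RBH map from two directed hit lists.

    When locus-tag sets are supplied, hits naming two genes from the same
    genome are rejected as a hard error.
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be > 0")
    if genome_a_tags is not None and genome_b_tags is not None:
        for hits, qset, sset in ((hits_ab, genome_a_tags, genome_b_tags),
                                 (hits_ba, genome_b_tags, genome_a_tags)):
            for h in hits:
                if h.query not in qset or h.subject not in sset:
                    raise ValueError(
                        f"hit {h.query}->{h.subject} does not link the two genomes "
                        "(same-genome or unknown locus tags)"
                    )
    fwd = _best_hits(hits_ab, e_cutoff)
    rev = _best_hits(hits_ba, e_cutoff)
    pairs: dict[str, str] = {}
    for a, b in sorted(fwd.items()):
        if rev.get(b) == a:
            pairs[a] = b
            pairs[b] = a
    return RBHMap(pairs=pairs, e_cutoff=e_cutoff)


def kmer_similarity_hits(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    k: int = 4,
    min_similarity: float = 0.05,
) -> tuple[list[HomologyHit], list[HomologyHit]]:
    """Internal fallback homology scorer: normalised shared k-mer content.

    Exists so synthetic benchmarks can run end to end without an external
    aligner.  Score = 1000 * |kmers(a) & kmers(b)| / max(|kmers(a)|,
    |kmers(b)|); the pseudo e-value is 10**(-100 * similarity) so the default
    RBH cutoff of 1e-10 corresponds to ~10% shared k-mer content.
    """

    def kmers(seq: str) -> set[str]:
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    ka = {t: kmers(s) for t, s in proteins_a.items()}
    kb = {t: kmers(s) for t, s in proteins_b.items()}
    ab: list[HomologyHit] = []
    for ta, sa in ka.items():
        for tb, sb in kb.items():
            denom = max(len(sa), len(sb))
            if denom == 0:
                continue
            sim = len(sa & sb) / denom
            if sim >= min_similarity:
                ab.append(HomologyHit(ta, tb, score=1000.0 * sim, evalue=10 ** (-100.0 * sim)))
    ba = [HomologyHit(h.subject, h.query, h.score, h.evalue) for h in ab]
    return ab, ba


# ---------------------------------------------------------------------------
# PUL matching and tiering

def match_candidate_pul(
    pulA: PUL,
    pulsB: Sequence[PUL],
    rbh: RBHMap,
    annA: GenomeAnnotation,
    annB: GenomeAnnotation,
) -> PUL | None:
    """Find the genome-B PUL containing the RBH partners of both members of
    some susC/susD pair of ``pulA``; ``None`` when absent or inconsistent."""
    genesA = annA.contigs[pulA.contig]

    def containing_pul(tag: str) -> PUL | None:
        contig, idx = annB.position(tag)
        for p in pulsB:
            if p.contig == contig and p.first_index <= idx <= p.last_index:
                return p
        return None

    for ci, di in pulA.susCD_pairs:
        pc = rbh.partner(genesA[ci].locus_tag)
        pdt = rbh.partner(genesA[di].locus_tag)
        if pc is None or pdt is None or pc not in annB or pdt not in annB:
            continue
        pul_c = containing_pul(pc)
        pul_d = containing_pul(pdt)
        if pul_c is not None and pul_d is not None and pul_c.pul_id == pul_d.pul_id:
            return pul_c
    return None


def longest_order_preserving_chain(pairs: Sequence[tuple[int, int]]) -> int:
    """Length of the longest subsequence of (A-index, B-index) pairs that is
    strictly increasing in both coordinates (classic LIS after sorting by
    the first coordinate)."""
    if not pairs:
        return 0
    seq = [b for _, b in sorted(pairs)]
    tails: list[int] = []
    import bisect

    for b in seq:
        i = bisect.bisect_left(tails, b)
        if i == len(tails):
            tails.append(b)
        else:
            tails[i] = b
    return len(tails)


def _flank_indices(pul: PUL, ann: GenomeAnnotation, window: int) -> list[int]:
    n = len(ann.contigs[pul.contig])
    left = range(max(0, pul.first_index - window), pul.first_index)
    right = range(pul.last_index + 1, min(n, pul.last_index + 1 + window))
    return list(left) + list(right)


def flanking_synteny(
    pulA: PUL,
    pulB: PUL,
    rbh: RBHMap,
    annA: GenomeAnnotation,
    annB: GenomeAnnotation,
    window: int = 5,
) -> int:
    """Count syntenic flanking genes: RBH pairs with both members within
    ``window`` genes of the respective PUL boundaries, scored as the longest
    order-preserving chain (total across both sides)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    genesA = annA.contigs[pulA.contig]
    flankB = set(_flank_indices(pulB, annB, window))
    pairs: list[tuple[int, int]] = []
    for ia in _flank_indices(pulA, annA, window):
        partner = rbh.partner(genesA[ia].locus_tag)
        if partner is None or partner not in annB:
            continue
        contig, ib = annB.position(partner)
        if contig == pulB.contig and ib in flankB:
            pairs.append((ia, ib))
    fwd = longest_order_preserving_chain(pairs)
    rev = longest_order_preserving_chain([(a, -b) for a, b in pairs])
    return max(fwd, rev)


@dataclass(frozen=True)
class OrthologyCall:
    pulA_id: str
    pulB_id: str | None
    tier: str  # homologous | probably_homologous | unique
    n_shared_pul_genes: int = 0
    same_orientation: bool = False
    n_syntenic_flanking: int = 0


def _linked_member_count(pul: PUL, ann: GenomeAnnotation, other: GenomeAnnotation, rbh: RBHMap) -> int:
    """Number of PUL member genes with an RBH partner anywhere in the other
    genome (per-locus homologous gene content)."""
    return sum(
        1
        for tag in pul.member_locus_tags(ann)
        if (p := rbh.partner(tag)) is not None and p in other
    )


def classify_pul_pair(
    pulA: PUL,
    pulB: PUL | None,
    rbh: RBHMap,
    annA: GenomeAnnotation,
    annB: GenomeAnnotation,
    window: int = 5,
    similar_frac: float = 0.25,
    min_syntenic: int = 3,
) -> OrthologyCall:
    """Tier a candidate PUL pair by shared gene content, orientation, and
    flanking synteny."""
    if pulB is None:
        return OrthologyCall(pulA.pul_id, None, "unique")
    genesA = annA.contigs[pulA.contig]
    shared: list[tuple[int, int, str, str]] = []  # (iA, iB, strandA, strandB)
    for i in pulA.member_indices():
        partner = rbh.partner(genesA[i].locus_tag)
        if partner is None or partner not in annB:
            continue
        contig, ib = annB.position(partner)
        if contig == pulB.contig and pulB.first_index <= ib <= pulB.last_index:
            shared.append((i, ib, genesA[i].strand, annB.contigs[contig][ib].strand))
    n_shared = len(shared)
    if n_shared == 0:
        return OrthologyCall(pulA.pul_id, pulB.pul_id, "unique")
    nA = _linked_member_count(pulA, annA, annB, rbh)
    nB = _linked_member_count(pulB, annB, annA, rbh)
    shared.sort()
    b_order = [ib for _, ib, _, _ in shared]
    increasing = all(x < y for x, y in zip(b_order, b_order[1:]))
    strands_equal = all(sa == sb for _, _, sa, sb in shared)
    same_orientation = increasing and strands_equal
    n_syn = flanking_synteny(pulA, pulB, rbh, annA, annB, window=window)
    call = dict(
        pulA_id=pulA.pul_id,
        pulB_id=pulB.pul_id,
        n_shared_pul_genes=n_shared,
        same_orientation=same_orientation,
        n_syntenic_flanking=n_syn,
    )
    if nA == nB and same_orientation and n_syn >= min_syntenic:
        return OrthologyCall(tier="homologous", **call)
    if abs(nA - nB) <= math.ceil(similar_frac * max(nA, nB)) and n_syn >= min_syntenic:
        return OrthologyCall(tier="probably_homologous", **call)
    return OrthologyCall(tier="unique", **call)


def compare_genomes(
    annA: GenomeAnnotation,
    annB: GenomeAnnotation,
    pulsA: Sequence[PUL],
    pulsB: Sequence[PUL],
    hits_ab: Sequence[HomologyHit],
    hits_ba: Sequence[HomologyHit],
    e_cutoff: float = 1e-10,
    window: int = 5,
    similar_frac: float = 0.25,
    min_syntenic: int = 3,
) -> tuple[list[OrthologyCall], dict]:
    """Classify every PUL of genome A against genome B and flag unmatched
    genome-B PULs as unique.

    Returns (calls, summary); the summary carries per-genome tier counts and
    the thresholds used, and is deterministic given the inputs.
    """
    rbh = reciprocal_best_hits(
        hits_ab, hits_ba, e_cutoff, genome_a_tags=annA.locus_tags(), genome_b_tags=annB.locus_tags()
    )
    calls: list[OrthologyCall] = []
    matched_b: dict[str, str] = {}
    for pulA in pulsA:
        cand = match_candidate_pul(pulA, pulsB, rbh, annA, annB)
        call = classify_pul_pair(
            pulA, cand, rbh, annA, annB,
            window=window, similar_frac=similar_frac, min_syntenic=min_syntenic,
        )
        calls.append(call)
        if call.tier != "unique" and call.pulB_id is not None:
            matched_b[call.pulB_id] = call.tier
    b_unique = [p.pul_id for p in pulsB if p.pul_id not in matched_b]
    tiers_a = {t: sum(1 for c in calls if c.tier == t) for t in ("homologous", "probably_homologous", "unique")}
    tiers_b = {
        "homologous": sum(1 for t in matched_b.values() if t == "homologous"),
        "probably_homologous": sum(1 for t in matched_b.values() if t == "probably_homologous"),
        "unique": len(b_unique),
    }
    summary = {
        "genome_a": annA.genome_id,
        "genome_b": annB.genome_id,
        "tiers_a": tiers_a,
        "tiers_b": tiers_b,
        "n_shared_loci": len(matched_b),
        "unmatched_b_puls": b_unique,
        "config": {
            "e_cutoff": e_cutoff,
            "flank_window": window,
            "similar_frac": similar_frac,
            "min_syntenic": min_syntenic,
        },
    }
    return calls, summary


def calls_to_table(calls: Sequence[OrthologyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.pulA_id, c.pulB_id or "", c.tier, c.n_shared_pul_genes, c.same_orientation, c.n_syntenic_flanking)
            for c in calls
        ],
        columns=["pulA_id", "pulB_id", "tier", "n_shared_pul_genes", "same_orientation", "n_syntenic_flanking"],
    )
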