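"""Gene models, annotation I/O, and polysaccharide utilization locus (PUL) detection.

A PUL is a contiguous run of genes anchored on at least one adjacent
susC--susD homolog pair: a TonB-dependent outer-membrane transporter gene
(susC-like) next to its partner glycan-binding lipoprotein gene (susD-like).
Detection works purely on functional-class labels supplied with the
annotation (``susC``, ``susD``, ``HTCS``, ``ECF_sigma``, CAZyme families such
as ``GH:43`` or ``PL:1``, and ``other``); no sequence homology search is
performed here.

Coordinates are 0-based half-open internally.  GFF3 input/output converts
from/to the 1-based inclusive convention of that format.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: non-CAZyme functional classes
CORE_CLASSES = frozenset({"susC", "susD", "HTCS", "ECF_sigma", "other"})
#: CAZy family prefixes accepted in ``<prefix>:<family>`` labels
CAZY_PREFIXES = ("GH", "PL", "CE", "CBM")

#: classes over which a PUL boundary may extend (plus gap-tolerated ``other``)
REGULATOR_CLASSES = frozenset({"HTCS", "ECF_sigma"})

TSV_COLUMNS = ["locus_tag", "contig", "start", "end", "strand", "functional_class", "product"]


def parse_functional_class(label: str) -> str:
    """Normalise a functional-class label; unknown labels map to ``other``.

    Accepted: the core classes, and CAZy family labels ``GH:<fam>``,
    ``PL:<fam>``, ``CE:<fam>``, ``CBM:<fam>``.  Anything else is soft-mapped
    to ``other`` with a warning, so that richer upstream annotations do not
    abort a run.
    """
    label = str(label).strip()
    if label in CORE_CLASSES:
        return label
    if ":" in label:
        prefix, fam = label.split(":", 1)
        if prefix in CAZY_PREFIXES and fam:
            return f"{prefix}:{fam}"
    logger.warning("unknown functional class %r mapped to 'other'", label)
    return "other"


def is_cazyme(functional_class: str) -> bool:
    return functional_class.partition(":")[0] in CAZY_PREFIXES


def is_pul_class(functional_class: str) -> bool:
    """True for classes that extend a PUL span (everything except ``other``)."""
    return functional_class != "other"


@dataclass(frozen=True)
class GeneRecord:
    """A stranded gene model with a functional class label."""

    locus_tag: str
    contig: str
    start: int
    end: int
    strand: str
    functional_class: str = "other"
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.locus_tag}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.locus_tag}: strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "functional_class", parse_functional_class(self.functional_class))

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeAnnotation:
    """Position-sorted, validated gene models grouped by contig."""

    def __init__(self, genome_id: str, contigs: dict[str, list[GeneRecord]]):
        self.genome_id = genome_id
        self.contigs: dict[str, list[GeneRecord]] = {}
        seen: set[str] = set()
        for contig, genes in contigs.items():
            ordered = sorted(genes, key=lambda g: (g.start, g.end))
            keys = set()
            for g in ordered:
                if g.locus_tag in seen:
                    raise ValueError(f"duplicate locus tag {g.locus_tag!r} in genome {genome_id!r}")
                seen.add(g.locus_tag)
                k = (g.start, g.end, g.strand)
                if k in keys:
                    raise ValueError(
                        f"contig {contig!r}: duplicate gene coordinates {k} ({g.locus_tag})"
                    )
                keys.add(k)
            self.contigs[contig] = ordered
        if not seen:
            raise ValueError(f"genome {genome_id!r} contains zero genes")
        self._index: dict[str, tuple[str, int]] = {
            g.locus_tag: (contig, i)
            for contig, genes in self.contigs.items()
            for i, g in enumerate(genes)
        }

    @classmethod
    def from_records(cls, genome_id: str, records: Iterable[GeneRecord]) -> "GenomeAnnotation":
        contigs: dict[str, list[GeneRecord]] = {}
        for rec in records:
            contigs.setdefault(rec.contig, []).append(rec)
        return cls(genome_id, contigs)

    def __len__(self) -> int:
        return len(self._index)

    def genes(self) -> Iterator[GeneRecord]:
        for contig in self.contigs:
            yield from self.contigs[contig]

    def locus_tags(self) -> set[str]:
        return set(self._index)

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag in self._index

    def position(self, locus_tag: str) -> tuple[str, int]:
        """(contig, gene index within contig) for a locus tag."""
        return self._index[locus_tag]

    def gene(self, locus_tag: str) -> GeneRecord:
        contig, i = self._index[locus_tag]
        return self.contigs[contig][i]

    def subset_contig(self, contig: str) -> "GenomeAnnotation":
        return GenomeAnnotation(self.genome_id, {contig: list(self.contigs[contig])})


@dataclass(frozen=True)
class PUL:
    """A detected locus: a contiguous gene-index range on one contig
    anchored on >=1 adjacent susC/susD pair."""

    pul_id: str
    genome_id: str
    contig: str
    first_index: int
    last_index: int  # inclusive
    susCD_pairs: tuple[tuple[int, int], ...]
    regulator_class: str = "none"

    def __post_init__(self) -> None:
        if not self.susCD_pairs:
            raise ValueError(f"{self.pul_id}: a PUL requires at least one susC/susD pair")
        for c, d in self.susCD_pairs:
            if abs(c - d) != 1:
                raise ValueError(f"{self.pul_id}: susC/susD pair ({c},{d}) not adjacent")
            if not (self.first_index <= c <= self.last_index and self.first_index <= d <= self.last_index):
                raise ValueError(f"{self.pul_id}: pair ({c},{d}) outside member range")
        if self.first_index > self.last_index:
            raise ValueError(f"{self.pul_id}: empty member range")

    @property
    def n_genes(self) -> int:
        return self.last_index - self.first_index + 1

    def member_indices(self) -> range:
        return range(self.first_index, self.last_index + 1)

    def members(self, ann: GenomeAnnotation) -> list[GeneRecord]:
        genes = ann.contigs[self.contig]
        return [genes[i] for i in self.member_indices()]

    def member_locus_tags(self, ann: GenomeAnnotation) -> list[str]:
        return [g.locus_tag for g in self.members(ann)]


# ---------------------------------------------------------------------------
# I/O

def _records_from_tsv(path: Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in TSV_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene table lacks required columns {missing}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed coordinates ({row.start!r}, {row.end!r})") from exc
        records.append(
            GeneRecord(
                locus_tag=row.locus_tag,
                contig=row.contig,
                start=start,
                end=end,
                strand=row.strand,
                functional_class=row.functional_class,
                product=getattr(row, "product", "") or "",
            )
        )
    return records


def _records_from_gff3(path: Path) -> list[GeneRecord]:
    import gffutils
    from gffutils.iterators import DataIterator

    records = []
    for feat in DataIterator(str(path)):
        if feat.featuretype not in ("gene", "CDS"):
            continue
        tag = feat.attributes.get("locus_tag", feat.attributes.get("ID", [None]))[0]
        if tag is None:
            raise ValueError(f"{path}: feature at {feat.seqid}:{feat.start} lacks locus_tag/ID")
        cls = feat.attributes.get("pul_class", ["other"])[0]
        product = feat.attributes.get("product", [""])[0]
        # GFF3 is 1-based inclusive
        records.append(
            GeneRecord(
                locus_tag=tag,
                contig=feat.seqid,
                start=int(feat.start) - 1,
                end=int(feat.end),
                strand=feat.strand,
                functional_class=cls,
                product=product,
            )
        )
    return records


def read_gene_table(path: str | Path, format: str | None = None, genome_id: str | None = None) -> GenomeAnnotation:
    """Read a gene table (``tsv`` or ``gff3``) into a validated annotation.

    The TSV dialect has columns locus_tag, contig, start, end, strand,
    functional_class[, product] with 0-based half-open coordinates; GFF3
    carries the class in a ``pul_class=`` attribute.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if format == "tsv":
        records = _records_from_tsv(path)
    elif format == "gff3":
        records = _records_from_gff3(path)
    else:
        raise ValueError(f"unknown gene-table format {format!r}")
    if not records:
        raise ValueError(f"{path}: zero genes parsed")
    return GenomeAnnotation.from_records(genome_id or path.stem, records)


def write_gene_table(ann: GenomeAnnotation, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        rows = [
            (g.locus_tag, g.contig, g.start, g.end, g.strand, g.functional_class, g.product)
            for g in ann.genes()
        ]
        pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in ann.genes():
                attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag};pul_class={g.functional_class}"
                if g.product:
                    attrs += f";product={g.product}"
                fh.write(
                    f"{g.contig}\tpulscape\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
    else:
        raise ValueError(f"unknown gene-table format {format!r}")


# ---------------------------------------------------------------------------
# PUL detection

def _adjacent_suscd_pairs(genes: Sequence[GeneRecord]) -> list[tuple[int, int]]:
    pairs = []
    for i in range(len(genes) - 1):
        classes = {genes[i].functional_class, genes[i + 1].functional_class}
        if classes == {"susC", "susD"}:
            pairs.append((i, i + 1))
    return pairs


def detect_puls(ann: GenomeAnnotation, max_gap: int = 1, merge_within: int = 5) -> list[PUL]:
    """Detect PULs: anchor on adjacent susC/susD pairs, merge nearby anchors,
    and expand over PUL-class genes.

    Expansion walks outwards from the (merged) anchor span, crossing at most
    ``max_gap`` consecutive ``other`` genes to reach the next susC/susD,
    regulator, or CAZyme gene; trailing ``other`` genes are not included.
    Anchor pairs separated by ``merge_within`` genes or fewer belong to one
    locus (tandem multi-susC loci).  Returns PULs in genome order with
    deterministic ids ``<genome>-PUL0001`` etc.
    """
    if max_gap < 0 or merge_within < 0:
        raise ValueError("max_gap and merge_within must be >= 0")
    puls: list[PUL] = []
    counter = 0
    for contig, genes in ann.contigs.items():
        pairs = _adjacent_suscd_pairs(genes)
        if not pairs:
            continue
        # cluster anchors whose index gap is <= merge_within
        clusters: list[list[tuple[int, int]]] = [[pairs[0]]]
        for pair in pairs[1:]:
            if pair[0] - clusters[-1][-1][1] <= merge_within:
                clusters[-1].append(pair)
            else:
                clusters.append([pair])
        spans: list[tuple[int, int, list[tuple[int, int]]]] = []
        for cluster in clusters:
            lo = min(i for p in cluster for i in p)
            hi = max(i for p in cluster for i in p)
            # expand left
            i, gap = lo - 1, 0
            while i >= 0:
                if is_pul_class(genes[i].functional_class):
                    lo, gap = i, 0
                else:
                    gap += 1
                    if gap > max_gap:
                        break
                i -= 1
            # expand right
            i, gap = hi + 1, 0
            while i < len(genes):
                if is_pul_class(genes[i].functional_class):
                    hi, gap = i, 0
                else:
                    gap += 1
                    if gap > max_gap:
                        break
                i += 1
            spans.append((lo, hi, cluster))
        # merge spans that expanded into overlap
        merged: list[tuple[int, int, list[tuple[int, int]]]] = [spans[0]]
        for lo, hi, cluster in spans[1:]:
            plo, phi, pcluster = merged[-1]
            if lo <= phi:
                merged[-1] = (plo, max(phi, hi), pcluster + cluster)
            else:
                merged.append((lo, hi, cluster))
        for lo, hi, cluster in merged:
            counter += 1
            puls.append(
                PUL(
                    pul_id=f"{ann.genome_id}-PUL{counter:04d}",
                    genome_id=ann.genome_id,
                    contig=contig,
                    first_index=lo,
                    last_index=hi,
                    susCD_pairs=tuple(cluster),
                )
            )
    return [replace(p, regulator_class=classify_regulator(p, ann)) for p in puls]


def classify_regulator(pul: PUL, ann: GenomeAnnotation, window: int = 3) -> str:
    """Regulator class of a PUL: ``HTCS`` if an HTCS gene lies inside the PUL
    or within ``window`` genes of either boundary, else ``ECF_sigma`` under
    the same rule, else ``none``.  HTCS wins when both occur."""
    genes = ann.contigs[pul.contig]
    lo = max(0, pul.first_index - window)
    hi = min(len(genes) - 1, pul.last_index + window)
    classes = {genes[i].functional_class for i in range(lo, hi + 1)}
    if "HTCS" in classes:
        return "HTCS"
    if "ECF_sigma" in classes:
        return "ECF_sigma"
    return "none"


# ---------------------------------------------------------------------------
# PUL report round-trip

PUL_REPORT_COLUMNS = [
    "pul_id", "genome_id", "contig", "first_locus_tag", "last_locus_tag",
    "first_index", "last_index", "n_genes", "n_susCD_pairs", "susCD_pairs",
    "regulator_class",
]


def puls_to_table(puls: Sequence[PUL], ann: GenomeAnnotation) -> pd.DataFrame:
    rows = []
    for p in puls:
        genes = ann.contigs[p.contig]
        rows.append(
            (
                p.pul_id, p.genome_id, p.contig,
                genes[p.first_index].locus_tag, genes[p.last_index].locus_tag,
                p.first_index, p.last_index, p.n_genes, len(p.susCD_pairs),
                ";".join(f"{c},{d}" for c, d in p.susCD_pairs),
                p.regulator_class,
            )
        )
    return pd.DataFrame(rows, columns=PUL_REPORT_COLUMNS)


def write_pul_report(puls: Sequence[PUL], ann: GenomeAnnotation, path: str | Path) -> None:
    puls_to_table(puls, ann).to_csv(path, sep="\t", index=False)


def read_pul_report(path: str | Path) -> list[PUL]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    puls = []
    for row in df.itertuples(index=False):
        pairs = tuple(
            tuple(int(x) for x in chunk.split(",")) for chunk in str(row.susCD_pairs).split(";")
        )
        puls.append(
            PUL(
                pul_id=row.pul_id,
                genome_id=row.genome_id,
                contig=row.contig,
                first_index=int(row.first_index),
                last_index=int(row.last_index),
                susCD_pairs=pairs,  # type: ignore[arg-type]
                regulator_class=row.regulator_class,
            )
        )
    return puls
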