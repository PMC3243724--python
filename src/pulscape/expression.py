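"""Fold-change computation, operon grouping, and induction calls.

Transcriptional responses are expressed as signed fold-changes against a
glucose minimal-medium reference condition (``MM-G``): for signal s and
reference r, fold = s/r when s >= r, else -(r/s), so the magnitude is always
>= 1 and the sign encodes direction.  Genes are grouped into putative
operons (maximal same-strand runs with small intergenic gaps), operon
induction is the arithmetic mean of member signed fold-changes, and a unit
is called regulated when its magnitude reaches the cutoff (default 10-fold).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import PUL, GenomeAnnotation


@dataclass
class ExpressionProfile:
    """Normalized signal matrix (rows = locus tags, columns = conditions)."""

    signals: pd.DataFrame
    reference_condition: str

    def __post_init__(self) -> None:
        if self.reference_condition not in self.signals.columns:
            raise ValueError(f"reference condition {self.reference_condition!r} not in matrix columns")
        if self.signals.index.has_duplicates:
            dup = self.signals.index[self.signals.index.duplicated()][0]
            raise ValueError(f"duplicate locus tag in expression matrix: {dup!r}")
        bad = np.argwhere(~(self.signals.to_numpy() > 0))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-positive signal at gene {self.signals.index[i]!r}, "
                f"condition {self.signals.columns[j]!r}"
            )

    @property
    def conditions(self) -> list[str]:
        return [c for c in self.signals.columns if c != self.reference_condition]


def read_expression_tsv(path: str | Path, reference_condition: str) -> ExpressionProfile:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionProfile(df, reference_condition)


def write_expression_tsv(profile: ExpressionProfile, path: str | Path) -> None:
    profile.signals.to_csv(path, sep="\t", index_label="locus_tag")


def fold_changes(profile: ExpressionProfile) -> pd.DataFrame:
    """Signed fold-change matrix relative to the reference condition.

    The reference column maps to all ones; every entry has magnitude >= 1.
    """
    ref = profile.signals[profile.reference_condition]
    out = {}
    for cond in profile.signals.columns:
        s = profile.signals[cond]
        up = s / ref
        down = -(ref / s)
        out[cond] = np.where(s >= ref, up, down)
    return pd.DataFrame(out, index=profile.signals.index)


@dataclass(frozen=True)
class OperonGroup:
    operon_id: str
    contig: str
    strand: str
    member_locus_tags: tuple[str, ...]


def group_operons(ann: GenomeAnnotation, max_intergenic_bp: int = 150) -> list[OperonGroup]:
    """Partition genes into putative operons: maximal same-contig,
    same-strand runs with successive intergenic gaps <= ``max_intergenic_bp``.
    Singletons are allowed; every gene appears in exactly one operon."""
    operons: list[OperonGroup] = []
    counter = 0
    for contig, genes in ann.contigs.items():
        run: list = []
        for g in genes:
            if run and (g.strand != run[-1].strand or g.start - run[-1].end > max_intergenic_bp):
                counter += 1
                operons.append(
                    OperonGroup(f"{ann.genome_id}-op{counter:04d}", contig, run[0].strand,
                                tuple(x.locus_tag for x in run))
                )
                run = []
            run.append(g)
        if run:
            counter += 1
            operons.append(
                OperonGroup(f"{ann.genome_id}-op{counter:04d}", contig, run[0].strand,
                            tuple(x.locus_tag for x in run))
            )
    return operons


@dataclass(frozen=True)
class InductionCall:
    unit_id: str
    condition: str
    fold_change: float
    passes_cutoff: bool


def operon_fold_changes(fc_matrix: pd.DataFrame, operons: Sequence[OperonGroup]) -> pd.DataFrame:
    """Operon x condition matrix of mean member signed fold-changes."""
    rows = {}
    for op in operons:
        missing = [t for t in op.member_locus_tags if t not in fc_matrix.index]
        if missing:
            raise KeyError(f"operon {op.operon_id}: members missing from fold-change matrix: {missing}")
        rows[op.operon_id] = fc_matrix.loc[list(op.member_locus_tags)].mean(axis=0)
    return pd.DataFrame(rows).T[fc_matrix.columns]


def operon_induction(
    fc_matrix: pd.DataFrame, operons: Sequence[OperonGroup], cutoff: float = 10.0
) -> list[InductionCall]:
    """Operon-level induction calls at the given magnitude cutoff."""
    op_fc = operon_fold_changes(fc_matrix, operons)
    calls = []
    for op_id, row in op_fc.iterrows():
        for cond, val in row.items():
            calls.append(InductionCall(str(op_id), str(cond), float(val), bool(abs(val) >= cutoff)))
    return calls


def regulated_summary(
    fc_matrix: pd.DataFrame,
    puls: Sequence[PUL] = (),
    ann: GenomeAnnotation | None = None,
    cutoff: float = 10.0,
    conditions: Sequence[str] | None = None,
    pul_locus_tags: Iterable[str] | None = None,
) -> dict:
    """Regulated-gene counts over a condition set.

    A gene is regulated when it passes the magnitude cutoff in at least one
    of the conditions; direction is taken from the condition of largest
    magnitude.  PUL membership may be supplied either as detected PULs plus
    their annotation or directly as a set of locus tags.  Percentages are
    rounded to one decimal: ``pct_up`` is the upregulated fraction of all
    regulated genes; ``pct_up_in_pul`` the PUL-resident fraction of
    upregulated genes.
    """
    if conditions is None:
        conditions = list(fc_matrix.columns)
    if pul_locus_tags is not None:
        pul_tags = set(pul_locus_tags)
    else:
        pul_tags = set()
        if puls and ann is None:
            raise ValueError("supply the annotation alongside detected PULs")
        for p in puls:
            pul_tags.update(p.member_locus_tags(ann))  # type: ignore[arg-type]
    sub = fc_matrix[list(conditions)]
    if sub.empty:
        zero = dict.fromkeys(
            ["n_regulated", "n_up", "n_down", "n_up_in_pul", "n_regulated_in_pul"], 0
        )
        return {**zero, "pct_up": 0.0, "pct_up_in_pul": 0.0,
                "set_partition": {"up_in_pul": [], "up_outside_pul": [], "down": []}}
    vals = sub.to_numpy(dtype=float)
    pass_mask = np.abs(vals) >= cutoff
    regulated = pd.Series(pass_mask.any(axis=1), index=sub.index)
    # direction from the condition of largest magnitude among passing calls
    peak = np.where(pass_mask, np.abs(vals), -np.inf).argmax(axis=1)
    direction = pd.Series(
        np.where(regulated, np.sign(vals[np.arange(vals.shape[0]), peak]), 0.0),
        index=sub.index,
    )
    up = direction > 0
    down = direction < 0
    in_pul = pd.Series([g in pul_tags for g in sub.index], index=sub.index)
    n_reg, n_up, n_down = int(regulated.sum()), int(up.sum()), int(down.sum())
    n_up_in_pul = int((up & in_pul).sum())
    pct_up = round(100.0 * n_up / n_reg, 1) if n_reg else 0.0
    pct_up_in_pul = round(100.0 * n_up_in_pul / n_up, 1) if n_up else 0.0
    return {
        "n_regulated": n_reg,
        "n_up": n_up,
        "n_down": n_down,
        "n_up_in_pul": n_up_in_pul,
        "n_regulated_in_pul": int((regulated & in_pul).sum()),
        "pct_up": pct_up,
        "pct_up_in_pul": pct_up_in_pul,
        "set_partition": {
            "up_in_pul": sorted(sub.index[up & in_pul]),
            "up_outside_pul": sorted(sub.index[up & ~in_pul]),
            "down": sorted(sub.index[down]),
        },
    }


def heatmap_matrix(
    fc_matrix: pd.DataFrame,
    operons: Sequence[OperonGroup],
    path: str | Path | None = None,
    ordering: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Serialize the operon x condition average fold-change matrix (the
    quantity drawn in PUL induction heatmaps) as a lossless TSV."""
    mat = operon_fold_changes(fc_matrix, operons)
    if ordering is not None:
        mat = mat.loc[list(ordering)]
    if path is not None:
        mat.to_csv(path, sep="\t", index_label="operon_id", float_format="%.17g")
    return mat
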