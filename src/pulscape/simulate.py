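"""Seeded synthetic-data generators with machine-readable truth records.

Each generator emulates one input class of the pipeline -- paired genome
annotations with planted shared/inverted/unique PULs and their homology hit
tables, expression matrices with planted induced operons, sigmoidal
plate-reader growth curves, and ITC titrations -- and returns a
:class:`TruthRecord` sufficient to score any downstream output.  Every
generator is a pure function of (configuration, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import itc as itc_mod
from .expression import ExpressionProfile, group_operons
from .genome import GeneRecord, GenomeAnnotation
from .orthology import HomologyHit

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
CAZY_FAMILIES = ["GH:2", "GH:3", "GH:10", "GH:26", "GH:43", "GH:51", "GH:97",
                 "PL:1", "PL:9", "CE:1", "CE:8", "CBM:6", "CBM:35"]


@dataclass
class TruthRecord:
    generator: str
    seed: int
    params: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True, default=_jsonable)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(generator=d["generator"], seed=d["seed"], params=d["params"])


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


# ---------------------------------------------------------------------------
# Genome pair with planted PULs

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    mask = rng.random(chars.size) < rate
    chars[mask] = rng.choice(AMINO_ACIDS, size=int(mask.sum()))
    return "".join(chars)


def _pul_pattern(rng: np.random.Generator, regulator: str, tandem: bool) -> list[str]:
    """Class pattern of one planted PUL: optional regulator gene, one or two
    adjacent susC/susD pairs, and a few CAZymes."""
    pattern: list[str] = []
    if regulator in ("HTCS", "ECF_sigma"):
        pattern.append(regulator)
    pattern += ["susC", "susD"]
    if tandem:
        pattern += ["susC", "susD"]
    n_caz = int(rng.integers(2, 6))
    pattern += list(rng.choice(CAZY_FAMILIES, size=n_caz))
    return pattern


@dataclass
class _Block:
    """One genome segment: conserved left flank, PUL, conserved right flank."""

    role: str  # shared | inverted | unique_a | unique_b
    pul_classes: list[str]
    regulator: str
    flank: int = 5
    pair_id: int = -1  # links the A and B copies of shared/inverted blocks


def synth_genome_pair(
    n_puls_shared: int = 10,
    n_puls_inverted: int = 5,
    n_puls_unique_each: int = 5,
    n_filler_genes: int = 200,
    mutation_rate: float = 0.0,
    flank_shuffle_rate: float = 0.0,
    flank_size: int = 5,
    tandem_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[GenomeAnnotation, GenomeAnnotation, dict, list[HomologyHit], list[HomologyHit], TruthRecord]:
    """Generate two annotated genomes with planted PUL orthology structure.

    Shared PULs have identical gene content and orientation in both genomes
    with ``flank_size`` conserved flanking genes per side; inverted PULs are
    reverse-complemented as a block (flanks stay conserved); unique PULs
    occur in one genome only.  Homology hit tables are emitted directly from
    the planting, with bit-scores decaying and e-values rising with
    ``mutation_rate`` (at rate 1.0 no pair passes the default 1e-10 cutoff).
    ``flank_shuffle_rate`` is the per-gene probability that a conserved
    flanking gene in genome B is replaced by an unrelated gene, eroding
    flanking synteny.  Returns (annA, annB, proteins, hits_ab, hits_ba,
    truth).
    """
    if not (0.0 <= mutation_rate <= 1.0):
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)

    blocks: list[_Block] = []
    pair_id = 0
    for role, count in (("shared", n_puls_shared), ("inverted", n_puls_inverted)):
        for _ in range(count):
            regulator = str(rng.choice(["HTCS", "HTCS", "HTCS", "ECF_sigma", "none"]))
            blocks.append(
                _Block(role, _pul_pattern(rng, regulator, rng.random() < tandem_fraction),
                       regulator, flank_size, pair_id)
            )
            pair_id += 1
    uniques_a = []
    uniques_b = []
    for _ in range(n_puls_unique_each):
        regulator = str(rng.choice(["HTCS", "ECF_sigma", "none"]))
        uniques_a.append(_Block("unique_a", _pul_pattern(rng, regulator, False), regulator, flank_size))
        regulator = str(rng.choice(["HTCS", "ECF_sigma", "none"]))
        uniques_b.append(_Block("unique_b", _pul_pattern(rng, regulator, False), regulator, flank_size))

    order_a = blocks + uniques_a
    order_b_shared = list(rng.permutation(len(blocks)))
    order_b = [blocks[i] for i in order_b_shared] + uniques_b

    n_blocks_total = len(order_a) + len(order_b)
    filler_per_gap = max(2, n_filler_genes // max(n_blocks_total, 1))

    proteins: dict[str, str] = {}
    homolog_pairs: list[tuple[str, str]] = []  # (tagA, tagB)
    truth_puls: list[dict] = []

    def build_genome(
        genome_id: str,
        prefix: str,
        block_order: Sequence[_Block],
        is_b: bool,
    ) -> GenomeAnnotation:
        records: list[GeneRecord] = []
        pos = 0
        counter = 0
        # per-block conserved gene tags are recorded on the A pass and
        # consumed on the B pass via block identity
        for blk in block_order:

            def add_gene(cls: str, strand: str, partner_tag: str | None = None) -> str:
                nonlocal pos, counter
                counter += 1
                length = int(rng.integers(900, 1500))
                tag = f"{prefix}_{counter:04d}"
                records.append(GeneRecord(tag, f"chr_{genome_id}", pos, pos + length, strand, cls))
                pos += length + int(rng.integers(50, 200))
                if partner_tag is not None:
                    proteins[tag] = _mutate_protein(rng, proteins[partner_tag], mutation_rate)
                    homolog_pairs.append((partner_tag, tag))
                else:
                    proteins[tag] = _random_protein(rng, length // 3)
                return tag

            # leading unrelated filler
            for _ in range(filler_per_gap):
                add_gene("other", "+" if rng.random() < 0.5 else "-")

            conserved = blk.role in ("shared", "inverted")
            partner_tags = blk.__dict__.get("_a_tags") if is_b and conserved else None

            block_tags: list[str] = []
            inverted_here = is_b and blk.role == "inverted"
            pul_strand = "-" if inverted_here else "+"
            pul_classes = list(reversed(blk.pul_classes)) if inverted_here else list(blk.pul_classes)

            # left flank
            for j in range(blk.flank):
                if partner_tags is not None:
                    if rng.random() < flank_shuffle_rate:
                        tag = add_gene("other", "+")
                    else:
                        tag = add_gene("other", "+", partner_tag=partner_tags["flank_l"][j])
                else:
                    tag = add_gene("other", "+")
                block_tags.append(tag)
            flank_l = block_tags[-blk.flank:]

            # PUL members
            pul_tags: list[str] = []
            for j, cls in enumerate(pul_classes):
                if partner_tags is not None:
                    src = partner_tags["pul"]
                    a_tag = src[len(src) - 1 - j] if inverted_here else src[j]
                    tag = add_gene(cls, pul_strand, partner_tag=a_tag)
                else:
                    tag = add_gene(cls, pul_strand)
                pul_tags.append(tag)

            # right flank
            flank_r: list[str] = []
            for j in range(blk.flank):
                if partner_tags is not None:
                    if rng.random() < flank_shuffle_rate:
                        tag = add_gene("other", "+")
                    else:
                        tag = add_gene("other", "+", partner_tag=partner_tags["flank_r"][j])
                else:
                    tag = add_gene("other", "+")
                flank_r.append(tag)

            if conserved and not is_b:
                blk.__dict__["_a_tags"] = {"flank_l": flank_l, "pul": pul_tags, "flank_r": flank_r}
            truth_puls.append(
                {
                    "genome": genome_id,
                    "role": blk.role,
                    "pair_id": blk.pair_id if conserved else None,
                    "first_locus_tag": pul_tags[0],
                    "last_locus_tag": pul_tags[-1],
                    "n_genes": len(pul_tags),
                    "regulator_class": blk.regulator,
                }
            )

        # trailing filler
        for _ in range(filler_per_gap):
            counter += 1
            length = int(rng.integers(900, 1500))
            tag = f"{prefix}_{counter:04d}"
            records.append(GeneRecord(tag, f"chr_{genome_id}", pos, pos + length,
                                      "+" if rng.random() < 0.5 else "-", "other"))
            proteins[tag] = _random_protein(rng, length // 3)
            pos += length + int(rng.integers(50, 200))
        return GenomeAnnotation.from_records(genome_id, records)

    ann_a = build_genome("genomeA", "GA", order_a, is_b=False)
    ann_b = build_genome("genomeB", "GB", order_b, is_b=True)

    # hit tables from the planting
    hits_ab: list[HomologyHit] = []
    hits_ba: list[HomologyHit] = []
    score = max(20.0, 600.0 * (1.0 - mutation_rate))
    evalue = 10.0 ** (-140.0 * (1.0 - mutation_rate))
    b_tags = sorted(t for t in proteins if t.startswith("GB_"))
    for k, (ta, tb) in enumerate(homolog_pairs):
        hits_ab.append(HomologyHit(ta, tb, score, evalue))
        hits_ba.append(HomologyHit(tb, ta, score, evalue))
        if k % 7 == 0:  # weaker secondary hit to exercise best-hit selection
            decoy = b_tags[int(rng.integers(len(b_tags)))]
            if decoy != tb:
                hits_ab.append(HomologyHit(ta, decoy, score * 0.4, max(evalue * 1e6, 1e-12)))
    # spurious cross hits above the cutoff
    a_tags = sorted(t for t in proteins if t.startswith("GA_"))
    for _ in range(20):
        hits_ab.append(HomologyHit(a_tags[int(rng.integers(len(a_tags)))],
                                   b_tags[int(rng.integers(len(b_tags)))], 25.0, 1e-3))

    truth = TruthRecord(
        generator="synth_genome_pair",
        seed=seed,
        params={
            "n_puls_shared": n_puls_shared,
            "n_puls_inverted": n_puls_inverted,
            "n_puls_unique_each": n_puls_unique_each,
            "n_filler_genes": n_filler_genes,
            "mutation_rate": mutation_rate,
            "flank_shuffle_rate": flank_shuffle_rate,
            "flank_size": flank_size,
            "puls": truth_puls,
            "n_homolog_pairs": len(homolog_pairs),
        },
    )
    return ann_a, ann_b, proteins, hits_ab, hits_ba, truth


# ---------------------------------------------------------------------------
# Expression matrices with planted induced operons

def synth_expression(
    ann: GenomeAnnotation,
    induced: dict[str, list[str]] | int = 5,
    conditions: Sequence[str] = ("MM-glycanA", "MM-glycanB"),
    effect_size: float = 50.0,
    noise_cv: float = 0.1,
    baseline_lognormal_sigma: float = 0.8,
    baseline_median: float = 200.0,
    reference_condition: str = "MM-G",
    max_intergenic_bp: int = 150,
    seed: int = 0,
) -> tuple[ExpressionProfile, TruthRecord]:
    """Generate a normalized expression matrix with planted induced operons.

    Baseline signals are log-normal around ``baseline_median``; in each
    condition the members of its induced operons are multiplied by
    ``effect_size`` before multiplicative log-normal noise of coefficient of
    variation ``noise_cv``.  ``induced`` is either a mapping condition ->
    operon ids or an integer count of operons to plant per condition
    (chosen deterministically from the genome's operon partition).
    """
    rng = np.random.default_rng(seed)
    operons = group_operons(ann, max_intergenic_bp=max_intergenic_bp)
    by_id = {op.operon_id: op for op in operons}
    if isinstance(induced, int):
        multi = [op.operon_id for op in operons if len(op.member_locus_tags) >= 2]
        chosen = {}
        for cond in conditions:
            take = rng.choice(len(multi), size=min(induced, len(multi)), replace=False)
            chosen[cond] = sorted(multi[i] for i in take)
        induced = chosen
    unknown = {o for ops in induced.values() for o in ops if o not in by_id}
    if unknown:
        raise KeyError(f"unknown operon ids: {sorted(unknown)}")

    tags = [g.locus_tag for g in ann.genes()]
    baseline = baseline_median * np.exp(rng.normal(0.0, baseline_lognormal_sigma, size=len(tags)))
    sigma_ln = np.sqrt(np.log1p(noise_cv**2))

    def noisy(values: np.ndarray) -> np.ndarray:
        if noise_cv <= 0:
            return values
        return values * np.exp(rng.normal(0.0, sigma_ln, size=values.size))

    data = {reference_condition: baseline if noise_cv <= 0 else noisy(baseline)}
    tag_index = {t: i for i, t in enumerate(tags)}
    for cond in conditions:
        vals = baseline.copy()
        for op_id in induced.get(cond, []):
            for t in by_id[op_id].member_locus_tags:
                vals[tag_index[t]] *= effect_size
        data[cond] = noisy(vals)
    profile = ExpressionProfile(pd.DataFrame(data, index=pd.Index(tags, name="locus_tag")),
                                reference_condition)
    truth = TruthRecord(
        generator="synth_expression",
        seed=seed,
        params={
            "effect_size": effect_size,
            "noise_cv": noise_cv,
            "baseline_lognormal_sigma": baseline_lognormal_sigma,
            "reference_condition": reference_condition,
            "induced_operons": {c: list(v) for c, v in induced.items()},
            "induced_genes": {
                c: sorted(t for o in v for t in by_id[o].member_locus_tags)
                for c, v in induced.items()
            },
        },
    )
    return profile, truth


# ---------------------------------------------------------------------------
# Plate-reader growth curves

def synth_plate(
    n_groups: int = 4,
    n_replicates: int = 3,
    noise_sd: float = 0.01,
    a0: float = 0.10,
    amplitude_range: tuple[float, float] = (0.5, 1.0),
    rate_range: tuple[float, float] = (0.008, 0.02),
    midpoint_range: tuple[float, float] = (900.0, 1400.0),
    duration_min: float = 2400.0,
    no_growth_groups: int = 1,
    biphasic_groups: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate a plate of logistic growth curves with replicate structure.

    Reads are taken at a fixed interval drawn from 10-15 min.  Each group
    (one strain x substrate combination) shares kinetic parameters across
    its replicate wells; ``no_growth_groups`` groups get zero amplitude and
    ``biphasic_groups`` get a second, later logistic phase.  Truth records
    per-well kinetics plus the closed-form window statistics (expected
    two-point rate and density under the quantification rules, the maximum
    slope, and the amplitude).
    """
    from .growth import logistic_window_truth

    rng = np.random.default_rng(seed)
    interval = float(rng.integers(10, 16))
    t = np.arange(0.0, duration_min + interval / 2, interval)

    wells: dict[str, np.ndarray] = {}
    layout_rows = []
    well_truth = {}
    w = 0
    for g in range(n_groups):
        no_growth = g < no_growth_groups
        biphasic = (not no_growth) and g >= n_groups - biphasic_groups
        amp = 0.0 if no_growth else float(rng.uniform(*amplitude_range))
        r = float(rng.uniform(*rate_range))
        tm = float(rng.uniform(*midpoint_range))
        phase2 = None
        if biphasic:
            phase2 = {
                "amplitude": float(rng.uniform(0.2, 0.4)),
                "rate_per_min": float(rng.uniform(*rate_range)),
                "midpoint_min": tm + float(rng.uniform(600.0, 900.0)),
            }
        expected = logistic_window_truth(a0, amp, r, tm) if amp > 0 else {"grew": False}
        for _ in range(n_replicates):
            w += 1
            well = f"W{w:02d}"
            y = np.full_like(t, a0)
            if amp > 0:
                y = y + amp / (1.0 + np.exp(-r * (t - tm)))
            if phase2 is not None:
                y = y + phase2["amplitude"] / (
                    1.0 + np.exp(-phase2["rate_per_min"] * (t - phase2["midpoint_min"]))
                )
            if noise_sd > 0:
                y = np.clip(y + rng.normal(0.0, noise_sd, size=t.size), 0.0, None)
            wells[well] = y
            layout_rows.append((well, "wt", f"substrate{g + 1:02d}"))
            well_truth[well] = {
                "a0": a0, "amplitude": amp, "rate_per_min": r, "midpoint_min": tm,
                "biphasic": phase2, "max_slope_per_min": amp * r / 4.0,
                "expected": expected,
            }
    plate = pd.DataFrame({"time_min": t, **wells})
    layout = pd.DataFrame(layout_rows, columns=["well_id", "strain", "substrate"])
    truth = TruthRecord(
        generator="synth_plate",
        seed=seed,
        params={
            "noise_sd": noise_sd, "read_interval_min": interval,
            "n_groups": n_groups, "n_replicates": n_replicates,
            "wells": well_truth,
        },
    )
    return plate, layout, truth


# ---------------------------------------------------------------------------
# ITC titrations

def synth_titration(
    sites: Sequence[itc_mod.BindingSite],
    design: itc_mod.TitrationSeries | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[itc_mod.TitrationSeries, TruthRecord]:
    """Simulate a titration from true binding parameters, with truth record."""
    if design is None:
        design = itc_mod.default_design()
    series = itc_mod.simulate_isotherm(sites, design, noise_sd=noise_sd, seed=seed)
    truth = TruthRecord(
        generator="synth_titration",
        seed=seed,
        params={
            "sites": [{"ka": s.ka, "dh": s.dh, "n": s.n} for s in sites],
            "noise_sd": noise_sd,
            "mode": design.mode,
            "cell_conc": design.cell_conc,
            "syringe_conc": design.syringe_conc,
            "c_values": [s.ka * (design.cell_conc if design.mode == "macromolecule_in_cell"
                                 else design.syringe_conc) * s.n for s in sites],
        },
    )
    return series, truth
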