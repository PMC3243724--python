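"""Isothermal titration calorimetry: isotherm simulation, nonlinear fitting,
and thermodynamic derivation.

The binding model is the standard equilibrium description of an ITC
experiment.  For one class of sites, M + L <=> ML with association constant
Ka, the complex concentration follows the exact quadratic mass-balance
solution; for two independent site classes the free-ligand concentration is
solved numerically from the coupled mass balance.  Injections dilute the
cell contents continuously (perfusion cell): after injecting volume dV into
a cell of volume V0, species originally in the cell are diluted by
d = exp(-dV/V0) and the syringe species accumulates as Cs*(1 - d).  The heat
of injection i is

    q_i = V0 * sum_s dH_s * ([ML_s]_i - d_i * [ML_s]_{i-1})    (kcal),

i.e. the enthalpy of complex formed in the cell beyond what survived
dilution (complex carried out by the overflow releases no heat).  Heats of
dilution are assumed pre-subtracted; a constant per-injection offset can be
fitted as a nuisance parameter.

Derived quantities use dG = -R*T*ln(Ka) with R = 1.9872e-3 kcal/(mol K) and
TdS = dH - dG.  Fits with no detectable signal are labelled ``NB`` (no
binding); fits whose Ka falls below 5e2 M^-1 are labelled ``TLTF`` (too low
to fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

R_KCAL = 1.9872e-3  # kcal mol^-1 K^-1
STANDARD_TEMPERATURE_K = 298.15  # 25 C
TLTF_KA_FLOOR = 5.0e2  # M^-1; below this, binding is too weak to fit reliably


@dataclass(frozen=True)
class BindingSite:
    """True or fitted parameters of one independent site class."""

    ka: float  # M^-1
    dh: float  # kcal/mol
    n: float   # sites per macromolecule

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.n <= 0:
            raise ValueError(f"non-physical site parameters (ka={self.ka}, n={self.n})")


@dataclass
class TitrationSeries:
    temperature: float  # K
    cell_volume: float  # L
    cell_conc: float    # M, species loaded in the cell
    syringe_conc: float  # M, species loaded in the syringe
    injection_volumes: np.ndarray  # L, per injection
    heats: np.ndarray  # kcal, per injection
    mode: str = "macromolecule_in_cell"  # or "ligand_in_cell"

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.cell_conc <= 0 or self.syringe_conc <= 0 or self.cell_volume <= 0:
            raise ValueError("concentrations and cell volume must be > 0")
        if self.injection_volumes.size < 5:
            raise ValueError("need >= 5 injections")
        if self.heats.size != self.injection_volumes.size:
            raise ValueError("heats and injection_volumes must have equal length")
        if not np.all(np.isfinite(self.heats)):
            raise ValueError("heats must be finite")
        if self.mode not in ("macromolecule_in_cell", "ligand_in_cell"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_injections(self) -> int:
        return int(self.injection_volumes.size)

    def molar_ratios(self) -> np.ndarray:
        """Syringe-species : cell-species total molar ratio in the cell after
        each injection (the conventional x-axis of an isotherm)."""
        cell, syr = _cell_concentrations(self)
        return syr / cell


def _cell_concentrations(series: TitrationSeries) -> tuple[np.ndarray, np.ndarray]:
    """Total concentrations in the cell after each injection under continuous
    overflow dilution: (cell-loaded species, syringe-loaded species)."""
    v0 = series.cell_volume
    cell = np.empty(series.n_injections)
    syr = np.empty(series.n_injections)
    c_cell, c_syr = series.cell_conc, 0.0
    for i, dv in enumerate(series.injection_volumes):
        d = math.exp(-dv / v0)
        c_cell *= d
        c_syr = c_syr * d + series.syringe_conc * (1.0 - d)
        cell[i] = c_cell
        syr[i] = c_syr
    return cell, syr


def _bound_concentrations(mt: float, lt: float, sites: Sequence[BindingSite]) -> list[float]:
    """Equilibrium complex concentration per site class.

    One site: exact quadratic root.  Several independent sites: solve the
    free-ligand mass balance L + sum_s n_s*Mt*Ka_s*L/(1+Ka_s*L) = Lt with a
    bracketed root finder.
    """
    if mt <= 0 or lt <= 0:
        return [0.0 for _ in sites]
    if len(sites) == 1:
        s = sites[0]
        cap = s.n * mt
        b = cap + lt + 1.0 / s.ka
        disc = b * b - 4.0 * cap * lt
        if disc < 0:
            raise ValueError("unsolvable one-site equilibrium (negative discriminant)")
        return [0.5 * (b - math.sqrt(disc))]

    def residual(free_l: float) -> float:
        bound = sum(s.n * mt * s.ka * free_l / (1.0 + s.ka * free_l) for s in sites)
        return free_l + bound - lt

    free = brentq(residual, 0.0, lt, xtol=1e-18, rtol=1e-14, maxiter=200)
    return [s.n * mt * s.ka * free / (1.0 + s.ka * free) for s in sites]


def predicted_heats(
    sites: Sequence[BindingSite],
    design: TitrationSeries,
    offset: float = 0.0,
) -> np.ndarray:
    """Noise-free per-injection heats (kcal) for the given site parameters."""
    cell, syr = _cell_concentrations(design)
    if design.mode == "macromolecule_in_cell":
        mt, lt = cell, syr
    else:
        mt, lt = syr, cell
    v0 = design.cell_volume
    q = np.empty(design.n_injections)
    prev = [0.0 for _ in sites]
    for i in range(design.n_injections):
        d = math.exp(-design.injection_volumes[i] / v0)
        bound = _bound_concentrations(mt[i], lt[i], sites)
        q[i] = v0 * sum(s.dh * (b - d * p) for s, b, p in zip(sites, bound, prev)) + offset
        prev = bound
    return q


def simulate_isotherm(
    sites: Sequence[BindingSite],
    design: TitrationSeries,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TitrationSeries:
    """Simulate a titration: predicted heats plus Gaussian noise (kcal)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    q = predicted_heats(sites, design)
    if noise_sd > 0:
        q = q + np.random.default_rng(seed).normal(0.0, noise_sd, size=q.size)
    return TitrationSeries(
        temperature=design.temperature,
        cell_volume=design.cell_volume,
        cell_conc=design.cell_conc,
        syringe_conc=design.syringe_conc,
        injection_volumes=design.injection_volumes.copy(),
        heats=q,
        mode=design.mode,
    )


def default_design(
    n_injections: int = 28,
    injection_volume: float = 10e-6,
    cell_volume: float = 1.4e-3,
    cell_conc: float = 1.0e-4,
    syringe_conc: float = 1.0e-3,
    temperature: float = STANDARD_TEMPERATURE_K,
    mode: str = "macromolecule_in_cell",
) -> TitrationSeries:
    """A typical VP-ITC style experimental design (~2:1 final molar ratio)."""
    return TitrationSeries(
        temperature=temperature,
        cell_volume=cell_volume,
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        injection_volumes=np.full(n_injections, injection_volume),
        heats=np.zeros(n_injections),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Thermodynamics

def derive_thermodynamics(ka: float, dh: float, temperature: float = STANDARD_TEMPERATURE_K) -> tuple[float, float]:
    """(dG, TdS) in kcal/mol from Ka (M^-1) and dH (kcal/mol)."""
    if ka <= 0:
        raise ValueError("Ka must be > 0")
    dg = -R_KCAL * temperature * math.log(ka)
    return dg, dh - dg


@dataclass
class SiteFit:
    ka: float
    dh: float
    n: float
    dg: float = math.nan
    tds: float = math.nan

    def __post_init__(self) -> None:
        if math.isnan(self.dg) and self.ka > 0:
            self.dg, self.tds = derive_thermodynamics(self.ka, self.dh)


@dataclass
class BindingFit:
    model: str  # one_site | two_site
    sites: list[SiteFit]
    status: str  # ok | NB | TLTF
    residual_norm: float = math.nan
    offset: float = 0.0
    poor_identifiability: bool = False
    n_injections: int = 0


def _noise_scale(heats: np.ndarray) -> float:
    """Robust per-injection noise estimate from first differences."""
    d = np.diff(heats)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0))


def _initial_guesses(
    series: TitrationSeries, n_sites: int, fit_offset: bool, n_fixed: bool = False
) -> list[np.ndarray]:
    """Heuristic starts: N from the molar ratio at the isotherm midpoint, dH
    from the first-injection heat per mole injected, Ka from two c-value
    guesses spanning shallow and steep curves."""
    q = series.heats
    ratios = series.molar_ratios()
    cum = np.cumsum(q)
    total = cum[-1] if cum[-1] != 0 else 1.0
    half_idx = int(np.argmin(np.abs(cum - 0.5 * total)))
    n0 = float(np.clip(ratios[half_idx], 0.05, 10.0))
    moles_first = series.syringe_conc * series.injection_volumes[0]
    dh0 = float(q[0] / moles_first) if moles_first > 0 else -1.0
    if dh0 == 0.0:
        dh0 = -1.0
    mt = series.cell_conc if series.mode == "macromolecule_in_cell" else series.syringe_conc
    guesses = []
    for c in (10.0, 100.0):
        ka0 = c / mt
        if n_sites == 1:
            site_params = [(math.log(ka0), dh0, n0)]
        else:
            site_params = [
                (math.log(ka0 * 3.0), dh0, max(n0 / 2.0, 0.05)),
                (math.log(max(ka0 / 10.0, 1.0)), dh0 / 2.0, max(n0 / 2.0, 0.05)),
            ]
        x: list[float] = []
        for lka, dh, n in site_params:
            x.extend([lka, dh] if n_fixed else [lka, dh, n])
        if fit_offset:
            x.append(0.0)
        guesses.append(np.array(x))
    return guesses


def fit_isotherm(
    series: TitrationSeries,
    model: str = "one_site",
    fix_n: Sequence[float] | None = None,
    fit_offset: bool = False,
    n_restarts: int = 10,
    seed: int = 0,
) -> BindingFit:
    """Least-squares fit of a one- or two-independent-site binding model.

    Parameters are (ln Ka, dH, N) per site plus an optional constant heat
    offset; ``fix_n`` pins stoichiometries (used when the ligand is a
    polysaccharide of unknown molarity).  Initialisation is heuristic with
    ``n_restarts`` jittered restarts (seeded); the best residual wins.
    Status: ``NB`` when the heat amplitude is within 3x the noise estimate,
    ``TLTF`` when the fitted Ka falls below 5e2 M^-1.  Two-site fits whose
    fitted Ka's differ by less than 2x are flagged poorly identifiable.
    """
    if model not in ("one_site", "two_site"):
        raise ValueError(f"unknown model {model!r}")
    n_sites = 1 if model == "one_site" else 2
    q = series.heats
    amp = float(np.max(np.abs(q))) if q.size else 0.0
    if amp <= 3.0 * _noise_scale(q):
        return BindingFit(model=model, sites=[], status="NB", n_injections=series.n_injections)

    n_fixed = fix_n is not None
    if n_fixed and len(fix_n) != n_sites:
        raise ValueError(f"fix_n must supply {n_sites} stoichiometries")
    pars_per_site = 2 if n_fixed else 3
    n_params = n_sites * pars_per_site + (1 if fit_offset else 0)
    if series.n_injections <= n_params:
        raise ValueError(
            f"{series.n_injections} injections cannot constrain {n_params} parameters"
        )

    def unpack(x: np.ndarray) -> tuple[list[BindingSite], float]:
        sites = []
        for s in range(n_sites):
            off = s * pars_per_site
            ka = math.exp(x[off])
            dh = x[off + 1]
            n = float(fix_n[s]) if n_fixed else x[off + 2]
            sites.append(BindingSite(ka=ka, dh=dh, n=max(n, 1e-6)))
        offset = x[-1] if fit_offset else 0.0
        return sites, offset

    def residuals(x: np.ndarray) -> np.ndarray:
        sites, offset = unpack(x)
        return predicted_heats(sites, series, offset) - q

    lo, hi = [], []
    for _ in range(n_sites):
        lo += [math.log(1e-1), -1e4] + ([] if n_fixed else [1e-6])
        hi += [math.log(1e12), 1e4] + ([] if n_fixed else [50.0])
    if fit_offset:
        lo.append(-abs(amp))
        hi.append(abs(amp))
    lo, hi = np.array(lo), np.array(hi)

    rng = np.random.default_rng(seed)
    bases = _initial_guesses(series, n_sites, fit_offset, n_fixed=n_fixed)
    starts = list(bases)
    while len(starts) < max(n_restarts, len(bases)):
        base = bases[len(starts) % len(bases)]
        jitter = rng.normal(0.0, 0.5, size=base.size)
        starts.append(np.clip(base + jitter * np.maximum(np.abs(base), 1.0), lo, hi))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("isotherm fit failed from every start")

    sites, offset = unpack(best.x)
    site_fits = sorted(
        (SiteFit(ka=s.ka, dh=s.dh, n=s.n) for s in sites), key=lambda s: -s.ka
    )
    status = "ok"
    if max(s.ka for s in site_fits) < TLTF_KA_FLOOR:
        status = "TLTF"
    poor = False
    if n_sites == 2:
        # Two sites are separable only if the two-site model fits decisively
        # better than a single site class; otherwise (or when the fitted
        # Ka's land within 2x of each other) the parameters sit on a
        # degenerate ridge and must be flagged rather than silently returned.
        ratio = site_fits[0].ka / site_fits[1].ka
        one = fit_isotherm(series, model="one_site", fit_offset=fit_offset,
                           n_restarts=n_restarts, seed=seed)
        rss_two = 2.0 * best.cost
        rss_one = one.residual_norm**2 if one.status != "NB" else math.inf
        floor = (1e-3 * amp) ** 2 * series.n_injections
        poor = bool(ratio < 2.0 or rss_one <= max(2.0 * rss_two, floor))
    return BindingFit(
        model=model,
        sites=site_fits,
        status=status,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        offset=float(offset),
        poor_identifiability=poor,
        n_injections=series.n_injections,
    )


# ---------------------------------------------------------------------------
# Audit of published / derived fit tables

def thermo_consistency(
    table: pd.DataFrame,
    temperature: float = STANDARD_TEMPERATURE_K,
    tol_dg: float = 0.06,
    tol_cycle: float = 0.15,
) -> pd.DataFrame:
    """Audit the internal identities of a fit table.

    Rows must carry columns ``ka``, ``dg``, ``dh``, ``tds`` (kcal/mol scale).
    Checks per row: |dg + RT ln ka| <= tol_dg and |dg - (dh - tds)| <=
    tol_cycle.  Returns the table with recomputed dG and boolean pass
    columns; an empty input yields an empty report.
    """
    out = table.copy()
    if out.empty:
        for col in ("dg_recomputed", "dg_dev", "cycle_dev", "dg_pass", "cycle_pass", "row_pass"):
            out[col] = pd.Series(dtype=float if col.endswith("dev") or col == "dg_recomputed" else bool)
        return out
    rt = R_KCAL * temperature
    out["dg_recomputed"] = -rt * np.log(out["ka"].astype(float))
    out["dg_dev"] = (out["dg"].astype(float) - out["dg_recomputed"]).abs()
    out["cycle_dev"] = (out["dg"].astype(float) - (out["dh"].astype(float) - out["tds"].astype(float))).abs()
    out["dg_pass"] = out["dg_dev"] <= tol_dg
    out["cycle_pass"] = out["cycle_dev"] <= tol_cycle
    out["row_pass"] = out["dg_pass"] & out["cycle_pass"]
    return out


# ---------------------------------------------------------------------------
# Serialization

def write_titration_tsv(series: TitrationSeries, path) -> None:
    pd.DataFrame(
        {
            "injection": np.arange(1, series.n_injections + 1),
            "volume_l": series.injection_volumes,
            "heat_kcal": series.heats,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_titration_tsv(path, metadata: dict) -> TitrationSeries:
    df = pd.read_csv(path, sep="\t")
    return TitrationSeries(
        temperature=float(metadata.get("temperature", STANDARD_TEMPERATURE_K)),
        cell_volume=float(metadata["cell_volume"]),
        cell_conc=float(metadata["cell_conc"]),
        syringe_conc=float(metadata["syringe_conc"]),
        injection_volumes=df["volume_l"].to_numpy(),
        heats=df["heat_kcal"].to_numpy(),
        mode=metadata.get("mode", "macromolecule_in_cell"),
    )


def fit_to_dict(fit: BindingFit) -> dict:
    return {
        "model": fit.model,
        "status": fit.status,
        "residual_norm": fit.residual_norm,
        "offset": fit.offset,
        "poor_identifiability": fit.poor_identifiability,
        "n_injections": fit.n_injections,
        "sites": [
            {"ka": s.ka, "dh": s.dh, "n": s.n, "dg": s.dg, "tds": s.tds} for s in fit.sites
        ],
    }
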