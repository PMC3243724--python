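"""Isotherm simulation, binding-model fitting, and thermodynamic audits."""

import math

import numpy as np
import pandas as pd
import pytest

from pulscape import datasets
from pulscape.itc import (
    R_KCAL,
    BindingSite,
    TitrationSeries,
    _bound_concentrations,
    _cell_concentrations,
    default_design,
    derive_thermodynamics,
    fit_isotherm,
    predicted_heats,
    simulate_isotherm,
    thermo_consistency,
)


def bisection_bound(mt, lt, sites, tol=1e-15):
    """Independent mass-balance solver: bisect on free ligand."""
    lo, hi = 0.0, lt
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        bound = sum(s.n * mt * s.ka * mid / (1.0 + s.ka * mid) for s in sites)
        if mid + bound > lt:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * max(lt, 1.0):
            break
    free = 0.5 * (lo + hi)
    return [s.n * mt * s.ka * free / (1.0 + s.ka * free) for s in sites]


def test_zero_enthalpy_gives_zero_heats():
    series = simulate_isotherm([BindingSite(1e5, 0.0, 1.0)], default_design())
    assert np.allclose(series.heats, 0.0)


def test_stoichiometric_limit_at_very_tight_binding():
    design = default_design()
    series = simulate_isotherm([BindingSite(1e12, -10.0, 1.0)], design)
    moles_per_inj = design.syringe_conc * design.injection_volumes[0]
    # early injections bind everything injected; past ratio 1 heats vanish
    assert series.heats[0] == pytest.approx(-10.0 * moles_per_inj, rel=0.01)
    assert abs(series.heats[-1]) < 1e-12
    ratios = series.molar_ratios()
    assert ratios[-1] > 1.5


@pytest.mark.parametrize(
    "sites",
    [
        [BindingSite(1e5, -10.0, 1.0)],
        [BindingSite(4.8e4, 1.6, 0.7), BindingSite(5.0e3, -17.5, 1.3)],
    ],
)
def test_equilibrium_matches_bisection_oracle(sites):
    design = default_design()
    mt_all, lt_all = _cell_concentrations(design)
    for mt, lt in zip(mt_all, lt_all):
        got = _bound_concentrations(mt, lt, sites)
        want = bisection_bound(mt, lt, sites)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, rel=1e-9, abs=1e-18)


def test_ligand_in_cell_mode_swaps_mass_balance():
    fwd = default_design(cell_conc=1e-4, syringe_conc=1e-3)
    rev = default_design(cell_conc=1e-4, syringe_conc=1e-3, mode="ligand_in_cell")
    # n != 1 breaks the (sites, ligand) symmetry of the 1:1 mass balance
    site = [BindingSite(1e5, -10.0, 2.0)]
    q_fwd = predicted_heats(site, fwd)
    q_rev = predicted_heats(site, rev)
    # same chemistry, different experimental geometry: totals differ, both
    # must satisfy the bisection mass balance with swapped roles
    cell, syr = _cell_concentrations(rev)
    for mt, lt, i in zip(syr, cell, range(rev.n_injections)):
        want = bisection_bound(mt, lt, site)[0]
        got = _bound_concentrations(mt, lt, site)[0]
        assert got == pytest.approx(want, rel=1e-9, abs=1e-18)
    assert not np.allclose(q_fwd, q_rev)


def test_simulation_validates_inputs():
    with pytest.raises(ValueError, match="injections"):
        TitrationSeries(298.15, 1.4e-3, 1e-4, 1e-3, np.full(3, 1e-5), np.zeros(3))
    with pytest.raises(ValueError):
        BindingSite(-1.0, -10.0, 1.0)
    with pytest.raises(ValueError, match="noise_sd"):
        simulate_isotherm([BindingSite(1e5, -10.0, 1.0)], default_design(), noise_sd=-1.0)


def test_noiseless_one_site_recovery_to_solver_tolerance():
    true = BindingSite(1e5, -10.0, 1.0)
    series = simulate_isotherm([true], default_design())
    fit = fit_isotherm(series, "one_site")
    assert fit.status == "ok"
    s = fit.sites[0]
    assert s.ka == pytest.approx(true.ka, rel=1e-4)
    assert s.dh == pytest.approx(true.dh, rel=1e-4)
    assert s.n == pytest.approx(true.n, rel=1e-4)
    # derived identities hold by construction
    assert s.dg == pytest.approx(-R_KCAL * 298.15 * math.log(s.ka))
    assert s.tds == pytest.approx(s.dh - s.dg)


def test_all_zero_heats_is_no_binding():
    design = default_design()
    series = TitrationSeries(
        298.15, design.cell_volume, design.cell_conc, design.syringe_conc,
        design.injection_volumes, np.zeros(design.n_injections),
    )
    assert fit_isotherm(series).status == "NB"


def test_weak_binding_flagged_tltf():
    # high syringe concentration (20 mM scale) makes a Ka of 3e2 observable
    # but below the reliable-fit floor
    design = default_design(syringe_conc=2e-2)
    series = simulate_isotherm([BindingSite(3e2, -10.0, 1.0)], design)
    fit = fit_isotherm(series)
    assert fit.status == "TLTF"
    assert fit.sites[0].ka < 5e2


def test_too_few_injections_for_parameters_errors():
    design = default_design(n_injections=5)
    series = simulate_isotherm([BindingSite(4.8e4, 1.6, 0.7), BindingSite(5e3, -17.5, 1.3)], design)
    with pytest.raises(ValueError, match="parameters"):
        fit_isotherm(series, "two_site")


def test_two_site_recovery_with_separated_kas():
    """Well-separated site classes (10x apart, as in the arabinooctaose
    two-site fit) are recovered from a titration that saturates both."""
    design = default_design(n_injections=35, syringe_conc=2.5e-3)
    true = [BindingSite(4.8e4, 1.6, 0.7), BindingSite(5.0e3, -17.5, 1.3)]
    fit = fit_isotherm(simulate_isotherm(true, design), "two_site")
    assert fit.status == "ok" and not fit.poor_identifiability
    for s, t in zip(fit.sites, true):
        assert s.ka == pytest.approx(t.ka, rel=0.10)
        assert s.dh == pytest.approx(t.dh, rel=0.10)
        assert s.n == pytest.approx(t.n, rel=0.10)


def test_two_site_close_kas_flagged_poorly_identifiable():
    design = default_design(n_injections=35, syringe_conc=2.5e-3)
    true = [BindingSite(5e4, -8.0, 1.0), BindingSite(3.5e4, -6.0, 1.0)]
    fit = fit_isotherm(simulate_isotherm(true, design), "two_site")
    assert fit.poor_identifiability


def test_fixed_stoichiometry_fit():
    design = default_design()
    true = BindingSite(1e5, -10.0, 1.0)
    fit = fit_isotherm(simulate_isotherm([true], design), "one_site", fix_n=[1.0])
    assert fit.sites[0].n == 1.0
    assert fit.sites[0].ka == pytest.approx(true.ka, rel=1e-4)


@pytest.mark.parametrize(
    "ka,t,expected_dg",
    [(4.8e4, 298.15, -6.4), (6.8e5, 298.15, -7.95), (1.0e6, 298.15, -8.2), (1.0, 298.15, 0.0)],
)
def test_derive_thermodynamics_published_values(ka, t, expected_dg):
    dg, _ = derive_thermodynamics(ka, -10.0, t)
    assert dg == pytest.approx(expected_dg, abs=0.05)


def test_tds_from_enthalpy_and_free_energy():
    # xylotriose: dH -12.9, dG -4.1 -> TdS -8.8
    _, tds = derive_thermodynamics(math.exp(4.1 / (R_KCAL * 298.15)), -12.9)
    assert tds == pytest.approx(-8.8, abs=0.01)
    with pytest.raises(ValueError):
        derive_thermodynamics(0.0, -10.0)


def test_audit_published_table_free_energies():
    """Every printed Ka reproduces its printed dG to within one-decimal
    rounding at 298.15 K."""
    report = thermo_consistency(datasets.itc_table(numeric_only=True))
    assert report["dg_pass"].all()
    assert report["dg_dev"].max() <= 0.05


def test_audit_flags_internally_inconsistent_rows():
    """The published table carries three rows whose printed dH - TdS does
    not return the printed dG within 0.15 kcal/mol; the audit reports
    exactly those."""
    report = thermo_consistency(datasets.itc_table(numeric_only=True))
    failing = report.loc[~report["cycle_pass"], ["htcs", "ligand", "site"]]
    got = {tuple(r) for r in failing.itertuples(index=False)}
    assert got == {
        ("BACOVA_02740", "glucotetraose C (b4,3,4)", 1),
        ("BACOVA_02097", "galactomannan (carob)", 1),
        ("BACOVA_02097", "galactomannan (carob)", 2),
    }


def test_audit_fabricated_row_fails():
    row = pd.DataFrame({"ka": [1e3], "dg": [-9.9], "dh": [-10.0], "tds": [-0.1]})
    report = thermo_consistency(row)
    assert not report["dg_pass"].iloc[0]


def test_audit_empty_table():
    report = thermo_consistency(pd.DataFrame(columns=["ka", "dg", "dh", "tds"]))
    assert len(report) == 0 and "row_pass" in report.columns
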