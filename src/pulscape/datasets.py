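"""Published reference tables used as pipeline inputs.

Three small tables from the comparative *B. thetaiotaomicron* (Bt) /
*B. ovatus* (Bo) glycan-utilization study are bundled as plain TSV text:

* ``growth_table`` -- mean growth rate (dA600/h) and final density (A600)
  +/- one SD over 6 replicate cultures, per species and substrate
  ("NG" = no growth);
* ``mutant_growth_table`` -- HTCS-mutant growth density as percent of
  wild-type on each mutant's primary substrate;
* ``itc_table`` -- ITC binding parameters of HTCS periplasmic sensor
  domains: Ka (M^-1), dG, dH, TdS (kcal/mol) and stoichiometry N per site
  at 25 C.  Two-site entries carry one row per site; NB = no binding,
  TLTF = too low to fit (Ka below ~5e2 M^-1).

These are *inputs* to the audit/summary operations (e.g. recomputing
dG = -RT ln Ka for every row, or the pectic-galactan vs galactose rate
ratio); nothing here is produced by the fitting code.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

_GROWTH_TSV = """\
substrate	class	bt_rate	bt_rate_sd	bt_density	bt_density_sd	bo_rate	bo_rate_sd	bo_density	bo_density_sd
arabinan	pectin	0.037	0.003	0.56	0.02	0.007	0.002	0.13	0.06
arabinogalactan	pectin	0.045	0.007	0.60	0.04	NG	NG	NG	NG
pectic galactan	pectin	0.093	0.013	0.82	0.10	0.057	0.012	0.75	0.17
homogalacturonan	pectin	0.066	0.013	0.70	0.13	0.042	0.008	0.55	0.06
rhamnogalacturonan I	pectin	0.027	0.004	0.54	0.04	0.036	0.005	0.65	0.06
rhamnogalacturonan II	pectin	0.033	0.005	0.50	0.04	0.040	0.003	0.61	0.01
arabinoxylan	hemicellulose	NG	NG	NG	NG	0.030	0.016	0.63	0.12
xylan, water soluble	hemicellulose	NG	NG	NG	NG	0.024	0.009	0.65	0.09
xyloglucan	hemicellulose	NG	NG	NG	NG	0.065	0.021	0.75	0.11
glucomannan	hemicellulose	NG	NG	NG	NG	0.027	0.003	0.27	0.05
galactomannan	hemicellulose	NG	NG	NG	NG	0.105	0.027	0.94	0.04
beta-glucan	hemicellulose	NG	NG	NG	NG	0.028	0.014	0.67	0.12
amylopectin (potato)	alpha-glucan	0.075	0.007	0.96	0.04	0.101	0.014	1.12	0.09
pullulan	alpha-glucan	0.063	0.004	0.82	0.05	0.068	0.039	0.76	0.20
dextran	alpha-glucan	0.108	0.017	1.07	0.05	0.114	0.028	1.15	0.09
inulin	fructan	0.005	0.002	0.25	0.07	0.026	0.004	0.59	0.05
levan	fructan	0.036	0.007	0.52	0.04	NG	NG	NG	NG
arabinose	monosaccharide	0.031	0.004	0.28	0.04	0.033	0.021	0.43	0.19
fructose	monosaccharide	0.073	0.006	0.99	0.03	0.048	0.005	0.88	0.04
galactose	monosaccharide	0.038	0.003	0.42	0.03	0.041	0.029	0.75	0.41
galacturonic acid	monosaccharide	0.021	0.002	0.62	0.02	0.010	0.003	0.57	0.08
glucose	monosaccharide	0.067	0.013	0.81	0.13	0.084	0.026	0.89	0.20
mannose	monosaccharide	0.103	0.006	1.24	0.05	0.061	0.041	0.95	0.12
xylose	monosaccharide	0.049	0.005	0.50	0.04	0.047	0.027	0.80	0.34
"""

_MUTANT_TSV = """\
pul	primary_substrate	htcs_mutant	pct_of_wild_type	pct_sd
BT3674-87	arabinogalactan	BT3678	149.9	4.4
BT0262-90	arabinogalactan	BT0267	78.9	5.5
BT0348-69	arabinan	BT0366	48.3	4.9
BT4145-83	rhamnogalacturonan I	BT4178	58.5	2.0
BT0977-30	rhamnogalacturonan II	BT0981	78.3	4.2
BT4667-72	pectic galactan	BT4673	21.6	1.0
BT4108-23	homogalacturonan	BT4111	11.6	0.9
"""

_ITC_TSV = """\
htcs	ligand	site	status	ka	ka_sd	dg	dh	tds	n	n_sd
BT0366	arabinohexaose	1	ok	3.9e3	0.9e3	-4.9	7.6	12.5	1.2	0.2
BT0366	arabinohexaose	2	ok	1.5e3	0.1e3	-4.3	-6.5	-2.2	4.6	0.7
BT0366	arabinoheptaose	1	ok	3.5e4	0.6e4	-6.2	0.6	6.8	1.3	0.1
BT0366	arabinoheptaose	2	ok	3.2e3	0.2e3	-4.8	-12.5	-7.7	1.6	0.2
BT0366	arabinooctaose	1	ok	4.8e4	0.1e4	-6.4	1.6	8.0	0.7	0.1
BT0366	arabinooctaose	2	ok	5.0e3	0.6e3	-5.0	-17.5	-12.5	1.3	0.1
BT0366	arabinan (linear)	1	ok	1.0e5	0.0	-6.8	-26.8	-20.0
BT0366	arabinopentaose	1	NB
BACOVA_04394	xylobiose	1	TLTF
BACOVA_04394	xylotriose	1	ok	1.1e3	0.1e3	-4.1	-12.9	-8.8	1.0	0.0
BACOVA_04394	xylotetraose	1	ok	6.8e5	1.2e5	-7.95	-10.5	-2.55	1.3	0.1
BACOVA_04394	xylopentaose	1	ok	8.8e4	2.9e4	-6.7	-1.2	5.5	1.1	0.2
BACOVA_04394	xylohexaose	1	TLTF
BACOVA_04394	xylan (oat)	1	NB
BACOVA_02740	glucotriose A (b3,4)	1	NB
BACOVA_02740	glucotriose B (b4,3)	1	ok	3.4e3	1.9e3	-4.8	-9.65	-4.85	1.1	0.1
BACOVA_02740	glucotetraose B (b4,4,3)	1	ok	2.5e3	1.3e3	-4.6	-8.6	-4.0	0.9	0.2
BACOVA_02740	glucotetraose C (b4,3,4)	1	ok	3.2e4	0.7e4	-6.1	-14.0	-8.1	1.2	0.1
BACOVA_02740	glucopentaose A (b3,4,4,4)	1	TLTF
BACOVA_02740	cellobiose	1	TLTF
BACOVA_02097	mannotetraose	1	ok	2.0e4	0.6e4	-5.9	2.3	8.2	1.0	0.0
BACOVA_02097	mannotetraose	2	ok	2.7e3	0.3e3	-4.7	-5.4	-0.7	4.8	0.5
BACOVA_02097	mannopentaose	1	ok	1.95e5	0.25e5	-7.2	0.4	7.6	0.2	0.0
BACOVA_02097	mannopentaose	2	ok	4.65e3	0.25e3	-5.0	-34.7	-29.7	1.0	0.1
BACOVA_02097	mannohexaose	1	ok	1.0e6	1.2e6	-8.2	1.4	9.6	0.05	0.01
BACOVA_02097	mannohexaose	2	ok	3.6e4	1.4e4	-6.2	-26.0	-19.8	1.2	0.1
BACOVA_02097	galactomannan (carob)	1	ok	6.0e5	2.4e5	-7.9	-8.6	-2.0
BACOVA_02097	galactomannan (carob)	2	ok	6.4e4	0.4e4	-6.55	-23.2	-16.45
BACOVA_02097	di-galactosyl mannopentaose	1	NB
"""


def growth_table() -> pd.DataFrame:
    """Per-substrate growth rates and densities; "NG" parsed to NaN with a
    per-species ``*_grew`` flag."""
    df = pd.read_csv(io.StringIO(_GROWTH_TSV), sep="\t", dtype=str)
    out = df[["substrate", "class"]].copy()
    for col in ("bt_rate", "bt_rate_sd", "bt_density", "bt_density_sd",
                "bo_rate", "bo_rate_sd", "bo_density", "bo_density_sd"):
        out[col] = pd.to_numeric(df[col].replace("NG", np.nan))
    out["bt_grew"] = df["bt_rate"] != "NG"
    out["bo_grew"] = df["bo_rate"] != "NG"
    return out


def mutant_growth_table() -> pd.DataFrame:
    """HTCS-mutant percent-of-wild-type growth densities."""
    return pd.read_csv(io.StringIO(_MUTANT_TSV), sep="\t")


def itc_table(numeric_only: bool = False) -> pd.DataFrame:
    """Published ITC binding parameters; ``numeric_only`` drops NB/TLTF rows."""
    df = pd.read_csv(io.StringIO(_ITC_TSV), sep="\t")
    for col in ("ka", "ka_sd", "dg", "dh", "tds", "n", "n_sd"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if numeric_only:
        df = df[df["status"] == "ok"].reset_index(drop=True)
    return df


def regulated_gene_counts() -> dict:
    """Genome-scale regulated-gene counts at the 10-fold cutoff.

    Bt: 280 genes altered on pectins/pullulan, 268 up, 12 down.  Bo: 259
    genes altered on hemicelluloses/homogalacturonan, 229 up, 30 down, of
    which 140 upregulated genes lay in the 112 detected PULs.
    """
    return {
        "bt": {"n_regulated": 280, "n_up": 268, "n_down": 12},
        "bo": {"n_regulated": 259, "n_up": 229, "n_down": 30, "n_up_in_pul": 140},
    }
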