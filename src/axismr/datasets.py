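"""Bundled example data.

``candidate_mediation_pathways()`` returns the 20 candidate gut-microbiota →
immune-cell → lung-cancer pathways from a published mediation screen: each
row is an immune-cell phenotype that passed the two UVMR steps and the
direction check for a given microbial exposure and lung-cancer subtype,
together with its marginal (UVMR) odds ratio and its multivariable (MV-IVW)
effect adjusted for the exposure.  It exercises the step-4 retention logic
without any per-variant GWAS data: applying the multivariable p < 0.05 rule
retains 7 pathways carried by 6 distinct immune-cell phenotypes.

``reported_mediation_proportions()`` returns the mediation proportions (in
percent) reported for the retained pathways, for side-by-side display.
"""

from __future__ import annotations

import io as _io

import pandas as pd

_CANDIDATES_TSV = """\
outcome	mediator	uvmr_or	uvmr_ci_low	uvmr_ci_high	uvmr_p	exposure	mvmr_beta	mvmr_ci_low	mvmr_ci_high	mvmr_p
NSCLC	CD45RA on naive CD8+ T cell	1.045	1.008	1.085	0.020	g_Eggerthella	0.048	-0.007	0.102	0.086
NSCLC	Plasma blast-plasma cell absolute count	0.963	0.935	0.992	0.012	c_Clostridia	-0.054	-0.128	0.019	0.148
NSCLC	Plasma blast-plasma cell absolute count	0.963	0.935	0.992	0.012	o_Clostridiales	-0.054	-0.128	0.019	0.148
LUAD	CD27 on CD20- B cell	1.078	1.003	1.160	0.042	s_Bacteroides_clarus	0.074	-0.035	0.183	0.182
LUAD	CCR7 on naive CD8+ T cell	1.069	1.010	1.132	0.022	s_Alistipes_putredinis	0.084	0.015	0.154	0.018
LUAD	CD45 on lymphocyte	0.932	0.880	0.988	0.017	s_Bacteroides_clarus	-0.022	-0.084	0.041	0.499
LUSC	IgD- CD24- B cell %B cell	0.963	0.928	0.999	0.046	g_Gordonibacter	-0.099	-0.204	0.005	0.062
LUSC	IgD- CD24- B cell %B cell	0.963	0.928	0.999	0.046	s_Gordonibacter_pamelaeae	-0.099	-0.203	0.005	0.063
LUSC	IgD- CD27- B cell %lymphocyte	0.924	0.861	0.992	0.028	g_Gordonibacter	-0.092	-0.176	-0.009	0.029
LUSC	IgD- CD27- B cell %lymphocyte	0.924	0.861	0.992	0.028	s_Gordonibacter_pamelaeae	-0.093	-0.175	-0.010	0.029
LUSC	SSC-A on lymphocyte	0.887	0.810	0.970	0.009	g_Gordonibacter	-0.035	-0.146	0.076	0.532
LUSC	SSC-A on lymphocyte	0.887	0.810	0.970	0.009	s_Gordonibacter_pamelaeae	-0.035	-0.146	0.076	0.531
SCLC	CD20- CD38- B cell %lymphocyte	0.867	0.767	0.981	0.023	s_Bacteroides_clarus	-0.235	-0.400	-0.071	0.005
SCLC	Effector memory CD8+ T cell absolute count	0.931	0.870	0.996	0.039	s_Bifidobacterium_bifidum	0.032	-0.069	0.134	0.533
SCLC	CD20 on IgD+ CD38- unswitched memory B cell	0.883	0.798	0.976	0.015	s_Streptococcus_thermophilus	-0.133	-0.247	-0.019	0.023
SCLC	CD25 on activated CD4 regulatory T cell	1.137	1.003	1.288	0.044	s_Escherichia_unclassified	0.083	-0.078	0.244	0.311
SCLC	HLA DR on CD14- CD16+ monocyte	0.844	0.747	0.953	0.006	s_Bifidobacterium_bifidum	-0.158	-0.282	-0.035	0.012
SCLC	CD45 on granulocytic myeloid-derived suppressor cells	0.891	0.803	0.989	0.030	f_Lactobacillaceae	-0.127	-0.235	-0.019	0.021
SCLC	CD8 on effector memory CD8+ T cell	1.133	1.005	1.277	0.041	s_Streptococcus_thermophilus	0.092	-0.077	0.260	0.286
SCLC	CD4 on CD39+ activated CD4 regulatory T cell	1.107	1.005	1.221	0.040	s_Streptococcus_thermophilus	0.067	-0.102	0.236	0.437
"""

_PROPORTIONS_TSV = """\
outcome	mediator	exposure	proportion_pct	p_mediation
LUAD	CCR7 on naive CD8+ T cell	s_Alistipes_putredinis	9.5	0.018
LUSC	IgD- CD27- B cell %lymphocyte	g_Gordonibacter	11.8	0.029
LUSC	IgD- CD27- B cell %lymphocyte	s_Gordonibacter_pamelaeae	11.9	0.029
SCLC	CD20- CD38- B cell %lymphocyte	s_Bacteroides_clarus	13.8	0.005
SCLC	CD20 on IgD+ CD38- unswitched memory B cell	s_Streptococcus_thermophilus	14.1	0.023
SCLC	HLA DR on CD14- CD16+ monocyte	s_Bifidobacterium_bifidum	8.7	0.012
SCLC	CD45 on granulocytic myeloid-derived suppressor cells	f_Lactobacillaceae	4.0	0.021
"""


def candidate_mediation_pathways() -> pd.DataFrame:
    """The 20 candidate pathways with UVMR and MV-IVW estimates."""
    return pd.read_csv(_io.StringIO(_CANDIDATES_TSV), sep="\t")


def reported_mediation_proportions() -> pd.DataFrame:
    """Published mediation proportions (%) for the retained pathways."""
    return pd.read_csv(_io.StringIO(_PROPORTIONS_TSV), sep="\t")
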