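"""Published reference estimates for worked examples and regression tests.

``reference_dmps`` returns the 13 epigenome-wide significant smoking-reactive
CpGs reported by a large within-pair EWAS of monozygotic twin pairs
discordant for current versus never smoking (n = 53 pairs), together with the
corresponding estimates in pairs discordant for former versus never smoking
(n = 72 pairs).  Mean differences are non-smoking twin minus smoking twin on
the residualized beta-value scale (positive = higher methylation in the
non-smoking twin); coordinates are genome build 37.  These printed estimates
serve as fixed inputs for worked examples (effect-size summaries, confidence
interval consistency, percent reduction after cessation); they are not
recomputed here because the underlying individual-level data are
access-controlled.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["reference_dmps", "STUDY_PAIR_COUNTS", "N_CPGS_TESTED"]

#: Pairs per group in the reference study.
STUDY_PAIR_COUNTS = {
    "discordant_current_never": 53,
    "discordant_former_never": 72,
    "discordant_current_former": 66,
    "concordant_current": 83,
    "concordant_former": 88,
    "concordant_never": 406,
}

#: Autosomal CpGs tested after probe filtering in the reference study.
N_CPGS_TESTED = 411_169

_DMP_TSV = """\
cpg_id	chrom	pos	gene	mean_diff_cn	p_cn	ci_low_cn	ci_high_cn	t_cn	mean_diff_fn	p_fn	ci_low_fn	ci_high_fn	t_fn
cg05575921	5	373378	AHRR	0.132	4.9e-11	0.100	0.165	8.265	0.027	3.3e-4	0.013	0.041	3.778
cg21566642	2	233284661		0.092	1.5e-10	0.069	0.115	7.960	0.033	3.2e-6	0.020	0.046	5.067
cg05951221	2	233284402		0.066	1.8e-9	0.048	0.084	7.270	0.026	4.6e-6	0.016	0.037	4.964
cg01940273	2	233284934		0.060	2.1e-9	0.044	0.077	7.240	0.018	1.3e-4	0.009	0.027	4.052
cg13411554	3	53700276	CACNA1D	-0.038	6.0e-9	-0.049	-0.027	-6.947	-0.007	0.10	-0.016	0.002	-1.655
cg01901332	11	75031054	ARRB1	0.025	8.0e-9	0.018	0.033	6.868	0.006	0.16	-0.002	0.013	1.425
cg21161138	5	399360	AHRR	0.046	1.9e-8	0.032	0.059	6.642	0.002	0.64	-0.006	0.009	0.466
cg00336149	3	53700195	CACNA1D	-0.027	2.0e-8	-0.035	-0.019	-6.615	-0.002	0.60	-0.008	0.005	-0.524
cg22132788	7	45002486	MYO1G	-0.056	2.4e-8	-0.073	-0.039	-6.596	-0.011	4.5e-3	-0.019	-0.004	-2.930
cg21188533	3	53700263	CACNA1D	-0.036	3.9e-8	-0.047	-0.025	-6.437	-0.006	0.24	-0.015	0.004	-1.196
cg09935388	1	92947588	GFI1	0.052	4.1e-8	0.035	0.068	6.423	0.002	0.61	-0.006	0.010	0.519
cg25648203	5	395444	AHRR	0.035	5.3e-8	0.024	0.046	6.353	0.002	0.48	-0.004	0.008	0.710
cg19089201	7	45002287	MYO1G	-0.040	7.5e-8	-0.053	-0.028	-6.260	-0.007	0.13	-0.017	0.002	-1.529
"""


def reference_dmps() -> pd.DataFrame:
    """The 13 published smoking-reactive CpGs (``_cn``: current/never pairs,
    ``_fn``: former/never pairs), indexed by CpG id."""
    df = pd.read_csv(io.StringIO(_DMP_TSV), sep="\t", dtype={"chrom": str})
    df["gene"] = df["gene"].fillna("")
    return df.set_index("cpg_id")
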