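"""Published group-level summaries used as generator calibration and worked-example inputs.

Striatal BPND group statistics (mean, SD, n) for wild-type (WT) and
heterozygous (HET) Q175DN mice under three reference-tissue models, from
the in-vivo study this package's synthetic cohorts emulate. The raw scans
were never deposited, so these printed summaries are the only quantitative
anchor: the cohort generator draws subject parameters from them, and the
worked examples recompute the derived table columns (inter-subject COV,
percent genotypic difference, effect size d) from them.
"""

from __future__ import annotations

#: model -> genotype -> (mean BPND, SD, n); 90-min acquisition, striatum.
GROUP_BPND: dict[str, dict[str, tuple[float, float, int]]] = {
    "srtm": {"WT": (11.54, 2.03, 9), "HET": (7.09, 0.65, 14)},
    "mrtm": {"WT": (11.99, 2.10, 9), "HET": (7.44, 0.70, 14)},
    "logan": {"WT": (12.31, 2.34, 9), "HET": (7.62, 0.98, 14)},
}

#: Test-retest cohort sizes (subjects with both sessions).
TRT_N = {"WT": 4, "HET": 7}

#: Manually delineated volume-of-interest sizes (cm^3).
VOI_VOLUMES_CM3 = {
    "striatum_wt": 0.0215,
    "striatum_het": 0.0208,
    "cerebellum": 0.0507,
}

#: Scanner reconstruction voxel edge length (mm).
VOXEL_SIZE_MM = 0.776
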