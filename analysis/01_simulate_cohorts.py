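#!/usr/bin/env python
"""Generate the two synthetic cohorts the downstream analyses consume.

Cross-sectional cohort: 9 WT + 14 HET subjects, one session each, subject
BPND drawn from the published genotype distributions (SRTM column).
Test-retest cohort: 4 WT + 7 HET subjects scanned twice, retest parameters
perturbed by the 3% within-subject default.

Writes per-scan TAC CSVs, a manifest and the ground-truth table for each
cohort under results/cohorts/.
"""

from pathlib import Path

from refkin import io as rio
from refkin import synth
from refkin.datasets import GROUP_BPND, TRT_N

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"
SEED = 20260926
NOISE = synth.NoiseModel(alpha=0.05)


def main() -> None:
    wt = GROUP_BPND["srtm"]["WT"]
    het = GROUP_BPND["srtm"]["HET"]

    cross = synth.simulate_cohort(
        synth.CohortSpec(
            groups={
                "WT": synth.GroupSpec(wt[2], wt[0], wt[1]),
                "HET": synth.GroupSpec(het[2], het[0], het[1]),
            },
            sessions=1,
            seed=SEED,
        ),
        noise=NOISE,
    )
    trt = synth.simulate_cohort(
        synth.CohortSpec(
            groups={
                "WT": synth.GroupSpec(TRT_N["WT"], wt[0], wt[1]),
                "HET": synth.GroupSpec(TRT_N["HET"], het[0], het[1]),
            },
            sessions=2,
            seed=SEED + 1,
        ),
        noise=NOISE,
    )
    for name, cohort in [("cross", cross), ("trt", trt)]:
        manifest = rio.write_cohort(cohort.scans, OUT / name)
        cohort.truth.to_csv(OUT / name / "truth.csv", index=False)
        print(f"{name}: {len(cohort.scans)} scans -> {manifest}")


if __name__ == "__main__":
    main()
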