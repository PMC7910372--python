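# refkin

Reference-tissue kinetic modelling and test–retest reproducibility analysis
for dynamic PET, built around the quantification of the dopamine D1 receptor
radioligand [11C]SCH23390 in mouse brain (wild-type vs heterozygous Q175DN
Huntington's-disease-model mice). The receptor-rich striatum is quantified
against the receptor-free cerebellum, so no arterial blood sampling is
needed.

## What it computes

For a striatal time–activity curve C_T(t) and a cerebellar reference curve
C_R(t) on a 39-frame, 90-min schedule (12×10 s, 3×20 s, 3×30 s, 3×60 s,
3×150 s, 15×300 s):

* **SRTM** (basis functions): C_T = R1·C_R + (k2 − R1·k2a)·(C_R ⊛ e^(−k2a·t)),
  with BP_ND = k2/k2a − 1 and R1 = K1/K1′ the relative delivery. Solved by a
  log-spaced grid over k2a with a bounded local polish.
* **SRTM2 / MRTM2**: two-parameter variants with the reference efflux k2′
  fixed (conventionally from a prior MRTM fit).
* **MRTM**: multilinear form C_T(T) = γ1·∫C_R + γ2·∫C_T + γ3·C_R(T);
  BP_ND = −(γ1/γ2 + 1), k2′ = γ1/γ3, R1 = γ3, with a noise-propagation-aware
  %SE for k2′.
* **Logan Ref**: DVR from the slope of ∫C_T/C_T vs (∫C_R + C_R/k2′)/C_T past
  t* = 15 min; BP_ND = DVR − 1.
* **SUVR−1** over the 40–60 and 70–90 min windows as a model-free surrogate.
* **Parametric maps**: the same fitters per voxel (NIfTI in/out) with
  explicit failed-voxel handling, plus map-vs-VOI agreement statistics.
* **Time stability**: refits on TACs truncated from 90 down to 45 min in
  5-min steps; a duration is acceptable when the group-mean change is
  within 10% with inter-individual SD below 5%.
* **Reproducibility**: TRV = 100·(retest − test)/mean, aTRV = |TRV|,
  intra-animal COV, Bland–Altman bias ± 1.96·SD on percent differences,
  absolute-agreement ICC (genotype as fixed effect), Pearson r², pooled
  t-test, Cohen's d = Δmean/√((SD₁² + SD₂²)/2).

Because the original scans were never deposited, the package ships a
synthetic generator (`refkin.synth`): a Feng-type plasma input drives one-
and two-tissue compartment models on a 1-s grid, curves are frame-averaged
onto the acquisition schedule, and decay-aware Gaussian noise plus
genotype-level parameter distributions produce cross-sectional and paired
test–retest cohorts with the published group structure.

## Worked example

```python
from refkin import synth, fit_srtm, fit_mrtm, fit_logan_ref
from refkin.tac import make_default_schedule

sched = make_default_schedule()
t = synth.fine_grid(sched.duration_min)
ref_curve = synth.simulate_1t(synth.feng_aif(t), synth.DEFAULT_REF_TISSUE, t)
truth = synth.SRTMTruth(r1=1.0, k2=0.35, bpnd=11.54)   # WT-like striatum
target = synth.srtm_forward(ref_curve, truth, t)
striatum = synth.frame_average(target, t, sched, "striatum")
cerebellum = synth.frame_average(ref_curve, t, sched, "cerebellum")

s = fit_srtm(striatum, cerebellum)
m = fit_mrtm(striatum, cerebellum)
l = fit_logan_ref(striatum, cerebellum, k2_prime=m.k2_prime)
print(f"SRTM  BPND {s.bpnd:.3f}  R1 {s.r1:.3f}")
print(f"MRTM  BPND {m.bpnd:.3f}  k2' {m.k2_prime:.4f}")
print(f"Logan BPND {l.bpnd:.3f}  (DVR {l.dvr:.3f})")
```

prints

```
SRTM  BPND 11.524  R1 1.002
MRTM  BPND 11.524  k2' 0.3514
Logan BPND 11.524  (DVR 12.524)
```

i.e. all three models recover the injected BP_ND = 11.54 within 0.15% on
noise-free data, and SRTM and MRTM agree to within 0.01% — the mechanism
behind the near-perfect cross-model correlations seen with this tracer.

## Analysis pipeline

The numbered drivers under `analysis/` run the full study on synthetic
cohorts and write tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py    # 9 WT + 14 HET, and 4 + 7 paired
python analysis/02_fit_kinetic_models.py  # per-scan fits + group summary
python analysis/03_time_stability.py      # stability vs scan duration
python analysis/04_test_retest.py         # TRV/aTRV/ICC/Bland-Altman table
python analysis/05_parametric_maps.py     # phantom maps, failed voxels
```

The same steps are available as a CLI (`refkin simulate|fit|maps|stability|
trt-report|suvr --config cfg.yaml --out dir [--seed N]`); each run writes
its resolved config next to its outputs. Config keys per subcommand are the
keyword arguments of the corresponding library functions (see
`tests/test_cli.py` for complete working configs).

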