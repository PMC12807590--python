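# imrteval

Paired evaluation of IMRT treatment plans for elongated cranio-caudal
targets: plan complexity, dosimetric indices, EUD-based radiobiology,
γ-index QA, and within-subject Wilcoxon statistics — driven either by your
own plan/dose/structure files or by a built-in synthetic paired-cohort
generator.

## The problem

Elective nodal irradiation of upper thoracic esophageal cancer forces a
single IMRT field to span ≥ 20 cm cranio-caudally, from the supraclavicular
fossae to the upper mediastinum. Modulating one long window ("extended
field", EF) produces small, ragged MLC apertures and a broad
intermediate-to-low-dose bath in the lungs — the dose range most strongly
associated with radiation pneumonitis. A pragmatic alternative is
*segmented jaw-locking* (SJL): the Y jaws split the target at the thoracic
inlet into a cervical-supraclavicular and an upper-mediastinal window, MLC
modulation is confined to each window, each window gets its own gantry-angle
set, and a 2-cm feathered overlap removes the junction cold/hot spot.

`imrteval` implements everything needed to quantify that comparison and to
exercise it end-to-end on synthetic patients:

* **Aperture complexity.** For each control point the jaw-clipped
  rectilinear aperture with exact area *A* and perimeter *P*, the edge-area
  metric `EAM = P²/(4πA)` (1 for a disc, 4/π for a square; higher = more
  irregular), and the MU-weighted plan value `EAM_plan = Σ MU_i·EAM_i / Σ MU_j`.
* **Sequence complexity.** The modulation complexity score
  `MCS = Σ_i MU_i · (AAV_{i-1}+AAV_i)/2 · (LSV_{i-1}+LSV_i)/2 / Σ_i MU_i ∈ [0,1]`,
  from aperture-area variability (AAV) and leaf-sequence variability (LSV).
* **Dosimetry.** Exact voxel-counting DVHs; V₅–V₃₀, MLD, D_max, D₂%, D₉₈%;
  `CI = V_RI/V_PTV`; `HI = (D₂% − D₉₈%)/D_p`;
  `GM = max|D50% surface − centroid| − R_PTV` with `R_PTV = (3V_PTV/4π)^(1/3)`.
* **Radiobiology.** `EUD = (Σ v_i D_i^a)^(1/a)` and the logistic models
  `TCP = 1/(1+(TCD50/EUD)^{4γ50})`, `NTCP = 1/(1+(TD50/EUD)^{4γ50})` with
  shipped parameters (esophageal tumor 49.09 Gy/2.16/−8; lung 34 Gy/0.9/3;
  cord 68.6 Gy/1.9/13).
* **γ QA.** 3%/3 mm global-normalization γ index with a 10% low-dose
  threshold, detector-array decimation, and gantry-0 phantom-plane
  composition at 5 cm depth.
* **Statistics.** Paired Wilcoxon signed-rank with an exact
  (tie-midranked) permutation distribution for n ≤ 25 and a corrected
  normal approximation beyond, summarized into the standard comparison
  tables.
* **Synthetic cohort.** `generate_cohort` draws paired patients (default
  n = 40): one anatomy (elongated PTV, two lungs, posterior cord), one EF
  plan (9 beams at 0°/25°/50°/75°/160°/200°/285°/310°/335°), one SJL plan
  (7 cervical beams at 285°–75° with the caudal window edge 2 cm below the
  isocenter, 6 "butterfly" thoracic beams at 330°/350°/10°/30°/160°/200°
  with the cranial edge at the isocenter), and a documented forward dose
  model normalized to PTV D₉₅% = 95% of 50 Gy.

## Worked example

`examples/paired_cohort_analysis.py` generates an 8-patient paired cohort
and prints the Wilcoxon comparison (SJL − EF differences):

```
        metric  SJL_mean  EF_mean  difference  p_value
           EAM    2.3978  12.2213     -9.8236   0.0078
           MCS    0.7984   0.5447      0.2537   0.0078
            CI    1.0366   1.3555     -0.3189   0.0078
            HI    0.1611   0.3950     -0.2340   0.0078
 lung_left_MLD    4.0105  10.1816     -6.1710   0.0078
 lung_left_V_5   19.5120  73.1166    -53.6046   0.0078
lung_left_V_20    5.8232   9.4795     -3.6564   0.0078
NTCP_lung_left    3.3065   5.2472     -1.9407   0.0078
       TCP_PTV   56.2947  74.2059    -17.9112   0.0078

worst jaw-locked junction deviation: 1.0% of prescription
```

Jaw locking lowers aperture complexity (EAM ↓, MCS ↑) and the
intermediate-to-low lung dose (MLD, V₅, V₂₀ and lung NTCP ↓), while the
feathered overlap keeps the junction flat to within 1% of the
prescription. With 8 pairs the smallest attainable two-tailed exact p is
2/2⁸ ≈ 0.0078 — every contrast here is maximally signed.

The other examples are single-capability walkthroughs:
`complexity_metrics.py` (EAM/MCS of a hand-built beam), `dose_and_dvh.py`
(sphere phantom: CI = 1.000, HI = 0.001, GM = 2.00 cm, R_PTV = 3.00 cm),
`radiobiology_models.py` (logistic midpoints and a partial-lung DVH),
`gamma_qa_check.py` (phantom-plane γ: 100% at +2% dose error, 66.8% at +5%).

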