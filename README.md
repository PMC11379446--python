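# emgspace

Spatiotemporal analysis of high-density surface EMG (HD-sEMG) during
sustained isometric contractions: topographical amplitude maps, tracking
of the activation centroid, and a suite of posturography-derived spatial
metrics that quantify how muscle activity redistributes as fatigue
develops — together with endurance-time detection and the
repeated-measures statistics used to assess fatigue progression.

## Who this is for

Researchers in neuromuscular physiology, rehabilitation and sport
science who record multichannel surface EMG with electrode grids (the
reference montage is two fused 13×5 grids → one 26×5 matrix, 8 mm
inter-electrode distance, two missing corner electrodes → 128 channels
over 200×32 mm) plus a torque channel from a dynamometer, and want to go
from raw monopolar signals to per-segment fatigue variables and cohort
statistics. A built-in simulator generates grid recordings and torque
traces with known ground truth (centroid drift path, spectral decline,
failure time), so the entire chain is testable without human data.

## The method

1. **Conditioning.** Torque: zero-phase 3rd-order Butterworth low-pass,
   10 Hz. EMG: zero-phase 3rd-order Butterworth band-pass 20–450 Hz plus
   a 50 Hz notch (Q = 30). Low-SNR channels are excluded (automatic
   screen against the quasi-zero reference, or declared in the sidecar).
2. **Segmentation.** Transient marks on the torque ascent/descent define
   two 4-s "quasi-zero activity" windows (mark ± 2 s); the analysis
   region lies strictly between them. Three 10-s segments are placed at
   the beginning (T1), middle (T2, centered) and end (T3) of the region.
   Endurance time runs from hold onset until torque stays ≤ 50 % MVT
   (maximum voluntary torque) for ≥ 3 s.
3. **Features.** Per channel: RMS envelope (500 ms moving average,
   sampled at the 10 Hz map rate) and AIF — the average instantaneous
   frequency, computed as the spectral centroid of non-overlapping
   500 ms Hann periodogram frames in the 20–450 Hz band.
4. **Topography.** Each envelope frame becomes a rows×cols map; the
   **Region of Activation (RoA)** is the amplitude-weighted centroid of
   the cells ≥ 70 % of the map maximum (the CoG is the threshold-free
   variant). Coordinates are physical: FT = fiber-transverse (columns),
   FP = fiber-parallel (rows), in mm.
5. **Spatial metrics.** Classical center-of-pressure sway statistics
   transplanted onto the RoA trajectory (u, v) per segment (N frames,
   duration T), with per-direction (FT / FP) variants:

   | metric | definition | CoP analog |
   |---|---|---|
   | AID (mm) | (1/N) Σ √(x²+y²), deviations from the initial-position reference | MDIST |
   | AIP (mm) | Σ √(Δu²+Δv²) (total path) | TOTEX |
   | AIV (mm/s) | AIP / T | MVELO |
   | AIS (mm) | √(std_FT² + std_FP²) | RDIST |
   | AEZ (mm²) | 2π F₀.₉₅(2, N−2) √(s_u² s_v² − s_uv²) (95 % confidence ellipse) | AREA-CE |
   | ACZ (mm²) | π (mean RD + 1.645 std RD)² (95 % confidence circle) | AREA-CC |
   | AMZ (mm²/s) | (1/2T) Σ \|xₙ yₙ₋₁ − xₙ₋₁ yₙ\| (swept area rate) | AREA-SW |

   plus the T1→T3 displacement of the mean RoA.
6. **Statistics.** Per variable: Shapiro–Wilk screening, the Friedman
   test over T1/T2/T3 with Kendall's W effect size (small < 0.3,
   moderate < 0.5, large ≥ 0.5; an exact permutation p is computed for
   small tie-free tables), Wilcoxon signed-rank post-hocs with a
   Bonferroni factor of 3, and per-metric OLS regression of endurance
   time on the subject-wise metric maxima (R², p).

## Worked example

`examples/02_fatigue_metrics.py` simulates one subject whose activity
center drifts 20 mm along the fibers while the spectral centroid falls,
then runs the full pipeline:

```
endurance time: 38.0 s (censored=False)
variable              T1        T2        T3
torque_cov         0.014     0.019     0.029
aif              237.993   226.483   217.142
aid                3.455    10.413    17.063
aid_fp             3.317    10.377    17.043
...
T1->T3 displacement of the RoA: 13.88 mm
```

Reading the numbers: torque variability (CoV) rises with fatigue, the
AIF falls by ~21 Hz from T1 to T3 (the injected spectral compression),
and the mean distance of the RoA from its initial position (AID, driven
here by its FP component) grows as the activity center migrates — the
displacement recovers the injected drift between segment centers.
`examples/01_simulate_and_track.py` shows frame-level tracking against
ground truth and `examples/03_cohort_statistics.py` runs the
repeated-measures battery and the endurance regression over a simulated
cohort.

A thin CLI wraps the same library calls:

```bash
emgspace simulate --config sim.json --out subj/ --seed 7
emgspace analyze --emg subj/rec.csv --sidecar subj/rec.json \
                 --torque subj/torque.csv --out subj_results/
emgspace stats subj1_results/ subj2_results/ ... --out cohort/
```

Recordings travel as channels×samples CSV plus a JSON sidecar
(`fs_hz`, grid geometry, missing/bad channels, `mvt_nm`); all result
tables are CSV/JSON stamped with the configuration hash, and reruns with
the same seed are byte-identical.

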