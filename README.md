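# fadynamics

Quantitative analysis of focal-adhesion (FA) dynamics for high-content
imaging screens, with three analysis arms around a common synthetic-data
backbone:

1. **FA morphometrics** — segment nuclei and focal adhesions from
   multi-channel fluorescence images (pTyr118-paxillin / vinculin
   staining) and extract per-adhesion features (area, perimeter,
   elongation, orientation, compact factor, …). Images with fewer than
   3 nuclei are excluded; objects smaller than 4 pixels (0.46 μm² at
   0.339 μm/px) are ignored.
2. **Screen statistics** — compare adhesion-size distributions across a
   three-condition perturbation assay (DMSO baseline, nocodazole-driven
   FA assembly, washout-driven FA disassembly) with a *signed*
   two-sample Kolmogorov–Smirnov test and classify genes into hit
   categories. The signed D-statistic is the maximal ECDF difference
   with a sign (positive = larger adhesions); p-values are carried in
   log10 because screen-scale samples push them far below double
   underflow. Stringent hit cuts: D > 0.1 with p < 10⁻⁴⁰ for size
   increase, D < −0.075 with p < 10⁻²⁵ for decrease; genes whose
   adhesions fail to enlarge under nocodazole are *assembly-blocked*,
   genes whose enlarged adhesions fail to shrink after washout are
   *disassembly-blocked*.
3. **Single-cell migration** — track nuclei through time-lapse movies by
   frame-to-frame pixel overlap, compute per-cell average speeds around
   a growth-factor stimulation, and compare populations with
   Kruskal–Wallis + Dunn's post test (normality assessed by the
   all-three-tests rule: Lilliefors-KS, d'Agostino–Pearson,
   Shapiro–Wilk).
4. **Micropillar traction forces** — convert movies of a hexagonal
   elastomeric micropillar array (4 μm pitch, 2 μm diameter, 4.1 μm
   height) into per-pillar force time series. Pillar tops are localized
   to ~8 nm by iterated intensity-weighted centroids, an undeflected
   reference grid is fitted to pillars outside the cell footprint, and
   forces follow F = k·δ with bending stiffness k = 65.8 nN/μm
   (effective Young's modulus E_eff = 9k/(4πr) ≈ 47 kPa). Pillars are
   tracked with a 2 μm gate and 2-frame gap closing; the top 5% deflected
   cell-coupled pillars enter force summaries and a force-magnitude
   autocorrelation whose exponential fit gives the force turnover
   half-time (ln 2 / λ over the first 2 h, 25 points at 5-min frames).
   Conditions are compared with Welch's t-test (mean forces) and the
   extra-sum-of-squares F-test (half-times).

The **synthetic** module generates seeded images, movies, and plate
tables with full ground truth (per-object positions, sizes, deflections
and identities), so every stage above is validated against known truth.

## Worked example

Analyse a synthetic micropillar movie end to end:

```python
from fadynamics import synthetic, tfm

cfg = synthetic.PillarSimConfig(
    n_pillars=400, n_frames=80,         # 400 min at 5-min frames
    ou_sd_um=0.3, ou_tau_min=30.0,      # force fluctuation scale and memory
    detection_noise_um=0.05, miss_rate=0.02, seed=42,
)
movie = synthetic.generate_pillar_movie(cfg)
res = tfm.analyze_pillar_movie(movie.pillar_movie, movie.actin_movie)

print(f"grid pitch: {res['grid'].pitch_um:.3f} um")
print(f"tracked full-length: {res['n_full_length']} / {len(movie.pillars)}")
print(f"mean force per selected pillar: "
      f"{res['summary']['per_pillar_mean_force'].mean():.1f} nN")
print(f"force half-time: {res['autocorr'].halftime_min:.1f} min")
```

prints

```
grid pitch: 4.001 um
tracked full-length: 357 / 389
mean force per selected pillar: 31.2 nN
force half-time: 11.8 min
```

The fitted pitch recovers the configured 4 μm lattice; 91.8% of pillars
are tracked through all 80 frames despite 2% missed detections; the
mean force of the top-5% pillars corresponds to the configured
Ornstein–Uhlenbeck deflection scale (0.3 μm/component × 65.8 nN/μm);
and the half-time ≈ τ·ln2/2 expected for the *magnitude* of a 2-D OU
force vector with 30-min component memory.

A command-line interface wraps the same pipelines:

```
fadyn simulate pillars --config pillars.yaml --out sim/
fadyn pillar-forces --movie sim/pillars.tif --actin sim/actin.tif --out tfm/
fadyn run-screen --layout plate.csv --effects effects.yaml --out hits/
```

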