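# respmech

Respiratory–postural coupling analysis for whole-body motion-capture trials.

Breathing and balance are coupled: trunk volume change displaces the body's
centre of mass (COM), and the postural system must absorb that perturbation.
Practices such as Tai Chi train slow, diaphragmatic breathing synchronized
with slow multi-directional movement, and quantifying *how* expert movers
coordinate (or deliberately decouple) respiration and posture requires a
pipeline that goes from raw laboratory signals to interpretable group
statistics. `respmech` implements that pipeline for movement-science
researchers working with optical motion capture, force plates and surface
EMG:

1. **Chest-wall volumetry** — optoelectronic-plethysmography style: a grid
   of trunk markers (default 4 rings × 8 columns = 32 markers) is meshed
   into a closed triangulated surface per frame and its enclosed volume is
   computed by the divergence theorem, `V = |Σ v₀ · (v₁ × v₂)| / 6` over the
   triangles, split into upper-thoracic, lower-thoracic and abdominal
   compartments whose volumes add to the total exactly.
2. **Breath analysis** — trough → peak → trough segmentation of the volume
   signal with prominence-based extremum picking; inspiratory time `Ti`,
   expiratory time `Te`, tidal volume `V_T`, and per-compartment
   contributions `100 · ΔV_k / ΔV_total`.
3. **Posture kinematics** — force-plate centre of pressure
   (`COP_x = −M_y/F_z`, `COP_y = M_x/F_z`), segment-model whole-body COM,
   Cardan joint angles (flexion → abduction → rotation sequence) and
   per-plane range of motion.
4. **EMG** — band-passed, full-wave rectified, integrated over each movement
   cycle (`iEMG = ∫|v| dt`), normalized by a reference-contraction peak.
5. **Coupling** — per movement cycle and axis, the cross-correlation
   coefficient `CCF = max_τ |r(τ)|` between the respiratory volume signal
   and COM displacement, with the lag and zero-lag value reported alongside.
6. **Group statistics** — Shapiro–Wilk routing to a pooled-variance t-test
   (Hedges' g, `g = J·(m₁−m₂)/s_p`, `J = 1 − 3/(4N−9)`) or a Mann–Whitney U
   test (rank-biserial `r = 2U/(n₁n₂) − 1`), Benjamini–Hochberg FDR within
   outcome families, 95% CIs, and a noncentral-t sample-size calculator.

Because raw chest-wall capture data of this kind are rarely shared, the
package ships a first-class **synthetic trial generator**
(`respmech.synthetic`) whose breathing trunk, articulated body, plate and
EMG channels all have analytic ground truth — including a coupling dial
κ ∈ [0, 1] that sets the fraction of anteroposterior COM sway driven by the
breathing signal. Every pipeline stage is validated against it.

## Worked example

```python
from respmech.pipeline import run_trial
from respmech.synthetic import SyntheticConfig, generate_trial

cfg = SyntheticConfig(seed=0, kappa=0.25)   # 25% of AP sway breathing-driven
trial = generate_trial(cfg)                 # markers + plate + EMG + truth
features = run_trial(trial.bundle)          # the full per-trial chain
tm = features.trial_means
print(f"breath period  {tm['inspiratory_time_s'] + tm['expiratory_time_s']:.2f} s")
print(f"tidal volume   {tm['max_respiratory_volume_L']:.3f} L")
print(f"knee sag ROM R {tm['knee_sagittal_rom_deg_R']:.1f} deg")
print(f"ccf_x          {tm['ccf_x']:.3f}")
```

prints

```
breath period  4.00 s
tidal volume   0.809 L
knee sag ROM R 60.1 deg
ccf_x          0.549
```

— the generator was configured for 15 breaths/min (4.0 s period), 0.8 L
tidal volume and a ±30° knee oscillation (60° ROM), so the pipeline is
recovering the generating parameters through the mesh/segmentation chain;
`ccf_x` sits between the uncoupled noise floor (~0.1) and full coupling
(~1.0), as it should at κ = 0.25.

The numbered scripts under `analysis/` run the package's own studies:
trial-level demo (`01`), parameter-recovery table (`02`), coupling sweep
over κ (`03`), a 21-vs-21 synthetic group battery with FDR control (`04`),
and recomputation of published effect sizes from printed group summaries
(`05`). Each writes its tables under `results/`.

There is also a CLI (`respmech simulate|features|volumes|breaths|posture|
emg|coupling|battery|report`) whose subcommands run single stages on a
trial directory, so the pipeline can be entered mid-way from files on disk.

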