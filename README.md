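# gaitbench

Benchmarking the stability of bipedal walking from whole-body dynamics and
foot placement.

`gaitbench` is aimed at movement scientists and legged-robotics researchers
who want quantitative stability benchmarks for walking trials: it
reconstructs dynamically consistent whole-body walking motions from marker
trajectories using subject-specific multibody models and a multi-phase
least-squares optimal control problem, and computes capture-point-based
stability measures from the result (or from any COM/CoP trajectory,
including synthetic ones).

## The quantities it computes

Walking is viewed through the linear inverted pendulum model (LIPM) with
eigenfrequency ω₀ = √(g/l):

* **Instantaneous Capture Point (ICaP)** — the ground point
  r_icap = r_ref + ṙ_com/ω₀: stepping onto it brings the LIPM to rest.
  Human walkers place their feet so the ICaP falls around the fore/midfoot
  of the landing foot; `gaitbench` reports the per-step anterior and medial
  ICaP offsets in the landing foot's frame.
* **Normalized orbital energy** — E′_lip = ½ ṙ′²_com − ½ (r′_com − r′_cop)² ω₀²,
  with all position-like quantities divided by the subject's leg length.
* **Residual orbital energy (E′_res)** — E′_lip evaluated right after each
  heel strike, side-labelled and stride-averaged. Forward-progressing gait
  maintains E′_res > 0; its magnitude and left/right asymmetry summarise how
  much "unfinished falling" a walker carries into each new step.
* **Whole-body angular momentum** about the COM, decomposed into upper-body
  and lower-body contributions per anatomical plane, revealing compensation
  strategies (e.g. with asymmetric limb inertia).

The reconstruction chain behind these numbers: subject-specific inertial
parameters from sex-specific regression tables (with optional prosthesis
adjustment), a 13-segment / 34-DoF multibody model (reduced from the full
16-segment / 43-DoF model), per-frame least-squares inverse kinematics on
marker data, and a least-squares optimal control problem over the eight
contact phases of a stride with perfectly inelastic impact transitions at
the four touch-downs. See `docs/methods.md` for the details.

## Worked example

Simulate ten steps of a synthetic LIPM gait (COM height 0.9 m, step length
0.6 m, step width 0.2 m, step time 0.55 s) and benchmark it:

```sh
gaitbench pipeline --out demo_run --seed 0
```

prints

```
Normalized residual orbital energy E'_res [1/s^2]
   Left HS   Right HS    Average
    0.5298     0.5298     0.5298
```

Each column is the mean E′_res over that side's heel strikes (here 1/s²,
normalized by the 0.9 m pendulum length). The synthetic gait is perfectly
periodic and mirror-symmetric, so left and right agree to machine
precision, and the value is positive — the signature of self-sustained
forward progression. A cautious walker (shorter steps, slower) gives a
smaller value; real recordings give asymmetries between the columns.
`demo_run/metrics/residual_orbital_energy.csv` holds the per-heel-strike
table and `summary.json` the side means, stride average and asymmetry
ratio, together with the configuration echo (ICaP mode, ω₀ mode, leg
length) that makes the run reproducible.

The same metrics come out of a full reconstruction of marker data:

```sh
gaitbench simulate --kind walker --out trial/      # or your own TRC file
gaitbench ik --markers trial/markers.trc --out trial/
gaitbench reconstruct --reference trial/reference_motion.csv \
    --events trial/events.csv --out trial/
```

As a library: `gaitbench.lipm.simulate_lipm_gait`,
`gaitbench.markerik.fit_trajectory`,
`gaitbench.reconstruction.solve_reconstruction` and
`gaitbench.metrics.residual_orbital_energy` are the main entry points.

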