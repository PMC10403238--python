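# anomtrans

Characterization of anomalous particle transport in crowded and active
media, coupling real-space single-particle-tracking (SPT) analysis with
reciprocal-space differential dynamic microscopy (DDM).

Micron-scale tracers in cytoskeleton-like composites — entangled biopolymer
networks driven by molecular motors — rarely diffuse normally.  Their
mean-squared displacement scales as `MSD ~ dt^alpha` with `alpha < 1`
(subdiffusion from caging and crowding) at short lag times and can cross
over to `alpha > 1` (superdiffusion from motor-driven advection) at longer
ones; their displacement distributions grow exponential tails, non-zero
modes and leading/trailing-edge asymmetry.  This package implements the
full analysis chain that quantifies those signatures, for experimentalists
with trajectory tables from standard tracking software and/or raw image
stacks:

* **`anomtrans.spt_msd`** — ensemble time-averaged MSDs on the half-sum
  convention `MSD = 0.5 (<dx^2> + <dy^2>)`; detection of the regime
  timescales `t1` (end of initial power law, largest expanding log–log
  window with R² > 0.99) and `t2` (first local minimum of MSD/dt); power-law
  exponents `alpha_1`, `alpha_12`, `alpha_2` per regime.
* **`anomtrans.vanhove`** — van Hove distributions `G(dd, dt)`; FWHM
  scaling `FWHM² ~ dt^alpha`; mode `dd_peak`, leading/trailing half-widths
  and the asymmetry `(HWHM₋ − HWHM₊)/HWHM₊`; Gaussian + exponential mixture
  fits `A e^{−dd²/2σ²} + B e^{−|dd|/λ}` with fractional amplitudes
  `a = A/(A+B)`, `b = B/(A+B)`.
* **`anomtrans.ddm`** — radially averaged image structure function
  `D(q, dt)`; per-q stretched-exponential fits
  `A(q)[1 − e^{−(dt/τ)^γ}] + B(q)`; the transport classifier
  `τ(q) ~ q^{−β}` (β = 2 diffusive, 1 ballistic) and `alpha_DDM = 2/β`;
  q-averaged stretching exponent γ.
* **`anomtrans.syntraj`** — synthetic trajectories (exact fractional
  Brownian motion, quenched-velocity advection, Ornstein–Uhlenbeck caging
  with Poisson hops, multi-mode sums with analytic crossovers) and a
  Gaussian-PSF renderer producing TIFF stacks, so the whole chain is
  testable with known ground truth.
* **`anomtrans.pipeline` / CLI `anomtrans`** — one config drives both
  analysis tracks over many conditions and emits a cross-method summary
  table comparing `alpha` from MSD, van Hove and DDM.

## Worked example

Generate a multi-mode synthetic ensemble — caged subdiffusion (`alpha =
0.35`) plus motor-like advection whose analytic MSD terms cross at 5 s —
and extract the regime structure:

```python
from anomtrans import syntraj as st
from anomtrans.spt_msd import analyze_msd

cfg = st.SimConfig(n_particles=150, n_frames=1500, frame_interval=0.1, seed=8)
model = st.MotionModel(kind="multimode", alpha=0.35,
                       generalized_coefficient=0.01, crossover_time=5.0)
tracks = st.gen_multimode_tracks(cfg, model)

curve, regimes = analyze_msd(tracks, max_lag=60.0, fit_cap=60.0)
print(f"t1 = {regimes.t1:.1f} s   t2 = {regimes.t2:.1f} s")
print(f"alpha1 = {regimes.alpha1.exponent:.2f} +/- {regimes.alpha1.stderr:.2f}")
print(f"alpha2 = {regimes.alpha2.exponent:.2f} +/- {regimes.alpha2.stderr:.2f}")
```

prints

```
t1 = 2.1 s   t2 = 3.9 s
alpha1 = 0.41 +/- 0.01
alpha2 = 1.71 +/- 0.02
```

Read: the initial subdiffusive power law holds out to 2.1 s; MSD/dt turns
up at 3.9 s — right where the analytic minimum of the generator's MSD sits
(≈ 0.77 × the 5 s term crossover) — and the fitted short/long-regime
exponents bracket 1 as advection takes over.  The slopes sit above the bare
component exponents (0.35 and 2) because over any finite window the sum of
two power laws fits an intermediate slope; `syntraj.
multimode_effective_exponents` gives the exact expected values per window.

The same tracks can be rendered into an image stack and pushed through DDM
(`syntraj.render_image_stack`, `ddm.analyze_stack`), or everything can be
driven from a YAML config:

```sh
anomtrans simulate --config sim.yaml --outdir data --seed 1
anomtrans all --config analysis.yaml --outdir results
```

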