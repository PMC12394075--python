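# smfretkit

Analysis chain for single-molecule FRET studies of dimeric receptor
activation — built around the conformational dynamics of metabotropic
glutamate receptor (mGluR) dimers, where ligand-binding-domain (LBD)
clamshell closure, inter-subunit twisting and cysteine-rich-domain (CRD)
approach are distinct, loosely coupled steps with rates spanning from well
below to far above the camera frame rate.

The package is aimed at single-molecule spectroscopists and modellers who
need the full quantitative chain testable on synthetic data with known
ground truth:

- **Trace simulation** — exact continuous-time Markov chain (CTMC) sampling
  with camera time-averaging, per-frame Gaussian noise and single-step
  photobleaching; every trace carries its latent path.
- **QC** — automated photobleach truncation (acceptor < 5, donor < 5,
  sum < 10 a.u., persistent over 3 frames) and the trace-count ratio
  c = n/n′ feeding the missed-trace correction.
- **HMM idealization** — shared maximum-likelihood Gaussian HMM (2–4
  states, 10 restarts, 10⁻⁶ tolerance), Viterbi paths, censored dwell
  statistics, and rate constants k = −ln(1−P)/τ.
- **Sub-frame kinetics** — Bayesian inference of rates faster than the
  frame rate from the time-averaged occupancy-fraction distribution
  (point masses plus a Bessel-form continuous part), with a global
  likelihood sharing emissions across datasets and affine-invariant
  ensemble MCMC (median, 16–84% credible interval, MAP).
- **Equilibria** — Gaussian-mixture histogram decomposition, the
  missed-trace occupancy correction (f′_A = c·f_A), the independent-closure
  expectation p², linear gating-scheme occupancies, and the Förster
  conversion R = R₀((1−E)/E)^(1/6).
- **Structure metrics** — Cα reporter distances, clamshell distance,
  lower-lobe center-of-mass separation, hydrogen-bond tests (3.5 Å / 50°),
  windowed RMSF and inter-helix angles on PDB/mmCIF models.
- **Differential HDX** — maximal-deuteration normalization, Woods-plot
  classification with the inclusive ±10 %D gray band, replicate uptake
  curves.

`docs/methods.md` documents the models, numerical choices and limitations.

## Worked example

Simulate clamshell-like dynamics far above the frame rate (k_f = k_r =
100 s⁻¹ at 20 ms frames, k·τ = 2), where idealization saturates, and
recover both rates from the shape of the efficiency distribution:

```python
import smfretkit as sk
from smfretkit.subres import infer_rates_global

model = sk.KineticModel.two_state(100.0, 100.0, 0.44, 0.66, noise_sd=0.05)
traces, _ = sk.simulate_trace_set(model, 100, 900, 0.02, seed=1)
pooled = sk.pooled_fret(traces)

result = infer_rates_global([pooled], tau=0.02, seed=1)
lo, med, hi = result.summary.interval("k1_0")
print(f"k1 = {med:.0f} [{lo:.0f}, {hi:.0f}] 1/s")
```

This prints (seed 1, 90,000 frames):

```
k1 = 95 [86, 101] 1/s
```

i.e. the posterior median recovers the generating 100 s⁻¹ within a few
percent and the 16–84% credible interval covers it — although at 50 frames
per second the molecule switches state roughly twice per frame and no
transition is directly observable. The same traces pooled into a histogram
center at the emission midpoint (E ≈ 0.505), the classic signature of
fast exchange.

The numbered scripts under `analysis/` run the narrative end-to-end —
simulation, QC, slow-regime HMM rates, fast-regime posterior, occupancy
correction and gating, structure metrics, HDX classification — writing
tables to `results/` (bulky per-trace files go to `scratch/`, which is
disposable). A `smfretkit` command-line interface wraps the same library
calls (`smfretkit simulate traces`, `qc`, `idealize`, `infer-subres`,
`fit-hist`, `correct`, `fret2dist`, `struct-dist`, `hdx-delta`, `run`,
`check`).

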