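# Methods

This note documents the models behind `smfretkit`, the choices made where
the design was genuinely open, and what the synthetic-data studies do and do
not establish about real measurements.

## The measurement model

A single receptor is modelled as a continuous-time Markov chain (CTMC) over
a small number of conformational states, each with an apparent-FRET emission
mean ε_s (unitless, typically within [−0.2, 1.2]). A camera integrates the
photon signal over a frame period τ, so the observed efficiency of frame *t*
is the dwell-time-weighted average of the state means plus Gaussian noise:

    E_t = Σ_s f_{t,s} · ε_s + N(0, σ),

where f_{t,s} is the fraction of the frame spent in state *s*. The simulator
(`synthetic.simulate_trace`) samples the latent path exactly — exponential
waiting times, stationary initial state (overridable), alternating dwells in
the two-state case — and computes the per-frame fraction matrix from the
exact jump times, so generated traces carry their full ground truth.

Donor and acceptor channels are synthesized from a fixed total intensity
(500 a.u.) as acceptor = total·E and donor = total·(1−E); apparent FRET is
always acceptor/(donor+acceptor) with no gamma or crosstalk correction, so
all quantities are in apparent-FRET units. Noise is modelled at the E level
only; the per-channel decomposition of noise is not identified by anything
downstream and is not modelled. Photobleaching is a single exponential-time
event after which both channels collapse to |N(0, 1)| a.u., safely below the
QC thresholds. Donor-only blinking and other photophysics are out of scope.

Seeding: one master seed per trace set; per-trace generators are spawned
from a single `SeedSequence`, so sets are reproducible and order-independent.

## Trace QC

Frames are flagged when acceptor < 5 a.u., donor < 5 a.u., or their sum
< 10 a.u.; a trace is truncated at the first run of K = 3 consecutive
flagged frames (K configurable). The persistence rule exists because single
noisy frames below threshold are common at realistic σ; K = 3 recovers the
true bleach frame within ±3 frames in ≈100% of simulated bleaching traces
at σ = 0.05. Trimming is idempotent and never lengthens a trace. Traces
shorter than 50 frames after trimming (≈5 s at 10 frames/s) are excluded
from kinetic analysis; shorter records carry too few dwells to constrain
rates.

The per-condition count of surviving traces, normalized by the count under
a saturating-ligand reference, gives the correction factor c = n/n′ used by
the missed-trace correction (below). Values above 1 are retained with a
warning, since they indicate the reference itself lost traces.

## HMM idealization

`idealize.fit_hmm` fits a Gaussian-emission hidden Markov model with a
user-fixed state count (2–4) by maximum-likelihood EM, shared across all
traces of a condition (pooling granularity is the caller's choice; the
default is to pool everything passed in). This is deliberately plain EM
rather than an empirical-Bayes engine: with the state count fixed, model
selection machinery adds nothing that these analyses use, and the
maximum-likelihood transition matrix is what the rate conversion consumes.
Restarts (default 10) jitter quantile-initialized means with a seeded RNG;
convergence is a 10⁻⁶ relative log-likelihood tolerance, and the
log-likelihood trace of the winning restart is kept so monotonicity is
testable. States are relabelled ascending by emission mean, so "high-FRET"
is always the last index.

Viterbi decoding is implemented in-package; exact ties are broken toward
the lowest state index. Per-frame transition probabilities convert to rates
via k = −ln(1−P)/τ. Dwell tables censor the first and last dwell of every
trace (their boundaries were not observed) and report the
maximum-likelihood exponential rate 1/mean.

Two systematic effects of idealization at frame resolution are documented
and tested rather than corrected: (i) frame discretization makes the mean
apparent dwell 1/P frames ≈ 1/k + τ/2, a few-percent bias at kτ = 0.1;
(ii) once rates approach 1/τ the recovered rates saturate far below the
truth, which is the motivation for the sub-frame likelihood below.

## Sub-frame-rate inference

For a stationary two-state chain with escape rates k₁ (out of the low-ε₁
state) and k₂ (out of ε₂), the fraction f of a τ-window spent in state 1
has the mixed distribution

    P(f=1) = π₁e^(−k₁τ),  P(f=0) = π₂e^(−k₂τ),  π₁ = k₂/(k₁+k₂),

plus a continuous part derived here by conditioning on the number of jumps
(the resulting Bessel series is summed in closed form):

    p(f) = τ·exp(−τ(√(k₁f) − √(k₂(1−f)))²) ·
           [ (2k₁k₂/(k₁+k₂))·I₀ᵉ(2z)
             + (k₂√(k₁k₂f/(1−f)) + k₁√(k₁k₂(1−f)/f))/(k₁+k₂) · I₁ᵉ(2z) ],

with z = τ√(k₁k₂f(1−f)) and I_νᵉ the exponentially scaled modified Bessel
functions; the exponent is algebraically combined with the Bessel scaling so
the expression stays finite through kτ ≈ 100. The distribution integrates
to 1 to 10⁻⁸ across k ∈ [10⁻², 10³] s⁻¹ and τ ∈ {0.02, 0.1} s, and matches
a brute-force Monte-Carlo window simulator (an independent code path kept as
the in-repo oracle) with KS distance < 0.01 at 10⁶ windows.

The per-frame marginal likelihood integrates N(E | fε₁+(1−f)ε₂, σ) against
this distribution: point masses analytically, the continuous part by
fixed-order Gauss–Legendre quadrature (101 nodes by default, configurable).
At 101 nodes the quadrature agrees with adaptive integration to ~10⁻¹⁴ for
kτ ≤ 100; far beyond the inference range (kτ ≳ 10⁴) the occupancy
distribution narrows below the node spacing and the order must be raised,
which the tests of the fast-exchange limit do explicitly. Everything is
assembled in log space, so efficiencies far outside [ε₁, ε₂] are handled
stably.

### Priors, likelihood and sampling

Priors: ε₁ ~ N(0.44, 0.2), ε₂ ~ N(0.66, 0.2), σ log-uniform on
[0.01, 1.0], each rate log-uniform on [10⁻³, 10³] s⁻¹. The support is
additionally restricted to ε₁ ≤ ε₂: the prior means already define which
state is "low", and without the constraint the posterior contains an exact
label-swapped mirror mode that only complicates summaries. σ and the rates
are sampled on the log scale (log-uniform priors are uniform there).

The global likelihood shares (ε₁, ε₂, σ) across datasets with independent
(k₁ᵢ, k₂ᵢ) per dataset. For speed the likelihood histograms each dataset's
efficiencies onto 512 bins and sums counts × log-marginal at bin centers;
bin widths (≲0.002) are far below the smallest admissible σ (0.01), so the
approximation error is orders of magnitude below sampling noise. The exact
per-frame `frame_loglik` remains the public operation.

Sampling uses an affine-invariant ensemble (emcee), 4× the parameter
dimension walkers by default. Burn-in runs in 100-step chunks until the
ensemble-mean log-posterior changes by less than 0.1 between chunks, with a
floor of 300 and a cap of 1700 steps; burn-in is discarded, 100 production
steps are taken, every 10th sample summarizes the posterior (median and the
16th–84th percentile central 1σ interval), and the MAP is read off the full
production chain.

Initialization is the one place this package departs from initializing
walkers purely from the priors. The posterior over the rates is bimodal: a
"static" mode (compressed emission means, inflated σ, slow rates mimicking
a two-Gaussian mixture) competes with the fast-exchange mode, and with
6-decade log-uniform rate priors a prior-initialized stretch-move ensemble
reliably traps in the broad static basin even when the fast mode is
hundreds of nats better. The default (`init="map"`) therefore runs a
multistart MAP search — log-spaced symmetric-rate probes at the prior-mean
emissions plus the best of 256 prior draws, refined by Nelder–Mead — and
disperses walkers around the optimum with per-parameter scales taken from
the diagonal Laplace curvature there; an underdispersed starting ball
demonstrably produces too-narrow credible intervals at these chain lengths.
`init="prior"` retains pure prior initialization (and is what the
posterior-equals-prior identity test uses, where it is exact). Results are
robust to halving or doubling the walker count.

Identifiability: as kτ → 0 the likelihood approaches the static mixture,
which is independent of the rates, so the marginal posterior for k widens
toward the prior; this boundary behavior is asserted qualitatively in the
tests. In the quantified regime (kτ ≈ 2, e.g. 100 s⁻¹ at 20 ms frames) the
16–84% intervals cover generating rates in 9/10 seeded repetitions at
300 traces × 900 frames. Frames of one trace are treated as independent
draws of the stationary window distribution — exact for the marginal, and
adjacent-frame correlation (≈e^(−(k₁+k₂)τ) scale) is small in the regimes
analyzed; at much smaller datasets the finite-sample scatter of the rate
estimate exceeds the nominal interval width and coverage degrades, which is
why the recovery study runs at full size.

## Equilibrium analysis

Histogram decomposition offers both an unbinned maximum-likelihood mixture
fit (seeded EM) and a binned least-squares fit of a sum of Gaussians to the
density histogram (40 bins over E ∈ [−0.1, 1.1] by default — the binning of
the figures is not stated anywhere, so a round default is used), since it
is not recorded which variant produced published high-FRET fractions; both
report weights summing to 1 with components ascending in mean, and the
high-FRET fraction is the weight of the last component (optionally with a
bootstrap SE). Per-movie histograms averaged with s.e.m. across movies are
also provided, matching how published histograms are presented.

The missed-trace correction assumes only inactive (dim, low-FRET) molecules
are dropped by automated selection while every active molecule is observed:
f′_A = c·f_A and f′_I = 1 − c·f_A, which sum to one exactly (the
implementation computes the complement directly so the identity is exact in
floating point, not just algebraically). K′_eq = f′_A/f′_I, and when the
high→low rate is trusted (all such transitions are observed),
k′_f = K′_eq·k_r.

Cooperativity: with independent subunit closure at probability p, both
clamshells are closed with probability p². A linear gating scheme over
ordered states with adjacent equilibrium constants K_i gives occupancies
proportional to Π_{j<i}K_j; no kinetic content is implied, and no published
numbers exist for these constants — any shipped values are illustrative.

Distance conversion: R = R₀·((1−E)/E)^(1/6) with the exact inverse; the
high-FRET proximity state (E ≈ 0.85, R₀ = 51 Å) maps to 38.2 Å.

## Structural metrics

Coordinates are read from PDB/mmCIF (gemmi), one frame per model, into flat
atom arrays; author residue numbering is used as-is, and cross-receptor
positional equivalences are the caller's responsibility. Metrics: Cα–Cα
reporter-pair distances; the clamshell distance (residues 144–272 Cα within
one chain); lower-lobe separation as the distance between centers of mass
of residues 188–317 ∪ 452–474 per chain (standard atomic masses, or unit
masses for toy point clouds); hydrogen bonds with a 3.5 Å donor–acceptor
cutoff and a 50° cutoff on the deviation of D–H···A from linearity (the
convention of common trajectory tools; both configurable); windowed RMSF of
Cα 166–180 after least-squares superposition on the flanking segments
155–166 and 180–188 (two-pass: align to frame 0, rebuild the mean, align to
the mean — or to a supplied reference); and the inter-subunit helix angle
as the angle between first principal components of Cα 95–108 of each chain,
axes oriented N→C, reported in [0°, 180°] (an undirected mode folds to
[0°, 90°]). All metrics are rigid-motion invariant, which randomized
rotation/translation tests assert.

## Differential HDX

Uptake tables are tidy per-peptide records keyed by (start, end, sequence)
so duplicate intervals from collapsed charge states coexist. Normalization
divides %D by the maximal-deuteration fraction (default 0.90) and caps at
100 with a warning. Woods tables compare replicate means per peptide ×
timepoint: Δ%D = mean(B) − mean(A), negative meaning more protection in B;
|Δ%D| ≤ 10 (boundary inclusive) is "unchanged". No significance test backs
the classification by default — the comparison is a thresholded effect
size — but a Welch t-test column is available. Uptake curves report
replicate mean ± SD and flag non-monotonic means (possible EX1 or
back-exchange signature) without altering values.

The uptake generator draws saturating-exponential mean curves with
per-peptide amplitude spread, applies condition protection that ramps with
the curve itself (so the target Δ%D is realized at the longest timepoint),
and adds Gaussian replicate noise. It emulates none of the mass-spectral
layer (centroiding, charge states, back-exchange kinetics), so passing
tests establish the correctness of the classification arithmetic, not
robustness to spectral artifacts. The exchange timepoint grid of the real
experiments is not fully published; synthetic defaults use a log-spaced
grid ending at 13,200 s.

## Problem sizes and runtime

The shipped analyses and tests are sized for a single CPU: trace sets of
100–300 traces × 900 frames, 10⁶-window oracle comparisons, and 10-seed
posterior recovery at 300 × 900 frames (the binned likelihood makes MCMC
cost independent of frame count). The full test suite runs in roughly a
quarter hour; the acceptance script in about a minute.

## Known limitations

- The sub-frame likelihood is two-state only; 3–4-state sensors are handled
  by HMM idealization, not by a multi-state time-averaged likelihood.
- No dose–response fitting, no ligand-binding model beyond independent
  closure, no TIRF image processing, no MD engine — inputs begin at traces,
  coordinate files and uptake tables.
- Posterior intervals inherit the independent-frame approximation; at
  small frame counts they undercover (documented above).
- The static/fast posterior bimodality is resolved by initialization at the
  dominant mode; the negligible-mass secondary mode is not represented in
  the reported intervals.
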