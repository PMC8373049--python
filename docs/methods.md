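# Methods

## The measurement model

In time-correlated single-photon counting (TCSPC) under pulsed excitation,
each detected photon is recorded as a *microtime* Δt_k — the delay between
the peak of the excitation pulse and the photon's detection. The model
decomposes each microtime into two independent contributions:

* the excited-state dwell of the emitting molecule, which is memoryless and
  therefore exponential: Δt_ext ~ Exponential(λ), with λ = 1/τ the inverse
  lifetime of the emitting species, and
* an instrument error term collecting pulse width and detector/electronics
  jitter, modeled as Gaussian: Δt_err ~ Normal(τ_IRF, σ_IRF²). The width may
  be supplied directly or as a FWHM via σ = FWHM/2.355 (the conventional
  rounded constant, kept verbatim so printed conversions reproduce exactly;
  it agrees with the exact Gaussian value 2√(2 ln 2) to four significant
  figures).

Their sum follows the exponentially modified Gaussian (EMG) distribution

    p(Δt | λ) = (λ/2) · exp[(λ/2)(2(τ_IRF − Δt) + λσ²)]
                · erfc((τ_IRF − Δt + λσ²) / (σ√2)),

which is the per-photon likelihood everywhere in the package. Its support
is the whole real line: the Gaussian jitter legitimately produces
microtimes slightly before the IRF peak, so negative microtimes are legal
inputs.

Two standing assumptions: every detected photon stems from the immediately
preceding pulse (no wrap-around), valid when the pulse period exceeds
roughly four times the longest lifetime — violations trigger a warning,
never an error, since real acquisitions (including the canonical 40 MHz /
10 ns benchmark) routinely strain it; and at most one photon per pulse
(weak excitation), so pile-up is ignored.

## Numerical evaluation

The EMG density is evaluated exclusively in the log domain through the
scaled complementary error function, using the identity
log erfc(u) = log erfcx(u) − u². The u² term cancels the exponential
prefactor *exactly*, leaving

    log p = log(λ/2) − (Δt − τ_IRF)²/(2σ²) + log erfcx(u),

finite for any finite inputs. For u < −25 (deep right tail), where erfcx
itself overflows, erfc(u) = 2 to double precision and the evaluation
switches to the exact exponential-tail expression
log λ + λ(τ_IRF − Δt) + (λσ)²/2. The unit tests pin this evaluation
against direct adaptive quadrature of the Normal∗Exponential convolution
to 1e−8 over a grid spanning λσ from 1e−3 to 50.

The EMG CDF used by the histogram baseline is the closed form
Φ((x − τ_IRF)/σ) − p(x|λ)/λ, stabilized the same way.

## Mixture prior and inference

The number of contributing species is unknown, so the species label s_k of
each photon is Categorical(π) with a symmetric Dirichlet(α/M, …, α/M)
prior on π over M components — the truncated Dirichlet-process construction:
for M large the estimates are insensitive to M, and the *occupied* count
(components holding at least one photon tag) plays the role of the number
of species present. Inverse lifetimes carry independent Gamma(α_λ, β_λ)
priors.

Defaults, all config-exposed:

| parameter | default | why |
|---|---|---|
| truncation M | 20 | far above plausible species counts (≤ 4 in practice) at modest per-sweep cost; robustness vs M = 40 is tested |
| concentration α | 0.05 | see below |
| Gamma shape α_λ | 1 | weakly informative |
| Gamma rate β_λ | 1 ns | prior mean lifetime 1 ns, heavy right tail covering the typical 1–10 ns fluorophore range |

**Choosing α.** The occupied-component count inherits the
Dirichlet-process prior's clustering behavior: beyond the clusters the
likelihood supports, the prior contributes roughly α·ln K additional
transient singleton clusters per sweep. With α = 1 that is 4–8 spurious
clusters at realistic trace lengths, which would swamp the modal count.
α = 0.05 keeps the expected spurious-cluster mass below ~0.5 up to
K ≈ 2×10⁴ photons, so the modal occupied count tracks the number of
species the likelihood demands, while genuine extra species are still
found quickly (a poorly-fit photon faces a likelihood ratio of order e⁸
in favor of a fresh component, dwarfing the weight penalty).

**Sweep structure** (Metropolis-within-Gibbs):

1. tags: exact categorical conditional, P(s_k = m) ∝ π_m p(Δt_k|λ_m),
   drawn for all photons at once via the Gumbel-max trick;
2. weights: conjugate Dirichlet(α/M + n_1, …, α/M + n_M) draw;
3. inverse lifetimes: per-component Metropolis-Hastings on log λ
   (proposal λ′ = λ e^ε, ε ~ Normal(0, s²), acceptance including the λ′/λ
   Jacobian). Components with no assigned photons are refreshed by a
   direct prior draw — a valid Gibbs move that doubles as the mechanism
   for proposing new species.

The proposal scale s adapts by Robbins-Monro during burn-in toward 30%
acceptance and is frozen afterwards, preserving detailed balance of the
retained chain. Defaults: 5,000 sweeps, 25% burn-in, no thinning, central
95% quantile credible intervals. All randomness flows from one explicit
seed; runs are bit-reproducible.

**Initialization.** One component starts at the moment-matched rate
1/(mean microtime − τ_IRF) with all the weight mass; the rest start from
the prior. Starting from the merged side matters: the tag draw splits off
genuinely needed species within a few sweeps, whereas merging spurious
duplicates is the chain's slowest move (see Limitations).

**Background.** A known background weight b adds a uniform-over-period
pseudo-component with fixed weight to the tag draw; species weights scale
by 1 − b and background-tagged photons are excluded from all species
updates. The weight itself is never inferred.

**Label switching and summaries.** The species-count posterior is the
normalized histogram of occupied counts. Per-species summaries are
computed conditional on the modal count: within each qualifying sweep the
occupied components are sorted by lifetime ascending, and means, medians
and 95% intervals are taken position-wise. This is a deliberately simple,
reproducible identification rule; relabeling algorithms (e.g.
cost-minimizing permutation matching) are a documented alternative that
matters only when lifetimes are nearly degenerate. With one photon (or a
thin retained chain) the report sets a low-information flag.

## The simulator

`simulate_trace` draws, per photon: a species tag from the fractions, an
exponential dwell, and a Gaussian IRF error; optionally a known fraction
of photons is replaced by uniform background over one pulse period. The
defaults mirror the standard acquisition: 40 MHz pulse train (25 ns
period), σ_IRF = 0.1 ns, IRF peak at 0 ns by convention. Because the
inference consumes only microtimes, pulse-level detection thinning
(roughly one detection per hundred pulses) affects only absolute
timestamps and is not simulated by default; an option emits geometric
pulse indices for realism studies. Microtimes beyond one period are kept
(consistent with the no-wraparound likelihood); a strict mode
rejection-samples them away.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: diffusion of emitters through the confocal
volume (fractions are photon-source probabilities, not concentrations),
detector dead time and afterpulsing, multi-photon pile-up, non-Gaussian
IRFs, and lifetime changes during acquisition.

## Baselines

*Histogram fitting.* Microtimes are binned uniformly over one pulse period
(256 bins by default — the standard TCSPC channelization scale; the last
bin absorbs the over-period tail so counts are conserved). For a fixed
component count M the fit maximizes the Poisson likelihood of the bin
counts under the bin-integrated EMG mixture — correct for counts, rather
than the least-squares reading of the classical decay-sum model — with the
total intensity profiled out analytically, lifetimes optimized on a log
scale and weights through a softmax, using deterministic multi-start
Nelder-Mead. Fixing M is the baseline's defining limitation and is
demonstrated deliberately: fitting 3-species data with M = 1 converges to
a lifetime matching none of the generating species.

*Phasors.* The empirical phasor is the first-harmonic Fourier coordinate
pair G = mean cos(ωΔt), S = mean sin(ωΔt) at ω = 2π·harmonic/period.
Mono-exponential decays map to G = 1/(1+(ωτ)²), S = ωτ/(1+(ωτ)²), the
semicircle of radius ½ from (1,0) (τ→0) to (0,0) (τ→∞); mixtures land on
interior chords, which reveals multi-component character but not the
component count. IRF rotation is removed by complex division with the
Gaussian characteristic function exp(iωτ_IRF − ω²σ²/2); raw phasors remain
available. The exact pulsed-excitation phasor estimator used elsewhere in
the literature is not uniquely standardized; the empirical Fourier
coefficient used here is the common choice.

## Problem sizes used by the test and acceptance suites

Chosen as desk-scale versions of the benchmark protocols: single species
τ = 4 ns at 100 photons (10–40 seeds); two species 1/10 ns at 3,000
photons (10 seeds; the test suite uses 3,000-sweep chains, the acceptance
script the 5,000-sweep default); three species 0.5/2/10 ns at 2×10⁴
photons with a 6,000-sweep chain and 3,000-sweep burn-in; the
photon-budget ladder 1,500→2,000→5,000→10,000 over 5 seeds with
2,000-sweep chains. Collapsed-consistency checks run exhaustive
enumeration on 3-photon traces against 40,000-sweep chains.

## Known limitations

* **Merge mixing.** Transient duplicate components (two components sharing
  one true species' photons) die by a diffusive count walk, so occupied
  counts can stay inflated for O(n) sweeps on long traces. The moment
  initialization avoids manufacturing duplicates at the start, and longer
  burn-ins are used at 2×10⁴ photons; a Jain-Neal split-merge move would
  be the principled upgrade.
* **Close lifetimes.** At 3,000 photons a 1 ns / 1.5 ns pair is not
  resolved to the 10% yardstick (the well-separated 1/10 ns pair is) —
  consistent with the need for an order of magnitude more photons. At
  2×10⁴ photons the sampler finds two species, but recovering both
  lifetimes to 10% requires chain lengths beyond the default desk-scale
  budget; the tests therefore assert the 3,000-photon contrast only.
* The background weight must be known; joint inference of IRF parameters
  is out of scope; only Gaussian IRFs are supported; decays are assumed
  exponential.
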