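"""Simulate a two-species microtime trace and infer species + lifetimes.

Generates 3,000 photons from an equal mixture of 1 ns and 10 ns emitters
under a 40 MHz pulse train (Gaussian IRF, sigma = 0.1 ns), then runs the
photon-by-photon sampler. The printed species-count posterior shows how
strongly the data support each number of species; the per-species lines
give posterior-mean lifetimes with 95% credible intervals and the photon
fraction each species contributes.
"""

import warnings

from photontau import (
    Priors,
    SamplerSettings,
    SimConfig,
    default_acquisition,
    run_mcmc,
    simulate_trace,
    summarize,
)

warnings.filterwarnings("ignore", category=UserWarning)

period, irf = default_acquisition()
config = SimConfig(
    lifetimes=(1.0, 10.0),
    fractions=(0.5, 0.5),
    n_photons=3000,
    irf=irf,
    pulse_period=period,
    seed=7,
)
trace, truth = simulate_trace(config)
print(f"simulated {trace.n_photons} photons, true lifetimes {config.lifetimes} ns")

samples = run_mcmc(trace, Priors(), irf, SamplerSettings(seed=11))
report = summarize(samples, trace)

print("species-count posterior:")
for count, prob in sorted(report.species_count_posterior.items()):
    print(f"  {count} species: {prob:.3f}")
print(f"modal species count: {report.modal_species_count}")
est, frac = report.lifetime_estimates, report.fraction_estimates
for i in range(report.modal_species_count):
    print(
        f"species {i + 1}: tau = {est.mean[i]:.2f} ns "
        f"(95% CI {est.ci_low[i]:.2f}-{est.ci_high[i]:.2f}), "
        f"fraction = {frac.mean[i]:.2f}"
    )
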