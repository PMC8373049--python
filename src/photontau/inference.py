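"""Metropolis-within-Gibbs sampler for the Dirichlet-process mixture of
exponential decays, and posterior summarization.

The model: each photon's species tag s_k is Categorical(pi); pi carries a
symmetric Dirichlet(alpha/M, ..., alpha/M) prior over a truncation of M
components (the Dirichlet-process limit as M grows); each inverse lifetime
lambda_m carries an independent Gamma prior; the microtime likelihood is
the exponentially modified Gaussian of :mod:`photontau.model`. The number
of species "present" in a sweep is operationally the number of components
holding at least one photon tag, so the posterior over species counts is
read off the chain without trans-dimensional moves.

Sweep structure: tags (exact categorical draw), weights (conjugate
Dirichlet draw), inverse lifetimes (per-component Metropolis-Hastings on
log lambda; unoccupied components are refreshed directly from the prior,
a valid Gibbs move that lets new species be proposed cheaply).

Optionally a fixed, known background weight adds a uniform-over-period
pseudo-component to the tag draw; its weight is never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import (
    IRFModel,
    MixtureState,
    PhotonTrace,
    Priors,
    component_log_densities,
    emg_log_density,
)

__all__ = [
    "SamplerSettings",
    "PosteriorSamples",
    "SpeciesEstimates",
    "PosteriorReport",
    "sample_tags",
    "sample_weights",
    "sample_lifetimes",
    "run_mcmc",
    "summarize",
]


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC run configuration.

    ``proposal_scale`` is the standard deviation of the Gaussian random
    walk on log lambda; with ``adapt`` it is tuned by Robbins-Monro during
    burn-in toward ~30% acceptance and frozen afterwards (preserving
    detailed balance of the retained chain).
    """

    n_sweeps: int = 5000
    burn_in: int = 1250
    thinning: int = 1
    proposal_scale: float = 0.5
    seed: int = 0
    adapt: bool = True
    target_acceptance: float = 0.3
    keep_tags: bool = False

    def __post_init__(self) -> None:
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if not (0 <= self.burn_in < self.n_sweeps):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_sweeps")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if not (np.isfinite(self.proposal_scale) and self.proposal_scale > 0):
            raise ValueError("proposal_scale must be > 0")
        if not (0 < self.target_acceptance < 1):
            raise ValueError("target_acceptance must lie in (0, 1)")


@dataclass
class PosteriorSamples:
    """Retained chain: one row per kept sweep.

    ``inverse_lifetimes`` and ``weights`` are (S, M); ``counts`` holds the
    number of photons tagged to each component (background photons, if a
    background weight was supplied, are excluded). ``occupied_counts[i]``
    is the number of components with at least one tag in sweep i —
    the operational species count. ``log_posteriors`` is the unnormalized
    log joint (complete-data likelihood plus priors) of each kept state.
    ``tags`` is (S, K) only when the run kept per-photon tags.
    """

    inverse_lifetimes: np.ndarray
    weights: np.ndarray
    counts: np.ndarray
    occupied_counts: np.ndarray
    log_posteriors: np.ndarray
    acceptance_rate: float
    n_photons: int
    settings: SamplerSettings
    priors: Priors
    tags: np.ndarray | None = None

    @property
    def n_retained(self) -> int:
        return int(self.occupied_counts.size)

    @property
    def lifetimes(self) -> np.ndarray:
        """(S, M) matrix of lifetimes tau = 1/lambda."""
        return 1.0 / self.inverse_lifetimes


@dataclass(frozen=True)
class SpeciesEstimates:
    """Per-species posterior summaries, one entry per inferred species
    (sorted by lifetime ascending), conditional on the modal species count.
    """

    mean: np.ndarray
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


@dataclass(frozen=True)
class PosteriorReport:
    """Posterior summary: species-count distribution and, conditional on
    the modal count, per-species lifetime (ns) and photon-fraction
    estimates with central 95% credible intervals."""

    species_count_posterior: dict[int, float]
    modal_species_count: int
    lifetime_estimates: SpeciesEstimates
    fraction_estimates: SpeciesEstimates
    n_photons: int
    n_retained: int
    low_information: bool = False


def sample_tags(
    state: MixtureState, trace: PhotonTrace, irf: IRFModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-photon tags from their exact conditional.

    P(s_k = m) is proportional to pi_m * p(dt_k | lambda_m), normalized in
    the log domain; the draw uses the Gumbel-max trick so all K photons are
    sampled in one vectorized pass.
    """
    if trace.n_photons == 0:
        return np.empty(0, dtype=np.int64)
    logd = component_log_densities(trace, state.inverse_lifetimes, irf)
    with np.errstate(divide="ignore"):
        logp = logd + np.log(state.weights)[None, :]
    return _gumbel_argmax(logp, rng)


def _gumbel_argmax(logp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    g = rng.gumbel(size=logp.shape)
    # -inf + finite gumbel stays -inf, so zero-weight components never win
    return np.argmax(logp + g, axis=1).astype(np.int64)


def sample_weights(
    tags: np.ndarray, priors: Priors, rng: np.random.Generator
) -> np.ndarray:
    """Draw mixture weights from the conjugate Dirichlet conditional.

    pi | tags ~ Dirichlet(alpha/M + n_1, ..., alpha/M + n_M), n_m the
    number of photons tagged m. With no photons this is the prior.
    """
    m = priors.truncation
    tags = np.asarray(tags, dtype=np.int64)
    counts = np.bincount(tags, minlength=m) if tags.size else np.zeros(m)
    w = rng.dirichlet(priors.concentration / m + counts)
    # guard against exact-zero draws from tiny Dirichlet parameters so the
    # simplex constraint holds after renormalization
    w = np.clip(w, 1e-300, None)
    return w / w.sum()


def _gamma_logpdf(lam, shape: float, rate: float):
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(lam) - rate * lam


def sample_lifetimes(
    state: MixtureState,
    trace: PhotonTrace,
    priors: Priors,
    irf: IRFModel,
    settings: SamplerSettings,
    rng: np.random.Generator,
    *,
    current_loglik: np.ndarray | None = None,
    proposal_scale: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One Metropolis-Hastings pass over the inverse lifetimes.

    For each component with assigned photons, propose lambda' =
    lambda * exp(eps), eps ~ Normal(0, proposal_scale**2), and accept with
    probability min(1, prior x likelihood ratio x lambda'/lambda) — the
    last factor being the Jacobian of the log-scale random walk.
    Unoccupied components are redrawn directly from the Gamma prior.

    Returns ``(new_inverse_lifetimes, accepted)`` where ``accepted[m]`` is
    True for accepted proposals and for prior refreshes.

    ``current_loglik`` (per-component log likelihood at the current
    lambdas) may be supplied to avoid recomputation inside a sweep.
    """
    lam = state.inverse_lifetimes.copy()
    tags = state.tags
    m_total = lam.size
    scale = settings.proposal_scale if proposal_scale is None else proposal_scale
    dt = trace.microtimes

    counts = np.bincount(tags, minlength=m_total) if tags.size else np.zeros(m_total, int)
    accepted = np.zeros(m_total, dtype=bool)

    eps = rng.normal(0.0, scale, size=m_total)
    log_u = np.log(rng.random(m_total))
    prior_draws = rng.gamma(priors.gamma_shape, 1.0 / priors.gamma_rate, size=m_total)

    for m in range(m_total):
        if counts[m] == 0:
            lam[m] = prior_draws[m]
            accepted[m] = True
            continue
        idx = np.flatnonzero(tags == m)
        lam_new = lam[m] * np.exp(eps[m])
        if current_loglik is not None:
            ll_old = current_loglik[m]
        else:
            ll_old = float(np.sum(emg_log_density(dt[idx], lam[m], irf)))
        ll_new = float(np.sum(emg_log_density(dt[idx], lam_new, irf)))
        log_ratio = (
            ll_new
            - ll_old
            + _gamma_logpdf(lam_new, priors.gamma_shape, priors.gamma_rate)
            - _gamma_logpdf(lam[m], priors.gamma_shape, priors.gamma_rate)
            + np.log(lam_new / lam[m])  # Jacobian of the log-scale walk
        )
        if log_u[m] < log_ratio:
            lam[m] = lam_new
            accepted[m] = True
    return lam, accepted


def _log_joint(logd_at_tags, tags, weights, lam, priors: Priors):
    """Unnormalized complete-data log joint of one state."""
    m = priors.truncation
    a = priors.concentration / m
    with np.errstate(divide="ignore"):
        logw = np.log(np.clip(weights, 1e-300, None))
    lik = float(np.sum(logd_at_tags)) + float(np.sum(logw[tags])) if tags.size else 0.0
    dir_prior = gammaln(priors.concentration) - m * gammaln(a) + (a - 1.0) * float(logw.sum())
    gam_prior = float(np.sum(_gamma_logpdf(lam, priors.gamma_shape, priors.gamma_rate)))
    return lik + dir_prior + gam_prior


def run_mcmc(
    trace: PhotonTrace,
    priors: Priors,
    irf: IRFModel,
    settings: SamplerSettings,
    *,
    background_fraction: float = 0.0,
) -> PosteriorSamples:
    """Run the full Metropolis-within-Gibbs chain.

    With ``trace.n_photons == 0`` the chain samples the prior predictive
    (weights and inverse lifetimes from their priors; no tags). A fixed
    ``background_fraction`` b adds a uniform-over-period component with
    known weight b to the tag draw; species weights are scaled by (1 - b)
    and background photons are excluded from all species updates.

    Deterministic given ``settings.seed``.
    """
    if not (0.0 <= background_fraction < 1.0):
        raise ValueError("background_fraction must lie in [0, 1)")
    rng = np.random.default_rng(settings.seed)
    m_total = priors.truncation
    k = trace.n_photons
    if k:
        trace.validate_support(irf)

    # Initialization: one occupied component at the moment-matched rate,
    # the rest fresh from the prior. Starting from the merged (single
    # species) side matters for mixing: the tag draw splits off genuinely
    # needed extra species within a few sweeps, whereas merging spurious
    # duplicates created by a diffuse init is the chain's slowest move.
    lam = rng.gamma(priors.gamma_shape, 1.0 / priors.gamma_rate, size=m_total)
    if k:
        mean_dwell = float(np.mean(trace.microtimes)) - irf.peak_time
        lam[0] = 1.0 / np.clip(mean_dwell, 1e-3, 1e3)
        init_tags = np.zeros(k, dtype=np.int64)
        weights = sample_weights(init_tags, priors, rng)
    else:
        weights = sample_weights(np.empty(0, dtype=np.int64), priors, rng)

    n_keep = -(-(settings.n_sweeps - settings.burn_in) // settings.thinning)
    kept_lam = np.empty((n_keep, m_total))
    kept_w = np.empty((n_keep, m_total))
    kept_counts = np.empty((n_keep, m_total), dtype=np.int64)
    kept_occ = np.empty(n_keep, dtype=np.int64)
    kept_lp = np.empty(n_keep)
    kept_tags = np.empty((n_keep, k), dtype=np.int64) if settings.keep_tags else None

    log_bg = (
        np.log(background_fraction) - np.log(trace.pulse_period)
        if background_fraction > 0
        else None
    )
    log_sig = np.log1p(-background_fraction)

    scale = settings.proposal_scale
    n_acc = 0
    n_occ_updates = 0
    kept = 0
    tags = np.empty(0, dtype=np.int64)

    for sweep in range(1, settings.n_sweeps + 1):
        if k:
            logd = component_log_densities(trace, lam, irf)
            with np.errstate(divide="ignore"):
                logp = logd + (np.log(weights) + log_sig)[None, :]
            if log_bg is not None:
                logp = np.hstack([logp, np.full((k, 1), log_bg)])
            tags_ext = _gumbel_argmax(logp, rng)
            signal = tags_ext < m_total
            tags = tags_ext[signal]
            weights = sample_weights(tags, priors, rng)

            # per-component log likelihood at current lambdas, reusing logd
            sig_idx = np.flatnonzero(signal)
            dens_at_tag = logd[sig_idx, tags]
            curr_ll = np.bincount(tags, weights=dens_at_tag, minlength=m_total)
            sub_trace = (
                trace
                if signal.all()
                else PhotonTrace(trace.microtimes[sig_idx], trace.pulse_period)
            )
            state = MixtureState(lam, weights, tags)
            lam, accepted = sample_lifetimes(
                state,
                sub_trace,
                priors,
                irf,
                settings,
                rng,
                current_loglik=curr_ll,
                proposal_scale=scale,
            )
            counts = np.bincount(tags, minlength=m_total)
            occ = counts > 0
            n_acc += int(np.sum(accepted & occ))
            n_occ_updates += int(np.sum(occ))
            if settings.adapt and sweep <= settings.burn_in and occ.any():
                rate = float(np.mean(accepted[occ]))
                scale = float(
                    np.exp(
                        np.log(scale)
                        + (rate - settings.target_acceptance) / sweep**0.6
                    )
                )
            lp = _log_joint(dens_at_tag, tags, weights, lam, priors)
        else:  # prior-predictive mode
            weights = sample_weights(tags, priors, rng)
            lam = rng.gamma(priors.gamma_shape, 1.0 / priors.gamma_rate, size=m_total)
            counts = np.zeros(m_total, dtype=np.int64)
            lp = _log_joint(np.empty(0), tags, weights, lam, priors)

        if sweep > settings.burn_in and (sweep - settings.burn_in - 1) % settings.thinning == 0:
            kept_lam[kept] = lam
            kept_w[kept] = weights
            kept_counts[kept] = counts
            kept_occ[kept] = int(np.count_nonzero(counts))
            kept_lp[kept] = lp
            if kept_tags is not None and k:
                # with a background weight, index m_total marks background
                kept_tags[kept] = tags_ext
            kept += 1

    return PosteriorSamples(
        inverse_lifetimes=kept_lam[:kept],
        weights=kept_w[:kept],
        counts=kept_counts[:kept],
        occupied_counts=kept_occ[:kept],
        log_posteriors=kept_lp[:kept],
        acceptance_rate=(n_acc / n_occ_updates) if n_occ_updates else float("nan"),
        n_photons=k,
        settings=settings,
        priors=priors,
        tags=kept_tags[:kept] if kept_tags is not None else None,
    )


def summarize(samples: PosteriorSamples, trace: PhotonTrace) -> PosteriorReport:
    """Summarize a chain into species-count and per-species estimates.

    The species-count posterior is the normalized histogram of occupied
    counts. Label switching is resolved by sorting each sweep's occupied
    lifetimes ascending; per-species summaries (posterior mean, median and
    central 95% credible interval of lifetime and photon fraction) are
    computed across the sweeps whose occupied count equals the modal count.
    """
    if samples.n_retained == 0:
        raise RuntimeError("cannot summarize an empty chain")
    occ = samples.occupied_counts
    values, freq = np.unique(occ, return_counts=True)
    post = {int(v): float(f) / occ.size for v, f in zip(values, freq)}
    modal = int(values[np.argmax(freq)])  # ties resolve to the smaller count

    sel = np.flatnonzero(occ == modal)
    if modal == 0:  # prior-predictive chain: no species summaries
        empty = SpeciesEstimates(*(np.empty(0),) * 4)
        return PosteriorReport(post, 0, empty, empty, samples.n_photons, samples.n_retained, True)

    taus = np.empty((sel.size, modal))
    fracs = np.empty((sel.size, modal))
    for i, s in enumerate(sel):
        occ_idx = np.flatnonzero(samples.counts[s] > 0)
        tau = 1.0 / samples.inverse_lifetimes[s, occ_idx]
        order = np.argsort(tau)
        taus[i] = tau[order]
        n_signal = samples.counts[s].sum()
        fracs[i] = samples.counts[s, occ_idx][order] / n_signal

    def est(arr: np.ndarray) -> SpeciesEstimates:
        return SpeciesEstimates(
            mean=arr.mean(axis=0),
            median=np.median(arr, axis=0),
            ci_low=np.quantile(arr, 0.025, axis=0),
            ci_high=np.quantile(arr, 0.975, axis=0),
        )

    low_info = samples.n_photons <= 1 or sel.size < 20
    return PosteriorReport(
        species_count_posterior=post,
        modal_species_count=modal,
        lifetime_estimates=est(taus),
        fraction_estimates=est(fracs),
        n_photons=samples.n_photons,
        n_retained=samples.n_retained,
        low_information=low_info,
    )
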