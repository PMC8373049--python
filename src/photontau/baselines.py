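"""Classical comparators: multi-exponential histogram fitting and phasor
analysis.

Both baselines share the defining limitation the photon-by-photon sampler
removes: the number of species must be fixed before the data are consulted.
The histogram fit maximizes the Poisson likelihood of binned counts under a
mixture of IRF-convolved exponentials with the component count fixed a
priori; the phasor maps a trace to first-harmonic Fourier coordinates
(G, S), on which mono-exponential decays fall on the semicircle of radius
1/2 centered at (1/2, 0) running from (1, 0) at tau -> 0 toward (0, 0) as
tau grows.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .model import IRFModel, PhotonTrace, emg_cdf

__all__ = [
    "DecayHistogram",
    "MultiExpFit",
    "PhasorPoint",
    "histogram_trace",
    "fit_multiexp",
    "phasor_of_lifetime",
    "phasor_from_trace",
    "plot_phasor",
]


@dataclass(frozen=True)
class DecayHistogram:
    """Binned decay curve: strictly increasing bin edges (ns) and
    non-negative counts, one per bin."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        if edges.ndim != 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if counts.shape != (edges.size - 1,):
            raise ValueError("counts must have one entry per bin")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", np.asarray(counts, dtype=np.int64))

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class MultiExpFit:
    """Result of a fixed-M multi-exponential fit.

    ``amplitudes`` are component photon fractions (sum to 1); lifetimes
    are sorted ascending. ``fit_quality`` is the Poisson negative log
    likelihood at the optimum (infinite when no restart converged, see
    ``converged``).
    """

    amplitudes: np.ndarray
    lifetimes: np.ndarray
    fit_quality: float
    converged: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        t = np.asarray(self.lifetimes, dtype=float)
        if a.shape != t.shape:
            raise ValueError("amplitudes and lifetimes must have equal length")
        if np.any(t <= 0) or np.any(a < 0):
            raise ValueError("lifetimes must be positive, amplitudes non-negative")
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "lifetimes", t)


@dataclass(frozen=True)
class PhasorPoint:
    """First-harmonic phasor coordinates at angular frequency omega
    (rad/ns): G = m cos(phi), S = m sin(phi)."""

    G: float
    S: float
    omega: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.omega) and self.omega > 0):
            raise ValueError("omega must be > 0")

    @property
    def modulation(self) -> float:
        return math.hypot(self.G, self.S)

    @property
    def phase(self) -> float:
        return math.atan2(self.S, self.G)


def histogram_trace(trace: PhotonTrace, n_bins: int = 256) -> DecayHistogram:
    """Bin a trace into uniform bins over [min(0, smallest microtime),
    pulse_period).

    Conserves the photon count: the rare microtimes at/above the pulse
    period (legal under the no-wraparound model) land in the last bin.
    """
    if trace.n_photons < 1:
        raise ValueError("cannot histogram an empty trace")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo = min(0.0, float(trace.microtimes.min()))
    edges = np.linspace(lo, trace.pulse_period, n_bins + 1)
    mt = np.clip(trace.microtimes, lo, np.nextafter(trace.pulse_period, lo))
    counts, _ = np.histogram(mt, bins=edges)
    return DecayHistogram(bin_edges=edges, counts=counts)


def _bin_probs(edges: np.ndarray, taus: np.ndarray, w: np.ndarray, irf: IRFModel):
    """Mixture probability mass per bin from the EMG CDF.

    The last bin absorbs the right tail beyond the final edge, mirroring
    how :func:`histogram_trace` conserves photons whose microtimes exceed
    the pulse period."""
    cdf = emg_cdf(edges[:, None], 1.0 / taus[None, :], irf)  # (E, M)
    cdf[-1, :] = 1.0
    per_comp = np.diff(cdf, axis=0)  # (B, M)
    return per_comp @ w


def fit_multiexp(
    hist: DecayHistogram,
    n_components: int,
    irf: IRFModel,
    n_restarts: int = 8,
) -> MultiExpFit:
    """Maximum-likelihood multi-exponential fit with a fixed component count.

    Bin counts are modeled as Poisson with expected counts proportional to
    the IRF-convolved mixture mass in each bin; the total intensity is
    profiled out analytically, leaving lifetimes (optimized on a log scale)
    and a softmax weight parameterization. Deterministically seeded
    multi-start optimization; the best restart is returned with lifetimes
    sorted ascending.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if hist.total < 1:
        raise ValueError("histogram is empty")
    edges = hist.bin_edges
    counts = hist.counts.astype(float)
    k_tot = counts.sum()
    m = int(n_components)

    def unpack(theta):
        taus = np.exp(theta[:m])
        z = np.concatenate([theta[m:], [0.0]])
        z = z - z.max()
        w = np.exp(z)
        return taus, w / w.sum()

    def nll(theta):
        taus, w = unpack(theta)
        if np.any(taus < 1e-4) or np.any(taus > 1e4):
            return 1e12
        q = _bin_probs(edges, taus, w, irf)
        q_tot = q.sum()
        if q_tot <= 0 or np.any(~np.isfinite(q)):
            return 1e12
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = counts * np.log(np.clip(q / q_tot, 1e-300, None))
        return -float(terms.sum())

    # moment-style init plus deterministic random restarts
    span = edges[-1] - edges[0]
    mean_t = float(np.sum(hist.centers * counts) / k_tot - irf.peak_time)
    inits = [np.log(np.clip(mean_t * np.geomspace(0.3, 3.0, m), 1e-3, span)) if m > 1
             else np.array([np.log(max(mean_t, 1e-3))])]
    rng = np.random.default_rng(1234)
    for _ in range(max(0, n_restarts - 1)):
        inits.append(np.log(np.exp(rng.uniform(np.log(2e-2 * span), np.log(0.8 * span), m))))

    best = None
    any_ok = False
    for t0 in inits:
        theta0 = np.concatenate([np.sort(t0), np.zeros(m - 1)])
        res = minimize(nll, theta0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
        any_ok = any_ok or bool(res.success)

    taus, w = unpack(best.x)
    order = np.argsort(taus)
    # full Poisson NLL at the profiled total intensity
    q = _bin_probs(edges, taus, w, irf)
    mu = k_tot * q / q.sum()
    full_nll = -float(np.sum(counts * np.log(np.clip(mu, 1e-300, None)) - mu - gammaln(counts + 1.0)))
    return MultiExpFit(
        amplitudes=w[order],
        lifetimes=taus[order],
        fit_quality=full_nll if any_ok else float("inf"),
        converged=any_ok,
    )


def phasor_of_lifetime(tau: float, omega: float) -> PhasorPoint:
    """Analytic phasor of a mono-exponential decay.

    G = 1 / (1 + (omega tau)^2), S = omega tau / (1 + (omega tau)^2);
    consequently (G - 1/2)^2 + S^2 = 1/4 exactly — the universal
    semicircle.
    """
    if not (np.isfinite(tau) and tau > 0):
        raise ValueError("tau must be > 0")
    if not (np.isfinite(omega) and omega > 0):
        raise ValueError("omega must be > 0")
    wt = omega * tau
    denom = 1.0 + wt * wt
    return PhasorPoint(G=1.0 / denom, S=wt / denom, omega=omega)


def phasor_from_trace(
    trace: PhotonTrace, harmonic: int = 1, irf: IRFModel | None = None
) -> PhasorPoint:
    """Empirical phasor of a microtime trace at a pulse-train harmonic.

    omega = 2 pi harmonic / pulse_period; raw coordinates are the sample
    means of cos(omega dt) and sin(omega dt). When an IRF is supplied, the
    raw complex phasor is divided by the Gaussian IRF's characteristic
    function exp(i omega mu - omega^2 sigma^2 / 2), removing the
    instrument's rotation and demodulation so that mono-exponential data
    land back on the universal semicircle.
    """
    if trace.n_photons < 1:
        raise ValueError("cannot compute a phasor of an empty trace")
    if harmonic < 1:
        raise ValueError("harmonic must be a positive integer")
    omega = 2.0 * math.pi * harmonic / trace.pulse_period
    ph = omega * trace.microtimes
    z = complex(float(np.mean(np.cos(ph))), float(np.mean(np.sin(ph))))
    if irf is not None:
        z /= cmath.exp(1j * omega * irf.peak_time - 0.5 * (omega * irf.sigma) ** 2)
    return PhasorPoint(G=z.real, S=z.imag, omega=omega)


def plot_phasor(points, path, labels=None) -> None:
    """Save a phasor plot (universal semicircle plus the given points)."""
    from matplotlib.figure import Figure

    fig = Figure(figsize=(5, 3.2))
    ax = fig.add_subplot(111)
    th = np.linspace(0.0, math.pi, 400)
    ax.plot(0.5 + 0.5 * np.cos(th), 0.5 * np.sin(th), "k-", lw=1, label="semicircle")
    pts = [points] if isinstance(points, PhasorPoint) else list(points)
    for i, p in enumerate(pts):
        lbl = labels[i] if labels else None
        ax.plot(p.G, p.S, "o", ms=6, label=lbl)
    ax.set_xlabel("G")
    ax.set_ylabel("S")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 0.65)
    ax.set_aspect("equal")
    if labels:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
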