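"""Constrained Gaussian-mixture calibration of read-depth thresholds.

Depth over 5-kub windows in known single-copy regions is modelled as a
mixture of four Gaussians representing copy numbers 1-4: component n has
mean ``n * avg`` and standard deviation ``sqrt(n) * sd`` (Poisson-like depth
variance scales with the mean), with mixture fractions summing to one:

    pdf(x) = sum_{n=1..4} f_n N(x; n*avg, sqrt(n)*sd)

The fitted G1 average and standard deviation give the classification
thresholds: borderline above ``avg + 2*sd``, duplication-positive at or
above ``avg + 3*sd``. The fit maximises the unbinned log-likelihood by
direct minimisation of -logL; binned normalised residuals ("pulls") are
reported for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MixtureModel",
    "Thresholds",
    "FitError",
    "mixture_pdf",
    "fit_mixture",
    "thresholds_from",
    "implied_sequencing_coverage",
    "pull_table",
    "plot_fit",
]

N_COMPONENTS = 4


class FitError(RuntimeError):
    """Raised when the mixture fit is degenerate or fails to converge."""


@dataclass
class MixtureModel:
    """Fitted constrained mixture: G1 mean/sd, fractions, fit metadata."""

    avg: float
    sd: float
    f: tuple[float, float, float, float]
    loglik: float = float("nan")
    n_obs: int = 0
    sd_scaling: str = "sqrt"  # component sd = sd * n**0.5 ("sqrt") or sd * n ("linear")

    def __post_init__(self):
        if self.avg <= 0 or self.sd <= 0:
            raise ValueError("avg and sd must be positive")
        f = np.asarray(self.f, dtype=float)
        if len(f) != N_COMPONENTS or np.any(f < -1e-9) or abs(f.sum() - 1) > 1e-6:
            raise ValueError("fractions must be non-negative and sum to 1")
        self.f = tuple(float(x) for x in f)

    def component_params(self) -> tuple[np.ndarray, np.ndarray]:
        n = np.arange(1, N_COMPONENTS + 1, dtype=float)
        scale = np.sqrt(n) if self.sd_scaling == "sqrt" else n
        return self.avg * n, self.sd * scale


@dataclass(frozen=True)
class Thresholds:
    """Window classification cuts derived from the fitted G1."""

    borderline_cut: float  # avg + 2 sd
    positive_cut: float  # avg + 3 sd

    def __post_init__(self):
        if not self.borderline_cut < self.positive_cut:
            raise ValueError("borderline cut must be below positive cut")


def mixture_pdf(x, model: MixtureModel) -> np.ndarray:
    """Mixture density at ``x`` (scalar or array)."""
    x = np.asarray(x, dtype=float)
    means, sds = model.component_params()
    dens = np.zeros(np.shape(x), dtype=float)
    for fn, mu, s in zip(model.f, means, sds):
        if fn > 0:
            dens = dens + fn * stats.norm.pdf(x, mu, s)
    return dens


def _neg_loglik(params: np.ndarray, x: np.ndarray, sd_scaling: str) -> float:
    log_avg, log_sd, l1, l2, l3 = params
    avg = np.exp(log_avg)
    sd = np.exp(log_sd)
    logits = np.array([l1, l2, l3, 0.0])
    logits -= logits.max()
    f = np.exp(logits)
    f /= f.sum()
    n = np.arange(1, N_COMPONENTS + 1, dtype=float)
    scale = np.sqrt(n) if sd_scaling == "sqrt" else n
    mu = avg * n
    s = sd * scale
    z = (x[:, None] - mu[None, :]) / s[None, :]
    comp = f[None, :] / (s[None, :] * np.sqrt(2 * np.pi)) * np.exp(-0.5 * z**2)
    dens = comp.sum(axis=1)
    return -np.sum(np.log(np.maximum(dens, 1e-300)))


def _pack(avg, sd, f):
    f = np.maximum(np.asarray(f, dtype=float), 1e-6)
    logits = np.log(f / f[-1])
    return np.array([np.log(avg), np.log(sd), logits[0], logits[1], logits[2]])


def _unpack(params):
    log_avg, log_sd, l1, l2, l3 = params
    logits = np.array([l1, l2, l3, 0.0])
    logits -= logits.max()
    f = np.exp(logits)
    f /= f.sum()
    return float(np.exp(log_avg)), float(np.exp(log_sd)), tuple(float(v) for v in f)


def _mode_estimate(x: np.ndarray) -> float:
    """Histogram-peak estimate of the dominant component's location."""
    lo, hi = np.percentile(x, [1, 99])
    if hi <= lo:
        return float(np.median(x))
    counts, edges = np.histogram(x, bins=50, range=(lo, hi))
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def fit_mixture(
    depths,
    sd_scaling: str = "sqrt",
    f0: tuple = (0.85, 0.10, 0.04, 0.01),
    min_obs: int = 50,
) -> MixtureModel:
    """Maximum-likelihood fit of the constrained 4-Gaussian model.

    Optimises (avg, sd, f1..f3) with f4 the simplex remainder, using
    L-BFGS-B on log/logit-transformed parameters with multi-start from the
    sample mode and the sample median. Deterministic given the data.

    Raises :class:`FitError` on degenerate samples (all depths identical) or
    optimiser failure.
    """
    x = np.asarray(depths, dtype=float).ravel()
    if len(x) < min_obs:
        raise FitError(f"need at least {min_obs} depth values, got {len(x)}")
    if np.any(x < 0):
        raise ValueError("depths must be non-negative")
    if np.ptp(x) == 0:
        raise FitError("all depth values identical: sd would be degenerate")
    mad = np.median(np.abs(x - np.median(x)))
    sd0 = max(1.4826 * mad, 1e-3 * max(np.std(x), 1.0), 1e-6)
    starts = []
    for avg0 in {_mode_estimate(x), float(np.median(x))}:
        if avg0 > 0:
            starts.append(_pack(avg0, sd0, f0))
    if not starts:
        raise FitError("no positive location estimate available")
    best = None
    for p0 in starts:
        res = optimize.minimize(
            _neg_loglik,
            p0,
            args=(x, sd_scaling),
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("mixture fit did not converge")
    init_nll = min(_neg_loglik(p0, x, sd_scaling) for p0 in starts)
    if best.fun > init_nll + 1e-6:
        raise FitError("optimizer ended below the initial likelihood")
    avg, sd, f = _unpack(best.x)
    return MixtureModel(
        avg=avg, sd=sd, f=f, loglik=-float(best.fun), n_obs=len(x),
        sd_scaling=sd_scaling,
    )


def thresholds_from(model: MixtureModel) -> Thresholds:
    """Classification cuts: borderline above avg+2sd, positive at avg+3sd."""
    return Thresholds(
        borderline_cut=model.avg + 2 * model.sd,
        positive_cut=model.avg + 3 * model.sd,
    )


def implied_sequencing_coverage(
    read_len: float, avg_depth: float, window_size: float
) -> float:
    """Fold sequencing coverage implied by a mean window depth.

    ``read_len * avg_depth / window_size`` reported to one decimal: a mean
    5-kub depth of 79.2 with 735 bp reads implies 11.6x coverage.
    """
    if read_len <= 0 or avg_depth <= 0 or window_size <= 0:
        raise ValueError("inputs must be positive")
    return round(read_len * avg_depth / window_size, 1)


def pull_table(depths, model: MixtureModel, bins: int = 50) -> pd.DataFrame:
    """Binned normalised residuals: pull = (N_data - N_fit) / sigma_data.

    ``sigma_data`` is sqrt(N_data) (Poisson); empty bins get sigma 1. When
    pulls sit within +/-3, deviations from the fit are statistical.
    """
    x = np.asarray(depths, dtype=float)
    counts, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    expected = len(x) * mixture_pdf(centers, model) * widths
    sigma = np.sqrt(np.maximum(counts, 1))
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "n_data": counts,
            "n_fit": expected,
            "pull": (counts - expected) / sigma,
        }
    )


def plot_fit(depths, model: MixtureModel, path, bins: int = 50) -> None:
    """Histogram of depths with fitted mixture and per-component curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(depths, dtype=float)
    fig, (ax_pull, ax) = plt.subplots(
        2, 1, figsize=(7, 6), sharex=True,
        gridspec_kw={"height_ratios": [1, 3], "hspace": 0.05},
    )
    tbl = pull_table(x, model, bins=bins)
    centers = 0.5 * (tbl["bin_low"] + tbl["bin_high"])
    ax_pull.bar(centers, tbl["pull"], width=np.diff(tbl[["bin_low", "bin_high"]].to_numpy()).ravel())
    ax_pull.axhline(3, color="r", ls=":")
    ax_pull.axhline(-3, color="r", ls=":")
    ax_pull.set_ylabel("pull")
    ax.hist(x, bins=bins, density=True, alpha=0.4, label="depths")
    grid = np.linspace(x.min(), x.max(), 400)
    means, sds = model.component_params()
    for i, (fn, mu, s) in enumerate(zip(model.f, means, sds), start=1):
        ax.plot(grid, fn * stats.norm.pdf(grid, mu, s), lw=1, label=f"G{i}")
    ax.plot(grid, mixture_pdf(grid, model), "b-", lw=2, label="model")
    ax.axvline(model.avg, color="r", lw=1)
    ax.set_xlabel("5-kub window depth")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
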