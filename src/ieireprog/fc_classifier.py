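"""Distribution-fit thresholding of log2 fold changes.

The background of a contrast's log2 fold changes is summarized by a
floor-binned histogram on a 0.1 grid: every value is rounded *down* to the
nearest decimal (toward minus infinity, so -0.01 falls in the -0.1 bin) and
equal values are added up. A Gaussian or Lorentzian peak is least-squares
fitted to the binned counts; the fitted center mu and width (sigma for the
Gaussian, half-width at half-maximum gamma for the Lorentzian) define the
thresholds mu +/- width. Significant genes (padj < alpha) beyond the upper
threshold are "increased", below the lower one "decreased", and in between
"unchanged"; non-significant genes are reported separately.

The histogram is built from all genes with a finite log2fc, not only the
significant ones: the fit characterizes the background distribution, while
significance gates only the final categories (the alternative is available
via ``significant_only`` where a replication requires it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io_formats import DETable

__all__ = [
    "FCHistogram",
    "DistributionFit",
    "build_histogram",
    "fit_distribution",
    "select_model",
    "classify_genes",
    "plot_fit",
    "CATEGORIES",
]

log = logging.getLogger(__name__)

CATEGORIES = ("increased", "decreased", "unchanged", "not_significant")

DEFAULT_BIN_WIDTH = 0.1
#: optimizer tolerances: deterministic single-start least squares
_FIT_TOL = 1e-12
_MAX_EVALS = 10_000


@dataclass(frozen=True)
class FCHistogram:
    """Floor-binned log2FC histogram on a fixed-width grid.

    ``bin_left`` holds the (sorted, unique) left bin edges; ``count`` the
    number of values whose floor fell on that edge. ``n_dropped`` counts
    non-finite inputs that were excluded.
    """

    bin_left: np.ndarray
    count: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.bin_left) != len(self.count):
            raise ValueError("bin_left and count lengths differ")
        if (np.diff(self.bin_left) <= 0).any():
            raise ValueError("bins must be strictly increasing")
        if (self.count < 0).any():
            raise ValueError("negative bin count")

    @property
    def centers(self) -> np.ndarray:
        return self.bin_left + self.bin_width / 2.0

    @property
    def total(self) -> int:
        return int(self.count.sum())


@dataclass(frozen=True)
class DistributionFit:
    """Fitted peak model for a log2FC histogram.

    ``width`` is the threshold half-width: the standard deviation sigma for
    a Gaussian, the half-width at half-maximum gamma for a Lorentzian (which
    has no finite standard deviation; this substitution is logged).
    """

    model: str  # "gaussian" | "lorentzian"
    center: float
    width: float
    amplitude: float
    sse: float
    converged: bool

    def thresholds(self) -> tuple[float, float]:
        return self.center - self.width, self.center + self.width


def build_histogram(
    log2fc: np.ndarray | pd.Series,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> FCHistogram:
    """Floor-bin log2 fold changes to the ``bin_width`` grid and sum ties.

    Rounding is toward minus infinity (floor), so -0.01 lands in bin -0.1;
    truncation toward zero would merge bins across the origin. Non-finite
    values are dropped with a logged count; an input with no finite value is
    an error.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(log2fc, dtype=float).ravel()
    finite = np.isfinite(x)
    n_dropped = int((~finite).sum())
    x = x[finite]
    if x.size == 0:
        raise ValueError("no finite log2fc values to bin")
    if n_dropped:
        log.info("build_histogram: dropped %d non-finite value(s)", n_dropped)
    # guard against float grid artefacts (0.7/0.1 = 6.999...) before flooring;
    # kept as floats so extreme values cannot overflow an integer bin index
    idx = np.floor(np.round(x / bin_width, 9))
    uniq, counts = np.unique(idx, return_counts=True)
    bin_left = np.round(uniq * bin_width, 10)
    return FCHistogram(bin_left=bin_left, count=counts, bin_width=bin_width, n_dropped=n_dropped)


def _gaussian(x: np.ndarray, amplitude: float, center: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def _lorentzian(x: np.ndarray, amplitude: float, center: float, gamma: float) -> np.ndarray:
    return amplitude * gamma**2 / ((x - center) ** 2 + gamma**2)


def _gaussian_jac(x: np.ndarray, amplitude: float, center: float, sigma: float) -> np.ndarray:
    d = x - center
    e = np.exp(-(d**2) / (2.0 * sigma**2))
    return np.stack([e, amplitude * e * d / sigma**2, amplitude * e * d**2 / sigma**3], axis=1)


def _lorentzian_jac(x: np.ndarray, amplitude: float, center: float, gamma: float) -> np.ndarray:
    d = x - center
    denom = d**2 + gamma**2
    return np.stack(
        [
            gamma**2 / denom,
            2.0 * amplitude * gamma**2 * d / denom**2,
            2.0 * amplitude * gamma * d**2 / denom**2,
        ],
        axis=1,
    )


_MODELS = {"gaussian": _gaussian, "lorentzian": _lorentzian}
_JACOBIANS = {"gaussian": _gaussian_jac, "lorentzian": _lorentzian_jac}
#: HWHM -> sigma for a Gaussian
_HWHM_TO_SIGMA = 1.0 / np.sqrt(2.0 * np.log(2.0))


def _initial_guess(h: FCHistogram, model: str) -> tuple[float, float, float]:
    """Deterministic start: modal bin for (A0, mu0), half-max span for width."""
    centers = h.centers
    counts = h.count.astype(float)
    imax = int(np.argmax(counts))
    a0 = counts[imax]
    mu0 = centers[imax]
    above = np.nonzero(counts >= a0 / 2.0)[0]
    span = centers[above[-1]] - centers[above[0]] + h.bin_width
    hwhm0 = max(span / 2.0, h.bin_width / 2.0)
    width0 = hwhm0 * _HWHM_TO_SIGMA if model == "gaussian" else hwhm0
    return a0, mu0, width0


def fit_distribution(h: FCHistogram, model: str) -> DistributionFit:
    """Nonlinear least squares of bin counts against a Gaussian or Lorentzian.

    The abscissa is the bin center (left edge + half width). Initialization
    is deterministic (modal bin and half-max span); no random restarts.
    Non-convergence is reported via ``converged=False``, not an exception.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; expected gaussian or lorentzian")
    if len(h.bin_left) < 5:
        raise ValueError("need at least 5 occupied bins to fit a peak")
    f = _MODELS[model]
    x = h.centers
    y = h.count.astype(float)
    p0 = _initial_guess(h, model)
    try:
        popt, _, info, _, ier = curve_fit(
            f,
            x,
            y,
            p0=p0,
            jac=_JACOBIANS[model],
            maxfev=_MAX_EVALS,
            xtol=_FIT_TOL,
            ftol=_FIT_TOL,
            full_output=True,
        )
        converged = ier in (1, 2, 3, 4)
    except RuntimeError:
        popt, converged = np.asarray(p0, dtype=float), False
    amplitude, center, width = popt
    width = abs(float(width))  # models are symmetric in the sign of the width
    amplitude = float(amplitude)
    sse = float(np.sum((f(x, amplitude, center, width) - y) ** 2))
    if model == "lorentzian":
        log.info("lorentzian fit: HWHM gamma=%.4g substitutes for sigma in thresholds", width)
    return DistributionFit(
        model=model,
        center=float(center),
        width=width,
        amplitude=amplitude,
        sse=sse,
        converged=bool(converged),
    )


def select_model(h: FCHistogram) -> DistributionFit:
    """Fit both peak models and keep the converged one with smaller SSE."""
    fits = {m: fit_distribution(h, m) for m in _MODELS}
    for m, fit in fits.items():
        log.info(
            "fit %s: center=%.4f width=%.4f amplitude=%.1f sse=%.2f converged=%s",
            m, fit.center, fit.width, fit.amplitude, fit.sse, fit.converged,
        )
    converged = [f for f in fits.values() if f.converged]
    if not converged:
        raise RuntimeError(
            "neither the Gaussian nor the Lorentzian fit converged; choose a "
            "model explicitly via the fit_model configuration key"
        )
    return min(converged, key=lambda f: f.sse)


def plot_fit(h: FCHistogram, fit: DistributionFit, path: str) -> None:
    """Histogram-plus-fit figure with the center +/- width thresholds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(h.centers, h.count, width=h.bin_width * 0.9, color="0.75", label="binned log2FC")
    xs = np.linspace(h.bin_left[0], h.bin_left[-1] + h.bin_width, 400)
    ax.plot(xs, _MODELS[fit.model](xs, fit.amplitude, fit.center, fit.width),
            color="crimson", label=f"{fit.model} fit")
    for t in fit.thresholds():
        ax.axvline(t, color="navy", linestyle="--", linewidth=1)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("genes per 0.1 bin")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def classify_genes(
    de: DETable,
    fit: DistributionFit,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Categorize every gene of a contrast against the fitted thresholds.

    padj >= alpha -> ``not_significant``; otherwise ``increased`` when
    log2fc > center + width, ``decreased`` when log2fc < center - width,
    else ``unchanged`` (boundary equality is unchanged). Returns a frame
    with columns gene, log2fc, padj, category; every gene gets exactly one
    category.
    """
    if not fit.converged:
        raise ValueError("refusing to classify against a non-converged fit")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    lo, hi = fit.thresholds()
    t = de.table
    category = np.full(len(t), "unchanged", dtype=object)
    category[t["log2fc"].to_numpy() > hi] = "increased"
    category[t["log2fc"].to_numpy() < lo] = "decreased"
    category[t["padj"].to_numpy() >= alpha] = "not_significant"
    return pd.DataFrame(
        {
            "gene": t["gene"].to_numpy(),
            "log2fc": t["log2fc"].to_numpy(),
            "padj": t["padj"].to_numpy(),
            "category": category,
        }
    )
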