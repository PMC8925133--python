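"""Agreement statistics between two paired CTR measurement series.

Implements the agreement toolkit used to compare an AI-derived CTR series with
a manual reference series (or two observers with each other): Bland–Altman
bias and 95% limits of agreement, the coefficient of variation (CV) in the
agreement sense, the paired Student's t-test, and histogram summaries of
percentage differences against an acceptance band.

CV convention: the standard deviation of the raw paired differences divided by
the grand mean of all raw measurements from both series, expressed in percent.
Dividing by the mean *difference* instead would blow up near zero bias, so the
grand-mean denominator is the one that yields small positive CVs for
well-agreeing methods; this choice is deliberate and documented.

The interval ``bias ± 1.96·sd(d)`` is named *limits of agreement* here; some
reports print the same interval under the label "95% CI".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ContractError, ParameterError

__all__ = [
    "AgreementStats",
    "DiffHistogram",
    "bland_altman",
    "paired_t",
    "diff_histogram",
]


@dataclass(frozen=True)
class AgreementStats:
    """Bias, limits of agreement, CV and paired-t for two paired series."""

    n: int
    bias: float          # mean of percentage differences, %
    loa_low: float       # bias - 1.96 sd(d), %
    loa_high: float      # bias + 1.96 sd(d), %
    cv: float            # 100 * sd(raw diffs) / grand mean of raw values, %
    t_statistic: float
    p_value: float
    degenerate_variance: bool = False  # differences had zero variance


@dataclass(frozen=True)
class DiffHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    inside_band_fraction: float
    skewness: float
    band: float


def _check_pair(a, b, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise ContractError(f"paired series must be 1-D and equal length, got {a.shape} vs {b.shape}")
    if a.size < min_n:
        raise ContractError(f"need at least {min_n} pairs, got {a.size}")
    return a, b


def paired_t(series_a, series_b) -> tuple[float, float]:
    """Classical paired t on the differences; two-sided p with n-1 df.

    Zero-variance differences are a degenerate case: identical series give
    (0.0, 1.0); a constant nonzero difference gives a signed infinite t with
    p = 0.  Callers needing the flag use :func:`bland_altman`.
    """
    a, b = _check_pair(series_a, series_b)
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def bland_altman(
    series_a,
    series_b,
    scale: str = "percent_of_reference",
) -> AgreementStats:
    """Bland–Altman agreement between paired series (``series_b`` = reference).

    ``scale`` selects the denominator of the percentage differences:
    ``percent_of_reference`` (relative to series_b, matching a signed
    AI-vs-manual percentage difference) or ``percent_of_pair_mean`` (the
    orthodox Bland–Altman scaling).  CV and the t-test always use the raw
    values, independent of ``scale``.
    """
    a, b = _check_pair(series_a, series_b)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ContractError("measurements must be positive")
    if scale == "percent_of_reference":
        d_pct = 100.0 * (a - b) / b
    elif scale == "percent_of_pair_mean":
        d_pct = 100.0 * (a - b) / ((a + b) / 2.0)
    else:
        raise ParameterError(f"unknown scale {scale!r}")

    bias = float(d_pct.mean())
    sd_pct = float(d_pct.std(ddof=1))
    raw_d = a - b
    grand_mean = float(np.concatenate([a, b]).mean())
    cv = 100.0 * float(raw_d.std(ddof=1)) / grand_mean
    t, p = paired_t(a, b)
    return AgreementStats(
        n=int(a.size),
        bias=bias,
        loa_low=bias - 1.96 * sd_pct,
        loa_high=bias + 1.96 * sd_pct,
        cv=cv,
        t_statistic=t,
        p_value=p,
        degenerate_variance=bool(raw_d.std(ddof=1) == 0.0),
    )


def diff_histogram(diffs, band: float = 1.8, bin_width: float = 0.5) -> DiffHistogram:
    """Histogram summary of percentage differences against an acceptance band.

    Reports binned counts, the fraction with |d| <= band (the excellent-grade
    yield under a pure band rule) and the sample skewness, whose sign exposes
    systematic under- or over-reading of a model.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ContractError("need at least one difference")
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be positive, got {bin_width}")
    if band <= 0:
        raise ParameterError(f"band must be positive, got {band}")
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    inside = float(np.mean(np.abs(d) <= band))
    skew = 0.0 if d.std() == 0 else float(sps.skew(d))
    return DiffHistogram(
        bin_edges=edges,
        counts=counts,
        inside_band_fraction=inside,
        skewness=skew,
        band=band,
    )


# ---------------------------------------------------------------------------
# Plotting (optional outputs; headless backend)

def bland_altman_plot(series_a, series_b, out_path, scale: str = "percent_of_reference"):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = _check_pair(series_a, series_b)
    res = bland_altman(a, b, scale=scale)
    mean_pair = (a + b) / 2.0
    if scale == "percent_of_reference":
        d = 100.0 * (a - b) / b
    else:
        d = 100.0 * (a - b) / mean_pair
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean_pair, d, s=8, alpha=0.5)
    for y, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, color="r", linestyle=style, linewidth=1)
    ax.set_xlabel("mean CTR of pair")
    ax.set_ylabel("difference (%)")
    ax.set_title(f"bias {res.bias:.2f}%, CV {res.cv:.2f}%")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return res


def diff_histogram_plot(diffs, out_path, band: float = 1.8, bin_width: float = 0.5):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = diff_histogram(diffs, band=band, bin_width=bin_width)
    fig, ax = plt.subplots(figsize=(5, 4))
    centers = (summary.bin_edges[:-1] + summary.bin_edges[1:]) / 2
    ax.bar(centers, summary.counts, width=bin_width * 0.9)
    ax.axvline(-band, color="r", linestyle="--")
    ax.axvline(band, color="r", linestyle="--")
    ax.set_xlabel("CTR difference (%)")
    ax.set_ylabel("count")
    ax.set_title(f"{100 * summary.inside_band_fraction:.1f}% inside ±{band}%")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return summary
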