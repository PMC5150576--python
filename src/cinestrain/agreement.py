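"""Reproducibility statistics for paired strain measurements.

Bland-Altman bias and 95% limits of agreement, the two-way random-effects
absolute-agreement single-measure intraclass correlation ICC(2,1), and the
Pearson correlation, for two raters/occasions measuring the same subjects
(e.g. intra- and inter-observer repeats of peak circumferential strain).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "bland_altman",
    "icc_absolute_agreement",
    "pearson",
    "compute_agreement",
    "bland_altman_plot",
]

_LOA_MULTIPLIER = 1.96  # two-sided 95% normal interval


def _as_pairs(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired measurements must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("measurements must be finite")
    return a, b


def bland_altman(a, b) -> tuple[float, float, float, float]:
    """(bias, sd, loa_low, loa_high) for differences a - b.

    bias is the mean difference, sd the sample (n-1) standard deviation of
    the differences, and the limits of agreement bias -/+ 1.96 sd.
    """
    a, b = _as_pairs(a, b)
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - _LOA_MULTIPLIER * sd, bias + _LOA_MULTIPLIER * sd


def icc_absolute_agreement(a, b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    Computed from the mean squares of the two-way (subject x rater) table:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with k = 2 raters and n subjects.
    """
    a, b = _as_pairs(a, b)
    x = np.stack([a, b], axis=1)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def pearson(a, b) -> float:
    """Sample Pearson correlation of the two columns."""
    a, b = _as_pairs(a, b)
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise ValueError("zero variance in a column: correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


@dataclass
class AgreementReport:
    """Table of agreement metrics for one pair of raters/occasions."""

    n: int
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    icc: float
    pearson_r: float
    label_a: str = "a"
    label_b: str = "b"

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def compute_agreement(a, b, label_a: str = "a", label_b: str = "b") -> AgreementReport:
    a_arr, b_arr = _as_pairs(a, b)
    bias, sd, lo, hi = bland_altman(a_arr, b_arr)
    return AgreementReport(
        n=int(a_arr.size),
        bias=bias,
        sd=sd,
        loa_low=lo,
        loa_high=hi,
        icc=icc_absolute_agreement(a_arr, b_arr),
        pearson_r=pearson(a_arr, b_arr),
        label_a=label_a,
        label_b=label_b,
    )


def bland_altman_plot(a, b, path, label_a: str = "a", label_b: str = "b") -> None:
    """Write a standard Bland-Altman scatter (mean vs difference) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = _as_pairs(a, b)
    bias, sd, lo, hi = bland_altman(a, b)
    mean = (a + b) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, a - b, s=18, color="k")
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, linestyle=style, color="tab:blue")
    ax.set_xlabel(f"mean of {label_a} and {label_b} (%)")
    ax.set_ylabel(f"{label_a} - {label_b} (%)")
    ax.set_title("Bland-Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
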