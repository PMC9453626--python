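"""Inferential utilities: repeated-measures correlation, multiple-testing
corrections, circular statistics and paired contrasts.

The repeated-measures correlation (rmcorr) is the common within-subject
association: both variables are centered within each subject and the
pooled centered values are correlated, with degrees of freedom
``N - k - 1`` for N pairs over k subjects.  It is implemented from that
definition; only the t-distribution tail probability comes from scipy's
special functions.

The full-scale analyses this package mirrors use linear mixed-effects
models for condition contrasts; at desk scale the package offers paired
t contrasts with Hochberg or Benjamini-Hochberg adjustment as the
clearly-labelled analogue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as scs


@dataclass
class RmcorrResult:
    r_rm: float
    df: int
    p: float
    n_subjects: int
    n_pairs: int


def rmcorr(x_by_subject, y_by_subject) -> RmcorrResult:
    """Repeated-measures correlation over per-subject paired observations.

    ``x_by_subject`` / ``y_by_subject`` are sequences (one entry per
    subject) of equal-length 1-D arrays.  Raises when any subject lacks
    within-subject variance in x or y, when fewer than 2 subjects or
    pairs per subject are given, or when df < 1.
    """
    if len(x_by_subject) != len(y_by_subject):
        raise ValueError("x and y must list the same subjects")
    k = len(x_by_subject)
    if k < 2:
        raise ValueError("need at least 2 subjects")
    xc, yc = [], []
    for i, (x, y) in enumerate(zip(x_by_subject, y_by_subject)):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size:
            raise ValueError(f"subject {i}: x and y lengths differ")
        if x.size < 2:
            raise ValueError(f"subject {i}: need >= 2 pairs")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(
                f"subject {i}: zero within-subject variance")
        xc.append(x - x.mean())
        yc.append(y - y.mean())
    xs = np.concatenate(xc)
    ys = np.concatenate(yc)
    n = xs.size
    df = n - k - 1
    if df < 1:
        raise ValueError(f"df = {df} < 1: too few pairs for {k} subjects")
    r = float(np.sum(xs * ys) / np.sqrt(np.sum(xs ** 2) * np.sum(ys ** 2)))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r ** 2))
        p = float(2.0 * scs.t.sf(abs(t), df))
    return RmcorrResult(r, df, p, k, n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def hochberg(p_values) -> np.ndarray:
    """Hochberg step-up adjusted p values (for condition post hocs)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * (m - np.arange(m))
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def circular_stats(phases_deg) -> tuple[float, float]:
    """Circular mean (deg, in [0, 360)) and resultant length R in [0, 1].

    Raises on an empty input; a vanishing resultant (R = 0) leaves the
    mean undefined and raises.
    """
    ph = np.deg2rad(np.asarray(phases_deg, dtype=float))
    if ph.size == 0:
        raise ValueError("need at least one phase")
    z = np.exp(1j * ph).mean()
    r = float(np.abs(z))
    if r < 1e-12:
        raise ValueError("resultant length ~0: circular mean undefined")
    return float(np.mod(np.degrees(np.angle(z)), 360.0)), r


def circular_sd_deg(phases_deg) -> float:
    """Circular standard deviation in degrees, sqrt(-2 ln R)."""
    _, r = circular_stats(phases_deg)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


@dataclass
class PairedContrast:
    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_contrast(a, b) -> PairedContrast:
    """Two-sided paired t-test of per-subject values a vs b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("expected equal-length 1-D paired samples")
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    sd = np.std(d, ddof=1)
    df = n - 1
    if sd == 0:
        if np.mean(d) == 0:
            return PairedContrast(0.0, df, 1.0)
        return PairedContrast(float(np.sign(np.mean(d)) * np.inf), df, 0.0,
                              degenerate=True)
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * scs.t.sf(abs(t), df))
    return PairedContrast(t, df, p)


def sign_test(values, mu: float = 0.0) -> float:
    """Two-sided exact sign test p value against median ``mu``."""
    v = np.asarray(values, dtype=float)
    v = v[v != mu]
    if v.size == 0:
        return 1.0
    k = int(np.sum(v > mu))
    return float(scs.binomtest(k, v.size, 0.5).pvalue)
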