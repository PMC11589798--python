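"""Small closed-form distribution helpers used by the samplers.

All samplers in the simulation draw through inverse CDFs applied to uniforms
from a single per-run generator. That keeps the number of uniforms consumed
per agent-week fixed regardless of parameter values, which is what makes
common-random-number pairing of baseline and counterfactual runs exact, and
makes outcomes monotone in location parameters agent by agent.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

_EPS = 1e-12


def truncnorm_ppf(u, mean, sd, lo=-np.inf, hi=np.inf):
    """Inverse CDF of a normal(mean, sd) truncated to [lo, hi].

    ``sd`` may be 0 (degenerate: returns the mean clipped into the interval).
    All arguments broadcast.
    """
    u = np.clip(np.asarray(u, float), _EPS, 1.0 - _EPS)
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    a = ndtr(np.where(np.isneginf(lo), -np.inf, (lo - mean) / np.where(sd > 0, sd, 1.0)))
    b = ndtr(np.where(np.isposinf(hi), np.inf, (hi - mean) / np.where(sd > 0, sd, 1.0)))
    x = mean + sd * ndtri(a + u * (b - a))
    degenerate = ~(sd > 0)
    if np.any(degenerate):
        x = np.where(degenerate, np.clip(mean, lo, hi), x)
    return x


def truncnorm_mean(mean, sd, lo=-np.inf, hi=np.inf):
    """Analytic mean of a normal(mean, sd) truncated to [lo, hi]."""
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    safe = np.where(sd > 0, sd, 1.0)
    alpha = np.where(np.isneginf(lo), -np.inf, (lo - mean) / safe)
    beta = np.where(np.isposinf(hi), np.inf, (hi - mean) / safe)
    phi = lambda t: np.exp(-0.5 * np.square(np.clip(t, -38, 38))) / np.sqrt(2 * np.pi)
    num = phi(alpha) - phi(beta)
    den = ndtr(beta) - ndtr(alpha)
    out = mean + safe * num / np.maximum(den, _EPS)
    return np.where(sd > 0, out, np.clip(mean, lo, hi))


def triangular_ppf(u, lo, mode, hi):
    """Inverse CDF of a triangular(lo, mode, hi) distribution."""
    u = np.clip(np.asarray(u, float), 0.0, 1.0)
    lo, mode, hi = (np.asarray(x, float) for x in (lo, mode, hi))
    span = hi - lo
    fc = np.where(span > 0, (mode - lo) / np.where(span > 0, span, 1.0), 0.5)
    left = lo + np.sqrt(np.maximum(u * span * (mode - lo), 0.0))
    right = hi - np.sqrt(np.maximum((1.0 - u) * span * (hi - mode), 0.0))
    return np.where(span > 0, np.where(u <= fc, left, right), lo)


def triangular_mean(lo, mode, hi):
    return (np.asarray(lo, float) + np.asarray(mode, float) + np.asarray(hi, float)) / 3.0
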