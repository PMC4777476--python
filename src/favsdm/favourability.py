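"""The favourability transformation and its inverse.

Logistic-regression probabilities depend on how common a species is: a
rare species has low predicted probability even in its best habitat.  The
favourability function removes that prevalence effect by dividing the
predicted odds by the sample presence/absence odds,

    F = [P / (1 - P)] / [n1/n0 + P / (1 - P)],

where P is the model probability in a cell, n1 the number of presences and
n0 the number of absences in the modelling dataset.  F = 0.5 marks cells
no better and no worse than the species' average condition, which makes
favourability comparable across species with different prevalence and
gives a natural neutral classification threshold.

Implementation uses the equivalent logit-shift identity
F = logistic(logit(P) - ln(n1/n0)), which is stable near P in {0, 1};
the endpoints are handled exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

#: Default favourability-class cuts (low / medium / high).
LOW_CUT_DEFAULT = 0.2
HIGH_CUT_DEFAULT = 0.8


def _check_counts(n1: int, n0: int) -> None:
    if n1 < 1 or n0 < 1:
        raise ValueError("need at least one presence and one absence")


def favourability(P, n1: int, n0: int):
    """Favourability F of probability P for a sample with n1 presences, n0 absences.

    Accepts scalars or arrays; P must lie in [0, 1].  F(0) = 0 and F(1) = 1
    exactly.
    """
    _check_counts(n1, n0)
    p = np.asarray(P, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("probabilities must lie in [0, 1]")
    shift = np.log(n1 / n0)
    with np.errstate(divide="ignore"):
        f = expit(logit(p) - shift)
    f = np.where(p == 0.0, 0.0, np.where(p == 1.0, 1.0, f))
    return float(f) if np.isscalar(P) else f


def probability_from_favourability(F, n1: int, n0: int):
    """Exact inverse of :func:`favourability`."""
    _check_counts(n1, n0)
    f = np.asarray(F, dtype=float)
    if np.any((f < 0) | (f > 1)) or not np.isfinite(f).all():
        raise ValueError("favourability must lie in [0, 1]")
    shift = np.log(n1 / n0)
    with np.errstate(divide="ignore"):
        p = expit(logit(f) + shift)
    p = np.where(f == 0.0, 0.0, np.where(f == 1.0, 1.0, p))
    return float(p) if np.isscalar(F) else p


def classify(F, low_cut: float = LOW_CUT_DEFAULT, high_cut: float = HIGH_CUT_DEFAULT):
    """Map favourability to {'low', 'medium', 'high'}.

    'low' when F < low_cut, 'high' when F >= high_cut (upper boundary
    inclusive), 'medium' otherwise.
    """
    if not 0.0 < low_cut < high_cut < 1.0:
        raise ValueError("need 0 < low_cut < high_cut < 1")
    f = np.asarray(F, dtype=float)
    out = np.where(f < low_cut, "low", np.where(f >= high_cut, "high", "medium"))
    return str(out) if np.isscalar(F) else out
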