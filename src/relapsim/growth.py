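"""Gompertzian growth kinetics for metastatic deposits.

A deposit of ``n0`` cells grows deterministically toward an asymptotic
size ``n_inf`` with an exponentially decaying specific growth rate::

    N(t) = n_inf * exp( ln(n0 / n_inf) * exp(-a * t) )

where ``a`` (per month) controls how quickly growth decelerates.  The law
saturates: ``N(0) = n0`` and ``N(t) -> n_inf`` from below.  Sizes are in
cells, times in months.

Per-deposit kinetic heterogeneity is modelled by drawing ``a``
log-symmetrically (lognormally) around a median rate, which is what turns
the sharply synchronized post-surgery initiation events into hazard peaks
of finite width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GompertzParams",
    "GrowthRateDistribution",
    "gompertz_size",
    "time_to_size",
    "sample_growth_rate",
    "rate_for_transit",
]


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the Gompertz growth law.

    Attributes
    ----------
    n0 : float
        Initial deposit size in cells (``1 <= n0 < n_inf``).
    n_inf : float
        Asymptotic (plateau) size in cells.
    a : float
        Gompertz rate in 1/month (``a > 0``).
    """

    n0: float
    n_inf: float
    a: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.n0 < self.n_inf):
            raise ValueError(
                f"require 1 <= n0 < n_inf, got n0={self.n0}, n_inf={self.n_inf}"
            )
        if not self.a > 0:
            raise ValueError(f"Gompertz rate must be positive, got a={self.a}")


@dataclass(frozen=True)
class GrowthRateDistribution:
    """Log-symmetric distribution of per-deposit Gompertz rates.

    ``ln(a)`` is normal with median ``median_a`` and scale ``sigma_log``;
    ``sigma_log = 0`` degenerates to a deterministic rate.
    """

    median_a: float
    sigma_log: float = 0.3

    def __post_init__(self) -> None:
        if not self.median_a > 0:
            raise ValueError(f"median_a must be positive, got {self.median_a}")
        if self.sigma_log < 0:
            raise ValueError(f"sigma_log must be >= 0, got {self.sigma_log}")


def gompertz_size(params: GompertzParams, t):
    """Deposit size (cells) after ``t`` months of Gompertzian growth.

    Strictly increasing in ``t``, bounded by ``(n0, n_inf)``.  ``t`` may be
    a scalar or array; negative times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    size = params.n_inf * np.exp(
        math.log(params.n0 / params.n_inf) * np.exp(-params.a * t)
    )
    return size if size.ndim else float(size)


def time_to_size(params: GompertzParams, n_target):
    """Months for a deposit to grow from ``n0`` to ``n_target`` cells.

    Closed-form inverse of :func:`gompertz_size`::

        t = -(1/a) * ln( ln(n_target/n_inf) / ln(n0/n_inf) )

    ``n_target`` must lie in ``[n0, n_inf)``; the asymptote is never
    reached in finite time.
    """
    n_target = np.asarray(n_target, dtype=float)
    if np.any(n_target < params.n0) or np.any(n_target >= params.n_inf):
        raise ValueError(
            f"n_target must lie in [{params.n0}, {params.n_inf}), got {n_target}"
        )
    t = -np.log(
        np.log(n_target / params.n_inf) / math.log(params.n0 / params.n_inf)
    ) / params.a
    return t if t.ndim else float(t)


def sample_growth_rate(
    dist: GrowthRateDistribution, rng: np.random.Generator, size=None
):
    """Draw per-deposit Gompertz rates; always positive.

    With ``sigma_log = 0`` returns exactly ``median_a`` (no randomness is
    consumed in that case for scalar draws of a degenerate distribution
    would still be deterministic; a normal draw with zero scale is used so
    the stream advances consistently).
    """
    z = rng.normal(0.0, 1.0, size)
    a = dist.median_a * np.exp(dist.sigma_log * z)
    return a


def rate_for_transit(n0: float, n_inf: float, n_target: float, t: float) -> float:
    """Gompertz rate for which growth from ``n0`` to ``n_target`` takes ``t`` months.

    Used to anchor the default median rate so that a vascularized deposit
    at the avascular size limit reaches clinical detection in a prescribed
    time.
    """
    if not t > 0:
        raise ValueError("transit time must be positive")
    return -math.log(math.log(n_target / n_inf) / math.log(n0 / n_inf)) / t
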