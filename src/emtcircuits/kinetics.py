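"""Kinetic primitives for microRNA/transcription-factor circuit models.

Two building blocks appear in every rate equation of the EMT decision
circuits:

* the *shifted Hill function* — a bounded regulation factor
  ``H(X) = (1 + lambda (X/X0)^n) / (1 + (X/X0)^n)`` that interpolates
  between 1 (no regulator) and the fold change ``lambda`` (saturating
  regulator); ``lambda < 1`` encodes inhibition, ``lambda > 1``
  activation, ``lambda = 1`` a disconnected link;

* the *miRNA silencing machinery* — a microRNA binding independently to
  ``n`` sites on a target mRNA.  The occupancy distribution is binomial
  with per-site occupancy ``(mu/mu0) / (1 + mu/mu0)``, and each occupancy
  level ``i`` carries a translation attenuation ``l_i`` and an active
  degradation rate ``gamma_i``.  Averaging over the occupancy
  distribution yields the translation factor ``L(mu)``, the mRNA
  silencing rate ``Ym(mu)`` and the miRNA consumption rate ``Ymu(mu)``.

All species levels are molecule counts per cell and all rates are per
hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb


__all__ = [
    "ShiftedHill",
    "MiRNABindingModel",
    "shifted_hill",
    "occupancy_weights",
    "mirna_modulation",
]


@dataclass(frozen=True)
class ShiftedHill:
    """A shifted Hill regulation factor.

    Parameters
    ----------
    threshold:
        Half-saturation level ``X0`` in molecules (> 0).
    hill_coefficient:
        Hill coefficient ``n`` (positive integer).
    fold_change:
        Saturating fold change ``lambda`` (> 0).  ``lambda < 1`` is
        inhibition, ``lambda > 1`` activation, ``lambda = 1`` neutral.
    """

    threshold: float
    hill_coefficient: int
    fold_change: float

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        n = self.hill_coefficient
        if not (isinstance(n, (int,)) and n >= 1):
            raise ValueError(f"hill_coefficient must be a positive integer, got {n}")
        if not self.fold_change > 0:
            raise ValueError(f"fold_change must be positive, got {self.fold_change}")

    def __call__(self, x: float) -> float:
        return shifted_hill(x, self)


def shifted_hill(x: float, h: ShiftedHill) -> float:
    """Evaluate ``(1 + lambda (x/X0)^n) / (1 + (x/X0)^n)``.

    Monotone in ``x`` (increasing iff ``lambda > 1``); bounded by
    ``[min(1, lambda), max(1, lambda)]``; identically 1 for a neutral
    link (``lambda = 1``).
    """
    if x < 0:
        raise ValueError(f"regulator level must be non-negative, got {x}")
    t = (x / h.threshold) ** h.hill_coefficient
    lam = h.fold_change
    if t > 1e30:  # saturated; avoid inf/inf
        return lam
    return (1.0 + lam * t) / (1.0 + t)


@dataclass(frozen=True)
class MiRNABindingModel:
    """Binomial occupancy model of a miRNA bound to sites on one mRNA.

    ``silencing_rates[i]`` (``gamma_i``, per hour) and
    ``translation_factors[i]`` (``l_i``, dimensionless) apply to the
    occupancy level with exactly ``i`` of the ``n_sites`` sites bound.
    Invariants: ``gamma_0 = 0``, ``l_0 = 1``, ``l`` non-increasing in
    ``[0, 1]``, ``gamma`` non-negative and non-decreasing.
    """

    n_sites: int
    mu0: float
    silencing_rates: tuple = field(default=())
    translation_factors: tuple = field(default=())
    #: per-occupancy miRNA turnover rates used for the consumption term
    #: ``Ymu``; defaults to ``silencing_rates``.  Catalytic recycling of
    #: the miRNA makes these smaller than the mRNA degradation rates.
    consumption_rates: tuple = field(default=())

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be non-negative")
        if not self.mu0 > 0:
            raise ValueError("mu0 must be positive")
        g = tuple(float(v) for v in self.silencing_rates)
        l = tuple(float(v) for v in self.translation_factors)
        gu = tuple(float(v) for v in self.consumption_rates) or g
        object.__setattr__(self, "silencing_rates", g)
        object.__setattr__(self, "translation_factors", l)
        object.__setattr__(self, "consumption_rates", gu)
        m = self.n_sites + 1
        if len(g) != m or len(l) != m or len(gu) != m:
            raise ValueError(
                f"need {m} silencing rates, translation factors and "
                f"consumption rates, got {len(g)}, {len(l)} and {len(gu)}"
            )
        for rates, what in ((g, "silencing"), (gu, "consumption")):
            if rates[0] != 0.0:
                raise ValueError(f"{what} rate at occupancy 0 must be 0")
            if any(b < 0 for b in rates) or any(
                b2 < b1 for b1, b2 in zip(rates, rates[1:])
            ):
                raise ValueError(
                    f"{what} rates must be non-negative and non-decreasing"
                )
        if l[0] != 1.0:
            raise ValueError("l_0 must be 1 (unbound mRNA translates fully)")
        if any(not 0.0 <= v <= 1.0 for v in l) or any(
            v2 > v1 for v1, v2 in zip(l, l[1:])
        ):
            raise ValueError("translation factors must be non-increasing within [0, 1]")


def occupancy_weights(mu: float, b: MiRNABindingModel) -> list[float]:
    """Binomial occupancy distribution over 0..n_sites bound sites.

    ``weight_i = C(n, i) (mu/mu0)^i / (1 + mu/mu0)^n``, computed through
    the per-site occupancy probability ``p = (mu/mu0)/(1 + mu/mu0)`` so
    that large ``mu/mu0`` never overflows.
    """
    if mu < 0:
        raise ValueError(f"miRNA level must be non-negative, got {mu}")
    n = b.n_sites
    r = mu / b.mu0
    p = r / (1.0 + r)
    q = 1.0 / (1.0 + r)
    return [comb(n, i) * p**i * q ** (n - i) for i in range(n + 1)]


def mirna_modulation(mu: float, b: MiRNABindingModel) -> tuple[float, float, float]:
    """Occupancy-averaged silencing quantities ``(L, Ym, Ymu)``.

    ``L`` is the translation factor in ``(0, 1]``, ``Ym`` the active
    mRNA degradation rate (per hour per mRNA) and ``Ymu`` the miRNA
    consumption rate (per hour per mRNA; a turnover event at occupancy
    ``i`` consumes ``i`` miRNA molecules, at the per-occupancy
    ``consumption_rates``, which default to the silencing rates).
    """
    w = occupancy_weights(mu, b)
    l = b.translation_factors
    g = b.silencing_rates
    gu = b.consumption_rates
    L = sum(li * wi for li, wi in zip(l, w))
    Ym = sum(gi * wi for gi, wi in zip(g, w))
    Ymu = sum(i * gi * wi for i, (gi, wi) in enumerate(zip(gu, w)))
    return L, Ym, Ymu
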