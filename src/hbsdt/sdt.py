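"""Classical equal-variance Gaussian signal detection theory.

Point estimates of discriminability (d') and response bias (criterion c)
from hit and false-alarm rates, plus the forward map from (c, d') back to
rates.  Conventions:

* ``d' = probit(hit_rate) - probit(fa_rate)`` — separation of the signal and
  noise strength distributions in SD units.
* ``c = -(probit(hit_rate) + probit(fa_rate)) / 2`` — distance of the
  decision threshold from the optimal midpoint; negative values mean a
  liberal ("yes"-leaning) observer.
* Forward map: ``hit_rate = Phi(d'/2 - c)``, ``fa_rate = Phi(-d'/2 - c)``.
"""

from __future__ import annotations

import math
from typing import NamedTuple, TYPE_CHECKING

from scipy.special import ndtr, ndtri

if TYPE_CHECKING:  # pragma: no cover
    from .agn_data import TrialCounts


class RatePair(NamedTuple):
    hit_rate: float
    fa_rate: float


class SDTEstimate(NamedTuple):
    d_prime: float
    criterion: float


def probit(p: float) -> float:
    """Standard-normal quantile; defined on the open interval (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probit requires 0 < p < 1, got {p}")
    return float(ndtri(p))


def probit_inv(z: float) -> float:
    """Standard-normal CDF (Phi); inverse of :func:`probit`."""
    return float(ndtr(z))


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (conventional reporting, unlike banker's)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def rates_from_counts(c: "TrialCounts", round_2dp: bool = False) -> RatePair:
    """Hit and false-alarm rates from counts.

    With ``round_2dp`` each rate is rounded half-away-from-zero to two
    decimals, the precision at which aggregate tables are conventionally
    reported.
    """
    if c.signal_total < 1 or c.noise_total < 1:
        raise ValueError("rates require at least one signal and one noise trial")
    h = c.hits / c.signal_total
    f = c.false_alarms / c.noise_total
    if round_2dp:
        h, f = round_half_away(h), round_half_away(f)
    return RatePair(h, f)


def adjusted_rates(c: "TrialCounts") -> RatePair:
    """Rates with the 1/(2N) correction for extreme proportions.

    A rate of 0 becomes 1/(2·total) and a rate of 1 becomes 1 - 1/(2·total),
    keeping the probit transform finite for subjects at ceiling or floor.
    """
    h, f = rates_from_counts(c)
    if h == 0.0:
        h = 1.0 / (2 * c.signal_total)
    elif h == 1.0:
        h = 1.0 - 1.0 / (2 * c.signal_total)
    if f == 0.0:
        f = 1.0 / (2 * c.noise_total)
    elif f == 1.0:
        f = 1.0 - 1.0 / (2 * c.noise_total)
    return RatePair(h, f)


def dprime(r: RatePair) -> float:
    """Discriminability: probit(hit rate) minus probit(false-alarm rate)."""
    return probit(r.hit_rate) - probit(r.fa_rate)


def criterion(r: RatePair) -> float:
    """Response bias: negative mean of the two probits.

    Negative values indicate a preference for "yes" responses (threshold
    nearer the noise distribution); positive values a preference for "no".
    """
    return -(probit(r.hit_rate) + probit(r.fa_rate)) / 2.0


def estimate(c: "TrialCounts") -> SDTEstimate:
    """Classical per-cell estimate with extreme-rate adjustment applied."""
    r = adjusted_rates(c)
    return SDTEstimate(d_prime=dprime(r), criterion=criterion(r))


def rates_from_sdt(criterion: float, d_prime: float) -> RatePair:
    """Forward map from (c, d') to response rates under the equal-variance model."""
    return RatePair(
        probit_inv(d_prime / 2.0 - criterion),
        probit_inv(-d_prime / 2.0 - criterion),
    )
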