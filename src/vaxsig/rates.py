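"""Exact Poisson rate estimation for rare vaccine adverse events.

Adverse-event surveillance reports an event count *k* over an exposure of
*D* administered doses. The rate per million doses is ``1e6 * k / D``; its
two-sided exact (Garwood) confidence interval comes from the chi-square
representation of the Poisson tail:

    lower = 0.5 * chi2.ppf(alpha / 2, 2k)          (0 when k = 0)
    upper = 0.5 * chi2.ppf(1 - alpha / 2, 2k + 2)

both scaled by ``1e6 / D``. The exact interval guarantees coverage at
least ``1 - alpha`` for any true rate, which matters at the single-digit
event counts typical of thrombosis-with-thrombocytopenia surveillance.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RateEstimate:
    """Event rate per million doses with an exact two-sided CI."""

    events: int
    exposure_doses: int
    rate_per_million: float
    ci_low_per_million: float
    ci_high_per_million: float
    alpha: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(rate, low, high) rounded for reporting; internals stay exact."""
        return (
            round(self.rate_per_million, ndigits),
            round(self.ci_low_per_million, ndigits),
            round(self.ci_high_per_million, ndigits),
        )


def poisson_rate_ci(events: int, exposure_doses: int, alpha: float = 0.05) -> RateEstimate:
    """Exact (Garwood) Poisson rate and CI, per million doses.

    Parameters
    ----------
    events
        Observed event count, >= 0.
    exposure_doses
        Number of administered doses, > 0.
    alpha
        Two-sided non-coverage level (0.05 for a 95% CI).
    """
    if events < 0 or int(events) != events:
        raise ValueError(f"events must be a non-negative integer, got {events}")
    if exposure_doses <= 0:
        raise ValueError(f"exposure_doses must be positive, got {exposure_doses}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    events = int(events)
    scale = 1e6 / exposure_doses
    # chi-square quantile at 0 df taken as 0: zero events pin the lower bound.
    lower = 0.0 if events == 0 else 0.5 * stats.chi2.ppf(alpha / 2, 2 * events)
    upper = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * events + 2)
    return RateEstimate(
        events=events,
        exposure_doses=int(exposure_doses),
        rate_per_million=events * scale,
        ci_low_per_million=lower * scale,
        ci_high_per_million=upper * scale,
        alpha=alpha,
    )


def rate_table(
    rows: list[tuple[str, int, int]], alpha: float = 0.05, ndigits: int = 2
) -> pd.DataFrame:
    """Surveillance-table layout: one row per (label, events, doses).

    Rounding to ``ndigits`` happens only here, at the reporting layer.
    """
    records = []
    for label, events, doses in rows:
        est = poisson_rate_ci(events, doses, alpha=alpha)
        rate, low, high = est.rounded(ndigits)
        records.append(
            {
                "label": label,
                "doses": est.exposure_doses,
                "events": est.events,
                "rate_per_million": rate,
                "ci_low_per_million": low,
                "ci_high_per_million": high,
            }
        )
    return pd.DataFrame.from_records(records)
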