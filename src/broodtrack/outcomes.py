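"""Breeding attempts, fates, cohort bookkeeping and nest survival.

Each maximal incubation segment of a bird's timeline is one breeding
attempt. Its fate follows from what comes next: chick guarding means
the clutch hatched; a return to non-breeding movement means the nest
failed; an attempt cut short by the end of tracking (tag loss) is right
censored. Daily nest survival is estimated from exposure days in the
classic way: with f failures over E nest-days the maximum-likelihood
daily survival rate is 1 - f/E, with a profile-likelihood interval on
the binomial-exposure likelihood.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2

from .focal_sites import FocalSite
from .stage_labels import StageLabel, StageSegment


class Fate(enum.Enum):
    FAILED = "N"
    HATCHED = "Y"
    CENSORED = "OU"


@dataclass
class BreedingAttempt:
    tag_id: str
    attempt_index: int
    incubation_start: pd.Timestamp | None
    incubation_end: pd.Timestamp | None
    exposure_days: float
    fate: Fate
    nest: FocalSite | None = None


class ConsistencyError(ValueError):
    pass


def assemble_attempts(
    segments: list[StageSegment],
    nests: dict[int, FocalSite] | None = None,
    tag_id: str = "",
) -> list[BreedingAttempt]:
    """Turn one bird's tiled stage segments into breeding attempts."""
    segs = sorted(segments, key=lambda s: s.start)
    for a, b in zip(segs, segs[1:]):
        if a.label is StageLabel.INCUBATION and b.label is StageLabel.INCUBATION and a.end > b.start:
            raise ConsistencyError(f"overlapping incubation segments for {tag_id}")
    attempts = []
    idx = 0
    for i, seg in enumerate(segs):
        if seg.label is not StageLabel.INCUBATION:
            continue
        idx += 1
        nxt = segs[i + 1] if i + 1 < len(segs) else None
        if nxt is None:
            fate = Fate.CENSORED  # tracking ended during incubation
        elif nxt.label is StageLabel.CHICK_GUARDING:
            fate = Fate.HATCHED
        else:
            fate = Fate.FAILED
        attempts.append(
            BreedingAttempt(
                tag_id=tag_id,
                attempt_index=idx,
                incubation_start=seg.start,
                incubation_end=seg.end,
                exposure_days=seg.days,
                fate=fate,
                nest=(nests or {}).get(seg.attempt_index if seg.attempt_index else idx),
            )
        )
    return attempts


def _pct(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half-up."""
    if denominator == 0:
        raise ValueError("denominator is zero")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def population_summary(attempts: list[BreedingAttempt], n_birds: int) -> dict:
    """Cohort bookkeeping: breeders, renesters, failures and hatches.

    ``attempts`` covers every attempt of every tracked bird; birds
    absent from it are non-breeders. Percentages are integer-rounded
    (half-up) to match the precision such tables are reported at.
    """
    if n_birds <= 0:
        raise ValueError("n_birds must be positive")
    by_bird: dict[str, list[BreedingAttempt]] = {}
    for a in attempts:
        by_bird.setdefault(a.tag_id, []).append(a)
    n_breeders = len(by_bird)
    n_nonbreeders = n_birds - n_breeders
    if n_nonbreeders < 0:
        raise ValueError("more breeders than birds")
    n_attempts = len(attempts)
    n_two_plus = sum(1 for v in by_bird.values() if len(v) >= 2)
    n_three_plus = sum(1 for v in by_bird.values() if len(v) >= 3)
    n_failed = sum(1 for a in attempts if a.fate is Fate.FAILED)
    hatched_birds = {a.tag_id for a in attempts if a.fate is Fate.HATCHED}
    n_hatched = len(hatched_birds)

    out = {
        "n_birds": n_birds,
        "n_nonbreeders": n_nonbreeders,
        "pct_nonbreeders": _pct(n_nonbreeders, n_birds),
        "n_breeders": n_breeders,
        "pct_breeders": _pct(n_breeders, n_birds),
        "n_attempts": n_attempts,
        "n_two_attempt_birds": n_two_plus,
        "pct_two_attempt_birds": _pct(n_two_plus, n_birds),
        "n_three_attempt_birds": n_three_plus,
        "pct_three_attempt_birds": _pct(n_three_plus, n_birds),
        "n_incubation_failures": n_failed,
        "pct_incubation_failures": _pct(n_failed, n_attempts) if n_attempts else 0,
        "n_hatched_birds": n_hatched,
        "pct_hatched_of_breeders": _pct(n_hatched, n_breeders) if n_breeders else 0,
        "pct_hatched_of_all": _pct(n_hatched, n_birds),
    }
    return out


@dataclass
class NestSurvivalEstimate:
    dsr: float
    ci_low: float
    ci_high: float
    n_failures: int
    total_exposure: float
    period_days: int
    period_success: float


def _profile_ci(f: int, E: float, alpha: float = 0.05) -> tuple[float, float]:
    """Profile-likelihood CI for daily survival on the exposure likelihood."""
    p_hat = 1.0 - f / E
    crit = chi2.ppf(1.0 - alpha, df=1) / 2.0

    def ll(p: float) -> float:
        s = E - f
        out = 0.0
        if s > 0:
            out += s * math.log(p) if p > 0 else -math.inf
        if f > 0:
            out += f * math.log(1.0 - p) if p < 1 else -math.inf
        return out

    ll_hat = ll(p_hat) if 0.0 < p_hat < 1.0 else (0.0 if f == 0 else ll(max(p_hat, 1e-12)))

    def g(p: float) -> float:
        return ll_hat - ll(p) - crit

    eps = 1e-12
    lo = brentq(g, eps, p_hat) if p_hat > eps and g(eps) > 0 else 0.0
    if f == 0:
        hi = 1.0
    else:
        hi = brentq(g, p_hat, 1.0 - eps) if p_hat < 1.0 - eps and g(1.0 - eps) > 0 else 1.0
    return float(lo), float(hi)


def mayfield_dsr(
    attempts: list[BreedingAttempt],
    period_days: int = 28,
    midpoint: bool = False,
) -> NestSurvivalEstimate:
    """Constant daily nest survival from exposure days.

    Hatched and censored attempts contribute exposure only; failed
    attempts contribute exposure plus one failure event. ``midpoint``
    subtracts half a day of exposure per failure — the classic
    correction for failure dates known only to the day; with
    transitions resolved to hours it stays off by default.
    """
    E = sum(a.exposure_days for a in attempts)
    f = sum(1 for a in attempts if a.fate is Fate.FAILED)
    if midpoint:
        E -= 0.5 * f
    if E <= 0:
        raise ValueError("total exposure must be positive")
    if f > E:
        raise ValueError("more failures than exposure days")
    dsr = 1.0 - f / E
    lo, hi = _profile_ci(f, E)
    return NestSurvivalEstimate(
        dsr=float(dsr), ci_low=lo, ci_high=hi, n_failures=int(f),
        total_exposure=float(E), period_days=period_days,
        period_success=period_success(dsr, period_days),
    )


def period_success(dsr: float, period_days: int = 28) -> float:
    """Probability a nest survives the whole incubation period."""
    if not 0.0 <= dsr <= 1.0:
        raise ValueError("dsr must be a probability")
    return float(dsr**period_days)


def attempts_to_frame(attempts: list[BreedingAttempt]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tag_id": a.tag_id,
                "attempt_index": a.attempt_index,
                "interval_days": a.exposure_days,
                "fate": a.fate.value,
                "incubation_start": a.incubation_start,
                "incubation_end": a.incubation_end,
                "nest_lon": a.nest.lon if a.nest else None,
                "nest_lat": a.nest.lat if a.nest else None,
            }
            for a in attempts
        ]
    )
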