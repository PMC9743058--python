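"""Stage-structured synthetic curlew tracks with ground-truth timelines.

The generator emulates the movement regimes that produce the published
weekly revisitation shapes:

* **Non-breeding movement** (pre- and post-breeding): a correlated
  random walk (gamma step lengths, wrapped-Cauchy turning angles) with
  a weak pull toward a home-range centre, producing wide-ranging tracks
  where most places are visited once.
* **Incubation**: alternating on-nest bouts (positions at the nest plus
  a few metres of settling jitter) and off-nest foraging excursions,
  with the tagged bird on the nest for roughly the configured duty
  share — both sexes share incubation, so the tag sees a strong focal
  site revisited many times per week (a bimodal weekly profile).
* **Chick guarding**: a latent brood point drifting slowly across the
  landscape with the adult dispersed around it — many places visited a
  few times each, with no single dominant focus.
* **Failure**: a multi-kilometre displacement followed by wide-ranging
  non-breeding movement (the scattering seen after nest or brood loss).

Isotropic Gaussian GPS noise is added to every fix. Same config and
seed give byte-identical output. All coordinates are generated in a
local metric frame and exported as WGS84 lon/lat around a configurable
origin, so the output is a raw relocation table like any field download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import geo
from .io_tracks import Trajectory
from .stage_labels import StageLabel, StageSegment, TransitionEvent, TransitionKind

NONBREEDING = (StageLabel.PRE_BREEDING, StageLabel.POST_BREEDING)


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one simulated bird."""

    seed: int
    tag_id: str = "SIM001"
    start: str = "2019-04-15T00:00:00"
    sampling_interval_min: float = 15.0
    gps_noise_sd_m: float = 10.0
    origin_lonlat: tuple[float, float] = (-4.2, 53.2)
    #: ordered stage plan: (StageLabel, duration in days)
    stages: tuple[tuple[StageLabel, float], ...] = (
        (StageLabel.PRE_BREEDING, 7.0),
        (StageLabel.INCUBATION, 28.0),
        (StageLabel.CHICK_GUARDING, 10.0),
        (StageLabel.POST_BREEDING, 7.0),
    )
    # incubation parameters (duty-cycle values are placeholders, see docs)
    on_bout_mean_min: float = 45.0
    off_bout_mean_min: float = 20.0
    nest_jitter_sd_m: float = 3.0
    excursion_range_m: float = 800.0
    # non-breeding correlated random walk
    step_mean_m: float = 200.0
    turn_concentration: float = 0.7  # wrapped-Cauchy rho
    home_pull: float = 0.02  # per-fix fractional pull to the range centre
    # chick guarding
    brood_drift_m_per_day: float = 300.0
    brood_heading_sd: float = 0.05  # radians per fix; small = ballistic drift
    dispersion_sd_m: float = 100.0
    # failure
    failure_displacement_km: float = 6.0

    @property
    def duty_share(self) -> float:
        return self.on_bout_mean_min / (self.on_bout_mean_min + self.off_bout_mean_min)


@dataclass
class SimOutput:
    trajectory: Trajectory
    truth_segments: list[StageSegment]
    truth_transitions: list[TransitionEvent]
    truth_nests: list[dict]  # per attempt: x, y, lon, lat, attempt_index


def _validate(config: SimConfig) -> None:
    seen_inc = False
    for label, days in config.stages:
        if days <= 0:
            raise SimConfigError("stage durations must be positive")
        if label is StageLabel.CHICK_GUARDING and not seen_inc:
            raise SimConfigError("chick guarding before any incubation")
        if label is StageLabel.INCUBATION:
            seen_inc = True
    if not 0 < config.duty_share < 1:
        raise SimConfigError("duty share must be in (0, 1)")


def simulate_bird(config: SimConfig) -> SimOutput:
    """Generate one bird's trajectory plus its ground-truth timeline."""
    _validate(config)
    rng = np.random.default_rng(config.seed)
    dt_s = config.sampling_interval_min * 60.0
    total_days = sum(d for _, d in config.stages)
    n_fix = int(round(total_days * 86400.0 / dt_s)) + 1  # inclusive grid
    t0 = pd.Timestamp(config.start)
    times = t0 + pd.to_timedelta(np.arange(n_fix) * dt_s, unit="s")

    # stage membership per fix (half-open stage intervals, last fix closes)
    bounds_s = np.cumsum([0.0] + [d * 86400.0 for _, d in config.stages])
    fix_s = np.arange(n_fix) * dt_s
    stage_idx = np.minimum(np.searchsorted(bounds_s, fix_s, side="right") - 1,
                           len(config.stages) - 1)

    xy = np.zeros((n_fix, 2))
    pos = np.zeros(2)
    heading = rng.uniform(-np.pi, np.pi)
    nests: list[dict] = []
    attempt = 0
    prev_label: StageLabel | None = None
    nest = None
    brood = None
    brood_heading = 0.0
    on_nest_until = off_until = -1.0
    forage_point = np.zeros(2)
    home = pos.copy()

    transitions: list[TransitionEvent] = []
    for k in range(n_fix):
        label = config.stages[stage_idx[k]][0]
        now = fix_s[k]
        if label is not prev_label:
            # stage-entry side effects
            kind: TransitionKind | None = None
            if label is StageLabel.INCUBATION:
                attempt += 1
                nest = pos + rng.normal(0.0, 300.0, 2)
                nests.append({"attempt_index": attempt, "x": float(nest[0]), "y": float(nest[1])})
                pos = nest.copy()
                on_nest_until = now + rng.exponential(config.on_bout_mean_min * 60.0)
                off_until = -1.0
                kind = TransitionKind.INCUBATION_START
            elif label is StageLabel.CHICK_GUARDING:
                brood = nest.copy()
                brood_heading = rng.uniform(-np.pi, np.pi)
                kind = TransitionKind.HATCH
            else:  # entering a non-breeding stage
                if prev_label is StageLabel.INCUBATION:
                    kind = TransitionKind.NEST_FAIL
                elif prev_label is StageLabel.CHICK_GUARDING:
                    kind = TransitionKind.BROOD_FAIL
                if kind is not None:  # failure: displace, then range widely
                    theta = rng.uniform(-np.pi, np.pi)
                    pos = pos + config.failure_displacement_km * 1000.0 * np.array(
                        [np.cos(theta), np.sin(theta)]
                    )
                home = pos.copy()
                heading = rng.uniform(-np.pi, np.pi)
            if prev_label is not None and kind is not None:
                transitions.append(TransitionEvent(kind=kind, time=times[k], resolution_s=0.0))
            prev_label = label

        if label in NONBREEDING:
            heading = heading + _wrapped_cauchy(rng, config.turn_concentration)
            step = rng.gamma(2.0, config.step_mean_m / 2.0)
            pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
            pos = pos + config.home_pull * (home - pos)
        elif label is StageLabel.INCUBATION:
            if now < on_nest_until:
                pos = nest + rng.normal(0.0, config.nest_jitter_sd_m, 2)
            else:
                if now >= off_until:
                    # start a new foraging excursion, then a fresh on-bout
                    theta = rng.uniform(-np.pi, np.pi)
                    dist = rng.uniform(100.0, config.excursion_range_m)
                    forage_point = nest + dist * np.array([np.cos(theta), np.sin(theta)])
                    off_until = now + rng.exponential(config.off_bout_mean_min * 60.0)
                    on_nest_until = off_until + rng.exponential(config.on_bout_mean_min * 60.0)
                pos = forage_point + rng.normal(0.0, 20.0, 2)
        else:  # chick guarding
            brood_heading += rng.normal(0.0, config.brood_heading_sd)
            speed = config.brood_drift_m_per_day / (86400.0 / dt_s)
            brood = brood + speed * np.array([np.cos(brood_heading), np.sin(brood_heading)])
            pos = brood + rng.normal(0.0, config.dispersion_sd_m, 2)

        xy[k] = pos

    xy_noisy = xy + rng.normal(0.0, config.gps_noise_sd_m, (n_fix, 2))
    lon, lat = geo.aeqd_inverse(xy_noisy[:, 0], xy_noisy[:, 1], *config.origin_lonlat)
    nsat = rng.integers(5, 13, n_fix)
    df = pd.DataFrame(
        {"timestamp": times, "lon": lon, "lat": lat, "n_satellites": nsat}
    )
    traj = Trajectory(
        tag_id=config.tag_id,
        df=df,
        sampling_interval=pd.Timedelta(minutes=config.sampling_interval_min),
        tagging_location=(float(lon[0]), float(lat[0])),
    )

    segments = []
    att = 0
    for i, (label, _) in enumerate(config.stages):
        start = t0 + pd.Timedelta(seconds=bounds_s[i])
        end = t0 + pd.Timedelta(seconds=bounds_s[i + 1])
        if label is StageLabel.INCUBATION:
            att += 1
        segments.append(
            StageSegment(label=label, start=start, end=end,
                         attempt_index=att if label is StageLabel.INCUBATION else None)
        )
    transitions.append(TransitionEvent(kind=TransitionKind.TAG_END, time=times[-1], resolution_s=0.0))

    for rec in nests:
        nlon, nlat = geo.aeqd_inverse(rec["x"], rec["y"], *config.origin_lonlat)
        rec["lon"], rec["lat"] = float(nlon), float(nlat)

    return SimOutput(traj, segments, transitions, nests)


def _wrapped_cauchy(rng: np.random.Generator, rho: float) -> float:
    """Wrapped-Cauchy turning angle centred on zero with concentration rho."""
    if rho <= 0:
        return rng.uniform(-np.pi, np.pi)
    u = rng.uniform()
    v = np.cos(2.0 * np.pi * u)
    c = 2.0 * rho / (1.0 + rho**2)
    angle = np.arccos(np.clip((v + c) / (1.0 + c * v), -1.0, 1.0))
    return angle if rng.uniform() < 0.5 else -angle


# ---------------------------------------------------------------------------
# cohorts

LIFE_HISTORIES = ("nonbreeder", "single", "renester")


@dataclass(frozen=True)
class CohortConfig:
    """Mix of life histories for a simulated cohort.

    ``mix`` maps life-history names to proportions summing to 1;
    membership counts are assigned by largest remainder so the realised
    cohort matches the proportions as closely as integers allow.
    ``daily_survival`` drives geometric failure timing for attempts that
    do not hatch; an attempt hatches when it survives ``incubation_days``.
    """

    n_birds: int = 23
    mix: dict[str, float] = field(
        default_factory=lambda: {"nonbreeder": 0.26, "single": 0.44, "renester": 0.30}
    )
    daily_survival: float = 0.95
    incubation_days: int = 28
    chick_guard_days: float = 10.0
    pre_days: float = 7.0
    post_days: float = 7.0
    renest_gap_days: float = 5.0


def _counts_from_mix(mix: dict[str, float], n: int) -> dict[str, int]:
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise SimConfigError(f"life-history proportions sum to {sum(mix.values())}, not 1")
    unknown = set(mix) - set(LIFE_HISTORIES)
    if unknown:
        raise SimConfigError(f"unknown life histories: {sorted(unknown)}")
    raw = {k: v * n for k, v in mix.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    remainder = n - sum(counts.values())
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def _attempt_days(rng: np.random.Generator, cohort: CohortConfig) -> tuple[float, bool]:
    """(incubation duration in days, hatched?) with geometric failure timing."""
    fail_day = rng.geometric(1.0 - cohort.daily_survival)
    if fail_day > cohort.incubation_days:
        return float(cohort.incubation_days), True
    return float(fail_day), False


def _bird_plan(history: str, rng: np.random.Generator, cohort: CohortConfig
               ) -> tuple[tuple[StageLabel, float], ...]:
    post = (StageLabel.POST_BREEDING, cohort.post_days)
    if history == "nonbreeder":
        # one undifferentiated non-breeding span: with no attempt there is
        # no event to separate pre- from post-breeding behaviour
        return (
            (StageLabel.PRE_BREEDING,
             cohort.pre_days + cohort.incubation_days + cohort.post_days),
        )
    # fractional-day jitter so stage changes fall at arbitrary hours
    stages: list[tuple[StageLabel, float]] = [
        (StageLabel.PRE_BREEDING, cohort.pre_days + rng.uniform())
    ]
    n_attempts = 1 if history == "single" else 2
    for i in range(n_attempts):
        days, hatched = _attempt_days(rng, cohort)
        # make every attempt span at least 3 days so it is observable
        days = max(days, 3.0) + rng.uniform()
        stages.append((StageLabel.INCUBATION, days))
        if hatched:
            stages.append((StageLabel.CHICK_GUARDING, cohort.chick_guard_days))
            break
        if i < n_attempts - 1:
            stages.append((StageLabel.POST_BREEDING, cohort.renest_gap_days))
    stages.append(post)
    return tuple(stages)


def simulate_cohort(
    cohort: CohortConfig, seed: int, base_config: SimConfig | None = None
) -> list[SimOutput]:
    """Reproducible cohort of simulated birds with mixed life histories."""
    if cohort.n_birds < 1:
        raise SimConfigError("n_birds must be >= 1")
    counts = _counts_from_mix(cohort.mix, cohort.n_birds)
    base = base_config or SimConfig(seed=0)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(cohort.n_birds * 2)]
    outputs = []
    i = 0
    for history in LIFE_HISTORIES:
        for _ in range(counts.get(history, 0)):
            plan_rng = np.random.default_rng(child_seeds[2 * i])
            stages = _bird_plan(history, plan_rng, cohort)
            cfg = dc_replace(
                base,
                seed=child_seeds[2 * i + 1],
                tag_id=f"SIM{i + 1:03d}",
                stages=stages,
            )
            outputs.append(simulate_bird(cfg))
            i += 1
    return outputs


def write_truth(outputs: list[SimOutput], out_dir: str | Path) -> None:
    """Write per-bird truth segments, transitions and nests as CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seg_rows, tr_rows, nest_rows = [], [], []
    for out in outputs:
        tag = out.trajectory.tag_id
        for seg in out.truth_segments:
            seg_rows.append({"tag_id": tag, "label": seg.label.name,
                             "start": seg.start, "end": seg.end,
                             "attempt_index": seg.attempt_index})
        for tr in out.truth_transitions:
            tr_rows.append({"tag_id": tag, "kind": tr.kind.name, "time": tr.time})
        for nest in out.truth_nests:
            nest_rows.append({"tag_id": tag, **nest})
    pd.DataFrame(seg_rows).to_csv(out_dir / "truth_segments.csv", index=False)
    pd.DataFrame(tr_rows).to_csv(out_dir / "truth_transitions.csv", index=False)
    pd.DataFrame(nest_rows).to_csv(out_dir / "truth_nests.csv", index=False)
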