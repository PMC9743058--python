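"""Per-bird and cohort tracking summaries, plus the packaged fixtures.

The fixtures transcribe the study cohort's published per-bird tracking
summaries (days of data, relocations, displacement from the tagging
location) and per-attempt breeding outcomes; they let the cohort
bookkeeping and survival estimators be exercised on the real numbers
without any download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import geo
from .io_tracks import Trajectory
from .outcomes import BreedingAttempt, Fate
from .stage_labels import StageLabel, StageSegment


def _round_half_up(x: float, decimals: int = 0) -> float:
    scale = 10.0**decimals
    return math.floor(x * scale + 0.5) / scale


@dataclass
class BirdSummary:
    tag_id: str
    n_days: float
    n_relocations: int
    mean_displacement_km: float
    max_displacement_km: float
    mean_displacement_incubation_km: float | None = None


def per_bird_summary(
    traj: Trajectory,
    tagging_location: tuple[float, float] | None = None,
    incubation_segments: list[StageSegment] | None = None,
) -> BirdSummary:
    """Tracking-effort and displacement summary for one bird.

    Displacements are great-circle distances (km) from the tagging
    location; the incubation mean is restricted to fixes inside
    incubation segments.
    """
    if len(traj) == 0:
        return BirdSummary(traj.tag_id, 0.0, 0, 0.0, 0.0, None)
    loc = tagging_location or traj.tagging_location
    if loc is None:
        loc = (float(traj.df["lon"].iloc[0]), float(traj.df["lat"].iloc[0]))
    d_km = geo.haversine_m(traj.df["lon"].to_numpy(), traj.df["lat"].to_numpy(),
                           loc[0], loc[1]) / 1000.0
    inc_mean = None
    if incubation_segments:
        mask = np.zeros(len(traj), dtype=bool)
        ts = traj.df["timestamp"]
        for seg in incubation_segments:
            if seg.label is StageLabel.INCUBATION:
                mask |= ((ts >= seg.start) & (ts < seg.end)).to_numpy()
        if mask.any():
            inc_mean = float(d_km[mask].mean())
    return BirdSummary(
        tag_id=traj.tag_id,
        n_days=traj.span_days,
        n_relocations=len(traj),
        mean_displacement_km=float(d_km.mean()),
        max_displacement_km=float(d_km.max()),
        mean_displacement_incubation_km=inc_mean,
    )


def cohort_summary(summaries: list[BirdSummary]) -> dict:
    """Cohort totals/means at the precision such tables are printed at.

    Days and kilometres are rounded half-up to one decimal, relocation
    counts to integers.
    """
    if not summaries:
        raise ValueError("no bird summaries")
    days = np.array([s.n_days for s in summaries], dtype=float)
    relocs = np.array([s.n_relocations for s in summaries], dtype=float)
    maxd = np.array([s.max_displacement_km for s in summaries], dtype=float)
    meand = np.array([s.mean_displacement_km for s in summaries], dtype=float)
    return {
        "n_birds": len(summaries),
        "total_relocations": int(relocs.sum()),
        "mean_days": _round_half_up(float(days.mean()), 1),
        "range_days": (float(days.min()), float(days.max())),
        "mean_relocations": int(_round_half_up(float(relocs.mean()))),
        "range_relocations": (int(relocs.min()), int(relocs.max())),
        "mean_displacement_km": _round_half_up(float(meand.mean()), 1),
        "mean_max_displacement_km": _round_half_up(float(maxd.mean()), 1),
        "overall_max_displacement_km": float(maxd.max()),
    }


# ---------------------------------------------------------------------------
# packaged fixtures


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("broodtrack.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#", na_values=["NA"])


def load_table1() -> pd.DataFrame:
    """Per-bird tracking summaries of the study cohort (26 tagged birds)."""
    return _read_fixture("table1_birds.csv")


def load_table2_birds() -> pd.DataFrame:
    """Per-bird breeding outcome rows (23 birds with analyzable data)."""
    return _read_fixture("table2_birds.csv")


def load_table2_attempts() -> pd.DataFrame:
    """Per-attempt nesting intervals and fates (25 attempts)."""
    return _read_fixture("table2_attempts.csv")


def summaries_from_table1(df: pd.DataFrame | None = None) -> list[BirdSummary]:
    """BirdSummary records for the birds with analyzable data."""
    df = load_table1() if df is None else df
    out = []
    for _, row in df.dropna(subset=["n_days"]).iterrows():
        out.append(
            BirdSummary(
                tag_id=row["tag_id"],
                n_days=float(row["n_days"]),
                n_relocations=int(row["n_relocations"]),
                mean_displacement_km=float(row["mean_km"]),
                max_displacement_km=float(row["max_km"]),
                mean_displacement_incubation_km=(
                    float(row["mean_incubation_km"])
                    if pd.notna(row["mean_incubation_km"]) else None
                ),
            )
        )
    return out


def attempts_from_table2(
    attempts_df: pd.DataFrame | None = None,
) -> list[BreedingAttempt]:
    """BreedingAttempt records from the per-attempt fixture."""
    df = load_table2_attempts() if attempts_df is None else attempts_df
    fate_map = {"Y": Fate.HATCHED, "N": Fate.FAILED, "OU": Fate.CENSORED}
    return [
        BreedingAttempt(
            tag_id=row["tag_id"],
            attempt_index=int(row["attempt_index"]),
            incubation_start=None,
            incubation_end=None,
            exposure_days=float(row["interval_days"]),
            fate=fate_map[row["fate"]],
        )
        for _, row in df.iterrows()
    ]
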