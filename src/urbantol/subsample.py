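"""Spatiotemporal, detection-class-balanced thinning of checklists.

Community-science effort is spatially clustered (towards cities and coasts)
and temporally uneven, and non-detections of any focal species vastly
outnumber detections.  Thinning to at most one detection and one
non-detection checklist per (hex cell, year, week) stratum removes both
biases at once: the spatial/temporal clustering and the class imbalance,
since the two classes are sampled independently.

Week is ``floor((day_of_year - 1) / 7) + 1`` capped at 52 (days 365/366
fold into week 52); strata are per calendar year, not pooled week-of-year,
with a switch for the pooled reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def week_of_year(dates: pd.Series) -> pd.Series:
    """Seven-day week index 1..52; days 365/366 belong to week 52."""
    doy = pd.to_datetime(dates).dt.dayofyear
    return ((doy - 1) // 7 + 1).clip(upper=52)


@dataclass
class SubsampleResult:
    """Outcome of one subsampling pass."""

    retained_ids: pd.Index
    n_strata: int
    n_input: int
    n_retained: int
    seed: int
    per_stratum: pd.DataFrame | None = field(default=None, repr=False)


def spatiotemporal_subsample(
    dataset: pd.DataFrame,
    seed: int,
    pool_years: bool = False,
    per_class: bool = True,
    keep_counts: bool = False,
) -> SubsampleResult:
    """Retain at most one checklist per stratum and detection class.

    ``dataset`` must carry columns ``checklist_id``, ``cell_q``, ``cell_r``,
    ``date`` and ``detection`` (boolean: count >= 1).  Within each
    (cell, year, week, class) stratum one row is chosen uniformly at random;
    the choice is a pure function of ``seed``.  With ``per_class=False`` the
    detection class is ignored and each stratum keeps a single checklist.

    Applying the subsampler to its own output returns it unchanged, since
    every stratum then holds at most one candidate.
    """
    df = dataset.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    dates = pd.to_datetime(df["date"])
    keys = [df["cell_q"], df["cell_r"], week_of_year(dates)]
    if not pool_years:
        keys.append(dates.dt.year)
    if per_class:
        keys.append(df["detection"].astype(bool))
    # order-independent: sort by checklist_id, then give each row an iid
    # uniform draw and keep the per-stratum argmax
    order = np.argsort(df["checklist_id"].to_numpy(), kind="stable")
    df_sorted = df.iloc[order]
    keys_sorted = [k.iloc[order] for k in keys]
    u = rng.random(len(df_sorted))
    grp = pd.Series(u, index=df_sorted.index).groupby(keys_sorted, sort=True)
    winners = grp.idxmax()
    retained = pd.Index(df.loc[winners.to_numpy(), "checklist_id"])
    per_stratum = None
    if keep_counts:
        per_stratum = grp.size().rename("n_candidates").reset_index()
    return SubsampleResult(
        retained_ids=retained,
        n_strata=int(grp.ngroups),
        n_input=len(df),
        n_retained=len(retained),
        seed=seed,
        per_stratum=per_stratum,
    )


def species_inclusion_check(
    dataset: pd.DataFrame, min_detections: int = 1000
) -> tuple[bool, int]:
    """Whether a species has enough detection checklists to model.

    Counted on the filtered, pre-subsampling data: a species needs at least
    ``min_detections`` checklists with count >= 1 (boundary inclusive;
    999 detections is excluded, 1000 included).  Species below the floor
    yield unstable tolerance profiles and are excluded.
    """
    n = int(dataset["detection"].astype(bool).sum())
    return n >= min_detections, n
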