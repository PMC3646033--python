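"""Segmentation quality (Dice), the full factorial parameter sweep and
descriptive group statistics.

The sweep varies image noise level (NOISE ∈ {0, 1, 2}), number of
generated seed regions (SEEDS ∈ {2, 3, 5, 9, 17, 33, 65, 129}), seed
region scaling (SCALING ∈ 0..5 mm) and fiber bundle membership
(FBM ∈ 10..100 %, step 10), i.e. 1440 parameterizations, and scores each
against ground truth with the Dice Similarity Coefficient
DSC = 2|A∩B| / (|A| + |B|).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masks import BinaryMask, fbm_threshold, run_repeated_tracking
from .centerline import SeedPlan
from .tracking import TrackingParams

NOISE_LEVELS = (0, 1, 2)
SEEDS_LEVELS = (2, 3, 5, 9, 17, 33, 65, 129)
SCALING_LEVELS = (0, 1, 2, 3, 4, 5)
FBM_LEVELS = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)


@dataclass(frozen=True)
class SweepRecord:
    noise_level: int
    n_seeds: int
    scaling_mm: int
    fbm_percent: int
    dsc: float


@dataclass(frozen=True)
class GroupSummary:
    variable: str
    group: int
    n: int
    mean: float  # DSC in percent
    std: float
    min: float
    max: float


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice Similarity Coefficient of two binary masks on the same grid.

    1 means a perfect match, 0 no overlap.  Two empty masks return 1.0
    with a warning (the formula is 0/0 there).
    """
    if not a.grid.same_as(b.grid):
        raise ValueError("masks are on different grids")
    na = int(a.data.sum())
    nb = int(b.data.sum())
    if na == 0 and nb == 0:
        warnings.warn("Dice of two empty masks; returning 1 by convention")
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def build_parameter_grid(
    noise=NOISE_LEVELS, seeds=SEEDS_LEVELS, scaling=SCALING_LEVELS, fbm=FBM_LEVELS
) -> list[tuple[int, int, int, int]]:
    """Cartesian product (noise, seeds, scaling, fbm); full grid has 1440 rows."""
    return list(itertools.product(noise, seeds, scaling, fbm))


def run_sweep(
    phantoms,
    grid,
    tparams: TrackingParams = TrackingParams(),
    **repeat_kwargs,
) -> list[SweepRecord]:
    """Evaluate every (noise, seeds, scaling, fbm) combination.

    Parameters
    ----------
    phantoms : mapping noise_level -> (TensorField, GroundTruth)
        One (fitted) tensor field per noise level, sharing geometry.
    grid : iterable of (noise, seeds, scaling, fbm)
        E.g. the output of :func:`build_parameter_grid`.

    Repeated tracking is cached per (noise, seeds, scaling): the FBM rows
    of one triple share a single count mask.
    """
    cache: dict[tuple[int, int, int], object] = {}
    records: list[SweepRecord] = []
    for noise, n_seeds, scaling, fbm in grid:
        key = (noise, n_seeds, scaling)
        if key not in cache:
            field, truth = phantoms[noise]
            cache[key] = run_repeated_tracking(
                field, truth.seed_roi, truth.include_roi,
                SeedPlan(n_seeds, float(scaling)), tparams, **repeat_kwargs,
            )
        result = cache[key]
        field, truth = phantoms[noise]
        seg = fbm_threshold(result.count_mask, fbm)
        d = dice(seg, BinaryMask(truth.bundle_mask, truth.grid))
        records.append(SweepRecord(noise, n_seeds, scaling, fbm, d))
    return records


_COLUMNS = {"noise": "noise_level", "seeds": "n_seeds",
            "scaling": "scaling_mm", "fbm": "fbm_percent"}


def records_to_frame(records) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    return df.rename(columns={v: k for k, v in _COLUMNS.items()})


def group_summary(records, variable: str) -> list[GroupSummary]:
    """Descriptive DSC statistics (in percent, sample std) per value of one
    grouping variable ('noise', 'seeds', 'scaling' or 'fbm')."""
    if variable not in _COLUMNS:
        raise ValueError(f"unknown grouping variable {variable!r}")
    if not records:
        raise ValueError("no records to summarize")
    df = records_to_frame(records)
    out = []
    for value, sub in df.groupby(variable):
        pct = sub["dsc"] * 100.0
        out.append(GroupSummary(
            variable=variable, group=int(value), n=len(sub),
            mean=float(pct.mean()),
            std=float(pct.std(ddof=1)) if len(sub) > 1 else 0.0,
            min=float(pct.min()), max=float(pct.max()),
        ))
    return out


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def best_band_mean(records, *, scaling=(1, 2, 3, 4, 5), min_seeds_exclusive: int = 2,
                   fbm=(30, 40, 50), noise_level: int | None = None) -> float:
    """Mean DSC over the preferred parameter band (scaling 1–5 mm, more than
    two seed regions, FBM 30–50 %), optionally restricted to one noise level."""
    df = records_to_frame(records)
    sel = (
        df["scaling"].isin(scaling)
        & (df["seeds"] > min_seeds_exclusive)
        & df["fbm"].isin(fbm)
    )
    if noise_level is not None:
        sel &= df["noise"] == noise_level
    sub = df[sel]
    if sub.empty:
        raise ValueError("no records in the requested band")
    return float(sub["dsc"].mean())
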