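"""Rating matrices: participants x images beauty ratings on the 1-4 scale.

The scale follows the German school-grade convention: 1 = most beautiful,
4 = least beautiful. Matrices carry a phase label: ``baseline`` (the initial
full rating pass), ``after_beautiful`` or ``after_least`` (post-adaptation
passes over each participant's evaluation set). The baseline matrix must be
complete; adaptation matrices may cover only the evaluation images (other
cells are missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHASES = ("baseline", "after_beautiful", "after_least")
RATING_MIN, RATING_MAX = 1, 4


@dataclass
class RatingMatrix:
    """Wide participants x images table of integer ratings (NaN = not rated)."""

    ratings: pd.DataFrame  # index: participant ids; columns: image ids
    phase: str = "baseline"

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        vals = self.ratings.to_numpy(dtype=float)
        observed = vals[~np.isnan(vals)]
        if observed.size and (
            (observed < RATING_MIN).any()
            or (observed > RATING_MAX).any()
            or np.any(observed != np.round(observed))
        ):
            raise ValueError("ratings must be integers in {1, 2, 3, 4}")
        if self.phase == "baseline" and np.isnan(vals).any():
            raise ValueError("baseline rating matrix is incomplete")

    @property
    def participants(self) -> list:
        return list(self.ratings.index)

    @property
    def images(self) -> list:
        return list(self.ratings.columns)

    @property
    def n_participants(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_images(self) -> int:
        return self.ratings.shape[1]


def load_ratings(path: str | Path, phase: str = "baseline") -> RatingMatrix:
    """Load one phase of a long-format ratings CSV.

    Expected columns: ``participant_id, image_id, phase, rating``. Rows with
    out-of-range ratings are rejected with a logged diagnostic; duplicate
    (participant, image, phase) entries and an incomplete baseline are hard
    errors.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "image_id", "phase", "rating"}
    if not required <= set(df.columns):
        raise ValueError(f"ratings CSV must have columns {sorted(required)}")
    df = df[df["phase"] == phase]
    if df.empty:
        raise ValueError(f"no rows with phase {phase!r} in {path}")
    ok = df["rating"].between(RATING_MIN, RATING_MAX) & (df["rating"] == df["rating"].round())
    if (~ok).any():
        for _, bad in df[~ok].iterrows():
            logger.warning(
                "rejecting rating %r for participant %r, image %r (must be integer 1-4)",
                bad["rating"], bad["participant_id"], bad["image_id"],
            )
        df = df[ok]
    dup = df.duplicated(["participant_id", "image_id"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (participant, image) ratings in phase {phase!r}")
    wide = df.pivot(index="participant_id", columns="image_id", values="rating")
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    return RatingMatrix(wide, phase=phase)


def to_long(matrix: RatingMatrix) -> pd.DataFrame:
    """Long-format view (participant_id, image_id, phase, rating), observed cells only."""
    long = matrix.ratings.stack().rename("rating").reset_index()
    long.columns = ["participant_id", "image_id", "rating"]
    long.insert(2, "phase", matrix.phase)
    return long
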