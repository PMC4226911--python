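"""Two-step densitometry normalization for the dual-fluorescence screen.

Band intensities (DLK1-HA, GFP, Tubulin) are first divided by their
membrane-specific channel averages computed over non-siRNA lanes, yielding
*relative* amounts; the relative DLK1 amount of each lane is then divided
by its relative GFP (or Tubulin) amount, yielding the *corrected* DLK1
amount — the screen's response variable. The siRNA positive control is
excluded from the membrane averages (it is an extreme outlier) but still
receives relative values against those averages.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

CHANNELS = ("DLK1", "GFP", "Tubulin")
NORMALIZERS = ("GFP", "Tubulin")
SIRNA = "siRNA"

INTENSITY_COLUMNS = [
    "membrane_id", "transfection_id", "lane_id", "treatment", "channel", "intensity",
]


class IntensityTableError(ValueError):
    """Raised for schema or validity violations in an intensity table."""


def validate_intensity_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INTENSITY_COLUMNS if c not in records.columns]
    if missing:
        raise IntensityTableError(f"intensity table missing columns: {missing}")
    df = records[INTENSITY_COLUMNS].copy()
    bad_channel = set(df["channel"]) - set(CHANNELS)
    if bad_channel:
        raise IntensityTableError(f"unknown channels: {sorted(bad_channel)}")
    if (df["intensity"] <= 0).any():
        bad = df.loc[df["intensity"] <= 0].iloc[0]
        raise IntensityTableError(
            f"non-positive intensity for membrane {bad.membrane_id!r} "
            f"lane {bad.lane_id!r} channel {bad.channel!r}"
        )
    dup = df.duplicated(subset=["membrane_id", "lane_id", "channel"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise IntensityTableError(
            f"duplicate record for membrane {bad.membrane_id!r} "
            f"lane {bad.lane_id!r} channel {bad.channel!r}"
        )
    return df


def relative_amounts(records: pd.DataFrame, mean: str = "arithmetic") -> pd.DataFrame:
    """Divide each band by its membrane x channel average over non-siRNA lanes.

    ``mean`` selects the membrane average: ``"arithmetic"`` (default) or
    ``"geometric"`` (natural under multiplicative noise). siRNA lanes are
    normalized against the same non-siRNA average for every channel.
    """
    if mean not in ("arithmetic", "geometric"):
        raise ValueError(f"mean must be 'arithmetic' or 'geometric', got {mean!r}")
    df = validate_intensity_table(records)
    non_sirna = df.loc[df["treatment"] != SIRNA]
    only_sirna = set(map(tuple, df[["membrane_id", "channel"]].itertuples(index=False))) - set(
        map(tuple, non_sirna[["membrane_id", "channel"]].itertuples(index=False))
    )
    if only_sirna:
        raise IntensityTableError(
            f"membrane x channel groups contain only siRNA lanes: {sorted(only_sirna)}"
        )
    if mean == "arithmetic":
        baselines = non_sirna.groupby(["membrane_id", "channel"])["intensity"].mean()
    else:
        import numpy as np

        baselines = non_sirna.groupby(["membrane_id", "channel"])["intensity"].apply(
            lambda x: float(np.exp(np.log(x).mean()))
        )
    keys = pd.MultiIndex.from_frame(df[["membrane_id", "channel"]])
    out = df.copy()
    out["relative"] = df["intensity"].to_numpy() / baselines.reindex(keys).to_numpy()
    return out


def corrected_dlk1(relative: pd.DataFrame, normalizer: str = "GFP") -> pd.DataFrame:
    """Per-lane corrected DLK1 amount = relative DLK1 / relative normalizer.

    Lanes missing either channel are dropped with a logged warning ("usable
    measures" only); a zero or negative normalizer value is an error.
    """
    if normalizer not in NORMALIZERS:
        raise ValueError(f"normalizer must be one of {NORMALIZERS}, got {normalizer!r}")
    if "relative" not in relative.columns:
        raise IntensityTableError("expected a relative-amounts table (missing 'relative')")
    keys = ["membrane_id", "transfection_id", "lane_id", "treatment"]
    wide = (
        relative.loc[relative["channel"].isin(["DLK1", normalizer])]
        .pivot_table(index=keys, columns="channel", values="relative", aggfunc="first")
        .reset_index()
    )
    incomplete = wide["DLK1"].isna() | wide[normalizer].isna()
    if incomplete.any():
        dropped = wide.loc[incomplete, ["membrane_id", "lane_id"]]
        logger.warning(
            "dropping %d lane(s) missing a DLK1 or %s band: %s",
            len(dropped), normalizer, dropped.to_records(index=False).tolist(),
        )
        wide = wide.loc[~incomplete]
    if (wide[normalizer] <= 0).any():
        bad = wide.loc[wide[normalizer] <= 0].iloc[0]
        raise IntensityTableError(
            f"non-positive relative {normalizer} for membrane {bad.membrane_id!r} "
            f"lane {bad.lane_id!r}"
        )
    out = wide.rename(columns={"DLK1": "relative_dlk1", normalizer: "relative_normalizer"})
    out["corrected"] = out["relative_dlk1"] / out["relative_normalizer"]
    out["normalizer"] = normalizer
    return out[keys + ["relative_dlk1", "relative_normalizer", "corrected", "normalizer"]]


def normalize_screen(
    records: pd.DataFrame, normalizer: str = "GFP", mean: str = "arithmetic"
) -> pd.DataFrame:
    """Full normalization: raw intensities -> corrected DLK1 amounts."""
    return corrected_dlk1(relative_amounts(records, mean=mean), normalizer=normalizer)
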