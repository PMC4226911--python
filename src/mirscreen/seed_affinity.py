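"""Seed-match site counting, affinity scores, and score–effect correlation.

Canonical seed-match site classes, written on the target sense strand
5'->3' with the guide bound antiparallel (guide positions 1-based):

======== =====================================  ======
class    target site string                      length
======== =====================================  ======
8mer      revcomp(guide[2..8]) + A               8
7mer-m8   revcomp(guide[2..8])                   7
7mer-A1   revcomp(guide[2..7]) + A               7
6mer      revcomp(guide[2..7])                   6
6mer-off  revcomp(guide[3..8])                   6
======== =====================================  ======

The terminal A of the 8mer/7mer-A1 classes is a target adenosine opposite
guide position 1, not a complement of it. Hierarchical counting assigns
each occurrence to the longest matching class only: a shorter-class match
whose footprint lies inside a counted longer-class footprint is suppressed.
Overlapping counting reports every class independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .transcripts import (
    FULL_LENGTH,
    REGION_NAMES,
    MiRNASpec,
    TargetTranscript,
    UNAMBIGUOUS,
    as_mirna,
    normalize_rna,
    reverse_complement,
)

logger = logging.getLogger(__name__)

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer", "6mer-offset")
#: Treatments never entering score-effect correlations.
CONTROL_TREATMENTS = frozenset({"NC1", "NC2", "siRNA"})

MODES = ("hierarchical", "overlapping")


class SeedAmbiguityError(ValueError):
    """Guide carries an IUPAC ambiguity inside positions 1-8."""


def site_strings(mirna: MiRNASpec | str) -> dict[str, str]:
    """Target-strand site string for each of the five seed-match classes."""
    spec = as_mirna(mirna)
    head = spec.guide[:8]
    bad = set(head) - UNAMBIGUOUS
    if bad:
        raise SeedAmbiguityError(
            f"miRNA {spec.name!r}: seed region (positions 1-8) must be unambiguous, "
            f"found {sorted(bad)!r}"
        )
    seed_2_7 = reverse_complement(spec.guide[1:7])
    seed_2_8 = reverse_complement(spec.guide[1:8])
    seed_3_8 = reverse_complement(spec.guide[2:8])
    return {
        "8mer": seed_2_8 + "A",
        "7mer-m8": seed_2_8,
        "7mer-A1": seed_2_7 + "A",
        "6mer": seed_2_7,
        "6mer-offset": seed_3_8,
    }


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) start indices of ``needle``."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def seed_matches(
    mirna: MiRNASpec | str, sequence: str, mode: str = "hierarchical"
) -> list[tuple[str, int]]:
    """All seed-match occurrences as (site_class, start) pairs.

    In hierarchical mode, classes are visited longest-first and a match is
    kept only if its [start, end) footprint is not contained in an
    already-kept footprint of a longer (or earlier same-length) class.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    seq = normalize_rna(sequence, allow_n=True)
    sites = site_strings(mirna)
    if mode == "overlapping":
        return [(cls, i) for cls in SITE_CLASSES for i in _find_all(seq, sites[cls])]
    kept: list[tuple[str, int]] = []
    claimed: list[tuple[int, int]] = []
    for cls in SITE_CLASSES:  # ordered by decreasing site length
        width = len(sites[cls])
        for start in _find_all(seq, sites[cls]):
            end = start + width
            if any(a <= start and end <= b for a, b in claimed):
                continue
            kept.append((cls, start))
            claimed.append((start, end))
    return kept


@dataclass(frozen=True)
class SeedMatchProfile:
    """Counts of the five site classes per region plus full-length."""

    mirna_name: str
    mode: str
    counts: Mapping[str, Mapping[str, int]]  # region -> class -> count

    def count(self, region: str, site_class: str) -> int:
        return int(self.counts.get(region, {}).get(site_class, 0))

    def total(self, region: str = FULL_LENGTH, classes: Iterable[str] = SITE_CLASSES) -> int:
        return sum(self.count(region, c) for c in classes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mirna": self.mirna_name, "mode": self.mode, "region": region,
             "site_class": cls, "count": self.count(region, cls)}
            for region in self.counts
            for cls in SITE_CLASSES
        ]
        return pd.DataFrame(rows)


def seed_sites(
    mirna: MiRNASpec | str,
    target: TargetTranscript,
    mode: str = "hierarchical",
) -> SeedMatchProfile:
    """Count seed-match sites per region of ``target``.

    A site is assigned to the region containing its start coordinate;
    ``full_length`` counts every match on the whole sequence, so it can
    exceed the per-region sum when sites start outside any annotated region.
    """
    spec = as_mirna(mirna)
    if len(target) < 8 or len(spec) < 8:
        raise ValueError("target and guide must both be >= 8 nt")
    matches = seed_matches(spec, target.sequence, mode=mode)
    region_names = [r.name for r in target.regions]
    counts: dict[str, dict[str, int]] = {
        name: {cls: 0 for cls in SITE_CLASSES}
        for name in dict.fromkeys(region_names)  # preserve order, dedupe
    }
    counts[FULL_LENGTH] = {cls: 0 for cls in SITE_CLASSES}
    for cls, start in matches:
        counts[FULL_LENGTH][cls] += 1
        region = target.region_at(start)
        if region is not None:
            counts[region][cls] += 1
    return SeedMatchProfile(mirna_name=spec.name, mode=mode, counts=counts)


DEFAULT_WEIGHTS = {cls: 1.0 for cls in SITE_CLASSES}


def seed_score(
    profile: SeedMatchProfile,
    weights: Mapping[str, float] | None = None,
    region: str = FULL_LENGTH,
) -> float:
    """Weighted site-count affinity score; unit weights give the plain total."""
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    for cls, val in w.items():
        if val < 0:
            raise ValueError(f"negative weight for {cls!r}: {val}")
    return float(sum(w[cls] * profile.count(region, cls) for cls in SITE_CLASSES))


@dataclass(frozen=True)
class CorrelationResult:
    score_type: str
    region: str
    pearson_r: float
    p_value: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.pearson_r)


def affinity_effect_correlation(
    scores: Mapping[str, float],
    effects: pd.DataFrame,
    *,
    effect_column: str = "mean_corrected",
    score_type: str = "seed",
    region: str = FULL_LENGTH,
) -> CorrelationResult:
    """Pearson correlation between per-miRNA scores and screen effects.

    ``effects`` must carry ``treatment`` and ``effect_column`` columns;
    control treatments (NC1, NC2, siRNA) are excluded. Constant scores or
    effects yield an undefined (NaN) correlation, flagged and logged rather
    than reported as zero.
    """
    df = effects.loc[~effects["treatment"].isin(CONTROL_TREATMENTS),
                     ["treatment", effect_column]].copy()
    df["score"] = df["treatment"].map(scores)
    df = df.dropna(subset=["score", effect_column])
    n = len(df)
    if n < 3:
        raise ValueError(f"need >= 3 paired observations, got {n}")
    x = df["score"].to_numpy(float)
    y = df[effect_column].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning(
            "correlation undefined for score_type=%s region=%s: constant input", score_type, region
        )
        return CorrelationResult(score_type, region, float("nan"), float("nan"), n)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(score_type, region, float(r), float(p), n)


def attach_external_scores(
    external: Mapping[str, float] | pd.DataFrame,
    effects: pd.DataFrame,
) -> dict[str, float]:
    """Join externally computed per-miRNA scores (e.g. Miranda) onto the screen.

    Returns the name->score mapping restricted to miRNAs present in the
    effect table; unmatched names are logged. An empty overlap is an error.
    """
    if isinstance(external, pd.DataFrame):
        if external.shape[1] < 2:
            raise ValueError("external score table needs (name, score) columns")
        external = dict(zip(external.iloc[:, 0], external.iloc[:, 1]))
    known = set(effects["treatment"])
    joined = {name: float(s) for name, s in external.items() if name in known}
    missing = sorted(set(external) - known)
    if missing:
        logger.warning("external scores for unknown miRNAs ignored: %s", missing)
    if not joined:
        raise ValueError("no overlap between external score names and effect table")
    return joined
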