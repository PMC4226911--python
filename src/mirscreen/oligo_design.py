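"""Oligo design: mimic duplexes, scrambled negative controls, isomir picks.

A mimic duplex pairs the mature guide with a synthetic passenger strand —
the perfect reverse complement of the guide minus its two 3'-terminal
nucleotides, with a UU dinucleotide appended — producing equal-length
strands with symmetric 2-nt 3' overhangs that promote RISC loading of the
guide. The passenger 5' end carries an NH2 modification (recorded as
metadata) to disfavour its own loading.

Scrambled negative controls are built by shuffle-filter-rank: permute each
source guide several times, discard shuffles with any 8mer / 7mer-m8 /
7mer-A1 / 6mer seed match to the target transcript, and rank survivors by
their seed-match burden against a background transcript set (a stand-in
for genome-wide conserved-target prediction).

Isomir selection reduces a small-RNA-seq catalog to the species worth
synthesizing: per precursor arm, the most abundant isomir, plus 5'-shifted
isomirs that are either over one third as abundant as the miRBase
reference or seen above a per-library read floor, plus unregistered star
sequences that were observed at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seed_affinity import site_strings, _find_all
from .transcripts import (
    MiRNASpec,
    SequenceError,
    TargetTranscript,
    UNAMBIGUOUS,
    as_mirna,
    reverse_complement,
)

logger = logging.getLogger(__name__)

#: Site classes used by the negative-control filter (the 6mer-offset class
#: is not part of the published filter).
NC_FILTER_CLASSES = ("8mer", "7mer-A1", "7mer-m8", "6mer")


@dataclass(frozen=True)
class MimicDuplex:
    guide: str
    passenger: str
    guide_five_prime: str = ""
    passenger_five_prime: str = "NH2"

    def __post_init__(self) -> None:
        if len(self.passenger) != len(self.guide):
            raise ValueError("guide and passenger must have equal length")


def build_mimic_duplex(guide: MiRNASpec | str) -> MimicDuplex:
    """Guide + perfect-reverse-complement passenger with 2-nt 3' overhangs.

    passenger = revcomp(guide[1 .. L-2]) + "UU" (1-based positions): the
    guide's 3'-terminal two nucleotides and the passenger's terminal UU are
    left unpaired, and the remaining L-2 positions pair Watson-Crick.
    Declared mixed (IUPAC) guide bases yield the complementary IUPAC code
    in the passenger; undeclared ambiguity is rejected by MiRNASpec.
    """
    spec = as_mirna(guide)
    passenger = reverse_complement(spec.guide[:-2]) + "UU"
    return MimicDuplex(guide=spec.guide, passenger=passenger)


def shuffle_sequence(sequence: str, rng: np.random.Generator) -> str:
    """Uniform letter permutation (nucleotide composition preserved)."""
    letters = list(sequence)
    rng.shuffle(letters)
    return "".join(letters)


def shuffle_sequence_dinucleotide(sequence: str, rng: np.random.Generator) -> str:
    """Composition-preserving shuffle of non-overlapping dinucleotide blocks.

    A lightweight alternative that retains local dinucleotide content
    better than a plain letter permutation.
    """
    pairs = [sequence[i:i + 2] for i in range(0, len(sequence) - 1, 2)]
    tail = sequence[len(pairs) * 2:]
    rng.shuffle(pairs)
    return "".join(pairs) + tail


def total_seed_matches(
    guide_sequence: str,
    target_sequence: str,
    classes: Sequence[str] = NC_FILTER_CLASSES,
) -> int:
    """Total occurrences of the given site classes on a target sequence."""
    sites = site_strings(MiRNASpec(name="query", guide=guide_sequence))
    return sum(len(_find_all(target_sequence, sites[c])) for c in classes)


@dataclass(frozen=True)
class NCCandidate:
    source_mirna: str
    shuffle_index: int
    sequence: str
    target_matches: int
    offtarget_burden: int
    selected: bool


def design_scrambled_controls(
    mirnas: Sequence[MiRNASpec],
    target: TargetTranscript,
    background: Sequence[TargetTranscript] = (),
    n_shuffles: int = 10,
    n_select: int = 2,
    rng_seed: int = 0,
    dinucleotide: bool = False,
) -> list[NCCandidate]:
    """Shuffle-filter-rank design of scrambled negative controls.

    Every candidate is scored against the target's full-length sequence;
    survivors (zero matches in any filter class) are ranked ascending by
    total seed-match burden over the background set, ties broken by
    (source miRNA name, shuffle index) for determinism. Returns all
    candidates, the top ``n_select`` survivors flagged ``selected``.
    """
    if n_shuffles < 1:
        raise ValueError(f"n_shuffles must be >= 1, got {n_shuffles}")
    if not len(target.sequence):
        raise ValueError("target transcript is empty")
    if not background:
        logger.warning("empty background set: off-target ranking skipped (burden = 0)")
    shuffler = shuffle_sequence_dinucleotide if dinucleotide else shuffle_sequence
    rng = np.random.default_rng(rng_seed)
    candidates: list[NCCandidate] = []
    for spec in mirnas:
        spec = as_mirna(spec)
        for k in range(1, n_shuffles + 1):
            shuffled = shuffler(spec.guide, rng)
            try:
                on_target = total_seed_matches(shuffled, target.sequence)
                burden = sum(
                    total_seed_matches(shuffled, bg.sequence) for bg in background
                )
            except SequenceError:
                # a shuffle can move a declared mixed base into the seed
                logger.info("shuffle %s#%d has an ambiguous seed; discarded", spec.name, k)
                continue
            candidates.append(
                NCCandidate(spec.name, k, shuffled, on_target, burden, selected=False)
            )
    survivors = sorted(
        (c for c in candidates if c.target_matches == 0),
        key=lambda c: (c.offtarget_burden, c.source_mirna, c.shuffle_index),
    )
    if not survivors:
        raise RuntimeError(
            "no shuffled sequence is free of seed matches to the target; "
            "increase n_shuffles"
        )
    chosen = {(c.source_mirna, c.shuffle_index) for c in survivors[:n_select]}
    return [
        NCCandidate(
            c.source_mirna, c.shuffle_index, c.sequence, c.target_matches,
            c.offtarget_burden, selected=(c.source_mirna, c.shuffle_index) in chosen,
        )
        for c in candidates
    ]


# ---------------------------------------------------------------------------
# isomir selection

ISOMIR_KEY_COLUMNS = ["name", "precursor", "arm", "sequence", "five_prime_offset",
                      "is_mirbase_reference"]


def _library_columns(catalog: pd.DataFrame) -> list[str]:
    cols = [c for c in catalog.columns if c.startswith("lib_")]
    if not cols:
        raise ValueError("isomir catalog has no lib_* read-count columns")
    return cols


def select_isomirs(
    catalog: pd.DataFrame,
    fraction: float = 1.0 / 3.0,
    min_reads: int = 200,
    per_library: bool = False,
) -> pd.DataFrame:
    """Choose the isomirs to synthesize from a read-count catalog.

    Per (precursor, arm): (a) the most abundant isomir — by total reads
    across libraries, or by best single-library count when
    ``per_library=True`` — is always selected; (b) additionally, any
    5'-shifted isomir whose total reads exceed ``fraction`` x the
    miRBase-reference isomir's total, or that exceeds ``min_reads`` in at
    least one library; (c) observed isomirs on an arm with no registered
    reference (unregistered star arms) are selected when they have reads.
    When an arm lacks a reference isomir the fraction rule is skipped with
    a warning; the per-library floor still applies.

    Returns the selected rows with a ``selection_reason`` column.
    """
    if fraction < 0 or min_reads < 0:
        raise ValueError("fraction and min_reads must be non-negative")
    missing = [c for c in ISOMIR_KEY_COLUMNS if c not in catalog.columns]
    if missing:
        raise ValueError(f"isomir catalog missing columns: {missing}")
    libs = _library_columns(catalog)
    df = catalog.copy()
    df["total_reads"] = df[libs].sum(axis=1)
    df["max_library_reads"] = df[libs].max(axis=1)

    selected_rows = []
    for (precursor, arm), group in df.groupby(["precursor", "arm"]):
        if group.empty:
            continue
        abundance = group["max_library_reads"] if per_library else group["total_reads"]
        top_idx = abundance.idxmax()
        refs = group.loc[group["is_mirbase_reference"]]
        ref_total = float(refs["total_reads"].max()) if not refs.empty else None
        if refs.empty:
            logger.warning(
                "arm %s-%s has no miRBase reference: fraction rule skipped "
                "(unregistered star arm)", precursor, arm,
            )
        for idx, row in group.iterrows():
            reasons = []
            if idx == top_idx and row["total_reads"] > 0:
                reasons.append("most_abundant")
            if row["five_prime_offset"] != 0:
                if ref_total is not None and row["total_reads"] > fraction * ref_total:
                    reasons.append("fraction_of_reference")
                if row["max_library_reads"] > min_reads:
                    reasons.append("library_read_floor")
            if refs.empty and row["total_reads"] > 0:
                reasons.append("unregistered_star")
            if reasons:
                out = row.copy()
                out["selection_reason"] = "+".join(reasons)
                selected_rows.append(out)
    if not selected_rows:
        return df.head(0).assign(selection_reason=pd.Series(dtype=str))
    return pd.DataFrame(selected_rows).reset_index(drop=True)


def selected_mirna_specs(selection: pd.DataFrame) -> list[MiRNASpec]:
    """Turn selected isomir rows into MiRNASpec objects (mixed bases verbatim)."""
    specs = []
    for _, row in selection.iterrows():
        mixed = frozenset(
            i for i, b in enumerate(str(row["sequence"]).upper().replace("T", "U"), start=1)
            if b not in UNAMBIGUOUS
        )
        specs.append(MiRNASpec(name=row["name"], guide=row["sequence"], mixed_positions=mixed))
    return specs
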