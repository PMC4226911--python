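"""Seeded synthetic inputs with the statistical structure the screen assumes.

The screen generator emulates a dual-fluorescence Western-blot reporter
assay: ~121 miRNA mimic treatments plus two scrambled negative controls
and one siRNA positive control, each transfected in several independent
wells whose lysates are run on several blots. Intensities combine, all
multiplicatively (lognormal):

* a membrane-level scale effect shared by every band on a blot,
* a per-well transfection efficiency shared by the DLK1 and GFP channels
  (but not by endogenous Tubulin),
* a planted per-treatment fold acting on DLK1 only,
* independent per-band measurement noise.

A Bernoulli dropout per (well x blot) models unusable measures. Every draw
comes from one seeded generator, so identical configs give byte-identical
tables.

Also here: a transcript simulator that plants seed-match sites of known
class/region and rejection-samples the background so no unplanned sites
exist, the deterministic reporter-construct layout arithmetic, and an
isomir read-count catalog generator with known expected selections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seed_affinity import SITE_CLASSES, seed_matches, site_strings
from .transcripts import (
    MiRNASpec,
    Region,
    SequenceError,
    TargetTranscript,
    normalize_rna,
)

CHANNELS = ("DLK1", "GFP", "Tubulin")
NC_NAMES = ("NC1", "NC2")
SIRNA = "siRNA"


class ConfigError(ValueError):
    """An invalid simulation configuration, naming the offending field."""


def mirna_names(n: int) -> list[str]:
    """Synthetic treatment names miR-sim-001 ... miR-sim-NNN."""
    return [f"miR-sim-{i:03d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic screen.

    Defaults emulate the study conditions: 121 mimic miRNAs, two negative
    controls, one ~3-fold-knockdown siRNA, five transfections with two
    blots each and 17% dropout so the expected number of usable measures
    per treatment is 8.3. All SDs are on the natural-log scale.
    """

    n_mirnas: int = 121
    n_neg_controls: int = 2
    include_sirna: bool = True
    n_transfections: int = 5
    n_blots_per_transfection: int = 2
    dropout_prob: float = 0.17
    planted_effects: Mapping[str, float] | None = None
    sirna_fold: float = 1.0 / 3.0
    membrane_sd: float = 0.30
    efficiency_sd: float = 0.20
    noise_sd: float = 0.15
    base_intensity: Mapping[str, float] = field(
        default_factory=lambda: {"DLK1": 1.0e4, "GFP": 2.0e4, "Tubulin": 5.0e4}
    )
    mirnas_per_membrane: int = 12
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("n_mirnas", "n_transfections", "n_blots_per_transfection",
                     "mirnas_per_membrane"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_neg_controls < 0:
            raise ConfigError(f"n_neg_controls must be >= 0, got {self.n_neg_controls}")
        if not 0 <= self.dropout_prob < 1:
            raise ConfigError(f"dropout_prob must be in [0, 1), got {self.dropout_prob}")
        for name in ("membrane_sd", "efficiency_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.sirna_fold <= 0:
            raise ConfigError(f"sirna_fold must be > 0, got {self.sirna_fold}")
        for ch in CHANNELS:
            if self.base_intensity.get(ch, 0) <= 0:
                raise ConfigError(f"base_intensity[{ch!r}] must be > 0")
        if self.planted_effects is not None:
            for k, v in self.planted_effects.items():
                if v <= 0:
                    raise ConfigError(f"planted_effects[{k!r}] must be > 0, got {v}")

    @property
    def treatments(self) -> list[str]:
        names = mirna_names(self.n_mirnas)
        names += [f"NC{i}" for i in range(1, self.n_neg_controls + 1)]
        if self.include_sirna:
            names.append(SIRNA)
        return names

    def effects(self) -> dict[str, float]:
        """Planted fold per treatment (default: null miRNAs, siRNA knockdown)."""
        eff = {t: 1.0 for t in self.treatments}
        if self.include_sirna:
            eff[SIRNA] = self.sirna_fold
        if self.planted_effects:
            unknown = set(self.planted_effects) - set(eff)
            if unknown:
                raise ConfigError(f"planted_effects names unknown treatments: {sorted(unknown)}")
            eff.update(self.planted_effects)
        return eff


@dataclass
class TruthTable:
    """Simulation ground truth for recovery tests."""

    treatment_fold: dict[str, float]
    membrane_effect: dict[str, float]
    lane_efficiency: dict[tuple[str, str], float]
    dropped_lanes: list[tuple[str, str]] = field(default_factory=list)


def simulate_screen(config: SimulationConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Generate one synthetic screen intensity table plus its ground truth.

    Membranes hold up to ``mirnas_per_membrane`` miRNA lanes plus one lane
    for each control, so every blot carries its own negative controls. The
    same well's lysate (one treatment x transfection) reappears on each
    blot replicate with the same transfection efficiency.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    effects = config.effects()
    controls = [t for t in config.treatments if t.startswith("NC")] + (
        [SIRNA] if config.include_sirna else []
    )
    mirnas = mirna_names(config.n_mirnas)
    groups = [
        mirnas[i:i + config.mirnas_per_membrane]
        for i in range(0, len(mirnas), config.mirnas_per_membrane)
    ]

    truth = TruthTable(treatment_fold=effects, membrane_effect={}, lane_efficiency={})
    base = config.base_intensity
    rows: list[tuple] = []
    for g, group in enumerate(groups, start=1):
        lanes = group + controls
        for t in range(1, config.n_transfections + 1):
            # one transfected well per treatment in this group and replicate
            eff = {
                lane: float(rng.lognormal(0.0, config.efficiency_sd)) for lane in lanes
            }
            dropout = {
                (lane, b): bool(rng.random() < config.dropout_prob)
                for lane in lanes
                for b in range(1, config.n_blots_per_transfection + 1)
            }
            for b in range(1, config.n_blots_per_transfection + 1):
                membrane = f"G{g:02d}T{t}B{b}"
                mem_effect = float(rng.lognormal(0.0, config.membrane_sd))
                truth.membrane_effect[membrane] = mem_effect
                transfection = f"G{g:02d}T{t}"
                for li, treatment in enumerate(lanes, start=1):
                    lane_id = f"L{li:02d}"
                    noise = rng.lognormal(0.0, config.noise_sd, size=3)
                    if dropout[(treatment, b)]:
                        truth.dropped_lanes.append((membrane, lane_id))
                        continue
                    truth.lane_efficiency[(membrane, lane_id)] = eff[treatment]
                    dlk1 = base["DLK1"] * mem_effect * eff[treatment] * effects[treatment] * noise[0]
                    gfp = base["GFP"] * mem_effect * eff[treatment] * noise[1]
                    tub = base["Tubulin"] * mem_effect * noise[2]
                    for channel, value in zip(CHANNELS, (dlk1, gfp, tub)):
                        rows.append(
                            (membrane, transfection, lane_id, treatment, channel, value)
                        )
    table = pd.DataFrame(
        rows,
        columns=["membrane_id", "transfection_id", "lane_id", "treatment",
                 "channel", "intensity"],
    )
    return table, truth


def simulate_guides(names: Sequence[str], rng_seed: int = 0, length: int = 22) -> dict[str, str]:
    """Random unambiguous guide strands, one per treatment name."""
    rng = np.random.default_rng(rng_seed)
    bases = np.array(list("ACGU"))
    return {name: "".join(rng.choice(bases, size=length)) for name in names}


# ---------------------------------------------------------------------------
# transcript simulation with planted seed sites


@dataclass(frozen=True)
class PlantSpec:
    """Request to plant one seed-match site."""

    mirna_name: str
    region_name: str
    site_class: str
    position: int | None = None  # transcript coordinate; None = place randomly

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")


@dataclass(frozen=True)
class PlantedSite:
    """One realized planted site (an entry of the plant truth)."""

    mirna_name: str
    region_name: str
    site_class: str
    position: int


class PlantingError(RuntimeError):
    """Planting is infeasible or rejection sampling exhausted its budget."""


def _sample_sequence(rng: np.random.Generator, length: int,
                     composition: Mapping[str, float] | None) -> list[str]:
    bases = list("ACGU")
    if composition is None:
        probs = None
    else:
        probs = np.array([composition.get(b, 0.0) for b in bases], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("background_composition must have positive mass on A/C/G/U")
        probs = probs / probs.sum()
    return list(rng.choice(np.array(bases), size=length, p=probs))


def simulate_transcript(
    region_lengths: Mapping[str, int],
    planted_sites: Sequence[PlantSpec],
    mirnas: Mapping[str, MiRNASpec | str],
    *,
    background_composition: Mapping[str, float] | None = None,
    rng_seed: int = 0,
    transcript_id: str = "synthetic-transcript",
    max_attempts: int = 10_000,
) -> tuple[TargetTranscript, list[PlantedSite]]:
    """Build a random transcript containing exactly the requested seed sites.

    ``region_lengths`` maps region names (in transcript order) to lengths.
    For every miRNA named in ``planted_sites`` the returned transcript
    contains the planted sites of the stated class at the stated (or
    randomly chosen non-overlapping) positions and *no other* sites of any
    class, verified with the hierarchical scanner; the background is
    rejection-sampled until that holds, erroring after ``max_attempts``.
    MiRNAs not named in any plant are left unconstrained.
    """
    regions: list[Region] = []
    cursor = 0
    for name, length in region_lengths.items():
        if length <= 0:
            raise ValueError(f"region {name!r} must have positive length")
        regions.append(Region(name=name, start=cursor, end=cursor + length))
        cursor += length
    total = cursor
    region_by_name = {r.name: r for r in regions}

    specs = {
        name: m if isinstance(m, MiRNASpec) else MiRNASpec(name=name, guide=m)
        for name, m in mirnas.items()
    }
    plant_sites: dict[str, dict[str, str]] = {}
    for p in planted_sites:
        if p.mirna_name not in specs:
            raise ValueError(f"planted site names unknown miRNA {p.mirna_name!r}")
        if p.region_name not in region_by_name:
            raise ValueError(f"planted site names unknown region {p.region_name!r}")
        plant_sites.setdefault(p.mirna_name, site_strings(specs[p.mirna_name]))
    constrained = sorted(plant_sites)

    rng = np.random.default_rng(rng_seed)
    for _attempt in range(max_attempts):
        seq = _sample_sequence(rng, total, background_composition)
        truth: list[PlantedSite] = []
        occupied: list[tuple[int, int]] = []
        feasible = True
        for p in planted_sites:
            site = plant_sites[p.mirna_name][p.site_class]
            reg = region_by_name[p.region_name]
            if p.position is not None:
                start = p.position
                if not (reg.start <= start and start + len(site) <= reg.end):
                    raise PlantingError(
                        f"site at {start} does not fit region {p.region_name!r}"
                    )
                if any(s < start + len(site) and start < e for s, e in occupied):
                    raise PlantingError(f"planted sites overlap at position {start}")
            else:
                max_start = reg.end - len(site)
                if max_start < reg.start:
                    raise PlantingError(
                        f"region {p.region_name!r} too short for a {p.site_class} site"
                    )
                candidates = [
                    s for s in range(reg.start, max_start + 1)
                    if not any(a < s + len(site) and s < b for a, b in occupied)
                ]
                if not candidates:
                    feasible = False
                    break
                start = int(rng.choice(candidates))
            seq[start:start + len(site)] = list(site)
            occupied.append((start, start + len(site)))
            truth.append(PlantedSite(p.mirna_name, p.region_name, p.site_class, start))
        if not feasible:
            continue
        sequence = "".join(seq)
        expected = {
            name: sorted(
                (t.site_class, t.position) for t in truth if t.mirna_name == name
            )
            for name in constrained
        }
        observed = {
            name: sorted(seed_matches(specs[name], sequence, mode="hierarchical"))
            for name in constrained
        }
        if observed == expected:
            transcript = TargetTranscript(
                transcript_id=transcript_id, sequence=sequence, regions=tuple(regions)
            )
            return transcript, truth
    raise PlantingError(
        f"could not realize the requested plants in {max_attempts} attempts; "
        "the plant set may be too dense for the region lengths"
    )


def simulate_inhibitor_pattern_example(
    rng_seed: int = 0,
) -> tuple[MiRNASpec, TargetTranscript, list[PlantedSite]]:
    """Synthetic stand-in for the screen's strongest-inhibitor worked example.

    Builds a reporter-layout transcript (210 nt 5' UTR including the
    upstream extras, 954 nt ORF, 236 nt 3' UTR) carrying exactly the site
    pattern reported for the screen's one significant inhibitor: two 6mer
    seed matches in the ORF and one in the 3' UTR. Both the guide and the
    transcript background are synthetic (the real sequences are not
    distributed with this package); only the pattern is meaningful.
    """
    rng = np.random.default_rng(rng_seed)
    guide = MiRNASpec(
        name="synthetic-inhibitor",
        guide="".join(rng.choice(np.array(list("ACGU")), size=22)),
    )
    transcript, truth = simulate_transcript(
        {"five_prime_utr": 210, "orf": 954, "three_prime_utr": 236},
        [
            PlantSpec(guide.name, "orf", "6mer"),
            PlantSpec(guide.name, "orf", "6mer"),
            PlantSpec(guide.name, "three_prime_utr", "6mer"),
        ],
        {guide.name: guide},
        rng_seed=rng_seed,
        transcript_id="synthetic-reporter-standin",
    )
    return guide, transcript, truth


# ---------------------------------------------------------------------------
# reporter construct layout arithmetic


@dataclass(frozen=True)
class ReporterComponents:
    """Lengths (bp) of the reporter transcript's components, 5'->3'.

    Defaults reproduce the full-length ovine DLK1 (C2 isoform) reporter:
    1 vector base upstream, 35 bp of non-ovine upstream genomic sequence,
    174 bp ovine 5' UTR, 927 bp ovine coding sequence, 27 bp HA-tag
    insertion, a 6 bp restriction-site linker, 236 bp ovine 3' UTR and
    30 bp of vector sequence before the polyadenylation site.
    """

    vector_5p: int = 1
    upstream_non_ovine: int = 35
    five_prime_utr: int = 174
    orf_ovine: int = 927
    ha_tag: int = 27
    linker: int = 6
    three_prime_utr: int = 236
    vector_3p: int = 30

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"component {name!r} must be non-negative")


def build_reporter_transcript(
    components: ReporterComponents | None = None,
) -> tuple[TargetTranscript, dict[str, float]]:
    """Layout arithmetic for the reporter transcript.

    Returns a length-only transcript skeleton (N placeholder sequence) with
    region coordinates — the 5' UTR region spans everything upstream of the
    start codon, the ORF includes the in-frame tag, the 3' UTR region is
    the ovine 3' UTR; linker and vector tails are ``other`` — plus a
    composition report: insert length (between the vector tails), total
    transcript length, and the percentage of the transcript that is ovine.
    """
    c = components or ReporterComponents()
    utr5_end = c.vector_5p + c.upstream_non_ovine + c.five_prime_utr
    orf_end = utr5_end + c.orf_ovine + c.ha_tag
    linker_end = orf_end + c.linker
    utr3_end = linker_end + c.three_prime_utr
    total = utr3_end + c.vector_3p

    regions = []
    if utr5_end > 0:
        regions.append(Region("five_prime_utr", 0, utr5_end))
    if orf_end > utr5_end:
        regions.append(Region("orf", utr5_end, orf_end))
    if linker_end > orf_end:
        regions.append(Region("other", orf_end, linker_end))
    if utr3_end > linker_end:
        regions.append(Region("three_prime_utr", linker_end, utr3_end))
    if total > utr3_end:
        regions.append(Region("other", utr3_end, total))

    ovine = c.five_prime_utr + c.orf_ovine + c.three_prime_utr
    insert = total - c.vector_5p - c.vector_3p
    report = {
        "insert_bp": insert,
        "transcript_bp": total,
        "ovine_bp": ovine,
        "ovine_percent": 100.0 * ovine / total if total else float("nan"),
        "extra_upstream_bp": c.vector_5p + c.upstream_non_ovine,
        "extra_internal_bp": c.ha_tag + c.linker,
        "extra_downstream_bp": c.vector_3p,
    }
    skeleton = TargetTranscript(
        transcript_id="reporter-skeleton", sequence="N" * total, regions=tuple(regions)
    )
    return skeleton, report


# ---------------------------------------------------------------------------
# isomir catalog simulation


@dataclass(frozen=True)
class IsomirTruthSpec:
    """One alternative isomir relative to its arm's reference isomir.

    ``fraction`` is the alternative's total reads as a fraction of the
    reference's; ``max_library_reads``, when set, forces the largest
    single-library count. ``expect_selected`` is the ground-truth label,
    stated by construction rather than by running the selection rules.
    """

    fraction: float
    max_library_reads: int | None = None
    five_prime_offset: int = 1
    expect_selected: bool = True


DEFAULT_ISOMIR_TRUTH = (
    IsomirTruthSpec(fraction=0.4, expect_selected=True),                      # >1/3 rule
    IsomirTruthSpec(fraction=0.1, max_library_reads=150, expect_selected=False),
    IsomirTruthSpec(fraction=0.1, max_library_reads=250, expect_selected=True),  # >200 reads rule
)


def simulate_isomir_catalog(
    n_precursors: int = 5,
    n_libraries: int = 4,
    rng_seed: int = 0,
    truth_spec: Sequence[IsomirTruthSpec] = DEFAULT_ISOMIR_TRUTH,
    reference_reads: int = 3000,
    guide_length: int = 22,
) -> tuple[pd.DataFrame, set[str]]:
    """Per-isomir, per-library read counts with a known expected selection.

    Each precursor contributes a miRBase-reference isomir on the 3p arm
    plus the alternatives described by ``truth_spec`` (cycled across
    precursors, one alternative each). Returns the catalog in long-ish
    form (one row per isomir, library counts as columns lib_1..lib_k) and
    the set of isomir names expected to be selected (references included).
    """
    if n_precursors < 1 or n_libraries < 1:
        raise ValueError("n_precursors and n_libraries must be >= 1")
    rng = np.random.default_rng(rng_seed)
    bases = np.array(list("ACGU"))
    lib_cols = [f"lib_{i}" for i in range(1, n_libraries + 1)]
    rows, expected = [], set()
    for p in range(1, n_precursors + 1):
        precursor = f"pre-mir-{p:03d}"
        ref_name = f"{precursor}-3p"
        ref_seq = "".join(rng.choice(bases, size=guide_length))
        ref_counts = rng.multinomial(reference_reads, np.full(n_libraries, 1 / n_libraries))
        rows.append(
            {"name": ref_name, "precursor": precursor, "arm": "3p", "sequence": ref_seq,
             "five_prime_offset": 0, "is_mirbase_reference": True,
             **dict(zip(lib_cols, map(int, ref_counts)))}
        )
        expected.add(ref_name)
        spec = truth_spec[(p - 1) % len(truth_spec)]
        total = int(round(spec.fraction * reference_reads))
        if spec.max_library_reads is not None:
            top = min(spec.max_library_reads, total)
            rest = total - top
            counts = [top] + list(
                rng.multinomial(rest, np.full(n_libraries - 1, 1 / (n_libraries - 1)))
                if n_libraries > 1 else []
            )
        else:
            counts = list(rng.multinomial(total, np.full(n_libraries, 1 / n_libraries)))
        off = spec.five_prime_offset
        alt_seq = ("".join(rng.choice(bases, size=abs(off))) + ref_seq[: guide_length - abs(off)]
                   if off < 0 else ref_seq[off:] + "".join(rng.choice(bases, size=off)))
        alt_name = f"{ref_name}.alt"
        rows.append(
            {"name": alt_name, "precursor": precursor, "arm": "3p", "sequence": alt_seq,
             "five_prime_offset": off, "is_mirbase_reference": False,
             **dict(zip(lib_cols, map(int, counts)))}
        )
        if spec.expect_selected:
            expected.add(alt_name)
    return pd.DataFrame(rows), expected
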