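"""End-to-end driver: simulate -> normalize -> screen -> seed-scan -> correlate.

Every stage writes its intermediate table under the output directory, so a
run is fully reproducible from (config, seed) and restartable from any
intermediate. A JSON summary collects the screen-level results: counts of
significant treatments against each reference, the overall ANOVA, and the
score-effect correlations per region.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .io import write_fasta, write_regions, write_table
from .quantify import normalize_screen
from .screen_stats import anova_mirna_effect, bonferroni_threshold, effect_vs_reference
from .seed_affinity import (
    FULL_LENGTH,
    affinity_effect_correlation,
    seed_score,
    seed_sites,
)
from .simulate import SimulationConfig, simulate_guides, simulate_screen, simulate_transcript
from .transcripts import MiRNASpec, TargetTranscript

logger = logging.getLogger(__name__)

#: Native-like transcript layout used for the default in-silico seed scan
#: (5' UTR / ORF / 3' UTR lengths of the full-length target mRNA).
DEFAULT_TARGET_REGIONS = {"five_prime_utr": 174, "orf": 954, "three_prime_utr": 236}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str | Path = "results/pipeline"
    rng_seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    normalizer: str = "GFP"
    alpha: float = 0.05
    counting_mode: str = "hierarchical"
    guide_length: int = 22
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        # the screen and its downstream stages share one seed
        self.simulation = dataclasses.replace(self.simulation, rng_seed=self.rng_seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full in-silico screen and return the summary dict."""
    logging.basicConfig(level=config.log_level, format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed
    conf_dict = config.to_dict()
    conf_dict.pop("out_dir")  # provenance hash covers the science, not paths
    logger.info("stage=simulate out=%s", out)

    intensities, truth = _stage("simulate")(simulate_screen)(config.simulation)
    write_table(out / "intensities.tsv", intensities, seed=seed, config=conf_dict)
    (out / "truth.json").write_text(json.dumps({
        "treatment_fold": truth.treatment_fold,
        "membrane_effect": truth.membrane_effect,
        "lane_efficiency": {f"{m}:{l}": v for (m, l), v in truth.lane_efficiency.items()},
        "dropped_lanes": [f"{m}:{l}" for m, l in truth.dropped_lanes],
    }, indent=1))

    logger.info("stage=normalize normalizer=%s", config.normalizer)
    corrected = _stage("normalize")(normalize_screen)(intensities, normalizer=config.normalizer)
    write_table(out / "corrected.tsv", corrected, seed=seed, config=conf_dict)

    logger.info("stage=screen alpha=%g", config.alpha)
    effects_nc = _stage("screen")(effect_vs_reference)(corrected, "nc_mean", config.alpha)
    effects_global = _stage("screen")(effect_vs_reference)(corrected, "global_mean", config.alpha)
    write_table(out / "effects_nc.tsv", effects_nc, seed=seed, config=conf_dict)
    write_table(out / "effects_global.tsv", effects_global, seed=seed, config=conf_dict)
    anova = _stage("screen")(anova_mirna_effect)(corrected)

    logger.info("stage=seedscan mode=%s", config.counting_mode)
    mirna_treatments = [
        t for t in config.simulation.treatments if t not in ("NC1", "NC2", "siRNA")
    ]
    guides = simulate_guides(mirna_treatments, rng_seed=seed, length=config.guide_length)
    write_fasta(out / "mirnas.fasta", sorted(guides.items()))
    target, _ = _stage("seedscan")(simulate_transcript)(
        DEFAULT_TARGET_REGIONS, [], {}, rng_seed=seed, transcript_id="synthetic-target"
    )
    write_fasta(out / "target.fasta", [(target.transcript_id, target.sequence)])
    write_regions(out / "target_regions.tsv", [target])

    profiles = {
        name: _stage("seedscan")(seed_sites)(
            MiRNASpec(name=name, guide=g), target, mode=config.counting_mode
        )
        for name, g in guides.items()
    }
    profile_table = pd.concat([p.to_frame() for p in profiles.values()], ignore_index=True)
    write_table(out / "seed_profiles.tsv", profile_table, seed=seed, config=conf_dict)

    logger.info("stage=correlate")
    regions = list(DEFAULT_TARGET_REGIONS) + [FULL_LENGTH]
    correlations = []
    for region in regions:
        scores = {name: seed_score(p, region=region) for name, p in profiles.items()}
        res = _stage("correlate")(affinity_effect_correlation)(
            scores, effects_nc, score_type="seed_count", region=region
        )
        correlations.append(dataclasses.asdict(res))
    write_table(out / "correlations.tsv", pd.DataFrame(correlations), seed=seed,
                config=conf_dict)

    m = len(mirna_treatments)
    summary = {
        "version": __version__,
        "seed": seed,
        "n_treatments": len(config.simulation.treatments),
        "m_tests": m,
        "bonferroni_threshold": bonferroni_threshold(config.alpha, m),
        "normalizer": config.normalizer,
        "significant_vs_nc": sorted(
            effects_nc.loc[effects_nc["significant"] & (effects_nc["treatment"] != "siRNA"),
                           "treatment"]
        ),
        "significant_vs_global": sorted(
            effects_global.loc[effects_global["significant"], "treatment"]
        ),
        "sirna_ratio_vs_nc": (
            float(effects_nc.set_index("treatment").loc["siRNA", "ratio"])
            if "siRNA" in set(effects_nc["treatment"]) else None
        ),
        "anova": dataclasses.asdict(anova),
        "correlations": correlations,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=_json_safe))
    logger.info("stage=done summary=%s", out / "summary.json")
    return summary


def _json_safe(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {obj!r}")
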