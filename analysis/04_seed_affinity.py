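#!/usr/bin/env python
"""Seed-match affinity scores and their correlation with screen effects.

Scans every simulated guide against the synthetic target transcript,
scores each region by total seed-match count, and computes the Pearson
correlation between scores and mean corrected DLK1 amounts (controls
excluded). Also reproduces the strongest-inhibitor worked example on the
synthetic stand-in reporter (two ORF 6mers, one 3' UTR 6mer).
"""

import dataclasses
from pathlib import Path

import pandas as pd

from mirscreen.io import attach_regions, read_fasta, read_regions, read_table, write_table
from mirscreen.seed_affinity import (
    FULL_LENGTH,
    affinity_effect_correlation,
    seed_score,
    seed_sites,
)
from mirscreen.simulate import simulate_inhibitor_pattern_example
from mirscreen.transcripts import MiRNASpec

SEED = 1
OUT = Path("results/screen")


def main() -> None:
    mirnas = [MiRNASpec(n, s) for n, s in read_fasta(OUT / "mirnas.fasta")]
    regions = read_regions(OUT / "target_regions.tsv")
    target = attach_regions(read_fasta(OUT / "target.fasta"), regions)[0]
    effects = read_table(OUT / "effects_nc.tsv")

    profiles = {m.name: seed_sites(m, target) for m in mirnas}
    write_table(OUT / "seed_profiles.tsv",
                pd.concat([p.to_frame() for p in profiles.values()], ignore_index=True),
                seed=SEED)

    rows = []
    for region in [r.name for r in target.regions] + [FULL_LENGTH]:
        scores = {name: seed_score(p, region=region) for name, p in profiles.items()}
        res = affinity_effect_correlation(scores, effects, region=region)
        rows.append(dataclasses.asdict(res))
        print(f"{region:>16}: r = {res.pearson_r:+.3f} (p = {res.p_value:.3f}, "
              f"n = {res.n}) — no real affinity signal is planted, so r ~ 0")
    write_table(OUT / "correlations.tsv", pd.DataFrame(rows), seed=SEED)

    guide, standin, _ = simulate_inhibitor_pattern_example(rng_seed=SEED)
    profile = seed_sites(guide, standin)
    print(f"stand-in inhibitor example: 6mer sites ORF = "
          f"{profile.count('orf', '6mer')}, 3' UTR = "
          f"{profile.count('three_prime_utr', '6mer')} "
          f"(synthetic sequences, published site pattern)")


if __name__ == "__main__":
    main()
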