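#!/usr/bin/env python
"""Design the screen's oligos: mimic duplexes, scrambled NCs, isomir picks.

Builds guide/passenger duplex sheets for the simulated miRNA panel,
designs two scrambled negative controls free of seed matches to the
target, and demonstrates isomir selection on a simulated read-count
catalog with known expected picks.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from mirscreen.io import attach_regions, read_fasta, write_table
from mirscreen.oligo_design import (
    build_mimic_duplex,
    design_scrambled_controls,
    select_isomirs,
)
from mirscreen.simulate import simulate_isomir_catalog
from mirscreen.transcripts import MiRNASpec

SEED = 1
OUT = Path("results/design")
SCREEN = Path("results/screen")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mirnas = [MiRNASpec(n, s) for n, s in read_fasta(SCREEN / "mirnas.fasta")]

    sheet = pd.DataFrame([
        {"name": m.name, "guide": (d := build_mimic_duplex(m)).guide,
         "passenger": d.passenger, "passenger_5p_mod": d.passenger_five_prime}
        for m in mirnas
    ])
    write_table(OUT / "mimic_duplexes.tsv", sheet, seed=SEED)

    target = attach_regions(read_fasta(SCREEN / "target.fasta"), {})[0]
    candidates = design_scrambled_controls(
        mirnas[:5], target, background=[target], n_shuffles=10, n_select=2,
        rng_seed=SEED,
    )
    write_table(OUT / "nc_candidates.tsv",
                pd.DataFrame([dataclasses.asdict(c) for c in candidates]), seed=SEED)
    selected = [c for c in candidates if c.selected]

    catalog, expected = simulate_isomir_catalog(n_precursors=9, rng_seed=SEED)
    selection = select_isomirs(catalog)
    write_table(OUT / "isomir_catalog.tsv", catalog, seed=SEED)
    write_table(OUT / "isomir_selection.tsv", selection, seed=SEED)

    print(f"{len(sheet)} mimic duplexes; {len(selected)} scrambled NCs selected "
          f"from {len(candidates)} candidates (both with zero target seed "
          f"matches); isomir selection recovered expected set: "
          f"{set(selection['name']) == expected} "
          f"({len(selection)} of {len(catalog)} isomirs kept)")


if __name__ == "__main__":
    main()
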