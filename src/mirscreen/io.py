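"""Readers and writers: FASTA sequences, BED-like regions, TSV tables.

All tabular interchange is TSV with a header row, preceded by ``#``
provenance comment lines (tool version, seed, config hash) that readers
skip. Region files are BED-like: ``transcript_id  start  end  region_name``
with 0-based half-open coordinates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .transcripts import Region, SequenceError, TargetTranscript, validate_regions

logger = logging.getLogger(__name__)


class FileFormatError(ValueError):
    """A malformed input file, with location detail where available."""


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (id, sequence) pairs; duplicate IDs are rejected.

    Sequences are returned verbatim (alphabet normalization happens in the
    consuming type). An empty file yields an empty list with a warning.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FileFormatError(
                        f"{path}:{lineno}: expected a '>' header, got {line.strip()[:40]!r}"
                    )
                break
        else:
            logger.warning("FASTA file %s is empty", path)
            return []
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    seen: set[str] = set()
    for rec_id, _ in records:
        if rec_id in seen:
            raise FileFormatError(f"{path}: duplicate FASTA ID {rec_id!r}")
        seen.add(rec_id)
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path), "fasta",
    )


REGION_COLUMNS = ["transcript_id", "start", "end", "region_name"]


def read_regions(path: str | Path) -> dict[str, tuple[Region, ...]]:
    """Read and validate BED-like region annotations per transcript."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing columns {missing}")
    out: dict[str, tuple[Region, ...]] = {}
    for tid, group in df.groupby("transcript_id", sort=False):
        regions = []
        for row in group.itertuples():
            try:
                regions.append(Region(str(row.region_name), int(row.start), int(row.end)))
            except SequenceError as exc:
                raise FileFormatError(f"{path}: row {row.Index + 2}: {exc}") from exc
        try:
            # bound check against the transcript happens when the sequence is
            # attached; here we enforce ordering/disjointness only
            out[str(tid)] = validate_regions(regions, max(r.end for r in regions))
        except SequenceError as exc:
            raise FileFormatError(f"{path}: transcript {tid!r}: {exc}") from exc
    return out


def write_regions(path: str | Path, transcripts: Iterable[TargetTranscript]) -> None:
    rows = [
        {"transcript_id": t.transcript_id, "start": r.start, "end": r.end,
         "region_name": r.name}
        for t in transcripts for r in t.regions
    ]
    pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(path, sep="\t", index=False)


def attach_regions(
    sequences: Sequence[tuple[str, str]],
    regions: Mapping[str, Sequence[Region]],
) -> list[TargetTranscript]:
    """Combine FASTA records with region annotations into transcripts."""
    return [
        TargetTranscript(
            transcript_id=name, sequence=seq, regions=tuple(regions.get(name, ()))
        )
        for name, seq in sequences
    ]


def provenance_lines(seed: int | None = None, config: Mapping | None = None) -> list[str]:
    lines = [f"# mirscreen {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        lines.append(f"# config_sha256={digest}")
    return lines


def write_table(
    path: str | Path,
    table: pd.DataFrame,
    *,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Write a TSV with provenance comment lines before the header."""
    path = Path(path)
    with open(path, "w") as handle:
        for line in provenance_lines(seed=seed, config=config):
            handle.write(line + "\n")
        table.to_csv(handle, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
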