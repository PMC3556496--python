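"""FASTA and hit-metadata readers used by the command-line interface."""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO

from .evolution import HomologHit, map_reference


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file (sequences or an alignment) as (id, sequence) rows."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_reference(path: str | Path) -> str:
    """Read the single reference sequence from a FASTA file."""
    rows = read_fasta(path)
    if len(rows) != 1:
        raise ValueError(f"{path}: expected exactly one reference sequence, "
                         f"found {len(rows)}")
    return rows[0][1]


def read_hit_metadata(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a 3-column TSV (id, identity, coverage) of homolog hit metadata."""
    meta: dict[str, tuple[float, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            meta[row[0]] = (float(row[1]), float(row[2]))
    return meta


def load_homologs(fasta_path: str | Path,
                  meta_path: str | Path | None = None,
                  query_seq: str | None = None) -> list[HomologHit]:
    """Build homolog hits from FASTA, with identities from TSV or recomputed.

    When no metadata file is given, identity and coverage against
    ``query_seq`` are computed by pairwise global alignment.
    """
    rows = read_fasta(fasta_path)
    meta = read_hit_metadata(meta_path) if meta_path else {}
    hits = []
    for hid, seq in rows:
        if hid in meta:
            identity, coverage = meta[hid]
        elif query_seq:
            m = map_reference(query_seq, seq, min_identity=0.0,
                              min_coverage=0.0)
            identity, coverage = m.identity, m.coverage
        else:
            raise ValueError(
                f"no identity/coverage for hit {hid!r}: provide a metadata "
                "TSV or a query sequence")
        hits.append(HomologHit(id=hid, sequence=seq, identity=identity,
                               coverage=coverage))
    return hits
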