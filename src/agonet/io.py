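"""Readers and writers for the plain-text formats used across the pipeline.

Conventions:

* FASTA via Biopython ``SeqIO``; RNA alphabets are converted to DNA (U -> T)
  on ingest, never on output.
* ``regions.gff3`` is standard GFF3 (1-based, inclusive); in memory all
  coordinates are 0-based half-open.
* ``alignments.tsv`` columns: read_id, transcript_id, start, end, mismatches
  with mismatches encoded ``pos:ref>alt;...`` in transcript coordinates
  (empty string for none).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]

# GFF3 feature types for the three transcript regions
REGION_TYPES = {"5UTR": "five_prime_UTR", "CDS": "CDS", "3UTR": "three_prime_UTR"}
_TYPE_TO_REGION = {v: k for k, v in REGION_TYPES.items()}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict, converting U to T."""
    return {
        rec.id: str(rec.seq).upper().replace("U", "T")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_regions_gff3(regions: pd.DataFrame, path: str | Path) -> None:
    """Write a region table (transcript_id, region, start, end; 0-based
    half-open) as GFF3 (1-based, inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in regions.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        row.transcript_id,
                        "agonet",
                        REGION_TYPES[row.region],
                        str(int(row.start) + 1),
                        str(int(row.end)),
                        ".",
                        "+",
                        ".",
                        f"ID={row.transcript_id}:{row.region}",
                    ]
                )
                + "\n"
            )


def read_regions_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 region annotation back into the 0-based half-open table."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLUMNS,
        dtype={"seqid": str},
    )
    out = pd.DataFrame(
        {
            "transcript_id": df["seqid"],
            "region": df["type"].map(_TYPE_TO_REGION),
            "start": df["start"].astype(int) - 1,
            "end": df["end"].astype(int),
        }
    )
    if out["region"].isna().any():
        bad = df.loc[out["region"].isna(), "type"].unique().tolist()
        raise ValueError(f"unrecognized GFF3 feature types: {bad}")
    return out


def write_counts(counts: pd.DataFrame, samples: pd.DataFrame,
                 counts_path: str | Path, samples_path: str | Path) -> None:
    counts.to_csv(counts_path, sep="\t", index_label="entity_id")
    samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_counts(counts_path: str | Path, samples_path: str | Path):
    counts = pd.read_csv(counts_path, sep="\t", index_col="entity_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    return counts, samples


def format_mismatches(mismatches: list[tuple[int, str, str]]) -> str:
    return ";".join(f"{pos}:{ref}>{alt}" for pos, ref, alt in mismatches)


def parse_mismatches(field: str, line: int | None = None):
    """Parse a ``pos:ref>alt;...`` mismatch field; empty/NaN means none."""
    if field is None or field == "" or (isinstance(field, float) and pd.isna(field)):
        return []
    out = []
    for token in str(field).split(";"):
        try:
            pos, change = token.split(":")
            ref, alt = change.split(">")
            out.append((int(pos), ref, alt))
        except ValueError as err:
            where = f" at line {line}" if line is not None else ""
            raise ValueError(f"malformed mismatch record {token!r}{where}") from err
    return out


def write_alignments(alignments: pd.DataFrame, path: str | Path) -> None:
    alignments.to_csv(path, sep="\t", index=False)


def read_alignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "transcript_id": str})
    required = {"read_id", "transcript_id", "start", "end", "mismatches"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"alignments file missing columns: {sorted(missing)}")
    df["mismatches"] = df["mismatches"].fillna("")
    return df
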