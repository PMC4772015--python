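"""PAR-CLIP binding-site cluster calling and T-content normalization.

Clusters are called in transcript space by merging overlapping reads into
maximal intervals and keeping intervals with enough read depth and enough
reads carrying diagnostic T->C conversions. This is a deliberately simple
density model — thresholds on merged pile-ups — rather than a kernel
density segmentation; the two thresholds (`min_reads`, `min_t2c_reads`)
are exposed.

Because crosslink-site selection favours T-rich sequence, the raw
per-region distribution of clusters over 5'UTR / CDS / 3'UTR is biased
toward T-rich regions (3'UTRs). `normalize_region_distribution` divides
each region's cluster fraction by its T frequency and renormalizes,
giving a composition-adjusted view of where AGO2 sits.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import parse_mismatches
from .simdata import Transcriptome


@dataclass
class Cluster:
    """A merged AGO2 binding interval on a transcript (0-based half-open)."""

    cluster_id: str
    transcript_id: str
    start: int
    end: int
    n_reads: int
    n_t2c_reads: int
    t2c_counts: dict[int, int]      # transcript position -> converted reads
    predominant_t2c: int            # argmax of t2c_counts, leftmost on ties
    region: str | None = None
    sequence: str | None = None


def call_clusters(
    alignments: pd.DataFrame,
    transcriptome: Transcriptome | None = None,
    min_reads: int = 5,
    min_t2c_reads: int = 2,
) -> list[Cluster]:
    """Merge overlapping reads per transcript and threshold the pile-ups.

    An interval is emitted iff it is covered by >= `min_reads` reads of
    which >= `min_t2c_reads` carry at least one T->C mismatch. Mismatches
    whose reference base is not T (or whose alternate is not C) never
    count as conversions. When a transcriptome is given, clusters also get
    their reference sequence and region label. Output is deterministic
    and independent of input row order.
    """
    required = {"read_id", "transcript_id", "start", "end", "mismatches"}
    missing = required - set(alignments.columns)
    if missing:
        raise ValueError(f"alignments missing columns: {sorted(missing)}")

    df = alignments.sort_values(
        ["transcript_id", "start", "end", "read_id"], kind="mergesort"
    )
    clusters: list[Cluster] = []
    serial = 0
    for tid, group in df.groupby("transcript_id", sort=True):
        cur_start = cur_end = None
        members: list[tuple] = []

        def flush():
            nonlocal serial
            if cur_start is None:
                return
            n_reads = len(members)
            t2c_counts: dict[int, int] = {}
            n_t2c_reads = 0
            for _, _, mm, line in members:
                conv = [
                    pos
                    for pos, ref, alt in parse_mismatches(mm, line=line)
                    if ref == "T" and alt == "C"
                ]
                if conv:
                    n_t2c_reads += 1
                for pos in conv:
                    t2c_counts[pos] = t2c_counts.get(pos, 0) + 1
            if n_reads < min_reads or n_t2c_reads < min_t2c_reads:
                return
            predominant = min(
                t2c_counts, key=lambda p: (-t2c_counts[p], p)
            )
            cluster = Cluster(
                cluster_id=f"cl{serial:06d}",
                transcript_id=tid,
                start=cur_start,
                end=cur_end,
                n_reads=n_reads,
                n_t2c_reads=n_t2c_reads,
                t2c_counts=t2c_counts,
                predominant_t2c=predominant,
            )
            serial += 1
            if transcriptome is not None:
                cluster.sequence = transcriptome.sequences[tid][
                    cur_start:cur_end
                ]
                cluster.region = annotate_region(cluster, transcriptome)
            clusters.append(cluster)

        for row in group.itertuples():
            start, end = int(row.start), int(row.end)
            if end <= start:
                raise ValueError(
                    f"malformed alignment row at line {row.Index}: "
                    f"end {end} <= start {start}"
                )
            if cur_start is None:
                cur_start, cur_end = start, end
                members = [(start, end, row.mismatches, row.Index)]
            elif start < cur_end:  # overlap with current merged interval
                cur_end = max(cur_end, end)
                members.append((start, end, row.mismatches, row.Index))
            else:
                flush()
                cur_start, cur_end = start, end
                members = [(start, end, row.mismatches, row.Index)]
        flush()
    return clusters


def annotate_region(cluster: Cluster, transcriptome: Transcriptome) -> str:
    """Region label of a cluster: the region containing its predominant
    T->C position (which settles boundary-spanning clusters)."""
    return transcriptome.region_at(
        cluster.transcript_id, cluster.predominant_t2c
    )


def region_t_frequency(transcriptome: Transcriptome) -> dict[str, float]:
    """Fraction of T among A/C/G/T in each region class, concatenated over
    all transcripts."""
    out = {}
    for region, seq in transcriptome.region_sequences().items():
        if not seq:
            raise ValueError(f"region class {region!r} has no sequence")
        counted = sum(seq.count(b) for b in "ACGT")
        out[region] = seq.count("T") / counted
    return out


def cluster_region_distribution(clusters: list[Cluster]) -> dict[str, float]:
    """Raw fraction of clusters per region label."""
    if not clusters:
        return {}
    counts: dict[str, int] = {}
    for c in clusters:
        if c.region is None:
            raise ValueError(f"cluster {c.cluster_id} is not region-annotated")
        counts[c.region] = counts.get(c.region, 0) + 1
    total = len(clusters)
    return {region: n / total for region, n in sorted(counts.items())}


def normalize_region_distribution(
    raw_fractions: dict[str, float], t_frequencies: dict[str, float]
) -> dict[str, float]:
    """Divide each region's cluster fraction by its T frequency and
    renormalize to sum to 1."""
    if set(raw_fractions) != set(t_frequencies):
        raise ValueError("fractions and T frequencies cover different regions")
    for region, f in t_frequencies.items():
        if f <= 0:
            raise ValueError(f"non-positive T frequency for region {region!r}")
    weights = {r: raw_fractions[r] / t_frequencies[r] for r in raw_fractions}
    total = sum(weights.values())
    return {r: w / total for r, w in sorted(weights.items())}


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    """Tabular cluster record (one row per cluster) for TSV export."""
    rows = [
        {
            "cluster_id": c.cluster_id,
            "transcript_id": c.transcript_id,
            "start": c.start,
            "end": c.end,
            "n_reads": c.n_reads,
            "n_t2c_reads": c.n_t2c_reads,
            "predominant_t2c": c.predominant_t2c,
            "region": c.region if c.region is not None else "",
            "t2c_counts": ";".join(
                f"{p}:{n}" for p, n in sorted(c.t2c_counts.items())
            ),
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "transcript_id", "start", "end", "n_reads",
                 "n_t2c_reads", "predominant_t2c", "region", "t2c_counts"],
    )


def write_clusters_bed(clusters: list[Cluster], path) -> None:
    """BED6: transcript, start, end, cluster id, read count, strand."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.transcript_id}\t{c.start}\t{c.end}\t{c.cluster_id}"
                f"\t{c.n_reads}\t+\n"
            )
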