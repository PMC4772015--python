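"""Detection and characterization of miRNA-target ligation chimeras.

During CLIP library preparation, endogenous ligase activity occasionally
joins a mature miRNA to the target fragment it was bound to, producing a
single read that directly reports one miRNA-target interaction. This
module finds such reads by exact matching — a read is a chimera iff one
end carries a >= `min_mirna_prefix` nt prefix of exactly one mature miRNA
and the remainder maps exactly once to the transcriptome — and then
reproduces the standard descriptive statistics of a chimera set: seed-match
class counts against a random-extension control, the positional profile of
k-mer complementarity along the miRNA, last-nucleotide composition of the
ligated ends, the per-seed-position pairing profile, and a Fisher-exact
comparison of chimera formation rates between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffassoc import bh_adjust
from .mre import SeedSiteSet, revcomp, seed_sites
from .simdata import Transcriptome

REJECTION_LABELS = ("no_mirna", "short_remainder", "ambiguous_target",
                    "ambiguous_mirna", "no_target")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ChimeraRead:
    """One accepted miRNA-target fusion read."""

    read_id: str
    mirna_id: str
    mirna_part_len: int
    orientation: str              # mirna_first | target_first
    transcript_id: str
    target_start: int             # 0-based half-open transcript interval
    target_end: int
    region: str | None = None
    mirna_last_nt: str = ""
    target_last_nt: str = ""
    target_seq: str = ""
    extended_seq: str = ""
    control_seq: str = ""
    seed_class: str = "none"


class _TranscriptIndex:
    """Exact-occurrence lookup over a transcript set via one concatenated
    string with separators (so matches never bridge transcripts)."""

    def __init__(self, sequences: Mapping[str, str]):
        self.ids = list(sequences)
        self.offsets = []
        parts = []
        pos = 0
        for tid in self.ids:
            self.offsets.append(pos)
            parts.append(sequences[tid])
            pos += len(sequences[tid]) + 1
        self.blob = "#".join(parts)
        self._starts = np.array(self.offsets)
        self._lengths = np.array([len(sequences[t]) for t in self.ids])

    def occurrences(self, query: str, limit: int = 2):
        """Up to `limit` occurrences as (transcript_id, start) tuples."""
        hits = []
        at = self.blob.find(query)
        while at != -1 and len(hits) < limit:
            idx = int(np.searchsorted(self._starts, at, side="right") - 1)
            start = at - self.offsets[idx]
            hits.append((self.ids[idx], start))
            at = self.blob.find(query, at + 1)
        return hits


def _build_prefix_index(mirnas: Mapping[str, str], min_prefix: int):
    """For each length l >= min_prefix, a dict mature[:l] -> miRNA ids."""
    by_len: dict[int, dict[str, list[str]]] = {}
    for mid, seq in mirnas.items():
        for l in range(min_prefix, len(seq) + 1):
            by_len.setdefault(l, {}).setdefault(seq[:l], []).append(mid)
    return by_len


def _mirna_matches(seq: str, prefix_index, from_start: bool) -> dict[str, int]:
    """miRNAs whose 5' end matches one end of the read, mapped to the
    maximal matched length (read prefix for ``from_start``, read suffix —
    a 3'-truncated or complete miRNA at the read's 3' end — otherwise)."""
    found: dict[str, int] = {}
    for l, table in prefix_index.items():
        if l > len(seq):
            continue
        key = seq[:l] if from_start else seq[-l:]
        for mid in table.get(key, ()):
            if l > found.get(mid, 0):
                found[mid] = l
    return found


def detect_chimeras(
    reads: pd.DataFrame,
    mirnas: Mapping[str, str],
    transcriptome: Transcriptome,
    min_mirna_prefix: int = 15,
    min_target_len: int = 8,
    search_both_ends: bool = True,
) -> tuple[list[ChimeraRead], pd.DataFrame]:
    """Split raw reads into chimeras and a labelled rejection log.

    `reads` needs columns ``read_id`` and ``sequence``. A read is accepted
    iff a prefix (or, with ``search_both_ends``, a suffix — then the read
    is target-first) of length >= `min_mirna_prefix` exactly matches the
    5' end of exactly one mature miRNA and the remaining >=
    `min_target_len` nucleotides match exactly one transcriptome location.
    Rejections are labelled no_mirna / ambiguous_mirna / short_remainder /
    ambiguous_target / no_target.
    """
    if reads["read_id"].duplicated().any():
        dup = reads.loc[reads["read_id"].duplicated(), "read_id"].iloc[0]
        raise ValueError(f"duplicate read id {dup!r}")
    mirnas = {
        mid: seq.upper().replace("U", "T") for mid, seq in mirnas.items()
    }
    prefix_index = _build_prefix_index(mirnas, min_mirna_prefix)
    index = _TranscriptIndex(transcriptome.sequences)

    accepted: list[ChimeraRead] = []
    rejected: list[tuple[str, str]] = []
    for row in reads.itertuples(index=False):
        seq = row.sequence.upper().replace("U", "T")
        hits = [
            (mid, mlen, "mirna_first")
            for mid, mlen in _mirna_matches(
                seq, prefix_index, from_start=True
            ).items()
        ]
        if search_both_ends:
            hits += [
                (mid, mlen, "target_first")
                for mid, mlen in _mirna_matches(
                    seq, prefix_index, from_start=False
                ).items()
                if len(seq) > mlen  # a bare miRNA read is not target-first
            ]
        mirna_ids = {mid for mid, _, _ in hits}
        if not mirna_ids:
            rejected.append((row.read_id, "no_mirna"))
            continue
        if len(mirna_ids) > 1:
            rejected.append((row.read_id, "ambiguous_mirna"))
            continue
        # prefer the 5'-miRNA reading when both ends match the same miRNA
        mid, mlen, orientation = sorted(
            hits, key=lambda h: (h[2] != "mirna_first", -h[1])
        )[0]
        remainder = seq[mlen:] if orientation == "mirna_first" else seq[:-mlen]
        if len(remainder) < min_target_len:
            rejected.append((row.read_id, "short_remainder"))
            continue
        occ = index.occurrences(remainder, limit=2)
        if not occ:
            rejected.append((row.read_id, "no_target"))
            continue
        if len(occ) > 1:
            rejected.append((row.read_id, "ambiguous_target"))
            continue
        tid, tstart = occ[0]
        tend = tstart + len(remainder)
        try:
            region = transcriptome.region_at(tid, tstart)
        except (KeyError, ValueError):
            region = None
        accepted.append(
            ChimeraRead(
                read_id=row.read_id,
                mirna_id=mid,
                mirna_part_len=mlen,
                orientation=orientation,
                transcript_id=tid,
                target_start=tstart,
                target_end=tend,
                region=region,
                mirna_last_nt=mirnas[mid][mlen - 1],
                target_last_nt=remainder[-1],
                target_seq=remainder,
                extended_seq=remainder,
            )
        )
    log = pd.DataFrame(rejected, columns=["read_id", "reason"])
    return accepted, log


def extend_target(
    chimera: ChimeraRead,
    transcriptome: Transcriptome,
    ext: int = 10,
    rng: np.random.Generator | None = None,
) -> ChimeraRead:
    """Attach flanking transcript sequence (up to `ext` nt each side,
    clipped at the transcript bounds) as ``extended_seq``, and an
    equally-long i.i.d. random extension as the ``control_seq`` used by
    the seed-match enrichment comparison. Mutates and returns `chimera`.
    """
    seq = transcriptome.sequences[chimera.transcript_id]
    lo = max(0, chimera.target_start - ext)
    hi = min(len(seq), chimera.target_end + ext)
    chimera.extended_seq = seq[lo:hi]
    if rng is None:
        rng = np.random.default_rng(0)
    left = "".join(rng.choice(list("ACGT"), chimera.target_start - lo))
    right = "".join(rng.choice(list("ACGT"), hi - chimera.target_end))
    chimera.control_seq = left + chimera.target_seq + right
    return chimera


def extend_targets(chimeras: Iterable[ChimeraRead],
                   transcriptome: Transcriptome, ext: int = 10,
                   seed: int = 0) -> list[ChimeraRead]:
    rng = np.random.default_rng(seed)
    return [extend_target(c, transcriptome, ext=ext, rng=rng) for c in chimeras]


SEED_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer", "5mer")


def seed_class_of(target_seq: str, sset: SeedSiteSet, mature: str) -> str:
    """Longest canonical class whose site string occurs in `target_seq`;
    the 5mer is the reverse complement of miRNA positions 2-6."""
    for site_type, site_str in sset.by_length():
        if site_str in target_seq:
            return site_type
    mer5 = revcomp(mature.upper().replace("U", "T")[1:6])
    if mer5 in target_seq:
        return "5mer"
    return "none"


def count_seed_matches(
    chimeras: Sequence[ChimeraRead],
    mirnas: Mapping[str, str],
    use_control: bool = True,
) -> pd.DataFrame:
    """Exclusive seed-class counts over a chimera set, real extension vs
    the random-extension control. Each chimera contributes to exactly one
    class (its longest match, or ``none``), so counts partition the set.
    Also annotates each chimera's ``seed_class`` in place.
    """
    mirnas = {m: s.upper().replace("U", "T") for m, s in mirnas.items()}
    ssets = {m: seed_sites(m, s) for m, s in mirnas.items()}
    classes = list(SEED_CLASSES) + ["none"]
    real = dict.fromkeys(classes, 0)
    control = dict.fromkeys(classes, 0)
    for c in chimeras:
        if c.mirna_id not in ssets:
            raise KeyError(f"unknown miRNA id {c.mirna_id!r}")
        cls = seed_class_of(
            c.extended_seq or c.target_seq, ssets[c.mirna_id],
            mirnas[c.mirna_id],
        )
        c.seed_class = cls
        real[cls] += 1
        if use_control:
            ctrl_seq = c.control_seq or c.target_seq
            control[
                seed_class_of(ctrl_seq, ssets[c.mirna_id], mirnas[c.mirna_id])
            ] += 1
    out = pd.DataFrame({"real": real})
    if use_control:
        out["control"] = pd.Series(control)
    return out.loc[classes]


def kmer_complementarity_scan(
    chimeras: Sequence[ChimeraRead],
    mirnas: Mapping[str, str],
    k: int = 4,
) -> pd.DataFrame:
    """For each 1-based start position s along the miRNA, the fraction of
    chimeras whose extended target contains revcomp(miRNA[s..s+k-1]).

    Positions beyond a shorter miRNA simply contribute to fewer
    denominators; the frame reports per-position n alongside the fraction.
    """
    mirnas = {m: s.upper().replace("U", "T") for m, s in mirnas.items()}
    if chimeras:
        min_len = min(len(mirnas[c.mirna_id]) for c in chimeras)
        if k > min_len:
            raise ValueError(f"k={k} exceeds shortest miRNA length {min_len}")
    hits: dict[int, int] = {}
    totals: dict[int, int] = {}
    for c in chimeras:
        mature = mirnas[c.mirna_id]
        target = c.extended_seq or c.target_seq
        for s in range(1, len(mature) - k + 2):
            totals[s] = totals.get(s, 0) + 1
            if revcomp(mature[s - 1:s - 1 + k]) in target:
                hits[s] = hits.get(s, 0) + 1
    positions = sorted(totals)
    return pd.DataFrame(
        {
            "position": positions,
            "fraction": [hits.get(s, 0) / totals[s] for s in positions],
            "n": [totals[s] for s in positions],
        }
    )


def last_nt_distribution(chimeras: Sequence[ChimeraRead]) -> pd.DataFrame:
    """Composition of the last nucleotide of the miRNA part and of the
    target part across a chimera set (fractions sum to 1 per part)."""
    if not chimeras:
        return pd.DataFrame(columns=["mirna_part", "target_part"])
    out = {}
    for part, values in (
        ("mirna_part", [c.mirna_last_nt for c in chimeras]),
        ("target_part", [c.target_last_nt for c in chimeras]),
    ):
        counts = pd.Series(values).value_counts()
        out[part] = counts.reindex(list("ACGT"), fill_value=0) / len(chimeras)
    return pd.DataFrame(out)


def seed_mismatch_profile(
    chimeras: Sequence[ChimeraRead],
    mirnas: Mapping[str, str],
) -> np.ndarray:
    """Per-position Watson-Crick pairing fraction over miRNA positions 1-8.

    For each chimera the best site is the length-8 window of the extended
    target with the fewest mismatches against revcomp(miRNA[1..8]) (ties:
    leftmost); the profile is the fraction of chimeras pairing at each
    seed position. Window position j pairs miRNA position 8 - j.
    """
    mirnas = {m: s.upper().replace("U", "T") for m, s in mirnas.items()}
    paired = np.zeros(8)
    n = 0
    for c in chimeras:
        target = c.extended_seq or c.target_seq
        if len(target) < 8:
            continue
        ref = revcomp(mirnas[c.mirna_id][:8])
        best = None
        for w in range(len(target) - 7):
            window = target[w:w + 8]
            match = np.frombuffer(window.encode(), np.uint8) == np.frombuffer(
                ref.encode(), np.uint8
            )
            mism = 8 - int(match.sum())
            if best is None or mism < best[0]:
                best = (mism, match)
        # window index j pairs miRNA position 8-j (1-based)
        paired += best[1][::-1]
        n += 1
    if n == 0:
        return np.zeros(8)
    return paired / n


def compare_chimera_fractions(
    counts_a: Mapping[str, int], totals_a: Mapping[str, int],
    counts_b: Mapping[str, int], totals_b: Mapping[str, int],
) -> pd.DataFrame:
    """Per-miRNA 2x2 Fisher exact comparison of chimera formation between
    two conditions, BH-adjusted across miRNAs.

    For each miRNA the table is [[chimera_A, other_A], [chimera_B,
    other_B]]; the two-sided p sums all hypergeometric outcomes at most as
    probable as the observed one.
    """
    rows = []
    for mid in sorted(set(counts_a) | set(counts_b)):
        ca, ta = int(counts_a.get(mid, 0)), int(totals_a.get(mid, 0))
        cb, tb = int(counts_b.get(mid, 0)), int(totals_b.get(mid, 0))
        if ca > ta or cb > tb or min(ca, cb, ta, tb) < 0:
            raise ValueError(f"invalid counts for {mid!r}")
        table = [[ca, ta - ca], [cb, tb - cb]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "mirna_id": mid,
                "chimeras_a": ca, "total_a": ta,
                "chimeras_b": cb, "total_b": tb,
                "odds_ratio": odds, "pvalue": p,
            }
        )
    out = pd.DataFrame(rows).set_index("mirna_id")
    out["padj"] = bh_adjust(out["pvalue"])
    return out


def chimeras_to_frame(chimeras: Sequence[ChimeraRead]) -> pd.DataFrame:
    rows = [
        {
            "read_id": c.read_id,
            "mirna_id": c.mirna_id,
            "mirna_part_len": c.mirna_part_len,
            "orientation": c.orientation,
            "transcript_id": c.transcript_id,
            "target_start": c.target_start,
            "target_end": c.target_end,
            "region": c.region or "",
            "mirna_last_nt": c.mirna_last_nt,
            "target_last_nt": c.target_last_nt,
            "seed_class": c.seed_class,
        }
        for c in chimeras
    ]
    return pd.DataFrame(
        rows,
        columns=["read_id", "mirna_id", "mirna_part_len", "orientation",
                 "transcript_id", "target_start", "target_end", "region",
                 "mirna_last_nt", "target_last_nt", "seed_class"],
    )
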