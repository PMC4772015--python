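"""Canonical miRNA recognition elements (MREs) and single-miRNA assignment.

A canonical seed site is the target-strand (5'->3', DNA alphabet) reverse
complement of the miRNA seed:

* 6mer     = revcomp(miRNA positions 2-7)
* 7mer-m8  = revcomp(positions 2-8)
* 7mer-A1  = revcomp(positions 2-7) + 'A'
* 8mer     = revcomp(positions 2-8) + 'A'

Candidate sites inside a binding-site cluster are kept when the offset of
their first nucleotide relative to the cluster's predominant T->C
transition lies in the canonical window (default -2..+5), and at most one
expressed miRNA is then assigned per cluster by the priority order
site length > conservation > |offset| > expression > miRNA id.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SITE_TYPE_RANK = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSiteSet:
    """The four canonical site strings of one miRNA."""

    mirna_id: str
    mer6: str
    mer7_m8: str
    mer7_a1: str
    mer8: str

    def site(self, site_type: str) -> str:
        return {
            "6mer": self.mer6,
            "7mer-m8": self.mer7_m8,
            "7mer-A1": self.mer7_a1,
            "8mer": self.mer8,
        }[site_type]

    def by_length(self) -> list[tuple[str, str]]:
        """(type, string) pairs, longest class first."""
        return [
            ("8mer", self.mer8),
            ("7mer-m8", self.mer7_m8),
            ("7mer-A1", self.mer7_a1),
            ("6mer", self.mer6),
        ]


@dataclass
class MRE:
    """One candidate (or assigned) seed match inside a cluster."""

    cluster_id: str
    mirna_id: str
    site_type: str
    start: int           # transcript coordinate of the first site nucleotide
    offset: int          # start - predominant T->C position (signed)
    conservation: float  # mean per-base score over the site; 0 when missing
    conservation_missing: bool = False
    assigned: bool = False


def seed_sites(mirna_id: str, mature: str) -> SeedSiteSet:
    """Derive the canonical site strings from a mature sequence (RNA or DNA)."""
    seq = mature.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError(
            f"mature sequence of {mirna_id!r} is shorter than 8 nt"
        )
    if set(seq) - set("ACGT"):
        raise ValueError(f"invalid alphabet in mature sequence of {mirna_id!r}")
    core6 = revcomp(seq[1:7])
    core7 = revcomp(seq[1:8])
    return SeedSiteSet(
        mirna_id=mirna_id,
        mer6=core6,
        mer7_m8=core7,
        mer7_a1=core6 + "A",
        mer8=core7 + "A",
    )


def find_mres_in_cluster(
    cluster,
    seed_sets: Iterable[SeedSiteSet],
    window: tuple[int, int] = (-2, 5),
    conservation: Mapping[str, np.ndarray] | None = None,
) -> list[MRE]:
    """All occurrences of any canonical site string whose first nucleotide
    lies within `window` of the cluster's predominant T->C transition.

    `cluster` needs ``cluster_id``, ``transcript_id``, ``start``,
    ``sequence`` and ``predominant_t2c`` attributes (see
    :class:`agonet.clusters.Cluster`).
    """
    if cluster.sequence is None:
        raise ValueError(f"cluster {cluster.cluster_id} carries no sequence")
    lo, hi = window
    seq = cluster.sequence
    track = None
    if conservation is not None:
        track = conservation.get(cluster.transcript_id)
    out: list[MRE] = []
    for sset in seed_sets:
        for site_type, site_str in sset.by_length():
            at = seq.find(site_str)
            while at != -1:
                start = cluster.start + at
                offset = start - cluster.predominant_t2c
                if lo <= offset <= hi:
                    if track is not None:
                        cons = float(
                            np.mean(track[start:start + len(site_str)])
                        )
                        missing = False
                    else:
                        cons, missing = 0.0, True
                    out.append(
                        MRE(
                            cluster_id=cluster.cluster_id,
                            mirna_id=sset.mirna_id,
                            site_type=site_type,
                            start=start,
                            offset=offset,
                            conservation=cons,
                            conservation_missing=missing,
                        )
                    )
                at = seq.find(site_str, at + 1)
    return out


def _priority_key(mre: MRE, expression: Mapping[str, float]):
    """Sort key: best candidate first."""
    return (
        -SITE_TYPE_RANK[mre.site_type],
        -mre.conservation,
        abs(mre.offset),
        -float(expression[mre.mirna_id]),
        mre.mirna_id,
        mre.start,
    )


def assign_mre(
    candidates: Sequence[MRE],
    expression: Mapping[str, float],
    min_expression: float = 1.0,
) -> MRE | None:
    """Pick at most one MRE for a cluster.

    Candidates from miRNAs below `min_expression` are dropped; the rest are
    ranked by (1) longer site class, (2) higher conservation, (3) |offset|
    closest to the predominant T->C position, (4) higher expression,
    (5) miRNA id, (6) leftmost start. Returns the winner flagged
    ``assigned=True``, or None when nothing survives the expression filter.
    """
    missing = {c.mirna_id for c in candidates} - set(expression)
    if missing:
        raise KeyError(
            f"expression table missing miRNAs: {sorted(missing)}"
        )
    viable = [
        c for c in candidates if float(expression[c.mirna_id]) >= min_expression
    ]
    if not viable:
        return None
    best = min(viable, key=lambda c: _priority_key(c, expression))
    return replace(best, assigned=True)


def assign_all(
    clusters,
    seed_sets: Iterable[SeedSiteSet],
    expression: Mapping[str, float],
    min_expression: float = 1.0,
    window: tuple[int, int] = (-2, 5),
    conservation: Mapping[str, np.ndarray] | None = None,
) -> dict[str, MRE]:
    """Run find + assign over many clusters; unassigned clusters are absent
    from the returned ``{cluster_id: MRE}`` mapping."""
    seed_sets = list(seed_sets)
    out: dict[str, MRE] = {}
    for cluster in clusters:
        cands = find_mres_in_cluster(
            cluster, seed_sets, window=window, conservation=conservation
        )
        winner = assign_mre(cands, expression, min_expression=min_expression)
        if winner is not None:
            out[cluster.cluster_id] = winner
    return out
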