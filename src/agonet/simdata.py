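"""Ground-truthed synthetic data emulating an AGO2 RIP/PAR-CLIP study.

The generator produces, from a single integer seed, everything the
downstream stages consume:

* a mature miRNA set containing at least one identical-seed family
  (let-7-like), written as DNA (U -> T);
* a transcriptome with contiguous 5'UTR / CDS / 3'UTR regions of
  controllable per-region T frequency, with exact canonical seed sites
  (8mer / 7mer-m8 / 7mer-A1 / 6mer) planted at recorded offsets;
* negative-binomial count tables for total RNA and AGO2-IP fractions over
  two genotypes (WT / null), two treatments (treated / vehicle) and
  replicates, with planted "association-only" ('o') and "abundance" ('&')
  effects applied only in the wild-type genotype;
* PAR-CLIP-like read alignments piling up on the planted sites, carrying
  T->C conversions inside a crosslink footprint, plus raw read sequences
  among which ligation chimeras (mature-miRNA prefix + target fragment)
  occur at a planted per-condition rate.

Every stochastic choice flows from `SimConfig.seed` through named
sub-generators, so identical configurations give byte-identical outputs
regardless of which operations are invoked or in what order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .mre import seed_sites

NUCLEOTIDES = np.array(list("ACGT"))

SITE_TYPE_WEIGHTS = {"8mer": 0.3, "7mer-m8": 0.3, "7mer-A1": 0.2, "6mer": 0.2}

# fixed per-purpose offsets so sub-streams are independent of call order
_RNG_OFFSETS = {
    "mirnas": 11,
    "classes": 23,
    "baselines": 37,
    "transcriptome": 51,
    "counts": 67,
    "parclip": 83,
    "conservation": 97,
    "clusters": 109,
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class GenerationError(RuntimeError):
    """A requested structure cannot be realized (e.g. site longer than region)."""


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    Counts are negative binomial with variance mu + dispersion * mu**2.
    `effect_lfc` is the magnitude (log2) of the planted treatment effect;
    class 'o' shifts only the IP means of wild-type treated samples, class
    '&' shifts IP and total alike, and the null genotype carries no planted
    effect. `chimera_rate` is the per-site-read probability of emitting a
    ligation chimera in vehicle libraries; treated libraries use the odds
    ratio `chimera_odds_ratio`.
    """

    seed: int = 0
    n_mirnas: int = 24
    n_transcripts: int = 120
    depth: float = 2e6
    dispersion: float = 0.05
    effect_lfc: float = 1.0
    frac_association_only: float = 0.20
    frac_abundance: float = 0.10
    frac_unchanged: float = 0.70
    chimera_rate: float = 0.05
    t2c_rate: float = 0.5
    read_len_range: tuple[int, int] = (20, 40)
    n_replicates: int = 3
    # transcriptome shape
    family_size: int = 4
    utr5_len_range: tuple[int, int] = (100, 250)
    cds_codon_range: tuple[int, int] = (100, 350)
    utr3_len_range: tuple[int, int] = (250, 700)
    t_freq: Mapping[str, float] = field(
        default_factory=lambda: {"5UTR": 0.24, "CDS": 0.22, "3UTR": 0.30}
    )
    sites_per_mirna: int = 4
    site_region_weights: Mapping[str, float] = field(
        default_factory=lambda: {"3UTR": 0.8, "CDS": 0.2}
    )
    min_site_separation: int = 150
    # PAR-CLIP read model
    reads_per_site: float = 30.0
    background_reads: int = 2000
    start_jitter_sd: float = 3.0
    chimera_odds_ratio: float = 2.0
    chimera_mirna_min_len: int = 16
    chimera_target_len_range: tuple[int, int] = (12, 26)
    ligation_g_bias: float = 0.6
    target_first_frac: float = 0.0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_association_only,
            self.frac_abundance,
            self.frac_unchanged,
        )
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError(f"class proportions must sum to 1, got {fracs}")
        for name in ("chimera_rate", "t2c_rate", "ligation_g_bias",
                     "target_first_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if any(f < 0 for f in fracs):
            raise ConfigError("class proportions must be non-negative")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if self.effect_lfc < 0:
            raise ConfigError("effect_lfc must be non-negative")
        if self.read_len_range[0] < 8:
            raise ConfigError("read_len_range minimum must be >= 8")
        if self.n_mirnas < 8:
            raise ConfigError("n_mirnas must be >= 8")
        if self.family_size < 4:
            raise ConfigError("family_size must be >= 4")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the synthetic data."""

    mirna_classes: pd.DataFrame  # mirna_id, cls in {&, o, unchanged}, direction
    sites: pd.DataFrame | None = None
    reads: pd.DataFrame | None = None
    chimera_fractions: dict | None = None


@dataclass
class Transcriptome:
    """Transcript sequences with contiguous 5'UTR/CDS/3'UTR intervals
    (0-based half-open) and a transcript -> gene mapping."""

    sequences: dict[str, str]
    regions: pd.DataFrame  # transcript_id, region, start, end
    gene_map: dict[str, str]
    conservation: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self._intervals: dict[str, list[tuple[int, int, str]]] = {}
        for row in self.regions.itertuples(index=False):
            self._intervals.setdefault(row.transcript_id, []).append(
                (int(row.start), int(row.end), row.region)
            )
        for ivs in self._intervals.values():
            ivs.sort()

    def length(self, transcript_id: str) -> int:
        return len(self.sequences[transcript_id])

    def region_at(self, transcript_id: str, pos: int) -> str:
        """Region label containing a transcript position."""
        if transcript_id not in self._intervals:
            raise KeyError(f"transcript {transcript_id!r} not in annotation")
        for start, end, region in self._intervals[transcript_id]:
            if start <= pos < end:
                return region
        raise ValueError(
            f"position {pos} of {transcript_id} outside all annotated regions"
        )

    def region_sequences(self) -> dict[str, str]:
        """Concatenated sequence of each region class across transcripts."""
        parts: dict[str, list[str]] = {}
        for row in self.regions.itertuples(index=False):
            seq = self.sequences[row.transcript_id][int(row.start):int(row.end)]
            parts.setdefault(row.region, []).append(seq)
        return {region: "".join(chunks) for region, chunks in parts.items()}


def _rng(config: SimConfig, purpose: str) -> np.random.Generator:
    return np.random.default_rng([_RNG_OFFSETS[purpose], int(config.seed)])


def _random_seq(rng: np.random.Generator, length: int,
                t_freq: float = 0.25) -> str:
    other = (1.0 - t_freq) / 3.0
    probs = [other, other, other, t_freq]  # A C G T
    return "".join(rng.choice(NUCLEOTIDES, size=length, p=probs))


def make_mirnas(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate mature miRNA sequences and their family table.

    The first `family_size` miRNAs form family ``fam0`` and share positions
    2-8 (the seed) exactly, mimicking a let-7-like family; all other seeds
    are unique. Sequences are 20-23 nt, DNA alphabet.
    """
    rng = _rng(config, "mirnas")
    n = config.n_mirnas
    ids = [f"miR-{i:04d}" for i in range(n)]
    seqs: dict[str, str] = {}
    seen_seeds: set[str] = set()

    family_seed = _random_seq(rng, 7)
    seen_seeds.add(family_seed)
    for i in range(config.family_size):
        length = int(rng.integers(20, 24))
        seq = list(_random_seq(rng, length))
        seq[1:8] = family_seed
        seqs[ids[i]] = "".join(seq)
    for i in range(config.family_size, n):
        while True:
            length = int(rng.integers(20, 24))
            seq = _random_seq(rng, length)
            if seq[1:8] not in seen_seeds:
                seen_seeds.add(seq[1:8])
                break
        seqs[ids[i]] = seq

    families = pd.DataFrame(
        {
            "mirna_id": ids,
            "family": [
                "fam0" if i < config.family_size else f"fam{i}"
                for i in range(n)
            ],
        }
    )
    return seqs, families


def assign_classes(config: SimConfig,
                   mirna_ids: list[str]) -> pd.DataFrame:
    """Randomly assign each miRNA a planted class and effect direction.

    Directions are balanced (half up, half down) within each affected class
    so that planted effects perturb library sizes as little as possible.
    """
    rng = _rng(config, "classes")
    m = len(mirna_ids)
    n_o = int(round(config.frac_association_only * m))
    n_amp = int(round(config.frac_abundance * m))
    order = rng.permutation(m)
    cls = np.array(["unchanged"] * m, dtype=object)
    cls[order[:n_o]] = "o"
    cls[order[n_o:n_o + n_amp]] = "&"
    direction = np.array(["none"] * m, dtype=object)
    for label in ("o", "&"):
        idx = np.flatnonzero(cls == label)
        half = len(idx) // 2
        direction[idx[:half]] = "up"
        direction[idx[half:]] = "down"
    return pd.DataFrame(
        {"mirna_id": mirna_ids, "cls": cls, "direction": direction}
    )


def baseline_means(config: SimConfig, mirna_ids: list[str]) -> pd.Series:
    """Deterministic per-miRNA baseline expected counts summing to `depth`.

    Relative abundances are log-normal (sigma = 1), the classic wide
    dynamic range of small-RNA libraries.
    """
    rng = _rng(config, "baselines")
    w = np.exp(rng.normal(0.0, 1.0, len(mirna_ids)))
    mu = config.depth * w / w.sum()
    return pd.Series(mu, index=mirna_ids, name="baseline_mean")


_SITE_REGION_ORDER = ["5UTR", "CDS", "3UTR"]


def make_transcriptome(
    config: SimConfig,
    mirnas: Mapping[str, str],
    families: pd.DataFrame | None = None,
    expression: Mapping[str, float] | None = None,
) -> tuple[Transcriptome, pd.DataFrame]:
    """Generate transcripts with planted canonical seed sites.

    Each transcript is a contiguous 5'UTR + CDS (length divisible by 3) +
    3'UTR with per-region nucleotide composition targeting
    ``config.t_freq``. For every miRNA, `sites_per_mirna` exact seed-site
    strings are written into randomly chosen regions; a crosslink anchor T
    is forced 3 nt upstream of each site and the crosslink footprint
    [site_start - 5, site_start + 3) is recorded so that the predominant
    T->C conversion of a resulting read cluster falls in the canonical
    -2..+5 window relative to the site start.

    Site ownership: members of an identical-seed family produce literally
    identical site strings, so family sites are attributed to the most
    expressed member when `expression` is given (standard CLIP-era
    attribution), otherwise to the lexicographically first member.
    """
    if not mirnas:
        raise ConfigError("miRNA set must be nonempty")
    rng = _rng(config, "transcriptome")

    ids = [f"tx{i:05d}" for i in range(config.n_transcripts)]
    seqs: dict[str, list[str]] = {}
    rows = []
    for tid in ids:
        l5 = int(rng.integers(*config.utr5_len_range))
        lc = 3 * int(rng.integers(*config.cds_codon_range))
        l3 = int(rng.integers(*config.utr3_len_range))
        seq = (
            _random_seq(rng, l5, config.t_freq["5UTR"])
            + _random_seq(rng, lc, config.t_freq["CDS"])
            + _random_seq(rng, l3, config.t_freq["3UTR"])
        )
        seqs[tid] = list(seq)
        rows.extend(
            [
                (tid, "5UTR", 0, l5),
                (tid, "CDS", l5, l5 + lc),
                (tid, "3UTR", l5 + lc, l5 + lc + l3),
            ]
        )
    regions = pd.DataFrame(
        rows, columns=["transcript_id", "region", "start", "end"]
    )
    region_lookup = {
        (r.transcript_id, r.region): (int(r.start), int(r.end))
        for r in regions.itertuples(index=False)
    }

    # transcript -> gene: ~20% of genes carry two isoforms
    n_genes = max(1, int(round(config.n_transcripts / 1.2)))
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    gene_map = {}
    for i, tid in enumerate(ids):
        if i < n_genes:
            gene_map[tid] = gene_ids[i]
        else:
            gene_map[tid] = gene_ids[int(rng.integers(0, n_genes))]

    # family ownership resolution
    owner_of: dict[str, str] = {m: m for m in mirnas}
    if families is not None:
        for fam, group in families.groupby("family"):
            members = sorted(group["mirna_id"])
            if len(members) > 1:
                if expression is not None:
                    top = max(members, key=lambda m: (expression[m], m))
                else:
                    top = members[0]
                for m in members:
                    owner_of[m] = top

    region_names = list(config.site_region_weights)
    region_probs = np.array(
        [config.site_region_weights[r] for r in region_names], dtype=float
    )
    region_probs /= region_probs.sum()
    type_names = list(SITE_TYPE_WEIGHTS)
    type_probs = np.array(list(SITE_TYPE_WEIGHTS.values()))

    placed: dict[str, list[int]] = {tid: [] for tid in ids}
    site_rows = []
    site_idx = 0
    for mirna_id, mature in mirnas.items():
        sset = seed_sites(mirna_id, mature)
        for _ in range(config.sites_per_mirna):
            site_type = type_names[
                int(rng.choice(len(type_names), p=type_probs))
            ]
            site_str = sset.site(site_type)
            pos = None
            for _attempt in range(200):
                tid = ids[int(rng.integers(0, len(ids)))]
                region = region_names[
                    int(rng.choice(len(region_names), p=region_probs))
                ]
                rstart, rend = region_lookup[(tid, region)]
                lo = max(rstart, 6)
                hi = min(rend, len(seqs[tid]) - 2) - len(site_str)
                if hi <= lo:
                    if len(site_str) > rend - rstart:
                        raise GenerationError(
                            f"site of length {len(site_str)} does not fit in "
                            f"{region} of {tid} (length {rend - rstart})"
                        )
                    continue
                cand = int(rng.integers(lo, hi))
                if all(
                    abs(cand - p) >= config.min_site_separation
                    for p in placed[tid]
                ):
                    pos = cand
                    break
            if pos is None:
                continue  # transcriptome saturated; site quota best-effort
            placed[tid].append(pos)
            seqs[tid][pos:pos + len(site_str)] = site_str
            seqs[tid][pos - 3] = "T"  # crosslink anchor
            site_rows.append(
                {
                    "site_id": f"site{site_idx:05d}",
                    "transcript_id": tid,
                    "start": pos,
                    "end": pos + len(site_str),
                    "planted_for": mirna_id,
                    "mirna_id": owner_of[mirna_id],
                    "site_type": site_type,
                    "region": region,
                    "footprint_start": pos - 5,
                    "footprint_end": pos + 3,
                }
            )
            site_idx += 1

    sequences = {tid: "".join(chars) for tid, chars in seqs.items()}
    sites = pd.DataFrame(
        site_rows,
        columns=[
            "site_id", "transcript_id", "start", "end", "planted_for",
            "mirna_id", "site_type", "region", "footprint_start",
            "footprint_end",
        ],
    )

    cons_rng = _rng(config, "conservation")
    conservation = {
        tid: cons_rng.uniform(0.0, 0.5, len(seq)).astype(np.float32)
        for tid, seq in sequences.items()
    }
    for row in sites.itertuples(index=False):
        level = cons_rng.uniform(0.6, 0.95)
        conservation[row.transcript_id][row.start:row.end] = level

    tr = Transcriptome(
        sequences=sequences,
        regions=regions,
        gene_map=gene_map,
        conservation=conservation,
    )
    return tr, sites


FRACTIONS = ("total", "IP")
GENOTYPES = ("WT", "null")
TREATMENTS = ("treated", "vehicle")


def simulate_counts(config: SimConfig, truth: GroundTruth):
    """Simulate the full count design: 2 fractions x 2 genotypes x 2
    treatments x `n_replicates`, negative binomial around planted means.

    Returns a :class:`agonet.diffassoc.CountTable`.
    """
    from .diffassoc import CountTable

    if config.dispersion < 0:
        raise ConfigError("dispersion must be non-negative")
    classes = truth.mirna_classes.set_index("mirna_id")
    mirna_ids = list(classes.index)
    mu0 = baseline_means(config, mirna_ids).to_numpy()
    sign = classes["direction"].map({"up": 1.0, "down": -1.0}).fillna(0.0)
    shift = 2.0 ** (config.effect_lfc * sign.to_numpy())
    is_o = (classes["cls"] == "o").to_numpy()
    is_amp = (classes["cls"] == "&").to_numpy()

    rng = _rng(config, "counts")
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for fraction in FRACTIONS:
        for genotype in GENOTYPES:
            for treatment in TREATMENTS:
                mu = mu0.copy()
                if genotype == "WT" and treatment == "treated":
                    affected = is_amp | (is_o & (fraction == "IP"))
                    mu = np.where(affected, mu * shift, mu)
                for rep in range(1, config.n_replicates + 1):
                    name = f"{fraction}_{genotype}_{treatment}_r{rep}"
                    if config.dispersion == 0:
                        counts = rng.poisson(mu)
                    else:
                        nparam = 1.0 / config.dispersion
                        p = nparam / (nparam + mu)
                        counts = rng.negative_binomial(nparam, p)
                    columns[name] = counts
                    meta_rows.append(
                        {
                            "sample_id": name,
                            "fraction": fraction,
                            "genotype": genotype,
                            "treatment": treatment,
                            "replicate": rep,
                        }
                    )
    counts = pd.DataFrame(columns, index=pd.Index(mirna_ids, name="entity_id"))
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountTable(counts=counts, samples=samples)


def _choose_with_g_bias(rng, candidates: list[int], last_nt: list[str],
                        g_bias: float) -> int:
    """Pick an end among candidates, preferring those that leave a 3' G."""
    g_idx = [i for i, nt in enumerate(last_nt) if nt == "G"]
    if g_idx and rng.random() < g_bias:
        return candidates[g_idx[int(rng.integers(0, len(g_idx)))]]
    return candidates[int(rng.integers(0, len(candidates)))]


def chimera_rate_for(config: SimConfig, condition: str) -> float:
    """Planted chimera emission probability for a treatment condition."""
    if condition == "vehicle":
        return config.chimera_rate
    if condition == "treated":
        odds = config.chimera_rate / (1.0 - config.chimera_rate)
        odds *= config.chimera_odds_ratio
        return odds / (1.0 + odds)
    raise ConfigError(f"unknown condition {condition!r}")


def simulate_parclip_reads(
    config: SimConfig,
    transcriptome: Transcriptome,
    truth: GroundTruth,
    mirnas: Mapping[str, str] | None = None,
    condition: str = "treated",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one PAR-CLIP library for one treatment condition.

    Returns ``(alignments, raw_reads)``. Alignments hold the mappable reads
    (site pile-ups plus uniform background) with T->C mismatch records in
    ``pos:T>C;...`` form; `raw_reads` holds every emitted read sequence,
    chimeras included, with per-read ground-truth columns. Site reads start
    near the planted site start (Gaussian jitter, sd `start_jitter_sd`) and
    every reference T inside the recorded crosslink footprint converts
    independently with probability `t2c_rate`. With the per-condition
    chimera rate, a site read is instead emitted as a ligation product:
    a 5' prefix of the owning mature miRNA joined to an (unconverted)
    fragment of the site's neighbourhood, with a configurable G preference
    at the ligated ends.
    """
    if config.read_len_range[0] < 8:
        raise ConfigError("read_len_range minimum must be >= 8")
    if truth.sites is None or len(truth.sites) == 0:
        raise ConfigError("ground truth carries no planted sites")
    rng = _rng(config, "parclip")
    rate = chimera_rate_for(config, condition)
    lmin, lmax = config.read_len_range

    aln_rows: list[tuple] = []
    raw_rows: list[tuple] = []
    n_read = 0

    def next_id() -> str:
        nonlocal n_read
        n_read += 1
        return f"read{n_read:07d}"

    tids = list(transcriptome.sequences)
    lengths = np.array([len(transcriptome.sequences[t]) for t in tids])
    tx_probs = lengths / lengths.sum()

    # --- site reads and chimeras -------------------------------------
    for site in truth.sites.itertuples(index=False):
        seq = transcriptome.sequences[site.transcript_id]
        tlen = len(seq)
        n_site = rng.poisson(config.reads_per_site)
        foot = [
            p
            for p in range(max(site.footprint_start, 0),
                           min(site.footprint_end, tlen))
            if seq[p] == "T"
        ]
        for _ in range(n_site):
            if mirnas is not None and rng.random() < rate:
                rid = next_id()
                mature = mirnas[site.planted_for]
                lo = min(config.chimera_mirna_min_len, len(mature))
                lens = list(range(lo, len(mature) + 1))
                mlen = _choose_with_g_bias(
                    rng, lens, [mature[l - 1] for l in lens],
                    config.ligation_g_bias,
                )
                t_start = max(0, site.start - int(rng.integers(0, 4)))
                tmin, tmax = config.chimera_target_len_range
                ends = [
                    e
                    for e in range(t_start + tmin, t_start + tmax + 1)
                    if e <= tlen
                ]
                if not ends:
                    ends = [tlen]
                t_end = _choose_with_g_bias(
                    rng, ends, [seq[e - 1] for e in ends],
                    config.ligation_g_bias,
                )
                frag = seq[t_start:t_end]
                if rng.random() < config.target_first_frac:
                    orientation, read_seq = "target_first", frag + mature[:mlen]
                else:
                    orientation, read_seq = "mirna_first", mature[:mlen] + frag
                raw_rows.append(
                    (rid, read_seq, "chimera", site.site_id,
                     site.planted_for, mlen, orientation,
                     site.transcript_id, t_start, t_end)
                )
                continue
            rid = next_id()
            start = int(round(site.start - 3 + rng.normal(0.0, config.start_jitter_sd)))
            start = max(0, min(start, tlen - lmin))
            end = min(start + int(rng.integers(lmin, lmax + 1)), tlen)
            converted = [
                p for p in foot
                if start <= p < end and rng.random() < config.t2c_rate
            ]
            frag = list(seq[start:end])
            for p in converted:
                frag[p - start] = "C"
            mm = ";".join(f"{p}:T>C" for p in sorted(converted))
            aln_rows.append(
                (rid, site.transcript_id, start, end, mm, "site", site.site_id)
            )
            raw_rows.append(
                (rid, "".join(frag), "site", site.site_id, "", 0, "",
                 site.transcript_id, start, end)
            )

    # --- uniform background -------------------------------------------
    bg_tx = rng.choice(len(tids), size=config.background_reads, p=tx_probs)
    for k in range(config.background_reads):
        rid = next_id()
        tid = tids[int(bg_tx[k])]
        tlen = lengths[int(bg_tx[k])]
        start = int(rng.integers(0, max(1, tlen - lmin)))
        end = min(start + int(rng.integers(lmin, lmax + 1)), tlen)
        frag = transcriptome.sequences[tid][start:end]
        aln_rows.append((rid, tid, start, end, "", "background", ""))
        raw_rows.append(
            (rid, frag, "background", "", "", 0, "", tid, start, end)
        )

    alignments = pd.DataFrame(
        aln_rows,
        columns=["read_id", "transcript_id", "start", "end", "mismatches",
                 "true_class", "site_id"],
    )
    raw_reads = pd.DataFrame(
        raw_rows,
        columns=["read_id", "sequence", "true_class", "site_id", "mirna_id",
                 "mirna_part_len", "orientation", "transcript_id",
                 "target_start", "target_end"],
    )
    return alignments, raw_reads


def sample_clusters_by_t_content(
    transcriptome: Transcriptome, n: int, seed: int = 0
) -> pd.DataFrame:
    """Sample `n` cluster region labels with P(region) proportional to
    region length x realized T frequency — the null model under which
    T-normalized per-nucleotide cluster density is uniform across regions.
    """
    rng = np.random.default_rng([_RNG_OFFSETS["clusters"], int(seed)])
    region_seqs = transcriptome.region_sequences()
    regions = sorted(region_seqs)
    lengths = np.array([len(region_seqs[r]) for r in regions], dtype=float)
    tfreq = np.array(
        [region_seqs[r].count("T") / len(region_seqs[r]) for r in regions]
    )
    p = lengths * tfreq
    p /= p.sum()
    counts = rng.multinomial(n, p)
    return pd.DataFrame({"region": regions, "n_clusters": counts,
                         "length": lengths.astype(int), "t_freq": tfreq})


def make_seed_mismatch_targets(
    mature: str,
    n: int,
    mismatch_rates,
    flank: int = 8,
    seed: int = 0,
) -> list[str]:
    """Target sequences pairing a miRNA's seed with planted per-position
    mismatch rates.

    Each sequence embeds the length-8 reverse complement of miRNA
    positions 1-8 between random flanks; independently per sequence,
    seed position i (1-based) is mismatched with probability
    ``mismatch_rates[i-1]`` by substituting the pairing base (window
    position 8-i) with a random non-complementary, non-reference base.
    Used to validate per-position pairing-profile recovery.
    """
    from .mre import revcomp

    mismatch_rates = list(mismatch_rates)
    if len(mismatch_rates) != 8:
        raise ConfigError("mismatch_rates must have length 8")
    rng = np.random.default_rng([127, int(seed)])
    seq = mature.upper().replace("U", "T")
    site = revcomp(seq[:8])
    out = []
    for _ in range(n):
        window = list(site)
        for i in range(8):
            if rng.random() < mismatch_rates[i]:
                j = 7 - i  # window position pairing miRNA position i+1
                choices = [b for b in "ACGT" if b != site[j]]
                window[j] = choices[int(rng.integers(0, 3))]
        out.append(
            _random_seq(rng, flank) + "".join(window) + _random_seq(rng, flank)
        )
    return out


@dataclass
class Dataset:
    """One fully simulated study, as produced by :func:`generate_dataset`."""

    config: SimConfig
    mirnas: dict[str, str]
    families: pd.DataFrame
    transcriptome: Transcriptome
    truth: GroundTruth
    counts: "object"  # CountTable
    alignments: pd.DataFrame
    raw_reads: pd.DataFrame


def generate_dataset(config: SimConfig, condition: str = "treated") -> Dataset:
    """Run the whole generator: miRNAs -> classes -> counts baselines ->
    transcriptome (ownership resolved by expression) -> counts -> PAR-CLIP
    reads for one condition."""
    mirnas, families = make_mirnas(config)
    classes = assign_classes(config, list(mirnas))
    expr = baseline_means(config, list(mirnas))
    transcriptome, sites = make_transcriptome(
        config, mirnas, families, expression=expr.to_dict()
    )
    truth = GroundTruth(mirna_classes=classes, sites=sites)
    counts = simulate_counts(config, truth)
    alignments, raw_reads = simulate_parclip_reads(
        config, transcriptome, truth, mirnas=mirnas, condition=condition
    )
    truth.reads = raw_reads[
        ["read_id", "true_class", "site_id", "mirna_id", "mirna_part_len",
         "orientation"]
    ].copy()
    truth.chimera_fractions = {
        "planted": {c: chimera_rate_for(config, c) for c in TREATMENTS},
        "realized": {
            condition: float((raw_reads["true_class"] == "chimera").mean())
        },
    }
    return Dataset(
        config=config,
        mirnas=mirnas,
        families=families,
        transcriptome=transcriptome,
        truth=truth,
        counts=counts,
        alignments=alignments,
        raw_reads=raw_reads,
    )
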