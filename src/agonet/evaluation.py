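"""Property-based benchmark routines over the synthetic-data generator.

Each function regenerates its inputs from a seed, runs the corresponding
pipeline stage, and measures recovery of the planted truth (or agreement
with an independent brute-force oracle). They are shared by the test
suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import chimera as chimera_mod
from . import clusters as clusters_mod
from . import mre as mre_mod
from .diffassoc import bh_adjust, normalize_log2cpm, run_mirna_classification
from .simdata import (
    GroundTruth,
    SimConfig,
    assign_classes,
    chimera_rate_for,
    generate_dataset,
    make_mirnas,
    make_seed_mismatch_targets,
    sample_clusters_by_t_content,
    simulate_counts,
)


def classifier_recovery(
    seeds=range(20),
    n_mirnas: int = 200,
    effect_lfc: float = 1.0,
    dispersion: float = 0.05,
    depth: float = 2e6,
    n_replicates: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Sensitivity / false-discovery proportion of the association-only
    classifier against the planted classes, plus raw-p calibration of the
    effect-free null genotype, averaged over seeds."""
    sens, fdp, null_calls = [], [], []
    for seed in seeds:
        cfg = SimConfig(
            seed=seed, n_mirnas=n_mirnas, effect_lfc=effect_lfc,
            dispersion=dispersion, depth=depth, n_replicates=n_replicates,
        )
        mirnas, _ = make_mirnas(cfg)
        classes = assign_classes(cfg, list(mirnas))
        table = simulate_counts(cfg, GroundTruth(mirna_classes=classes))
        res = run_mirna_classification(table, genotype="WT", alpha=alpha)
        truth = classes.set_index("mirna_id")["cls"]
        called = res["category"] == "association_only"
        true_o = truth == "o"
        sens.append(float((called & true_o).sum() / max(true_o.sum(), 1)))
        fdp.append(
            0.0 if called.sum() == 0
            else float((called & ~true_o).sum() / called.sum())
        )
        res_null = run_mirna_classification(table, genotype="null",
                                            alpha=alpha)
        null_calls.append(int((res_null["pvalue_ip"] < alpha).sum()))
    return {
        "sensitivity": float(np.mean(sens)),
        "fdp": float(np.mean(fdp)),
        "null_significant_calls": float(np.mean(null_calls)),
        "null_expected": alpha * n_mirnas,
        "n_seeds": len(sens),
        "m": n_mirnas,
    }


def _brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition, written independently of bh_adjust."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bh_equivalence(n_vectors: int = 1000, max_m: int = 200,
                   seed: int = 0) -> dict:
    """Maximal absolute deviation between bh_adjust and the brute-force
    step-up definition over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, max_m + 1))
        p = rng.uniform(0, 1, m)
        worst = max(worst, float(np.abs(bh_adjust(p) - _brute_force_bh(p)).max()))
    return {"max_abs_diff": worst, "n_vectors": n_vectors}


def t_normalization(seed: int = 0, n_clusters: int = 10_000) -> dict:
    """Analytic T-normalization check plus uniformity of the normalized
    per-nucleotide cluster density when clusters are planted proportional
    to region length x T frequency."""
    analytic = clusters_mod.normalize_region_distribution(
        {"3UTR": 0.5, "CDS": 0.3, "5UTR": 0.2},
        {"3UTR": 0.30, "CDS": 0.20, "5UTR": 0.25},
    )
    expected = {"3UTR": 0.4202, "CDS": 0.3781, "5UTR": 0.2017}
    analytic_err = max(abs(analytic[r] - expected[r]) for r in expected)

    cfg = SimConfig(seed=seed, n_transcripts=150)
    mirnas, fam = make_mirnas(cfg)
    from .simdata import make_transcriptome

    tr, _ = make_transcriptome(cfg, mirnas, fam)
    sampled = sample_clusters_by_t_content(tr, n_clusters, seed=seed)
    raw = dict(zip(sampled["region"],
                   sampled["n_clusters"] / sampled["n_clusters"].sum()))
    tfreq = dict(zip(sampled["region"], sampled["t_freq"]))
    norm = clusters_mod.normalize_region_distribution(raw, tfreq)
    length_frac = dict(zip(sampled["region"],
                           sampled["length"] / sampled["length"].sum()))
    # uniform per-nucleotide density <=> normalized fraction ~ length share
    uniformity_err = max(abs(norm[r] - length_frac[r]) for r in norm)
    return {
        "analytic_max_abs_err": float(analytic_err),
        "uniformity_max_abs_err": float(uniformity_err),
        "n_clusters": n_clusters,
    }


def _oracle_assign(candidates, expression, min_expression):
    """Exhaustive pairwise-dominance oracle for the MRE priority order."""
    viable = [c for c in candidates
              if expression[c.mirna_id] >= min_expression]

    def beats(a, b):
        for av, bv, bigger in (
            (mre_mod.SITE_TYPE_RANK[a.site_type],
             mre_mod.SITE_TYPE_RANK[b.site_type], True),
            (a.conservation, b.conservation, True),
            (abs(a.offset), abs(b.offset), False),
            (expression[a.mirna_id], expression[b.mirna_id], True),
            (a.mirna_id, b.mirna_id, False),
            (a.start, b.start, False),
        ):
            if av != bv:
                return (av > bv) if bigger else (av < bv)
        return True

    winners = [a for a in viable if all(beats(a, b) for b in viable)]
    return winners[0] if winners else None


def mre_assignment(seed: int = 0, n_sets: int = 500,
                   recovery_seeds=range(20)) -> dict:
    """Exact agreement of assign_mre with the enumeration oracle on random
    candidate sets, plus planted-site owner recovery through the full
    cluster -> MRE pipeline."""
    rng = np.random.default_rng(seed)
    mirna_ids = [f"m{i}" for i in range(4)]
    expression = {m: float(rng.choice([0.5, 2.0, 8.0, 32.0]))
                  for m in mirna_ids}
    agree = 0
    for _ in range(n_sets):
        cands = [
            mre_mod.MRE(
                cluster_id="c0",
                mirna_id=mirna_ids[int(rng.integers(0, 4))],
                site_type=list(mre_mod.SITE_TYPE_RANK)[int(rng.integers(0, 4))],
                start=int(rng.integers(0, 50)),
                offset=int(rng.integers(-2, 6)),
                conservation=float(rng.choice([0.0, 0.2, 0.5, 0.5, 0.9])),
            )
            for _ in range(int(rng.integers(1, 8)))
        ]
        got = mre_mod.assign_mre(cands, expression, min_expression=1.0)
        want = _oracle_assign(cands, expression, 1.0)
        if (got is None) == (want is None) and (
            got is None
            or (got.mirna_id, got.site_type, got.start)
            == (want.mirna_id, want.site_type, want.start)
        ):
            agree += 1

    recovered = total = 0
    for s in recovery_seeds:
        ds = generate_dataset(SimConfig(seed=s))
        called = clusters_mod.call_clusters(ds.alignments, ds.transcriptome)
        seed_sets = [mre_mod.seed_sites(m, seq)
                     for m, seq in ds.mirnas.items()]
        log2cpm = normalize_log2cpm(ds.counts)
        cols = ds.counts.select(fraction="total", genotype="WT",
                                treatment="vehicle")
        expr = (2.0 ** log2cpm[cols]).mean(axis=1).to_dict()
        assigned = mre_mod.assign_all(
            called, seed_sets, expr,
            conservation=ds.transcriptome.conservation,
        )
        by_tx = {}
        for c in called:
            by_tx.setdefault(c.transcript_id, []).append(c)
        for site in ds.truth.sites.itertuples(index=False):
            if expr[site.mirna_id] < 1.0:
                continue
            overlapping = [
                c for c in by_tx.get(site.transcript_id, [])
                if c.start < site.end and site.start < c.end
            ]
            if not overlapping:
                continue
            total += 1
            winner = assigned.get(overlapping[0].cluster_id)
            if winner is not None and winner.mirna_id == site.mirna_id:
                recovered += 1
    return {
        "oracle_agreement": agree / n_sets,
        "owner_recovery": recovered / max(total, 1),
        "n_sites": total,
    }


def chimera_detection(
    seed: int = 0,
    n_background: int = 100_000,
    target_chimeras: int = 1000,
    fisher_seeds=range(20),
    reads_per_condition: int = 5000,
) -> dict:
    """Recall/precision of chimera detection against the planted labels,
    and power of the per-condition Fisher comparison at the generator's
    planted odds ratio."""
    rate = 0.05
    cfg = SimConfig(
        seed=seed, n_mirnas=24, n_transcripts=150, sites_per_mirna=6,
        reads_per_site=target_chimeras / rate / (24 * 6),
        chimera_rate=rate, background_reads=n_background,
    )
    ds = generate_dataset(cfg, condition="vehicle")
    found, _ = chimera_mod.detect_chimeras(
        ds.raw_reads[["read_id", "sequence"]], ds.mirnas, ds.transcriptome
    )
    truth = ds.raw_reads.set_index("read_id")["true_class"]
    detected = {c.read_id for c in found}
    planted = set(truth.index[truth == "chimera"])
    tp = len(detected & planted)
    recall = tp / max(len(planted), 1)
    precision = tp / max(len(detected), 1)

    # Fisher power at the planted per-condition rates (odds ratio 2)
    p_veh = chimera_rate_for(cfg, "vehicle")
    p_tre = chimera_rate_for(cfg, "treated")
    hits = 0
    for s in fisher_seeds:
        rng = np.random.default_rng([211, seed, s])
        ca = int(rng.binomial(reads_per_condition, p_tre))
        cb = int(rng.binomial(reads_per_condition, p_veh))
        res = chimera_mod.compare_chimera_fractions(
            {"m": ca}, {"m": reads_per_condition},
            {"m": cb}, {"m": reads_per_condition},
        )
        if res.loc["m", "pvalue"] < 0.05:
            hits += 1
    return {
        "recall": recall,
        "precision": precision,
        "n_planted": len(planted),
        "n_background": n_background,
        "fisher_power": hits / len(list(fisher_seeds)),
        "planted_odds_ratio": cfg.chimera_odds_ratio,
    }


def fisher_equivalence(max_margin: int = 30) -> dict:
    """Two-sided Fisher p from the pipeline vs a full hypergeometric
    summation, over every 2x2 table with both row margins <= max_margin."""
    worst = 0.0
    n_tables = 0
    for ta in range(1, max_margin + 1):
        for tb in range(1, max_margin + 1):
            N = ta + tb
            for K in range(0, N + 1):
                support = np.arange(max(0, K - tb), min(K, ta) + 1)
                pmf = stats.hypergeom.pmf(support, N, K, ta)
                for idx, a in enumerate(support):
                    ca = int(a)
                    cb = K - ca
                    _, p_impl = stats.fisher_exact(
                        [[ca, ta - ca], [cb, tb - cb]],
                        alternative="two-sided",
                    )
                    p_oracle = float(
                        pmf[pmf <= pmf[idx] * (1 + 1e-9)].sum()
                    )
                    worst = max(worst, abs(p_impl - min(p_oracle, 1.0)))
                    n_tables += 1
    return {"max_abs_diff": worst, "n_tables": n_tables}


def positional_properties(seed: int = 0, n_profile: int = 1000) -> dict:
    """Peak position of the 4-mer complementarity scan on seed-planted
    chimeras, and recovery error of a planted per-position seed-mismatch
    profile."""
    ds = generate_dataset(SimConfig(seed=seed, chimera_rate=0.2))
    found, _ = chimera_mod.detect_chimeras(
        ds.raw_reads[["read_id", "sequence"]], ds.mirnas, ds.transcriptome
    )
    found = chimera_mod.extend_targets(found, ds.transcriptome, ext=10,
                                       seed=seed)
    scan = chimera_mod.kmer_complementarity_scan(found, ds.mirnas, k=4)
    peak = int(scan.loc[scan["fraction"].idxmax(), "position"])

    mature = next(iter(ds.mirnas.values()))
    rates = np.array([0.0, 0.05, 0.0, 0.0, 0.3, 0.1, 0.0, 0.2])
    targets = make_seed_mismatch_targets(mature, n_profile, rates, seed=seed)
    chims = [
        chimera_mod.ChimeraRead(
            read_id=f"r{i}", mirna_id="m", mirna_part_len=len(mature),
            orientation="mirna_first", transcript_id="tx",
            target_start=0, target_end=len(t), target_seq=t, extended_seq=t,
        )
        for i, t in enumerate(targets)
    ]
    profile = chimera_mod.seed_mismatch_profile(chims, {"m": mature})
    profile_err = float(np.abs(profile - (1 - rates)).max())
    return {
        "kmer_peak_position": peak,
        "profile_max_abs_err": profile_err,
        "n_chimeras_scan": len(found),
        "n_chimeras_profile": n_profile,
    }
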