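"""Joint total/IP differential analysis of AGO2 association.

The central idea: compare the treatment response of each miRNA in the
AGO2-immunoprecipitated fraction with its response in total RNA. A miRNA
whose IP abundance changes while its total abundance does not
("association-only", the 'o' class) is regulated at the level of RISC
loading rather than expression; concordant changes in both fractions
('&', "abundance") reflect ordinary expression regulation.

Significance in each fraction means |log2 fold change| >= `cutoff`
(default 0.35) together with a Benjamini-Hochberg-adjusted Welch t-test
p < `alpha` (default 0.05) on log2 CPM values; BH is applied separately
within the IP and within the total comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("abundance_concordant", "association_only", "total_only",
              "unchanged")


@dataclass
class CountTable:
    """Entities x samples integer counts plus per-sample metadata
    (fraction in {total, IP}, genotype in {WT, null}, treatment in
    {treated, vehicle}, replicate index)."""

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for: {sorted(missing)}")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")

    def select(self, **criteria) -> list[str]:
        """Sample ids matching all metadata criteria, e.g.
        ``select(fraction="IP", genotype="WT", treatment="treated")``."""
        mask = pd.Series(True, index=self.samples.index)
        for key, value in criteria.items():
            mask &= self.samples[key] == value
        return [s for s in self.counts.columns if mask.get(s, False)]


def normalize_log2cpm(counts: pd.DataFrame | CountTable,
                      pseudocount: float = 0.5) -> pd.DataFrame:
    """log2(counts per million + pseudocount), per sample."""
    mat = counts.counts if isinstance(counts, CountTable) else counts
    libsize = mat.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(
            f"zero library size in sample(s): {list(zero.index)}"
        )
    cpm = mat.div(libsize, axis=1) * 1e6
    return np.log2(cpm + pseudocount)


def log2_fold_change(matrix: pd.DataFrame, group_a: list[str],
                     group_b: list[str], welch: bool = True) -> pd.DataFrame:
    """Per-entity LFC = mean(A) - mean(B) on the log2 scale with a
    two-sided t-test p (Welch by default, Student when ``welch=False``).

    Degenerate rows where both groups have zero variance get p = 1 when
    the means agree and p = 0 otherwise.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = matrix[group_a].to_numpy(dtype=float)
    b = matrix[group_b].to_numpy(dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate, np.where(lfc == 0, 1.0, 0.0), p)
    return pd.DataFrame({"lfc": lfc, "pvalue": p}, index=matrix.index)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    Computed literally as adj_(i) = min_{j >= i} p_(j) * m / j clipped at
    1, so results agree bit-for-bit with the textbook definition.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def classify_mirnas(diff_ip: pd.DataFrame, diff_total: pd.DataFrame,
                    cutoff: float = 0.35,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Joint classification of each entity from its IP and total results.

    Inputs carry columns ``lfc`` and ``padj`` over an identical index.
    significant(x) := |lfc| >= cutoff and padj < alpha. Both significant
    with the same sign -> abundance_concordant; IP only ->
    association_only; total only -> total_only; neither -> unchanged.
    Both significant with opposite signs -> association_only (the IP
    direction governs) with ``opposite_sign`` flagged.
    """
    if not diff_ip.index.equals(diff_total.index):
        raise ValueError("IP and total results cover different entities")
    sig_ip = (diff_ip["lfc"].abs() >= cutoff) & (diff_ip["padj"] < alpha)
    sig_tot = (diff_total["lfc"].abs() >= cutoff) & (diff_total["padj"] < alpha)
    same_sign = np.sign(diff_ip["lfc"]) == np.sign(diff_total["lfc"])

    category = pd.Series("unchanged", index=diff_ip.index, dtype=object)
    category[sig_ip & ~sig_tot] = "association_only"
    category[~sig_ip & sig_tot] = "total_only"
    category[sig_ip & sig_tot & same_sign] = "abundance_concordant"
    opposite = sig_ip & sig_tot & ~same_sign
    category[opposite] = "association_only"

    direction = pd.Series("none", index=diff_ip.index, dtype=object)
    ip_driven = category.isin(["association_only", "abundance_concordant"])
    direction[ip_driven] = np.where(
        diff_ip.loc[ip_driven, "lfc"] > 0, "up", "down"
    )
    tot_driven = category == "total_only"
    direction[tot_driven] = np.where(
        diff_total.loc[tot_driven, "lfc"] > 0, "up", "down"
    )
    out = pd.DataFrame(
        {
            "lfc_ip": diff_ip["lfc"],
            "padj_ip": diff_ip["padj"],
            "lfc_total": diff_total["lfc"],
            "padj_total": diff_total["padj"],
            "category": category,
            "direction": direction,
            "opposite_sign": opposite,
        }
    )
    out.attrs["cutoff"] = cutoff
    out.attrs["alpha"] = alpha
    return out


def run_mirna_classification(
    table: CountTable,
    genotype: str = "WT",
    cutoff: float = 0.35,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    welch: bool = True,
) -> pd.DataFrame:
    """End-to-end driver: CPM-normalize, test treated vs vehicle within the
    IP and the total fraction of one genotype, BH-adjust within each
    fraction, and classify. Raw p-values are kept alongside the adjusted
    ones (columns ``pvalue_ip`` / ``pvalue_total``)."""
    log2cpm = normalize_log2cpm(table, pseudocount=pseudocount)
    results = {}
    for fraction in ("IP", "total"):
        treated = table.select(fraction=fraction, genotype=genotype,
                               treatment="treated")
        vehicle = table.select(fraction=fraction, genotype=genotype,
                               treatment="vehicle")
        diff = log2_fold_change(log2cpm, treated, vehicle, welch=welch)
        diff["padj"] = bh_adjust(diff["pvalue"])
        results[fraction] = diff
    out = classify_mirnas(results["IP"], results["total"],
                          cutoff=cutoff, alpha=alpha)
    out["pvalue_ip"] = results["IP"]["pvalue"]
    out["pvalue_total"] = results["total"]["pvalue"]
    return out


def classify_genes_replicate_intersection(
    ip_lfcs: pd.DataFrame, total_lfcs: pd.DataFrame, cutoff: float = 0.35
) -> pd.Series:
    """Gene-level rule: a gene is `more_bound` when every per-replicate IP
    LFC is >= cutoff while no total-RNA replicate LFC leaves (-cutoff,
    +cutoff); symmetric for `less_bound`; otherwise `none`.

    Both inputs are genes x replicates LFC matrices with identical indexes
    and at least 2 replicate columns each.
    """
    if ip_lfcs.shape[1] < 2 or total_lfcs.shape[1] < 2:
        raise ValueError("need at least 2 replicates per fraction")
    if not ip_lfcs.index.equals(total_lfcs.index):
        raise ValueError("IP and total gene universes differ")
    if ip_lfcs.isna().any().any() or total_lfcs.isna().any().any():
        raise ValueError("missing replicate LFC values")
    ip = ip_lfcs.to_numpy(dtype=float)
    tot = total_lfcs.to_numpy(dtype=float)
    total_flat = (np.abs(tot) < cutoff).all(axis=1)
    more = (ip >= cutoff).all(axis=1) & total_flat
    less = (ip <= -cutoff).all(axis=1) & total_flat
    out = pd.Series("none", index=ip_lfcs.index, dtype=object)
    out[more] = "more_bound"
    out[less] = "less_bound"
    return out


def seed_enrichment_test(
    selected: set[str] | list[str],
    universe: set[str] | list[str],
    sites_by_family: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric seed-match enrichment per miRNA family.

    For each family, with N = |universe|, K = genes in the universe with
    >= 1 site of that family, n = |selected| and k the sited genes among
    the selected, p = P[X >= k] for X ~ Hypergeom(N, K, n); BH-adjusted
    across families.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    rows = []
    for family in sorted(sites_by_family):
        with_site = sites_by_family[family] & universe
        K = len(with_site)
        k = len(with_site & selected)
        p = float(stats.hypergeom.sf(k - 1, len(universe), K, len(selected)))
        rows.append({"family": family, "n_selected_with_site": k,
                     "n_universe_with_site": K, "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("family")
    out["padj"] = bh_adjust(out["pvalue"])
    return out
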