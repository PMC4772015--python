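"""Chimera detection and characterization statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agonet.chimera import (
    ChimeraRead,
    chimeras_to_frame,
    compare_chimera_fractions,
    count_seed_matches,
    detect_chimeras,
    extend_target,
    extend_targets,
    kmer_complementarity_scan,
    last_nt_distribution,
    seed_mismatch_profile,
)
from agonet.mre import revcomp
from agonet.simdata import Transcriptome, make_seed_mismatch_targets

MIRNA = "TGAGGTAGTAGGTTGTATAGTT"  # let-7a-like, 22 nt


def tiny_transcriptome():
    rng = np.random.default_rng(99)
    seqs = {}
    for i in range(3):
        seqs[f"tx{i}"] = "".join(rng.choice(list("ACGT"), 300))
    # a 12-mer present exactly once, in tx0's "3'UTR"
    seqs["tx0"] = seqs["tx0"][:250] + "ACGTACGTTGCA" + seqs["tx0"][262:]
    regions = pd.DataFrame(
        [(f"tx{i}", r, s, e) for i in range(3)
         for r, s, e in (("5UTR", 0, 50), ("CDS", 50, 200), ("3UTR", 200, 300))],
        columns=["transcript_id", "region", "start", "end"],
    )
    return Transcriptome(sequences=seqs, regions=regions,
                         gene_map={f"tx{i}": f"g{i}" for i in range(3)})


class TestDetectChimeras:
    tr = tiny_transcriptome()
    mirnas = {"let7": MIRNA}

    def detect(self, sequences, **kwargs):
        reads = pd.DataFrame(
            {"read_id": [f"r{i}" for i in range(len(sequences))],
             "sequence": sequences}
        )
        return detect_chimeras(reads, self.mirnas, self.tr, **kwargs)

    def test_bare_mirna_is_short_remainder(self):
        found, log = self.detect([MIRNA])
        assert found == []
        assert log["reason"].tolist() == ["short_remainder"]

    def test_mirna_plus_unique_fragment_accepted(self):
        frag = self.tr.sequences["tx0"][250:262]
        found, log = self.detect([MIRNA + frag])
        assert len(found) == 1
        c = found[0]
        assert (c.mirna_id, c.orientation) == ("let7", "mirna_first")
        assert (c.transcript_id, c.target_start, c.target_end) == ("tx0", 250, 262)
        assert c.region == "3UTR"
        assert c.mirna_last_nt == MIRNA[-1]
        assert c.target_last_nt == frag[-1]

    def test_truncated_mirna_prefix_accepted(self):
        frag = self.tr.sequences["tx0"][250:262]
        found, _ = self.detect([MIRNA[:17] + frag])
        assert len(found) == 1
        assert found[0].mirna_part_len == 17

    def test_target_first_orientation(self):
        frag = self.tr.sequences["tx0"][250:262]
        found, _ = self.detect([frag + MIRNA])
        assert len(found) == 1
        assert found[0].orientation == "target_first"

    def test_ambiguous_target_rejected(self):
        shared = self.tr.sequences["tx1"][100:112]
        # plant the same 12-mer into a second transcript
        tr2 = Transcriptome(
            sequences={**self.tr.sequences,
                       "tx2": shared + self.tr.sequences["tx2"][12:]},
            regions=self.tr.regions, gene_map=self.tr.gene_map,
        )
        reads = pd.DataFrame({"read_id": ["r0"], "sequence": [MIRNA + shared]})
        found, log = detect_chimeras(reads, self.mirnas, tr2)
        assert found == []
        assert log["reason"].tolist() == ["ambiguous_target"]

    def test_ambiguous_mirna_rejected(self):
        frag = self.tr.sequences["tx0"][250:262]
        twins = {"mirA": MIRNA, "mirB": MIRNA[:18] + "CCCC"}
        reads = pd.DataFrame({"read_id": ["r0"],
                              "sequence": [MIRNA[:16] + frag]})
        found, log = detect_chimeras(reads, twins, self.tr)
        assert found == []
        assert log["reason"].tolist() == ["ambiguous_mirna"]

    def test_unmappable_remainder_labelled(self):
        found, log = self.detect([MIRNA + "TTTTTTTTTTTT"])
        assert log["reason"].tolist() == ["no_target"]

    def test_random_read_is_no_mirna(self):
        found, log = self.detect(["ACGT" * 10])
        assert log["reason"].tolist() == ["no_mirna"]

    def test_duplicate_read_ids_rejected(self):
        reads = pd.DataFrame({"read_id": ["r0", "r0"],
                              "sequence": [MIRNA, MIRNA]})
        with pytest.raises(ValueError):
            detect_chimeras(reads, self.mirnas, self.tr)


class TestExtendTarget:
    tr = tiny_transcriptome()

    def make(self, start, end):
        return ChimeraRead(
            read_id="r0", mirna_id="let7", mirna_part_len=22,
            orientation="mirna_first", transcript_id="tx0",
            target_start=start, target_end=end,
            target_seq=self.tr.sequences["tx0"][start:end],
        )

    def test_extension_takes_flanks(self):
        c = extend_target(self.make(100, 120), self.tr, ext=10)
        assert c.extended_seq == self.tr.sequences["tx0"][90:130]

    def test_boundary_clipping(self):
        c = extend_target(self.make(292, 300), self.tr, ext=10)
        assert c.extended_seq == self.tr.sequences["tx0"][282:300]

    def test_ext_zero_identity(self):
        c = extend_target(self.make(100, 120), self.tr, ext=0)
        assert c.extended_seq == c.target_seq
        assert c.control_seq == c.target_seq

    def test_control_reproducible_and_same_length(self):
        a = extend_target(self.make(100, 120), self.tr, ext=10,
                          rng=np.random.default_rng(5))
        b = extend_target(self.make(100, 120), self.tr, ext=10,
                          rng=np.random.default_rng(5))
        assert a.control_seq == b.control_seq
        assert len(a.control_seq) == len(a.extended_seq)
        assert a.control_seq[10:30] == a.target_seq


def make_chimera(target, mirna_id="let7", read_id="r0"):
    return ChimeraRead(
        read_id=read_id, mirna_id=mirna_id, mirna_part_len=22,
        orientation="mirna_first", transcript_id="tx0",
        target_start=0, target_end=len(target), target_seq=target,
        extended_seq=target,
        mirna_last_nt="G", target_last_nt=target[-1],
    )


class TestSeedMatchCounts:
    mirnas = {"let7": MIRNA}

    def test_longest_class_is_exclusive(self):
        # contains 7mer-m8 CTACCTC but not the 8mer (no trailing A)
        out = count_seed_matches(
            [make_chimera("GGG" + "CTACCTC" + "GGG")], self.mirnas,
            use_control=False,
        )
        assert out.loc["7mer-m8", "real"] == 1
        assert out["real"].drop("7mer-m8").sum() == 0

    def test_no_match_is_none_and_partition(self):
        chims = [make_chimera("G" * 20, read_id=f"r{i}") for i in range(3)]
        out = count_seed_matches(chims, self.mirnas, use_control=False)
        assert out.loc["none", "real"] == 3
        assert out["real"].sum() == len(chims)

    def test_unknown_mirna_rejected(self):
        with pytest.raises(KeyError):
            count_seed_matches([make_chimera("G" * 20, mirna_id="xx")],
                               self.mirnas, use_control=False)

    def test_random_sequence_hit_rate_matches_dp_oracle(self):
        """Frequency of >= 5mer seed matches in random sequences agrees
        with the exact occurrence probability from an automaton DP."""
        def occurrence_prob(pattern, length):
            # DP over a KMP automaton of the pattern, iid uniform letters
            k = len(pattern)
            fail = [0] * k
            for i in range(1, k):
                j = fail[i - 1]
                while j and pattern[i] != pattern[j]:
                    j = fail[j - 1]
                fail[i] = j + 1 if pattern[i] == pattern[j] else 0
            # transition[state][letter] -> next state
            probs = np.zeros(k + 1)
            probs[0] = 1.0
            for _ in range(length):
                nxt = np.zeros(k + 1)
                nxt[k] = probs[k]
                for state in range(k):
                    for letter in "ACGT":
                        s = state
                        while s and letter != pattern[s]:
                            s = fail[s - 1]
                        s = s + 1 if letter == pattern[s] else 0
                        nxt[s] += probs[state] * 0.25
                probs = nxt
            return probs[k]

        rng = np.random.default_rng(17)
        length, n = 30, 10_000
        mer5 = revcomp(MIRNA[1:6])
        p5 = occurrence_prob(mer5, length)
        chims = [
            make_chimera("".join(rng.choice(list("ACGT"), length)),
                         read_id=f"r{i}")
            for i in range(n)
        ]
        out = count_seed_matches(chims, self.mirnas, use_control=False)
        # all longer canonical classes contain the 5mer, so any non-none
        # class implies a 5mer occurrence
        hits = int(out["real"].drop("none").sum())
        lo, hi = stats.binom.interval(0.99, n, p5)
        assert lo <= hits <= hi


class TestKmerScan:
    mirnas = {"let7": MIRNA}

    def test_full_complement_hits_everywhere(self):
        c = make_chimera(revcomp(MIRNA))
        out = kmer_complementarity_scan([c], self.mirnas, k=4)
        assert (out["fraction"] == 1.0).all()
        assert out["position"].tolist() == list(range(1, len(MIRNA) - 3 + 1))

    def test_random_targets_flat_profile(self):
        rng = np.random.default_rng(3)
        chims = [
            make_chimera("".join(rng.choice(list("ACGT"), 30)),
                         read_id=f"r{i}")
            for i in range(400)
        ]
        out = kmer_complementarity_scan(chims, self.mirnas, k=4)
        # expected per-position hit rate ~ 27 windows * 4^-4 ~ 0.1
        assert out["fraction"].max() < 0.25
        assert out["fraction"].std() < 0.05

    def test_k_longer_than_mirna_rejected(self):
        with pytest.raises(ValueError):
            kmer_complementarity_scan([make_chimera("ACGTACGT")],
                                      {"let7": MIRNA}, k=30)


class TestLastNt:
    def test_empty_set(self):
        assert last_nt_distribution([]).empty

    def test_simple_fractions(self):
        chims = []
        for i, (m, t) in enumerate([("G", "G"), ("G", "G"), ("A", "A"),
                                    ("T", "T")]):
            c = make_chimera("ACGT", read_id=f"r{i}")
            c.mirna_last_nt, c.target_last_nt = m, t
            chims.append(c)
        out = last_nt_distribution(chims)
        assert out.loc["G", "mirna_part"] == pytest.approx(0.5)
        assert out["mirna_part"].sum() == pytest.approx(1.0)
        assert out["target_part"].sum() == pytest.approx(1.0)

    def test_planted_ligation_bias_recovered(self, chimera_rich_dataset):
        """The generator's G preference at the ligated target end is
        recoverable from the last-nucleotide distribution."""
        ds = chimera_rich_dataset
        found, _ = detect_chimeras(
            ds.raw_reads[["read_id", "sequence"]], ds.mirnas, ds.transcriptome
        )
        out = last_nt_distribution(found)
        g = out.loc["G", "target_part"]
        # G chosen with prob ~beta when available (almost always), else 1/4
        beta_hat = (g - 0.25) / (1 - 0.25)
        assert beta_hat == pytest.approx(ds.config.ligation_g_bias, abs=0.12)


class TestSeedMismatchProfile:
    mirnas = {"let7": MIRNA}

    def test_perfect_8mers_all_one(self):
        chims = [
            make_chimera("GGGG" + revcomp(MIRNA[:8]) + "GGGG",
                         read_id=f"r{i}")
            for i in range(5)
        ]
        prof = seed_mismatch_profile(chims, self.mirnas)
        assert prof == pytest.approx(np.ones(8))

    def test_planted_position_five_mismatches(self):
        site = list(revcomp(MIRNA[:8]))
        mismatched = site.copy()
        j = 8 - 5  # window position pairing seed position 5
        mismatched[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[j]]
        chims = []
        for i in range(10):
            target = "".join(site if i % 2 == 0 else mismatched)
            chims.append(make_chimera(target, read_id=f"r{i}"))
        prof = seed_mismatch_profile(chims, self.mirnas)
        expected = np.ones(8)
        expected[4] = 0.5
        assert prof == pytest.approx(expected)

    def test_best_window_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        ref = revcomp(MIRNA[:8])
        for _ in range(50):
            target = "".join(rng.choice(list("ACGT"), 30))
            prof = seed_mismatch_profile([make_chimera(target)], self.mirnas)
            best = min(
                range(len(target) - 7),
                key=lambda w: sum(
                    target[w + j] != ref[j] for j in range(8)
                ),
            )
            expected = np.array(
                [target[best + j] == ref[j] for j in range(8)][::-1], float
            )
            assert prof == pytest.approx(expected)

    def test_recovers_planted_rates(self):
        """Per-position pairing profile matches 1 - planted mismatch rate
        on generator-built targets."""
        rates = [0.0, 0.05, 0.0, 0.0, 0.3, 0.1, 0.0, 0.2]
        targets = make_seed_mismatch_targets(MIRNA, 1000, rates, seed=3)
        chims = [make_chimera(t, read_id=f"r{i}")
                 for i, t in enumerate(targets)]
        prof = seed_mismatch_profile(chims, self.mirnas)
        assert prof == pytest.approx(1 - np.array(rates), abs=0.05)


class TestCompareFractions:
    def test_identical_proportions_p_one(self):
        out = compare_chimera_fractions(
            {"m": 5}, {"m": 100}, {"m": 5}, {"m": 100}
        )
        assert out.loc["m", "pvalue"] == pytest.approx(1.0)

    def test_extreme_table_exact_value(self):
        out = compare_chimera_fractions({"m": 0}, {"m": 10},
                                        {"m": 10}, {"m": 10})
        assert out.loc["m", "pvalue"] == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9
        )

    def test_matches_hypergeometric_summation_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            ta, tb = int(rng.integers(1, 30)), int(rng.integers(1, 30))
            ca, cb = int(rng.integers(0, ta + 1)), int(rng.integers(0, tb + 1))
            out = compare_chimera_fractions({"m": ca}, {"m": ta},
                                            {"m": cb}, {"m": tb})
            # sum all hypergeometric outcomes at most as likely as observed
            K, n, N = ca + cb, ta, ta + tb
            support = range(max(0, K - tb), min(K, ta) + 1)
            pmf = {a: stats.hypergeom.pmf(a, N, K, n) for a in support}
            p = sum(v for v in pmf.values() if v <= pmf[ca] * (1 + 1e-9))
            assert out.loc["m", "pvalue"] == pytest.approx(p, abs=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            compare_chimera_fractions({"m": 11}, {"m": 10},
                                      {"m": 0}, {"m": 10})


def test_simulated_chimera_set_properties(chimera_rich_dataset):
    """End-to-end on the generator: detection recovers planted chimeras,
    the scan peaks at seed position 2, and target regions are
    3'UTR-dominated as planted."""
    ds = chimera_rich_dataset
    found, _ = detect_chimeras(
        ds.raw_reads[["read_id", "sequence"]], ds.mirnas, ds.transcriptome
    )
    truth = ds.raw_reads.set_index("read_id")
    det = {c.read_id for c in found}
    planted = set(truth.index[truth["true_class"] == "chimera"])
    assert len(det & planted) / len(planted) >= 0.95
    assert len(det & planted) / len(det) >= 0.95
    for c in found:
        assert truth.loc[c.read_id, "mirna_id"] == c.mirna_id

    found = extend_targets(found, ds.transcriptome, ext=10, seed=0)
    scan = kmer_complementarity_scan(found, ds.mirnas, k=4)
    assert scan.loc[scan["fraction"].idxmax(), "position"] == 2

    regions = pd.Series([c.region for c in found]).value_counts()
    assert regions.idxmax() == "3UTR"

    counts = count_seed_matches(found, ds.mirnas)
    assert counts["real"].sum() == len(found)
    frame = chimeras_to_frame(found)
    assert len(frame) == len(found)
    assert set(frame["seed_class"]) <= {"8mer", "7mer-m8", "7mer-A1", "6mer",
                                        "5mer", "none"}
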