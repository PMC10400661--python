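"""Filter/trim, dereplication, denoising, pairing and chimera removal."""

import itertools

import numpy as np
import pandas as pd
import pytest

from amplikit import asv_pipeline as ap
from amplikit import insilico_pcr as ip
from amplikit import read_sim
from amplikit.primer_model import revcomp


def _read(seq, q=30, title="r"):
    return (title, seq, chr(33 + q) * len(seq))


class TestExpectedErrors:
    @pytest.mark.parametrize(
        "qual,expected",
        [
            (chr(33 + 20) * 150, 1.5),
            (chr(33 + 15) * 150, 150 * 10 ** -1.5),
            ("", 0.0),
        ],
    )
    def test_closed_form(self, qual, expected):
        assert ap.expected_errors(qual) == pytest.approx(expected)

    def test_rejects_sub_phred33(self):
        with pytest.raises(ValueError):
            ap.expected_errors(" \x1f")


class TestFilterAndTrim:
    def test_clean_reads_kept_and_truncated(self):
        reads = [_read("A" * 150, q=30, title=f"r{i}/1") for i in range(5)]
        mates = [_read("C" * 150, q=30, title=f"r{i}/2") for i in range(5)]
        out1, out2, counts = ap.filter_and_trim(reads, mates)
        assert counts == {"in": 5, "kept": 5, "dropped": 0}
        assert all(len(r[1]) == 140 for r in out1 + out2)

    def test_ambiguous_base_drops_pair(self):
        r1 = [_read("A" * 100, title="r0/1")]
        r2 = [_read("C" * 50 + "N" + "C" * 49, title="r0/2")]
        _, _, counts = ap.filter_and_trim(r1, r2)
        assert counts["kept"] == 0

    def test_high_expected_errors_drop_pair(self):
        r1 = [_read("A" * 150, q=15, title="r0/1")]  # EE ~ 4.7 > 2
        r2 = [_read("C" * 150, q=30, title="r0/2")]
        _, _, counts = ap.filter_and_trim(r1, r2)
        assert counts["kept"] == 0

    def test_count_conservation_on_simulated_input(self, community_v12m):
        reads1 = community_v12m["reads1"]
        reads2 = community_v12m["reads2"]
        _, _, counts = ap.filter_and_trim(reads1, reads2)
        assert counts["kept"] + counts["dropped"] == counts["in"]


class TestDereplicate:
    def test_small_case(self):
        out = ap.dereplicate(["AA", "AA", "AC"])
        assert [(s, a) for s, a, _ in out] == [("AA", 2), ("AC", 1)]

    def test_all_distinct(self):
        out = ap.dereplicate(["AA", "CC", "GG"])
        assert all(a == 1 for _, a, _ in out)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(8)
        seqs = [
            "".join(rng.choice(list("ACGT"), size=5)) for _ in range(300)
        ]
        out = ap.dereplicate(seqs)
        from collections import Counter

        oracle = Counter(seqs)
        assert {s: a for s, a, _ in out} == dict(oracle)
        assert sum(a for _, a, _ in out) == len(seqs)
        abundances = [a for _, a, _ in out]
        assert abundances == sorted(abundances, reverse=True)

    def test_mean_quality_averaged(self):
        reads = [("a", "AC", "!I"), ("b", "AC", "I!")]
        out = ap.dereplicate(reads)
        assert np.allclose(out[0][2], [20.0, 20.0])


class TestDenoise:
    def test_singleton_error_cloud_absorbed(self):
        center = "ACGTACGTACGT"
        variants = []
        for i in range(12):
            for b in "ACGT":
                if b != center[i]:
                    variants.append(center[:i] + b + center[i + 1 :])
        uniques = [(center, 1000)] + [(v, 1) for v in variants[:30]]
        result, mapping = ap.denoise(uniques)
        assert result == [(center, 1030)]
        assert all(mapping[v] == center for v in variants[:30])

    def test_distant_comparable_sequences_stay_separate(self):
        a = "AAAAAAAAAA"
        b = "AAAATTTAAA"  # 3 mismatches from a
        result, _ = ap.denoise([(a, 100), (b, 80)])
        assert len(result) == 2

    def test_d_max_zero_is_identity(self):
        uniques = [("AAAA", 10), ("AAAT", 1)]
        result, mapping = ap.denoise(uniques, d_max=0)
        assert result == [("AAAA", 10), ("AAAT", 1)]
        assert mapping == {"AAAA": "AAAA", "AAAT": "AAAT"}

    def test_min_abundance_discards_orphan_singletons(self):
        uniques = [("AAAAAAAA", 100), ("TTTTAAAA", 1)]  # d=4 > d_max
        result, mapping = ap.denoise(uniques, min_abundance=2)
        assert result == [("AAAAAAAA", 100)]
        assert "TTTTAAAA" not in mapping

    def test_abundance_skew_threshold_respected(self):
        a = "AAAAAAAAAA"
        b = "AAAAAAAAAT"  # d=1; absorption needs ab(b) <= ab(a)/4
        result, _ = ap.denoise([(a, 100), (b, 30)])
        assert len(result) == 2
        result, _ = ap.denoise([(a, 100), (b, 25)])
        assert len(result) == 1 and result[0][1] == 125


class TestMergeOrConcat:
    def test_v4_like_overlap_merges(self):
        rng = np.random.default_rng(9)
        amplicon = "".join(rng.choice(list("ACGT"), size=253))
        r1, r2 = amplicon[:150], revcomp(amplicon)[:150]
        seq, construction = ap.merge_or_concat(r1, r2)
        assert construction == "merged"
        assert seq == amplicon

    def test_v12_like_no_overlap_concatenates(self):
        rng = np.random.default_rng(10)
        amplicon = "".join(rng.choice(list("ACGT"), size=290))
        r1, r2 = amplicon[:150], revcomp(amplicon)[:150]
        seq, construction = ap.merge_or_concat(r1, r2)
        assert construction == "concatenated"
        assert len(seq) == 150 + 10 + 150
        assert seq == r1 + "N" * 10 + revcomp(r2)
        runs = [r for r in seq.split("A") if set(r) == {"N"}]
        assert "N" * 10 in seq and "N" * 11 not in seq

    def test_mismatched_overlap_falls_back_to_concat(self):
        rng = np.random.default_rng(11)
        amplicon = "".join(rng.choice(list("ACGT"), size=253))
        r1 = amplicon[:150]
        corrupted = list(amplicon)
        # corrupt inside the expected overlap window (positions 103..149)
        for pos in (110, 120, 130):
            corrupted[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[
                corrupted[pos]
            ]
        r2 = revcomp("".join(corrupted))[:150]
        _, construction = ap.merge_or_concat(r1, r2, max_overlap_mismatch=0)
        assert construction == "concatenated"

    def test_quality_resolves_overlap_conflicts(self):
        rng = np.random.default_rng(13)
        amplicon = "".join(rng.choice(list("ACGT"), size=20))
        r1 = amplicon[:14]
        r2_seq = revcomp(amplicon)[:14]
        # corrupt one overlap base in read1; read2 has higher quality there
        r1 = r1[:10] + "A" + r1[11:]
        assert amplicon[10] != "A"
        q1 = np.full(14, 10.0)
        q2 = np.full(14, 35.0)
        seq, construction = ap.merge_or_concat(
            r1, r2_seq, q1, q2, min_overlap=6, max_overlap_mismatch=1
        )
        assert construction == "merged"
        assert seq == amplicon


def brute_force_bimeras(counts: pd.DataFrame, seqs: dict) -> set:
    """Oracle: exhaustive parent-pair x split-point evaluation per sample."""
    flagged = set()
    for asv in counts.index:
        a_seq = seqs[asv]
        present = [s for s in counts.columns if counts.at[asv, s] > 0]
        votes = 0
        for sample in present:
            hit = False
            for p1, p2 in itertools.permutations(counts.index, 2):
                if p1 == asv or p2 == asv:
                    continue
                if (
                    counts.at[p1, sample] < 2 * counts.at[asv, sample]
                    or counts.at[p2, sample] < 2 * counts.at[asv, sample]
                ):
                    continue
                for split in range(1, len(a_seq)):
                    if seqs[p1].startswith(a_seq[:split]) and seqs[
                        p2
                    ].endswith(a_seq[split:]):
                        hit = True
                        break
                if hit:
                    break
            if hit:
                votes += 1
        if present and votes > len(present) / 2:
            flagged.add(asv)
    return flagged


class TestRemoveBimeras:
    def _table(self, rows):
        counts = pd.DataFrame(
            {k: v["counts"] for k, v in rows.items()}
        ).T
        counts.columns = [f"s{i}" for i in range(counts.shape[1])]
        meta = pd.DataFrame(
            {
                "sequence": {k: v["seq"] for k, v in rows.items()},
                "construction": "merged",
            }
        )
        return ap.ASVTable(counts, meta)

    def test_constructed_bimera_flagged_parents_not(self):
        p1 = "AAAACCCCGGGG"
        p2 = "TTTTGGGGAAAA"
        chimera = p1[:6] + p2[6:]
        table = self._table(
            {
                "A1": {"seq": p1, "counts": [500]},
                "A2": {"seq": p2, "counts": [400]},
                "A3": {"seq": chimera, "counts": [20]},
            }
        )
        out = ap.remove_bimeras(table)
        assert out.meta.loc["A3", "chimera"]
        assert not out.meta.loc["A1", "chimera"]
        assert not out.meta.loc["A2", "chimera"]

    def test_low_parent_abundance_not_flagged(self):
        p1 = "AAAACCCCGGGG"
        p2 = "TTTTGGGGAAAA"
        chimera = p1[:6] + p2[6:]
        table = self._table(
            {
                "A1": {"seq": p1, "counts": [30]},
                "A2": {"seq": p2, "counts": [30]},
                "A3": {"seq": chimera, "counts": [20]},
            }
        )
        out = ap.remove_bimeras(table)
        assert not out.meta["chimera"].any()

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(12)
        for trial in range(8):
            n = int(rng.integers(4, 12))
            parents = [
                "".join(rng.choice(list("ACGT"), size=30)) for _ in range(n)
            ]
            seqs = {}
            counts = {}
            for i, p in enumerate(parents):
                seqs[f"P{i}"] = p
                counts[f"P{i}"] = list(rng.integers(50, 500, size=3))
            # add a few candidate chimeras of random parent pairs
            for j in range(3):
                i1, i2 = rng.choice(n, size=2, replace=False)
                split = int(rng.integers(5, 25))
                seqs[f"C{j}"] = parents[i1][:split] + parents[i2][split:]
                counts[f"C{j}"] = list(rng.integers(0, 40, size=3))
            counts_df = pd.DataFrame(counts).T
            counts_df.columns = ["s0", "s1", "s2"]
            meta = pd.DataFrame(
                {"sequence": seqs, "construction": "merged"}
            )
            table = ap.ASVTable(counts_df, meta)
            out = ap.remove_bimeras(table)
            got = set(out.meta.index[out.meta["chimera"]])
            assert got == brute_force_bimeras(counts_df, seqs)


class TestRemoveContaminants:
    def _table(self):
        counts = pd.DataFrame(
            {
                "s1": [10, 5, 0],
                "s2": [8, 0, 3],
                "ctrl1": [0, 4, 0],
                "ctrl2": [0, 5, 0],
            },
            index=["A1", "A2", "A3"],
        )
        meta = pd.DataFrame(
            {
                "sequence": ["ACGT" * 10, "TGCA" * 10, "GGCC" * 10],
                "construction": "merged",
            },
            index=["A1", "A2", "A3"],
        )
        return ap.ASVTable(counts, meta)

    def test_signature_genus_flagged(self):
        table = self._table()
        tax = {"A1": "d__B;p__P;c__C;o__O;f__F;g__Ralstonia;s__x",
               "A2": "g__Good", "A3": "g__Fine"}
        out = ap.remove_contaminants(table, tax, ["Ralstonia"], [])
        assert list(out.meta["contaminant"]) == [True, False, False]

    def test_control_prevalence_rule(self):
        table = self._table()
        tax = {"A1": "g__X", "A2": "g__Y", "A3": "g__Z"}
        out = ap.remove_contaminants(
            table, tax, [], negative_controls=["ctrl1", "ctrl2"]
        )
        # A2: in 2/2 controls, 1/2 samples -> flagged; A3 absent in controls
        assert list(out.meta["contaminant"]) == [False, True, False]

    def test_empty_rules_are_identity(self):
        table = self._table()
        out = ap.remove_contaminants(table, {}, [], [])
        assert not out.meta["contaminant"].any()

    def test_packaged_signature_list_loads(self):
        signatures = ap.load_contaminant_signatures()
        assert "Ralstonia" in signatures and len(signatures) > 5


class TestPipelineEndToEnd:
    def test_recovers_planted_community(self, v12m, toy_refs_v12m, community_v12m):
        table, summary = ap.run_pipeline(
            {"s1": (community_v12m["reads1"], community_v12m["reads2"])}
        )
        unflagged = table.unflagged()
        planted = set()
        for spec in community_v12m["taxa"]:
            amp = ip.predict_amplicons(v12m, spec.sequence)[0]
            s = spec.sequence[amp.fwd_site.start : amp.rev_site.end]
            seq, _ = ap.merge_or_concat(s[:140], revcomp(s)[:140])
            planted.add(seq)
        assert set(unflagged.sequences) == planted
        rel = unflagged.counts["s1"] / unflagged.counts["s1"].sum()
        expected = np.sort(community_v12m["abundances"])
        assert np.max(np.abs(np.sort(rel.to_numpy()) - expected)) < 0.02

    def test_concatenation_path_and_spacer_invariant(self, community_v12m):
        table, _ = ap.run_pipeline(
            {"s1": (community_v12m["reads1"], community_v12m["reads2"])}
        )
        assert (table.meta["construction"] == "concatenated").all()
        for seq in table.sequences:
            assert seq.count("N" * 10) == 1 and "N" * 11 not in seq

    def test_deterministic_tables(self, community_v12m):
        args = {"s1": (community_v12m["reads1"], community_v12m["reads2"])}
        t1, _ = ap.run_pipeline(args)
        t2, _ = ap.run_pipeline(args)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        pd.testing.assert_frame_equal(t1.meta, t2.meta)

    def test_tsv_roundtrip(self, community_v12m, tmp_path):
        table, _ = ap.run_pipeline(
            {"s1": (community_v12m["reads1"], community_v12m["reads2"])}
        )
        table.to_tsv(tmp_path / "counts.tsv", tmp_path / "meta.tsv")
        counts = pd.read_csv(tmp_path / "counts.tsv", sep="\t", index_col=0)
        assert counts["s1"].sum() == table.counts["s1"].sum()
        meta = pd.read_csv(tmp_path / "meta.tsv", sep="\t", index_col=0)
        assert list(meta["sequence"]) == table.sequences
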