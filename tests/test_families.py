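import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepfam.families import (
    align_family,
    assign_product,
    build_family,
    build_profile,
    call_families,
    default_background,
    gathering_cutoff,
    score_profile,
)
from pepfam.io import Msa, ProteinRecord
from pepfam.mcl import Clustering

from .oracles import profile_score_oracle


def _clustering(groups):
    assignment = {}
    for cid, members in enumerate(groups):
        for m in members:
            assignment[m] = cid
    return Clustering(assignment=assignment)


class TestCallFamilies:
    def test_size_threshold_and_reporting(self):
        groups = [
            [f"a{i}" for i in range(6)],
            [f"b{i}" for i in range(5)],
            [f"c{i}" for i in range(4)],
            ["solo"],
        ]
        report = call_families(_clustering(groups))
        assert [len(f) for f in report.families] == [6, 5]
        assert len(report.small_clusters) == 1
        assert report.singletons == ["solo"]

    def test_exactly_five_is_a_family(self):
        report = call_families(_clustering([[f"m{i}" for i in range(5)]]))
        assert len(report.families) == 1

    def test_empty_clustering(self):
        report = call_families(_clustering([]))
        assert report.families == [] and report.singletons == []


class TestAlignFamily:
    def test_identical_sequences_gapless(self, scheme):
        members = [ProteinRecord(f"p{i}", "MKRWLVTAEG") for i in range(5)]
        msa = align_family(members, scheme)
        assert set(msa.rows) == {"MKRWLVTAEG"}

    def test_indel_pair_round_trip(self, scheme):
        members = [ProteinRecord("a", "MKKR"), ProteinRecord("b", "MKR")]
        msa = align_family(members, scheme)
        by_id = dict(zip(msa.ids, msa.rows))
        assert by_id["a"].replace("-", "") == "MKKR"
        assert by_id["b"].replace("-", "") == "MKR"
        assert "-" in by_id["b"]

    def test_rows_ungap_to_members(self, scheme, rng):
        base = "MKRWLVTAEGDNQS"
        members = []
        for i in range(6):
            seq = list(base)
            pos = int(rng.integers(0, len(base)))
            seq[pos] = "A"
            if i % 2:
                del seq[3]
            members.append(ProteinRecord(f"p{i}", "".join(seq)))
        msa = align_family(members, scheme)
        originals = {m.id: m.sequence for m in members}
        for idx, rid in enumerate(msa.ids):
            assert msa.ungapped(idx) == originals[rid]

    def test_center_has_max_summed_score(self, scheme):
        from pepfam.scoring import local_align

        members = [
            ProteinRecord("a", "MKRWLVTAEG"),
            ProteinRecord("b", "MKRWLVTAEG"),
            ProteinRecord("c", "MKRWLVTADG"),
            ProteinRecord("d", "WWPPGGHHCC"),
        ]
        msa = align_family(members, scheme)
        center_id = msa.ids[0]
        sums = {}
        for m in members:
            sums[m.id] = sum(
                local_align(m, o, scheme).bit_score for o in members if o.id != m.id
            )
        assert sums[center_id] == max(sums.values())

    def test_needs_two_sequences(self, scheme):
        with pytest.raises(ValueError):
            align_family([ProteinRecord("a", "MKR")], scheme)


class TestBuildProfile:
    def test_unanimous_columns_peak_at_consensus(self):
        msa = Msa(ids=("a", "b", "c"), rows=("MKW", "MKW", "MKW"))
        profile = build_profile(msa)
        from pepfam.families import _RES_INDEX

        for k, consensus in enumerate("MKW"):
            assert int(np.argmax(profile.match_logodds[k])) == _RES_INDEX[consensus]

    def test_majority_gap_column_not_match(self):
        rows = ("MKW", "M-W", "M-W", "M-W", "M-W")
        profile = build_profile(Msa(ids=tuple("abcde"), rows=rows))
        assert profile.match_columns == (0, 2)

    def test_emissions_normalized(self):
        msa = Msa(ids=("a", "b"), rows=("MKW", "MRW"))
        profile = build_profile(msa)
        assert np.allclose(profile.match_probs.sum(axis=1), 1.0, atol=1e-9)

    def test_transitions_normalized_per_state(self):
        msa = Msa(ids=("a", "b", "c"), rows=("MK-W", "MKAW", "M-AW"))
        t = build_profile(msa).transitions
        assert t["MM"] + t["MI"] + t["MD"] == pytest.approx(1.0)
        assert t["IM"] + t["II"] == pytest.approx(1.0)
        assert t["DM"] + t["DD"] == pytest.approx(1.0)

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_profile(Msa(ids=("a", "b"), rows=("-", "-")))


class TestScoreProfile:
    def _profile(self, rows):
        return build_profile(Msa(ids=tuple(f"r{i}" for i in range(len(rows))), rows=tuple(rows)))

    def test_consensus_beats_substitution(self):
        profile = self._profile(["MKWR"] * 5)
        assert score_profile(profile, "MKWR") >= score_profile(profile, "MKWA")

    def test_matches_exhaustive_path_oracle(self, rng):
        alphabet = "ACDE"
        for _ in range(60):
            n_rows = int(rng.integers(2, 5))
            n_cols = int(rng.integers(1, 5))
            rows = []
            for _ in range(n_rows):
                row = "".join(
                    rng.choice(list(alphabet + "-"), size=n_cols, p=[0.22, 0.22, 0.22, 0.22, 0.12])
                )
                rows.append(row)
            if all(set(r) == {"-"} for r in rows):
                continue
            try:
                profile = self._profile(rows)
            except ValueError:
                continue
            query = "".join(rng.choice(list(alphabet), size=rng.integers(1, 6)))
            got = score_profile(profile, query)
            expect = profile_score_oracle(profile, query)
            assert got == pytest.approx(expect, abs=1e-9), (rows, query)

    def test_length_one_query_finite(self):
        profile = self._profile(["MKWR"] * 3)
        assert np.isfinite(score_profile(profile, "A"))


class TestGatheringCutoff:
    def test_min_member_score(self):
        profile = build_profile(Msa(ids=tuple("abcde"), rows=("MKWR",) * 5))
        members = ["MKWR", "MKWA", "AKWR"]
        ga = gathering_cutoff(profile, members)
        scores = [score_profile(profile, m) for m in members]
        assert ga == min(scores)
        assert all(s >= ga for s in scores)

    def test_decoys_score_below_cutoff(self, scheme, rng):
        """Random same-length decoys rarely reach a family's gathering cutoff."""
        root = "MKRWLVTAEGDNQSHPYFCA"
        members = []
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        for i in range(8):
            seq = list(root)
            for pos in rng.choice(len(root), size=3, replace=False):
                seq[pos] = residues[int(rng.integers(0, 20))]
            members.append(ProteinRecord(f"m{i}", "".join(seq)))
        fam = build_family("F1", members, scheme)
        hits = 0
        trials = 100
        for _ in range(trials):
            decoy = "".join(rng.choice(residues, size=len(root)))
            if score_profile(fam.profile, decoy) >= fam.gathering_cutoff:
                hits += 1
        assert hits / trials <= 0.05


class TestAssignProduct:
    def test_plurality_after_discarding_uninformative(self):
        labels = ["DUF1127 family protein"] * 3 + ["hypothetical protein"] * 2
        assert assign_product(labels) == "DUF1127 family protein"

    def test_exact_tie_no_assignment(self):
        assert assign_product(["A protein"] * 2 + ["B protein"] * 2) is None

    def test_all_uninformative_no_assignment(self):
        assert assign_product(["hypothetical protein"] * 5) is None
        assert assign_product([None, "", "uncharacterized protein"]) is None

    def test_case_and_whitespace_insensitive_counting(self):
        labels = ["Cold-shock  protein", "cold-shock protein", "other protein"]
        assert assign_product(labels) == "Cold-shock protein"

    @given(st.permutations(["toxin A"] * 3 + ["antitoxin B"] * 2 + ["hypothetical protein"] * 2))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariant(self, labels):
        assert assign_product(labels) == "toxin A"


class TestFamilyContracts:
    def test_family_invariants(self, scheme, rng):
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        root = "".join(rng.choice(residues, size=24))
        members = []
        for i in range(6):
            seq = list(root)
            for pos in rng.choice(len(root), size=2, replace=False):
                seq[pos] = residues[int(rng.integers(0, 20))]
            members.append(
                ProteinRecord(f"m{i}", "".join(seq), product="widget protein")
            )
        fam = build_family("F1", members, scheme)
        assert len(fam.member_ids) >= 5
        for m in members:
            assert score_profile(fam.profile, m) >= fam.gathering_cutoff
        originals = {m.id: m.sequence for m in members}
        for idx, rid in enumerate(fam.msa.ids):
            assert fam.msa.ungapped(idx) == originals[rid]
        assert fam.product == "widget protein"
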