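import itertools

import numpy as np
import pytest

from premirna.encoding import EncodedStructure, encode
from premirna.folding import DotBracket
from premirna.profiles import (
    GAP_SCORE,
    MATCH,
    MISMATCH,
    ProfileError,
    ProfileLibrary,
    StructuralProfile,
    _nw,
    anchored_align,
    build_library,
    build_profile,
    cluster,
    progressive_msa,
    scan,
)


def _enc(text: str, mature: tuple[int, int], sid: str = "x") -> EncodedStructure:
    return EncodedStructure(text, mature, sid)


class TestAnchoredAlign:
    def test_identical_encodings(self):
        a = _enc("LLLMMOONNRRR", (3, 9))
        aln = anchored_align(a, a)
        assert aln.identity == 1.0
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_single_substitution_identity(self):
        # brute-force check over every gap placement: with match +1,
        # mismatch 0, gap -1, the ungapped alignment of equal-length
        # strings is optimal, so identity = 3/4
        a = _enc("MMMM", (0, 4))
        b = _enc("MMOM", (0, 4))
        aln = anchored_align(a, b)
        best = max(
            sum(1 for x, y in zip("MMMM", p) if x == y)
            for p in itertools.permutations("MMOM")
        )  # any gapped variant has <= 3 matches and pays gaps
        assert aln.identity == pytest.approx(best / 4) == 0.75

    def test_disjoint_flank_alphabets_do_not_match(self):
        a = _enc("LLLMM", (3, 5))
        b = _enc("RRRMM", (3, 5))
        aln = anchored_align(a, b)
        left_cols = [
            (x, y) for x, y in zip(aln.aligned_a, aln.aligned_b)
            if {x, y} <= set("LDR-")
        ]
        assert all(x != y for x, y in left_cols if "-" not in (x, y))

    def test_no_column_mixes_mature_and_flank(self):
        a = _enc("LLDDMMOONNRR", (4, 10))
        b = _enc("DMMONNRRRRRR", (1, 6))
        aln = anchored_align(a, b)
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if "-" in (x, y):
                continue
            assert (x in "MON") == (y in "MON")

    def test_nw_scores_respect_scheme(self):
        a, b = _nw("MON", "MN")
        score = sum(
            GAP_SCORE if "-" in (x, y) else (MATCH if x == y else MISMATCH)
            for x, y in zip(a, b)
        )
        assert score == 2 * MATCH + GAP_SCORE


class TestCluster:
    def test_identical_inputs_form_one_cluster(self):
        encs = [_enc("MMOONN", (0, 6), f"s{i}") for i in range(4)]
        assert len(cluster(encs)) == 1

    def test_dissimilar_inputs_stay_singletons(self):
        encs = [
            _enc("MMMMMM", (0, 6), "a"),
            _enc("OOOOOO", (0, 6), "b"),
            _enc("NNNNNN", (0, 6), "c"),
        ]
        assert len(cluster(encs)) == 3

    def test_single_linkage_chains(self):
        # a~b and b~c at >= 0.8 but a~c below: one chained cluster
        a = _enc("MMMMMMMMMM", (0, 10), "a")
        b = _enc("MMMMMMMMOO", (0, 10), "b")  # 0.8 to a
        c = _enc("MMMMMMOOOO", (0, 10), "c")  # 0.8 to b, 0.6 to a
        assert anchored_align(a, b).identity >= 0.8
        assert anchored_align(b, c).identity >= 0.8
        assert anchored_align(a, c).identity < 0.8
        (only,) = cluster([a, b, c])
        assert {e.source_id for e in only} == {"a", "b", "c"}

    def test_permutation_invariance(self, rng):
        encs = [
            _enc("".join(rng.choice(list("MON"), 12)), (0, 12), f"s{i}")
            for i in range(8)
        ]
        ref = [{e.source_id for e in c} for c in cluster(encs)]
        for _ in range(3):
            perm = [encs[i] for i in rng.permutation(len(encs))]
            got = [{e.source_id for e in c} for c in cluster(perm)]
            assert got == ref


class TestProgressiveMsa:
    def test_singleton(self):
        m = _enc("LLMMONRR", (2, 6), "solo")
        msa = progressive_msa([m])
        assert msa.row(0) == "LLMMONRR" and msa.anchor == 2

    def test_identical_pair_has_no_gaps(self):
        a = _enc("LLMMONRR", (2, 6), "a")
        b = _enc("LLMMONRR", (2, 6), "b")
        msa = progressive_msa([a, b])
        assert msa.row(0) == msa.row(1) == "LLMMONRR"

    def test_anchor_column_shared_across_rows(self):
        members = [
            _enc("LLLMMOONNRR", (3, 9), "a"),
            _enc("LMMOONNRRRR", (1, 7), "b"),
            _enc("LLLLMMONNDR".replace("D", "R"), (4, 9), "c"),
        ]
        msa = progressive_msa(members)
        anchor = msa.anchor
        for i in range(3):
            row = msa.row(i)
            # first mature-state character of every row sits at the anchor
            first_mature = min(
                row.index(ch) for ch in "MON" if ch in row
            )
            assert first_mature >= anchor
            assert set(row[:anchor]) <= set("LDR-")


class TestBuildProfile:
    def test_single_member_is_one_hot(self):
        msa = progressive_msa([_enc("LLMMONRR", (2, 6), "a")])
        prof = build_profile(msa)
        assert len(prof) == 8
        assert np.all(np.sort(prof.probs, axis=1)[:, -1] == 1.0)

    def test_disagreement_column_splits_mass(self):
        a = _enc("MMMM", (0, 4), "a")
        b = _enc("MMOM", (0, 4), "b")
        prof = build_profile(progressive_msa([a, b]))
        col = prof.probs[2]
        assert sorted(col[col > 0]) == [0.5, 0.5]

    def test_intersection_trimming_uses_shortest_flank(self):
        a = _enc("L" * 10 + "MMMM", (10, 14), "a")
        b = _enc("L" * 14 + "MMMM", (14, 18), "b")
        prof = build_profile(progressive_msa([a, b]))
        assert prof.anchor == 10  # profile extends 10 left of the anchor
        assert len(prof) == 14

    def test_columns_sum_to_one(self, positives):
        from premirna.pipeline import library_from_positives

        lib = library_from_positives(positives[:10])
        for prof in lib.profiles:
            assert np.allclose(prof.probs.sum(axis=1), 1.0, atol=1e-9)


class TestScan:
    def _one_hot_profile(self, db: str, mature=(0, 4)) -> StructuralProfile:
        enc = encode(db, mature, "self")
        return build_profile(progressive_msa([enc]))

    def test_self_match_scores_one(self):
        db = "((((....))))"
        lib = ProfileLibrary([self._one_hot_profile(db)])
        assert scan(lib, DotBracket(db)) == pytest.approx(1.0)

    def test_all_dot_candidate_vs_paired_profile_scores_zero(self):
        lib = ProfileLibrary([self._one_hot_profile("((((", (0, 4))])
        assert scan(lib, "......") == pytest.approx(0.0)

    def test_matches_exhaustive_window_oracle(self):
        cand = "..((((...))))..."
        p1 = self._one_hot_profile("((((", (0, 4))
        p2 = self._one_hot_profile("(((...)))", (0, 4))
        lib = ProfileLibrary([p1, p2])
        # oracle: enumerate every placement of each collapsed profile
        def brute(profile, s):
            C = profile.collapsed()
            L = len(profile)
            idx = {"(": 0, ".": 1, ")": 2}
            best = -1.0
            for off in range(len(s) - L + 1):
                vals = [C[k, idx[s[off + k]]] for k in range(L)]
                best = max(best, sum(vals) / L)
            return best

        expected = max(brute(p1, cand), brute(p2, cand))
        assert scan(lib, cand) == pytest.approx(expected)

    def test_score_bounds_and_max_monotonicity(self, library, negatives):
        for item in negatives[:10]:
            s = scan(library, item.candidate.structure)
            assert 0.0 <= s <= 1.0
            bigger = ProfileLibrary(
                library.profiles + [self._one_hot_profile("((((", (0, 4))]
            )
            assert scan(bigger, item.candidate.structure) >= s

    def test_oversized_profiles_are_skipped_or_error(self):
        long_profile = self._one_hot_profile("(" * 30, (0, 30))
        lib = ProfileLibrary([long_profile])
        with pytest.raises(ProfileError):
            scan(lib, "....")  # every profile longer than the candidate


def test_library_json_round_trip(tmp_path, library):
    path = tmp_path / "lib.json"
    library.to_json(path)
    back = ProfileLibrary.from_json(path)
    assert len(back) == len(library)
    for a, b in zip(library.profiles, back.profiles):
        assert np.allclose(a.probs, b.probs)
        assert a.anchor == b.anchor and a.members == b.members


def test_build_library_metadata(positives):
    lib = build_library(
        [
            encode(c.candidate.structure, c.candidate.mature, c.source_id)
            for c in positives[:6]
        ]
    )
    assert len(lib) >= 1
    assert lib.metadata["identity_threshold"] == 0.80
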