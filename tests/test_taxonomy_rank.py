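import numpy as np
import pytest

from planctostrat import (
    AlignmentParams,
    RankThresholds,
    SequenceRecord,
    align_identity,
    best_hit,
    classify_queries,
    delineate,
    make_identity_ladder,
    make_random_reference,
)


# ---------------------------------------------------------------------------
# Exhaustive alignment oracle (free end gaps, affine runs, same tie rules:
# end cell scanned corner -> last row right-to-left -> last column bottom-up,
# then lexicographically smallest reversed move string with D < U < L)
# ---------------------------------------------------------------------------

def oracle_align(q, s, match, mismatch, go, ge):
    n, m = len(q), len(s)
    end_index = {}
    end_index[(n, m)] = 0
    idx = 1
    for j in range(m - 1, 0, -1):
        end_index[(n, j)] = idx
        idx += 1
    for i in range(n - 1, 0, -1):
        end_index[(i, m)] = idx
        idx += 1

    # "M" and "D" are both diagonal moves (match / mismatch) for tie-breaking
    move_rank = {"M": 0, "D": 0, "U": 1, "L": 2}
    candidates = []  # (-score, end_idx, reversed-move-ranks, matches, columns)

    def walk(i, j, score, moves, last):
        if moves and (i, j) in end_index:
            rev = tuple(move_rank[mv] for mv in reversed(moves))
            matches = sum(1 for mv in moves if mv == "M")
            candidates.append(
                (-score, end_index[(i, j)], rev, matches, len(moves))
            )
        if i < n and j < m:
            sub = match if q[i] == s[j] else mismatch
            walk(i + 1, j + 1, score + sub,
                 moves + [("M" if q[i] == s[j] else "D")], "D")
        if i < n and j > 0:  # U move (gap in subject) not allowed along column 0
            cost = ge if last == "U" else go
            walk(i + 1, j, score + cost, moves + ["U"], "U")
        if j < m and i > 0:  # L move (gap in query) not allowed along row 0
            cost = ge if last == "L" else go
            walk(i, j + 1, score + cost, moves + ["L"], "L")

    for b in range(m):
        walk(0, b, 0.0, [], None)
    for a in range(1, n):
        walk(a, 0, 0.0, [], None)

    best = min(candidates, key=lambda c: (c[0], c[1], c[2]))
    _, _, _, matches, cols = best
    return -best[0], 100.0 * matches / cols, cols


def _rec(name, seq):
    return SequenceRecord(id=name, seq=seq)


class TestAlignIdentity:
    def test_identical_sequences(self, reference_1200):
        ident, length = align_identity(reference_1200, reference_1200)
        assert ident == 100.0 and length == 1200

    def test_internal_slice_scores_100(self, reference_1200):
        q = _rec("slice", reference_1200.seq[400:700])
        ident, length = align_identity(q, reference_1200)
        assert ident == 100.0 and length == 300

    def test_ladder_identity_close_to_realized(self, reference_1200):
        # free end gaps + affine gaps can trim mismatch-dense edges, so the
        # aligned identity sits slightly above the planted ungapped identity
        for seed in (0, 1, 2):
            (q, realized, _), = make_identity_ladder(
                reference_1200, [90.0], seed=seed
            )
            ident, _ = align_identity(q, reference_1200)
            assert ident == pytest.approx(realized, abs=0.35)
            assert ident >= realized - 1e-9

    def test_symmetry_in_arguments(self, reference_1200):
        (q, _, _), = make_identity_ladder(reference_1200, [92.0], seed=3)
        a, la = align_identity(q, reference_1200)
        b, lb = align_identity(reference_1200, q)
        assert a == pytest.approx(b, abs=1e-9) and la == lb

    def test_short_sequences_rejected_at_default_min_length(self):
        short = _rec("s", "ACGT" * 10)
        with pytest.raises(ValueError, match="shorter"):
            align_identity(short, short)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration_linear_gaps(self, seed):
        from planctostrat.taxonomy_rank import _align_kernel, _encode

        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        m = int(rng.integers(3, 7))
        q = "".join(rng.choice(list("ACGT"), size=n))
        s = "".join(rng.choice(list("ACGT"), size=m))
        params = AlignmentParams(match=5, mismatch=-4, gap_open=-6,
                                 gap_extend=-6, end_gaps_free=True)
        score, matches, cols = _align_kernel(
            _encode(q), _encode(s), params.match, params.mismatch,
            params.gap_open, params.gap_extend, True,
        )
        o_score, o_ident, o_cols = oracle_align(q, s, 5.0, -4.0, -6.0, -6.0)
        assert score == pytest.approx(o_score)
        assert cols == o_cols
        assert 100.0 * matches / cols == pytest.approx(o_ident)


class TestBestHit:
    def test_self_hit(self, reference_1200):
        sid, ident = best_hit(reference_1200, [reference_1200])
        assert sid == reference_1200.id and ident == 100.0

    def test_picks_closest_ladder_member(self, reference_1200):
        ladder = make_identity_ladder(reference_1200, [99.0, 90.0, 80.0], seed=8)
        db = [q for q, _, _ in ladder]
        sid, ident = best_hit(reference_1200, db)
        assert sid == ladder[0][0].id
        assert ident > 98.0

    def test_tie_broken_by_smaller_id(self, reference_1200):
        s1 = _rec("b_subject", reference_1200.seq)
        s2 = _rec("a_subject", reference_1200.seq)
        sid, ident = best_hit(reference_1200, [s1, s2])
        assert sid == "a_subject" and ident == 100.0

    def test_empty_db_rejected(self, reference_1200):
        with pytest.raises(ValueError, match="empty"):
            best_hit(reference_1200, [])


class TestDelineate:
    @pytest.mark.parametrize("identity,shared,novelty", [
        (99.2, "species", "known_species"),
        (98.7, "species", "known_species"),   # inclusive boundary
        (96.0, "genus", "novel_species"),
        (94.5, "genus", "novel_species"),
        (90.0, "family", "novel_genus"),
        (84.0, "order", "novel_family"),
        (80.0, "class", "novel_order"),
        (78.5, "class", "novel_order"),       # inclusive boundary
        (78.4, "none", "novel_class"),
        (0.0, "none", "novel_class"),
    ])
    def test_threshold_mapping(self, identity, shared, novelty):
        assert delineate(identity) == (shared, novelty)

    @pytest.mark.parametrize("bad", [-0.1, 100.1])
    def test_identity_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            delineate(bad)

    def test_monotonicity_of_shared_rank(self):
        depth = {"none": 0, "class": 1, "order": 2, "family": 3,
                 "genus": 4, "species": 5}
        grid = np.linspace(0, 100, 401)
        ranks = [depth[delineate(x)[0]] for x in grid]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))

    def test_thresholds_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            RankThresholds(species=90.0, genus=94.5)


class TestClassifyQueries:
    def test_ladder_novelty_sequence(self, reference_1200):
        ladder = make_identity_ladder(
            reference_1200, [100.0, 96.0, 90.0, 84.0, 80.0, 75.0], seed=9
        )
        calls, _ = classify_queries([q for q, _, _ in ladder], [reference_1200])
        assert [c.novelty for c in calls] == [nov for _, _, nov in ladder]

    def test_unknown_at_genus_percentage(self, reference_1200):
        targets = [99.0] + [90.0] * 9  # 9 of 10 below the genus threshold
        ladder = make_identity_ladder(reference_1200, targets, seed=10)
        _, summary = classify_queries([q for q, _, _ in ladder], [reference_1200])
        assert summary["genus"]["n_unknown"] == 9
        assert summary["genus"]["pct_unknown"] == pytest.approx(90.0)

    def test_empty_query_set(self, reference_1200):
        calls, summary = classify_queries([], [reference_1200])
        assert calls == []
        assert all(row["n_unknown"] == 0 for row in summary.values())
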