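"""Disorder tracks, quantile profile aggregation, dips and MoRF rules."""

import numpy as np
import pytest

from conftest import random_protein
from oracles import quantile_sorted
from rbskit.disorder import (
    DisorderProfile,
    aggregate_profile,
    builtin_disorder_score,
    detect_dip,
    filter_short_runs,
    load_external_scores,
    morf_conservation,
)
from rbskit.seqcore import Alignment, GappedRow, Sequence
from rbskit.synthdata import make_family


class TestBuiltinScore:
    def test_charged_sequence_more_disordered_than_hydrophobic(self):
        e = builtin_disorder_score(Sequence("e", "E" * 30))
        l = builtin_disorder_score(Sequence("l", "L" * 30))
        assert e.scores.mean() > l.scores.mean()

    def test_outputs_clamped(self, rng):
        for _ in range(20):
            seq = random_protein(rng, int(rng.integers(5, 40)))
            t = builtin_disorder_score(seq)
            assert ((t.scores >= 0) & (t.scores <= 1)).all()

    def test_centre_residue_matches_direct_formula(self):
        seq = Sequence("s", "EEEEELLLLL")
        window = 5
        t = builtin_disorder_score(seq, window)
        i = 4  # centre of the E/L junction, window covers EELL plus one E
        win = seq.residues[i - 2 : i + 3]
        kd = {"E": -3.5, "L": 3.8}
        mh = np.mean([(kd[a] + 4.5) / 9 for a in win])
        mq = np.mean([-1.0 if a == "E" else 0.0 for a in win])
        expected = min(1.0, max(0.0, 0.5 - (2.785 * mh - abs(mq) - 1.151) / 2))
        assert t.scores[i] == pytest.approx(expected, abs=1e-12)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            builtin_disorder_score(Sequence("s", "ML"))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            builtin_disorder_score(Sequence("s", "MLLVA"), window=6)


class TestExternalScores:
    def _write(self, tmp_path, rows):
        p = tmp_path / "scores.tsv"
        p.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        return p

    def test_matching_file_loads(self, tmp_path):
        seq = Sequence("s", "MLK")
        p = self._write(tmp_path, [(1, "M", 0.1), (2, "L", 0.5), (3, "K", 0.9)])
        t = load_external_scores(p, seq)
        assert len(t) == 3 and t.source == "external"

    def test_residue_mismatch_names_position(self, tmp_path):
        seq = Sequence("s", "MLK")
        p = self._write(tmp_path, [(1, "M", 0.1), (2, "V", 0.5), (3, "K", 0.9)])
        with pytest.raises(ValueError, match="pos 2"):
            load_external_scores(p, seq)

    def test_out_of_range_scores_clamped_with_warning(self, tmp_path):
        seq = Sequence("s", "MLK")
        p = self._write(tmp_path, [(1, "M", -0.2), (2, "L", 0.5), (3, "K", 1.4)])
        with pytest.warns(UserWarning):
            t = load_external_scores(p, seq)
        assert t.scores[0] == 0.0 and t.scores[2] == 1.0


from rbskit.disorder import ResidueScoreTrack


def _tracks_for(alignment, score_fn):
    out = {}
    for row in alignment.rows:
        seq = row.degap()
        out[row.id] = ResidueScoreTrack(row.id, score_fn(len(seq)), "external")
    return out


class TestAggregateProfile:
    def test_single_row_columns_flagged_undefined(self):
        # Columns with fewer than 3 contributing rows carry no statistics.
        aln = Alignment([GappedRow("r", "MLLVA")])
        tracks = _tracks_for(aln, lambda n: np.linspace(0.1, 0.9, n))
        prof = aggregate_profile(aln, tracks)
        assert not prof.defined().any()

    def test_stated_quantile_rule(self):
        rows = [GappedRow(f"r{i}", "A") for i in range(4)]
        aln = Alignment(rows)
        vals = [0.1, 0.2, 0.3, 0.4]
        tracks = {
            f"r{i}": ResidueScoreTrack(f"r{i}", np.array([v]), "external")
            for i, v in enumerate(vals)
        }
        prof = aggregate_profile(aln, tracks)
        assert prof.median[0] == pytest.approx(0.25)
        assert prof.q1[0] == pytest.approx(0.175)
        assert prof.q3[0] == pytest.approx(0.325)

    def test_missing_track_raises(self, family_alignment):
        with pytest.raises(ValueError, match="missing"):
            aggregate_profile(family_alignment, {})

    def test_brute_force_oracle_random_alignments(self, rng):
        for _ in range(1000):
            nrows = int(rng.integers(3, 7))
            ncol = int(rng.integers(3, 12))
            rows = []
            for r in range(nrows):
                chars = ["A" if rng.random() > 0.25 else "-" for _ in range(ncol)]
                if all(c == "-" for c in chars):
                    chars[0] = "A"
                rows.append(GappedRow(f"r{r}", "".join(chars)))
            aln = Alignment(rows)
            tracks = _tracks_for(aln, lambda n: rng.random(n))
            prof = aggregate_profile(aln, tracks)
            per_row = {r.id: tracks[r.id].scores for r in aln.rows}
            for col in range(ncol):
                vals = []
                for r in aln.rows:
                    res = aln.coordinate_map(r.id).to_residue(col + 1)
                    if res is not None:
                        vals.append(per_row[r.id][res - 1])
                if len(vals) < 3:
                    assert np.isnan(prof.median[col])
                    continue
                assert prof.minimum[col] == pytest.approx(min(vals))
                assert prof.maximum[col] == pytest.approx(max(vals))
                for stat, q in ((prof.q1, 0.25), (prof.median, 0.5), (prof.q3, 0.75)):
                    assert stat[col] == pytest.approx(quantile_sorted(vals, q), abs=1e-12)

    def test_quantile_ordering_invariant(self, rng):
        fx = make_family(n_rows=8, seed=11)
        tracks = {s.id: builtin_disorder_score(s) for s in fx.sequences}
        prof = aggregate_profile(fx.alignment, tracks)
        ok = prof.defined()
        assert (prof.minimum[ok] <= prof.q1[ok] + 1e-12).all()
        assert (prof.q1[ok] <= prof.median[ok] + 1e-12).all()
        assert (prof.median[ok] <= prof.q3[ok] + 1e-12).all()
        assert (prof.q3[ok] <= prof.maximum[ok] + 1e-12).all()

    def test_ordered_vs_disordered_segment_medians(self):
        fx = make_family(n_rows=10, length=150, seed=5)
        tracks = {s.id: builtin_disorder_score(s) for s in fx.sequences}
        prof = aggregate_profile(fx.alignment, tracks)
        o_lo, o_hi = fx.ordered_span
        t_lo, t_hi = fx.tail_span
        ordered_med = np.nanmedian(prof.median[o_lo - 1 : o_hi])
        tail_med = np.nanmedian(prof.median[t_lo - 1 : t_hi])
        assert ordered_med < 0.5 < tail_med


class TestDetectDip:
    def _flat_profile(self, n, level=0.7):
        arr = np.full(n, level)
        return DisorderProfile(arr, arr, arr.copy(), arr, arr, np.full(n, 5))

    def test_flat_profile_has_no_dip(self):
        prof = self._flat_profile(60)
        dip, depth = detect_dip(prof, (25, 33))
        assert not dip and depth == pytest.approx(0.0)

    def test_planted_ordered_segment_under_motif(self):
        arr = np.full(60, 0.75)
        arr[24:33] = 0.35
        prof = DisorderProfile(arr, arr, arr.copy(), arr, arr, np.full(60, 5))
        dip, depth = detect_dip(prof, (25, 33))
        assert dip
        assert depth == pytest.approx(0.4, abs=1e-9)

    def test_zero_delta_any_strict_decrease(self):
        arr = np.full(60, 0.7)
        arr[29] = 0.69
        prof = DisorderProfile(arr, arr, arr.copy(), arr, arr, np.full(60, 5))
        dip, _ = detect_dip(prof, (30, 30), delta=0.0)
        assert dip


class TestMorf:
    def test_three_residue_run_removed(self):
        flags = np.array([0, 1, 1, 1, 0, 1, 1, 1, 1], dtype=bool)
        out = filter_short_runs(flags)
        assert out.tolist() == [False] * 5 + [True] * 4

    def test_conserved_everywhere_flagged(self):
        aln = Alignment([GappedRow(f"r{i}", "MLLVA") for i in range(4)])
        tracks = {f"r{i}": np.ones(5, dtype=bool) for i in range(4)}
        mt = morf_conservation(aln, tracks)
        assert mt.column_conserved.all()

    def test_exactly_half_is_not_conserved(self):
        aln = Alignment([GappedRow(f"r{i}", "MLLVA") for i in range(4)])
        tracks = {
            "r0": np.ones(5, dtype=bool),
            "r1": np.ones(5, dtype=bool),
            "r2": np.zeros(5, dtype=bool),
            "r3": np.zeros(5, dtype=bool),
        }
        mt = morf_conservation(aln, tracks)
        assert not mt.column_conserved.any()  # strict > 50%

    def test_majority_is_conserved(self):
        aln = Alignment([GappedRow(f"r{i}", "MLLVA") for i in range(4)])
        tracks = {f"r{i}": np.full(5, i < 3, dtype=bool) for i in range(4)}
        mt = morf_conservation(aln, tracks)
        assert mt.column_conserved.all()
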