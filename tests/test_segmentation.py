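"""Unit detection, non-maximal merging and layer-I symbolization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ecghmm.pipeline import PipelineConfig, align_filtered
from ecghmm.records import EcgRecord
from ecghmm.segmentation import (MergeThresholds, QuantizerConfig, Unit,
                                 detect_local_maxima, merge_non_maximal,
                                 symbolize_units)
from ecghmm.synthetic import NoiseSettings, make_plan, make_rhythm


def _filtered_single_beat():
    rec = make_rhythm(make_plan(3, seed=0, pvc_rate=0, apc_rate=0,
                                noise=NoiseSettings.none()), 400.0)
    return align_filtered(rec, PipelineConfig().filter_spec), rec


class TestDetectLocalMaxima:
    def test_clean_beat_yields_three_units_per_beat(self):
        # oracle: the synthetic beat has exactly three extrema (P, R, T)
        filtered, rec = _filtered_single_beat()
        units = detect_local_maxima(filtered)
        beat = rec.annotations.beats[1]
        inside = [u for u in units if beat.onset <= u.peak_time < beat.offset]
        assert len(inside) == 3
        p, r, t = inside
        assert beat.intervals["P"][0] <= p.peak_time < beat.intervals["P"][1]
        assert beat.intervals["QRS"][0] <= r.peak_time < beat.intervals["QRS"][1]
        assert beat.intervals["T"][0] <= t.peak_time < beat.intervals["T"][1]

    def test_all_zero_signal_empty(self):
        assert detect_local_maxima(EcgRecord(np.zeros(2000), 400.0)) == []

    def test_tie_break_keeps_earlier_of_equal_peaks(self):
        x = np.zeros(400)
        x[100] = 1.0
        x[110] = 1.0  # identical peak inside the search window
        units = detect_local_maxima(EcgRecord(x, 400.0), search_window=20)
        assert len(units) == 1
        assert units[0].peak_time == 100

    def test_inverted_peaks_detected(self):
        x = np.zeros(600)
        x[200:240] = -np.sin(np.pi * np.arange(40) / 40)
        units = detect_local_maxima(EcgRecord(x, 400.0))
        assert len(units) == 1
        assert units[0].peak_value < 0

    def test_spans_ordered_and_non_overlapping(self):
        rec = make_rhythm(make_plan(20, seed=4, pvc_rate=0.2), 400.0)
        filtered = align_filtered(rec, PipelineConfig().filter_spec)
        units = detect_local_maxima(filtered)
        for a, b in zip(units, units[1:]):
            assert a.peak_time < b.peak_time
            assert a.offset <= b.onset

    def test_detection_completeness_on_clean_rhythm(self):
        # every ground-truth P/R/T peak is covered by exactly one unit
        rec = make_rhythm(make_plan(30, seed=8, pvc_rate=0.1, apc_rate=0.1,
                                    noise=NoiseSettings.none()), 400.0)
        filtered = align_filtered(rec, PipelineConfig().filter_spec)
        units = detect_local_maxima(filtered)
        for b in rec.annotations.beats[1:-1]:
            for state in ("P", "QRS", "T"):
                on, off = b.intervals[state]
                if off == on:
                    continue
                peak = (on + off) // 2
                covering = [u for u in units if u.onset <= peak < u.offset]
                assert len(covering) == 1, (b.index, state)


class TestMergeNonMaximal:
    def test_merges_when_both_constraints_hold(self):
        units = [Unit(1.0, 100, 90, 104), Unit(1.05, 104, 104, 115)]
        out = merge_non_maximal(units, MergeThresholds(delta_p=0.1, delta_t=10))
        assert len(out) == 1
        assert out[0].onset == 90 and out[0].offset == 115
        assert out[0].peak_value == 1.05  # larger |P| wins

    def test_not_merged_when_peak_difference_exceeds_threshold(self):
        units = [Unit(1.0, 100, 90, 104), Unit(2.0, 104, 104, 115)]
        out = merge_non_maximal(units, MergeThresholds(delta_p=0.1, delta_t=10))
        assert len(out) == 2

    def test_unordered_input_rejected(self):
        units = [Unit(1.0, 200, 190, 210), Unit(1.0, 100, 90, 110)]
        with pytest.raises(ValueError, match="ordered"):
            merge_non_maximal(units, MergeThresholds(0.1, 10))

    @staticmethod
    def _closure_oracle(units, thr):
        """Brute-force transitive closure: group adjacent units connected by
        the pairwise constraint, then merge each group."""
        groups = []
        for u in units:
            if groups and any(abs(v.peak_value - u.peak_value) <= thr.delta_p
                              and abs(v.peak_time - u.peak_time) <= thr.delta_t
                              for v in groups[-1]):
                groups[-1].append(u)
            else:
                groups.append([u])
        merged = []
        for g in groups:
            best = max(g, key=lambda v: abs(v.peak_value))
            merged.append(Unit(best.peak_value, best.peak_time,
                               min(v.onset for v in g), max(v.offset for v in g)))
        return merged

    @given(st.lists(st.tuples(st.floats(0.1, 2.0), st.integers(0, 40)),
                    min_size=1, max_size=8))
    def test_matches_transitive_closure_oracle_on_small_inputs(self, raw):
        pos = 0
        units = []
        for value, gap in sorted(raw, key=lambda r: r[1]):
            pos += gap + 1
            units.append(Unit(round(value, 3), pos, pos, pos + 1))
        thr = MergeThresholds(delta_p=0.25, delta_t=5)
        got = merge_non_maximal(units, thr)
        want = self._closure_oracle(units, thr)
        assert [(u.peak_time, u.onset, u.offset) for u in got] == \
            [(u.peak_time, u.onset, u.offset) for u in want]

    @given(st.lists(st.tuples(st.floats(0.1, 2.0), st.integers(1, 30)),
                    min_size=1, max_size=10))
    def test_idempotent(self, raw):
        pos = 0
        units = []
        for value, gap in raw:
            pos += gap
            units.append(Unit(round(value, 3), pos, pos, pos + 1))
        thr = MergeThresholds(delta_p=0.3, delta_t=6)
        once = merge_non_maximal(units, thr)
        twice = merge_non_maximal(once, thr)
        assert [(u.peak_time, u.onset, u.offset) for u in once] == \
            [(u.peak_time, u.onset, u.offset) for u in twice]

    def test_count_monotone_in_thresholds(self):
        rng = np.random.default_rng(6)
        pos = np.cumsum(rng.integers(2, 30, 40))
        units = [Unit(float(v), int(p), int(p), int(p) + 1)
                 for v, p in zip(rng.uniform(0.1, 2.0, 40), pos)]
        counts = []
        for dp in (0.05, 0.2, 0.6, 1.5):
            for dt in (2, 8, 20):
                counts.append(((dp, dt),
                               len(merge_non_maximal(units, MergeThresholds(dp, dt)))))
        by = dict(counts)
        for dp in (0.05, 0.2, 0.6):
            assert by[(dp, 8)] >= by[(0.6 if dp < 0.6 else 1.5, 8)]
        for dt in (2, 8):
            assert by[(0.2, dt)] >= by[(0.2, 20)]


class TestSymbolize:
    def test_r_like_unit_gets_tall_symbol(self, clean_stream):
        tall = [t for t in clean_stream.tokens if t.symbol == 1]
        assert tall, "no tall-narrow symbols emitted"
        assert all(abs(t.unit.peak_value) > 0.5 for t in tall)

    def test_gaps_get_iso_symbol(self, clean_stream):
        assert all(t.symbol == 0 for t in clean_stream.tokens if not t.is_unit)

    def test_tokens_tile_the_record(self, clean_stream, clean_rhythm):
        pos = 0
        for t in clean_stream.tokens:
            assert t.onset == pos
            pos = t.offset
        assert pos == len(clean_rhythm)

    def test_clean_normal_rhythm_symbol_pattern_periodic(self):
        # oracle: applying the bin thresholds to the known template peaks
        # gives iso* P iso* R iso* T per beat
        rec = make_rhythm(make_plan(8, seed=1, pvc_rate=0, apc_rate=0,
                                    noise=NoiseSettings.none()), 400.0)
        filtered = align_filtered(rec, PipelineConfig().filter_spec)
        units = detect_local_maxima(filtered)
        stream = symbolize_units(units, len(filtered), 400.0)
        unit_syms = [t.symbol for t in stream.tokens if t.is_unit]
        assert unit_syms[:9] == [2, 1, 3] * 3  # P, R, T repeating

    def test_too_few_symbols_rejected(self):
        with pytest.raises(ValueError):
            QuantizerConfig(n_symbols=1)

    def test_deterministic_given_config(self, clean_rhythm):
        filtered = align_filtered(clean_rhythm, PipelineConfig().filter_spec)
        units = detect_local_maxima(filtered)
        s1 = symbolize_units(units, len(filtered), 400.0)
        s2 = symbolize_units(units, len(filtered), 400.0)
        assert np.array_equal(s1.symbols, s2.symbols)
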