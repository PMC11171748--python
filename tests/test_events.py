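"""Event detection, ECD filtering, fold exclusion and ID decoding."""

import numpy as np
import pandas as pd
import pytest

from nanoduplex.events import (DEFAULT_CODEBOOK, EventFilterConfig,
                               analyze_trace, apply_ecd_filter,
                               classify_linear, compute_ecd, decode_id,
                               detect_events, estimate_baseline,
                               ratio_with_error, summarize)
from nanoduplex.sem import CurrentTrace

RATE = 1e6
FILT = EventFilterConfig()


def make_trace(events=(), baseline=9000.0, n=200_000, noise=0.0, seed=0):
    """events: (start_idx, n_samples, depth) or with spike spec dict."""
    x = np.full(n, baseline)
    for ev in events:
        i0, ns, depth = ev[:3]
        x[i0:i0 + ns] -= depth
        if len(ev) == 4:
            for c_frac, extra in ev[3]:
                c = i0 + int(c_frac * ns)
                x[c - 4:c + 4] -= extra
    if noise:
        x = x + np.random.default_rng(seed).normal(0, noise, n)
    return CurrentTrace(x, RATE, baseline_pA=baseline)


class TestBaseline:
    def test_constant_trace(self):
        assert estimate_baseline(make_trace()) == 9000.0

    def test_with_events_within_1pct(self):
        evs = [(i * 18000, 500, 300.0) for i in range(10)]
        assert estimate_baseline(make_trace(evs)) == pytest.approx(
            9000.0, rel=0.01)

    def test_noise_robust(self):
        evs = [(i * 18000, 500, 300.0) for i in range(10)]
        b0 = estimate_baseline(make_trace(evs))
        b1 = estimate_baseline(make_trace(evs, noise=30.0))
        assert abs(b1 - b0) < 5.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline(CurrentTrace(np.ones(5), RATE))


class TestDetect:
    def test_flat_trace_empty(self):
        assert detect_events(make_trace(), FILT) == []

    def test_planted_events_all_found(self):
        evs = [(10_000 + i * 15_000, 400, 200.0) for i in range(8)]
        found = detect_events(make_trace(evs), FILT)
        assert len(found) == 8
        assert found[0].start_idx == pytest.approx(10_000, abs=2)

    def test_short_event_rejected(self):
        # 0.05 ms = 50 samples < the 0.1 ms minimum
        found = detect_events(make_trace([(10_000, 50, 200.0)]), FILT)
        assert found == []

    def test_shallow_event_rejected(self):
        found = detect_events(make_trace([(10_000, 400, 60.0)]), FILT)
        assert found == []


class TestECD:
    def test_rectangle_arithmetic(self):
        # 200 pA x 0.5 ms -> 100 fC
        trace = make_trace([(10_000, 500, 200.0)])
        ev = detect_events(trace, FILT)[0]
        assert compute_ecd(ev, trace, 9000.0) == pytest.approx(100.0,
                                                               rel=1e-6)

    def test_fold_conserves_ecd(self):
        t1 = make_trace([(10_000, 500, 200.0)])
        t2 = make_trace([(10_000, 250, 400.0)])
        e1 = detect_events(t1, FILT)[0]
        e2 = detect_events(t2, FILT)[0]
        assert compute_ecd(e1, t1, 9000.0) == pytest.approx(
            compute_ecd(e2, t2, 9000.0), rel=1e-6)

    def test_range_filter(self):
        evs = [
            type("E", (), {"ecd_fC": 5.0})(),
            type("E", (), {"ecd_fC": 50.0})(),
            type("E", (), {"ecd_fC": 700.0})(),
        ]
        kept = apply_ecd_filter(evs, (10.0, 500.0))
        assert [e.ecd_fC for e in kept] == [50.0]


class TestClassifyLinear:
    def test_single_level_event_is_linear(self):
        trace = make_trace([(10_000, 400, 250.0)])
        ev = detect_events(trace, FILT)[0]
        assert classify_linear(ev, trace, 9000.0, FILT)

    def test_partial_fold_detected(self):
        # first 40% of the event at doubled depth
        x = np.full(200_000, 9000.0)
        x[10_000:10_400] -= 250.0
        x[10_000:10_160] -= 250.0
        trace = CurrentTrace(x, RATE)
        ev = detect_events(trace, FILT)[0]
        assert not classify_linear(ev, trace, 9000.0, FILT)

    def test_spikes_do_not_trigger_fold(self):
        trace = make_trace([(10_000, 400, 250.0,
                             [(0.1, 150.0), (0.3, 150.0), (0.5, 150.0)])])
        ev = detect_events(trace, FILT)[0]
        assert classify_linear(ev, trace, 9000.0, FILT)


class TestDecode:
    def _event(self, code, n=500, depth=250.0, spike=150.0):
        slots = [((i + 0.5) / len(code), spike)
                 for i, b in enumerate(code) if b == "1"]
        trace = make_trace([(10_000, n, depth, slots)])
        ev = detect_events(trace, FILT)[0]
        return ev, trace

    @pytest.mark.parametrize("code, expect_id", [
        ("11100", "RD"), ("11001", "DD")])
    def test_codebook_ids(self, code, expect_id):
        ev, trace = self._event(code)
        bits, ident, orientation = decode_id(ev, trace, 9000.0, FILT)
        assert bits == code
        assert ident == expect_id
        assert orientation == "as_read"

    def test_reversed_read(self):
        ev, trace = self._event("00111")  # "11100" read backwards
        bits, ident, orientation = decode_id(ev, trace, 9000.0, FILT)
        assert (bits, ident, orientation) == ("11100", "RD", "reversed")

    def test_no_spikes_unclassified(self):
        ev, trace = self._event("00000")
        bits, ident, _ = decode_id(ev, trace, 9000.0, FILT)
        assert bits == "00000"
        assert ident == "unclassified"

    def test_time_reversal_invariance(self):
        """Decoding a reversed event yields the same canonical ID."""
        ev, trace = self._event("11100")
        rev = CurrentTrace(trace.samples_pA[::-1].copy(), RATE)
        ev_r = detect_events(rev, FILT)[0]
        _, id_fwd, _ = decode_id(ev, trace, 9000.0, FILT)
        _, id_rev, _ = decode_id(ev_r, rev, 9000.0, FILT)
        assert id_fwd == id_rev == "RD"


class TestSummarize:
    def _table(self):
        rng = np.random.default_rng(0)
        rows = []
        for ident, tau, di in (("RD", 0.32, 285.0), ("DD", 0.57, 250.0)):
            for _ in range(80):
                rows.append(dict(identity=ident,
                                 tau_ms=tau * np.exp(rng.normal(0, 0.1)),
                                 mean_blockage_pA=di + rng.normal(0, 20),
                                 ecd_fC=tau * di))
        return pd.DataFrame(rows)

    def test_population_ratio_recovery(self):
        s = summarize(self._table())
        r, err = ratio_with_error(
            s.loc["DD", "tau_mean_ms"], s.loc["DD", "tau_sem_ms"],
            s.loc["RD", "tau_mean_ms"], s.loc["RD", "tau_sem_ms"])
        assert abs(r - 0.57 / 0.32) < 3 * err

    def test_identical_populations_cover_unity(self):
        df = self._table()
        half = df[df.identity == "RD"].copy()
        half2 = half.copy()
        half2.identity = "RD2"
        half2.tau_ms = half.tau_ms.sample(frac=1.0, random_state=1).values
        s = summarize(pd.concat([half, half2]))
        r, err = ratio_with_error(
            s.loc["RD", "tau_mean_ms"], s.loc["RD", "tau_sem_ms"],
            s.loc["RD2", "tau_mean_ms"], s.loc["RD2", "tau_sem_ms"])
        assert abs(r - 1.0) < 3 * err

    def test_single_event_group(self):
        df = pd.DataFrame([dict(identity="X", tau_ms=0.4,
                                mean_blockage_pA=100.0, ecd_fC=40.0)])
        s = summarize(df)
        assert s.loc["X", "tau_mean_ms"] == 0.4
        assert np.isnan(s.loc["X", "tau_sem_ms"])

    def test_permutation_invariance(self):
        df = self._table()
        s1 = summarize(df)
        s2 = summarize(df.sample(frac=1.0, random_state=5))
        pd.testing.assert_frame_equal(s1, s2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame())
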