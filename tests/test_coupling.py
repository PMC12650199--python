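import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcsleep.config import CouplingParams
from hcsleep.core import EventTable, Hypnogram, Stage
from hcsleep.coupling import (
    compare_phases,
    coupling_rates,
    pair_events,
    triple_sequences,
)
from hcsleep.errors import ValidationError

from oracles import enumerate_pairs


def _table(peaks, kind="DELTA", region="MPFC", width=0.1):
    rows = [
        {
            "session_id": "s",
            "region": region,
            "kind": kind,
            "start_s": t - width / 2,
            "peak_s": t,
            "end_s": t + width / 2,
            "peak_z": 5.0,
            "duration_ms": width * 1000,
        }
        for t in peaks
    ]
    return EventTable(pd.DataFrame(rows)) if rows else EventTable()


DS = (0.100, 1.300)
RD = (0.050, 0.250)


class TestPairWindows:
    def test_ds_pair_at_half_second_lag(self):
        pairs = pair_events(_table([10.0]), _table([10.5], kind="SPINDLE"), DS)
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(0.5)

    def test_ds_rejected_beyond_window(self):
        assert not pair_events(_table([10.0]), _table([11.5], kind="SPINDLE"), DS)

    def test_rd_pair_at_100ms_lag(self):
        pairs = pair_events(
            _table([5.00], kind="RIPPLE", region="CA1"), _table([5.10]), RD
        )
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(0.10)

    def test_rd_rejected_at_400ms_lag(self):
        assert not pair_events(
            _table([5.00], kind="RIPPLE", region="CA1"), _table([5.40]), RD
        )

    def test_window_half_open_semantics(self):
        """Lag exactly at the lower edge is excluded; at the upper edge kept."""
        at_lo = pair_events(_table([10.0]), _table([10.1], kind="SPINDLE"), DS)
        at_hi = pair_events(_table([10.0]), _table([11.3], kind="SPINDLE"), DS)
        assert len(at_lo) == 0
        assert len(at_hi) == 1

    def test_greedy_takes_earliest_follower(self):
        leaders = _table([10.0])
        followers = _table([10.4, 10.9], kind="SPINDLE")
        greedy = pair_events(leaders, followers, DS, "GREEDY_ONE_TO_ONE")
        allp = pair_events(leaders, followers, DS, "ALL_PAIRS")
        assert len(greedy) == 1 and greedy[0][2] == pytest.approx(0.4)
        assert len(allp) == 2

    def test_each_event_used_once_under_greedy(self):
        leaders = _table([10.0, 10.2])
        followers = _table([10.5], kind="SPINDLE")
        pairs = pair_events(leaders, followers, DS, "GREEDY_ONE_TO_ONE")
        assert len(pairs) == 1

    def test_unsorted_table_rejected(self):
        t = _table([1.0, 5.0])
        t.df = t.df.iloc[::-1].reset_index(drop=True)  # deliberately corrupt
        with pytest.raises(ValidationError):
            pair_events(t, _table([2.0], kind="SPINDLE"), DS)


class TestTriples:
    def test_chain_within_both_windows(self):
        r = _table([5.00], kind="RIPPLE", region="CA1")
        d = _table([5.10])
        s = _table([5.60], kind="SPINDLE")
        assert triple_sequences(r, d, s) == [(0, 0, 0)]

    def test_broken_rd_link_gives_no_triple(self):
        r = _table([5.00], kind="RIPPLE", region="CA1")
        d = _table([5.40])  # lag 0.40 > 0.25
        s = _table([5.90], kind="SPINDLE")
        assert triple_sequences(r, d, s) == []

    def test_empty_ripples_give_no_triples(self):
        assert triple_sequences(
            _table([], kind="RIPPLE"), _table([5.1]), _table([5.6], kind="SPINDLE")
        ) == []

    def test_triple_counts_bounded_by_pairs(self):
        rng = np.random.default_rng(1)
        r = _table(np.sort(rng.uniform(0, 100, 30)) + np.arange(30) * 0.2,
                   kind="RIPPLE", region="CA1", width=0.05)
        d = _table(np.sort(rng.uniform(0, 100, 40)) + np.arange(40) * 0.2, width=0.05)
        s = _table(np.sort(rng.uniform(0, 100, 20)) + np.arange(20) * 0.2,
                   kind="SPINDLE", width=0.05)
        params = CouplingParams()
        rd = pair_events(r, d, params.rd_window_s)
        ds = pair_events(d, s, params.ds_window_s)
        rds = triple_sequences(r, d, s, params)
        assert len(rds) <= min(len(rd), len(ds))


class TestOracleEquivalence:
    @pytest.mark.parametrize("pairing", ["GREEDY_ONE_TO_ONE", "ALL_PAIRS"])
    def test_random_tables_match_exhaustive_enumeration(self, pairing):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_l = int(rng.integers(0, 26))
            n_f = int(rng.integers(0, 26))
            lp = np.sort(rng.uniform(0, 60, n_l))
            # keep events separated so tables satisfy non-overlap
            lp = lp + np.arange(n_l) * 0.2
            fp = np.sort(rng.uniform(0, 60, n_f)) + np.arange(n_f) * 0.2
            leaders = _table(lp, width=0.05)
            followers = _table(fp, kind="SPINDLE", width=0.05)
            got = pair_events(leaders, followers, DS, pairing)
            expected = enumerate_pairs(lp, fp, DS[0], DS[1], pairing)
            assert sorted((i, j) for i, j, _ in got) == sorted(expected)

    def test_greedy_never_exceeds_all_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            lp = np.sort(rng.uniform(0, 30, 15)) + np.arange(15) * 0.2
            fp = np.sort(rng.uniform(0, 30, 15)) + np.arange(15) * 0.2
            leaders, followers = _table(lp, width=0.05), _table(fp, kind="SPINDLE", width=0.05)
            g = pair_events(leaders, followers, DS, "GREEDY_ONE_TO_ONE")
            a = pair_events(leaders, followers, DS, "ALL_PAIRS")
            assert len(g) <= len(a)


@settings(max_examples=30, deadline=None)
@given(st.floats(min_value=-1000.0, max_value=1000.0))
def test_translation_invariance(shift):
    rng = np.random.default_rng(9)
    lp = np.sort(rng.uniform(0, 50, 20)) + np.arange(20) * 0.2
    fp = np.sort(rng.uniform(0, 50, 20)) + np.arange(20) * 0.2
    base = pair_events(_table(lp, width=0.05), _table(fp, kind="SPINDLE", width=0.05), DS)
    moved = pair_events(
        _table(lp + shift, width=0.05), _table(fp + shift, kind="SPINDLE", width=0.05), DS
    )
    assert [(i, j) for i, j, _ in base] == [(i, j) for i, j, _ in moved]


class TestCouplingRates:
    def _nrem_hypnogram(self, minutes):
        return Hypnogram(stages=[Stage.NREM] * int(minutes * 15), epoch_length_s=4.0)

    def test_rate_arithmetic(self):
        hyp = self._nrem_hypnogram(6)
        deltas = _table(np.arange(12) * 20.0 + 10.0, width=0.1)
        spindles = _table(np.arange(12) * 20.0 + 10.5, kind="SPINDLE", width=0.1)
        import pandas as pd

        events = EventTable(pd.concat([deltas.df, spindles.df], ignore_index=True))
        res = coupling_rates(events, hyp)
        assert res.counts["ds"] == 12
        assert res.rates_per_min["ds"] == pytest.approx(2.0)

    def test_zero_sleep_guard(self):
        hyp = Hypnogram(stages=[Stage.WAKE] * 100, epoch_length_s=4.0)
        with pytest.raises(ZeroDivisionError):
            coupling_rates(EventTable(), hyp)

    def test_greedy_equals_all_pairs_when_sparse(self):
        hyp = self._nrem_hypnogram(10)
        deltas = _table(np.arange(10) * 50.0 + 10.0, width=0.1)
        spindles = _table(np.arange(10) * 50.0 + 10.4, kind="SPINDLE", width=0.1)
        import pandas as pd

        events = EventTable(pd.concat([deltas.df, spindles.df], ignore_index=True))
        g = coupling_rates(events, hyp, CouplingParams(pairing="GREEDY_ONE_TO_ONE"))
        a = coupling_rates(events, hyp, CouplingParams(pairing="ALL_PAIRS"))
        assert g.counts == a.counts

    def test_poisson_null_matches_analytic(self):
        """Fraction of deltas with an in-window spindle partner under
        independence matches 1 - exp(-(hi-lo) * lambda)."""
        lam = 0.2
        lo, hi = 0.1, 1.3
        expected = 1.0 - np.exp(-(hi - lo) * lam)
        fractions = []
        rng = np.random.default_rng(100)
        for _ in range(20):
            T = 600.0
            d = np.sort(rng.uniform(0, T, rng.poisson(0.1 * T)))
            s = np.sort(rng.uniform(0, T, rng.poisson(lam * T)))
            pairs = enumerate_pairs(d, s, lo, hi, "ALL_PAIRS")
            with_partner = len({i for i, _ in pairs})
            if len(d):
                fractions.append(with_partner / len(d))
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(np.mean(fractions) - expected) <= 3 * se + 1e-12


class TestComparePhases:
    def _result(self, rates, phase):
        from hcsleep.coupling import CouplingResult

        return CouplingResult(
            session_id="s", phase=phase,
            counts={k: int(v * 10) for k, v in rates.items()},
            sleep_minutes=10.0, rates_per_min=rates,
        )

    def test_identical_phases_give_zero_differences(self):
        pre = [self._result({"ds": 1.0, "rd": 0.5, "rds": 0.2}, "PRE")] * 4
        post = [self._result({"ds": 1.0, "rd": 0.5, "rds": 0.2}, "POST")] * 4
        out = compare_phases(pre, post, seed=1)
        assert (out["mean_diff_per_min"] == 0).all()

    def test_single_replicate_ci_undefined(self):
        pre = [self._result({"ds": 1.0, "rd": 0.5, "rds": 0.2}, "PRE")]
        post = [self._result({"ds": 2.0, "rd": 0.5, "rds": 0.3}, "POST")]
        out = compare_phases(pre, post, seed=1)
        assert out["ci_lo"].isna().all() and out["ci_hi"].isna().all()
        assert out.loc[out["sequence"] == "DS", "mean_diff_per_min"].iloc[0] == 1.0

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValidationError):
            compare_phases([], [], seed=1)

    def test_seeded_bootstrap_reproducible(self):
        rng = np.random.default_rng(3)
        pre = [self._result({"ds": float(r), "rd": 0.5, "rds": 0.2}, "PRE")
               for r in rng.uniform(0.5, 1.5, 6)]
        post = [self._result({"ds": float(r), "rd": 0.5, "rds": 0.2}, "POST")
                for r in rng.uniform(1.5, 2.5, 6)]
        a = compare_phases(pre, post, seed=42)
        b = compare_phases(pre, post, seed=42)
        pd.testing.assert_frame_equal(a, b)
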