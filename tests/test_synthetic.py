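"""Generator: population structure, injected effects, corruption model."""

from dataclasses import replace
from datetime import date

import numpy as np
import pandas as pd
import pytest

from partmig.config import MigrationPhenology, QiModel, SimConfig
from partmig import synthetic


def _config(**kw) -> SimConfig:
    return SimConfig(**kw)


class TestPopulation:
    def test_counts_and_fixed_flight_nights(self):
        cfg = _config(n_residents=2, n_migrants=1, seed=1)
        cfg.phenology = replace(cfg.phenology, nights_min=4, nights_mean=4.0, nights_max=4)
        meta, truth = synthetic.generate_population(cfg)
        assert len(meta) == 3
        migrant = meta.loc[meta["strategy"] == "migrant", "bird_id"].iloc[0]
        assert len(truth.events[migrant].fall_flight_nights) == 4

    def test_all_resident_degenerate(self):
        meta, truth = synthetic.generate_population(_config(n_residents=3, n_migrants=0, seed=2))
        assert (meta["strategy"] == "resident").all()
        assert all(ev.is_empty for ev in truth.events.values())

    def test_determinism_byte_identical(self):
        cfg = _config(n_residents=2, n_migrants=2, seed=9)
        m1, t1 = synthetic.generate_population(cfg)
        m2, t2 = synthetic.generate_population(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        assert {b: e for b, e in t1.events.items()} == t2.events
        a1 = synthetic.generate_ambient_series(cfg)
        a2 = synthetic.generate_ambient_series(cfg)
        pd.testing.assert_frame_equal(a1, a2)
        r1 = synthetic.generate_biologger_series(m1, t1, a1, cfg)
        r2 = synthetic.generate_biologger_series(m2, t2, a2, cfg)
        pd.testing.assert_frame_equal(r1, r2)

    def test_nights_within_bounds_and_ordered(self):
        cfg = _config(n_residents=0, n_migrants=20, seed=3)
        _, truth = synthetic.generate_population(cfg)
        ph = cfg.phenology
        for ev in truth.events.values():
            n = len(ev.fall_flight_nights)
            assert ph.nights_min <= n <= ph.nights_max
            assert ev.fall_flight_nights == sorted(ev.fall_flight_nights)
            assert ev.winter_arrival > ev.fall_departure

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda c: setattr(c, "cadence_min", 7),
            lambda c: setattr(c.predeparture, "max_fraction", 1.2),
            lambda c: setattr(c, "n_residents", -1),
            lambda c: setattr(c, "phenology", MigrationPhenology(nights_min=5, nights_mean=2.0)),
        ],
    )
    def test_invalid_configs_rejected(self, mutate):
        cfg = _config()
        mutate(cfg)
        with pytest.raises(ValueError):
            cfg.validate()


class TestAmbient:
    def test_winter_offset_recovered(self):
        cfg = _config(seed=4)
        amb = synthetic.generate_ambient_series(cfg)
        w0, w1 = cfg.winter_window_dates()
        piv = amb.pivot(index="timestamp", columns="site", values="T_a_C")
        win = piv.loc[str(w0) : str(w1)]
        diff = (win["wintering_mean"] - win["breeding"]).mean()
        assert diff == pytest.approx(5.7, abs=0.2)

    def test_zero_offset_indistinguishable(self):
        cfg = _config(seed=5, winter_offset_C=0.0)
        amb = synthetic.generate_ambient_series(cfg)
        piv = amb.pivot(index="timestamp", columns="site", values="T_a_C")
        assert abs((piv["wintering_mean"] - piv["breeding"]).mean()) < 0.2

    def test_quantiles_bracket_mean_pointwise(self):
        amb = synthetic.generate_ambient_series(_config(seed=6))
        piv = amb.pivot(index="timestamp", columns="site", values="T_a_C")
        assert (piv["wintering_q25"] <= piv["wintering_mean"]).all()
        assert (piv["wintering_mean"] <= piv["wintering_q75"]).all()

    def test_zero_spread_collapses_quantiles(self):
        cfg = _config(seed=6)
        cfg.ambient.quantile_spread_C = 0.0
        piv = synthetic.generate_ambient_series(cfg).pivot(
            index="timestamp", columns="site", values="T_a_C"
        )
        assert (piv["wintering_q25"] == piv["wintering_mean"]).all()
        assert (piv["wintering_q75"] == piv["wintering_mean"]).all()


def _noise_free(cfg: SimConfig) -> SimConfig:
    cfg.fH.individual_sd_bpm = 0.0
    cfg.fH.noise_sd_bpm = 0.0
    cfg.Tb.individual_sd_C = 0.0
    cfg.Tb.noise_sd_C = 0.0
    return cfg


class TestBiologgerSeries:
    def test_flight_deltas_at_zero_noise(self):
        cfg = _noise_free(_config(n_residents=1, n_migrants=1, seed=8))
        meta, truth = synthetic.generate_population(cfg)
        amb = synthetic.generate_ambient_series(cfg)
        rec = synthetic.generate_biologger_series(meta, truth, amb, cfg)
        lat = truth.latent
        mig = meta.loc[meta["strategy"] == "migrant", "bird_id"].iloc[0]
        res = meta.loc[meta["strategy"] == "resident", "bird_id"].iloc[0]
        flights = lat.loc[(lat["bird_id"] == mig) & lat["is_flight"], "timestamp"]
        rm = rec.set_index(["bird_id", "timestamp"])
        d_fh = (
            rm.loc[mig].loc[flights, "f_H_bpm"].to_numpy()
            - rm.loc[res].loc[flights, "f_H_bpm"].to_numpy()
        )
        d_tb = (
            rm.loc[mig].loc[flights, "T_b_C"].to_numpy()
            - rm.loc[res].loc[flights, "T_b_C"].to_numpy()
        )
        # the migrant still carries the tail of the pre-departure ramp on the
        # departure night, so allow its magnitude on top of the +199 shift
        assert np.all(d_fh > 199.0 - 0.2 * cfg.fH.nocturnal_mean_bpm)
        assert d_fh.max() == pytest.approx(199.0, abs=1.0)
        assert d_tb == pytest.approx(1.23, abs=1e-9)

    def test_ramp_disabled_equalizes_predeparture_nights(self):
        cfg = _noise_free(_config(n_residents=1, n_migrants=1, seed=8))
        cfg.predeparture.max_fraction = 1e-9
        meta, truth = synthetic.generate_population(cfg)
        amb = synthetic.generate_ambient_series(cfg)
        rec = synthetic.generate_biologger_series(meta, truth, amb, cfg)
        mig_ev = next(ev for ev in truth.events.values() if not ev.is_empty)
        pre_end = pd.Timestamp(mig_ev.fall_departure) - pd.Timedelta(days=1)
        sub = rec.loc[rec["is_night"] & (rec["timestamp"] < pre_end)]
        means = sub.groupby("bird_id")["f_H_bpm"].mean()
        assert means.max() - means.min() < 1e-6

    def test_winter_strategy_contrasts(self, winter_population):
        """Clean winter data: no f_H contrast, +0.18 C T_b contrast (2 MC SE)."""
        cfg, meta, truth, amb, rec = winter_population
        sub = rec.loc[rec["is_night"]].merge(meta[["bird_id", "strategy"]], on="bird_id")
        w0, w1 = cfg.winter_window_dates()
        sub = sub.loc[
            (sub["timestamp"] >= pd.Timestamp(w0)) & (sub["timestamp"] <= pd.Timestamp(w1))
        ]
        bird_means = sub.groupby(["strategy", "bird_id"])[["f_H_bpm", "T_b_C"]].mean()
        for col, expected, indiv_sd in (
            ("f_H_bpm", 0.0, cfg.fH.individual_sd_bpm),
            ("T_b_C", cfg.Tb.resident_winter_decline_C, cfg.Tb.individual_sd_C),
        ):
            mig = bird_means.loc["migrant", col]
            res = bird_means.loc["resident", col]
            diff = mig.mean() - res.mean()
            se = indiv_sd * np.sqrt(1 / len(mig) + 1 / len(res))
            assert abs(diff - expected) < 2 * se + 1e-6

    def test_missing_ambient_coverage_raises(self, small_population):
        cfg, meta, truth, amb, _ = small_population
        short = amb.loc[amb["timestamp"] < pd.Timestamp(date(2017, 1, 1))]
        with pytest.raises(ValueError, match="does not cover"):
            synthetic.generate_biologger_series(meta, truth, short, cfg)


class TestCorruption:
    def _clean(self, n=5000):
        ts = pd.date_range("2016-09-01", periods=n, freq="30min")
        return pd.DataFrame(
            {
                "bird_id": "B000",
                "logger_id": "L000",
                "timestamp": ts,
                "f_H_bpm": 400.0,
                "T_b_C": 40.0,
                "is_night": False,
            }
        )

    def test_zero_probability_class_untouched(self):
        qi = QiModel(class_probs=(1.0,), corruption_probs=(0.0,))
        out = synthetic.corrupt_with_qi(self._clean(), qi, seed=1)
        assert (out["f_H_bpm"] == 400.0).all()

    def test_full_probability_class_all_corrupted(self):
        qi = QiModel(class_probs=(1.0,), corruption_probs=(1.0,))
        out = synthetic.corrupt_with_qi(self._clean(10000), qi, seed=1)
        assert (out["f_H_bpm"] != 400.0).all()
        assert set(out["f_H_bpm"].unique()) <= {200.0, 800.0}

    def test_binomial_corruption_rate(self):
        qi = QiModel(class_probs=(1.0,), corruption_probs=(0.2,))
        out = synthetic.corrupt_with_qi(self._clean(5000), qi, seed=3)
        rate = (out["f_H_bpm"] != 400.0).mean()
        assert rate == pytest.approx(0.20, abs=0.02)

    def test_truth_subsample_cadence_60h(self):
        qi = QiModel()
        out = synthetic.corrupt_with_qi(self._clean(1000), qi, seed=2)
        idx = np.flatnonzero(out["has_ecg_truth"].to_numpy())
        assert np.all(np.diff(idx) == 120)
        assert out.loc[out["has_ecg_truth"], "true_fH_bpm"].notna().all()

    def test_tb_never_corrupted(self):
        qi = QiModel(class_probs=(1.0,), corruption_probs=(1.0,))
        out = synthetic.corrupt_with_qi(self._clean(), qi, seed=1)
        assert (out["T_b_C"] == 40.0).all()

    def test_invalid_probability_rejected(self):
        qi = QiModel(class_probs=(1.0,), corruption_probs=(1.5,))
        with pytest.raises(ValueError):
            synthetic.corrupt_with_qi(self._clean(10), qi, seed=1)
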