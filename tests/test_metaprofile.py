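"""Binned proportion profiles, LOESS trend, and plot rendering."""

import numpy as np
import pandas as pd
import pytest

from r2d.annotate import ANNOTATION_COLUMNS
from r2d.metaprofile import (
    PredicateColumnError,
    SignificancePredicate,
    TooFewPointsError,
    bin_metatranscript,
    codon_profile,
    junction_profile,
    loess_trend,
    render_profile,
)

PRED = SignificancePredicate("stoich", ">", 10.0)


def frame_from(meta=None, up=None, down=None, d_start=None, d_end=None, stoich=None):
    """Minimal annotated table with only the columns profiles consume."""
    n = max(len(v) for v in (meta, up, down, d_start, d_end, stoich) if v is not None)

    def col(v, default="NA"):
        return [str(x) if x is not None else default for x in (v if v is not None else [None] * n)]

    data = {name: ["x"] * n for name in ("transcript", "start", "end")}
    data["stoich"] = col(stoich, default="0")
    data["transcript_metacoordinate"] = col(meta)
    data["up_junc_dist"] = col(up)
    data["down_junc_dist"] = col(down)
    data["abs_cds_start"] = col(d_start)
    data["abs_cds_end"] = col(d_end)
    for name in ANNOTATION_COLUMNS:
        data.setdefault(name, ["NA"] * n)
    return pd.DataFrame(data)


class TestBinMetatranscript:
    def test_default_segmentation_is_120_bins_of_width_0025(self):
        table = bin_metatranscript(frame_from(meta=[0.5], stoich=[50]), PRED)
        assert len(table) == 120
        widths = np.diff(table["axis_value"])
        assert np.allclose(widths, 0.025)
        assert table["axis_value"].iloc[0] == pytest.approx(0.0125)
        assert table["axis_value"].iloc[-1] == pytest.approx(3 - 0.0125)

    @pytest.mark.parametrize("meta,bin_idx", [(0.5, 20), (0.0, 0), (2.999, 119), (1.0, 40)])
    def test_bin_assignment(self, meta, bin_idx):
        table = bin_metatranscript(frame_from(meta=[meta], stoich=[50]), PRED)
        assert table.loc[bin_idx, "n_total"] == 1
        assert table["n_total"].sum() == 1

    def test_proportion_within_bin(self):
        table = bin_metatranscript(
            frame_from(meta=[0.51, 0.52, 0.51, 0.52], stoich=[50, 5, 5, 5]), PRED
        )
        assert table.loc[20, "n_total"] == 4
        assert table.loc[20, "proportion"] == pytest.approx(0.25)

    def test_na_meta_excluded_and_conservation(self):
        frame = frame_from(meta=[0.5, None, 2.5, 1.5], stoich=[50, 50, 5, "notnum"])
        table = bin_metatranscript(frame, PRED)
        # NA meta row and non-numeric predicate row both excluded
        assert table["n_total"].sum() == 2
        assert table.attrs["non_numeric_filtered"] == 1

    def test_shuffle_invariance(self):
        rng = np.random.default_rng(5)
        meta = rng.uniform(0, 3, 200).round(3)
        stoich = rng.uniform(0, 100, 200).round(2)
        frame = frame_from(meta=list(meta), stoich=list(stoich))
        base = bin_metatranscript(frame, PRED)
        shuffled = bin_metatranscript(frame.sample(frac=1, random_state=3), PRED)
        pd.testing.assert_frame_equal(base, shuffled)

    def test_predicate_complementarity(self):
        rng = np.random.default_rng(6)
        frame = frame_from(
            meta=list(rng.uniform(0, 3, 300).round(3)),
            stoich=list(rng.uniform(0, 100, 300).round(2)),
        )
        gt = bin_metatranscript(frame, SignificancePredicate("stoich", ">", 10.0))
        le = bin_metatranscript(frame, SignificancePredicate("stoich", "<=", 10.0))
        assert (gt["n_positive"] + le["n_positive"]).equals(gt["n_total"])

    def test_missing_column_raises_with_available_names(self):
        with pytest.raises(PredicateColumnError, match="transcript_metacoordinate"):
            bin_metatranscript(frame_from(meta=[1.0]), SignificancePredicate("nope", ">", 1))

    def test_predicate_by_one_based_index(self):
        frame = frame_from(meta=[0.5], stoich=[50])
        idx = frame.columns.get_loc("stoich") + 1
        table = bin_metatranscript(frame, SignificancePredicate(idx, ">", 10.0))
        assert table["n_positive"].sum() == 1


class TestLandmarkProfiles:
    def test_junction_keying(self):
        frame = frame_from(up=[11, None], down=[None, 40], stoich=[50, 50])
        up, down = junction_profile(frame, PRED, window=50)
        assert list(up["axis_value"]) == list(range(-50, 0))
        assert up.loc[up["axis_value"] == -11, "n_total"].item() == 1
        assert down.loc[down["axis_value"] == 40, "n_total"].item() == 1
        assert up["n_total"].sum() == 1 and down["n_total"].sum() == 1

    def test_sites_beyond_window_excluded(self):
        frame = frame_from(up=[400], down=[500], stoich=[50])
        up, down = junction_profile(frame, PRED, window=300)
        assert up["n_total"].sum() == 0 and down["n_total"].sum() == 0
        assert len(up) == len(down) == 300
        assert up["proportion"].isna().all()

    def test_codon_keying_and_anchor_switch(self):
        frame = frame_from(d_start=[11, -5], d_end=[-200, -300], stoich=[50, 5])
        stop = codon_profile(frame, PRED, window=100, anchor="stop")
        assert stop["n_total"].sum() == 0  # both stop distances outside window
        start = codon_profile(frame, PRED, window=100, anchor="start")
        assert start.loc[start["axis_value"] == 11, "n_positive"].item() == 1
        assert start.loc[start["axis_value"] == -5, "n_total"].item() == 1
        assert len(start) == 201

    def test_axis_strictly_increasing(self):
        frame = frame_from(d_end=[11], stoich=[50])
        table = codon_profile(frame, PRED, window=30, anchor="stop")
        assert (np.diff(table["axis_value"]) > 0).all()


class TestLoessTrend:
    @staticmethod
    def table(x, y):
        return pd.DataFrame(
            {
                "axis_value": x,
                "n_positive": np.zeros(len(x), dtype=int),
                "n_total": np.ones(len(x), dtype=int),
                "proportion": y,
            }
        )

    def test_constant_signal_recovered(self):
        x = np.linspace(0, 3, 60)
        trend = loess_trend(self.table(x, np.full(60, 0.4)), span=0.3)
        assert np.max(np.abs(trend["fit"] - 0.4)) < 1e-6
        assert ((trend["ci_low"] <= trend["fit"]) & (trend["fit"] <= trend["ci_high"])).all()

    def test_linear_ramp_fit_monotone(self):
        x = np.linspace(0, 1, 50)
        trend = loess_trend(self.table(x, 0.1 + 0.8 * x), span=0.4)
        assert (np.diff(trend["fit"]) > -1e-9).all()

    def test_matches_statsmodels_lowess_on_smooth_signal(self):
        """Independent cross-check: on a smooth noisy signal the in-package
        local linear fit tracks statsmodels' lowess closely."""
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(11)
        x = np.linspace(0, 3, 150)
        y = 0.4 + 0.2 * np.sin(2 * x) + rng.normal(0, 0.02, 150)
        trend = loess_trend(self.table(x, y), span=0.3)
        reference = lowess(y, x, frac=0.3, it=0, return_sorted=False)
        assert np.max(np.abs(trend["fit"].to_numpy() - reference)) < 0.02

    def test_step_depletion_preserved(self):
        x = np.arange(1, 301, dtype=float)
        y = np.where(x <= 200, 0.02, 0.3) + np.random.default_rng(2).normal(0, 0.01, 300)
        trend = loess_trend(self.table(x, y), span=0.3)
        inside = trend.loc[trend["axis_value"] <= 150, "fit"].mean()
        outside = trend.loc[trend["axis_value"] > 250, "fit"].mean()
        assert inside < 0.5 * outside

    def test_too_few_rows_raises(self):
        x = np.arange(5, dtype=float)
        with pytest.raises(TooFewPointsError):
            loess_trend(self.table(x, x / 10), span=0.5)

    def test_na_rows_excluded_and_clipping(self):
        x = np.linspace(0, 3, 40)
        y = np.full(40, 1.05)  # out-of-range input proportion, clipped for display
        y[::7] = np.nan
        trend = loess_trend(self.table(x, y), span=0.5)
        assert len(trend) == 40 - len(y[::7])
        assert (trend["fit_clipped"] <= 1.0).all()

    def test_bootstrap_band_is_seeded(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 3, 40)
        y = 0.3 + rng.normal(0, 0.05, 40)
        a = loess_trend(self.table(x, y), span=0.5, bootstrap=True, seed=9)
        b = loess_trend(self.table(x, y), span=0.5, bootstrap=True, seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert (a["ci_high"] > a["ci_low"]).all()


class TestRenderProfile:
    def test_metatranscript_writes_image_and_table(self, tmp_path):
        rng = np.random.default_rng(0)
        frame = frame_from(
            meta=list(rng.uniform(0, 3, 400).round(3)),
            stoich=list(rng.uniform(0, 100, 400).round(2)),
        )
        table = bin_metatranscript(frame, PRED)
        trend = loess_trend(table, span=0.3)
        out = tmp_path / "mt.png"
        render_profile(table, trend, out, kind="metatranscript")
        assert out.exists() and out.stat().st_size > 0
        written = pd.read_csv(tmp_path / "mt.png.tsv", sep="\t")
        assert len(written) == 120

    def test_metajunction_two_panels_single_figure(self, tmp_path):
        rng = np.random.default_rng(1)
        frame = frame_from(
            up=list(rng.integers(1, 300, 300)),
            down=list(rng.integers(1, 300, 300)),
            stoich=list(rng.uniform(0, 100, 300).round(2)),
        )
        up, down = junction_profile(frame, PRED, window=300)
        out = tmp_path / "mj.svg"
        render_profile((up, down), None, out, kind="metajunction")
        assert out.exists()
        written = pd.read_csv(tmp_path / "mj.svg.tsv", sep="\t")
        assert set(written["panel"]) == {"upstream", "downstream"}

    def test_empty_table_errors_without_writing(self, tmp_path):
        empty = bin_metatranscript(frame_from(meta=[None], stoich=[1]), PRED)
        out = tmp_path / "empty.png"
        with pytest.raises(ValueError, match="empty"):
            render_profile(empty, None, out, kind="metatranscript")
        assert not out.exists()
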