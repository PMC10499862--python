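"""Window sweeps, cutoff-radius masking, n̂, ΔPCC/ΔAtoms, group summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from caflex.evaluation import pearson_cc
from caflex.features import encode_protein
from caflex.interpret import (
    RcutSweep,
    delta_pcc_per_atom,
    group_summary,
    masked_predict_all,
    masked_predict_rcut,
    nhat,
    nhat_curve,
    pccn_vs_rcut,
    rcut_sweep,
    window_predict,
    window_predict_all,
    window_sweep,
)
from caflex.model import ModelConfig, build_model
from conftest import helix_coords, make_record

TINY = ModelConfig(encoder_widths=(5,), lstm_hidden=4, lstm_layers=1,
                   decoder_widths=(3, 1))


@pytest.fixture(scope="module")
def toy_setup():
    model = build_model(TINY, 13)
    rec = make_record(helix_coords(20), np.linspace(10, 40, 20))
    feats, target = encode_protein(rec)
    return model, rec, feats, target


class TestWindowPredict:
    def test_full_span_equals_full_sequence(self, toy_setup):
        model, rec, feats, _ = toy_setup
        full = model.predict(feats.values)
        n = rec.n_residues
        for i in (0, 7, n - 1):
            assert window_predict(model, feats, i, n - 1) == pytest.approx(
                full[i], abs=1e-14)
            assert window_predict(model, feats, i, 5 * n) == pytest.approx(
                full[i], abs=1e-14)

    def test_span_zero_uses_own_row_only(self, toy_setup):
        model, _, feats, _ = toy_setup
        for i in (0, 10, 19):
            single = model.predict(feats.values[i : i + 1])[0]
            assert window_predict(model, feats, i, 0) == pytest.approx(single, abs=1e-14)

    def test_batched_equals_per_residue(self, toy_setup):
        model, _, feats, _ = toy_setup
        for ws in (0, 4, 9):
            batched = window_predict_all(model, feats, ws)
            singles = [window_predict(model, feats, i, ws)
                       for i in range(feats.n_residues)]
            np.testing.assert_allclose(batched, singles, atol=1e-12)

    def test_out_of_range_errors(self, toy_setup):
        model, _, feats, _ = toy_setup
        with pytest.raises(IndexError):
            window_predict(model, feats, 20, 3)


class TestWindowSweep:
    def test_plateau_consistency_and_degenerate_tol(self, toy_setup):
        model, rec, feats, target = toy_setup
        sweep = window_sweep(model, rec, feats, target, [0, 4, 8, 19], 0.02)
        full = model.predict(feats.values)
        assert sweep.pcc_at_ws[-1] == pytest.approx(pearson_cc(full, target), abs=1e-12)
        inf_tol = window_sweep(model, rec, feats, target, [0, 4, 8, 19],
                               plateau_tol=np.inf)
        assert inf_tol.wsc_estimate == 0

    def test_pcc_rises_and_plateaus_on_trained_model(self, trained_small):
        """On a trained model the window PCC must increase with span and
        the critical span must be modest for a locally generated law."""
        model, _, records, encoded = trained_small
        rec = records[25]
        feats, target = encoded[25]
        grid = [0, 2, 4, 8, 16, 32, rec.n_residues - 1]
        sweep = window_sweep(model, rec, feats, target, grid)
        pcc = np.array(sweep.pcc_at_ws)
        assert pcc[-1] > pcc[0]  # sharp rise from span 0
        assert sweep.wsc_estimate <= 32  # plateau well before full span


class TestMaskedPredict:
    def test_infinite_cutoff_is_bit_identical(self, toy_setup):
        model, rec, feats, _ = toy_setup
        full = model.predict(feats.values)
        diameter = cdist(rec.coordinates, rec.coordinates).max()
        # single-probe path: same shapes as a plain forward -> identical bits
        for i in (0, 3, 19):
            assert masked_predict_rcut(model, rec, feats, i, 1e9) == full[i]
        # batched path: covering cutoff reproduces the infinite one exactly
        np.testing.assert_array_equal(
            masked_predict_all(model, rec, feats, np.inf),
            masked_predict_all(model, rec, feats, diameter + 1.0))

    def test_tiny_cutoff_keeps_only_probe_row(self, toy_setup):
        model, rec, feats, _ = toy_setup
        i = 5
        lone = feats.values * 0.0
        lone[i] = feats.values[i]
        expected = model.predict(lone)[i]
        assert masked_predict_rcut(model, rec, feats, i, 0.5) == pytest.approx(
            expected, abs=1e-14)

    def test_negative_cutoff_errors(self, toy_setup):
        model, rec, feats, _ = toy_setup
        with pytest.raises(ValueError):
            masked_predict_rcut(model, rec, feats, 0, -1.0)


class TestRcutSweep:
    def test_ratio_converges_and_telescopes(self, trained_small):
        model, _, records, encoded = trained_small
        items = [(records[i], *encoded[i]) for i in (24, 25)]
        diameter = max(cdist(r.coordinates, r.coordinates).max()
                       for r, _, _ in items)
        sweep = rcut_sweep(model, items, [2, 6, 10, 16, diameter + 1])
        assert sweep.pcc_ratio[-1] == pytest.approx(1.0, abs=1e-12)
        assert all(b >= a for a, b in zip(sweep.atoms_considered,
                                          sweep.atoms_considered[1:]))
        # stepwise PCC changes telescope exactly
        deltas = np.diff(sweep.pcc)
        assert deltas.sum() == pytest.approx(sweep.pcc[-1] - sweep.pcc[0],
                                             abs=1e-12)

    def test_atom_count_grows_cubically_in_bulk(self):
        """For a dense globule the pair count within rcut scales like
        rcut³ in the bulk regime (count-versus-volume fit)."""
        rng = np.random.default_rng(8)
        pts = rng.uniform(-1, 1, size=(6000, 3))
        pts = 25.0 * pts[np.linalg.norm(pts, axis=1) <= 1.0]  # dense sphere
        d = cdist(pts, pts)
        rcuts = np.array([4.0, 6.0, 8.0, 10.0])
        counts = np.array([(d <= rc).sum() - len(d) for rc in rcuts])
        slope = np.polyfit(np.log(rcuts), np.log(counts), 1)[0]
        assert 2.6 < slope < 3.4


class TestDeltaPccPerAtom:
    def test_hand_computed_ratios(self):
        sweep = RcutSweep([1.0, 2.0, 3.0], [0.2, 0.6, 0.8], [0.25, 0.75, 1.0],
                          [10, 40, 80], pcc_all=0.8)
        mids, ratios = delta_pcc_per_atom(sweep)
        assert mids == [1.5, 2.5]
        np.testing.assert_allclose(ratios, [0.4 / 30, 0.2 / 40])

    def test_constant_pcc_gives_zero(self):
        sweep = RcutSweep([1, 2, 3], [0.5, 0.5, 0.5], [1, 1, 1],
                          [5, 10, 20], pcc_all=0.5)
        _, ratios = delta_pcc_per_atom(sweep)
        assert ratios == [0.0, 0.0]

    def test_zero_increment_skipped_and_all_zero_errors(self):
        sweep = RcutSweep([1, 2, 3], [0.2, 0.4, 0.6], [0.3, 0.6, 1.0],
                          [10, 10, 30], pcc_all=0.6)
        mids, _ = delta_pcc_per_atom(sweep)
        assert mids == [2.5]
        with pytest.raises(ValueError):
            delta_pcc_per_atom(RcutSweep([1, 2], [0.1, 0.2], [0.5, 1.0],
                                         [7, 7], pcc_all=0.2))


class TestNhat:
    def test_collinear_oracle(self):
        coords = np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0]], dtype=float)
        rec = make_record(coords, [1.0, 2.0, 3.0])
        point = nhat(rec, rcut=6.0)
        assert point.n_bar == pytest.approx(4 / 3)
        assert point.n_hat == pytest.approx(2 / 3)

    def test_trivial_limits(self):
        rec = make_record(helix_coords(15), np.linspace(1, 2, 15))
        d = cdist(rec.coordinates, rec.coordinates)
        assert nhat(rec, rcut=d[d > 0].min() * 0.9).n_hat == 0.0
        assert nhat(rec, rcut=d.max()).n_hat == 1.0

    def test_brute_force_agreement_with_window(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 20, size=(12, 3))
        rec = make_record(coords, rng.uniform(1, 2, 12))
        rcut, ws = 9.0, 4
        # independent brute-force count
        cnt = 0
        for i in range(12):
            for j in range(12):
                if i != j and abs(i - j) <= ws and np.linalg.norm(coords[i] - coords[j]) <= rcut:
                    cnt += 1
        expected = cnt / 12 / 11
        assert nhat(rec, rcut, ws).n_hat == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=30.0),
           st.floats(min_value=0.0, max_value=10.0),
           st.integers(min_value=0, max_value=20))
    @settings(max_examples=30, deadline=None)
    def test_bounds_and_monotonicity(self, rcut, extra, ws):
        """n̂ ∈ [0,1], nondecreasing in rcut, nonincreasing when a window
        constraint is added."""
        rec = make_record(helix_coords(14), np.linspace(1, 2, 14))
        lo = nhat(rec, rcut).n_hat
        hi = nhat(rec, rcut + extra).n_hat
        windowed = nhat(rec, rcut, ws).n_hat
        assert 0.0 <= lo <= hi <= 1.0
        assert windowed <= lo


class TestPccn:
    def test_affine_nhat_curve_gives_unit_pccn(self):
        rec = make_record(helix_coords(25), np.linspace(1, 2, 25))
        ws_grid = [0, 2, 4, 8, 16]
        nh = nhat_curve(rec, 7.0, ws_grid)
        assert np.ptp(nh) > 0
        curves = [(rec, ws_grid, (3.0 * nh - 0.5).tolist())]
        res = pccn_vs_rcut(curves, [7.0])
        assert res.pccn_values[0] == pytest.approx(1.0, abs=1e-12)

    def test_single_protein_mean_is_its_pccn(self):
        rec = make_record(helix_coords(25), np.linspace(1, 2, 25))
        ws_grid = [0, 2, 4, 8, 16]
        nh = nhat_curve(rec, 7.0, ws_grid)
        pcc_curve = (nh ** 2).tolist()  # some nonlinear but varying curve
        res = pccn_vs_rcut([(rec, ws_grid, pcc_curve)], [7.0])
        assert res.pccn_values[0] == pytest.approx(
            pearson_cc(nh, np.array(pcc_curve)), abs=1e-12)

    def test_degenerate_curves_excluded(self):
        rec = make_record(helix_coords(25), np.linspace(1, 2, 25))
        ws_grid = [0, 2, 4]
        # at a sub-contact rcut the n̂ curve is constant zero -> the protein
        # is excluded there (and counted), while a realistic rcut still works
        res = pccn_vs_rcut([(rec, ws_grid, [0.1, 0.2, 0.3])], [0.1, 7.0])
        assert res.n_excluded[0] == 1
        assert np.isnan(res.pccn_values[0])
        assert np.isfinite(res.pccn_values[1])
        assert res.argmax_rcut == 7.0


class TestGroupSummary:
    def test_constructed_groups(self):
        coords = helix_coords(6)
        rec = make_record(coords, np.linspace(10, 20, 6),
                          aa_codes=["GLY", "ALA"] * 3)
        actual = np.array([1.0, -1.0] * 3)
        predicted = np.array([0.5, -0.5] * 3)
        rows = group_summary([rec], [actual], [predicted], "amino_acid")
        by = {g.group: g for g in rows}
        assert by["GLY"].mean_actual == 1.0 and by["GLY"].sd_actual == 0.0
        assert by["ALA"].mean_predicted == -0.5
        assert sum(g.count for g in rows) == 6

    def test_matches_pandas_groupby_oracle(self, small_corpus):
        _, records, manifest = small_corpus
        records = records[:5]
        actual = [np.array(p["clean_bhat"]) for p in manifest["proteins"][:5]]
        predicted = [a * 0.5 + 0.1 for a in actual]
        rows = group_summary(records, actual, predicted, "ss_class")
        df = pd.DataFrame({
            "key": sum(([s for s in r.ss_labels] for r in records), []),
            "act": np.concatenate(actual),
            "pred": np.concatenate(predicted),
        })
        expected = df.groupby("key").agg(
            mean_act=("act", "mean"), sd_act=("act", lambda s: s.std(ddof=0)),
            n=("act", "size"))
        for g in rows:
            assert g.mean_actual == pytest.approx(expected.loc[g.group, "mean_act"])
            assert g.sd_actual == pytest.approx(expected.loc[g.group, "sd_act"])
            assert g.count == expected.loc[g.group, "n"]
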