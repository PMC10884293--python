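"""Compartment masks, correlation/colocalization statistics, decay fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from carsflim import flimfeat, synth
from carsflim.exceptions import InvalidArgumentError, UndefinedStatisticError
from carsflim.flimfeat import (
    build_feature_table,
    costes_coefficients,
    costes_thresholds,
    derive_compartments,
    fit_biexponential,
    intensity_features,
    morphology_features,
    pearson_corr,
    rwc_coefficients,
)


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestDeriveCompartments:
    def test_concentric_disks_partition(self):
        cells = disk_mask((32, 32), (16, 16), 10).astype(int)
        nuclei = disk_mask((32, 32), (16, 16), 4).astype(int)
        records = derive_compartments(cells, nuclei)
        assert len(records) == 1
        rec = records[0]
        assert rec.cytoplasm.sum() == rec.cell.sum() - rec.nucleus.sum()
        assert not (rec.nucleus & rec.cytoplasm).any()
        assert ((rec.nucleus | rec.cytoplasm) == rec.cell).all()

    def test_border_touching_cell_dropped(self):
        cells = np.zeros((20, 20), dtype=int)
        cells[0:6, 5:10] = 1  # touches row 0
        cells[10:16, 5:10] = 2
        nuclei = np.zeros_like(cells)
        nuclei[2:4, 6:8] = 1
        nuclei[12:14, 6:8] = 2
        records = derive_compartments(cells, nuclei)
        assert [r.cell_id for r in records] == [2]

    def test_nucleus_spanning_two_cells_skipped(self):
        cells = np.zeros((20, 20), dtype=int)
        cells[5:10, 2:9] = 1
        cells[5:10, 9:16] = 2
        nuclei = np.zeros_like(cells)
        nuclei[6:8, 7:12] = 1  # straddles both cells
        with pytest.warns(UserWarning):
            records = derive_compartments(cells, nuclei)
        assert records == []

    def test_group_and_hour_propagate(self):
        cells = disk_mask((32, 32), (16, 16), 8).astype(int)
        nuclei = disk_mask((32, 32), (16, 16), 3).astype(int)
        rec = derive_compartments(cells, nuclei, group="lnp", hour=4)[0]
        assert rec.group == "lnp" and rec.hour == 4


class TestPearson:
    def test_affine_and_negation(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, (8, 8))
        mask = np.ones((8, 8), dtype=bool)
        assert pearson_corr(a, 2 * a + 1, mask) == pytest.approx(1.0)
        assert pearson_corr(a, -a, mask) == pytest.approx(-1.0)

    def test_hand_computed_three_by_three(self):
        a = np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]])
        b = np.array([[2.0, 1, 4], [3, 6, 5], [8, 7, 9]])
        mask = np.ones((3, 3), dtype=bool)
        av, bv = a.ravel(), b.ravel()
        manual = (((av - av.mean()) * (bv - bv.mean())).sum()
                  / np.sqrt(((av - av.mean()) ** 2).sum() * ((bv - bv.mean()) ** 2).sum()))
        assert pearson_corr(a, b, mask) == pytest.approx(manual, rel=1e-12)

    def test_constant_channel_undefined(self):
        mask = np.ones((3, 3), dtype=bool)
        with pytest.raises(UndefinedStatisticError):
            pearson_corr(np.ones((3, 3)), np.arange(9.0).reshape(3, 3), mask)


def brute_force_costes(a, b, t_a, t_b):
    """Definition-level oracle for the coefficients on flat arrays."""
    gate = (a >= t_a) & (b >= t_b)
    return a[gate].sum() / a.sum(), b[gate].sum() / b.sum()


def brute_force_rwc(a, b, t_a, t_b):
    n = a.size
    r_a, r_b = rankdata(a), rankdata(b)
    w = (n - np.abs(r_a - r_b)) / n
    gate = (a >= t_a) & (b >= t_b)
    return (a[gate] * w[gate]).sum() / a.sum(), (b[gate] * w[gate]).sum() / b.sum()


class TestCostes:
    def test_identical_channels_fully_colocalized(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.5, 2.0, (20, 20))
        mask = np.ones((20, 20), dtype=bool)
        t_a, t_b = costes_thresholds(a, a.copy(), mask)
        assert t_a == pytest.approx(a.min())
        c_a, c_b = costes_coefficients(a, a.copy(), mask, (t_a, t_b))
        assert c_a == pytest.approx(1.0) and c_b == pytest.approx(1.0)

    def test_independent_noise_mostly_uncolocalized(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, (40, 40))
        b = rng.uniform(0, 1, (40, 40))
        mask = np.ones((40, 40), dtype=bool)
        t_a, t_b = costes_thresholds(a, b, mask)
        assert t_a > np.quantile(a, 0.8)  # thresholds stay near the maxima
        c_a, c_b = costes_coefficients(a, b, mask)
        assert c_a < 0.3 and c_b < 0.3

    def test_disjoint_signals_give_zero(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[:5] = np.linspace(1, 2, 50).reshape(5, 10)
        b[5:] = np.linspace(1, 2, 50).reshape(5, 10)
        mask = np.ones((10, 10), dtype=bool)
        c_a, c_b = costes_coefficients(a, b, mask)
        assert c_a < 0.05 and c_b < 0.05

    def test_toy_four_by_four_matches_brute_force(self):
        a = np.array([[0.1, 0.2, 0.3, 0.4],
                      [0.5, 0.6, 0.7, 0.8],
                      [0.9, 1.0, 1.1, 1.2],
                      [1.3, 1.4, 1.5, 1.6]])
        b = np.array([[0.2, 0.1, 0.4, 0.3],
                      [0.6, 0.5, 0.9, 0.7],
                      [1.0, 0.8, 1.2, 1.1],
                      [1.4, 1.3, 1.6, 1.5]])
        mask = np.ones((4, 4), dtype=bool)
        thr = costes_thresholds(a, b, mask)
        got = costes_coefficients(a, b, mask, thr)
        expected = brute_force_costes(a.ravel(), b.ravel(), *thr)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 1, (15, 15))
        a = base + rng.normal(0, 0.2, base.shape)
        b = base + rng.normal(0, 0.2, base.shape)
        mask = np.ones((15, 15), dtype=bool)
        t_a, t_b = costes_thresholds(a, b, mask)
        t_a10, t_b10 = costes_thresholds(10 * a, b, mask)
        assert t_a10 == pytest.approx(10 * t_a, rel=1e-9)
        assert t_b10 == pytest.approx(t_b, rel=1e-9)
        c = costes_coefficients(a, b, mask)
        c10 = costes_coefficients(10 * a, 3 * b + 1, mask)
        assert c10[0] == pytest.approx(c[0], abs=0.05)

    def test_constant_channel_degenerate(self):
        mask = np.ones((4, 4), dtype=bool)
        with pytest.raises(UndefinedStatisticError):
            costes_thresholds(np.ones((4, 4)), np.arange(16.0).reshape(4, 4), mask)


class TestRWC:
    def test_identical_channels_weight_one(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.5, 1.5, (12, 12))
        mask = np.ones((12, 12), dtype=bool)
        thr = costes_thresholds(a, a.copy(), mask)
        rw_a, rw_b = rwc_coefficients(a, a.copy(), mask, thr)
        assert rw_a == pytest.approx(1.0) and rw_b == pytest.approx(1.0)

    def test_anti_ranked_channels_near_zero(self):
        a = np.linspace(0.1, 1.0, 64).reshape(8, 8)
        b = a.max() + a.min() - a  # perfect rank reversal
        mask = np.ones((8, 8), dtype=bool)
        rw_a, rw_b = rwc_coefficients(a, b, mask)
        assert rw_a < 0.05 and rw_b < 0.05

    def test_four_pixel_toy_hand_computed(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[1.0, 2.0], [4.0, 3.0]])
        mask = np.ones((2, 2), dtype=bool)
        # floor thresholds: every pixel colocalized
        thr = (a.min(), b.min())
        # ranks a: 1,2,3,4; b: 1,2,4,3 -> D = 0,0,1,1 -> W = 1,1,.75,.75
        exp_a = (1 + 2 + 3 * 0.75 + 4 * 0.75) / 10
        exp_b = (1 + 2 + 4 * 0.75 + 3 * 0.75) / 10
        got = rwc_coefficients(a, b, mask, thr)
        assert got == pytest.approx((exp_a, exp_b), rel=1e-12)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 5, (6, 6)).astype(float) + 0.5
        b = rng.integers(0, 5, (6, 6)).astype(float) + 0.5
        mask = np.ones((6, 6), dtype=bool)
        thr = (1.5, 1.5)
        got = rwc_coefficients(a, b, mask, thr)
        expected = brute_force_rwc(a.ravel(), b.ravel(), *thr)
        assert got == pytest.approx(expected, rel=1e-12)


class TestIntensityFeatures:
    def test_three_by_three_statistics(self):
        vals = np.arange(1.0, 10.0).reshape(3, 3)
        mask = np.ones((3, 3), dtype=bool)
        stats = intensity_features(vals, mask)
        assert stats["min"] == 1 and stats["max"] == 9
        assert stats["mean"] == 5 and stats["median"] == 5
        # every pixel except the center is on the 4-connected edge
        assert stats["min_edge"] == 1
        assert stats["mean_edge"] == pytest.approx((45 - 5) / 8)

    def test_constant_map(self):
        mask = disk_mask((9, 9), (4, 4), 3)
        stats = intensity_features(np.full((9, 9), 2.5), mask)
        assert stats["min"] == stats["mean"] == stats["max"] == 2.5
        assert stats["sd"] == 0

    def test_five_square_edge_is_perimeter(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True
        vals = np.arange(81.0).reshape(9, 9)
        edge = flimfeat._edge_mask(mask)
        assert edge.sum() == 16  # 5x5 square -> 16 perimeter pixels
        stats = intensity_features(vals, mask)
        assert stats["min_edge"] == vals[edge].min()

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidArgumentError):
            intensity_features(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))


class TestMorphologyFeatures:
    def test_square(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        feats = morphology_features(mask)
        assert feats["area"] == 100
        assert feats["solidity"] == pytest.approx(1.0)

    def test_eccentricity_ordering(self):
        disk = disk_mask((40, 40), (20, 20), 8)
        rr, cc = np.mgrid[0:40, 0:40]
        ellipse = ((rr - 20) / 14.0) ** 2 + ((cc - 20) / 4.0) ** 2 <= 1
        assert morphology_features(disk)["eccentricity"] < \
            morphology_features(ellipse)["eccentricity"]


@pytest.fixture(scope="module")
def scene_records(flim_scene):
    ch = flim_scene.channels[0]
    records = flimfeat.derive_compartments(flim_scene.cell_mask,
                                           flim_scene.nucleus_mask,
                                           group="g", hour=0)
    return records, ch


class TestBuildFeatureTable:
    def test_three_rows_per_cell(self, scene_records):
        records, ch = scene_records
        table = build_feature_table(records, ch, clean=False)
        assert len(table) == 3 * len(records)
        assert set(table["compartment"]) == {"cell", "nucleus", "cytoplasm"}

    def test_nan_and_constant_columns_dropped(self, scene_records):
        records, ch = scene_records
        table = build_feature_table(records, ch, clean=False)
        table["bad_nan"] = np.nan
        table.loc[table.index[0], "bad_nan"] = 1.0
        table["bad_const"] = 7.0
        meta = ["cell_id", "compartment", "group", "hour"]
        dropped = [c for c in table.columns if c not in meta
                   and (table[c].isna().any() or np.nanstd(table[c].to_numpy()) == 0)]
        cleaned = build_feature_table(records, ch, clean=True)
        assert "bad_nan" not in cleaned.columns and "bad_const" not in cleaned.columns
        for col in cleaned.columns:
            if col in meta:
                continue
            assert not cleaned[col].isna().any()
            assert np.nanstd(cleaned[col].to_numpy()) > 0
        assert set(cleaned.attrs["dropped_columns"]) <= set(dropped)


class TestColocTracksGenerator:
    def test_costes_increases_with_coloc_rho(self):
        """Mean cytoplasmic Costes(beta1, tau_m) rises monotonically with
        the generator's target correlation (rank correlation >= 0.9 over
        five levels) -- the mechanism behind the rising uptake curve."""
        from scipy.stats import spearmanr

        levels = [0.1, 0.3, 0.5, 0.7, 0.9]
        means = []
        for i, rho in enumerate(levels):
            spec = synth.FlimSceneSpec(n_cells=4, coloc_rho=rho, hours=(0,), seed=30 + i)
            scene = synth.simulate_flim_scene(spec, (128, 128))
            ch = scene.channels[0]
            vals = []
            for rec in derive_compartments(scene.cell_mask, scene.nucleus_mask):
                try:
                    c_a, _ = costes_coefficients(ch.beta1, ch.taum, rec.cytoplasm)
                except UndefinedStatisticError:
                    continue
                vals.append(c_a)
            means.append(np.mean(vals))
        rho_rank, _ = spearmanr(levels, means)
        assert rho_rank >= 0.9


class TestBiexponentialFit:
    def test_noiseless_recovery(self):
        trace = synth.simulate_decay(0.7, 2.0, 0.4, amplitude=1000.0)
        fit = fit_biexponential(trace)
        assert fit.converged
        # components reported by ascending lifetime: tau1=0.4 carries 0.3
        assert fit.tau1 == pytest.approx(0.4, rel=0.01)
        assert fit.tau2 == pytest.approx(2.0, rel=0.01)
        assert fit.beta1 == pytest.approx(0.3, rel=0.01)
        assert fit.amplitude == pytest.approx(1000.0, rel=0.01)

    def test_taum_identity(self):
        trace = synth.simulate_decay(0.6, 1.8, 0.5, amplitude=500.0)
        fit = fit_biexponential(trace)
        assert fit.taum == pytest.approx(fit.beta1 * fit.tau1 + (1 - fit.beta1) * fit.tau2,
                                         rel=1e-12)

    def test_monoexponential_flagged_degenerate(self):
        trace = synth.simulate_decay(1.0, 2.0, 0.4, amplitude=800.0)
        fit = fit_biexponential(trace)
        assert fit.degenerate
        # the dominant lifetime is recovered
        assert min(abs(fit.tau1 - 2.0), abs(fit.tau2 - 2.0)) < 0.05

    def test_too_few_bins_rejected(self):
        trace = synth.DecayTrace(time_bins=np.linspace(0, 10, 10), counts=np.ones(10))
        with pytest.raises(InvalidArgumentError):
            fit_biexponential(trace)
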