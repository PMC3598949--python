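"""Follicle cap analysis: axis finding, cap selection, compression
percentages, histograms, pooling and exception classification."""

import numpy as np
import pandas as pd
import pytest

from eruptsim.caps import (
    APICAL_BRU_EDGES,
    CORONAL_BRU_EDGES,
    CapSpec,
    classify_exceptions,
    compression_bru_percent,
    compression_volume_percent,
    histogram_bru,
    histogram_volume,
    pool_caps,
    select_cap_elements,
    summarize_cap,
    tooth_axis,
)
from eruptsim.materials import REGION_CODES, RegionLabel
from eruptsim.table2 import load_printed_table


def records_frame(volumes, stresses):
    volumes = np.asarray(volumes, dtype=float)
    stresses = np.asarray(stresses, dtype=float)
    return pd.DataFrame(
        {
            "element": np.arange(len(volumes)),
            "region": "follicle_pdl",
            "volume": volumes,
            "sigma_h": stresses,
            "S_e": 0.0,
            "bru": volumes * stresses,
        }
    )


class FakeMesh:
    """Minimal mesh stand-in: explicit centroids and region codes."""

    def __init__(self, centroids, region_codes):
        self._centroids = np.asarray(centroids, dtype=float)
        self.region = np.asarray(region_codes)

    def centroids(self):
        return self._centroids

    def mask(self, label):
        return self.region == REGION_CODES[RegionLabel(label)]


def prolate_mesh(rotation=np.eye(3)):
    """Elongated centroid cloud along z; enamel centroids at the high-z
    (crown) end, dentine below."""
    rng = np.random.default_rng(0)
    z = rng.uniform(-5, 5, size=400)
    xy = rng.normal(0, 0.5, size=(400, 2))
    pts = np.column_stack([xy, z]) @ rotation.T
    codes = np.where(
        z > 3.0, REGION_CODES[RegionLabel.ENAMEL], REGION_CODES[RegionLabel.DENTINE]
    )
    return FakeMesh(pts, codes), rotation


class TestToothAxis:
    def test_prolate_cloud_crown_to_apex(self):
        mesh, _ = prolate_mesh()
        axis = tooth_axis(mesh, np.ones(len(mesh.region), dtype=bool))
        assert abs(axis @ np.array([0, 0, -1.0])) >= 0.999
        # crown (enamel, high z) must project to the low end: axis points down
        assert axis[2] < 0

    def test_rotation_equivariance(self):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec([0.4, 0.2, -0.7]).as_matrix()
        mesh0, _ = prolate_mesh()
        mesh1, _ = prolate_mesh(R)
        a0 = tooth_axis(mesh0, np.ones(len(mesh0.region), dtype=bool))
        a1 = tooth_axis(mesh1, np.ones(len(mesh1.region), dtype=bool))
        assert np.abs(R @ a0 - a1).max() < 1e-6

    def test_isotropic_cloud_ambiguous(self):
        """Cube corners have an exactly isotropic covariance: no axis."""
        pts = np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
            dtype=float,
        )
        codes = np.full(len(pts), REGION_CODES[RegionLabel.ENAMEL])
        with pytest.raises(ValueError, match="ambiguous|explicit axis"):
            tooth_axis(FakeMesh(pts, codes), np.ones(len(pts), dtype=bool))


class TestSelectCapElements:
    AXIS = (0.0, 0.0, -1.0)  # crown at high z, apex at low z

    def shell(self):
        rng = np.random.default_rng(2)
        z = rng.uniform(0.0, 10.0, size=2000)
        xy = rng.normal(0, 1, size=(2000, 2))
        return np.column_stack([xy, z])

    def test_matches_bruteforce_axial_filter(self):
        centroids = self.shell()
        t = centroids @ np.array(self.AXIS)
        for kind in ("coronal", "apical"):
            spec = CapSpec("t", "left", kind, self.AXIS, depth=3.0)
            mask = select_cap_elements(centroids, spec)
            if kind == "coronal":
                expected = t <= t.min() + 3.0
            else:
                expected = t >= t.max() - 3.0
            assert (mask == expected).all()

    def test_infinite_depth_covers_follicle(self):
        centroids = self.shell()
        spec = CapSpec("t", "left", "coronal", self.AXIS, depth=np.inf)
        assert select_cap_elements(centroids, spec).all()

    def test_short_tooth_overlap_rejected(self):
        centroids = self.shell()
        centroids[:, 2] *= 0.5  # 5 mm span
        spec = CapSpec("t", "left", "coronal", self.AXIS, depth=3.0)
        with pytest.raises(ValueError, match="too short|span"):
            select_cap_elements(centroids, spec)

    def test_caps_disjoint_when_long_enough(self):
        centroids = self.shell()
        cor = select_cap_elements(
            centroids, CapSpec("t", "left", "coronal", self.AXIS, 3.0)
        )
        api = select_cap_elements(
            centroids, CapSpec("t", "left", "apical", self.AXIS, 3.0)
        )
        assert not (cor & api).any()


class TestCompressionPercents:
    def test_symmetric_volumes(self):
        rec = records_frame([1.0, 1.0], [-0.01, 0.01])
        assert compression_volume_percent(rec) == pytest.approx(50.0)

    def test_all_compressive_saturates(self):
        rec = records_frame([1.0, 2.0], [-0.01, -0.02])
        assert compression_volume_percent(rec) == pytest.approx(100.0)

    def test_weighted_arithmetic(self):
        rec = records_frame([3.0, 1.0], [-0.01, 0.02])
        assert compression_volume_percent(rec) == pytest.approx(75.0)

    def test_zero_stress_stays_in_denominator(self):
        rec = records_frame([1.0, 1.0, 2.0], [-0.01, 0.01, 0.0])
        assert compression_volume_percent(rec) == pytest.approx(25.0)

    def test_bru_ratio(self):
        rec = records_frame([1.0, 1.0], [-0.02, 0.01])
        assert compression_bru_percent(rec) == pytest.approx(200 / 3)

    def test_bru_symmetry(self):
        rec = records_frame([2.0, 1.0], [-0.01, 0.02])
        assert compression_bru_percent(rec) == pytest.approx(50.0)

    def test_bru_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        rec = records_frame(
            rng.lognormal(-3, 0.5, 10_000), rng.normal(0, 0.03, 10_000)
        )
        num = den = 0.0
        for s, v in zip(rec["sigma_h"], rec["volume"]):
            den += abs(s * v)
            if s < 0:
                num += abs(s * v)
        assert compression_bru_percent(rec) == pytest.approx(
            100 * num / den, abs=1e-9
        )

    def test_bases_agree_when_stress_magnitudes_equal(self):
        rec = records_frame([1.0, 2.0, 3.0], [-0.01, 0.01, -0.01])
        assert compression_volume_percent(rec) == pytest.approx(
            compression_bru_percent(rec)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compression_volume_percent(records_frame([], []))
        with pytest.raises(ValueError, match="BRU"):
            compression_bru_percent(records_frame([1.0], [0.0]))


class TestHistograms:
    def test_point_mass_single_bin(self):
        rec = records_frame([1.0, 2.0], [-0.012, -0.013])
        hist = histogram_volume(rec)
        curve = hist.curve("compression_volume_pct")
        assert curve.sum() == pytest.approx(100.0)
        assert curve[hist.table.index.get_loc("[0.01,0.015)")] == pytest.approx(100.0)

    def test_normalization_both_curves(self):
        rng = np.random.default_rng(5)
        rec = records_frame(rng.lognormal(-3, 0.5, 500), rng.normal(0, 0.03, 500))
        hist = histogram_volume(rec)
        assert hist.curve("compression_volume_pct").sum() == pytest.approx(100.0, abs=1e-9)
        assert hist.curve("tension_volume_pct").sum() == pytest.approx(100.0, abs=1e-9)

    def test_matches_bruteforce_binning_oracle(self):
        rng = np.random.default_rng(6)
        rec = records_frame(rng.lognormal(-3, 0.5, 2000), rng.normal(0, 0.03, 2000))
        hist = histogram_volume(rec)
        edges = hist.edges
        comp = rec[rec["sigma_h"] < 0]
        x = -comp["sigma_h"].to_numpy()
        w = comp["volume"].to_numpy()
        oracle = np.zeros(len(edges) + 1)
        for xi, wi in zip(x, w):
            if xi < edges[0]:
                oracle[0] += wi
            elif xi >= edges[-1]:
                oracle[-1] += wi
            else:
                for b, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
                    if lo <= xi < hi:
                        oracle[b + 1] += wi
                        break
        oracle *= 100.0 / oracle.sum()
        assert np.allclose(hist.curve("compression_volume_pct"), oracle, atol=1e-9)

    def test_underflow_overflow_aggregation(self):
        rec = records_frame([1.0, 1.0], [-0.001, -0.5])
        hist = histogram_volume(rec)
        curve = hist.curve("compression_volume_pct")
        assert curve[0] == pytest.approx(50.0)
        assert curve[-1] == pytest.approx(50.0)

    def test_bru_uniform_curves_coincide(self):
        """With equal |bru| everywhere the volume and BRU curves match."""
        rec = records_frame([1.0, 2.0, 4.0], [-0.001, -0.0005, -0.00025])
        hist = histogram_bru(rec, "coronal")
        assert np.allclose(
            hist.curve("compression_volume_pct"), hist.curve("compression_bru_pct")
        )

    def test_bru_curve_right_shifted_for_heavy_tail(self):
        """Two-mass example: equal volumes, unequal |bru| -> the BRU curve
        puts more relative mass in the high-|bru| bin than the volume curve."""
        rec = records_frame([1.0, 1.0], [-0.0005, -0.002])
        hist = histogram_bru(rec, "coronal")
        vol = hist.curve("compression_volume_pct")
        bru_c = hist.curve("compression_bru_pct")
        cum_vol = np.cumsum(vol)
        cum_bru = np.cumsum(bru_c)
        assert (cum_bru <= cum_vol + 1e-9).all()
        assert cum_bru[0:-1].sum() < cum_vol[0:-1].sum()

    def test_default_bin_edges(self):
        assert CORONAL_BRU_EDGES[0] == pytest.approx(0.00029)
        assert CORONAL_BRU_EDGES[-1] == pytest.approx(0.00250)
        assert np.allclose(np.diff(CORONAL_BRU_EDGES), 0.00017)
        assert APICAL_BRU_EDGES[0] == pytest.approx(0.000050)
        assert APICAL_BRU_EDGES[-1] == pytest.approx(0.000630)


class TestPooling:
    AXIS = (0.0, 0.0, -1.0)

    def summary(self, tooth, volumes, stresses):
        spec = CapSpec(tooth, "left", "coronal", self.AXIS, 3.0)
        rec = records_frame(volumes, stresses)
        return summarize_cap(spec, "incisive", rec), rec

    def test_equal_totals_average(self):
        """60% and 40% compression with equal cap volumes pool to 50%."""
        s1, r1 = self.summary("canine", [3.0, 2.0], [-0.01, 0.01])
        s2, r2 = self.summary("first_premolar", [2.0, 3.0], [-0.01, 0.01])
        pooled = pool_caps([(s1, r1), (s2, r2)])
        assert pooled.compression_volume_pct == pytest.approx(50.0)

    def test_equals_recomputation_over_concatenated_records(self):
        rng = np.random.default_rng(8)
        entries = []
        frames = []
        for tooth in ("canine", "first_premolar", "second_premolar"):
            s, r = self.summary(
                tooth, rng.lognormal(-3, 0.5, 200), rng.normal(0, 0.03, 200)
            )
            entries.append((s, r))
            frames.append(r)
        pooled = pool_caps(entries)
        allrec = pd.concat(frames, ignore_index=True)
        assert pooled.compression_volume_pct == pytest.approx(
            compression_volume_percent(allrec)
        )
        assert pooled.compression_bru_pct == pytest.approx(
            compression_bru_percent(allrec)
        )

    def test_pooled_between_min_and_max(self):
        s1, r1 = self.summary("canine", [1.0, 1.0], [-0.01, 0.01])
        s2, r2 = self.summary("first_premolar", [9.0, 1.0], [-0.01, 0.01])
        pooled = pool_caps([(s1, r1), (s2, r2)])
        lo = min(s1.compression_volume_pct, s2.compression_volume_pct)
        hi = max(s1.compression_volume_pct, s2.compression_volume_pct)
        assert lo <= pooled.compression_volume_pct <= hi

    def test_second_molar_excluded(self, caplog):
        s1, r1 = self.summary("canine", [1.0], [-0.01])
        s2, r2 = self.summary("second_molar", [100.0], [0.01])
        import logging

        with caplog.at_level(logging.INFO, logger="eruptsim.caps"):
            pooled = pool_caps([(s1, r1), (s2, r2)])
        assert pooled.compression_volume_pct == pytest.approx(100.0)
        assert any("second_molar" in m for m in caplog.messages)

    def test_bare_percentages_rejected(self):
        s1, r1 = self.summary("canine", [1.0], [-0.01])
        with pytest.raises(ValueError, match="records|weight"):
            pool_caps([(s1, None)])


class TestClassifyExceptions:
    def test_printed_table_volume_basis(self):
        """Volume basis over canines and premolars: 7 exceptions of 24."""
        report = classify_exceptions(load_printed_table(), basis="volume")
        assert report.n_instances == 24
        assert report.n_exceptions == 7

    def test_printed_table_bru_basis(self):
        """BRU basis: 5 exceptions of 24, 4 within 4 points of 50%."""
        report = classify_exceptions(load_printed_table(), basis="bru")
        assert report.n_instances == 24
        assert report.n_exceptions == 5
        assert report.n_near_miss_exceptions == 4

    def test_second_molars_reported_separately(self):
        report = classify_exceptions(load_printed_table(), basis="volume")
        assert set(report.second_molars["tooth"]) == {"second_molar"}
        assert len(report.second_molars) == 8
        assert "second_molar" not in set(report.table["tooth"])

    def test_all_conforming_zero_exceptions(self):
        rows = []
        for tooth in ("canine", "first_premolar", "second_premolar"):
            for side in ("left", "right"):
                for load in ("incisive", "right_molar"):
                    rows.append((side, load, tooth, "coronal", "volume", 80.0))
                    rows.append((side, load, tooth, "apical", "volume", 20.0))
        table = pd.DataFrame(
            rows, columns=["side", "load", "tooth", "cap", "basis", "compression_pct"]
        )
        report = classify_exceptions(table, basis="volume")
        assert report.n_exceptions == 0

    def test_exactly_fifty_is_no_exception(self):
        table = load_printed_table().copy()
        table.loc[:, "compression_pct"] = 50.0
        report = classify_exceptions(table, basis="volume")
        assert report.n_exceptions == 0

    def test_missing_cells_reported(self):
        table = load_printed_table()
        truncated = table[table["tooth"] != "canine"]
        with pytest.raises(ValueError, match="missing"):
            classify_exceptions(truncated, basis="volume")

    def test_near_miss_margin_inclusive(self):
        """|x - 50| == margin counts as a near miss."""
        table = load_printed_table().copy()
        mask = (
            (table["tooth"] == "canine")
            & (table["cap"] == "coronal")
            & (table["basis"] == "volume")
            & (table["side"] == "left")
            & (table["load"] == "incisive")
        )
        table.loc[mask, "compression_pct"] = 46.0
        report = classify_exceptions(table, basis="volume", margin=4.0)
        row = report.table[
            (report.table["tooth"] == "canine")
            & (report.table["cap"] == "coronal")
            & (report.table["side"] == "left")
            & (report.table["load"] == "incisive")
        ]
        assert bool(row["is_exception"].iloc[0]) and bool(row["near_miss"].iloc[0])
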