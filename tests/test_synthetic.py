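"""Ground-truth properties of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from tme_evolve.contacts import build_contact_graph, mixing_and_assortativity
from tme_evolve.synthetic import (
    DEFAULT_CELL_TYPES,
    SimConfig,
    generate_dataset,
    generate_marker_image,
    generate_variants,
)


class TestGenerateDataset:
    def test_single_type_degenerate_composition(self):
        comp = pd.DataFrame(1.0, index=["normal"], columns=["only"])
        cfg = SimConfig(n_rois_per_stage=2, stages=("normal",), cell_types=("only",),
                        composition_by_stage=comp,
                        marker_means=pd.DataFrame(1.0, index=["only"], columns=["m"]),
                        cells_per_roi=50, seed=0)
        ds = generate_dataset(cfg)
        assert (ds.cells["cell_type"] == "only").all()
        assert (ds.realized_composition["only"] == 1.0).all()

    def test_same_seed_reproduces_cell_table_exactly(self):
        cfg = SimConfig(n_rois_per_stage=2, cells_per_roi=80, seed=42)
        a = generate_dataset(cfg).cells
        b = generate_dataset(SimConfig(n_rois_per_stage=2, cells_per_roi=80, seed=42)).cells
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = generate_dataset(SimConfig(n_rois_per_stage=1, cells_per_roi=80, seed=1)).cells
        b = generate_dataset(SimConfig(n_rois_per_stage=1, cells_per_roi=80, seed=2)).cells
        assert not a[["x_um", "y_um"]].equals(b[["x_um", "y_um"]])

    def test_every_cell_belongs_to_a_listed_roi(self, small_dataset):
        assert set(small_dataset.cells["roi_id"]) <= set(small_dataset.rois["roi_id"])

    def test_realized_composition_matches_cells(self, small_dataset):
        roi = small_dataset.rois["roi_id"].iloc[0]
        sub = small_dataset.cells_for_roi(roi)
        frac = sub["cell_type"].value_counts(normalize=True)
        rec = small_dataset.realized_composition.loc[roi]
        for t, v in frac.items():
            assert rec[t] == pytest.approx(v)

    def test_composition_trajectory_recovered_within_binomial_error(self):
        """Macrophage fraction rising 0.05 -> 0.25 over 5 stages is recovered
        to within 3 binomial standard errors of the per-stage target."""
        types = list(DEFAULT_CELL_TYPES)
        comp_rows = []
        targets = np.linspace(0.05, 0.25, 5)
        for p_mac in targets:
            row = pd.Series((1 - p_mac) / (len(types) - 1), index=types)
            row["macrophage"] = p_mac
            comp_rows.append(row)
        comp = pd.DataFrame(comp_rows, index=list(SimConfig().stages))
        cfg = SimConfig(n_rois_per_stage=40, cells_per_roi=500,
                        composition_by_stage=comp, seed=5)
        ds = generate_dataset(cfg)
        stages = ds.rois.set_index("roi_id")["stage"]
        for stage, p in zip(cfg.stages, targets):
            rois = stages.index[stages == stage]
            frac = ds.realized_composition.loc[rois, "macrophage"].mean()
            n_cells = 40 * 500
            se = np.sqrt(p * (1 - p) / n_cells)
            assert abs(frac - p) <= 3 * se, (stage, frac, p)

    def test_invalid_configs_rejected(self):
        bad_comp = pd.DataFrame(0.4, index=["normal"], columns=["a", "b"])
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(stages=("normal",), cell_types=("a", "b"),
                      composition_by_stage=bad_comp,
                      marker_means=pd.DataFrame(1.0, index=["a", "b"], columns=["m"]),
                      ).validate()
        with pytest.raises(ValueError, match="cells_per_roi"):
            SimConfig(cells_per_roi=0).validate()
        W = pd.DataFrame(0.0, index=list(DEFAULT_CELL_TYPES), columns=list(DEFAULT_CELL_TYPES))
        W.iloc[0, 1] = 1.0  # asymmetric
        with pytest.raises(ValueError, match="symmetric"):
            SimConfig(interaction_strength=W).validate()

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = SimConfig(n_rois_per_stage=2, cells_per_roi=60, seed=9)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = SimConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back.stages == cfg.stages and back.cell_types == cfg.cell_types
        pd.testing.assert_frame_equal(back.composition_by_stage, cfg.composition_by_stage)
        a = generate_dataset(cfg).cells
        b = generate_dataset(back).cells
        pd.testing.assert_frame_equal(a, b)


class TestSpatialInteractionGroundTruth:
    def _mean_assortativity(self, cfg):
        ds = generate_dataset(cfg)
        rs = []
        for _, sub in ds.cells.groupby("roi_id"):
            g = build_contact_graph(sub)
            rs.append(mixing_and_assortativity(g, sub["cell_type"].to_numpy()).r)
        return np.mean(rs), np.std(rs) / np.sqrt(len(rs))

    def test_zero_interaction_gives_random_mixing(self, flat_two_type_config):
        cfg = flat_two_type_config
        cfg = SimConfig(**{**cfg.__dict__, "n_rois_per_stage": 10, "seed": 13})
        mean_r, se = self._mean_assortativity(cfg)
        assert abs(mean_r) <= max(3 * se, 0.02)

    def test_positive_diagonal_gives_assortative_mixing(self, flat_two_type_config):
        cfg = flat_two_type_config
        W = pd.DataFrame(0.0, index=["alpha", "beta"], columns=["alpha", "beta"])
        np.fill_diagonal(W.values, 2.0)
        cfg = SimConfig(**{**cfg.__dict__, "interaction_strength": W,
                           "n_rois_per_stage": 10, "seed": 13})
        mean_r, se = self._mean_assortativity(cfg)
        assert mean_r > 0.2 and mean_r > 5 * se


class TestMarkerImage:
    def _tiny_cells(self):
        return pd.DataFrame(
            {"cell_id": [0, 1], "roi_id": "r", "x_um": [10.0, 30.0],
             "y_um": [10.0, 30.0], "cell_type": "t", "area_um2": [50.0, 50.0],
             "m1": [100.0, 40.0]}
        )

    def test_no_artifacts_is_clean_rendering(self):
        cells = self._tiny_cells()
        img, mask = generate_marker_image(cells, ["m1"], 48, seed=0)
        img2, mask2 = generate_marker_image(cells, ["m1"], 48, seed=99)
        np.testing.assert_array_equal(img, img2)  # no randomness without artifacts
        assert set(np.unique(mask)) == {0, 1, 2}
        assert (img[0][mask == 0] == 0).all()    # background stays empty
        assert img[0][mask > 0].sum() > 0        # signal lands on footprints

    def test_aggregates_are_countable_components(self):
        empty = self._tiny_cells().iloc[:0]
        img, _ = generate_marker_image(empty, ["m1"], 64,
                                       aggregate_sizes_px=(5, 5, 5), seed=3)
        lab, n = ndimage.label(img[0] > 0)
        assert n == 3
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        assert sorted(sizes) == [5, 5, 5]

    def test_same_seed_same_image(self):
        cells = self._tiny_cells()
        kw = dict(hot_pixel_rate=0.01, aggregate_sizes_px=(4,), seed=17)
        a, _ = generate_marker_image(cells, ["m1"], 48, **kw)
        b, _ = generate_marker_image(cells, ["m1"], 48, **kw)
        np.testing.assert_array_equal(a, b)

    def test_tiff_roundtrip(self, tmp_path):
        from tme_evolve.synthetic import read_marker_image, write_marker_image

        img, _ = generate_marker_image(self._tiny_cells(), ["m1"], 48, seed=0)
        write_marker_image(tmp_path / "roi.tiff", img)
        np.testing.assert_array_equal(read_marker_image(tmp_path / "roi.tiff"), img)

    def test_oversized_aggregate_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_marker_image(self._tiny_cells(), ["m1"], 48,
                                  aggregate_sizes_px=(48 * 48 + 1,), seed=0)


class TestGenerateVariants:
    def test_point_mass_spectrum(self):
        spec = np.zeros(12)
        spec[1] = 1.0  # "A>G"
        v = generate_variants(3, 40, spec, scheme="12", seed=0)
        assert len(v) == 120
        assert (v["REF"] == "A").all() and (v["ALT"] == "G").all()
        assert (v["CONTEXT"].str[1] == "A").all()

    def test_uniform_96_counts_within_multinomial_error(self):
        from tme_evolve.spectrum import spectrum_matrix

        v = generate_variants(1, 10_000, None, scheme="96", seed=4)
        counts = spectrum_matrix(v, "96").counts.iloc[0]
        expected = 10_000 / 96
        sd = np.sqrt(10_000 * (1 / 96) * (1 - 1 / 96))
        assert (np.abs(counts - expected) <= 4 * sd).all()

    def test_seed_determinism(self):
        a = generate_variants(2, 100, None, scheme="96", seed=8)
        b = generate_variants(2, 100, None, scheme="96", seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_spectrum_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            generate_variants(1, 10, np.full(13, 1 / 13), scheme="12", seed=0)
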