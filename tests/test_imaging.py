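import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbconform import imaging, synthetic
from nbconform.imaging import CellSpotTable, NucleusMask, Spot


def cell(rnu1=(), vgoi=(), cb=(), cell_id="c0"):
    def spots(channel, coords):
        return [Spot(channel, float(x), float(y)) for x, y in coords]

    return CellSpotTable(
        cell_id=cell_id,
        spots={
            "RNU1": spots("RNU1", rnu1),
            "VGOI": spots("VGOI", vgoi),
            "CB": spots("CB", cb),
        },
    )


class TestMaxProject:
    def test_single_plane_identity(self, rng):
        plane = rng.random((8, 9))
        assert np.array_equal(imaging.max_project(plane[None]), plane)

    def test_dominates_every_plane(self, rng):
        stack = rng.random((4, 8, 9))
        proj = imaging.max_project(stack)
        assert (proj[None] >= stack).all()
        assert np.array_equal(proj, np.max(stack, axis=0))

    def test_rejects_2d_input(self):
        with pytest.raises(ValueError):
            imaging.max_project(np.zeros((5, 5)))


class TestSegmentNuclei:
    def test_border_touching_nucleus_flagged(self):
        img, n_planted, n_non_border = synthetic.simulate_nuclei_field(
            shape=(200, 200), n_nuclei=5, seed=42
        )
        nuclei = imaging.segment_nuclei(img)
        assert len(nuclei) == n_planted
        retained = [n for n in nuclei if not n.touches_border]
        assert len(retained) == n_non_border

    def test_blank_image_gives_empty_list(self):
        assert imaging.segment_nuclei(np.zeros((50, 50))) == []

    def test_retained_count_matches_ground_truth_over_many_fields(self):
        for seed in range(100):
            img, _, n_non_border = synthetic.simulate_nuclei_field(
                shape=(192, 192), n_nuclei=4, seed=seed
            )
            nuclei = imaging.segment_nuclei(img)
            assert sum(not n.touches_border for n in nuclei) == n_non_border


class TestDetectSpots:
    def _nucleus(self, shape):
        return NucleusMask(1, np.ones(shape, dtype=bool), touches_border=False)

    def test_single_gaussian_spot_centre_is_brightest_pixel(self):
        yy, xx = np.mgrid[0:32, 0:32]
        img = 200 * np.exp(-((xx - 12) ** 2 + (yy - 10) ** 2) / 2.0)
        (spot,) = imaging.detect_spots(
            img, self._nucleus(img.shape), "RNU1", min_intensity=50
        )
        assert (spot.x, spot.y) == (12.0, 10.0)

    def test_equal_intensity_plateau_takes_smallest_yx(self):
        img = np.zeros((10, 10))
        img[4, 4] = img[4, 5] = 100.0
        (spot,) = imaging.detect_spots(
            img, self._nucleus(img.shape), "CB", min_intensity=10
        )
        assert (spot.y, spot.x) == (4.0, 4.0)

    def test_planted_multi_spot_cell_recovered_within_one_pixel(self):
        model = synthetic.CellPopulationModel(n_cells=4, p_dep=0.5, p_indep=0.25)
        cells = synthetic.simulate_cell_spots(model, seed=9)
        for sim in cells:
            images = synthetic.render_cell(sim, poisson_noise=False, seed=1)
            mask = images["DAPI"] > 50
            nucleus = NucleusMask(1, mask, touches_border=False)
            for channel in ("RNU1", "VGOI", "CB"):
                truth = sim.table.channel(channel)
                detected = imaging.detect_spots(
                    images[channel], nucleus, channel,
                    min_intensity=30, min_separation=2.0,
                )
                # merged planted pairs closer than the suppression radius
                # are allowed; every planted spot must be near a detection
                assert len(detected) <= len(truth)
                for t in truth:
                    assert min(
                        math.hypot(t.x - d.x, t.y - d.y) for d in detected
                    ) <= 1.5


class TestMinPairwiseDistances:
    def test_three_four_five_triangle(self):
        c = cell(rnu1=[(0, 0)], vgoi=[(3, 4)], cb=[(0, 10)])
        (rec,) = imaging.min_pairwise_distances(c)
        assert rec["d_gene"] == pytest.approx(5.0)
        assert rec["d_cb"] == pytest.approx(10.0)

    def test_minimum_over_multiple_partners(self):
        c = cell(rnu1=[(0, 0)], vgoi=[(2, 0), (9, 0)], cb=[(0, 1)])
        (rec,) = imaging.min_pairwise_distances(c)
        assert rec["d_gene"] == pytest.approx(2.0)

    def test_bridging_uses_cb_realizing_the_minimum(self):
        # nearest CB is at (0,1); its min distance to VGOI is 1 + 3 = sqrt(10)
        c = cell(rnu1=[(0, 0)], vgoi=[(3, 0)], cb=[(0, 1), (20, 0)])
        (rec,) = imaging.min_pairwise_distances(c)
        assert rec["d_cb_vgoi"] == pytest.approx(math.hypot(3, 1))

    def test_ineligible_cell_rejected(self):
        with pytest.raises(ValueError, match="ineligible"):
            imaging.min_pairwise_distances(cell(rnu1=[(0, 0)], vgoi=[], cb=[(1, 1)]))

    def test_matches_all_pairs_brute_force(self, rng):
        for _ in range(30):
            pts = lambda n: [(rng.uniform(0, 50), rng.uniform(0, 50)) for _ in range(n)]
            r, v, b = pts(int(rng.integers(1, 5))), pts(int(rng.integers(1, 5))), pts(
                int(rng.integers(1, 4))
            )
            recs = imaging.min_pairwise_distances(cell(r, v, b))
            for i, rec in enumerate(recs):
                d_gene = min(math.dist(r[i], q) for q in v)
                d_to_cbs = [math.dist(r[i], q) for q in b]
                j = int(np.argmin(d_to_cbs))
                assert rec["d_gene"] == pytest.approx(d_gene)
                assert rec["d_cb"] == pytest.approx(d_to_cbs[j])
                assert rec["d_cb_vgoi"] == pytest.approx(
                    min(math.dist(b[j], q) for q in v)
                )


class TestClassification:
    @pytest.mark.parametrize(
        "d_gene,d_cb,expected",
        [
            (2.0, 4.0, "CB_dependent"),
            (2.0, 6.0, "CB_independent"),
            (3.5, 1.0, "none"),
            (3.0, 5.0, "CB_dependent"),  # inclusive threshold bounds
            (3.0, 5.0001, "CB_independent"),  # CB-distal bound is strict
        ],
    )
    def test_threshold_rules(self, d_gene, d_cb, expected):
        label, _ = imaging.classify_rnu1_spot(d_gene, d_cb, d_cb_vgoi=99.0)
        assert label == expected

    def test_bridging_is_orthogonal(self):
        label, bridging = imaging.classify_rnu1_spot(3.5, 1.0, 4.0)
        assert label == "none" and bridging

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        d_gene=st.floats(0, 10),
        d_cb=st.floats(0, 10),
        d_cb_vgoi=st.floats(0, 10),
    )
    def test_exactly_one_pair_label(self, d_gene, d_cb, d_cb_vgoi):
        label, _ = imaging.classify_rnu1_spot(d_gene, d_cb, d_cb_vgoi)
        assert label in {"CB_dependent", "CB_independent", "none"}

    def test_pixel_micron_threshold_consistency(self):
        assert imaging.px_to_um(3) == pytest.approx(0.96)
        assert imaging.px_to_um(5) == pytest.approx(1.6)
        assert imaging.um_to_px(1.6) == pytest.approx(5.0)


class TestInteractionFrequency:
    def test_all_cells_with_event_is_100_percent(self):
        cells = [
            cell(rnu1=[(0, 0)], vgoi=[(1, 0)], cb=[(0, 1)], cell_id=f"c{i}")
            for i in range(5)
        ]
        pct, _, n = imaging.interaction_frequency(
            cells, lambda label, bridging: label == "CB_dependent"
        )
        assert pct == 100.0 and n == 5

    def test_cells_without_cb_leave_the_denominator(self):
        with_cb = cell(rnu1=[(0, 0)], vgoi=[(1, 0)], cb=[(0, 1)], cell_id="a")
        without_cb = cell(rnu1=[(0, 0)], vgoi=[(1, 0)], cb=[], cell_id="b")
        pct, _, n = imaging.interaction_frequency(
            [with_cb, without_cb], lambda label, bridging: label == "CB_dependent"
        )
        assert n == 1 and pct == 100.0

    def test_channel_swap_leaves_gene_pairing_invariant(self):
        model = synthetic.CellPopulationModel(n_cells=300, p_dep=0.25, p_indep=0.15)
        sims = synthetic.simulate_cell_spots(model, seed=21)
        tables = [s.table for s in sims]
        swapped = [
            CellSpotTable(
                cell_id=t.cell_id,
                spots={
                    "RNU1": [
                        Spot("RNU1", s.x, s.y, s.intensity) for s in t.channel("VGOI")
                    ],
                    "VGOI": [
                        Spot("VGOI", s.x, s.y, s.intensity) for s in t.channel("RNU1")
                    ],
                    "CB": t.channel("CB"),
                },
            )
            for t in tables
        ]
        pairing = lambda label, bridging: label != "none"  # noqa: E731
        pct_a, _, _ = imaging.interaction_frequency(tables, pairing)
        pct_b, _, _ = imaging.interaction_frequency(swapped, pairing)
        assert pct_a == pytest.approx(pct_b)


class TestLocusPositionClass:
    def _disc_mask(self, shape=(101, 101), radius=30):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return (xx - 50) ** 2 + (yy - 50) ** 2 <= radius**2

    def test_centroid_of_large_disc_is_interior(self):
        mask = self._disc_mask()
        assert imaging.locus_position_class(Spot("RNU1", 50, 50), mask, 3) == "interior"

    def test_far_outside_is_exterior(self):
        mask = self._disc_mask()
        assert imaging.locus_position_class(Spot("RNU1", 2, 2), mask, 3) == "exterior"

    def test_matches_analytic_circle_oracle_away_from_discretization(self, rng):
        mask = self._disc_mask()
        edge = 4.0
        checked = 0
        for _ in range(300):
            x, y = rng.uniform(5, 95, size=2)
            r = math.hypot(x - 50, y - 50)
            signed = 30 - r  # analytic signed distance to the circle
            if min(abs(signed - edge), abs(signed + edge)) < 1.5:
                continue  # skip the discretization shell around each boundary
            expected = (
                "interior" if signed > edge else
                "periphery" if signed >= -edge else "exterior"
            )
            got = imaging.locus_position_class(
                Spot("RNU1", float(x), float(y)), mask, edge
            )
            assert got == expected
            checked += 1
        assert checked > 150
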