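"""Disorder pipeline: plot counts, smoothing, calibration, prediction, tandem."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import admap
from admap.adm import ADM
from admap.disorder import (
    labels_from_segments,
    segments_from_labels,
    smooth,
)
from admap.errors import CalibrationError, SequenceError, ValidationError
from admap.synthetic import SyntheticLaw


class TestResiduePlotCounts:
    def test_empty_map_all_zero(self):
        adm = ADM.from_plots(30, np.empty((0, 2)))
        counts = admap.residue_plot_counts(adm)
        assert np.all(counts.raw == 0)

    def test_in_band_plot_counted_at_both_endpoints(self):
        adm = ADM.from_plots(30, np.array([[10, 25]]))  # k = 15 in [9, 29]
        raw = admap.residue_plot_counts(adm).raw
        assert raw[9] == 1 and raw[24] == 1
        assert raw.sum() == 2

    def test_short_separation_outside_band(self):
        adm = ADM.from_plots(30, np.array([[10, 12]]))  # k = 2 < 9
        assert admap.residue_plot_counts(adm).raw.sum() == 0

    def test_invalid_band_rejected(self):
        adm = ADM.from_plots(30, np.empty((0, 2)))
        with pytest.raises(ValidationError):
            admap.residue_plot_counts(adm, 9, 9)


class TestSmooth:
    def test_constant_series_unchanged(self):
        assert np.allclose(smooth(np.full(20, 3.0)), 3.0)

    def test_impulse_with_full_window(self):
        x = np.zeros(11)
        x[5] = 11.0
        assert smooth(x)[5] == pytest.approx(1.0)

    def test_interior_windows_conserve_periodic_mean(self, rng):
        """Full 11-wide windows of an 11-periodic series average to the series mean."""
        period = rng.random(11)
        x = np.tile(period, 3)
        sm = smooth(x)
        interior = sm[5:-5]
        assert np.allclose(interior, period.mean())

    def test_truncated_edges_average_existing_neighbours(self):
        x = np.arange(8, dtype=float)
        sm = smooth(x)
        assert sm[0] == pytest.approx(np.mean(x[:6]))
        assert sm[-1] == pytest.approx(np.mean(x[2:]))


class TestCalibrate:
    def test_all_disordered_training_gives_unit_curve(self, two_class_table):
        items = admap.make_annotated_set(4, seed=2, table=two_class_table)
        all_dis = [
            (rec, admap.IntervalAnnotation(
                protein_id=ann.protein_id, length=ann.length,
                disordered=((1, ann.length),)))
            for rec, ann in items
        ]
        curve = admap.calibrate(all_dis, two_class_table, min_coverage=0.0)
        assert np.all(curve.bin_fraction == 1.0)
        assert np.allclose(curve(np.linspace(*curve.domain, 50)), 1.0)

    def test_step_law_produces_step_bins(self, two_class_table):
        """A hard step law at count 12 yields bin fractions 1 below and 0 above."""
        items = admap.make_annotated_set(
            12, seed=5, table=two_class_table, law=SyntheticLaw.step(12.0)
        )
        curve = admap.calibrate(items, two_class_table)
        below = curve.bin_counts <= 10  # away from the rounding-boundary bin
        above = curve.bin_counts >= 13
        assert np.all(curve.bin_fraction[below] == 1.0)
        assert np.all(curve.bin_fraction[above] == 0.0)

    def test_low_coverage_protein_excluded(self, two_class_table):
        items = admap.make_annotated_set(6, seed=7, table=two_class_table)
        rec, _ = items[0]
        n = len(rec.residues)
        sliver = admap.IntervalAnnotation(
            protein_id="sliver", length=n,
            disordered=((1, max(1, n // 20)),), ordered=((max(1, n // 20) + 1, n),),
        )
        base = admap.calibrate(items, two_class_table)
        with_sliver = admap.calibrate(items + [(rec, sliver)], two_class_table)
        assert np.array_equal(base.bin_counts, with_sliver.bin_counts)
        assert np.array_equal(base.bin_n, with_sliver.bin_n)
        assert np.allclose(base.coefficients, with_sliver.coefficients)

    def test_no_admissible_protein_raises(self, two_class_table):
        items = admap.make_annotated_set(2, seed=2, table=two_class_table)
        all_dis = [
            (rec, admap.IntervalAnnotation(
                protein_id=ann.protein_id, length=ann.length,
                disordered=((1, ann.length),)))
            for rec, ann in items
        ]
        with pytest.raises(CalibrationError):
            admap.calibrate(all_dis, two_class_table)  # default 10% coverage rule


@pytest.fixture(scope="module")
def curve(two_class_table):
    items = admap.make_annotated_set(10, seed=3, table=two_class_table)
    return admap.calibrate(items, two_class_table)


class TestPredict:
    def test_theta_zero_labels_everything(self, two_class_table, curve):
        rec, _ = admap.make_annotated_set(1, seed=9, table=two_class_table)[0]
        pred = admap.predict(rec.residues, two_class_table, curve, theta=0.0)
        assert pred.labels.all()
        assert pred.segments == ((1, len(rec.residues)),)

    def test_theta_one_keeps_only_certain_residues(self, two_class_table, curve):
        rec, _ = admap.make_annotated_set(1, seed=9, table=two_class_table)[0]
        pred = admap.predict(rec.residues, two_class_table, curve, theta=1.0)
        assert np.array_equal(pred.labels, pred.probability >= 1.0)

    def test_monotone_threshold_nesting(self, two_class_table, curve):
        """The disordered set at a higher theta is a subset of that at a lower theta."""
        rec, _ = admap.make_annotated_set(1, seed=13, table=two_class_table)[0]
        previous = None
        for theta in (0.2, 0.4, 0.6, 0.8):
            labels = admap.predict(rec.residues, two_class_table, curve, theta=theta).labels
            if previous is not None:
                assert np.all(previous | ~labels)  # labels subset of previous
            previous = labels

    def test_step_curve_composed_with_threshold(self, two_class_table):
        """With a step calibration, theta = 0.62 labels exactly the low-count side."""
        items = admap.make_annotated_set(12, seed=5, table=two_class_table,
                                         law=SyntheticLaw.step(12.0))
        curve = admap.calibrate(items, two_class_table)
        rec, _ = items[0]
        pred = admap.predict(rec.residues, two_class_table, curve, theta=0.62)
        clear = np.abs(pred.smoothed_counts - 12.0) > 2.0
        expected = pred.smoothed_counts < 12.0
        assert np.array_equal(pred.labels[clear], expected[clear])

    def test_rejects_unknown_letters(self, two_class_table, curve):
        with pytest.raises(SequenceError):
            admap.predict("ACDB" * 10, two_class_table, curve)

    def test_invalid_theta_rejected(self, two_class_table, curve):
        with pytest.raises(ValidationError):
            admap.predict("ACDE" * 10, two_class_table, curve, theta=1.5)


class TestSegments:
    @given(st.lists(st.booleans(), max_size=60))
    def test_round_trip_identity(self, labels):
        labels = np.array(labels, dtype=bool)
        segs = segments_from_labels(labels)
        assert np.array_equal(labels_from_segments(segs, len(labels)), labels)
        # segments are maximal: consecutive segments never touch
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            assert s2 > e1 + 1


class TestTandem:
    def test_tandem_length_doubles(self, two_class_table):
        items = admap.make_annotated_set(4, seed=3, table=two_class_table)
        curve = admap.calibrate(items, two_class_table)
        rec, _ = items[0]
        res = admap.tandem_predict(rec.residues, two_class_table, curve)
        assert res.tandem.N == 2 * res.monomer.N
        assert res.copies[0].N == res.copies[1].N == res.monomer.N

    def test_band_empty_statistics_give_identical_zero_counts(self):
        """Statistics only at short range: no band plots, so monomer == tandem counts."""
        from test_adm import sparse_table

        entries = [(a, b, 1, 5.0) for a in "ACD" for b in "ACD"]
        table = sparse_table(entries)
        items = admap.make_annotated_set(2, seed=1)
        curve = admap.calibrate(items, admap.make_table("two-class", seed=1))
        res = admap.tandem_predict("ACD" * 20, table, curve)
        assert res.monomer.raw_counts.sum() == 0
        assert res.tandem.raw_counts.sum() == 0

    def test_junction_spanning_pairs_raise_tandem_counts(self, two_class_table):
        """Order-prone termini gain band-separation partners across the junction."""
        items = admap.make_annotated_set(4, seed=3, table=two_class_table)
        curve = admap.calibrate(items, two_class_table)
        seq = "W" * 15 + "K" * 30 + "W" * 15
        res = admap.tandem_predict(seq, two_class_table, curve)
        N = len(seq)
        junction = slice(N - 8, N + 8)  # tandem positions around the seam
        terminal_monomer = np.concatenate(
            [res.monomer.raw_counts[-8:], res.monomer.raw_counts[:8]]
        )
        assert res.tandem.raw_counts[junction].sum() > terminal_monomer.sum()
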