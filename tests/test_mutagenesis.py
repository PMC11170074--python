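import numpy as np
import pytest

from crmcval.genomic_io import ConservationTrack, GenomeManifest, GenomicInterval, ValidatedElement
from crmcval.mutagenesis import (
    MutWindow,
    TsvVariantScorer,
    average_profile,
    conservation_profile,
    extract_window,
    impact_conservation_correlation,
    position_impact,
    ConservationProfile,
    ImpactProfile,
)
from crmcval.synthetic import SyntheticVariantScorer


def manifest(length=100_000):
    return GenomeManifest([("chr1", length)])


def element(s, e, id="E1", label="VNR"):
    return ValidatedElement(GenomicInterval("chr1", s, e), id, label)


class TestExtractWindow:
    def test_short_element_gains_flanks(self):
        w = extract_window(element(1000, 1500), manifest(), window_size=2000)
        assert w.interval == GenomicInterval("chr1", 250, 2250)

    def test_long_element_central_window(self):
        w = extract_window(element(0, 3000), manifest(), window_size=2000)
        assert w.interval == GenomicInterval("chr1", 500, 2500)

    def test_near_boundary_skipped(self, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="crmcval.mutagenesis"):
            w = extract_window(element(100, 200), manifest(1000), window_size=2000)
        assert w is None
        assert any("skipping" in r.message for r in caplog.records)

    def test_unknown_chromosome_error(self):
        with pytest.raises(KeyError):
            extract_window(element(0, 10), GenomeManifest([("chr9", 10_000)]))

    def test_sequence_extraction(self):
        seqs = {"chr1": "A" * 500 + "C" * 500}
        w = extract_window(element(400, 600), manifest(1000), window_size=100,
                           sequences=seqs)
        assert w.interval == GenomicInterval("chr1", 450, 550)
        assert w.sequence == "A" * 50 + "C" * 50


class StubScorer:
    """Maps (position, alt) to fixed feature vectors."""

    def __init__(self, table):
        self.table = table

    def __call__(self, window, position, alt):
        return np.asarray(self.table[(position, alt)], dtype=float)


class TestPositionImpact:
    def window(self, seq="AAAA"):
        return MutWindow("w", GenomicInterval("chr1", 0, len(seq)), seq)

    def test_max_over_alleles(self):
        sc = StubScorer({(0, "C"): [0.2], (0, "G"): [0.5], (0, "T"): [0.1]})
        assert position_impact(sc, self.window(), 0, "max") == pytest.approx(0.5)

    def test_all_zero_scorer(self):
        sc = StubScorer({(0, a): [0.0, 0.0] for a in "CGT"})
        assert position_impact(sc, self.window(), 0) == 0.0

    def test_abs_then_mean_then_max(self):
        sc = StubScorer({
            (0, "C"): (0.1, -0.3),  # mean |.| = 0.2
            (0, "G"): (0.2, 0.2),   # 0.2
            (0, "T"): (0.0, 0.0),   # 0.0
        })
        assert position_impact(sc, self.window(), 0, "mean") == pytest.approx(0.2)

    def test_invariant_to_feature_and_allele_order(self):
        base = {(0, "C"): [0.1, -0.3], (0, "G"): [0.2, 0.2], (0, "T"): [0.4, 0.0]}
        permuted = {(0, "C"): [-0.3, 0.1], (0, "G"): [0.2, 0.2], (0, "T"): [0.0, 0.4]}
        v1 = position_impact(StubScorer(base), self.window(), 0)
        v2 = position_impact(StubScorer(permuted), self.window(), 0)
        assert v1 == pytest.approx(v2)

    def test_ambiguous_reference_skipped(self):
        sc = StubScorer({})
        assert np.isnan(position_impact(sc, self.window("ANAA"), 1))


class ConstScorer:
    def __init__(self, value, n_features=2):
        self.value = value
        self.n = n_features

    def __call__(self, window, position, alt):
        return np.full(self.n, self.value)


class TestProfiles:
    def windows(self, n, size=10):
        seq = "ACGT" * (size // 4 + 1)
        return [
            MutWindow(f"w{i}", GenomicInterval("chr1", 100 * i, 100 * i + size),
                      seq[:size])
            for i in range(n)
        ]

    def test_single_window_profile_equals_position_scores(self):
        (w,) = self.windows(1)
        sc = StubScorer({
            (p, a): [0.1 * p] for p in range(10) for a in "ACGT"
        })
        prof = average_profile([w], sc)
        expected = [0.1 * p for p in range(10)]
        np.testing.assert_allclose(prof.mean_impact, expected, atol=1e-12)
        assert prof.window_size == 10
        assert (prof.counts == 1).all()

    def test_two_constant_windows_average(self):
        wins = self.windows(2)
        # scorer that returns 1.0 for the first window, 3.0 for the second
        class PerWindow:
            def __call__(self, window, position, alt):
                return np.array([1.0 if window.element_id == "w0" else 3.0])

        prof = average_profile(wins, PerWindow())
        np.testing.assert_allclose(prof.mean_impact, 2.0)
        assert (prof.counts == 2).all()

    def test_offsets_span_window(self):
        prof = average_profile(self.windows(1), ConstScorer(1.0))
        assert prof.offsets[0] == -5 and prof.offsets[-1] == 4

    def test_synthetic_profile_peaks_at_midpoint_without_noise(self):
        m = manifest(4000)
        track = ConservationTrack({"chr1": np.full(4000, 2.0)}, m)
        sc = SyntheticVariantScorer(track, gain=0.5, noise_sd=0.0, seed=0)
        el = element(1500, 2500)
        w = extract_window(el, m, window_size=2000,
                           sequences={"chr1": "ACGT" * 1000})
        prof = average_profile([w], sc)
        assert int(prof.offsets[np.argmax(prof.mean_impact)]) == 0
        assert prof.mean_impact[1000] == pytest.approx(1.0)  # 0.5 * 2.0 * w(0)

    def test_bulk_path_matches_per_position_calls(self):
        m = manifest(4000)
        rng = np.random.default_rng(3)
        track = ConservationTrack({"chr1": rng.normal(1.0, 0.5, 4000)}, m)
        sc = SyntheticVariantScorer(track, gain=0.5, noise_sd=0.2, seed=5)
        w = extract_window(element(1000, 1040), m, window_size=40,
                           sequences={"chr1": "ACGT" * 1000})
        prof = average_profile([w], sc)
        direct = [position_impact(sc, w, p) for p in range(40)]
        np.testing.assert_allclose(prof.mean_impact, direct, atol=1e-12)


class TestConservationProfile:
    def track_const(self, value, length=1000):
        m = GenomeManifest([("chr1", length)])
        return m, ConservationTrack({"chr1": np.full(length, float(value))}, m)

    def test_absolute_value_of_negative_track(self):
        m, track = self.track_const(-2.0)
        wins = [MutWindow("w", GenomicInterval("chr1", 0, 10))]
        prof = conservation_profile(wins, track)
        np.testing.assert_allclose(prof.mean_abs_score, 2.0)

    def test_zero_track(self):
        m, track = self.track_const(0.0)
        prof = conservation_profile([MutWindow("w", GenomicInterval("chr1", 0, 10))], track)
        np.testing.assert_allclose(prof.mean_abs_score, 0.0)

    def test_mean_of_absolutes_across_windows(self):
        m = GenomeManifest([("chr1", 100)])
        arr = np.zeros(100)
        arr[0], arr[10] = 1.0, -3.0
        track = ConservationTrack({"chr1": arr}, m)
        wins = [
            MutWindow("a", GenomicInterval("chr1", 0, 4)),
            MutWindow("b", GenomicInterval("chr1", 10, 14)),
        ]
        prof = conservation_profile(wins, track)
        assert prof.mean_abs_score[0] == pytest.approx(2.0)

    def test_all_missing_offset_is_nan(self):
        m = GenomeManifest([("chr1", 100)])
        arr = np.full(100, np.nan)
        arr[1:4] = 1.0
        track = ConservationTrack({"chr1": arr}, m)
        prof = conservation_profile([MutWindow("w", GenomicInterval("chr1", 0, 4))], track)
        assert np.isnan(prof.mean_abs_score[0]) and prof.counts[0] == 0


class TestCorrelation:
    @staticmethod
    def profiles(cons_values, impact_values):
        offsets = np.arange(len(cons_values)) - len(cons_values) // 2
        return (
            ImpactProfile(offsets, np.asarray(impact_values, float),
                          np.ones(len(offsets), int)),
            ConservationProfile(offsets, np.asarray(cons_values, float),
                                np.ones(len(offsets), int)),
        )

    def test_perfect_linearity(self):
        cons = np.linspace(0.5, 3.0, 20)
        imp, cp = self.profiles(cons, 2 * cons)
        r, n = impact_conservation_correlation(imp, cp, 0.0)
        assert r == pytest.approx(1.0) and n == 20

    def test_perfect_anticorrelation(self):
        cons = np.linspace(0.5, 3.0, 20)
        imp, cp = self.profiles(cons, -cons + 5.0)
        r, _ = impact_conservation_correlation(imp, cp, 0.0)
        assert r == pytest.approx(-1.0)

    def test_neutral_filter_drops_offsets(self):
        cons = np.array([0.2, 0.5, 1.2, 2.0, 3.0])
        imp, cp = self.profiles(cons, 2 * cons)
        r, n = impact_conservation_correlation(imp, cp, 1.0)
        assert n == 3

    def test_too_few_retained_error(self):
        imp, cp = self.profiles([0.1, 0.2, 0.3], [1, 2, 3])
        with pytest.raises(ValueError, match="retained"):
            impact_conservation_correlation(imp, cp, 1.0)


class TestTsvScorer:
    def test_round_trip_scores(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text(
            "element_id\toffset\talt_allele\tfeature\tscore\n"
            "E1\t0\tC\tf1\t0.4\n"
            "E1\t0\tC\tf2\t-0.2\n"
            "E1\t-2\tG\tf1\t0.9\n"
        )
        sc = TsvVariantScorer(path)
        w = MutWindow("E1", GenomicInterval("chr1", 0, 6), "AAAAAA")
        # offset 0 -> position 3 for a 6 bp window
        np.testing.assert_allclose(sc(w, 3, "C"), [0.4, -0.2])
        assert position_impact(sc, w, 3, "mean") == pytest.approx(0.3)
        np.testing.assert_allclose(sc(w, 1, "G"), [0.9, 0.0])
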