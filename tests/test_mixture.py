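"""Ks histogram, trough split and Gaussian component fitting, including a
grid-search oracle and sample-level peak recovery."""

import numpy as np
import pytest

from wgdkit import mixture


def _truncated_normal(rng, mean, sd, lo, hi, n):
    out = []
    while len(out) < n:
        draw = rng.normal(mean, sd, size=n)
        out.extend(draw[(draw > lo) & (draw < hi)].tolist())
    return np.array(out[:n])


class TestHistogram:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0.05, 1.5, size=5000)
        values = values[(values > 0.05) & (values < 1.5)]
        edges, dens = mixture.ks_histogram(values)
        widths = np.diff(edges)
        assert np.sum(dens * widths) == pytest.approx(1.0, abs=1e-9)

    def test_single_bin_occupancy(self):
        edges, dens = mixture.ks_histogram([0.3] * 10, n_bins=10, range=(0.05, 1.05))
        assert np.count_nonzero(dens) == 1

    def test_counts_match_bruteforce_binning(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0.05, 1.5, size=777)
        n_bins, (lo, hi) = 50, (0.05, 1.5)
        edges, dens = mixture.ks_histogram(values, n_bins, (lo, hi))
        width = (hi - lo) / n_bins
        counts = np.zeros(n_bins)
        for v in values:  # brute-force per-value binning loop
            idx = min(int((v - lo) / width), n_bins - 1)
            counts[idx] += 1
        expected = counts / (values.size * width)
        assert np.allclose(dens, expected, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(mixture.MixtureError):
            mixture.ks_histogram([])

    def test_out_of_range_rejected(self):
        with pytest.raises(mixture.MixtureError):
            mixture.ks_histogram([2.0])


class TestSplit:
    def test_boundary_goes_old(self):
        young, old = mixture.split_at_trough([0.3, 0.59, 0.6, 0.9])
        assert young.tolist() == [0.3, 0.59]
        assert old.tolist() == [0.6, 0.9]

    def test_all_young(self):
        young, old = mixture.split_at_trough([0.1, 0.2])
        assert old.size == 0 and young.size == 2

    def test_partition_exhaustive_disjoint(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0.05, 1.5, size=500)
        young, old = mixture.split_at_trough(values)
        assert young.size + old.size == values.size
        assert np.all(young < 0.6) and np.all(old >= 0.6)


class TestFitComponent:
    def test_symmetric_sample_peak_near_median(self):
        rng = np.random.default_rng(3)
        subset = _truncated_normal(rng, 0.3, 0.05, 0.05, 0.6, 4000)
        peak, sd, weight = mixture.fit_component(subset)
        bin_width = (subset.max() - subset.min()) / 200
        assert abs(peak - np.median(subset)) <= 2 * bin_width
        assert weight == 1.0

    def test_small_subset_rejected(self):
        with pytest.raises(mixture.MixtureError, match="too small"):
            mixture.fit_component(np.linspace(0.1, 0.5, 20))

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(4)
        subset = _truncated_normal(rng, 0.27, 0.06, 0.05, 0.6, 3000)
        peak, sd, _ = mixture.fit_component(subset)
        lo, hi = subset.min(), subset.max()
        dens, edges = np.histogram(subset, bins=200, range=(lo, hi), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        # dense grid over (peak, sd) with the amplitude solved in closed form
        peak_grid = np.linspace(lo, hi, 401)
        sd_grid = np.linspace(0.005, 0.3, 250)
        best = (np.inf, None, None)
        for mu in peak_grid:
            for s in sd_grid:
                g = np.exp(-0.5 * ((centers - mu) / s) ** 2)
                denom = float(g @ g)
                amp = float(dens @ g) / denom if denom > 0 else 0.0
                sse = float(np.sum((dens - amp * g) ** 2))
                if sse < best[0]:
                    best = (sse, mu, s)
        step = peak_grid[1] - peak_grid[0]
        assert abs(peak - best[1]) <= step / 2 + 1e-9


class TestFitWgdPeaks:
    def test_two_component_recovery(self):
        rng = np.random.default_rng(5)
        values = np.concatenate(
            [
                _truncated_normal(rng, 0.27, 0.06, 0.05, 1.5, 5000),
                _truncated_normal(rng, 0.97, 0.20, 0.05, 1.5, 5000),
            ]
        )
        fit = mixture.fit_wgd_peaks(values)
        assert len(fit.components) == 2
        assert fit.peaks[0] == pytest.approx(0.27, abs=0.03)
        assert fit.peaks[1] == pytest.approx(0.97, abs=0.03)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(6)
        values = np.concatenate(
            [
                _truncated_normal(rng, 0.3, 0.05, 0.05, 1.5, 2000),
                _truncated_normal(rng, 1.0, 0.15, 0.05, 1.5, 1000),
            ]
        )
        fit = mixture.fit_wgd_peaks(values)
        assert sum(w for _, _, w in fit.components) == pytest.approx(1.0, abs=1e-12)

    def test_single_wgd_raises_or_skips_per_config(self):
        rng = np.random.default_rng(7)
        values = _truncated_normal(rng, 0.3, 0.05, 0.05, 0.59, 2000)
        with pytest.raises(mixture.MixtureError):
            mixture.fit_wgd_peaks(values, on_small="raise")
        fit = mixture.fit_wgd_peaks(values, on_small="skip")
        assert len(fit.components) == 1

    def test_peak_invariant_under_sample_duplication(self):
        rng = np.random.default_rng(8)
        values = np.concatenate(
            [
                _truncated_normal(rng, 0.3, 0.05, 0.05, 1.5, 1500),
                _truncated_normal(rng, 1.0, 0.15, 0.05, 1.5, 1500),
            ]
        )
        once = mixture.fit_wgd_peaks(values)
        twice = mixture.fit_wgd_peaks(np.concatenate([values, values]))
        assert np.allclose(once.peaks, twice.peaks, atol=1e-6)

    def test_recovery_error_below_bin_width(self):
        # median |fitted - true| over 20 seeds under a bin width per component
        errors = {0.268: [], 0.97: []}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = np.concatenate(
                [
                    _truncated_normal(rng, 0.268, 0.06, 0.05, 1.5, 4000),
                    _truncated_normal(rng, 0.97, 0.20, 0.05, 1.5, 4000),
                ]
            )
            fit = mixture.fit_wgd_peaks(values)
            errors[0.268].append(abs(fit.peaks[0] - 0.268))
            errors[0.97].append(abs(fit.peaks[1] - 0.97))
        young_width = (0.6 - 0.05) / 200
        old_width = (1.5 - 0.6) / 200
        assert np.median(errors[0.268]) < young_width
        assert np.median(errors[0.97]) < old_width


class TestModelInterface:
    def test_summary_reports_both_components(self):
        rng = np.random.default_rng(9)
        values = np.concatenate(
            [
                _truncated_normal(rng, 0.3, 0.05, 0.05, 1.5, 1000),
                _truncated_normal(rng, 1.0, 0.15, 0.05, 1.5, 1000),
            ]
        )
        results = mixture.KsMixtureModel(values).fit()
        text = results.summary()
        assert "young" in text and "old" in text
        table = results.density_table()
        assert set(table["component"]) == {"young", "old"}
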