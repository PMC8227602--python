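import math

import pytest
from hypothesis import given, settings, strategies as st

from msicall import (
    MarkerPair,
    PanelConfig,
    Peak,
    Trace,
    allelic_variability,
    filter_noise,
    label_novel,
)
from msicall.novel_peaks import ZERO_SIGNAL_FLAG
from msicall.trace_io import NORMAL, TUMOUR


def T(sizes_signals, role=TUMOUR, marker="BAT-25"):
    return Trace("s1", marker, role, tuple(Peak(s, r) for s, r in sizes_signals))


def N(sizes_signals, marker="BAT-25"):
    return T(sizes_signals, role=NORMAL, marker=marker)


def pair(tumour, normal, marker="BAT-25"):
    return MarkerPair("s1", marker, tumour, normal)


def brute_force_novel(tumour_peaks, normal_peaks, cfg: PanelConfig):
    """Independent exhaustive check of the novelty rules, peak by peak.

    Re-derives everything with explicit loops: which normal peaks survive
    the noise filter, the extended size range, and for each noise-surviving
    tumour peak whether both novelty criteria hold.
    """
    total_n = sum(sig for _, sig in normal_peaks)
    if cfg.filter_normal:
        kept_normal = [s for s, sig in normal_peaks if sig >= cfg.noise_fraction * total_n]
    else:
        kept_normal = [s for s, _ in normal_peaks]
    assert kept_normal, "degenerate instance"
    total_t = sum(sig for _, sig in tumour_peaks)
    labels = {}
    for size, sig in tumour_peaks:
        if sig < cfg.noise_fraction * total_t:
            continue
        far_from_all = True
        for ns in kept_normal:
            if abs(size - ns) < cfg.min_novel_distance_bp:
                far_from_all = False
        inside = (
            size >= min(kept_normal) - cfg.max_outside_range_bp
            and size <= max(kept_normal) + cfg.max_outside_range_bp
        )
        labels[size] = far_from_all and inside
    return labels


class TestFilterNoise:
    def test_drops_sub_threshold_peaks(self):
        assert filter_noise(T([(100, 98), (101, 1), (102, 1)]), 0.02).sizes == (100.0,)

    def test_keeps_balanced_peaks(self):
        assert filter_noise(T([(100, 50), (102, 50)]), 0.02).sizes == (100.0, 102.0)

    def test_zero_fraction_is_identity(self):
        t = T([(100, 98), (101, 1)])
        assert filter_noise(t, 0.0).peaks == t.peaks

    def test_threshold_is_inclusive(self):
        # a peak at exactly noise_fraction x total survives
        assert filter_noise(T([(100, 98), (103, 2)]), 0.02).sizes == (100.0, 103.0)

    def test_threshold_uses_pre_filter_total(self):
        # 96/2/2: the 2s are exactly 2% of 100 and survive; they would fail
        # against any recomputed post-filter total
        assert len(filter_noise(T([(100, 96), (103, 2), (106, 2)]), 0.02).peaks) == 3

    def test_zero_signal_trace_flagged(self):
        filtered = filter_noise(T([(100, 0.0)]), 0.02)
        assert filtered.peaks == ()
        assert ZERO_SIGNAL_FLAG in filtered.qc_flags


class TestLabelNovel:
    def test_identical_traces_have_no_novel_peaks(self, config):
        sizes = [(120, 80), (121, 15), (122, 5)]
        calls = label_novel(T(sizes), N(sizes), config)
        assert all(not c.is_novel for c in calls)
        assert all(c.distance_to_nearest_normal_bp == 0 for c in calls)

    def test_shifted_peak_two_bases_away_is_novel(self, config):
        normal = N([(120, 40), (121, 40), (122, 20)])
        calls = {c.size_bp: c for c in label_novel(T([(118, 30), (120, 70)]), normal, config)}
        assert calls[118].is_novel
        assert calls[118].signal_proportion == pytest.approx(0.30)
        assert not calls[120].is_novel

    def test_peak_beyond_extended_range_never_novel(self, config):
        normal = N([(120, 30), (121, 40), (122, 30)])
        calls = {c.size_bp: c for c in label_novel(T([(135, 90), (120, 10)]), normal, config)}
        assert not calls[135].is_novel
        assert not calls[135].within_extended_range

    def test_range_bound_is_inclusive(self, config):
        calls = {c.size_bp: c for c in
                 label_novel(T([(110, 50), (109.9, 50)]), N([(120, 100)]), config)}
        assert calls[110].is_novel          # exactly 10 bp outside
        assert not calls[109.9].is_novel    # just beyond

    def test_empty_normal_raises(self, config):
        with pytest.raises(ValueError, match="empty normal"):
            label_novel(T([(120, 100)]), N([]), config)

    def test_filtered_normal_peaks_do_not_anchor_distances(self):
        # a 1% stutter remnant in the normal is filtered out, so a tumour
        # peak 1 bp from it can still be novel
        cfg = PanelConfig(filter_normal=True)
        normal = N([(120, 99), (117, 1)])
        calls = {c.size_bp: c for c in label_novel(T([(116, 30), (120, 70)]), normal, cfg)}
        assert calls[116].is_novel
        cfg_off = PanelConfig(filter_normal=False)
        calls = {c.size_bp: c for c in label_novel(T([(116, 30), (120, 70)]), normal, cfg_off)}
        assert not calls[116].is_novel

    def test_proportions_sum_to_one_pre_filter(self):
        cfg = PanelConfig(noise_fraction=0.0)
        calls = label_novel(T([(118, 30), (120, 60), (125, 10)]), N([(120, 100)]), cfg)
        assert math.isclose(sum(c.signal_proportion for c in calls), 1.0, abs_tol=1e-9)


peak_lists = st.lists(
    st.tuples(
        st.floats(min_value=100.0, max_value=150.0, allow_nan=False),
        st.floats(min_value=0.1, max_value=1000.0, allow_nan=False),
    ),
    min_size=1,
    max_size=8,
)


class TestOracleEquivalence:
    @settings(max_examples=300, derandomize=True)
    @given(tumour=peak_lists, normal=peak_lists)
    def test_matches_brute_force_on_random_instances(self, tumour, normal):
        cfg = PanelConfig()
        t, n = T(tumour), N(normal)
        total_n = sum(sig for _, sig in normal)
        if not any(sig >= cfg.noise_fraction * total_n for _, sig in normal):
            return  # brute-force precondition: normal survives its filter
        expected = brute_force_novel(
            [(p.size_bp, p.signal_rfu) for p in t.peaks],
            [(p.size_bp, p.signal_rfu) for p in n.peaks],
            cfg,
        )
        got = {c.size_bp: c.is_novel for c in label_novel(t, n, cfg)}
        assert got == expected


class TestAllelicVariability:
    def test_identical_pair_is_exactly_zero(self, config):
        sizes = [(120, 80), (121, 20)]
        r = allelic_variability(pair(T(sizes), N(sizes)), config)
        assert r.allelic_variability_pct == 0.0
        assert r.unstable is False

    def test_single_novel_peak_carries_its_share(self, config):
        r = allelic_variability(pair(T([(110, 64), (105, 36)]), N([(110, 100)])), config)
        assert r.allelic_variability_pct == pytest.approx(36.0)
        assert r.unstable is True

    def test_novel_proportions_sum(self, config):
        r = allelic_variability(
            pair(T([(110, 80), (105, 13), (116, 7)]), N([(110, 100)])), config
        )
        novel = [c for c in r.novel_calls if c.is_novel]
        assert len(novel) == 2
        assert r.allelic_variability_pct == pytest.approx(
            100 * sum(c.signal_proportion for c in novel)
        )
        assert r.allelic_variability_pct == pytest.approx(20.0)

    def test_incomplete_pair_flagged_missing(self, config):
        r = allelic_variability(pair(T([(120, 1)]), None), config)
        assert r.missing
        assert r.allelic_variability_pct is None
        assert r.unstable is None

    def test_variability_at_exact_threshold_is_stable(self, config):
        # 2% novel signal survives the (inclusive) filter but instability
        # itself requires strictly more than 2%
        r = allelic_variability(pair(T([(110, 98), (105, 2)]), N([(110, 100)])), config)
        assert r.allelic_variability_pct == pytest.approx(2.0)
        assert r.unstable is False

    @settings(max_examples=200, derandomize=True)
    @given(tumour=peak_lists, normal=peak_lists,
           scale=st.floats(min_value=0.01, max_value=1e4))
    def test_scale_invariance_and_bounds(self, tumour, normal, scale):
        cfg = PanelConfig()
        base = allelic_variability(pair(T(tumour), N(normal)), cfg)
        scaled = allelic_variability(
            pair(T([(s, sig * scale) for s, sig in tumour]), N(normal)), cfg
        )
        if base.missing:
            assert scaled.missing
            return
        assert 0.0 <= base.allelic_variability_pct <= 100.0
        assert scaled.allelic_variability_pct == pytest.approx(
            base.allelic_variability_pct, abs=1e-9
        )

    def test_filtered_peak_enters_pre_filter_denominator_only(self, config):
        # in pre-filter mode an added sub-threshold peak is never novel but
        # still dilutes every proportion; in post-filter mode it vanishes
        base = allelic_variability(pair(T([(110, 70), (105, 30)]), N([(110, 100)])), config)
        noisy_tumour = T([(110, 70), (105, 30), (130, 1)])
        pre = allelic_variability(pair(noisy_tumour, N([(110, 100)])), config)
        assert base.allelic_variability_pct == pytest.approx(30.0)
        assert pre.allelic_variability_pct == pytest.approx(100 * 30 / 101)
        post_cfg = PanelConfig(denominator_mode="post-filter")
        post = allelic_variability(pair(noisy_tumour, N([(110, 100)])), post_cfg)
        assert post.allelic_variability_pct == pytest.approx(30.0)
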