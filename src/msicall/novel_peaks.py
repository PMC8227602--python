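"""Novel-peak detection and per-marker percentage allelic variability.

The caller compares the tumour electropherogram of one microsatellite marker
against the matched normal.  A tumour peak is *novel* — evidence of an
instability-derived allele — when all of the following hold:

* it survives the noise filter (its signal is at least ``noise_fraction`` of
  the tumour trace's total signal; default 2%),
* it lies at least ``min_novel_distance_bp`` (default 2 bp) from every peak
  of the matched normal, and
* it is no more than ``max_outside_range_bp`` (default 10 bp) outside the
  range of peak sizes observed in the normal.

The marker's percentage allelic variability is 100 x the summed signal
proportion of its novel peaks; a marker strictly above the instability
threshold (default 2%) is unstable.  Stutter artifacts one repeat unit from
a true allele are handled implicitly by the 2 bp distance rule.
"""

from __future__ import annotations

from dataclasses import dataclass

from .trace_io import DEFAULT_CONFIG, MarkerPair, PanelConfig, Trace

ZERO_SIGNAL_FLAG = "zero_total_signal"


@dataclass(frozen=True)
class NovelCall:
    """Novelty assessment of one tumour peak.

    ``signal_proportion`` is the peak's share of the tumour trace's total
    signal (denominator per ``PanelConfig.denominator_mode``).
    """

    size_bp: float
    signal_rfu: float
    is_novel: bool
    distance_to_nearest_normal_bp: float
    within_extended_range: bool
    signal_proportion: float


@dataclass(frozen=True)
class MarkerResult:
    """Per-marker outcome: variability, novel calls, instability flag.

    A *missing* marker (tumour or normal trace absent, or normal empty after
    preprocessing) carries no variability and no instability verdict.
    """

    marker_id: str
    allelic_variability_pct: float | None
    novel_calls: tuple[NovelCall, ...]
    unstable: bool | None
    missing: bool = False
    qc_flags: tuple[str, ...] = ()


def filter_noise(trace: Trace, noise_fraction: float) -> Trace:
    """Drop peaks below ``noise_fraction`` of the trace's total signal.

    The threshold is computed against the *pre-filter* total; peaks exactly
    at the threshold are retained.  A trace with zero total signal comes
    back empty with a QC flag.
    """
    total = trace.total_signal
    if total == 0:
        if not trace.peaks:
            return trace
        return trace.with_peaks((), extra_flags=(ZERO_SIGNAL_FLAG,))
    cutoff = noise_fraction * total
    return trace.with_peaks(p for p in trace.peaks if p.signal_rfu >= cutoff)


def label_novel(
    tumour: Trace, normal: Trace, config: PanelConfig = DEFAULT_CONFIG
) -> tuple[NovelCall, ...]:
    """Label every noise-surviving tumour peak as novel or not.

    The normal trace is noise-filtered first when ``config.filter_normal``
    is set; distances and the size range are then taken over the remaining
    normal peaks.

    Raises
    ------
    ValueError
        If the normal trace has no peaks after preprocessing — the marker
        must be treated as missing (QC failure), which
        :func:`allelic_variability` does.
    """
    normal_eff = filter_noise(normal, config.noise_fraction) if config.filter_normal else normal
    if not normal_eff.peaks:
        raise ValueError(
            f"{normal.sample_id}/{normal.marker_id}: empty normal trace after preprocessing"
        )
    normal_sizes = normal_eff.sizes
    lo = min(normal_sizes) - config.max_outside_range_bp
    hi = max(normal_sizes) + config.max_outside_range_bp

    tumour_kept = filter_noise(tumour, config.noise_fraction)
    if config.denominator_mode == "pre-filter":
        denom = tumour.total_signal
    else:
        denom = tumour_kept.total_signal

    calls = []
    for p in tumour_kept.peaks:
        dist = min(abs(p.size_bp - s) for s in normal_sizes)
        in_range = lo <= p.size_bp <= hi
        calls.append(
            NovelCall(
                size_bp=p.size_bp,
                signal_rfu=p.signal_rfu,
                is_novel=dist >= config.min_novel_distance_bp and in_range,
                distance_to_nearest_normal_bp=dist,
                within_extended_range=in_range,
                signal_proportion=p.signal_rfu / denom if denom > 0 else 0.0,
            )
        )
    return tuple(calls)


def allelic_variability(
    pair: MarkerPair, config: PanelConfig = DEFAULT_CONFIG
) -> MarkerResult:
    """Compute the marker's percentage allelic variability from a pair.

    Returns a missing :class:`MarkerResult` when the pair is incomplete or
    the normal trace is empty after preprocessing; otherwise the variability
    is 100 x the summed signal proportion over novel peaks, and the marker
    is unstable iff the variability strictly exceeds the configured
    threshold.
    """
    if not pair.complete:
        absent = [r for r, t in ((("tumour"), pair.tumour), (("normal"), pair.normal)) if t is None]
        return MarkerResult(
            marker_id=pair.marker_id,
            allelic_variability_pct=None,
            novel_calls=(),
            unstable=None,
            missing=True,
            qc_flags=tuple(f"missing_{r}_trace" for r in absent),
        )
    try:
        calls = label_novel(pair.tumour, pair.normal, config)
    except ValueError:
        return MarkerResult(
            marker_id=pair.marker_id,
            allelic_variability_pct=None,
            novel_calls=(),
            unstable=None,
            missing=True,
            qc_flags=("empty_normal_after_filter",),
        )
    variability = 100.0 * sum(c.signal_proportion for c in calls if c.is_novel)
    # guard against float roundoff when novel peaks carry the whole trace
    variability = min(100.0, max(0.0, variability))
    flags = tuple(
        f for f in (ZERO_SIGNAL_FLAG,) if f in pair.tumour.qc_flags or not pair.tumour.peaks
    )
    if pair.tumour.total_signal == 0:
        flags = (ZERO_SIGNAL_FLAG,)
    return MarkerResult(
        marker_id=pair.marker_id,
        allelic_variability_pct=variability,
        novel_calls=calls,
        unstable=variability > config.marker_instability_threshold_pct,
        missing=False,
        qc_flags=flags,
    )
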