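"""Synthetic tumour/normal electropherogram simulator.

Stands in for the wet-lab assay (PCR of the five-marker panel followed by
capillary electrophoresis) so the caller can be exercised end-to-end with
known ground truth.  Each marker is modelled as one or two germline allele
peaks with a geometric stutter ladder below each allele (PCR slippage),
plus Poisson-count baseline noise peaks at uniform positions.  A tumour
trace is a signal-weighted mixture of the normal profile and a shifted
profile, the shift emulating the instability-derived allele; the shifted
signal share scales with the tumour fraction, which is what makes the
limit-of-detection behaviour of the caller measurable.

All randomness flows from one integer seed, split deterministically per
sample x marker x role, so any single trace is reproducible in isolation.

What this deliberately does not model: fragment-sizing error (sizes are
exact by default; ``size_jitter_bp`` exists but defaults to 0), dye
saturation, and electrophoretic mobility effects.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trace_io import (
    DEFAULT_WINDOWS,
    NORMAL,
    TUMOUR,
    Peak,
    Trace,
)


@dataclass(frozen=True)
class MarkerModel:
    """Generative model of one marker's germline electropherogram.

    ``stutter_decay`` is the per-step signal ratio of the stutter ladder:
    the k-th stutter peak sits at ``allele - k * repeat_unit_bp`` with
    signal ``main_signal_rfu * stutter_decay**k``.  Noise peaks are drawn
    Poisson(``noise_peak_rate``) per trace at uniform positions in the
    window, with signals uniform on (0, ``noise_signal_frac`` x main
    signal); the default 1% cap keeps them under the caller's 2% filter so
    ground truth stays closed-form.  ``signal_cv`` applies multiplicative
    lognormal jitter to every peak signal (run-to-run RFU variation).
    """

    marker_id: str
    repeat_unit_bp: int
    allele_sizes_bp: tuple[float, ...]
    window_bp: tuple[float, float]
    stutter_decay: float = 0.10
    n_stutter: int = 2
    main_signal_rfu: float = 1000.0
    noise_peak_rate: float = 2.0
    noise_signal_frac: float = 0.01
    signal_cv: float = 0.10
    size_jitter_bp: float = 0.0

    def __post_init__(self) -> None:
        if self.repeat_unit_bp not in (1, 2):
            raise ValueError("repeat_unit_bp must be 1 (mono) or 2 (dinucleotide)")
        if not 0.0 < self.stutter_decay < 1.0 and self.n_stutter > 0:
            raise ValueError("stutter_decay must be in (0, 1)")
        if not 1 <= len(self.allele_sizes_bp) <= 2:
            raise ValueError("1 or 2 germline alleles")
        lo, hi = self.window_bp
        for a in self.allele_sizes_bp:
            if not lo <= a <= hi:
                raise ValueError(f"allele {a} outside window {self.window_bp}")


@dataclass(frozen=True)
class TumourModel:
    """Ground truth of the simulated tumour.

    ``shift_bp`` is the signed fragment-length shift of the unstable allele
    set (deletions in microsatellite tracts make it typically negative);
    ``tumour_fraction`` is the fraction of DNA from the unstable clone.
    """

    tumour_fraction: float
    shift_bp: float = -3.0
    unstable_markers: tuple[str, ...] = ("BAT-25", "BAT-26", "D5S346")

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumour_fraction <= 1.0:
            raise ValueError("tumour_fraction must be in [0, 1]")


def default_mss_models() -> dict[str, MarkerModel]:
    """Germline models for the five-marker panel of an MSS specimen."""
    panel = {
        "BAT-25": (1, (124.0,)),
        "BAT-26": (1, (116.0,)),
        "D5S346": (2, (105.0, 113.0)),
        "D2S123": (2, (205.0, 213.0)),
        "D17S250": (2, (155.0, 163.0)),
    }
    return {
        m: MarkerModel(m, unit, alleles, DEFAULT_WINDOWS[m])
        for m, (unit, alleles) in panel.items()
    }


def default_msih_models(
    shift_bp: float = -3.0,
    unstable_markers: Sequence[str] = ("BAT-25", "BAT-26", "D5S346"),
) -> dict[str, MarkerModel]:
    """An MSI-H profile: the MSS models with shifted alleles where unstable."""
    models = default_mss_models()
    for m in unstable_markers:
        base = models[m]
        models[m] = replace(
            base, allele_sizes_bp=tuple(a + shift_bp for a in base.allele_sizes_bp)
        )
    return models


def trace_seed(root_seed: int, sample_id: str, marker_id: str, role: str) -> np.random.Generator:
    """Deterministic per-trace RNG: one root seed split by sample x marker x role."""
    entropy = [
        int(root_seed),
        zlib.crc32(sample_id.encode()),
        zlib.crc32(marker_id.encode()),
        zlib.crc32(role.encode()),
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _profile(model: MarkerModel) -> dict[float, float]:
    """Noise-free expected signal by position: alleles plus stutter ladder."""
    prof: dict[float, float] = {}
    for a in model.allele_sizes_bp:
        for k in range(model.n_stutter + 1):
            pos = a - k * model.repeat_unit_bp
            prof[pos] = prof.get(pos, 0.0) + model.main_signal_rfu * model.stutter_decay**k
    return prof


def _mix_profiles(
    normal: Mapping[float, float], shifted: Mapping[float, float], fraction: float
) -> dict[float, float]:
    mixed: dict[float, float] = {}
    for pos, sig in normal.items():
        mixed[pos] = mixed.get(pos, 0.0) + (1.0 - fraction) * sig
    for pos, sig in shifted.items():
        mixed[pos] = mixed.get(pos, 0.0) + fraction * sig
    return {pos: sig for pos, sig in mixed.items() if sig > 0.0}


def _realize(
    profile: Mapping[float, float],
    model: MarkerModel,
    rng: np.random.Generator,
    sample_id: str,
    role: str,
) -> Trace:
    """Turn an expected profile into a concrete noisy trace."""
    peaks = []
    for pos in sorted(profile):
        sig = profile[pos]
        if model.signal_cv > 0:
            sig *= rng.lognormal(mean=0.0, sigma=model.signal_cv)
        if model.size_jitter_bp > 0:
            pos = pos + rng.normal(0.0, model.size_jitter_bp)
        peaks.append(Peak(pos, sig))
    lo, hi = model.window_bp
    for _ in range(rng.poisson(model.noise_peak_rate)):
        peaks.append(
            Peak(
                rng.uniform(lo, hi),
                rng.uniform(0.0, model.noise_signal_frac * model.main_signal_rfu),
            )
        )
    return Trace(sample_id, model.marker_id, role, tuple(peaks))


def make_normal_trace(model: MarkerModel, seed: int, sample_id: str = "synthetic") -> Trace:
    """Simulate the matched-normal trace of one marker. Deterministic per seed."""
    rng = trace_seed(seed, sample_id, model.marker_id, NORMAL)
    return _realize(_profile(model), model, rng, sample_id, NORMAL)


def make_tumour_trace(
    model: MarkerModel,
    tmodel: TumourModel,
    seed: int,
    sample_id: str = "synthetic",
) -> Trace:
    """Simulate the tumour trace: a (1-f):f mixture of normal and shifted profiles.

    For markers outside ``tmodel.unstable_markers`` (or at tumour fraction
    0) the profile is purely germline; note the *noise* realisation still
    uses the tumour role's RNG stream, so tumour and normal traces of a
    stable marker differ only in their noise peaks.
    """
    rng = trace_seed(seed, sample_id, model.marker_id, TUMOUR)
    base = _profile(model)
    if model.marker_id in tmodel.unstable_markers and tmodel.tumour_fraction > 0:
        shifted_model = replace(
            model,
            allele_sizes_bp=tuple(a + tmodel.shift_bp for a in model.allele_sizes_bp),
        )  # validates the shifted alleles stay inside the window
        profile = _mix_profiles(base, _profile(shifted_model), tmodel.tumour_fraction)
    else:
        profile = base
    return _realize(profile, model, rng, sample_id, TUMOUR)


def simulate_sample(
    sample_id: str,
    tmodel: TumourModel,
    seed: int,
    models: Mapping[str, MarkerModel] | None = None,
) -> list[Trace]:
    """All ten traces (five markers x tumour/normal) of one synthetic specimen."""
    models = models or default_mss_models()
    traces = []
    for model in models.values():
        traces.append(make_normal_trace(model, seed, sample_id))
        traces.append(make_tumour_trace(model, tmodel, seed, sample_id))
    return traces


def traces_to_frame(traces: Sequence[Trace]) -> pd.DataFrame:
    """Flatten traces into the delimited peak-table format trace_io reads."""
    rows = [
        {
            "sample_id": t.sample_id,
            "marker": t.marker_id,
            "role": t.role,
            "size_bp": p.size_bp,
            "rfu": p.signal_rfu,
        }
        for t in traces
        for p in t.peaks
    ]
    return pd.DataFrame(rows, columns=["sample_id", "marker", "role", "size_bp", "rfu"])


DEFAULT_FRACTIONS = (0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 1.00)


def mixing_series(
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    msih_models: Mapping[str, MarkerModel] | None = None,
    mss_models: Mapping[str, MarkerModel] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an MSI-H-into-MSS cell-line dilution series.

    One synthetic specimen per mixing fraction: the tumour trace mixes the
    MSI-H profile into the MSS profile at that fraction, the matched normal
    is the unmixed MSS profile.  Returns ``(peak_table, ground_truth)``
    DataFrames; the peak table is in the format :func:`trace_io.read_peak_table`
    accepts and the ground truth records fraction and shifted markers.
    """
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"mixing fraction must be in [0, 1], got {f}")
    mss = dict(mss_models or default_mss_models())
    msih = dict(msih_models or default_msih_models())
    if set(mss) != set(msih):
        raise ValueError("MSS and MSI-H model panels must cover the same markers")

    traces: list[Trace] = []
    truth_rows = []
    for f in fractions:
        sid = f"mix{int(round(100 * f)):03d}"
        shifted_markers = [
            m for m in mss if _profile(msih[m]) != _profile(mss[m])
        ]
        for m, model in mss.items():
            rng_n = trace_seed(seed, sid, m, NORMAL)
            traces.append(_realize(_profile(model), model, rng_n, sid, NORMAL))
            rng_t = trace_seed(seed, sid, m, TUMOUR)
            profile = _mix_profiles(_profile(model), _profile(msih[m]), f)
            traces.append(_realize(profile, model, rng_t, sid, TUMOUR))
        truth_rows.append(
            {
                "sample_id": sid,
                "tumour_fraction": f,
                "shifted_markers": ";".join(sorted(shifted_markers)),
            }
        )
    return traces_to_frame(traces), pd.DataFrame(truth_rows)


def pair_from_variability(
    marker_id: str,
    variability_pct: float,
    sample_id: str = "synthetic",
    total_rfu: float = 1000.0,
):
    """Degenerate tumour/normal pair whose allelic variability is exact.

    Normal: one allele peak mid-window.  Tumour: the same allele carrying
    ``100 - v`` percent of the signal plus one shifted peak 5 bp below
    carrying ``v`` percent — far enough to be novel, inside the extended
    range.  Useful for turning tabulated per-marker percentages back into
    traces the full pipeline can consume.
    """
    from .trace_io import MarkerPair

    if not 0.0 <= variability_pct <= 100.0:
        raise ValueError("variability_pct must be in [0, 100]")
    lo, hi = DEFAULT_WINDOWS[marker_id]
    allele = round((lo + hi) / 2.0)
    normal = Trace(sample_id, marker_id, NORMAL, (Peak(allele, total_rfu),))
    v = variability_pct / 100.0
    tumour_peaks = []
    if v < 1.0:
        tumour_peaks.append(Peak(allele, (1.0 - v) * total_rfu))
    if v > 0.0:
        tumour_peaks.append(Peak(allele - 5.0, v * total_rfu))
    tumour = Trace(sample_id, marker_id, TUMOUR, tuple(tumour_peaks))
    return MarkerPair(sample_id, marker_id, tumour, normal)
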