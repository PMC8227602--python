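"""Sample-level MSI classification.

Two classification systems run side by side on the five per-marker
percentage allelic variabilities:

* **NCI marker-count rule** — a marker is unstable when its variability
  strictly exceeds 2%; 0 unstable markers -> MSS, exactly 1 -> MSI-L,
  >=2 -> MSI-H.
* **MSI score** — the sum of the five variabilities (range 0-500), tiered
  as MSS (< 3), MSI-L (3-5 inclusive) and MSI-H (> 5).  Scores of exactly 5
  are MSI-L; the MSS tier extends down to 0.

The two systems can legitimately disagree near the boundaries (e.g. five
markers each at 1% are individually stable yet sum into the MSI-L tier).
For MSI-H samples the score doubles as the *Toh score*, a measure of the
degree of allelic instability.  Classification always runs on unrounded
variabilities; rounding is a display concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .novel_peaks import MarkerResult, allelic_variability
from .trace_io import DEFAULT_CONFIG, MSI_H, MSI_L, MSS, MarkerPair, PanelConfig

NA = "NA"

ALL_MISSING_FLAG = "all_markers_missing"
MISSING_MARKER_FLAG = "missing_markers"


@dataclass(frozen=True)
class SampleResult:
    """Full classification of one specimen across the five-marker panel."""

    sample_id: str
    marker_results: Mapping[str, MarkerResult]
    n_unstable: int | None
    nci_status: str
    msi_score: float | None
    score_status: str
    max_variability_pct: float | None
    toh_score: float | None
    qc_flags: tuple[str, ...] = ()


def _present(marker_results: Sequence[MarkerResult]) -> list[MarkerResult]:
    return [m for m in marker_results if not m.missing]


def nci_status(marker_results: Sequence[MarkerResult]) -> tuple[int | None, str]:
    """Unstable-marker count and the traditional marker-count status.

    0 unstable -> MSS, 1 -> MSI-L, >=2 -> MSI-H, computed over non-missing
    markers.  All five missing -> (None, NA).
    """
    present = _present(marker_results)
    if not present:
        return None, NA
    n = sum(1 for m in present if m.unstable)
    if n == 0:
        return n, MSS
    if n == 1:
        return n, MSI_L
    return n, MSI_H


def msi_score(marker_results: Sequence[MarkerResult]) -> float | None:
    """Total allelic variability: the unrounded sum over non-missing markers."""
    present = _present(marker_results)
    if not present:
        return None
    return sum(m.allelic_variability_pct for m in present)


def score_status(score: float | None, config: PanelConfig = DEFAULT_CONFIG) -> str:
    """Tier an MSI score: MSS below the MSI-L band, MSI-H strictly above it."""
    if score is None:
        return NA
    if score < config.score_msil_min:
        return MSS
    if score <= config.score_msil_max:
        return MSI_L
    return MSI_H


def summarize_sample(
    sample_id: str,
    marker_results: Mapping[str, MarkerResult],
    config: PanelConfig = DEFAULT_CONFIG,
) -> SampleResult:
    """Assemble the per-sample result from five marker results.

    ``toh_score`` equals the MSI score when the score tier is MSI-H, and is
    absent otherwise.  Missing markers are summarised over the remaining
    markers with a QC flag; the score stays a plain sum (not rescaled).
    """
    ordered = [marker_results[m] for m in marker_results]
    present = _present(ordered)
    n, nci = nci_status(ordered)
    score = msi_score(ordered)
    tier = score_status(score, config)
    max_var = max((m.allelic_variability_pct for m in present), default=None)
    flags: list[str] = []
    n_missing = len(ordered) - len(present)
    if n_missing == len(ordered):
        flags.append(ALL_MISSING_FLAG)
    elif n_missing:
        flags.append(f"{MISSING_MARKER_FLAG}:{n_missing}")
    for m in ordered:
        flags.extend(f"{m.marker_id}:{f}" for f in m.qc_flags)
    return SampleResult(
        sample_id=sample_id,
        marker_results=dict(marker_results),
        n_unstable=n,
        nci_status=nci,
        msi_score=score,
        score_status=tier,
        max_variability_pct=max_var,
        toh_score=score if tier == MSI_H else None,
        qc_flags=tuple(flags),
    )


def call_sample(
    pairs: Mapping[str, MarkerPair], config: PanelConfig = DEFAULT_CONFIG
) -> SampleResult:
    """Run the full caller on one sample's marker pairs."""
    sample_id = next(iter(pairs.values())).sample_id
    results = {m: allelic_variability(p, config) for m, p in pairs.items()}
    return summarize_sample(sample_id, results, config)


def call_samples(
    grouped: Mapping[str, Mapping[str, MarkerPair]], config: PanelConfig = DEFAULT_CONFIG
) -> list[SampleResult]:
    """Run the caller on every sample of a parsed peak table."""
    return [call_sample(pairs, config) for pairs in grouped.values()]


def sample_result_from_variabilities(
    sample_id: str,
    variabilities: Mapping[str, float | None],
    config: PanelConfig = DEFAULT_CONFIG,
) -> SampleResult:
    """Classify directly from known per-marker variabilities (no traces).

    Used when per-marker percentages are already tabulated (e.g. a published
    cohort) and only the classification layer is needed; ``None`` marks a
    missing marker.
    """
    results = {}
    for marker, v in variabilities.items():
        if v is None:
            results[marker] = MarkerResult(marker, None, (), None, missing=True)
        else:
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"variability must be in [0, 100], got {v} for {marker}")
            results[marker] = MarkerResult(
                marker, float(v), (), float(v) > config.marker_instability_threshold_pct
            )
    return summarize_sample(sample_id, results, config)
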