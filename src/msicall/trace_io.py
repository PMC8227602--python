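"""Peak-table and label I/O, core domain types and panel configuration.

The instrument side of the assay is abstracted to a *peak table*: one row per
detected fragment peak, carrying the sample it came from, the microsatellite
marker amplified, whether the trace is tumour or matched normal, the fragment
size in base pairs and the peak signal in relative fluorescence units (RFU).
This module reads and validates such tables, pairs tumour and normal traces
per marker, and writes per-sample reports.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MSS = "MSS"
MSI_L = "MSI-L"
MSI_H = "MSI-H"

TUMOUR = "tumour"
NORMAL = "normal"

#: The Bethesda/NCI consensus panel: two mononucleotide repeats and three
#: dinucleotide repeats.  Order is the conventional reporting order.
DEFAULT_MARKERS = ("BAT-25", "BAT-26", "D5S346", "D2S123", "D17S250")

#: Default per-marker size gates (bp), generous windows around the expected
#: amplicon ranges; peaks outside are primer/ladder artifacts and are dropped
#: before any computation.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "BAT-25": (90.0, 150.0),
    "BAT-26": (90.0, 150.0),
    "D5S346": (80.0, 140.0),
    "D2S123": (180.0, 250.0),
    "D17S250": (130.0, 200.0),
}


class PeakTableError(ValueError):
    """Malformed peak table (bad value, unknown marker, missing column)."""


class LabelTableError(ValueError):
    """Malformed IHC label table."""


@dataclass(frozen=True)
class Peak:
    """One detected fragment: size in base pairs, signal in RFU."""

    size_bp: float
    signal_rfu: float

    def __post_init__(self) -> None:
        if not self.size_bp > 0:
            raise ValueError(f"peak size must be positive, got {self.size_bp}")
        if self.signal_rfu < 0:
            raise ValueError(f"peak signal must be non-negative, got {self.signal_rfu}")


@dataclass(frozen=True)
class Trace:
    """All peaks for one sample x marker x role, ordered by fragment size.

    Peaks at identical sizes are merged by summing signal: a single position
    on the electropherogram cannot carry two peaks.
    """

    sample_id: str
    marker_id: str
    role: str
    peaks: tuple[Peak, ...]
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in (TUMOUR, NORMAL):
            raise ValueError(f"role must be {TUMOUR!r} or {NORMAL!r}, got {self.role!r}")
        merged = merge_duplicate_sizes(self.peaks)
        object.__setattr__(self, "peaks", merged)

    @property
    def total_signal(self) -> float:
        return sum(p.signal_rfu for p in self.peaks)

    @property
    def sizes(self) -> tuple[float, ...]:
        return tuple(p.size_bp for p in self.peaks)

    def with_peaks(self, peaks: Iterable[Peak], extra_flags: tuple[str, ...] = ()) -> "Trace":
        return replace(self, peaks=tuple(peaks), qc_flags=self.qc_flags + extra_flags)


def merge_duplicate_sizes(peaks: Iterable[Peak]) -> tuple[Peak, ...]:
    """Sort peaks by size and merge exact duplicates by summing signal."""
    by_size: dict[float, float] = {}
    for p in peaks:
        by_size[p.size_bp] = by_size.get(p.size_bp, 0.0) + p.signal_rfu
    return tuple(Peak(s, by_size[s]) for s in sorted(by_size))


@dataclass(frozen=True)
class MarkerPair:
    """Tumour and matched-normal trace for one marker of one specimen.

    Either trace may be absent (FFPE dropout is common); an incomplete pair
    is carried through the pipeline as a *missing* marker, never an error.
    """

    sample_id: str
    marker_id: str
    tumour: Trace | None
    normal: Trace | None

    def __post_init__(self) -> None:
        for t in (self.tumour, self.normal):
            if t is not None and t.marker_id != self.marker_id:
                raise ValueError(
                    f"trace marker {t.marker_id!r} does not match pair marker {self.marker_id!r}"
                )

    @property
    def complete(self) -> bool:
        return self.tumour is not None and self.normal is not None


@dataclass(frozen=True)
class IhcLabel:
    """Immunohistochemistry MSI status for one specimen.

    IHC reads mismatch-repair protein expression, so it is binary: MSS or
    MSI-H.  It can never yield MSI-L.
    """

    sample_id: str
    status: str
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.status not in (MSS, MSI_H):
            raise ValueError(
                f"IHC status must be {MSS!r} or {MSI_H!r} (IHC cannot call MSI-L); "
                f"got {self.status!r} for sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class PanelConfig:
    """All tunable thresholds of the caller.

    Parameters
    ----------
    markers
        Marker name -> (min_bp, max_bp) size gate.  Exactly five markers:
        the MSI score is a sum of five percentages, hence "/500".
    noise_fraction
        Peaks carrying less than this fraction of a trace's total signal are
        filtered as potential noise (default 0.02, i.e. the 2% noise floor;
        adjustable per laboratory calibration).
    min_novel_distance_bp
        A tumour peak must lie at least this far (bp) from every peak of the
        matched normal to count as novel (default 2, inclusive).
    max_outside_range_bp
        A tumour peak more than this far (bp) outside the normal trace's
        peak-size range is treated as an artifact, never novel (default 10,
        inclusive bounds).
    marker_instability_threshold_pct
        A marker whose percentage allelic variability strictly exceeds this
        is unstable (default 2.0).
    score_msil_min, score_msil_max
        MSI-score tier bounds: score < msil_min -> MSS, msil_min <= score <=
        msil_max -> MSI-L, score > msil_max -> MSI-H (defaults 3 and 5).
    filter_normal
        Whether the noise filter is also applied to the normal trace before
        distances and the size range are computed (default True).
    denominator_mode
        "pre-filter" (default): signal proportions are over the gated tumour
        trace's total signal before noise filtering; "post-filter": over the
        total after filtering.
    """

    markers: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    noise_fraction: float = 0.02
    min_novel_distance_bp: float = 2.0
    max_outside_range_bp: float = 10.0
    marker_instability_threshold_pct: float = 2.0
    score_msil_min: float = 3.0
    score_msil_max: float = 5.0
    filter_normal: bool = True
    denominator_mode: str = "pre-filter"

    def __post_init__(self) -> None:
        if len(self.markers) != 5:
            raise ValueError(
                f"the panel is fixed at five markers (score is /500); got {len(self.markers)}"
            )
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError(f"noise_fraction must be in [0, 1), got {self.noise_fraction}")
        for name, value in (
            ("min_novel_distance_bp", self.min_novel_distance_bp),
            ("max_outside_range_bp", self.max_outside_range_bp),
            ("marker_instability_threshold_pct", self.marker_instability_threshold_pct),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not self.score_msil_min <= self.score_msil_max:
            raise ValueError("score tier bounds must satisfy msil_min <= msil_max")
        if self.denominator_mode not in ("pre-filter", "post-filter"):
            raise ValueError(f"unknown denominator_mode {self.denominator_mode!r}")
        for name, (lo, hi) in self.markers.items():
            if not lo < hi:
                raise ValueError(f"marker {name!r}: window must satisfy min < max")

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(self.markers)

    def window(self, marker_id: str) -> tuple[float, float]:
        return self.markers[marker_id]

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelConfig":
        """Build a config from a plain mapping (e.g. parsed YAML)."""
        d = dict(d)
        if "markers" in d:
            d["markers"] = {k: (float(v[0]), float(v[1])) for k, v in dict(d["markers"]).items()}
        return cls(**d)


DEFAULT_CONFIG = PanelConfig()

#: Default column names of the delimited peak table; remappable at read time.
PEAK_COLUMNS = {
    "sample_id": "sample_id",
    "marker": "marker",
    "role": "role",
    "size_bp": "size_bp",
    "rfu": "rfu",
}


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read comma- or tab-delimited text with a header, all columns as str."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)


def gate_trace(trace: Trace, config: PanelConfig) -> Trace:
    """Drop peaks outside the marker's size window.  Idempotent."""
    lo, hi = config.window(trace.marker_id)
    kept = tuple(p for p in trace.peaks if lo <= p.size_bp <= hi)
    n_dropped = len(trace.peaks) - len(kept)
    if n_dropped:
        logger.info(
            "%s/%s/%s: dropped %d peak(s) outside window [%g, %g]",
            trace.sample_id, trace.marker_id, trace.role, n_dropped, lo, hi,
        )
    return trace.with_peaks(kept)


def read_peak_table(
    path: str | Path,
    config: PanelConfig = DEFAULT_CONFIG,
    column_map: Mapping[str, str] | None = None,
) -> dict[str, dict[str, MarkerPair]]:
    """Read a delimited peak table into marker pairs grouped by sample.

    Returns ``{sample_id: {marker_id: MarkerPair}}`` with one entry per panel
    marker per sample.  A marker with no tumour or no normal trace yields an
    incomplete pair (flagged missing downstream), not an error.

    Raises
    ------
    PeakTableError
        On a missing column, a non-numeric size/signal (named by line
        number), an unknown marker name, or an invalid role.
    """
    cols = dict(PEAK_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = _read_delimited(path)
    missing_cols = [c for c in cols.values() if c not in df.columns]
    if missing_cols:
        raise PeakTableError(f"peak table {path}: missing column(s) {missing_cols}")

    accepted = set(config.marker_names)
    role_alias = {"tumour": TUMOUR, "tumor": TUMOUR, "normal": NORMAL}
    # line numbers: header is line 1, first data row line 2
    peaks: dict[tuple[str, str, str], list[Peak]] = {}
    for idx, row in df.iterrows():
        line_no = int(idx) + 2
        marker = row[cols["marker"]]
        if marker not in accepted:
            raise PeakTableError(
                f"line {line_no}: unknown marker {marker!r}; accepted: {sorted(accepted)}"
            )
        role_raw = str(row[cols["role"]]).strip().lower()
        if role_raw not in role_alias:
            raise PeakTableError(f"line {line_no}: role must be tumour or normal, got {role_raw!r}")
        try:
            size = float(row[cols["size_bp"]])
            rfu = float(row[cols["rfu"]])
        except (TypeError, ValueError):
            raise PeakTableError(
                f"line {line_no}: non-numeric size_bp/rfu "
                f"({row[cols['size_bp']]!r}, {row[cols['rfu']]!r})"
            ) from None
        key = (str(row[cols["sample_id"]]), marker, role_alias[role_raw])
        try:
            peaks.setdefault(key, []).append(Peak(size, rfu))
        except ValueError as exc:
            raise PeakTableError(f"line {line_no}: {exc}") from None

    sample_ids = sorted({k[0] for k in peaks})
    out: dict[str, dict[str, MarkerPair]] = {}
    for sid in sample_ids:
        out[sid] = {}
        for marker in config.marker_names:
            traces: dict[str, Trace | None] = {}
            for role in (TUMOUR, NORMAL):
                plist = peaks.get((sid, marker, role))
                if plist is None:
                    traces[role] = None
                else:
                    traces[role] = gate_trace(
                        Trace(sid, marker, role, tuple(plist)), config
                    )
            out[sid][marker] = MarkerPair(sid, marker, traces[TUMOUR], traces[NORMAL])
    return out


def read_ihc_labels(path: str | Path) -> dict[str, IhcLabel]:
    """Read a delimited IHC label table (sample_id, ihc_status[, subgroup]).

    Raises
    ------
    LabelTableError
        On a duplicate sample_id or a status outside {MSS, MSI-H}.
    """
    df = _read_delimited(path)
    for col in ("sample_id", "ihc_status"):
        if col not in df.columns:
            raise LabelTableError(f"label table {path}: missing column {col!r}")
    labels: dict[str, IhcLabel] = {}
    for idx, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in labels:
            raise LabelTableError(f"duplicate sample_id {sid!r} in label table")
        subgroup = None
        if "subgroup" in df.columns and pd.notna(row["subgroup"]):
            subgroup = str(row["subgroup"])
        try:
            labels[sid] = IhcLabel(sid, str(row["ihc_status"]).strip(), subgroup)
        except ValueError as exc:
            raise LabelTableError(f"line {int(idx) + 2}: {exc}") from None
    return labels


def _round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _report_records(results: Sequence, marker_order: Sequence[str]) -> list[dict]:
    records = []
    for r in results:
        rec: dict = {"sample_id": r.sample_id}
        for m in marker_order:
            mr = r.marker_results[m]
            rec[m] = None if mr.missing else _round_half_up(mr.allelic_variability_pct)
        rec["n_unstable"] = r.n_unstable
        rec["nci_status"] = r.nci_status
        rec["max_variability_pct"] = (
            None if r.max_variability_pct is None else _round_half_up(r.max_variability_pct)
        )
        rec["msi_score"] = None if r.msi_score is None else _round_half_up(r.msi_score)
        rec["score_status"] = r.score_status
        rec["toh_score"] = None if r.toh_score is None else _round_half_up(r.toh_score)
        rec["qc_flags"] = ";".join(r.qc_flags)
        # full-precision values so a parsed JSON report reproduces every field
        rec["exact"] = {
            "variability_pct": {
                m: (None if r.marker_results[m].missing else r.marker_results[m].allelic_variability_pct)
                for m in marker_order
            },
            "msi_score": r.msi_score,
            "max_variability_pct": r.max_variability_pct,
            "toh_score": r.toh_score,
        }
        records.append(rec)
    return records


def write_report(
    results: Sequence,
    path: str | Path,
    format: str = "tsv",
    marker_order: Sequence[str] = DEFAULT_MARKERS,
) -> None:
    """Write per-sample results as TSV or JSON.

    Percent columns are displayed as integers (half-up); the JSON format
    additionally carries the exact unrounded values under ``exact``.  Output
    is byte-stable across runs on identical input.
    """
    if not results:
        raise ValueError("no results to report")
    records = _report_records(results, marker_order)
    path = Path(path)
    if format == "json":
        text = json.dumps(records, indent=2, sort_keys=False)
        path.write_text(text + "\n")
    elif format == "tsv":
        buf = io.StringIO()
        cols = [c for c in records[0] if c != "exact"]
        buf.write("\t".join(cols) + "\n")
        for rec in records:
            buf.write("\t".join("NA" if rec[c] is None else str(rec[c]) for c in cols) + "\n")
        path.write_text(buf.getvalue())
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path: str | Path) -> list[dict]:
    """Parse a JSON report back into its records (exact values included)."""
    return json.loads(Path(path).read_text())
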