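"""Packaged reference tables.

Two small tab-separated tables ship with the package:

``patient_cohort.tsv``
    A 56-specimen colorectal-cancer reference cohort: per-marker percentage
    allelic variabilities (integer percent) for the five-marker panel, the
    IHC status (MSS or MSI-H), the subgroup label (MSS, MSI-H:BRAF-mutant,
    MSI-H:BRAF-wild-type) and, for cross-checking, the classifications as
    originally reported.

``dilution_series.tsv``
    A cell-line limit-of-detection experiment: an MSI-H line mixed into an
    MSS line at 5-100%, with the per-marker variabilities measured at each
    mixing fraction.

These drive the golden classification and concordance tests and the worked
examples; the variabilities are inputs here (the peak-level data behind
them is not published), so they enter the pipeline at the classification
layer via :func:`msicall.classify.sample_result_from_variabilities`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classify import SampleResult, sample_result_from_variabilities
from .trace_io import DEFAULT_CONFIG, DEFAULT_MARKERS, IhcLabel, PanelConfig


def _load(name: str) -> pd.DataFrame:
    with resources.files("msicall.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"sample_id": str})


def load_patient_cohort() -> pd.DataFrame:
    """The 56-specimen reference cohort as a DataFrame."""
    return _load("patient_cohort.tsv")


def load_dilution_series() -> pd.DataFrame:
    """The MSI-H-into-MSS dilution series as a DataFrame."""
    return _load("dilution_series.tsv")


def cohort_results(
    config: PanelConfig = DEFAULT_CONFIG,
) -> tuple[list[SampleResult], dict[str, IhcLabel]]:
    """Classify the reference cohort and return results with IHC labels."""
    df = load_patient_cohort()
    results = [
        sample_result_from_variabilities(
            row["sample_id"],
            {m: float(row[m]) for m in DEFAULT_MARKERS},
            config,
        )
        for _, row in df.iterrows()
    ]
    labels = {
        row["sample_id"]: IhcLabel(row["sample_id"], row["ihc_status"], row["subgroup"])
        for _, row in df.iterrows()
    }
    return results, labels


def dilution_results(config: PanelConfig = DEFAULT_CONFIG) -> list[SampleResult]:
    """Classify the dilution series from its tabulated variabilities."""
    df = load_dilution_series()
    return [
        sample_result_from_variabilities(
            row["sample_id"], {m: float(row[m]) for m in DEFAULT_MARKERS}, config
        )
        for _, row in df.iterrows()
    ]
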