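"""Packaged example data."""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .count_table import CategoryCountVector, read_count_table


def seer_table1_path() -> Path:
    """Path of the packaged SEER 17-registry aggregated count table.

    Counts of U.S. cancer patients by age group (15 bins), sex, and cancer
    site group (Breast, Colorectal, Genitourinary, Lung, Melanoma) for the
    years 2000 and 2015-2020, as published by the SEER*Stat rate sessions.
    Site groups overlap (one patient can contribute to several), so shares
    are meaningful within a variable only.
    """
    return Path(str(files("psidrift").joinpath("data/seer_table1.csv")))


def load_seer_table1() -> list[CategoryCountVector]:
    """The packaged table as one count vector per (variable, year)."""
    return read_count_table(seer_table1_path())
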