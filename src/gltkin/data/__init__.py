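"""Bundled reference tables (published initial-rate and fit values)."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def fixture_path(name: str):
    """Filesystem path of a bundled CSV fixture."""
    return resources.files(__package__) / name


def load_table1():
    """Initial-rate grid (mean +/- SEM, min^-1) as a RateTable."""
    from ..fitting import RateTable

    return RateTable.from_csv(fixture_path("glttk_table1.csv"),
                              metadata={"label": "GltTk mixed-orientation grid"})


def load_table2_reference() -> pd.DataFrame:
    """Published apparent aspartate vmax/K_M values per [Na+] row."""
    return pd.read_csv(fixture_path("glttk_table2.csv"), comment="#")


def load_table3_vmax() -> pd.DataFrame:
    """Published apparent sodium vmax values per [Asp] column."""
    return pd.read_csv(fixture_path("glttk_table3_vmax.csv"), comment="#")
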