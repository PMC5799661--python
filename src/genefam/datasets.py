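"""Bundled published data tables for the grape bHLH family."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("genefam.data").joinpath(name)
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def cold_stress_replicates() -> pd.DataFrame:
    """Published cold-stress replicate intensities for grape bHLH genes.

    Three paired control (ck1-3) and cold-treatment (cold1-3) replicates per
    gene and timepoint, plus the means, fold changes and p-values as printed
    in the source table.
    """
    return _read("grape_cold_stress_replicates.tsv")


def triplicate_group_omega() -> pd.DataFrame:
    """Published Ka/Ks values for member pairs of the nine triplicated groups."""
    return _read("grape_triplicate_omega.tsv")
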