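"""Packaged survey tables.

Two small delimited tables transcribed from the printed report of the emulated
survey ship the package's worked examples and regression anchors:

* ``load_contribution_inputs`` — per station x UCYN-A sublineage measured inputs
  (single-cell rate, nifH abundance, community rate) together with the printed
  derived values (volumetric rate, % contribution, dilution-corrected maxima),
  used to exercise and cross-check the scaling engine.
* ``load_hydrochemistry`` — station/depth hydrochemistry (temperature, salinity,
  nutrients, chlorophyll) with printed P* and volumetric rates.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_contribution_inputs", "load_hydrochemistry"]


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("n2fix.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, **kwargs)


def load_contribution_inputs() -> pd.DataFrame:
    """Measured inputs and printed outputs of the contribution table."""
    printed = ["printed_volumetric", "printed_contribution_pct",
               "printed_max_cell_nfr", "printed_max_volumetric",
               "printed_max_contribution_pct"]
    # printed columns stay strings so their printed precision is preserved
    df = _read("sccs_contribution_inputs.csv",
               dtype={"station": str, **{c: str for c in printed}})
    df["community_nfr_is_lod"] = df["community_nfr_is_lod"].astype(bool)
    return df


def load_hydrochemistry() -> pd.DataFrame:
    """Station/depth hydrochemistry with printed P* and rate columns."""
    df = _read("sccs_hydrochemistry.csv", dtype={"station": str})
    df["is_dcm"] = df["is_dcm"].astype(bool)
    return df
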