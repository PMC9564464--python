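"""Packaged worked-example tables for a 31-region pollution network.

The package ships a transcription of a published 2020 analysis of the
inter-provincial PM2.5 association network of mainland China: the
per-province centrality table, the four-block flow summary, the block
density matrix, the binary image matrix, and the block membership lists.
They serve as ground truth for the report-level arithmetic (means, sums,
ratios, thresholding) without requiring the non-redistributable raw
panel.  Files are verified against frozen SHA-256 checksums on load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["FixtureTables", "FixtureIntegrityError", "load_fixtures"]

_CHECKSUMS = {
    "table1_centrality.tsv":
        "2d91195558259e69428382b229a5a42af2a0655b6057386288f4c2ab4e86077c",
    "table2_block_flows.tsv":
        "7ab8b71a48704e810122db2c6737f3bb688c6d2d159a13275338fd2b80b499c0",
    "table3_block_density.tsv":
        "ba865b504a0a30e85caf65ecfd8129663a5127d737c0859b222033c0ad4ae369",
    "table4_image_matrix.tsv":
        "a05b8186cb74cdb2462268e5dd5e926636cfe3202a52c6b573fe56998c0f02b6",
    "block_membership.tsv":
        "f7ac10b46fad4110082a8b6c006b9d6bb8f110e8945c6486af7df6de74d7c0c1",
}


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture file does not match its frozen checksum."""


@dataclass
class FixtureTables:
    """The transcribed report tables of the worked example.

    table1: per-province in-degree, out-degree, degree, betweenness and
        closeness centrality (percent conventions), indexed by province.
    table2: per-block inside/outside received/sent tie counts with the
        printed expected and actual internal-tie ratios.
    table3: 4x4 block-to-block density matrix.
    table4: 4x4 binary image matrix (densities cut at overall density).
    membership: province -> block assignment (blocks I..IV, sizes
        6/5/9/11).
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    membership: pd.Series

    @property
    def block_sizes(self) -> pd.Series:
        return self.membership.value_counts().reindex(list(self.table2.index))


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("spanet.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"fixture {name} is corrupted (sha256 {digest[:12]}... does not "
            f"match the packaged checksum)"
        )
    return pd.read_csv(ref.open("r"), sep="\t", index_col=0)


def load_fixtures() -> FixtureTables:
    """Load and integrity-check the packaged worked-example tables."""
    t1 = _read("table1_centrality.tsv")
    t2 = _read("table2_block_flows.tsv")
    t3 = _read("table3_block_density.tsv")
    t4 = _read("table4_image_matrix.tsv")
    mem = _read("block_membership.tsv")["block"]
    return FixtureTables(t1, t2, t3, t4, mem)
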