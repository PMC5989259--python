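import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from intervaltree import IntervalTree

from poolscan.io import GeneModel

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_site_table(rows, pools=("p",)):
    """Build a site table from (scaffold, pos, ref, alt, qual, {pool: (ref, alt)})."""
    cols = ["scaffold", "pos", "ref", "alt", "base_quality"] + [
        f"{p}.{k}" for p in pools for k in ("ref", "alt")
    ]
    data = []
    for scaffold, pos, ref, alt, qual, counts in rows:
        row = [scaffold, pos, ref, alt, qual]
        for p in pools:
            row.extend(counts[p])
        data.append(row)
    df = pd.DataFrame(data, columns=cols)
    return df.astype({"pos": np.int64, **{c: np.int64 for c in cols[5:]}})


@pytest.fixture
def filter_fixture():
    """Five sites, one per failure mode plus one clean site.

    Depths are 1, 2, 120, 30, 30 (mean 36.6), so the third site exceeds
    3x the mean; the fourth sits inside the SSR mask.
    """
    sites = make_site_table(
        [
            ("scaffold1", 10, "A", "C", 30.0, {"p": (1, 0)}),      # depth < 2
            ("scaffold1", 20, "A", "C", 30.0, {"p": (1, 1)}),      # het at depth 2
            ("scaffold1", 30, "A", "C", 30.0, {"p": (60, 60)}),    # > 3x mean depth
            ("scaffold1", 40, "A", "C", 30.0, {"p": (20, 10)}),    # inside SSR
            ("scaffold1", 50, "A", "C", 30.0, {"p": (20, 10)}),    # clean
        ]
    )
    mask = {"scaffold1": IntervalTree()}
    mask["scaffold1"].addi(39, 41)
    return sites, mask


@pytest.fixture
def toy_genes():
    """Two genes on scaffold1: one with two exons, one single-exon."""
    return [
        GeneModel("gA", "scaffold1", "+", 1000, 3000, ((1000, 1500), (2500, 3000))),
        GeneModel("gB", "scaffold1", "-", 10_000, 12_000, ((10_000, 12_000),)),
    ]
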