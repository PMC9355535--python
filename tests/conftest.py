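"""Shared fixtures: small hand-built design tables for the contrast engine."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from amfspread.model import OtuTable, Side, TableMode, Treatment, validate_metadata


def build_proportions_table(rows: list[dict]) -> OtuTable:
    """Build a PROPORTIONS-mode OtuTable from row dicts.

    Each row dict needs sample design fields plus an ``otus`` mapping of
    OTU id -> proportion; a FILL column absorbs the remainder so every row
    sums to one.
    """
    meta_rows, value_rows, ids = [], [], []
    all_otus: list[str] = []
    for row in rows:
        for otu in row["otus"]:
            if otu not in all_otus:
                all_otus.append(otu)
    for i, row in enumerate(rows):
        sid = row.get("sample_id", f"s{i + 1:03d}")
        ids.append(sid)
        meta_rows.append(
            {
                "sample_id": sid,
                "site": row.get("site", "siteA"),
                "year": row.get("year", 1),
                "block": row.get("block", "b1"),
                "plot": row.get("plot", "p1"),
                "treatment": row.get("treatment", Treatment.AMF.value),
                "distance_m": row.get("distance_m", 0.0),
                "side": row.get("side", Side.NONE.value),
            }
        )
        vals = {otu: float(row["otus"].get(otu, 0.0)) for otu in all_otus}
        total = sum(vals.values())
        assert total <= 1.0 + 1e-12, "proportions exceed 1"
        vals["FILL"] = 1.0 - total
        value_rows.append(vals)
    metadata = validate_metadata(pd.DataFrame(meta_rows))
    values = pd.DataFrame(value_rows, index=ids)
    return OtuTable(values, metadata, TableMode.PROPORTIONS)


@pytest.fixture
def two_group_fixture():
    """3+3 samples at distances 0 and 2, one block, one OTU."""
    y0 = [0.12, 0.10, 0.14]
    y2 = [0.05, 0.07, 0.03]
    rows = [
        {"distance_m": 0.0, "otus": {"X": v}, "block": "b1"} for v in y0
    ] + [
        {"distance_m": 2.0, "otus": {"X": v}, "block": "b1"} for v in y2
    ]
    return build_proportions_table(rows), np.array(y0), np.array(y2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
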