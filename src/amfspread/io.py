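"""Tab-separated readers and writers for the experiment's tabular artifacts.

Formats:

* OTU matrix -- TSV, first column ``sample_id``, remaining columns OTU ids,
  integer sequence counts.
* Sample metadata -- TSV with columns sample_id, site, year, block, plot,
  treatment, distance_m, side.
* Inocula profile -- TSV with columns site, otu_id, inoculum (AMF|WHOLE).
* Trials -- TSV with one row per (otu, inoculum, site, year) and its
  assigned spread category (plus any extra statistics columns).
"""

from __future__ import annotations

import pandas as pd

from .model import (
    FormatError,
    InoculaProfile,
    Inoculum,
    OtuTable,
    SpreadCategory,
    TableMode,
    Trial,
    ValidationError,
    validate_metadata,
)


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(md)


def read_otu_table(path, metadata_path) -> OtuTable:
    """Read a counts matrix and its metadata into a validated OtuTable.

    Samples present in the matrix but missing from the metadata (or vice
    versa) raise a validation error naming the offenders.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count in OTU matrix: {exc}") from exc
    metadata = read_metadata(metadata_path)

    matrix_only = sorted(set(values.index) - set(metadata.index))
    meta_only = sorted(set(metadata.index) - set(values.index))
    if matrix_only:
        raise ValidationError(
            f"sample(s) in OTU matrix missing from metadata: {matrix_only}"
        )
    if meta_only:
        raise ValidationError(
            f"sample(s) in metadata missing from OTU matrix: {meta_only}"
        )
    return OtuTable(values, metadata.loc[values.index], TableMode.COUNTS)


def write_otu_table(table: OtuTable, path, metadata_path=None) -> None:
    out = table.values.copy()
    if table.mode is TableMode.COUNTS:
        out = out.astype(int)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
    if metadata_path is not None:
        table.metadata.to_csv(metadata_path, sep="\t", index=False)


def read_inocula(path) -> dict[str, InoculaProfile]:
    """Read per-site inocula membership; returns {site: InoculaProfile}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"site", "otu_id", "inoculum"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"inocula table is missing columns: {sorted(missing)}")
    allowed = {i.value for i in Inoculum}
    bad = sorted(set(df["inoculum"]) - allowed)
    if bad:
        raise ValidationError(
            f"unknown inoculum label(s) {bad}; allowed labels are {sorted(allowed)}"
        )
    profiles = {}
    for site, grp in df.groupby("site"):
        profiles[site] = InoculaProfile(
            site=site,
            amf_otus=frozenset(grp.loc[grp["inoculum"] == "AMF", "otu_id"]),
            whole_otus=frozenset(grp.loc[grp["inoculum"] == "WHOLE", "otu_id"]),
        )
    return profiles


def write_inocula(profiles: dict[str, InoculaProfile], path) -> None:
    rows = []
    for site, prof in profiles.items():
        rows += [(site, otu, "AMF") for otu in sorted(prof.amf_otus)]
        rows += [(site, otu, "WHOLE") for otu in sorted(prof.whole_otus)]
    pd.DataFrame(rows, columns=["site", "otu_id", "inoculum"]).to_csv(
        path, sep="\t", index=False
    )


def trials_to_frame(trials: list[Trial]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "otu": t.otu,
                "inoculum": t.inoculum.value,
                "site": t.site,
                "year": t.year,
                "category": t.category.value,
            }
            for t in trials
        ]
    )


def frame_to_trials(df: pd.DataFrame) -> list[Trial]:
    return [
        Trial(
            otu=str(row.otu),
            inoculum=Inoculum(row.inoculum),
            site=str(row.site),
            year=int(row.year),
            category=SpreadCategory(row.category),
        )
        for row in df.itertuples()
    ]
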