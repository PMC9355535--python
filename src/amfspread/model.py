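"""Core domain types for AMF dispersal analysis.

The experimental unit is a soil/root sample taken at a fixed distance from a
row of inoculated nurse plants.  Samples carry community composition (an OTU
count or proportion matrix) plus the design metadata needed by the spread
classifier: site, experiment year, block, plot, inoculation treatment,
distance from the nurse-plant row, and (where host "bridges" were planted)
the plot side.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Distances (metres from the nurse-plant row) allowed by the design.
DESIGN_DISTANCES = (0.0, 0.5, 1.0, 2.0)


class Treatment(str, enum.Enum):
    """Inoculation treatment of the nurse-plant row in a plot."""

    AMF = "AMF"          # greenhouse-cultured AMF inoculum
    WHOLE = "WHOLE"      # whole prairie soil inoculum
    CONTROL = "CONTROL"  # sterilized control soil (non-inoculated)


class Side(str, enum.Enum):
    """Plot side relative to the nurse-plant row.

    BRIDGE sides carry host plants at 0.5, 1 and 2 m; ISLAND sides carry
    hosts only at 2 m.  Nurse-row samples (distance 0) have side NONE, as do
    samples from sites without the bridge/island layout.
    """

    BRIDGE = "BRIDGE"
    ISLAND = "ISLAND"
    NONE = "NONE"


class Inoculum(str, enum.Enum):
    """Which inoculum a dispersal trial refers to (CONTROL is never a trial)."""

    AMF = "AMF"
    WHOLE = "WHOLE"


class SpreadCategory(str, enum.Enum):
    """Outcome of the per-trial dispersal classification.

    NO_SPREAD      -- abundance concentrated in the nurse row only
    SPREAD_0_5     -- nurse row and 0.5 m equivalent, 2 m depleted
    DISTANCE_DECAY -- gradual decline with distance
    SPREAD_2M      -- no distance structure but enrichment over controls
                      (or the bridge/island override)
    UNKNOWN        -- inconclusive distance effects
    """

    NO_SPREAD = "NO_SPREAD"
    SPREAD_0_5 = "SPREAD_0_5"
    DISTANCE_DECAY = "DISTANCE_DECAY"
    SPREAD_2M = "SPREAD_2M"
    UNKNOWN = "UNKNOWN"


#: Display/ordering convention used by tabulations and reports.
CATEGORY_ORDER = (
    SpreadCategory.NO_SPREAD,
    SpreadCategory.SPREAD_0_5,
    SpreadCategory.DISTANCE_DECAY,
    SpreadCategory.SPREAD_2M,
    SpreadCategory.UNKNOWN,
)


class ValidationError(ValueError):
    """Raised when input tables violate the experimental-design contract."""


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted at all."""


@dataclass(frozen=True)
class SampleRecord:
    """Design metadata for one sequenced sample."""

    sample_id: str
    site: str
    year: int
    block: str
    plot: str
    treatment: Treatment
    distance_m: float
    side: Side = Side.NONE

    def __post_init__(self) -> None:
        if self.distance_m not in DESIGN_DISTANCES:
            raise ValidationError(
                f"sample {self.sample_id!r}: distance {self.distance_m} is not one of "
                f"the designed distances {DESIGN_DISTANCES}"
            )
        if self.distance_m == 0.0 and self.side is not Side.NONE:
            raise ValidationError(
                f"sample {self.sample_id!r}: nurse-row samples (distance 0) must have side NONE"
            )


METADATA_COLUMNS = (
    "sample_id", "site", "year", "block", "plot", "treatment", "distance_m", "side",
)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame and normalize dtypes.

    Required columns: sample_id, site, year, block, plot, treatment,
    distance_m, side.  A missing ``side`` column is filled with NONE.
    Returns a copy indexed by sample_id.
    """
    md = metadata.copy()
    if "side" not in md.columns:
        md["side"] = Side.NONE.value
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValidationError(f"metadata is missing required columns: {missing}")

    md["sample_id"] = md["sample_id"].astype(str)
    if md["sample_id"].duplicated().any():
        dups = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")

    allowed_treat = {t.value for t in Treatment}
    bad = sorted(set(md["treatment"].astype(str)) - allowed_treat)
    if bad:
        raise ValidationError(
            f"unknown treatment label(s) {bad}; allowed labels are {sorted(allowed_treat)}"
        )
    allowed_side = {s.value for s in Side}
    bad = sorted(set(md["side"].astype(str)) - allowed_side)
    if bad:
        raise ValidationError(
            f"unknown side label(s) {bad}; allowed labels are {sorted(allowed_side)}"
        )

    md["year"] = md["year"].astype(int)
    md["distance_m"] = md["distance_m"].astype(float)
    bad_d = sorted(set(md["distance_m"]) - set(DESIGN_DISTANCES))
    if bad_d:
        raise ValidationError(
            f"distance(s) {bad_d} are outside the designed set {DESIGN_DISTANCES}"
        )
    zero_side = md[(md["distance_m"] == 0.0) & (md["side"] != Side.NONE.value)]
    if len(zero_side):
        raise ValidationError(
            "nurse-row samples (distance 0) must have side NONE: "
            f"{zero_side['sample_id'].tolist()}"
        )
    return md.set_index("sample_id", drop=False)


class TableMode(str, enum.Enum):
    COUNTS = "COUNTS"
    PROPORTIONS = "PROPORTIONS"


@dataclass
class OtuTable:
    """Samples x OTUs abundance matrix joined to sample metadata.

    ``values`` is a DataFrame indexed by sample_id with OTU ids as columns.
    ``metadata`` is indexed by sample_id and row-aligned with ``values``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    mode: TableMode = TableMode.COUNTS

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.metadata.index):
            # allow same set in different order; realign
            if set(self.values.index) != set(self.metadata.index):
                unmatched = sorted(
                    set(self.values.index).symmetric_difference(self.metadata.index)
                )
                raise ValidationError(
                    f"sample ids of matrix and metadata differ: {unmatched}"
                )
            self.metadata = self.metadata.loc[self.values.index]
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("abundance matrix contains non-numeric entries")
        if np.isnan(arr).any():
            raise FormatError("abundance matrix contains missing values")
        if (arr < 0).any():
            raise FormatError("abundance matrix contains negative entries")
        if self.mode is TableMode.COUNTS:
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("COUNTS-mode matrix contains non-integer entries")
        else:
            sums = arr.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.values.index[~np.isclose(sums, 1.0, atol=1e-9)].tolist()
                raise ValidationError(
                    f"PROPORTIONS-mode rows must sum to 1 (tolerance 1e-9): {bad}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def otus(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, mask: pd.Series) -> "OtuTable":
        keep = self.metadata.index[mask.loc[self.metadata.index]]
        return OtuTable(self.values.loc[keep], self.metadata.loc[keep], self.mode)


def to_proportions(table: OtuTable) -> OtuTable:
    """Convert per-sample sequence counts into within-sample proportions.

    Each count is divided by the sample's total sequence count, so every
    OTU's value is its share of the whole community in that sample.  Samples
    with zero total are dropped with a warning.  Applying to a table already
    in PROPORTIONS mode is a no-op (with a warning).
    """
    if table.mode is TableMode.PROPORTIONS:
        warnings.warn("table is already in PROPORTIONS mode; returning unchanged")
        return table
    totals = table.values.sum(axis=1)
    zero = totals[totals == 0].index
    if len(zero):
        warnings.warn(
            f"dropping {len(zero)} sample(s) with zero total counts: {list(zero)}"
        )
    keep = totals[totals > 0].index
    values = table.values.loc[keep].div(totals.loc[keep], axis=0)
    return OtuTable(values, table.metadata.loc[keep], TableMode.PROPORTIONS)


@dataclass
class InoculaProfile:
    """OTU membership of the two inocula applied at one site."""

    site: str
    amf_otus: frozenset[str] = field(default_factory=frozenset)
    whole_otus: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "amf_otus", frozenset(self.amf_otus))
        object.__setattr__(self, "whole_otus", frozenset(self.whole_otus))
        if not self.amf_otus and not self.whole_otus:
            warnings.warn(f"inocula profile for site {self.site!r} is empty")

    @property
    def shared_otus(self) -> frozenset[str]:
        return self.amf_otus & self.whole_otus

    def otus_of(self, inoculum: Inoculum) -> frozenset[str]:
        return self.amf_otus if inoculum is Inoculum.AMF else self.whole_otus


@dataclass
class Trial:
    """One dispersal-assessment unit: an OTU in one inoculum at one site-year.

    An OTU present in both inocula is assessed once per inoculum and
    therefore contributes two trials.
    """

    otu: str
    inoculum: Inoculum
    site: str
    year: int
    category: SpreadCategory = SpreadCategory.UNKNOWN
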