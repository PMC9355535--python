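"""Spread-category decision rules and trial bookkeeping.

An OTU found in an inoculum constitutes one dispersal *trial* per inoculum,
site and year.  Each trial is assigned one of five spread categories from
the pattern of significant distance contrasts of its relative abundance:

1. NO_SPREAD       -- significantly higher in the nurse row than at both
                      0.5 m and 2 m.
2. SPREAD_0_5      -- nurse row and 0.5 m not significantly different, 2 m
                      significantly lower than both.
3. DISTANCE_DECAY  -- nurse row vs 0.5 m and 0.5 vs 2 m not significantly
                      different but nurse row significantly above 2 m; or no
                      pairwise contrast significant while the overall
                      distance effect is, with abundance declining.
4. SPREAD_2M       -- no significant distance differences but enrichment of
                      inoculated over control nurse rows; or the
                      bridge/island override (more abundant on the bridge
                      side at 2 m with no distance structure on the bridge).
5. UNKNOWN         -- anything else, including untestable designs.

Rules are evaluated in this fixed precedence order; the first match wins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import (
    BridgeIslandResult,
    ContrastResult,
    DistanceContrasts,
    EnrichmentResult,
    fit_marginal_means,
    test_bridge_island,
    test_enrichment,
)
from .model import (
    CATEGORY_ORDER,
    InoculaProfile,
    Inoculum,
    OtuTable,
    SpreadCategory,
    Treatment,
    Trial,
)


def classify_otu(
    dc: DistanceContrasts,
    enrichment: EnrichmentResult | None,
    bridge_island: BridgeIslandResult | None,
    alpha: float = 0.05,
    bridge_override: bool = True,
) -> SpreadCategory:
    """Assign a spread category from fitted contrasts (pure function).

    Untestable contrasts never satisfy a rule's significance *or*
    non-significance requirement, so degenerate designs fall through to
    UNKNOWN rather than raising.
    """
    c_0_05 = dc.contrast(0.0, 0.5)
    c_0_2 = dc.contrast(0.0, 2.0)
    c_05_2 = dc.contrast(0.5, 2.0)

    if c_0_05.significant_positive(alpha) and c_0_2.significant_positive(alpha):
        return SpreadCategory.NO_SPREAD

    if (
        c_0_05.nonsignificant(alpha)
        and c_0_2.significant_positive(alpha)
        and c_05_2.significant_positive(alpha)
    ):
        return SpreadCategory.SPREAD_0_5

    all_pairwise_ns = (
        c_0_05.nonsignificant(alpha)
        and c_0_2.nonsignificant(alpha)
        and c_05_2.nonsignificant(alpha)
    )
    if (
        c_0_05.nonsignificant(alpha)
        and c_05_2.nonsignificant(alpha)
        and c_0_2.significant_positive(alpha)
    ) or (
        all_pairwise_ns
        and dc.overall_distance.significant(alpha)
        and dc.trend_sign > 0
    ):
        return SpreadCategory.DISTANCE_DECAY

    enriched = (
        enrichment is not None
        and enrichment.contrast.significant_positive(alpha)
    )
    override = (
        bridge_override
        and bridge_island is not None
        and bridge_island.override(alpha)
    )
    if (all_pairwise_ns and enriched) or override:
        return SpreadCategory.SPREAD_2M

    return SpreadCategory.UNKNOWN


def enumerate_trials(profile: InoculaProfile, site: str, year: int) -> list[Trial]:
    """One trial per OTU per inoculum: an OTU present in both the AMF and
    whole-soil inocula is assessed twice, so the number of trials is
    ``|amf| + |whole|``, not the size of the union."""
    trials = [
        Trial(otu=otu, inoculum=Inoculum.AMF, site=site, year=year)
        for otu in sorted(profile.amf_otus)
    ] + [
        Trial(otu=otu, inoculum=Inoculum.WHOLE, site=site, year=year)
        for otu in sorted(profile.whole_otus)
    ]
    return trials


@dataclass
class TrialRecord:
    """A classified trial with the statistics that produced its category."""

    trial: Trial
    distance: DistanceContrasts
    enrichment: EnrichmentResult | None = None
    bridge_island: BridgeIslandResult | None = None


def _bh_adjust(records: list["TrialRecord"]) -> None:
    """Benjamini-Hochberg adjustment across trials, one family per test slot.

    Adjusts in place the p-values of each pairwise distance contrast, the
    overall distance F, the enrichment contrast and the bridge/island side
    contrast, each slot as its own family over all trials of the call.
    The within-bridge screen inside the override stays unadjusted.
    """
    from statsmodels.stats.multitest import multipletests

    def gather(getter):
        tests = [(rec, getter(rec)) for rec in records]
        tests = [(rec, c) for rec, c in tests if c is not None and c.testable]
        if not tests:
            return
        pvals = [c.p_value for _, c in tests]
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        for (_, c), p in zip(tests, adjusted):
            c.p_value = float(p)

    from .contrasts import PAIRWISE_KEYS

    for key in PAIRWISE_KEYS:
        gather(lambda r, k=key: r.distance.pairwise.get(k))
    gather(lambda r: r.distance.overall_distance)
    gather(lambda r: r.enrichment.contrast if r.enrichment else None)
    gather(lambda r: r.bridge_island.side_contrast if r.bridge_island else None)


def classify_trials(
    table: OtuTable,
    profile: InoculaProfile,
    site: str,
    year: int,
    alpha: float = 0.05,
    bridge_override: bool = True,
    include_block: bool = True,
    transform: str = "identity",
    p_adjust: str = "none",
) -> list[TrialRecord]:
    """Enumerate and classify every trial of one site-year.

    For each trial the distance model is fitted within the trial's own
    inoculated treatment; enrichment compares that treatment's nurse rows to
    controls; the bridge/island test is attempted and silently unavailable
    at sites without side-structured sampling.

    ``transform="logit"`` and ``p_adjust="bh"`` (Benjamini-Hochberg across
    the site-year's trials) are sensitivity-analysis options; both default
    off.
    """
    if p_adjust not in ("none", "bh"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}; use 'none' or 'bh'")
    records = []
    for trial in enumerate_trials(profile, site, year):
        treat = (Treatment(trial.inoculum.value),)
        dc = fit_marginal_means(
            table, trial.otu, site, year, treatments=treat,
            include_block=include_block, transform=transform,
        )
        enr = test_enrichment(
            table, trial.otu, site, year, trial.inoculum,
            include_block=include_block, transform=transform,
        )
        bi = test_bridge_island(
            table, trial.otu, site, year, treatments=treat,
            alpha=alpha, include_block=include_block, transform=transform,
        )
        records.append(
            TrialRecord(trial=trial, distance=dc, enrichment=enr, bridge_island=bi)
        )
    if p_adjust == "bh":
        _bh_adjust(records)
    for rec in records:
        rec.trial.category = classify_otu(
            rec.distance, rec.enrichment, rec.bridge_island,
            alpha=alpha, bridge_override=bridge_override,
        )
    return records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Flatten classified trials into a per-trial statistics table."""
    rows = []
    for rec in records:
        t = rec.trial
        row = {
            "otu": t.otu,
            "inoculum": t.inoculum.value,
            "site": t.site,
            "year": t.year,
            "category": t.category.value,
        }
        for (d1, d2), c in rec.distance.pairwise.items():
            tag = f"{d1:g}v{d2:g}"
            row[f"est_{tag}"] = c.estimate
            row[f"p_{tag}"] = c.p_value
            row[f"testable_{tag}"] = c.testable
        row["p_overall_distance"] = rec.distance.overall_distance.p_value
        row["trend_sign"] = rec.distance.trend_sign
        if rec.enrichment is not None:
            row["est_enrichment"] = rec.enrichment.contrast.estimate
            row["p_enrichment"] = rec.enrichment.contrast.p_value
        if rec.bridge_island is not None:
            row["est_bridge_island"] = rec.bridge_island.side_contrast.estimate
            row["p_bridge_island"] = rec.bridge_island.side_contrast.p_value
            row["within_bridge_differences"] = (
                rec.bridge_island.within_bridge_differences
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tabulation


def tabulate_categories(trials: list[Trial]) -> pd.DataFrame:
    """Per site-year counts of trials in each spread category.

    Counts partition the trials: each row sums to the number of trials of
    that site-year."""
    rows = []
    key = lambda t: (t.site, t.year)
    for (site, year), group in itertools.groupby(sorted(trials, key=key), key=key):
        group = list(group)
        counts = {cat: 0 for cat in CATEGORY_ORDER}
        for t in group:
            counts[t.category] += 1
        row = {"site": site, "year": year}
        row.update({cat.value: counts[cat] for cat in CATEGORY_ORDER})
        row["n_trials"] = len(group)
        rows.append(row)
    return pd.DataFrame(rows)


def transition_matrix(trials: list[Trial], year1: int, year2: int) -> pd.DataFrame:
    """Year-to-year category transition counts over matched trials.

    A trial is matched by (otu, inoculum, site); trials present in only one
    of the two years are omitted with a warning note in the index name.
    Row sums equal the year-1 category counts of matched trials.
    """
    by_key_1 = {
        (t.otu, t.inoculum, t.site): t.category for t in trials if t.year == year1
    }
    by_key_2 = {
        (t.otu, t.inoculum, t.site): t.category for t in trials if t.year == year2
    }
    cats = [c.value for c in CATEGORY_ORDER]
    mat = pd.DataFrame(0, index=cats, columns=cats)
    for k, c1 in by_key_1.items():
        if k in by_key_2:
            mat.loc[c1.value, by_key_2[k].value] += 1
    mat.index.name = f"year{year1}"
    mat.columns.name = f"year{year2}"
    return mat


def discordance_counts(trials: list[Trial]) -> pd.DataFrame:
    """Per site-year: OTUs assessed in both inocula and how many of those
    landed in different categories under the AMF vs whole-soil trials."""
    df = pd.DataFrame(
        [(t.site, t.year, t.otu, t.inoculum.value, t.category.value) for t in trials],
        columns=["site", "year", "otu", "inoculum", "category"],
    )
    rows = []
    for (site, year), grp in df.groupby(["site", "year"]):
        wide = grp.pivot_table(
            index="otu", columns="inoculum", values="category", aggfunc="first"
        )
        if {"AMF", "WHOLE"} <= set(wide.columns):
            both = wide.dropna(subset=["AMF", "WHOLE"])
            n_shared = len(both)
            n_discordant = int((both["AMF"] != both["WHOLE"]).sum())
        else:
            n_shared, n_discordant = 0, 0
        rows.append(
            {
                "site": site,
                "year": year,
                "n_shared_otus": n_shared,
                "n_discordant": n_discordant,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# family-level spread test


@dataclass
class FamilySpreadTest:
    """Chi-square test of spread vs no-spread counts across families."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    statistic: float = float("nan")
    df: int = 0
    p_value: float = float("nan")
    testable: bool = False
    note: str = ""


SPREAD_SET = {
    SpreadCategory.SPREAD_0_5,
    SpreadCategory.DISTANCE_DECAY,
    SpreadCategory.SPREAD_2M,
}


def family_spread_test(trials: list[Trial], families: dict[str, str]) -> FamilySpreadTest:
    """Contrast the likelihood of spreading (categories 2-4) against the
    absence of spread across taxonomic families.

    UNKNOWN trials and trials of OTUs without a family label are excluded.
    The chi-square is computed without continuity correction.
    """
    rows = []
    for t in trials:
        if t.category is SpreadCategory.UNKNOWN:
            continue
        fam = families.get(t.otu)
        if fam is None:
            continue
        rows.append((fam, t.category in SPREAD_SET))
    if not rows:
        return FamilySpreadTest(note="untestable: no determined trials with families")
    df = pd.DataFrame(rows, columns=["family", "spread"])
    ct = pd.crosstab(df["family"], df["spread"])
    ct = ct.reindex(columns=[True, False], fill_value=0)
    ct.columns = ["spread", "no_spread"]
    if ct.shape[0] < 2:
        return FamilySpreadTest(table=ct, note="untestable: fewer than two families")
    chi2, p, dof, _ = stats.chi2_contingency(ct.to_numpy(), correction=False)
    return FamilySpreadTest(
        table=ct, statistic=float(chi2), df=int(dof), p_value=float(p), testable=True
    )
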