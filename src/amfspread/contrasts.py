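"""Marginal-means contrast engine for per-OTU dispersal tests.

Each OTU's relative abundance is modeled within one site-year scope by an
ordinary least-squares linear model with distance as a categorical factor
and, when the design provides replication, block as an additive term.
Marginal means are model-adjusted means per distance level (averaged over
blocks with equal weight), and pairwise contrasts are tested with
pooled-error F tests.  The same engine drives the nurse-row enrichment test
(inoculated vs control) and the bridge/island side test at 2 m.

A community-level MANOVA (Pillai's trace) over the joint inocula-OTU
response is provided separately; the per-OTU contrasts are what the spread
categories consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.multivariate.manova import MANOVA
from statsmodels.regression.linear_model import OLS

from .model import Inoculum, OtuTable, Side, TableMode, Treatment

#: Distances that participate in category decision rules.  1.0-m samples
#: enter the model (improving the pooled error) but no rule references them.
DECISION_DISTANCES = (0.0, 0.5, 2.0)
PAIRWISE_KEYS = ((0.0, 0.5), (0.0, 2.0), (0.5, 2.0))


@dataclass
class ContrastResult:
    """A single linear contrast with its pooled-error F test.

    ``estimate`` is the difference of marginal means (first level minus
    second, proportion units).  ``testable`` is False when the design cannot
    support the comparison (a level with < 2 samples, or no residual df);
    untestable contrasts propagate to the UNKNOWN category downstream.
    """

    estimate: float = float("nan")
    statistic: float = float("nan")
    df: tuple[float, float] = (0.0, 0.0)
    p_value: float = float("nan")
    testable: bool = False
    note: str = ""

    def significant(self, alpha: float) -> bool:
        return self.testable and self.p_value < alpha

    def significant_positive(self, alpha: float) -> bool:
        return self.significant(alpha) and self.estimate > 0

    def nonsignificant(self, alpha: float) -> bool:
        return self.testable and self.p_value >= alpha


@dataclass
class DistanceContrasts:
    """Distance marginal means and contrasts for one OTU in one scope."""

    otu: str
    marginal_means: dict[float, float] = field(default_factory=dict)
    pairwise: dict[tuple[float, float], ContrastResult] = field(default_factory=dict)
    overall_distance: ContrastResult = field(default_factory=ContrastResult)
    trend_sign: int = 0

    def contrast(self, d1: float, d2: float) -> ContrastResult:
        return self.pairwise.get((d1, d2), ContrastResult(note="missing"))


@dataclass
class EnrichmentResult:
    """Nurse-row (distance 0) contrast: inoculated treatment minus control."""

    otu: str
    contrast: ContrastResult = field(default_factory=ContrastResult)


@dataclass
class BridgeIslandResult:
    """2-m side contrast (bridge minus island) and within-bridge structure."""

    otu: str
    side_contrast: ContrastResult = field(default_factory=ContrastResult)
    within_bridge_differences: bool = False

    def override(self, alpha: float) -> bool:
        """True when the bridge/island rule upgrades a trial to 2-m spread:
        significantly more abundant on the bridge side at 2 m AND no
        significant differences among bridge-side distances."""
        return (
            self.side_contrast.significant_positive(alpha)
            and not self.within_bridge_differences
        )


@dataclass
class MultivariateTestResult:
    """Pillai-trace test of one factor over a joint multi-OTU response."""

    factor: str
    pillai: float = float("nan")
    statistic: float = float("nan")
    df: tuple[float, float] = (0.0, 0.0)
    p_value: float = float("nan")
    testable: bool = False
    n_responses: int = 0
    note: str = ""


# ---------------------------------------------------------------------------
# univariate engine


class _LevelModel:
    """OLS of y on a categorical factor (+ optional additive block)."""

    def __init__(self, df: pd.DataFrame, factor: str, block: str | None):
        self.levels = sorted(df[factor].unique())
        self.counts = df[factor].value_counts().to_dict()
        self.block_levels = sorted(df[block].unique()) if block else []
        use_block = block is not None and len(self.block_levels) >= 2

        n = len(df)
        cols: list[np.ndarray] = [np.ones(n)]
        self.names = ["intercept"]
        for lev in self.levels[1:]:
            cols.append((df[factor] == lev).to_numpy(float))
            self.names.append(f"level:{lev}")
        if use_block:
            for b in self.block_levels[1:]:
                cols.append((df[block] == b).to_numpy(float))
                self.names.append(f"block:{b}")
        X = np.column_stack(cols)
        y = df["y"].to_numpy(float)
        self.fit = OLS(y, X).fit()
        self.k = X.shape[1]
        # residual variance can be exactly zero on degenerate fixtures
        self.zero_resid = bool(self.fit.ssr <= max(1e-12 * max(y @ y, 1.0), 1e-300))

    def _level_vec(self, level) -> np.ndarray:
        """Parameter weights giving the marginal mean of one factor level
        (block effects averaged with equal weight)."""
        v = np.zeros(self.k)
        v[0] = 1.0
        for i, name in enumerate(self.names):
            if name == f"level:{level}":
                v[i] = 1.0
            elif name.startswith("block:"):
                v[i] = 1.0 / len(self.block_levels)
        return v

    def marginal_mean(self, level) -> float:
        return float(self._level_vec(level) @ self.fit.params)

    def level_testable(self, level) -> bool:
        return self.counts.get(level, 0) >= 2

    def contrast(self, lev1, lev2) -> ContrastResult:
        """F test of marginal-mean difference lev1 - lev2 (pooled error)."""
        if lev1 not in self.counts or lev2 not in self.counts:
            return ContrastResult(note=f"level missing: {lev1} or {lev2}")
        c = self._level_vec(lev1) - self._level_vec(lev2)
        est = float(c @ self.fit.params)
        if not self.level_testable(lev1) or not self.level_testable(lev2):
            return ContrastResult(
                estimate=est, note="untestable: a level has < 2 samples"
            )
        if self.fit.df_resid < 1:
            return ContrastResult(estimate=est, note="untestable: no residual df")
        if self.zero_resid:
            warnings.warn("zero residual variance; contrast p set by estimate equality")
            p = 1.0 if np.isclose(est, 0.0) else 0.0
            return ContrastResult(
                estimate=est,
                statistic=float("inf") if p == 0.0 else 0.0,
                df=(1.0, float(self.fit.df_resid)),
                p_value=p,
                testable=True,
                note="zero residual variance",
            )
        ft = self.fit.f_test(c)
        return ContrastResult(
            estimate=est,
            statistic=float(ft.fvalue),
            df=(float(ft.df_num), float(ft.df_denom)),
            p_value=float(ft.pvalue),
            testable=True,
        )

    def overall_factor_test(self) -> ContrastResult:
        """Joint F test that all factor-level effects are zero."""
        idx = [i for i, n in enumerate(self.names) if n.startswith("level:")]
        if not idx:
            return ContrastResult(note="untestable: single factor level")
        if any(self.counts[lev] < 2 for lev in self.levels) or self.fit.df_resid < 1:
            return ContrastResult(note="untestable: insufficient replication")
        if self.zero_resid:
            ests = [self.marginal_mean(lev) for lev in self.levels]
            p = 1.0 if np.allclose(ests, ests[0]) else 0.0
            return ContrastResult(
                estimate=0.0,
                df=(float(len(idx)), float(self.fit.df_resid)),
                p_value=p,
                testable=True,
                note="zero residual variance",
            )
        L = np.zeros((len(idx), self.k))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        ft = self.fit.f_test(L)
        return ContrastResult(
            estimate=0.0,
            statistic=float(ft.fvalue),
            df=(float(ft.df_num), float(ft.df_denom)),
            p_value=float(ft.pvalue),
            testable=True,
        )


def _transform_y(y: pd.Series, transform: str) -> pd.Series:
    """Optional variance-stabilizing transform of the proportion response."""
    if transform == "identity":
        return y
    if transform == "logit":
        eps = 1e-6
        p = y.clip(eps, 1.0 - eps)
        return np.log(p / (1.0 - p))
    raise ValueError(f"unknown transform {transform!r}; use 'identity' or 'logit'")


def _scoped_frame(
    table: OtuTable,
    otu: str,
    site: str,
    year: int,
    treatments: tuple[Treatment, ...],
    transform: str = "identity",
) -> pd.DataFrame:
    if table.mode is not TableMode.PROPORTIONS:
        raise ValueError("contrast engine requires a PROPORTIONS-mode table")
    md = table.metadata
    treat_vals = {t.value for t in treatments}
    mask = (
        (md["site"] == site)
        & (md["year"] == year)
        & (md["treatment"].isin(treat_vals))
    )
    df = md.loc[mask, ["site", "year", "block", "treatment", "distance_m", "side"]].copy()
    df["y"] = _transform_y(table.values.loc[df.index, otu], transform)
    return df


def fit_marginal_means(
    table: OtuTable,
    otu: str,
    site: str,
    year: int,
    treatments: tuple[Treatment, ...] = (Treatment.AMF, Treatment.WHOLE),
    include_block: bool = True,
    transform: str = "identity",
) -> DistanceContrasts:
    """Distance marginal means and pairwise contrasts for one OTU.

    The model is ``proportion ~ C(distance) [+ C(block)]`` over the
    inoculated samples of one site-year.  All designed distance levels
    present in the data enter the model; decision rules downstream only use
    the 0 / 0.5 / 2-m contrasts.  ``transform="logit"`` fits the model on
    logit proportions (sensitivity analysis; estimates are then in logit
    units).
    """
    df = _scoped_frame(table, otu, site, year, treatments, transform)
    out = DistanceContrasts(otu=otu)
    levels_present = sorted(df["distance_m"].unique()) if len(df) else []
    if len(levels_present) < 2:
        note = "untestable: fewer than two distance levels in scope"
        out.overall_distance = ContrastResult(note=note)
        for key in PAIRWISE_KEYS:
            out.pairwise[key] = ContrastResult(note=note)
        if len(levels_present) == 1:
            out.marginal_means[levels_present[0]] = float(df["y"].mean())
        return out

    model = _LevelModel(df, "distance_m", "block" if include_block else None)
    for lev in model.levels:
        out.marginal_means[lev] = model.marginal_mean(lev)
    for d1, d2 in PAIRWISE_KEYS:
        out.pairwise[(d1, d2)] = model.contrast(d1, d2)
    out.overall_distance = model.overall_factor_test()
    if 0.0 in out.marginal_means and 2.0 in out.marginal_means:
        out.trend_sign = int(np.sign(out.marginal_means[0.0] - out.marginal_means[2.0]))
    return out


def test_enrichment(
    table: OtuTable,
    otu: str,
    site: str,
    year: int,
    inoculum: Inoculum,
    include_block: bool = True,
    transform: str = "identity",
) -> EnrichmentResult:
    """Nurse-row abundance contrast: inoculated treatment minus control.

    Positive, significant estimates mean the OTU is enriched where its
    inoculum was applied, relative to sterilized-control nurse rows.
    """
    treat = Treatment(inoculum.value)
    md = table.metadata
    mask = (
        (md["site"] == site)
        & (md["year"] == year)
        & (md["distance_m"] == 0.0)
        & (md["treatment"].isin({treat.value, Treatment.CONTROL.value}))
    )
    df = md.loc[mask, ["block", "treatment"]].copy()
    df["y"] = _transform_y(table.values.loc[df.index, otu], transform)
    groups = set(df["treatment"].unique())
    if Treatment.CONTROL.value not in groups or treat.value not in groups:
        return EnrichmentResult(
            otu=otu,
            contrast=ContrastResult(note="untestable: missing nurse-row arm"),
        )
    # order levels so the contrast is inoculated - control
    model = _LevelModel(df, "treatment", "block" if include_block else None)
    return EnrichmentResult(
        otu=otu, contrast=model.contrast(treat.value, Treatment.CONTROL.value)
    )


def test_bridge_island(
    table: OtuTable,
    otu: str,
    site: str,
    year: int,
    treatments: tuple[Treatment, ...] = (Treatment.AMF, Treatment.WHOLE),
    alpha: float = 0.05,
    include_block: bool = True,
    transform: str = "identity",
) -> BridgeIslandResult | None:
    """Bridge vs island contrast at 2 m plus within-bridge distance check.

    Returns None when the site-year has no side-structured sampling, in
    which case the 2-m override is simply unavailable.
    """
    df = _scoped_frame(table, otu, site, year, treatments, transform)
    at2 = df[df["distance_m"] == 2.0]
    sides = set(at2["side"].unique())
    if not {Side.BRIDGE.value, Side.ISLAND.value} <= sides:
        return None

    side_model = _LevelModel(at2, "side", "block" if include_block else None)
    side_contrast = side_model.contrast(Side.BRIDGE.value, Side.ISLAND.value)

    bridge = df[(df["side"] == Side.BRIDGE.value) & (df["distance_m"] > 0)]
    within = False
    if bridge["distance_m"].nunique() >= 2:
        bmodel = _LevelModel(bridge, "distance_m", "block" if include_block else None)
        blevels = bmodel.levels
        for i, d1 in enumerate(blevels):
            for d2 in blevels[i + 1 :]:
                if bmodel.contrast(d1, d2).significant(alpha):
                    within = True
    return BridgeIslandResult(
        otu=otu, side_contrast=side_contrast, within_bridge_differences=within
    )


# ---------------------------------------------------------------------------
# community-level MANOVA


def _pillai_direct(
    Y: np.ndarray, X: np.ndarray, L: np.ndarray
) -> tuple[float, float, tuple[float, float], float]:
    """Pillai's trace with its standard F approximation from SSCP matrices.

    Fallback path for hypothesis SSCPs the packaged solver rejects (it is
    exact in the degenerate all-zero case: V = 0, p = 1).
    """
    from scipy import stats as _st

    n, k = X.shape
    p = Y.shape[1]
    q = L.shape[0]
    XtX_inv = np.linalg.pinv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid
    LB = L @ B
    M = np.linalg.pinv(L @ XtX_inv @ L.T)
    H = LB.T @ M @ LB
    eigvals = np.real(np.linalg.eigvals(np.linalg.solve(H + E, H)))
    V = float(np.clip(eigvals, 0.0, 1.0).sum())
    df_e = n - k
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (df_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0 or V >= s:
        return V, float("nan"), (df1, df2), float("nan")
    F = (df2 / df1) * (V / (s - V))
    return V, float(F), (df1, df2), float(_st.f.sf(F, df1, df2))


def manova_overall(
    table: OtuTable,
    otus: list[str],
    site: str,
    year: int,
    treatments: tuple[Treatment, ...] = (Treatment.AMF, Treatment.WHOLE, Treatment.CONTROL),
    include_block: bool = True,
) -> dict[str, MultivariateTestResult]:
    """Pillai-trace MANOVA of treatment and distance over a joint OTU response.

    When the scope holds fewer samples than the model needs (responses +
    design parameters), the response set is reduced to the most abundant
    OTUs until estimable, with the reduction noted on the result.
    """
    if table.mode is not TableMode.PROPORTIONS:
        raise ValueError("manova_overall requires a PROPORTIONS-mode table")
    md = table.metadata
    mask = (
        (md["site"] == site)
        & (md["year"] == year)
        & (md["treatment"].isin({t.value for t in treatments}))
    )
    meta = md.loc[mask]
    Y_full = table.values.loc[meta.index, otus]
    n = len(meta)

    # design matrix: intercept + treatment + distance (+ block)
    parts = [pd.Series(1.0, index=meta.index, name="intercept")]
    slices: dict[str, list[str]] = {"treatment": [], "distance": []}
    for t in sorted(meta["treatment"].unique())[1:]:
        s = (meta["treatment"] == t).astype(float)
        s.name = f"treatment:{t}"
        parts.append(s)
        slices["treatment"].append(s.name)
    for d in sorted(meta["distance_m"].unique())[1:]:
        s = (meta["distance_m"] == d).astype(float)
        s.name = f"distance:{d}"
        parts.append(s)
        slices["distance"].append(s.name)
    if include_block and meta["block"].nunique() >= 2:
        for b in sorted(meta["block"].unique())[1:]:
            s = (meta["block"] == b).astype(float)
            s.name = f"block:{b}"
            parts.append(s)
    X = pd.concat(parts, axis=1)
    k = X.shape[1]

    note = ""
    max_resp = n - k - 1
    resp = list(otus)
    if max_resp < 2:
        return {
            f: MultivariateTestResult(factor=f, note="untestable: too few samples")
            for f in slices
        }
    if len(resp) > max_resp:
        order = Y_full.mean(axis=0).sort_values(ascending=False).index
        resp = list(order[:max_resp])
        note = f"response reduced from {len(otus)} to {len(resp)} most abundant OTUs"
    Y = Y_full[resp]

    results: dict[str, MultivariateTestResult] = {}
    try:
        mv = MANOVA(endog=Y.to_numpy(), exog=X.to_numpy())
        for factor, colnames in slices.items():
            if not colnames:
                results[factor] = MultivariateTestResult(
                    factor=factor, note="untestable: single level", n_responses=len(resp)
                )
                continue
            L = np.zeros((len(colnames), k))
            for r, cn in enumerate(colnames):
                L[r, X.columns.get_loc(cn)] = 1.0
            try:
                res = mv.mv_test(hypotheses=[(factor, L, None)])
                stat = res.results[factor]["stat"]
                row = stat.loc["Pillai's trace"]
                pillai, fval = float(row["Value"]), float(row["F Value"])
                dfs = (float(row["Num DF"]), float(row["Den DF"]))
                pval = float(row["Pr > F"])
            except ValueError:
                # statsmodels chokes on a degenerate hypothesis SSCP (e.g.
                # responses identical across groups); compute Pillai directly
                pillai, fval, dfs, pval = _pillai_direct(
                    Y.to_numpy(), X.to_numpy(), L
                )
            results[factor] = MultivariateTestResult(
                factor=factor,
                pillai=pillai,
                statistic=fval,
                df=dfs,
                p_value=pval,
                testable=True,
                n_responses=len(resp),
                note=note,
            )
    except np.linalg.LinAlgError as exc:
        for factor in slices:
            results[factor] = MultivariateTestResult(
                factor=factor,
                note=f"untestable: singular within-group covariance ({exc})",
                n_responses=len(resp),
            )
    return results
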