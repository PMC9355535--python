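"""Simulation-based validation of the spread classifier.

Two standard experiments, both at the package's reference study conditions
(7 blocks, sequencing depth 10^4, nurse-row abundances at least 100x the
pre-existing background):

* :func:`recovery_rates` -- one OTU per generating kernel; how often does
  each kernel's trial land in its matching category?
* :func:`null_rates` -- all-NULL kernels; how often is each non-UNKNOWN
  category assigned at all (type-I behaviour of the decision rules), and
  how often does each pairwise distance contrast reject (engine
  calibration)?
"""

from __future__ import annotations

import warnings

import pandas as pd

from .classify import classify_trials
from .contrasts import PAIRWISE_KEYS
from .model import InoculaProfile, SpreadCategory, to_proportions
from .simulate import KernelType, SimConfig, SpreadKernel, make_kernel, simulate_experiment

REFERENCE_CONDITIONS = dict(
    n_blocks=7,
    n_years=1,
    n_otus_background=40,
    sequencing_depth=10_000,
)


def _classify_once(kernels, seed, alpha):
    cfg = SimConfig(
        n_otus_inocula=len(kernels), seed=seed, **REFERENCE_CONDITIONS
    )
    sim = simulate_experiment(cfg, kernels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prop = to_proportions(sim.table)
        profile = InoculaProfile(
            site="site1", amf_otus=frozenset(k.otu for k in kernels)
        )
        return classify_trials(prop, profile, "site1", 1, alpha=alpha)


def recovery_rates(
    n_replicates: int = 100, seed: int = 0, alpha: float = 0.05
) -> pd.DataFrame:
    """Confusion table of generating kernel vs assigned category.

    One OTU per kernel type per replicate; returns a DataFrame indexed by
    kernel with one column per assigned category (rates summing to 1) plus
    a ``recovery`` column for the matching category.
    """
    ktypes = list(KernelType)
    kernels = [make_kernel(kt, f"K_{kt.value}") for kt in ktypes]
    counts = {kt: {c: 0 for c in SpreadCategory} for kt in ktypes}
    for rep in range(n_replicates):
        records = _classify_once(kernels, seed + rep, alpha)
        for rec in records:
            kt = KernelType(rec.trial.otu.removeprefix("K_"))
            counts[kt][rec.trial.category] += 1
    rows = []
    for kt in ktypes:
        row = {"kernel": kt.value}
        for c in SpreadCategory:
            row[c.value] = counts[kt][c] / n_replicates
        row["recovery"] = counts[kt][kt.expected_category] / n_replicates
        rows.append(row)
    return pd.DataFrame(rows).set_index("kernel")


def null_rates(
    n_replicates: int = 100,
    n_otus: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Category-assignment and contrast-rejection rates under NULL kernels.

    Returns ``{"category_rates": {...}, "contrast_rejection": {...},
    "n_trials": N}``.  Under the null every non-UNKNOWN category requires at
    least one false rejection, so each rate should sit at or below alpha;
    the pairwise contrast rejection rates should sit near alpha.
    """
    # null taxa are moderately abundant residents (2% each): abundant enough
    # that the contrast engine's normal-theory calibration is meaningful
    kernels = [
        SpreadKernel(f"NULL{i + 1}", KernelType.NULL, 0.08, 0.0, 0.02)
        for i in range(n_otus)
    ]
    cat_counts = {c: 0 for c in SpreadCategory}
    rej = {key: 0 for key in PAIRWISE_KEYS}
    n_trials = 0
    for rep in range(n_replicates):
        records = _classify_once(kernels, seed + rep, alpha)
        for rec in records:
            n_trials += 1
            cat_counts[rec.trial.category] += 1
            for key in PAIRWISE_KEYS:
                if rec.distance.contrast(*key).significant(alpha):
                    rej[key] += 1
    return {
        "category_rates": {c.value: cat_counts[c] / n_trials for c in SpreadCategory},
        "contrast_rejection": {
            f"{k[0]:g}v{k[1]:g}": rej[k] / n_trials for k in PAIRWISE_KEYS
        },
        "n_trials": n_trials,
    }
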