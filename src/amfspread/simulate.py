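"""Synthetic inoculation experiments with known dispersal ground truth.

The generator emulates the post-clustering artifacts of a multi-site
nurse-plant inoculation experiment: an OTU count table over a randomized
block design (three inoculation treatments x distances 0/0.5/1/2 m, with
optional bridge/island side structure), the inocula membership lists, a
bootstrap support tree, and plant point-intersect cover tables.

Each inoculated OTU carries a *spread kernel* -- the generative counterpart
of a spread category -- that fixes its expected relative abundance at every
distance in inoculated plots.  Pre-existing "background" OTUs are present
at the same level in every treatment including controls, reproducing the
central nuisance of such field data: inocula taxa are usually also present
before inoculation.  Count noise is Dirichlet-multinomial, the standard
over-dispersed compositional model for amplicon counts, with a single
concentration ("dispersion") knob.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .model import (
    InoculaProfile,
    OtuTable,
    Side,
    SpreadCategory,
    TableMode,
    Treatment,
    validate_metadata,
)
from .tree import SupportTree, support_tree_from_string


class KernelType(str, enum.Enum):
    """Generating modes matching the spread categories, plus a null mode."""

    NO_SPREAD = "NO_SPREAD"
    SPREAD_0_5 = "SPREAD_0_5"
    DISTANCE_DECAY = "DISTANCE_DECAY"
    SPREAD_2M = "SPREAD_2M"
    NULL = "NULL"

    @property
    def expected_category(self) -> SpreadCategory:
        if self is KernelType.NULL:
            return SpreadCategory.UNKNOWN
        return SpreadCategory(self.value)


@dataclass(frozen=True)
class SpreadKernel:
    """Expected relative-abundance profile of one inoculated OTU.

    ``base_abundance`` is the expected relative abundance at the nurse row
    in inoculated plots; ``background_level`` is the pre-existing level seen
    in control plots (and, for most kernels, away from the row);
    ``decay_rate`` is the per-metre exponential decline of the
    DISTANCE_DECAY kernel.
    """

    otu: str
    kernel: KernelType
    base_abundance: float = 0.1
    decay_rate: float = 0.0
    background_level: float = 0.001

    def __post_init__(self) -> None:
        if self.base_abundance <= 0:
            raise ValueError("base_abundance must be > 0")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")

    def expected(self, treatment: Treatment, distance: float) -> float:
        """Expected relative abundance before any bridge/island adjustment."""
        if treatment is Treatment.CONTROL or self.kernel is KernelType.NULL:
            return self.background_level
        k = self.kernel
        if k is KernelType.NO_SPREAD:
            return self.base_abundance if distance == 0.0 else self.background_level
        if k is KernelType.SPREAD_0_5:
            return self.base_abundance if distance <= 0.5 else self.background_level
        if k is KernelType.DISTANCE_DECAY:
            return self.background_level + (
                self.base_abundance - self.background_level
            ) * float(np.exp(-self.decay_rate * distance))
        if k is KernelType.SPREAD_2M:
            return self.base_abundance
        raise AssertionError(k)


@dataclass(frozen=True)
class SimConfig:
    """Design and noise parameters of a synthetic experiment.

    Defaults mirror the field design: 7 blocks per site (one studied site
    had 9), three treatments per block, two years, sampling at 0/0.5/1/2 m
    with bridge/island structure, and a sequencing depth of 10^4 reads.
    ``dispersion`` is the Dirichlet concentration: smaller values mean more
    over-dispersion relative to multinomial noise.
    """

    n_sites: int = 1
    n_blocks: int = 7
    n_years: int = 2
    distances: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    n_otus_inocula: int = 10
    n_otus_background: int = 40
    sequencing_depth: int = 10_000
    dispersion: float = 30.0
    bridge_effect: float = 1.0
    side_structured: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_blocks", "n_years", "n_otus_background"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be > 0")
        if not np.isfinite(self.dispersion) or self.dispersion <= 0:
            raise ValueError("dispersion must be positive and finite")
        if self.bridge_effect < 1:
            raise ValueError("bridge_effect must be >= 1")

    @property
    def sites(self) -> list[str]:
        return [f"site{i + 1}" for i in range(self.n_sites)]


def default_kernels(
    config: SimConfig,
    composition: tuple[KernelType, ...] = (
        KernelType.NO_SPREAD,
        KernelType.SPREAD_0_5,
        KernelType.DISTANCE_DECAY,
        KernelType.SPREAD_2M,
        KernelType.NULL,
    ),
    background_level: float = 0.0008,
) -> list[SpreadKernel]:
    """A kernel list cycling through ``composition`` for the inocula OTUs.

    Effect sizes are the package's reference study conditions: abundant
    nurse-row signals (base 100x over background or more) with a decay
    kernel whose decline over 2 m is resolvable while its step between
    adjacent distances is not (see docs/methods.md).
    """
    kernels = []
    for i in range(config.n_otus_inocula):
        ktype = composition[i % len(composition)]
        kernels.append(
            make_kernel(ktype, f"OTU{i + 1:04d}", background_level=background_level)
        )
    return kernels


def make_kernel(
    ktype: KernelType, otu: str, background_level: float = 0.0008
) -> SpreadKernel:
    """Reference kernel parameterization per generating mode.

    Bases sit 100x or more above background; they are sized so that up to
    ten inoculated OTUs fit in one community (expected nurse-row abundances
    must sum below 1).
    """
    if ktype is KernelType.DISTANCE_DECAY:
        # gentle decline: the drop over the full 2 m is statistically
        # resolvable under the default noise while the step between adjacent
        # distances is not, which is the data pattern the decay category
        # describes (see docs/methods.md on the decay category's power)
        return SpreadKernel(
            otu=otu,
            kernel=ktype,
            base_abundance=0.08,
            decay_rate=0.35,
            background_level=background_level,
        )
    base = {
        KernelType.NO_SPREAD: 0.12,
        KernelType.SPREAD_0_5: 0.12,
        KernelType.SPREAD_2M: 0.08,
        KernelType.NULL: 0.08,  # unused: NULL sits at background everywhere
    }[ktype]
    return SpreadKernel(
        otu=otu, kernel=ktype, base_abundance=base, background_level=background_level
    )


def _sample_rows(config: SimConfig) -> list[tuple[float, Side]]:
    rows: list[tuple[float, Side]] = []
    for d in config.distances:
        if d == 0.0:
            rows.append((0.0, Side.NONE))
        elif config.side_structured:
            rows.append((d, Side.BRIDGE))
        else:
            rows.append((d, Side.NONE))
    if config.side_structured and 2.0 in config.distances:
        rows.append((2.0, Side.ISLAND))
    return rows


def _expected_vector(
    kernels: list[SpreadKernel],
    bg_weights: np.ndarray,
    treatment: Treatment,
    distance: float,
    side: Side,
    bridge_effect: float,
) -> np.ndarray:
    """Expected proportions for one sample: inocula OTUs then background OTUs."""
    inoc = np.array([k.expected(treatment, distance) for k in kernels])
    if (
        side is Side.ISLAND
        and bridge_effect > 1.0
        and treatment is not Treatment.CONTROL
    ):
        # hosts are absent between the row and 2 m on the island side, so the
        # spread signal there is attenuated by the bridge effect
        bg = np.array([k.background_level for k in kernels])
        inoc = bg + (inoc - bg) / bridge_effect
    total_inoc = inoc.sum()
    if total_inoc >= 1.0:
        raise ValueError(
            f"expected inocula abundance sums to {total_inoc:.3f} >= 1; "
            "reduce kernel base abundances"
        )
    return np.concatenate([inoc, (1.0 - total_inoc) * bg_weights])


@dataclass
class SimulatedExperiment:
    """Bundle returned by :func:`simulate_experiment`."""

    table: OtuTable                       # COUNTS mode, metadata attached
    profiles: dict[str, InoculaProfile]   # per site
    truth: pd.DataFrame                   # otu -> generating kernel
    expected: pd.DataFrame                # per-sample expected proportions


def _background_weights(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Relative abundances of the pre-existing community (lognormal ranks)."""
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_otus_background)
    return raw / raw.sum()


def expected_proportions(
    config: SimConfig, kernels: list[SpreadKernel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic expected proportions per sample (no count noise).

    Returns (metadata, expectations); expectation rows sum to 1.  Used by
    calibration tests and exposed for power analysis.
    """
    rng = np.random.default_rng(config.seed)
    bg_weights = _background_weights(config, rng)
    otus = [k.otu for k in kernels] + [
        f"BG{j + 1:04d}" for j in range(config.n_otus_background)
    ]
    meta_rows, exp_rows, ids = [], [], []
    for site in config.sites:
        for year in range(1, config.n_years + 1):
            for b in range(1, config.n_blocks + 1):
                for treatment in (Treatment.AMF, Treatment.WHOLE, Treatment.CONTROL):
                    for distance, side in _sample_rows(config):
                        sid = (
                            f"{site}_y{year}_b{b:02d}_{treatment.value}"
                            f"_d{distance:g}_{side.value}"
                        )
                        ids.append(sid)
                        meta_rows.append(
                            {
                                "sample_id": sid,
                                "site": site,
                                "year": year,
                                "block": f"b{b:02d}",
                                "plot": f"{site}_b{b:02d}_{treatment.value}",
                                "treatment": treatment.value,
                                "distance_m": distance,
                                "side": side.value,
                            }
                        )
                        exp_rows.append(
                            _expected_vector(
                                kernels, bg_weights, treatment, distance, side,
                                config.bridge_effect,
                            )
                        )
    metadata = validate_metadata(pd.DataFrame(meta_rows))
    expected = pd.DataFrame(exp_rows, index=ids, columns=otus)
    return metadata, expected


def simulate_experiment(
    config: SimConfig, kernels: list[SpreadKernel] | None = None
) -> SimulatedExperiment:
    """Draw a full synthetic experiment under Dirichlet-multinomial noise.

    Identical config (including seed) gives identical output.  Every count
    row sums to ``config.sequencing_depth``.
    """
    if kernels is None:
        kernels = default_kernels(config)
    seen: set[str] = set()
    for k in kernels:
        if k.otu in seen:
            raise ValueError(f"duplicate OTU {k.otu!r} in kernel list")
        seen.add(k.otu)

    metadata, expected = expected_proportions(config, kernels)
    rng = np.random.default_rng(config.seed)
    _ = _background_weights(config, rng)  # keep the stream aligned with expected_proportions
    counts = np.empty(expected.shape, dtype=int)
    exp_arr = expected.to_numpy()
    for i in range(exp_arr.shape[0]):
        alpha = config.dispersion * exp_arr[i]
        # Dirichlet draws reject exact zeros; floor harmlessly below depth^-2
        alpha = np.maximum(alpha, 1e-12)
        p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(config.sequencing_depth, p)
    values = pd.DataFrame(counts, index=expected.index, columns=expected.columns)
    table = OtuTable(values, metadata, TableMode.COUNTS)

    inocula_ids = frozenset(k.otu for k in kernels)
    profiles = {
        site: InoculaProfile(site=site, amf_otus=inocula_ids, whole_otus=inocula_ids)
        for site in config.sites
    }
    truth = pd.DataFrame(
        {
            "otu": [k.otu for k in kernels],
            "kernel": [k.kernel.value for k in kernels],
            "expected_category": [k.kernel.expected_category.value for k in kernels],
        }
    )
    return SimulatedExperiment(
        table=table, profiles=profiles, truth=truth, expected=expected
    )


# ---------------------------------------------------------------------------
# random support trees with a brute-force collapse oracle


def simulate_support_tree(
    n_leaves: int,
    p_low_support: float = 0.3,
    p_zero_length: float = 0.1,
    seed: int = 0,
    support_threshold: float = 70.0,
    labels: list[str] | None = None,
) -> tuple[SupportTree, list[frozenset[str]]]:
    """A random rooted binary tree with bootstrap supports, plus the true
    virtual-OTU partition under the collapse rules.

    Each internal node gets support below ``support_threshold`` with
    probability ``p_low_support`` (uniform in [0, threshold)), otherwise
    uniform in [threshold, 100].  Each cherry's two terminal branches are
    set to zero length with probability ``p_zero_length``.  The returned
    partition is computed by :func:`brute_force_partition`, an exhaustive
    reference walker independent of the production collapse code.
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    for name, p in (("p_low_support", p_low_support), ("p_zero_length", p_zero_length)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)

    if labels is None:
        labels = [f"L{i + 1}" for i in range(n_leaves)]
    elif len(labels) != n_leaves or len(set(labels)) != n_leaves:
        raise ValueError("labels must be n_leaves unique strings")
    nodes = list(labels)  # newick fragments
    is_cherry = {}
    leafset = {n: True for n in nodes}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        if rng.uniform() < p_low_support:
            support = rng.uniform(0.0, support_threshold)
        else:
            support = rng.uniform(support_threshold, 100.0)
        if leafset.get(left) and leafset.get(right) and rng.uniform() < p_zero_length:
            bl_left = bl_right = 0.0
        else:
            bl_left = float(np.round(rng.exponential(0.05), 6))
            bl_right = float(np.round(rng.exponential(0.05), 6))
        merged = f"({left}:{bl_left:g},{right}:{bl_right:g}){support:.3f}"
        leafset[merged] = False
        nodes.append(merged)
    newick = nodes[0] + ";"
    stree = support_tree_from_string(newick)
    partition = brute_force_partition(stree, support_threshold=support_threshold)
    return stree, partition


def brute_force_partition(
    stree: SupportTree,
    support_threshold: float = 70.0,
    distance_epsilon: float = 0.0,
) -> list[frozenset[str]]:
    """Exhaustive reference implementation of the collapse rules.

    For every pair of candidate leaves, the pair is mergeable iff every
    internal node in the subtree rooted at their MRCA (MRCA included) is
    collapsible: its clade contains no reference leaf and it either has
    support below the threshold or all pairwise patristic distances among
    its clade's leaves are zero.  Clusters are the transitive closure of
    mergeable pairs.  Quadratic-plus; intended for small trees and oracle
    duty, not production use.
    """
    tree = stree.tree
    refs = stree.reference_leaves
    pdm = tree.phylogenetic_distance_matrix()
    leaves = list(tree.leaf_node_iter())
    taxa = {lf.taxon.label: lf.taxon for lf in leaves}

    def clade_leaf_labels(node) -> list[str]:
        return [lf.taxon.label for lf in node.leaf_iter()]

    def node_collapsible(node) -> bool:
        labels = clade_leaf_labels(node)
        if any(lab in refs for lab in labels):
            return False
        support = getattr(node, "support", None)
        if support is None:
            return False
        if support < support_threshold:
            return True
        return all(
            pdm.patristic_distance(taxa[a], taxa[b]) <= distance_epsilon
            for i, a in enumerate(labels)
            for b in labels[i + 1 :]
        )

    candidates = [lab for lab in taxa if lab not in refs]
    parent = {lab: lab for lab in candidates}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            mrca = pdm.mrca(taxa[a], taxa[b])
            ok = all(
                node_collapsible(nd)
                for nd in mrca.preorder_iter()
                if not nd.is_leaf()
            )
            if ok:
                parent[find(a)] = find(b)

    groups: dict[str, set[str]] = {}
    for lab in candidates:
        groups.setdefault(find(lab), set()).add(lab)
    return [frozenset(g) for g in groups.values()]


# ---------------------------------------------------------------------------
# plant cover


def simulate_plant_cover(
    n_quadrats: int,
    species_pool: int,
    effect: float = 0.0,
    seed: int = 0,
    base_occupancy: float = 0.4,
    mean_hits: float = 3.0,
) -> pd.DataFrame:
    """Point-intersect cover tables for two arms with a known richness effect.

    Each arm ("CONTROL", "INOCULATED") has ``n_quadrats`` quadrats; each of
    ``species_pool`` species is present independently with probability
    ``base_occupancy`` (control) or ``base_occupancy + effect/species_pool``
    (inoculated), so expected richness differs by exactly ``effect``
    species.  Present species receive 1 + Poisson(mean_hits - 1) hits.
    """
    if n_quadrats < 1:
        raise ValueError("n_quadrats must be >= 1")
    if species_pool < 1:
        raise ValueError("species_pool must be >= 1")
    p1 = base_occupancy + effect / species_pool
    if not (0.0 <= p1 <= 1.0) or not (0.0 <= base_occupancy <= 1.0):
        raise ValueError("occupancy probabilities fall outside [0, 1]")
    rng = np.random.default_rng(seed)
    species = [f"sp{j + 1:03d}" for j in range(species_pool)]
    rows = []
    for arm, p in (("CONTROL", base_occupancy), ("INOCULATED", p1)):
        for q in range(1, n_quadrats + 1):
            present = rng.uniform(size=species_pool) < p
            hits = np.where(present, 1 + rng.poisson(max(mean_hits - 1.0, 0.0), species_pool), 0)
            row = {"quadrat_id": f"{arm}_q{q:03d}", "treatment": arm}
            row.update(dict(zip(species, hits.astype(int))))
            rows.append(row)
    return pd.DataFrame(rows)
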