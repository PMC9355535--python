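"""Virtual OTUs: support-threshold tree collapsing and cross-site dominance.

OTUs clustered at 97% similarity can split one biological taxon across
several OTUs.  To compare taxa across sites, OTUs are merged into "virtual
OTUs" by collapsing poorly supported or zero-length structure in a joint
bootstrap tree:

1. starting from the terminal nodes, collapse branches whose support is
   below the threshold (default 70), otherwise retain the branching pattern;
2. never collapse across unresolved/polyphyletic structure -- operationally,
   a clade containing a flagged database reference leaf is not collapsible;
3. collapse well-supported splits whose OTUs have no genetic distance
   (all pairwise patristic distances zero).

The collapse is a leaves-up greedy merge: a cluster is a maximal clade in
which every internal node (including the clade root) satisfies a collapse
rule.  Nodes without a support label are retained (not collapsible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import CATEGORY_ORDER, SpreadCategory, Trial
from .tree import SupportTree

TALLY_CATEGORIES = (
    SpreadCategory.NO_SPREAD,
    SpreadCategory.SPREAD_0_5,
    SpreadCategory.DISTANCE_DECAY,
    SpreadCategory.SPREAD_2M,
)


def _zero_below(node, epsilon: float) -> bool:
    """True when every edge strictly below ``node`` has length <= epsilon.

    Equivalent to all pairwise patristic distances among the clade's leaves
    being zero.  A missing branch length is treated as non-zero (retain)."""
    for child in node.child_nodes():
        if child.edge.length is None or child.edge.length > epsilon:
            return False
        if not child.is_leaf() and not _zero_below(child, epsilon):
            return False
    return True


def collapse_tree(
    stree: SupportTree,
    support_threshold: float = 70.0,
    distance_epsilon: float = 0.0,
) -> list[frozenset[str]]:
    """Partition the candidate OTU leaves into virtual-OTU member sets.

    Returns a list of disjoint frozensets covering every non-reference leaf
    exactly once.  Reference leaves never join a cluster (rule 2) and are
    not part of the returned partition.
    """
    if not 0.0 <= support_threshold <= 100.0:
        raise ValueError(
            f"support threshold {support_threshold} outside [0, 100]"
        )
    refs = stree.reference_leaves
    tree = stree.tree

    def leaf_label(node) -> str:
        return node.taxon.label if node.taxon is not None else node.label

    # post-order: per node, the clade leaf set, reference flag, and whether
    # the whole subtree (node included) is collapsible
    info: dict[int, dict] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = leaf_label(node)
            info[id(node)] = {
                "leaves": frozenset([lab]),
                "has_ref": lab in refs,
                "fully": True,  # a single leaf is trivially mergeable
            }
            continue
        children = node.child_nodes()
        leaves = frozenset().union(*(info[id(c)]["leaves"] for c in children))
        has_ref = any(info[id(c)]["has_ref"] for c in children)
        support = getattr(node, "support", None)
        collapsible = (
            not has_ref
            and support is not None
            and (support < support_threshold or _zero_below(node, distance_epsilon))
        )
        fully = collapsible and all(info[id(c)]["fully"] for c in children)
        info[id(node)] = {"leaves": leaves, "has_ref": has_ref, "fully": fully}

    clusters: list[frozenset[str]] = []
    covered: set[str] = set()

    def walk(node) -> None:
        rec = info[id(node)]
        if node.is_leaf():
            lab = leaf_label(node)
            if lab not in refs:
                clusters.append(frozenset([lab]))
                covered.add(lab)
            return
        if rec["fully"]:
            clusters.append(rec["leaves"])
            covered.update(rec["leaves"])
            return
        for child in node.child_nodes():
            walk(child)

    walk(tree.seed_node)
    assert covered == set(stree.otu_leaves)
    return clusters


# ---------------------------------------------------------------------------
# trial aggregation over virtual OTUs


@dataclass
class VirtualOtu:
    """A collapsed cluster of OTUs with per-category trial tallies."""

    votu_id: str
    members: frozenset[str]
    member_sites: frozenset[str] = field(default_factory=frozenset)
    trial_tallies: dict[SpreadCategory, int] = field(default_factory=dict)
    n_unknown: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a virtual OTU must have at least one member")
        for cat in TALLY_CATEGORIES:
            self.trial_tallies.setdefault(cat, 0)

    @property
    def n_trials(self) -> int:
        return sum(self.trial_tallies.values()) + self.n_unknown

    @property
    def n_non_unknown(self) -> int:
        return sum(self.trial_tallies.values())


def assign_trials(
    partition: list[frozenset[str]], trials: list[Trial]
) -> list[VirtualOtu]:
    """Aggregate classified trials over a virtual-OTU partition.

    Trials in the UNKNOWN category are counted separately and excluded from
    the dominance arithmetic.  A trial whose OTU is absent from the
    partition is an error naming the OTU.
    """
    otu_to_cluster: dict[str, int] = {}
    for i, members in enumerate(partition):
        for otu in members:
            if otu in otu_to_cluster:
                raise ValueError(f"OTU {otu!r} appears in more than one cluster")
            otu_to_cluster[otu] = i

    votus = [
        VirtualOtu(votu_id=f"vOTU{i + 1}", members=members)
        for i, members in enumerate(partition)
    ]
    sites: list[set[str]] = [set() for _ in partition]
    for t in trials:
        idx = otu_to_cluster.get(t.otu)
        if idx is None:
            raise ValueError(f"trial OTU {t.otu!r} is missing from the partition")
        sites[idx].add(t.site)
        if t.category is SpreadCategory.UNKNOWN:
            votus[idx].n_unknown += 1
        else:
            votus[idx].trial_tallies[t.category] += 1
    for v, s in zip(votus, sites):
        v.member_sites = frozenset(s)
    return votus


def dominance(votu: VirtualOtu) -> SpreadCategory | None:
    """The category holding a strict majority (> 50%) of the non-UNKNOWN
    trials, or None.  An exact 50/50 split is non-dominant; zero non-UNKNOWN
    trials mean there is no evidence to judge."""
    total = votu.n_non_unknown
    if total == 0:
        return None
    for cat, count in votu.trial_tallies.items():
        if count * 2 > total:
            return cat
    return None


def consistency_summary(
    votus: list[VirtualOtu],
    min_trials: int = 2,
    min_member_otus: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Cross-site dominance consistency of virtual OTUs.

    Virtual OTUs with at least ``min_trials`` non-UNKNOWN trials drawn from
    at least ``min_member_otus`` original OTUs are retained; for each, the
    per-category share of its non-UNKNOWN trials and its strict-majority
    dominant category (if any) are reported, together with headline counts:
    how many selected virtual OTUs have a dominant category and the
    breakdown of those dominant categories.
    """
    rows = []
    for v in votus:
        if v.n_non_unknown < min_trials or len(v.members) < min_member_otus:
            continue
        dom = dominance(v)
        row = {
            "votu_id": v.votu_id,
            "n_members": len(v.members),
            "n_trials": v.n_trials,
            "n_non_unknown": v.n_non_unknown,
            "sites": ",".join(sorted(v.member_sites)),
        }
        for cat in TALLY_CATEGORIES:
            row[f"pct_{cat.value}"] = (
                100.0 * v.trial_tallies[cat] / v.n_non_unknown
            )
        row["dominant"] = dom.value if dom is not None else "NONE"
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        import warnings

        warnings.warn("no virtual OTUs pass the consistency-summary filters")
        headline = {
            "n_selected": 0,
            "n_dominant": 0,
            "fraction_dominant": float("nan"),
            "dominant_breakdown": {},
        }
        return table, headline
    dominant = table[table["dominant"] != "NONE"]
    breakdown = dominant["dominant"].value_counts().to_dict()
    headline = {
        "n_selected": int(len(table)),
        "n_dominant": int(len(dominant)),
        "fraction_dominant": float(len(dominant) / len(table)),
        "dominant_breakdown": {c.value: int(breakdown.get(c.value, 0)) for c in TALLY_CATEGORIES},
    }
    return table, headline
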