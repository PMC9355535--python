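"""Bundled example data: cross-site virtual-OTU trial tallies.

``cross_site_votus()`` returns the published cross-site dominance table of
a four-experiment prairie-restoration inoculation study: 15 virtual OTUs
that accumulated at least two non-UNKNOWN dispersal trials from at least
two original OTUs, with their trial tallies per spread category.  Tallies
were reconstructed from the printed per-category percentages and
non-UNKNOWN trial counts (all reconstructions are exact integers).

Member OTU ids are synthetic placeholders (the selection rule requires at
least two members per virtual OTU; the source table does not print member
identities).
"""

from __future__ import annotations

from .model import SpreadCategory
from .votu import VirtualOtu

_CHANUTE = "Chanute"
_FR_BB = "Ft. Riley B. bladhii"
_FR_BI = "Ft. Riley B. inermis"
_TINKER = "Tinker"

# (votu_id, n_trials, n_non_unknown, sites, no_spread, spread_0_5, decay, spread_2m)
_ROWS = [
    ("1", 10, 2, (_CHANUTE, _FR_BB), 2, 0, 0, 0),
    ("2", 20, 7, (_CHANUTE, _FR_BB, _FR_BI), 6, 0, 1, 0),
    ("3", 42, 18, (_CHANUTE, _FR_BI, _TINKER), 14, 0, 2, 2),
    ("4", 46, 17, (_CHANUTE, _FR_BB, _TINKER), 9, 3, 5, 0),
    ("7", 12, 2, (_FR_BB, _TINKER), 2, 0, 0, 0),
    ("9", 12, 3, (_CHANUTE, _FR_BI), 1, 0, 0, 2),
    ("10", 6, 2, (_CHANUTE,), 2, 0, 0, 0),
    ("14", 14, 4, (_CHANUTE,), 3, 0, 1, 0),
    ("16", 14, 2, (_CHANUTE,), 0, 0, 1, 1),
    ("17", 12, 4, (_CHANUTE,), 4, 0, 0, 0),
    ("18", 12, 4, (_CHANUTE,), 4, 0, 0, 0),
    ("19", 6, 2, (_CHANUTE, _FR_BI), 0, 2, 0, 0),
    ("20", 10, 3, (_CHANUTE, _FR_BI), 2, 0, 1, 0),
    ("21", 6, 4, (_CHANUTE,), 3, 0, 1, 0),
    ("22", 6, 2, (_TINKER,), 0, 0, 1, 1),
]


def cross_site_votus() -> list[VirtualOtu]:
    """The 15-row cross-site virtual-OTU dominance table as VirtualOtu objects."""
    votus = []
    for votu_id, n_trials, n_non_unknown, sites, ns, s05, dd, s2m in _ROWS:
        assert ns + s05 + dd + s2m == n_non_unknown
        votus.append(
            VirtualOtu(
                votu_id=votu_id,
                # synthetic member ids; see module docstring
                members=frozenset({f"v{votu_id}_otu_a", f"v{votu_id}_otu_b"}),
                member_sites=frozenset(sites),
                trial_tallies={
                    SpreadCategory.NO_SPREAD: ns,
                    SpreadCategory.SPREAD_0_5: s05,
                    SpreadCategory.DISTANCE_DECAY: dd,
                    SpreadCategory.SPREAD_2M: s2m,
                },
                n_unknown=n_trials - n_non_unknown,
            )
        )
    return votus
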