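"""Hub detection and lost/gained hub accounting.

A hub is a node whose cohort-mean nodal strength OR betweenness strictly
exceeds the control threshold (across-node mean + 1 across-node sample SD of
the HC cohort-mean measures).  Control thresholds are applied unchanged to
disease cohorts; an HC hub absent in disease is *lost*, a disease hub absent
in HC is *gained*.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .metrics import NodeMeasures
from .staging import PhaseAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "HubCriteria",
    "HubSet",
    "hub_thresholds",
    "detect_hubs",
    "compare_hubs",
    "phase_hub_summary",
]


@dataclasses.dataclass(frozen=True)
class HubCriteria:
    strength_threshold: float
    betweenness_threshold: float
    source: str = "HC"


@dataclasses.dataclass
class HubSet:
    members: set[int]
    reasons: dict[int, set[str]]    # node -> subset of {"strength", "betweenness"}

    def __contains__(self, node: int) -> bool:
        return node in self.members

    def __len__(self) -> int:
        return len(self.members)


def hub_thresholds(hc_node_measures: NodeMeasures, source: str = "HC") -> HubCriteria:
    """Across-node mean + 1 sample SD (ddof=1) per measure.

    Zero across-node variance degenerates the threshold to the mean (logged);
    under the strict exceedance rule no node is then a hub.
    """
    s, b = hc_node_measures.strength, hc_node_measures.betweenness
    if s.shape[0] < 3:
        raise ValueError("need at least 3 nodes to derive hub thresholds")
    s_sd, b_sd = s.std(ddof=1), b.std(ddof=1)
    if s_sd == 0 or b_sd == 0:
        logger.warning("zero across-node variance; hub threshold equals the mean")
    return HubCriteria(strength_threshold=float(s.mean() + s_sd),
                       betweenness_threshold=float(b.mean() + b_sd),
                       source=source)


def detect_hubs(node_measures: NodeMeasures, criteria: HubCriteria) -> HubSet:
    """Node is a hub iff strength OR betweenness strictly exceeds its threshold."""
    members: set[int] = set()
    reasons: dict[int, set[str]] = {}
    for i in range(node_measures.strength.shape[0]):
        why = set()
        if node_measures.strength[i] > criteria.strength_threshold:
            why.add("strength")
        if node_measures.betweenness[i] > criteria.betweenness_threshold:
            why.add("betweenness")
        if why:
            members.add(i)
            reasons[i] = why
    return HubSet(members=members, reasons=reasons)


def compare_hubs(hc_hubs: HubSet, disease_hubs: HubSet
                 ) -> tuple[set[int], set[int], set[int]]:
    """Return (lost, gained, retained) hub node sets."""
    lost = hc_hubs.members - disease_hubs.members
    gained = disease_hubs.members - hc_hubs.members
    retained = hc_hubs.members & disease_hubs.members
    return lost, gained, retained


def phase_hub_summary(hc_hubs: HubSet, disease_hubs: HubSet,
                      phases: PhaseAssignment) -> dict[int, dict[str, float | None]]:
    """Per-phase hub percentages.

    For each phase p:
      ``pct_nodes_hub``   100 * |HC hubs in p| / |p|                (diseased
                          nodes associated with control hubs)
      ``pct_hubs_lost``   100 * |lost in p|   / |HC hubs in p|
      ``pct_hubs_gained`` 100 * |gained in p| / |HC hubs in p|
    Undefined denominators yield None, never 0.
    """
    lost, gained, _ = compare_hubs(hc_hubs, disease_hubs)
    out: dict[int, dict[str, float | None]] = {}
    for p in range(1, 6):
        nodes = set(phases.regions_in_phase(p).tolist())
        hc_in = hc_hubs.members & nodes
        entry: dict[str, float | None] = {
            "pct_nodes_hub": 100.0 * len(hc_in) / len(nodes) if nodes else None,
            "pct_hubs_lost": 100.0 * len(lost & nodes) / len(hc_in) if hc_in else None,
            "pct_hubs_gained": 100.0 * len(gained & nodes) / len(hc_in) if hc_in else None,
        }
        out[p] = entry
    return out
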