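"""Proximal spreading connections.

A *proximal spreading connection* is a pair of physically adjacent regions
spanning an earlier phase p and a later phase q, counted per individual:
the subject must show binarized atrophy at an endpoint (by default at both
endpoints).  Counts are normalized by the total possible connections between
the two phases (product of the phase sizes).
"""

from __future__ import annotations

import numpy as np

from .staging import AtrophyTable, PhaseAssignment

__all__ = [
    "adjacent_phase_pairs",
    "subject_proximal_stats",
    "cohort_proximal_stats",
    "EPICENTRE_PAIRS",
    "SEQUENTIAL_PAIRS",
]

EPICENTRE_PAIRS = ((1, 2), (1, 3), (1, 4), (1, 5))
SEQUENTIAL_PAIRS = ((1, 2), (2, 3), (3, 4), (4, 5))


def adjacent_phase_pairs(phases: PhaseAssignment, adjacency: np.ndarray,
                         pair: tuple[int, int]) -> list[tuple[int, int]]:
    """All unordered region pairs (a in phase p, b in phase q, adjacent)."""
    p, q = pair
    if not p < q:
        raise ValueError("phase pair must be ordered earlier < later")
    a_set = phases.regions_in_phase(p)
    b_set = phases.regions_in_phase(q)
    return [(int(a), int(b)) for a in a_set for b in b_set if adjacency[a, b]]


def subject_proximal_stats(subject_atrophy: np.ndarray,
                           candidates: list[tuple[int, int]],
                           n_p: int, n_q: int,
                           require_both: bool = True) -> dict[str, float | None]:
    """Raw and product-normalized proximal-spread count for one subject.

    ``require_both`` demands atrophy at both endpoints (the default reading
    of spread having occurred along the pair); ``False`` accepts either end.
    """
    if require_both:
        raw = sum(1 for (a, b) in candidates
                  if subject_atrophy[a] and subject_atrophy[b])
    else:
        raw = sum(1 for (a, b) in candidates
                  if subject_atrophy[a] or subject_atrophy[b])
    if n_p == 0 or n_q == 0:
        return {"raw": float(raw), "normalized": None}
    return {"raw": float(raw), "normalized": raw / (n_p * n_q)}


def cohort_proximal_stats(atrophy: AtrophyTable, phases: PhaseAssignment,
                          adjacency: np.ndarray,
                          pairs: tuple[tuple[int, int], ...] = EPICENTRE_PAIRS,
                          require_both: bool = True
                          ) -> dict[tuple[int, int], list[dict[str, float | None]]]:
    """Per-subject proximal stats for each requested phase pair."""
    sizes = phases.phase_sizes()
    out: dict[tuple[int, int], list[dict[str, float | None]]] = {}
    for pair in pairs:
        cands = adjacent_phase_pairs(phases, adjacency, pair)
        n_p, n_q = sizes[pair[0]], sizes[pair[1]]
        out[pair] = [
            subject_proximal_stats(row, cands, n_p, n_q, require_both)
            for row in atrophy.table
        ]
    return out
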