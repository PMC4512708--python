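"""Shared cohort construction for the numbered analysis drivers.

Every driver operates on the same synthetic study cohort (seed 7): 212 ROIs,
14 subjects, conditions rest / syllable / speech, 62 weakly coupled regions.
"""

from pathlib import Path

from fconn.construct import correlation_graph, eliminate_nodes
from fconn.graph_core import DensitySchedule
from fconn.synthdata import simulate_panel, study_cohort_spec

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"
SUBJECT_SCHEDULE = DensitySchedule.linear(0.77, 0.86, 10)
MIN_PRESENCE = 0.7
REFERENCE = "speech"


def build_cohort(seed: int = SEED):
    """Simulate the cohort and return (spec, per-condition correlation graphs)."""
    spec = study_cohort_spec(seed)
    by_condition: dict[str, list] = {}
    for panel in simulate_panel(spec):
        by_condition.setdefault(panel.condition, []).append(
            correlation_graph(panel)
        )
    return spec, by_condition


def reduced_cohort(seed: int = SEED):
    """Cohort after nodal elimination against the reference condition."""
    spec, by_condition = build_cohort(seed)
    keep = eliminate_nodes(by_condition[REFERENCE], 0.5, 0.05)
    reduced = {
        cond: [g.subgraph(keep) for g in graphs]
        for cond, graphs in by_condition.items()
    }
    return spec, reduced, keep
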