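"""Reverse Kaplan-Meier versus the competing-risk follow-up curve.

Two 2-year cohorts share identical dropout (30 subjects at 1.5 y) but
differ in early events (30 vs 10 at 0.5 y).  The reverse KM curve treats
events as censored, so the event-heavy cohort looks worse-followed; the
competing-risk curve keeps events in the risk set and is identical for
both.  Its mean height equals the simplified person-time rate.
"""

from ptfr import competing_followup_curve, curve_auc, reverse_km, spt_rate
from ptfr.datasets import CURVE_DEMO_TAU, curve_demo_cohort

for scenario in ("A", "B"):
    cohort = curve_demo_cohort(scenario)
    rk = reverse_km(cohort, CURVE_DEMO_TAU)
    cc = competing_followup_curve(cohort, CURVE_DEMO_TAU)
    auc = curve_auc(cc, CURVE_DEMO_TAU)
    n_events = sum(r.status.value == "event" for r in cohort)
    print(f"scenario {scenario}: {n_events} early events, 30 dropouts at 1.5 y")
    print(f"  reverse KM value after 1.5 y      : {rk(1.6):.3f}")
    print(f"  competing-risk value after 1.5 y  : {cc(1.6):.3f}")
    print(f"  competing-curve AUC/tau           : {auc:.4f}"
          f"  (= SPT {spt_rate(cohort, CURVE_DEMO_TAU):.2f}% / 100)")

print(
    "\nReverse KM drops to 0.571 (A) vs 0.667 (B) purely because of event"
    "\ntiming; the competing-risk curve is 0.700 in both, and its average"
    "\nheight reproduces the simplified person-time rate exactly."
)
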