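"""Five follow-up rates on a hand-checkable toy cohort.

100 subjects, annual visits for 3 years: 10/5/5 events at mid-years
0.5/1.5/2.5, and 40 dropouts either early (scenario A, 0.5 y) or late
(scenario B, 2.5 y).  The Percentage Method cannot tell the scenarios
apart; every person-time rate can.
"""

from ptfr import followup_report
from ptfr.datasets import TOY_TAU, toy_cohort

for scenario in ("A", "B"):
    cohort = toy_cohort(scenario)
    rep = followup_report(cohort, TOY_TAU, boundaries=[0, 1, 2, 3])
    print(f"scenario {scenario} (dropouts at {'0.5' if scenario == 'A' else '2.5'} y)")
    print(f"  percentage method : {rep.rate_percentage:5.1f} %")
    print(f"  completeness index: {rep.rate_cci:5.1f} %   (= lower bound)")
    print(f"  simplified PT     : {rep.rate_spt:5.1f} %")
    print(f"  formal PT (NPMLE) : {rep.rate_fpt:5.1f} %")
    print(f"  true PT rate      : {rep.rate_true_ptfr:5.1f} %  (oracle)")

print(
    "\nThe Percentage Method prints 60.0 for both scenarios because it only"
    "\ncounts heads; the person-time rates rise from ~62-67% (early dropout)"
    "\nto ~92-93% (late dropout) because late dropouts contributed almost"
    "\ntheir full potential follow-up."
)
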