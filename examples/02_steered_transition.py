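"""Drive the closed-to-open transition by steered dynamics.

Runs two steering sets on the synthetic gated model, five replicas each:
the minimal successful set (d1, d2, d6, χ1 steered with the α3 helix
restrained) and a deliberately insufficient one (d1 alone). A replica
counts as successful when every steered CV stays within 2σ of its
open-state mean over the final half of the bias-free stage.
"""

from cvsteer.analysis import success_summary
from cvsteer.model import build_cv_space_model
from cvsteer.smd import make_run_spec, run_smd

model = build_cv_space_model()
reports = []
for set_name in ("126a3x-d", "1"):
    spec = make_run_spec(set_name, model.refs, n_replicas=5, base_seed=1)
    trajs, report = run_smd(model, spec)
    reports.append(report)
    print(f"set {set_name}: {report.n_success}/{report.n_replicas} successful")
    for rep in report.replicas:
        devs = ", ".join(f"{k}={v:+.1f}σ" for k, v in rep["deviations"].items())
        print(f"  seed {rep['seed']}: success={rep['success']}  ({devs})")

print("\nSummary table (one row per steering set):")
print(success_summary(reports).to_string(index=False))
print(
    "\nSteering only the hinge distance d1 moves d1 but the salt bridge,"
    "\nrotamer and second hinge CV all relax back once the bias is released;"
    "\nthe four-CV set with the helix restraint converts every replica."
)
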