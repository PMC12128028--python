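"""Validate the CV choice without a target bias (temperature-accelerated).

Couples d1, d2, d6 and χ1 to hot auxiliary variables and integrates the
joint system. If the CV set is sufficient, all four CVs visit the open
2σ window together; representative snapshots are then ranked by their
standardized CV distance to the open state and relaxed without any bias
to confirm the open state is genuinely metastable.
"""

from cvsteer.model import build_cv_space_model
from cvsteer.references import OPEN_STATE
from cvsteer.tamd import (TAMDParams, joint_open_visit, rank_frames,
                          relax_from_frames, run_tamd)

model = build_cv_space_model()
params = TAMDParams()  # full coupling set, helix restrained

traj = None
for seed in range(1, 6):
    t = run_tamd(model, params, 100000, seed=seed)
    visited = joint_open_visit(t, OPEN_STATE, list(params.kappas))
    print(f"seed {seed}: joint open-window visit = {visited}")
    if visited and traj is None:
        traj = t

frames, shortfall = rank_frames(traj, OPEN_STATE, n=10)
print(f"\nranked {len(frames)} snapshots (shortfall={shortfall}); best three:")
for f in frames[:3]:
    vals = ", ".join(f"{k}={v:.2f}" for k, v in f.cv_values.items())
    print(f"  frame {f.index} t={f.time:.2f}  distance={f.distance:.2f}σ  {vals}")

relaxed, report = relax_from_frames(model, traj, frames, 25000,
                                    seeds=range(101, 111))
stays = sum(r["stays_open"] for r in report)
print(f"\nunbiased relaxation: {stays}/{len(report)} replicas remain open")
print("per-CV density overlap with the open reference (replica 1):")
for k, v in report[0]["overlap"].items():
    print(f"  {k}: {v:.2f}")
print(
    "\nA high overlap and near-total retention mean the accelerated CVs"
    "\nfound a genuine metastable open basin, not a forced artefact."
)
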