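#!/usr/bin/env python
"""Short stimuli produce composite lead VEPs; long stimuli resolve them.

Simulates the same synthetic subjects viewing 150 ms and 300 ms sequences.
With 150 ms elements, the slow second negativity of the sequence-initial
stimulus (N2, ~185 ms post-onset) overlaps the next stimulus' fast N1
(~60 ms post its own onset), so the apparent "B" response is biphasic.
With 300 ms elements the two components separate cleanly and can be
quantified independently.  Writes results/composite/.
"""

from pathlib import Path

import pandas as pd

from srpt.simulate import simulate_cohort
from srpt.vep import (
    average_vep,
    component_measures,
    default_component_specs,
    detect_biphasic,
    extract_epochs,
)

OUT = Path("results/composite")
OUT.mkdir(parents=True, exist_ok=True)
N = 20

rows = []
n_biphasic = 0
co150 = simulate_cohort("sequence-150", n_per_group=N, seed=42,
                        channels=("ACC",), include_novel=False)
for rec, proto, lfp in co150.iter_sessions(channels=["ACC"]):
    if rec.day != 1:
        continue
    vep = average_vep(
        extract_epochs(lfp, proto.select(seq_position=1), (-100.0, 1020.0), "ACC")
    )
    ok, troughs = detect_biphasic(vep, (170.0, 270.0))
    n_biphasic += ok
    rows.append(dict(subject=rec.subject_id, duration_ms=150, biphasic=ok,
                     troughs_post_b_ms=[round(t - 150.0, 1) for t in troughs]))

co300 = simulate_cohort("sequence-300", n_per_group=N, seed=42,
                        channels=("ACC",), include_novel=False)
comp_rows = []
for rec, proto, lfp in co300.iter_sessions(channels=["ACC"]):
    if rec.day != 1:
        continue
    vep = average_vep(
        extract_epochs(lfp, proto.select(seq_position=1), (-100.0, 1620.0), "ACC")
    )
    specs = default_component_specs("ABCD", 300.0, "ACC")
    for m in component_measures(vep, specs, 300.0):
        comp_rows.append(dict(subject=rec.subject_id, component=m.name,
                              latency_ms=m.latency, magnitude_uv=m.magnitude,
                              valid=m.valid))

pd.DataFrame(rows).to_csv(OUT / "biphasic_150ms.csv", index=False)
comp = pd.DataFrame(comp_rows)
comp.to_csv(OUT / "components_300ms.csv", index=False)

print(f"150 ms sequences, Day 1: biphasic lead VEP in {n_biphasic}/{N} subjects")
print("\n300 ms sequences, Day 1 component latencies (ms, own-onset):")
print(comp.groupby("component")["latency_ms"].agg(["mean", "std"]).round(1).to_string())
resolved = comp.pivot_table(index="subject", columns="component", values="valid",
                            aggfunc="first")[["A2", "B1"]].all(axis=1).sum()
print(f"\nA2 and B1 separately quantifiable in {resolved}/{N} subjects")
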