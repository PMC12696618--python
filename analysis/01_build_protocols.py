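#!/usr/bin/env python
"""Construct all five stimulus protocols and tabulate their session structure.

Writes one event-log CSV per protocol plus a structural summary
(results/protocols/): trial counts, block layout, gray-screen spacing.
"""

from pathlib import Path

import pandas as pd

import srpt
from srpt.io import write_event_log

OUT = Path("results/protocols")
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for kind, dur, kwargs in [
    ("ABCD", 150.0, {}),
    ("ABCD", 300.0, {}),
    ("DCBA", 300.0, {}),
    ("AXXX", 300.0, dict(seed=7)),
    ("SINGLE", 300.0, {}),
    ("SINGLE", 1500.0, {}),
    ("PHASE_REVERSAL", 300.0, {}),
]:
    p = srpt.make_protocol(kind, stimulus_duration=dur, **kwargs)
    stem = f"{kind.lower()}_{int(p.stimulus_duration)}ms"
    write_event_log(p, OUT / f"{stem}.events.csv", session_id=stem)
    rows.append(
        dict(
            kind=kind,
            stimulus_ms=p.stimulus_duration,
            events=len(p.events),
            trials=p.n_trials,
            blocks=p.n_blocks,
            block_size=p.block_size,
            gray_ms=p.gray_ms,
            interblock_s=p.interblock_gap_ms / 1000,
            session_min=round(p.duration_ms / 60_000, 1),
        )
    )

summary = pd.DataFrame(rows)
summary.to_csv(OUT / "summary.csv", index=False)
print(summary.to_string(index=False))
print(f"\nwrote event logs and summary to {OUT}/")
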