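"""Step log: JSON Lines, one StepRecord per line.

Line-oriented so a crashed or aborted run leaves an inspectable log.
Records carry no wall-clock data — replaying a run from its configuration
reproduces the file byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path

from ..supervision import Decision, StepRecord


def write_step_log(path: str | Path, records: list[StepRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json_dict(), sort_keys=True) + "\n")


def read_step_log(path: str | Path) -> list[StepRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        records.append(
            StepRecord(
                phase_name=d["phase_name"],
                step_index=d["step_index"],
                attempt_index=d["attempt_index"],
                seed=d["seed"],
                distance_series=[tuple(p) for p in d["distance_series"]],
                slope=d["slope"],
                decision=Decision(d["decision"]),
                frames_kept=d["frames_kept"],
                snapshot_interval=d.get("snapshot_interval"),
            )
        )
    return records
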