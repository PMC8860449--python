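#!/usr/bin/env python
"""Generate the demo session: a 60-min synthetic ECoG/EMG/plethysmography
recording cycling 40 min normoxia → 20 min hypoxia, with spike-wave events
at 0.89 / 1.73 per 5-min bin and breathing at 1.03 / 1.33 Hz.

Writes the injected ground truth to results/ and the full multi-channel
recording (large) to scratch/demo_session/.
"""

from pathlib import Path

from swdlab.io_formats import write_events, write_protocol, write_recording, CoarseEvent
from swdlab.synth import SynthConfig, generate_session

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "demo_session"


def main() -> None:
    cfg = SynthConfig(session_length=3600.0, seed=1)
    rec, truth = generate_session(cfg)

    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    write_recording(rec, SCRATCH / "recording.csv")
    write_protocol(truth.condition_timeline, SCRATCH / "protocol.json")
    write_events(
        [CoarseEvent(e.t_start, e.t_end, f"f0={e.f0:.2f}") for e in truth.events],
        RESULTS / "01_ground_truth_events.csv",
    )

    t_zero = truth.condition_timeline.t_zero
    pre = sum(1 for e in truth.events if e.t_start < t_zero)
    post = len(truth.events) - pre
    print(f"session: {rec.duration:.0f} s at {rec.fs:.0f} Hz, "
          f"{len(rec.channels)} channels")
    print(f"injected events: {len(truth.events)} "
          f"({pre} before gas exchange, {post} during hypoxia)")
    print(f"breathing schedule: "
          + ", ".join(f"{r:.2f} Hz in [{a:.0f}, {b:.0f}) s"
                      for a, b, r in truth.resp_schedule))
    print(f"recording written to {SCRATCH / 'recording.csv'}")


if __name__ == "__main__":
    main()
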