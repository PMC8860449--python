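#!/usr/bin/env python
"""Refine and characterize the demo session's spike-wave events.

Regenerates the same session as 01_simulate.py, builds jittered coarse
candidate windows around the ground truth (standing in for the manual
screening step), runs the refinement pipeline, and reports boundary accuracy
against the injected truth.  Writes results/02_events.csv.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from swdlab.pipeline import coarse_from_truth
from swdlab.swd import process_events
from swdlab.synth import SynthConfig, generate_session

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rec, truth = generate_session(SynthConfig(session_length=3600.0, seed=1))
    rng = np.random.default_rng(2)
    coarse = coarse_from_truth(truth.events, jitter_s=1.0, pad_s=1.0, rng=rng)
    events, rejections = process_events(rec, coarse)

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame([dataclasses.asdict(e) for e in events]).to_csv(
        RESULTS / "02_events.csv", index=False, float_format="%.17g")

    print(f"coarse candidates: {len(coarse)}; accepted: {len(events)}; "
          f"rejected: {len(rejections)}")
    truth_long = [t for t in truth.events if t.duration >= 2.0]
    errs = []
    for t in truth_long:
        best = min(events, key=lambda d: abs(d.t_onset - t.t_start), default=None)
        if best is not None and abs(best.t_onset - t.t_start) < 2.0:
            errs.append((abs(best.t_onset - t.t_start),
                         abs(best.t_offset - t.t_end),
                         abs(best.dominant_freq - t.f0)))
    if errs:
        errs = np.array(errs)
        print(f"matched {len(errs)}/{len(truth_long)} events ≥ 2 s; "
              f"median |onset error| {np.median(errs[:,0])*1e3:.0f} ms, "
              f"median |offset error| {np.median(errs[:,1])*1e3:.0f} ms, "
              f"median |f0 error| {np.median(errs[:,2]):.3f} Hz")
    durs = [e.duration for e in events]
    freqs = [e.dominant_freq for e in events]
    print(f"event duration {np.mean(durs):.1f} ± "
          f"{np.std(durs, ddof=1)/np.sqrt(len(durs)):.1f} s; "
          f"frequency {np.mean(freqs):.1f} ± "
          f"{np.std(freqs, ddof=1)/np.sqrt(len(freqs)):.1f} Hz (mean ± SE)")


if __name__ == "__main__":
    main()
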