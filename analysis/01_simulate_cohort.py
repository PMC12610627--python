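#!/usr/bin/env python
"""Generate the default synthetic cohort (21 participants x 3 scenarios).

Writes the cohort manifest and per-session data files under
results/cohort/. The defaults are the contaminated, biased study
conditions: EMG bursts and motion transients in the EEG, a positive
social-desirability bias and discretization noise in the questionnaire,
and small indicator noise in the behavioral codings.
"""
import argparse
from pathlib import Path

from trustfuse import io
from trustfuse.synthetic import CohortConfig, cohort_manifest, simulate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    ap.add_argument("--participants", type=int, default=21)
    args = ap.parse_args()

    cohort = simulate_cohort(args.participants, CohortConfig(), args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    for pid, scen, sess in cohort.sessions():
        stem = args.out / f"{pid}_{scen}"
        io.write_eeg_csv(sess.recording, f"{stem}_eeg.csv")
        io.write_events_json(sess.timeline, f"{stem}_events.json")
        io.write_questionnaire_csv(sess.responses, f"{stem}_questionnaire.csv")
        io.write_behavior_csv(sess.codings, f"{stem}_behavior.csv")
    (args.out / "manifest.json").write_text(cohort_manifest(cohort))
    n_sessions = len(cohort.sessions())
    print(f"wrote {n_sessions} sessions ({args.participants} participants x 3 scenarios) "
          f"to {args.out} (seed={args.seed})")


if __name__ == "__main__":
    main()
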