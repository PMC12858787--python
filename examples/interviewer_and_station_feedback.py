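"""Interviewer severity feedback and station difficulty diagnostics.

Prints one plain-text feedback letter, the distribution of narrative
bands, and the stations flagged as unusually easy or hard (|U_k| >= 1).
"""

from collections import Counter

from mmiprobit import (
    fit_cpmm,
    interviewer_feedback,
    reference_cohort,
    simulate_cohort,
    station_diagnostics,
)
from mmiprobit.reports import feedback_letter

cfg = reference_cohort(
    seed=3,
    n_candidates=120,
    n_interviewers=36,
    n_days=4,
    circuits_per_day=1,
    sigma={"candidate": 0.6, "interviewer": 0.8, "station": 1.1, "day": 0.055},
)
cohort = simulate_cohort(cfg)
model = fit_cpmm(cohort.dataset)

feedback = interviewer_feedback(model, cohort.dataset)
most_severe = min(feedback, key=lambda f: f.severity)
print(feedback_letter(most_severe))

bands = Counter(f.narrative_band for f in feedback)
print("\nband counts:", dict(bands))

print("\nstation diagnostics (threshold 1.0 latent SD):")
for d in station_diagnostics(model, flag_threshold=1.0):
    mark = " <-- flagged" if d.flagged else ""
    print(f"  {d.station_id}: U = {d.effect:+.3f} ({d.direction}){mark}")

# Interpretation: a flagged 'easy' station lifted scores for everyone who
# sat it, a 'hard' one depressed them; the model has already removed these
# effects from each candidate's ability, so flagging informs station
# design review rather than scoring corrections.
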