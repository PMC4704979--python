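# wmtrain

Adaptive working-memory training engines with simulated responders.

`wmtrain` re-creates, as a testable Python library and CLI, the
computational core of a tablet-based cognitive-rehabilitation trainer for
people with working-memory impairment (the pilot population was patients
with multiple sclerosis): three working-memory exercises, the adaptive
working-load staircase that personalises their difficulty, the
training-intensiveness scheduler, text-file raw logging with per-patient
reports, and the adherence / usability-questionnaire outcome statistics.
Because no touchscreen user sits at a desk build, a parametric simulated
responder closes the loop and exercises the whole system end to end.

## The exercises

* **Vs-WM** — visuospatial working memory: reproduce, in order, a random
  sequence of cells lit on an *R×C* grid (cells are not repeated within a
  sequence).
* **Op-NB** — operation n-back: digit pairs (e.g. `1+4`) are presented;
  answer the **sum** of the pair shown *N* stimuli earlier. With the full
  1–9 digit span the sums range from 2 to 18.
* **D-NB** — dual n-back: a digit 1–4 appears in one of 4 cells in a row;
  answer **both** the digit (buttons 1–4) and the cell (buttons 5–8,
  5 = left-most) of the stimulus *N* back. Both buttons must match.

Each block of *S* stimuli has *S − N* scored positions (the first *N* are
memorise-only) and yields counts `n_correct + n_incorrect + n_missed =
scored` with `pct_correct = 100·n_correct/scored`.

## The adaptive working load

A block is **valid** when its percent correct meets the paradigm threshold
(100% Vs-WM, 80% Op-NB, 75% D-NB). The staircase is 1-up /
3-consecutive-down:

* valid → level + 1 and a new exercise record is auto-generated, bound to
  the patient;
* 1st or 2nd consecutive invalid → nothing changes, the last record is
  reused;
* 3rd consecutive invalid → level − 1 (never below the easiest rung).

Levels map to configurations through a *difficulty ladder*: the
presentation rate speeds up first (to 1 s/stimulus for Vs-WM, 3 s for the
n-back types), then the task parameter grows — sequence length for Vs-WM,
*N* for the n-back types, whose block length follows `stimuli = (N+1)×5`
(so a 2-back block presents 15 stimuli).

The staircase with a level-dependent validity probability is an explicit
Markov chain on `(level, invalid-streak)` states; `wmtrain.responder`
provides both its exact stationary distribution and long closed-loop
simulations, which agree within Monte-Carlo error.

## Worked example

```python
from wmtrain import (PROTOCOL_PROGRAM, ResponderModel, adherence_summary,
                     protocol_ladders, protocol_starting_records, run_program)

model = ResponderModel(capacity_level=4, miss_rate=0.02)
history = run_program(model, PROTOCOL_PROGRAM, protocol_starting_records("ms-01"),
                      protocol_ladders(), seed=42)
print("sessions:", len(history.sessions))
print("blocks:", len(history.raw_lines))
print("max levels:", {t.value: l for t, l in sorted(history.max_levels().items())})
summary = adherence_summary({"ms-01": len(history.sessions)}, PROTOCOL_PROGRAM)
print("adherence:", summary.adherence_percent, "%")
```

prints

```
sessions: 40
blocks: 8840
max levels: {'d-nb': 6, 'op-nb': 6, 'vs-wm': 6}
adherence: 100 %
```

— the 8-week, 5-sessions/week program yields exactly 40 sessions; a
responder with capacity level 4 is driven to oscillate around levels 4–6
in all three paradigms (the staircase's equilibrium sits where the
probability of a valid block crosses ≈ 0.21, the balance point of a 1-up /
3-consecutive-down rule); full attendance is 100% adherence.

The same run is available from the shell:

```sh
wmtrain --store demo add-patient ms-01 --name "Subject One" --meta EDSS=3.5
wmtrain --store demo assign ms-01 --exercise all --adaptive
wmtrain --store demo simulate ms-01 --seed 42
wmtrain --store demo report ms-01
wmtrain --store demo export backup/
```

Raw per-block data are appended to a tab-separated UTF-8 text log (one
line per block: timestamp, patient, paradigm, level, config snapshot,
stimulus seed, answer counts, validity) from which the per-patient report
— and the per-exercise maximum level achieved — is regenerated exactly.

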