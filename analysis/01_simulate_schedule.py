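#!/usr/bin/env python
"""Generate and validate one pseudorandomized flanker session.

Writes the trial table to results/schedule.tsv and prints the design
counts that every downstream stage relies on: 240 trials in 10
mini-blocks of 24, 60 trials per congruency x direction cell, a 24 s
stimulation span per block, and run-length constraints satisfied.
"""

import os

from flankerlab import paradigm

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main(seed: int = 7) -> None:
    os.makedirs(OUT, exist_ok=True)
    sch = paradigm.generate_sequence(seed=seed)
    violations = paradigm.validate_sequence(sch)
    assert not violations, violations

    cells = {}
    for t in sch.trials:
        cells[(t.congruency, t.direction)] = cells.get(
            (t.congruency, t.direction), 0) + 1
    spans = []
    for blk in sch.blocks:
        bt = [t for t in sch.trials if t.block_index == blk.block_index]
        spans.append(bt[-1].onset + 1.0 - bt[0].onset)

    print(f"seed {seed}: {len(sch.trials)} trials in {len(sch.blocks)} blocks "
          f"({len(sch.training_trials)} training trials, not analyzed)")
    for cell, n in sorted(cells.items()):
        print(f"  {cell[0]:>11s} / {cell[1]:<5s}: {n} trials")
    print(f"  stimulation span per mini-block: {spans[0]:.1f} s")
    print(f"  session duration: {sch.duration_s:.1f} s")
    print("  pseudorandomization constraints: all satisfied")

    path = os.path.join(OUT, "schedule.tsv")
    paradigm.write_schedule(sch, path)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
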