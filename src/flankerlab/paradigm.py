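"""Eriksen flanker mini-block stimulus schedule: generation and validation.

The session consists of 10 mini-blocks of 24 trials each (240 analyzed
trials), preceded by two 10-trial training blocks.  Half of the blocks
are mainly congruent (18 congruent + 6 incongruent trials) and half
mainly incongruent (the reverse); left and right targets are balanced
within every block (12/12), giving 60 trials per congruency x direction
cell over the session.  Pseudorandomization constraints: no more than
three consecutive trials of the same congruency or the same target
direction within a block, and no more than three consecutive blocks of
the same type.  Each trial shows the stimulus for 250 ms followed by a
750 ms inter-stimulus interval (1 s pitch); blocks are separated by an
inter-block interval drawn uniformly from 6-14 s (10 s mean).

Schedules are generated by seeded rejection sampling against the same
validator that checks them, so generator and validator cannot drift
apart.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrialSpec",
    "BlockSpec",
    "SequenceDesign",
    "StimulusSchedule",
    "generate_sequence",
    "validate_sequence",
    "schedule_to_events",
    "write_schedule",
    "read_schedule",
]

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
LEFT = "left"
RIGHT = "right"
MAINLY_CONGRUENT = "mainly_congruent"
MAINLY_INCONGRUENT = "mainly_incongruent"

STIM_DURATION_S = 0.250
ISI_DURATION_S = 0.750
TRIAL_PITCH_S = STIM_DURATION_S + ISI_DURATION_S

#: Event marker codes per congruency x direction cell (BrainVision-style
#: "S  n" stimulus codes) plus block-onset codes per block type.
TRIAL_CODES = {
    (CONGRUENT, LEFT): 11,
    (CONGRUENT, RIGHT): 12,
    (INCONGRUENT, LEFT): 21,
    (INCONGRUENT, RIGHT): 22,
}
BLOCK_CODES = {MAINLY_CONGRUENT: 101, MAINLY_INCONGRUENT: 102}


@dataclass(frozen=True)
class TrialSpec:
    index: int
    congruency: str
    direction: str
    block_index: int
    onset: float  # seconds from session start
    stim_duration: float = STIM_DURATION_S
    isi_duration: float = ISI_DURATION_S
    training: bool = False


@dataclass(frozen=True)
class BlockSpec:
    block_index: int
    block_type: str
    trial_count: int
    ibi_after: float


@dataclass(frozen=True)
class SequenceDesign:
    """Design parameters of one session.

    ``majority_fraction`` is the share of the majority congruency inside
    each block (0.75 -> 18 of 24 trials).
    """

    n_blocks: int = 10
    trials_per_block: int = 24
    majority_fraction: float = 0.75
    max_run: int = 3
    max_block_run: int = 3
    ibi_range_s: tuple[float, float] = (6.0, 14.0)
    n_training_blocks: int = 2
    training_trials: int = 10
    lead_in_s: float = 2.0  # quiet period before the first stimulus

    def __post_init__(self) -> None:
        if self.n_blocks % 2 != 0:
            raise ValueError("n_blocks must be even (half per block type)")
        n_major = self.majority_fraction * self.trials_per_block
        if abs(n_major - round(n_major)) > 1e-9:
            raise ValueError("majority_fraction * trials_per_block must be integral")
        if self.trials_per_block % 2 != 0:
            raise ValueError("trials_per_block must be even (left/right balance)")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def majority_count(self) -> int:
        return round(self.majority_fraction * self.trials_per_block)


@dataclass
class StimulusSchedule:
    trials: list[TrialSpec]
    blocks: list[BlockSpec]
    seed: int
    design: SequenceDesign = field(default_factory=SequenceDesign)
    training_trials: list[TrialSpec] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        """Session length: last trial offset plus the final IBI."""
        if not self.trials:
            return 0.0
        last = self.trials[-1]
        tail = self.blocks[-1].ibi_after if self.blocks else 0.0
        return last.onset + TRIAL_PITCH_S + tail


def _max_run_ok(labels, max_run: int) -> bool:
    run = 0
    prev = None
    for lab in labels:
        run = run + 1 if lab == prev else 1
        prev = lab
        if run > max_run:
            return False
    return True


def _shuffle_with_runs(items: list, max_run: int, rng: np.random.Generator,
                       key=lambda x: x, max_tries: int = 10_000) -> list:
    items = list(items)
    for _ in range(max_tries):
        rng.shuffle(items)
        if _max_run_ok([key(x) for x in items], max_run):
            return items
    raise RuntimeError(
        f"could not satisfy run-length <= {max_run} after {max_tries} shuffles; "
        "the design is likely constraint-unsatisfiable"
    )


def _constrained_binary_sequence(counts: dict, max_run: int,
                                 rng: np.random.Generator) -> list:
    """Random sequence with the given label counts and no run > max_run.

    Sequential sampling with a feasibility lookahead: a label is a
    candidate only if, after placing it, each remaining label count can
    still be packed into runs of length <= max_run separated by the
    other label.  Raises when the counts are unsatisfiable outright.
    """
    labels = list(counts)
    remaining = dict(counts)
    seq: list = []
    prev, run = None, 0
    for _ in range(sum(counts.values())):
        candidates = []
        for lab in labels:
            if remaining[lab] == 0 or (lab == prev and run >= max_run):
                continue
            rem = dict(remaining)
            rem[lab] -= 1
            new_run = run + 1 if lab == prev else 1
            ok = True
            for a in labels:
                other = sum(v for k, v in rem.items() if k != a)
                first_cap = max_run - new_run if a == lab else max_run
                if rem[a] > first_cap + max_run * other:
                    ok = False
                    break
            if ok:
                candidates.append(lab)
        if not candidates:
            raise RuntimeError(
                f"label counts {counts} unsatisfiable with run limit {max_run}")
        lab = candidates[int(rng.integers(len(candidates)))]
        run = run + 1 if lab == prev else 1
        prev = lab
        remaining[lab] -= 1
        seq.append(lab)
    return seq


def _block_trial_labels(design: SequenceDesign, block_type: str,
                        rng: np.random.Generator) -> list[tuple[str, str]]:
    """Pseudorandomized (congruency, direction) pairs for one block."""
    n = design.trials_per_block
    n_major = design.majority_count
    majority = CONGRUENT if block_type == MAINLY_CONGRUENT else INCONGRUENT
    minority = INCONGRUENT if majority == CONGRUENT else CONGRUENT
    cong = _constrained_binary_sequence(
        {majority: n_major, minority: n - n_major}, design.max_run, rng)
    # directions balanced within each congruency class (so the session's
    # congruency x direction cells come out exactly equal) and run-limited
    n_minor = n - n_major
    for _ in range(10_000):
        d_major = [LEFT] * (n_major // 2) + [RIGHT] * (n_major - n_major // 2)
        d_minor = [RIGHT] * (n_minor // 2) + [LEFT] * (n_minor - n_minor // 2)
        rng.shuffle(d_major)
        rng.shuffle(d_minor)
        it_major, it_minor = iter(d_major), iter(d_minor)
        dirs = [next(it_major if c == majority else it_minor) for c in cong]
        if _max_run_ok(dirs, design.max_run):
            return list(zip(cong, dirs))
    raise RuntimeError("could not pseudorandomize target directions within retry cap")


def generate_sequence(design: SequenceDesign | None = None,
                      seed: int = 0) -> StimulusSchedule:
    """Generate a pseudorandomized schedule; pure function of (design, seed).

    Raises ``RuntimeError`` after a bounded number of rejection-sampling
    retries if the constraints cannot be satisfied.
    """
    design = design or SequenceDesign()
    rng = np.random.default_rng(seed)

    if design.n_blocks == 0:
        return StimulusSchedule([], [], seed, design)

    half = design.n_blocks // 2
    block_types = [MAINLY_CONGRUENT] * half + [MAINLY_INCONGRUENT] * half
    block_types = _shuffle_with_runs(block_types, design.max_block_run, rng)

    t = design.lead_in_s
    training: list[TrialSpec] = []
    for tb in range(design.n_training_blocks):
        n = design.training_trials
        cong = [CONGRUENT] * ((n + 1) // 2) + [INCONGRUENT] * (n // 2)
        dirs = [LEFT] * ((n + 1) // 2) + [RIGHT] * (n // 2)
        rng.shuffle(cong)
        rng.shuffle(dirs)
        for k in range(n):
            training.append(TrialSpec(len(training), cong[k], dirs[k],
                                      block_index=-(tb + 1), onset=t, training=True))
            t += TRIAL_PITCH_S
        t += rng.uniform(*design.ibi_range_s)

    trials: list[TrialSpec] = []
    blocks: list[BlockSpec] = []
    for bi, btype in enumerate(block_types):
        labels = _block_trial_labels(design, btype, rng)
        for cong, direction in labels:
            trials.append(TrialSpec(len(trials), cong, direction, bi, t))
            t += TRIAL_PITCH_S
        ibi = float(rng.uniform(*design.ibi_range_s))
        blocks.append(BlockSpec(bi, btype, len(labels), ibi))
        t += ibi

    return StimulusSchedule(trials, blocks, seed, design, training)


@dataclass(frozen=True)
class Violation:
    rule: str
    where: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.rule} @ {self.where}"


def validate_sequence(schedule: StimulusSchedule) -> list[Violation]:
    """Check every schedule invariant; empty list iff the schedule is valid."""
    design = schedule.design
    out: list[Violation] = []
    trials, blocks = schedule.trials, schedule.blocks

    if len(blocks) != design.n_blocks:
        out.append(Violation("block_count", f"{len(blocks)} != {design.n_blocks}"))
    if len(trials) != design.n_trials:
        out.append(Violation("trial_count", f"{len(trials)} != {design.n_trials}"))

    onsets = [tr.onset for tr in trials]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        out.append(Violation("onsets_increasing", "non-monotone onset"))

    cells: dict[tuple[str, str], int] = {}
    for tr in trials:
        cells[(tr.congruency, tr.direction)] = cells.get((tr.congruency, tr.direction), 0) + 1
    expect = design.n_trials // 4
    for cell, count in sorted(cells.items()):
        if design.n_trials % 4 == 0 and count != expect:
            out.append(Violation("cell_balance", f"{cell}: {count} != {expect}"))

    for blk in blocks:
        bt = [tr for tr in trials if tr.block_index == blk.block_index]
        if len(bt) != design.trials_per_block:
            out.append(Violation("block_size", f"block {blk.block_index}"))
            continue
        n_left = sum(tr.direction == LEFT for tr in bt)
        if n_left != design.trials_per_block // 2:
            out.append(Violation("direction_balance", f"block {blk.block_index}"))
        majority = CONGRUENT if blk.block_type == MAINLY_CONGRUENT else INCONGRUENT
        n_major = sum(tr.congruency == majority for tr in bt)
        if n_major != design.majority_count:
            out.append(Violation("congruency_mixture",
                                 f"block {blk.block_index}: {n_major} majority trials"))
        for attr, rule in (("congruency", "congruency_run"), ("direction", "direction_run")):
            labels = [getattr(tr, attr) for tr in bt]
            run, prev = 0, None
            for j, lab in enumerate(labels):
                run = run + 1 if lab == prev else 1
                prev = lab
                if run == design.max_run + 1:
                    out.append(Violation(rule,
                                         f"block {blk.block_index} trials "
                                         f"{bt[j - design.max_run].index}-{bt[j].index}"))
        if not (design.ibi_range_s[0] <= blk.ibi_after <= design.ibi_range_s[1]):
            out.append(Violation("ibi_range", f"block {blk.block_index}"))

    types = [blk.block_type for blk in blocks]
    run, prev = 0, None
    for j, lab in enumerate(types):
        run = run + 1 if lab == prev else 1
        prev = lab
        if run == design.max_block_run + 1:
            out.append(Violation("block_type_run", f"blocks {j - design.max_block_run}-{j}"))

    return out


def schedule_to_events(schedule: StimulusSchedule, include_training: bool = False):
    """Event marker table: one stimulus marker per trial, one onset marker
    per block; (onset_s, code, label) tuples in temporal order."""
    events: list[tuple[float, int, str]] = []
    if include_training:
        for tr in schedule.training_trials:
            events.append((tr.onset, TRIAL_CODES[(tr.congruency, tr.direction)],
                           f"training/{tr.congruency}/{tr.direction}"))
    first_of_block = {}
    for tr in schedule.trials:
        first_of_block.setdefault(tr.block_index, tr.onset)
    for blk in schedule.blocks:
        events.append((first_of_block[blk.block_index], BLOCK_CODES[blk.block_type],
                       f"block/{blk.block_type}"))
    for tr in schedule.trials:
        events.append((tr.onset, TRIAL_CODES[(tr.congruency, tr.direction)],
                       f"{tr.congruency}/{tr.direction}"))
    events.sort(key=lambda e: (e[0], e[1]))
    return events


def write_schedule(schedule: StimulusSchedule, path) -> None:
    """Export one row per trial as tab-separated text."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["index", "block", "block_type", "congruency", "direction",
                    "onset_s", "training"])
        by_block = {blk.block_index: blk.block_type for blk in schedule.blocks}
        for tr in schedule.training_trials + schedule.trials:
            w.writerow([tr.index, tr.block_index,
                        by_block.get(tr.block_index, "training"),
                        tr.congruency, tr.direction, f"{tr.onset:.6f}",
                        int(tr.training)])


def read_schedule(path, design: SequenceDesign | None = None,
                  seed: int = -1) -> StimulusSchedule:
    """Read a schedule written by :func:`write_schedule`.

    IBIs are reconstructed from consecutive onsets, so a written/re-read
    schedule validates against the same design.
    """
    design = design or SequenceDesign()
    trials: list[TrialSpec] = []
    training: list[TrialSpec] = []
    block_type: dict[int, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            tr = TrialSpec(int(row["index"]), row["congruency"], row["direction"],
                           int(row["block"]), float(row["onset_s"]),
                           training=bool(int(row["training"])))
            (training if tr.training else trials).append(tr)
            if not tr.training:
                block_type[tr.block_index] = row["block_type"]
    blocks: list[BlockSpec] = []
    order = sorted(block_type)
    for k, bi in enumerate(order):
        bt = [tr for tr in trials if tr.block_index == bi]
        if k + 1 < len(order):
            nxt = min(tr.onset for tr in trials if tr.block_index == order[k + 1])
            ibi = nxt - (bt[-1].onset + TRIAL_PITCH_S)
        else:
            ibi = float(np.mean(design.ibi_range_s))
        blocks.append(BlockSpec(bi, block_type[bi], len(bt), float(ibi)))
    return StimulusSchedule(trials, blocks, seed, design, training)
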