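"""Generation and classification of IDED set-shifting trial sequences.

The IDED task presents a target stimulus plus two probe stimuli; exactly one
probe matches the target under a covert rule attending either its colour or
its shape.  The rule (and with it the target) changes every few trials,
producing intra-dimensional (ID) shifts -- new feature, same dimension -- and
extra-dimensional (ED) shifts -- the other dimension becomes relevant.  Each
shift is followed by a pseudorandom run of 2-7 same-rule trials; only the
second trial after a shift serves as the matched "repeat" control condition,
all other non-shift trials are fillers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

COLOURS = ("red", "green", "blue", "beige", "magenta", "cyan")
SHAPES = ("circle", "star", "diamond", "triangle", "pentagon", "cross")

DIMENSIONS = ("colour", "shape")

#: conditions entering the analysis
CONDITIONS = ("repeat", "ID", "ED")

#: maximum time allowed for a response; later responses count as errors
RESPONSE_DEADLINE_MS = 4000.0

SHIFT_SUBTYPES = (
    "colour-to-colour",
    "shape-to-shape",
    "colour-to-shape",
    "shape-to-colour",
)


class TaskConfigError(ValueError):
    """Raised for infeasible or invalid task configurations."""


@dataclass(frozen=True)
class Stimulus:
    """A coloured shape; one of the 36 colour x shape combinations."""

    colour: str
    shape: str

    def feature(self, dimension: str) -> str:
        if dimension == "colour":
            return self.colour
        if dimension == "shape":
            return self.shape
        raise ValueError(f"unknown dimension {dimension!r}")


@dataclass(frozen=True)
class Rule:
    """The covert matching rule: attend `feature` in `dimension`."""

    dimension: str
    feature: str

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        palette = COLOURS if self.dimension == "colour" else SHAPES
        if self.feature not in palette:
            raise ValueError(
                f"feature {self.feature!r} not in the {self.dimension} palette"
            )

    def matches(self, stimulus: Stimulus) -> bool:
        return stimulus.feature(self.dimension) == self.feature


@dataclass(frozen=True)
class TrialSpec:
    index: int
    target: Stimulus
    left_stimulus: Stimulus
    right_stimulus: Stimulus
    rule: Rule
    correct_side: str  # "left" | "right"
    trial_class: str  # "shift_ID" | "shift_ED" | "repeat" | "filler"
    shift_subtype: str  # one of SHIFT_SUBTYPES or "none"
    block: int

    @property
    def condition(self) -> str | None:
        """Analysis condition, or None for filler trials."""
        return {"shift_ID": "ID", "shift_ED": "ED", "repeat": "repeat"}.get(
            self.trial_class
        )


@dataclass
class TrialSequence:
    trials: list[TrialSpec]
    n_blocks: int
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def analysis_trials(self) -> list[TrialSpec]:
        return [t for t in self.trials if t.condition is not None]


def build_stimulus_set(
    colours: tuple[str, ...] = COLOURS, shapes: tuple[str, ...] = SHAPES
) -> list[Stimulus]:
    """Full Cartesian product of the colour and shape palettes."""
    if not colours or not shapes:
        raise TaskConfigError("palettes must be non-empty")
    if len(set(colours)) != len(colours) or len(set(shapes)) != len(shapes):
        raise TaskConfigError("palettes must not contain duplicates")
    return [Stimulus(c, s) for c in colours for s in shapes]


def classify_shift(old_rule: Rule, new_rule: Rule) -> tuple[str, str]:
    """Classify a rule change as (trial_class, shift_subtype).

    Returns ("none", "none") for an identical rule (no shift).
    """
    if old_rule == new_rule:
        return "none", "none"
    if old_rule.dimension == new_rule.dimension:
        return "shift_ID", f"{old_rule.dimension}-to-{new_rule.dimension}"
    return "shift_ED", f"{old_rule.dimension}-to-{new_rule.dimension}"


def score_response(trial: TrialSpec, response: str, rt_ms: float) -> str:
    """Score one response: correct side within the 4 s deadline, else error."""
    if rt_ms < 0:
        raise ValueError("rt_ms must be non-negative")
    if response == "none" or rt_ms > RESPONSE_DEADLINE_MS:
        return "error"
    return "correct" if response == trial.correct_side else "error"


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the trial plan.

    Defaults reproduce the study design: 25 shifts per subtype (50 ID + 50 ED),
    runs of 2-7 same-rule trials after each shift, 6 blocks, and a few filler
    trials at the start of each block (trials before a block's first shift are
    excluded from analysis).
    """

    shifts_per_subtype: int = 25
    run_min: int = 2
    run_max: int = 7
    n_blocks: int = 6
    fillers_per_block: int = 3
    distractor_overlap: bool = False  # distractor may share the irrelevant feature

    def __post_init__(self) -> None:
        if self.shifts_per_subtype < 1:
            raise TaskConfigError("shifts_per_subtype must be >= 1")
        if not (1 <= self.run_min <= self.run_max):
            raise TaskConfigError("invalid run-length range")
        if self.n_blocks < 1:
            raise TaskConfigError("n_blocks must be >= 1")


def _balanced_multiset(values: np.ndarray, n: int, rng: np.random.Generator):
    """n draws covering `values` as evenly as possible, shuffled."""
    reps = n // len(values)
    out = np.repeat(values, reps)
    extra = rng.choice(values, size=n - len(out), replace=False)
    out = np.concatenate([out, extra])
    rng.shuffle(out)
    return out


def _completable(remaining: dict[str, int], dim: str) -> bool:
    """Can the leftover shift multiset be ordered starting from `dim`?

    The dimension chain is a walk on {colour, shape}: within-dimension shifts
    are self-loops, cross-dimension shifts are crossings which must alternate.
    """
    other = "shape" if dim == "colour" else "colour"
    out = remaining[f"{dim}-to-{other}"]
    back = remaining[f"{other}-to-{dim}"]
    if out == 0:
        return back == 0 and remaining[f"{other}-to-{other}"] == 0
    return out in (back, back + 1)


def _order_shifts(
    counts: dict[str, int], start_dim: str, rng: np.random.Generator
) -> list[str]:
    """Random order of shift subtypes respecting the dimension chain.

    Greedy sampling among moves that leave a completable remainder; sampling
    weights follow the remaining counts, so any feasible order has positive
    probability and subtype positions are well mixed.
    """
    remaining = dict(counts)
    dim = start_dim
    order: list[str] = []
    n = sum(counts.values())
    for _ in range(n):
        safe = []
        for s in SHIFT_SUBTYPES:
            if remaining[s] == 0 or not s.startswith(dim):
                continue
            remaining[s] -= 1
            if _completable(remaining, s.split("-to-")[1]):
                safe.append(s)
            remaining[s] += 1
        if not safe:
            raise TaskConfigError("could not order shifts; infeasible subtype counts")
        weights = np.array([remaining[s] for s in safe], dtype=float)
        pick = str(rng.choice(safe, p=weights / weights.sum()))
        order.append(pick)
        remaining[pick] -= 1
        dim = pick.split("-to-")[1]
    return order


def _new_rule(old_rule: Rule, subtype: str, rng: np.random.Generator) -> Rule:
    src, dst = subtype.split("-to-")
    if old_rule.dimension != src:
        raise TaskConfigError(
            f"subtype {subtype} requires current dimension {src}, got {old_rule.dimension}"
        )
    palette = COLOURS if dst == "colour" else SHAPES
    if dst == old_rule.dimension:
        choices = [f for f in palette if f != old_rule.feature]
    else:
        choices = list(palette)
    return Rule(dst, str(rng.choice(choices)))


def _make_target(rule: Rule, rng: np.random.Generator) -> Stimulus:
    other = "shape" if rule.dimension == "colour" else "colour"
    palette = SHAPES if other == "shape" else COLOURS
    other_feature = str(rng.choice(palette))
    kwargs = {rule.dimension: rule.feature, other: other_feature}
    return Stimulus(**kwargs)


def _make_pair(
    target: Stimulus, rule: Rule, rng: np.random.Generator, overlap: bool
) -> tuple[Stimulus, Stimulus]:
    """(matching stimulus, distractor) for one trial.

    The matching stimulus shares only the relevant feature with the target;
    the distractor shares neither feature unless `overlap` allows it to match
    the irrelevant one.
    """
    other = "shape" if rule.dimension == "colour" else "colour"
    other_palette = SHAPES if other == "shape" else COLOURS
    rel_palette = COLOURS if rule.dimension == "colour" else SHAPES

    match_other = str(rng.choice([f for f in other_palette if f != target.feature(other)]))
    matching = Stimulus(**{rule.dimension: rule.feature, other: match_other})

    d_rel = str(rng.choice([f for f in rel_palette if f != rule.feature]))
    if overlap and rng.random() < 0.5:
        d_other = target.feature(other)
    else:
        d_other = str(
            rng.choice([f for f in other_palette if f != target.feature(other)])
        )
    distractor = Stimulus(**{rule.dimension: d_rel, other: d_other})
    return matching, distractor


def generate_sequence(config: TaskConfig | None = None, seed: int = 0) -> TrialSequence:
    """Generate a pseudorandomized IDED trial plan.

    Shift subtypes are balanced exactly (``shifts_per_subtype`` each), the
    order of shifts is shuffled, and run lengths after shifts are drawn from a
    shuffled, approximately balanced multiset over ``run_min..run_max``.
    Deterministic for a fixed seed.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)

    n_shifts = len(SHIFT_SUBTYPES) * config.shifts_per_subtype
    run_lengths = _balanced_multiset(
        np.arange(config.run_min, config.run_max + 1), n_shifts, rng
    )

    # Shuffle shift order subject to feasibility: a colour-to-* shift requires
    # the currently relevant dimension to be colour, etc.
    start_dim = str(rng.choice(DIMENSIONS))
    palette = COLOURS if start_dim == "colour" else SHAPES
    rule = Rule(start_dim, str(rng.choice(palette)))
    order = _order_shifts(
        {s: config.shifts_per_subtype for s in SHIFT_SUBTYPES}, start_dim, rng
    )

    # distribute shifts over blocks as evenly as possible
    per_block = np.full(config.n_blocks, n_shifts // config.n_blocks)
    per_block[: n_shifts % config.n_blocks] += 1

    trials: list[TrialSpec] = []
    target = _make_target(rule, rng)
    shift_i = 0

    def add_trial(trial_class: str, subtype: str, block: int) -> None:
        matching, distractor = _make_pair(target, rule, rng, config.distractor_overlap)
        if rng.random() < 0.5:
            left, right, side = matching, distractor, "left"
        else:
            left, right, side = distractor, matching, "right"
        trials.append(
            TrialSpec(
                index=len(trials),
                target=target,
                left_stimulus=left,
                right_stimulus=right,
                rule=rule,
                correct_side=side,
                trial_class=trial_class,
                shift_subtype=subtype,
                block=block,
            )
        )

    for block in range(config.n_blocks):
        # trials before the block's first shift: fillers (post-break warm-up)
        for _ in range(config.fillers_per_block):
            add_trial("filler", "none", block)
        for _ in range(per_block[block]):
            subtype = order[shift_i]
            run_len = int(run_lengths[shift_i])
            shift_i += 1
            trial_class, subtype_full = classify_shift(rule, _peek := _new_rule(rule, subtype, rng))
            rule = _peek
            target = _make_target(rule, rng)
            add_trial(trial_class, subtype_full, block)
            for j in range(run_len):
                add_trial("repeat" if j == 1 else "filler", "none", block)

    seq = TrialSequence(trials=trials, n_blocks=config.n_blocks, seed=seed)
    _validate_sequence(seq, config)
    return seq


def _validate_sequence(seq: TrialSequence, config: TaskConfig) -> None:
    counts = {s: 0 for s in SHIFT_SUBTYPES}
    prev_rule = None
    for t in seq.trials:
        if t.trial_class in ("shift_ID", "shift_ED"):
            counts[t.shift_subtype] += 1
        # exactly one of the two stimuli matches the target under the rule
        m_left = t.rule.matches(t.left_stimulus)
        m_right = t.rule.matches(t.right_stimulus)
        if m_left == m_right:
            raise TaskConfigError(f"trial {t.index}: ambiguous or missing match")
        if ("left" if m_left else "right") != t.correct_side:
            raise TaskConfigError(f"trial {t.index}: correct_side inconsistent")
        if prev_rule is not None:
            changed = t.rule != prev_rule
            is_shift = t.trial_class in ("shift_ID", "shift_ED")
            if changed != is_shift:
                raise TaskConfigError(f"trial {t.index}: rule change/shift mismatch")
        prev_rule = t.rule
    if any(c != config.shifts_per_subtype for c in counts.values()):
        raise TaskConfigError(f"unbalanced shift subtypes: {counts}")


def sequence_to_frame(seq: TrialSequence) -> pd.DataFrame:
    rows = []
    for t in seq.trials:
        rows.append(
            {
                "index": t.index,
                "block": t.block,
                "trial_class": t.trial_class,
                "shift_subtype": t.shift_subtype,
                "rule_dimension": t.rule.dimension,
                "rule_feature": t.rule.feature,
                "target_colour": t.target.colour,
                "target_shape": t.target.shape,
                "left_colour": t.left_stimulus.colour,
                "left_shape": t.left_stimulus.shape,
                "right_colour": t.right_stimulus.colour,
                "right_shape": t.right_stimulus.shape,
                "correct_side": t.correct_side,
            }
        )
    return pd.DataFrame(rows)


def write_sequence_tsv(seq: TrialSequence, path: str | Path) -> None:
    sequence_to_frame(seq).to_csv(path, sep="\t", index=False)


def read_sequence_tsv(path: str | Path) -> TrialSequence:
    df = pd.read_csv(path, sep="\t")
    trials = []
    for _, r in df.iterrows():
        trials.append(
            TrialSpec(
                index=int(r["index"]),
                target=Stimulus(r["target_colour"], r["target_shape"]),
                left_stimulus=Stimulus(r["left_colour"], r["left_shape"]),
                right_stimulus=Stimulus(r["right_colour"], r["right_shape"]),
                rule=Rule(r["rule_dimension"], r["rule_feature"]),
                correct_side=r["correct_side"],
                trial_class=r["trial_class"],
                shift_subtype=r["shift_subtype"],
                block=int(r["block"]),
            )
        )
    return TrialSequence(trials=trials, n_blocks=int(df["block"].max()) + 1, seed=-1)
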