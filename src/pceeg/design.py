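"""Cue-stimulus experimental design: factor codes and probabilistic trial schedules.

The experiment is a 2-modality (picture / pain) x 3-intensity probabilistic
cueing design.  Each trial starts with a cue whose colour signals the modality
of the upcoming stimulus and whose digit signals its intensity.  The cue is
valid in modality on 70% of trials and valid in intensity on 60% of trials;
the two wrong intensities share the remaining mass equally.  Only trials in
which a picture was cued and a picture was shown enter the EEG analysis; those
nine cue x stimulus cells carry the three within-subject factors:

* ``INT`` - stimulus intensity, coded -1 / 0 / +1 for low / medium / high,
* ``EXP`` - cued (expected) intensity, coded the same way,
* ``PE``  - absolute prediction error, ``|EXP - INT|`` in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "LEVEL_CODE",
    "MODALITIES",
    "FACTORS",
    "ConditionCell",
    "ScheduleSummary",
    "code_factors",
    "build_condition_grid",
    "build_trial_schedule",
    "schedule_summary",
    "SCHEDULE_COLUMNS",
]

LEVELS = ("low", "medium", "high")
LEVEL_CODE = {"low": -1, "medium": 0, "high": 1}
MODALITIES = ("picture", "pain")
FACTORS = ("INT", "EXP", "PE")

#: probability that the cue colour correctly indicates the stimulus modality
P_MODALITY_CONGRUENT = Fraction(7, 10)
#: probability that the cue digit correctly indicates the stimulus intensity
P_INTENSITY_CONGRUENT = Fraction(3, 5)

SCHEDULE_COLUMNS = (
    "block",
    "trial_index",
    "cue_modality",
    "cue_intensity",
    "stim_modality",
    "stim_intensity",
    "is_catch",
    "soa_ms",
)


@dataclass(frozen=True)
class ConditionCell:
    """One cell of the 3 x 3 cue-intensity x stimulus-intensity grid."""

    cue_intensity: str
    stim_intensity: str
    int_code: int
    exp_code: int
    pe_code: int


def _check_level(name: str, value: str) -> None:
    if value not in LEVELS:
        raise ValueError(f"unknown {name} level {value!r}; expected one of {LEVELS}")


def code_factors(cue_intensity: str, stim_intensity: str) -> tuple[int, int, int]:
    """Map a cue/stimulus intensity pair to its ``(INT, EXP, PE)`` codes.

    INT and EXP code low/medium/high as -1/0/+1; PE is the absolute
    difference of the expected and actual intensity codes.
    """
    _check_level("cue_intensity", cue_intensity)
    _check_level("stim_intensity", stim_intensity)
    exp_code = LEVEL_CODE[cue_intensity]
    int_code = LEVEL_CODE[stim_intensity]
    return int_code, exp_code, abs(exp_code - int_code)


def build_condition_grid() -> list[ConditionCell]:
    """All nine condition cells in deterministic stimulus-major order.

    The outer loop runs over stimulus intensity (low to high), the inner over
    cue intensity, so cell ``3*i + j`` has stimulus level ``i`` and cue level
    ``j``.  Every module that indexes "subject x 9 cells" arrays uses this
    order.
    """
    cells = []
    for stim in LEVELS:
        for cue in LEVELS:
            int_code, exp_code, pe_code = code_factors(cue, stim)
            cells.append(ConditionCell(cue, stim, int_code, exp_code, pe_code))
    return cells


def cell_index(cue_intensity: str, stim_intensity: str) -> int:
    """Position of a cue/stimulus cell in the canonical grid order."""
    _check_level("cue_intensity", cue_intensity)
    _check_level("stim_intensity", stim_intensity)
    return 3 * LEVELS.index(stim_intensity) + LEVELS.index(cue_intensity)


def _per_cue_joint() -> dict[tuple[bool, bool], Fraction]:
    """Joint probability of (modality congruent, intensity congruent) per cue.

    Modality and intensity congruence are assumed independent; the wrong
    intensity mass later splits equally between the two wrong levels.
    """
    pm, pi = P_MODALITY_CONGRUENT, P_INTENSITY_CONGRUENT
    return {
        (True, True): pm * pi,
        (True, False): pm * (1 - pi) / 2,   # per wrong intensity level
        (False, True): (1 - pm) * pi,
        (False, False): (1 - pm) * (1 - pi) / 2,
    }


def build_trial_schedule(
    n_per_cue: int,
    n_blocks: int = 4,
    catch_per_block: int = 4,
    seed: int = 0,
    soa_range_ms: tuple[float, float] = (1500.0, 1900.0),
) -> pd.DataFrame:
    """Build a pseudorandomized trial schedule realizing the cue contingencies.

    Each of the six cue types (2 modalities x 3 intensities) appears exactly
    ``n_per_cue`` times among non-catch trials.  Per cue, the stimulus modality
    matches on exactly 70% of trials and the stimulus intensity on exactly 60%,
    with the two incorrect intensities receiving equal counts.  ``n_per_cue``
    must make every joint cell count integral (multiples of 50 qualify).

    Trial order is a uniform shuffle driven by ``seed``; ``catch_per_block``
    catch trials (cue only, no stimulus) are appended to each block.  The
    ``soa_ms`` column holds the cue-onset-to-stimulus-onset interval (500 ms
    cue plus a 1000-1400 ms blank), drawn uniformly in ``soa_range_ms`` at
    1 ms resolution.
    """
    if n_per_cue < 1:
        raise ValueError("n_per_cue must be >= 1")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")

    joint = _per_cue_joint()
    for (mod_ok, int_ok), p in joint.items():
        count = p * n_per_cue
        if count.denominator != 1:
            raise ValueError(
                "non-integral trial count for cell "
                f"(modality_congruent={mod_ok}, intensity_congruent={int_ok}): "
                f"{float(p)} * {n_per_cue} = {float(count)}"
            )

    rng = np.random.default_rng(seed)
    rows = []
    for cue_modality in MODALITIES:
        other_modality = MODALITIES[1 - MODALITIES.index(cue_modality)]
        for cue_intensity in LEVELS:
            wrong_levels = [lv for lv in LEVELS if lv != cue_intensity]
            for stim_modality, mod_ok in ((cue_modality, True), (other_modality, False)):
                n_correct = int(joint[(mod_ok, True)] * n_per_cue)
                n_wrong = int(joint[(mod_ok, False)] * n_per_cue)
                rows += [(cue_modality, cue_intensity, stim_modality, cue_intensity)] * n_correct
                for wl in wrong_levels:
                    rows += [(cue_modality, cue_intensity, stim_modality, wl)] * n_wrong

    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    lo, hi = soa_range_ms
    soa = rng.integers(int(lo), int(hi) + 1, size=len(rows)).astype(float)

    # split the shuffled trials into nearly equal blocks, catch trials appended
    block_sizes = [len(rows) // n_blocks] * n_blocks
    for i in range(len(rows) % n_blocks):
        block_sizes[i] += 1

    records = []
    pos = 0
    cue_types = [(m, lv) for m in MODALITIES for lv in LEVELS]
    for block, size in enumerate(block_sizes, start=1):
        trial_index = 1
        for cue_mod, cue_int, stim_mod, stim_int in rows[pos:pos + size]:
            records.append(
                (block, trial_index, cue_mod, cue_int, stim_mod, stim_int,
                 False, soa[pos + trial_index - 1])
            )
            trial_index += 1
        pos += size
        for _ in range(catch_per_block):
            cue_mod, cue_int = cue_types[rng.integers(len(cue_types))]
            records.append((block, trial_index, cue_mod, cue_int, None, None, True, np.nan))
            trial_index += 1

    schedule = pd.DataFrame.from_records(records, columns=SCHEDULE_COLUMNS)
    return schedule


@dataclass
class ScheduleSummary:
    """Realized contingency proportions of a trial schedule (non-catch trials)."""

    joint: pd.Series
    modality_congruent: float
    intensity_congruent: float
    n_trials: int


def schedule_summary(schedule: pd.DataFrame) -> ScheduleSummary:
    """Contingency table of realized joint and marginal proportions.

    Proportions are taken over non-catch trials and sum to one.
    """
    trials = schedule.loc[~schedule["is_catch"].astype(bool)]
    if len(trials) == 0:
        raise ValueError("schedule contains no non-catch trials")
    joint = (
        trials.groupby(
            ["cue_modality", "cue_intensity", "stim_modality", "stim_intensity"],
            observed=True,
        ).size()
        / len(trials)
    )
    mod_ok = (trials["cue_modality"] == trials["stim_modality"]).mean()
    int_ok = (trials["cue_intensity"] == trials["stim_intensity"]).mean()
    return ScheduleSummary(joint, float(mod_ok), float(int_ok), len(trials))
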