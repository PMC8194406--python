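"""Experimental designs for face-voice gender comparison studies.

Two designs are generated here:

* a paired-comparison psychophysics design on a face x voice morph lattice
  (each stimulus is a face morph level crossed with a voice morph level,
  both running from most feminine to most masculine), with random
  subsampling of the very large pair universe;
* an event-related fMRI schedule on the reduced 3 x 3 grid
  (feminine / gender-neutral / masculine for each modality), with
  habituation-avoiding succession constraints and interleaved response
  trials used to verify task compliance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MorphGrid",
    "TrialDesign",
    "EventSchedule",
    "build_grid",
    "enumerate_pairs",
    "sample_design",
    "build_fmri_schedule",
    "filter_response_trials",
    "SchedulingError",
    "FMRI_LEVELS",
    "ITI_CHOICES",
]

#: Morph labels of the reduced fMRI grid, in increasing masculinity.
FMRI_LEVELS = ("fem", "neutral", "masc")

#: Inter-trial fixation durations (seconds) used in the event-related protocol.
ITI_CHOICES = (5.0, 5.5, 6.0, 6.5, 7.0)

#: Events per acquisition: 9 combinations x 3 repeats + 8 response trials.
EVENTS_PER_ACQUISITION = 35
RESPONSE_TRIALS_PER_ACQUISITION = 8


class SchedulingError(RuntimeError):
    """Raised when schedule constraints cannot be satisfied within the retry cap."""


@dataclass(frozen=True)
class MorphGrid:
    """A face x voice morph lattice.

    Morph coordinates are equally spaced on [0, 1] with 0 the most feminine
    and 1 the most masculine morph of each modality.
    """

    n_face: int
    n_voice: int
    face_coords: np.ndarray = field(repr=False)
    voice_coords: np.ndarray = field(repr=False)

    @property
    def n_stimuli(self) -> int:
        return self.n_face * self.n_voice

    def stimuli(self) -> list[tuple[int, int]]:
        """All (face_level, voice_level) index pairs, 0-based."""
        return list(itertools.product(range(self.n_face), range(self.n_voice)))


@dataclass(frozen=True)
class TrialDesign:
    """A subsampled, ordered paired-comparison trial list.

    ``trials`` columns: session, trial, face1, voice1, face2, voice2
    (all levels 0-based indices into the grid).
    """

    grid: MorphGrid
    trials: pd.DataFrame = field(repr=False)
    n_sessions: int
    trials_per_session: int
    seed: int | None

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class EventSchedule:
    """Event-related fMRI schedule on the 3 x 3 reduced grid.

    ``events`` columns: acquisition, event_index, face, voice
    (labels from :data:`FMRI_LEVELS`), is_response (bool), iti (seconds).
    """

    events: pd.DataFrame = field(repr=False)
    n_acquisitions: int
    seed: int | None


def build_grid(n_face: int, n_voice: int) -> MorphGrid:
    """Build a morph lattice with equally spaced coordinates spanning [0, 1].

    A single-level modality takes coordinate 0 by convention.
    """
    if n_face < 1 or n_voice < 1:
        raise ValueError(f"grid sizes must be positive, got ({n_face}, {n_voice})")

    def coords(n: int) -> np.ndarray:
        if n == 1:
            return np.zeros(1)
        return np.linspace(0.0, 1.0, n)

    return MorphGrid(int(n_face), int(n_voice), coords(n_face), coords(n_voice))


def enumerate_pairs(grid: MorphGrid) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All unordered, non-matching stimulus pairs: n(n-1)/2 for n stimuli."""
    return list(itertools.combinations(grid.stimuli(), 2))


def sample_design(
    grid: MorphGrid,
    n_trials: int,
    n_sessions: int = 5,
    seed: int | None = None,
    pairs: list[tuple[tuple[int, int], tuple[int, int]]] | None = None,
) -> TrialDesign:
    """Uniformly subsample the pair universe without replacement.

    Presentation order within each pair is randomized and recorded (the
    decision model treats the first and second stimulus asymmetrically).
    Sessions partition the trial list into equal consecutive blocks.
    """
    if pairs is None:
        pairs = enumerate_pairs(grid)
    if n_trials > len(pairs):
        raise ValueError(
            f"cannot sample {n_trials} distinct pairs from a universe of {len(pairs)}"
        )
    if n_sessions < 1 or n_trials % n_sessions:
        raise ValueError(
            f"n_trials={n_trials} must divide into n_sessions={n_sessions} equal blocks"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n_trials, replace=False)
    flip = rng.random(n_trials) < 0.5

    rows = np.empty((n_trials, 4), dtype=int)
    for i, (j, fl) in enumerate(zip(idx, flip)):
        s1, s2 = pairs[j]
        if fl:
            s1, s2 = s2, s1
        rows[i] = (*s1, *s2)

    per_session = n_trials // n_sessions
    df = pd.DataFrame(rows, columns=["face1", "voice1", "face2", "voice2"])
    df.insert(0, "trial", np.arange(n_trials))
    df.insert(0, "session", np.repeat(np.arange(n_sessions), per_session))
    return TrialDesign(grid, df, n_sessions, per_session, seed)


def _acquisition_events(rng: np.random.Generator) -> pd.DataFrame:
    """One candidate acquisition: shuffled events plus ITIs (constraints unchecked)."""
    combos = list(itertools.product(FMRI_LEVELS, FMRI_LEVELS))
    stim = combos * 3
    resp = [c for c in combos if c != ("neutral", "neutral")]
    events = [(f, v, False) for f, v in stim] + [(f, v, True) for f, v in resp]
    order = rng.permutation(len(events))
    events = [events[i] for i in order]
    itis = rng.choice(ITI_CHOICES, size=len(events), replace=True)
    return pd.DataFrame(
        {
            "face": [e[0] for e in events],
            "voice": [e[1] for e in events],
            "is_response": [e[2] for e in events],
            "iti": itis,
        }
    )


def _max_run(seq) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _has_long_alternation(stims: list, reps: int = 4) -> bool:
    """True if some A/B alternation repeats the AB pair >= `reps` times in a row."""
    window = 2 * reps
    for i in range(len(stims) - window + 1):
        w = stims[i : i + window]
        if w[0] == w[1]:
            continue
        if all(w[j] == w[j % 2] for j in range(window)):
            return True
    return False


def _acquisition_ok(df: pd.DataFrame) -> bool:
    stims = list(zip(df["face"], df["voice"]))
    if _max_run(stims) > 3:
        return False
    if _has_long_alternation(stims):
        return False
    if _max_run(list(df["iti"])) > 3:
        return False
    return True


def build_fmri_schedule(
    n_acquisitions: int,
    seed: int | None = None,
    max_retries: int = 10_000,
) -> EventSchedule:
    """Generate an event-related schedule by constrained rejection sampling.

    Per acquisition: each of the 9 gender combinations appears exactly 3
    times as a non-response event, plus 8 response trials covering every
    combination except gender-neutral face with gender-neutral voice.  No
    more than three successive repetitions of the same stimulus, of the
    same alternating stimulus pair, or of the same fixation duration.
    """
    if n_acquisitions < 1:
        raise ValueError("n_acquisitions must be >= 1")
    rng = np.random.default_rng(seed)
    acqs = []
    for a in range(n_acquisitions):
        for attempt in range(max_retries):
            cand = _acquisition_events(rng)
            if _acquisition_ok(cand):
                break
        else:
            raise SchedulingError(
                f"acquisition {a}: no valid ordering in {max_retries} attempts"
            )
        cand.insert(0, "event_index", np.arange(len(cand)))
        cand.insert(0, "acquisition", a)
        acqs.append(cand)
    return EventSchedule(pd.concat(acqs, ignore_index=True), n_acquisitions, seed)


def filter_response_trials(schedule: EventSchedule, task: str) -> pd.DataFrame:
    """Response trials that admit an unambiguous correct/incorrect response.

    Excluded per task: gender-neutral faces (face task), gender-neutral
    voices (voice task), incongruent face-voice combinations (stimulus
    task).  ``task='none'`` applies no exclusion (null filter).
    """
    resp = schedule.events[schedule.events["is_response"]]
    if task == "face":
        keep = resp["face"] != "neutral"
    elif task == "voice":
        keep = resp["voice"] != "neutral"
    elif task == "stimulus":
        incongruent = ((resp["face"] == "fem") & (resp["voice"] == "masc")) | (
            (resp["face"] == "masc") & (resp["voice"] == "fem")
        )
        keep = ~incongruent
    elif task == "none":
        keep = pd.Series(True, index=resp.index)
    else:
        raise ValueError(f"unknown task {task!r}; expected face, voice, stimulus or none")
    return resp[keep].reset_index(drop=True)
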