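"""Trial epoching and concatenation.

Continuous recordings are cut into fixed-length stimulus-locked epochs
(default -750..+1500 ms around image onset at 1000 Hz, i.e. 2250 samples,
half-open window) which are then abutted into one concatenated series for
spectral analysis. The mapping between concatenated sample index and
(trial, within-epoch sample) is exact and invertible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: canonical 4-category stimulus set
CATEGORIES = ("house", "tool", "scene", "face")


@dataclass
class TrialEpochSet:
    """Stimulus-locked voltage epochs for one electrode.

    Attributes
    ----------
    epochs : (n_trials, n_samples) float array, volts
    sampling_rate : Hz
    labels : (n_trials,) array of category names (4-category set)
    onset_sample : index of stimulus onset within each epoch
    concat_map : (n_trials,) start offsets of each trial in the
        concatenated series (strictly increasing, non-overlapping)
    categories : the allowed label set, in canonical order
    stimulus_duration : seconds the image stays on screen (default 1.0)
    """

    epochs: np.ndarray
    sampling_rate: float
    labels: np.ndarray
    onset_sample: int
    categories: tuple = CATEGORIES
    stimulus_duration: float = 1.0
    concat_map: np.ndarray = field(default=None)

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 2:
            raise ValueError("epochs must be 2-D (n_trials, n_samples)")
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.n_trials:
            raise ValueError("one label per trial required")
        unknown = set(np.unique(self.labels)) - set(self.categories)
        if unknown:
            raise ValueError(f"labels outside the category set: {sorted(unknown)}")
        if not 0 <= self.onset_sample < self.n_samples:
            raise ValueError("onset_sample outside the epoch")
        if self.concat_map is None:
            self.concat_map = np.arange(self.n_trials) * self.n_samples
        self.concat_map = np.asarray(self.concat_map, dtype=int)
        if np.any(np.diff(self.concat_map) < self.n_samples):
            raise ValueError("concat_map offsets overlap")

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[1]

    @property
    def concatenated(self) -> np.ndarray:
        """The trial-concatenated series (direct abutment, no tapering)."""
        return self.epochs.reshape(-1)

    @property
    def epoch_boundaries(self) -> np.ndarray:
        """Concatenated-sample indices where a new epoch starts (excl. 0)."""
        return self.concat_map[1:]

    def concat_to_trial(self, idx) -> tuple[np.ndarray, np.ndarray]:
        """Map concatenated sample index -> (trial, within-epoch sample)."""
        idx = np.asarray(idx, dtype=int)
        trial = idx // self.n_samples
        return trial, idx - trial * self.n_samples

    def trial_to_concat(self, trial, offset) -> np.ndarray:
        return np.asarray(trial, dtype=int) * self.n_samples + np.asarray(offset, dtype=int)

    # -- masks -----------------------------------------------------------
    def stimulus_mask(self) -> np.ndarray:
        """Boolean mask over the concatenated series: stimulus on screen.

        The stimulus period is [onset, onset + stimulus_duration) within
        each epoch.
        """
        n_stim = int(round(self.stimulus_duration * self.sampling_rate))
        per_epoch = np.zeros(self.n_samples, dtype=bool)
        per_epoch[self.onset_sample : min(self.onset_sample + n_stim, self.n_samples)] = True
        return np.tile(per_epoch, self.n_trials)

    def label_per_sample(self) -> np.ndarray:
        """Category code (index into ``categories``) for every concatenated sample."""
        codes = np.array([self.categories.index(l) for l in self.labels])
        return np.repeat(codes, self.n_samples)

    def category_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.categories}


def epoch_and_concatenate(
    raw: np.ndarray,
    onsets,
    labels,
    sampling_rate: float,
    window_ms: tuple[float, float] = (-750.0, 1500.0),
    categories: tuple = CATEGORIES,
) -> TrialEpochSet:
    """Cut a continuous recording into stimulus-locked epochs.

    Onsets closer than one epoch to either recording edge are dropped with
    a logged warning. The epoch window is half-open [start, stop) in ms
    relative to onset.
    """
    raw = np.asarray(raw, dtype=float).ravel()
    onsets = np.asarray(onsets, dtype=int)
    labels = np.asarray(labels)
    if onsets.shape[0] != labels.shape[0]:
        raise ValueError("onsets and labels must have equal length")
    start_off = int(round(window_ms[0] * sampling_rate / 1000.0))
    stop_off = int(round(window_ms[1] * sampling_rate / 1000.0))
    if stop_off <= start_off:
        raise ValueError("empty epoch window")
    valid = (onsets + start_off >= 0) & (onsets + stop_off <= raw.size)
    n_dropped = int(np.sum(~valid))
    if n_dropped:
        logger.warning(
            "dropped %d/%d trials with onsets too close to a recording edge",
            n_dropped,
            onsets.size,
        )
    onsets, labels = onsets[valid], labels[valid]
    epochs = np.stack([raw[o + start_off : o + stop_off] for o in onsets])
    return TrialEpochSet(
        epochs=epochs,
        sampling_rate=sampling_rate,
        labels=labels,
        onset_sample=-start_off,
        categories=categories,
    )


def load_edf_session(
    edf_path,
    events_csv,
    window_ms: tuple[float, float] = (-750.0, 1500.0),
    channel: int = 0,
    categories: tuple = CATEGORIES,
    stimulus_duration: float = 1.0,
) -> TrialEpochSet:
    """Real-data path: EDF recording plus a trial-events table.

    The events CSV needs columns trial_index, category_label and
    onset_sample (sample indices into the EDF channel). Amplitudes come
    back in volts as read by the EDF parser.
    """
    import pandas as pd

    from .edf import read_edf

    signals, rate = read_edf(edf_path)
    df = pd.read_csv(events_csv)
    required = {"trial_index", "category_label", "onset_sample"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events CSV missing columns: {sorted(missing)}")
    df = df.sort_values("trial_index")
    session = epoch_and_concatenate(
        signals[channel],
        df["onset_sample"].to_numpy(dtype=int),
        df["category_label"].to_numpy(dtype=str),
        rate,
        window_ms,
        categories,
    )
    session.stimulus_duration = stimulus_duration
    return session


def drop_trials(epoch_set: TrialEpochSet, exclude_mask) -> TrialEpochSet:
    """Remove trials flagged in ``exclude_mask`` (True = drop).

    Retained trials keep their order; the concatenation map is rebuilt.
    Raises if any category would lose all its trials (phase-difference
    scores are undefined then).
    """
    exclude_mask = np.asarray(exclude_mask, dtype=bool)
    if exclude_mask.shape[0] != epoch_set.n_trials:
        raise ValueError("mask length must equal trial count")
    keep = ~exclude_mask
    new_labels = epoch_set.labels[keep]
    for cat in epoch_set.categories:
        if np.any(epoch_set.labels == cat) and not np.any(new_labels == cat):
            raise ValueError(f"mask removes every '{cat}' trial; scores undefined")
    return TrialEpochSet(
        epochs=epoch_set.epochs[keep],
        sampling_rate=epoch_set.sampling_rate,
        labels=new_labels,
        onset_sample=epoch_set.onset_sample,
        categories=epoch_set.categories,
        stimulus_duration=epoch_set.stimulus_duration,
    )
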