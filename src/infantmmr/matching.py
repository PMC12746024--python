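"""Standard-trial selection to balance deviant counts.

The default "preceding standard" strategy pairs each retained deviant with
the nearest earlier retained standard not already used, preserving temporal
proximity (and hence arousal/time-on-task comparability) between conditions.
A seeded random-subset strategy is available as a robustness check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import DEVIANT, STANDARD, EpochSet

logger = logging.getLogger(__name__)

__all__ = ["MatchedPairs", "match_preceding_standard", "match_random_subset"]


@dataclass
class MatchedPairs:
    """Equal-length arrays of retained deviant and standard trial indices."""

    deviant_indices: np.ndarray
    standard_indices: np.ndarray
    strategy: str

    def __post_init__(self) -> None:
        self.deviant_indices = np.asarray(self.deviant_indices, dtype=int)
        self.standard_indices = np.asarray(self.standard_indices, dtype=int)
        if self.deviant_indices.shape != self.standard_indices.shape:
            raise ValueError("deviant and standard index lists must have equal length")
        if len(set(self.standard_indices.tolist())) != len(self.standard_indices):
            raise ValueError("a standard trial may not be used twice")
        if self.strategy not in ("preceding", "random"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "preceding" and np.any(
                self.standard_indices >= self.deviant_indices):
            raise ValueError("preceding strategy requires standard index < deviant index")

    def __len__(self) -> int:
        return len(self.deviant_indices)


def match_preceding_standard(epochs: EpochSet) -> MatchedPairs:
    """Pair each retained deviant with the nearest earlier unused retained
    standard; deviants with no available earlier standard are dropped."""
    retained = set(epochs.retained_indices.tolist())
    labels = epochs.trial_labels
    deviants = [i for i in sorted(retained) if labels[i] == DEVIANT]
    if not deviants:
        raise ValueError("no retained deviant trials to match")
    used: set[int] = set()
    dev_out, std_out = [], []
    n_dropped = 0
    for d in deviants:
        chosen = None
        for s in range(d - 1, -1, -1):
            if s in retained and s not in used and labels[s] == STANDARD:
                chosen = s
                break
        if chosen is None:
            n_dropped += 1
            continue
        used.add(chosen)
        dev_out.append(d)
        std_out.append(chosen)
    if n_dropped:
        logger.warning("dropped %d deviants with no available earlier standard",
                       n_dropped)
    if not dev_out:
        raise ValueError("no deviant/standard pairs could be formed")
    return MatchedPairs(np.array(dev_out), np.array(std_out), "preceding")


def match_random_subset(epochs: EpochSet, seed: int) -> MatchedPairs:
    """Uniform sample of retained standards without replacement, one per
    retained deviant."""
    deviants = epochs.retained_by_label(DEVIANT)
    standards = epochs.retained_by_label(STANDARD)
    if deviants.size == 0:
        raise ValueError("no retained deviant trials to match")
    if standards.size < deviants.size:
        raise ValueError(
            f"only {standards.size} retained standards for {deviants.size} deviants")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(standards, size=deviants.size, replace=False)
    return MatchedPairs(deviants, np.sort(chosen), "random")
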