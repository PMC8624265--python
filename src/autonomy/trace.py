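"""Trial-structured activity traces and plug-in empirical distributions.

All observational measures in this package are computed from an
:class:`ActivityTrace`: an ordered list of trials, each an array of full
system states (one row per time step, one column per unit, binary
values).  Probabilities are plug-in (maximum-likelihood) estimates from
pooled counts; lagged statistics never straddle a trial boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ActivityTrace", "EmpiricalDistribution", "entropy"]


class ActivityTrace:
    """Trial-delimited recording of joint (sensor, hidden, motor) states."""

    def __init__(self, trials, labels=None):
        self.trials = [np.asarray(t, dtype=np.uint8) for t in trials]
        if not self.trials:
            raise ValueError("trace needs at least one trial")
        n = self.trials[0].shape[1]
        for t in self.trials:
            if t.ndim != 2 or t.shape[1] != n:
                raise ValueError("all trials must have the same unit count")
            if t.shape[0] == 0:
                raise ValueError("empty trial")
            if np.any(t > 1):
                raise ValueError("trace values must be binary")
        self.labels = list(labels) if labels is not None else [f"U{i}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("label count mismatch")

    @property
    def n_units(self) -> int:
        return self.trials[0].shape[1]

    @property
    def n_steps(self) -> int:
        return sum(t.shape[0] for t in self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def concatenate(self, other: "ActivityTrace") -> "ActivityTrace":
        """Pool two traces, preserving trial boundaries."""
        if other.n_units != self.n_units:
            raise ValueError("unit count mismatch")
        return ActivityTrace(self.trials + other.trials, self.labels)

    # -- lagged sampling ---------------------------------------------------
    def lagged_samples(self, slots) -> np.ndarray:
        """Pooled joint samples of lagged unit subsets.

        ``slots`` is a sequence of ``(units, lag)`` pairs; a sample at
        time ``t`` within a trial combines, for each slot, the state of
        ``units`` at ``t - lag``.  Only times where every lag fits inside
        the trial contribute, so lag-m statistics drop the first m steps
        of each trial.  Returns an integer-coded array of shape
        ``(n_samples, n_slots)`` (little-endian coding per slot).
        """
        max_lag = max(lag for _, lag in slots)
        if max_lag < 0 or any(lag < 0 for _, lag in slots):
            raise ValueError("lags must be non-negative")
        cols = []
        for units, lag in slots:
            units = list(units)
            weights = 1 << np.arange(len(units))
            per_trial = []
            for tr in self.trials:
                if tr.shape[0] <= max_lag:
                    continue
                block = tr[max_lag - lag: tr.shape[0] - lag, units]
                per_trial.append(block @ weights)
            if not per_trial:
                raise ValueError("all trials shorter than the maximum lag")
            cols.append(np.concatenate(per_trial))
        return np.column_stack(cols)

    def distribution(self, slots) -> "EmpiricalDistribution":
        """Plug-in joint distribution over the given lagged slots."""
        samples = self.lagged_samples(slots)
        return EmpiricalDistribution.from_samples(samples, slots)

    # -- serialization -----------------------------------------------------
    def to_csv(self, path) -> None:
        frames = []
        for i, tr in enumerate(self.trials):
            df = pd.DataFrame(tr, columns=self.labels)
            df.insert(0, "t", np.arange(tr.shape[0]))
            df.insert(0, "trial_id", i)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ActivityTrace":
        path = Path(path)
        df = pd.read_csv(path)
        if "trial_id" not in df.columns or "t" not in df.columns:
            raise ValueError("trace CSV needs trial_id and t columns")
        unit_cols = [c for c in df.columns if c not in ("trial_id", "t")]
        trials = [
            g.sort_values("t")[unit_cols].to_numpy(dtype=np.uint8)
            for _, g in df.groupby("trial_id", sort=True)
        ]
        return cls(trials, labels=unit_cols)


class EmpiricalDistribution:
    """Probability table over joint configurations of lagged unit subsets."""

    def __init__(self, support: np.ndarray, probs: np.ndarray, slots=None):
        self.support = np.asarray(support)
        self.probs = np.asarray(probs, dtype=float)
        self.slots = slots
        if np.any(self.probs < 0):
            raise ValueError("negative probability")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 (tolerance 1e-12)")

    @classmethod
    def from_samples(cls, samples: np.ndarray, slots=None) -> "EmpiricalDistribution":
        samples = np.atleast_2d(np.asarray(samples))
        support, counts = np.unique(samples, axis=0, return_counts=True)
        return cls(support, counts / counts.sum(), slots)

    def entropy(self) -> float:
        return entropy(self.probs)

    def __len__(self) -> int:
        return len(self.probs)


def entropy(dist) -> float:
    """Shannon entropy in bits; ``0 * log 0`` is taken as 0.

    Accepts an :class:`EmpiricalDistribution` or any array of
    probabilities (which must sum to 1 within 1e-12).
    """
    if isinstance(dist, EmpiricalDistribution):
        p = dist.probs
    else:
        p = np.asarray(dist, dtype=float).ravel()
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("not a normalized probability table")
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())
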