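"""Trials-by-condition container for paired responses, with text-file I/O.

The on-disk format is a delimited text table (CSV by default) with header
``pair_id,stimulus,trial,r1,r2``: one row per trial of one pair at one
stimulus contrast (percent).  Ground truth for synthetic datasets travels as a
JSON sidecar (see :mod:`pairrog.simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Dataset", "PairObservations", "read_dataset", "write_dataset", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("pair_id", "stimulus", "trial", "r1", "r2")


@dataclass
class PairObservations:
    """Per-condition arrays for a single pair, ready for fitting.

    ``responses`` is a list of (T_s, 2) arrays aligned with ``contrasts``.
    Empirical moments use the maximum-likelihood convention (ddof=0) so the
    matrix form of the likelihood matches per-trial Gaussian log-densities.
    """

    pair_id: object
    contrasts: np.ndarray          # (S,)
    counts: np.ndarray             # (S,) trials per condition
    responses: list                # S arrays of shape (T_s, 2)

    @property
    def n_conditions(self) -> int:
        return len(self.contrasts)

    def empirical_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-condition mean (S, 2) and ML covariance (S, 2, 2)."""
        means = np.stack([r.mean(axis=0) for r in self.responses])
        covs = np.stack([np.cov(r.T, ddof=0) if len(r) > 1 else np.zeros((2, 2))
                         for r in self.responses])
        return means, covs

    def pooled_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean and ML covariance pooling all trials across conditions."""
        allr = np.vstack(self.responses)
        return allr.mean(axis=0), np.cov(allr.T, ddof=0)

    def noise_correlations(self) -> np.ndarray:
        """Per-condition empirical response correlation."""
        _, covs = self.empirical_moments()
        sd = np.sqrt(covs[:, 0, 0] * covs[:, 1, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sd > 0, covs[:, 0, 1] / np.where(sd > 0, sd, 1.0), 0.0)
        return out

    def resample(self, rng: np.random.Generator) -> "PairObservations":
        """Bootstrap resample: paired trials drawn with replacement within
        each condition, preserving per-condition counts."""
        new = [r[rng.integers(0, len(r), size=len(r))] for r in self.responses]
        return PairObservations(self.pair_id, self.contrasts, self.counts.copy(), new)

    def split(self, test_masks: list) -> tuple["PairObservations", "PairObservations"]:
        """Train/test split from per-condition boolean test masks."""
        train = [r[~m] for r, m in zip(self.responses, test_masks)]
        test = [r[m] for r, m in zip(self.responses, test_masks)]
        keep_tr = [len(r) > 0 for r in train]
        keep_te = [len(r) > 0 for r in test]
        tr = PairObservations(
            self.pair_id, self.contrasts[keep_tr],
            np.array([len(r) for r, k in zip(train, keep_tr) if k]),
            [r for r, k in zip(train, keep_tr) if k])
        te = PairObservations(
            self.pair_id, self.contrasts[keep_te],
            np.array([len(r) for r, k in zip(test, keep_te) if k]),
            [r for r, k in zip(test, keep_te) if k])
        return tr, te


class Dataset:
    """Table of paired responses keyed by (pair, stimulus, trial)."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset missing required column(s): {', '.join(missing)}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def pair_ids(self) -> list:
        return list(pd.unique(self.frame["pair_id"]))

    @property
    def stimulus_set(self) -> np.ndarray:
        return np.sort(pd.unique(self.frame["stimulus"]))

    def trial_counts(self) -> pd.DataFrame:
        """Trials per (pair, stimulus); mixed stimulus sets across pairs allowed."""
        return (self.frame.groupby(["pair_id", "stimulus"], sort=True)
                .size().rename("n_trials").reset_index())

    def pair(self, pair_id) -> PairObservations:
        sub = self.frame[self.frame["pair_id"] == pair_id]
        if sub.empty:
            raise KeyError(f"no such pair_id: {pair_id!r}")
        contrasts = np.sort(sub["stimulus"].unique())
        responses = []
        counts = []
        for c in contrasts:
            block = sub[sub["stimulus"] == c].sort_values("trial")
            r = block[["r1", "r2"]].to_numpy(dtype=float)
            if len(r) < 2:
                raise ValueError(
                    f"pair {pair_id!r}, stimulus {c}: need >= 2 trials for "
                    f"empirical covariance, got {len(r)}")
            responses.append(r)
            counts.append(len(r))
        return PairObservations(pair_id, contrasts.astype(float), np.array(counts), responses)

    def iter_pairs(self):
        for pid in self.pair_ids:
            yield self.pair(pid)

    def condition_moments(self) -> pd.DataFrame:
        """Empirical mean vector, covariance and correlation per (pair, stimulus)."""
        rows = []
        for po in self.iter_pairs():
            means, covs = po.empirical_moments()
            corr = po.noise_correlations()
            for i, c in enumerate(po.contrasts):
                rows.append({
                    "pair_id": po.pair_id, "stimulus": c, "n_trials": po.counts[i],
                    "mean1": means[i, 0], "mean2": means[i, 1],
                    "var1": covs[i, 0, 0], "var2": covs[i, 1, 1],
                    "cov": covs[i, 0, 1], "corr": corr[i],
                })
        return pd.DataFrame(rows)


def write_dataset(dataset: Dataset, path, sep: str = ",") -> None:
    dataset.frame.to_csv(path, sep=sep, index=False,
                         columns=list(REQUIRED_COLUMNS))


def read_dataset(path, sep: str = ",") -> Dataset:
    """Read a dataset table, validating the schema with line-aware errors."""
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited text: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in ("stimulus", "r1", "r2"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}")
        if coerced.isna().any():
            raise ValueError(
                f"{path}: missing value in column {col!r} at line "
                f"{frame.index[coerced.isna()][0] + 2}")
        frame[col] = coerced
    return Dataset(frame)
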