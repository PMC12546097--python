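"""Per-trial feature-vector assembly and dataset construction.

Each tasting trial yields a 306-long feature vector: 190 normalized
spectral powers (38 channels × 5 IAF-anchored bands) and 114 Hjorth
parameters (38 channels × 3), extracted from the tasting (TL) epoch and
normalized element-wise against the water-rinse (WR) epoch of the same
trial, plus the subject's age and expertise group.

Feature ordering is channels-major and fixed: first the spectral block
(``<ch>.p_delta`` … ``<ch>.p_gamma`` per channel), then the temporal
block (``<ch>.hjorth_A``, ``.hjorth_M``, ``.hjorth_C``), then ``age``
and ``group``.  The WR normalization is ``(x − y) ⊘ y`` (element-wise)
and applies to the 304 EEG-derived entries only; demographics are
appended afterwards (normalizing them against themselves would zero
them out).

Targets are the 0–10 attribute ratings transformed as ``log(1 + y)``.
Standardization is subject-wise, so no information crosses subjects and
leave-one-subject-out evaluation is leakage-free by construction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    BAND_NAMES,
    band_powers,
    define_bands,
    estimate_iaf,
    hjorth,
    welch_psd,
)
from .montage import OCCIPITAL
from .synthetic import ATTRIBUTES, N_TRIALS, PHASES, SessionRecording, VirtualSubject

logger = logging.getLogger(__name__)

HJORTH_NAMES: tuple[str, ...] = ("A", "M", "C")
STANDARDIZERS: tuple[str, ...] = ("z-score", "min-max", "median", "none")
_STANDARDIZER_ALIASES = {"zscore": "z-score", "minmax": "min-max"}
DATASET_TAGS: tuple[str, ...] = ("Be", "Co", "BeCo")

GROUP_CODES = {"T": 0.0, "E": 1.0}


def eeg_feature_names(channels: list[str] | tuple[str, ...]) -> list[str]:
    """The 304 EEG-derived feature names, channels-major."""
    spectral = [f"{ch}.p_{band}" for ch in channels for band in BAND_NAMES]
    temporal = [f"{ch}.hjorth_{p}" for ch in channels for p in HJORTH_NAMES]
    return spectral + temporal


def feature_names(channels: list[str] | tuple[str, ...]) -> list[str]:
    """All 306 feature names (EEG features + age + group)."""
    return eeg_feature_names(channels) + ["age", "group"]


def canonical_standardizer(method: str) -> str:
    method = _STANDARDIZER_ALIASES.get(method, method)
    if method not in STANDARDIZERS:
        raise ValueError(f"standardizer must be one of {STANDARDIZERS}, got {method!r}")
    return method


def transform_targets(y):
    """Ratio-scale target transform log(1 + y); inverse is expm1."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("ratings must be ≥ 0")
    return np.log1p(y)


def inverse_transform_targets(t):
    """Inverse of :func:`transform_targets`: exp(t) − 1."""
    return np.expm1(np.asarray(t, dtype=float))


def wr_normalize(x_tl: np.ndarray, y_wr: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Element-wise relative change of TL vs WR features: (x − y) ⊘ y."""
    x = np.asarray(x_tl, dtype=float)
    y = np.asarray(y_wr, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    bad = np.nonzero(np.abs(y) < eps)[0]
    if bad.size:
        raise ValueError(
            f"WR reference features too close to zero at indices {bad.tolist()[:20]}"
        )
    return (x - y) / y


def _epoch_eeg_vector(epoch, bands) -> np.ndarray:
    """304-long (spectral + Hjorth) vector of one epoch."""
    psd = welch_psd(epoch)
    spectral = band_powers(psd, bands).as_vector(epoch.channel_names)
    temporal = hjorth(epoch).as_vector(epoch.channel_names)
    return np.concatenate([spectral, temporal])


def extract_panel_features(
    subjects: list[VirtualSubject],
    sessions: list[SessionRecording],
    occipital: tuple[str, ...] = OCCIPITAL,
) -> pd.DataFrame:
    """Per-epoch feature records for every (subject, phase, trial, task).

    Estimates each subject's IAF from the baseline epoch, anchors the
    band scheme on it, and extracts the 304 EEG features from every WR
    and TL epoch.  Returns a tidy frame keyed by
    (subject_id, phase, trial, task) with an ``iaf`` column.
    """
    by_id = {s.subject_id: s for s in subjects}
    rows = []
    for session in sessions:
        if session.subject_id not in by_id:
            raise KeyError(f"session subject {session.subject_id!r} not in panel")
        iaf = estimate_iaf(session.baseline, occipital)
        bands = define_bands(iaf)
        names = session.baseline.channel_names
        for phase in PHASES:
            for trial in range(1, N_TRIALS + 1):
                for task, epochs in (("WR", session.wr_epochs), ("TL", session.tl_epochs)):
                    if (phase, trial) not in epochs:
                        raise KeyError(
                            f"missing {task} epoch for "
                            f"({session.subject_id}, {phase}, trial {trial})"
                        )
                    vec = _epoch_eeg_vector(epochs[(phase, trial)], bands)
                    rows.append(
                        {
                            "subject_id": session.subject_id,
                            "phase": phase,
                            "trial": trial,
                            "task": task,
                            "iaf": iaf,
                            **dict(zip(eeg_feature_names(names), vec)),
                        }
                    )
    return pd.DataFrame(rows)


def demographics_frame(subjects: list[VirtualSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age": [s.age for s in subjects],
            "group": [s.group for s in subjects],
        }
    )


def ratings_frame(sessions: list[SessionRecording]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": sess.subject_id,
            "phase": phase,
            "trial": trial,
            "attribute": attr,
            "rating": rating,
        }
        for sess in sessions
        for (phase, trial, attr), rating in sorted(sess.ratings.items())
    ]
    return pd.DataFrame(rows)


@dataclass
class FeatureTable:
    """One analysis dataset: rows are tasting trials.

    ``X`` holds the 306 feature columns, ``y`` the log(1+rating) targets
    (one column per attribute), ``meta`` the (subject_id, phase, trial)
    keys.  ``tag`` is "Be", "Co" or "BeCo".
    """

    meta: pd.DataFrame
    X: pd.DataFrame
    y: pd.DataFrame
    tag: str
    standardizer: str = "none"

    def __post_init__(self) -> None:
        n = len(self.meta)
        if len(self.X) != n or len(self.y) != n:
            raise ValueError("meta, X and y must have equal row counts")

    @property
    def n_rows(self) -> int:
        return len(self.meta)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.meta["subject_id"].to_numpy()

    def rows_of(self, subject_id: str) -> np.ndarray:
        return np.nonzero(self.subject_ids == subject_id)[0]

    def to_csv(self, path: str | Path) -> None:
        """Write the table as one CSV plus a JSON manifest alongside."""
        path = Path(path)
        full = pd.concat(
            [self.meta.reset_index(drop=True), self.X.reset_index(drop=True),
             self.y.add_prefix("target_").reset_index(drop=True)],
            axis=1,
        )
        full.to_csv(path, index=False)
        manifest = {
            "tag": self.tag,
            "standardizer": self.standardizer,
            "target_transform": "log1p",
            "n_rows": self.n_rows,
            "n_features": self.X.shape[1],
            "attributes": list(self.y.columns),
        }
        path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".manifest.json").read_text())
        full = pd.read_csv(path, float_precision="round_trip")
        meta_cols = ["subject_id", "phase", "trial"]
        target_cols = [f"target_{a}" for a in manifest["attributes"]]
        feat_cols = [c for c in full.columns if c not in meta_cols + target_cols]
        y = full[target_cols].copy()
        y.columns = manifest["attributes"]
        return cls(
            meta=full[meta_cols],
            X=full[feat_cols],
            y=y,
            tag=manifest["tag"],
            standardizer=manifest["standardizer"],
        )


def assemble_dataset(
    records: pd.DataFrame,
    demographics: pd.DataFrame,
    ratings: pd.DataFrame,
    tag: str,
) -> FeatureTable:
    """Build the Be, Co or BeCo feature table from per-epoch records.

    One row per tasting trial: the TL feature vector WR-normalized
    ((x−y)⊘y element-wise), demographics appended after normalization.
    BeCo is the row-concatenation of Be and Co.
    """
    if tag not in DATASET_TAGS:
        raise ValueError(f"tag must be one of {DATASET_TAGS}, got {tag!r}")
    if tag == "BeCo":
        be = assemble_dataset(records, demographics, ratings, "Be")
        co = assemble_dataset(records, demographics, ratings, "Co")
        return FeatureTable(
            meta=pd.concat([be.meta, co.meta], ignore_index=True),
            X=pd.concat([be.X, co.X], ignore_index=True),
            y=pd.concat([be.y, co.y], ignore_index=True),
            tag="BeCo",
        )

    demo = demographics.set_index("subject_id")
    eeg_cols = [c for c in records.columns
                if c not in ("subject_id", "phase", "trial", "task", "iaf")]
    recs = records[records["phase"] == tag]
    meta_rows, x_rows, y_rows = [], [], []
    for subject_id in demographics["subject_id"]:
        sub = recs[recs["subject_id"] == subject_id]
        for trial in range(1, N_TRIALS + 1):
            tl = sub[(sub["trial"] == trial) & (sub["task"] == "TL")]
            wr = sub[(sub["trial"] == trial) & (sub["task"] == "WR")]
            if len(tl) != 1 or len(wr) != 1:
                raise KeyError(
                    f"missing TL/WR features for ({subject_id}, {tag}, trial {trial})"
                )
            x_prime = wr_normalize(
                tl[eeg_cols].to_numpy()[0], wr[eeg_cols].to_numpy()[0]
            )
            age = float(demo.loc[subject_id, "age"])
            group = GROUP_CODES[str(demo.loc[subject_id, "group"])]
            meta_rows.append((subject_id, tag, trial))
            x_rows.append(np.concatenate([x_prime, [age, group]]))
            trial_ratings = ratings[
                (ratings["subject_id"] == subject_id)
                & (ratings["phase"] == tag)
                & (ratings["trial"] == trial)
            ].set_index("attribute")["rating"]
            if not set(ATTRIBUTES) <= set(trial_ratings.index):
                raise KeyError(
                    f"missing ratings for ({subject_id}, {tag}, trial {trial})"
                )
            y_rows.append([transform_targets(trial_ratings[a]) for a in ATTRIBUTES])

    names = eeg_cols + ["age", "group"]
    return FeatureTable(
        meta=pd.DataFrame(meta_rows, columns=["subject_id", "phase", "trial"]),
        X=pd.DataFrame(x_rows, columns=names),
        y=pd.DataFrame(y_rows, columns=list(ATTRIBUTES)),
        tag=tag,
    )


def _standardize_block(values: np.ndarray, method: str) -> tuple[np.ndarray, bool]:
    """Standardize one subject's column; flags a degenerate (zero) scale."""
    if method == "z-score":
        mu, sd = values.mean(), values.std()
        if sd == 0:
            return values - mu, True
        return (values - mu) / sd, False
    if method == "min-max":
        lo, hi = values.min(), values.max()
        if hi == lo:
            return values - lo, True
        return (values - lo) / (hi - lo), False
    if method == "median":
        med = np.median(values)
        iqr = np.subtract(*np.percentile(values, [75, 25]))
        if iqr == 0:
            z = values - med
            degenerate = True
        else:
            z = (values - med) / (iqr / 1.349)
            degenerate = False
        return 1.0 / (1.0 + np.exp(-z)), degenerate
    raise AssertionError(method)


def standardize(table: FeatureTable, method: str) -> FeatureTable:
    """Subject-wise feature standardization.

    Methods: ``z-score``, ``min-max`` (to [0, 1]), ``median`` (robust
    median/IQR z-score squashed through a logistic to (0, 1)), ``none``.
    The categorical ``group`` column is never standardized.  A zero
    subject-level scale leaves the feature centered only (warning).
    """
    method = canonical_standardizer(method)
    if method == "none":
        return FeatureTable(
            meta=table.meta.copy(), X=table.X.copy(), y=table.y.copy(),
            tag=table.tag, standardizer="none",
        )
    counts = table.meta.groupby("subject_id").size()
    if (counts < 2).any():
        raise ValueError("need ≥ 2 rows per subject for subject-wise scaling")
    X = table.X.copy()
    cols = [c for c in X.columns if c != "group"]
    subj = table.subject_ids
    degenerate_cols: set[str] = set()
    for sid in pd.unique(subj):
        mask = subj == sid
        block = X.loc[mask, cols].to_numpy()
        outs = []
        for j in range(block.shape[1]):
            out, degenerate = _standardize_block(block[:, j], method)
            if degenerate:
                degenerate_cols.add(cols[j])
            outs.append(out)
        X.loc[mask, cols] = np.column_stack(outs)
    if degenerate_cols:
        shown = sorted(degenerate_cols)[:5]
        warnings.warn(
            f"zero subject-level scale for {len(degenerate_cols)} feature(s) "
            f"(e.g. {shown}); centered only",
            stacklevel=2,
        )
    return FeatureTable(
        meta=table.meta.copy(), X=X, y=table.y.copy(),
        tag=table.tag, standardizer=method,
    )
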