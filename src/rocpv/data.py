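"""Labeled risk-score data and delimited-text input.

The canonical in-memory container for a case-control sample is
:class:`LabeledScores`: one continuous risk score and one binary outcome
label per subject.  Higher scores mean higher predicted risk throughout
the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputDataError

logger = logging.getLogger(__name__)

__all__ = ["LabeledScores", "read_scores", "write_scores"]


@dataclass(frozen=True)
class LabeledScores:
    """Per-subject continuous risk scores with binary outcome labels.

    Parameters
    ----------
    scores
        Real-valued risk scores, higher = higher predicted risk.
    labels
        Binary outcome indicators: 1 for subjects who develop the
        condition (cases), 0 for controls.

    Both vectors must have equal length >= 2 and each class must be
    represented at least once.
    """

    scores: np.ndarray
    labels: np.ndarray
    _skip_validation: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "scores", scores)
        if self._skip_validation:
            object.__setattr__(self, "labels", labels)
            return
        if scores.ndim != 1 or labels.ndim != 1:
            raise InputDataError("scores and labels must be 1-D")
        if scores.shape != labels.shape:
            raise InputDataError(
                f"scores ({scores.size}) and labels ({labels.size}) differ in length"
            )
        if scores.size < 2:
            raise InputDataError("need at least two subjects")
        if not np.all(np.isfinite(scores)):
            raise InputDataError("scores must be finite")
        uniq = np.unique(labels)
        if not np.isin(uniq, [0, 1]).all():
            raise InputDataError(f"labels must be 0/1, got values {uniq}")
        labels = labels.astype(np.int8)
        if labels.min() == labels.max():
            raise InputDataError("need at least one case and one control")
        object.__setattr__(self, "labels", labels)

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int(self.labels.size - self.labels.sum())

    @property
    def case_scores(self) -> np.ndarray:
        return self.scores[self.labels == 1]

    @property
    def control_scores(self) -> np.ndarray:
        return self.scores[self.labels == 0]

    @property
    def sample_case_fraction(self) -> float:
        """Case fraction of the sample.

        In a case-control design this is fixed by the investigator and is
        *not* an estimate of disease prevalence; prevalence must always be
        supplied externally.
        """
        return self.n_cases / self.labels.size

    def __len__(self) -> int:
        return int(self.labels.size)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_scores(path: str | Path) -> LabeledScores:
    """Read a score/label table from delimited text.

    Comma- or tab-separated (auto-detected from the extension), with a
    header row.  Required columns: ``score`` (float) and ``label`` (0/1).
    Extra columns are ignored; rows with a missing score or label are
    dropped with a logged count.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise InputDataError(f"cannot read {path}: {exc}") from exc
    missing = {"score", "label"} - set(df.columns)
    if missing:
        raise InputDataError(f"{path}: missing required column(s) {sorted(missing)}")
    sub = df[["score", "label"]].apply(pd.to_numeric, errors="coerce")
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with missing score or label", path, n_dropped)
    sub = sub[keep]
    if len(sub) == 0:
        raise InputDataError(f"{path}: no complete rows")
    return LabeledScores(sub["score"].to_numpy(), sub["label"].to_numpy())


def write_scores(data: LabeledScores, path: str | Path) -> None:
    """Write a score/label table as delimited text (inverse of read_scores)."""
    path = Path(path)
    pd.DataFrame({"score": data.scores, "label": data.labels}).to_csv(
        path, sep=_sep_for(path), index=False
    )
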