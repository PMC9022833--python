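"""Core in-memory containers shared across the pipeline.

Expression data travel as probes x samples :class:`pandas.DataFrame` objects
wrapped in :class:`ExpressionMatrix`, which tracks the measurement scale
(``raw`` intensities vs ``log2``) and the optional per-entry detection
p-values produced by bead-array scanners. Sample/probe removal decisions are
recorded as :class:`SampleMask` / :class:`ProbeMask` so every filtering stage
leaves an auditable trail (id, keep flag, reason, score).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMask",
    "ProbeMask",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class ExpressionMatrix:
    """Probes x samples expression values with optional detection p-values.

    Parameters
    ----------
    values
        Probes (rows) x samples (columns) matrix. Index = probe ids,
        columns = sample ids; both must be unique.
    detection_p
        Optional matrix of the same shape/labels with per-entry detection
        p-values in [0, 1] (small = signal above negative-control background).
    scale
        ``"raw"`` for linear-scale intensities, ``"log2"`` after transform.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate probe ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in expression matrix")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValidationError(
                    "detection_p shape "
                    f"{self.detection_p.shape} != values shape {self.values.shape}"
                )
            if not self.detection_p.index.equals(self.values.index) or not (
                self.detection_p.columns.equals(self.values.columns)
            ):
                raise ValidationError("detection_p ids do not match values ids")
            dp = self.detection_p.to_numpy()
            if np.nanmin(dp) < 0 or np.nanmax(dp) > 1:
                raise ValidationError("detection p-values outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(
        self,
        probes: pd.Index | list | None = None,
        samples: pd.Index | list | None = None,
    ) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given probes/samples."""
        values = self.values
        detp = self.detection_p
        if probes is not None:
            values = values.loc[probes]
            detp = detp.loc[probes] if detp is not None else None
        if samples is not None:
            values = values[samples]
            detp = detp[samples] if detp is not None else None
        return ExpressionMatrix(values=values, detection_p=detp, scale=self.scale)


@dataclass
class _Mask:
    """Ordered id -> (keep, reason, score) record of one filtering decision."""

    ids: pd.Index
    keep: np.ndarray
    reason: list[str] = field(default_factory=list)
    score: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = pd.Index(self.ids)
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.ids.has_duplicates:
            raise ValidationError("duplicate ids in mask")
        if len(self.ids) != len(self.keep):
            raise ValidationError("mask ids and keep flags differ in length")
        if not self.reason:
            self.reason = ["" for _ in range(len(self.ids))]
        if len(self.reason) != len(self.ids):
            raise ValidationError("mask reasons differ in length from ids")
        if self.score is not None:
            self.score = np.asarray(self.score, dtype=float)
            if len(self.score) != len(self.ids):
                raise ValidationError("mask scores differ in length from ids")

    @property
    def kept_ids(self) -> pd.Index:
        return self.ids[self.keep]

    @property
    def removed_ids(self) -> pd.Index:
        return self.ids[~self.keep]

    @property
    def n_removed(self) -> int:
        return int((~self.keep).sum())

    def to_frame(self) -> pd.DataFrame:
        """Two-column TSV-ready frame (id, keep) plus reason/score columns."""
        return pd.DataFrame(
            {
                "id": self.ids,
                "keep": self.keep.astype(int),
                "reason": self.reason,
                "score": self.score if self.score is not None else np.nan,
            }
        )


class SampleMask(_Mask):
    pass


class ProbeMask(_Mask):
    pass
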