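"""Shared domain containers for the vaccine-signature pipeline.

The pipeline moves three kinds of object between stages: expression
matrices (RNA-seq counts or SomaScan RFU intensities, features in rows),
sample metadata tables keyed by ``sample_id``, and named gene-set
collections (GMT-backed). All three are thin, validated wrappers around
numpy/pandas structures so downstream code can rely on their invariants
(unique IDs, matching dimensions, non-negative counts) without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

ASSAY_KINDS = ("rnaseq_counts", "soma_rfu", "mesoscale_pg_ml")

TIMEPOINTS = ("D1", "D2", "D8", "D15", "D16", "D19", "D58", "D64", "other")

GROUPS = (
    "ad26_5e10",
    "ad26_1e11",
    "mrna1273",
    "bnt162b2",
    "sham",
    "tts_patient",
    "healthy_reference",
    "seropositive",
    "seronegative",
)

SAMPLE_TABLE_COLUMNS = ("sample_id", "subject_id", "timepoint", "group", "pair_key")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class ExpressionMatrix:
    """Features x samples grid of counts or intensities.

    Parameters
    ----------
    feature_ids, sample_ids
        Unique, case-sensitive identifiers; order defines row/column order.
    values
        2-D float array, shape ``(n_features, n_samples)``. Counts must be
        non-negative; RFU intensities strictly positive.
    assay_kind
        One of ``rnaseq_counts``, ``soma_rfu``, ``mesoscale_pg_ml``.
    below_detection
        Optional boolean mask marking cells that were below the assay's
        detection range (the ``#`` cells of a Mesoscale export); same shape
        as ``values``. Masked cells carry a placeholder value until
        :func:`vaxsig.diffstats.impute_below_detection` is applied.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    assay_kind: str
    below_detection: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.assay_kind not in ASSAY_KINDS:
            raise ValidationError(
                f"unknown assay_kind {self.assay_kind!r}; expected one of {ASSAY_KINDS}"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = _duplicates(self.feature_ids)
            raise ValidationError(f"duplicate feature IDs: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample IDs: {dupes}")
        if self.values.ndim != 2 or self.values.shape != (
            len(self.feature_ids),
            len(self.sample_ids),
        ):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.below_detection is not None:
            self.below_detection = np.asarray(self.below_detection, dtype=bool)
            if self.below_detection.shape != self.values.shape:
                raise ValidationError("below_detection mask shape mismatch")
        observed = self.values if self.below_detection is None else self.values[
            ~self.below_detection
        ]
        if observed.size and np.isnan(observed).any():
            raise ValidationError("values contain NaN outside the below-detection mask")
        if self.assay_kind == "rnaseq_counts" and observed.size and (observed < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.assay_kind == "soma_rfu" and observed.size and (observed <= 0).any():
            raise ValidationError("RFU intensities must be strictly positive")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.feature_ids, name="feature_id"),
            columns=self.sample_ids,
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = self.sample_index()
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ValidationError(f"unknown sample IDs: {missing}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, cols].copy(),
            assay_kind=self.assay_kind,
            below_detection=None
            if self.below_detection is None
            else self.below_detection[:, cols].copy(),
        )

    def subset_features(self, feature_ids: list[str]) -> "ExpressionMatrix":
        idx = self.feature_index()
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise ValidationError(f"unknown feature IDs: {missing}")
        rows = [idx[f] for f in feature_ids]
        return ExpressionMatrix(
            feature_ids=list(feature_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :].copy(),
            assay_kind=self.assay_kind,
            below_detection=None
            if self.below_detection is None
            else self.below_detection[rows, :].copy(),
        )


@dataclass
class SampleTable:
    """Per-sample metadata: subject, timepoint, study arm, optional pairing.

    ``pair_key`` links the two members of a matched pair (e.g. the D2 and
    D58 samples of one subject for a paired contrast); it must appear on
    exactly two samples or not at all.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        df = df.loc[:, list(SAMPLE_TABLE_COLUMNS)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample table")
        bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValidationError(f"unknown timepoints: {sorted(bad_tp)}")
        bad_grp = set(df["group"]) - set(GROUPS)
        if bad_grp:
            raise ValidationError(f"unknown groups: {sorted(bad_grp)}")
        dup = df.duplicated(subset=["subject_id", "timepoint", "group"])
        if dup.any():
            raise ValidationError(
                "duplicate (subject_id, timepoint) within a group: "
                f"{df.loc[dup, 'sample_id'].tolist()}"
            )
        keys = df["pair_key"].dropna()
        keys = keys[keys != ""]
        counts = keys.value_counts()
        bad_pairs = counts[counts != 2]
        if len(bad_pairs):
            raise ValidationError(
                f"pair_key must mark exactly two samples: {bad_pairs.index.tolist()}"
            )
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def select(
        self,
        group: str | None = None,
        timepoint: str | None = None,
        subject_id: str | None = None,
    ) -> list[str]:
        """Sample IDs matching every given condition, in table order."""
        df = self.frame
        mask = pd.Series(True, index=df.index)
        if group is not None:
            mask &= df["group"] == group
        if timepoint is not None:
            mask &= df["timepoint"] == timepoint
        if subject_id is not None:
            mask &= df["subject_id"] == subject_id
        return df.loc[mask, "sample_id"].tolist()

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        """Reject matrices whose samples are not described by this table."""
        known = set(self.frame["sample_id"])
        orphans = [s for s in matrix.sample_ids if s not in known]
        if orphans:
            raise ValidationError(f"matrix samples absent from sample table: {orphans}")


@dataclass
class GeneSetCollection:
    """Named gene sets with constant-time membership tests."""

    sets: dict[str, frozenset[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            fs = frozenset(str(m) for m in members)
            if not fs:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[name] = fs
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def filter_sizes(
        self, universe: set[str], min_size: int, max_size: int
    ) -> "GeneSetCollection":
        """Intersect each set with ``universe`` and keep those whose usable
        size lies in ``[min_size, max_size]``."""
        kept = {
            name: members & universe
            for name, members in self.sets.items()
            if min_size <= len(members & universe) <= max_size
        }
        return GeneSetCollection(
            sets={k: frozenset(v) for k, v in kept.items()},
            provenance=dict(self.provenance),
        )


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene mapping used by probe collapsing."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    def __getitem__(self, probe: str) -> str:
        return self.mapping[probe]

    def __contains__(self, probe: str) -> bool:
        return probe in self.mapping


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    dupes: list[str] = []
    for x in items:
        if x in seen and x not in dupes:
            dupes.append(x)
        seen.add(x)
    return dupes
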