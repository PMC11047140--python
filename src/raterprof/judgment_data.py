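"""Domain types, validation, and delimited-text I/O for judgment tables.

A *judgment table* is the universal input of the pipeline: one row per
(rater, trial) holding the rater's group, the trial's ground-truth type
(``same`` / ``different`` identity), the identity judgment on the signed
7-point scale (-3 strongly supports different identities ... +3 strongly
supports the same identity), and the perceived difficulty on a 5-point
scale (1 easy ... 5 not possible).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("raterprof")

#: The seven admissible identity-judgment values, in scale order.
SCALE_POINTS: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
#: The five admissible difficulty ratings.
DIFFICULTY_POINTS: tuple[int, ...] = (1, 2, 3, 4, 5)
#: Admissible trial types.
TRIAL_TYPES: tuple[str, ...] = ("same", "different")

#: Canonical column order for delimited-text files.
COLUMNS: tuple[str, ...] = (
    "rater_id",
    "group",
    "trial_id",
    "trial_type",
    "judgment",
    "difficulty",
)


class SchemaError(ValueError):
    """A delimited-text file does not expose the six required columns."""


class ValidationError(ValueError):
    """A record violates a domain invariant (range, duplication, consistency)."""


@dataclass(frozen=True)
class StudyDesign:
    """Trial composition of the study.

    Defaults mirror the face-comparison task this pipeline targets:
    twelve same-identity and eight different-identity image pairs, the
    imbalance preventing a process-of-elimination strategy.
    """

    n_same: int = 12
    n_different: int = 8

    def __post_init__(self) -> None:
        if self.n_same < 1 or self.n_different < 1:
            raise ValidationError(
                "a study design needs at least one trial of each type, got "
                f"n_same={self.n_same}, n_different={self.n_different}"
            )

    @property
    def n_trials(self) -> int:
        return self.n_same + self.n_different


@dataclass(frozen=True)
class JudgmentRecord:
    """One rater's response to one trial."""

    rater_id: str
    group: str
    trial_id: str
    trial_type: str
    judgment: int
    difficulty: int

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValidationError(
                f"trial_type must be one of {TRIAL_TYPES}, got {self.trial_type!r} "
                f"(rater {self.rater_id}, trial {self.trial_id})"
            )
        if self.judgment not in SCALE_POINTS:
            raise ValidationError(
                f"judgment must lie in [-3, 3], got {self.judgment!r} "
                f"(rater {self.rater_id}, trial {self.trial_id})"
            )
        if self.difficulty not in DIFFICULTY_POINTS:
            raise ValidationError(
                f"difficulty must lie in [1, 5], got {self.difficulty!r} "
                f"(rater {self.rater_id}, trial {self.trial_id})"
            )


class JudgmentTable:
    """Validated collection of judgment records with a rater-to-group mapping.

    Parameters
    ----------
    records
        DataFrame with the six canonical columns, or an iterable of
        :class:`JudgmentRecord`.
    design
        Trial composition. If omitted it is inferred from the distinct
        trial ids of each type present in the data.

    Raises
    ------
    ValidationError
        On out-of-range values, duplicate (rater, trial) pairs, raters
        assigned to more than one group, or trial ids whose type is
        inconsistent across raters.
    """

    def __init__(
        self,
        records: pd.DataFrame | Iterable[JudgmentRecord],
        design: StudyDesign | None = None,
    ) -> None:
        if isinstance(records, pd.DataFrame):
            df = records.copy()
        else:
            df = pd.DataFrame(
                [
                    (r.rater_id, r.group, r.trial_id, r.trial_type, r.judgment, r.difficulty)
                    for r in records
                ],
                columns=list(COLUMNS),
            )
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df[list(COLUMNS)].reset_index(drop=True)
        for col in ("rater_id", "group", "trial_id", "trial_type"):
            df[col] = df[col].astype(str)
        self._validate(df)
        df["judgment"] = df["judgment"].astype(int)
        df["difficulty"] = df["difficulty"].astype(int)
        # canonical order: rater, then trial
        df = df.sort_values(["rater_id", "trial_id"], kind="mergesort").reset_index(drop=True)
        self._df = df
        if design is None:
            by_type = df.drop_duplicates("trial_id")["trial_type"].value_counts()
            design = StudyDesign(
                n_same=int(by_type.get("same", 0)) or 1 if len(df) else 1,
                n_different=int(by_type.get("different", 0)) or 1 if len(df) else 1,
            )
        self.design = design

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if df.empty:
            return
        bad_type = df.loc[~df["trial_type"].isin(TRIAL_TYPES)]
        if not bad_type.empty:
            i = bad_type.index[0]
            raise ValidationError(
                f"row {i}: trial_type {df.at[i, 'trial_type']!r} not in {TRIAL_TYPES}"
            )
        for col, allowed, lo, hi in (
            ("judgment", SCALE_POINTS, -3, 3),
            ("difficulty", DIFFICULTY_POINTS, 1, 5),
        ):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.loc[vals.isna() | ~vals.isin(allowed)]
            if not bad.empty:
                i = bad.index[0]
                raise ValidationError(
                    f"row {i}: {col} = {df.at[i, col]!r} outside [{lo}, {hi}] "
                    f"(rater {df.at[i, 'rater_id']}, trial {df.at[i, 'trial_id']})"
                )
        dup = df.duplicated(subset=["rater_id", "trial_id"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValidationError(
                f"row {i}: duplicate response of rater {df.at[i, 'rater_id']} "
                f"to trial {df.at[i, 'trial_id']}"
            )
        multi_group = df.groupby("rater_id")["group"].nunique()
        offenders = multi_group[multi_group > 1]
        if not offenders.empty:
            raise ValidationError(
                f"rater {offenders.index[0]} assigned to {offenders.iloc[0]} groups; "
                "every rater must belong to exactly one group"
            )
        multi_type = df.groupby("trial_id")["trial_type"].nunique()
        offenders = multi_type[multi_type > 1]
        if not offenders.empty:
            raise ValidationError(
                f"trial {offenders.index[0]} labelled with inconsistent trial_type "
                "across raters"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        """The records as a DataFrame in canonical column and row order."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, JudgmentTable):
            return NotImplemented
        return self.design == other.design and self._df.equals(other._df)

    @property
    def raters(self) -> list[str]:
        return sorted(self._df["rater_id"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self._df["group"].unique())

    @property
    def trial_ids(self) -> list[str]:
        return sorted(self._df["trial_id"].unique())

    def group_of(self, rater_id: str) -> str:
        sub = self._df.loc[self._df["rater_id"] == rater_id, "group"]
        if sub.empty:
            raise KeyError(rater_id)
        return sub.iloc[0]

    def raters_in(self, group: str) -> list[str]:
        return sorted(self._df.loc[self._df["group"] == group, "rater_id"].unique())

    def trial_type_of(self, trial_id: str) -> str:
        sub = self._df.loc[self._df["trial_id"] == trial_id, "trial_type"]
        if sub.empty:
            raise KeyError(trial_id)
        return sub.iloc[0]

    def select(self, group: str | None = None, trial_type: str | None = None) -> pd.DataFrame:
        df = self._df
        if group is not None:
            df = df[df["group"] == group]
        if trial_type is not None:
            df = df[df["trial_type"] == trial_type]
        return df

    def ratings_matrix(self, group: str) -> tuple[list[str], list[str], np.ndarray]:
        """Dense raters x trials judgment matrix for one group.

        Returns ``(rater_ids, trial_ids, matrix)`` with rows in rater order
        and columns in trial order. Raises :class:`ValidationError` if any
        rater of the group misses any trial the group responded to, since
        pairwise agreement requires a common trial set.
        """
        sub = self.select(group=group)
        if sub.empty:
            raise ValidationError(f"group {group!r} not present in table")
        pivot = sub.pivot(index="rater_id", columns="trial_id", values="judgment")
        if pivot.isna().any().any():
            n_missing = int(pivot.isna().sum().sum())
            raise ValidationError(
                f"group {group!r} has {n_missing} missing responses; pairwise "
                "analyses need every rater on the same trial set"
            )
        pivot = pivot.sort_index(axis=0).sort_index(axis=1)
        return list(pivot.index), list(pivot.columns), pivot.to_numpy(dtype=int)


# -- delimited-text I/O ---------------------------------------------------


def read_judgments(
    path: str | Path,
    sep: str = ",",
    allow_missing: bool = False,
    design: StudyDesign | None = None,
) -> JudgmentTable:
    """Read a judgment table from a delimited text file.

    The file must carry a header naming the six record fields (any column
    order); extra columns are ignored. With ``allow_missing=True`` raters
    who did not respond to every trial present in the file are dropped with
    a warning instead of failing validation downstream.

    A JSON sidecar ``<path>.design.json`` with keys ``n_same`` and
    ``n_different``, if present, overrides the design inferred from data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype={"rater_id": str, "trial_id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    if allow_missing and not df.empty:
        n_trials = df["trial_id"].nunique()
        counts = df.groupby("rater_id")["trial_id"].nunique()
        incomplete = counts[counts < n_trials].index
        if len(incomplete):
            logger.warning(
                "dropping %d incomplete rater(s): %s",
                len(incomplete),
                ", ".join(map(str, incomplete[:10])),
            )
            df = df[~df["rater_id"].isin(incomplete)]
    if design is None:
        sidecar = path.with_suffix(path.suffix + ".design.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            design = StudyDesign(n_same=meta["n_same"], n_different=meta["n_different"])
    return JudgmentTable(df, design=design)


def write_judgments(table: JudgmentTable, path: str | Path, sep: str = ",") -> None:
    """Write a judgment table as delimited text, deterministically ordered.

    Columns follow :data:`COLUMNS`; rows are sorted by rater then trial so
    that identical tables always serialize identically.
    """
    path = Path(path)
    table.df.to_csv(path, sep=sep, index=False)


def records(table: JudgmentTable) -> list[JudgmentRecord]:
    """Materialize the table as a list of frozen records."""
    return [
        JudgmentRecord(
            rater_id=row.rater_id,
            group=row.group,
            trial_id=row.trial_id,
            trial_type=row.trial_type,
            judgment=int(row.judgment),
            difficulty=int(row.difficulty),
        )
        for row in table.df.itertuples(index=False)
    ]
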