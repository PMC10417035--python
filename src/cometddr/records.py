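"""Domain types, validation and tabular I/O for per-nucleoid comet measurements.

The comet assay (single-cell gel electrophoresis) scores DNA strand breaks per
nucleoid.  The damage metric used throughout this package is the tail moment

    TM = (% tail DNA x tail length) / 100,

which is unitless apart from the arbitrary length unit of the tail.  Records
carry the full experimental design annotation (strain, dose, extract, gel and
experiment replicate) needed by the downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_STRAINS",
    "DEFAULT_EXTRACTS",
    "CometRecord",
    "ConditionSummary",
    "StudyDesign",
    "CometValidationError",
    "compute_tail_moment",
    "read_records",
    "records_to_frame",
    "frame_to_records",
    "write_summaries",
    "read_summaries",
    "summaries_to_frame",
]

#: Strain vocabulary of the four-strain repair-mutant design: wild-type
#: Oregon-K, the NER (XPG homolog) mutant, the polymerase-theta mutant and
#: their double mutant.  User-defined labels are accepted with a warning.
DEFAULT_STRAINS = ("OK", "mus201", "mus308", "mus201;mus308")

#: Extract vocabulary for the ex vivo assay; ``none`` marks in vivo records.
DEFAULT_EXTRACTS = ("none", "buffer", "OK", "mus201", "mus308", "mus201;mus308")

_TM_RTOL = 1e-9


class CometValidationError(ValueError):
    """A record or table violated a comet-data invariant."""


def compute_tail_moment(percent_tail_dna: float, tail_length: float) -> float:
    """Tail moment from % tail DNA and tail length.

    Parameters
    ----------
    percent_tail_dna
        Percentage of DNA in the comet tail, in ``[0, 100]``.
    tail_length
        Tail extent in arbitrary length units, ``>= 0``.

    Returns
    -------
    float
        ``percent_tail_dna * tail_length / 100`` (non-negative).
    """
    if not 0.0 <= percent_tail_dna <= 100.0:
        raise CometValidationError(
            f"percent_tail_dna must be in [0, 100], got {percent_tail_dna!r}"
        )
    if tail_length < 0:
        raise CometValidationError(f"tail_length must be >= 0, got {tail_length!r}")
    return percent_tail_dna * tail_length / 100.0


@dataclass(frozen=True)
class CometRecord:
    """One nucleoid's comet measurements with full design annotation."""

    strain: str
    dose: float
    tail_moment: float
    percent_tail_dna: float | None = None
    tail_length: float | None = None
    extract: str = "none"
    gel_id: str = "g1"
    experiment_id: str = "e1"
    hedgehog_flag: bool = False

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise CometValidationError(f"dose must be >= 0, got {self.dose!r}")
        if self.tail_moment < 0:
            raise CometValidationError(
                f"tail_moment must be >= 0, got {self.tail_moment!r}"
            )
        if self.percent_tail_dna is not None and not (
            0.0 <= self.percent_tail_dna <= 100.0
        ):
            raise CometValidationError(
                f"percent_tail_dna must be in [0, 100], got {self.percent_tail_dna!r}"
            )
        if self.tail_length is not None and self.tail_length < 0:
            raise CometValidationError(
                f"tail_length must be >= 0, got {self.tail_length!r}"
            )
        if self.percent_tail_dna is not None and self.tail_length is not None:
            expected = self.percent_tail_dna * self.tail_length / 100.0
            scale = max(abs(expected), abs(self.tail_moment), 1e-300)
            if abs(self.tail_moment - expected) > _TM_RTOL * scale:
                raise CometValidationError(
                    "tail_moment inconsistent with percent_tail_dna x tail_length"
                    f" / 100: {self.tail_moment!r} vs {expected!r}"
                )


@dataclass(frozen=True)
class ConditionSummary:
    """Mean tail moment +/- SE for one condition at a given aggregation level.

    ``level`` is one of ``gel`` (nucleoids of one gel), ``experiment``
    (nucleoids of one experiment's gels pooled) or ``study`` (mean of
    experiment means; ``n`` is then the number of independent experiments).
    """

    strain: str
    dose: float
    extract: str
    level: str
    mean_tm: float
    se_tm: float
    n: int

    def __post_init__(self) -> None:
        if self.level not in ("gel", "experiment", "study"):
            raise CometValidationError(f"unknown level {self.level!r}")
        if self.n < 1:
            raise CometValidationError("n must be >= 1")
        if not np.isnan(self.se_tm) and self.se_tm < 0:
            raise CometValidationError("se_tm must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """Replication structure and extract protein content of a comet study."""

    strains: tuple[str, ...] = DEFAULT_STRAINS
    doses: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0)
    extracts: tuple[str, ...] = ("none",)
    n_experiments: int = 3
    n_gels_per_condition: int = 2
    n_nucleoids_per_gel: int = 50
    protein_conc: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_experiments", "n_gels_per_condition", "n_nucleoids_per_gel"):
            if getattr(self, name) < 1:
                raise CometValidationError(f"{name} must be >= 1")
        for k, v in self.protein_conc.items():
            if v <= 0:
                raise CometValidationError(
                    f"protein concentration for {k!r} must be > 0, got {v!r}"
                )


_RECORD_COLUMNS = [
    "strain",
    "dose",
    "extract",
    "experiment_id",
    "gel_id",
    "percent_tail_dna",
    "tail_length",
    "tail_moment",
    "hedgehog_flag",
]


def _coerce_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "yes", "t")
    if pd.isna(x):
        return False
    return bool(x)


def read_records(
    path: str | Path,
    dialect: str = "csv",
    known_strains: Sequence[str] = DEFAULT_STRAINS,
    known_extracts: Sequence[str] = DEFAULT_EXTRACTS,
) -> pd.DataFrame:
    """Read a per-nucleoid records table from delimited text.

    The table must name at least ``strain``, ``dose`` and either
    ``tail_moment`` or both ``percent_tail_dna`` and ``tail_length`` (the TM
    is then computed per row).  Missing optional columns are defaulted
    (``extract='none'``, ``hedgehog_flag=False``, single gel/experiment).
    Unknown strain or extract labels trigger a warning but pass through;
    non-numeric measurements raise with the offending row number.

    Returns a validated :class:`pandas.DataFrame` with the canonical columns.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'csv' or 'tsv')")
    df = pd.read_csv(path, sep=sep, dtype={"strain": str})
    if "strain" not in df.columns or "dose" not in df.columns:
        raise CometValidationError("records table must have 'strain' and 'dose' columns")

    have_tm = "tail_moment" in df.columns
    have_parts = "percent_tail_dna" in df.columns and "tail_length" in df.columns
    if not have_tm and not have_parts:
        raise CometValidationError(
            "need a 'tail_moment' column or both 'percent_tail_dna' and 'tail_length'"
        )

    for col in ("dose", "percent_tail_dna", "tail_length", "tail_moment"):
        if col in df.columns:
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = numeric.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
                raise CometValidationError(
                    f"non-numeric value in column {col!r} at file row {row}"
                )
            df[col] = numeric

    if "extract" not in df.columns:
        df["extract"] = "none"
    df["extract"] = df["extract"].fillna("none")
    if "gel_id" not in df.columns:
        df["gel_id"] = "g1"
    if "experiment_id" not in df.columns:
        df["experiment_id"] = "e1"
    if "hedgehog_flag" not in df.columns:
        df["hedgehog_flag"] = False
    df["hedgehog_flag"] = df["hedgehog_flag"].map(_coerce_bool)

    if not have_parts:
        df["percent_tail_dna"] = np.nan
        df["tail_length"] = np.nan
    if not have_tm:
        df["tail_moment"] = np.nan
    derive = df["tail_moment"].isna() & df["percent_tail_dna"].notna()
    if derive.any():
        df.loc[derive, "tail_moment"] = (
            df.loc[derive, "percent_tail_dna"] * df.loc[derive, "tail_length"] / 100.0
        )

    df = df[_RECORD_COLUMNS].copy()
    validate_frame(df)

    unknown = sorted(set(df["strain"]) - set(known_strains))
    if unknown:
        warnings.warn(f"unknown strain labels passed through: {unknown}", stacklevel=2)
    unknown = sorted(set(df["extract"]) - set(known_extracts))
    if unknown:
        warnings.warn(f"unknown extract labels passed through: {unknown}", stacklevel=2)
    return df


def validate_frame(df: pd.DataFrame) -> None:
    """Check record-frame invariants, raising with the first offending row."""
    pct = df["percent_tail_dna"]
    bad = (pct.notna() & ((pct < 0) | (pct > 100))) | (df["tail_moment"] < 0)
    bad |= df["tail_length"].notna() & (df["tail_length"] < 0)
    bad |= df["dose"] < 0
    if bad.any():
        idx = bad.idxmax()
        raise CometValidationError(
            f"invalid measurement at row {int(idx) + 2}: "
            f"{df.loc[idx, ['percent_tail_dna', 'tail_length', 'tail_moment', 'dose']].to_dict()}"
        )
    both = df["percent_tail_dna"].notna() & df["tail_length"].notna()
    if both.any():
        expected = df.loc[both, "percent_tail_dna"] * df.loc[both, "tail_length"] / 100.0
        tm = df.loc[both, "tail_moment"]
        scale = np.maximum(np.maximum(expected.abs(), tm.abs()), 1e-300)
        mism = (tm - expected).abs() > _TM_RTOL * scale
        if mism.any():
            idx = mism.idxmax()
            raise CometValidationError(
                f"tail_moment inconsistent with its parts at row {int(idx) + 2}"
            )


def records_to_frame(records: Iterable[CometRecord]) -> pd.DataFrame:
    rows = [
        {
            "strain": r.strain,
            "dose": r.dose,
            "extract": r.extract,
            "experiment_id": r.experiment_id,
            "gel_id": r.gel_id,
            "percent_tail_dna": np.nan if r.percent_tail_dna is None else r.percent_tail_dna,
            "tail_length": np.nan if r.tail_length is None else r.tail_length,
            "tail_moment": r.tail_moment,
            "hedgehog_flag": r.hedgehog_flag,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[CometRecord]:
    out = []
    for _, row in df.iterrows():
        out.append(
            CometRecord(
                strain=row["strain"],
                dose=float(row["dose"]),
                tail_moment=float(row["tail_moment"]),
                percent_tail_dna=None
                if pd.isna(row.get("percent_tail_dna"))
                else float(row["percent_tail_dna"]),
                tail_length=None
                if pd.isna(row.get("tail_length"))
                else float(row["tail_length"]),
                extract=row.get("extract", "none"),
                gel_id=str(row.get("gel_id", "g1")),
                experiment_id=str(row.get("experiment_id", "e1")),
                hedgehog_flag=bool(row.get("hedgehog_flag", False)),
            )
        )
    return out


_SUMMARY_COLUMNS = ["strain", "dose", "extract", "level", "mean_tm", "se_tm", "n"]


def summaries_to_frame(summaries: Iterable[ConditionSummary]) -> pd.DataFrame:
    rows = [
        {
            "strain": s.strain,
            "dose": s.dose,
            "extract": s.extract,
            "level": s.level,
            "mean_tm": s.mean_tm,
            "se_tm": s.se_tm,
            "n": s.n,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)


def write_summaries(summaries: Sequence[ConditionSummary], path: str | Path) -> None:
    """Write condition summaries to CSV; round-trips at 6 significant digits."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("cannot write an empty summary set")
    df = summaries_to_frame(summaries)
    df.to_csv(path, index=False, float_format="%.6g")


def read_summaries(path: str | Path) -> list[ConditionSummary]:
    df = pd.read_csv(path)
    return [
        ConditionSummary(
            strain=row["strain"],
            dose=float(row["dose"]),
            extract=row["extract"],
            level=row["level"],
            mean_tm=float(row["mean_tm"]),
            se_tm=float(row["se_tm"]),
            n=int(row["n"]),
        )
        for _, row in df.iterrows()
    ]
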