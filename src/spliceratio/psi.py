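"""Percent-spliced-in (PSI) quantification from junction read counts.

PSI for a two-isoform event is the junction-ratio estimator
``inc / (inc + exc)``: the fraction of informative (isoform-assignable)
junction reads supporting the inclusion isoform.  For cassette exons the
inclusion isoform is supported by two junctions (upstream and downstream of
the exon) that no single read can span, so when both junction counts are
available they are averaged before the ratio.  A PSI value is only *defined*
when the event has at least ``min_informative`` informative reads in that
sample (default 20); undefined cells are carried as NaN/"NA" throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DataValidationError, InvalidParameterError
from .events import SpliceEvent

DEFAULT_MIN_INFORMATIVE = 20

Counts = Union[float, int, Sequence[float]]

_JUNCTION_COLUMNS = ["sample_id", "event_id", "inclusion_reads", "exclusion_reads"]


@dataclass(frozen=True)
class PsiValue:
    psi: float
    informative_reads: float
    defined: bool


def compute_psi(
    inclusion_reads: Counts,
    exclusion_reads: float,
    event_type: str = "se",
    min_informative: float = DEFAULT_MIN_INFORMATIVE,
) -> PsiValue:
    """PSI for one event in one sample.

    ``inclusion_reads`` may be a single pre-summarised count or, for cassette
    exons, the pair of upstream/downstream inclusion-junction counts, which
    are averaged.  Informative reads = (averaged) inclusion + exclusion.
    """
    if isinstance(inclusion_reads, (Sequence, np.ndarray)) and not isinstance(
        inclusion_reads, (str, bytes)
    ):
        parts = [float(x) for x in inclusion_reads]
        if not parts:
            raise InvalidParameterError("empty inclusion-read vector")
        if any(x < 0 for x in parts):
            raise InvalidParameterError("negative inclusion read count")
        inc = float(np.mean(parts))
    else:
        inc = float(inclusion_reads)
    exc = float(exclusion_reads)
    if inc < 0 or exc < 0:
        raise InvalidParameterError(
            f"read counts must be non-negative (got inc={inc}, exc={exc})"
        )
    informative = inc + exc
    if informative < min_informative or informative == 0:
        return PsiValue(psi=math.nan, informative_reads=informative, defined=False)
    return PsiValue(psi=inc / informative, informative_reads=informative, defined=True)


class PsiMatrix:
    """Samples x events grid of PSI values with informative-read support.

    ``psi`` and ``informative`` are aligned DataFrames indexed by sample_id
    with one column per event_id; undefined cells are NaN in ``psi``.
    """

    def __init__(self, psi: pd.DataFrame, informative: pd.DataFrame):
        if not psi.index.equals(informative.index) or not psi.columns.equals(
            informative.columns
        ):
            raise DataValidationError("psi and informative grids are not aligned")
        self.psi = psi.astype(float)
        self.informative = informative.astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.psi.index)

    @property
    def event_ids(self) -> list[str]:
        return list(self.psi.columns)

    @property
    def defined(self) -> pd.DataFrame:
        return self.psi.notna()

    def value(self, sample_id: str, event_id: str) -> PsiValue:
        p = self.psi.at[sample_id, event_id]
        n = self.informative.at[sample_id, event_id]
        return PsiValue(psi=float(p), informative_reads=float(n), defined=not math.isnan(p))

    # ---- I/O: events as rows, samples as columns, NA for undefined ----

    def to_tsv(self, path, informative_path=None) -> None:
        self.psi.T.to_csv(path, sep="\t", na_rep="NA", index_label="event_id",
                          float_format="%.6g")
        if informative_path is not None:
            self.informative.T.to_csv(
                informative_path, sep="\t", na_rep="NA", index_label="event_id",
                float_format="%.6g",
            )

    @classmethod
    def from_tsv(cls, path, informative_path=None) -> "PsiMatrix":
        psi = pd.read_csv(path, sep="\t", index_col="event_id", na_values="NA").T
        if informative_path is not None:
            informative = pd.read_csv(
                informative_path, sep="\t", index_col="event_id", na_values="NA"
            ).T
        else:
            informative = pd.DataFrame(
                np.nan, index=psi.index, columns=psi.columns
            )
        psi.index.name = "sample_id"
        informative.index.name = "sample_id"
        return cls(psi, informative)


def read_junction_table(path) -> pd.DataFrame:
    """Read and validate a junction-count TSV.

    Errors name the file, 1-based line and column so a corrupt table is
    traceable.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    for col in ("inclusion_reads", "exclusion_reads"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values != values.round()) | (values < 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataValidationError(
                f"{path}: line {i + 2}, column '{col}': "
                f"not a non-negative integer: {df[col].iloc[i]!r}"
            )
        df[col] = values.astype(int)
    return df


def psi_matrix(
    junctions: pd.DataFrame,
    events: Iterable[SpliceEvent],
    min_informative: float = DEFAULT_MIN_INFORMATIVE,
) -> PsiMatrix:
    """Build a PSI matrix from a long junction-count table.

    Each (sample, event) pair may appear at most once; counts for events
    absent from the definitions are an error; (sample, event) pairs absent
    from the table are undefined cells.
    """
    events = list(events)
    if not events:
        raise InvalidParameterError("empty event list")
    known = {e.event_id for e in events}
    junctions = junctions.copy()

    dup = junctions.duplicated(subset=["sample_id", "event_id"])
    if dup.any():
        first = junctions.loc[dup, ["sample_id", "event_id"]].iloc[0]
        raise DataValidationError(
            f"duplicate (sample, event) pair: ({first['sample_id']}, {first['event_id']})"
        )
    unknown = set(junctions["event_id"]) - known
    if unknown:
        raise DataValidationError(
            f"junction counts reference undefined event(s): {sorted(unknown)[:5]}"
        )
    if (junctions[["inclusion_reads", "exclusion_reads"]].to_numpy() < 0).any():
        raise InvalidParameterError("negative read counts in junction table")

    event_order = [e.event_id for e in events]
    sample_order = list(dict.fromkeys(junctions["sample_id"])) if len(junctions) else []

    informative = (
        junctions.assign(n=lambda d: d.inclusion_reads + d.exclusion_reads)
        .pivot(index="sample_id", columns="event_id", values="n")
        .reindex(index=sample_order, columns=event_order)
    )
    inc = (
        junctions.pivot(index="sample_id", columns="event_id", values="inclusion_reads")
        .reindex(index=sample_order, columns=event_order)
        .astype(float)
    )
    psi = inc / informative
    psi = psi.where((informative >= min_informative) & (informative > 0))
    informative = informative.fillna(0.0)
    psi.index.name = "sample_id"
    informative.index.name = "sample_id"
    return PsiMatrix(psi, informative)
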