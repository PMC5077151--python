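"""Splice-event definitions and their tab-separated table format.

An event is a single alternative-splicing unit: a cassette exon (``se``),
competing 5'/3' splice sites (``a5ss``/``a3ss``), mutually exclusive exons
(``mxe``), a retained intron annotated as alternative (``ri``) or constitutive
(``ci``), or a constitutive junction (``cj``).  Coordinates are 0-based
half-open on the plus strand of the named contig.  For the 3' splice-site
analyses, ``start``/``end`` delimit the intron whose acceptor is under study
(the upstream intron of a cassette exon); ``proximal_3ss``/``distal_3ss``
record the competing acceptor coordinates where the event type has them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import DataValidationError

EVENT_TYPES = frozenset({"se", "a5ss", "a3ss", "mxe", "ri", "ci", "cj"})

_EVENT_COLUMNS = [
    "event_id",
    "gene_name",
    "event_type",
    "chrom",
    "start",
    "end",
    "strand",
    "proximal_3ss",
    "distal_3ss",
]


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    gene_name: str
    event_type: str
    chrom: str
    start: int
    end: int
    strand: str
    proximal_3ss: Optional[int] = None
    distal_3ss: Optional[int] = None

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise DataValidationError(
                f"event {self.event_id}: unknown event type {self.event_type!r} "
                f"(expected one of {sorted(EVENT_TYPES)})"
            )
        if not self.start < self.end:
            raise DataValidationError(
                f"event {self.event_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise DataValidationError(
                f"event {self.event_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.event_type == "a3ss":
            if self.proximal_3ss is None or self.distal_3ss is None:
                raise DataValidationError(
                    f"event {self.event_id}: a3ss events need proximal and distal acceptors"
                )
            if self.proximal_3ss == self.distal_3ss:
                raise DataValidationError(
                    f"event {self.event_id}: a3ss acceptor coordinates must differ"
                )

    @property
    def acceptor(self) -> int:
        """Genomic coordinate of the analysed acceptor boundary.

        On '+' this is the intron ``end`` (exclusive boundary, intron ends
        ``...AG``); on '-' it is the intron ``start``.
        """
        return self.end if self.strand == "+" else self.start


def write_event_table(events: Iterable[SpliceEvent], path) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "event_id": e.event_id,
                "gene_name": e.gene_name,
                "event_type": e.event_type,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "strand": e.strand,
                "proximal_3ss": "NA" if e.proximal_3ss is None else e.proximal_3ss,
                "distal_3ss": "NA" if e.distal_3ss is None else e.distal_3ss,
            }
        )
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_event_table(path) -> list[SpliceEvent]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    events = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise DataValidationError(f"{path}: line {line}: bad coordinate: {exc}") from exc

        def _opt(col):
            v = row[col]
            return None if v in ("", "NA") else int(v)

        events.append(
            SpliceEvent(
                event_id=row["event_id"],
                gene_name=row["gene_name"],
                event_type=row["event_type"],
                chrom=row["chrom"],
                start=start,
                end=end,
                strand=row["strand"],
                proximal_3ss=_opt("proximal_3ss"),
                distal_3ss=_opt("distal_3ss"),
            )
        )
    return events
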