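"""S34F splicing-signature calling and 3' splice-site consensus logos.

A query sample's differential-splicing signature is the set of events whose
inclusion changes by at least a threshold (default 10 percentage points,
inclusive) relative to the median PSI of a mutation-free reference cohort.
The 3' splice-site windows of the promoted and repressed event sets are
summarised as position frequency matrices with per-position information
content IC = 2 + sum_b f_b log2 f_b (bits; 2 = invariant position), and the
sample is classified from the -3 position alone: the characteristic mutant
("typical S34F") pattern requires A > T among promoted acceptors and T > C
among repressed ones; anything weaker collapses to "quasi-WT".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError, InvalidParameterError, WindowRejected
from .events import SpliceEvent
from .psi import PsiMatrix
from .synthetic import DEFAULT_WINDOW, revcomp

DELTA_PSI_THRESHOLD = 0.10
_TOL = 1e-9  # float guard so "ten percent or more" is inclusive at exactly 0.10

TYPICAL_S34F = "typical_S34F"
QUASI_WT = "quasi_WT"
UNDETERMINED = "undetermined"


# --------------------------------------------------------------------------
# Delta-PSI calling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DeltaPsiRecord:
    event_id: str
    sample_id: str
    delta_psi: float
    call: str  # promoted | repressed | unaffected


def delta_psi_vs_reference(
    psi: PsiMatrix,
    reference_sample_ids: Sequence[str],
    query_sample_id: str,
    threshold: float = DELTA_PSI_THRESHOLD,
    min_reference_fraction: float = 0.5,
) -> list[DeltaPsiRecord]:
    """Per-event delta-PSI of a query sample against the reference median.

    Events undefined in the query, or defined in fewer than
    ``min_reference_fraction`` of the reference samples, are dropped.
    """
    refs = list(reference_sample_ids)
    if not refs:
        raise InvalidParameterError("empty reference sample set")
    if query_sample_id in refs:
        raise InvalidParameterError(
            f"query sample {query_sample_id!r} is in the reference set"
        )
    ref_psi = psi.psi.loc[refs]
    query = psi.psi.loc[query_sample_id]
    n_def = ref_psi.notna().sum(axis=0)
    keep = (n_def >= min_reference_fraction * len(refs)) & (n_def >= 1) & query.notna()
    median = ref_psi.median(axis=0, skipna=True)
    records = []
    for event_id in psi.event_ids:
        if not keep[event_id]:
            continue
        d = float(query[event_id] - median[event_id])
        if d >= threshold - _TOL:
            call = "promoted"
        elif d <= -threshold + _TOL:
            call = "repressed"
        else:
            call = "unaffected"
        records.append(
            DeltaPsiRecord(
                event_id=event_id, sample_id=query_sample_id, delta_psi=d, call=call
            )
        )
    return records


def records_to_frame(records: Iterable[DeltaPsiRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": r.event_id,
                "sample_id": r.sample_id,
                "delta_psi": r.delta_psi,
                "call": r.call,
            }
            for r in records
        ],
        columns=["event_id", "sample_id", "delta_psi", "call"],
    )


# --------------------------------------------------------------------------
# 3'SS window extraction
# --------------------------------------------------------------------------


def _fetch(sequences: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    seq = sequences[chrom]
    seq = seq if isinstance(seq, str) else str(seq)
    return seq[start:end].upper()


def extract_3ss_window(
    event: SpliceEvent,
    sequences: Mapping[str, str],
    window: tuple = DEFAULT_WINDOW,
) -> str:
    """Strand-corrected acceptor window, restricted to canonical GT-AG introns.

    ``window = (-20, +3)`` yields 20 intronic bases ending in the invariant
    AG followed by 3 exonic bases.  Raises :class:`WindowRejected` when the
    contig is missing, the window exceeds contig bounds, or the intron is not
    GT..AG.
    """
    up, down = window
    if up >= 0 or down < 0:
        raise InvalidParameterError("window must be (negative, non-negative)")
    if event.chrom not in sequences:
        raise WindowRejected(event.event_id, "missing_contig", event.chrom)
    n_intron = -up
    contig_len = len(sequences[event.chrom])
    if event.strand == "+":
        if event.start < 0 or event.end + down > contig_len or event.end - n_intron < event.start:
            raise WindowRejected(event.event_id, "out_of_bounds")
        donor = _fetch(sequences, event.chrom, event.start, event.start + 2)
        acceptor = _fetch(sequences, event.chrom, event.end - 2, event.end)
        if donor != "GT" or acceptor != "AG":
            raise WindowRejected(
                event.event_id, "non_canonical", f"intron {donor}..{acceptor}"
            )
        return _fetch(sequences, event.chrom, event.end - n_intron, event.end + down)
    else:
        if event.end > contig_len or event.start - down < 0 or event.start + n_intron > event.end:
            raise WindowRejected(event.event_id, "out_of_bounds")
        donor = revcomp(_fetch(sequences, event.chrom, event.end - 2, event.end))
        acceptor = revcomp(_fetch(sequences, event.chrom, event.start, event.start + 2))
        if donor != "GT" or acceptor != "AG":
            raise WindowRejected(
                event.event_id, "non_canonical", f"intron {donor}..{acceptor}"
            )
        return revcomp(
            _fetch(sequences, event.chrom, event.start - down, event.start + n_intron)
        )


def collect_windows(
    events: Iterable[SpliceEvent],
    sequences: Mapping[str, str],
    window: tuple = DEFAULT_WINDOW,
) -> tuple[dict[str, str], dict[str, str]]:
    """Extract windows for many events; returns (accepted, rejected-reasons)."""
    accepted: dict[str, str] = {}
    rejected: dict[str, str] = {}
    for event in events:
        try:
            accepted[event.event_id] = extract_3ss_window(event, sequences, window)
        except WindowRejected as exc:
            rejected[event.event_id] = exc.reason
    return accepted, rejected


# --------------------------------------------------------------------------
# Sequence logos
# --------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


def window_positions(window: tuple = DEFAULT_WINDOW) -> list[int]:
    """Position labels relative to the acceptor boundary; no position 0.

    -2/-1 are the invariant AG; +1.. are exonic.
    """
    up, down = window
    return list(range(up, 0)) + list(range(1, down + 1))


@dataclass
class LogoMatrix:
    """Position frequency matrix with per-position information content."""

    frequencies: pd.DataFrame  # index: positions, columns: A C G T
    information_content: pd.Series  # bits, [0, 2]
    n_sequences: int
    counts: pd.DataFrame = field(repr=False, default=None)

    def frequencies_at(self, position: int) -> dict[str, float]:
        return self.frequencies.loc[position].to_dict()

    def to_frame(self) -> pd.DataFrame:
        out = self.frequencies.copy()
        out["IC_bits"] = self.information_content
        out.index.name = "position"
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def build_logo(
    windows: Sequence[str], window: tuple = DEFAULT_WINDOW
) -> LogoMatrix:
    """Position frequencies and information content of equal-length windows.

    Ambiguous bases (anything outside ACGT) are dropped per column with
    renormalisation.  IC = 2 + sum_b f_b log2 f_b with 0*log(0) := 0; no
    small-sample correction is applied.
    """
    windows = [w.upper() for w in windows]
    if not windows:
        raise InvalidParameterError("cannot build a logo from zero sequences")
    positions = window_positions(window)
    length = len(positions)
    if any(len(w) != length for w in windows):
        raise InvalidParameterError(
            f"all windows must have length {length} for window {window}"
        )
    arr = np.array([list(w) for w in windows])
    counts = np.stack([(arr == b).sum(axis=0) for b in _BASES], axis=1).astype(float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = positions[int(np.argmax(totals == 0))]
        raise DataValidationError(
            f"position {bad}: no unambiguous bases to build a logo from"
        )
    freqs = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    freq_df = pd.DataFrame(freqs, index=positions, columns=_BASES)
    counts_df = pd.DataFrame(counts, index=positions, columns=_BASES)
    return LogoMatrix(
        frequencies=freq_df,
        information_content=pd.Series(np.clip(ic, 0.0, 2.0), index=positions),
        n_sequences=len(windows),
        counts=counts_df,
    )


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------


@dataclass
class SignatureCall:
    sample_id: str
    signature_class: str  # typical_S34F | quasi_WT | undetermined
    promoted_minus3: dict[str, float]
    repressed_minus3: dict[str, float]
    score: float


def classify_signature(
    promoted_logo: LogoMatrix,
    repressed_logo: LogoMatrix,
    sample_id: str = "",
    min_sequences: int = 10,
) -> SignatureCall:
    """Two-class call from the -3 composition of promoted/repressed sets.

    typical_S34F requires *both* f_A > f_T among promoted acceptors and
    f_T > f_C among repressed ones; partial patterns collapse to quasi_WT.
    Fewer than ``min_sequences`` windows on either side yields an
    undetermined call.  The score (f_A - f_T)_prom + (f_T - f_C)_rep grades
    how strongly the mutant pattern is expressed.
    """
    for logo in (promoted_logo, repressed_logo):
        if -3 not in logo.frequencies.index:
            raise InvalidParameterError("logo does not cover the -3 position")
    prom = promoted_logo.frequencies_at(-3)
    rep = repressed_logo.frequencies_at(-3)
    score = (prom["A"] - prom["T"]) + (rep["T"] - rep["C"])
    if (
        promoted_logo.n_sequences < min_sequences
        or repressed_logo.n_sequences < min_sequences
    ):
        cls = UNDETERMINED
    elif prom["A"] > prom["T"] and rep["T"] > rep["C"]:
        cls = TYPICAL_S34F
    else:
        cls = QUASI_WT
    return SignatureCall(
        sample_id=sample_id,
        signature_class=cls,
        promoted_minus3=prom,
        repressed_minus3=rep,
        score=score,
    )


def call_sample_signature(
    psi: PsiMatrix,
    reference_sample_ids: Sequence[str],
    query_sample_id: str,
    windows: Mapping[str, str],
    threshold: float = DELTA_PSI_THRESHOLD,
    window: tuple = DEFAULT_WINDOW,
    min_sequences: int = 10,
) -> tuple[SignatureCall, list[DeltaPsiRecord]]:
    """Full per-sample signature: delta-PSI calls -> logos -> class call.

    ``windows`` maps event_id to its accepted acceptor window (see
    :func:`collect_windows`); events without a window are ignored for the
    logos but kept in the delta-PSI records.
    """
    records = delta_psi_vs_reference(
        psi, reference_sample_ids, query_sample_id, threshold=threshold
    )
    promoted = [windows[r.event_id] for r in records
                if r.call == "promoted" and r.event_id in windows]
    repressed = [windows[r.event_id] for r in records
                 if r.call == "repressed" and r.event_id in windows]
    if not promoted or not repressed:
        empty = {b: math.nan for b in _BASES}
        call = SignatureCall(
            sample_id=query_sample_id,
            signature_class=UNDETERMINED,
            promoted_minus3=empty if not promoted else
            build_logo(promoted, window).frequencies_at(-3),
            repressed_minus3=empty if not repressed else
            build_logo(repressed, window).frequencies_at(-3),
            score=math.nan,
        )
        return call, records
    call = classify_signature(
        build_logo(promoted, window),
        build_logo(repressed, window),
        sample_id=query_sample_id,
        min_sequences=min_sequences,
    )
    return call, records


# --------------------------------------------------------------------------
# Signature comparison (overlap + enhancement waterfall)
# --------------------------------------------------------------------------


@dataclass
class SignatureComparison:
    counts: pd.DataFrame  # index: direction; columns: only_a, shared, only_b
    shared: pd.DataFrame  # event_id, direction, delta_a, delta_b, enhancement


def compare_signatures(
    delta_a: Sequence[DeltaPsiRecord], delta_b: Sequence[DeltaPsiRecord]
) -> SignatureComparison:
    """Overlap of two signatures from the same event universe.

    For events called in the same direction in both, the enhancement
    ``delta_b - delta_a`` quantifies how much stronger the change is in B;
    the shared table is sorted by enhancement (waterfall order).
    """
    a = {r.event_id: r for r in delta_a}
    b = {r.event_id: r for r in delta_b}
    if set(a) != set(b):
        raise DataValidationError(
            "signatures derive from different event universes "
            f"({len(set(a) ^ set(b))} events differ)"
        )
    count_rows = []
    shared_rows = []
    for direction in ("promoted", "repressed"):
        ids_a = {e for e, r in a.items() if r.call == direction}
        ids_b = {e for e, r in b.items() if r.call == direction}
        shared_ids = ids_a & ids_b
        count_rows.append(
            {
                "direction": direction,
                "only_a": len(ids_a - ids_b),
                "shared": len(shared_ids),
                "only_b": len(ids_b - ids_a),
            }
        )
        for event_id in shared_ids:
            shared_rows.append(
                {
                    "event_id": event_id,
                    "direction": direction,
                    "delta_a": a[event_id].delta_psi,
                    "delta_b": b[event_id].delta_psi,
                    "enhancement": b[event_id].delta_psi - a[event_id].delta_psi,
                }
            )
    counts = pd.DataFrame(count_rows).set_index("direction")
    shared = pd.DataFrame(
        shared_rows,
        columns=["event_id", "direction", "delta_a", "delta_b", "enhancement"],
    ).sort_values("enhancement", ascending=False, ignore_index=True)
    return SignatureComparison(counts=counts, shared=shared)


# --------------------------------------------------------------------------
# Group comparison tests
# --------------------------------------------------------------------------

_EXACT_LIMIT = 400  # exact U-distribution up to n_a * n_b of 400


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    method: str


def group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "mann_whitney",
) -> GroupTestResult:
    """Two-sided two-group comparison.

    ``mann_whitney`` uses the exact U null distribution when
    n_a * n_b <= 400 (ties tolerated, uncorrected), otherwise the normal
    approximation with tie and continuity correction.  ``student_t`` is the
    classic equal-variance t test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidParameterError("both groups must be non-empty")
    if method == "mann_whitney":
        how = "exact" if len(a) * len(b) <= _EXACT_LIMIT else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=how)
        return GroupTestResult(
            statistic=float(res.statistic),
            p_value=float(min(res.pvalue, 1.0)),
            method=f"mann_whitney[{how}]",
        )
    elif method == "student_t":
        if len(a) < 2 or len(b) < 2:
            raise InvalidParameterError("student_t needs n >= 2 per group")
        res = stats.ttest_ind(a, b, equal_var=True)
        return GroupTestResult(
            statistic=float(res.statistic), p_value=float(res.pvalue), method="student_t"
        )
    raise InvalidParameterError(f"unknown method {method!r}")
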