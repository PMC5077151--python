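"""S34F:WT allelic-ratio estimation and ratio-PSI correlation.

The mutant:wild-type ratio rho of U2AF1 gene products is estimated either
from RNA-seq reads spanning the variant (rho = alt/ref) or from an
allele-sensitive TaqMan qPCR assay (rho from the Ct difference of the
mutant- and wild-type-specific probes at a shared amplification efficiency).
The mutant fraction is f = rho/(1+rho) = alt/(alt+ref).  The qPCR route
optionally unmixes probe cross-reactivity: a mutant-specific probe that
detects the wild-type template ``cross_reactivity_fold``-fold less
efficiently contributes 1/x of the wild-type signal to the raw ratio, which
the linear correction removes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlleleRatio:
    sample_id: str
    alt_reads: float
    ref_reads: float
    rho: float  # S34F:WT ratio; may be math.inf when ref evidence is absent
    mutant_fraction: float  # f in [0, 1]
    source: str  # rnaseq | qpcr


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    included_reference_point: bool
    reason: str = ""


def ratio_from_reads(
    alt_reads: float, ref_reads: float, sample_id: str = ""
) -> AlleleRatio:
    """rho and f from variant-spanning read counts."""
    if alt_reads < 0 or ref_reads < 0:
        raise InvalidParameterError("read counts must be non-negative")
    if alt_reads == 0 and ref_reads == 0:
        raise InvalidParameterError(
            f"sample {sample_id or '<unnamed>'}: no variant-spanning reads, "
            "ratio undefined"
        )
    if ref_reads == 0:
        rho, f = math.inf, 1.0
    else:
        rho = alt_reads / ref_reads
        f = alt_reads / (alt_reads + ref_reads)
    return AlleleRatio(
        sample_id=sample_id,
        alt_reads=float(alt_reads),
        ref_reads=float(ref_reads),
        rho=rho,
        mutant_fraction=f,
        source="rnaseq",
    )


def ratios_from_table(alleles: pd.DataFrame) -> list[AlleleRatio]:
    """Apply :func:`ratio_from_reads` to an allele-count table."""
    return [
        ratio_from_reads(row.alt_reads, row.ref_reads, sample_id=row.sample_id)
        for row in alleles.itertuples()
    ]


def ratios_to_frame(ratios: Sequence[AlleleRatio]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "alt_reads": r.alt_reads,
                "ref_reads": r.ref_reads,
                "rho": r.rho,
                "mutant_fraction": r.mutant_fraction,
                "source": r.source,
            }
            for r in ratios
        ]
    )


def fold_from_ct(delta_ct: float, efficiency: float = 2.0) -> float:
    """Convert a qPCR cycle difference to a fold change: fold = eff**delta_ct.

    With perfect doubling (efficiency 2), 3.5 cycles is an ~11-fold
    difference.
    """
    if not (1.0 < efficiency <= 2.0):
        raise InvalidParameterError("efficiency must be in (1, 2]")
    return float(efficiency**delta_ct)


def ratio_from_qpcr(
    ct_alt: float,
    ct_ref: float,
    efficiency: float = 2.0,
    cross_reactivity_fold: float = math.inf,
    sample_id: str = "",
) -> AlleleRatio:
    """rho from allele-specific Ct values with optional cross-talk correction.

    raw rho = efficiency**(ct_ref - ct_alt).  When the mutant probe detects
    the wild-type template at 1/x efficiency (x = ``cross_reactivity_fold``),
    a pure wild-type sample yields raw = 1/x; the linear unmixing
    ``corrected = max(0, (raw - 1/x) / (1 - 1/x))`` maps that to 0 while
    leaving a pure-mutant raw ratio unchanged at large x.
    """
    if not (math.isfinite(ct_alt) and math.isfinite(ct_ref)):
        raise InvalidParameterError("Ct values must be finite")
    if ct_alt <= 0 or ct_ref <= 0:
        raise InvalidParameterError("Ct values must be positive")
    raw = fold_from_ct(ct_ref - ct_alt, efficiency)
    if math.isinf(cross_reactivity_fold):
        rho = raw
    else:
        if cross_reactivity_fold <= 1:
            raise InvalidParameterError("cross_reactivity_fold must be > 1")
        leak = 1.0 / cross_reactivity_fold
        rho = max(0.0, (raw - leak) / (1.0 - leak))
    f = 1.0 if math.isinf(rho) else rho / (1.0 + rho)
    return AlleleRatio(
        sample_id=sample_id,
        alt_reads=math.nan,
        ref_reads=math.nan,
        rho=rho,
        mutant_fraction=f,
        source="qpcr",
    )


def correlate_ratio_psi(
    ratios: Sequence[AlleleRatio],
    psi_column: pd.Series,
    include_reference_point: bool = False,
    reference_psi_median: Optional[float] = None,
) -> CorrelationResult:
    """Pearson correlation of rho against an event's PSI across samples.

    ``psi_column`` maps sample_id to PSI.  Samples with infinite rho or
    undefined PSI are excluded (with a logged warning for infinite rho).
    With ``include_reference_point`` an extra (rho=0, reference median PSI)
    point — the mutation-free cohort's centre — is appended before computing
    r.
    """
    xs, ys = [], []
    for r in ratios:
        if math.isinf(r.rho):
            logger.warning(
                "sample %s: infinite S34F:WT ratio excluded from correlation",
                r.sample_id,
            )
            continue
        p = psi_column.get(r.sample_id, math.nan)
        if p is None or (isinstance(p, float) and math.isnan(p)):
            continue
        xs.append(r.rho)
        ys.append(float(p))
    if include_reference_point:
        if reference_psi_median is None:
            raise InvalidParameterError(
                "reference_psi_median is required when include_reference_point is set"
            )
        xs.append(0.0)
        ys.append(float(reference_psi_median))
    if len(xs) < 3:
        raise InvalidParameterError(
            f"need >= 3 paired finite observations, got {len(xs)}"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            r=math.nan,
            n=len(xs),
            included_reference_point=include_reference_point,
            reason="zero variance in one variable",
        )
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(
        r=r, n=len(xs), included_reference_point=include_reference_point
    )
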