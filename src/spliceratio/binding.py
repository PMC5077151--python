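"""Equilibrium binding fits and proximal/distal affinity-competition predictions.

Anisotropy titrations of a fluorescein-labelled 3' splice-site RNA with a
U2AF1-containing complex are fit to the two-state ligand-depletion isotherm

    A(P) = a_free + (a_bound - a_free) * FB(P)
    FB   = [(P + R + K_D) - sqrt((P + R + K_D)^2 - 4 P R)] / (2 R)

with free parameters K_D, a_free and a_bound (R is the fixed RNA
concentration; the quadratic form is needed because the labelled RNA is at
finite concentration, not trace dilution).  Replicate apparent association
constants K_A = 1/K_D for mutant vs wild-type complexes are compared by a
Welch t test on log K_A, and the per-site fold changes feed a competition
rule for the direction of the splicing change: a significant gain at the
proximal acceptor (or loss at the distal one) predicts increased proximal
use, and when both sites shift, the net fold change fc_prox/fc_dist decides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InvalidParameterError
from .synthetic import Titration, bound_fraction

ALPHA = 0.05

INCREASED = "increased"
DECREASED = "decreased"
NO_CALL = "no_call"


# --------------------------------------------------------------------------
# Isotherm fitting
# --------------------------------------------------------------------------


@dataclass
class BindingFit:
    """Fitted apparent affinity of one titration series."""

    series_id: str
    kd: float
    a_free: float
    a_bound: float
    kd_sd: float
    residual_norm: float
    converged: bool
    message: str = ""

    @property
    def ka(self) -> float:
        return 1.0 / self.kd


def _model(P, kd, a_free, a_bound, rna_conc):
    return a_free + (a_bound - a_free) * bound_fraction(P, rna_conc, kd)


def fit_titration(t: Titration, n_starts: int = 5) -> BindingFit:
    """Least-squares fit of the ligand-depletion isotherm to one series.

    Start values: endpoints at the observed extremes and K_D seeded both at
    the concentration where the signal crosses its midpoint and at
    ``n_starts`` log-spaced concentrations across the titration range; the
    best-residual solution is kept.  Degenerate data (flat series, no
    anisotropy increase, unidentifiable K_D) yield ``converged=False`` with
    a diagnostic message, never a silent fit.
    """
    P = t.protein_concs
    y = t.anisotropy
    if len(P) < 4:
        raise InvalidParameterError("need at least 4 titration points to fit")
    span = float(y.max() - y.min())
    pos = P[P > 0]
    if len(pos) == 0:
        raise InvalidParameterError("titration has no positive protein concentration")

    seeds = list(np.geomspace(pos.min(), pos.max(), n_starts))
    mid_idx = int(np.argmin(np.abs(y - (y.min() + 0.5 * span))))
    seeds.append(max(float(P[mid_idx]), float(pos.min())))

    best = None
    for kd0 in seeds:
        try:
            popt, pcov = optimize.curve_fit(
                lambda Pv, kd, af, ab: _model(Pv, kd, af, ab, t.rna_conc),
                P,
                y,
                p0=[kd0, float(y.min()), float(y.max())],
                bounds=([1e-12, -1.0, -1.0], [np.inf, 1.0, 1.0]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = float(np.linalg.norm(y - _model(P, *popt, t.rna_conc)))
        if best is None or resid < best[2]:
            best = (popt, pcov, resid)

    if best is None:
        return BindingFit(
            series_id=t.series_id,
            kd=math.nan,
            a_free=math.nan,
            a_bound=math.nan,
            kd_sd=math.nan,
            residual_norm=math.nan,
            converged=False,
            message="optimizer failed from every start value",
        )
    (kd, a_free, a_bound), pcov, resid = best
    kd_sd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.inf
    message = ""
    converged = True
    if not a_bound > a_free:
        converged, message = False, "no anisotropy increase (a_bound <= a_free)"
    elif span == 0:
        converged, message = False, "flat series"
    elif not np.isfinite(kd_sd) or kd_sd > 10.0 * kd:
        converged, message = False, "K_D unidentifiable (unbounded uncertainty)"
    return BindingFit(
        series_id=t.series_id,
        kd=float(kd),
        a_free=float(a_free),
        a_bound=float(a_bound),
        kd_sd=kd_sd,
        residual_norm=resid,
        converged=converged,
        message=message,
    )


def fits_to_frame(fits: Sequence[BindingFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "series_id": f.series_id,
                "kd": f.kd,
                "kd_sd": f.kd_sd,
                "a_free": f.a_free,
                "a_bound": f.a_bound,
                "residual_norm": f.residual_norm,
                "converged": f.converged,
            }
            for f in fits
        ]
    )


# --------------------------------------------------------------------------
# Fold changes and direction prediction
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldChangeResult:
    site_id: str
    fc: float  # K_A(S34F) / K_A(WT)
    t_statistic: float
    p_value: float
    significant: bool


def fold_change(
    wt_fits: Sequence[BindingFit],
    mut_fits: Sequence[BindingFit],
    site_id: str = "",
    alpha: float = ALPHA,
) -> FoldChangeResult:
    """Mutant/wild-type affinity fold change with a Welch t test on log K_A.

    Affinities are ratio-scale quantities, so replicate K_A's are compared on
    the log scale; significance is two-sided at ``alpha`` without multiplicity
    correction.
    """
    if len(wt_fits) < 3 or len(mut_fits) < 3:
        raise InvalidParameterError("need >= 3 replicate fits per protein form")
    if not all(f.converged for f in (*wt_fits, *mut_fits)):
        raise InvalidParameterError("all replicate fits must have converged")
    ka_wt = np.array([f.ka for f in wt_fits])
    ka_mut = np.array([f.ka for f in mut_fits])
    fc = float(ka_mut.mean() / ka_wt.mean())
    res = stats.ttest_ind(np.log(ka_mut), np.log(ka_wt), equal_var=False)
    t_stat, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t_stat):  # zero variance on both sides (identical replicates)
        t_stat, p = 0.0, 1.0
    return FoldChangeResult(
        site_id=site_id, fc=fc, t_statistic=t_stat, p_value=p, significant=p <= alpha
    )


@dataclass(frozen=True)
class CompetitionPrediction:
    event_id: str
    prox: FoldChangeResult
    dist: FoldChangeResult
    predicted: str  # increased | decreased | no_call
    observed: Optional[str]  # increased | decreased | None
    concordant: bool


def predict_direction(prox: FoldChangeResult, dist: FoldChangeResult) -> str:
    """Direction of proximal-isoform change implied by per-site fold changes.

    One significant site: its sign decides (proximal gain -> increased
    proximal use; distal changes act inversely).  Both significant: the net
    fold change fc_prox/fc_dist vs 1 decides.  Neither: no_call.
    """
    if prox.significant and not dist.significant:
        return INCREASED if prox.fc > 1 else DECREASED
    if dist.significant and not prox.significant:
        return DECREASED if dist.fc > 1 else INCREASED
    if prox.significant and dist.significant:
        net = prox.fc / dist.fc
        if net > 1:
            return INCREASED
        if net < 1:
            return DECREASED
        return NO_CALL
    return NO_CALL


def predict_event(
    event_id: str,
    prox: FoldChangeResult,
    dist: FoldChangeResult,
    observed: Optional[str],
) -> CompetitionPrediction:
    predicted = predict_direction(prox, dist)
    concordant = observed is not None and predicted == observed
    return CompetitionPrediction(
        event_id=event_id,
        prox=prox,
        dist=dist,
        predicted=predicted,
        observed=observed,
        concordant=concordant,
    )


@dataclass
class ConcordanceSummary:
    concordant: int
    total: int
    table: pd.DataFrame

    @property
    def fraction(self) -> float:
        return self.concordant / self.total if self.total else math.nan


def concordance(predictions: Sequence[CompetitionPrediction]) -> ConcordanceSummary:
    """Count predictions matching the observed splicing direction.

    Events without an observed direction are excluded from the total;
    ``no_call`` predictions count as discordant.
    """
    rows = []
    n_conc = 0
    total = 0
    for p in predictions:
        if p.observed is None:
            continue
        total += 1
        n_conc += int(p.concordant)
        rows.append(
            {
                "event_id": p.event_id,
                "fc_prox": p.prox.fc,
                "prox_significant": p.prox.significant,
                "fc_dist": p.dist.fc,
                "dist_significant": p.dist.significant,
                "predicted": p.predicted,
                "observed": p.observed,
                "concordant": p.concordant,
            }
        )
    return ConcordanceSummary(
        concordant=n_conc, total=total, table=pd.DataFrame(rows)
    )


# --------------------------------------------------------------------------
# Characterized S34F-responsive events
# --------------------------------------------------------------------------

# Seven splice events whose proximal/distal 3'SS affinities for mutant vs
# wild-type U2AF1 complexes have been measured in vitro, encoded as
# qualitative directions with nominal magnitudes (only direction and
# significance enter the prediction rule).  The skipped cassette exons of
# DEK, CEP164 and the 5'-extended exon of FMR1 lose proximal affinity; the
# promoted ZFAND1/FXR1 exons gain it; ATR loses affinity at both sites but
# more at the distal one (a net proximal gain); MED15's proximal site loses
# affinity even though its exon is promoted — the one event a pure affinity
# model does not explain.
_SIG_P, _NS_P = 0.01, 0.5


def _fc(site_id: str, fc: float, p: float) -> FoldChangeResult:
    t = 0.0 if fc == 1.0 else math.copysign(3.0, math.log(fc))
    return FoldChangeResult(
        site_id=site_id, fc=fc, t_statistic=t, p_value=p, significant=p <= ALPHA
    )


CHARACTERIZED_SPLICE_EVENTS: list[dict] = [
    {"event_id": "DEK", "fc_prox": 0.5, "p_prox": _SIG_P,
     "fc_dist": 1.0, "p_dist": _NS_P, "observed": DECREASED},
    {"event_id": "CEP164", "fc_prox": 0.5, "p_prox": _SIG_P,
     "fc_dist": 1.0, "p_dist": _NS_P, "observed": DECREASED},
    {"event_id": "FMR1", "fc_prox": 0.5, "p_prox": _SIG_P,
     "fc_dist": 1.0, "p_dist": _NS_P, "observed": DECREASED},
    {"event_id": "ZFAND1", "fc_prox": 2.0, "p_prox": _SIG_P,
     "fc_dist": 1.0, "p_dist": _NS_P, "observed": INCREASED},
    {"event_id": "FXR1", "fc_prox": 2.0, "p_prox": _SIG_P,
     "fc_dist": 1.0, "p_dist": _NS_P, "observed": INCREASED},
    {"event_id": "ATR", "fc_prox": 0.6, "p_prox": _SIG_P,
     "fc_dist": 0.3, "p_dist": _SIG_P, "observed": INCREASED},
    {"event_id": "MED15", "fc_prox": 0.5, "p_prox": _SIG_P,
     "fc_dist": 1.0, "p_dist": _NS_P, "observed": INCREASED},
]


def characterized_event_predictions() -> list[CompetitionPrediction]:
    """Apply the competition rule to the characterized event panel."""
    out = []
    for e in CHARACTERIZED_SPLICE_EVENTS:
        prox = _fc(f"{e['event_id']}:prox", e["fc_prox"], e["p_prox"])
        dist = _fc(f"{e['event_id']}:dist", e["fc_dist"], e["p_dist"])
        out.append(predict_event(e["event_id"], prox, dist, e["observed"]))
    return out
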