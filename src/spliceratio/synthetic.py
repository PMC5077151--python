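"""Synthetic cohorts, junction/allele counts, and binding titrations.

The generator embodies a competition model of 3' splice-site choice: within a
single pre-mRNA, a proximal and a distal acceptor compete for U2AF-dependent
recognition, and the mutant (S34F) and wild-type forms of U2AF1 bind each
site with different apparent association constants K_A.  With mutant fraction
``f = rho / (1 + rho)`` (``rho`` = S34F:WT gene-product ratio) and total U2AF1
held constant across samples, the proximal site's share of recognition — and
hence the inclusion fraction PSI of the proximal isoform — is the linear
mixture

    PSI = [f*KAm_p + (1-f)*KAw_p] / ([f*KAm_p + (1-f)*KAw_p]
                                     + [f*KAm_d + (1-f)*KAw_d])

This mixture form is one admissible dose-response choice (the simplest one
consistent with ratio-controlled splicing); it is a modelling decision of this
package, not an experimentally measured curve.

Counts are sampled binomially around the model PSI (junction reads) and the
mutant fraction (variant-spanning allele reads); titration series add
homoscedastic Gaussian noise to a two-state ligand-depletion isotherm.  All
randomness flows from explicit integer seeds; there is no global random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import InvalidParameterError
from .events import SpliceEvent

# -3 nucleotide composition of canonical GT-AG acceptors (CAG > TAG > AAG > GAG).
BACKGROUND_MINUS3 = {"C": 0.57, "T": 0.27, "A": 0.11, "G": 0.05}

# Fold change in the mutant complex's proximal-site K_A by -3 base: the mutant
# gains a few-fold affinity at CAG/AAG acceptors and loses most at TAG ones.
DEFAULT_MUTANT_EFFECT = {"C": 3.0, "A": 3.0, "T": 0.2, "G": 1.0}

DEFAULT_WINDOW = (-20, 3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimEvent:
    """Ground-truth parameters of one simulated splice event.

    ``ka_*`` are apparent association constants (arbitrary reciprocal-
    concentration units) of the wild-type/mutant U2AF1 complex for the
    proximal/distal acceptor; ``sequence_window`` is the strand-corrected
    acceptor window (default -20..+3, ending ``...AG`` + 3 exonic bases).
    """

    event_id: str
    minus3_base: str
    ka_wt_prox: float
    ka_wt_dist: float
    ka_mut_prox: float
    ka_mut_dist: float
    sequence_window: str

    def __post_init__(self):
        for name in ("ka_wt_prox", "ka_wt_dist", "ka_mut_prox", "ka_mut_dist"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(
                    f"event {self.event_id}: {name} must be strictly positive"
                )
        if self.minus3_base not in "ACGT":
            raise InvalidParameterError(
                f"event {self.event_id}: minus3_base must be one of A/C/G/T"
            )
        intronic = self.sequence_window[: len(self.sequence_window) - 3]
        if not intronic.endswith("AG"):
            raise InvalidParameterError(
                f"event {self.event_id}: sequence window must end in 'AG' at the "
                f"splice-site boundary"
            )


@dataclass
class SimCohortConfig:
    """Study conditions for a simulated cohort.

    Defaults emulate the tumor-cohort setting the analysis targets: a
    minority of mutant samples whose S34F:WT ratios span 0.26-0.82, junction
    depth of a couple hundred informative reads per event, and ~100
    variant-spanning reads per sample.
    """

    noise_seed: int
    n_wt_samples: int = 30
    n_mut_samples: int = 13
    ratio_per_mut_sample: Optional[Sequence[float]] = None
    read_depth_per_event: float = 200.0
    allele_depth: int = 100
    biological_sd: float = 0.2  # sample-level jitter, logit(PSI) scale

    def __post_init__(self):
        if self.ratio_per_mut_sample is None:
            self.ratio_per_mut_sample = (
                list(np.linspace(0.26, 0.82, self.n_mut_samples))
                if self.n_mut_samples
                else []
            )
        self.ratio_per_mut_sample = [float(r) for r in self.ratio_per_mut_sample]
        if len(self.ratio_per_mut_sample) != self.n_mut_samples:
            raise InvalidParameterError(
                "ratio_per_mut_sample length must equal n_mut_samples"
            )
        if any(r < 0 for r in self.ratio_per_mut_sample):
            raise InvalidParameterError("S34F:WT ratios must be >= 0")
        if self.read_depth_per_event < 0 or self.allele_depth < 0:
            raise InvalidParameterError("depths must be >= 0")
        if self.biological_sd < 0:
            raise InvalidParameterError("biological_sd must be >= 0")


@dataclass
class SimTruth:
    """Ground truth written alongside simulated tables for recovery tests."""

    psi: pd.DataFrame  # samples x events, the per-sample jittered true PSI
    rho: pd.Series  # per sample
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "samples": list(self.psi.index),
            "event_ids": list(self.psi.columns),
            "psi": np.round(self.psi.to_numpy(), 6).tolist(),
            "rho": [float(r) for r in self.rho],
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        psi = pd.DataFrame(
            payload["psi"], index=payload["samples"], columns=payload["event_ids"]
        )
        psi.index.name = "sample_id"
        rho = pd.Series(payload["rho"], index=payload["samples"], name="rho")
        return cls(psi=psi, rho=rho, config=payload.get("config", {}))


@dataclass
class CohortData:
    junctions: pd.DataFrame
    alleles: pd.DataFrame
    truth: SimTruth


@dataclass
class Titration:
    """One anisotropy titration series at fixed labelled-RNA concentration."""

    series_id: str
    rna_conc: float
    protein_concs: np.ndarray
    anisotropy: np.ndarray
    replicate_id: str = ""

    def __post_init__(self):
        self.protein_concs = np.asarray(self.protein_concs, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.rna_conc <= 0:
            raise InvalidParameterError("rna_conc must be > 0")
        if len(self.protein_concs) != len(self.anisotropy):
            raise InvalidParameterError("protein and anisotropy vectors differ in length")
        if (self.protein_concs < 0).any():
            raise InvalidParameterError("protein concentrations must be >= 0")
        if (np.diff(self.protein_concs) < 0).any():
            raise InvalidParameterError("protein concentrations must be sorted ascending")


# --------------------------------------------------------------------------
# Occupancy model
# --------------------------------------------------------------------------


def mutant_fraction(rho: float) -> float:
    """f = rho / (1 + rho); rho may be numpy.inf (pure mutant, f = 1)."""
    if rho < 0:
        raise InvalidParameterError("S34F:WT ratio must be >= 0")
    if np.isinf(rho):
        return 1.0
    return rho / (1.0 + rho)


def occupancy_psi(event: SimEvent, rho: float) -> float:
    """Model PSI of the proximal isoform at S34F:WT ratio ``rho``."""
    f = mutant_fraction(rho)
    prox = f * event.ka_mut_prox + (1.0 - f) * event.ka_wt_prox
    dist = f * event.ka_mut_dist + (1.0 - f) * event.ka_wt_dist
    return prox / (prox + dist)


def _occupancy_psi_vec(events: Sequence[SimEvent], rho: float) -> np.ndarray:
    f = mutant_fraction(rho)
    kawp = np.array([e.ka_wt_prox for e in events])
    kawd = np.array([e.ka_wt_dist for e in events])
    kamp = np.array([e.ka_mut_prox for e in events])
    kamd = np.array([e.ka_mut_dist for e in events])
    prox = f * kamp + (1 - f) * kawp
    dist = f * kamd + (1 - f) * kawd
    return prox / (prox + dist)


# --------------------------------------------------------------------------
# Event panel with toy genome
# --------------------------------------------------------------------------


@dataclass
class EventPanel:
    sim_events: list[SimEvent]
    splice_events: list[SpliceEvent]
    genome: dict[str, str]


def _random_bases(rng, n, probs=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=list(probs)))


def make_event_panel(
    n_events: int = 2000,
    seed: int = 0,
    responsive_fraction: float = 0.2,
    background_minus3: dict = None,
    mutant_effect: dict = None,
    baseline_log_sd: float = 0.4,
    window: tuple = DEFAULT_WINDOW,
) -> EventPanel:
    """Build a cassette-exon event panel with a one-contig-per-event toy genome.

    A ``responsive_fraction`` of events respond to the mutant: their proximal
    K_A is scaled by ``mutant_effect[minus3_base]`` for the mutant complex.
    The rest bind both forms identically (their PSI varies only stochastically).
    Wild-type K_A's are log-normal around 1 so baseline inclusion spreads
    around 0.5.  Each contig is exon(30) - GT..intron..AG(40) - exon(30); half
    the events are placed on the minus strand.
    """
    if n_events <= 0:
        raise InvalidParameterError("n_events must be positive")
    background_minus3 = dict(background_minus3 or BACKGROUND_MINUS3)
    mutant_effect = dict(mutant_effect or DEFAULT_MUTANT_EFFECT)
    up, down = window
    intron_window = -up  # bases of intron in the window, ends with AG
    if intron_window < 5 or down < 0:
        raise InvalidParameterError("window must cover the acceptor AG and -3 position")

    rng = np.random.default_rng(seed)
    bases = list(background_minus3)
    probs = np.array([background_minus3[b] for b in bases], dtype=float)
    probs = probs / probs.sum()

    sim_events, splice_events, genome = [], [], {}
    intron_comp = (0.15, 0.30, 0.15, 0.40)  # A C G T: pyrimidine-rich tract
    for i in range(n_events):
        event_id = f"EV{i:05d}"
        minus3 = str(rng.choice(bases, p=probs))
        responsive = rng.random() < responsive_fraction
        ka_wt_prox = float(np.exp(rng.normal(0.0, baseline_log_sd)))
        ka_wt_dist = float(np.exp(rng.normal(0.0, baseline_log_sd)))
        effect = mutant_effect.get(minus3, 1.0) if responsive else 1.0
        ka_mut_prox = ka_wt_prox * effect
        ka_mut_dist = ka_wt_dist

        # window: intronic (ends [-3]AG) then exonic bases
        tract = "".join(
            rng.choice(list("ACGT"), size=intron_window - 3, p=intron_comp)
        )
        exonic = _random_bases(rng, down)
        window_seq = tract + minus3 + "AG" + exonic

        # plus-strand contig layout: exon(30) + intron(40) + exon(30)
        filler = "".join(
            rng.choice(list("ACGT"), size=40 - 2 - intron_window, p=intron_comp)
        )
        intron = "GT" + filler + window_seq[:intron_window]
        contig = _random_bases(rng, 30 - 0) + intron + exonic + _random_bases(rng, 30 - down)
        start, end = 30, 70
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            contig = revcomp(contig)
            start, end = len(contig) - 70, len(contig) - 30

        genome[event_id] = contig
        sim_events.append(
            SimEvent(
                event_id=event_id,
                minus3_base=minus3,
                ka_wt_prox=ka_wt_prox,
                ka_wt_dist=ka_wt_dist,
                ka_mut_prox=ka_mut_prox,
                ka_mut_dist=ka_mut_dist,
                sequence_window=window_seq,
            )
        )
        splice_events.append(
            SpliceEvent(
                event_id=event_id,
                gene_name=f"GENE{i:05d}",
                event_type="se",
                chrom=event_id,
                start=start,
                end=end,
                strand=strand,
                proximal_3ss=end if strand == "+" else start,
            )
        )
    return EventPanel(sim_events=sim_events, splice_events=splice_events, genome=genome)


def write_genome_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for j in range(0, len(seq), width):
                fh.write(seq[j : j + width] + "\n")


def read_genome_fasta(path) -> dict[str, str]:
    genome: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line.upper())
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------


def simulate_cohort(events: Sequence[SimEvent], config: SimCohortConfig) -> CohortData:
    """Sample junction and allele read counts for a cohort.

    Per sample, the true PSI of each event is the occupancy-model PSI at the
    sample's rho, jittered on the logit scale by ``biological_sd`` (sample-to-
    sample biological variability around the dose-response).  Junction depth
    is Poisson around ``read_depth_per_event``; inclusion reads are binomial
    at the true PSI.  Mutant samples' alt allele reads are binomial at the
    mutant fraction f; wild-type samples have f = 0.
    """
    events = list(events)
    if not events:
        raise InvalidParameterError("empty event list")
    rng = np.random.default_rng(config.noise_seed)
    event_ids = [e.event_id for e in events]

    sample_ids = [f"WT_{i + 1:03d}" for i in range(config.n_wt_samples)] + [
        f"MUT_{i + 1:03d}" for i in range(config.n_mut_samples)
    ]
    rhos = [0.0] * config.n_wt_samples + list(config.ratio_per_mut_sample)

    junction_rows = []
    allele_rows = []
    truth_psi = np.empty((len(sample_ids), len(events)))
    for s, (sample_id, rho) in enumerate(zip(sample_ids, rhos)):
        psi = _occupancy_psi_vec(events, rho)
        if config.biological_sd > 0:
            jitter = rng.normal(0.0, config.biological_sd, size=len(events))
            psi = expit(logit(np.clip(psi, 1e-12, 1 - 1e-12)) + jitter)
        truth_psi[s] = psi
        depth = rng.poisson(config.read_depth_per_event, size=len(events))
        inc = rng.binomial(depth, psi)
        exc = depth - inc
        junction_rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "event_id": event_ids,
                    "inclusion_reads": inc,
                    "exclusion_reads": exc,
                }
            )
        )
        f = mutant_fraction(rho)
        alt = int(rng.binomial(config.allele_depth, f)) if f > 0 else 0
        allele_rows.append(
            {
                "sample_id": sample_id,
                "alt_reads": alt,
                "ref_reads": config.allele_depth - alt,
            }
        )

    junctions = pd.concat(junction_rows, ignore_index=True)
    alleles = pd.DataFrame(allele_rows, columns=["sample_id", "alt_reads", "ref_reads"])
    psi_df = pd.DataFrame(truth_psi, index=sample_ids, columns=event_ids)
    psi_df.index.name = "sample_id"
    truth = SimTruth(
        psi=psi_df,
        rho=pd.Series(rhos, index=sample_ids, name="rho"),
        config={
            "noise_seed": config.noise_seed,
            "n_wt_samples": config.n_wt_samples,
            "n_mut_samples": config.n_mut_samples,
            "ratio_per_mut_sample": config.ratio_per_mut_sample,
            "read_depth_per_event": config.read_depth_per_event,
            "allele_depth": config.allele_depth,
            "biological_sd": config.biological_sd,
        },
    )
    return CohortData(junctions=junctions, alleles=alleles, truth=truth)


def write_junction_tsv(junctions: pd.DataFrame, path) -> None:
    junctions.to_csv(path, sep="\t", index=False)


def write_allele_tsv(alleles: pd.DataFrame, path) -> None:
    alleles.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Titration simulation
# --------------------------------------------------------------------------


def bound_fraction(protein_conc, rna_conc: float, kd: float):
    """Two-state ligand-depletion isotherm (quadratic solution).

    FB = [(P + R + K_D) - sqrt((P + R + K_D)^2 - 4 P R)] / (2 R); reduces to
    the hyperbola P / (P + K_D) when R << K_D.
    """
    P = np.asarray(protein_conc, dtype=float)
    s = P + rna_conc + kd
    disc = np.maximum(s * s - 4.0 * P * rna_conc, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * rna_conc)


def simulate_titration(
    kd: float,
    rna_conc: float,
    protein_concs: Sequence[float],
    a_free: float = 0.06,
    a_bound: float = 0.18,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    series_id: str = "sim",
    replicate_id: str = "",
) -> Titration:
    """Simulate one anisotropy series from the ligand-depletion isotherm."""
    if kd <= 0 or rna_conc <= 0:
        raise InvalidParameterError("kd and rna_conc must be > 0")
    if a_bound <= a_free:
        raise InvalidParameterError(
            "a_bound must exceed a_free: anisotropy increases on binding"
        )
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if noise_sd > 0 and seed is None:
        raise InvalidParameterError("a seed is required when noise_sd > 0")
    P = np.asarray(protein_concs, dtype=float)
    fb = bound_fraction(P, rna_conc, kd)
    y = a_free + (a_bound - a_free) * fb
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(P))
    return Titration(
        series_id=series_id,
        rna_conc=rna_conc,
        protein_concs=P,
        anisotropy=y,
        replicate_id=replicate_id,
    )


def write_titration_csv(titrations: Sequence[Titration], path) -> None:
    rows = []
    for t in titrations:
        for p, a in zip(t.protein_concs, t.anisotropy):
            rows.append(
                {
                    "series_id": t.series_id,
                    "replicate_id": t.replicate_id,
                    "rna_conc": t.rna_conc,
                    "protein_conc": p,
                    "anisotropy": round(float(a), 8),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_titration_csv(path) -> list[Titration]:
    df = pd.read_csv(path)
    titrations = []
    for (series_id, replicate_id), grp in df.groupby(
        ["series_id", "replicate_id"], sort=False, dropna=False
    ):
        grp = grp.sort_values("protein_conc")
        titrations.append(
            Titration(
                series_id=str(series_id),
                rna_conc=float(grp["rna_conc"].iloc[0]),
                protein_concs=grp["protein_conc"].to_numpy(),
                anisotropy=grp["anisotropy"].to_numpy(),
                replicate_id="" if pd.isna(replicate_id) else str(replicate_id),
            )
        )
    return titrations
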