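"""Declarative pipeline: simulate -> psi -> signature -> ratio/correlate -> binding -> predict.

A run is described by a YAML config (stage list plus per-stage parameters);
every stage reads/writes plain-text TSV/CSV/JSON under one output directory
and appends an entry to ``manifest.json`` (inputs, outputs, parameters, a
config digest and the package version — no timestamps, so reruns with the
same config and seeds are byte-identical).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import alleles as alleles_mod
from . import binding as binding_mod
from . import signature as signature_mod
from . import synthetic
from .errors import DataValidationError, StageError
from .events import read_event_table, write_event_table
from .psi import DEFAULT_MIN_INFORMATIVE, PsiMatrix, psi_matrix, read_junction_table

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "psi", "signature", "ratio", "correlate", "binding", "predict"]


@dataclass
class RunConfig:
    outdir: str = "out"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGE_ORDER))
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        stages = raw.pop("stages", list(STAGE_ORDER))
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise DataValidationError(f"{path}: unknown stage(s) {unknown}")
        return cls(
            outdir=raw.pop("outdir", "out"),
            seed=int(raw.pop("seed", 0)),
            stages=stages,
            params=raw,
        )

    def stage_params(self, stage: str) -> dict:
        return dict(self.params.get(stage) or {})

    def digest(self) -> str:
        # outdir excluded: a rerun of the same analysis into another directory
        # is the same run
        blob = json.dumps(
            {"seed": self.seed, "stages": self.stages, "params": self.params},
            sort_keys=True, default=str,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _rel(out: Path, path: Path) -> str:
    """Record paths relative to the run directory when they live under it."""
    try:
        return str(Path(path).relative_to(out))
    except ValueError:
        return str(path)


# --------------------------------------------------------------------------
# Stage implementations
# --------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    p = cfg.stage_params("simulate")
    panel = synthetic.make_event_panel(
        n_events=int(p.get("n_events", 2000)),
        seed=cfg.seed,
        responsive_fraction=float(p.get("responsive_fraction", 0.2)),
    )
    sim_cfg = synthetic.SimCohortConfig(
        noise_seed=cfg.seed + 1,
        n_wt_samples=int(p.get("n_wt_samples", 30)),
        n_mut_samples=int(p.get("n_mut_samples", 13)),
        ratio_per_mut_sample=p.get("ratios"),
        read_depth_per_event=float(p.get("read_depth", 200.0)),
        allele_depth=int(p.get("allele_depth", 100)),
        biological_sd=float(p.get("biological_sd", 0.2)),
    )
    cohort = synthetic.simulate_cohort(panel.sim_events, sim_cfg)

    write_event_table(panel.splice_events, out / "events.tsv")
    synthetic.write_genome_fasta(panel.genome, out / "genome.fa")
    synthetic.write_junction_tsv(cohort.junctions, out / "junctions.tsv")
    synthetic.write_allele_tsv(cohort.alleles, out / "alleles.tsv")
    cohort.truth.to_json(out / "truth.json")

    # demo titration panel: wt/mut x prox/dist triplicates for two events
    titrations = []
    rng_seed = cfg.seed + 1000
    responsive = next(
        (e for e in panel.sim_events if e.ka_mut_prox != e.ka_wt_prox), None
    )
    neutral = next(
        (e for e in panel.sim_events if e.ka_mut_prox == e.ka_wt_prox), None
    )
    chosen = [e for e in (responsive, neutral) if e is not None]
    for e in chosen:
        for form, ka_p, ka_d in (
            ("wt", e.ka_wt_prox, e.ka_wt_dist),
            ("mut", e.ka_mut_prox, e.ka_mut_dist),
        ):
            for site, ka in (("prox", ka_p), ("dist", ka_d)):
                kd = 1.0 / ka
                concs = np.geomspace(0.01 * kd, 100 * kd, 12)
                for rep in range(3):
                    rng_seed += 1
                    titrations.append(
                        synthetic.simulate_titration(
                            kd=kd,
                            rna_conc=0.1 * kd,
                            protein_concs=concs,
                            noise_sd=0.0024,  # 2% of the 0.12 dynamic range
                            seed=rng_seed,
                            series_id=f"{e.event_id}:{site}:{form}",
                            replicate_id=f"rep{rep + 1}",
                        )
                    )
    synthetic.write_titration_csv(titrations, out / "titrations.csv")
    return {
        "inputs": [],
        "outputs": ["events.tsv", "genome.fa", "junctions.tsv", "alleles.tsv",
                    "truth.json", "titrations.csv"],
        "params": {**p, "seed": cfg.seed},
    }


def _stage_psi(cfg: RunConfig, out: Path) -> dict:
    p = cfg.stage_params("psi")
    junctions_path = Path(p.get("junctions", out / "junctions.tsv"))
    events_path = Path(p.get("events", out / "events.tsv"))
    min_informative = float(p.get("min_informative", DEFAULT_MIN_INFORMATIVE))
    junctions = read_junction_table(junctions_path)
    events = read_event_table(events_path)
    matrix = psi_matrix(junctions, events, min_informative=min_informative)
    matrix.to_tsv(out / "psi.tsv", informative_path=out / "informative.tsv")
    return {
        "inputs": [_rel(out, junctions_path), _rel(out, events_path)],
        "outputs": ["psi.tsv", "informative.tsv"],
        "params": {"min_informative": min_informative},
    }


def _reference_samples(cfg: RunConfig, out: Path, p: dict) -> list[str]:
    if p.get("reference_samples"):
        return list(p["reference_samples"])
    alleles = pd.read_csv(out / "alleles.tsv", sep="\t")
    return list(alleles.loc[alleles.alt_reads == 0, "sample_id"])


def _stage_signature(cfg: RunConfig, out: Path) -> dict:
    p = cfg.stage_params("signature")
    matrix = PsiMatrix.from_tsv(out / "psi.tsv", out / "informative.tsv")
    events = read_event_table(Path(p.get("events", out / "events.tsv")))
    genome = synthetic.read_genome_fasta(Path(p.get("fasta", out / "genome.fa")))
    threshold = float(p.get("threshold", signature_mod.DELTA_PSI_THRESHOLD))
    min_sequences = int(p.get("min_sequences", 10))
    window = tuple(p.get("window", synthetic.DEFAULT_WINDOW))

    refs = _reference_samples(cfg, out, p)
    queries = p.get("queries") or [s for s in matrix.samples if s not in refs]
    windows, rejected = signature_mod.collect_windows(events, genome, window)
    if rejected:
        logger.info("rejected %d events from logos (non-canonical or out of bounds)",
                    len(rejected))
    calls, all_records = [], []
    for q in queries:
        call, records = signature_mod.call_sample_signature(
            matrix, refs, q, windows,
            threshold=threshold, window=window, min_sequences=min_sequences,
        )
        calls.append(call)
        all_records.extend(records)
    signature_mod.records_to_frame(all_records).to_csv(
        out / "delta_psi.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "class": c.signature_class,
                "score": c.score,
                **{f"promoted_minus3_{b}": c.promoted_minus3[b] for b in "ACGT"},
                **{f"repressed_minus3_{b}": c.repressed_minus3[b] for b in "ACGT"},
            }
            for c in calls
        ]
    ).to_csv(out / "signature_calls.tsv", sep="\t", index=False, float_format="%.6g")
    return {
        "inputs": ["psi.tsv", "events.tsv", "genome.fa"],
        "outputs": ["delta_psi.tsv", "signature_calls.tsv"],
        "params": {"threshold": threshold, "min_sequences": min_sequences,
                   "window": list(window), "reference_samples": refs},
    }


def _stage_ratio(cfg: RunConfig, out: Path) -> dict:
    p = cfg.stage_params("ratio")
    alleles_path = Path(p.get("alleles", out / "alleles.tsv"))
    table = pd.read_csv(alleles_path, sep="\t")
    ratios = alleles_mod.ratios_from_table(table)
    alleles_mod.ratios_to_frame(ratios).to_csv(
        out / "ratios.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return {
        "inputs": [_rel(out, alleles_path)],
        "outputs": ["ratios.tsv"],
        "params": {},
    }


def _stage_correlate(cfg: RunConfig, out: Path) -> dict:
    p = cfg.stage_params("correlate")
    matrix = PsiMatrix.from_tsv(out / "psi.tsv")
    ratios_df = pd.read_csv(out / "ratios.tsv", sep="\t")
    refs = _reference_samples(cfg, out, p)
    mut = ratios_df[~ratios_df.sample_id.isin(refs)]
    ratios = alleles_mod.ratios_from_table(mut)
    event_id = p.get("event")
    if not event_id:
        # default: the strongest signature event (largest |mean delta-PSI|
        # across mutant samples), falling back to the first event
        dpsi_path = out / "delta_psi.tsv"
        if dpsi_path.exists():
            dpsi = pd.read_csv(dpsi_path, sep="\t")
            event_id = dpsi.groupby("event_id").delta_psi.mean().abs().idxmax()
        else:
            event_id = matrix.event_ids[0]
    include_ref = bool(p.get("include_reference_point", False))
    column = matrix.psi[event_id]
    ref_median = float(column.loc[refs].median()) if include_ref else None
    result = alleles_mod.correlate_ratio_psi(
        ratios, column,
        include_reference_point=include_ref, reference_psi_median=ref_median,
    )
    with open(out / "correlation.json", "w") as fh:
        json.dump(
            {"event_id": event_id, "r": result.r, "n": result.n,
             "included_reference_point": result.included_reference_point,
             "reason": result.reason},
            fh, sort_keys=True,
        )
        fh.write("\n")
    return {
        "inputs": ["psi.tsv", "ratios.tsv"],
        "outputs": ["correlation.json"],
        "params": {"event": event_id, "include_reference_point": include_ref},
    }


def _stage_binding(cfg: RunConfig, out: Path) -> dict:
    p = cfg.stage_params("binding")
    titrations_path = Path(p.get("titrations", out / "titrations.csv"))
    titrations = synthetic.read_titration_csv(titrations_path)
    fits = [binding_mod.fit_titration(t) for t in titrations]
    frame = binding_mod.fits_to_frame(fits)
    frame.insert(1, "replicate_id", [t.replicate_id for t in titrations])
    frame.to_csv(out / "fits.tsv", sep="\t", index=False, float_format="%.6g")
    return {
        "inputs": [_rel(out, titrations_path)],
        "outputs": ["fits.tsv"],
        "params": {},
    }


def _stage_predict(cfg: RunConfig, out: Path) -> dict:
    """Fold changes per event x site from replicate fits -> direction calls.

    Series ids follow ``<event>:<site>:<form>``; the observed direction is
    the sign of the mean delta-PSI of that event across mutant samples.
    """
    p = cfg.stage_params("predict")
    fits_df = pd.read_csv(out / "fits.tsv", sep="\t")
    parts = fits_df.series_id.str.split(":", expand=True)
    fits_df["event"], fits_df["site"], fits_df["form"] = parts[0], parts[1], parts[2]

    dpsi = pd.read_csv(out / "delta_psi.tsv", sep="\t")
    mean_dpsi = dpsi.groupby("event_id").delta_psi.mean()

    predictions = []
    for event_id, grp in fits_df.groupby("event"):
        fcs = {}
        for site in ("prox", "dist"):
            wt = grp[(grp.site == site) & (grp.form == "wt")]
            mu = grp[(grp.site == site) & (grp.form == "mut")]
            wt_fits = [
                binding_mod.BindingFit(r.series_id, r.kd, r.a_free, r.a_bound,
                                       r.kd_sd, r.residual_norm, bool(r.converged))
                for r in wt.itertuples()
            ]
            mut_fits = [
                binding_mod.BindingFit(r.series_id, r.kd, r.a_free, r.a_bound,
                                       r.kd_sd, r.residual_norm, bool(r.converged))
                for r in mu.itertuples()
            ]
            fcs[site] = binding_mod.fold_change(
                wt_fits, mut_fits, site_id=f"{event_id}:{site}"
            )
        observed = None
        if event_id in mean_dpsi.index:
            observed = (
                binding_mod.INCREASED if mean_dpsi[event_id] > 0 else binding_mod.DECREASED
            )
        predictions.append(
            binding_mod.predict_event(event_id, fcs["prox"], fcs["dist"], observed)
        )
    summary = binding_mod.concordance(predictions)
    summary.table.to_csv(out / "predictions.tsv", sep="\t", index=False,
                         float_format="%.6g")
    with open(out / "concordance.json", "w") as fh:
        json.dump(
            {"concordant": summary.concordant, "total": summary.total,
             "fraction": summary.fraction if summary.total else None},
            fh, sort_keys=True,
        )
        fh.write("\n")
    return {
        "inputs": ["fits.tsv", "delta_psi.tsv"],
        "outputs": ["predictions.tsv", "concordance.json"],
        "params": p,
    }


_STAGES = {
    "simulate": _stage_simulate,
    "psi": _stage_psi,
    "signature": _stage_signature,
    "ratio": _stage_ratio,
    "correlate": _stage_correlate,
    "binding": _stage_binding,
    "predict": _stage_predict,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in canonical order; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": [],
    }
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        try:
            entry = _STAGES[stage](config, out)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        manifest["stages"].append({"name": stage, **entry})
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
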