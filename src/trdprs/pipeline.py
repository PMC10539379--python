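"""End-to-end orchestration: simulate/load -> classify -> QC -> score -> associate.

A single :class:`RunConfig` carries every stage parameter with the
published analysis values as defaults (120-day gap, 42-day adequacy,
the QC thresholds, K = 0.10, four PCs, six-test FDR).  One global seed
fans out to per-stage child streams by stable derivation, and every
intermediate table is written to the output directory together with a
provenance record sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .assoc import quartile_trend, run_battery
from .genoprs import (
    SampleQcThresholds,
    SnpQcThresholds,
    filter_weights,
    relatedness_prune,
    sample_qc,
    score,
    snp_qc,
)
from .phenotype import DEFINITIONS, PhenotypeParams, build_comparison, classify_all
from .synthdata import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs; the defaults form the reference-analysis profile."""

    out_dir: str = "trdprs_run"
    seed: int = 0
    #: simulate a study (None disables simulation; inputs must then exist)
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    #: real-use input paths: genotypes (PLINK prefix or .vcf), prescriptions,
    #: ect_events, subjects, weights_<trait>
    inputs: dict = field(default_factory=dict)
    phenotype: PhenotypeParams = field(default_factory=PhenotypeParams)
    snp_qc: SnpQcThresholds = field(default_factory=SnpQcThresholds)
    sample_qc: SampleQcThresholds = field(default_factory=SampleQcThresholds)
    pihat_threshold: float = 0.2
    n_pcs: int = 4
    population_K: float = 0.10
    run_relatedness: bool = True
    lithium_sensitivity: bool = True

    def validate(self) -> None:
        if self.simulation is None:
            required = {"genotypes", "prescriptions", "ect_events", "subjects"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(
                    f"simulation disabled and inputs missing: {sorted(missing)}"
                )
            if not any(k.startswith("weights_") for k in self.inputs):
                raise ValueError("simulation disabled and no weights_<trait> inputs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "simulation" in kwargs:
            sim = kwargs["simulation"]
            kwargs["simulation"] = (
                None if sim is None else SimulationConfig(
                    **{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()}
                )
            )
        for key, klass in (
            ("phenotype", PhenotypeParams),
            ("snp_qc", SnpQcThresholds),
            ("sample_qc", SampleQcThresholds),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)


def compute_pcs(G, n_pcs: int = 4) -> pd.DataFrame:
    """Top principal components of the standardized dosage matrix.

    Variants are centered at 2p and scaled by sqrt(2p(1-p)); missing
    entries contribute zero after centering.  Component signs follow a
    fixed convention (largest-|loading| entry positive) so reruns are
    bit-identical.
    """
    p = G.allele_frequency()
    ok = (p > 0) & (p < 1) & ~np.isnan(p)
    X = G.dosages[:, ok]
    p = p[ok]
    Z = np.nan_to_num((X - 2 * p) / np.sqrt(2 * p * (1 - p)), nan=0.0)
    k = min(n_pcs, min(Z.shape) - 1)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    pcs = u[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            pcs[:, j] *= -1
    return pd.DataFrame(
        pcs, columns=[f"PC{i + 1}" for i in range(k)]
    ).assign(subject_id=G.subjects)[["subject_id"] + [f"PC{i + 1}" for i in range(k)]]


def _load_inputs(config: RunConfig):
    paths = config.inputs
    gpath = str(paths["genotypes"])
    if gpath.endswith(".vcf") or gpath.endswith(".vcf.gz"):
        G = tio.read_vcf(gpath)
    else:
        G = tio.read_plink(gpath)
    weights = {
        k.removeprefix("weights_"): tio.read_weight_table(v)
        for k, v in paths.items()
        if k.startswith("weights_")
    }
    subjects = pd.read_csv(paths["subjects"], dtype={"subject_id": str})
    return (
        subjects,
        tio.read_prescriptions(paths["prescriptions"]),
        tio.read_ect_events(paths["ect_events"]),
        G,
        weights,
    )


def run(config: RunConfig) -> dict:
    """Execute every stage; returns the results bundle.

    The bundle maps stage names to their in-memory outputs; everything
    is also written under ``config.out_dir`` (classifications, QC
    reports, PCs, scores, the association table, provenance).
    """
    config.validate()
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"seed": config.seed, "stages": {}}

    # -- stage 1: obtain the study ------------------------------------
    if config.simulation is not None:
        sim = replace(config.simulation, seed=config.seed)
        study = simulate_study(sim)
        subjects, prescriptions, ect = study.subjects, study.prescriptions, study.ect_events
        G, weights = study.genotypes, study.weights
        study.truth.to_csv(out / "truth.csv", index=False, float_format="%.10g")
        provenance["simulation"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(sim).items()
        }
    else:
        subjects, prescriptions, ect, G, weights = _load_inputs(config)
    provenance["stages"]["input"] = {
        "n_subjects": int(len(subjects)),
        "n_prescriptions": int(len(prescriptions)),
        "n_ect_events": int(len(ect)),
        "n_variants": int(G.n_variants),
        "traits": sorted(weights),
    }

    # -- stage 2: phenotype classification ----------------------------
    try:
        classifications = classify_all(subjects, prescriptions, ect, config.phenotype)
    except Exception as err:
        raise RuntimeError(f"stage 'classify' failed: {err}") from err
    classifications.to_csv(out / "classifications.csv", index=False)
    provenance["stages"]["classify"] = {
        f"cases_{d}": int((classifications[f"label_{d}"] == "TRD").sum())
        for d in DEFINITIONS
    }

    # -- stage 3: genotype & sample QC --------------------------------
    meta = subjects.set_index("subject_id").loc[G.subjects]
    broad_status = (
        classifications.set_index("subject_id")
        .loc[G.subjects, "label_broad"]
        .eq("TRD")
        .to_numpy()
        .astype(int)
    )
    qc_reports = {}
    try:
        rep_snp = snp_qc(G, broad_status, config.snp_qc)
        G = G.take_variants(rep_snp.retained_mask)
        qc_reports["snp"] = rep_snp
        rep_sample = sample_qc(
            G,
            meta["reported_sex"].to_numpy(dtype=object),
            meta["x_het_rate"].to_numpy(dtype=float),
            config.sample_qc,
        )
        G = G.take_subjects(rep_sample.retained_mask)
        qc_reports["sample"] = rep_sample
        if config.run_relatedness:
            rep_rel = relatedness_prune(G, config.pihat_threshold)
            G = G.take_subjects(rep_rel.retained_mask)
            qc_reports["relatedness"] = rep_rel
    except Exception as err:
        raise RuntimeError(f"stage 'qc' failed: {err}") from err
    with open(out / "qc_report.json", "w") as fh:
        json.dump({k: r.to_dict() for k, r in qc_reports.items()}, fh, indent=2)
    (out / "qc_report.txt").write_text(
        "\n\n".join(r.summary() for r in qc_reports.values()) + "\n"
    )
    provenance["stages"]["qc"] = {
        k: {"n_input": r.n_input, "n_retained": r.n_retained}
        for k, r in qc_reports.items()
    }

    # -- stage 4: principal components --------------------------------
    pcs = compute_pcs(G, config.n_pcs)
    pcs.to_csv(out / "pcs.csv", index=False, float_format="%.10g")

    # -- stage 5: polygenic scores ------------------------------------
    scores = {}
    score_meta = {}
    try:
        for trait, tbl in weights.items():
            filtered, counts = filter_weights(tbl, G)
            scores[trait] = score(G, filtered, trait=trait)
            score_meta[trait] = {"n_snps_scored": int(len(filtered)), "filters": counts}
    except Exception as err:
        raise RuntimeError(f"stage 'score' failed: {err}") from err
    score_table = pd.concat(scores.values(), ignore_index=True)
    score_table.to_csv(out / "scores.csv", index=False, float_format="%.10g")
    provenance["stages"]["score"] = score_meta

    # -- stage 6: association battery ---------------------------------
    wide = score_table.pivot(index="subject_id", columns="trait", values="z")
    wide.columns = [f"score_{t}" for t in wide.columns]
    covars = pcs.set_index("subject_id")
    lith = classifications.set_index("subject_id")["lithium_user"]
    datasets = {}
    try:
        for definition in DEFINITIONS:
            roster = build_comparison(classifications, definition)
            roster = roster[roster["subject_id"].isin(wide.index)]
            df = (
                roster.set_index("subject_id")
                .join(wide, how="inner")
                .join(covars, how="left")
            )
            df["lithium_user"] = lith.loc[df.index].to_numpy()
            datasets[definition] = df.reset_index()
        results = run_battery(
            datasets,
            traits=tuple(sorted(t for t in weights if t in ("lithium", "antidep")))
            or tuple(sorted(weights)),
            covariate_sets=None,
            lithium_sensitivity=config.lithium_sensitivity,
            population_K=config.population_K,
        )
        trends = []
        for definition, df in datasets.items():
            for trait in weights:
                col = f"score_{trait}"
                if col not in df.columns:
                    continue
                tr = quartile_trend(df[col].to_numpy(), df["status"].to_numpy())
                trends.append(
                    {
                        "definition": definition,
                        "trait": trait,
                        "p_trend": tr.p,
                        "statistic": tr.statistic,
                        **{
                            f"case_prop_q{i + 1}": v
                            for i, v in enumerate(tr.case_proportion)
                        },
                    }
                )
    except Exception as err:
        raise RuntimeError(f"stage 'assoc' failed: {err}") from err
    results.to_csv(out / "association_results.csv", index=False, float_format="%.10g")
    trend_table = pd.DataFrame(trends)
    trend_table.to_csv(out / "quartile_trends.csv", index=False, float_format="%.10g")
    provenance["stages"]["assoc"] = {
        "n_tests": int(len(results)),
        "n_primary": int(
            ((results["covariate_set"] == "base") & (~results["lithium_excluded"])).sum()
        ),
    }

    provenance["runtime_seconds"] = round(time.time() - t0, 2)
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    return {
        "classifications": classifications,
        "qc_reports": qc_reports,
        "pcs": pcs,
        "scores": score_table,
        "datasets": datasets,
        "results": results,
        "quartile_trends": trend_table,
        "provenance": provenance,
    }
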