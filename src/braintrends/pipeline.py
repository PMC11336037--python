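"""End-to-end pipeline driver.

Ties the stages together for every study group: normalization, per-region
trends and direction summaries, the matched-subsample bootstrap against the
reference population of the same sex, Welch comparisons and kappa,
laterality summaries, and (optionally) the CT/MRI agreement report and the
mediation analyses.  Every stochastic step derives its seed from the single
master seed, so a (config, seed) pair fully determines all outputs; a run
manifest records the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import bootstrap_group_betas
from .comparison import compare_regions, kappa, laterality_summary
from .ctmri import validate_ct_mri
from .io import ensure_dir, read_cohort, read_validation_pairs, write_cohort
from .mediation import combined_positive_volume, mediate, standardize
from .normalization import anchor_by_group
from .regions import N_REGIONS, compute_region_weights, load_region_registry
from .synthetic import SynthConfig, generate_cohort, generate_validation_pairs
from .trends import fit_region_trends, summarize_directions


@dataclass
class PipelineConfig:
    """Everything a full run needs.

    When ``cohort_csv`` (or ``validation_csv``) is None the corresponding
    table is simulated from the master seed with the synthetic generator's
    defaults.
    """

    outdir: str = "braintrends_run"
    seed: int = 0
    cohort_csv: Optional[str] = None
    validation_csv: Optional[str] = None
    study_populations: Sequence[str] = ("study_A", "study_B")
    reference_population: str = "reference"
    anchor_age: object = "auto"  # float or "auto" (group minimum age)
    B: int = 1000
    m_sub: int = 100
    alpha: float = 0.05
    n_comparisons: int = N_REGIONS
    weights_from: str = "study"  # or "reference" | "pooled"
    replace: bool = False
    n_validation_subjects: int = 13
    run_validation: bool = True
    run_mediation: bool = True
    mediators: Sequence[str] = ("stick_score", "moderate_minutes")
    mediation_n_boot: int = 1000
    write_draws: bool = False
    # cell sizes for the simulated cohort, keyed "population,sex"
    # (JSON/YAML-friendly); None uses the generator defaults
    synth_n_per_group: Optional[dict] = None

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("B", "m_sub", "n_comparisons", "mediation_n_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _weights_for(config, cohort, registry, pop, sex):
    if config.weights_from == "study":
        return compute_region_weights(cohort, registry, population=pop, sex=sex)
    if config.weights_from == "reference":
        return compute_region_weights(
            cohort, registry, population=config.reference_population, sex=sex
        )
    if config.weights_from == "pooled":
        return compute_region_weights(cohort, registry, sex=sex)
    raise ValueError(f"unknown weights_from policy {config.weights_from!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``config.outdir``.

    Returns a dictionary of the in-memory results keyed by stage.
    """
    config.validate()
    registry = load_region_registry()
    outdir = ensure_dir(config.outdir)
    seed = int(config.seed)

    # --- inputs ---------------------------------------------------------
    if config.cohort_csv:
        cohort = read_cohort(config.cohort_csv, registry)
    else:
        synth_kwargs = {}
        if config.synth_n_per_group is not None:
            synth_kwargs["n_per_group"] = {
                tuple(k.split(",")): int(v) for k, v in config.synth_n_per_group.items()
            }
        cohort = generate_cohort(SynthConfig(seed=seed, **synth_kwargs), registry)
        write_cohort(cohort, outdir / "cohort.csv")

    anchored = anchor_by_group(cohort, registry, a0=config.anchor_age)

    results: dict = {"groups": {}, "comparisons": {}}
    sexes = sorted(cohort["sex"].unique())

    # --- per-group trends ----------------------------------------------
    for (pop, sex), anc in sorted(anchored.items()):
        tag = f"{pop}_{sex}"
        anc.fits.to_csv(outdir / f"anchor_fits_{tag}.tsv", sep="\t", index=False)
        tr = fit_region_trends(anc, alpha=config.alpha, n_comparisons=config.n_comparisons)
        out = tr.rename(columns={"beta_se": "beta_sd"})[
            ["region", "beta", "beta_sd", "beta_s", "effect_class", "p", "significant"]
        ]
        out.to_csv(outdir / f"trends_{tag}.tsv", sep="\t", index=False)
        w = compute_region_weights(cohort, registry, population=pop, sex=sex)
        direction = summarize_directions(tr, w, registry)
        results["groups"][(pop, sex)] = {
            "anchored": anc,
            "trends": tr,
            "weights": w,
            "directions": direction,
        }

    directions_payload = {
        f"{pop}_{sex}": results["groups"][(pop, sex)]["directions"].as_dict()
        for (pop, sex) in results["groups"]
    }
    (outdir / "directions.json").write_text(json.dumps(directions_payload, indent=2))

    # --- bootstrap + comparison per study group x sex -------------------
    kappa_payload = {}
    laterality_payload = {}
    comparison_seeds = {}
    ss = np.random.SeedSequence([seed, 100])
    pairs = [
        (pop, sex)
        for pop in config.study_populations
        for sex in sexes
        if (pop, sex) in anchored and (config.reference_population, sex) in anchored
    ]
    children = ss.spawn(len(pairs))
    for child, (pop, sex) in zip(children, pairs):
        comparison_seeds[(pop, sex)] = int(child.generate_state(1)[0] % (2**31))

    for (pop, sex) in pairs:
        tag = f"{pop}_{sex}"
        boot = bootstrap_group_betas(
            anchored[(pop, sex)],
            anchored[(config.reference_population, sex)],
            B=config.B,
            m_sub=config.m_sub,
            seed=comparison_seeds[(pop, sex)],
            replace=config.replace,
        )
        if config.write_draws:
            boot.draws_frame().to_csv(outdir / f"bootstrap_draws_{tag}.csv", index=False)
        boot.summary().to_csv(outdir / f"bootstrap_summary_{tag}.tsv", sep="\t", index=False)
        comp = compare_regions(boot, alpha_family=config.alpha, n_comparisons=config.n_comparisons)
        comp.to_csv(outdir / f"comparison_{tag}.tsv", sep="\t", index=False)
        w = _weights_for(config, cohort, registry, pop, sex)
        ks = kappa(comp, w, registry)
        kappa_payload[tag] = ks.as_dict()
        tr = results["groups"][(pop, sex)]["trends"]
        laterality_payload[tag] = laterality_summary(tr, registry, comp, w)
        results["comparisons"][(pop, sex)] = {"bootstrap": boot, "welch": comp, "kappa": ks}

    (outdir / "kappa.json").write_text(json.dumps(kappa_payload, indent=2))
    (outdir / "laterality.json").write_text(json.dumps(laterality_payload, indent=2))

    # --- CT/MRI validation ----------------------------------------------
    if config.run_validation:
        if config.validation_csv:
            pairs_df = read_validation_pairs(config.validation_csv)
        else:
            pairs_df = generate_validation_pairs(
                SynthConfig(seed=seed), config.n_validation_subjects, registry
            )
            pairs_df.to_csv(outdir / "validation_pairs.csv", index=False)
        vw = compute_region_weights(cohort, registry)
        vres = validate_ct_mri(pairs_df, vw)
        pd.DataFrame(
            {"region": vres.deltas_mm3.index,
             "delta_mm3": vres.deltas_mm3.values,
             "delta_percent": vres.deltas_percent.loc[vres.deltas_mm3.index].values}
        ).to_csv(outdir / "validation_deltas.tsv", sep="\t", index=False)
        (outdir / "varpi.json").write_text(json.dumps({
            "varpi_weighted_percent": vres.varpi_weighted_percent,
            "varpi_verbatim_mm3": vres.varpi_verbatim,
        }, indent=2))
        results["validation"] = vres

    # --- mediation -------------------------------------------------------
    if config.run_mediation:
        med_payload = {}
        med_ss = np.random.SeedSequence([seed, 200])
        study_groups = [
            (pop, sex) for pop in config.study_populations for sex in sexes
            if (pop, sex) in results["groups"]
        ]
        med_children = med_ss.spawn(len(study_groups) * len(config.mediators))
        i = 0
        for (pop, sex) in study_groups:
            sub = cohort[(cohort["population"] == pop) & (cohort["sex"] == sex)]
            tr = results["groups"][(pop, sex)]["trends"]
            voi = combined_positive_volume(sub, tr)
            for mediator in config.mediators:
                child_seed = int(med_children[i].generate_state(1)[0] % (2**31))
                i += 1
                key = f"{pop}_{sex}_{mediator}"
                if voi is None or mediator not in sub.columns:
                    med_payload[key] = None
                    continue
                res = mediate(
                    standardize(sub["age"]),
                    standardize(sub[mediator]),
                    standardize(voi),
                    n_boot=config.mediation_n_boot,
                    seed=child_seed,
                )
                med_payload[key] = res.as_dict()
        (outdir / "mediation.json").write_text(json.dumps(med_payload, indent=2))
        results["mediation"] = med_payload

    manifest = {
        "seed": seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "config_sha256": _config_hash(config),
        "versions": {
            "braintrends": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
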