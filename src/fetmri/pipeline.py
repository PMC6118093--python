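"""End-to-end orchestration: simulate -> extract -> screen -> fit -> validate.

`PipelineConfig` collects every tunable of the analysis; its defaults are the
frozen "paper-defaults" profile: 1 mm reslicing, LoG sigma 0.5 mm / 5x5,
coif1 DWT3 (HHH reconstruction), TBR threshold 1.6, 100-voxel VOI rule, 64
grey-level bins, alpha 0.05 screening, top-8 PET features in the combined
pool, a 5-variable model cap, and LOOCV / 5-fold / 10-fold validation.

One master seed drives everything: the phantom cohort seed and the fold
shuffling seed are derived from it deterministically, so re-running a config
reproduces every artifact bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import screening, texture, validation
from .modelling import best_subset, metrics_from_scores
from .phantoms import PhantomSpec, generate_cohort, read_cohort
from .validation import FIVE_FOLD, LOOCV, TEN_FOLD, CvScheme, cross_validate

logger = logging.getLogger(__name__)

SCHEMES = {"apparent": None, "loocv": LOOCV, "5fold": FIVE_FOLD, "10fold": TEN_FOLD}


@dataclasses.dataclass
class PipelineConfig:
    # cohort: either a manifest path or a simulation block
    manifest: str | None = None
    n_cases: int = 52
    prevalence: float = 0.40
    phantom: dict = dataclasses.field(default_factory=dict)
    # extraction
    channels: tuple[str, ...] = ("T1", "T1_LoG", "T1_DWT3", "PET")
    tbr_threshold: float = 1.6
    connectivity: int = 26
    min_voxels: int = 100
    bins: int = 64
    dwt3_mode: str = "hhh"
    reslice_pet: bool = False
    # screening / modelling
    alpha: float = 0.05
    pet_top_k: int = 8
    mri_top_k: int | None = None
    max_vars: int = 5
    modalities: tuple[str, ...] = ("MRI", "PET", "combined")
    # validation
    cv_schemes: tuple[str, ...] = ("apparent", "loocv", "5fold", "10fold")
    cv_mode: str = "fixed_subset"
    threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("channels", "cv_schemes", "modalities"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(seed=self.seed, **self.phantom)


def load_cases(config: PipelineConfig):
    if config.manifest:
        return read_cohort(config.manifest)
    return generate_cohort(config.n_cases, config.prevalence, config.phantom_spec())


def extract_stage(config: PipelineConfig, cases):
    return texture.build_feature_table(
        cases,
        channels=config.channels,
        G=config.bins,
        tbr_threshold=config.tbr_threshold,
        connectivity=config.connectivity,
        min_voxels=config.min_voxels,
        dwt3_mode=config.dwt3_mode,
        reslice_pet=config.reslice_pet,
    )


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the whole pipeline and write all artifacts; returns the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(exist_ok=True)

    cases = load_cases(config)
    logger.info("cohort: %d cases", len(cases))
    table, exclusions = extract_stage(config, cases)
    table.to_csv(out / "features.csv")
    with open(out / "exclusions.log", "w") as fh:
        for case_id, causes in exclusions.items():
            for channel, cause in causes.items():
                fh.write(f"{case_id}\t{channel}\t{cause}\n")

    screens = {}
    if {"MRI", "combined"} & set(config.modalities):
        screens["MRI"] = screening.screen_features(table, "MRI", alpha=config.alpha)
    if {"PET", "combined"} & set(config.modalities):
        screens["PET"] = screening.screen_features(table, "PET", alpha=config.alpha)
    for name, screen in screens.items():
        screen.table.to_csv(out / f"screen_{name.lower()}.csv")

    cv_seed = (config.seed * 9973 + 17) % (2**31)
    runs: dict[str, dict] = {}
    models: dict[str, dict] = {}
    for modality in config.modalities:
        pool = screening.build_pool(
            screens.get("MRI"), screens.get("PET"), modality,
            pet_top_k=config.pet_top_k, mri_top_k=config.mri_top_k,
        )
        result, apparent = validation.apparent_performance(
            table, pool, max_vars=config.max_vars, threshold=config.threshold
        )
        models[modality] = {
            "pool": list(pool.features),
            "subset": list(result.subset),
            "coefficients_raw": result.params.to_dict(),
            "coefficients_standardized": result.fit.params_standardized.to_dict(),
            "logL": result.llf,
            "AIC": result.aic,
        }
        with open(out / "models" / f"{modality}.json", "w") as fh:
            json.dump(models[modality], fh, indent=2)
        runs[modality] = {}
        for scheme_name in config.cv_schemes:
            if scheme_name == "apparent":
                runs[modality]["apparent"] = apparent
                continue
            base = SCHEMES[scheme_name]
            scheme = base if base.kind == "loocv" else CvScheme(base.kind, base.k, seed=cv_seed)
            runs[modality][scheme.name] = cross_validate(
                table, pool, scheme, mode=config.cv_mode,
                max_vars=config.max_vars, threshold=config.threshold,
                alpha=config.alpha, pet_top_k=config.pet_top_k,
                mri_top_k=config.mri_top_k,
            )

    metric_table = validation.report(runs)
    metric_table.to_csv(out / "report.csv", index=False)
    summary = {
        "n_cases": len(cases),
        "n_recurrence": sum(c.label == "recurrence" for c in cases),
        "n_injury": sum(c.label == "injury" for c in cases),
        "models": models,
        "metrics": metric_table.to_dict(orient="records"),
        "exclusions": exclusions,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
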