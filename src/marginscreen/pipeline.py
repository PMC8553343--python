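"""End-to-end orchestration: simulate → calibrate → quantify → threshold →
classify → evaluate.

A run is fully determined by a :class:`PipelineConfig` and its seed; every
intermediate artifact (spectra CSVs, channel TIFFs, cohort tables, the
calibration JSON, the called test table, the crosstab and the final report)
is written under ``outdir`` so any stage can be re-run or swapped for
external instrument data.  The global seed is fanned out to per-stage
sub-seeds by fixed offsets, so toggling one stage never perturbs another's
randomness.

The cohort verdict mirrors the intended clinical use: if every test
specimen is called ``-`` the report flags the cohort as negative
(pre-screen suggests clear margins); any ``++``/``+`` call flags those
specimens for priority pathological review.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from marginscreen.evaluation import (
    ConfusionSummary,
    confusion_summary,
    group_crosstab,
    write_crosstab_csv,
)
from marginscreen.image_quant import (
    SampleRecord,
    read_channel_tiff,
    read_records_csv,
    records_to_frame,
    segment_samples,
    measure_sample,
    write_records_csv,
)
from marginscreen.photophysics import (
    blank_sigma,
    compute_lod,
    fit_forster_hoffmann,
    fit_titration,
    fold_enhancement,
    read_emission_csv,
    write_emission_csv,
)
from marginscreen.screening import Threshold, classify_cohort, derive_threshold
from marginscreen.synthetic_data import (
    CohortConfig,
    ImageConfig,
    SpectraConfig,
    gen_margin_cohort,
    gen_ntr_titration,
    gen_tissue_image,
    gen_viscosity_series,
    write_cohort_csv,
    write_tissue_image,
)

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_pipeline",
           "load_config", "save_config"]

log = logging.getLogger("marginscreen")

STAGES = ("simulate", "calibrate", "quantify", "threshold", "classify", "evaluate")

# fixed per-stage seed offsets (kept < 2**16 so derived seeds stay small)
_SEED_OFFSETS = {"spectra": 101, "image": 202, "cohort": 303, "kmeans": 404}


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat, human-editable run configuration.

    ``threshold_source`` is either ``"derive_from_training"`` (K-means
    centroid of the training scatter) or ``"fixed"`` with explicit
    ``fixed_t_ntr``/``fixed_t_vis`` in [0, 255].  External CSV tables may
    replace the simulated training/test tables via ``training_csv`` /
    ``test_csv``.
    """

    outdir: str = "run"
    seed: int = 42
    stages: tuple[str, ...] = STAGES
    threshold_source: str = "derive_from_training"
    fixed_t_ntr: Optional[float] = None
    fixed_t_vis: Optional[float] = None
    training_csv: Optional[str] = None
    test_csv: Optional[str] = None
    spectra: SpectraConfig = field(default_factory=SpectraConfig)
    image: ImageConfig = field(default_factory=ImageConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.threshold_source not in ("derive_from_training", "fixed"):
            raise ValueError(
                f"threshold_source must be 'derive_from_training' or 'fixed', "
                f"got {self.threshold_source!r}")
        if self.threshold_source == "fixed":
            if self.fixed_t_ntr is None or self.fixed_t_vis is None:
                raise ValueError("fixed threshold requires fixed_t_ntr and fixed_t_vis")
            Threshold(self.fixed_t_ntr, self.fixed_t_vis)  # range check
        for name in ("training_csv", "test_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} path does not exist: {p}")

    def stage_seed(self, key: str) -> int:
        return (self.seed + _SEED_OFFSETS[key]) % (2 ** 31)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["spectra"]["viscosities"] = list(d["spectra"]["viscosities"])
        d["spectra"]["titration_concs"] = list(d["spectra"]["titration_concs"])
        return d


@dataclass
class RunReport:
    """What a run produced: stage statuses, artifacts, threshold, rates."""

    stages: dict[str, str]
    artifacts: list[str]
    threshold: Optional[tuple[float, float]]
    confusion: Optional[ConfusionSummary]
    verdict: Optional[str]
    calibration: Optional[dict]
    seed: int
    config: dict
    version: str
    error: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "artifacts": self.artifacts,
            "threshold": list(self.threshold) if self.threshold else None,
            "confusion": self.confusion.to_dict() if self.confusion else None,
            "verdict": self.verdict,
            "calibration": self.calibration,
            "seed": self.seed,
            "config": self.config,
            "version": self.version,
            "error": self.error,
        }


def _version() -> str:
    import marginscreen
    return marginscreen.__version__


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat YAML config; nested generator options use dotted keys
    (e.g. ``cohort.n_test_neg: 26``)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    nested: dict[str, dict] = {"spectra": {}, "image": {}, "cohort": {}}
    flat: dict = {}
    for key, value in raw.items():
        if "." in key:
            group, sub = key.split(".", 1)
            if group not in nested:
                raise ValueError(f"unknown config group {group!r}")
            nested[group][sub] = tuple(value) if isinstance(value, list) else value
        elif key == "stages":
            flat[key] = tuple(value)
        else:
            flat[key] = value
    for group, cls in (("spectra", SpectraConfig), ("image", ImageConfig),
                       ("cohort", CohortConfig)):
        if nested[group]:
            if group == "image" and "class_means" in nested[group]:
                cm = nested[group]["class_means"]
                nested[group]["class_means"] = {k: tuple(v) for k, v in cm.items()}
            if group == "cohort":
                for m in ("pos_mean", "neg_mean"):
                    if m in nested[group]:
                        nested[group][m] = tuple(nested[group][m])
            flat[group] = cls(**nested[group])
    return PipelineConfig(**flat)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    raw: dict = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if f.name in ("spectra", "image", "cohort"):
            for sf in dataclasses.fields(v):
                sv = getattr(v, sf.name)
                if isinstance(sv, tuple):
                    sv = list(sv)
                if isinstance(sv, dict):
                    sv = {k: list(x) if isinstance(x, tuple) else x for k, x in sv.items()}
                raw[f"{f.name}.{sf.name}"] = sv
        elif isinstance(v, tuple):
            raw[f.name] = list(v)
        else:
            raw[f.name] = v
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True), encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order and write all artifacts.

    Raises :class:`PipelineError` on stage failure, after writing a report
    that names the failing stage.  Two runs with the same config and seed
    produce byte-identical outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "config.yaml")

    stages: dict[str, str] = {s: "skipped" for s in STAGES}
    artifacts: list[str] = [str(outdir / "config.yaml")]
    threshold: Optional[Threshold] = None
    summary: Optional[ConfusionSummary] = None
    verdict: Optional[str] = None
    calibration: Optional[dict] = None
    training: Optional[list[SampleRecord]] = None
    test: Optional[list[SampleRecord]] = None

    def _art(p: Path) -> Path:
        artifacts.append(str(p))
        return p

    def _fail(stage: str, exc: Exception) -> PipelineError:
        stages[stage] = "failed"
        report = RunReport(stages=stages, artifacts=artifacts, threshold=None,
                           confusion=None, verdict=None, calibration=calibration,
                           seed=config.seed, config=config.echo(),
                           version=_version(), error=f"{stage}: {exc}")
        (outdir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8")
        return PipelineError(stage, exc)

    enabled = set(config.stages)

    for stage in STAGES:
        if stage not in enabled:
            continue
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                sp = dataclasses.replace(config.spectra, seed=config.stage_seed("spectra"))
                visc = gen_viscosity_series(sp)
                titr, blanks = gen_ntr_titration(sp)
                write_emission_csv(visc, _art(outdir / "viscosity_series.csv"))
                write_emission_csv(titr, _art(outdir / "titration_series.csv"))
                (_art(outdir / "blanks.csv")).write_text(
                    "intensity\n" + "".join(f"{b!r}\n" for b in blanks), encoding="utf-8")
                im = dataclasses.replace(config.image, seed=config.stage_seed("image"))
                ntr_img, vis_img, truths = gen_tissue_image(im)
                for p in write_tissue_image(outdir / "tissue", ntr_img, vis_img, truths):
                    _art(p)
                co = dataclasses.replace(config.cohort, seed=config.stage_seed("cohort"))
                cohort = gen_margin_cohort(co)
                write_cohort_csv(cohort, _art(outdir / "training.csv"),
                                 _art(outdir / "test.csv"))
                training = list(cohort.training)
                test = list(cohort.test)

            elif stage == "calibrate":
                visc = read_emission_csv(outdir / "viscosity_series.csv")
                titr = read_emission_csv(outdir / "titration_series.csv")
                blanks = [float(x) for x in
                          (outdir / "blanks.csv").read_text().splitlines()[1:] if x]
                fh = fit_forster_hoffmann(visc)
                lin = fit_titration(titr)
                sigma = blank_sigma(blanks)
                lod = compute_lod(lin.slope_k, sigma)
                calibration = {
                    "forster_hoffmann": {"slope_x": fh.slope_x, "intercept_c": fh.intercept_c,
                                         "pearson_r": fh.pearson_r, "n": fh.n},
                    "fold_enhancement": fold_enhancement(visc),
                    "titration": {"slope_k": lin.slope_k, "intercept": lin.intercept,
                                  "pearson_r": lin.pearson_r, "n": lin.n},
                    "blank_sigma": sigma,
                    "lod_ng_per_ml": lod.lod_ng_per_ml,
                    "lod_ng_per_ml_display": lod.display_ng_per_ml(),
                }
                (_art(outdir / "calibration.json")).write_text(
                    json.dumps(calibration, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")

            elif stage == "quantify":
                ntr_img = read_channel_tiff(outdir / "tissue_ntr.tif", "ntr")
                vis_img = read_channel_tiff(outdir / "tissue_vis.tif", "vis")
                regions = segment_samples(ntr_img, vis_img)
                recs = [measure_sample(r, ntr_img, vis_img) for r in regions]
                write_records_csv(recs, _art(outdir / "image_records.csv"))

            elif stage == "threshold":
                if config.threshold_source == "fixed":
                    threshold = Threshold(float(config.fixed_t_ntr),
                                          float(config.fixed_t_vis))
                else:
                    if training is None:
                        src = config.training_csv or outdir / "training.csv"
                        training = read_records_csv(src)
                    threshold = derive_threshold(training,
                                                 seed=config.stage_seed("kmeans"))
                log.info("threshold (t_ntr, t_vis) = (%.1f, %.1f)",
                         threshold.t_ntr, threshold.t_vis)

            elif stage == "classify":
                if test is None:
                    src = config.test_csv or outdir / "test.csv"
                    test = read_records_csv(src)
                if not test:
                    raise ValueError("empty test cohort at classify stage")
                if threshold is None:
                    raise ValueError("no threshold available: enable the "
                                     "threshold stage or supply a fixed one")
                test = classify_cohort(test, threshold)
                write_records_csv(test, _art(outdir / "test_called.csv"))
                verdict = ("cohort_negative" if all(r.call == "-" for r in test)
                           else "priority_review")

            elif stage == "evaluate":
                if test is None or any(r.call is None for r in test):
                    raise ValueError("evaluate requires a classified test cohort")
                summary = confusion_summary(test)
                crosstab = group_crosstab(test)
                write_crosstab_csv(_art(outdir / "crosstab.csv"), crosstab)

            stages[stage] = "ok"
            log.info("stage %-9s ok (%.3f s)", stage, time.perf_counter() - t0)
        except Exception as exc:  # noqa: BLE001 — report then re-raise
            raise _fail(stage, exc) from exc

    report = RunReport(
        stages=stages, artifacts=artifacts,
        threshold=(threshold.t_ntr, threshold.t_vis) if threshold else None,
        confusion=summary, verdict=verdict, calibration=calibration,
        seed=config.seed, config=config.echo(), version=_version(),
    )
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    artifacts.append(str(outdir / "report.json"))
    return report
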