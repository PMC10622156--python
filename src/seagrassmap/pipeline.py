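"""End-to-end orchestration from a YAML/JSON config: simulate (or load),
correct, classify, compare — with structured logging, a machine-readable run
manifest, and byte-reproducible outputs under a fixed seed.

Each stage consumes and produces only documented file formats, so any stage
can be replaced by user-supplied files — e.g. a pre-classified map dropped in
place of the classifier. The comparison routine is selected from the
reference dialect: presence data routes to balanced agreement; continuous
cover points to the reference-cover-by-satellite-class test; ordinal density
polygons to the two-class or gated multi-class cover comparison.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import yaml

from . import classification as cls_mod
from . import cover as cover_mod
from . import presence as presence_mod
from . import radiometry as radio_mod
from . import synthetic as synth_mod
from .core import (
    ClassMap,
    ConfigurationError,
    DensityScheme,
    ReferenceSet,
    read_classmap,
    read_geojson,
    read_raster,
    scheme_from_config,
    write_classmap,
    write_geojson,
    write_raster,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def select_comparison(dialect: str, n_scheme_classes: int | None = None) -> str:
    """Route a reference dialect to its agreement test."""
    if dialect in ("presence_polygons", "presence_points"):
        return "balanced_agreement"
    if dialect == "cover_points":
        return "reference_cover_by_satellite_class"
    if dialect == "density_polygons":
        if n_scheme_classes is None:
            raise ConfigurationError("density_polygons routing needs the scheme size")
        return "cover_two_class" if n_scheme_classes == 2 else "cover_multiclass"
    raise ConfigurationError(f"unknown reference dialect: {dialect!r}")


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _RunLog:
    """JSON-lines structured log; one record per event (incl. each QC decision)."""

    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, event: str, **fields) -> None:
        rec = {"stage": stage, "event": event, **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2, default=str)
        fh.write("\n")


def _write_records_csv(path: Path, records) -> None:
    cols = ["ref_id", "reference_label", "n_total_pixels", "n_nodata", "n_land",
            "n_valid", "n_seagrass", "satellite_cover_pct", "qc_status"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for r in records:
            w.writerow(r.to_dict())


def _write_presence_csv(path: Path, report) -> None:
    cols = ["n_reference_seagrass", "n_reference_noseagrass",
            "sensitivity", "specificity", "balanced_agreement"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        w.writerow({c: getattr(report, c) for c in cols})


def run_pipeline(config_source, output_dir) -> dict:
    """Run the configured stages; returns the manifest dict.

    Artifacts are written under ``output_dir`` with a ``manifest.json`` listing
    every output file with a checksum, the config hash, and the seeds used.
    On stage failure, partial outputs are retained alongside a FAILED marker
    and a PipelineError naming the stage is raised.
    """
    config = load_config(config_source)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run_log.jsonl")
    seed = int(config.get("seed", 0))
    try:
        manifest = _run_stages(config, outdir, log, seed)
    except Exception as exc:
        (outdir / "FAILED").write_text(str(exc) + "\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("pipeline", str(exc)) from exc
    return manifest


def _run_stages(config: dict, outdir: Path, log: _RunLog, seed: int) -> dict:
    scheme: DensityScheme | None = None
    ref: ReferenceSet | None = None
    scene = None
    rois = None
    cmap: ClassMap | None = None
    truth = None

    # --- simulate -----------------------------------------------------------
    syn = config.get("synthetic")
    inputs = config.get("inputs", {})
    if syn:
        try:
            truth = synth_mod.generate_truth_field(
                width=int(syn.get("width", 128)),
                height=int(syn.get("height", 128)),
                cell_size=float(syn.get("cell_size", 2.0)),
                patch_scale=float(syn.get("patch_scale", 20.0)),
                target_cover=float(syn.get("target_cover", 0.4)),
                land_band_width=int(syn.get("land_band_width", 8)),
                seed=seed,
                trend_scale=(float(syn["trend_scale"])
                             if syn.get("trend_scale") is not None else None),
                trend_weight=float(syn.get("trend_weight", 0.7)),
            )
            spectra = synth_mod.default_spectra(
                noise_sd=float(syn.get("noise_sd", 0.0010))
            )
            scene, rois = synth_mod.render_scene(truth, spectra, seed=seed + 1)
            refcfg = dict(syn.get("reference", {}))
            dialect = refcfg.pop("dialect", "density_polygons")
            if dialect == "density_polygons":
                scheme = scheme_from_config(refcfg.pop("scheme", "chesapeake"))
            ref = synth_mod.delineate_reference(
                truth, dialect, scheme=scheme, seed=seed + 2, **refcfg
            )
            path_nir = float(syn.get("path_at_reference", 0.0))
            atm_cfg = _atmospheric_config(config)
            if path_nir > 0:
                scene = radio_mod.RrsScene(
                    bands=radio_mod.add_path_signal(
                        scene.bands, scene.wavelengths, path_nir, atm_cfg),
                    wavelengths=scene.wavelengths,
                    grid=scene.grid,
                    valid_mask=scene.valid_mask,
                    metadata=scene.metadata,
                )
            write_raster(outdir / "truth_cover.tif", truth.cover, truth.grid,
                         metadata={"seed": seed})
            write_raster(outdir / "scene.tif", scene.bands, scene.grid,
                         wavelengths=scene.wavelengths)
            write_geojson(outdir / "reference.geojson", ref)
            roi_ref = ReferenceSet(
                dialect="presence_polygons",
                features=[
                    synth_mod.ReferenceFeature(f"roi{i}", geom, {"class": label})
                    for i, (geom, label) in enumerate(rois.regions)
                ],
                crs=truth.grid.crs,
            )
            write_geojson(outdir / "rois.geojson", roi_ref)
            log.event("simulate", "complete", seed=seed,
                      n_reference_features=len(ref))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
    else:
        for key in ("reference",):
            if key not in inputs:
                raise PipelineError("inputs", f"missing required input {key!r}")
            if not Path(inputs[key]).exists():
                raise PipelineError("inputs", f"file not found: {inputs[key]}")
        dialect = config.get("reference_dialect")
        ref = read_geojson(inputs["reference"], dialect=dialect)
        dialect = ref.dialect
        if dialect == "density_polygons":
            scheme = scheme_from_config(config.get("scheme", "chesapeake"))
        if "scene" in inputs:
            bands, grid, side = read_raster(inputs["scene"])
            scene = radio_mod.RrsScene(
                bands=bands,
                wavelengths=tuple(side.get("wavelengths_nm", [])),
                grid=grid,
            )
        if "rois" in inputs:
            roi_set = read_geojson(inputs["rois"], dialect="presence_polygons")
            labels = sorted({f.attrs["class"] for f in roi_set.features})
            rois = cls_mod.ROISet(
                regions=[(f.geometry, f.attrs["class"]) for f in roi_set.features],
                catalog=tuple(labels),
            )
        if "classmap" in inputs:
            cmap = read_classmap(inputs["classmap"])

    # --- correct ------------------------------------------------------------
    radio = config.get("radiometry", {})
    if radio.get("enabled", bool(syn)) and scene is not None:
        try:
            water = truth.water_mask if truth is not None else None
            scene = radio_mod.atmospheric_correct(
                scene, _atmospheric_config(config), water_mask=water
            )
            write_raster(outdir / "scene_rrs.tif", scene.bands, scene.grid,
                         wavelengths=scene.wavelengths,
                         metadata=scene.metadata.get("atmospheric_correction"))
            log.event("correct", "complete",
                      **scene.metadata.get("atmospheric_correction", {}))
        except Exception as exc:
            raise PipelineError("correct", str(exc)) from exc

    # --- classify -----------------------------------------------------------
    if cmap is None:
        if scene is None or rois is None:
            raise PipelineError("classify", "need a scene and ROIs (or a pre-classified map)")
        try:
            clf_cfg = config.get("classification", {})
            model = cls_mod.train_classifier(
                scene, rois,
                window_size=int(clf_cfg.get("window_size", 1)),
                model_config=clf_cfg.get("model"),
                seed=seed + 3,
            )
            log.event("classify", "trained", **model.training_report)
            scene_map = cls_mod.classify_scene(model, scene)
            collapse = clf_cfg.get(
                "collapse", {"seagrass": "seagrass", "bare": "no_seagrass", "land": "land"}
            )
            cmap = cls_mod.collapse_classes(scene_map, collapse)
            write_classmap(outdir / "classmap.tif", cmap)
            log.event("classify", "complete", counts=cmap.counts())
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("classify", str(exc)) from exc

    # --- compare ------------------------------------------------------------
    try:
        routine = select_comparison(
            ref.dialect, len(scheme.classes) if scheme else None
        )
        report_obj: dict
        if routine == "balanced_agreement":
            rep = presence_mod.assess_presence(cmap, ref)
            report_obj = rep.to_dict()
            _write_presence_csv(outdir / "presence_report.csv", rep)
        elif routine == "reference_cover_by_satellite_class":
            rep = cover_mod.compare_reference_cover_by_satellite_class(ref, cmap)
            report_obj = rep.to_dict()
        else:
            records = cover_mod.clip_and_cover(cmap, ref)
            for r in records:
                log.event("compare", "polygon_qc", ref_id=r.ref_id,
                          qc_status=r.qc_status, n_total=r.n_total_pixels,
                          n_nodata=r.n_nodata, n_valid=r.n_valid)
            _write_records_csv(outdir / "polygon_records.csv", records)
            if routine == "cover_two_class":
                rep = cover_mod.compare_cover_two_class(records, scheme)
            else:
                rep = cover_mod.compare_cover_multiclass(records, scheme)
            report_obj = rep.to_dict()
        report_obj["comparison_routine"] = routine
        _write_json(outdir / "agreement_report.json", report_obj)
        log.event("compare", "complete", routine=routine)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("compare", str(exc)) from exc

    # --- manifest -----------------------------------------------------------
    files = sorted(
        p.name for p in outdir.iterdir()
        if p.is_file() and p.name not in ("manifest.json",)
    )
    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "comparison_routine": routine,
        "files": {name: _sha256(outdir / name) for name in files},
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def _atmospheric_config(config: dict) -> radio_mod.AtmosphericConfig:
    radio = config.get("radiometry", {})
    return radio_mod.AtmosphericConfig(
        rayleigh_exponent=float(radio.get("rayleigh_exponent", 4.75)),
        haze_mode=bool(radio.get("haze", False)),
        reference_band_nm=float(radio.get("reference_band_nm", 908.0)),
        dark_percentile=float(radio.get("dark_percentile", 1.0)),
    )
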