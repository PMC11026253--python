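"""End-to-end orchestration: simulate → extract → detect → quantify → fit.

A run is driven by a single hierarchical config (YAML on disk) with a
mandatory seed; all stage outputs are CSV/JSON/PNG files under the run
directory, and a manifest records config, seeds and SHA-256 checksums so a
run can be reproduced bit-identically (model fits to numerical tolerance).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abnormal import analyse_recording, combine_reports
from .apfeatures import measurements_frame, summarise_location
from .assoc import ConvergenceFailure, ModelSpec, fit_ap_mixed_model, render_results_table, format_text_table
from .fibrosis import aggregate_patient, quantify_section
from .simulate import child_seeds
from .synth import (
    AbnormalityConfig,
    APWaveformParams,
    CohortGeneratingModel,
    HistologyGroundTruth,
    generate_cohort,
    generate_histology_image,
    generate_recording,
)
from .trace import read_trace, sidecar_path, write_trace

logger = logging.getLogger("myotrace")

__all__ = ["DEFAULT_CONFIG", "RunConfig", "run_pipeline", "validate_inputs", "StageFailure"]


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "outdir": "runs/default",
    "cohort": {
        "n_patients": 25,
        "locations_per_patient": 3,
        "freqs": [0.5, 1.0, 2.0, 3.0, 4.0],
    },
    "traces": {
        "n_patients": 2,
        "locations_per_patient": 1,
        "freqs": [1.0, 2.0],
        "n_beats": 12,
        "noise_sd": 0.5,
        "artifact_amp": 25.0,
        "waveform": {
            "rmp_mV": -80.0,
            "apa_mV": 100.0,
            "apd90_ms": 220.0,
            "plateau_fraction": 0.25,
            "repolarisation_shape": "sigmoidal",
        },
        "abnormalities": {
            "ead_prob": 0.0,
            "extrasystole_prob": 0.0,
            "couplet_prob": 0.0,
            "alternans_depth_ms": 0.0,
            "capture_failure_freqs_Hz": [],
        },
    },
    "histology": {
        "n_patients": 2,
        "sections_per_patient": 3,
        "width_px": 256,
        "height_px": 256,
        "collagen_fraction_mean": 0.159,
        "collagen_fraction_sd": 0.04,
        "endocardium_band_px": 8,
        "gap_fraction": 0.05,
        "min_sections": 30,
    },
    "thresholds": {
        "blanking_ms": 5.0,
        "capture_window_ms": 50.0,
        "ead_min_prominence_mV": 5.0,
        "couplet_max_interval_ms": 500.0,
        "alternans_min_beats": 6,
    },
    "models": {
        "estimation": "REML",
        "p_value_method": "wald-t-bw",
    },
}


class RunConfig:
    """Validated hierarchical run configuration."""

    def __init__(self, data: dict | None = None):
        merged = copy.deepcopy(DEFAULT_CONFIG)
        if data:
            _validate_keys(data, DEFAULT_CONFIG, path="")
            _deep_update(merged, data)
        if merged.get("seed") is None:
            raise ValueError("config: seed is mandatory for simulation stages")
        self.data = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.data[key]


def _validate_keys(data: dict, template: dict, path: str) -> None:
    for key, value in data.items():
        if key not in template:
            full = f"{path}.{key}".lstrip(".")
            raise ValueError(f"config: unknown key {full!r}")
        if isinstance(template[key], dict) and isinstance(value, dict):
            _validate_keys(value, template[key], f"{path}.{key}")


def _deep_update(base: dict, upd: dict) -> None:
    for key, value in upd.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------- stages ---

def stage_simulate_cohort(cfg: RunConfig, outdir: Path) -> list[Path]:
    c = cfg["cohort"]
    table, intercepts = generate_cohort(
        CohortGeneratingModel(),
        n_patients=c["n_patients"],
        locations_per_patient=c["locations_per_patient"],
        freqs=tuple(c["freqs"]),
        seed=cfg["seed"],
    )
    p1 = outdir / "cohort.csv"
    p2 = outdir / "cohort_true_intercepts.csv"
    table.to_csv(p1, index=False)
    intercepts.to_csv(p2)
    return [p1, p2]


def stage_simulate_traces(cfg: RunConfig, outdir: Path) -> list[Path]:
    t = cfg["traces"]
    wf = APWaveformParams(**t["waveform"])
    abn = AbnormalityConfig(
        **{
            **t["abnormalities"],
            "capture_failure_freqs_Hz": frozenset(
                t["abnormalities"].get("capture_failure_freqs_Hz", [])
            ),
        }
    )
    tdir = outdir / "traces"
    tdir.mkdir(exist_ok=True)
    paths = []
    combos = [
        (p, l, f)
        for p in range(t["n_patients"])
        for l in range(t["locations_per_patient"])
        for f in t["freqs"]
    ]
    seeds = child_seeds(cfg["seed"] + 1, len(combos))
    for (p, l, f), s in zip(combos, seeds):
        rec, _ = generate_recording(
            wf,
            pacing_freq=f,
            n_beats=t["n_beats"],
            abnormalities=abn,
            noise_sd=t["noise_sd"],
            artifact_amp=t["artifact_amp"],
            seed=int(s),
            patient_id=f"P{p:03d}",
            location_id=f"L{l}",
        )
        paths.append(write_trace(rec, tdir / f"P{p:03d}_L{l}_{f:g}Hz.csv"))
        paths.append(sidecar_path(paths[-1]))
    return paths


def stage_extract_and_detect(cfg: RunConfig, outdir: Path) -> list[Path]:
    tdir = outdir / "traces"
    trace_files = sorted(tdir.glob("*.csv"))
    if not trace_files:
        raise StageFailure("extract-features", f"no trace CSVs under {tdir}")
    all_ap, all_summaries, reports = [], [], []
    by_location: dict[tuple, dict] = {}
    for f in trace_files:
        rec = read_trace(f)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report, ms, ratio = analyse_recording(rec)
            summary = summarise_location(ms)
        all_ap.append(measurements_frame(ms))
        summary.insert(0, "patient_id", rec.patient_id)
        summary.insert(1, "location_id", rec.location_id)
        all_summaries.append(summary)
        key = (rec.patient_id, rec.location_id)
        loc = by_location.setdefault(
            key, {"reports": [], "apd90": {}, "ratios": {}}
        )
        loc["reports"].append(report)
        if not summary.empty:
            loc["apd90"][rec.pacing_freq] = float(summary["APD90"].iloc[0])
        loc["ratios"][rec.pacing_freq] = ratio

    ap_path = outdir / "ap_features.csv"
    pd.concat(all_ap, ignore_index=True).to_csv(ap_path, index=False)
    sum_path = outdir / "location_summaries.csv"
    pd.concat(all_summaries, ignore_index=True).to_csv(sum_path, index=False)

    report_path = outdir / "abnormality_reports.json"
    patient_rows = {}
    merged_all = []
    for (pid, lid), loc in sorted(by_location.items()):
        merged = combine_reports(loc["reports"], loc["apd90"], loc["ratios"])
        merged_all.append(merged.as_dict())
        row = patient_rows.setdefault(
            pid,
            {"patient_id": pid, "tissue_arrhythmia": 0,
             "impaired_apd_shortening": 0, "apd_alternans": 0},
        )
        row["tissue_arrhythmia"] |= int(merged.tissue_arrhythmia)
        row["impaired_apd_shortening"] |= int(bool(merged.impaired_shortening))
        row["apd_alternans"] |= int(merged.any_alternans)
    report_path.write_text(json.dumps(merged_all, indent=1))
    patient_path = outdir / "patient_abnormalities.csv"
    pd.DataFrame(list(patient_rows.values())).to_csv(patient_path, index=False)
    return [ap_path, sum_path, report_path, patient_path]


def stage_histology(cfg: RunConfig, outdir: Path) -> list[Path]:
    h = cfg["histology"]
    hdir = outdir / "histology"
    hdir.mkdir(exist_ok=True)
    rng = np.random.default_rng(cfg["seed"] + 2)
    paths, rows, patient_rows = [], [], []
    for p in range(h["n_patients"]):
        fractions = np.clip(
            rng.normal(h["collagen_fraction_mean"], h["collagen_fraction_sd"],
                       size=h["sections_per_patient"]),
            0.0, 0.9,
        )
        quants = []
        for s, frac in enumerate(fractions):
            truth = HistologyGroundTruth(
                collagen_fraction=float(frac),
                endocardium_band_px=h["endocardium_band_px"],
                gap_fraction=h["gap_fraction"],
            )
            img, mask = generate_histology_image(
                truth, h["width_px"], h["height_px"],
                seed=int(rng.integers(2**31)),
            )
            img_path = hdir / f"P{p:03d}_S{s:02d}.png"
            iio.imwrite(img_path, img)
            iio.imwrite(hdir / f"P{p:03d}_S{s:02d}_mask.png", mask)
            q = quantify_section(img, section_id=f"P{p:03d}_S{s:02d}")
            quants.append(q)
            rows.append({"patient_id": f"P{p:03d}", **q.as_dict()})
            paths.append(img_path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            agg = aggregate_patient(quants, min_sections=h["min_sections"])
        patient_rows.append({"patient_id": f"P{p:03d}", **agg})
    p1 = hdir / "sections.csv"
    pd.DataFrame(rows).to_csv(p1, index=False)
    p2 = hdir / "patients.csv"
    pd.DataFrame(patient_rows).to_csv(p2, index=False)
    return [*paths, p1, p2]


def stage_fit_models(cfg: RunConfig, outdir: Path) -> list[Path]:
    table = pd.read_csv(outdir / "cohort.csv")
    m = cfg["models"]
    results = []
    for dep in ("RMP", "APA", "dVdt_max", "APD20", "APD50", "APD90", "AUC90"):
        spec = ModelSpec(
            dependent=dep,
            estimation=m["estimation"],
            p_value_method=m["p_value_method"],
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results.append(fit_ap_mixed_model(table, spec))
        except ConvergenceFailure as exc:
            logger.warning("fit failed for %s: %s", dep, exc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wide = render_results_table(results)
    p1 = outdir / "model_results.csv"
    wide.to_csv(p1)
    p2 = outdir / "model_results.txt"
    p2.write_text(format_text_table(wide) + "\n")
    p3 = outdir / "model_results.json"
    p3.write_text(json.dumps(
        {
            r.dependent: {
                "adjusted_r2": r.adjusted_r2,
                "n_obs": r.n_obs,
                "n_groups": r.n_groups,
                "estimates": r.params["estimate"].round(6).to_dict(),
                "p_values": r.params["p"].round(6).to_dict(),
            }
            for r in results
        },
        indent=1,
        allow_nan=True,
    ))
    return [p1, p2, p3]


def run_pipeline(config: RunConfig | dict | None = None) -> dict:
    """Run every stage and write a reproducibility manifest; returns it."""
    cfg = config if isinstance(config, RunConfig) else RunConfig(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stages = [
        ("simulate-cohort", stage_simulate_cohort),
        ("simulate-traces", stage_simulate_traces),
        ("extract-features", stage_extract_and_detect),
        ("simulate-histology", stage_histology),
        ("fit-models", stage_fit_models),
    ]
    for name, fn in stages:
        logger.info("stage %s", name)
        try:
            outputs.extend(fn(cfg, outdir))
        except StageFailure:
            raise
        except Exception as exc:
            raise StageFailure(name, str(exc)) from exc
    manifest = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "config": cfg.data,
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ------------------------------------------------------------- validation ---

def validate_inputs(paths) -> list[dict]:
    """Per-file validity report for trace CSVs (+ sidecars) and images.

    Never raises; each entry carries ``path``, ``kind``, ``valid`` and a list
    of problems.
    """
    out = []
    for path in paths:
        path = Path(path)
        entry = {"path": str(path), "kind": "unknown", "valid": False, "problems": []}
        if not path.exists():
            entry["problems"].append("file not found")
            out.append(entry)
            continue
        try:
            if path.suffix.lower() == ".csv":
                entry["kind"] = "trace"
                df = pd.read_csv(path, nrows=500000)
                if list(df.columns[:2]) != ["time_s", "voltage_mV"]:
                    entry["problems"].append(
                        f"expected columns time_s,voltage_mV, got {list(df.columns)}"
                    )
                elif np.any(np.diff(df["time_s"].to_numpy()) <= 0):
                    entry["problems"].append("time_s is not strictly increasing")
                sc = sidecar_path(path)
                if not sc.exists():
                    entry["problems"].append("missing JSON sidecar")
                else:
                    meta = json.loads(sc.read_text())
                    for key in ("pacing_freq_hz", "stim_times_s"):
                        if key not in meta:
                            entry["problems"].append(f"sidecar missing {key}")
                    stim = np.asarray(meta.get("stim_times_s", []), dtype=float)
                    if stim.size and np.any(np.diff(stim) <= 0):
                        entry["problems"].append("stim_times_s not strictly increasing")
            elif path.suffix.lower() in (".png", ".tif", ".tiff"):
                entry["kind"] = "image"
                img = iio.imread(path)
                if img.ndim == 3 and img.shape[2] == 3 and img.dtype == np.uint8:
                    pass
                elif img.ndim == 2:
                    entry["kind"] = "mask"
                else:
                    entry["problems"].append(
                        f"expected 8-bit RGB or single-channel image, got "
                        f"shape {img.shape} dtype {img.dtype}"
                    )
            else:
                entry["problems"].append("unrecognised file type")
        except Exception as exc:  # report, never crash
            entry["problems"].append(f"unreadable: {exc}")
        entry["valid"] = not entry["problems"]
        out.append(entry)
    return out
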