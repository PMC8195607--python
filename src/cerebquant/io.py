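"""Shared tabular I/O, run configuration and module dispatch.

Tables are CSV with ``#``-prefixed header comments documenting column
units; schemas are checked on read (missing columns raise, extra columns
are preserved with a warning).  :func:`run` dispatches a
:class:`RunConfig` to the named module, writes its result tables plus a
metadata JSON carrying the package version, seed and a hash of the
configuration, and is the single entry point behind the ``cereb`` CLI.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import tifffile

from . import eyeblink, eyemov, histo, morpho, sorting, spikestats, synth
from .exceptions import ParameterError, SchemaError
from .spiketrain import LabeledSpikeTrain, RawTrace


def read_table(path, required: Optional[list] = None) -> pd.DataFrame:
    """Read a CSV table, skipping ``#`` comments, enforcing a schema."""
    frame = pd.read_csv(path, comment="#")
    if required:
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        extra = [c for c in frame.columns if c not in required]
        if extra:
            warnings.warn(f"{path}: extra column(s) preserved: {', '.join(extra)}",
                          UserWarning, stacklevel=2)
    return frame


def write_table(frame: pd.DataFrame, path, units: Optional[Dict[str, str]] = None) -> None:
    """Write a CSV table with unit documentation as header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for col, unit in (units or {}).items():
            fh.write(f"# {col}: {unit}\n")
        frame.to_csv(fh, index=False)


@dataclass
class RunConfig:
    """One analysis run: module name, inputs, overrides, seed, output dir."""

    module: str
    inputs: Dict[str, str] = field(default_factory=dict)
    params: Dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "out"
    log_level: str = "INFO"

    def hash(self) -> str:
        blob = json.dumps(
            {"module": self.module, "inputs": self.inputs, "params": self.params, "seed": self.seed},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    tables: Dict[str, pd.DataFrame]
    metadata: Dict


# ---------------------------------------------------------------- dispatch

def _run_synth_spikes(cfg: RunConfig) -> ResultBundle:
    params = synth.SpikeSimParams(seed=cfg.seed, **cfg.params)
    train = synth.simulate_spike_train(params)
    return ResultBundle({"events": train.to_frame()}, {"duration_s": train.duration})


def _run_synth_trace(cfg: RunConfig) -> ResultBundle:
    sp = {k: v for k, v in cfg.params.items() if k in ("ss_rate", "ss_shape", "cs_rate", "cf_pause", "duration")}
    tp = {k: v for k, v in cfg.params.items() if k in ("sampling_rate", "noise_sd")}
    train = synth.simulate_spike_train(synth.SpikeSimParams(seed=cfg.seed, **sp))
    trace = synth.render_trace(train, synth.TraceSimParams(seed=cfg.seed + 1, **tp))
    return ResultBundle(
        {"trace": pd.DataFrame({"value": trace.samples}), "events": train.to_frame()},
        {"sampling_rate_hz": trace.sampling_rate, "duration_s": trace.duration},
    )


def _run_synth_tree(cfg: RunConfig) -> ResultBundle:
    tree = synth.generate_tree(synth.TreeSimParams(seed=cfg.seed, **cfg.params))
    frame = pd.DataFrame(
        {
            "id": tree.ids,
            "type": tree.types,
            "x_um": tree.xyz[:, 0],
            "y_um": tree.xyz[:, 1],
            "z_um": tree.xyz[:, 2],
            "radius_um": tree.radius,
            "parent": tree.parent,
        }
    )
    return ResultBundle({"swc": frame}, {"n_nodes": tree.n_nodes})


def _run_synth_puncta(cfg: RunConfig) -> ResultBundle:
    image, truth = synth.generate_puncta_image(seed=cfg.seed, **cfg.params)
    return ResultBundle(
        {"truth": truth},
        {
            "um_per_px": image.um_per_px,
            "soma_line_um": image.soma_line_um,
            "_image": image,  # written as TIFF by run()
        },
    )


def _run_synth_eye(cfg: RunConfig) -> ResultBundle:
    trace = synth.simulate_eye_session(synth.EyeSimParams(seed=cfg.seed, **cfg.params))
    frame = pd.DataFrame({"time_s": trace.time, "eye_deg": trace.eye, "stim_deg": trace.stim})
    return ResultBundle(
        {"trace": frame},
        {"frequency_hz": trace.frequency, "amplitude_deg": trace.stimulus_amplitude,
         "condition": trace.condition},
    )


def _run_synth_blink(cfg: RunConfig) -> ResultBundle:
    ts = synth.simulate_eyeblink_session(synth.BlinkSimParams(seed=cfg.seed, **cfg.params))
    rows = []
    for k, tr in enumerate(ts.trials):
        rows.append(pd.DataFrame({"trial": k, "type": tr.trial_type,
                                  "time_ms": tr.time_ms, "fec": tr.fec}))
    return ResultBundle({"session": pd.concat(rows, ignore_index=True), "truth": ts.truth}, {})


def _run_spikestats(cfg: RunConfig) -> ResultBundle:
    frame = read_table(cfg.inputs["events"], required=["time_s", "label"])
    duration = float(cfg.params["duration"])
    train = LabeledSpikeTrain.from_frame(frame, duration)
    cell = spikestats.summarize(train, **{k: v for k, v in cfg.params.items()
                                          if k in ("min_duration", "exclude_cs_spanning")})
    row = {
        "ss_rate_hz": cell.ss.rate,
        "ss_cv": cell.ss.cv,
        "ss_cv2_mean": cell.ss.cv2_mean,
        "ss_regularity_index": cell.ss.regularity_index,
        "cs_rate_hz": cell.cs.rate,
        "cs_cv2_mean": cell.cs.cv2_mean,
        "cf_pause_ms": cell.cf_pause.mean_pause if cell.cf_pause else np.nan,
        "n_ss": cell.ss.n_events,
        "n_cs": cell.cs.n_events,
        "duration_s": duration,
        "included": cell.included,
        "is_single_unit": cell.validation.is_single_unit,
    }
    return ResultBundle({"stats": pd.DataFrame([row])}, {"validation_status": cell.validation.status})


def _run_sorting(cfg: RunConfig) -> ResultBundle:
    frame = read_table(cfg.inputs["trace"], required=["value"])
    fs = float(cfg.params["sampling_rate"])
    trace = RawTrace(frame["value"].to_numpy(), fs)
    det = sorting.detect_events(trace, **{k: v for k, v in cfg.params.items()
                                          if k in ("threshold_k", "refractory_ms")})
    if det.times.size >= 2:
        cls = sorting.classify_events(det.snippets)
        labels, pcs, review = cls.labels, cls.pcs, cls.needs_review
    else:
        labels = np.full(det.times.size, "SS", dtype="U2")
        pcs = np.zeros((det.times.size, 2))
        review = False
    events = pd.DataFrame({"time_s": det.times, "label": labels,
                           "pc1": pcs[:, 0], "pc2": pcs[:, 1]})
    train = sorting.to_spike_train(det.times, labels, trace.duration)
    val = sorting.validate_single_unit(train)
    meta = {"needs_review": review, "validation_status": val.status,
            "is_single_unit": val.is_single_unit,
            "mean_cs_to_ss_s": val.mean_cs_to_ss, "mean_ss_isi_s": val.mean_ss_isi}
    return ResultBundle({"events": events}, meta)


def _run_morpho_sholl(cfg: RunConfig) -> ResultBundle:
    tree = morpho.read_swc(cfg.inputs["swc"])
    mode = cfg.params.get("mode", "2d")
    step = cfg.params.get("radius_step", 1.0)
    profile = morpho.sholl(tree, radius_step=step, mode=mode)
    summary = morpho.summarize(tree, radius_step=step, mode=mode)
    return ResultBundle(
        {"profile": pd.DataFrame({"radius_um": profile.radii, "crossings": profile.crossings})},
        {"total_intersections": summary.total_intersections,
         "max_length_um": summary.max_length, "area_um2": summary.area},
    )


def _run_histo(cfg: RunConfig) -> ResultBundle:
    pixels = tifffile.imread(cfg.inputs["image"])
    with open(cfg.inputs["meta"]) as fh:
        meta = json.load(fh)
    image = histo.PunctaImage(pixels, meta["um_per_px"], meta["soma_line_um"])
    puncta = histo.detect_puncta(image, cfg.params.get("puncta_threshold", 0.6),
                                 cfg.params.get("min_size_px", 3))
    roi = histo.ROI(*meta["roi"]) if "roi" in meta else None
    xs = meta.get("measurement_xs", [image.width_um * f for f in (0.25, 0.5, 0.75)])
    measure = histo.cf_extension(image, xs, puncta=puncta)
    row = {
        "n_puncta": len(puncta),
        "density_per_um2": histo.puncta_density(puncta, roi) if roi else np.nan,
        "ml_height_um": measure.ml_height,
        "cf_height_um": measure.cf_height,
        "cf_extension_pct": measure.cf_extension,
    }
    return ResultBundle({"measures": pd.DataFrame([row]), "puncta": puncta}, {})


def _run_eyemov(cfg: RunConfig) -> ResultBundle:
    frame = read_table(cfg.inputs["trace"], required=["time_s", "eye_deg", "stim_deg"])
    with open(cfg.inputs["meta"]) as fh:
        meta = json.load(fh)
    trace = eyemov.EyeTrace(frame["time_s"].to_numpy(), frame["eye_deg"].to_numpy(),
                            frame["stim_deg"].to_numpy(), meta["frequency_hz"],
                            meta["amplitude_deg"], meta.get("condition", "VOR"))
    gp = eyemov.gain_phase(trace)
    row = {"gain": gp.gain, "phase_deg": gp.phase, "fit_r2": gp.fit_r2, "status": gp.status}
    return ResultBundle({"gain_phase": pd.DataFrame([row])}, {})


def _run_eyeblink(cfg: RunConfig) -> ResultBundle:
    frame = read_table(cfg.inputs["session"], required=["trial", "type", "time_ms", "fec"])
    raw = []
    for k, sub in frame.groupby("trial", sort=True):
        ttype = sub["type"].iloc[0]
        us = eyeblink.CS_US_INTERVAL_MS if ttype in (eyeblink.PAIRED, eyeblink.US_ONLY) else None
        raw.append(eyeblink.EyelidTrial(sub["time_ms"].to_numpy(), sub["fec"].to_numpy(),
                                        ttype, us))
    trials = eyeblink.normalize_session(raw)
    rows = []
    for k, tr in enumerate(trials):
        eyeblink.validate_trial(tr)
        row = {"trial": k, "type": tr.trial_type, "valid": tr.valid,
               "is_cr": np.nan, "amplitude": np.nan, "onset_ms": np.nan, "peak_ms": np.nan}
        if tr.trial_type != eyeblink.US_ONLY and tr.valid:
            out = eyeblink.detect_cr(tr)
            row.update({"is_cr": out.is_cr, "amplitude": out.amplitude,
                        "onset_ms": out.onset_latency, "peak_ms": out.peak_latency})
        rows.append(row)
    cr_pct = eyeblink.cr_percentage(trials)
    return ResultBundle({"trials": pd.DataFrame(rows)}, {"cr_percent": cr_pct})


_DISPATCH = {
    "synth.spikes": _run_synth_spikes,
    "synth.trace": _run_synth_trace,
    "synth.tree": _run_synth_tree,
    "synth.puncta": _run_synth_puncta,
    "synth.eye": _run_synth_eye,
    "synth.blink": _run_synth_blink,
    "spikestats": _run_spikestats,
    "sorting": _run_sorting,
    "morpho.sholl": _run_morpho_sholl,
    "histo.quantify": _run_histo,
    "eyemov.gainphase": _run_eyemov,
    "eyeblink.analyze": _run_eyeblink,
}


def available_modules() -> list:
    return sorted(_DISPATCH)


def run(config: RunConfig) -> ResultBundle:
    """Dispatch to the named module and write results under ``out_dir``.

    Inputs are checked for existence before anything is written, so a
    missing file never leaves partial outputs behind.
    """
    if config.module not in _DISPATCH:
        raise ParameterError(
            f"unknown module {config.module!r}; choose from {', '.join(available_modules())}"
        )
    for key, p in config.inputs.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"input {key!r}: no such file: {p}")
    bundle = _DISPATCH[config.module](config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image = bundle.metadata.pop("_image", None)
    for name, frame in bundle.tables.items():
        write_table(frame, out / f"{name}.csv")
    if image is not None:
        tifffile.imwrite(out / "image.tif", image.pixels.astype(np.float32))
    meta = {
        "module": config.module,
        "version": "0.1.0",
        "seed": config.seed,
        "config_hash": config.hash(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **{k: v for k, v in bundle.metadata.items()},
    }
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    bundle.metadata = meta
    return bundle
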