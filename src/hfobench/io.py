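"""File formats and fixtures: EDF signals, ground-truth/detection TSVs,
benchmark manifests and the ready-made synthetic benchmark profiles.

Signals are stored as single-channel 16-bit EDF with the physical range
auto-scaled to twice the signal's peak amplitude (quantization error about
6e-5 of full scale).  The writer/reader here implement the plain EDF layout
(ASCII header + int16 little-endian records) directly so the package has no
I/O dependency beyond numpy.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .background import ARBackgroundModel, high_hf_model, low_hf_model
from .detectors.base import Detection
from .events import EventTemplate, make_default_dictionary
from .simulate import (
    GroundTruthComponent,
    GroundTruthEvent,
    SimulatedChannel,
    SimulationConfig,
    generate_benchmark,
)

__all__ = [
    "write_edf",
    "read_edf",
    "export_channel",
    "load_channel",
    "ground_truth_to_tsv",
    "ground_truth_from_tsv",
    "detections_to_tsv",
    "detections_from_tsv",
    "fixture_components",
    "make_fixture_benchmark",
    "load_manifest",
]

GT_COLUMNS = ["event_id", "class_id", "kind", "t_center_s", "snr_db", "k", "jitter_s"]
DET_COLUMNS = ["detector", "t_start_s", "t_end_s", "t_peak_s", "type", "peak_freq_hz", "score"]


# ---------------------------------------------------------------------------
# Minimal EDF (16-bit, single channel, 1 s data records)
# ---------------------------------------------------------------------------


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(path, samples: np.ndarray, fs: float, label: str = "SEEG") -> None:
    """Write one channel as 16-bit EDF with >= 2x amplitude headroom.

    The sampling rate must be a whole number of samples per 1 s record; the
    final partial record, if any, is zero-padded (callers that need the
    exact length keep it in a sidecar).  Output bytes are deterministic.
    """
    x = np.asarray(samples, dtype=float)
    spr = int(fs)
    if spr != fs:
        raise ValueError("sampling rate must be an integer for 1 s EDF records")
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    phys_max = 2.0 * peak if peak > 0 else 1.0
    phys_max = float(f"{phys_max:.5g}")  # store exactly what the header says
    n_rec = int(np.ceil(x.size / spr))
    padded = np.zeros(n_rec * spr)
    padded[: x.size] = x
    digital = np.clip(np.round(padded / phys_max * 32767), -32768, 32767).astype("<i2")

    header = b"".join(
        [
            _field(0, 8),
            _field("X X X X", 80),
            _field(f"Startdate 01-JAN-2000 {label}", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(512, 8),  # header bytes: 256 + 256 * 1 signal
            _field("", 44),
            _field(n_rec, 8),
            _field(1, 8),
            _field(1, 4),
            # per-signal fields (one signal)
            _field(label[:16], 16),
            _field("", 80),
            _field("uV", 8),
            _field(f"{-phys_max:.5g}", 8),
            _field(f"{phys_max:.5g}", 8),
            _field(-32768, 8),
            _field(32767, 8),
            _field("", 80),
            _field(spr, 8),
            _field("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def read_edf(path) -> tuple[np.ndarray, float]:
    """Read a single-channel EDF written by :func:`write_edf` (or compatible)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_rec = int(head[236:244].decode().strip())
        rec_dur = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())
        if ns != 1:
            raise ValueError(f"expected a single-channel EDF, found {ns} signals")
        sig = fh.read(256)
        # single-signal block offsets: label 0, transducer 16, dim 96,
        # phys min/max 104/112, dig min/max 120/128, prefilter 136, spr 216
        phys_min = float(sig[104:112].decode())
        phys_max = float(sig[112:120].decode())
        dig_min = float(sig[120:128].decode())
        dig_max = float(sig[128:136].decode())
        spr = int(sig[216:224].decode().strip())
        data = np.frombuffer(fh.read(n_rec * spr * 2), dtype="<i2").astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    fs = spr / rec_dur
    return data * scale + (phys_max - scale * dig_max), fs


# ---------------------------------------------------------------------------
# Ground truth and detections as TSV
# ---------------------------------------------------------------------------


def ground_truth_to_tsv(ground_truth: list[GroundTruthEvent], path) -> None:
    rows = [
        {
            "event_id": ei,
            "class_id": ev.class_id,
            "kind": c.kind,
            "t_center_s": f"{c.t_center_s:.6f}",
            "snr_db": f"{c.snr_db:.6f}",
            "k": f"{c.k:.6f}",
            "jitter_s": f"{c.jitter_s:.6f}",
        }
        for ei, ev in enumerate(ground_truth)
        for c in ev.components
    ]
    pd.DataFrame(rows, columns=GT_COLUMNS).to_csv(path, sep="\t", index=False)


def ground_truth_from_tsv(path) -> list[GroundTruthEvent]:
    df = pd.read_csv(path, sep="\t")
    events = []
    for eid, grp in df.groupby("event_id", sort=True):
        comps = [
            GroundTruthComponent(
                kind=r.kind,
                t_center_s=float(r.t_center_s),
                snr_db=float(r.snr_db),
                k=float(r.k),
                jitter_s=float(r.jitter_s),
            )
            for r in grp.itertuples()
        ]
        events.append(GroundTruthEvent(int(grp.class_id.iloc[0]), comps[0].t_center_s, comps))
    return events


def detections_to_tsv(detections: list[Detection], path) -> None:
    rows = [
        {
            "detector": d.detector,
            "t_start_s": f"{d.t_start_s:.6f}",
            "t_end_s": f"{d.t_end_s:.6f}",
            "t_peak_s": f"{d.t_peak_s:.6f}",
            "type": d.type,
            "peak_freq_hz": "" if d.peak_freq_hz is None else f"{d.peak_freq_hz:.3f}",
            "score": f"{d.score:.6g}",
        }
        for d in detections
    ]
    pd.DataFrame(rows, columns=DET_COLUMNS).to_csv(path, sep="\t", index=False)


def detections_from_tsv(path) -> list[Detection]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        out.append(
            Detection(
                t_start_s=float(r.t_start_s),
                t_end_s=float(r.t_end_s),
                t_peak_s=float(r.t_peak_s),
                detector=str(r.detector),
                type=str(r.type),
                peak_freq_hz=None if pd.isna(r.peak_freq_hz) else float(r.peak_freq_hz),
                score=float(r.score),
            )
        )
    return out


def load_baseline_segments(edf_path, markers_tsv) -> list:
    """Read reviewer-marked baseline stretches for AR model fitting.

    The marker TSV has columns channel_id, t_start_s, t_end_s, label; only
    rows labelled ``baseline`` are used.  Returns BaselineSegment objects
    ready for :func:`hfobench.background.estimate_ar`.
    """
    from .background import BaselineSegment

    samples, fs = read_edf(edf_path)
    df = pd.read_csv(markers_tsv, sep="\t")
    segments = []
    for r in df.itertuples():
        if str(r.label) != "baseline":
            continue
        i0, i1 = int(round(r.t_start_s * fs)), int(round(r.t_end_s * fs))
        if not 0 <= i0 < i1 <= samples.size:
            raise ValueError(f"marker [{r.t_start_s}, {r.t_end_s}] s outside the recording")
        segments.append(BaselineSegment(str(r.channel_id), samples[i0:i1], fs))
    return segments


def export_channel(chan: SimulatedChannel, path) -> Path:
    """Write one simulated record: EDF signal + ground-truth TSV + JSON sidecar."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    try:
        write_edf(out / "signal.edf", chan.samples, chan.fs, label=chan.model_id)
        ground_truth_to_tsv(chan.ground_truth, out / "ground_truth.tsv")
        meta = {
            "model_id": chan.model_id,
            "fs": chan.fs,
            "n_samples": int(chan.samples.size),
            "snr_db": chan.snr_db,
            "seed": chan.seed,
            "config": chan.config.to_dict(),
        }
        with open(out / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)
    except OSError:
        for name in ("signal.edf", "ground_truth.tsv", "meta.json"):
            (out / name).unlink(missing_ok=True)
        raise
    return out


def load_channel(path) -> tuple[np.ndarray, float, list[GroundTruthEvent], dict]:
    out = Path(path)
    with open(out / "meta.json") as fh:
        meta = json.load(fh)
    samples, fs = read_edf(out / "signal.edf")
    samples = samples[: meta["n_samples"]]
    return samples, fs, ground_truth_from_tsv(out / "ground_truth.tsv"), meta


def load_manifest(root) -> dict:
    root = Path(root)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    missing = [
        r["path"]
        for r in manifest["records"]
        if not (root / r["path"] / "signal.edf").exists()
    ]
    if missing:
        raise FileNotFoundError(f"manifest references missing records: {missing[:5]}")
    return manifest


# ---------------------------------------------------------------------------
# Ready-made benchmark profiles
# ---------------------------------------------------------------------------

FIXTURE_SCALES = ("tiny", "small", "paper")


def fixture_components(
    scale: str, seed: int = 0
) -> tuple[list[ARBackgroundModel], list[EventTemplate], SimulationConfig]:
    """Models, dictionary and config for a named benchmark profile.

    ``tiny`` (1 channel x 2 SNR x 2 x 60 s) is a smoke-test size; ``small``
    (4 channels -- two 1/f-like, two with semi-continuous high-frequency
    activity to exercise the MNI mode switch -- x 4 SNR x 5 x 120 s) is the
    evaluation size; ``paper`` is the full 8 x 4 x 30 x 600 s grid.
    """
    fs = 2048.0
    if scale == "tiny":
        models = [low_hf_model("lowHF_a", fs)]
        cfg = SimulationConfig(
            duration_s=60.0, n_realizations=2, snr_grid_db=(0.0, 15.0), seed=seed
        )
    elif scale == "small":
        models = [
            low_hf_model("lowHF_a", fs),
            low_hf_model("lowHF_b", fs),
            high_hf_model("highHF_a", fs),
            high_hf_model("highHF_b", fs),
        ]
        cfg = SimulationConfig(duration_s=120.0, n_realizations=5, seed=seed)
    elif scale == "paper":
        models = [low_hf_model(f"lowHF_{i}", fs) for i in "abcde"] + [
            high_hf_model(f"highHF_{i}", fs) for i in "abc"
        ]
        cfg = SimulationConfig(duration_s=600.0, n_realizations=30, seed=seed)
    else:
        raise ValueError(f"unknown scale {scale!r}; choose from {FIXTURE_SCALES}")
    dictionary = make_default_dictionary(seed=seed, fs=fs)
    return models, dictionary, cfg


def make_fixture_benchmark(scale: str, out_dir, seed: int = 0) -> Path:
    """Materialize a named benchmark profile on disk."""
    models, dictionary, cfg = fixture_components(scale, seed)
    return generate_benchmark(models, dictionary, cfg, out_dir)
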