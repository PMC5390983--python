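"""Benchmark channel assembly: event timing, SNR scaling and insertion.

Seven event classes are simulated: 1 Spk, 2 Spk-R, 3 Spk-FR, 4 Spk-R-FR,
5 R, 6 FR, 7 R-FR.  Event timings follow a homogeneous Poisson process with
class labels drawn according to the configured per-class rates.  Each HFO
component is scaled so that its power in its own frequency band sits at a
fixed dB ratio above the background's power in that band; spike components
get an independently drawn broadband SNR, a random time-stretch factor k and
a multiplicative post-spike silencing notch on the background.  HFOs that
co-occur with a spike or another HFO receive an independent timing jitter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .background import ARBackgroundModel, synthesize_background
from .events import (
    BROADBAND,
    FAST_RIPPLE_BAND,
    RIPPLE_BAND,
    EventTemplate,
    band_power,
)

__all__ = [
    "CLASS_COMPONENTS",
    "SimulationConfig",
    "GroundTruthComponent",
    "GroundTruthEvent",
    "SimulatedChannel",
    "draw_event_timeline",
    "scale_to_snr",
    "insert_spike",
    "generate_channel",
    "generate_benchmark",
]

CLASS_COMPONENTS: dict[int, tuple[str, ...]] = {
    1: ("SPK",),
    2: ("SPK", "R"),
    3: ("SPK", "FR"),
    4: ("SPK", "R", "FR"),
    5: ("R",),
    6: ("FR",),
    7: ("R", "FR"),
}

MIN_EVENT_SPACING_S = 0.5  # keeps the 100 ms scoring windows unambiguous
EDGE_GUARD_S = 1.0


@dataclass
class SimulationConfig:
    """Knobs of one benchmark run; defaults are the benchmark profile
    (3 events/min for every class, SNR grid 0/5/10/15 dB)."""

    class_rates: dict[int, float] = field(
        default_factory=lambda: {c: 3.0 for c in range(1, 8)}
    )  # events/min
    hfo_snr_db: float = 10.0
    spk_snr_range_db: tuple[float, float] = (0.0, 15.0)
    duration_s: float = 120.0
    n_realizations: int = 30
    snr_grid_db: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0)
    stretch_range: tuple[float, float] = (0.8, 1.25)
    jitter_ms: float = 20.0
    silencing_depth: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_rates = {int(k): float(v) for k, v in self.class_rates.items()}
        if any(r < 0 for r in self.class_rates.values()):
            raise ValueError("class rates must be non-negative")
        if set(self.class_rates) - set(CLASS_COMPONENTS):
            raise ValueError("class ids must be in 1..7")
        if self.stretch_range[0] <= 0:
            raise ValueError("stretch factors must be positive")
        if not np.all(np.isfinite(list(self.snr_grid_db))):
            raise ValueError("SNR grid must be finite")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_rates"] = {str(k): v for k, v in self.class_rates.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "class_rates" in d:
            d["class_rates"] = {int(k): float(v) for k, v in d["class_rates"].items()}
        for key in ("spk_snr_range_db", "snr_grid_db", "stretch_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruthComponent:
    kind: str  # SPK | R | FR
    t_center_s: float  # actual inserted centre (jitter included)
    snr_db: float
    k: float = 1.0  # stretch factor, 1 for HFOs
    jitter_s: float = 0.0


@dataclass
class GroundTruthEvent:
    class_id: int
    t_s: float  # nominal Poisson timing
    components: list[GroundTruthComponent]

    def __post_init__(self) -> None:
        kinds = tuple(c.kind for c in self.components)
        if kinds != CLASS_COMPONENTS[self.class_id]:
            raise ValueError(
                f"class {self.class_id} must have components "
                f"{CLASS_COMPONENTS[self.class_id]}, got {kinds}"
            )


@dataclass
class SimulatedChannel:
    samples: np.ndarray
    fs: float
    ground_truth: list[GroundTruthEvent]
    model_id: str
    snr_db: float
    config: SimulationConfig
    seed: int

    def hfo_components(self) -> list[tuple[int, GroundTruthComponent]]:
        """(class_id, component) pairs for every inserted R/FR."""
        return [
            (ev.class_id, c)
            for ev in self.ground_truth
            for c in ev.components
            if c.kind in ("R", "FR")
        ]


def draw_event_timeline(
    config: SimulationConfig, seed: int | np.random.Generator
) -> list[tuple[float, int]]:
    """Poisson arrivals over the record with class labels drawn by rate.

    Arrivals falling closer than 500 ms to an already placed event, or inside
    the 1 s edge guards, are re-drawn so the scoring windows never overlap.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = {c: r for c, r in config.class_rates.items() if r > 0}
    total_per_s = sum(rates.values()) / 60.0
    if total_per_s <= 0:
        raise ValueError("at least one class rate must be positive")
    usable = config.duration_s - 2 * EDGE_GUARD_S
    if usable <= MIN_EVENT_SPACING_S:
        raise ValueError(
            f"duration {config.duration_s} s too short to host one event"
        )
    n = rng.poisson(total_per_s * usable)
    times: list[float] = []
    for _ in range(n):
        for _attempt in range(100):
            t = rng.uniform(EDGE_GUARD_S, config.duration_s - EDGE_GUARD_S)
            if all(abs(t - u) >= MIN_EVENT_SPACING_S for u in times):
                times.append(t)
                break
        # silently dropped when the record is saturated with events
    times.sort()
    class_ids = list(rates)
    probs = np.array([rates[c] for c in class_ids]) / sum(rates.values())
    labels = rng.choice(class_ids, size=len(times), p=probs)
    return [(float(t), int(c)) for t, c in zip(times, labels)]


def scale_to_snr(
    template: EventTemplate,
    bkg: np.ndarray,
    snr_db: float,
    fs: float | None = None,
    bkg_band_power: float | None = None,
) -> np.ndarray:
    """Scale a template so its band power sits ``snr_db`` above the background.

    Both powers are measured with the same band-pass filter: the template
    over its own support, the background per unit time over the whole
    provided stretch.  Passing a precomputed ``bkg_band_power`` avoids
    re-filtering the background for every insertion.
    """
    fs = fs or template.fs
    p_tmpl = band_power(template.waveform, template.band, fs)
    if p_tmpl <= 0:
        raise ValueError("cannot scale a zero-energy template")
    if bkg_band_power is None:
        bkg = np.asarray(bkg, dtype=float)
        if bkg.size < 5 * fs:
            raise ValueError("need >= 5 s of background for a stable power estimate")
        bkg_band_power = band_power(bkg, template.band, fs)
    g = np.sqrt(10.0 ** (snr_db / 10.0) * bkg_band_power / p_tmpl)
    return g * template.waveform


def _stretch(waveform: np.ndarray, k: float) -> np.ndarray:
    """Resample a waveform in time by factor k (k > 1 lengthens)."""
    n = waveform.size
    m = max(2, int(round(n * k)))
    return np.interp(np.linspace(0.0, n - 1.0, m), np.arange(n), waveform)


def _silencing_envelope(n: int, depth: float) -> np.ndarray:
    """Multiplicative notch dipping to 1 - depth with raised-cosine edges."""
    return 1.0 - depth * sp_signal.windows.tukey(n, alpha=0.5)


def insert_spike(
    bkg: np.ndarray,
    spike: EventTemplate,
    t_s: float,
    k: float,
    snr_db: float,
    silencing_depth: float,
    fs: float | None = None,
    bkg_broadband_power: float | None = None,
) -> np.ndarray:
    """Insert one stretched, SNR-scaled spike with post-spike silencing.

    Returns a modified copy of the background: over the stretched spike
    support the background is multiplied by the silencing notch, then the
    scaled spike is added.  The spike SNR is referenced to the background's
    broadband (1-500 Hz) power since spikes are not band-limited.
    """
    fs = fs or spike.fs
    bkg = np.asarray(bkg, dtype=float).copy()
    w = _stretch(spike.waveform, k)
    stretched = EventTemplate(waveform=w, fs=fs, kind="SPK", band=spike.band)
    scaled = scale_to_snr(stretched, bkg, snr_db, fs=fs, bkg_band_power=bkg_broadband_power)
    i0 = int(round(t_s * fs)) - scaled.size // 2
    i1 = i0 + scaled.size
    if i0 < 0 or i1 > bkg.size:
        raise ValueError(f"spike support [{i0}, {i1}) outside the record")
    if silencing_depth > 0:
        bkg[i0:i1] *= _silencing_envelope(scaled.size, silencing_depth)
    bkg[i0:i1] += scaled
    return bkg


def _pick(rng: np.random.Generator, templates: list[EventTemplate], kind: str) -> EventTemplate:
    pool = [t for t in templates if t.kind == kind]
    if not pool:
        raise ValueError(f"dictionary has no template of kind {kind}")
    return pool[rng.integers(len(pool))]


def generate_channel(
    model: ARBackgroundModel,
    dictionary: list[EventTemplate],
    config: SimulationConfig,
    snr_db: float,
    realization_seed: int,
) -> SimulatedChannel:
    """Build one benchmark record: background + events + ground truth.

    The HFO SNR is fixed at ``snr_db`` for the whole realization while every
    spike draws its own SNR from the configured range.  Background band
    powers are measured on the clean realization before any insertion, so
    re-measuring an inserted HFO against an event-free twin recovers the
    target SNR.  With all class rates zero the output equals the plain
    background realization sample for sample.
    """
    ss = np.random.SeedSequence([int(realization_seed)])
    rng_bkg, rng_timeline, rng_events = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )
    fs = model.fs
    bkg = synthesize_background(model, config.duration_s, rng_bkg)
    if not any(r > 0 for r in config.class_rates.values()):
        return SimulatedChannel(bkg, fs, [], model.channel_id, snr_db, config, realization_seed)

    p_band = {
        "R": band_power(bkg, RIPPLE_BAND, fs),
        "FR": band_power(bkg, FAST_RIPPLE_BAND, fs),
        "SPK": band_power(bkg, BROADBAND, fs),
    }
    timeline = draw_event_timeline(config, rng_timeline)

    events: list[GroundTruthEvent] = []
    additions: list[tuple[int, np.ndarray]] = []  # (start index, waveform)
    signal = bkg.copy()
    jitter = config.jitter_ms / 1000.0
    for t_nominal, class_id in timeline:
        kinds = CLASS_COMPONENTS[class_id]
        comps: list[GroundTruthComponent] = []
        for kind in kinds:
            tmpl = _pick(rng_events, dictionary, kind)
            if kind == "SPK":
                k = rng_events.uniform(*config.stretch_range)
                s_db = rng_events.uniform(*config.spk_snr_range_db)
                w = _stretch(tmpl.waveform, k)
                stretched = EventTemplate(waveform=w, fs=fs, kind="SPK", band=tmpl.band)
                scaled = scale_to_snr(
                    stretched, bkg, s_db, fs=fs, bkg_band_power=p_band["SPK"]
                )
                i0 = int(round(t_nominal * fs)) - scaled.size // 2
                # silencing applies to the background, before any addition
                if config.silencing_depth > 0:
                    env = _silencing_envelope(scaled.size, config.silencing_depth)
                    signal[i0 : i0 + scaled.size] *= env
                additions.append((i0, scaled))
                comps.append(GroundTruthComponent(kind, t_nominal, s_db, k=k))
            else:
                j = rng_events.uniform(-jitter, jitter) if len(kinds) > 1 else 0.0
                t_center = t_nominal + j
                scaled = scale_to_snr(
                    tmpl, bkg, snr_db, fs=fs, bkg_band_power=p_band[kind]
                )
                i0 = int(round(t_center * fs)) - scaled.size // 2
                additions.append((i0, scaled))
                comps.append(
                    GroundTruthComponent(kind, t_center, snr_db, jitter_s=j)
                )
        events.append(GroundTruthEvent(class_id, t_nominal, comps))

    for i0, w in additions:
        if i0 < 0 or i0 + w.size > signal.size:
            raise ValueError("event support outside the record")
        signal[i0 : i0 + w.size] += w
    return SimulatedChannel(signal, fs, events, model.channel_id, snr_db, config, realization_seed)


def realization_seed(master_seed: int, channel_idx: int, snr_idx: int, realization: int) -> int:
    """Deterministic per-record seed derived from one master seed."""
    ss = np.random.SeedSequence([int(master_seed), channel_idx, snr_idx, realization])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def generate_benchmark(
    models: list[ARBackgroundModel],
    dictionary: list[EventTemplate],
    config: SimulationConfig,
    out_dir,
) -> "Path":
    """Materialize the full channel x SNR x realization tree on disk.

    Each record is written as an EDF signal, a ground-truth TSV and a JSON
    sidecar; a manifest.json at the root records the layout and the master
    seed so a re-run is byte-identical.
    """
    from . import io as hio  # local import: io depends on the types above

    if not models:
        raise ValueError("need at least one channel model")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for ci, model in enumerate(models):
        for si, snr in enumerate(config.snr_grid_db):
            for ri in range(config.n_realizations):
                seed = realization_seed(config.seed, ci, si, ri)
                chan = generate_channel(model, dictionary, config, snr, seed)
                rel = Path(model.channel_id) / f"snr_{snr:g}dB" / f"real_{ri:02d}"
                hio.export_channel(chan, out / rel)
                records.append(
                    {
                        "channel_id": model.channel_id,
                        "snr_db": snr,
                        "realization": ri,
                        "path": str(rel),
                        "seed": seed,
                    }
                )
    manifest = {
        "master_seed": config.seed,
        "channels": [m.channel_id for m in models],
        "snr_grid_db": list(config.snr_grid_db),
        "n_realizations": config.n_realizations,
        "config": config.to_dict(),
        "records": records,
        "format_version": 1,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
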