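"""The five benchmarked HFO detectors and their shared front-end."""

from .base import Detection, DetectorOutput, bandpass_80_500
from .delphos import DelphosParams, detect_delphos, hfo_oscillations
from .hil import HILParams, detect_hil
from .mni import MNIParams, detect_mni
from .sll import SLLParams, detect_sll
from .ste import STEParams, detect_ste

DETECTORS = {
    "ste": detect_ste,
    "sll": detect_sll,
    "hil": detect_hil,
    "mni": detect_mni,
    "delphos": detect_delphos,
}


def run_detector(name: str, signal, fs: float, params=None) -> DetectorOutput:
    """Dispatch by detector name; Delphos output is reduced to its in-band
    oscillation detections so every detector yields comparable HFO calls."""
    try:
        fn = DETECTORS[name]
    except KeyError:
        raise ValueError(f"unknown detector {name!r}; choose from {sorted(DETECTORS)}")
    out = fn(signal, fs) if params is None else fn(signal, fs, params)
    if name == "delphos":
        out = DetectorOutput(hfo_oscillations(out.detections), out.threshold, out.extras)
    return out


__all__ = [
    "Detection",
    "DetectorOutput",
    "bandpass_80_500",
    "detect_ste",
    "detect_sll",
    "detect_hil",
    "detect_mni",
    "detect_delphos",
    "hfo_oscillations",
    "run_detector",
    "STEParams",
    "SLLParams",
    "HILParams",
    "MNIParams",
    "DelphosParams",
    "DETECTORS",
]
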