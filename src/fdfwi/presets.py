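"""Shipped frequency-schedule presets and YAML config loading.

Each preset mirrors a published acquisition protocol: two-pass FWI frequency
lists (pass 2 staggered half a step above pass 1), the recorded band used for
frequency differencing, the difference-frequency grid, and the homogeneous
starting sound speed.
"""

from __future__ import annotations

import warnings

import yaml

from .freqdiff import FDBand
from .fwi import FrequencySchedule

__all__ = ["frange", "SCHEDULE_PRESETS", "get_schedule", "load_schedule_yaml"]


def frange(start_hz: float, stop_hz: float, step_hz: float) -> tuple[float, ...]:
    """Inclusive frequency ladder start:step:stop, robust to float drift."""
    n = int(round((stop_hz - start_hz) / step_hz)) + 1
    return tuple(float(start_hz + i * step_hz) for i in range(n))


def _preset(p1, p2, band, deltas, start_c):
    with warnings.catch_warnings():
        # published configurations knowingly stretch the df << f_low regime
        warnings.simplefilter("ignore")
        fd_band = FDBand(band[0], band[1], deltas)
    return {
        "schedule": FrequencySchedule(
            pass1_frequencies=p1,
            pass2_frequencies=p2,
            fd_band=fd_band,
        ),
        "start_sound_speed": start_c,
    }


#: Protocols for the four study configurations: a 512-element simulated ring,
#: an in vitro breast phantom, an ethanol-preserved human brain (elevated
#: 1600 m/s start), and a transcranial replica-skull scenario.
SCHEDULE_PRESETS: dict[str, dict] = {
    "simulated": _preset(
        frange(0.60e6, 1.25e6, 50e3),
        frange(0.625e6, 1.275e6, 50e3),
        (0.6e6, 5.0e6),
        frange(0.15e6, 0.95e6, 50e3),
        1480.0,
    ),
    "breast_phantom": _preset(
        frange(0.75e6, 1.0e6, 50e3),
        frange(0.775e6, 1.025e6, 50e3),
        (0.75e6, 4.0e6),
        frange(0.10e6, 0.55e6, 50e3),
        1480.0,
    ),
    "preserved_brain": _preset(
        frange(0.45e6, 1.0e6, 50e3),
        frange(0.475e6, 1.025e6, 50e3),
        (1.0e6, 5.0e6),
        frange(0.10e6, 0.55e6, 50e3),
        1600.0,
    ),
    "transcranial": _preset(
        frange(0.55e6, 1.0e6, 50e3),
        frange(0.575e6, 1.025e6, 50e3),
        (1.0e6, 5.0e6),
        frange(0.10e6, 0.90e6, 50e3),
        1480.0,
    ),
}


def get_schedule(name: str) -> tuple[FrequencySchedule, float]:
    """Look up a shipped preset; returns (schedule, starting sound speed)."""
    if name not in SCHEDULE_PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(SCHEDULE_PRESETS)}")
    p = SCHEDULE_PRESETS[name]
    return p["schedule"], p["start_sound_speed"]


def load_schedule_yaml(path) -> tuple[FrequencySchedule, float]:
    """Load a schedule from YAML.

    Layout (all frequencies in Hz)::

        pass1: {start: 0.6e6, stop: 1.25e6, step: 50.0e3}   # or a list
        pass2: {start: 0.625e6, stop: 1.275e6, step: 50.0e3}
        fd: {band: [0.6e6, 5.0e6], delta: {start: 0.15e6, stop: 0.95e6, step: 50.0e3}}
        cg_iterations_main: 3
        cg_iterations_fd: 2
        start_sound_speed: 1480.0
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    def flist(entry):
        if isinstance(entry, dict):
            return frange(float(entry["start"]), float(entry["stop"]), float(entry["step"]))
        return tuple(float(f) for f in entry)

    fd_band = None
    if "fd" in cfg:
        band = cfg["fd"]["band"]
        fd_band = FDBand(float(band[0]), float(band[1]), flist(cfg["fd"]["delta"]))
    schedule = FrequencySchedule(
        pass1_frequencies=flist(cfg.get("pass1", ())),
        pass2_frequencies=flist(cfg.get("pass2", ())),
        fd_band=fd_band,
        cg_iterations_main=int(cfg.get("cg_iterations_main", 3)),
        cg_iterations_fd=int(cfg.get("cg_iterations_fd", 2)),
    )
    return schedule, float(cfg.get("start_sound_speed", 1480.0))
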