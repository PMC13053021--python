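"""Perceptually smooth stimulus continua for colour and material.

Colour stimuli live in CIELAB, which is approximately perceptually
uniform, so a straight line between two endpoint coordinates yields a
smooth categorical gradient (e.g. blue -> green).  Material stimuli are
impact sounds characterised by their resonant modes; interpolating the
modal parameters (amplitude, centre frequency, decay rate) between two
materials yields a smooth wood -> metal style gradient.  Both continua
use 1-based step indexing with the endpoints included in the step count,
so "10 steps" means the two endpoints plus eight interior stimuli.

Impact sounds are rendered with a minimal additive synthesiser: a sum of
exponentially damped sinusoids, one per mode.  This is deliberately the
simplest generative model consistent with (amplitude, frequency, decay)
triples; it is not a full contact-acoustics simulation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LabColour",
    "ColourContinuum",
    "ModeParams",
    "MaterialSpec",
    "SoundContinuum",
    "Waveform",
    "interpolate_lab",
    "lab_to_srgb",
    "interpolate_modal",
    "synthesize_impact",
    "normalise_volume",
    "default_material",
    "write_wav",
    "write_colour_manifest",
    "colour_continuum_from_config",
    "sound_continuum_from_config",
    "EXP1_COLOUR_ENDPOINTS",
    "EXP2_COLOUR_ENDPOINTS",
]

# CIELAB endpoint coordinates of the two experiment-one colour continua
# (cool: blue->green, warm: yellow->orange), and the perceptually
# proximate experiment-two pair with equalised lightness.
EXP1_COLOUR_ENDPOINTS = {
    "cool": (("blue", (73.03, -19.98, 37.84)), ("green", (87.24, -62.94, 41.00))),
    "warm": (("yellow", (88.29, -0.98, 69.51)), ("orange", (68.55, 40.91, 49.37))),
}
EXP2_COLOUR_ENDPOINTS = {
    "blue": (73.0, -36.31, -13.94),
    "green": (73.0, -54.46, 13.65),
}


@dataclass(frozen=True)
class LabColour:
    """A point in CIELAB space: lightness L* in [0, 100], opponent axes a*, b*."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        vals = (self.L, self.a, self.b)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite CIELAB coordinates: {vals}")
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"lightness must be in [0, 100], got {self.L}")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class ColourContinuum:
    """An ordered, equally spaced sequence of CIELAB colours between two labels."""

    label_A: str
    label_B: str
    steps: tuple[LabColour, ...]

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def __getitem__(self, step: int) -> LabColour:
        """1-based access: step 1 is endpoint A, step ``n_steps`` is endpoint B."""
        if not 1 <= step <= self.n_steps:
            raise IndexError(f"step {step} outside [1, {self.n_steps}]")
        return self.steps[step - 1]


@dataclass(frozen=True)
class ModeParams:
    """One resonant mode of an impact sound."""

    amplitude: float  # linear gain, >= 0
    frequency: float  # Hz, > 0
    decay: float      # exponential decay rate, 1/s, >= 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.decay < 0:
            raise ValueError("decay rate must be >= 0")


@dataclass(frozen=True)
class MaterialSpec:
    """A material's impact sound: a set of modes plus a fixed 1 s duration."""

    label: str
    modes: tuple[ModeParams, ...]
    duration: float = 1.0

    def __post_init__(self) -> None:
        if len(self.modes) < 1:
            raise ValueError("a material needs at least one mode")


@dataclass(frozen=True)
class SoundContinuum:
    label_A: str
    label_B: str
    steps: tuple[MaterialSpec, ...]

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def __getitem__(self, step: int) -> MaterialSpec:
        if not 1 <= step <= self.n_steps:
            raise IndexError(f"step {step} outside [1, {self.n_steps}]")
        return self.steps[step - 1]


@dataclass(frozen=True)
class Waveform:
    samples: np.ndarray
    sample_rate: int

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def peak(self) -> float:
        return float(np.max(np.abs(self.samples)))


def _affine_grid(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    """Rows are steps 1..n; row s = a + (b - a) * (s - 1) / (n - 1)."""
    w = np.linspace(0.0, 1.0, n)[:, None]
    return a[None, :] + w * (b - a)[None, :]


def interpolate_lab(A: LabColour, B: LabColour, n: int,
                    label_A: str = "A", label_B: str = "B") -> ColourContinuum:
    """Linearly interpolate ``n`` equally spaced CIELAB steps from A to B.

    Step 1 reproduces A exactly and step ``n`` reproduces B exactly; every
    coordinate is affine in the step index.
    """
    if n < 2:
        raise ValueError(f"a continuum needs at least 2 steps, got n={n}")
    grid = _affine_grid(A.as_array(), B.as_array(), n)
    grid[0] = A.as_array()
    grid[-1] = B.as_array()
    steps = tuple(LabColour(*row) for row in grid)
    return ColourContinuum(label_A=label_A, label_B=label_B, steps=steps)


# --- CIELAB -> sRGB ---------------------------------------------------------
# Standard D65 2-degree white point and the sRGB (IEC 61966-2-1) matrix.
_D65 = np.array([0.95047, 1.0, 1.08883])
_XYZ_TO_RGB = np.array([
    [3.2404542, -1.5371385, -0.4985314],
    [-0.9692660, 1.8760108, 0.0415560],
    [0.0556434, -0.2040259, 1.0572252],
])
_DELTA = 6.0 / 29.0


def _lab_f_inv(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA, t ** 3, 3.0 * _DELTA ** 2 * (t - 4.0 / 29.0))


def _srgb_encode(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * np.power(np.clip(c, 0, None), 1 / 2.4) - 0.055)


def lab_to_srgb(c: LabColour) -> tuple[tuple[int, int, int], str]:
    """Convert a CIELAB colour to an 8-bit sRGB triple and hex string.

    Uses the D65 white point and the standard piecewise sRGB gamma.
    Out-of-gamut channels are clipped to [0, 255] with a warning logged;
    staircase logic only ever depends on the step index, so clipping is
    cosmetically safe.
    """
    fy = (c.L + 16.0) / 116.0
    fx = fy + c.a / 500.0
    fz = fy - c.b / 200.0
    xyz = _D65 * _lab_f_inv(np.array([fx, fy, fz]))
    rgb_lin = _XYZ_TO_RGB @ xyz
    if np.any(rgb_lin < -1e-4) or np.any(rgb_lin > 1 + 1e-4):
        logger.warning("CIELAB %s out of sRGB gamut; clipping", (c.L, c.a, c.b))
    rgb = _srgb_encode(np.clip(rgb_lin, 0.0, 1.0))
    rgb8 = tuple(int(v) for v in np.clip(np.round(rgb * 255.0), 0, 255).astype(int))
    hexcode = "#{:02x}{:02x}{:02x}".format(*rgb8)
    return rgb8, hexcode


# --- material continua ------------------------------------------------------

def interpolate_modal(A: MaterialSpec, B: MaterialSpec, n: int = 10) -> SoundContinuum:
    """Linearly interpolate modal parameters between two materials.

    Modes are paired in ascending-frequency order (deterministic and
    spectral-order preserving); each paired mode's amplitude, frequency
    and decay are affine in the step index, endpoints reproduced exactly.
    """
    if n < 2:
        raise ValueError(f"a continuum needs at least 2 steps, got n={n}")
    if len(A.modes) != len(B.modes):
        raise ValueError(
            f"mode counts differ: {A.label} has {len(A.modes)}, {B.label} has {len(B.modes)}"
        )
    mode_arr = lambda m: np.array([[p.amplitude, p.frequency, p.decay]
                                   for p in sorted(m.modes, key=lambda p: p.frequency)])
    a, b = mode_arr(A), mode_arr(B)
    steps = []
    w = np.linspace(0.0, 1.0, n)
    for s, ws in enumerate(w):
        params = (1.0 - ws) * a + ws * b
        if s == 0:
            params = a
        elif s == n - 1:
            params = b
        modes = tuple(ModeParams(*row) for row in params)
        steps.append(MaterialSpec(label=f"{A.label}-{B.label}:{s + 1}", modes=modes,
                                  duration=A.duration))
    return SoundContinuum(label_A=A.label, label_B=B.label, steps=tuple(steps))


def synthesize_impact(m: MaterialSpec, sample_rate: int = 44100) -> Waveform:
    """Render a material spec as a 1 s sum of damped sinusoids.

    samples(t) = sum_i a_i * exp(-d_i t) * sin(2 pi f_i t), then
    peak-limited (clipped) to [-1, 1].
    """
    fmax = max(p.frequency for p in m.modes)
    if sample_rate <= 2 * fmax:
        raise ValueError(
            f"sample rate {sample_rate} Hz violates Nyquist for mode at {fmax} Hz"
        )
    n = int(round(m.duration * sample_rate))
    t = np.arange(n) / sample_rate
    samples = np.zeros(n)
    for p in m.modes:
        samples += p.amplitude * np.exp(-p.decay * t) * np.sin(2 * np.pi * p.frequency * t)
    samples = np.clip(samples, -1.0, 1.0)
    return Waveform(samples=samples, sample_rate=sample_rate)


def normalise_volume(w: Waveform, target_rms: float = 0.1, mode: str = "rms") -> Waveform:
    """Rescale a waveform to a target level (RMS by default, optionally peak)."""
    if mode not in ("rms", "peak"):
        raise ValueError(f"mode must be 'rms' or 'peak', got {mode!r}")
    level = w.rms() if mode == "rms" else w.peak()
    if level <= 0.0:
        raise ValueError("cannot normalise a zero-energy waveform")
    return Waveform(samples=w.samples * (target_rms / level), sample_rate=w.sample_rate)


# --- default material fixtures ---------------------------------------------
# Placeholder modal parameter sets for the four materials.  The source
# recordings' parameters are not published; these are synthetic stand-ins
# chosen so that soft materials (wood, cardboard) have low-frequency,
# fast-decaying modes and hard materials (metal, glass) have higher,
# ring-ier modes.  All continuum/staircase logic depends only on step
# indices, never on these values.
_DEFAULT_MATERIALS: Mapping[str, tuple[tuple[float, float, float], ...]] = {
    "wood": tuple((0.9 / (i + 1), 180.0 * (i + 1) * 1.12, 28.0 + 4.0 * i) for i in range(10)),
    "cardboard": tuple((0.8 / (i + 1), 150.0 * (i + 1) * 1.07, 40.0 + 5.0 * i) for i in range(10)),
    "metal": tuple((0.9 / (i + 1), 420.0 * (i + 1) * 1.31, 3.0 + 0.8 * i) for i in range(10)),
    "glass": tuple((0.85 / (i + 1), 520.0 * (i + 1) * 1.48, 5.0 + 1.1 * i) for i in range(10)),
}


def default_material(name: str) -> MaterialSpec:
    """Packaged synthetic modal parameter set for wood/cardboard/metal/glass."""
    try:
        rows = _DEFAULT_MATERIALS[name]
    except KeyError:
        raise ValueError(f"unknown material {name!r}; choose from {sorted(_DEFAULT_MATERIALS)}")
    return MaterialSpec(label=name, modes=tuple(ModeParams(*r) for r in rows))


# --- I/O --------------------------------------------------------------------

def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV."""
    from scipy.io import wavfile

    pcm = np.clip(np.round(w.samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), w.sample_rate, pcm)


def write_colour_manifest(path: str | Path, continua: Mapping[str, ColourContinuum]) -> None:
    """CSV manifest: continuum, step, L, a, b, hex."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["continuum", "step", "L", "a", "b", "hex"])
        for name, cont in continua.items():
            for s in range(1, cont.n_steps + 1):
                c = cont[s]
                _, hexcode = lab_to_srgb(c)
                writer.writerow([name, s, f"{c.L:.4f}", f"{c.a:.4f}", f"{c.b:.4f}", hexcode])


def colour_continuum_from_config(cfg: Mapping) -> ColourContinuum:
    """Build a colour continuum from a config block.

    Expected keys: ``label_A``, ``label_B``, ``endpoint_A``, ``endpoint_B``
    (each a [L, a, b] triple) and ``n_steps``.
    """
    for key in ("label_A", "label_B", "endpoint_A", "endpoint_B", "n_steps"):
        if key not in cfg:
            raise ValueError(f"colour continuum config missing field {key!r}")
    return interpolate_lab(
        LabColour(*cfg["endpoint_A"]), LabColour(*cfg["endpoint_B"]),
        int(cfg["n_steps"]), label_A=cfg["label_A"], label_B=cfg["label_B"],
    )


def sound_continuum_from_config(cfg: Mapping) -> SoundContinuum:
    """Build a sound continuum from a config block.

    Expected keys: ``material_A``, ``material_B`` (names from the packaged
    fixture set, or explicit ``modes_A``/``modes_B`` lists of
    [amplitude, frequency, decay] triples) and ``n_steps``.
    """
    if "n_steps" not in cfg:
        raise ValueError("sound continuum config missing field 'n_steps'")

    def spec(side: str) -> MaterialSpec:
        if f"modes_{side}" in cfg:
            modes = tuple(ModeParams(*row) for row in cfg[f"modes_{side}"])
            return MaterialSpec(label=cfg.get(f"material_{side}", side), modes=modes)
        if f"material_{side}" not in cfg:
            raise ValueError(f"sound continuum config missing field 'material_{side}'")
        return default_material(cfg[f"material_{side}"])

    return interpolate_modal(spec("A"), spec("B"), int(cfg["n_steps"]))
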