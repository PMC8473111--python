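"""Seeded synthetic generator of labeled seat-pressure frames.

Real seat-pressure maps of a seated adult show two sharp peaks under the
ischial tuberosities plus two broader, lighter thigh regions. Each of the six
posture classes perturbs that base pattern in a characteristic way:

* ``SS`` (standard sitting) — symmetric two-peak pattern.
* ``LL`` / ``LR`` (lean left/right) — the whole pattern and its load share
  shift toward the named side.
* ``LC`` / ``RC`` (left/right cross-legs) — the crossed leg's thigh lifts off
  the seat (that thigh component is suppressed) and the opposite ischial peak
  carries extra load.
* ``WB`` (waist bow, slumping forward) — the pattern shifts toward the seat
  front and concentrates, with more load on the thighs.

Templates are sums of anisotropic 2-D Gaussian load components; amplitudes are
relative load shares summing to 1, and the frame total scales linearly with
subject weight. Generated ideal pressures are pushed through the electrical
chain (pressure -> cell resistance -> divider voltage, Gaussian voltage noise,
back to pressure) so frames carry realistic acquisition noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .sensor import (
    POSTURE_CLASSES,
    PressureFrame,
    SensorSpec,
    apply_collection_threshold,
    pressure_to_resistance,
    resistance_to_pressure,
    resistance_to_voltage,
    voltage_to_resistance,
)

__all__ = [
    "PostureTemplate",
    "GeneratorConfig",
    "posture_template",
    "generate_frame",
    "generate_dataset",
    "inject_midpoint_frames",
]

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PostureTemplate:
    """Generative template for one posture class.

    ``component_centers`` are (row, col) coordinates on the sensor grid
    (row 0 = seat front edge, col 0 = sitter's left); ``component_spreads`` are
    (row_sd, col_sd) scales in cells; ``component_amplitudes`` are relative
    load shares (non-negative, summing to 1).
    """

    class_id: str
    component_centers: tuple[tuple[float, float], ...]
    component_spreads: tuple[tuple[float, float], ...]
    component_amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.class_id not in POSTURE_CLASSES:
            raise ValueError(f"unknown posture class {self.class_id!r}")
        n = len(self.component_centers)
        if not (len(self.component_spreads) == len(self.component_amplitudes) == n):
            raise ValueError("component lists must have equal length")
        amps = np.asarray(self.component_amplitudes, float)
        if np.any(amps < 0):
            raise ValueError("amplitudes must be non-negative")
        if abs(amps.sum() - 1.0) > 1e-9:
            raise ValueError("amplitudes must sum to 1")


def _normalized(amps: Sequence[float]) -> tuple[float, ...]:
    a = np.asarray(amps, float)
    return tuple(a / a.sum())


def _mirror(template: PostureTemplate, class_id: str, n_cols: int = 32) -> PostureTemplate:
    """Left-right reflection of a template (col -> n_cols - 1 - col)."""
    centers = tuple((r, n_cols - 1 - c) for r, c in template.component_centers)
    return replace(template, class_id=class_id, component_centers=centers)


def _build_templates() -> dict[str, PostureTemplate]:
    # Component order: ischial L, ischial R, thigh L, thigh R.
    isch_l, isch_r = (20.0, 11.5), (20.0, 20.5)
    thigh_l, thigh_r = (10.0, 11.5), (10.0, 20.5)
    isch_sd, thigh_sd = (2.8, 2.5), (5.0, 3.0)
    sds = (isch_sd, isch_sd, thigh_sd, thigh_sd)

    ss = PostureTemplate("SS", (isch_l, isch_r, thigh_l, thigh_r), sds,
                         _normalized((0.30, 0.30, 0.20, 0.20)))

    # Lean left: pattern shifts 4 cells left, load share follows.
    ll = PostureTemplate(
        "LL",
        tuple((r, c - 4.0) for r, c in ss.component_centers),
        sds,
        _normalized((0.44, 0.16, 0.27, 0.13)),
    )

    # Left cross-legs: the left thigh lifts off the seat, the left ischium
    # rises and slides forward/inward with the pelvic tilt, and the right
    # side carries the extra load.
    lc = PostureTemplate(
        "LC",
        ((16.0, 13.5), (20.5, 21.5), (7.0, 15.0), (10.0, 21.5)),
        sds,
        _normalized((0.25, 0.45, 0.03, 0.27)),
    )

    # Waist bow: 5-cell shift toward the seat front (low rows), tighter
    # spreads, thigh-heavy load.
    wb = PostureTemplate(
        "WB",
        tuple((r - 5.0, c) for r, c in ss.component_centers),
        tuple((0.75 * sr, 0.75 * sc) for sr, sc in sds),
        _normalized((0.26, 0.26, 0.24, 0.24)),
    )

    return {
        "SS": ss,
        "LL": ll,
        "LR": _mirror(ll, "LR"),
        "LC": lc,
        "RC": _mirror(lc, "RC"),
        "WB": wb,
    }


_TEMPLATES = _build_templates()


def posture_template(class_id: str) -> PostureTemplate:
    """Default generative template for ``class_id``."""
    try:
        return _TEMPLATES[class_id]
    except KeyError:
        raise ValueError(f"unknown posture class {class_id!r}") from None


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-frame generator.

    ``weight_range`` is the sampled subject-weight interval in kg;
    ``load_per_kg`` converts weight into summed frame pressure (fit units per
    kg). The jitter scales perturb component geometry per frame:
    ``center_jitter`` (cells) translates the whole pattern,
    ``component_jitter`` (cells) moves each component independently, and
    ``spread_jitter`` / ``amp_jitter`` are log-normal sigmas on spreads and
    amplitudes. ``voltage_noise`` (volts, sd) is added at the ADC input.
    """

    weight_range: tuple[float, float] = (45.0, 80.0)
    load_per_kg: float = 5.0
    center_jitter: float = 0.5
    component_jitter: float = 0.25
    spread_jitter: float = 0.06
    amp_jitter: float = 0.06
    voltage_noise: float = 0.005
    sensor: SensorSpec = field(default_factory=SensorSpec)


def _render_template(template: PostureTemplate, rng: np.random.Generator,
                     cfg: GeneratorConfig) -> np.ndarray:
    """Ideal (noise-free chain) pressure pattern with per-frame jitter,
    normalised to unit total load."""
    rows, cols = cfg.sensor.shape
    rr, cc = np.meshgrid(np.arange(rows, dtype=float),
                         np.arange(cols, dtype=float), indexing="ij")
    frame = np.zeros((rows, cols))
    d_row, d_col = rng.normal(0.0, cfg.center_jitter, size=2)
    amps = np.asarray(template.component_amplitudes) * np.exp(
        rng.normal(0.0, cfg.amp_jitter, size=len(template.component_amplitudes)))
    amps /= amps.sum()
    for (r0, c0), (sr, sc), amp in zip(template.component_centers,
                                       template.component_spreads, amps):
        r0 = r0 + d_row + rng.normal(0.0, cfg.component_jitter)
        c0 = c0 + d_col + rng.normal(0.0, cfg.component_jitter)
        sr = sr * np.exp(rng.normal(0.0, cfg.spread_jitter))
        sc = sc * np.exp(rng.normal(0.0, cfg.spread_jitter))
        bump = np.exp(-0.5 * (((rr - r0) / sr) ** 2 + ((cc - c0) / sc) ** 2))
        total = bump.sum()
        if total > 0:
            frame += amp * bump / total
    return frame


def _sensor_chain(pressure: np.ndarray, rng: np.random.Generator,
                  cfg: GeneratorConfig) -> np.ndarray:
    """Emulate acquisition: pressure -> resistance -> noisy voltage -> pressure."""
    spec = cfg.sensor
    r = pressure_to_resistance(pressure, spec)
    u = resistance_to_voltage(r, spec)
    if cfg.voltage_noise > 0:
        u = u + rng.normal(0.0, cfg.voltage_noise, size=u.shape)
    eps = 1e-6
    u = np.clip(u, eps, spec.v_ref - eps)
    measured = resistance_to_pressure(voltage_to_resistance(u, spec), spec, clamp=True)
    return measured


def generate_frame(class_id: str, weight_kg: Optional[float] = None,
                   rng_seed: RngLike = 0,
                   config: GeneratorConfig = GeneratorConfig(),
                   subject_id: Optional[str] = None) -> PressureFrame:
    """Draw one labeled synthetic frame; deterministic given the seed.

    ``weight_kg`` defaults to a uniform draw from ``config.weight_range``.
    Total frame load is ``weight_kg * config.load_per_kg`` before acquisition
    noise, so load is monotone in weight.
    """
    rng = _rng(rng_seed)
    template = posture_template(class_id)
    if weight_kg is None:
        weight_kg = float(rng.uniform(*config.weight_range))
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    ideal = _render_template(template, rng, config) * weight_kg * config.load_per_kg
    measured = _sensor_chain(ideal, rng, config)
    frame = PressureFrame(measured, label=class_id, subject_id=subject_id,
                          weight_kg=weight_kg)
    return apply_collection_threshold(frame, config.sensor)


def generate_dataset(n_per_class: int, rng_seed: RngLike = 0,
                     config: GeneratorConfig = GeneratorConfig()) -> list[PressureFrame]:
    """Class-balanced labeled dataset: ``6 * n_per_class`` frames.

    Classes appear in the fixed order LC, RC, LL, LR, WB, SS, ``n_per_class``
    frames each, with per-frame subject weights drawn from
    ``config.weight_range``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = _rng(rng_seed)
    frames: list[PressureFrame] = []
    for class_id in POSTURE_CLASSES:
        for i in range(n_per_class):
            frames.append(generate_frame(class_id, None, rng, config,
                                         subject_id=f"{class_id}{i:04d}"))
    return frames


def inject_midpoint_frames(frames: Sequence[PressureFrame], fraction: float = 0.1,
                           rng_seed: RngLike = 0) -> list[PressureFrame]:
    """Salt a dataset with ambiguous between-class frames.

    Appends ``round(fraction * len(frames))`` frames, each the cell-wise mean
    of two frames drawn from different classes and labeled as one of the two
    parents (chosen at random). These sit near class boundaries and are the
    kind of sample the differentiation filter is designed to discard.
    """
    if not 0 <= fraction:
        raise ValueError("fraction must be non-negative")
    rng = _rng(rng_seed)
    frames = list(frames)
    by_class: dict[str, list[int]] = {}
    for i, f in enumerate(frames):
        if f.label is not None:
            by_class.setdefault(f.label, []).append(i)
    classes = [c for c in POSTURE_CLASSES if c in by_class]
    if len(classes) < 2:
        raise ValueError("need labeled frames from at least two classes")
    n_extra = int(round(fraction * len(frames)))
    out = list(frames)
    for _ in range(n_extra):
        ca, cb = rng.choice(len(classes), size=2, replace=False)
        ca, cb = classes[ca], classes[cb]
        fa = frames[rng.choice(by_class[ca])]
        fb = frames[rng.choice(by_class[cb])]
        label = ca if rng.random() < 0.5 else cb
        mid = 0.5 * (fa.values + fb.values)
        out.append(PressureFrame(mid, label=label, subject_id="midpoint"))
    return out
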