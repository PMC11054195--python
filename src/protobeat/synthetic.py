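"""Seeded generator of labeled single-beat waveforms.

Emulates the three-class single-heartbeat task at a 300 Hz sampling rate:

- **N** (normal sinus): Gaussian P wave, narrow tall biphasic QRS (positive R
  lobe followed by a negative S lobe), Gaussian T wave.
- **A** (atrial fibrillation): no P wave; instead an irregular low-amplitude
  fibrillatory baseline (a few 5-9 Hz sinusoids with random phase), plus
  wider beat-to-beat variation of the QRS amplitude.
- **O** (other rhythm): P wave present but the QRS or T is deformed — widened
  QRS, inverted T, or a supplementary notch peak after the R wave.

White Gaussian noise is added on top. Every beat is fully determined by its
``BeatRecipe`` (component parameters + a noise seed), which the generator
returns alongside the data as ground-truth provenance for tests. Component
timing is expressed in seconds and placed at fixed fractions of the beat
duration, so the generator works at any ``samples_per_beat``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledSequence

CLASS_CODES = {"N": 0, "A": 1, "O": 2}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}


@dataclass
class SyntheticConfig:
    samples_per_beat: int = 180  # 0.6 s at 300 Hz
    n_per_class: int = 600
    classes: tuple[str, ...] = ("N", "A", "O")
    noise_sd: float = 0.03
    seed: int = 0
    sampling_rate: float = 300.0

    def __post_init__(self) -> None:
        if self.samples_per_beat < 30:
            raise ValueError("samples_per_beat must be >= 30")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.classes) - set(CLASS_CODES)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")

    @property
    def duration(self) -> float:
        return self.samples_per_beat / self.sampling_rate


@dataclass
class WaveComponent:
    """One additive component: a Gaussian bump, or a fibrillatory oscillation."""

    kind: str  # P | R | S | T | notch | fib
    center: float = 0.0      # seconds (bump kinds)
    width: float = 0.0       # seconds (bump kinds)
    amplitude: float = 0.0   # signed peak (bump kinds)
    freqs: tuple[float, ...] = ()    # Hz (fib)
    amps: tuple[float, ...] = ()     # fib sinusoid amplitudes
    phases: tuple[float, ...] = ()   # radians (fib)


@dataclass
class BeatRecipe:
    label: int
    class_name: str
    components: list[WaveComponent]
    noise_seed: int
    noise_sd: float = 0.0
    id: str = ""

    def has(self, kind: str) -> bool:
        return any(c.kind == kind for c in self.components)

    @property
    def amplitude_budget(self) -> float:
        """Upper bound on the noise-free |signal|: sum of component peak amplitudes."""
        total = 0.0
        for c in self.components:
            total += sum(abs(a) for a in c.amps) if c.kind == "fib" else abs(c.amplitude)
        return total


def synth_beat(recipe: BeatRecipe, config: SyntheticConfig) -> LabeledSequence:
    """Render one recipe into a waveform; deterministic given the recipe."""
    t = np.arange(config.samples_per_beat) / config.sampling_rate
    wave = np.zeros_like(t)
    for c in recipe.components:
        if c.kind == "fib":
            for f, a, ph in zip(c.freqs, c.amps, c.phases):
                wave += a * np.sin(2.0 * np.pi * f * t + ph)
        else:
            wave += c.amplitude * np.exp(-0.5 * ((t - c.center) / c.width) ** 2)
    if recipe.noise_sd > 0:
        rng = np.random.default_rng(recipe.noise_seed)
        wave = wave + rng.normal(0.0, recipe.noise_sd, wave.size)
    return LabeledSequence(wave, recipe.label, recipe.id)


def _sample_recipe(cls: str, config: SyntheticConfig, rng: np.random.Generator,
                   beat_id: str) -> BeatRecipe:
    dur = config.duration
    u = rng.uniform
    comps: list[WaveComponent] = []
    r_center = u(0.48, 0.52) * dur
    r_width = u(0.013, 0.020) * dur
    if cls == "N":
        comps.append(WaveComponent("P", u(0.17, 0.23) * dur, u(0.030, 0.042) * dur,
                                   u(0.12, 0.20)))
        r_amp = u(0.90, 1.10)
        t_amp = u(0.25, 0.35)
        t_width = u(0.058, 0.083) * dur
    elif cls == "A":
        nfib = int(rng.integers(2, 4))
        comps.append(WaveComponent(
            "fib",
            freqs=tuple(u(5.0, 9.0) for _ in range(nfib)),
            amps=tuple(u(0.02, 0.05) for _ in range(nfib)),
            phases=tuple(u(0.0, 2.0 * np.pi) for _ in range(nfib)),
        ))
        r_amp = u(0.65, 1.35)  # irregular ventricular filling -> amplitude swings
        t_amp = u(0.15, 0.35)
        t_width = u(0.058, 0.100) * dur
    elif cls == "O":
        comps.append(WaveComponent("P", u(0.17, 0.23) * dur, u(0.030, 0.042) * dur,
                                   u(0.12, 0.20)))
        r_amp = u(0.90, 1.10)
        t_amp = u(0.25, 0.35)
        t_width = u(0.058, 0.083) * dur
        deform = rng.integers(3)
        if deform == 0:    # widened, lower QRS
            r_width = u(0.033, 0.058) * dur
            r_amp = u(0.60, 0.85)
        elif deform == 1:  # inverted T
            t_amp = -t_amp
        else:              # supplementary notch peak after R
            comps.append(WaveComponent("notch", r_center + 0.067 * dur,
                                       u(0.013, 0.020) * dur, u(0.40, 0.60)))
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(cls)
    comps.append(WaveComponent("R", r_center, r_width, r_amp))
    comps.append(WaveComponent("S", r_center + 0.042 * dur, u(0.013, 0.020) * dur,
                               -u(0.18, 0.32)))
    comps.append(WaveComponent("T", u(0.73, 0.80) * dur, t_width, t_amp))
    return BeatRecipe(
        label=CLASS_CODES[cls], class_name=cls, components=comps,
        noise_seed=int(rng.integers(2**31)), noise_sd=config.noise_sd, id=beat_id,
    )


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[list[LabeledSequence], list[BeatRecipe]]:
    """Draw ``n_per_class`` recipes per class from the seeded generator and render them."""
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    seqs: list[LabeledSequence] = []
    recipes: list[BeatRecipe] = []
    for cls in config.classes:
        for i in range(config.n_per_class):
            recipe = _sample_recipe(cls, config, rng, f"{cls}{i:04d}")
            recipes.append(recipe)
            seqs.append(synth_beat(recipe, config))
    return seqs, recipes


def fixture_tiny() -> tuple[list[LabeledSequence], list[BeatRecipe]]:
    """Deterministic 2-class (N vs A), 60-beat, noise-free mini dataset.

    Linearly separable in raw space: the mean amplitude over the P-wave window
    alone separates the classes, since only class N carries a P bump there.
    """
    config = SyntheticConfig(samples_per_beat=90, n_per_class=30,
                             classes=("N", "A"), noise_sd=0.0, seed=424243)
    return generate_dataset(config)
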