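"""Synthetic single-trial EEG generator with known latent component structure.

Each simulated trial is the sum of

* an N400-like component: a gaussian kernel (peak 1 at ``center_ms``,
  standard deviation ``width_ms``) scaled by a latent per-trial amplitude
  (negative = larger N400),
* a P600-like component: a plateau kernel equal to 1 on
  [``onset_ms``, ``offset_ms``] with raised-cosine ramps of ``width_ms/2``
  on each side, scaled by a latent positive amplitude,
* a directed linear voltage drift (per-trial slope in µV per second,
  anchored at the epoch start),
* an alpha-band sinusoid with a per-trial uniform random phase,
* a per-subject constant offset, and
* i.i.d. gaussian white noise per sample.

The two latent amplitudes are drawn from a bivariate normal whose
condition-specific correlation (``coupling_rho``) is the ground-truth
within-trial N400–P600 coupling that the downstream regression analysis
tries to detect. The generator returns both the epochs and a ground-truth
table of the exact injected latents, so every pipeline stage can be tested
against known truth. No baseline correction is applied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .errors import ConfigurationError

#: Ground truth is a tidy frame with one row per trial and columns
#: subject, item, condition, latent_n400, latent_p600, drift_slope (µV/s)
#: and alpha_phase (radians).
GroundTruth = pd.DataFrame

GROUND_TRUTH_COLUMNS = [
    "subject", "item", "condition",
    "latent_n400", "latent_p600", "drift_slope", "alpha_phase",
]


@dataclass
class ComponentSpec:
    """Temporal kernel and scalp topography of one simulated component."""

    name: str
    kernel: str  # "gaussian" | "plateau"
    topography: dict[str, float]
    center_ms: float | None = None
    width_ms: float = 0.0
    onset_ms: float | None = None
    offset_ms: float | None = None

    def validate(self) -> None:
        if self.kernel not in ("gaussian", "plateau"):
            raise ConfigurationError(f"unknown kernel {self.kernel!r}")
        if self.kernel == "gaussian":
            if self.center_ms is None or self.width_ms <= 0:
                raise ConfigurationError(
                    f"gaussian component {self.name!r} needs center_ms and width_ms > 0"
                )
        else:
            if self.onset_ms is None or self.offset_ms is None or \
                    self.onset_ms >= self.offset_ms:
                raise ConfigurationError(
                    f"plateau component {self.name!r} needs onset_ms < offset_ms"
                )
        if not self.topography:
            raise ConfigurationError(f"component {self.name!r} has empty topography")
        weights = np.asarray(list(self.topography.values()), dtype=float)
        if not np.all(np.isfinite(weights)) or not np.any(weights > 0):
            raise ConfigurationError(
                f"component {self.name!r}: topography weights must be finite "
                "with at least one positive entry"
            )

    def evaluate(self, times_ms: np.ndarray) -> np.ndarray:
        """Unitless kernel values on the time grid (peak value 1)."""
        t = np.asarray(times_ms, dtype=float)
        if self.kernel == "gaussian":
            return np.exp(-0.5 * ((t - self.center_ms) / self.width_ms) ** 2)
        k = np.zeros_like(t)
        on, off, half = self.onset_ms, self.offset_ms, self.width_ms / 2.0
        k[(t >= on) & (t <= off)] = 1.0
        if half > 0:
            rising = (t >= on - half) & (t < on)
            k[rising] = 0.5 * (1.0 - np.cos(np.pi * (t[rising] - (on - half)) / half))
            falling = (t > off) & (t <= off + half)
            k[falling] = 0.5 * (1.0 + np.cos(np.pi * (t[falling] - off) / half))
        return k

    def weight(self, electrode: str) -> float:
        return float(self.topography.get(electrode, 0.0))


@dataclass
class ConditionSpec:
    """Latent amplitude distribution of one experimental condition.

    ``mu_n400`` is the mean latent N400 amplitude in µV (negative = larger
    N400), ``mu_p600`` the mean latent P600 amplitude (positive = larger
    P600), and ``coupling_rho`` the within-condition correlation between
    the two latents.
    """

    name: str
    mu_n400: float
    mu_p600: float
    coupling_rho: float
    sd_n400: float
    sd_p600: float

    def validate(self) -> None:
        if not abs(self.coupling_rho) <= 1:
            raise ConfigurationError(
                f"condition {self.name!r}: |coupling_rho| must be <= 1"
            )
        if self.sd_n400 < 0 or self.sd_p600 < 0:
            raise ConfigurationError(
                f"condition {self.name!r}: latent sds must be >= 0"
            )


@dataclass
class GeneratorConfig:
    """Full specification of one simulated experiment."""

    n_subjects: int
    n_items: int
    conditions: list[ConditionSpec]
    components: list[ComponentSpec]
    electrodes: list[str]
    sampling_rate_hz: float = 250.0
    epoch_start_ms: float = -200.0
    epoch_end_ms: float = 1200.0
    drift_sd: float = 0.0       # µV per 1000 ms (per-trial slope spread)
    alpha_amp_uv: float = 0.0
    alpha_freq_hz: float = 10.0
    noise_sd: float = 0.0
    subject_offset_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be > 0")
        if not (self.epoch_start_ms < 0 < self.epoch_end_ms):
            raise ConfigurationError("epoch must satisfy start < 0 < end (ms)")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not self.conditions:
            raise ConfigurationError("at least one condition is required")
        if self.n_items < len(self.conditions):
            raise ConfigurationError("n_items must be >= number of conditions")
        for p in ("drift_sd", "alpha_amp_uv", "noise_sd", "subject_offset_sd"):
            if getattr(self, p) < 0:
                raise ConfigurationError(f"{p} must be >= 0")
        names = [c.name for c in self.components]
        for required in ("N400", "P600"):
            if names.count(required) != 1:
                raise ConfigurationError(
                    f"components must contain exactly one entry named {required!r}"
                )
        for comp in self.components:
            comp.validate()
        for cond in self.conditions:
            cond.validate()
        if len(set(c.name for c in self.conditions)) != len(self.conditions):
            raise ConfigurationError("condition names must be unique")

    def time_grid(self) -> np.ndarray:
        dt = 1000.0 / self.sampling_rate_hz
        n = int(math.floor((self.epoch_end_ms - self.epoch_start_ms) / dt + 1e-9)) + 1
        return self.epoch_start_ms + dt * np.arange(n)

    def component(self, name: str) -> ComponentSpec:
        for comp in self.components:
            if comp.name == name:
                return comp
        raise ConfigurationError(f"no component named {name!r}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["conditions"] = [
            c if isinstance(c, ConditionSpec) else ConditionSpec(**c)
            for c in d["conditions"]
        ]
        d["components"] = [
            c if isinstance(c, ComponentSpec) else ComponentSpec(**c)
            for c in d["components"]
        ]
        return cls(**d)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_DEFAULT_TOPOGRAPHY = {"Fz": 0.4, "Cz": 0.7, "Pz": 1.0}


def _default_components() -> list[ComponentSpec]:
    return [
        ComponentSpec(name="N400", kernel="gaussian", center_ms=400.0,
                      width_ms=80.0, topography=dict(_DEFAULT_TOPOGRAPHY)),
        ComponentSpec(name="P600", kernel="plateau", onset_ms=600.0,
                      offset_ms=1000.0, width_ms=100.0,
                      topography=dict(_DEFAULT_TOPOGRAPHY)),
    ]


_NOISE_DEFAULTS = dict(
    drift_sd=8.0,
    alpha_amp_uv=2.0,
    alpha_freq_hz=10.0,
    noise_sd=10.0,
    subject_offset_sd=2.0,
)


def preset_biphasic(**overrides) -> GeneratorConfig:
    """Two-condition expectancy design with a biphasic N400–P600 contrast.

    40 subjects x 120 items, conditions Expected/Unexpected with ~3 µV
    effects on both components at Pz, negative within-condition latent
    coupling, and realistic drift/alpha/noise levels. Keyword overrides
    replace individual GeneratorConfig fields.
    """
    cfg = GeneratorConfig(
        n_subjects=40,
        n_items=120,
        conditions=[
            ConditionSpec("Expected", mu_n400=-1.0, mu_p600=1.0,
                          coupling_rho=-0.4, sd_n400=2.0, sd_p600=2.0),
            ConditionSpec("Unexpected", mu_n400=-4.0, mu_p600=4.0,
                          coupling_rho=-0.4, sd_n400=2.0, sd_p600=2.0),
        ],
        components=_default_components(),
        electrodes=["Fz", "Cz", "Pz"],
        **_NOISE_DEFAULTS,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def preset_monophasic(**overrides) -> GeneratorConfig:
    """Three-condition design with monophasic between-condition contrasts.

    Relative to Baseline, the EventRelated condition differs only in the
    mean P600 latent (a P600-only effect) and the EventUnrelated condition
    only in the mean N400 latent (an N400-only effect), while the latent
    coupling inside every condition is the same negative value as in the
    biphasic preset.
    """
    cfg = GeneratorConfig(
        n_subjects=40,
        n_items=120,
        conditions=[
            ConditionSpec("Baseline", mu_n400=-1.0, mu_p600=1.0,
                          coupling_rho=-0.4, sd_n400=2.0, sd_p600=2.0),
            ConditionSpec("EventRelated", mu_n400=-1.0, mu_p600=4.0,
                          coupling_rho=-0.4, sd_n400=2.0, sd_p600=2.0),
            ConditionSpec("EventUnrelated", mu_n400=-4.0, mu_p600=1.0,
                          coupling_rho=-0.4, sd_n400=2.0, sd_p600=2.0),
        ],
        components=_default_components(),
        electrodes=["Fz", "Cz", "Pz"],
        **_NOISE_DEFAULTS,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_dataset(config: GeneratorConfig) -> tuple[EpochSet, GroundTruth]:
    """Simulate a full experiment; deterministic given the config (incl. seed).

    Conditions rotate over items in a pseudo-Latin square: subject s sees
    item i in condition ``(s + i) mod n_conditions``, so per-subject trial
    counts per condition are balanced (up to the remainder of
    n_items / n_conditions) and each item appears in every condition across
    subjects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    times = config.time_grid()
    n_samples = times.size
    n_cond = len(config.conditions)
    n_trials = config.n_subjects * config.n_items

    subj_idx = np.repeat(np.arange(config.n_subjects), config.n_items)
    item_idx = np.tile(np.arange(config.n_items), config.n_subjects)
    cond_idx = (subj_idx + item_idx) % n_cond

    subj_labels = np.array([f"S{i + 1:02d}" for i in range(config.n_subjects)])
    item_labels = np.array([f"I{i + 1:03d}" for i in range(config.n_items)])
    cond_labels = np.array([c.name for c in config.conditions])

    mu_n = np.array([c.mu_n400 for c in config.conditions])[cond_idx]
    mu_p = np.array([c.mu_p600 for c in config.conditions])[cond_idx]
    sd_n = np.array([c.sd_n400 for c in config.conditions])[cond_idx]
    sd_p = np.array([c.sd_p600 for c in config.conditions])[cond_idx]
    rho = np.array([c.coupling_rho for c in config.conditions])[cond_idx]

    # bivariate normal latents via the Cholesky transform of iid normals
    z = rng.standard_normal((n_trials, 2))
    latent_n400 = mu_n + sd_n * z[:, 0]
    latent_p600 = mu_p + sd_p * (rho * z[:, 0] + np.sqrt(1.0 - rho ** 2) * z[:, 1])

    drift_slope = rng.normal(0.0, config.drift_sd, n_trials) if config.drift_sd > 0 \
        else np.zeros(n_trials)
    alpha_phase = rng.uniform(0.0, 2.0 * np.pi, n_trials)
    subject_offset = rng.normal(0.0, config.subject_offset_sd, config.n_subjects) \
        if config.subject_offset_sd > 0 else np.zeros(config.n_subjects)

    comp_n400 = config.component("N400")
    comp_p600 = config.component("P600")
    k_n400 = comp_n400.evaluate(times)
    k_p600 = comp_p600.evaluate(times)
    w_n400 = np.array([comp_n400.weight(e) for e in config.electrodes])
    w_p600 = np.array([comp_p600.weight(e) for e in config.electrodes])

    drift = drift_slope[:, None] * (times - config.epoch_start_ms)[None, :] / 1000.0
    alpha = config.alpha_amp_uv * np.sin(
        2.0 * np.pi * config.alpha_freq_hz * times[None, :] / 1000.0
        + alpha_phase[:, None]
    )
    base = drift + alpha + subject_offset[subj_idx, None]  # (n_trials, n_samples)

    voltages = (
        latent_n400[:, None, None] * w_n400[None, :, None] * k_n400[None, None, :]
        + latent_p600[:, None, None] * w_p600[None, :, None] * k_p600[None, None, :]
        + base[:, None, :]
    )
    if config.noise_sd > 0:
        voltages = voltages + rng.normal(
            0.0, config.noise_sd, (n_trials, len(config.electrodes), n_samples)
        )

    trials = pd.DataFrame({
        "subject": subj_labels[subj_idx],
        "item": item_labels[item_idx],
        "condition": cond_labels[cond_idx],
    })
    epochs = EpochSet(trials=trials, electrodes=list(config.electrodes),
                      times=times, voltages=voltages)
    truth = pd.DataFrame({
        "subject": trials["subject"],
        "item": trials["item"],
        "condition": trials["condition"],
        "latent_n400": latent_n400,
        "latent_p600": latent_p600,
        "drift_slope": drift_slope,
        "alpha_phase": alpha_phase,
    })
    return epochs, truth
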