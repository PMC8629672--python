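"""Configuration objects shared across the FWNNet pipeline.

All tunables live in small dataclasses so that a run is fully described by
(config, seed).  YAML round-tripping is provided for the CLI; library users
construct the dataclasses directly.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

# Numerical floors (projection targets during training; see docs/methods.md).
A_MIN = 1e-3        # dilation floor: |a| >= A_MIN, sign preserved
SIGMA_MIN = 1e-3    # membership width floor
EPS_DEN = 1e-12     # defuzzification denominator floor

WAVELET_FAMILIES = ("mexican_hat", "morlet")


class ConfigurationError(ValueError):
    """Raised for invalid configuration values (unknown family, bad bank...)."""


@dataclass
class NetworkConfig:
    """Architecture of one FWNNet.

    Parameters
    ----------
    n : int
        Number of input features.
    M : int
        Number of fuzzy rules.
    N_k : int
        Number of wavelet neurons per rule (uniform across rules).
    num_classes : int
        Number of output labels for classification, or 0 for regression
        (no rounding layer).
    wavelet_family : str
        Mother wavelet, ``"mexican_hat"`` (default) or ``"morlet"``.
    normalize_wavelet : bool
        If True, apply the |a|^(-1/2) prefactor to each wavelet activation;
        the default uses the bare form.
    """

    n: int
    M: int = 2
    N_k: int = 2
    num_classes: int = 0
    wavelet_family: str = "mexican_hat"
    normalize_wavelet: bool = False

    def __post_init__(self) -> None:
        if self.n < 1 or self.M < 1 or self.N_k < 1:
            raise ConfigurationError("n, M and N_k must all be >= 1")
        if self.num_classes < 0:
            raise ConfigurationError("num_classes must be >= 0")
        if self.wavelet_family not in WAVELET_FAMILIES:
            raise ConfigurationError(
                f"unknown wavelet family {self.wavelet_family!r}; "
                f"choose one of {WAVELET_FAMILIES}"
            )


@dataclass
class TrainingConfig:
    """Gradient-descent stage settings.

    One learning rate per parameter group (centers, widths, translations,
    dilations, weights, biases), full-batch by default.
    """

    gamma_c: float = 0.01
    gamma_sigma: float = 0.01
    gamma_b: float = 0.01
    gamma_a: float = 0.01
    gamma_w: float = 0.01
    gamma_ybar: float = 0.01
    max_epochs: int = 500
    batch_mode: str = "full"  # "full" | "online"
    rng_seed: int = 0
    loss_floor: float = 0.0
    # classification only: stop once every training sample rounds to its label
    stop_at_full_accuracy: bool = False

    def __post_init__(self) -> None:
        rates = (self.gamma_c, self.gamma_sigma, self.gamma_b,
                 self.gamma_a, self.gamma_w, self.gamma_ybar)
        if any(g <= 0 for g in rates):
            raise ConfigurationError("all learning rates must be > 0")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if self.batch_mode not in ("full", "online"):
            raise ConfigurationError("batch_mode must be 'full' or 'online'")

    def rates(self) -> dict:
        return {
            "c": self.gamma_c, "sigma": self.gamma_sigma,
            "b": self.gamma_b, "a": self.gamma_a,
            "w": self.gamma_w, "ybar": self.gamma_ybar,
        }


@dataclass
class PSOConfig:
    """Particle-swarm settings for the initialization stage.

    Defaults follow the small-budget regime used for FWNNet training:
    20 particles, 50 generations, c1 = c2 = 2 and a linearly decreasing
    inertia weight (0.9 -> 0.4).  ``mode`` selects plain global-best PSO
    over the full parameter vector or the blockwise "inline" variant that
    cycles through the (c, sigma), (b, a), (w, ybar) groups within each
    generation.
    """

    psize: int = 20
    maxgen: int = 50
    c1: float = 2.0
    c2: float = 2.0
    w_start: float = 0.9
    w_end: float = 0.4
    rng_seed: int = 0
    mode: str = "inline_pso"  # "plain_pso" | "inline_pso"
    # Optional (lo, hi) overrides per parameter group; data-driven when None.
    position_bounds: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.psize < 2:
            raise ConfigurationError("psize must be >= 2")
        if self.maxgen < 1:
            raise ConfigurationError("maxgen must be >= 1")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ConfigurationError("c1 and c2 must be > 0")
        if not (self.w_start >= self.w_end > 0):
            raise ConfigurationError("need w_start >= w_end > 0")
        if self.mode not in ("plain_pso", "inline_pso"):
            raise ConfigurationError("mode must be 'plain_pso' or 'inline_pso'")


@dataclass
class PatchScheme:
    """Geometry of the segmentation sweep.

    A mask patch of side ``m`` is paired with the co-centered input window of
    side ``2m``; windows running off the image edge are filled per
    ``padding``.
    """

    m: int = 4
    stride: int = 0  # 0 -> defaults to m (non-overlapping targets)
    padding: str = "reflect"  # "reflect" | "zero"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigurationError("mask patch side m must be >= 1")
        if self.stride == 0:
            self.stride = self.m
        if self.stride < 1:
            raise ConfigurationError("stride must be >= 1")
        if self.padding not in ("reflect", "zero"):
            raise ConfigurationError("padding must be 'reflect' or 'zero'")

    @property
    def input_patch_side(self) -> int:
        return 2 * self.m


@dataclass
class GaborBank:
    """Oriented Gabor filter bank used to texture-transform images before
    segmentation.

    ``orientations`` are angles in degrees; ``wavelength`` is the carrier
    wavelength in pixels; ``aggregation`` combines per-orientation magnitude
    responses (``max``, ``mean``) or stacks them (``concat``).
    """

    orientations: Sequence[float] = (0.0, 45.0, 90.0, 135.0)
    wavelength: float = 8.0
    aspect: float = 1.0
    bandwidth: float = 1.0
    aggregation: str = "max"

    def __post_init__(self) -> None:
        if len(self.orientations) < 1:
            raise ConfigurationError("need at least one orientation")
        if self.wavelength <= 1:
            raise ConfigurationError("wavelength must be > 1 pixel")
        if self.aggregation not in ("max", "mean", "concat"):
            raise ConfigurationError(
                "aggregation must be 'max', 'mean' or 'concat'")


_SECTIONS = {
    "network": NetworkConfig,
    "training": TrainingConfig,
    "pso": PSOConfig,
    "patch_scheme": PatchScheme,
    "gabor": GaborBank,
}


def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def load_config(path, *, n: Optional[int] = None) -> dict:
    """Load a YAML config file into a dict of config dataclasses.

    Recognized top-level sections: network, training, pso, patch_scheme,
    gabor.  Missing sections fall back to defaults; ``n`` supplies the
    feature count when the network section omits it.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for name, cls in _SECTIONS.items():
        section = dict(raw.get(name, {}))
        if name == "network" and "n" not in section:
            if n is None and name in raw:
                raise ConfigurationError("network config requires 'n'")
            section["n"] = n if n is not None else 1
        if name == "network" and n is not None:
            section["n"] = n
        try:
            out[name] = cls(**section)
        except TypeError as exc:
            raise ConfigurationError(f"bad '{name}' section: {exc}") from exc
    return out


def save_config(configs: dict, path) -> None:
    doc = {name: config_to_dict(cfg) for name, cfg in configs.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
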