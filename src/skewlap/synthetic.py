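"""Seeded synthetic event generators emulating cytometer and particle-counter samples.

Two kinds of fixture are produced:

* **Axenic-culture surrogates** — skew-Laplace draws at published-looking
  parameter triples: forward/side scatter on the instrument channel scale
  (location in the hundreds, tail rates of order 0.01-0.2 per channel) and
  log-skew-Laplace "cell sizes" whose natural log is skew-Laplace.  Presets
  cover three morphologically distinct organisms (E. coli rods, S. aureus
  cocci, B. subtilis endospore-formers) at 6/20/36 h of batch incubation.
* **Aquatic-community surrogates** — a right-skewed three-component Gaussian
  mixture on log cell size, well separated (>= 2 component sds), standing in
  for natural bacterioplankton whose size spectra a single skew-Laplace
  cannot describe.  The component values are a fixture convention, not
  estimates from any real lake or coastal dataset.

Optional quantization maps draws onto an evenly spaced integer channel grid
with clipping, mimicking a cytometer's ADC (default 10-bit, channels 0-1023).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Optional

import numpy as np
from numpy.typing import NDArray

from .distributions import SkewLaplaceParams, GammaModelParams, sl_sample

__all__ = [
    "SyntheticSpec",
    "MixtureParams",
    "generate",
    "preset",
    "preset_names",
    "write_csv",
]

FAMILIES = ("skew_laplace", "log_skew_laplace", "gamma_model", "gaussian_mixture")

DEFAULT_N = 50_000
DEFAULT_QUANTIZATION = (0, 1023, 1024)


@dataclass(frozen=True)
class MixtureParams:
    """Gaussian mixture on log size; draws are exponentiated to positive sizes."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ValueError("weights, means, sds must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if any(w <= 0 for w in self.weights) or any(s <= 0 for s in self.sds):
            raise ValueError("weights and sds must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one generated sample: family, parameters, size, seed, quantization."""

    family: str
    params: Any
    n: int = DEFAULT_N
    seed: int = 0
    quantization: Optional[tuple[float, float, int]] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.quantization is not None:
            lo, hi, nch = self.quantization
            if not (hi > lo and nch >= 2):
                raise ValueError("quantization must be (min, max, channels>=2) with max > min")
        expected = {
            "skew_laplace": SkewLaplaceParams,
            "log_skew_laplace": SkewLaplaceParams,
            "gamma_model": GammaModelParams,
            "gaussian_mixture": MixtureParams,
        }[self.family]
        if not isinstance(self.params, expected):
            raise ValueError(f"family {self.family!r} requires {expected.__name__} params")


def _quantize(x: NDArray[np.float64], rule: tuple[float, float, int]) -> NDArray[np.float64]:
    lo, hi, nch = rule
    step = (hi - lo) / (nch - 1)
    idx = np.clip(np.round((x - lo) / step), 0, nch - 1)
    return lo + idx * step


def generate(spec: SyntheticSpec) -> tuple[NDArray[np.float64], dict[str, Any]]:
    """Draw one reproducible sample from the spec; returns (values, provenance)."""
    rng = np.random.default_rng(spec.seed)
    if spec.family in ("skew_laplace", "log_skew_laplace"):
        x = sl_sample(spec.params, spec.n, spec.seed)
        if spec.family == "log_skew_laplace":
            x = np.exp(x)
    elif spec.family == "gamma_model":
        p: GammaModelParams = spec.params
        x = p.m0 + rng.gamma(p.gamma_shape + 1.0, 1.0 / p.beta_rate, size=spec.n)
    else:  # gaussian_mixture on log size
        m: MixtureParams = spec.params
        comp = rng.choice(len(m.weights), size=spec.n, p=np.asarray(m.weights))
        logx = rng.normal(np.asarray(m.means)[comp], np.asarray(m.sds)[comp])
        x = np.exp(logx)
    if spec.quantization is not None:
        x = _quantize(x, spec.quantization)
    provenance = {
        "family": spec.family,
        "params": spec.params.to_dict() if hasattr(spec.params, "to_dict") else vars(spec.params),
        "n": int(spec.n),
        "seed": int(spec.seed),
        "quantization": spec.quantization,
    }
    return x, provenance


# Fitted (mu, alpha, |beta|) triples by organism, channel and incubation time.
# FS/SS are on the instrument channel scale; multisizer triples are the
# log-scale parameters of log-skew-Laplace cell sizes (microns).
_TRIPLES: dict[str, tuple[float, float, float]] = {
    "ecoli_fs_6h": (575, 0.023, 0.022),
    "ecoli_fs_20h": (580, 0.025, 0.028),
    "ecoli_fs_36h": (576, 0.011, 0.024),
    "saureus_fs_6h": (565, 0.006, 0.017),
    "saureus_fs_20h": (575, 0.009, 0.018),
    "saureus_fs_36h": (521, 0.010, 0.013),
    "bsubtilis_fs_6h": (592, 0.008, 0.023),
    "bsubtilis_fs_20h": (472, 0.054, 0.012),
    "bsubtilis_fs_36h": (497, 0.032, 0.010),
    "ecoli_ss_6h": (432, 0.071, 0.024),
    "ecoli_ss_20h": (438, 0.056, 0.024),
    "ecoli_ss_36h": (427, 0.103, 0.011),
    "saureus_ss_6h": (424, 0.134, 0.009),
    "saureus_ss_20h": (424, 0.133, 0.011),
    "saureus_ss_36h": (428, 0.129, 0.013),
    "bsubtilis_ss_6h": (427, 0.168, 0.016),
    "bsubtilis_ss_20h": (444, 0.119, 0.026),
    "bsubtilis_ss_36h": (434, 0.145, 0.027),
    "ecoli_multisizer_6h": (1.046, 9.537, 6.461),
    "ecoli_multisizer_20h": (1.017, 10.093, 5.480),
    "ecoli_multisizer_36h": (1.060, 8.806, 5.866),
    "saureus_multisizer_6h": (0.976, 9.90, 2.968),
    "saureus_multisizer_20h": (0.815, 18.884, 2.664),
    "saureus_multisizer_36h": (0.750, 10.854, 3.410),
    "bsubtilis_multisizer_6h": (0.910, 10.200, 2.410),
    "bsubtilis_multisizer_20h": (1.204, 11.050, 2.151),
    "bsubtilis_multisizer_36h": (0.898, 10.733, 2.422),
}

# Aquatic bacterioplankton surrogate: trimodal, right-skewed on log size.
_AQUATIC = MixtureParams(weights=(0.5, 0.3, 0.2), means=(-0.6, 0.3, 1.4), sds=(0.15, 0.20, 0.25))


def preset_names() -> list[str]:
    return sorted(_TRIPLES) + ["aquatic"]


def preset(name: str, n: int = DEFAULT_N, seed: int = 0) -> SyntheticSpec:
    """A fully populated SyntheticSpec for a named fixture.

    Scatter presets (``*_fs_*``, ``*_ss_*``) are skew-Laplace on the channel
    scale; ``*_multisizer_*`` presets are log-skew-Laplace sizes in microns;
    ``aquatic`` is the community mixture no skew-Laplace should fit.
    """
    if name == "aquatic":
        return SyntheticSpec(family="gaussian_mixture", params=_AQUATIC, n=n, seed=seed)
    try:
        mu, alpha, beta = _TRIPLES[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    family = "log_skew_laplace" if "multisizer" in name else "skew_laplace"
    return SyntheticSpec(
        family=family,
        params=SkewLaplaceParams(mu=mu, alpha=alpha, beta=beta),
        n=n,
        seed=seed,
    )


def write_csv(values: NDArray[np.float64], path: str) -> None:
    """Write events as a one-column CSV with header ``value``."""
    import pandas as pd

    pd.DataFrame({"value": np.asarray(values, dtype=float)}).to_csv(path, index=False)
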