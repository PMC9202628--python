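"""Correlation-gated wavelet-packet threshold denoising.

The front end of the forecasting pipeline decomposes a sensor series with
VMD, computes each mode's Pearson correlation with the original series,
and classifies modes as effective-information-dominant (|r| >= 0.5, kept
verbatim) or noise-dominant (|r| < 0.5, wavelet-packet threshold denoised).
The cleaned series is the sum of kept and denoised components.

Thresholding follows the Donoho universal-threshold convention: the noise
scale is the median absolute level-1 detail coefficient divided by 0.6745
(the MAD of a standard normal), and

    lambda = ( median|W_{1,j}| / 0.6745 ) * sqrt(2 ln N)

is shared across all detail nodes of the packet tree.  Hard thresholding
keeps coefficients of magnitude >= lambda and zeroes the rest; soft
thresholding additionally shrinks survivors by lambda; the compromise rule
is the elementwise convex combination w*soft + (1-w)*hard.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pywt

from .timeseries import UniformSeries
from .vmd import VMDConfig, VMDResult, vmd_decompose

__all__ = [
    "ThresholdRule",
    "ThresholdSpec",
    "pearson_correlation",
    "route_components",
    "universal_threshold",
    "apply_threshold",
    "denoise_component",
    "joint_denoise",
]

NOISE_DOMINANT_CUTOFF = 0.5


class ThresholdRule(str, Enum):
    HARD = "hard"
    SOFT = "soft"
    COMPROMISE = "compromise"


@dataclass(frozen=True)
class ThresholdSpec:
    """Wavelet basis, packet depth, and shrinkage rule.

    Defaults (sym8, 3 levels, compromise with equal weight) match common
    practice for slowly varying sensor series.
    """

    wavelet: str = "sym8"
    levels: int = 3
    rule: ThresholdRule = ThresholdRule.COMPROMISE
    compromise_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not (0.0 <= self.compromise_weight <= 1.0):
            raise ValueError("compromise_weight must lie in [0, 1]")


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation; errors on constant input (undefined)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal lengths >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


def route_components(modes: VMDResult | np.ndarray, original: UniformSeries | np.ndarray,
                     cutoff: float = NOISE_DOMINANT_CUTOFF
                     ) -> tuple[list[int], list[int], np.ndarray]:
    """Split mode indices into (keep, denoise) by |correlation| vs *cutoff*.

    Returns ``(keep_indices, denoise_indices, correlations)``.  A mode that
    is constant (e.g. an exactly-zero mode) has no defined correlation and
    is treated as noise-dominant with correlation 0.
    """
    mode_arr = modes.modes if isinstance(modes, VMDResult) else np.asarray(modes, float)
    x = original.values if isinstance(original, UniformSeries) else np.asarray(original, float)
    if mode_arr.ndim != 2 or mode_arr.shape[0] < 1:
        raise ValueError("modes must be a non-empty 2-D array")
    corrs = np.array([
        0.0 if np.ptp(m) == 0 else pearson_correlation(m, x) for m in mode_arr
    ])
    keep = [i for i, r in enumerate(corrs) if abs(r) >= cutoff]
    denoise = [i for i, r in enumerate(corrs) if abs(r) < cutoff]
    return keep, denoise, corrs


def universal_threshold(level1_detail: np.ndarray, n: int) -> float:
    """lambda = (median|W1| / 0.6745) * sqrt(2 ln N)."""
    w = np.asarray(level1_detail, float)
    if w.size == 0:
        raise ValueError("empty coefficient array")
    if n < 2:
        raise ValueError("N must be >= 2")
    return float(np.median(np.abs(w)) / 0.6745 * np.sqrt(2.0 * np.log(n)))


def _shrink(c: np.ndarray, lam: float, rule: ThresholdRule, w: float) -> np.ndarray:
    keep = np.abs(c) >= lam
    hard = np.where(keep, c, 0.0)
    soft = np.where(keep, np.sign(c) * (np.abs(c) - lam), 0.0)
    if rule == ThresholdRule.HARD:
        return hard
    if rule == ThresholdRule.SOFT:
        return soft
    return w * soft + (1.0 - w) * hard


def apply_threshold(coeffs: dict[str, np.ndarray], lam: float, spec: ThresholdSpec
                    ) -> dict[str, np.ndarray]:
    """Threshold every detail node; the pure-approximation node is untouched.

    *coeffs* maps wavelet-packet node paths (strings of 'a'/'d') to
    coefficient arrays.  The all-'a' path carries the coarse approximation
    and is passed through.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    out = {}
    for path, c in coeffs.items():
        if set(path) == {"a"}:
            out[path] = np.asarray(c, float)
        else:
            out[path] = _shrink(np.asarray(c, float), lam, spec.rule, spec.compromise_weight)
    return out


def _packet_decompose(x: np.ndarray, spec: ThresholdSpec) -> dict[str, np.ndarray]:
    wp = pywt.WaveletPacket(data=x, wavelet=spec.wavelet, mode="symmetric",
                            maxlevel=spec.levels)
    return {node.path: node.data.copy() for node in wp.get_level(spec.levels, "natural")}


def _packet_reconstruct(coeffs: dict[str, np.ndarray], spec: ThresholdSpec, n: int) -> np.ndarray:
    wp = pywt.WaveletPacket(data=None, wavelet=spec.wavelet, mode="symmetric",
                            maxlevel=spec.levels)
    for path, c in coeffs.items():
        wp[path] = c
    return wp.reconstruct(update=False)[:n]


def denoise_component(series: UniformSeries | np.ndarray,
                      spec: ThresholdSpec = ThresholdSpec()) -> np.ndarray:
    """Wavelet-packet threshold denoising of one series.

    The threshold comes from the series' own level-1 detail coefficients
    (finest scale, where noise dominates) and is applied to every detail
    node of the depth-``spec.levels`` packet tree.  Output length equals
    input length.
    """
    x = series.values if isinstance(series, UniformSeries) else np.asarray(series, float)
    if x.size < 2 ** spec.levels:
        raise ValueError(f"series too short for {spec.levels} packet levels")
    _, d1 = pywt.dwt(x, spec.wavelet, mode="symmetric")
    lam = universal_threshold(d1, x.size)
    coeffs = _packet_decompose(x, spec)
    return _packet_reconstruct(apply_threshold(coeffs, lam, spec), spec, x.size)


def joint_denoise(series: UniformSeries, vmd_config: VMDConfig,
                  spec: ThresholdSpec = ThresholdSpec(),
                  cutoff: float = NOISE_DOMINANT_CUTOFF,
                  ) -> tuple[UniformSeries, dict]:
    """VMD-decompose, route by correlation, denoise flagged modes, re-sum.

    Returns the cleaned series and an artifacts dict with the decomposition,
    per-mode correlations and the routing.
    """
    result = vmd_decompose(series, vmd_config)
    keep, noisy_idx, corrs = route_components(result, series, cutoff)
    parts = []
    for i in range(result.k):
        if i in noisy_idx:
            parts.append(denoise_component(result.modes[i], spec))
        else:
            parts.append(result.modes[i])
    cleaned = np.sum(parts, axis=0)
    artifacts = {
        "vmd_result": result,
        "correlations": corrs,
        "kept": keep,
        "denoised": noisy_idx,
    }
    return series.with_values(cleaned, name=f"{series.name}_denoised"), artifacts
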