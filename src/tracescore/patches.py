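"""Consensus heatmaps, categorized patch sampling, and patch feature statistics.

Ground-truth trace maps from all observers are stacked into a per-pixel
consensus count. Square patches (default 51×51) are sampled at centers whose
consensus falls in one of three disjoint categories:

* ``salient`` — at least ``ceil(0.95·n)`` observers traced the pixel
  (19 of 20 at the study scale),
* ``some`` — between 25% and 75% of observers (inclusive),
* ``none`` — no observer.

Per-patch features are mean luminance and RMS contrast; directional power
spectra aggregate 2-D FFT power within an angular wedge around the vertical
or horizontal frequency axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .scoring import TraceMap
from .stimuli import LuminanceImage

CATEGORIES = ("salient", "some", "none")


@dataclass
class ConsensusHeatmap:
    """Per-pixel count of observers that traced each pixel."""

    counts: np.ndarray
    n_observers: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.min() < 0 or self.counts.max() > self.n_observers:
            raise ValueError("counts must lie in [0, n_observers]")


@dataclass(frozen=True)
class Patch:
    row: int
    col: int
    category: str
    values: np.ndarray  # luminance grid, side = patch_size


@dataclass
class PatchSet:
    patches: list[Patch]
    patch_size: int

    def __len__(self) -> int:
        return len(self.patches)


def stack_ground_truths(maps: list[TraceMap]) -> ConsensusHeatmap:
    """Sum binary trace maps into a consensus count grid."""
    if not maps:
        raise ValueError("no trace maps given")
    size = maps[0].size_px
    if any(m.size_px != size for m in maps):
        raise ValueError("trace maps differ in size")
    counts = np.sum([m.mask.astype(int) for m in maps], axis=0)
    return ConsensusHeatmap(counts=counts, n_observers=len(maps))


def category_bounds(category: str, n_observers: int) -> tuple[int, int]:
    """Inclusive (lo, hi) consensus-count bounds for a category.

    salient: count ≥ ceil(0.95·n); some: ceil(0.25·n) ≤ count ≤ floor(0.75·n);
    none: count = 0. At n = 20 these give ≥19, 5–15, and 0.
    """
    if category == "salient":
        return math.ceil(0.95 * n_observers), n_observers
    if category == "some":
        return math.ceil(0.25 * n_observers), math.floor(0.75 * n_observers)
    if category == "none":
        return 0, 0
    raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")


def category_mask(heatmap: ConsensusHeatmap, category: str) -> np.ndarray:
    lo, hi = category_bounds(category, heatmap.n_observers)
    return (heatmap.counts >= lo) & (heatmap.counts <= hi)


def sample_patches(
    heatmap: ConsensusHeatmap,
    scene: LuminanceImage,
    category: str,
    k: int,
    seed: int = 0,
    patch_size: int = 51,
    min_spacing: int | None = None,
) -> PatchSet:
    """Draw up to ``k`` seeded random patches of one consensus category.

    Centers must satisfy the category rule, lie far enough from the border
    that the patch is fully inside the image, and keep at least
    ``min_spacing`` pixels (default: one patch width) between accepted
    centers. If fewer than ``k`` centers qualify, all eligible ones are
    returned with a warning.
    """
    if patch_size % 2 == 0:
        raise ValueError("patch side must be odd")
    if heatmap.counts.shape != scene.values.shape:
        raise ValueError("heatmap and scene size mismatch")
    if min_spacing is None:
        min_spacing = patch_size
    half = patch_size // 2
    eligible = category_mask(heatmap, category).copy()
    eligible[:half], eligible[-half:] = False, False
    eligible[:, :half], eligible[:, -half:] = False, False
    coords = np.argwhere(eligible)

    rng = np.random.default_rng(seed)
    rng.shuffle(coords)
    accepted: list[tuple[int, int]] = []
    for r, c in coords:
        if len(accepted) == k:
            break
        if all(np.hypot(r - ar, c - ac) >= min_spacing for ar, ac in accepted):
            accepted.append((int(r), int(c)))
    if len(accepted) < k:
        warnings.warn(
            f"only {len(accepted)} eligible '{category}' centers found (requested {k})",
            stacklevel=2,
        )
    patches = [
        Patch(r, c, category, scene.values[r - half : r + half + 1, c - half : c + half + 1].copy())
        for r, c in accepted
    ]
    return PatchSet(patches=patches, patch_size=patch_size)


def patch_features(values: np.ndarray) -> dict[str, float]:
    """Mean luminance and RMS contrast (std / mean) of one patch."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty patch")
    mean = float(values.mean())
    if mean <= 0:
        raise ValueError("patch mean luminance must be positive for RMS contrast")
    return {"mean_luminance": mean, "rms_contrast": float(values.std() / mean)}


def power_spectrum_2d(values: np.ndarray, window: str | None = "hann") -> np.ndarray:
    """Mean-subtracted 2-D FFT power, ``|F|²/N²``.

    With ``window=None`` the total equals the patch variance exactly
    (Parseval); the default Hann window limits spectral leakage at the cost
    of that identity.
    """
    v = np.asarray(values, dtype=float)
    v = v - v.mean()
    if window == "hann":
        w1 = np.hanning(v.shape[0])
        v = v * np.outer(w1, w1)
        v = v - v.mean()
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    return np.abs(np.fft.fft2(v)) ** 2 / v.size ** 2


def directional_power(
    values: np.ndarray,
    direction: str,
    ppd: float,
    wedge_deg: float = 30.0,
    window: str | None = "hann",
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Power vs spatial frequency (cpd) within a wedge around one axis.

    ``direction='vertical'`` aggregates power around the vertical frequency
    axis (energy produced by horizontally oriented structure);
    ``'horizontal'`` around the horizontal axis. Frequencies are binned in
    annuli one frequency-pixel wide; ``normalize=True`` divides by the
    maximum power.
    """
    if direction not in ("horizontal", "vertical"):
        raise ValueError("direction must be 'horizontal' or 'vertical'")
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    power = power_spectrum_2d(v, window=window)
    f = np.fft.fftfreq(n, d=1.0 / ppd)
    fx, fy = np.meshgrid(f, f)  # fx: column (horizontal) frequency, fy: row (vertical)
    fr = np.hypot(fx, fy)
    # angle from the horizontal-frequency axis, folded to [0, 90]
    ang = np.degrees(np.arctan2(np.abs(fy), np.abs(fx)))
    in_wedge = ang >= 90.0 - wedge_deg / 2 if direction == "vertical" else ang <= wedge_deg / 2

    df = ppd / n
    k = np.rint(fr / df).astype(int)
    kmax = n // 2
    sel = in_wedge & (k >= 1) & (k <= kmax)
    sums = np.bincount(k[sel], weights=power[sel], minlength=kmax + 1)
    counts = np.bincount(k[sel], minlength=kmax + 1)
    idx = np.nonzero(counts)[0]
    freqs = idx * df
    prof = sums[idx] / counts[idx]
    if normalize and prof.max() > 0:
        prof = prof / prof.max()
    return freqs, prof
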