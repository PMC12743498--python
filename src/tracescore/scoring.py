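"""Signal-detection scoring of binary trace maps with an error margin.

Each pixel is treated as one trial. The observer's noise-free trace is the
signal ("ground truth") and the noisy-condition trace is the response. A
response pixel within ``margin_px`` (Euclidean) of any ground-truth pixel is
a hit; other response pixels are false alarms. A ground-truth pixel with no
response pixel within the margin is a miss (a ground-truth pixel that is
itself a hit is never also a miss); everything else is a correct rejection.
The four categories always partition the pixel grid.

Derived measures: proportion correct p = H/(H+M+FA) (optionally including
CRs in both numerator and denominator), d' = z(hit rate) − z(FA rate), and
bias c = −½·(z(hit rate) + z(FA rate)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import norm

#: Rules for handling hit/FA rates of exactly 0 or 1 before the z-transform.
RATE_CORRECTIONS = ("loglinear", "clamp")


@dataclass
class TraceMap:
    """Binary 2-D map of traced pixels with trial identifiers."""

    mask: np.ndarray
    observer_id: str = ""
    image_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        uniques = np.unique(arr)
        if not np.all(np.isin(uniques, (0, 1))):
            raise ValueError("trace map values must be strictly binary (0/1)")
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"trace map must be square 2-D, got shape {arr.shape}")
        self.mask = arr.astype(bool)

    @property
    def size_px(self) -> int:
        return self.mask.shape[0]

    @property
    def n_traced(self) -> int:
        return int(self.mask.sum())


@dataclass
class ScoringConfig:
    """Margin and rate-handling configuration.

    Exactly one of ``margin_px`` / ``margin_fraction`` must be given; a
    fractional margin resolves to ``round(fraction × size_px)`` at scoring
    time. The default fraction 0.025 yields a 13-pixel margin on a 512-pixel
    image side.
    """

    margin_px: int | None = None
    margin_fraction: float | None = None
    rate_correction: str = "loglinear"
    include_cr_in_pc: bool = False
    #: If True, the miss test dilates the response map by the margin
    #: (the default); if False, only exact response pixels rescue a
    #: ground-truth pixel from being a miss.
    dilate_response_for_misses: bool = True

    def __post_init__(self) -> None:
        if (self.margin_px is None) == (self.margin_fraction is None):
            raise ValueError("specify exactly one of margin_px / margin_fraction")
        if self.margin_px is not None and self.margin_px < 0:
            raise ValueError("margin_px must be non-negative")
        if self.margin_fraction is not None and not 0 <= self.margin_fraction < 1:
            raise ValueError("margin_fraction must lie in [0, 1)")
        if self.rate_correction not in RATE_CORRECTIONS:
            raise ValueError(f"rate_correction must be one of {RATE_CORRECTIONS}")

    def resolve_margin(self, size_px: int) -> int:
        if self.margin_px is not None:
            return self.margin_px
        return int(round(self.margin_fraction * size_px))


@dataclass(frozen=True)
class ContingencyCounts:
    """Hit/miss/FA/CR counts for one scored (ground truth, response) pair."""

    hits: int
    misses: int
    fa: int
    cr: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "fa", "cr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.hits + self.misses + self.fa + self.cr


@dataclass(frozen=True)
class SdtMeasures:
    """Proportion correct, sensitivity d', and bias c for one pair."""

    p: float
    dprime: float
    c: float


def _distance_to(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from every pixel to the nearest True pixel."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask)


def score_traces(ground_truth: TraceMap, response: TraceMap, cfg: ScoringConfig) -> ContingencyCounts:
    """Classify every pixel into hit / miss / FA / CR with the error margin.

    Equivalent to dilating the ground truth by a Euclidean disk of radius
    ``margin_px``: response pixels inside the dilated map are hits, the rest
    are false alarms. Ground-truth pixels with no response pixel within the
    margin are misses; the remainder of the grid are correct rejections.
    """
    if ground_truth.size_px != response.size_px:
        raise ValueError(
            f"size mismatch: ground truth {ground_truth.size_px} vs response {response.size_px}"
        )
    margin = cfg.resolve_margin(ground_truth.size_px)
    gt, resp = ground_truth.mask, response.mask

    near_gt = _distance_to(gt) <= margin
    hits = int((resp & near_gt).sum())
    fa = int((resp & ~near_gt).sum())

    if cfg.dilate_response_for_misses:
        rescued = _distance_to(resp) <= margin
    else:
        rescued = resp
    misses = int((gt & ~rescued).sum())
    cr = gt.size - hits - fa - misses
    return ContingencyCounts(hits=hits, misses=misses, fa=fa, cr=cr)


def proportion_correct(counts: ContingencyCounts, include_cr: bool = False) -> float:
    """Proportion correct: H/(H+M+FA), or (H+CR)/N with ``include_cr``."""
    if include_cr:
        denom = counts.n_pixels
        if denom == 0:
            raise ValueError("proportion correct undefined: no pixels")
        return (counts.hits + counts.cr) / denom
    denom = counts.hits + counts.misses + counts.fa
    if denom == 0:
        raise ValueError("proportion correct undefined: hits+misses+fa == 0")
    return counts.hits / denom


def corrected_rates(counts: ContingencyCounts, correction: str = "loglinear") -> tuple[float, float]:
    """Hit and FA rates with degenerate (0 or 1) rates corrected.

    ``loglinear`` adds 0.5 to each cell of the affected pair; ``clamp``
    replaces 0 with 1/(2n) and 1 with 1 − 1/(2n) for the pair's trial count
    n. Rates strictly inside (0, 1) are returned untouched.
    """
    if correction not in RATE_CORRECTIONS:
        raise ValueError(f"unknown rate correction {correction!r}")
    n_sig = counts.hits + counts.misses
    n_noise = counts.fa + counts.cr
    if n_sig == 0:
        raise ValueError("hit rate undefined: no signal pixels")
    if n_noise == 0:
        raise ValueError("FA rate undefined: no noise pixels")

    def fix(k: int, n: int) -> float:
        rate = k / n
        if 0.0 < rate < 1.0:
            return rate
        if correction == "loglinear":
            return (k + 0.5) / (n + 1.0)
        return 1.0 / (2 * n) if rate == 0.0 else 1.0 - 1.0 / (2 * n)

    return fix(counts.hits, n_sig), fix(counts.fa, n_noise)


def dprime(counts: ContingencyCounts, correction: str = "loglinear") -> float:
    """Sensitivity: difference of z-transformed hit and FA rates."""
    hr, far = corrected_rates(counts, correction)
    return float(norm.ppf(hr) - norm.ppf(far))


def bias(counts: ContingencyCounts, correction: str = "loglinear") -> float:
    """Response bias c = −½·(z(hit rate) + z(FA rate))."""
    hr, far = corrected_rates(counts, correction)
    return float(-0.5 * (norm.ppf(hr) + norm.ppf(far)))


def sdt_measures(counts: ContingencyCounts, cfg: ScoringConfig) -> SdtMeasures:
    """All three measures from one contingency table, sharing corrected rates."""
    return SdtMeasures(
        p=proportion_correct(counts, include_cr=cfg.include_cr_in_pc),
        dprime=dprime(counts, cfg.rate_correction),
        c=bias(counts, cfg.rate_correction),
    )


def pairwise_consistency(
    maps: list[TraceMap], cfg: ScoringConfig, include_cr: bool = False
) -> tuple[float, float]:
    """Mean ± SD of proportion correct over all ordered pairs of maps.

    Each ordered pair (signal, response) is scored with the margin and
    reduced to proportion correct; used for between-observer consistency of
    ground-truth maps of the same image.
    """
    if len(maps) < 2:
        raise ValueError("need at least two trace maps")
    ps = [
        proportion_correct(score_traces(sig, resp, cfg), include_cr=include_cr)
        for sig, resp in itertools.permutations(maps, 2)
    ]
    return float(np.mean(ps)), float(np.std(ps))


def pool_counts(counts: list[ContingencyCounts]) -> ContingencyCounts:
    """Sum contingency tables across trials (pixel pooling)."""
    if not counts:
        raise ValueError("no counts to pool")
    return ContingencyCounts(
        hits=sum(c.hits for c in counts),
        misses=sum(c.misses for c in counts),
        fa=sum(c.fa for c in counts),
        cr=sum(c.cr for c in counts),
    )
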