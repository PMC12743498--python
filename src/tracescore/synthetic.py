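"""Synthetic scenes with known boundaries and simulated tracing observers.

Scenes are rendered as flat-amplitude regions (ellipses, polygons, and a
horizon step) on a mid-gray ground, so every region boundary is an exact
luminance discontinuity with a known 1-pixel edge map. Observers are
simulated with four behavioral ingredients:

* a cumulative-Gaussian visibility link — a boundary segment is traced with
  probability Φ((c_eff − omission_mu)/omission_sigma), where the effective
  contrast is image contrast × segment amplitude attenuated by a per-noise
  masking strength: c_eff = c·a / (1 + masking_strength·noise_rms);
* persistent per-observer segment preferences (the same latent decides the
  segment in every session, so within-observer consistency exceeds
  between-observer consistency);
* smooth spatial jitter of the drawn lines;
* spurious traces rendered as smooth bounded-turning pen strokes.

Everything is deterministic given the seeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm
from skimage import draw as skdraw

from .scoring import ContingencyCounts, ScoringConfig, TraceMap, pool_counts, proportion_correct, score_traces
from .stimuli import LuminanceImage, NoiseSpec, StimulusSpec
from .psychometric import PsychometricData, fit_cumulative_gaussian, scale_by_max

_FOUR_NEIGHBORHOOD = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class PlacedShape:
    """One rendered region: label in the label grid, kind, and contrast amplitude."""

    label: int
    kind: str  # ellipse | polygon | horizon
    amplitude: float  # positive contrast amplitude of the region
    sign: int  # +1 or -1 relative to the mid-gray ground
    minor: bool  # low-amplitude detail subject to the observer's detail level
    n_boundary_px: int


@dataclass
class SyntheticScene:
    """Rendered scene, its exact 1-px boundary map, and the shape catalog."""

    scene: LuminanceImage
    true_edges: TraceMap
    shapes: list[PlacedShape]
    labels: np.ndarray  # region label per pixel (0 = ground)
    edge_owner: np.ndarray  # shape label per boundary pixel, 0 elsewhere

    @property
    def size_px(self) -> int:
        return self.scene.size_px


@dataclass(frozen=True)
class ObserverModel:
    """Behavioral parameters of one simulated observer."""

    jitter_sd: float = 0.0
    omission_mu: float = 0.05
    omission_sigma: float = 0.02
    fa_rate: float = 0.0
    detail_level: float = 1.0
    seed: int = 0
    #: optional contrast dependence of the false-trace budget:
    #: expected FA pixels = fa_rate · max(0, 1 − fa_contrast_slope · contrast)
    fa_contrast_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0 or self.fa_rate < 0:
            raise ValueError("jitter_sd and fa_rate must be non-negative")
        if self.omission_sigma <= 0:
            raise ValueError("omission_sigma must be positive")
        if not 0.0 <= self.detail_level <= 1.0:
            raise ValueError("detail_level must lie in [0, 1]")


def _region_boundary(mask: np.ndarray) -> np.ndarray:
    """1-px inner boundary: region pixels with a 4-neighbor outside the region.

    ``border_value=1`` so that the image frame itself is never a boundary —
    only genuine luminance discontinuities between regions count as edges.
    """
    return mask & ~ndimage.binary_erosion(mask, structure=_FOUR_NEIGHBORHOOD, border_value=1)


def make_scene(
    n_shapes: int,
    size_px: int = 256,
    ppd: float = 44.0,
    contrast_range: tuple[float, float] = (0.3, 1.0),
    seed: int = 0,
    mean_luminance: float = 100.0,
    blur_sigma: float = 0.0,
    horizon: bool = True,
) -> SyntheticScene:
    """Render a scene of flat regions with an exact ground-truth edge map.

    Region amplitudes are drawn uniformly from ``contrast_range`` with random
    sign; shapes drawn later occlude earlier ones. Shapes whose amplitude
    falls below the 40th percentile are flagged as minor detail. Optional
    Gaussian blur softens the rendered luminance but the edge map always
    marks the pre-blur discontinuities. Deterministic given ``seed``.
    """
    if n_shapes < 0:
        raise ValueError("n_shapes must be non-negative")
    rng = np.random.default_rng(seed)
    n = size_px
    labels = np.zeros((n, n), dtype=int)
    amp_signed: list[float] = [0.0]  # ground
    catalog_raw: list[tuple[int, str]] = []

    next_label = 1
    if horizon:
        horizon_row = int(rng.integers(int(0.45 * n), int(0.7 * n)))
        labels[horizon_row:, :] = next_label
        amp = float(rng.uniform(*contrast_range))
        sign = int(rng.choice((-1, 1)))
        amp_signed.append(sign * amp)
        catalog_raw.append((next_label, "horizon"))
        next_label += 1

    for _ in range(n_shapes):
        kind = str(rng.choice(("ellipse", "polygon")))
        cr = rng.uniform(0.18 * n, 0.82 * n)
        cc = rng.uniform(0.18 * n, 0.82 * n)
        if kind == "ellipse":
            r_rad = rng.uniform(0.04 * n, 0.14 * n)
            c_rad = rng.uniform(0.04 * n, 0.14 * n)
            rot = rng.uniform(0, np.pi)
            rr, cc_px = skdraw.ellipse(cr, cc, r_rad, c_rad, shape=(n, n), rotation=rot)
        else:
            n_vert = int(rng.integers(3, 6))
            angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
            radii = rng.uniform(0.05 * n, 0.15 * n, n_vert)
            rr, cc_px = skdraw.polygon(
                cr + radii * np.sin(angles), cc + radii * np.cos(angles), shape=(n, n)
            )
        labels[rr, cc_px] = next_label
        amp = float(rng.uniform(*contrast_range))
        sign = int(rng.choice((-1, 1)))
        amp_signed.append(sign * amp)
        catalog_raw.append((next_label, kind))
        next_label += 1

    pattern = np.asarray(amp_signed)[labels]
    if blur_sigma > 0:
        pattern = ndimage.gaussian_filter(pattern, blur_sigma)
    lum = np.clip(mean_luminance * (1.0 + pattern), 0.0, None)

    edge_owner = np.zeros((n, n), dtype=int)
    shapes: list[PlacedShape] = []
    amps = [abs(amp_signed[lbl]) for lbl, _ in catalog_raw]
    minor_cut = np.quantile(amps, 0.4) if amps else 0.0
    for lbl, kind in catalog_raw:
        boundary = _region_boundary(labels == lbl)
        edge_owner[boundary] = lbl
        shapes.append(
            PlacedShape(
                label=lbl,
                kind=kind,
                amplitude=abs(amp_signed[lbl]),
                sign=int(np.sign(amp_signed[lbl])),
                minor=abs(amp_signed[lbl]) < minor_cut,
                n_boundary_px=int(boundary.sum()),
            )
        )

    return SyntheticScene(
        scene=LuminanceImage(lum, ppd),
        true_edges=TraceMap(edge_owner > 0),
        shapes=shapes,
        labels=labels,
        edge_owner=edge_owner,
    )


def _persistent_uniform(observer_seed: int, stream: int, label: int) -> float:
    """Per-(observer, shape) latent that is stable across trials and sessions."""
    return float(np.random.default_rng([observer_seed, stream, label]).random())


def _smooth_stroke(rng: np.random.Generator, size_px: int, max_len: int = 60) -> list[tuple[int, int]]:
    """A pen-like stroke: unit steps with a bounded random turning angle."""
    pos = rng.uniform(0, size_px, size=2)
    heading = rng.uniform(0, 2 * np.pi)
    length = int(rng.integers(max_len // 3, max_len + 1))
    pts = []
    for _ in range(length):
        pos = pos + np.array([np.sin(heading), np.cos(heading)])
        heading += rng.normal(0.0, 0.25)
        r, c = int(round(pos[0])), int(round(pos[1]))
        if 0 <= r < size_px and 0 <= c < size_px:
            pts.append((r, c))
    return pts


def simulate_observer(
    scene: SyntheticScene,
    stim: StimulusSpec,
    model: ObserverModel,
    masking_strength: float = 0.0,
    trial_id: int = 0,
) -> TraceMap:
    """Simulate one drawing trial as a 1-px binary trace map.

    Each boundary segment (one placed shape) is traced iff its visibility
    probability exceeds the observer's persistent latent for that segment;
    minor segments additionally require the observer's detail preference.
    Traced pixels are displaced by a smooth random field of standard
    deviation ``jitter_sd`` and spurious smooth strokes are added to an
    expected total of the (possibly contrast-dependent) false-trace budget.
    """
    n = scene.size_px
    noise_rms = stim.noise.rms_contrast if stim.noise is not None else 0.0
    attenuation = 1.0 + masking_strength * noise_rms
    rng = np.random.default_rng([model.seed, 1 + trial_id])

    out = np.zeros((n, n), dtype=bool)
    for shape in scene.shapes:
        if shape.minor and _persistent_uniform(model.seed, 104729, shape.label) >= model.detail_level:
            continue
        c_eff = stim.image_contrast * shape.amplitude / attenuation
        p_draw = norm.cdf((c_eff - model.omission_mu) / model.omission_sigma)
        if p_draw > _persistent_uniform(model.seed, 7919, shape.label):
            out |= scene.edge_owner == shape.label

    if model.jitter_sd > 0 and out.any():
        fields = []
        for _ in range(2):
            g = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=8.0)
            fields.append(g / g.std() * model.jitter_sd)
        dr, dc = fields
        rows, cols = np.nonzero(out)
        new_r = np.clip(np.rint(rows + dr[rows, cols]).astype(int), 0, n - 1)
        new_c = np.clip(np.rint(cols + dc[rows, cols]).astype(int), 0, n - 1)
        out = np.zeros((n, n), dtype=bool)
        out[new_r, new_c] = True

    fa_budget = model.fa_rate * max(0.0, 1.0 - model.fa_contrast_slope * stim.image_contrast)
    if fa_budget > 0:
        target = int(rng.poisson(fa_budget))
        placed = 0
        while placed < target:
            for r, c in _smooth_stroke(rng, n):
                if placed >= target:
                    break
                if not out[r, c]:
                    out[r, c] = True
                    placed += 1

    return TraceMap(
        out,
        observer_id=f"obs{model.seed}",
        condition=stim.noise.label if stim.noise is not None else "nonoise",
    )


def condition_cells(contrasts_per_noise: dict[str, list[float]]) -> list[tuple[str, float]]:
    """All (noise label, contrast) condition cells of a design."""
    return [(fam, c) for fam, levels in contrasts_per_noise.items() for c in levels]


def generate_design(
    n_images: int,
    contrasts_per_noise: dict[str, list[float]],
    seed: int = 0,
    n_observers: int = 1,
) -> pd.DataFrame:
    """Random trial table: each observer sees each image exactly once.

    The (noise, contrast) condition of each trial is drawn uniformly from
    the full condition grid, so a given cell lands on different image
    identities across observers. Columns: observer_id, image_id, noise,
    image_contrast.
    """
    cells = condition_cells(contrasts_per_noise)
    if n_images < 1:
        raise ValueError("n_images must be at least 1")
    rng = np.random.default_rng(seed)
    rows = []
    for obs in range(n_observers):
        order = rng.permutation(n_images)
        for image_id in order:
            fam, contrast = cells[int(rng.integers(len(cells)))]
            rows.append(
                {
                    "observer_id": f"obs{obs}",
                    "image_id": int(image_id),
                    "noise": fam,
                    "image_contrast": contrast,
                }
            )
    return pd.DataFrame(rows)


def noise_spec_from_label(label: str, rms_contrast: float = 0.1, seed: int = 0) -> NoiseSpec:
    """Build a NoiseSpec from a condition label like ``pink`` or ``narrowband-3``."""
    if label.startswith("narrowband-"):
        return NoiseSpec(
            family="narrowband",
            center_sf=float(label.split("-", 1)[1]),
            rms_contrast=rms_contrast,
            seed=seed,
        )
    return NoiseSpec(family=label, rms_contrast=rms_contrast, seed=seed)


def end_to_end_recovery(
    masking_strengths: dict[str, float],
    contrasts: list[float],
    n_observers: int = 20,
    n_images: int = 30,
    size_px: int = 256,
    model: ObserverModel = ObserverModel(jitter_sd=1.5, fa_rate=200.0, detail_level=0.8),
    noise_rms: float = 0.1,
    gt_contrast: float = 0.16,
    margin_fraction: float = 0.025,
    n_shapes: int = 6,
    contrast_range: tuple[float, float] = (0.3, 1.0),
    seed: int = 0,
) -> dict:
    """Simulate a full experiment and recover thresholds per noise family.

    Simulates ground-truth and noisy sessions for every observer, scores
    each noisy trial against the same observer's ground truth, pools counts
    per (noise, contrast) cell, fits a scaled cumulative Gaussian per noise
    family, and reports fitted thresholds against the injected
    visibility-link midpoints.
    """
    families = list(masking_strengths)
    scenes = [
        make_scene(
            n_shapes=n_shapes, size_px=size_px, contrast_range=contrast_range,
            seed=seed * 100_003 + i,
        )
        for i in range(n_images)
    ]
    cfg = ScoringConfig(margin_fraction=margin_fraction)
    design = generate_design(
        n_images, {fam: contrasts for fam in families}, seed=seed + 1, n_observers=n_observers
    )

    observers = {
        f"obs{seed + 10_000 + i}": replace(model, seed=seed + 10_000 + i)
        for i in range(n_observers)
    }
    obs_ids = list(observers)
    gt_maps: dict[tuple[str, int], TraceMap] = {}
    gt_spec = StimulusSpec(image_contrast=gt_contrast, noise=None)
    for oid, om in observers.items():
        for img in range(n_images):
            gt_maps[(oid, img)] = simulate_observer(scenes[img], gt_spec, om, trial_id=1_000_000 + img)

    cell_counts: dict[tuple[str, float], list[ContingencyCounts]] = {}
    for i, row in enumerate(design.itertuples(index=False)):
        oid = obs_ids[int(row.observer_id.removeprefix("obs"))]
        om = observers[oid]
        spec = StimulusSpec(
            image_contrast=row.image_contrast,
            noise=noise_spec_from_label(row.noise, rms_contrast=noise_rms),
        )
        resp = simulate_observer(
            scenes[row.image_id], spec, om,
            masking_strength=masking_strengths[row.noise], trial_id=i,
        )
        counts = score_traces(gt_maps[(oid, row.image_id)], resp, cfg)
        cell_counts.setdefault((row.noise, row.image_contrast), []).append(counts)

    per_cell = {
        cell: pool_counts(lst) for cell, lst in cell_counts.items()
    }
    fits, thresholds, p_by_contrast = {}, {}, {}
    for fam in families:
        xs = sorted(c for (f, c) in per_cell if f == fam)
        ps, ws = [], []
        for c in xs:
            pooled = per_cell[(fam, c)]
            ps.append(proportion_correct(pooled))
            ws.append(pooled.hits + pooled.misses + pooled.fa)
        data = PsychometricData(np.array(xs), np.array(ps), np.array(ws, dtype=float))
        scaled, pmax = scale_by_max(data)
        fit = fit_cumulative_gaussian(scaled)
        fits[fam] = fit
        thresholds[fam] = fit.threshold
        p_by_contrast[fam] = dict(zip(xs, ps))

    amp_ref = float(
        np.average(
            [s.amplitude for sc in scenes for s in sc.shapes],
            weights=[s.n_boundary_px for sc in scenes for s in sc.shapes],
        )
    )
    true_midpoints = {
        fam: model.omission_mu * (1.0 + ms * noise_rms) / amp_ref
        for fam, ms in masking_strengths.items()
    }
    order_true = sorted(families, key=masking_strengths.get)
    order_fit = sorted(families, key=thresholds.get)
    return {
        "thresholds": thresholds,
        "true_midpoints": true_midpoints,
        "fits": fits,
        "p_by_contrast": p_by_contrast,
        "ordering_recovered": order_true == order_fit,
        "amp_ref": amp_ref,
    }
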