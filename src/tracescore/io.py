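"""File formats, run configuration, and the batch scoring/fit pipeline.

Luminance images travel as 16-bit grayscale PNG plus a JSON sidecar holding
the calibration ({mean_luminance, ppd, cd_per_level}); 8-bit files are
accepted on read with a warning. Trace maps are 1-bit/8-bit PNGs where any
nonzero pixel counts as traced. Tabular inputs and outputs are UTF-8 CSV;
every output CSV embeds the package version and a hash of the run
configuration as ``#``-comment header lines, and reruns with identical
inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .scoring import ScoringConfig, TraceMap, pool_counts, proportion_correct, score_traces, sdt_measures
from .psychometric import PsychometricData, fit_cumulative_gaussian, scale_by_max
from .stimuli import LuminanceImage

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "observer_id",
    "image_id",
    "session",  # "gt" (noise-free ground truth) or "noisy"
    "noise",
    "image_contrast",
    "trace_path",
]


@dataclass
class RunConfig:
    """Pipeline parameters; serializes losslessly to/from YAML or JSON."""

    margin_fraction: float | None = 0.025
    margin_px: int | None = None
    rate_correction: str = "loglinear"
    include_cr_in_pc: bool = False
    criterion: float = 0.5
    lapse_max: float = 0.05
    n_eff: float = 100.0
    seed: int = 0

    def scoring_config(self) -> ScoringConfig:
        return ScoringConfig(
            margin_px=self.margin_px,
            margin_fraction=self.margin_fraction,
            rate_correction=self.rate_correction,
            include_cr_in_pc=self.include_cr_in_pc,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def save(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def write_image_png(img: LuminanceImage, path: str | Path) -> None:
    """Write a 16-bit grayscale PNG and a JSON calibration sidecar."""
    path = Path(path)
    peak = float(img.values.max())
    cd_per_level = peak / 65535.0 if peak > 0 else 1.0
    levels = np.rint(img.values / cd_per_level).astype(np.uint16)
    Image.fromarray(levels).save(path)  # uint16 -> 16-bit grayscale
    sidecar = {
        "mean_luminance": img.mean_luminance,
        "ppd": img.ppd,
        "cd_per_level": cd_per_level,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_image_png(path: str | Path) -> LuminanceImage:
    """Read a grayscale PNG and its JSON sidecar back to luminance."""
    path = Path(path)
    with Image.open(path) as im:
        if im.mode in ("I;16", "I"):
            arr = np.asarray(im, dtype=np.float64)
        elif im.mode == "L":
            warnings.warn(f"{path}: 8-bit image; expected 16-bit", stacklevel=2)
            arr = np.asarray(im, dtype=np.float64)
        else:
            raise ValueError(f"{path}: unsupported image mode {im.mode!r}; expected grayscale")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing calibration sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    return LuminanceImage(arr * sidecar["cd_per_level"], ppd=sidecar["ppd"])


def write_trace_png(trace: TraceMap, path: str | Path) -> None:
    """Write a trace map as a 1-bit PNG."""
    Image.fromarray(trace.mask).save(Path(path))


def read_trace_png(path: str | Path, **ids) -> TraceMap:
    """Read a trace map PNG; any nonzero pixel is traced.

    Rejects color images; warns when the file contains intermediate gray
    levels (e.g. anti-aliased strokes), which are thresholded at > 0.
    """
    path = Path(path)
    with Image.open(path) as im:
        if im.mode not in ("1", "L", "I;16", "I"):
            raise ValueError(f"{path}: trace maps must be grayscale, got mode {im.mode!r}")
        arr = np.asarray(im)
    uniques = np.unique(arr)
    nonbinary = uniques[(uniques != 0) & (uniques != uniques.max())]
    if nonbinary.size > 0:
        warnings.warn(
            f"{path}: {nonbinary.size} intermediate gray levels thresholded at > 0",
            stacklevel=2,
        )
        logger.warning("%s: anti-aliased trace thresholded at > 0", path)
    return TraceMap((arr > 0).astype(np.uint8), **ids)


# ---------------------------------------------------------------------------
# Manifests and CSV output
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["observer_id", "image_id", "session", "noise", "image_contrast"])
    if dup.any():
        raise ValueError(f"manifest {path} contains duplicate trial keys")
    return df


def write_csv(df: pd.DataFrame, path: str | Path, config: RunConfig) -> None:
    """Write a CSV with version/config-hash header comments, deterministically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# tracescore_version={__version__}\n# config_hash={config.config_hash}\n"
    body = df.to_csv(index=False, float_format="%.10g", lineterminator="\n")
    path.write_text(header + body)


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig,
    out_dir: str | Path,
    base_dir: str | Path | None = None,
) -> dict:
    """Score every noisy trial against its observer's ground truth, then fit.

    Every noisy row is paired with the SAME observer's ground-truth ("gt"
    session) map of the same image. Trials without a ground truth are
    skipped and reported, never silently dropped. Writes ``scores.csv`` (one
    row per scored trial) and ``fits.csv`` (one row per noise condition) to
    ``out_dir`` and returns a summary report.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir) if base_dir is not None else Path(".")
    cfg = config.scoring_config()

    gt_rows = manifest[manifest["session"] == "gt"]
    noisy_rows = manifest[manifest["session"] == "noisy"]
    gt_lookup = {
        (r.observer_id, r.image_id): r.trace_path for r in gt_rows.itertuples(index=False)
    }

    records, skipped = [], []
    for r in noisy_rows.itertuples(index=False):
        key = (r.observer_id, r.image_id)
        if key not in gt_lookup:
            skipped.append(key)
            logger.warning("no ground truth for observer=%s image=%s; trial skipped", *key)
            continue
        gt = read_trace_png(base / gt_lookup[key])
        resp = read_trace_png(base / r.trace_path)
        counts = score_traces(gt, resp, cfg)
        measures = sdt_measures(counts, cfg)
        records.append(
            {
                "observer_id": r.observer_id,
                "image_id": r.image_id,
                "noise": r.noise,
                "image_contrast": r.image_contrast,
                "hits": counts.hits,
                "misses": counts.misses,
                "fa": counts.fa,
                "cr": counts.cr,
                "p": measures.p,
                "dprime": measures.dprime,
                "c": measures.c,
            }
        )

    scores = pd.DataFrame(
        records,
        columns=[
            "observer_id", "image_id", "noise", "image_contrast",
            "hits", "misses", "fa", "cr", "p", "dprime", "c",
        ],
    ).sort_values(["observer_id", "image_id", "noise", "image_contrast"], kind="mergesort")
    write_csv(scores, out_dir / "scores.csv", config)

    fits_df = fit_conditions(scores, config)
    write_csv(fits_df, out_dir / "fits.csv", config)

    report = {
        "n_scored": len(records),
        "n_skipped": len(skipped),
        "skipped": skipped,
        "config_hash": config.config_hash,
        "version": __version__,
    }
    if not records:
        logger.warning("empty manifest: no trials scored")
    return report


def fit_conditions(scores: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Pool counts per (noise, contrast) and fit one curve per noise condition."""
    rows = []
    for fam, grp in scores.groupby("noise", sort=True):
        cells = grp.groupby("image_contrast", sort=True)[["hits", "misses", "fa"]].sum()
        denom = cells["hits"] + cells["misses"] + cells["fa"]
        ok = denom > 0
        if ok.sum() < 3:
            logger.warning("noise %s: fewer than 3 usable contrast levels; skipped", fam)
            continue
        data = PsychometricData(
            cells.index.values[ok],
            (cells["hits"][ok] / denom[ok]).values,
            denom[ok].values.astype(float),
        )
        scaled, pmax = scale_by_max(data)
        fit = fit_cumulative_gaussian(
            scaled, lapse_max=config.lapse_max, n_eff=config.n_eff, criterion=config.criterion
        )
        rows.append(
            {
                "noise": fam,
                "mu": fit.mu,
                "sigma": fit.sigma,
                "lapse": fit.lapse,
                "pmax": pmax,
                "threshold": fit.threshold,
                "gof": fit.gof,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["noise", "mu", "sigma", "lapse", "pmax", "threshold", "gof", "converged"],
    )
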