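"""Statistics, summary tables, fixture generation, configuration and I/O.

A single run seed fans out to per-stage child seeds through
:func:`spawn_seeds` (numpy ``SeedSequence``), so every stage of a pipeline
is independently reproducible. Each CLI run writes a JSON manifest with
parameters, seeds and counts next to its outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import stats as sstats

from .periodic_cvt import SeedSet, periodic_voronoi, lloyd_relax, sample_seeds
from .tube_model import build_tube, intermediate_surface
from .motif_analysis import MotifSample

logger = logging.getLogger(__name__)

__all__ = [
    "KSResult",
    "ConditionSummary",
    "ks_two_sample",
    "summarize",
    "polar_export",
    "make_fixtures",
    "spawn_seeds",
    "load_config",
    "write_manifest",
    "write_label_tiff",
    "read_label_tiff",
    "seeds_to_csv",
    "seeds_from_csv",
]


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    n1: int
    n2: int


def ks_two_sample(sample_a, sample_b) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test (two-sided)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sstats.ks_2samp(a, b, alternative="two-sided")
    return KSResult(float(res.statistic), float(res.pvalue), len(a), len(b))


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    n_replicates: int
    n_cells_total: int
    mean_pct_scutoids: float
    sd_pct_scutoids: float


def summarize(
    results: dict[str, list[tuple[float, int]]]
) -> pd.DataFrame:
    """Mean +/- SD of scutoid percentages per condition.

    ``results`` maps a condition label to a list of (percentage, n_cells)
    replicate entries. SD is the population SD over replicates (0 for a
    single replicate).
    """
    rows = []
    for cond, entries in results.items():
        pcts = np.array([p for p, _ in entries], dtype=float)
        cells = int(sum(n for _, n in entries))
        rows.append(
            asdict(
                ConditionSummary(
                    condition=cond,
                    n_replicates=len(entries),
                    n_cells_total=cells,
                    mean_pct_scutoids=float(np.mean(pcts)),
                    sd_pct_scutoids=float(np.std(pcts)),
                )
            )
        )
    return pd.DataFrame(rows)


def polar_export(sample: MotifSample, surface: str | None = None) -> pd.DataFrame:
    """(theta_deg, edge_len, class) table for polar scatter plotting."""
    rows = []
    for cls, motifs in (
        ("transition", sample.transition),
        ("no_transition", sample.no_transition),
    ):
        for m in motifs:
            g = m.geometry.get(surface or m.reference)
            if g is None:
                continue
            rows.append(
                {"theta_deg": g.theta_deg, "edge_len": g.edge_length, "class": cls}
            )
    return pd.DataFrame(rows)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def load_config(path: str | Path) -> dict:
    """YAML or JSON configuration mirroring the CLI flags."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def write_manifest(out_dir: str | Path, **fields) -> Path:
    """Write a JSON run manifest (parameters, seeds, counts) next to outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    payload = {}
    for k, v in fields.items():
        if isinstance(v, (np.integer, np.floating)):
            v = v.item()
        payload[k] = v
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path


def write_label_tiff(path: str | Path, planes) -> None:
    """Write one or more integer label rasters as a (multi-page) TIFF."""
    arrs = [np.asarray(getattr(p, "labels", p), dtype=np.int32) for p in planes]
    tifffile.imwrite(str(path), np.stack(arrs))


def read_label_tiff(path: str | Path) -> list[np.ndarray]:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        return [arr]
    return [arr[i] for i in range(arr.shape[0])]


def seeds_to_csv(path: str | Path, seeds: SeedSet) -> None:
    df = pd.DataFrame(
        {"id": np.arange(seeds.n), "x": seeds.points[:, 0], "y": seeds.points[:, 1]}
    )
    df.to_csv(path, index=False)


def seeds_from_csv(path: str | Path, width_px: int, height_px: int) -> SeedSet:
    df = pd.read_csv(path)
    pts = df[["x", "y"]].to_numpy(dtype=float)
    return SeedSet(pts, width_px, height_px)


def make_fixtures(
    kind: str,
    out_dir: str | Path,
    rng: int = 0,
    size: str = "small",
) -> dict:
    """Generate small, seeded on-disk test assets.

    kinds: 'tube' (40-cell, 128x1024 CVT tube at ratio 2.5 with seeds CSV
    and apical/basal TIFFs), 'stack' (interpolated 11-plane label stack of
    the same tube), 'flip' (hand-built 12x8 apical/basal pair containing
    exactly one diagonal flip). Returns a manifest of written files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict = {"kind": kind, "rng": rng}
    if kind in ("tube", "stack"):
        n, w, h = (40, 128, 1024) if size == "small" else (200, 512, 4096)
        seeds = lloyd_relax(sample_seeds(n, w, h, rng=rng), iterations=4)
        tube = build_tube(seeds, 2.5)
        seeds_to_csv(out_dir / "seeds.csv", seeds)
        written["seeds"] = "seeds.csv"
        if kind == "tube":
            write_label_tiff(out_dir / "apical.tif", [tube.apical])
            write_label_tiff(out_dir / "basal.tif", [tube.basal])
            written["files"] = ["apical.tif", "basal.tif"]
        else:
            lams = np.linspace(0, 1, 11)
            planes = [intermediate_surface(tube, float(l)).labels for l in lams]
            # common raster frame: planes differ in width, store separately
            for i, p in enumerate(planes):
                write_label_tiff(out_dir / f"plane_{i:02d}.tif", [p])
            written["files"] = [f"plane_{i:02d}.tif" for i in range(len(planes))]
    elif kind == "flip":
        apical, basal = flip_fixture()
        write_label_tiff(out_dir / "apical.tif", [apical])
        write_label_tiff(out_dir / "basal.tif", [basal])
        written["files"] = ["apical.tif", "basal.tif"]
    else:
        raise ValueError(f"unknown fixture kind: {kind}")
    write_manifest(out_dir, **written)
    return written


def flip_fixture(scale: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Hand-built 12x8 periodic apical/basal rasters with one diagonal flip.

    Cells: T/U are top/bottom border bands (non-valid), L/R lateral cells,
    and the motif A, B (central pair, apical) with flanks C (above) and D
    (below). On the basal raster C and D meet between A and B instead:
    exactly one apico-basal transition. ``scale`` magnifies every pixel
    (scale >= 3 brings the central edge above the 4 px measurement filter).
    """
    T, U, L, R, A, B, C, D = 1, 2, 3, 4, 5, 6, 7, 8
    apical = np.zeros((12, 8), dtype=np.int32)
    apical[0:2, :] = T
    apical[2:5, :] = C
    apical[5:8, :] = [L, A, A, A, B, B, B, R]
    apical[8:10, :] = D
    apical[10:12, :] = U
    basal = apical.copy()
    basal[5:8, :] = [L, A, A, C, C, B, B, R]
    if scale > 1:
        k = np.ones((scale, scale), dtype=np.int32)
        apical = np.kron(apical, k)
        basal = np.kron(basal, k)
    return apical, basal
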