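"""Batch orchestration: map a plate directory of TIFFs to per-well,
per-timepoint phenotypic metrics.

Filenames are parsed with a configurable regex capturing ``well``,
``time``, ``z`` and ``channel`` groups; files sharing (well, time,
channel) form one Z-stack, ordered by the ``z`` capture (top first).
Each channel is routed to one or more analyses (``coverage``,
``invasion``, ``vessels``) and results land in a tidy table, one row
per (well, time, analysis).  Partial failures are logged per well and
never abort the batch.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mpmtools.coverage import coverage_from_image
from mpmtools.errors import MpmToolsError
from mpmtools.imaging_io import detect_well_boundary, project_zstack, read_zstack
from mpmtools.invasion import InvasionClassifier, classify_stack, compute_invasion_depth
from mpmtools.morse_graph import MorseParams, extract_morse_skeleton, prune_and_filter, smooth_branches
from mpmtools.topology_stats import network_statistics
from mpmtools.vessel_seg import ProbabilityMap, refine_probability_map, sato_vesselness_2d

logger = logging.getLogger("mpmtools")

DEFAULT_FILENAME_REGEX = r"(?P<well>[A-Za-z]+\d+)_t(?P<time>\d+)_z(?P<z>\d+)_(?P<channel>[A-Za-z0-9]+)\.tiff?$"


@dataclass
class RunConfig:
    """Everything a batch run needs; YAML-serialisable."""

    input_dir: str = "."
    output_dir: str = "results"
    filename_regex: str = DEFAULT_FILENAME_REGEX
    channel_analyses: dict = field(default_factory=lambda: {"GFP": ["coverage", "vessels"], "TexasRed": ["coverage", "invasion"]})
    pixel_size_um: float = 1.0
    z_step_um: float = 1.0
    coverage_lambda: float = 0.0
    invasion_threshold: float = 0.5
    morse: MorseParams = field(default_factory=MorseParams)
    seed: int = 0
    save_intermediates: bool = False
    projection_method: str = "focus_stack"

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        morse = MorseParams(**d.pop("morse", {}))
        return cls(morse=morse, **d)


@dataclass
class BatchResult:
    table: pd.DataFrame
    skipped_files: list[str]
    warnings: list[str]


def _scan(config: RunConfig) -> tuple[dict, list[str]]:
    pat = re.compile(config.filename_regex)
    groups: dict[tuple, list[tuple[int, Path]]] = {}
    skipped = []
    root = Path(config.input_dir)
    for path in sorted(root.iterdir()):
        if not path.is_file() or path.suffix.lower() not in (".tif", ".tiff"):
            continue
        m = pat.search(path.name)
        if not m:
            skipped.append(path.name)
            continue
        key = (m.group("well"), int(m.group("time")), m.group("channel"))
        groups.setdefault(key, []).append((int(m.group("z")), path))
    for key in groups:
        groups[key].sort()
    return groups, skipped


def analyze_vessel_input(vesselness: ProbabilityMap, config: RunConfig):
    """Graph extraction + topology statistics from a refined vesselness map."""
    g = extract_morse_skeleton(vesselness, config.morse, pixel_size_um=config.pixel_size_um)
    g = prune_and_filter(g, config.morse)
    g = smooth_branches(g, config.morse.smoothing_window)
    stats, barcode = network_statistics(g)
    return stats, barcode, g


def run_batch(
    config: RunConfig,
    classifier: InvasionClassifier | None = None,
) -> BatchResult:
    """Run every configured analysis over the input directory.

    Returns a tidy table with one row per (well, time, channel,
    analysis); metric columns are filled according to the analysis.
    Deterministic under a fixed config/seed.
    """
    groups, skipped = _scan(config)
    rows = []
    warnings: list[str] = []
    for (well, time, channel), files in sorted(groups.items()):
        analyses = config.channel_analyses.get(channel, [])
        if not analyses:
            continue
        try:
            stack = read_zstack([str(p) for _, p in files], config.z_step_um, config.pixel_size_um, channel_label=channel)
        except MpmToolsError as exc:
            warnings.append(f"{well}/t{time}/{channel}: unreadable stack ({exc})")
            continue
        base = {"well": well, "time": time, "channel": channel}
        stem = f"{well}_t{time}_{channel}"
        viz_dir = Path(config.output_dir) / "intermediates"
        for analysis in analyses:
            try:
                if analysis == "coverage":
                    proj = project_zstack(stack, config.projection_method)
                    boundary = detect_well_boundary(proj.image)
                    result, fit, mask = coverage_from_image(proj.image, boundary, lam=config.coverage_lambda, seed=config.seed)
                    rows.append({**base, "analysis": "coverage",
                                 "cell_area_px": result.cell_area_px,
                                 "well_area_px": result.well_area_px,
                                 "coverage_fraction": result.fraction})
                    if config.save_intermediates:
                        save_visualizations(viz_dir, stem, image=proj.image, mask=mask)
                elif analysis == "invasion":
                    if classifier is None:
                        warnings.append(f"{well}/t{time}/{channel}: invasion requested but no classifier supplied")
                        continue
                    call = classify_stack(classifier, stack, threshold=config.invasion_threshold)
                    depth = compute_invasion_depth(call, config.z_step_um)
                    rows.append({**base, "analysis": "invasion",
                                 "deepest_invaded_index": depth.deepest_invaded_index,
                                 "invasion_depth_um": depth.depth_um})
                elif analysis == "vessels":
                    if len(stack) > 1:
                        vess = sato_vesselness_2d(stack)
                    else:
                        img = stack.planes[0].astype(np.float64)
                        span = img.max() - img.min()
                        prob = ProbabilityMap(image=(img - img.min()) / span if span > 0 else np.zeros_like(img))
                        vess = refine_probability_map(prob)
                    stats, barcode, graph = analyze_vessel_input(vess, config)
                    rows.append({**base, "analysis": "vessels",
                                 "branch_count": stats.branch_count,
                                 "total_length_um": stats.total_length_um,
                                 "mean_branch_length_um": stats.mean_branch_length_um,
                                 "tree_length_um": stats.tree_length_um})
                    if config.save_intermediates:
                        save_visualizations(viz_dir, stem, image=stack.planes[0],
                                            vesselness=vess.image, graph=graph, barcode=barcode)
                else:
                    warnings.append(f"{well}/t{time}/{channel}: unknown analysis {analysis!r}")
            except MpmToolsError as exc:
                warnings.append(f"{well}/t{time}/{channel}/{analysis}: {exc}")
                logger.warning("analysis failure: %s", warnings[-1])
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(["well", "time", "channel", "analysis"]).reset_index(drop=True)
    else:
        warnings.append("no analyzable files found")
    return BatchResult(table=table, skipped_files=skipped, warnings=warnings)


def save_visualizations(
    out_dir: str | Path,
    name: str,
    *,
    image: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    vesselness: np.ndarray | None = None,
    graph=None,
    barcode=None,
) -> list[Path]:
    """Write per-stage PNGs (threshold mask, refined vesselness, graph
    overlay, barcode diagram) with deterministic names."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save(fig, suffix):
        path = out / f"{name}_{suffix}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if mask is not None:
        fig, ax = plt.subplots()
        ax.imshow(mask, cmap="gray")
        ax.set_title("threshold mask")
        save(fig, "mask")
    if vesselness is not None:
        fig, ax = plt.subplots()
        ax.imshow(vesselness, cmap="magma")
        ax.set_title("refined vesselness")
        save(fig, "vesselness")
    if graph is not None:
        fig, ax = plt.subplots()
        if image is not None:
            ax.imshow(image, cmap="gray")
        for _, _, d in graph.graph.edges(data=True):
            poly = d["polyline"]
            if len(poly):
                ax.plot(poly[:, 0], poly[:, 1], lw=1.2)
        ax.set_title("extracted network")
        save(fig, "graph")
    if barcode is not None and len(barcode):
        fig, ax = plt.subplots()
        for i, bar in enumerate(barcode.bars):
            ax.plot([bar.birth, bar.death], [i, i], lw=2)
        ax.set_xlabel("filtration value (-distance to root, um)")
        ax.set_ylabel("bar")
        ax.set_title("persistence barcode")
        save(fig, "barcode")
    return written
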