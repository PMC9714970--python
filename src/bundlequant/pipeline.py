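"""Run orchestration: validated stage configs, deterministic execution,
provenance logging, and CSV/JSON report output.

A run config (YAML or dict) declares an ordered stage list.  Supported
stages:

``phantom``   simulate a hair-cell stack (+ ground truth)
``quantify``  ROI quantification of one channel into a table
``vesicles``  vesicle detection on the ground-truth lysosome mask or an
              adaptively segmented channel
``fisher``    exact 2×2 test, on configured counts or on the phantom's
              enlarged-cell flags against a configured reference group

The whole config is validated before any stage runs; identical config +
seed reproduces bit-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .imaging import AdaptiveSegmenter, quantify_group_stacks
from .morphometry import ContingencyTable2x2, detect_vesicles, vesicle_table
from .phantoms import GroundTruth, PhantomSpec, ProbeModel, simulate_stack
from .stack import RoiBox, rle_encode, save_json, write_stack
from .stats import fisher_exact_2x2

__all__ = ["RunConfig", "PipelineConfigError", "run_config", "load_config"]

logger = logging.getLogger("bundlequant")

_KNOWN_STAGES = {"phantom", "quantify", "vesicles", "fisher"}


class PipelineConfigError(ValueError):
    """Raised before execution when the config is invalid."""


@dataclass
class RunConfig:
    """Declared stages, output directory and seed."""

    stages: list[dict[str, Any]]
    out_dir: str
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, cfg: dict[str, Any]) -> "RunConfig":
        missing = [k for k in ("stages", "out_dir") if k not in cfg]
        if missing:
            raise PipelineConfigError(f"config missing required keys: {missing}")
        return cls(
            stages=list(cfg["stages"]),
            out_dir=str(cfg["out_dir"]),
            seed=int(cfg.get("seed", 0)),
            log_level=str(cfg.get("log_level", "INFO")),
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _validate(cfg: RunConfig) -> None:
    if not cfg.stages:
        raise PipelineConfigError("config declares no stages")
    errors = []
    have_phantom = False
    for i, stage in enumerate(cfg.stages):
        if not isinstance(stage, dict) or "stage" not in stage:
            errors.append(f"stage {i}: missing 'stage' key")
            continue
        name = stage["stage"]
        if name not in _KNOWN_STAGES:
            errors.append(
                f"stage {i}: unknown stage {name!r} (known: {sorted(_KNOWN_STAGES)})"
            )
            continue
        if name == "phantom":
            have_phantom = True
        if name in ("quantify", "vesicles") and not have_phantom:
            errors.append(f"stage {i} ({name}): requires a prior 'phantom' stage")
        if name == "fisher" and "counts" not in stage and "reference_counts" not in stage:
            errors.append(
                f"stage {i} (fisher): needs 'counts' [[a,b],[c,d]] or "
                "'reference_counts' [flagged, total] to compare the phantom against"
            )
    if errors:
        raise PipelineConfigError("; ".join(errors))


def run_config(cfg: RunConfig | dict[str, Any]) -> dict[str, Any]:
    """Validate then execute all stages; returns the report bundle.

    The report maps stage names to their primary outputs; all tables are
    also written under ``cfg.out_dir`` together with ``provenance.json``.
    """
    if isinstance(cfg, dict):
        cfg = RunConfig.from_dict(cfg)
    _validate(cfg)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {}
    stack = None
    truth: GroundTruth | None = None
    for i, stage in enumerate(cfg.stages):
        name = stage["stage"]
        params = {k: v for k, v in stage.items() if k != "stage"}
        logger.info("stage %d: %s", i, name)
        if name == "phantom":
            spec = _phantom_spec(params, cfg.seed)
            stack, truth = simulate_stack(spec)
            write_stack(out / "phantom.ome.tif", stack)
            save_json(
                out / "phantom_truth.json",
                {
                    "n_cells": len(truth.cells),
                    "enlarged_cells": [c.cell_id for c in truth.cells if c.has_enlarged],
                    "lysosome_mask": rle_encode(truth.union("lysosomes")),
                },
            )
            report["phantom"] = {
                "channels": list(stack.channel_names),
                "shape": list(stack.shape),
                "n_cells": len(truth.cells),
            }
        elif name == "quantify":
            channel = params.get("channel", stack.channel_names[0])
            roi = None
            if "roi_origin_um" in params and "roi_extent_um" in params:
                roi = RoiBox(
                    tuple(params["roi_origin_um"]), tuple(params["roi_extent_um"])
                )
            seg = None
            if params.get("segment", False):
                seg = AdaptiveSegmenter(
                    window_um=params.get("window_um", 5.0),
                    offset_frac=params.get("offset_frac", 0.10),
                )
            table = quantify_group_stacks(
                [("phantom", params.get("group", "phantom"), stack)],
                roi,
                channel,
                segmenter=seg,
            )
            table.to_csv(out / "quantify.csv", index=False)
            report["quantify"] = table.to_dict("records")
        elif name == "vesicles":
            if params.get("source", "truth") == "truth":
                mask = truth.union("lysosomes")
            else:
                seg = AdaptiveSegmenter(
                    window_um=params.get("window_um", 5.0),
                    offset_frac=params.get("offset_frac", 0.10),
                )
                mask = seg.transform(stack, params.get("channel", 0)).mask
            calls = detect_vesicles(
                mask,
                stack.voxel_size,
                diameter_threshold_um=params.get("diameter_threshold_um", 2.0),
            )
            table = vesicle_table(calls)
            table.to_csv(out / "vesicles.csv", index=False)
            report["vesicles"] = {
                "n_vesicles": len(calls),
                "n_enlarged": int(sum(c.enlarged for c in calls)),
            }
        elif name == "fisher":
            if "counts" in params:
                (a, b), (c, d) = params["counts"]
                tab = ContingencyTable2x2(a, b, c, d)
            else:
                flagged = sum(c.has_enlarged for c in truth.cells) if truth else 0
                total = len(truth.cells) if truth else 0
                ref_flagged, ref_total = params["reference_counts"]
                tab = ContingencyTable2x2(
                    flagged, total - flagged, ref_flagged, ref_total - ref_flagged
                )
            result = fisher_exact_2x2(tab)
            payload = {
                "method": result.method,
                "p_value": result.p_value,
                "odds_ratio": result.statistic,
                "table": result.table.to_array().tolist(),
            }
            save_json(out / "fisher.json", payload)
            report["fisher"] = payload

    provenance = {
        "config": {
            "stages": cfg.stages,
            "out_dir": cfg.out_dir,
            "seed": cfg.seed,
        },
        "versions": {
            "bundlequant": __version__,
            "numpy": np.__version__,
        },
    }
    save_json(out / "provenance.json", provenance)
    report["provenance"] = provenance
    return report


def _phantom_spec(params: dict[str, Any], seed: int) -> PhantomSpec:
    kwargs = dict(params)
    if "probes" in kwargs:
        kwargs["probes"] = tuple(ProbeModel(**p) for p in kwargs["probes"])
    for key in ("cell_semi_axes_um", "voxel_size_um", "stack_shape", "lysosome_diameter_um"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    kwargs.setdefault("seed", seed)
    try:
        return PhantomSpec(**kwargs)
    except TypeError as exc:
        raise PipelineConfigError(f"phantom stage: {exc}") from None
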