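"""Config-driven end-to-end runs of the segmentation workflow.

A run executes, in order: input (file or phantom) -> optional pore noise ->
optional local normalization -> binarization (or the phantom's exact mask)
-> optional small-component cleanup -> distance transform (rwdt / edt /
ensemble) -> contour-tree segmentation -> optional merging -> optional
morphometrics and evaluation against phantom truth.  Every intermediate
volume, a stage-timing log, and a manifest echoing the exact configuration
(including all seeds) are written to the run directory; the manifest alone
reproduces the run bit-exactly.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import binarize, distance, io, phantoms, postprocess, preprocess, quantify, segment
from .grids import BinaryMask, IntensityVolume, LabelVolume

log = logging.getLogger(__name__)

PHANTOM_BUILDERS = {
    "voronoi": phantoms.voronoi_tiling_phantom,
    "hex": phantoms.hexagonal_tiling_phantom,
    "prisms": phantoms.columnar_prism_phantom,
}


def _walk_spec(config: dict) -> distance.WalkSpec:
    walk = config.get("walk", {})
    return distance.WalkSpec(
        connectivity=int(walk.get("connectivity", 6)),
        border=walk.get("border", "reflecting"),
        solver_tolerance=float(walk.get("tolerance", 1e-8)),
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the configured workflow; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    raise StageError(name, exc) from exc
                return False

        return _Timer()

    (out / "manifest.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    truth: LabelVolume | None = None
    phantom_params: dict = {}
    with stage("input"):
        if "phantom" in config:
            pconf = dict(config["phantom"])
            kind = pconf.pop("kind")
            if "shape" in pconf:
                pconf["shape"] = tuple(pconf["shape"])
            bundle = PHANTOM_BUILDERS[kind](**pconf)
            volume, truth, mask = bundle.image, bundle.truth, bundle.mask
            phantom_params = bundle.params
            io.write_volume(volume, out / "input.tif")
            io.write_labels(truth, out / "truth.tif")
        else:
            volume = io.read_volume(config["input"], config.get("spacing"))
            mask = None
            if config.get("truth"):
                truth = io.read_labels(config["truth"])

    if "normalize" in config:
        with stage("normalize"):
            nconf = config["normalize"]
            volume = preprocess.local_normalize(
                volume, float(nconf["sigma"]), float(nconf.get("epsilon", 1e-6))
            )
            io.write_volume(volume, out / "normalized.tif")

    with stage("binarize"):
        if "threshold" in config:
            mask = binarize.threshold_mask(
                volume, float(config["threshold"]), invert=bool(config.get("invert", False))
            )
        elif mask is None:
            raise ValueError("config needs 'threshold' (or a phantom supplying a mask)")
        if "pore_rate" in config:
            mask = phantoms.inject_pore_noise(
                mask, float(config["pore_rate"]), int(config.get("pore_seed", 0))
            )
        io.write_mask(mask, out / "mask.tif")

    if "clean" in config:
        with stage("clean"):
            cconf = config["clean"]
            mask = binarize.remove_small_components(
                mask, int(cconf["min_voxels"]), int(cconf.get("connectivity", 26))
            )
            io.write_mask(mask, out / "mask_clean.tif")

    with stage("distance"):
        method = config.get("distance", "rwdt")
        if method == "rwdt":
            dmap = distance.random_walk_distance(mask, _walk_spec(config))
        elif method == "edt":
            dmap = distance.euclidean_distance(mask, use_spacing=bool(config.get("physical", False)))
        elif method == "ensemble":
            econf = config["ensemble"]
            thresholds = np.arange(
                float(econf["t_min"]), float(econf["t_max"]) + 1e-9, float(econf["t_step"])
            ).tolist()
            dmap = distance.ensemble_rwdt(volume, thresholds, _walk_spec(config))
            mask = dmap.mask
        else:
            raise ValueError(f"unknown distance method {method!r}")
        io.write_volume(dmap, out / "distance.tif")

    with stage("segment"):
        sconf = config.get("segment", {})
        params = segment.SegmentationParams(
            persistence_threshold=float(sconf.get("persistence", 0.15)),
            connectivity=int(sconf.get("connectivity", 6)),
            normalize_first=bool(sconf.get("normalize", True)),
        )
        labels = segment.contour_tree_segment(dmap, params)

    if "merge_pairs" in config:
        with stage("merge"):
            labels = postprocess.apply_merges(
                labels, postprocess.MergeDirective(config["merge_pairs"])
            )
    if "directed_merge" in config:
        with stage("merge_directed"):
            dconf = config["directed_merge"]
            labels = postprocess.directed_merge(
                labels,
                postprocess.DirectedMergeParams(
                    growth_axis=dconf.get("axis", "z"),
                    angle_tolerance=float(dconf.get("angle", 30.0)),
                    min_overlap_fraction=float(dconf.get("overlap", 0.5)),
                    max_gap=int(dconf.get("gap", 3)),
                ),
            )

    io.write_labels(labels, out / "labels.tif")

    summary: dict = {"n_labels": labels.n_labels, "phantom": phantom_params.get("kind")}
    if config.get("quantify", False):
        with stage("quantify"):
            rag = quantify.build_rag(labels, int(config.get("min_contact", 1)))
            stats = quantify.tile_stats(labels, volume, rag)
            import pandas as pd

            pd.DataFrame(
                {
                    "label": [s.label for s in stats],
                    "voxel_count": [s.voxel_count for s in stats],
                    "volume": [s.volume for s in stats],
                    "neighbor_count": [s.neighbor_count for s in stats],
                    "mean_intensity": [s.mean_intensity for s in stats],
                }
            ).to_csv(out / "tile_stats.csv", index=False)
            hist, mean_n = quantify.neighbor_histogram(stats)
            summary["neighbor_mean"] = mean_n
            summary["neighbor_histogram"] = {str(k): v for k, v in hist.items()}

    if "prisms" in config:
        with stage("prisms"):
            profiles = quantify.prism_profiles(labels, config["prisms"].get("axis", "z"))
            import pandas as pd

            pd.DataFrame(
                {
                    "label": [p.label for p in profiles],
                    "slope": [p.slope for p in profiles],
                    "growth_class": [p.growth_class for p in profiles],
                    "relative_curvature": [p.relative_curvature for p in profiles],
                }
            ).to_csv(out / "prism_profiles.csv", index=False)
            summary["n_prisms"] = len(profiles)

    if config.get("evaluate", False) and truth is not None:
        with stage("evaluate"):
            report = quantify.evaluate_segmentation(labels, truth)
            summary["evaluation"] = report.as_dict()

    summary["stage_seconds"] = {k: round(v, 3) for k, v in timings.items()}
    (out / "report.json").write_text(json.dumps(summary, indent=2))
    log.info("run complete: %s", out)
    return out
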