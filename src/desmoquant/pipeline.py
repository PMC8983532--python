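"""Config-driven pipeline runner.

``run_pipeline`` executes the requested stages of a YAML/JSON run
configuration, writes all CSV outputs, QC images, a run log and a manifest,
and returns a :class:`ReportBundle`.  Stage outputs are deterministic given
the configured seeds (timestamps appear only in the log file, never in CSVs
or the manifest).

Minimal demo configuration::

    outdir: run1
    simulate:
      monolayer: {rng_seed: 1, enrichment_ratio: 3.0}
      fragments: {rng_seed: 1, n_fragments: 12}
    linescan: {spacing_px: 10}
    irregularity: {width_px: 3}
    dispase: {min_size_px: 50}
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as dio
from .afm import analyze_map, map_statistics, pool_events
from .core import DesmoquantError
from .dispase import count_fragments
from .irregularity import border_irregularity
from .linescan import aggregate_ratios, measure_line_scan, place_line_scans, trace_borders
from .skeleton import binarize, prune_spurs, skeleton_metrics, skeletonize
from .synthetic import (
    FilamentNetworkParams,
    FragmentSimParams,
    MapSimParams,
    MonolayerParams,
    generate_filament_network,
    generate_force_map,
    generate_fragment_image,
    generate_monolayer,
)

log = logging.getLogger("desmoquant")

STAGES = ("simulate", "linescan", "irregularity", "skeleton", "afm", "dispase", "report")


@dataclass
class ReportBundle:
    outdir: Path
    outputs: dict = field(default_factory=dict)    # stage -> list of file paths
    tables: dict = field(default_factory=dict)     # name -> DataFrame

    def manifest(self) -> dict:
        return {stage: [str(p) for p in paths] for stage, paths in self.outputs.items()}


def _load_config(config):
    if isinstance(config, dict):
        return dict(config)
    path = Path(config)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


class _StageError(DesmoquantError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config, stages=None) -> ReportBundle:
    """Run the configured stages; see module docstring for the config shape.

    ``stages`` restricts execution to a subset (in canonical order).  Each
    analysis stage consumes either the artifacts produced by ``simulate`` in
    the same run or explicit input paths from its config section.  Missing
    inputs raise an error naming the failing stage.
    """
    cfg = _load_config(config)
    outdir = Path(cfg.get("outdir", "desmoquant_run"))
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    bundle = ReportBundle(outdir=outdir)
    ctx: dict = {}
    requested = [s for s in STAGES if s in cfg and (stages is None or s in stages)]
    try:
        for stage in requested:
            log.info("running stage %s", stage)
            try:
                _RUNNERS[stage](cfg[stage] or {}, outdir, ctx, bundle)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise _StageError(stage, exc) from exc
        (outdir / "manifest.json").write_text(
            json.dumps({"config": _jsonable_cfg(cfg), "outputs": bundle.manifest()},
                       indent=1, sort_keys=True))
    finally:
        log.removeHandler(handler)
        handler.close()
    return bundle


def _jsonable_cfg(cfg):
    return json.loads(json.dumps(cfg, default=str))


def _write_csv(df, path, bundle, stage):
    df.to_csv(path, index=False)
    bundle.outputs.setdefault(stage, []).append(path)
    bundle.tables[Path(path).stem] = df


# --------------------------------------------------------------------------
# stage runners
# --------------------------------------------------------------------------

def _run_simulate(section, outdir, ctx, bundle):
    sim_dir = outdir / "simulate"
    sim_dir.mkdir(exist_ok=True)
    outs = bundle.outputs.setdefault("simulate", [])
    if "monolayer" in section:
        params = MonolayerParams(**section["monolayer"])
        image, mask, truth = generate_monolayer(params)
        dio.write_image(sim_dir / "monolayer.tif", image, truth=truth)
        dio.write_image(sim_dir / "monolayer_labels.tif", mask)
        outs += [sim_dir / "monolayer.tif", sim_dir / "monolayer_labels.tif"]
        ctx["monolayer"] = (image, mask, truth)
    if "filaments" in section:
        params = FilamentNetworkParams(**section["filaments"])
        image, net = generate_filament_network(params)
        dio.write_image(sim_dir / "filaments.tif", image,
                        truth={"n_edges": net.n_edges, "n_junctions": net.n_junctions})
        outs.append(sim_dir / "filaments.tif")
        ctx["filaments"] = (image, net)
    if "force_map" in section:
        sub = dict(section["force_map"])
        from .synthetic import BorderStripe, CurveSimParams

        if "border_stripe" in sub:
            sub["border_stripe"] = BorderStripe(**sub["border_stripe"])
        if "curve_params" in sub:
            sub["curve_params"] = CurveSimParams(**sub["curve_params"])
        fmap = generate_force_map(MapSimParams(**sub))
        dio.write_force_map(sim_dir / "force_map", fmap)
        outs.append(sim_dir / "force_map" / "map.json")
        ctx["force_map"] = fmap
    if "fragments" in section:
        params = FragmentSimParams(**section["fragments"])
        img, n_true = generate_fragment_image(params)
        dio.write_image(sim_dir / "fragments.tif", img, truth={"n_fragments": n_true})
        outs.append(sim_dir / "fragments.tif")
        ctx["fragments"] = (img, n_true, params)


def _get_image_and_mask(section, ctx):
    if "image" in section and "mask" in section:
        return dio.read_image(section["image"]), dio.read_label_mask(section["mask"])
    if "monolayer" in ctx:
        image, mask, _ = ctx["monolayer"]
        return image, mask
    raise DesmoquantError("no input image/mask: provide 'image' and 'mask' paths "
                          "or a simulate.monolayer section")


def _run_linescan(section, outdir, ctx, bundle):
    import pandas as pd

    image, mask = _get_image_and_mask(section, ctx)
    spacing = int(section.get("spacing_px", 10))
    length = int(section.get("length_px", 31))
    width = int(section.get("width_px", 3))
    band = int(section.get("junction_band_px", 3))
    rows, results = [], []
    for b_id, trace in enumerate(trace_borders(mask)):
        for s_id, seg in enumerate(place_line_scans(trace, spacing, length, width,
                                                    junction_band_px=band)):
            res = measure_line_scan(image, seg)
            results.append(res)
            rows.append({"border_id": b_id, "segment_id": s_id,
                         "junctional_mean": res.junctional_mean,
                         "cytoplasmic_mean": res.cytoplasmic_mean,
                         "ratio": res.ratio})
    if not rows:
        raise DesmoquantError("no line scans could be placed")
    _write_csv(pd.DataFrame(rows), outdir / "linescan_segments.csv", bundle, "linescan")
    summary = aggregate_ratios(results)
    _write_csv(summary.table, outdir / "linescan_summary.csv", bundle, "linescan")


def _run_irregularity(section, outdir, ctx, bundle):
    import pandas as pd

    image, mask = _get_image_and_mask(section, ctx)
    width = int(section.get("width_px", 3))
    rows = []
    for b_id, trace in enumerate(trace_borders(mask)):
        if len(trace) < 2:
            continue
        score = border_irregularity(image, trace, width_px=width)
        rows.append({"border_id": b_id, "n_pixels": score.n_pixels,
                     "mean_intensity": score.mean_intensity, "score": score.score})
    if not rows:
        raise DesmoquantError("no borders found for irregularity scoring")
    _write_csv(pd.DataFrame(rows), outdir / "irregularity.csv", bundle, "irregularity")


def _run_skeleton(section, outdir, ctx, bundle):
    import pandas as pd

    if "image" in section:
        image = dio.read_image(section["image"])
    elif "filaments" in ctx:
        image = ctx["filaments"][0]
    else:
        raise DesmoquantError("no input image: provide 'image' path or a "
                              "simulate.filaments section")
    method = section.get("threshold_method", "otsu")
    thr = section.get("threshold")
    mask = binarize(image, method=method, threshold=thr)
    graph = skeletonize(mask)
    graph = prune_spurs(graph, int(section.get("min_branch_px", 3)))
    roi = section.get("roi", (0, 0, image.shape[0], image.shape[1]))
    metrics = skeleton_metrics(graph, roi, image.pixel_size_um)
    df = pd.DataFrame([{
        "roi_id": 0, "area_um2": metrics.roi_area_um2,
        "n_bundles": metrics.n_bundles, "n_junctions": metrics.n_junctions,
        "n_components": metrics.n_components,
        "bundle_density": metrics.bundle_density,
        "junction_density": metrics.junction_density,
        "threshold": mask.threshold, "threshold_method": mask.method,
    }])
    _write_csv(df, outdir / "skeleton_metrics.csv", bundle, "skeleton")
    overlay = (graph.skeleton.astype(np.uint8) * 255)
    import imageio.v3 as iio

    iio.imwrite(outdir / "skeleton_overlay.png", overlay)
    bundle.outputs["skeleton"].append(outdir / "skeleton_overlay.png")


def _run_afm(section, outdir, ctx, bundle):
    import pandas as pd

    if "map_dir" in section:
        fmap = dio.read_force_map(section["map_dir"])
    elif "force_map" in ctx:
        fmap = ctx["force_map"]
    else:
        raise DesmoquantError("no input force map: provide 'map_dir' or a "
                              "simulate.force_map section")
    thr = float(section.get("threshold_sigma", 6.0))
    analyze_map(fmap, thr)
    events = pool_events([fmap], threshold_sigma=thr)
    _write_csv(events, outdir / "afm_events.csv", bundle, "afm")
    stats = map_statistics(fmap, thr)
    df = pd.DataFrame([{
        "binding_frequency": stats.binding_frequency,
        "binding_frequency_border": stats.binding_frequency_border,
        "binding_frequency_surface": stats.binding_frequency_surface,
        "distribution_coefficient": stats.distribution_coefficient,
        "n_border_px": stats.n_border_px, "n_surface_px": stats.n_surface_px,
        "threshold_sigma": thr,
    }])
    _write_csv(df, outdir / "afm_map_stats.csv", bundle, "afm")
    # adhesion map QC image: border stripe in gray, binding events in white
    bound = np.array([[len(ev) > 0 for ev in row] for row in fmap.events])
    qc = np.zeros(fmap.shape, dtype=np.uint8)
    qc[fmap.junction_mask] = 96
    qc[bound] = 255
    import imageio.v3 as iio

    iio.imwrite(outdir / "adhesion_map.png", qc)
    bundle.outputs["afm"].append(outdir / "adhesion_map.png")


def _run_dispase(section, outdir, ctx, bundle):
    import pandas as pd

    min_size = int(section.get("min_size_px", 50))
    rows = []
    wells = section.get("wells")
    if wells:
        for w in wells:
            image = dio.read_image(w["path"])
            fc = count_fragments(image.pixels, threshold=w.get("threshold"),
                                 min_size_px=min_size, well_id=w.get("well_id"))
            rows.append({"well_id": fc.well_id, "n_fragments": fc.n_fragments,
                         "min_size_px": fc.min_size_px})
    elif "fragments" in ctx:
        img, _, params = ctx["fragments"]
        fc = count_fragments(img, min_size_px=min_size, well_id="simulated")
        rows.append({"well_id": fc.well_id, "n_fragments": fc.n_fragments,
                     "min_size_px": fc.min_size_px})
    else:
        raise DesmoquantError("no input wells: provide 'wells' or a "
                              "simulate.fragments section")
    _write_csv(pd.DataFrame(rows), outdir / "dispase_counts.csv", bundle, "dispase")


def _run_report(section, outdir, ctx, bundle):
    import pandas as pd

    rows = []
    for name, df in bundle.tables.items():
        for col in df.columns:
            if pd.api.types.is_numeric_dtype(df[col]):
                rows.append({"table": name, "metric": col,
                             "mean": float(df[col].mean()), "n": int(df[col].count())})
    summary = pd.DataFrame(rows)
    _write_csv(summary, outdir / "summary.csv", bundle, "report")


_RUNNERS = {
    "simulate": _run_simulate,
    "linescan": _run_linescan,
    "irregularity": _run_irregularity,
    "skeleton": _run_skeleton,
    "afm": _run_afm,
    "dispase": _run_dispase,
    "report": _run_report,
}
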