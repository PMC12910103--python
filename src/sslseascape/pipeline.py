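"""End-to-end orchestration: simulate -> integrate -> extract -> DVM -> cluster -> GAM.

A single run consumes one config, fans the run seed out into per-stage seed
streams (so stages are independently reproducible), writes every result
table to the output directory and finishes with a manifest holding the
config snapshot, seed and a checksum of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as scl
from . import dvm as sdvm
from . import gam as sgam
from . import io as sio
from . import layers as slayers
from . import preprocess as sprep
from . import synthetic as ssyn

logger = logging.getLogger("sslseascape")

FREQUENCIES = (18, 38)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    seed: int
    outputs: dict[str, str]  # relative path -> sha256
    stages: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ["simulate", "ctd", "cluster", "gam"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(
    config: sio.PipelineConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    n_days: int = 2,
    ping_interval_s: float = 20.0,
    depth_max_m: float = 800.0,
    n_ctd_per_region: int = 20,
    presets: list[ssyn.RegionPreset] | None = None,
) -> RunManifest:
    """Run the full synthetic-scene analysis and write all result tables.

    Simulates ``n_days`` days per region preset at both frequencies, then
    surface offset, echo-integration, thresholding, layer extraction,
    diel/profile/WMD analyses, cross-frequency matching, per-day seascape
    clustering and (with simulated CTD casts) the Sv driver GAMs.
    """
    if not isinstance(config, sio.PipelineConfig):
        config = sio.load_config(config)
    if seed is None:
        seed = config.rng_seed
    seeds = _stage_seeds(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    presets = presets if presets is not None else list(ssyn.PRESETS.values())
    outputs: dict[str, Path] = {}
    stages: list[str] = []

    all_layers: dict[int, list] = {f: [] for f in FREQUENCIES}
    all_pairs = []
    profile_frames = []
    wmd_frames = []
    gam_records = []

    def _stage(name):
        stages.append(name)
        logger.info("pipeline stage: %s", name)

    try:
        _stage("simulate+extract")
        for ri, preset in enumerate(presets):
            # regions are traversed sequentially, as on a transect cruise,
            # and each day is segmented as its own scene (daily batches)
            for day in range(n_days):
                start = np.datetime64("2021-12-15T06:00:00") + np.timedelta64(ri * n_days + day, "D")
                grids: dict[int, sprep.IntegrationGrid] = {}
                for f in FREQUENCIES:
                    e = ssyn.generate_echogram(
                        preset,
                        frequency_khz=f,
                        start=start,
                        duration_h=24.0,
                        ping_interval_s=ping_interval_s,
                        depth_max_m=depth_max_m,
                        seed=seeds["simulate"] + 10 * ri + day,  # same scene at both frequencies
                    )
                    e = sprep.apply_surface_offset(e, config.surface_offset_m)
                    grids[f] = sprep.echo_integrate(e, config.integration_distance_nmi, config.depth_bin_m)
                masks = {f: sprep.threshold_mask(grids[f], config.threshold_db) for f in FREQUENCIES}
                region_layers = {
                    f: slayers.extract_layers(
                        masks[f], grids[f], min_cells=config.min_cells, diel_threshold_deg=config.diel_altitude_deg
                    )
                    for f in FREQUENCIES
                }
                pairs, *_ = slayers.match_frequencies(
                    region_layers[18], region_layers[38], grids[18], grids[38], config.jaccard_threshold
                )
                offset18 = len(all_layers[18])
                offset38 = len(all_layers[38])
                all_pairs.extend((i + offset18, j + offset38, jac) for i, j, jac in pairs)
                for f in FREQUENCIES:
                    all_layers[f].extend(region_layers[f])

                labels = sdvm.column_diel_labels(grids[38], config.diel_altitude_deg)
                prof = sdvm.mean_profiles(grids[38], labels)
                pf = prof.to_frame()
                pf.insert(0, "region", preset.name)
                pf.insert(1, "day", day)
                profile_frames.append(pf)
                wmd = {f: sdvm.compute_wmd(grids[f]) for f in FREQUENCIES}
                wf = wmd[38].to_frame().rename(columns={"wmd_m": "wmd38_m"})
                wf["wmd18_m"] = wmd[18].wmd
                wf.insert(0, "region", preset.name)
                wmd_frames.append(wf)

                if day == 0 and n_ctd_per_region > 0:
                    _stage(f"ctd:{preset.name}")
                    n_cols = grids[38].n_cols
                    idx = np.linspace(0, n_cols - 1, n_ctd_per_region).astype(int)
                    positions = np.column_stack([grids[38].cell_lat[idx], grids[38].cell_lon[idx]])
                    times = grids[38].cell_time[idx]
                    stations = ssyn.generate_ctd(
                        preset, n_ctd_per_region, seed=seeds["ctd"] + ri, positions=positions, times=times
                    )
                    recs = sgam.match_acoustic_to_ctd(
                        grids, stations, radius_nmi=config.ctd_match_radius_nmi, threshold_db=config.threshold_db
                    )
                    gam_records.append(recs)

        for f in FREQUENCIES:
            sio.write_layers(all_layers[f], out / f"layers_{f}khz.csv")
            outputs[f"layers_{f}khz.csv"] = out / f"layers_{f}khz.csv"
        pd.concat(profile_frames, ignore_index=True).to_csv(out / "profiles.csv", index=False)
        outputs["profiles.csv"] = out / "profiles.csv"
        pd.concat(wmd_frames, ignore_index=True).to_csv(out / "wmd.csv", index=False)
        outputs["wmd.csv"] = out / "wmd.csv"
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stages[-1] if stages else "setup", exc) from exc

    try:
        _stage("cluster")
        frame = scl.build_descriptor_matrix(all_layers[18], all_layers[38], all_pairs, unit=config.cluster_unit)
        classification = scl.classify_seascapes(
            frame, k_range=config.k_range, seed=seeds["cluster"], n_init=config.n_init
        )
        cls_df = frame.copy()
        cls_df["cluster"] = classification.labels
        cls_df.to_csv(out / "classification.csv", index=False)
        outputs["classification.csv"] = out / "classification.csv"
        pd.DataFrame(
            {"k": list(classification.silhouette_by_k), "mean_silhouette": list(classification.silhouette_by_k.values())}
        ).to_csv(out / "silhouette.csv", index=False)
        outputs["silhouette.csv"] = out / "silhouette.csv"
        classification.summaries.to_csv(out / "cluster_summaries.csv", index=False)
        outputs["cluster_summaries.csv"] = out / "cluster_summaries.csv"
    except Exception as exc:
        raise StageError("cluster", exc) from exc

    gam_summary: dict = {}
    if gam_records:
        try:
            _stage("gam")
            records = pd.concat(gam_records, ignore_index=True)
            corr, flags = sgam.screen_collinearity(records, r_flag=config.collinearity_r)
            term_frames = []
            for response in ("sv18", "sv38"):
                spec = sgam.MODEL_TERMS[response]
                smooth = [t for t in spec["smooth"] if t not in config.exclude_predictors]
                linear = [t for t in spec["linear"] if t not in config.exclude_predictors]
                result = sgam.fit_gam(records, response=response, linear_terms=linear, smooth_terms=smooth)
                diag = sgam.diagnostics(result)
                tf = result.terms.copy()
                tf.insert(0, "response", response)
                term_frames.append(tf)
                gam_summary[response] = {
                    "deviance_explained_pct": result.deviance_explained,
                    "aic": result.aic,
                    "shapiro_p": diag["shapiro_p"],
                    "breusch_pagan_p": diag["breusch_pagan_p"],
                }
            pd.concat(term_frames, ignore_index=True).to_csv(out / "gam_terms.csv", index=False)
            outputs["gam_terms.csv"] = out / "gam_terms.csv"
            (out / "gam_summary.json").write_text(json.dumps(gam_summary, indent=2, sort_keys=True))
            outputs["gam_summary.json"] = out / "gam_summary.json"
        except Exception as exc:
            raise StageError("gam", exc) from exc
    else:
        logger.info("pipeline: no CTD records; GAM stage skipped")

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seed=seed,
        outputs={name: _sha256(p) for name, p in sorted(outputs.items())},
        stages=stages,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
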