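"""End-to-end pipeline driver: simulate -> preprocess -> quantify -> CPCA
-> imaging, reproducibly from a single config + seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .axes import FT_RAMAN, FTIR_MICRO, HTS_FTIR
from .band_metrics import (FTIR_TARGETS, RAMAN_TARGETS, TrajectoryTable,
                           metabolite_trajectories)
from .chemometrics import CPCAModel, cpca_fit, correlation_loadings
from .imaging import (BasisFitResult, HyperspectralImage, absorbance_map,
                      basis_fit, bin_image, derive_basis, remove_empty_pixels)
from .io import save_cube, write_wide_csv
from .preprocess import apply_recipe, get_recipe
from .synthetic import (DEFAULT_TIMEPOINTS, Design, MEDIA, TrajectoryParams,
                        make_scene, medium, simulate_design_dataset,
                        simulate_hyperspectral_image)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: design, recipes, seed."""

    seed: int = 0
    media: tuple[str, ...] = tuple(MEDIA)
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    replicates: int = 3
    recipe_ftir_metrics: str = "htsftir_bandratio"
    recipe_raman_metrics: str = "ftraman_bandratio"
    recipe_ftir_mva: str = "htsftir_mva"
    recipe_raman_mva: str = "ftraman_mva"
    cpca_ncomp: int = 5
    include_imaging: bool = True
    scene_medium: str = "iGlu1:Gly7"
    scene_timepoint_h: float = 120.0
    scene_shape: tuple[int, int] = (128, 128)
    basis_components: int = 3
    outdir: str = "specflux_run"

    # -- serialisation (flat TOML-style key/value text) --------------------
    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            lines.append(f"{f.name} = {json.dumps(v)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs = {}
        names = {f.name for f in dataclasses.fields(cls)}
        for line in text.splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in names:
                raise ValueError(f"unknown config key {key!r}")
            v = json.loads(value.strip())
            if isinstance(v, list):
                v = tuple(v)
            kwargs[key] = v
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Objects and file paths produced by one pipeline run."""

    config: RunConfig
    outdir: Path
    datasets: dict
    trajectories: TrajectoryTable
    cpca: CPCAModel
    image: HyperspectralImage | None
    basis_result: BasisFitResult | None
    lipid_map: np.ndarray | None
    paths: dict[str, Path]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig | None = None,
                 params: TrajectoryParams | None = None) -> RunReport:
    """Execute the full workflow on a synthetic design.

    Writes, under ``config.outdir``: the raw bulk datasets (wide CSV +
    metadata TSV), the tidy trajectory table, CPCA scores and correlation
    loadings, imaging products (cube, component maps, lipid absorbance
    map) and a JSON run log with the config, its hash and the recipe
    parameters actually applied.
    """
    config = config or RunConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # validate recipe names up front so a typo aborts before simulation
    for name in (config.recipe_ftir_metrics, config.recipe_raman_metrics,
                 config.recipe_ftir_mva, config.recipe_raman_mva):
        get_recipe(name)

    design = Design(media=tuple(medium(m) for m in config.media),
                    timepoints=tuple(config.timepoints),
                    replicates=config.replicates,
                    modalities=(HTS_FTIR, FT_RAMAN))

    datasets = _stage("simulate")(simulate_design_dataset)(
        design, params=params, seed=config.seed)
    for modality, ds in datasets.items():
        p = outdir / f"bulk_{modality}.csv"
        write_wide_csv(ds, p, outdir / f"bulk_{modality}_meta.tsv")
        paths[f"bulk_{modality}"] = p

    @_stage("band_metrics")
    def _trajectories():
        ftir = apply_recipe(datasets[HTS_FTIR], config.recipe_ftir_metrics)
        raman = apply_recipe(datasets[FT_RAMAN], config.recipe_raman_metrics)
        t1 = metabolite_trajectories(ftir, FTIR_TARGETS, config.recipe_ftir_metrics)
        t2 = metabolite_trajectories(raman, RAMAN_TARGETS, config.recipe_raman_metrics)
        table = pd.concat([t1.table, t2.table], ignore_index=True)
        return TrajectoryTable(table, f"{config.recipe_ftir_metrics}+"
                                      f"{config.recipe_raman_metrics}",
                               FTIR_TARGETS + RAMAN_TARGETS)

    trajectories = _trajectories()
    paths["trajectories"] = outdir / "trajectories.tsv"
    trajectories.to_tsv(paths["trajectories"])

    @_stage("cpca")
    def _cpca():
        blocks = {}
        for modality, recipe in ((HTS_FTIR, config.recipe_ftir_mva),
                                 (FT_RAMAN, config.recipe_raman_mva)):
            pre = apply_recipe(datasets[modality], recipe)
            blocks[modality] = pre.average_replicates().intensities
        ncomp = min(config.cpca_ncomp,
                    min(b.shape[0] for b in blocks.values()) - 1)
        model = cpca_fit(blocks, ncomp)
        corr = correlation_loadings(model, blocks)
        return model, corr, blocks

    cpca_model, corr, blocks = _cpca()
    scores = pd.DataFrame(cpca_model.global_scores,
                          columns=[f"PC{i + 1}" for i in range(cpca_model.ncomp)])
    paths["cpca_scores"] = outdir / "cpca_global_scores.tsv"
    scores.to_csv(paths["cpca_scores"], sep="\t", index=False)
    paths["cpca_corr"] = outdir / "cpca_correlation_loadings.tsv"
    pd.DataFrame(corr.r).to_csv(paths["cpca_corr"], sep="\t", index=False)

    image = basis_result = lipid_map = None
    if config.include_imaging:
        @_stage("imaging")
        def _imaging():
            scene = make_scene(config.scene_medium, config.scene_timepoint_h,
                               shape=tuple(config.scene_shape),
                               params=params, seed=config.seed)
            img = simulate_hyperspectral_image(scene, FTIR_MICRO,
                                               seed=config.seed + 1)
            remove_empty_pixels(img)
            binned = bin_image(img)
            basis = derive_basis(img, config.basis_components, seed=config.seed)
            fit = basis_fit(img, basis)
            amap = absorbance_map(img, nu=1745.0)
            return img, binned, fit, amap

        image, binned, basis_result, lipid_map = _imaging()
        paths["cube"] = outdir / "ftir_micro_cube.npy"
        save_cube(image, outdir / "ftir_micro_cube")
        np.save(outdir / "component_maps.npy", basis_result.factors)
        np.save(outdir / "lipid_1745_map.npy", lipid_map)
        write_wide_csv(binned, outdir / "ftir_micro_binned.csv",
                       outdir / "ftir_micro_binned_meta.tsv")

    log = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "config": json.loads("{" + ", ".join(
            f'"{line.split(" = ")[0]}": {line.split(" = ", 1)[1]}'
            for line in config.to_text().strip().splitlines()) + "}"),
        "recipes": {
            name: get_recipe(name).step_list()
            for name in (config.recipe_ftir_metrics, config.recipe_raman_metrics,
                         config.recipe_ftir_mva, config.recipe_raman_mva)
        },
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    paths["run_log"] = outdir / "run_log.json"
    paths["run_log"].write_text(json.dumps(log, indent=2))

    return RunReport(config=config, outdir=outdir, datasets=datasets,
                     trajectories=trajectories, cpca=cpca_model, image=image,
                     basis_result=basis_result, lipid_map=lipid_map, paths=paths)
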