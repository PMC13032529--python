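"""Synthetic-data generator for the mixed-substrate labelling study design.

Emulates nitrogen-limited fermentations of an oleaginous, carotenogenic
filamentous fungus grown on seven glucose/glycerol media (with glucose
either ¹²C or ¹³C), sampled at 8, 14, 24, 36, 60 and 120 h, and measured
by four vibrational modalities: bulk FT-Raman and HTS-FTIR (three
technical replicates each) plus Raman and FTIR microspectroscopy imaging.

The generator has three layers:

1. :func:`composition_trajectory` — deterministic, piecewise-smooth rules
   mapping (medium, time) to a biomass composition with per-metabolite
   ¹³C fractions. The rules encode the fermentation timeline: yeast-extract
   (¹²C) driven protein/carbohydrate growth in the first 8 h; carotenoid
   production peaking around 14 h; glucose-driven TAG accumulation from
   8 h until glucose exhaustion followed by depletion; glycerol-based TAG
   production after ~36 h only under a large glycerol surplus; and
   polyphosphate reserves peaking late (24 h on glycerol alone).
2. :func:`simulate_bulk_spectrum` — forward model: mixture of metabolite
   component spectra, scaled by a multiplicative path-length factor,
   plus a modality-specific baseline (polynomial fluorescence surrogate
   for Raman, offset + broad sigmoid scatter surrogate for FTIR) and
   i.i.d. Gaussian noise.
3. :func:`simulate_design_dataset` / :func:`simulate_hyperspectral_image`
   — assemble the full design and 128 x 128-pixel imaging scenes with
   ground truth retained for recovery checks.

All randomness flows from a single seed through ``numpy`` seed-sequence
spawning, so outputs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .axes import (FT_RAMAN, FTIR_MICRO, HTS_FTIR, RAMAN_MICRO, WavenumberAxis,
                   default_axis)
from .bands import BandTable, METABOLITES, component_spectrum, default_band_table
from .imaging import HyperspectralImage
from .spectra import SpectralDataset, Spectrum

DEFAULT_TIMEPOINTS = (8.0, 14.0, 24.0, 36.0, 60.0, 120.0)
DEFAULT_NOISE_SD = 5e-4

#: Default baseline amplitude by modality (intensity units). Raman
#: baselines (fluorescence, heating) are large relative to the signal;
#: FTIR dry-film baselines are gentler.
DEFAULT_BASELINE_AMPLITUDE = {
    FT_RAMAN: 0.15, RAMAN_MICRO: 0.15, HTS_FTIR: 0.03, FTIR_MICRO: 0.02,
}


# ---------------------------------------------------------------------------
# Experimental design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediumSpec:
    """Carbon sources of one growth medium (g/L)."""

    name: str
    glucose12: float = 0.0
    glucose13: float = 0.0
    glycerol: float = 0.0

    @property
    def glucose(self) -> float:
        return self.glucose12 + self.glucose13

    @property
    def isotope_fraction_glucose(self) -> float:
        """¹³C fraction of the glucose pool (0 when no glucose)."""
        return self.glucose13 / self.glucose if self.glucose > 0 else 0.0


#: The seven study media (concentrations in g/L).
MEDIA: dict[str, MediumSpec] = {
    m.name: m for m in (
        MediumSpec("nGlu", glucose12=40),
        MediumSpec("iGlu", glucose13=40),
        MediumSpec("nGlu1:Gly1", glucose12=20, glycerol=20),
        MediumSpec("iGlu1:Gly1", glucose13=20, glycerol=20),
        MediumSpec("nGlu1:Gly7", glucose12=5, glycerol=35),
        MediumSpec("iGlu1:Gly7", glucose13=5, glycerol=35),
        MediumSpec("Gly", glycerol=40),
    )
}


def medium(name: str) -> MediumSpec:
    try:
        return MEDIA[name]
    except KeyError:
        raise KeyError(f"unknown medium {name!r}; expected one of {list(MEDIA)}")


@dataclass(frozen=True)
class Design:
    """Cultivation/measurement design: media x timepoints x replicates."""

    media: tuple[MediumSpec, ...] = tuple(MEDIA.values())
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    replicates: int = 3
    modalities: tuple[str, ...] = (HTS_FTIR, FT_RAMAN)

    @property
    def n_samples(self) -> int:
        """Biological samples: one culture well per medium and timepoint."""
        return len(self.media) * len(self.timepoints)

    @property
    def n_spectra_per_modality(self) -> int:
        return self.n_samples * self.replicates


def default_design() -> Design:
    return Design()


# ---------------------------------------------------------------------------
# Composition trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Composition:
    """Ground-truth biomass composition: metabolite weights (relative to
    protein = 1) and per-metabolite ¹³C fractions."""

    weight: dict[str, float]
    f13: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weight:
            raise ValueError("empty composition")
        for m, w in self.weight.items():
            if w < 0:
                raise ValueError(f"negative weight for {m}")
        if not any(w > 0 for w in self.weight.values()):
            raise ValueError("at least one weight must be positive")
        for m, f in self.f13.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"f13 for {m} outside [0, 1]")

    def scaled(self, factors: dict[str, float]) -> "Composition":
        w = {m: v * factors.get(m, 1.0) for m, v in self.weight.items()}
        return Composition(weight=w, f13=dict(self.f13))


@dataclass(frozen=True)
class TrajectoryParams:
    """Rate constants of the fermentation-timeline rules.

    The study reports qualitative dynamics; these defaults encode them as
    explicit kinetics. Units: hours, g/L, and protein-relative weights.
    """

    protein_weight: float = 1.0
    carb_weight_final: float = 0.5     # cell-wall pool relative weight, late
    carb_weight_extra: float = 0.3     # extra early carbohydrate, decaying
    carb_weight_tau: float = 40.0
    protein_f13_max: float = 0.3       # late glucose-derived protein fraction
    protein_f13_tau: float = 24.0
    carb_f13_max: float = 0.7          # cell wall partly from yeast extract
    carb_f13_tau: float = 12.0
    glucose_rate: float = 0.33         # g/L/h consumed
    lipogenesis_onset: float = 8.0     # h; nitrogen limitation sets in
    tag_yield: float = 0.08            # weight per g/L glucose consumed
    tag_decay_tau: float = 70.0        # h; depletion after glucose exhaustion
    glycerol_tag_rate: float = 0.005   # weight/h once glycerol lipogenesis starts
    glycerol_tag_onset: float = 36.0   # h
    glycerol_surplus_ratio: float = 4.0   # glycerol:glucose ratio enabling it
    negligible_lipid: float = 0.05     # bound for glycerol-only TAG
    glycerol_only_tag_peak: float = 0.02
    polyp_amp: float = 0.5
    polyp_amp_glucose_limited: float = 0.8
    polyp_onset: float = 6.0
    polyp_peak_glucose: float = 120.0  # pure-glucose media accumulate to the end
    polyp_peak_mixed: float = 60.0
    polyp_peak_glycerol: float = 24.0
    carotenoid_amp: float = 0.3
    carotenoid_amp_glycerol: float = 0.1
    carotenoid_onset: float = 6.0
    carotenoid_rise_tau: float = 8.0   # peak at onset + tau = 14 h
    carotenoid_f13_mix: tuple[float, float] = (0.25, 0.85)


def _bump(x: float) -> float:
    """Smooth rise-and-decline pulse: x*exp(1-x) for x>0, peak 1 at x=1."""
    return x * math.exp(1.0 - x) if x > 0 else 0.0


def composition_trajectory(med: MediumSpec | str, t_hours: float,
                           params: TrajectoryParams | None = None,
                           rng: np.random.Generator | None = None) -> Composition:
    """Ground-truth composition of biomass in ``med`` at time ``t_hours``.

    ``rng`` is only consulted for the per-sample carotenoid isotope-mixing
    draw in ¹³C-glucose media with a large glycerol surplus; without it the
    midpoint of the mixing continuum is used.
    """
    if isinstance(med, str):
        med = medium(med)
    if t_hours < 0:
        raise ValueError("t_hours must be non-negative")
    p = params or TrajectoryParams()
    t = float(t_hours)
    glc, gly, iso = med.glucose, med.glycerol, med.isotope_fraction_glucose
    surplus = glc > 0 and gly / glc >= p.glycerol_surplus_ratio

    # protein: the amide-normalisation reference, constant by construction;
    # mostly yeast-extract (12C) derived, with a modest late glucose share
    w_prot = p.protein_weight
    f13_prot = p.protein_f13_max * iso * (1.0 - math.exp(-t / p.protein_f13_tau))

    # cell-wall carbohydrates: dominant early, relatively diluted later
    w_carb = p.carb_weight_final + p.carb_weight_extra * math.exp(-t / p.carb_weight_tau)
    f13_carb = p.carb_f13_max * iso * (1.0 - math.exp(-t / p.carb_f13_tau))

    # TAG from glucose: grows with glucose consumed after lipogenesis onset,
    # depleted exponentially after exhaustion
    t_exhaust = glc / p.glucose_rate
    consumed = p.glucose_rate * max(0.0, min(t, t_exhaust) - p.lipogenesis_onset)
    decay = math.exp(-max(0.0, t - t_exhaust) / p.tag_decay_tau)
    tag_glc = p.tag_yield * consumed * decay
    # TAG from glycerol: late, and only under a large glycerol surplus
    tag_gly = (p.glycerol_tag_rate * max(0.0, t - p.glycerol_tag_onset)
               if surplus else 0.0)
    # glycerol-only media: a negligible transient only
    tag_gly_only = (p.glycerol_only_tag_peak * _bump((t - p.polyp_onset) / 18.0)
                    if glc == 0 and gly > 0 else 0.0)
    w_tag = tag_glc + tag_gly + tag_gly_only
    f13_tag = iso * tag_glc / w_tag if w_tag > 0 else 0.0

    # polyphosphates: energy/phosphate reserve, strongest when glucose is
    # limited; peak time depends on the carbon regime
    if glc > 0 and gly == 0:
        pp_peak, pp_amp = p.polyp_peak_glucose, p.polyp_amp
    elif glc == 0:
        pp_peak, pp_amp = p.polyp_peak_glycerol, p.polyp_amp_glucose_limited
    else:
        pp_peak = p.polyp_peak_mixed
        pp_amp = p.polyp_amp_glucose_limited if surplus else p.polyp_amp
    w_pp = pp_amp * _bump((t - p.polyp_onset) / (pp_peak - p.polyp_onset))

    # carotenoids: produced early (peak ~14 h), then diluted/consumed
    car_amp = p.carotenoid_amp_glycerol if glc == 0 else p.carotenoid_amp
    w_car = car_amp * _bump((t - p.carotenoid_onset) / p.carotenoid_rise_tau)
    if iso > 0 and surplus:
        # mixed-isotope carotenoids: molecules assembled from both 13C
        # glucose and 12C glycerol precursors
        lo, hi = p.carotenoid_f13_mix
        f13_car = float(rng.uniform(lo, hi)) if rng is not None else 0.5 * (lo + hi)
    else:
        f13_car = iso

    return Composition(
        weight={"protein": w_prot, "carbohydrate": w_carb, "TAG": w_tag,
                "polyphosphate": w_pp, "carotenoid": w_car},
        f13={"protein": f13_prot, "carbohydrate": f13_carb, "TAG": f13_tag,
             "polyphosphate": 0.0, "carotenoid": f13_car},
    )


# ---------------------------------------------------------------------------
# Forward model: composition -> spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineParams:
    """Baseline surrogate parameters.

    Raman: degree-3 polynomial with per-spectrum random coefficients
    (fluorescence/heating surrogate). FTIR: constant offset plus a broad
    sigmoid (scatter surrogate). ``amplitude`` scales the whole artefact;
    zero disables it.
    """

    amplitude: float = 0.1
    poly_degree: int = 3
    sigmoid_width_range: tuple[float, float] = (600.0, 1200.0)
    sigmoid_center_range: tuple[float, float] = (1200.0, 2400.0)


def _draw_baseline(axis: WavenumberAxis, modality: str, params: BaselineParams,
                   rng: np.random.Generator) -> np.ndarray:
    nu = axis.values
    a = params.amplitude
    if a == 0:
        return np.zeros_like(nu)
    if modality in (FT_RAMAN, RAMAN_MICRO):
        # fluorescence-like: positive, smooth, gently varying
        x = (nu - nu[0]) / (nu[-1] - nu[0])
        coef = rng.uniform(-0.5, 0.5, size=params.poly_degree + 1)
        coef[0] = rng.uniform(0.5, 1.0)
        base = np.polynomial.polynomial.polyval(x, coef)
        return a * (base - base.min() + 0.1)
    # FTIR scatter surrogate
    offset = rng.uniform(0.1, 0.4)
    height = rng.uniform(0.2, 0.6)
    center = rng.uniform(*params.sigmoid_center_range)
    width = rng.uniform(*params.sigmoid_width_range)
    return a * (offset + height / (1.0 + np.exp(-(nu - center) / width)))


def simulate_bulk_spectrum(composition: Composition, modality: str,
                           band_table: BandTable | None = None,
                           baseline: BaselineParams | None = None,
                           pathlength: float = 1.0,
                           noise_sd: float = 0.0,
                           seed: int | np.random.Generator | None = None,
                           axis: WavenumberAxis | None = None) -> Spectrum:
    """One bulk spectrum: pathlength * mixture + baseline + noise."""
    if pathlength <= 0:
        raise ValueError("pathlength must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    table = band_table or default_band_table()
    axis = axis or default_axis(modality)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    y = np.zeros(len(axis))
    for metab, w in composition.weight.items():
        if w == 0:
            continue
        comp = table.component(metab, modality)
        if not comp.bands:
            continue
        y += w * component_spectrum(comp, axis, composition.f13.get(metab, 0.0)).intensity
    y *= pathlength
    if baseline is not None and baseline.amplitude > 0:
        y = y + _draw_baseline(axis, modality, baseline, rng)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return Spectrum(axis, y, meta={"modality": modality},
                    derivative_order=0)


def simulate_design_dataset(design: Design | None = None,
                            band_table: BandTable | None = None,
                            params: TrajectoryParams | None = None,
                            baseline: BaselineParams | None = BaselineParams(),
                            noise_sd: float = DEFAULT_NOISE_SD,
                            pathlength_sigma: float = 0.15,
                            seed: int = 0) -> dict[str, SpectralDataset]:
    """Simulate the full bulk design: one dataset per bulk modality.

    Replicates share the biological composition but differ in path length,
    baseline and noise draws. Ground-truth compositions are attached to
    each dataset as ``dataset.truth``.
    """
    design = design or default_design()
    table = band_table or default_band_table()
    root = np.random.SeedSequence(seed)
    # one substream per biological sample (composition draw), plus one per
    # measured spectrum (instrumental draws); spawn in a fixed order
    n_bio = design.n_samples
    bio_streams = root.spawn(n_bio + 1)
    meas_root = bio_streams[-1]

    compositions: dict[tuple[str, float], Composition] = {}
    truth_rows = []
    k = 0
    for med in design.media:
        for t in design.timepoints:
            rng = np.random.default_rng(bio_streams[k]); k += 1
            comp = composition_trajectory(med, t, params, rng=rng)
            compositions[(med.name, t)] = comp
            row = {"medium": med.name, "timepoint_h": t}
            row.update({f"w_{m}": comp.weight[m] for m in METABOLITES})
            row.update({f"f13_{m}": comp.f13[m] for m in METABOLITES})
            truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    out: dict[str, SpectralDataset] = {}
    meas_streams = iter(meas_root.spawn(
        len(design.modalities) * n_bio * design.replicates))
    for modality in design.modalities:
        axis = default_axis(modality)
        rows, meta = [], []
        for med in design.media:
            for t in design.timepoints:
                comp = compositions[(med.name, t)]
                for rep in range(1, design.replicates + 1):
                    rng = np.random.default_rng(next(meas_streams))
                    pl = float(np.exp(rng.normal(0.0, pathlength_sigma)))
                    amp = (DEFAULT_BASELINE_AMPLITUDE[modality]
                           if baseline is not None and baseline.amplitude > 0 else 0.0)
                    bl = (BaselineParams(amplitude=amp) if amp > 0 else None)
                    sp = simulate_bulk_spectrum(
                        comp, modality, table, baseline=bl, pathlength=pl,
                        noise_sd=noise_sd, seed=rng, axis=axis)
                    rows.append(sp.intensity)
                    meta.append({
                        "sample_id": f"{med.name}_{t:g}h_r{rep}_{modality}",
                        "medium": med.name, "timepoint_h": t, "replicate": rep,
                        "modality": modality, "seed": seed,
                    })
        out[modality] = SpectralDataset(axis, np.array(rows),
                                        pd.DataFrame(meta), truth=truth)
    return out


# ---------------------------------------------------------------------------
# Imaging scenes
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """Spatial layout of an imaging scene: hyphae with lipid bodies and
    polyphosphate granules embedded, on an empty background."""

    shape: tuple[int, int] = (128, 128)
    hyphae_mask: np.ndarray | None = None
    lipid_body_mask: np.ndarray | None = None
    polyp_granule_mask: np.ndarray | None = None
    hyphae_composition: Composition | None = None
    lipid_body_composition: Composition | None = None
    polyp_granule_composition: Composition | None = None
    pixel_size: float = 2.7  # µm

    def validate(self) -> None:
        for name in ("hyphae_mask", "lipid_body_mask", "polyp_granule_mask"):
            m = getattr(self, name)
            if m is not None and m.shape != self.shape:
                raise ValueError(f"{name} shape {m.shape} != scene shape {self.shape}")
        h = self.hyphae_mask
        if h is not None:
            for name in ("lipid_body_mask", "polyp_granule_mask"):
                m = getattr(self, name)
                if m is not None and np.any(m & ~h):
                    raise ValueError(f"{name} extends outside hyphae")


def make_scene(medium_name: str = "iGlu1:Gly7", t_hours: float = 120.0,
               shape: tuple[int, int] = (128, 128),
               n_hyphae: int = 5, n_lipid_bodies: int = 10,
               n_granules: int = 12,
               params: TrajectoryParams | None = None,
               seed: int | np.random.Generator = 0) -> Scene:
    """Random scene: filamentous hyphae with organelle inclusions.

    Lipid bodies are TAG-enriched disks, granules polyphosphate-enriched
    disks, both inside hyphae. Compositions come from the trajectory rules
    for the requested medium and time.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    nr, nc = shape
    hyphae = np.zeros(shape, dtype=bool)
    for _ in range(n_hyphae):
        # a filament: smooth random walk across the frame
        r, c = rng.uniform(0, nr), rng.uniform(0, nc)
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(int(2.2 * max(nr, nc))):
            ri, ci = int(round(r)), int(round(c))
            if 0 <= ri < nr and 0 <= ci < nc:
                hyphae[ri, ci] = True
            angle += rng.normal(0.0, 0.22)
            r += np.sin(angle)
            c += np.cos(angle)
            if not (-8 < r < nr + 8 and -8 < c < nc + 8):
                break
    hyphae = ndimage.binary_dilation(hyphae, iterations=2)

    comp = composition_trajectory(medium_name, t_hours, params, rng=rng)

    def _disks(n: int, rmin: int, rmax: int) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        idx = np.argwhere(hyphae)
        if idx.size == 0 or n == 0:
            return mask
        rr, cc = np.ogrid[:nr, :nc]
        for _ in range(n):
            cy, cx = idx[rng.integers(len(idx))]
            rad = rng.integers(rmin, rmax + 1)
            mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= rad ** 2
        return mask & hyphae

    lipid = _disks(n_lipid_bodies if comp.weight["TAG"] > 0 else 0, 2, 4)
    gran = _disks(n_granules if comp.weight["polyphosphate"] > 0 else 0, 1, 2)
    gran &= ~lipid

    scene = Scene(
        shape=shape, hyphae_mask=hyphae, lipid_body_mask=lipid,
        polyp_granule_mask=gran,
        hyphae_composition=comp,
        lipid_body_composition=comp.scaled({"TAG": 6.0}) if comp.weight["TAG"] > 0 else comp,
        polyp_granule_composition=(comp.scaled({"polyphosphate": 6.0})
                                   if comp.weight["polyphosphate"] > 0 else comp),
    )
    scene.validate()
    return scene


def simulate_hyperspectral_image(scene: Scene, modality: str = FTIR_MICRO,
                                 band_table: BandTable | None = None,
                                 noise_sd: float = DEFAULT_NOISE_SD,
                                 baseline: BaselineParams | None = BaselineParams(amplitude=0.02),
                                 pathlength_sigma: float = 0.15,
                                 seed: int = 0) -> HyperspectralImage:
    """Hyperspectral cube for a scene: per-pixel region spectrum times a
    smooth spatial path-length field, plus baseline and pixel noise.

    Background pixels contain baseline + noise only. Ground-truth
    metabolite weight maps are stored on the image.
    """
    scene.validate()
    table = band_table or default_band_table()
    axis = default_axis(modality)
    rng = np.random.default_rng(seed)
    nr, nc = scene.shape
    n_nu = len(axis)

    hyphae = (scene.hyphae_mask if scene.hyphae_mask is not None
              else np.zeros(scene.shape, dtype=bool))
    lipid = (scene.lipid_body_mask if scene.lipid_body_mask is not None
             else np.zeros(scene.shape, dtype=bool))
    gran = (scene.polyp_granule_mask if scene.polyp_granule_mask is not None
            else np.zeros(scene.shape, dtype=bool))

    region_specs: list[tuple[np.ndarray, Composition | None]] = [
        (lipid, scene.lipid_body_composition),
        (gran & ~lipid, scene.polyp_granule_composition),
        (hyphae & ~lipid & ~gran, scene.hyphae_composition),
    ]
    signal = np.zeros((nr, nc, n_nu))
    truth: dict[str, np.ndarray] = {m: np.zeros((nr, nc)) for m in METABOLITES}
    for mask, comp in region_specs:
        if comp is None or not mask.any():
            continue
        sp = simulate_bulk_spectrum(comp, modality, table, baseline=None,
                                    pathlength=1.0, noise_sd=0.0, axis=axis)
        signal[mask] = sp.intensity
        for m in METABOLITES:
            truth[m][mask] = comp.weight[m]

    # smooth multiplicative path-length (film thickness) field
    if pathlength_sigma > 0:
        field = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), sigma=8.0)
        field = field / max(field.std(), 1e-12) * pathlength_sigma
        signal *= np.exp(field)[..., None]

    cube = signal
    if baseline is not None and baseline.amplitude > 0:
        cube = cube + _draw_baseline(axis, modality, baseline, rng)[None, None, :]
    if noise_sd > 0:
        cube = cube + rng.normal(0.0, noise_sd, size=cube.shape)

    return HyperspectralImage(
        cube=cube, axis=axis, pixel_size=scene.pixel_size,
        truth={**truth, "hyphae": hyphae.astype(float),
               "lipid_body": lipid.astype(float),
               "polyp_granule": gran.astype(float)},
    )
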