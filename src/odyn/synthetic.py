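"""Synthetic cohort generator: masks, nuclei, and clinical follow-up.

Emulates the inputs the pipeline consumes downstream of deep segmentation —
co-registered epithelium/dysplasia label masks, classed nuclear instance
polygons, and a clinical table with transformation outcomes — with a
controllable transformation effect so every stage can be exercised and
calibrated without any clinical data.

A slide is a smoothed mucosa-like epithelial band across the canvas; the
dysplastic region is a contiguous sub-band occupying a per-slide fraction
of the band thickness, which guarantees dysplasia ⊆ epithelium by
construction. Nuclei are ellipses polygonized at 16 vertices with
per-class size/shape distributions, placed with non-overlapping centroids:
dysplastic epithelial nuclei inside the dysplastic sub-band, normal
epithelial nuclei in the remaining epithelium, and 'other' nuclei both
inside the epithelium (future IELs) and in the stroma (future PELs).

``nuclear_effect`` is a standardized effect size: in transforming slides
it shifts the dysplastic-nucleus area distribution upward by that many
within-class standard deviations, inflates its coefficient of variation
(pleomorphism), and increases stromal 'other' density. Event times for
transforming patients are exponential with rate scaled by
exp(nuclear_effect), so a larger effect also shortens time-to-event.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from odyn.datamodel import CohortTable, MaskRaster, NucleusInstance, SlideRecord
from odyn import io as odyn_io


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one synthetic cohort.

    Densities are nuclei per mm² of the relevant compartment at
    ``mask_mpp``; areas are µm². Defaults are deliberately sparser than
    real tissue to keep generated cohorts small.
    """

    n_patients: int = 20
    n_controls: int = 0  # extra non-dysplastic control patients
    slides_per_patient: int = 1
    canvas_size: int = 1536
    mask_mpp: float = 0.5
    transform_fraction: float = 0.5
    # identical per-outcome ranges by default: the transformation signal is
    # carried by nuclear_effect alone, giving an exact null at effect 0
    dysplasia_fraction_range: dict = field(
        default_factory=lambda: {0: (0.3, 0.7), 1: (0.3, 0.7)}
    )
    nuclear_effect: float = 1.0
    censor_rate: float = 0.1
    seed: int = 0

    # tissue architecture
    band_thickness_fraction: float = 0.5  # of canvas height
    # nuclear morphology: class -> (area mean µm², area CV, eccentricity)
    morphology: dict = field(
        default_factory=lambda: {
            "dysplastic_epithelial": (52.0, 0.25, 0.75),
            "normal_epithelial": (42.0, 0.15, 0.6),
            "other": (18.0, 0.12, 0.4),
        }
    )
    # densities per mm²: epithelial nuclei, intra-epithelial other, stromal other
    epithelial_density: float = 2400.0
    iel_density: float = 300.0
    pel_density: float = 350.0
    min_centroid_spacing_px: float = 8.0

    # follow-up model (months)
    base_event_rate: float = math.log(2) / 60.0
    admin_horizon_months: float = 120.0

    def __post_init__(self) -> None:
        for rng_pair in self.dysplasia_fraction_range.values():
            lo, hi = rng_pair
            if not (0 <= lo <= hi <= 1):
                raise ValueError("dysplasia_fraction_range pairs must lie in [0,1]")
        if not 0 <= self.transform_fraction <= 1:
            raise ValueError("transform_fraction must lie in [0,1]")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor_rate must lie in [0,1]")
        if self.nuclear_effect < 0:
            raise ValueError("nuclear_effect must be >= 0")
        if self.canvas_size < 512:
            raise ValueError("canvas_size must be >= 512 at the scoring resolution")


def _slide_rng(cfg: SynthConfig, patient_idx: int, slide_idx: int) -> np.random.Generator:
    """Per-slide substream; regeneration is order-independent."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(patient_idx, slide_idx))
    )


def _band_masks(cfg: SynthConfig, rng: np.random.Generator,
                dysplasia_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Epithelial band and its dysplastic sub-band as binary arrays."""
    n = cfg.canvas_size
    x = np.arange(n)
    amp = rng.uniform(0.03, 0.1) * n
    period = rng.uniform(0.6, 1.4)
    phase = rng.uniform(0, 2 * np.pi)
    centre = n / 2 + amp * np.sin(2 * np.pi * period * x / n + phase)
    thick = cfg.band_thickness_fraction * n * (1 + 0.1 * np.sin(
        2 * np.pi * rng.uniform(0.5, 1.5) * x / n + rng.uniform(0, 2 * np.pi)))
    top = centre - thick / 2
    bot = centre + thick / 2
    rows = np.arange(n)[:, None]
    epith = (rows >= top[None, :]) & (rows < bot[None, :])
    # dysplasia: contiguous sub-band growing from the top boundary
    dys_bot = top + dysplasia_fraction * thick
    if dysplasia_fraction >= 1.0:
        dysp = epith.copy()
    else:
        dysp = (rows >= top[None, :]) & (rows < dys_bot[None, :]) & epith
    return epith.astype(np.uint8), dysp.astype(np.uint8)


def _place_centroids(region: np.ndarray, n_target: int, spacing: float,
                     rng: np.random.Generator,
                     grid: dict | None = None) -> np.ndarray:
    """Greedy non-overlapping centroid placement inside a binary region.

    Draws candidate pixels uniformly from the region and accepts each if
    no previously accepted centroid lies within ``spacing`` (grid hash).
    Passing a shared ``grid`` enforces the spacing across calls, so nuclei
    of different classes never overlap either.
    """
    ys, xs = np.nonzero(region)
    if len(ys) == 0 or n_target <= 0:
        return np.empty((0, 2))
    idx = rng.choice(len(ys), size=min(len(ys), n_target * 4), replace=False)
    cell = spacing
    if grid is None:
        grid = {}
    accepted: list[tuple[float, float]] = []
    for i in idx:
        if len(accepted) >= n_target:
            break
        # sub-pixel jitter, clipped so centroids stay inside the canvas
        px = min(max(xs[i] + rng.uniform(-0.5, 0.5), 0.0), region.shape[1] - 0.51)
        py = min(max(ys[i] + rng.uniform(-0.5, 0.5), 0.0), region.shape[0] - 0.51)
        cx, cy = int(px // cell), int(py // cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for qx, qy in grid.get((cx + dx, cy + dy), ()):
                    if (px - qx) ** 2 + (py - qy) ** 2 < spacing**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append((px, py))
            grid.setdefault((cx, cy), []).append((px, py))
    return np.array(accepted).reshape(-1, 2)


_ELLIPSE_T = 2 * np.pi * np.arange(16) / 16


def _ellipse_contour(cx: float, cy: float, area_px: float, ecc: float,
                     theta: float) -> np.ndarray:
    """16-vertex polygon of an ellipse with given area and eccentricity."""
    # a*b*pi = area; b/a = sqrt(1-ecc^2)
    ratio = math.sqrt(max(1e-6, 1 - ecc**2))
    a = math.sqrt(area_px / (math.pi * ratio))
    b = a * ratio
    ex = a * np.cos(_ELLIPSE_T)
    ey = b * np.sin(_ELLIPSE_T)
    ct, st = math.cos(theta), math.sin(theta)
    return np.column_stack([cx + ct * ex - st * ey, cy + st * ex + ct * ey])


def generate_slide(
    cfg: SynthConfig, outcome: int, rng: np.random.Generator,
    slide_id: str = "slide", is_control: bool = False,
) -> tuple[MaskRaster, MaskRaster, list[NucleusInstance], float]:
    """Generate one slide: epithelium mask, dysplasia mask, nuclei.

    Returns the two masks, the nuclear instances, and the dysplasia
    fraction drawn for the slide. Control slides carry (near) zero
    dysplasia and no dysplastic nuclei.
    """
    if is_control:
        frac = 0.0
    else:
        lo, hi = cfg.dysplasia_fraction_range[int(outcome)]
        frac = float(rng.uniform(lo, hi))
    epith, dysp = _band_masks(cfg, rng, frac)

    mm2_per_px = (cfg.mask_mpp / 1000.0) ** 2
    effect = cfg.nuclear_effect if (outcome == 1 and not is_control) else 0.0

    nuclei: list[NucleusInstance] = []
    counter = 0
    occupancy: dict = {}  # shared across classes: no centroid pair overlaps

    def _add(region: np.ndarray, density: float, raw_class: str,
             area_mean: float, area_cv: float, ecc: float) -> None:
        nonlocal counter
        n_target = rng.poisson(density * region.sum() * mm2_per_px)
        pts = _place_centroids(region, int(n_target), cfg.min_centroid_spacing_px,
                               rng, occupancy)
        mu = math.log(area_mean / math.sqrt(1 + area_cv**2))
        sig = math.sqrt(math.log(1 + area_cv**2))
        for px, py in pts:
            area_um2 = float(rng.lognormal(mu, sig))
            contour = _ellipse_contour(
                px, py, area_um2 / cfg.mask_mpp**2,
                min(0.95, max(0.0, ecc + rng.normal(0, 0.05))),
                rng.uniform(0, math.pi),
            )
            nuclei.append(
                NucleusInstance(f"{slide_id}_n{counter}", raw_class, contour, (px, py))
            )
            counter += 1

    dmean, dcv, decc = cfg.morphology["dysplastic_epithelial"]
    # standardized shift: mean up by `effect` within-class SDs, CV inflated
    dmean_eff = dmean * (1 + effect * dcv)
    dcv_eff = dcv * (1 + 0.3 * effect)
    nmean, ncv, necc = cfg.morphology["normal_epithelial"]
    omean, ocv, oecc = cfg.morphology["other"]

    normal_region = epith & ~dysp
    _add(dysp, cfg.epithelial_density, "dysplastic_epithelial", dmean_eff, dcv_eff, decc)
    _add(normal_region, cfg.epithelial_density, "normal_epithelial", nmean, ncv, necc)
    _add(epith, cfg.iel_density, "other", omean, ocv, oecc)
    stroma = (1 - epith).astype(np.uint8)
    pel_density = cfg.pel_density * (1 + 0.5 * effect)
    _add(stroma, pel_density, "other", omean, ocv, oecc)

    ep_mask = MaskRaster(epith, cfg.mask_mpp, slide_id)
    dy_mask = MaskRaster(dysp, cfg.mask_mpp, slide_id)
    return ep_mask, dy_mask, nuclei, frac


def _deterministic_split(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean flags with exactly round(n * fraction) True, by sorted draw."""
    k = int(round(n * fraction))
    draws = rng.random(n)
    chosen = np.argsort(draws)[:k]
    flags = np.zeros(n, dtype=bool)
    flags[chosen] = True
    return flags


SITES = ("tongue", "floor_of_mouth", "buccal_mucosa", "other_site")


def generate_cohort(
    cfg: SynthConfig, out_dir: str | Path | None = None
) -> tuple[CohortTable, dict[str, tuple[MaskRaster, MaskRaster, list[NucleusInstance]]]]:
    """Generate a full cohort and optionally write it to disk.

    Returns the cohort table plus an in-memory bundle mapping slide_id to
    (epithelium mask, dysplasia mask, nuclei). Transformation events are
    assigned to exactly ``round(n_patients * transform_fraction)`` OED
    patients (deterministic sorted draw); all slides of one patient share
    the outcome. Event times are truncated-exponential inside the
    administrative horizon; non-transforming patients are censored at the
    horizon, or earlier with probability ``censor_rate``.
    """
    assign_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(999_999,))
    )
    transformed_flags = _deterministic_split(cfg.n_patients, cfg.transform_fraction, assign_rng)

    records: list[SlideRecord] = []
    bundle: dict[str, tuple[MaskRaster, MaskRaster, list[NucleusInstance]]] = {}
    n_total = cfg.n_patients + cfg.n_controls
    for p in range(n_total):
        is_control = p >= cfg.n_patients
        outcome = 0 if is_control else int(transformed_flags[p])
        pid = f"P{p:04d}"
        prng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(p, 10_000))
        )
        age = float(np.clip(prng.normal(62, 11), 25, 95))
        sex = "F" if prng.random() < 0.45 else "M"
        site = SITES[prng.integers(len(SITES))]

        rate = cfg.base_event_rate * math.exp(cfg.nuclear_effect) if outcome else 0.0
        if outcome:
            # truncated exponential: event observed inside the horizon
            u = prng.random()
            h = cfg.admin_horizon_months
            t = -math.log(1 - u * (1 - math.exp(-rate * h))) / rate
            follow_up, event = t, 1
        else:
            follow_up, event = cfg.admin_horizon_months, 0
            if not is_control and prng.random() < cfg.censor_rate:
                follow_up = float(prng.uniform(6.0, cfg.admin_horizon_months))

        for s in range(cfg.slides_per_patient):
            sid = f"S{p:04d}_{s}"
            srng = _slide_rng(cfg, p, s)
            ep, dy, nuclei, frac = generate_slide(cfg, outcome, srng, sid, is_control)
            bundle[sid] = (ep, dy, nuclei)
            grade = None
            binary = None
            if not is_control:
                grade = "mild" if frac < 0.35 else ("moderate" if frac < 0.55 else "severe")
                binary = "low_risk" if grade == "mild" else "high_risk"
            records.append(
                SlideRecord(
                    slide_id=sid, patient_id=pid, transformed=event,
                    follow_up_months=follow_up, who_grade=grade,
                    binary_grade=binary, age=age, sex=sex, site=site,
                )
            )

    cohort = CohortTable(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, (ep, dy, nuclei) in bundle.items():
            odyn_io.write_mask(ep, out_dir / f"{sid}_epithelium.png")
            odyn_io.write_mask(dy, out_dir / f"{sid}_dysplasia.png")
            odyn_io.write_nuclei_geojson(nuclei, out_dir / f"{sid}_nuclei.geojson")
        odyn_io.write_cohort(cohort, out_dir / "cohort.csv")
        with open(out_dir / "synth_manifest.json", "w") as fh:
            json.dump(asdict(cfg), fh, indent=1, default=str)
    return cohort, bundle
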