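"""Synthetic two-channel qFISH specimen generator with per-cell ground truth.

Renders Cy3 (telomere probe) and DAPI (nuclear counterstain) planes for a
simulated tissue section containing crypt-arranged epithelial nuclei and
scattered stromal nuclei, together with an integer ROI label mask and a truth
table holding each cell's true integrated telomeric signal ``T_true`` and
nuclear DAPI signal ``D_true``.  The render is linear in the underlying
signals before noise and clipping, mirroring the acquisition assumption that
telomere-probe fluorescence is proportional to telomere length at constant
exposure.

Rendering model, per channel::

    noiseless = gaussian_psf(signal) * exposure_gain + offset + gradient * x
    observed  = Poisson(noiseless)            (if shot noise enabled)
    observed += Normal(0, read_noise_sd)
    observed  = clip(observed, 0, 2**bit_depth - 1)

Telomeric spots are Gaussian blobs whose *integrated* (not peak) intensity
equals the drawn per-spot signal; the blob footprint is confined to the
nucleus mask and renormalized, so that with ``psf_sigma = 0`` the noiseless
Cy3 integral over a cell's ROI equals ``T_true * exposure_scale_cy3``
exactly.  DAPI is spread uniformly over the nucleus, with optional low-DAPI
vacuole holes (the goblet/mucus-cell look) that redistribute rather than
destroy signal, so the nuclear DAPI total stays ``D_true``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

__all__ = [
    "AcquisitionSpec",
    "CompartmentSpec",
    "SpecimenSpec",
    "PlacementError",
    "simulate_specimen",
    "simulate_cohort",
    "default_acquisition",
    "default_compartments",
]

#: pixel sigma of the rendered telomeric blob (nominal spot size)
SPOT_SIGMA = 1.5

#: nominal number of epithelial cells per simulated crypt ring
CELLS_PER_CRYPT = 8


class PlacementError(RuntimeError):
    """Raised when a nucleus cannot be placed without overlap."""


@dataclass(frozen=True)
class AcquisitionSpec:
    """Imaging/acquisition parameters shared by both channels of a cohort.

    Exposure gains are held constant within a cohort, mirroring constant
    exposure time on the microscope.
    """

    width: int = 1024
    height: int = 1024
    psf_sigma: float = 1.0
    background_offset: float = 150.0
    background_gradient: float = 0.05
    read_noise_sd: float = 5.0
    shot_noise: bool = True
    bit_depth: int = 16
    exposure_scale_cy3: float = 1.0
    exposure_scale_dapi: float = 1.0

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ValueError("image dimensions must be >= 16 pixels")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        for name in ("background_offset", "background_gradient", "read_noise_sd",
                     "exposure_scale_cy3", "exposure_scale_dapi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def max_value(self) -> float:
        return float(2 ** self.bit_depth - 1)


@dataclass(frozen=True)
class CompartmentSpec:
    """One cell population within a specimen.

    Per-spot integrated intensities (AU*px) and per-nucleus DAPI totals (AU)
    are lognormal; ``spot_intensity_mu``/``sigma`` and ``dapi_total_mu``/
    ``sigma`` are the log-scale parameters.  ``arrangement`` is ``crypt-ring``
    (cells in straight array along a ring, the epithelial look) or
    ``scattered`` (stromal look).  ``vacuole`` renders low-DAPI holes, the
    autofluorescence pattern of mucus-producing goblet cells.
    """

    compartment: str  # "epithelial" | "stromal"
    subtype: str = "not-applicable"  # "mucus" | "non-mucus" | "not-applicable"
    n_cells: int = 0
    nucleus_radius_mean: float = 24.0
    nucleus_radius_sd: float = 2.0
    spots_per_cell_lambda: float = 15.0
    spot_intensity_mu: float = float(np.log(3.0e4))
    spot_intensity_sigma: float = 0.5
    dapi_total_mu: float = float(np.log(2.5e6))
    dapi_total_sigma: float = 0.2
    arrangement: str = "scattered"
    vacuole: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in ("epithelial", "stromal"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.subtype not in ("mucus", "non-mucus", "not-applicable"):
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.arrangement not in ("crypt-ring", "scattered"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.nucleus_radius_mean <= 0:
            raise ValueError("nucleus radius mean must be > 0")
        if self.spots_per_cell_lambda < 0:
            raise ValueError("spots_per_cell_lambda must be >= 0")
        if self.spot_intensity_sigma < 0 or self.dapi_total_sigma < 0:
            raise ValueError("sigma parameters must be >= 0")


@dataclass(frozen=True)
class SpecimenSpec:
    """A full simulated specimen: acquisition settings plus cell populations."""

    specimen_id: str
    tissue_class: str
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    compartments: tuple[CompartmentSpec, ...] = ()
    seed: int = 0


@dataclass
class _Cell:
    label: int
    compartment: str
    subtype: str
    cx: float
    cy: float
    a: float  # long semi-axis, px
    b: float  # short semi-axis, px
    theta: float  # orientation, radians


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipse_mask(cell: _Cell, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixels inside the cell's ellipse."""
    h, w = shape
    r = int(np.ceil(cell.a)) + 1
    y0, y1 = max(0, int(cell.cy) - r), min(h, int(cell.cy) + r + 1)
    x0, x1 = max(0, int(cell.cx) - r), min(w, int(cell.cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cell.cx, yy - cell.cy
    c, s = np.cos(cell.theta), np.sin(cell.theta)
    u = (dx * c + dy * s) / cell.a
    v = (-dx * s + dy * c) / cell.b
    inside = u * u + v * v <= 1.0
    return yy[inside], xx[inside]


def _overlaps(cx: float, cy: float, a: float, placed: list[_Cell]) -> bool:
    for other in placed:
        d = np.hypot(cx - other.cx, cy - other.cy)
        if d < a + other.a + 1.0:
            return True
    return False


def _crypt_centers(n_crypts: int, acq: AcquisitionSpec, crypt_radius: float,
                   cell_radius: float,
                   rng: np.random.Generator) -> list[tuple[float, float]]:
    """Crypt ring centers on a grid spaced so neighboring rings (plus the
    nuclei sitting on them) cannot collide."""
    margin = crypt_radius + 2.0 * cell_radius + 3.0 * SPOT_SIGMA + 6.0
    spacing = 2.0 * margin + 4.0
    nx = max(1, int((acq.width - 2 * margin) // spacing) + 1)
    ny = max(1, int((acq.height - 2 * margin) // spacing) + 1)
    if (acq.width < 2 * margin or acq.height < 2 * margin
            or nx * ny < n_crypts):
        raise PlacementError(
            f"cannot fit {n_crypts} crypt ring(s) of radius {crypt_radius:.0f} px "
            f"in a {acq.width}x{acq.height} image (epithelial compartment too dense)")
    xs = np.linspace(margin, acq.width - margin, nx)
    ys = np.linspace(margin, acq.height - margin, ny)
    centers = [(x, y) for y in ys for x in xs][:n_crypts]
    return [(x + rng.uniform(-4, 4), y + rng.uniform(-4, 4)) for x, y in centers]


def _place_compartment(comp: CompartmentSpec, acq: AcquisitionSpec,
                       placed: list[_Cell], rng: np.random.Generator,
                       next_label: int) -> list[_Cell]:
    """Place ``comp.n_cells`` nuclei, appending to ``placed``; returns new cells."""
    cells: list[_Cell] = []
    if comp.n_cells == 0:
        return cells
    aspect = 0.7 if comp.arrangement == "crypt-ring" else 0.85

    if comp.arrangement == "crypt-ring":
        n_crypts = int(np.ceil(comp.n_cells / CELLS_PER_CRYPT))
        per = int(np.ceil(comp.n_cells / n_crypts))
        ring_r = per * 2.6 * comp.nucleus_radius_mean / (2 * np.pi)
        centers = _crypt_centers(n_crypts, acq, ring_r, comp.nucleus_radius_mean, rng)
        slots = []
        for ci, (gx, gy) in enumerate(centers):
            phase = rng.uniform(0, 2 * np.pi)
            for k in range(per):
                slots.append((gx, gy, phase + 2 * np.pi * k / per))
        slots = slots[: comp.n_cells]
        for (gx, gy, ang0) in slots:
            for attempt in range(200):
                ang = ang0 + rng.normal(0, 0.02)
                rr = ring_r + rng.normal(0, 0.6)
                cx, cy = gx + rr * np.cos(ang), gy + rr * np.sin(ang)
                a = max(2.0, rng.normal(comp.nucleus_radius_mean, comp.nucleus_radius_sd))
                b = aspect * a
                if not (a <= cx <= acq.width - 1 - a and a <= cy <= acq.height - 1 - a):
                    continue
                if _overlaps(cx, cy, a, placed):
                    continue
                # long axis radial (columnar nuclei point into the crypt lumen)
                cell = _Cell(next_label + len(cells), comp.compartment,
                             comp.subtype, cx, cy, a, b, ang)
                placed.append(cell)
                cells.append(cell)
                break
            else:
                raise PlacementError(
                    f"could not place {comp.compartment} cell without overlap "
                    f"after 200 attempts (crypt arrangement too dense)")
    else:
        for _ in range(comp.n_cells):
            for attempt in range(200):
                a = max(2.0, rng.normal(comp.nucleus_radius_mean, comp.nucleus_radius_sd))
                b = aspect * a
                cx = rng.uniform(a + 1, acq.width - 2 - a)
                cy = rng.uniform(a + 1, acq.height - 2 - a)
                if _overlaps(cx, cy, a, placed):
                    continue
                cell = _Cell(next_label + len(cells), comp.compartment,
                             comp.subtype, cx, cy, a, b,
                             rng.uniform(0, np.pi))
                placed.append(cell)
                cells.append(cell)
                break
            else:
                raise PlacementError(
                    f"could not place {comp.compartment} cell without overlap "
                    f"after 200 attempts (field too crowded)")
    return cells


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_dapi_cell(dapi: np.ndarray, cell: _Cell, d_true: float,
                      vacuole: bool, rng: np.random.Generator,
                      ys: np.ndarray, xs: np.ndarray) -> None:
    weights = np.ones(ys.size)
    if vacuole and ys.size > 8:
        # one or two circular low-DAPI holes; signal is redistributed so the
        # nuclear total stays exactly D_true (vacuoles change appearance only)
        for _ in range(rng.integers(1, 3)):
            hr = 0.35 * cell.b
            hu = rng.uniform(-0.4, 0.4) * cell.a
            hv = rng.uniform(-0.4, 0.4) * cell.b
            c, s = np.cos(cell.theta), np.sin(cell.theta)
            hx = cell.cx + hu * c - hv * s
            hy = cell.cy + hu * s + hv * c
            hole = (ys - hy) ** 2 + (xs - hx) ** 2 <= hr * hr
            weights[hole] = 0.15
    weights *= d_true / weights.sum()
    dapi[ys, xs] += weights


def _render_spot(cy3: np.ndarray, cell_ys: np.ndarray, cell_xs: np.ndarray,
                 sx: float, sy: float, value: float) -> None:
    """Add one telomeric spot: Gaussian profile truncated to the nucleus mask,
    renormalized so the masked integral equals ``value`` exactly."""
    d2 = (cell_ys - sy) ** 2 + (cell_xs - sx) ** 2
    w = np.exp(-d2 / (2.0 * SPOT_SIGMA ** 2))
    total = w.sum()
    if total <= 0:  # pragma: no cover - degenerate geometry
        return
    cy3[cell_ys, cell_xs] += value * (w / total)


def simulate_specimen(spec: SpecimenSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one specimen.

    Returns
    -------
    cy3, dapi : float64 arrays (height, width)
        Observed channel images, clipped to the detector range.
    labels : int32 array
        ROI label mask, 0 = background, k > 0 = cell k.
    truth : DataFrame
        One row per cell: specimen_id, tissue_class, cell_label, compartment,
        subtype, T_true, D_true, centroid_x, centroid_y.
    """
    acq = spec.acquisition
    rng = np.random.default_rng(spec.seed)
    h, w = acq.height, acq.width
    labels = np.zeros((h, w), dtype=np.int32)
    cy3_sig = np.zeros((h, w))
    dapi_sig = np.zeros((h, w))

    placed: list[_Cell] = []
    rows = []
    next_label = 1
    for comp in spec.compartments:
        cells = _place_compartment(comp, acq, placed, rng, next_label)
        next_label += len(cells)
        for cell in cells:
            ys, xs = _ellipse_mask(cell, (h, w))
            labels[ys, xs] = cell.label
            d_true = float(rng.lognormal(comp.dapi_total_mu, comp.dapi_total_sigma))
            _render_dapi_cell(dapi_sig, cell, d_true, comp.vacuole, rng, ys, xs)
            n_spots = int(rng.poisson(comp.spots_per_cell_lambda))
            t_true = 0.0
            for _ in range(n_spots):
                v = float(rng.lognormal(comp.spot_intensity_mu, comp.spot_intensity_sigma))
                # uniform position inside a slightly shrunk ellipse
                r = 0.8 * np.sqrt(rng.uniform())
                phi = rng.uniform(0, 2 * np.pi)
                uu, vv = r * np.cos(phi) * cell.a, r * np.sin(phi) * cell.b
                c, s = np.cos(cell.theta), np.sin(cell.theta)
                sx = cell.cx + uu * c - vv * s
                sy = cell.cy + uu * s + vv * c
                _render_spot(cy3_sig, ys, xs, sx, sy, v)
                t_true += v
            rows.append(dict(specimen_id=spec.specimen_id,
                             tissue_class=spec.tissue_class,
                             cell_label=cell.label,
                             compartment=cell.compartment,
                             subtype=cell.subtype,
                             T_true=t_true, D_true=d_true,
                             centroid_x=cell.cx, centroid_y=cell.cy))

    cy3 = _acquire(cy3_sig, acq.exposure_scale_cy3, acq, rng, "cy3")
    dapi = _acquire(dapi_sig, acq.exposure_scale_dapi, acq, rng, "dapi")
    truth = pd.DataFrame(rows, columns=["specimen_id", "tissue_class", "cell_label",
                                        "compartment", "subtype", "T_true", "D_true",
                                        "centroid_x", "centroid_y"])
    return cy3, dapi, labels, truth


def _acquire(signal: np.ndarray, gain: float, acq: AcquisitionSpec,
             rng: np.random.Generator, channel: str) -> np.ndarray:
    img = ndi.gaussian_filter(signal, acq.psf_sigma) if acq.psf_sigma > 0 else signal.copy()
    img *= gain
    x = np.arange(img.shape[1], dtype=float)
    img += acq.background_offset + acq.background_gradient * x[None, :]
    if acq.shot_noise:
        img = rng.poisson(np.maximum(img, 0)).astype(float)
    if acq.read_noise_sd > 0:
        img += rng.normal(0.0, acq.read_noise_sd, size=img.shape)
    clipped = np.clip(img, 0.0, acq.max_value)
    n_sig = int(np.count_nonzero(signal > 0))
    if n_sig:
        n_clip = int(np.count_nonzero((img > acq.max_value) & (signal > 0)))
        if n_clip > 0.01 * n_sig:
            msg = (f"{channel}: clipping affected {n_clip}/{n_sig} signal pixels "
                   f"(> 1%) — consider lowering exposure")
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
            logger.warning(msg)
    return clipped


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def default_acquisition(**overrides) -> AcquisitionSpec:
    """Acquisition defaults used throughout examples and tests."""
    return replace(AcquisitionSpec(), **overrides) if overrides else AcquisitionSpec()


def default_compartments(n_epithelial: int = 64, n_stromal: int = 36,
                         epithelial_signal_ratio: float = 0.9,
                         mucus_fraction: float = 0.0,
                         mucus_signal_boost: float = 1.0,
                         spot_sigma_log: float = 0.5,
                         nucleus_radius: float = 24.0,
                         spots_per_cell: float = 15.0) -> tuple[CompartmentSpec, ...]:
    """Epithelial + stromal compartments with a chosen true epithelial/stromal
    mean-signal ratio.

    The ratio is imposed on the lognormal per-spot intensity scale: the
    epithelial log-mean is shifted by ``log(epithelial_signal_ratio)`` from
    the stromal one, so the expected per-cell ``T_true/D_true`` ratio between
    compartments equals ``epithelial_signal_ratio``.
    """
    common = dict(nucleus_radius_mean=nucleus_radius,
                  spots_per_cell_lambda=spots_per_cell,
                  spot_intensity_sigma=spot_sigma_log)
    stromal = CompartmentSpec(compartment="stromal", n_cells=n_stromal,
                              arrangement="scattered", **common)
    comps: list[CompartmentSpec] = []
    n_mucus = int(round(mucus_fraction * n_epithelial))
    n_non = n_epithelial - n_mucus
    base_mu = stromal.spot_intensity_mu + float(np.log(epithelial_signal_ratio))
    if n_non:
        comps.append(CompartmentSpec(compartment="epithelial", subtype="non-mucus",
                                     n_cells=n_non, arrangement="crypt-ring",
                                     spot_intensity_mu=base_mu, **common))
    if n_mucus:
        comps.append(CompartmentSpec(compartment="epithelial", subtype="mucus",
                                     n_cells=n_mucus, arrangement="crypt-ring",
                                     spot_intensity_mu=base_mu + float(np.log(mucus_signal_boost)),
                                     vacuole=True, **common))
    comps.append(stromal)
    return tuple(comps)


def simulate_cohort(group_specs: Sequence[tuple[str, SpecimenSpec, int]],
                    master_seed: int, out_dir: str | Path) -> dict:
    """Simulate a multi-group cohort and write it to ``out_dir``.

    Parameters
    ----------
    group_specs : list of (tissue_class, template SpecimenSpec, n_specimens)
        The template's ``specimen_id`` is used as a prefix; its seed is
        replaced by a sub-seed derived from ``master_seed``.
    master_seed : int
        Single source of randomness; per-specimen sub-seeds are spawned from
        a ``numpy.random.SeedSequence`` and recorded in the manifest.

    Returns
    -------
    manifest : dict (also written as ``manifest.json``)
        Per-specimen file paths, sub-seeds, and the combined ``truth.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for _, _, n in group_specs:
        if n < 1:
            raise ValueError("each group needs n_specimens >= 1")

    seq = np.random.SeedSequence(master_seed)
    total = sum(n for _, _, n in group_specs)
    children = seq.spawn(total)
    sub_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]

    manifest: dict = {"master_seed": int(master_seed), "specimens": []}
    truths = []
    seen_ids: set[str] = set()
    i = 0
    for tissue_class, template, n in group_specs:
        for k in range(n):
            sid = f"{template.specimen_id}_{tissue_class}_{k + 1}"
            if sid in seen_ids:
                raise ValueError(f"duplicate specimen_id {sid!r}")
            seen_ids.add(sid)
            spec = replace(template, specimen_id=sid, tissue_class=tissue_class,
                           seed=sub_seeds[i])
            cy3, dapi, lbl, truth = simulate_specimen(spec)
            paths = {
                "cy3": f"{sid}_cy3.tif",
                "dapi": f"{sid}_dapi.tif",
                "labels": f"{sid}_labels.tif",
            }
            tifffile.imwrite(out_dir / paths["cy3"],
                             np.round(cy3).astype(np.uint16))
            tifffile.imwrite(out_dir / paths["dapi"],
                             np.round(dapi).astype(np.uint16))
            tifffile.imwrite(out_dir / paths["labels"], lbl.astype(np.uint16))
            truths.append(truth)
            manifest["specimens"].append({
                "specimen_id": sid, "tissue_class": tissue_class,
                "seed": sub_seeds[i], **paths,
            })
            i += 1
    truth_all = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    truth_all.to_csv(out_dir / "truth.csv", index=False)
    manifest["truth"] = "truth.csv"
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
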