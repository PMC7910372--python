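"""Voxelwise parametric BPND / R1 mapping with explicit failed-voxel handling.

Each masked voxel's TAC is fitted with the same regional fitter used for
VOI analysis (sharing one precomputed reference basis), so a spatially
homogeneous region reproduces the regional fit exactly. Voxels whose fit
violates the plausibility rules are marked failed (NaN), never silently
coerced to a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import SRTMBasis, fit_logan_ref, fit_mrtm, fit_mrtm2, fit_srtm, fit_srtm2
from .tac import TAC, DynamicImage, LabelVolume

__all__ = ["ParametricMap", "fit_voxelwise", "regional_mean_from_map",
           "map_voi_agreement"]

#: Plausibility bounds for a voxel fit; generous around the BPND 7-12
#: range of a receptor-rich mouse striatum.
BPND_BOUNDS = (-1.0, 50.0)
DVR_ABS_MAX = 51.0


@dataclass
class ParametricMap:
    """3-D parameter volume; failed and out-of-mask voxels are NaN."""

    values: np.ndarray
    failed_mask: np.ndarray
    model: str
    parameter: str
    n_failed: int
    n_fitted: int

    @property
    def failed_fraction(self) -> float:
        return self.n_failed / self.n_fitted if self.n_fitted else 0.0


def _voxel_fit(model, y_tac, ref, basis, k2_prime, t_star):
    """Run one voxel fit; returns dict of parameter values or None if failed."""
    try:
        if model == "srtm":
            f = fit_srtm(y_tac, ref, basis=basis)
        elif model == "srtm2":
            f = fit_srtm2(y_tac, ref, k2_prime, basis=basis)
        elif model == "mrtm":
            f = fit_mrtm(y_tac, ref, t_star=t_star, _degenerate_ok=False)
        elif model == "mrtm2":
            f = fit_mrtm2(y_tac, ref, k2_prime, t_star=t_star)
        elif model == "logan":
            f = fit_logan_ref(y_tac, ref, k2_prime, t_star=t_star)
        else:
            raise ValueError(f"unknown model {model!r}")
    except (ValueError, np.linalg.LinAlgError):
        return None

    if model == "logan":
        if not np.isfinite(f.dvr) or abs(f.dvr) > DVR_ABS_MAX:
            return None
        return {"bpnd": f.bpnd}
    if not (np.isfinite(f.bpnd) and np.isfinite(f.r1)):
        return None
    # open lower bound: BPND = -1 means DVR = 0, a degenerate (e.g. all-zero)
    # voxel. A basis-grid boundary hit alone is NOT a failure: in
    # receptor-free voxels the convolution term has ~zero weight, leaving
    # k2a unidentifiable while BPND ~ 0 remains perfectly usable.
    if not (BPND_BOUNDS[0] < f.bpnd <= BPND_BOUNDS[1]):
        return None
    if model in ("mrtm", "mrtm2") and abs(f.bpnd + 1.0) > DVR_ABS_MAX:
        return None
    return {"bpnd": f.bpnd, "r1": f.r1}


def fit_voxelwise(
    img: DynamicImage,
    ref: TAC,
    model: str = "srtm",
    brain_mask: np.ndarray | None = None,
    k2_prime: float | None = None,
    t_star: float | None = None,
) -> dict[str, ParametricMap]:
    """Fit every voxel inside ``brain_mask`` and return parameter maps.

    Returns a BPND map and, for SRTM/SRTM2/MRTM/MRTM2, an R1 map. The
    Logan and fixed-k2' models require ``k2_prime`` (conventionally the
    subject's regional MRTM cerebellum-vs-striatum estimate).
    """
    model = model.lower()
    if brain_mask is None:
        raise ValueError("a brain mask is required for voxelwise fitting")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != img.shape3d:
        raise ValueError("mask shape does not match image grid")
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    if ref.schedule != img.schedule:
        raise ValueError("reference TAC must be on the image schedule")
    if model in ("srtm2", "mrtm2", "logan") and k2_prime is None:
        raise ValueError(f"{model} needs a fixed k2_prime")
    if t_star is None:
        t_star = 15.0 if model == "logan" else 0.0

    basis = SRTMBasis(ref) if model in ("srtm", "srtm2") else None
    params = ["bpnd"] if model == "logan" else ["bpnd", "r1"]
    out = {
        p: np.full(img.shape3d, np.nan) for p in params
    }
    failed = np.zeros(img.shape3d, dtype=bool)
    idx = np.argwhere(brain_mask)
    for ix, iy, iz in idx:
        values = img.voxels[ix, iy, iz]
        if not np.all(np.isfinite(values)):
            failed[ix, iy, iz] = True
            continue
        try:
            y_tac = TAC(schedule=img.schedule, values=values)
        except ValueError:
            failed[ix, iy, iz] = True
            continue
        result = _voxel_fit(model, y_tac, ref, basis, k2_prime, t_star)
        if result is None:
            failed[ix, iy, iz] = True
        else:
            for p in params:
                out[p][ix, iy, iz] = result[p]

    n_fitted = int(brain_mask.sum())
    n_failed = int(failed.sum())
    return {
        p: ParametricMap(
            values=out[p], failed_mask=failed, model=model,
            parameter=p, n_failed=n_failed, n_fitted=n_fitted,
        )
        for p in params
    }


def regional_mean_from_map(
    pmap: ParametricMap, labels: LabelVolume, region: str
) -> tuple[float, float]:
    """Mean over non-failed labelled voxels and the fraction excluded.

    Mirrors applying the VOI of the regional analysis to a parametric map.
    """
    m = labels.mask(region)
    if not m.any():
        raise ValueError(f"region {region!r} contains no voxels")
    vals = pmap.values[m]
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError(f"all {region!r} voxels failed in the {pmap.model} map")
    return float(vals[ok].mean()), float(1.0 - ok.mean())


def map_voi_agreement(map_values, voi_values) -> tuple[float, float, float]:
    """Agreement of map-derived vs VOI-derived values: (r^2, slope, intercept)."""
    from scipy.stats import linregress

    x = np.asarray(voi_values, dtype=float)
    y = np.asarray(map_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in paired values")
    reg = linregress(x, y)
    return float(reg.rvalue**2), float(reg.slope), float(reg.intercept)
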