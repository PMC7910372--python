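"""Synthetic dynamic-PET generation.

Produces continuous-time tissue curves from compartment models driven by a
Feng-type plasma input function, frame-averages them onto an acquisition
schedule, applies a decay-aware Gaussian noise model, and assembles paired
test-retest cohorts with genotype-level parameter distributions.

The plasma input is a fixture: reference-tissue quantification never sees
it, so its exact shape only needs to be physiologically plausible (sharp
sub-minute peak, slow multi-exponential tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import truncnorm

from .tac import TAC, DynamicImage, FrameSchedule, LabelVolume, ScanRecord

__all__ = [
    "AIFParams",
    "Tissue1TParams",
    "Tissue2TParams",
    "SRTMTruth",
    "NoiseModel",
    "GroupSpec",
    "CohortSpec",
    "SimulatedCohort",
    "feng_aif",
    "fine_grid",
    "expconv",
    "simulate_1t",
    "simulate_2t",
    "srtm_forward",
    "frame_average",
    "add_noise",
    "build_phantom",
    "fill_regions",
    "simulate_cohort",
    "DEFAULT_AIF",
    "DEFAULT_REF_TISSUE",
]

#: Carbon-11 half-life in minutes.
C11_HALFLIFE_MIN = 20.3

#: Fine simulation grid step (seconds); all convolutions run on this grid.
FINE_DT_S = 1.0


@dataclass(frozen=True)
class AIFParams:
    """Feng-type arterial input function parameters.

    Cp(t) = (A1*(t-tau) - A2 - A3)*exp(l1*(t-tau))
            + A2*exp(l2*(t-tau)) + A3*exp(l3*(t-tau))   for t >= tau, else 0.

    A1 in kBq/mL/min; A2, A3 in kBq/mL; l1 < l2 < l3 < 0 in 1/min; tau in min.
    The A2+A3 terms cancel the linear term at t = tau, so Cp is continuous.
    """

    A1: float = 600.0
    A2: float = 20.0
    A3: float = 15.0
    l1: float = -4.0
    l2: float = -0.25
    l3: float = -0.013
    tau: float = 0.25


@dataclass(frozen=True)
class Tissue1TParams:
    """One-tissue compartment: K1 (mL/cm^3/min), k2 (1/min)."""

    K1: float
    k2: float


@dataclass(frozen=True)
class Tissue2TParams:
    """Two-tissue compartment: K1 (mL/cm^3/min), k2, k3, k4 (1/min); BPND=k3/k4."""

    K1: float
    k2: float
    k3: float
    k4: float


@dataclass(frozen=True)
class SRTMTruth:
    """Ground-truth target-tissue kinetics relative to a reference region."""

    r1: float
    k2: float
    bpnd: float

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.bpnd)


@dataclass(frozen=True)
class NoiseModel:
    """Frame-wise Gaussian TAC noise scaled by count statistics.

    sigma_j = alpha * sqrt(C(t_j) * exp(lambda*t_j) / dt_j), with t_j the
    frame midpoint (min), dt_j the frame duration (min) and lambda the
    isotope decay constant: short frames and late (decay-corrected) frames
    are noisier, as in real PET.
    """

    alpha: float = 0.05
    halflife_min: float = C11_HALFLIFE_MIN
    seed: int = 0


# Reference-region (cerebellum) kinetics giving mouse-like washout.
DEFAULT_REF_TISSUE = Tissue1TParams(K1=0.9, k2=0.35)
DEFAULT_AIF = AIFParams()


def feng_aif(t_min, p: AIFParams = DEFAULT_AIF) -> np.ndarray:
    """Evaluate the plasma input function at times ``t_min`` (minutes)."""
    t = np.asarray(t_min, dtype=float)
    u = t - p.tau
    cp = np.where(
        u >= 0,
        (p.A1 * u - p.A2 - p.A3) * np.exp(p.l1 * u)
        + p.A2 * np.exp(p.l2 * u)
        + p.A3 * np.exp(p.l3 * u),
        0.0,
    )
    return cp


def fine_grid(duration_min: float, dt_s: float = FINE_DT_S) -> np.ndarray:
    """Uniform time grid (minutes) from 0 to ``duration_min`` inclusive."""
    n = int(round(duration_min * 60.0 / dt_s))
    return np.arange(n + 1) * (dt_s / 60.0)


def expconv(c: np.ndarray, k: float, dt_min: float) -> np.ndarray:
    """Convolution (c * exp(-k t))(t) on a uniform grid, piecewise-linear in c.

    Uses the analytic update for a linear segment driven into a single
    exponential, evaluated as an IIR filter, so the result is exact for
    piecewise-linear inputs regardless of step size.
    """
    if k <= 0:
        raise ValueError("rate constant must be positive")
    E = np.exp(-k * dt_min)
    b0 = 1.0 / k - (1.0 - E) / (k * k * dt_min)
    b1 = (1.0 - E) / k - b0
    y = lfilter([b0, b1], [1.0, -E], c)
    if c[0] != 0.0:  # recursion must start from y(0) = 0
        y -= b0 * c[0] * E ** np.arange(c.size)
    return y


def simulate_1t(aif_values: np.ndarray, p: Tissue1TParams, t_min: np.ndarray) -> np.ndarray:
    """One-tissue curve C(t) = K1 * (Cp * exp(-k2 t)) on a uniform grid."""
    dt = t_min[1] - t_min[0]
    return p.K1 * expconv(aif_values, p.k2, dt)


def simulate_2t(aif_values: np.ndarray, p: Tissue2TParams, t_min: np.ndarray) -> np.ndarray:
    """Total (free+bound) two-tissue curve via its bi-exponential impulse response.

    dC1/dt = K1*Cp - (k2+k3)*C1 + k4*C2;  dC2/dt = k3*C1 - k4*C2.
    The impulse response of C1+C2 is a sum of two exponentials with rates
    given by the eigenvalues of the transfer matrix.
    """
    dt = t_min[1] - t_min[0]
    s = p.k2 + p.k3 + p.k4
    disc = np.sqrt(s * s - 4.0 * p.k2 * p.k4)
    a1 = (s + disc) / 2.0
    a2 = (s - disc) / 2.0
    if a1 == a2:
        raise ValueError("degenerate equal eigenvalues; perturb k-values")
    # C1+C2 impulse response: K1*[(k3+k4-a1)e^{-a1 t} + (a2-k3-k4)e^{-a2 t}]/(a2-a1)
    w1 = p.K1 * (p.k3 + p.k4 - a1) / (a2 - a1)
    w2 = p.K1 * (a2 - p.k3 - p.k4) / (a2 - a1)
    return w1 * expconv(aif_values, a1, dt) + w2 * expconv(aif_values, a2, dt)


def srtm_forward(ref_values: np.ndarray, truth: SRTMTruth, t_min: np.ndarray) -> np.ndarray:
    """Target curve implied by the simplified reference-tissue model.

    C_T(t) = R1*C_R(t) + (k2 - R1*k2a) * (C_R * exp(-k2a t))(t),
    with the apparent efflux k2a = k2/(1+BPND).
    """
    dt = t_min[1] - t_min[0]
    coef = truth.k2 - truth.r1 * truth.k2a
    return truth.r1 * ref_values + coef * expconv(ref_values, truth.k2a, dt)


def frame_average(curve: np.ndarray, t_min: np.ndarray, schedule: FrameSchedule,
                  region: str = "") -> TAC:
    """Average a continuous curve over each frame: (1/dt) * integral over frame.

    Trapezoidal integration on the fine grid; the grid must cover the
    schedule.
    """
    if t_min[-1] < schedule.duration_min - 1e-9:
        raise ValueError(
            f"grid ends at {t_min[-1]:.3f} min but schedule needs "
            f"{schedule.duration_min:.3f} min"
        )
    dt = t_min[1] - t_min[0]
    cum = np.concatenate([[0.0], np.cumsum((curve[1:] + curve[:-1]) * 0.5 * dt)])
    f_start = np.interp(schedule.start_s / 60.0, t_min, cum)
    f_end = np.interp(schedule.end_s / 60.0, t_min, cum)
    values = (f_end - f_start) / schedule.durations_min
    return TAC(schedule=schedule, values=values, region=region)


def noise_sigma(tac: TAC, nm: NoiseModel) -> np.ndarray:
    lam = np.log(2.0) / nm.halflife_min
    t = tac.schedule.mid_min
    dtm = tac.schedule.durations_min
    return nm.alpha * np.sqrt(np.maximum(tac.values, 0.0) * np.exp(lam * t) / dtm)


def add_noise(tac: TAC, nm: NoiseModel) -> TAC:
    """Add independent Gaussian frame noise; identical output for equal seeds."""
    if nm.alpha == 0:
        return tac
    rng = np.random.default_rng(nm.seed)
    return tac.with_values(tac.values + rng.normal(0.0, 1.0, tac.values.size)
                           * noise_sigma(tac, nm))


def _ellipsoid_pick(shape, voxel_size_mm, center_frac, n_vox, taken):
    """Indices of the n_vox voxels closest to the centre in ellipsoidal norm."""
    axes = np.array([1.4, 1.0, 0.8])  # mild anisotropy, arbitrary orientation
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    center = np.array([f * (s - 1) for f, s in zip(center_frac, shape)])
    d2 = sum(
        ((g - c) * vs / a) ** 2
        for g, c, vs, a in zip(grids, center, voxel_size_mm, axes)
    )
    d2 = np.where(taken, np.inf, d2)
    if n_vox > d2.size:
        raise ValueError("requested volume does not fit in grid")
    flat = np.argsort(d2, axis=None, kind="stable")[:n_vox]
    if not np.all(np.isfinite(d2.ravel()[flat])):
        raise ValueError("requested volume does not fit in grid")
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[flat] = True
    return mask


def build_phantom(
    shape: tuple,
    voxel_size_mm,
    volumes_cm3: dict[str, float],
    schedule: FrameSchedule,
) -> tuple[DynamicImage, LabelVolume]:
    """Digital phantom: disjoint ellipsoidal regions of requested volumes.

    Each region's voxel count times the voxel volume is within one voxel of
    the requested volume. Returns a zero-filled dynamic image (fill with
    :func:`fill_regions`) and the label volume.
    """
    voxel_size_mm = np.asarray(voxel_size_mm, dtype=float)
    voxvol = float(np.prod(voxel_size_mm)) / 1000.0  # cm^3
    centers = {"striatum": (0.30, 0.5, 0.5), "cerebellum": (0.72, 0.5, 0.5)}
    labels = np.zeros(shape, dtype=np.int16)
    legend: dict[int, str] = {}
    taken = np.zeros(shape, dtype=bool)
    for i, (region, vol) in enumerate(volumes_cm3.items(), start=1):
        n_vox = int(round(vol / voxvol))
        if n_vox < 1:
            raise ValueError(f"{region}: volume {vol} cm^3 below one voxel ({voxvol})")
        frac = centers.get(region, ((0.2 + 0.3 * i) % 1.0, 0.5, 0.5))
        mask = _ellipsoid_pick(shape, voxel_size_mm, frac, n_vox, taken)
        if abs(n_vox * voxvol - vol) > voxvol:
            raise ValueError(f"{region}: volume {vol} unattainable within one voxel")
        labels[mask] = i
        legend[i] = region
        taken |= mask
    img = DynamicImage(
        voxels=np.zeros((*shape, schedule.n_frames)),
        voxel_size_mm=voxel_size_mm,
        schedule=schedule,
    )
    return img, LabelVolume(labels=labels, legend=legend)


def fill_regions(img: DynamicImage, labels: LabelVolume,
                 region_tacs: dict[str, TAC]) -> DynamicImage:
    """Return a copy of ``img`` with each labelled region set to its TAC."""
    voxels = img.voxels.copy()
    for region, tac in region_tacs.items():
        if tac.schedule != img.schedule:
            raise ValueError(f"{region}: TAC schedule differs from image schedule")
        voxels[labels.mask(region)] = tac.values
    return DynamicImage(voxels=voxels, voxel_size_mm=img.voxel_size_mm,
                        schedule=img.schedule)


#: Two-tissue target kinetics with slow dissociation (k4 << k2): specific
#: binding has not equilibrated by 90 min, the realistic model mismatch that
#: makes reference-tissue BPND drift with scan duration.
DEFAULT_2T_MISMATCH = Tissue2TParams(K1=0.9, k2=0.35, k3=0.07, k4=0.006)


def simulate_2t_cohort(
    n: int,
    p2t: Tissue2TParams = DEFAULT_2T_MISMATCH,
    param_cv: float = 0.10,
    noise: NoiseModel | None = None,
    seed: int = 0,
    genotype: str = "WT",
    schedule: FrameSchedule | None = None,
    aif: AIFParams = DEFAULT_AIF,
    ref: Tissue1TParams = DEFAULT_REF_TISSUE,
) -> list[ScanRecord]:
    """Cohort whose striatum follows two-tissue kinetics (model mismatch).

    Each subject's (K1, k2, k3, k4) are jittered by a truncated-normal
    factor with CV ``param_cv``; the cerebellum stays one-tissue. Used to
    study how reference-tissue fits drift with scan duration when the
    target is not truly one-tissue.
    """
    from .tac import make_default_schedule

    schedule = schedule or make_default_schedule()
    noise = noise or NoiseModel()
    t = fine_grid(schedule.duration_min)
    cp = feng_aif(t, aif)
    ref_curve = simulate_1t(cp, ref, t)
    scans = []
    for si in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(si,)))
        f = np.clip(1.0 + param_cv * rng.normal(size=4), 0.2, None)
        p = Tissue2TParams(
            K1=p2t.K1 * f[0], k2=p2t.k2 * f[1], k3=p2t.k3 * f[2], k4=p2t.k4 * f[3]
        )
        tgt_curve = simulate_2t(cp, p, t)
        tacs = {
            "striatum": frame_average(tgt_curve, t, schedule, "striatum"),
            "cerebellum": frame_average(ref_curve, t, schedule, "cerebellum"),
        }
        if noise.alpha > 0:
            for ri, region in enumerate(sorted(tacs)):
                nm = NoiseModel(
                    alpha=noise.alpha,
                    halflife_min=noise.halflife_min,
                    seed=int(
                        np.random.SeedSequence(seed, spawn_key=(si, 1, ri))
                        .generate_state(1)[0] % 2**31
                    ),
                )
                tacs[region] = add_noise(tacs[region], nm)
        scans.append(
            ScanRecord(
                subject_id=f"{genotype}{si + 1:02d}",
                genotype=genotype,
                session="test",
                tacs=tacs,
            )
        )
    return scans


@dataclass(frozen=True)
class GroupSpec:
    """Per-genotype cohort parameters (between-subject truncated normals)."""

    n: int
    bpnd_mean: float
    bpnd_sd: float
    r1_mean: float = 1.0
    r1_sd: float = 0.05


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: genotype groups, sessions, retest perturbation, seed.

    ``retest_sd_frac`` is the within-subject SD of the retest parameters as
    a fraction of the subject's own value; it models day-to-day biological
    plus procedural variability not captured by TAC noise.
    """

    groups: dict = field(default_factory=dict)
    sessions: int = 1
    retest_sd_frac: float = 0.03
    seed: int = 0


@dataclass
class SimulatedCohort:
    scans: list
    truth: pd.DataFrame


def _trunc_draw(rng, mean, sd):
    if sd == 0:
        return float(mean)
    a = (0.0 - mean) / sd
    return float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def simulate_cohort(
    spec: CohortSpec,
    schedule: FrameSchedule | None = None,
    aif: AIFParams = DEFAULT_AIF,
    ref: Tissue1TParams = DEFAULT_REF_TISSUE,
    noise: NoiseModel | None = None,
) -> SimulatedCohort:
    """Generate a (possibly paired test-retest) cohort of regional scans.

    Per subject, BPND and R1 are drawn from the genotype's truncated-normal
    distributions; the striatum follows the reference-tissue forward model
    with k2 = R1*k2' and the cerebellum is the shared one-tissue reference
    curve. Retest sessions perturb the subject's parameters by
    ``retest_sd_frac``. Seeding fans out per subject/session, so enlarging
    the cohort never reshuffles existing subjects.
    """
    from .tac import make_default_schedule

    schedule = schedule or make_default_schedule()
    noise = noise or NoiseModel()
    t = fine_grid(schedule.duration_min)
    cp = feng_aif(t, aif)
    ref_curve = simulate_1t(cp, ref, t)
    session_names = ["test", "retest"][: spec.sessions]

    scans: list[ScanRecord] = []
    truth_rows = []
    for gi, (genotype, g) in enumerate(spec.groups.items()):
        for si in range(g.n):
            ss = np.random.SeedSequence(spec.seed, spawn_key=(gi, si, 0))
            rng = np.random.default_rng(ss)
            bpnd_base = _trunc_draw(rng, g.bpnd_mean, g.bpnd_sd)
            r1_base = _trunc_draw(rng, g.r1_mean, g.r1_sd)
            subject_id = f"{genotype}{si + 1:02d}"
            for sess_i, session in enumerate(session_names):
                ss_sess = np.random.SeedSequence(
                    spec.seed, spawn_key=(gi, si, 1, sess_i)
                )
                rng_s = np.random.default_rng(ss_sess)
                if sess_i == 0 or spec.retest_sd_frac == 0:
                    bpnd, r1 = bpnd_base, r1_base
                else:
                    bpnd = max(bpnd_base * (1 + spec.retest_sd_frac * rng_s.normal()), 0.0)
                    r1 = max(r1_base * (1 + spec.retest_sd_frac * rng_s.normal()), 0.0)
                truth = SRTMTruth(r1=r1, k2=r1 * ref.k2, bpnd=bpnd)
                target = srtm_forward(ref_curve, truth, t)
                tacs = {
                    "striatum": frame_average(target, t, schedule, "striatum"),
                    "cerebellum": frame_average(ref_curve, t, schedule, "cerebellum"),
                }
                if noise.alpha > 0:
                    for ri, region in enumerate(sorted(tacs)):
                        nm = NoiseModel(
                            alpha=noise.alpha,
                            halflife_min=noise.halflife_min,
                            seed=int(
                                np.random.SeedSequence(
                                    spec.seed, spawn_key=(gi, si, 2, sess_i, ri)
                                ).generate_state(1)[0]
                                % 2**31
                            ),
                        )
                        tacs[region] = add_noise(tacs[region], nm)
                scans.append(
                    ScanRecord(
                        subject_id=subject_id,
                        genotype=genotype,
                        session=session,
                        tacs=tacs,
                    )
                )
                truth_rows.append(
                    {
                        "subject_id": subject_id,
                        "genotype": genotype,
                        "session": session,
                        "bpnd_true": bpnd,
                        "r1_true": r1,
                        "k2_true": truth.k2,
                    }
                )
    return SimulatedCohort(scans=scans, truth=pd.DataFrame(truth_rows))
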