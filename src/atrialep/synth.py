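"""Synthetic inputs with ground truth for every downstream stage.

Three generators:

* :func:`gen_ecg` — multi-beat 12-lead ECGs (1 kHz) with parameterised
  P-wave duration/amplitude/morphology, powerline and broadband noise,
  returning exact beat-level fiducial annotations.
* :func:`gen_wavefront` — travelling activation wavefronts (planar,
  radial, or two-wave collision) on a surface mesh, sampled by
  irregularly placed electrodes that record biphasic unipolar
  electrograms whose steepest negative slope falls exactly on the true
  LAT, plus the true CV vector at every electrode.
* :func:`gen_cohort` — two Gaussian samples with specified moments,
  emulating a two-group cohort feature table.

All generators are deterministic for a fixed seed.

The synthetic P wave is a Gaussian pulse whose width parameter is tied to
the requested duration through the 5%-of-peak crossing: the annotated
onset/offset are exactly the instants where the pulse reaches 5% of its
peak, the same operational definition used by the delineator.  The
synthetic unipolar electrogram is the derivative of a Gaussian centred on
the local activation time, i.e. an R/S biphasic deflection whose maximum
negative slope is exactly at the LAT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.spatial import cKDTree

import trimesh

from .egm import EgmDataset
from .mesh import SurfaceMesh, flat_rectangle
from .pwave import STANDARD_LEADS, EcgRecording

# 5%-of-peak crossing of a unit Gaussian: exp(-x^2/2) = 0.05 at
# x = sqrt(2 ln 20), so a Gaussian P wave of "duration" d has
# sigma = d / (2 sqrt(2 ln 20)).
_P_CROSS = 2.0 * np.sqrt(2.0 * np.log(20.0))

# typical sinus P amplitudes (mV) per standard lead
_DEFAULT_P_AMP = {
    "I": 0.08, "II": 0.12, "III": 0.06, "aVR": -0.10, "aVL": 0.03,
    "aVF": 0.09, "V1": 0.06, "V2": 0.07, "V3": 0.08, "V4": 0.08,
    "V5": 0.07, "V6": 0.06,
}
_DEFAULT_R_AMP = {
    "I": 0.7, "II": 1.2, "III": 0.6, "aVR": -0.9, "aVL": 0.3, "aVF": 0.9,
    "V1": 0.4, "V2": 0.8, "V3": 1.1, "V4": 1.4, "V5": 1.2, "V6": 0.9,
}


@dataclass
class EcgSynthSpec:
    n_leads: int = 12
    fs: float = 1000.0
    duration_s: float = 30.0
    heart_rate_bpm: float = 60.0
    p_duration_ms: float = 110.0
    pr_interval_ms: float = 160.0
    p_amplitude_mv: dict[str, float] | None = None
    p_morphology: str = "gaussian"          # or "biphasic_v1"
    noise_sd_mv: float = 0.0
    powerline_hz: float | None = None       # 50, 60 or None
    powerline_amp_mv: float = 0.05
    drift_mv_per_s: float = 0.0
    qrs_half_width_ms: float = 50.0         # QRS onset is R - this
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0 or self.heart_rate_bpm <= 0:
            raise ValueError("fs, duration and heart rate must be positive")
        if self.p_duration_ms >= self.pr_interval_ms:
            raise ValueError("p_duration must be shorter than the PR interval")
        if self.p_morphology not in ("gaussian", "biphasic_v1"):
            raise ValueError(f"unknown p_morphology {self.p_morphology!r}")


@dataclass
class EcgGroundTruth:
    r_times_ms: np.ndarray
    p_onset_ms: np.ndarray
    p_offset_ms: np.ndarray
    p_duration_ms: float
    pr_interval_ms: float

    def to_json(self) -> str:
        return json.dumps({
            "r_times_ms": self.r_times_ms.tolist(),
            "p_onset_ms": self.p_onset_ms.tolist(),
            "p_offset_ms": self.p_offset_ms.tolist(),
            "p_duration_ms": self.p_duration_ms,
            "pr_interval_ms": self.pr_interval_ms,
        })


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def gen_ecg(spec: EcgSynthSpec) -> tuple[EcgRecording, EcgGroundTruth]:
    """Synthesize an annotated 12-lead sinus-rhythm ECG."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs * 1000.0          # ms
    period = 60000.0 / spec.heart_rate_bpm
    first_r = 450.0
    r_times = np.arange(first_r, spec.duration_s * 1000.0 - 50.0, period)
    if len(r_times) == 0:
        raise ValueError("duration too short to contain one beat")

    leads = STANDARD_LEADS[:spec.n_leads]
    p_amp = dict(_DEFAULT_P_AMP)
    if spec.p_amplitude_mv:
        p_amp.update(spec.p_amplitude_mv)

    sig = np.zeros((len(leads), n))
    sigma_p = spec.p_duration_ms / _P_CROSS
    qrs_onsets = r_times - spec.qrs_half_width_ms
    p_onsets = qrs_onsets - spec.pr_interval_ms
    p_centers = p_onsets + spec.p_duration_ms / 2.0

    for li, name in enumerate(leads):
        amp_p = p_amp.get(name, 0.08)
        amp_r = _DEFAULT_R_AMP.get(name, 1.0)
        x = np.zeros(n)
        for rt, pc in zip(r_times, p_centers):
            if spec.p_morphology == "biphasic_v1" and name == "V1":
                # positive then negative lobe, each half-duration wide
                s2 = sigma_p / 2.0
                x += abs(amp_p) * _gauss(t, pc - spec.p_duration_ms / 4.0, s2)
                x -= abs(amp_p) * _gauss(t, pc + spec.p_duration_ms / 4.0, s2)
            else:
                x += amp_p * _gauss(t, pc, sigma_p)
            x += amp_r * _gauss(t, rt, 12.0)          # R wave
            x -= 0.25 * amp_r * _gauss(t, rt + 30.0, 9.0)   # S wave
            x += 0.25 * abs(amp_r) * _gauss(t, rt + 300.0, 45.0)  # T wave
        sig[li] = x

    if spec.powerline_hz:
        phase = rng.uniform(0, 2 * np.pi)
        sig += spec.powerline_amp_mv * np.sin(
            2 * np.pi * spec.powerline_hz * t / 1000.0 + phase)
    if spec.drift_mv_per_s:
        sig += spec.drift_mv_per_s * (t / 1000.0)
    if spec.noise_sd_mv > 0:
        sig += rng.normal(0.0, spec.noise_sd_mv, size=sig.shape)

    rec = EcgRecording(samples=sig, fs=fs, lead_names=list(leads),
                       patient_id=f"synth-{spec.seed}")
    truth = EcgGroundTruth(
        r_times_ms=r_times, p_onset_ms=p_onsets,
        p_offset_ms=p_onsets + spec.p_duration_ms,
        p_duration_ms=spec.p_duration_ms,
        pr_interval_ms=spec.pr_interval_ms)
    return rec, truth


# ---------------------------------------------------------------------------
# wavefronts

@dataclass
class WavefrontSynthSpec:
    mesh: SurfaceMesh = field(default_factory=flat_rectangle)
    electrode_density_per_cm2: float = 15.0
    wave_kind: str = "planar"          # planar | radial | collision
    speed_m_per_s: float = 0.5
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    focus_xyz: tuple[float, float, float] | None = None
    egm_fs_hz: float = 953.6
    egm_width_ms: float = 10.0
    egm_amp_mv: float = 1.0
    noise_sd_mv: float = 0.0
    lat_noise_sd_ms: float = 0.0
    cs_reference_time_ms: float = 20.0
    activation_delay_ms: float = 30.0   # first activation after the reference
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_m_per_s <= 0:
            raise ValueError("speed must be positive")
        if self.wave_kind not in ("planar", "radial", "collision"):
            raise ValueError(f"unknown wave_kind {self.wave_kind!r}")


@dataclass
class WaveGroundTruth:
    lat_ms: np.ndarray             # per electrode, relative to the CS reference
    cv_vectors: np.ndarray         # (n, 3) m/s true local CV
    speed_m_per_s: float
    cs_distal_time_ms: float       # wave arrival at the distal-CS proxy point
    collision_coord_mm: float | None = None   # position of the collision line
    collision_axis: np.ndarray | None = None

    def to_json(self) -> str:
        return json.dumps({
            "lat_ms": self.lat_ms.tolist(),
            "cv_vectors": self.cv_vectors.tolist(),
            "speed_m_per_s": self.speed_m_per_s,
            "cs_distal_time_ms": self.cs_distal_time_ms,
            "collision_coord_mm": self.collision_coord_mm,
        })


def poisson_disk_sample(mesh: SurfaceMesh, density_per_cm2: float,
                        seed: int = 0) -> np.ndarray:
    """Blue-noise electrode placement on a mesh by dart throwing.

    Mimics the irregular coverage of basket/multi-spline catheters: area-
    weighted random candidates are accepted greedily subject to a minimum
    mutual distance derived from the requested density.
    """
    area_mm2 = float(mesh.face_areas().sum())
    n_target = max(4, int(round(density_per_cm2 * area_mm2 / 100.0)))
    r_min = 0.75 * np.sqrt(area_mm2 / n_target)
    tm = mesh.as_trimesh()
    rng = np.random.default_rng(seed)
    cand, _ = trimesh.sample.sample_surface(
        tm, 20 * n_target, seed=int(rng.integers(2 ** 31)))
    accepted: list[np.ndarray] = []
    for p in cand:
        if len(accepted) >= n_target:
            break
        if not accepted:
            accepted.append(p)
            continue
        d, _ = cKDTree(np.asarray(accepted)).query(p)
        if d >= r_min:
            accepted.append(p)
    return np.asarray(accepted)


def _true_lat_field(spec: WavefrontSynthSpec, xyz: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Absolute activation times (ms) and true CV vectors at points."""
    s = spec.speed_m_per_s                      # mm/ms
    t0 = spec.cs_reference_time_ms + spec.activation_delay_ms
    nhat = np.asarray(spec.direction, dtype=float)
    nhat = nhat / np.linalg.norm(nhat)
    proj = xyz @ nhat
    lo, hi = float(proj.min()), float(proj.max())
    if spec.wave_kind == "planar":
        lat = t0 + (proj - lo) / s
        cv = np.tile(s * nhat, (len(xyz), 1))
        return lat, cv, None
    if spec.wave_kind == "radial":
        focus = (np.asarray(spec.focus_xyz, dtype=float)
                 if spec.focus_xyz is not None else xyz.mean(axis=0))
        d = xyz - focus
        r = np.linalg.norm(d, axis=1)
        lat = t0 + r / s
        with np.errstate(invalid="ignore", divide="ignore"):
            rhat = np.where(r[:, None] > 1e-9, d / r[:, None], 0.0)
        cv = s * rhat
        return lat, cv, None
    # collision: two opposing planar waves released simultaneously from the
    # two extreme faces along nhat, meeting mid-domain
    lat_a = t0 + (proj - lo) / s
    lat_b = t0 + (hi - proj) / s
    lat = np.minimum(lat_a, lat_b)
    mid = 0.5 * (lo + hi)
    cv = np.where((proj < mid)[:, None], s * nhat, -s * nhat)
    return lat, cv, mid


def gen_wavefront(spec: WavefrontSynthSpec
                  ) -> tuple[EgmDataset, WaveGroundTruth]:
    """Synthesize electrograms for a travelling wavefront with known CV."""
    spec.mesh.validate()
    rng = np.random.default_rng(spec.seed)
    xyz = poisson_disk_sample(spec.mesh, spec.electrode_density_per_cm2,
                              seed=spec.seed + 1)
    lat_abs, cv_true, mid = _true_lat_field(spec, xyz)
    if spec.lat_noise_sd_ms > 0:
        lat_abs = lat_abs + rng.normal(0.0, spec.lat_noise_sd_ms,
                                       size=lat_abs.shape)

    fs = spec.egm_fs_hz
    sigma = spec.egm_width_ms / 4.0
    # leave room after the last activation, and never shorter than the
    # downstream conditioning filters can handle (SG span 201 samples)
    dur = max(float(lat_abs.max()) + 6 * sigma + spec.activation_delay_ms,
              260.0)
    n = int(round(dur / 1000.0 * fs))
    t = np.arange(n) / fs * 1000.0

    # R/S biphasic deflection: derivative-of-Gaussian, peak |amp| = egm_amp,
    # steepest negative slope exactly at the (possibly jittered) LAT
    arg = (t[None, :] - lat_abs[:, None]) / sigma
    sig = spec.egm_amp_mv * (-arg) * np.exp(0.5 - 0.5 * arg ** 2)
    if spec.noise_sd_mv > 0:
        sig = sig + rng.normal(0.0, spec.noise_sd_mv, size=sig.shape)

    cs_arg = (t - spec.cs_reference_time_ms) / sigma
    cs_sig = spec.egm_amp_mv * (-cs_arg) * np.exp(0.5 - 0.5 * cs_arg ** 2)

    ds = EgmDataset(signals=sig, fs=fs, electrode_xyz=xyz, mesh=spec.mesh,
                    cs_reference_time_ms=spec.cs_reference_time_ms,
                    cs_signal=cs_sig)
    nhat = np.asarray(spec.direction, dtype=float)
    nhat = nhat / np.linalg.norm(nhat)
    # distal-CS proxy: the wave's arrival at the far end of the domain
    cs_distal = float(lat_abs.max() - spec.cs_reference_time_ms)
    truth = WaveGroundTruth(
        lat_ms=lat_abs - spec.cs_reference_time_ms,
        cv_vectors=cv_true, speed_m_per_s=spec.speed_m_per_s,
        cs_distal_time_ms=cs_distal, collision_coord_mm=mid,
        collision_axis=nhat if mid is not None else None)
    return ds, truth


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortSynthSpec:
    n_group_a: int
    n_group_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("need n >= 2 per group")
        if self.sd_a <= 0 or self.sd_b <= 0:
            raise ValueError("sd must be positive")


def gen_cohort(spec: CohortSynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """Two Gaussian samples with the requested moments."""
    rng = np.random.default_rng(spec.seed)
    a = rng.normal(spec.mean_a, spec.sd_a, size=spec.n_group_a)
    b = rng.normal(spec.mean_b, spec.sd_b, size=spec.n_group_b)
    return a, b


# ---------------------------------------------------------------------------
# file interchange

def write_ecg_csv(rec: EcgRecording, truth: EcgGroundTruth,
                  csv_path, json_path=None) -> None:
    """ECG as CSV (rows = samples, columns = leads) + JSON annotations."""
    header = ",".join(rec.lead_names)
    np.savetxt(csv_path, rec.samples.T, delimiter=",", header=header,
               comments="")
    if json_path is not None:
        with open(json_path, "w") as fh:
            fh.write(truth.to_json())


def read_ecg_csv(csv_path, fs: float = 1000.0,
                 patient_id: str = "") -> EcgRecording:
    with open(csv_path) as fh:
        leads = fh.readline().strip().split(",")
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    return EcgRecording(samples=data.T, fs=fs, lead_names=leads,
                        patient_id=patient_id)


def write_egm_h5(ds: EgmDataset, path, truth: WaveGroundTruth | None = None
                 ) -> None:
    """EgmDataset as HDF5 (/signals, /electrode_xyz, /fs, /cs_reference)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=ds.signals)
        f.create_dataset("electrode_xyz", data=ds.electrode_xyz)
        f.create_dataset("fs", data=ds.fs)
        f.create_dataset("cs_reference", data=ds.cs_reference_time_ms)
        f.create_dataset("mesh/vertices", data=ds.mesh.vertices)
        f.create_dataset("mesh/faces", data=ds.mesh.faces)
        if ds.cs_signal is not None:
            f.create_dataset("cs_signal", data=ds.cs_signal)
        if truth is not None:
            f.attrs["ground_truth"] = truth.to_json()


def read_egm_h5(path) -> EgmDataset:
    with h5py.File(path, "r") as f:
        return EgmDataset(
            signals=f["signals"][()], fs=float(f["fs"][()]),
            electrode_xyz=f["electrode_xyz"][()],
            mesh=SurfaceMesh(f["mesh/vertices"][()], f["mesh/faces"][()]),
            cs_reference_time_ms=float(f["cs_reference"][()]),
            cs_signal=f["cs_signal"][()] if "cs_signal" in f else None)
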