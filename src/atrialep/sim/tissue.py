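"""Monodomain reaction–diffusion tissue simulation on a 2-D sheet.

Numerics: operator splitting per time step — explicit anisotropic
finite-difference diffusion with no-flux boundaries (sub-cycled when the
explicit stability bound requires it), Rush–Larsen exponential updates
for the voltage-dependent gates, forward Euler for concentrations and
the membrane reaction term.  All purely voltage-dependent quantities
(gate steady states, the per-step Rush–Larsen factors, and the
voltage-dependent current factors) are tabulated on a fine Vm grid and
linearly interpolated inside the compiled kernel.

Fibres run along x: longitudinal coupling lives on x-edges, transverse
coupling on y-edges.  Fibrosis is modelled as transverse electrical
decoupling — a randomly selected fraction of y-edges is removed.  The
heterogeneous Na+ loss-of-function is node-wise: a randomly selected
fraction of nodes carries a reduced g_Na factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage

from .crn import (AF_REMODELING, BASELINE, BRS_GNA_FACTOR, CA_O, CM, CMDN_MAX,
                  CSQN_MAX, FARADAY, G_B_CA, G_B_NA, G_CAL, G_K1, G_KR, G_KS,
                  G_NA, G_TO, I_NACA_MAX, I_NAK_MAX, I_PCA_MAX, I_UP_MAX,
                  CA_UP_MAX, K_O, K_REL, K_SAT, K_UP, KM_CA, KM_CMDN, KM_CSQN,
                  KM_K_O, KM_NA, KM_NA_I, KM_TRPN, NA_O, RESTING_STATE, RTF,
                  TAU_F_CA, TAU_TR, TAU_U, TRPN_MAX, V_I, V_REL, V_UP,
                  IonicParams, gate_inf_tau, voltage_factors)

# state indices of the 12 voltage gates within the 21-variable CRN state
_GATE_STATE_IDX = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 15])

_INACA_DENOM = (KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O)
_INAK_KFACT = K_O / (K_O + KM_K_O)


@dataclass
class TissueModel:
    """2-D sheet of nx*ny nodes at spacing h_mm with per-edge coupling."""

    nx: int
    ny: int
    h_mm: float
    d_long: float                  # mm^2/ms
    d_trans: float
    gna_factor: np.ndarray         # per node
    brs_mask: np.ndarray           # per node
    gx: np.ndarray                 # x-edge coupling, 1/ms ((nx-1)*ny open,
                                   # nx*ny when periodic in x)
    gy: np.ndarray                 # y-edge coupling nx*(ny-1), 1/ms
    fib_edge_mask: np.ndarray      # per y-edge
    seed: int = 0
    brs_fraction: float = 0.0
    fibrosis_fraction: float = 0.0
    periodic_x: bool = False       # cylindrical sheet: closed path along fibers

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    def node_index(self, ix: int, iy: int) -> int:
        return ix * self.ny + iy


def build_tissue(nx: int = 201, ny: int = 201, h_mm: float = 0.25,
                 brs_fraction: float = 0.0, fibrosis_fraction: float = 0.0,
                 brs_gna_factor: float = BRS_GNA_FACTOR,
                 d_long: float = 0.3, d_trans: float = 0.06,
                 periodic_x: bool = False, seed: int = 0) -> TissueModel:
    """Assemble a tissue sheet with random BrS and fibrosis masks.

    Exactly ``floor(fraction * n)`` elements are flagged in each mask
    (nodes for the g_Na reduction, transverse edges for fibrosis), via a
    seeded shuffle, so masks are reproducible.  With ``periodic_x`` the
    sheet closes on itself along the fibre direction (a cylinder), the
    idealized stand-in for the closed atrial surface on which macro-
    reentry can circulate.
    """
    for name, frac in (("brs_fraction", brs_fraction),
                       ("fibrosis_fraction", fibrosis_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if d_long <= d_trans:
        raise ValueError("anisotropy requires d_long > d_trans")
    rng = np.random.default_rng(seed)
    n = nx * ny
    gna = np.ones(n)
    brs_mask = np.zeros(n, dtype=bool)
    n_brs = int(np.floor(brs_fraction * n))
    if n_brs:
        brs_mask[rng.permutation(n)[:n_brs]] = True
        gna[brs_mask] = brs_gna_factor
    n_te = nx * (ny - 1)
    fib = np.zeros(n_te, dtype=bool)
    n_fib = int(np.floor(fibrosis_fraction * n_te))
    if n_fib:
        fib[rng.permutation(n_te)[:n_fib]] = True
    n_xe = nx * ny if periodic_x else (nx - 1) * ny
    gx = np.full(n_xe, d_long / h_mm ** 2)
    gy = np.full(n_te, d_trans / h_mm ** 2)
    gy[fib] = 0.0
    return TissueModel(nx=nx, ny=ny, h_mm=h_mm, d_long=d_long,
                       d_trans=d_trans, gna_factor=gna, brs_mask=brs_mask,
                       gx=gx, gy=gy, fib_edge_mask=fib, seed=seed,
                       brs_fraction=brs_fraction,
                       fibrosis_fraction=fibrosis_fraction,
                       periodic_x=periodic_x)


# ---------------------------------------------------------------------------
# voltage lookup tables

def build_lut(dt: float, vmin: float = -120.0, vmax: float = 80.0,
              dv: float = 0.02) -> tuple[np.ndarray, float, float]:
    """Tabulate gate steady states, per-step Rush–Larsen factors and
    voltage-dependent current factors on a uniform Vm grid."""
    V = np.arange(vmin, vmax + dv / 2, dv)
    inf, tau = gate_inf_tau(V)
    lut = np.empty((30, len(V)))
    lut[0:12] = inf
    lut[12:24] = np.exp(-dt / tau)
    lut[24:30] = voltage_factors(V)
    return np.ascontiguousarray(lut), vmin, 1.0 / dv


@njit(inline="always")
def _lk(lut, k, i0, w):
    return lut[k, i0] + w * (lut[k, i0 + 1] - lut[k, i0])


@njit(cache=True, fastmath=True)
def _advance(Vm, gates, fca, u, v, conc, gna_eff, gk1_eff, gto_eff, gcal_eff,
             gx, gy, nx, ny, dt, nsteps, ndiff, lut, vmin, inv_dv,
             stim, lap, rl_fca, rl_u, periodic):
    N = nx * ny
    nv = lut.shape[1]
    sub = dt / ndiff
    for _ in range(nsteps):
        # --- diffusion (no-flux boundaries; x wraps when periodic),
        #     sub-cycled for stability
        for _rep in range(ndiff):
            for ix in range(nx):
                base = ix * ny
                for iy in range(ny):
                    i = base + iy
                    acc = 0.0
                    if ix > 0:
                        acc += gx[(ix - 1) * ny + iy] * (Vm[i - ny] - Vm[i])
                    elif periodic:
                        acc += gx[(nx - 1) * ny + iy] \
                            * (Vm[(nx - 1) * ny + iy] - Vm[i])
                    if ix < nx - 1:
                        acc += gx[ix * ny + iy] * (Vm[i + ny] - Vm[i])
                    elif periodic:
                        acc += gx[ix * ny + iy] * (Vm[iy] - Vm[i])
                    if iy > 0:
                        acc += gy[ix * (ny - 1) + iy - 1] * (Vm[i - 1] - Vm[i])
                    if iy < ny - 1:
                        acc += gy[ix * (ny - 1) + iy] * (Vm[i + 1] - Vm[i])
                    lap[i] = acc
            for i in range(N):
                Vm[i] += sub * lap[i]
        # --- reaction
        for i in range(N):
            V = Vm[i]
            ti = (V - vmin) * inv_dv
            if ti < 0.0:
                ti = 0.0
            elif ti > nv - 2.0:
                ti = nv - 2.0
            i0 = int(ti)
            w8 = ti - i0

            for k in range(12):
                infk = _lk(lut, k, i0, w8)
                rlk = _lk(lut, 12 + k, i0, w8)
                gates[k, i] = infk + (gates[k, i] - infk) * rlk
            m = gates[0, i]
            h = gates[1, i]
            j = gates[2, i]
            oa = gates[3, i]
            oi = gates[4, i]
            ua = gates[5, i]
            ui = gates[6, i]
            xr = gates[7, i]
            xs = gates[8, i]
            d = gates[9, i]
            f = gates[10, i]
            wg = gates[11, i]

            Nai = conc[0, i]
            Ki = conc[1, i]
            Cai = conc[2, i]
            Caup = conc[3, i]
            Carel = conc[4, i]

            fca_inf = 1.0 / (1.0 + Cai / 0.00035)
            fca[i] = fca_inf + (fca[i] - fca_inf) * rl_fca
            fc = fca[i]

            gkur = _lk(lut, 24, i0, w8)
            ik1f = _lk(lut, 25, i0, w8)
            ikrf = _lk(lut, 26, i0, w8)
            fnak = _lk(lut, 27, i0, w8)
            expg = _lk(lut, 28, i0, w8)
            expg1 = _lk(lut, 29, i0, w8)

            ena = RTF * np.log(NA_O / Nai)
            ek = RTF * np.log(K_O / Ki)
            eca = 0.5 * RTF * np.log(CA_O / Cai)

            ina = gna_eff[i] * m * m * m * h * j * (V - ena)
            ik1 = gk1_eff * ik1f * (V - ek)
            ito = gto_eff * oa * oa * oa * oi * (V - ek)
            ikur = gkur * ua * ua * ua * ui * (V - ek)
            ikr = G_KR * xr * ikrf * (V - ek)
            iks = G_KS * xs * xs * (V - ek)
            ical = gcal_eff * d * f * fc * (V - 65.0)
            inak = I_NAK_MAX * fnak * _INAK_KFACT \
                / (1.0 + (KM_NA_I / Nai) ** 1.5)
            inaca = I_NACA_MAX * (expg * Nai * Nai * Nai * CA_O
                                  - expg1 * NA_O * NA_O * NA_O * Cai) \
                / (_INACA_DENOM * (1.0 + K_SAT * expg1))
            ibna = G_B_NA * (V - ena)
            ibca = G_B_CA * (V - eca)
            ipca = I_PCA_MAX * Cai / (0.0005 + Cai)

            irel = K_REL * u[i] * u[i] * v[i] * wg * (Carel - Cai)
            itr = (Caup - Carel) / TAU_TR
            iup = I_UP_MAX / (1.0 + K_UP / Cai)
            iupleak = I_UP_MAX * Caup / CA_UP_MAX

            Fn = 1e-12 * V_REL * irel \
                - (5e-13 / FARADAY) * (0.5 * ical * CM - 0.2 * inaca * CM)
            s = 1.0 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 1.367e-15))
            u_inf = s
            tau_v = 1.91 + 2.09 * s
            v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 1.367e-15))
            u[i] = u_inf + (u[i] - u_inf) * rl_u
            v[i] = v_inf + (v[i] - v_inf) * np.exp(-dt / tau_v)

            iion = (ina + ik1 + ito + ikur + ikr + iks + ical + inak
                    + inaca + ibna + ibca + ipca)

            conc[0, i] = Nai + dt * (-3.0 * inak - 3.0 * inaca - ibna - ina) \
                * CM / (FARADAY * V_I)
            conc[1, i] = Ki + dt * (2.0 * inak - ik1 - ito - ikur - ikr - iks) \
                * CM / (FARADAY * V_I)
            b1 = (2.0 * inaca - ipca - ical - ibca) * CM \
                / (2.0 * FARADAY * V_I) \
                + (V_UP * (iupleak - iup) + irel * V_REL) / V_I
            b2 = 1.0 + TRPN_MAX * KM_TRPN / ((Cai + KM_TRPN) * (Cai + KM_TRPN)) \
                + CMDN_MAX * KM_CMDN / ((Cai + KM_CMDN) * (Cai + KM_CMDN))
            conc[2, i] = Cai + dt * b1 / b2
            conc[3, i] = Caup + dt * (iup - iupleak - itr * V_REL / V_UP)
            conc[4, i] = Carel + dt * (itr - irel) \
                / (1.0 + CSQN_MAX * KM_CSQN
                   / ((Carel + KM_CSQN) * (Carel + KM_CSQN)))

            Vm[i] = V + dt * (stim[i] - iion)


# ---------------------------------------------------------------------------
# wave counting

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def count_waves(vm_field: np.ndarray, threshold: float = -60.0,
                connectivity: int = 4, periodic_x: bool = False) -> int:
    """Number of fibrillation waves in a Vm snapshot.

    A wave is a contiguous region of nodes with Vm above the -60 mV
    threshold; contiguity is 4-neighbour on the grid (8-neighbour when
    ``connectivity=8``).  With ``periodic_x`` regions touching across the
    x seam of a cylindrical sheet are merged.
    """
    mask = np.asarray(vm_field) > threshold
    if connectivity == 4:
        structure = _STRUCT4
    elif connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask, structure=structure)
    if not periodic_x or n <= 1:
        return int(n)
    # union labels joined across the seam
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in zip(labels[0], labels[-1]):
        if a > 0 and b > 0:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    return len({find(k) for k in range(1, n + 1)})


def count_waves_mesh(values: np.ndarray, faces: np.ndarray,
                     threshold: float = -60.0) -> int:
    """Wave count on a triangulated surface: connected components of the
    suprathreshold vertex set, with adjacency via shared triangle edges."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    values = np.asarray(values)
    mask = values > threshold
    if not mask.any():
        return 0
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]])
    keep = mask[edges[:, 0]] & mask[edges[:, 1]]
    edges = edges[keep]
    n = len(values)
    adj = coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
                     shape=(n, n))
    n_comp, labels = connected_components(adj + adj.T, directed=False)
    # count only components containing suprathreshold vertices
    return int(len(np.unique(labels[mask])))


# ---------------------------------------------------------------------------
# simulation driver

class TissueSim:
    """Stateful monodomain simulation over a :class:`TissueModel`."""

    def __init__(self, model: TissueModel, ionic: IonicParams = BASELINE,
                 dt: float = 0.02, allow_subcycle: bool = True):
        self.model = model
        self.ionic = ionic
        self.dt = float(dt)
        n = model.n_nodes
        self.Vm = np.full(n, RESTING_STATE[0])
        self.gates = np.ascontiguousarray(
            np.tile(RESTING_STATE[_GATE_STATE_IDX][:, None], (1, n)))
        self.fca = np.full(n, RESTING_STATE[12])
        self.u = np.full(n, RESTING_STATE[13])
        self.v = np.full(n, RESTING_STATE[14])
        self.conc = np.ascontiguousarray(
            np.tile(RESTING_STATE[16:21][:, None], (1, n)))
        self._lap = np.empty(n)
        self._gna_eff = G_NA * ionic.gna_factor * model.gna_factor
        self._lut, self._vmin, self._inv_dv = build_lut(self.dt)
        self._rl_fca = float(np.exp(-self.dt / TAU_F_CA))
        self._rl_u = float(np.exp(-self.dt / TAU_U))
        self.time_ms = 0.0

        # explicit-diffusion stability: sub*max(node conductance sum) <= 0.5
        max_sum = self._max_conductance_sum()
        if max_sum > 0:
            self.ndiff = max(1, int(np.ceil(self.dt * max_sum / 0.5)))
        else:
            self.ndiff = 1
        if self.ndiff > 1 and not allow_subcycle:
            raise ValueError(
                f"dt={self.dt} ms violates the explicit diffusion stability "
                f"bound dt <= {0.5 / max_sum:.4f} ms; enable sub-cycling or "
                "reduce dt")

    def _max_conductance_sum(self) -> float:
        m = self.model
        total = np.zeros(m.n_nodes)
        n_xcols = m.nx if m.periodic_x else m.nx - 1
        for ix in range(n_xcols):
            for iy in range(m.ny):
                g = m.gx[ix * m.ny + iy]
                total[ix * m.ny + iy] += g
                total[((ix + 1) % m.nx) * m.ny + iy] += g
        for ix in range(m.nx):
            for iy in range(m.ny - 1):
                g = m.gy[ix * (m.ny - 1) + iy]
                total[ix * m.ny + iy] += g
                total[ix * m.ny + iy + 1] += g
        return float(total.max()) if len(total) else 0.0

    def step(self, n_steps: int = 1, stim: np.ndarray | None = None) -> None:
        """Advance ``n_steps`` reaction steps with a fixed stimulus field."""
        if stim is None:
            stim = np.zeros(self.model.n_nodes)
        _advance(self.Vm, self.gates, self.fca, self.u, self.v, self.conc,
                 self._gna_eff, G_K1 * self.ionic.f_gk1,
                 G_TO * self.ionic.f_gto, G_CAL * self.ionic.f_gcal,
                 self.model.gx, self.model.gy, self.model.nx, self.model.ny,
                 self.dt, n_steps, self.ndiff, self._lut, self._vmin,
                 self._inv_dv, stim, self._lap, self._rl_fca, self._rl_u,
                 self.model.periodic_x)
        self.time_ms += n_steps * self.dt

    def vm_grid(self) -> np.ndarray:
        return self.Vm.reshape(self.model.nx, self.model.ny)

    def run(self, duration_ms: float,
            stim_schedule: list[tuple[float, float, float, np.ndarray]] = (),
            frame_ms: float = 1.0, record_vm: bool = False,
            wave_threshold: float = -60.0,
            check_finite_every: int = 200) -> dict:
        """Advance the simulation, recording wave counts each frame.

        ``stim_schedule`` entries are ``(onset_ms, duration_ms, amp, nodes)``
        with ``amp`` in pA/pF applied to the listed node indices.
        Returns a dict with ``times_ms``, ``wave_counts`` and optionally
        ``vm`` snapshots at the frame cadence (1 ms by default, matching
        the per-millisecond wave counting).
        """
        steps_per_frame = max(1, int(round(frame_ms / self.dt)))
        n_frames = int(round(duration_ms / frame_ms))
        counts = np.zeros(n_frames, dtype=int)
        times = np.zeros(n_frames)
        snaps = [] if record_vm else None
        stim = np.zeros(self.model.n_nodes)
        t_start = self.time_ms
        for fr in range(n_frames):
            t = t_start + fr * frame_ms
            stim[:] = 0.0
            for onset, dur, amp, nodes in stim_schedule:
                if onset <= t < onset + dur:
                    stim[nodes] += amp
            self.step(steps_per_frame, stim)
            counts[fr] = count_waves(self.vm_grid(), wave_threshold,
                                     periodic_x=self.model.periodic_x)
            times[fr] = self.time_ms
            if record_vm:
                snaps.append(self.Vm.copy())
            if fr % check_finite_every == 0 and not np.isfinite(self.Vm).all():
                raise FloatingPointError(
                    f"non-finite Vm at t={self.time_ms:.1f} ms "
                    "(time step too large?)")
        out = {"times_ms": times, "wave_counts": counts}
        if record_vm:
            out["vm"] = np.asarray(snaps)
        return out


# ---------------------------------------------------------------------------
# pacing protocol

def make_schedule(train_duration_ms: float = 2500.0,
                  start_interval_ms: float = 200.0,
                  end_interval_ms: float = 120.0,
                  first_onset_ms: float = 10.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Burst-pacing schedule: linearly decreasing coupling intervals whose
    sum approximates the train duration within one interval.

    Returns ``(onsets_ms, intervals_ms)``; ``onsets`` are the stimulus
    times, ``intervals`` the gaps following each stimulus.
    """
    if end_interval_ms > start_interval_ms:
        raise ValueError("end interval must not exceed start interval")
    if end_interval_ms <= 0:
        raise ValueError("intervals must be positive")
    if train_duration_ms < end_interval_ms:
        raise ValueError("train shorter than a single pacing interval")
    if end_interval_ms == start_interval_ms:
        warnings.warn("constant pacing train (start == end interval)",
                      stacklevel=2)
    n = max(1, int(round(2.0 * train_duration_ms
                         / (start_interval_ms + end_interval_ms))))
    intervals = np.linspace(start_interval_ms, end_interval_ms, n)
    onsets = first_onset_ms + np.concatenate(([0.0], np.cumsum(intervals[:-1])))
    return onsets, intervals


def pacing_sites(model: TissueModel, n_sites: int = 20,
                 margin_frac: float = 0.15) -> list[int]:
    """Evenly spaced lattice of pacing node indices over the sheet."""
    cols = int(np.ceil(np.sqrt(n_sites)))
    rows = int(np.ceil(n_sites / cols))
    xs = np.linspace(margin_frac, 1 - margin_frac, cols)
    ys = np.linspace(margin_frac, 1 - margin_frac, rows)
    sites = []
    for y in ys:
        for x in xs:
            ix = int(round(x * (model.nx - 1)))
            iy = int(round(y * (model.ny - 1)))
            sites.append(model.node_index(ix, iy))
    return sites[:n_sites]


def _stim_patch(model: TissueModel, node: int,
                half_mm: float = 0.75) -> np.ndarray:
    """Node indices of a square stimulus patch centred on ``node``."""
    r = max(1, int(round(half_mm / model.h_mm)))
    ix0, iy0 = divmod(node, model.ny)
    idx = []
    for ix in range(max(0, ix0 - r), min(model.nx, ix0 + r + 1)):
        for iy in range(max(0, iy0 - r), min(model.ny, iy0 + r + 1)):
            idx.append(ix * model.ny + iy)
    return np.asarray(idx)


@dataclass
class SiteResult:
    site: int
    sustained: bool
    mean_wave_count: float
    wave_counts: np.ndarray
    post_start_ms: float


@dataclass
class AfProtocolResult:
    site_results: list[SiteResult]
    inducibility_rate: float
    mean_wave_count: float            # over sustained runs (all runs if none)
    mean_wave_counts: np.ndarray      # per site

    @property
    def n_induced(self) -> int:
        return sum(r.sustained for r in self.site_results)


def run_af_protocol(model: TissueModel, ionic: IonicParams = AF_REMODELING,
                    sites: list[int] | None = None, n_sites: int = 20,
                    train_duration_ms: float = 2500.0,
                    start_interval_ms: float = 200.0,
                    end_interval_ms: float = 120.0,
                    post_ms: float = 1000.0,
                    stim_amp: float = 40.0, stim_dur_ms: float = 2.0,
                    patch_half_mm: float = 0.75, dt: float = 0.02,
                    wave_threshold: float = -60.0,
                    sustained_window_ms: float = 100.0) -> AfProtocolResult:
    """Burst-pace every site and score AF induction.

    Per site: a fresh simulation from rest, a 2.5-s (by default) train of
    stimuli with progressively shorter coupling intervals, then a
    stimulus-free observation period.  Induction is sustained when
    suprathreshold activity persists through the final
    ``sustained_window_ms`` of the simulation; conduction-pattern
    complexity is the wave count per millisecond averaged over the whole
    post-pacing period.
    """
    if sites is None:
        sites = pacing_sites(model, n_sites)
    onsets, intervals = make_schedule(train_duration_ms, start_interval_ms,
                                      end_interval_ms)
    train_end = float(onsets[-1] + intervals[-1])
    total = train_end + post_ms
    results = []
    for site in sites:
        sim = TissueSim(model, ionic, dt=dt)
        patch = _stim_patch(model, site, patch_half_mm)
        schedule = [(float(t), stim_dur_ms, stim_amp, patch) for t in onsets]
        rec = sim.run(total, stim_schedule=schedule,
                      wave_threshold=wave_threshold)
        post = rec["times_ms"] > train_end
        counts = rec["wave_counts"][post]
        tail = rec["times_ms"] > total - sustained_window_ms
        sustained = bool(np.all(rec["wave_counts"][tail] > 0)) \
            and bool(np.any(counts > 0))
        results.append(SiteResult(
            site=site, sustained=sustained,
            mean_wave_count=float(counts.mean()) if len(counts) else 0.0,
            wave_counts=counts, post_start_ms=train_end))
    rate = float(np.mean([r.sustained for r in results]))
    mwc_all = np.array([r.mean_wave_count for r in results])
    sus = [r.mean_wave_count for r in results if r.sustained]
    mwc = float(np.mean(sus)) if sus else float(mwc_all.mean())
    return AfProtocolResult(site_results=results, inducibility_rate=rate,
                            mean_wave_count=mwc, mean_wave_counts=mwc_all)


def compare_scenarios(results: dict[str, AfProtocolResult]) -> pd.DataFrame:
    """Pairwise scenario statistics: Welch t on per-site mean wave counts,
    Fisher exact on induced counts, Bonferroni-adjusted p-values."""
    from .. import stats as ast

    names = list(results)
    if len(names) < 2:
        raise ValueError("need at least 2 scenarios to compare")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = results[names[i]], results[names[j]]
            try:
                p_t = ast.welch_t(a.mean_wave_counts, b.mean_wave_counts).p
            except ValueError:
                p_t = 1.0 if np.allclose(a.mean_wave_counts.mean(),
                                         b.mean_wave_counts.mean()) else np.nan
            na, nb = len(a.site_results), len(b.site_results)
            tab = np.array([[a.n_induced, na - a.n_induced],
                            [b.n_induced, nb - b.n_induced]])
            try:
                p_f = ast.contingency(tab, method="fisher")
            except ValueError:
                # degenerate margin (e.g. every site induced in both arms):
                # identical proportions carry no evidence of a difference
                p_f = 1.0 if a.inducibility_rate == b.inducibility_rate \
                    else np.nan
            rows.append({"scenario_a": names[i], "scenario_b": names[j],
                         "mean_waves_a": float(a.mean_wave_counts.mean()),
                         "mean_waves_b": float(b.mean_wave_counts.mean()),
                         "inducibility_a": a.inducibility_rate,
                         "inducibility_b": b.inducibility_rate,
                         "p_wave_count": p_t, "p_inducibility": p_f})
    df = pd.DataFrame(rows)
    for col in ("p_wave_count", "p_inducibility"):
        finite = df[col].notna().to_numpy()
        adj = np.full(len(df), np.nan)
        if finite.any():
            adj[finite] = np.minimum(1.0, len(df) * df[col].to_numpy()[finite])
        df[col + "_bonferroni"] = adj
    return df


# ---------------------------------------------------------------------------
# single-cell utilities

def simulate_cell(ionic: IonicParams = BASELINE, bcl_ms: float = 1000.0,
                  n_beats: int = 4, dt: float = 0.02,
                  stim_amp: float = 30.0, stim_dur_ms: float = 2.0,
                  frame_ms: float = 1.0) -> np.ndarray:
    """Paced single-cell Vm trace at the frame cadence (default 1 ms)."""
    model = TissueModel(nx=1, ny=1, h_mm=1.0, d_long=1.0, d_trans=0.5,
                        gna_factor=np.ones(1), brs_mask=np.zeros(1, bool),
                        gx=np.zeros(0), gy=np.zeros(0),
                        fib_edge_mask=np.zeros(0, bool))
    sim = TissueSim(model, ionic, dt=dt)
    node = np.array([0])
    schedule = [(k * bcl_ms + 5.0, stim_dur_ms, stim_amp, node)
                for k in range(n_beats)]
    rec = sim.run(n_beats * bcl_ms, stim_schedule=schedule,
                  frame_ms=frame_ms, record_vm=True)
    return rec["vm"][:, 0]


def apd90(trace_mv: np.ndarray, frame_ms: float = 1.0,
          bcl_ms: float = 1000.0) -> float:
    """APD90 of the last complete action potential in a paced Vm trace:
    time from the -40 mV upstroke crossing until repolarization to 90% of
    the beat's amplitude."""
    v = np.asarray(trace_mv, dtype=float)
    up = np.nonzero((v[1:] > -40.0) & (v[:-1] <= -40.0))[0] + 1
    if len(up) == 0:
        return np.nan
    # use the last upstroke with a full diastolic tail available
    c = None
    for cand in up[::-1]:
        if len(v) - cand >= int(0.9 * bcl_ms / frame_ms):
            c = int(cand)
            break
    if c is None:
        c = int(up[-1])
    pre = v[max(0, c - int(50 / frame_ms)):c]
    v_rest = float(pre.min()) if len(pre) else float(v.min())
    seg = v[c:]
    v_peak = float(seg.max())
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    pk = int(np.argmax(seg))
    below = np.nonzero(seg[pk:] <= v90)[0]
    if len(below) == 0:
        return np.nan
    return float((pk + below[0]) * frame_ms)
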