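"""Desk-scale AF-susceptibility scenario definitions.

The clinical-scale experiment compares AF induction between a substrate
with heterogeneous Na+ loss-of-function (70% g_Na reduction on half of
the nodes, the BrS-like substrate) and a control substrate without it,
both carrying AF electrical remodeling and a configurable degree of
fibrotic transverse decoupling.

The desk-scale domain is a cylindrical strip: 120 mm closed perimeter
along the fibre direction and a 2-mm transverse extent at 0.5-mm node
spacing.  The closed path stands in for the macroscopic reentrant
circuits of the real atria; a sheet with no-flux boundaries at desk size
cannot sustain reentry regardless of substrate, whereas on the closed
path sustained circulation requires a unidirectional-block event during
the pacing train plus an excitation wavelength that fits the perimeter —
both properties of the slowed, dispersed, heterogeneous substrate and of
neither the control substrate nor a too-short path.
"""

from __future__ import annotations

import numpy as np

from .crn import AF_REMODELING, IonicParams
from .tissue import AfProtocolResult, TissueModel, build_tissue, run_af_protocol

# desk-scale defaults (see docs/methods.md for rationale)
DESK_NX = 240            # 120 mm perimeter at 0.5 mm
DESK_NY = 5              # 2 mm transverse extent
DESK_H_MM = 0.5
DESK_D_LONG = 0.15       # mm^2/ms -> planar CV ~0.45 m/s, matching the
DESK_D_TRANS = 0.03      # slow CVs measured in diseased atria
DESK_TRAIN_MS = 2500.0
DESK_START_INTERVAL_MS = 200.0
DESK_END_INTERVAL_MS = 125.0
DESK_POST_MS = 800.0
DESK_STIM_AMP = 60.0
DESK_SITES = (20, 140)   # pacing-site x-indices (mid-strip row)


def planar_strand_cv(gna_factor: float = 1.0, h_mm: float = 0.5,
                     length_mm: float = 40.0, d_long: float = 0.3,
                     ionic: IonicParams | None = None,
                     stim_amp: float = 40.0) -> float:
    """Planar conduction velocity (m/s) on a thin homogeneous strand.

    A line stimulus at one end; CV is measured between activation at the
    1/4 and 3/4 marks (-40 mV upstroke crossing at 1-ms resolution).
    Returns NaN on propagation failure.
    """
    from .tissue import TissueSim

    nx = int(length_mm / h_mm) + 1
    ny = 3
    model = build_tissue(nx=nx, ny=ny, h_mm=h_mm, d_long=d_long,
                         d_trans=d_long / 5, seed=0)
    if ionic is None:
        ionic = IonicParams(f_gto=0.40, f_gcal=0.35, f_gk1=2.00,
                            gna_factor=gna_factor)
    sim = TissueSim(model, ionic)
    stim_nodes = np.array([model.node_index(ix, iy)
                           for ix in range(max(2, int(1.5 / h_mm)))
                           for iy in range(ny)])
    rec = sim.run(150.0, stim_schedule=[(2.0, 2.0, stim_amp, stim_nodes)],
                  record_vm=True)
    vm = rec["vm"]
    i1, i2 = int(nx * 0.25), int(nx * 0.75)

    def t_act(ix):
        tr = vm[:, model.node_index(ix, 1)]
        idx = np.nonzero(tr > -40.0)[0]
        return float(idx[0]) if len(idx) else np.nan

    t1, t2 = t_act(i1), t_act(i2)
    if not np.isfinite(t1) or not np.isfinite(t2) or t2 <= t1:
        return float("nan")
    return (i2 - i1) * h_mm / (t2 - t1)


def desk_model(brs: bool, fibrosis_fraction: float = 0.5,
               seed: int = 0) -> TissueModel:
    """Cylindrical desk-scale tissue for one scenario arm."""
    return build_tissue(nx=DESK_NX, ny=DESK_NY, h_mm=DESK_H_MM,
                        brs_fraction=0.5 if brs else 0.0,
                        fibrosis_fraction=fibrosis_fraction,
                        d_long=DESK_D_LONG, d_trans=DESK_D_TRANS,
                        periodic_x=True, seed=seed)


def run_desk_protocol(model: TissueModel,
                      ionic: IonicParams = AF_REMODELING,
                      sites: list[int] | None = None) -> AfProtocolResult:
    """Burst-pace the desk-scale model with the scaled-down train."""
    if sites is None:
        sites = [model.node_index(ix, model.ny // 2) for ix in DESK_SITES]
    return run_af_protocol(model, ionic, sites=sites,
                           train_duration_ms=DESK_TRAIN_MS,
                           start_interval_ms=DESK_START_INTERVAL_MS,
                           end_interval_ms=DESK_END_INTERVAL_MS,
                           post_ms=DESK_POST_MS, stim_amp=DESK_STIM_AMP,
                           patch_half_mm=1.5)


def compare_desk_scenarios(seed: int, fibrosis_fraction: float = 0.5
                           ) -> dict[str, AfProtocolResult]:
    """One replicate: BrS vs control at matched fibrosis and seed."""
    out = {}
    for name, brs in (("brs", True), ("control", False)):
        model = desk_model(brs, fibrosis_fraction, seed=seed)
        out[name] = run_desk_protocol(model)
    return out
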