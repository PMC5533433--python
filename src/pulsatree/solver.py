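"""Time integration of the 1-D tree to a periodic steady state.

The solver discretizes every segment on a uniform grid (spacing bounded by
``dx_max``), calibrates a Langewouters wall law at each node from the
decade's PWV(diameter) relation, and advances whole cardiac cycles with
the compiled MacCormack kernel until the pressure waveforms at the
monitored sites repeat to within ``periodicity_tol`` from one cycle to the
next.  The converged cycle is resampled to a uniform 1 kHz grid and
returned as one :class:`~pulsatree.records.WaveRecord` per named site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .ageing import AgeingProfile, ConfiguredModel, ageing_profile, apply_profile
from .heart import DEFAULT_SHAPE, ElastanceShape, ValveState, elastance
from .records import WaveRecord
from .tree import ArterialTree, validate_tree
from .units import MMHG
from .wall import MU_BLOOD, P_REF, RHO_BLOOD, pwv_from_diameter

log = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "SimulationResult",
    "run_to_periodic",
    "simulate_decade",
    "run_prescribed_inflow",
    "calibrate_filling",
]


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings of the 1-D scheme."""

    dx_max: float = 2.5e-3  # m
    CFL: float = 0.9
    n_cycles_max: int = 20
    n_cycles_min: int = 4
    periodicity_tol: float = 0.5 * MMHG  # Pa
    rho: float = RHO_BLOOD
    mu: float = MU_BLOOD
    zeta_v: float = 6.0  # velocity-profile friction coefficient
    wall_visc_tau: float = 0.002  # s; Voigt time constant Gamma*C_A of the wall
    wall_visc_tau_small: float | None = None  # s; muscular vessels (d <= 1 cm); None = same
    p_init: float = 75.0 * MMHG  # initial uniform pressure
    sample_rate: float = 1000.0  # Hz, analysis resampling
    c_headroom_pressure: float = 170.0 * MMHG  # pressure at which dt is sized
    u_headroom: float = 2.5  # m/s advective margin for dt sizing

    def __post_init__(self):
        if not 0 < self.CFL <= 1:
            raise ValueError("CFL must lie in (0, 1]")
        if self.periodicity_tol <= 0:
            raise ValueError("periodicity_tol must be positive")


class CFLError(RuntimeError):
    pass


@dataclass
class _Mesh:
    """Flat-array discretization consumed by the kernel."""

    seg_ids: list  # segment id per kernel index
    seg_start: np.ndarray
    seg_n: np.ndarray
    dx: np.ndarray
    Am: np.ndarray
    P0n: np.ndarray
    P1n: np.ndarray
    gam: np.ndarray
    jparent: np.ndarray
    jcoff: np.ndarray
    jchild: np.ndarray
    tseg: np.ndarray
    tR1: np.ndarray
    tR2: np.ndarray
    tC: np.ndarray
    tPout: np.ndarray
    sites: dict  # label -> flat node index
    n_nodes: int


def discretize(tree: ArterialTree, age: float | None, config: SolverConfig,
               extra_sites: dict | None = None) -> _Mesh:
    """Grid the tree and calibrate nodal wall laws.

    With ``age`` given, every node gets a wall calibrated at the reference
    pressure so its local PWV follows the decade relation at the local
    (tapered) diameter.  With ``age=None`` each segment must carry an
    explicit :class:`WallLaw`, applied uniformly along the segment (the
    raw-physics test harness path).
    """
    diags = validate_tree(tree, dx_max=config.dx_max if age is not None else 1e9)
    diags = [d for d in diags if d.rule != "grid-spacing"]
    if diags:
        raise ValueError("invalid tree: " + "; ".join(str(d) for d in diags))

    root = tree.root_id
    order = [root] + [sid for sid in sorted(tree.segments) if sid != root]
    idx_of = {sid: k for k, sid in enumerate(order)}

    seg_start, seg_n, dxs = [], [], []
    Am, P0n, P1n, gam = [], [], [], []
    pos = 0
    for sid in order:
        s = tree.segments[sid]
        n = s.grid_nodes(config.dx_max)
        seg_start.append(pos)
        seg_n.append(n)
        dxs.append(s.length / (n - 1))
        d = s.diameters(n)
        if age is not None:
            a_ref = np.pi * d * d / 4.0
            c_ref = np.array([pwv_from_diameter(di, age) for di in d])
            am = 2.0 * a_ref
            p1 = 2.0 * config.rho * c_ref ** 2 / np.pi
            Am.append(am)
            P0n.append(np.full(n, P_REF))
            P1n.append(p1)
            if s.wall is not None and s.wall.gamma > 0:
                g = np.full(n, s.wall.gamma)
            elif config.wall_visc_tau > 0:
                # Voigt relaxation time Gamma*C_A; muscular (small) vessels
                # are lossier than the elastic aorta
                tau_lo = config.wall_visc_tau
                tau_hi = (config.wall_visc_tau_small
                          if config.wall_visc_tau_small is not None else tau_lo)
                tau = np.interp(d, [1e-2, 2e-2], [tau_hi, tau_lo])
                g = tau * np.pi * p1 / am
            else:
                g = np.zeros(n)
            gam.append(g)
        else:
            if s.wall is None:
                raise ValueError(f"segment {sid} has no wall law and no age was given")
            Am.append(np.full(n, s.wall.A_m))
            P0n.append(np.full(n, s.wall.P0))
            P1n.append(np.full(n, s.wall.P1))
            gam.append(np.full(n, s.wall.gamma))
        pos += n

    seg_start = np.asarray(seg_start, dtype=np.int64)
    seg_n = np.asarray(seg_n, dtype=np.int64)

    jparent, jchild, jcoff = [], [], [0]
    for sid in order:
        kids = tree.children_of(sid)
        if kids:
            jparent.append(idx_of[sid])
            jchild.extend(idx_of[k] for k in kids)
            jcoff.append(len(jchild))

    leaves = tree.leaves()
    tseg = np.asarray([idx_of[l] for l in leaves], dtype=np.int64)
    tR1 = np.asarray([tree.terminals[l].R1 for l in leaves])
    tR2 = np.asarray([tree.terminals[l].R2 for l in leaves])
    tC = np.asarray([tree.terminals[l].C for l in leaves])
    tPout = np.asarray([tree.terminals[l].P_out for l in leaves])

    sites = {}
    all_sites = dict(tree.named_sites)
    if extra_sites:
        all_sites.update(extra_sites)
    for label, (sid, frac) in all_sites.items():
        k = idx_of[sid]
        sites[label] = int(seg_start[k] + round(frac * (seg_n[k] - 1)))

    return _Mesh(
        seg_ids=order, seg_start=seg_start, seg_n=seg_n,
        dx=np.asarray(dxs), Am=np.concatenate(Am), P0n=np.concatenate(P0n),
        P1n=np.concatenate(P1n), gam=np.concatenate(gam),
        jparent=np.asarray(jparent, dtype=np.int64),
        jcoff=np.asarray(jcoff, dtype=np.int64),
        jchild=np.asarray(jchild, dtype=np.int64),
        tseg=tseg, tR1=tR1, tR2=tR2, tC=tC, tPout=tPout,
        sites=sites, n_nodes=pos)


def _stable_dt(mesh: _Mesh, config: SolverConfig) -> float:
    """CFL-bounded time step sized at a pressure/velocity headroom."""
    dt = np.inf
    for k in range(len(mesh.seg_n)):
        sl = slice(mesh.seg_start[k], mesh.seg_start[k] + mesh.seg_n[k])
        a = _area_at(config.c_headroom_pressure, mesh, sl)
        c = _speed_at(a, mesh, sl, config.rho)
        dt = min(dt, config.CFL * mesh.dx[k] / float(np.max(c) + config.u_headroom))
    return dt


def _area_at(p, mesh, sl):
    th = (p - mesh.P0n[sl]) / mesh.P1n[sl]
    return mesh.Am[sl] * (0.5 + np.arctan(th) / np.pi)


def _speed_at(a, mesh, sl, rho):
    x = np.clip(a / mesh.Am[sl] - 0.5, -0.499, 0.499)
    th = np.tan(np.pi * x)
    ca = mesh.Am[sl] / (np.pi * mesh.P1n[sl] * (1.0 + th * th))
    return np.sqrt(a / (rho * ca))


@dataclass
class SimulationResult:
    """Converged-run output bundle."""

    records: dict  # site -> WaveRecord (uniform 1 kHz over one period)
    converged: bool
    n_cycles: int
    residuals: list  # per-cycle max |P - P_prev| at monitored sites, Pa
    period: float
    dt: float
    co_mean: float  # mean aortic flow over the final cycle, m^3/s
    map_aortic: float  # time-averaged aortic-root pressure, Pa
    stroke_volume: float  # m^3
    edv: float
    esv: float
    mass_error: float  # |dV_tree - (V_in - V_out)| / stroke volume
    lv: dict = field(default_factory=dict)  # t, P_lv, Q_av, Q_mit, V at 1 kHz
    meta: dict = field(default_factory=dict)

    def cycles_to_converge(self, tol: float) -> int | None:
        """First cycle index (1-based) at which the residual drops below tol."""
        for i, r in enumerate(self.residuals):
            if r < tol:
                return i + 1
        return None


def _resample(t_raw, y, t_new, period):
    return np.interp(np.mod(t_new, period), t_raw, y, period=period)


def run_to_periodic(model_or_tree, profile: AgeingProfile | None = None, *,
                    valve: ValveState | None = None,
                    shape: ElastanceShape = DEFAULT_SHAPE,
                    config: SolverConfig | None = None,
                    ideal_valve: bool = False,
                    extra_sites: dict | None = None) -> SimulationResult:
    """Run successive cardiac cycles until the waveforms are periodic.

    Accepts a :class:`ConfiguredModel` (from :func:`apply_profile`) or a
    raw tree plus profile.  Returns records at every named site.
    """
    if isinstance(model_or_tree, ConfiguredModel):
        model = model_or_tree
    else:
        if profile is None:
            raise ValueError("profile required when passing a bare tree")
        model = apply_profile(model_or_tree, profile)
    config = config or SolverConfig()
    valve = valve or ValveState(rho=config.rho)
    profile = model.profile
    cardiac = profile.cardiac

    mesh = discretize(model.tree, profile.age, config, extra_sites)
    T = cardiac.period
    dt = _stable_dt(mesh, config)
    nsteps = int(np.ceil(T / dt))
    dt = T / nsteps

    N = mesh.n_nodes
    A = _area_at(config.p_init, mesh, slice(0, N)).copy()
    Q = np.zeros(N)
    P = np.empty(N)
    As = np.empty(N)
    Qs = np.empty(N)
    Ps = np.empty(N)
    dAdt = np.zeros(N)
    Aprev = np.zeros(N)
    tPc = np.full(len(mesh.tseg), config.p_init)

    t_steps = np.arange(nsteps) * dt
    E_arr = np.asarray(elastance(t_steps, cardiac, shape))
    Qin_arr = np.zeros(1)

    hp = np.array([cardiac.V0, cardiac.P_ven, cardiac.R_mitral,
                   valve.A_max, valve.l_eff, valve.K_vo, valve.K_vc, 1e-6])
    hs = np.array([cardiac.V0 + cardiac.P_ven / cardiac.E_ed, 0.0, 0.0])

    mode = _kernel.MODE_IDEAL_VALVE if ideal_valve else _kernel.MODE_VALVE
    visco = bool(np.any(mesh.gam > 0))
    fric_c = 2.0 * (config.zeta_v + 2.0) * np.pi * config.mu / config.rho

    mon_labels = list(mesh.sites)
    mon_idx = np.asarray([mesh.sites[l] for l in mon_labels], dtype=np.int64)
    M = len(mon_idx)
    P_mon = np.empty((nsteps, M))
    Q_mon = np.empty((nsteps, M))
    A_mon = np.empty((nsteps, M))
    lv_out = np.empty((nsteps, 4))

    residuals = []
    P_prev = None
    converged = False
    n_cycles = 0
    vol_io = np.zeros(2)
    mass_error = np.nan
    co = np.nan
    for cyc in range(config.n_cycles_max):
        vol_io[:] = 0.0
        vol_before = _tree_volume(A, mesh)
        try:
            max_cfl, max_seg = _kernel.run_cycle(
                A, Q, P, As, Qs, Ps, mesh.Am, mesh.P0n, mesh.P1n, mesh.gam, dAdt, Aprev,
                mesh.seg_start, mesh.seg_n, mesh.dx,
                mesh.jparent, mesh.jcoff, mesh.jchild,
                mesh.tseg, mesh.tR1, mesh.tR2, mesh.tC, mesh.tPout, tPc,
                mon_idx, E_arr, Qin_arr, hp, hs,
                mode, visco, dt, config.rho, fric_c,
                P_mon, Q_mon, A_mon, lv_out, vol_io)
        except ZeroDivisionError:
            raise CFLError(f"numerical instability during cycle {cyc + 1} "
                           "(state collapsed; CFL or parameter problem)")
        n_cycles = cyc + 1
        if max_cfl > 1.0:
            raise CFLError(
                f"CFL violated (number {max_cfl:.2f}) in segment "
                f"{mesh.seg_ids[max_seg]} during cycle {n_cycles}")
        if P_prev is not None:
            res = float(np.max(np.abs(P_mon - P_prev)))
            residuals.append(res)
            log.info("cycle %d: residual %.3f mmHg, CO %.2f L/min",
                     n_cycles, res / MMHG, np.mean(Q_mon[:, mon_labels.index('aortic_root')]
                                                   if 'aortic_root' in mon_labels else lv_out[:, 1])
                     * 6e4)
            if res < config.periodicity_tol and n_cycles >= config.n_cycles_min:
                converged = True
        P_prev = P_mon.copy()
        vol_after = _tree_volume(A, mesh)
        mass_error = abs((vol_after - vol_before) - (vol_io[0] - vol_io[1]))
        if converged:
            break

    # resample final cycle to the analysis rate
    fs = config.sample_rate
    n_out = int(round(T * fs))
    t_out = np.arange(n_out) / fs
    records = {}
    for m, label in enumerate(mon_labels):
        records[label] = WaveRecord(
            site=label, t=t_out,
            P=_resample(t_steps, P_mon[:, m], t_out, T),
            Q=_resample(t_steps, Q_mon[:, m], t_out, T),
            A=_resample(t_steps, A_mon[:, m], t_out, T),
            converged=converged,
            meta={"age": profile.age, "n_cycles": n_cycles})

    sv = float(np.sum(lv_out[:, 1]) * dt)  # ejected volume per cycle
    co = sv / T
    root_label = "aortic_root" if "aortic_root" in records else mon_labels[0]
    map_aortic = float(np.mean(P_mon[:, mon_labels.index(root_label)]))
    lv = {
        "t": t_out,
        "P_lv": _resample(t_steps, lv_out[:, 0], t_out, T),
        "Q_av": _resample(t_steps, lv_out[:, 1], t_out, T),
        "Q_mit": _resample(t_steps, lv_out[:, 2], t_out, T),
        "V": _resample(t_steps, lv_out[:, 3], t_out, T),
    }
    edv = float(np.max(lv_out[:, 3]))
    esv = float(np.min(lv_out[:, 3]))
    return SimulationResult(
        records=records, converged=converged, n_cycles=n_cycles,
        residuals=residuals, period=T, dt=dt, co_mean=co,
        map_aortic=map_aortic, stroke_volume=sv, edv=edv, esv=esv,
        mass_error=mass_error / max(sv, 1e-12), lv=lv,
        meta={"age": profile.age, "dt": dt, "nsteps": nsteps})


def _tree_volume(A, mesh):
    v = 0.0
    for k in range(len(mesh.seg_n)):
        sl = slice(mesh.seg_start[k], mesh.seg_start[k] + mesh.seg_n[k])
        v += float(np.trapezoid(A[sl], dx=mesh.dx[k]))
    return v


def simulate_decade(age: float, tree: ArterialTree | None = None, *,
                    config: SolverConfig | None = None,
                    valve: ValveState | None = None,
                    ideal_valve: bool = False,
                    r_mitral: float | None = None) -> SimulationResult:
    """Convenience wrapper: reference tree + decade profile + periodic run."""
    from .reference_tree import build_reference_tree

    tree = tree or build_reference_tree()
    profile = ageing_profile(age)
    if r_mitral is not None:
        from dataclasses import replace
        profile = replace(profile, cardiac=replace(profile.cardiac, R_mitral=r_mitral))
    model = apply_profile(tree, profile)
    return run_to_periodic(model, config=config, valve=valve, ideal_valve=ideal_valve)


def run_prescribed_inflow(tree: ArterialTree, q_of_t, T: float, *,
                          n_cycles: int = 1, config: SolverConfig | None = None,
                          extra_sites: dict | None = None,
                          p_init: float | None = None):
    """Raw-physics harness: drive the root with a prescribed inflow Q(t).

    Segments must carry explicit wall laws.  Returns (records, state) where
    records are the (final-cycle) site recordings at the solver rate and
    ``state`` exposes the flat mesh arrays for detailed inspection.
    """
    config = config or SolverConfig()
    if p_init is not None:
        from dataclasses import replace as _rep
        config = _rep(config, p_init=p_init)
    mesh = discretize(tree, None, config, extra_sites)
    dt = _stable_dt(mesh, config)
    nsteps = int(np.ceil(T / dt))
    dt = T / nsteps
    t_steps = np.arange(nsteps) * dt

    N = mesh.n_nodes
    A = _area_at(config.p_init, mesh, slice(0, N)).copy()
    Q = np.zeros(N)
    P = np.empty(N)
    As = np.empty(N)
    Qs = np.empty(N)
    Ps = np.empty(N)
    dAdt = np.zeros(N)
    Aprev = np.zeros(N)
    tPc = np.full(len(mesh.tseg), config.p_init)
    Qin_arr = np.asarray([q_of_t(t) for t in t_steps], dtype=float)
    E_arr = np.zeros(nsteps)
    hp = np.zeros(8)
    hs = np.zeros(3)
    visco = bool(np.any(mesh.gam > 0))
    fric_c = 2.0 * (config.zeta_v + 2.0) * np.pi * config.mu / config.rho

    mon_labels = list(mesh.sites)
    mon_idx = np.asarray([mesh.sites[l] for l in mon_labels], dtype=np.int64)
    M = max(len(mon_idx), 1)
    if len(mon_idx) == 0:
        mon_idx = np.asarray([0], dtype=np.int64)
        mon_labels = ["_root_node"]
    P_mon = np.empty((nsteps, M))
    Q_mon = np.empty((nsteps, M))
    A_mon = np.empty((nsteps, M))
    lv_out = np.empty((nsteps, 4))
    vol_io = np.zeros(2)

    for _ in range(n_cycles):
        vol_io[:] = 0.0
        try:
            max_cfl, max_seg = _kernel.run_cycle(
                A, Q, P, As, Qs, Ps, mesh.Am, mesh.P0n, mesh.P1n, mesh.gam, dAdt, Aprev,
                mesh.seg_start, mesh.seg_n, mesh.dx,
                mesh.jparent, mesh.jcoff, mesh.jchild,
                mesh.tseg, mesh.tR1, mesh.tR2, mesh.tC, mesh.tPout, tPc,
                mon_idx, E_arr, Qin_arr, hp, hs,
                _kernel.MODE_PRESCRIBED_Q, visco, dt, config.rho, fric_c,
                P_mon, Q_mon, A_mon, lv_out, vol_io)
        except ZeroDivisionError:
            raise CFLError("numerical instability (state collapsed; CFL violation)")
        if max_cfl > 1.0 or not np.isfinite(max_cfl):
            raise CFLError(f"CFL violated in segment {mesh.seg_ids[max_seg]}")

    records = {}
    for m, label in enumerate(mon_labels):
        records[label] = WaveRecord(site=label, t=t_steps, P=P_mon[:, m].copy(),
                                    Q=Q_mon[:, m].copy(), A=A_mon[:, m].copy())
    state = {"mesh": mesh, "A": A, "Q": Q, "dt": dt, "tPc": tPc, "vol_io": vol_io}
    return records, state


def calibrate_filling(age: float, tree: ArterialTree | None = None, *,
                      target_co: float | None = None, tol: float = 0.004,
                      max_iter: int = 10, config: SolverConfig | None = None):
    """Solve for the mitral resistance delivering the prescribed CO.

    Secant iteration on log R_mitral against the full 1-D model; returns
    (R_mitral, SimulationResult at the solution).
    """
    from .ageing import CARDIAC_OUTPUT
    from .reference_tree import build_reference_tree

    target = target_co or CARDIAC_OUTPUT
    tree = tree or build_reference_tree()
    base = ageing_profile(age)
    x0 = np.log(base.cardiac.R_mitral)

    def co_of(x):
        res = simulate_decade(age, tree, config=config, r_mitral=float(np.exp(x)))
        return res.co_mean, res

    c0, res0 = co_of(x0)
    if abs(c0 / target - 1) < tol:
        return float(np.exp(x0)), res0
    x1 = x0 + (0.3 if c0 > target else -0.3)
    c1, res1 = co_of(x1)
    for _ in range(max_iter):
        if abs(c1 / target - 1) < tol:
            return float(np.exp(x1)), res1
        denom = (c1 - c0)
        if denom == 0:
            break
        x2 = x1 - (c1 - target) * (x1 - x0) / denom
        x0, c0 = x1, c1
        x1 = x2
        c1, res1 = co_of(x1)
    return float(np.exp(x1)), res1
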