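"""Stochastic step-by-step simulation of NHEJ double-strand-break repair.

Each DSB contributes two DNA ends that progress through a
protein-recruitment state machine.  Both compartments share the early
steps: Ku70/80 binds the free end (rate ``k1``), then DNA-PKcs is
recruited to form the DNA-PK complex (``k2``).  When two DNA-PK-bound
ends come within the synapsis distance a synaptic complex forms and the
pair advances as one entity: DNA-PK autophosphorylation (``k3``), then

* fast (resection-independent) pathway: XRCC4/Ligase IV recruitment
  (``k4``) and ligation (``k5``);
* slow (resection-dependent) pathway: end resection and processing by
  CtIP/EXO1/Artemis (``k9``, ``k10``), fill-in synthesis by pol mu/lambda
  (``k11``) and ligation (``k12``).  The CtIP (``k7``) and EXO1 (``k8``)
  recruitment clocks start at Ku binding; Artemis arrives together with
  DNA-PKcs.  Without Artemis the slow pathway stalls before resection
  and those DSBs never complete.

Ends perform a Brownian random walk (diffusion coefficient ``d_pre``)
inside a reflecting spherical nucleus until synapsis.  Within each time
step a state advances with probability ``1 - exp(-k dt)``, the exact
single-step waiting probability of an exponential clock.  Synapsis picks
the nearest eligible end within range, so ends may join a wrong partner
at high DSB density (misrepair).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import curve_fit

from .damage import DamageSet, Pathway

__all__ = [
    "RepairParams",
    "RepairEvent",
    "RepairTrajectory",
    "step_transition_probability",
    "random_walk_step",
    "simulate_repair",
    "repair_curve",
    "fit_biexponential",
    "write_event_log_tsv",
    "write_repair_curve_tsv",
]


@dataclass(frozen=True)
class RepairParams:
    """Rate constants (per second) and numerical settings of the repair model.

    Rates are reciprocals of the characteristic protein-recruitment
    times; ``k6`` is an alternate long-time constant kept configurable
    but unused by the default chain mapping.
    """

    k1: float = 1 / 0.1       # Ku70/80 binding
    k2: float = 1 / 3.0       # DNA-PKcs recruitment
    k3: float = 1 / 72.0      # DNA-PK autophosphorylation
    k4: float = 1 / 180.0     # XRCC4/LigIV recruitment (fast)
    k5: float = 1 / 240.0     # ligation (fast)
    k6: float = 1 / 720.0     # alternate long-time constant (unused by default)
    k7: float = 1 / 7.0       # CtIP recruitment (slow, clock from Ku binding)
    k8: float = 1 / 1.2       # EXO1 recruitment (slow, clock from Ku binding)
    k9: float = 1 / 1000.0    # resection step 1 (slow)
    k10: float = 1 / 450.0    # resection step 2 (slow)
    k11: float = 1 / 14400.0  # fill-in by pol mu/lambda (slow)
    k12: float = 1 / 6545.0   # ligation (slow)
    synapsis_distance: float = 100.0  # nm
    d_pre: float = 1.0        # nm^2/s, end diffusion before synapsis
    d_post: float = 100.0     # nm^2/s, pair diffusion after synapsis
    dt: float = 0.01          # s, base (finest) time step
    t_max: float = 24 * 3600.0  # s
    artemis_active: bool = True
    adaptive_dt: bool = True  # grow the step as fast processes finish
    step_accuracy: float = 0.02  # max k*dt when adapting
    synapsis_dt_cap: float = 1.0  # s, step cap while unsynapsed eligible ends exist
    dt_max: float = 60.0      # s, absolute step cap

    def rates(self) -> np.ndarray:
        return np.array(
            [self.k1, self.k2, self.k3, self.k4, self.k5, self.k6,
             self.k7, self.k8, self.k9, self.k10, self.k11, self.k12]
        )

    def __post_init__(self) -> None:
        if np.any(self.rates() <= 0):
            raise ValueError("all rate constants must be > 0")
        if self.synapsis_distance <= 0 or self.dt <= 0 or self.t_max <= 0:
            raise ValueError("synapsis_distance, dt and t_max must be > 0")
        kdt = float(self.rates().max() * self.dt)
        if kdt > 0.5:
            raise ValueError(
                f"dt={self.dt} does not resolve the fastest rate (k*dt={kdt:.2f} > 0.5)"
            )
        if kdt > 0.1:
            warnings.warn(
                f"k*dt = {kdt:.2f} > 0.1; step probabilities are coarse", stacklevel=2
            )


@dataclass(frozen=True)
class RepairEvent:
    dsb_id: int
    completion_time: float  # s
    pathway: Pathway
    correct_partner: bool


@dataclass
class RepairTrajectory:
    """Unrepaired-DSB count over time plus the per-DSB completion log."""

    time_grid: np.ndarray       # s, event-resolved grid
    unrepaired_count: np.ndarray
    events: list[RepairEvent]
    n_initial: int
    t_max: float

    def unrepaired_at(self, t: float | np.ndarray) -> np.ndarray:
        """Piecewise-constant unrepaired count at arbitrary times."""
        idx = np.searchsorted(self.time_grid, np.asarray(t, dtype=float), side="right") - 1
        return self.unrepaired_count[np.clip(idx, 0, len(self.unrepaired_count) - 1)]


def step_transition_probability(k: float, dt: float) -> float:
    """Probability that an exponential clock of rate ``k`` fires within ``dt``."""
    if k <= 0 or dt <= 0:
        raise ValueError("k and dt must be > 0")
    return -math.expm1(-k * dt)


def random_walk_step(
    coord: np.ndarray,
    diffusion: float,
    dt: float,
    rng: np.random.Generator,
    nucleus_radius: float | None = None,
) -> np.ndarray:
    """One Brownian step: Gaussian displacement of std sqrt(2 D dt) per axis.

    With ``nucleus_radius`` given, positions are reflected radially at
    the nuclear envelope.
    """
    if diffusion < 0:
        raise ValueError("diffusion must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    new = np.asarray(coord, dtype=float) + rng.normal(
        0.0, math.sqrt(2.0 * diffusion * dt), size=3
    )
    if nucleus_radius is not None:
        r = float(np.linalg.norm(new))
        if r > nucleus_radius:
            new = new * ((2.0 * nucleus_radius - r) / r)
    return new


# ---------------------------------------------------------------------------
# Stepping kernel.  End states: 0 FREE, 1 KU_BOUND, 2 DNAPK_BOUND (eligible
# for synapsis), 3 IN_PAIR.  Pair states: 0 SYNAPSED, 1 AUTOPHOSPHORYLATED,
# 2 fast XRCC4/LigIV bound | slow resection step 1 done, 3 RESECTED,
# 4 FILLED, 9 LIGATED.

@njit(cache=True)
def _repair_kernel(
    seed,
    coords0,       # (n_dsb, 3)
    slow,          # (n_dsb,) uint8
    radius,
    k,             # (12,) rates
    syn_dist,
    d_pre,
    dt_base,
    eps,
    syn_cap,
    dt_max,
    t_max,
    artemis_active,
):
    np.random.seed(seed)
    n_dsb = coords0.shape[0]
    n_ends = 2 * n_dsb
    pos = np.empty((n_ends, 3))
    estate = np.zeros(n_ends, dtype=np.int8)
    ctip = np.zeros(n_ends, dtype=np.int8)
    exo1 = np.zeros(n_ends, dtype=np.int8)
    partner = np.full(n_ends, -1, dtype=np.int64)
    lig_time = np.full(n_ends, np.inf)
    for d in range(n_dsb):
        for e in range(2):
            i = 2 * d + e
            pos[i, 0] = coords0[d, 0]
            pos[i, 1] = coords0[d, 1]
            pos[i, 2] = coords0[d, 2]
            if slow[d] == 0:
                ctip[i] = 1
                exo1[i] = 1

    max_pairs = n_dsb + 1
    pa = np.empty(max_pairs, dtype=np.int64)
    pb = np.empty(max_pairs, dtype=np.int64)
    pstate = np.empty(max_pairs, dtype=np.int8)
    pslow = np.empty(max_pairs, dtype=np.int8)
    n_pairs = 0

    syn2 = syn_dist * syn_dist
    t = 0.0
    while t < t_max:
        # --- fastest currently-active rate and synapsis bookkeeping ---
        kmax = 0.0
        n_elig = 0
        n_pre = 0
        for i in range(n_ends):
            s = estate[i]
            if s == 0:
                if k[0] > kmax:
                    kmax = k[0]
                n_pre += 1
            elif s == 1:
                if k[1] > kmax:
                    kmax = k[1]
                n_pre += 1
            elif s == 2:
                n_elig += 1
                n_pre += 1
            if s >= 1:
                if ctip[i] == 0 and k[6] > kmax:
                    kmax = k[6]
                if exo1[i] == 0 and k[7] > kmax:
                    kmax = k[7]
        for p in range(n_pairs):
            ps = pstate[p]
            if ps == 9:
                continue
            if ps == 0:
                kk = k[2]
            elif ps == 1:
                if pslow[p] == 0:
                    kk = k[3]
                else:
                    a, b = pa[p], pb[p]
                    gate = ctip[a] == 1 and ctip[b] == 1 and exo1[a] == 1 and exo1[b] == 1
                    kk = k[8] if (gate and artemis_active) else 0.0
            elif ps == 2:
                kk = k[4] if pslow[p] == 0 else k[9]
            elif ps == 3:
                kk = k[10]
            else:  # ps == 4
                kk = k[11]
            if kk > kmax:
                kmax = kk

        if kmax == 0.0 and n_elig < 2:
            break  # nothing can ever fire again

        if kmax > 0.0:
            dt = eps / kmax
            if dt < dt_base:
                dt = dt_base
            if dt > dt_max:
                dt = dt_max
        else:
            dt = syn_cap
        if n_elig >= 2 and dt > syn_cap:
            dt = syn_cap

        # --- per-end diffusion and early recruitment ---
        if n_pre > 0:
            sigma = math.sqrt(2.0 * d_pre * dt)
            for i in range(n_ends):
                s = estate[i]
                if s >= 3:
                    continue
                for ax in range(3):
                    pos[i, ax] += np.random.normal(0.0, sigma)
                r = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
                if r > radius and r > 0.0:
                    f = (2.0 * radius - r) / r
                    pos[i, 0] *= f
                    pos[i, 1] *= f
                    pos[i, 2] *= f
                if s == 0:
                    if np.random.random() < -math.expm1(-k[0] * dt):
                        estate[i] = 1
                elif s == 1:
                    if np.random.random() < -math.expm1(-k[1] * dt):
                        estate[i] = 2

        # --- CtIP / EXO1 recruitment clocks (slow ends, from Ku binding) ---
        for i in range(n_ends):
            if estate[i] >= 1:
                if ctip[i] == 0 and np.random.random() < -math.expm1(-k[6] * dt):
                    ctip[i] = 1
                if exo1[i] == 0 and np.random.random() < -math.expm1(-k[7] * dt):
                    exo1[i] = 1

        # --- synapsis: nearest eligible end within range, lowest id first ---
        if n_elig >= 2:
            for i in range(n_ends):
                if estate[i] != 2:
                    continue
                best_j = -1
                best_d2 = syn2
                for j in range(n_ends):
                    if j == i or estate[j] != 2:
                        continue
                    dx = pos[i, 0] - pos[j, 0]
                    dy = pos[i, 1] - pos[j, 1]
                    dz = pos[i, 2] - pos[j, 2]
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 <= best_d2 and (best_j == -1 or d2 < best_d2 or j < best_j):
                        best_d2 = d2
                        best_j = j
                if best_j >= 0:
                    estate[i] = 3
                    estate[best_j] = 3
                    partner[i] = best_j
                    partner[best_j] = i
                    pa[n_pairs] = i
                    pb[n_pairs] = best_j
                    pstate[n_pairs] = 0
                    pslow[n_pairs] = 1 if (slow[i // 2] == 1 or slow[best_j // 2] == 1) else 0
                    n_pairs += 1

        # --- pair-level chain transitions ---
        for p in range(n_pairs):
            ps = pstate[p]
            if ps == 9:
                continue
            if ps == 0:
                kk = k[2]
            elif ps == 1:
                if pslow[p] == 0:
                    kk = k[3]
                else:
                    a, b = pa[p], pb[p]
                    gate = ctip[a] == 1 and ctip[b] == 1 and exo1[a] == 1 and exo1[b] == 1
                    kk = k[8] if (gate and artemis_active) else 0.0
            elif ps == 2:
                kk = k[4] if pslow[p] == 0 else k[9]
            elif ps == 3:
                kk = k[10]
            else:
                kk = k[11]
            if kk > 0.0 and np.random.random() < -math.expm1(-kk * dt):
                if pslow[p] == 0 and ps == 2:
                    pstate[p] = 9
                elif pslow[p] == 1 and ps == 4:
                    pstate[p] = 9
                else:
                    pstate[p] = ps + 1
                if pstate[p] == 9:
                    lig_time[pa[p]] = t + dt
                    lig_time[pb[p]] = t + dt

        t += dt

    return lig_time, partner


def simulate_repair(
    damage: DamageSet, params: RepairParams | None = None, seed: int = 0
) -> RepairTrajectory:
    """Run the stochastic repair state machine on an assigned damage set.

    Every DSB must already carry a pathway label (see
    :func:`radfate.compartments.assign_pathways`).  Returns the
    event-resolved unrepaired-count trajectory; fixed seed and
    parameters give a bit-identical event log.
    """
    params = params or RepairParams()
    n = len(damage)
    pathways = [d.pathway for d in damage.dsbs]
    if any(p == Pathway.UNASSIGNED for p in pathways):
        raise ValueError("all DSBs must have an assigned pathway before repair")

    if n == 0:
        grid = np.array([0.0, params.t_max])
        return RepairTrajectory(grid, np.zeros(2, dtype=int), [], 0, params.t_max)

    coords = damage.coords()
    slow = np.array([1 if p == Pathway.SLOW else 0 for p in pathways], dtype=np.uint8)
    dt_base = params.dt if params.adaptive_dt else params.dt
    eps = params.step_accuracy if params.adaptive_dt else params.rates().max() * params.dt
    lig_time, partner = _repair_kernel(
        int(seed) % (2**31),
        np.ascontiguousarray(coords, dtype=np.float64),
        slow,
        float(damage.nucleus_radius),
        params.rates(),
        params.synapsis_distance,
        params.d_pre,
        dt_base,
        eps,
        params.synapsis_dt_cap,
        params.dt_max if params.adaptive_dt else params.dt,
        params.t_max,
        params.artemis_active,
    )

    events: list[RepairEvent] = []
    completion = np.full(n, np.inf)
    for d in range(n):
        t_done = max(lig_time[2 * d], lig_time[2 * d + 1])
        if np.isfinite(t_done) and t_done <= params.t_max:
            completion[d] = t_done
            correct = partner[2 * d] == 2 * d + 1
            events.append(
                RepairEvent(
                    dsb_id=damage.dsbs[d].id,
                    completion_time=float(t_done),
                    pathway=pathways[d],
                    correct_partner=bool(correct),
                )
            )
    events.sort(key=lambda e: e.completion_time)

    times = np.array([e.completion_time for e in events])
    grid = np.concatenate([[0.0], times, [params.t_max]])
    counts = np.concatenate([[n], n - np.arange(1, len(events) + 1), [n - len(events)]])
    return RepairTrajectory(grid, counts.astype(int), events, n, params.t_max)


def repair_curve(
    trajectory: RepairTrajectory,
    normalize: bool = True,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Unrepaired count (or fraction) versus time, monotone non-increasing."""
    if trajectory.n_initial == 0:
        raise ValueError("empty trajectory: no DSBs to build a curve from")
    t = np.asarray(grid, dtype=float) if grid is not None else trajectory.time_grid
    y = trajectory.unrepaired_at(t).astype(float)
    if normalize:
        y = y / trajectory.n_initial
    return t, y


def _biexp(t: np.ndarray, f_fast: float, tau_fast: float, tau_slow: float) -> np.ndarray:
    return f_fast * np.exp(-t / tau_fast) + (1.0 - f_fast) * np.exp(-t / tau_slow)


def fit_biexponential(
    curve: tuple[np.ndarray, np.ndarray]
) -> tuple[float, float, float, float]:
    """Fit f*exp(-t/tau_f) + (1-f)*exp(-t/tau_s) to an unrepaired fraction.

    Returns ``(fraction_fast, tau_fast, fraction_slow, tau_slow)`` with
    ``tau_fast < tau_slow`` enforced by ordering.  The curve should span
    both kinetic phases (t_max of several slow time constants).
    """
    t, y = np.asarray(curve[0], dtype=float), np.asarray(curve[1], dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 curve points for a biexponential fit")
    span = t.max() - t.min()
    guesses = [
        (0.8, span / 50.0, span / 2.0),
        (0.5, span / 200.0, span / 5.0),
        (0.2, span / 20.0, span),
    ]
    best = None
    for g in guesses:
        try:
            popt, _ = curve_fit(
                _biexp,
                t,
                y,
                p0=g,
                bounds=([0.0, 1e-9, 1e-9], [1.0, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((_biexp(t, *popt) - y) ** 2))
        if best is None or resid < best[0]:
            best = (resid, popt)
    if best is None:
        raise RuntimeError(
            "biexponential fit failed to converge; check that the curve covers "
            "both kinetic phases"
        )
    f_fast, tau_a, tau_b = best[1]
    if tau_a <= tau_b:
        tau_fast, tau_slow = tau_a, tau_b
    else:
        tau_fast, tau_slow = tau_b, tau_a
        f_fast = 1.0 - f_fast
    if tau_slow / max(tau_fast, 1e-300) < 3.0:
        warnings.warn(
            "degenerate time constants: the two phases are poorly separated",
            stacklevel=2,
        )
    return float(f_fast), float(tau_fast), float(1.0 - f_fast), float(tau_slow)


def write_event_log_tsv(trajectory: RepairTrajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("dsb_id\tpathway\tcompletion_time_s\tcorrect_partner\n")
        for e in trajectory.events:
            fh.write(
                f"{e.dsb_id}\t{e.pathway.value}\t{e.completion_time:.6g}\t"
                f"{str(e.correct_partner).lower()}\n"
            )


def write_repair_curve_tsv(trajectory: RepairTrajectory, path, normalize: bool = True) -> None:
    t, y = repair_curve(trajectory, normalize=normalize)
    with open(path, "w") as fh:
        col = "unrepaired_fraction" if normalize else "unrepaired_count"
        fh.write(f"time_s\t{col}\n")
        for ti, yi in zip(t, y):
            fh.write(f"{ti:.6g}\t{yi:.6g}\n")
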