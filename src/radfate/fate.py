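"""Cell-fate readouts and dose x slow-fraction x M ensemble sweeps.

Fate is read off the network trajectory of each simulated cell:

* apoptosis — the Bax-driven trigger species first crossing a threshold
  (a configurable multiple of its basal level) before the readout
  horizon; the crossing is treated as an irreversible state jump;
* cycle arrest — total time cyclin E spends below a fraction of its
  basal level;
* TGFbeta burden — the time integral of the secreted TGFbeta level.

`run_sweep` reproduces the study design: a full factorial grid of dose,
imposed slow-compartment fraction and ATM half-saturation threshold M,
with an ensemble of independently seeded cells per condition, each cell
running the coupled repair + Gillespie simulation to 72 h.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compartments import CompartmentParams, assign_pathways
from .damage import DamageSet, generate_damage
from .p53net import (
    ReactionNetwork,
    Trajectory,
    build_network,
    simulate_deterministic,
    simulate_stochastic,
)
from .repair import RepairParams, RepairTrajectory, simulate_repair

__all__ = [
    "FateThresholds",
    "CellFateRecord",
    "detect_apoptosis",
    "arrest_duration",
    "tgfb_cumulative",
    "simulate_cell",
    "run_sweep",
    "write_sweep_tsv",
    "sweep_manifest",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FateThresholds:
    """Detection rules for the per-cell readouts."""

    apoptosis_species: str = "Bax"
    apoptosis_multiple: float = 5.0   # x basal level
    apoptosis_threshold: float | None = None  # absolute copies, overrides multiple
    arrest_species: str = "cyclin_E"
    arrest_fraction: float = 0.1      # below this x basal counts as arrest
    tgfb_species: str = "TGFb"

    def __post_init__(self) -> None:
        if self.apoptosis_multiple <= 0 or self.arrest_fraction <= 0:
            raise ValueError("thresholds must be > 0")
        if self.apoptosis_threshold is not None and self.apoptosis_threshold <= 0:
            raise ValueError("apoptosis_threshold must be > 0")


@dataclass
class CellFateRecord:
    """Fate summary of one simulated cell."""

    apoptotic: bool
    apoptosis_time_h: float | None
    arrest_duration_h: float
    tgfb_cumulative: float  # copy-hours
    dose_gy: float = 0.0
    f_slow: float | None = None
    m_gy: float = 0.14
    seed: int = 0


def _basal_of(traj: Trajectory, species: str) -> float:
    return float(traj.get(species)[0])


def detect_apoptosis(
    traj: Trajectory, thresholds: FateThresholds | None = None
) -> tuple[bool, float | None]:
    """First upward crossing of the apoptosis trigger, if any.

    Returns ``(apoptotic, crossing_time_h)``.  The threshold is
    ``apoptosis_multiple`` times the trajectory's initial (basal) level
    unless an absolute ``apoptosis_threshold`` is set.
    """
    thresholds = thresholds or FateThresholds()
    y = traj.get(thresholds.apoptosis_species)
    thr = thresholds.apoptosis_threshold
    if thr is None:
        thr = thresholds.apoptosis_multiple * max(_basal_of(traj, thresholds.apoptosis_species), 1.0)
    above = y >= thr
    if not np.any(above):
        return False, None
    first = int(np.argmax(above))
    if first == 0:  # already above at t=0: treat as immediate crossing
        return True, float(traj.time_h[0])
    return True, float(traj.time_h[first])


def arrest_duration(
    traj: Trajectory, thresholds: FateThresholds | None = None
) -> float:
    """Total hours with cyclin E below ``arrest_fraction`` x basal."""
    thresholds = thresholds or FateThresholds()
    y = traj.get(thresholds.arrest_species)
    thr = thresholds.arrest_fraction * _basal_of(traj, thresholds.arrest_species)
    below = y < thr
    if traj.time_h.size < 2:
        return 0.0
    dt = np.diff(traj.time_h)
    # a grid interval counts when its left endpoint is below threshold
    return float(np.sum(dt[below[:-1]]))


def tgfb_cumulative(
    traj: Trajectory, thresholds: FateThresholds | None = None
) -> float:
    """Time integral of secreted TGFbeta (copy-hours, trapezoid rule)."""
    thresholds = thresholds or FateThresholds()
    return float(np.trapezoid(traj.get(thresholds.tgfb_species), traj.time_h))


def simulate_cell(
    dose: float,
    f_slow: float | None = None,
    m_gy: float = 0.14,
    seed: int = 0,
    t_max: float = 72.0,
    engine: str = "stochastic",
    network: ReactionNetwork | None = None,
    repair_params: RepairParams | None = None,
    compartment_params: CompartmentParams | None = None,
    thresholds: FateThresholds | None = None,
    dsb_yield: float = 40.0,
    complex_fraction: float = 0.1,
    hc_fraction: float = 0.2,
    nucleus_radius: float = 5000.0,
) -> tuple[CellFateRecord, Trajectory, RepairTrajectory]:
    """One coupled repair + p53 simulation and its fate readouts.

    With ``f_slow`` given, pathway assignment is an imposed
    Bernoulli(F_slow) per DSB (sweep mode); otherwise the mechanistic
    chromatin/complexity rule applies.  The repair trajectory's
    unrepaired count is the piecewise-constant DSB forcing of the
    network engine.
    """
    thresholds = thresholds or FateThresholds()
    if network is None:
        network = build_network(m_gy=m_gy)
    rp = repair_params or RepairParams(t_max=t_max * 3600.0)
    # three decorrelated sub-seeds from one cell seed
    s_damage, s_assign, s_engine = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    damage = generate_damage(
        dose,
        dsb_yield=dsb_yield,
        complex_fraction=complex_fraction,
        hc_fraction=hc_fraction,
        nucleus_radius=nucleus_radius,
        seed=int(s_damage),
    )
    damage = assign_pathways(
        damage, compartment_params, seed=int(s_assign), forced_f_slow=f_slow
    )
    repair_traj = simulate_repair(damage, rp, seed=int(s_engine))
    if engine == "stochastic":
        traj = simulate_stochastic(network, repair_traj, t_max=t_max, seed=int(s_engine))
    elif engine == "deterministic":
        traj = simulate_deterministic(network, repair_traj, t_max=t_max)
    else:
        raise ValueError(f"engine must be 'deterministic' or 'stochastic', got {engine!r}")
    apoptotic, t_apo = detect_apoptosis(traj, thresholds)
    record = CellFateRecord(
        apoptotic=apoptotic,
        apoptosis_time_h=t_apo,
        arrest_duration_h=arrest_duration(traj, thresholds),
        tgfb_cumulative=tgfb_cumulative(traj, thresholds),
        dose_gy=dose,
        f_slow=f_slow,
        m_gy=m_gy,
        seed=seed,
    )
    return record, traj, repair_traj


def _cell_seed(master_seed: int, condition_index: int, cell_index: int) -> int:
    """Counter-based per-cell seed: independent of execution order."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(condition_index, cell_index)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(
    doses: tuple[float, ...] = (2.0, 4.0, 8.0),
    f_slows: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
    m_values: tuple[float, ...] = (0.14, 0.5),
    n_cells: int = 100,
    seed: int = 0,
    t_max: float = 72.0,
    thresholds: FateThresholds | None = None,
    repair_params: RepairParams | None = None,
    param_file=None,
    dsb_yield: float = 40.0,
    keep_records: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[CellFateRecord]]:
    """Full factorial dose x F_slow x M ensemble of stochastic cells.

    Per condition, ``n_cells`` coupled repair + Gillespie simulations
    run to ``t_max`` hours; the apoptosis percentage and the ensemble
    means of arrest duration and cumulative TGFbeta are tabulated with
    sampling errors.  Failures of single cells are logged and counted
    in the ``n_failed`` column without aborting the sweep.
    """
    thresholds = thresholds or FateThresholds()
    networks = {m: build_network(param_file, m_gy=m, dsb_per_gy=dsb_yield) for m in m_values}
    for net in networks.values():
        net.basal_state()  # pre-solve once per M

    rows = []
    records: list[CellFateRecord] = []
    cond_idx = 0
    for m in m_values:
        for dose in doses:
            for fs in f_slows:
                cell_records = []
                n_failed = 0
                for c in range(n_cells):
                    cs = _cell_seed(seed, cond_idx, c)
                    try:
                        rec, _, _ = simulate_cell(
                            dose,
                            f_slow=fs,
                            m_gy=m,
                            seed=cs,
                            t_max=t_max,
                            network=networks[m],
                            repair_params=repair_params,
                            thresholds=thresholds,
                            dsb_yield=dsb_yield,
                        )
                        cell_records.append(rec)
                    except Exception:  # noqa: BLE001 - sweep must survive a bad cell
                        n_failed += 1
                        logger.exception(
                            "cell failed: dose=%s f_slow=%s m=%s seed=%s", dose, fs, m, cs
                        )
                n_ok = len(cell_records)
                apo = np.array([r.apoptotic for r in cell_records], dtype=float)
                arr = np.array([r.arrest_duration_h for r in cell_records])
                tgf = np.array([r.tgfb_cumulative for r in cell_records])
                p_hat = float(apo.mean()) if n_ok else np.nan
                rows.append(
                    {
                        "dose_gy": dose,
                        "f_slow": fs,
                        "m_gy_equiv": m,
                        "n_cells": n_ok,
                        "n_failed": n_failed,
                        "apoptosis_pct": 100.0 * p_hat,
                        "apoptosis_pct_se": 100.0 * float(
                            np.sqrt(p_hat * (1 - p_hat) / n_ok)
                        ) if n_ok else np.nan,
                        "mean_arrest_h": float(arr.mean()) if n_ok else np.nan,
                        "se_arrest_h": float(arr.std(ddof=1) / np.sqrt(n_ok))
                        if n_ok > 1 else np.nan,
                        "mean_tgfb": float(tgf.mean()) if n_ok else np.nan,
                        "se_tgfb": float(tgf.std(ddof=1) / np.sqrt(n_ok))
                        if n_ok > 1 else np.nan,
                    }
                )
                records.extend(cell_records)
                cond_idx += 1
    table = pd.DataFrame(rows)
    if keep_records:
        return table, records
    return table


def write_sweep_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def sweep_manifest(
    seed: int, n_cells: int, param_file=None, extra: dict | None = None
) -> str:
    """JSON manifest sufficient to reproduce a sweep bit-exactly."""
    from . import __version__
    from .p53net import default_param_path

    pf = param_file if param_file is not None else default_param_path()
    digest = hashlib.sha256(open(pf, "rb").read()).hexdigest()
    payload = {
        "radfate_version": __version__,
        "master_seed": int(seed),
        "n_cells": int(n_cells),
        "param_file_sha256": digest,
        "seeding": "SeedSequence(master, spawn_key=(condition_index, cell_index))",
    }
    if extra:
        payload.update(extra)
    return json.dumps(payload, indent=2)
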