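"""The p53 damage-response network: ODE and Gillespie engines.

DSBs activate the ATM kinase through a Hill-type mechanism (cooperative
intermolecular autophosphorylation), so activation saturates with dose:

    dATM_act/dt = k * ATM_inactive * DSB^2 / (DSB^2 + M^2)

with ``M`` the DSB count at half-saturation (configured in
Gy-equivalents).  Active ATM phosphorylates p53 at Ser15/20 into the
*arrester* phosphoform, which drives p21 transcription (cell-cycle
arrest via cyclin-E inhibition) and the p21-GADD45-p38-TGFbeta
secretion arm, and induces its own negative regulators Mdm2 and Wip1.
Wip1 dephosphorylates active ATM and both p53 phosphoforms while Mdm2
degrades p53: these feedback loops generate the characteristic p53
relaxation oscillations while damage persists.  Sustained signalling
converts the arrester into the Ser46 *killer* phosphoform, which
represses the pro-survival Akt arm and induces Bax, the apoptosis
trigger.

The network is a list of elementary reaction channels (mass-action with
optional Hill-type transcriptional modifiers) shared by both engines:
the deterministic engine integrates the mean-field rate equations, the
stochastic engine runs the exact Gillespie direct method on integer
copy numbers, with the external DSB count interleaved as a
piecewise-constant forcing.  All rate constants live in a flat
parameter file, never in code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

__all__ = [
    "ConfigurationError",
    "HillParams",
    "Reaction",
    "ReactionNetwork",
    "Trajectory",
    "SPECIES",
    "atm_activation_rate",
    "load_params",
    "default_param_path",
    "build_network",
    "simulate_deterministic",
    "simulate_stochastic",
    "write_trajectory_tsv",
]


class ConfigurationError(ValueError):
    """A parameter file is missing or supplies invalid constants."""


#: Species order shared by both engines.  ``DSB`` is the external
#: forcing slot: reactions read it but never change it.
SPECIES = [
    "DSB",
    "ATM_i",       # inactive ATM
    "ATM_p",       # active (phosphorylated) ATM
    "p53",         # unphosphorylated p53
    "p53_arrester",
    "p53_killer",
    "mdm2_mrna",
    "Mdm2",
    "wip1_mrna",
    "Wip1",
    "p21_mrna",
    "p21",
    "cyclin_E",
    "bax_mrna",
    "Bax",
    "Akt_p",
    "GADD45",
    "p38",
    "TGFb",
]

_MOD_NONE, _MOD_ACT, _MOD_REP = 0, 1, 2


@dataclass(frozen=True)
class HillParams:
    """ATM activation parameters (Hill input stage)."""

    k: float = 5e-3           # per second, activation coefficient
    m_dsb: float = 5.6        # DSB count at half-saturation
    atm_total: float = 200.0  # copies, conserved ATM_i + ATM_p pool
    dsb_per_gy: float = 40.0  # DSB yield used to express M in Gy-equivalents

    def __post_init__(self) -> None:
        if self.k <= 0 or self.m_dsb <= 0 or self.atm_total <= 0:
            raise ValueError("k, m_dsb and atm_total must be > 0")

    @classmethod
    def from_gy(cls, m_gy: float, k: float = 5e-3, atm_total: float = 200.0,
                dsb_per_gy: float = 40.0) -> "HillParams":
        return cls(k=k, m_dsb=m_gy * dsb_per_gy, atm_total=atm_total,
                   dsb_per_gy=dsb_per_gy)


def atm_activation_rate(dsb: float, atm_inactive: float, params: HillParams) -> float:
    """Flux (copies/s) from the inactive to the active ATM pool.

    The Hill exponent is 2; at ``dsb == m_dsb`` the flux is exactly half
    the saturating value ``k * atm_inactive``.  The inactive-pool
    scaling makes activation stop once the pool empties, conserving
    total ATM.
    """
    if dsb < 0 or atm_inactive < 0:
        raise ValueError("dsb and atm_inactive must be >= 0")
    d2 = dsb * dsb
    return params.k * atm_inactive * d2 / (d2 + params.m_dsb * params.m_dsb)


@dataclass(frozen=True)
class Reaction:
    """One channel: mass-action reactants, optional Hill modifier."""

    name: str
    rate_name: str            # parameter-file key of the rate constant
    reactants: tuple[int, ...]      # species indices consumed (order <= 2)
    products: tuple[int, ...]       # species indices produced
    catalysts: tuple[int, ...] = ()  # enter the propensity, unchanged by the firing
    modifier: int = -1
    mod_type: int = _MOD_NONE
    mod_k_name: str = ""      # parameter-file key of the Hill K
    mod_n: float = 2.0


@dataclass
class ReactionNetwork:
    """Compiled reaction system plus its parameter values."""

    species: list[str]
    reactions: list[Reaction]
    params: dict[str, float]
    hill: HillParams
    omega: float = 1.0
    basal: np.ndarray | None = None  # cached basal steady state

    # compiled arrays (built in __post_init__)
    _c: np.ndarray = field(default=None, repr=False)
    _s1: np.ndarray = field(default=None, repr=False)
    _s2: np.ndarray = field(default=None, repr=False)
    _mod: np.ndarray = field(default=None, repr=False)
    _mtype: np.ndarray = field(default=None, repr=False)
    _K: np.ndarray = field(default=None, repr=False)
    _n: np.ndarray = field(default=None, repr=False)
    _stoich: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ns, nr = len(self.species), len(self.reactions)
        c = np.zeros(nr)
        s1 = np.full(nr, -1, dtype=np.int64)
        s2 = np.full(nr, -1, dtype=np.int64)
        mod = np.full(nr, -1, dtype=np.int64)
        mtype = np.zeros(nr, dtype=np.int64)
        K = np.ones(nr)
        n_exp = np.ones(nr)
        stoich = np.zeros((nr, ns), dtype=np.int64)
        for r, rx in enumerate(self.reactions):
            if rx.rate_name not in self.params:
                raise ConfigurationError(f"missing rate constant: {rx.rate_name}")
            base_c = self.params[rx.rate_name]
            if base_c < 0:
                raise ConfigurationError(f"negative rate constant: {rx.rate_name}")
            inputs = rx.reactants + rx.catalysts
            if len(inputs) > 2:
                raise ConfigurationError(f"{rx.name}: at most bimolecular channels")
            # volume scaling: zeroth order ~ omega, bimolecular ~ 1/omega
            order = len(inputs)
            c[r] = base_c * self.omega ** (1 - order)
            if order >= 1:
                s1[r] = inputs[0]
            if order == 2:
                s2[r] = inputs[1]
            if rx.mod_type != _MOD_NONE:
                if rx.mod_k_name not in self.params:
                    raise ConfigurationError(f"missing Hill constant: {rx.mod_k_name}")
                mod[r] = rx.modifier
                mtype[r] = rx.mod_type
                # the DSB forcing slot is an external count: never rescaled
                k_scale = 1.0 if rx.modifier == 0 else self.omega
                K[r] = self.params[rx.mod_k_name] * k_scale
                n_exp[r] = rx.mod_n
            for s in rx.reactants:
                stoich[r, s] -= 1
            for s in rx.products:
                stoich[r, s] += 1
            if np.any(stoich[r, 0] != 0):
                raise ConfigurationError("the DSB forcing slot must not be consumed")
        self._c, self._s1, self._s2 = c, s1, s2
        self._mod, self._mtype, self._K, self._n = mod, mtype, K, n_exp
        self._stoich = stoich

    # -- evaluation --------------------------------------------------------

    def propensities(self, x: np.ndarray) -> np.ndarray:
        a = self._c.copy()
        has1 = self._s1 >= 0
        a[has1] *= x[self._s1[has1]]
        has2 = self._s2 >= 0
        a[has2] *= x[self._s2[has2]]
        hm = self._mtype > 0
        if np.any(hm):
            xm = x[self._mod[hm]]
            xn = np.maximum(xm, 0.0) ** self._n[hm]
            Kn = self._K[hm] ** self._n[hm]
            act = xn / (xn + Kn)
            rep = Kn / (xn + Kn)
            a[hm] *= np.where(self._mtype[hm] == _MOD_ACT, act, rep)
        return np.maximum(a, 0.0)

    def rhs(self, x: np.ndarray) -> np.ndarray:
        return self._stoich.T @ self.propensities(x)

    # -- helpers -----------------------------------------------------------

    def index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise ConfigurationError(
                f"unknown species {name!r}; known: {self.species}"
            ) from None

    def scaled(self, omega: float) -> "ReactionNetwork":
        """Rescale copy numbers by ``omega`` (thermodynamic-limit studies)."""
        basal = None if self.basal is None else self.basal * omega
        return ReactionNetwork(
            species=self.species,
            reactions=self.reactions,
            params=dict(self.params),
            hill=self.hill,
            omega=self.omega * omega,
            basal=basal,
        )

    def basal_state(self) -> np.ndarray:
        """Steady state with zero damage, found by long unforced relaxation."""
        if self.basal is not None:
            return self.basal.copy()
        x0 = np.zeros(len(self.species))
        x0[self.index("ATM_i")] = self.hill.atm_total * self.omega
        sol = solve_ivp(
            lambda t, x: self.rhs(x),
            (0.0, 2000.0 * 3600.0),
            x0,
            method="LSODA",
            rtol=1e-8,
            atol=1e-8,
        )
        self.basal = np.maximum(sol.y[:, -1], 0.0)
        return self.basal.copy()

    def edge_list(self) -> list[tuple[str, str, str]]:
        """Documented regulatory edges (source, kind, target) for audits."""
        edges = []
        for rx in self.reactions:
            for cat in rx.catalysts:
                for prod in rx.products:
                    if prod != cat:
                        edges.append((self.species[cat], "catalysis", self.species[prod]))
                if not rx.products or set(rx.products) <= set(rx.catalysts):
                    for rea in rx.reactants:
                        edges.append((self.species[cat], "degradation", self.species[rea]))
            if rx.mod_type == _MOD_ACT:
                for prod in rx.products:
                    edges.append((self.species[rx.modifier], "activation", self.species[prod]))
            elif rx.mod_type == _MOD_REP:
                for prod in rx.products:
                    edges.append((self.species[rx.modifier], "repression", self.species[prod]))
        return sorted(set(edges))

    def to_json(self) -> str:
        """Serialize the reaction list for auditability."""
        return json.dumps(
            {
                "species": self.species,
                "omega": self.omega,
                "reactions": [
                    {
                        "name": rx.name,
                        "rate_name": rx.rate_name,
                        "rate_value": self.params[rx.rate_name],
                        "reactants": [self.species[i] for i in rx.reactants],
                        "products": [self.species[i] for i in rx.products],
                        "catalysts": [self.species[i] for i in rx.catalysts],
                        "modifier": None if rx.modifier < 0 else self.species[rx.modifier],
                        "mod_type": {0: None, 1: "hill_activation", 2: "hill_repression"}[
                            rx.mod_type
                        ],
                        "mod_K": self.params.get(rx.mod_k_name),
                        "mod_n": rx.mod_n if rx.mod_type else None,
                    }
                    for rx in self.reactions
                ],
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Network topology.  Indices refer to SPECIES; rate names refer to the
# parameter file.  Transcriptional induction is modeled with Hill-type
# modifiers; post-translational steps are mass-action.

def _default_reactions() -> list[Reaction]:
    ix = {name: i for i, name in enumerate(SPECIES)}
    R = Reaction
    rx = [
        # --- ATM input stage -------------------------------------------------
        R("atm_activation", "k_atm_act", (ix["ATM_i"],), (ix["ATM_p"],),
          modifier=ix["DSB"], mod_type=_MOD_ACT, mod_k_name="m_dsb", mod_n=2.0),
        # intermolecular autophosphorylation: active ATM converts inactive
        # ATM, making activation switch-like once seeded
        R("atm_autoactivation", "k_atm_auto", (ix["ATM_i"],), (ix["ATM_p"],),
          catalysts=(ix["ATM_p"],),
          modifier=ix["DSB"], mod_type=_MOD_ACT, mod_k_name="m_dsb", mod_n=2.0),
        R("atm_deactivation_basal", "k_atm_deact", (ix["ATM_p"],), (ix["ATM_i"],)),
        # cooperative Wip1-driven dephosphorylation: the sharp off-switch of
        # the ATM/Wip1 relaxation oscillator
        R("atm_deactivation_wip1", "k_atm_wip1", (ix["ATM_p"],), (ix["ATM_i"],),
          modifier=ix["Wip1"], mod_type=_MOD_ACT, mod_k_name="K_atm_wip1",
          mod_n=4.0),
        # --- p53 core --------------------------------------------------------
        R("p53_synthesis", "s_p53", (), (ix["p53"],)),
        R("p53_degradation", "d_p53", (ix["p53"],), ()),
        R("p53_degradation_mdm2", "d_p53_mdm2", (ix["p53"],), (),
          catalysts=(ix["Mdm2"],)),
        R("p53_phosphorylation", "k_p53_phos", (ix["p53"],), (ix["p53_arrester"],),
          catalysts=(ix["ATM_p"],)),
        R("arrester_dephosphorylation", "k_arr_dephos",
          (ix["p53_arrester"],), (ix["p53"],), catalysts=(ix["Wip1"],)),
        R("arrester_degradation", "d_p53", (ix["p53_arrester"],), ()),
        R("arrester_degradation_mdm2", "d_arr_mdm2", (ix["p53_arrester"],), (),
          catalysts=(ix["Mdm2"],)),
        R("killer_phosphorylation", "k_killer_phos",
          (ix["p53_arrester"],), (ix["p53_killer"],), catalysts=(ix["ATM_p"],)),
        R("killer_dephosphorylation", "k_killer_dephos",
          (ix["p53_killer"],), (ix["p53_arrester"],), catalysts=(ix["Wip1"],)),
        R("killer_degradation", "d_killer", (ix["p53_killer"],), ()),
        R("killer_degradation_mdm2", "d_kil_mdm2", (ix["p53_killer"],), (),
          catalysts=(ix["Mdm2"],)),
        # --- Mdm2 negative feedback ------------------------------------------
        R("mdm2_transcription", "s_mdm2_mrna", (), (ix["mdm2_mrna"],),
          modifier=ix["p53_arrester"], mod_type=_MOD_ACT, mod_k_name="K_mdm2",
          mod_n=4.0),
        R("mdm2_transcription_basal", "s_mdm2_mrna0", (), (ix["mdm2_mrna"],)),
        R("mdm2_mrna_decay", "d_mdm2_mrna", (ix["mdm2_mrna"],), ()),
        R("mdm2_translation", "k_mdm2_tln", (), (ix["Mdm2"],),
          catalysts=(ix["mdm2_mrna"],)),
        R("mdm2_degradation", "d_mdm2", (ix["Mdm2"],), ()),
        R("mdm2_degradation_atm", "d_mdm2_atm", (ix["Mdm2"],), (),
          catalysts=(ix["ATM_p"],)),
        # --- Wip1 negative feedback ------------------------------------------
        R("wip1_transcription", "s_wip1_mrna", (), (ix["wip1_mrna"],),
          modifier=ix["p53_arrester"], mod_type=_MOD_ACT, mod_k_name="K_wip1",
          mod_n=4.0),
        R("wip1_transcription_basal", "s_wip1_mrna0", (), (ix["wip1_mrna"],)),
        R("wip1_mrna_decay", "d_wip1_mrna", (ix["wip1_mrna"],), ()),
        R("wip1_translation", "k_wip1_tln", (), (ix["Wip1"],),
          catalysts=(ix["wip1_mrna"],)),
        R("wip1_degradation", "d_wip1", (ix["Wip1"],), ()),
        # --- p21 / cyclin-E arrest arm ---------------------------------------
        R("p21_transcription", "s_p21_mrna", (), (ix["p21_mrna"],),
          modifier=ix["p53_arrester"], mod_type=_MOD_ACT, mod_k_name="K_p21",
          mod_n=2.0),
        R("p21_transcription_basal", "s_p21_mrna0", (), (ix["p21_mrna"],)),
        R("p21_mrna_decay", "d_p21_mrna", (ix["p21_mrna"],), ()),
        R("p21_translation", "k_p21_tln", (), (ix["p21"],),
          catalysts=(ix["p21_mrna"],)),
        R("p21_degradation", "d_p21", (ix["p21"],), ()),
        R("cyclin_e_synthesis", "s_cyce", (), (ix["cyclin_E"],),
          modifier=ix["p21"], mod_type=_MOD_REP, mod_k_name="K_cyce", mod_n=4.0),
        R("cyclin_e_degradation", "d_cyce", (ix["cyclin_E"],), ()),
        # --- Bax / Akt apoptosis arm -----------------------------------------
        R("bax_transcription", "s_bax_mrna", (), (ix["bax_mrna"],),
          modifier=ix["p53_killer"], mod_type=_MOD_ACT, mod_k_name="K_bax",
          mod_n=4.0),
        R("bax_transcription_basal", "s_bax_mrna0", (), (ix["bax_mrna"],)),
        R("bax_mrna_decay", "d_bax_mrna", (ix["bax_mrna"],), ()),
        R("bax_translation", "k_bax_tln", (), (ix["Bax"],),
          catalysts=(ix["bax_mrna"],)),
        R("bax_degradation", "d_bax", (ix["Bax"],), ()),
        R("bax_degradation_akt", "d_bax_akt", (ix["Bax"],), (),
          catalysts=(ix["Akt_p"],)),
        R("akt_activation", "s_akt", (), (ix["Akt_p"],),
          modifier=ix["p53_killer"], mod_type=_MOD_REP, mod_k_name="K_akt",
          mod_n=4.0),
        R("akt_deactivation", "d_akt", (ix["Akt_p"],), ()),
        # --- p21-GADD45-p38-TGFb secretion arm --------------------------------
        R("gadd45_synthesis", "s_gadd45", (), (ix["GADD45"],),
          modifier=ix["p21"], mod_type=_MOD_ACT, mod_k_name="K_gadd45", mod_n=2.0),
        R("gadd45_synthesis_basal", "s_gadd450", (), (ix["GADD45"],)),
        R("gadd45_degradation", "d_gadd45", (ix["GADD45"],), ()),
        R("p38_activation", "s_p38", (), (ix["p38"],),
          modifier=ix["GADD45"], mod_type=_MOD_ACT, mod_k_name="K_p38", mod_n=2.0),
        R("p38_activation_basal", "s_p380", (), (ix["p38"],)),
        R("p38_deactivation", "d_p38", (ix["p38"],), ()),
        R("tgfb_secretion", "s_tgfb", (), (ix["TGFb"],),
          modifier=ix["p38"], mod_type=_MOD_ACT, mod_k_name="K_tgfb", mod_n=2.0),
        R("tgfb_clearance", "d_tgfb", (ix["TGFb"],), ()),
    ]
    return rx


def default_param_path():
    """Path to the packaged default p53 parameter file."""
    return resources.files("radfate.data") / "p53_params.tsv"


def load_params(path=None) -> dict[str, float]:
    """Read a flat parameter file: name, value, unit, source (TSV)."""
    path = path if path is not None else default_param_path()
    params: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:2] != ["name", "value"]:
            raise ConfigurationError(
                "parameter file must start with columns: name, value, unit, source"
            )
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            name, value = parts[0], float(parts[1])
            if name in params:
                raise ConfigurationError(f"duplicate parameter: {name}")
            params[name] = value
    return params


def build_network(
    param_file=None,
    m_gy: float | None = None,
    dsb_per_gy: float | None = None,
    omega: float = 1.0,
) -> ReactionNetwork:
    """Assemble the p53 reaction network from a parameter file.

    ``m_gy`` (ATM half-saturation in Gy-equivalents) and ``dsb_per_gy``
    override the file values; every referenced constant must be present
    or a :class:`ConfigurationError` naming the offenders is raised.
    """
    params = load_params(param_file)
    if dsb_per_gy is not None:
        params["dsb_per_gy"] = dsb_per_gy
    if m_gy is not None:
        params["m_gy"] = m_gy
    for key in ("m_gy", "dsb_per_gy", "k_atm_act", "atm_total"):
        if key not in params:
            raise ConfigurationError(f"missing parameter: {key}")
    params["m_dsb"] = params["m_gy"] * params["dsb_per_gy"]
    hill = HillParams(
        k=params["k_atm_act"],
        m_dsb=params["m_dsb"],
        atm_total=params["atm_total"],
        dsb_per_gy=params["dsb_per_gy"],
    )
    reactions = _default_reactions()
    missing = sorted(
        {rx.rate_name for rx in reactions if rx.rate_name not in params}
        | {rx.mod_k_name for rx in reactions
           if rx.mod_type != _MOD_NONE and rx.mod_k_name not in params}
    )
    if missing:
        raise ConfigurationError(f"missing parameters: {missing}")
    net = ReactionNetwork(
        species=list(SPECIES), reactions=reactions, params=params, hill=hill,
        omega=omega,
    )
    return net


# ---------------------------------------------------------------------------
# Trajectories and forcing

@dataclass
class Trajectory:
    """Species copy numbers on a time grid (hours)."""

    time_h: np.ndarray
    values: np.ndarray  # (n_times, n_species)
    species: list[str]
    engine: str = "deterministic"

    def get(self, name: str) -> np.ndarray:
        try:
            return self.values[:, self.species.index(name)]
        except ValueError:
            raise ConfigurationError(
                f"unknown species {name!r}; known: {self.species}"
            ) from None


def _as_forcing(dsb_forcing):
    """Normalize a forcing spec to (times_s ascending, counts) step arrays.

    Accepts a repair trajectory (event-resolved counts), a constant, a
    ``(times_s, counts)`` pair, or None (no damage).
    """
    if dsb_forcing is None:
        return np.array([0.0]), np.array([0.0])
    if hasattr(dsb_forcing, "time_grid") and hasattr(dsb_forcing, "unrepaired_count"):
        return (
            np.asarray(dsb_forcing.time_grid, dtype=float),
            np.asarray(dsb_forcing.unrepaired_count, dtype=float),
        )
    if np.isscalar(dsb_forcing):
        return np.array([0.0]), np.array([float(dsb_forcing)])
    times, counts = dsb_forcing
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if times.ndim != 1 or times.shape != counts.shape or np.any(np.diff(times) < 0):
        raise ValueError("forcing must be (ascending times_s, counts) of equal length")
    return times, counts


def _forcing_value(times: np.ndarray, counts: np.ndarray, t: float) -> float:
    idx = int(np.searchsorted(times, t, side="right")) - 1
    return float(counts[max(idx, 0)])


def simulate_deterministic(
    network: ReactionNetwork,
    dsb_forcing=None,
    t_max: float = 72.0,
    x0: np.ndarray | None = None,
    n_grid: int = 1441,
) -> Trajectory:
    """Integrate the mean-field rate equations under a DSB forcing.

    ``t_max`` is in hours.  The initial state defaults to the basal
    (zero-damage) steady state.  Uses a stiff-capable integrator
    (LSODA); the piecewise-constant DSB input is integrated segment by
    segment so discontinuities land on integrator restarts.
    """
    ftimes, fcounts = _as_forcing(dsb_forcing)
    x = network.basal_state() if x0 is None else np.asarray(x0, dtype=float).copy()
    t_max_s = t_max * 3600.0
    grid = np.linspace(0.0, t_max_s, n_grid)
    out = np.empty((n_grid, len(network.species)))

    # segment boundaries: forcing steps clipped to [0, t_max]
    bounds = np.concatenate([[0.0], ftimes[(ftimes > 0) & (ftimes < t_max_s)], [t_max_s]])
    bounds = np.unique(bounds)
    dsb_idx = 0  # DSB slot
    gi = 0
    for a, b in zip(bounds[:-1], bounds[1:]):
        x[dsb_idx] = _forcing_value(ftimes, fcounts, a)
        seg_mask = (grid >= a) & (grid <= b) if b == t_max_s else (grid >= a) & (grid < b)
        t_eval = grid[seg_mask]
        sol = solve_ivp(
            lambda t, y: network.rhs(y),
            (a, b),
            x,
            method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            rtol=1e-6,
            atol=1e-6,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed on [{a:.1f}, {b:.1f}] s: {sol.message}; "
                f"state={x}"
            )
        if t_eval.size:
            out[gi:gi + t_eval.size] = sol.y.T
            gi += t_eval.size
        x = sol.y[:, -1]
    out[:, dsb_idx] = np.interp(
        grid, ftimes, fcounts, left=fcounts[0], right=fcounts[-1]
    ) if len(ftimes) > 1 else fcounts[0]
    return Trajectory(grid / 3600.0, np.maximum(out, 0.0), list(network.species))


@njit(cache=True)
def _ssa_kernel(seed, x0, c, s1, s2, mod, mtype, K, hn, stoich,
                ftimes, fcounts, t_max, grid):
    np.random.seed(seed)
    ns = x0.shape[0]
    nr = c.shape[0]
    n_grid = grid.shape[0]
    x = x0.copy()
    out = np.empty((n_grid, ns))
    a = np.empty(nr)
    t = 0.0
    gi = 0
    fi = 0
    nf = ftimes.shape[0]
    while fi + 1 < nf and ftimes[fi + 1] <= 0.0:
        fi += 1
    x[0] = fcounts[fi]
    while True:
        # propensities
        a0 = 0.0
        for r in range(nr):
            ar = c[r]
            if s1[r] >= 0:
                ar *= x[s1[r]]
            if s2[r] >= 0:
                ar *= x[s2[r]]
            if mtype[r] != 0:
                xm = x[mod[r]]
                if xm < 0.0:
                    xm = 0.0
                xn = xm ** hn[r]
                Kn = K[r] ** hn[r]
                if mtype[r] == 1:
                    ar *= xn / (xn + Kn)
                else:
                    ar *= Kn / (xn + Kn)
            if ar < 0.0:
                ar = 0.0
            a[r] = ar
            a0 += ar
        t_next_force = ftimes[fi + 1] if fi + 1 < nf else np.inf
        if a0 <= 0.0:
            t_jump = np.inf
        else:
            u = np.random.random()
            while u <= 0.0:
                u = np.random.random()
            t_jump = t - math.log(u) / a0
        if t_jump >= t_next_force and t_next_force <= t_max:
            # forcing step first: advance time, update DSB, re-draw
            while gi < n_grid and grid[gi] < t_next_force:
                if grid[gi] >= t:
                    for s in range(ns):
                        out[gi, s] = x[s]
                    gi += 1
                else:
                    gi += 1
            t = t_next_force
            fi += 1
            x[0] = fcounts[fi]
            continue
        if t_jump > t_max:
            while gi < n_grid:
                for s in range(ns):
                    out[gi, s] = x[s]
                gi += 1
            break
        # record grid points passed before the jump
        while gi < n_grid and grid[gi] < t_jump:
            for s in range(ns):
                out[gi, s] = x[s]
            gi += 1
        t = t_jump
        # choose channel
        u2 = np.random.random() * a0
        acc = 0.0
        rsel = nr - 1
        for r in range(nr):
            acc += a[r]
            if u2 <= acc:
                rsel = r
                break
        for s in range(ns):
            x[s] += stoich[rsel, s]
            if x[s] < 0:
                x[s] = 0
    return out


def simulate_stochastic(
    network: ReactionNetwork,
    dsb_forcing=None,
    t_max: float = 72.0,
    seed: int = 0,
    x0: np.ndarray | None = None,
    n_grid: int = 1441,
) -> Trajectory:
    """Exact Gillespie simulation under a piecewise-constant DSB forcing.

    The initial state is the rounded basal steady state; copy numbers
    stay integer-valued.  Propensities are recomputed whenever the
    external DSB count changes (repair events interleave as external
    events).  A fixed seed reproduces the event sequence exactly.
    """
    ftimes, fcounts = _as_forcing(dsb_forcing)
    base = network.basal_state() if x0 is None else np.asarray(x0, dtype=float)
    x_int = np.round(base).astype(np.float64)
    t_max_s = t_max * 3600.0
    grid = np.linspace(0.0, t_max_s, n_grid)
    out = _ssa_kernel(
        int(seed) % (2**31),
        x_int,
        network._c,
        network._s1,
        network._s2,
        network._mod,
        network._mtype,
        network._K,
        network._n,
        network._stoich,
        ftimes,
        np.round(fcounts),
        t_max_s,
        grid,
    )
    return Trajectory(grid / 3600.0, out, list(network.species), engine="stochastic")


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("time_h\t" + "\t".join(traj.species) + "\n")
        for i, t in enumerate(traj.time_h):
            row = "\t".join(f"{v:.6g}" for v in traj.values[i])
            fh.write(f"{t:.6g}\t{row}\n")
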