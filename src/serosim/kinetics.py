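"""Rate laws, parameters and the right-hand side of the presynapse model.

The model tracks eight molecular species of serotonin (5-HT) metabolism in
the presynaptic terminal, all in µM, in this fixed order everywhere:

    0  trp_serum   serum tryptophan, outside the terminal
    1  trp         tryptophan available for 5-HT synthesis
    2  trp_pool    cellular tryptophan sequestered for other pathways
    3  htp5        5-hydroxytryptophan (5-HTP), the synthesis intermediate
    4  fc5ht       free cellular 5-HT
    5  v5ht        vesicular (stored) 5-HT
    6  e5ht        extracellular (synaptic-cleft) 5-HT
    7  hiaa5       5-hydroxy-3-indolacetic acid (5-HIAA), degradation product

Transport and enzymatic steps (Trp transporter, TPH2, AADC, VMAT, SERT,
MAOA) follow Michaelis-Menten kinetics; pool exchange, vesicular leakage,
exocytosis and the removal sinks follow the law of mass action.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Literal

import numpy as np

__all__ = [
    "SPECIES",
    "N_SPECIES",
    "StateVector",
    "ModelParameters",
    "RateVector",
    "michaelis_menten_rate",
    "mass_action_rate",
    "reaction_rates",
    "ode_rhs",
]

SPECIES = ("trp_serum", "trp", "trp_pool", "htp5", "fc5ht", "v5ht", "e5ht", "hiaa5")
N_SPECIES = len(SPECIES)

#: species more negative than this (µM) indicate integrator failure;
#: values in [NEGATIVITY_TOL, 0) are solver undershoot and are clipped to 0.
NEGATIVITY_TOL = -1e-9


@dataclass(frozen=True)
class StateVector:
    """Concentrations (µM) of the eight species at one time point."""

    trp_serum: float = 0.0
    trp: float = 0.0
    trp_pool: float = 0.0
    htp5: float = 0.0
    fc5ht: float = 0.0
    v5ht: float = 0.0
    e5ht: float = 0.0
    hiaa5: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StateVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_SPECIES,):
            raise ValueError(f"state must have {N_SPECIES} entries, got {arr.shape}")
        return cls(**dict(zip(SPECIES, arr.tolist())))


@dataclass(frozen=True)
class ModelParameters:
    """Fixed kinetic constants of the presynapse model.

    Defaults are the published values of the model: Km in µM, Vmax in µM/h,
    first-order constants in 1/h.  The three genotype-dependent maximal
    rates (TPH2, SERT, MAOA) are *not* here -- see
    :class:`serosim.genotype.VmaxSet`.
    """

    km_trpin: float = 64.0
    vmax_trpin: float = 400.0
    k1: float = 6.0
    k_minus1: float = 0.6
    k_pool_removal: float = 0.2
    k_trp_removal: float = 0.2
    km_tph2: float = 44.0
    km_aadc: float = 160.0
    vmax_aadc: float = 400.0
    km_vmat: float = 19.0
    vmax_vmat: float = 3500.0
    k_out: float = 40.0
    k_release: float = 20.0
    km_sert: float = 0.2605
    km_maoa: float = 86.0
    k_5ht_removal: float = 400.0
    k_hiaa_removal: float = 1.0
    trp_serum_init: float = 100.0
    # The printed model is ambiguous on two points; both readings are exposed.
    # 'first' treats exocytosis as V = k_release * [v5ht]; 'zeroth' as a
    # constant flux k_release (µM/h) while v5ht > 0.
    release_order: Literal["first", "zeroth"] = "first"
    # substrate of the pool-leakage term V_pool_reverse: the printed table
    # makes it proportional to [trp]; 'trp_pool' is the alternative reading.
    pool_reverse_substrate: Literal["trp", "trp_pool"] = "trp"

    def __post_init__(self) -> None:
        for km in ("km_trpin", "km_tph2", "km_aadc", "km_vmat", "km_sert", "km_maoa"):
            if getattr(self, km) <= 0:
                raise ValueError(f"{km} must be > 0, got {getattr(self, km)}")
        for k in (
            "vmax_trpin", "k1", "k_minus1", "k_pool_removal", "k_trp_removal",
            "vmax_aadc", "vmax_vmat", "k_out", "k_release", "k_5ht_removal",
            "k_hiaa_removal",
        ):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be >= 0, got {getattr(self, k)}")
        if self.trp_serum_init <= 0:
            raise ValueError("trp_serum_init must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**d)

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(N_SPECIES)
        y0[0] = self.trp_serum_init
        return y0


@dataclass(frozen=True)
class RateVector:
    """All fluxes (µM/h) evaluated at one state."""

    v_trpin: float
    v_pool_forward: float
    v_pool_reverse: float
    v_tph2: float
    v_aadc: float
    v_vmat: float
    v_release: float
    v_sert: float
    v_maoa: float
    v_leak: float  # vesicular leakage k_out * [v5ht]
    r_trp: float
    r_pool: float
    r_e5ht: float
    r_hiaa: float

    @property
    def total_removal(self) -> float:
        """Sum of the four irreversible sinks (µM/h)."""
        return self.r_trp + self.r_pool + self.r_e5ht + self.r_hiaa


def michaelis_menten_rate(vmax: float, km: float, s: float) -> float:
    """Michaelis-Menten flux V = Vmax*[S]/(Km+[S]), µM/h.

    Bounded above by ``vmax`` and monotone non-decreasing in ``s``.
    """
    if vmax < 0:
        raise ValueError(f"vmax must be >= 0, got {vmax}")
    if km <= 0:
        raise ValueError(f"km must be > 0, got {km}")
    if s < 0:
        raise ValueError(f"substrate concentration must be >= 0, got {s}")
    return vmax * s / (km + s)


def mass_action_rate(k: float, s: float) -> float:
    """First-order mass-action flux V = k*[S], µM/h."""
    if k < 0:
        raise ValueError(f"rate constant must be >= 0, got {k}")
    if s < 0:
        raise ValueError(f"substrate concentration must be >= 0, got {s}")
    return k * s


def _as_state_array(state) -> np.ndarray:
    if isinstance(state, StateVector):
        return state.to_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape != (N_SPECIES,):
        raise ValueError(f"state must have {N_SPECIES} entries, got {arr.shape}")
    return arr


def reaction_rates(state, params: ModelParameters, vmaxes) -> RateVector:
    """Evaluate every model flux at ``state``.

    ``vmaxes`` is any object with ``tph2``, ``sert`` and ``maoa``
    attributes (µM/h), typically :class:`serosim.genotype.VmaxSet`.
    """
    trp_serum, trp, trp_pool, htp5, fc5ht, v5ht, e5ht, hiaa5 = _as_state_array(state)
    p = params
    pool_rev_sub = trp if p.pool_reverse_substrate == "trp" else trp_pool
    if p.release_order == "first":
        v_release = mass_action_rate(p.k_release, v5ht)
    else:
        v_release = p.k_release if v5ht > 0 else 0.0
    return RateVector(
        v_trpin=michaelis_menten_rate(p.vmax_trpin, p.km_trpin, trp_serum),
        v_pool_forward=mass_action_rate(p.k1, trp),
        v_pool_reverse=mass_action_rate(p.k_minus1, pool_rev_sub),
        v_tph2=michaelis_menten_rate(vmaxes.tph2, p.km_tph2, trp),
        v_aadc=michaelis_menten_rate(p.vmax_aadc, p.km_aadc, htp5),
        v_vmat=michaelis_menten_rate(p.vmax_vmat, p.km_vmat, fc5ht),
        v_release=v_release,
        v_sert=michaelis_menten_rate(vmaxes.sert, p.km_sert, e5ht),
        v_maoa=michaelis_menten_rate(vmaxes.maoa, p.km_maoa, fc5ht),
        v_leak=mass_action_rate(p.k_out, v5ht),
        r_trp=mass_action_rate(p.k_trp_removal, trp),
        r_pool=mass_action_rate(p.k_pool_removal, trp_pool),
        r_e5ht=mass_action_rate(p.k_5ht_removal, e5ht),
        r_hiaa=mass_action_rate(p.k_hiaa_removal, hiaa5),
    )


def ode_rhs(state, params: ModelParameters, vmaxes) -> np.ndarray:
    """Time derivatives d[species]/dt (µM/h) of the eight balance equations.

    Every non-removal flux appears twice with opposite signs (a transfer),
    so the derivatives sum to minus the total removal flux exactly.
    """
    v = reaction_rates(state, params, vmaxes)
    return np.array(
        [
            -v.v_trpin,
            v.v_trpin - v.v_pool_forward + v.v_pool_reverse - v.r_trp - v.v_tph2,
            v.v_pool_forward - v.v_pool_reverse - v.r_pool,
            v.v_tph2 - v.v_aadc,
            v.v_aadc - v.v_vmat + v.v_leak + v.v_sert - v.v_maoa,
            v.v_vmat - v.v_leak - v.v_release,
            v.v_release - v.v_sert - v.r_e5ht,
            v.v_maoa - v.r_hiaa,
        ]
    )
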