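"""Concentric three-node multi-step FRET network (donor → relay → acceptor).

Models the QD → AF647 → AF750 topology with one excited donor feeding two
competing transfer channels (donor→relay and donor→acceptor) and the relay
feeding a sequential channel (relay→acceptor). All quantities are expressed
through relative rates γ = k_transfer/k_natural:

* donor quench:       Q_D = (γ₁+γ₂)/(1+γ₁+γ₂)
* competitive relay:  Q_c = 1 − (1+γ₁)/(1+γ₁+γ₂)
* sequential relay:   Q_s = γ₃/(1+γ₃)
* total relay quench: Q_relay = 1 − (1−Q_c)(1−Q_s)

where γ₁ = γ_donor→relay, γ₂ = γ_donor→acceptor, γ₃ = γ_relay→acceptor.
Each γ may be given directly or derived from a (R0, R) pair as (R0/R)⁶.
Back-transfer, homo-FRET and direct excitation of the relay are not
modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .fret import efficiency_from_relative_rate

__all__ = [
    "FretNetwork",
    "NetworkResult",
    "donor_quench",
    "relay_quench_competitive",
    "relay_quench_sequential",
    "relay_quench_total",
    "evaluate_network",
    "gamma_from_geometry",
]

EDGES = ("donor_relay", "donor_acceptor", "relay_acceptor")


@dataclass(frozen=True)
class FretNetwork:
    """Relative transfer rates of the three network edges."""

    gamma_donor_relay: float
    gamma_donor_acceptor: float
    gamma_relay_acceptor: float

    def __post_init__(self) -> None:
        for name in (
            "gamma_donor_relay",
            "gamma_donor_acceptor",
            "gamma_relay_acceptor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class NetworkResult:
    """Quench efficiencies of the evaluated network, all in [0, 1]."""

    Q_donor: float
    Q_relay: float
    Q_competitive: float
    Q_sequential: float
    gammas: FretNetwork

    def __post_init__(self) -> None:
        for name in ("Q_donor", "Q_relay", "Q_competitive", "Q_sequential"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def donor_quench(gamma_d_relay: float, gamma_d_acceptor: float) -> float:
    """Total donor quench efficiency: sum of both outgoing FRET channels."""
    if gamma_d_relay < 0 or gamma_d_acceptor < 0:
        raise ValueError("relative rates must be >= 0")
    g = gamma_d_relay + gamma_d_acceptor
    return g / (1.0 + g)


def relay_quench_competitive(gamma_d_relay: float, gamma_d_acceptor: float) -> float:
    """Competitive component: relay excitation lost to the donor→acceptor path."""
    if gamma_d_relay < 0 or gamma_d_acceptor < 0:
        raise ValueError("relative rates must be >= 0")
    return 1.0 - (1.0 + gamma_d_relay) / (1.0 + gamma_d_relay + gamma_d_acceptor)


def relay_quench_sequential(gamma_relay_acceptor: float) -> float:
    """Sequential component: relay→acceptor transfer efficiency γ/(1+γ)."""
    return efficiency_from_relative_rate(gamma_relay_acceptor)


def relay_quench_total(Q_c: float, Q_s: float) -> float:
    """Combine competitive and sequential components: 1 − (1−Q_c)(1−Q_s)."""
    for name, v in (("Q_c", Q_c), ("Q_s", Q_s)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return 1.0 - (1.0 - Q_c) * (1.0 - Q_s)


def gamma_from_geometry(R0_nm: float, R_nm: float) -> float:
    """Relative rate of one edge from its Förster distance and separation."""
    if R0_nm <= 0 or R_nm <= 0:
        raise ValueError("R0 and R must be > 0")
    return (R0_nm / R_nm) ** 6


def evaluate_network(
    distances_nm: dict[str, float] | None = None,
    forster_distances_nm: dict[str, float] | None = None,
    gammas: dict[str, float] | None = None,
) -> NetworkResult:
    """Evaluate the three-node network from geometry or direct rates.

    Parameters
    ----------
    distances_nm, forster_distances_nm : dict
        Center-to-center separations R and Förster distances R0, keyed by
        edge name (``donor_relay``, ``donor_acceptor``, ``relay_acceptor``);
        each edge's γ is (R0/R)⁶.
    gammas : dict
        Direct relative rates per edge. When both a direct γ and a
        geometric one are available for an edge, the direct value wins
        and a warning is emitted.
    """
    gammas = dict(gammas or {})
    resolved: dict[str, float] = {}
    for edge in EDGES:
        geometric = None
        if distances_nm is not None and forster_distances_nm is not None:
            if edge in distances_nm and edge in forster_distances_nm:
                geometric = gamma_from_geometry(
                    forster_distances_nm[edge], distances_nm[edge]
                )
        direct = gammas.get(edge)
        if direct is not None and geometric is not None:
            warnings.warn(
                f"edge {edge!r}: both direct gamma and (R0, R) given; "
                "using the direct value",
                stacklevel=2,
            )
        if direct is not None:
            resolved[edge] = direct
        elif geometric is not None:
            resolved[edge] = geometric
        else:
            raise ValueError(
                f"edge {edge!r} is missing: provide either gamma or (R0, R)"
            )
    net = FretNetwork(
        gamma_donor_relay=resolved["donor_relay"],
        gamma_donor_acceptor=resolved["donor_acceptor"],
        gamma_relay_acceptor=resolved["relay_acceptor"],
    )
    q_d = donor_quench(net.gamma_donor_relay, net.gamma_donor_acceptor)
    q_c = relay_quench_competitive(net.gamma_donor_relay, net.gamma_donor_acceptor)
    q_s = relay_quench_sequential(net.gamma_relay_acceptor)
    q_r = relay_quench_total(q_c, q_s)
    return NetworkResult(
        Q_donor=q_d, Q_relay=q_r, Q_competitive=q_c, Q_sequential=q_s, gammas=net
    )
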