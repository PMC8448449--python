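"""Self-limiting sequential cell loading of a trap-array chip.

Cells are introduced one at a time at the chip inlet, split over the
parallel streets by the binary flow-division tree, and advected down a
street past successive trap entrances.  At each entrance the probability of
entering the apartment equals the instantaneous flow-split fraction at that
node (see :mod:`trapchip.ladder`); in the high-efficiency regime an empty
trap captures with probability exactly one, so ideal loading fills the
street deterministically in introduction order.  Captured cells raise their
trap's resistance by ``kappa``, diverting later cells downstream — the
self-limiting principle.  Cells passing the last trap are washed out.

A brief pressure pulse then transfers trapped cells into the apartments
behind the constrictions; repeating load + transfer builds cell pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ladder import LadderSpec, street_entry_fractions

__all__ = [
    "ChipLayout",
    "LoadingParams",
    "OccupancyState",
    "PairingTable",
    "make_chip_layout",
    "simulate_loading",
    "apply_transfer_pulse",
    "occupancy_histogram",
    "simulate_pairing",
]

#: branch probabilities within this distance of 0 or 1 are treated as
#: degenerate and consume no randomness
DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class ChipLayout:
    """Street/apartment geometry of one chip.

    The inlet feeds ``n_streets = 2**tree_depth`` parallel streets through a
    binary flow-division tree; each street holds ``apartments_per_street``
    traps in series.
    """

    n_streets: int = 128
    apartments_per_street: int = 47
    tree_depth: int = 7

    def __post_init__(self) -> None:
        if self.n_streets < 1 or self.apartments_per_street < 1:
            raise ValueError("layout dimensions must be positive")
        if 2 ** self.tree_depth != self.n_streets:
            raise ValueError(
                f"n_streets={self.n_streets} is not 2**tree_depth={self.tree_depth}"
            )

    @property
    def total_traps(self) -> int:
        return self.n_streets * self.apartments_per_street


def make_chip_layout(config: dict | None = None, **kwargs) -> ChipLayout:
    """Build a :class:`ChipLayout` from a config mapping.

    ``tree_depth`` is inferred from ``n_streets`` when omitted; a street
    count that is not a power of two is rejected.
    """
    cfg = dict(config or {})
    cfg.update(kwargs)
    allowed = {"n_streets", "apartments_per_street", "tree_depth"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown layout keys: {sorted(unknown)}")
    n_streets = int(cfg.get("n_streets", 128))
    if n_streets < 1 or (n_streets & (n_streets - 1)) != 0:
        raise ValueError(f"n_streets={n_streets} must be a power of two")
    depth = int(cfg.get("tree_depth", n_streets.bit_length() - 1))
    return ChipLayout(
        n_streets=n_streets,
        apartments_per_street=int(cfg.get("apartments_per_street", 47)),
        tree_depth=depth,
    )


@dataclass(frozen=True)
class LoadingParams:
    """Stochastic loading parameters.

    ``defect_prob`` is the per-trap probability of a fabrication defect or
    lodged debris that prevents the trap from retaining a cell;
    ``doublet_prob`` is the probability that an arriving "cell" is an
    incompletely dissociated pair (depositing two cells on capture).
    ``trap_capacity`` of 1 is the single-cell mode; 6–10 emulates the
    open-trap cluster mode.  ``street_bias`` weights the binary-tree flow
    split (uniform by default).  Trap-geometry metadata (trap width, pulse
    pressure) is carried for provenance only and does not enter the flow
    model.
    """

    defect_prob: float = 0.0
    doublet_prob: float = 0.0
    transfer_success_prob: float = 1.0
    kappa: float = 100.0
    trap_capacity: int = 1
    street_bias: tuple[float, ...] | None = None
    R_A: float = 1.0
    R_S: float = 10.0
    R_rung: float | None = None
    seed: int = 0
    geometry_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("defect_prob", "doublet_prob", "transfer_success_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.trap_capacity < 1:
            raise ValueError("trap_capacity must be >= 1")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")


@dataclass
class OccupancyState:
    """Per-trap and per-apartment cell counts during loading.

    ``trap_counts`` are cells sitting in the constrictions; ``apartment_counts``
    are cells already transferred behind them.  Both are ``(n_streets,
    apartments_per_street)`` integer arrays.  ``fill_order`` records
    ``(street, position)`` capture events in order.  Book-keeping counters
    support the cell-conservation invariant
    ``introduced == captured + washed_out``.
    """

    layout: ChipLayout
    trap_counts: np.ndarray
    apartment_counts: np.ndarray
    defect_flags: np.ndarray
    fill_order: list[tuple[int, int]] = field(default_factory=list)
    introduced: int = 0
    captured: int = 0
    washed_out: int = 0

    @classmethod
    def empty(cls, layout: ChipLayout, params: LoadingParams,
              rng: np.random.Generator) -> "OccupancyState":
        shape = (layout.n_streets, layout.apartments_per_street)
        defects = rng.random(shape) < params.defect_prob
        return cls(
            layout=layout,
            trap_counts=np.zeros(shape, dtype=int),
            apartment_counts=np.zeros(shape, dtype=int),
            defect_flags=defects,
        )

    @property
    def site_counts(self) -> np.ndarray:
        """Effective occupancy per apartment site (trap + apartment cells)."""
        return self.trap_counts + self.apartment_counts


class _Street:
    """Caches the solved entry fractions of one street's ladder."""

    def __init__(self, n_traps: int, params: LoadingParams):
        self.n_traps = n_traps
        self.params = params
        self.occupied: set[int] = set()
        self._fractions: np.ndarray | None = None

    def entry_fractions(self) -> np.ndarray:
        if self._fractions is None:
            spec = LadderSpec(
                n_traps=self.n_traps,
                R_A=self.params.R_A,
                R_S=self.params.R_S,
                R_rung=self.params.R_rung,
                kappa=self.params.kappa,
                occupied=frozenset(self.occupied),
            )
            self._fractions = street_entry_fractions(spec)
        return self._fractions

    def mark_occupied(self, trap: int) -> None:
        self.occupied.add(trap)
        self._fractions = None


def simulate_loading(layout: ChipLayout, params: LoadingParams, n_cells: int,
                     seed: int | None = None,
                     state: OccupancyState | None = None) -> OccupancyState:
    """Introduce ``n_cells`` sequentially and return the occupancy state.

    Each cell is assigned a street with probability proportional to the
    street weights, then advected past that street's trap entrances.  At a
    retaining (non-defective, non-full) trap it is captured with probability
    equal to the current flow-split fraction at the entrance; the street's
    flows are re-solved after every capture with the occupied trap carrying
    ``kappa``.  Full or defective traps reject the cell without consuming
    randomness (the outcome is the same either way).  Doublet arrivals
    deposit two cells.  Cells passing the last trap are washed out.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    if state is None:
        state = OccupancyState.empty(layout, params, rng)

    weights = params.street_bias
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (layout.n_streets,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("street_bias must be non-negative weights, one per street")
        w = w / w.sum()
    else:
        w = None

    streets = [_Street(layout.apartments_per_street, params) for _ in range(layout.n_streets)]
    for s in range(layout.n_streets):  # resume from existing trap occupancy
        for t in np.flatnonzero(state.trap_counts[s] >= params.trap_capacity):
            streets[s].occupied.add(int(t))

    for _ in range(int(n_cells)):
        if w is None:
            s = int(rng.integers(layout.n_streets))
        else:
            s = int(rng.choice(layout.n_streets, p=w))
        n_deposit = 2 if (params.doublet_prob > 0 and rng.random() < params.doublet_prob) else 1
        state.introduced += n_deposit

        street = streets[s]
        fractions = street.entry_fractions()
        captured = False
        for t in range(layout.apartments_per_street):
            if state.defect_flags[s, t] or state.trap_counts[s, t] >= params.trap_capacity:
                continue  # rejected without consuming randomness
            f = fractions[t]
            if f >= 1.0 - DEGENERATE_TOL:
                enters = True
            elif f <= DEGENERATE_TOL:
                enters = False
            else:
                enters = rng.random() < f
            if enters:
                state.trap_counts[s, t] += n_deposit
                state.fill_order.append((s, t))
                state.captured += n_deposit
                captured = True
                if state.trap_counts[s, t] >= params.trap_capacity:
                    street.mark_occupied(t)
                break
        if not captured:
            state.washed_out += n_deposit
    return state


def apply_transfer_pulse(state: OccupancyState, params: LoadingParams,
                         seed: int | None = None) -> OccupancyState:
    """Move trapped cells into their apartments with a pressure pulse.

    Each trapped cell transfers independently with
    ``transfer_success_prob``; failures stay in the trap.  Apartment counts
    accumulate over successive load/transfer rounds.
    """
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    p = params.transfer_success_prob
    if p >= 1.0:
        moved = state.trap_counts.copy()
    elif p <= 0.0:
        moved = np.zeros_like(state.trap_counts)
    else:
        moved = rng.binomial(state.trap_counts, p)
    state.apartment_counts = state.apartment_counts + moved
    state.trap_counts = state.trap_counts - moved
    return state


def occupancy_histogram(state: OccupancyState) -> dict[str, float]:
    """Fractions of apartments that are empty / singlet / doublet / multiplet.

    Counts are the effective per-site occupancy (trap + apartment cells);
    the four fractions sum to one.
    """
    counts = state.site_counts.ravel()
    n = counts.size
    if n == 0:
        raise ValueError("layout has zero apartments")
    return {
        "empty": float(np.mean(counts == 0)),
        "singlet": float(np.mean(counts == 1)),
        "doublet": float(np.mean(counts == 2)),
        "multiplet": float(np.mean(counts >= 3)),
    }


@dataclass
class PairingTable:
    """Apartment counts by (first-load count : second-load count) category."""

    counts: dict[tuple[int, int], int]
    n_apartments: int

    def fraction(self, first: int, second: int) -> float:
        return self.counts.get((first, second), 0) / self.n_apartments


def simulate_pairing(layout: ChipLayout, params: LoadingParams,
                     n_cells_1: int, n_cells_2: int, seed: int | None = None) -> PairingTable:
    """Run two load-and-transfer rounds and tabulate pairing categories.

    Trap-level defects persist across rounds (they are physical).  After the
    first transfer the constrictions are empty again, so the second load
    re-captures across the whole array; categories are keyed by the cells
    each apartment received in round one versus round two (e.g. ``(1, 1)``
    is a single-cell pair).
    """
    if n_cells_1 < 0 or n_cells_2 < 0:
        raise ValueError("cell loads must be non-negative")
    base = params.seed if seed is None else seed
    rng = np.random.default_rng(base)
    state = OccupancyState.empty(layout, params, rng)

    state = simulate_loading(layout, params, n_cells_1, seed=int(rng.integers(2**31)), state=state)
    state = apply_transfer_pulse(state, params, seed=int(rng.integers(2**31)))
    first = state.apartment_counts.copy()

    state = simulate_loading(layout, params, n_cells_2, seed=int(rng.integers(2**31)), state=state)
    state = apply_transfer_pulse(state, params, seed=int(rng.integers(2**31)))
    second = state.apartment_counts - first

    table: dict[tuple[int, int], int] = {}
    for a, b in zip(first.ravel(), second.ravel()):
        key = (int(a), int(b))
        table[key] = table.get(key, 0) + 1
    return PairingTable(counts=table, n_apartments=layout.total_traps)
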