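"""Exact stochastic simulation of reaction networks (Gillespie direct method),
extended with *immediate reactions* and timed control actions.

The direct method draws the waiting time to the next reaction event from
Exp(a0), where a0 is the sum of all reaction propensities, and picks the
reaction with probability proportional to its propensity.  Immediate
reactions are all-or-nothing rules that fire as soon as their left-hand
stoichiometry is satisfiable; they encode sequential/steric constraints
(site occupancy, gated forward motion) inside an otherwise concurrent
simulation.  Timed control actions let an operator add/remove molecules or
change a rate constant at a prescribed simulation time.

State is an integer copy-number vector; propensities use the exact
combinatorial count h_j of distinct reactant combinations (binomial
coefficients for stoichiometries >= 2), so the simulation samples the
chemical master equation exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SpeciesState",
    "KineticReaction",
    "ImmediateReaction",
    "TimedEvent",
    "SimulationConfig",
    "Trajectory",
    "CompiledModel",
    "SimulationError",
    "ImmediateCascadeError",
    "MaxEventsExceeded",
    "TimedEventError",
    "propensity",
    "sample_next_event",
    "fire_immediates",
    "apply_timed_event",
    "compile_model",
    "run",
]

HALT = None  # sentinel returned by sample_next_event when a0 == 0

DEFAULT_IMMEDIATE_CAP = 10**6


class SimulationError(RuntimeError):
    pass


class ImmediateCascadeError(SimulationError):
    """An immediate-reaction cascade exceeded the iteration cap.

    Almost always a self-triggering immediate (its products replenish its
    own trigger), which is a model error, not a numerical one.
    """


class TimedEventError(SimulationError):
    """A timed removal asked for more molecules than are present."""


class MaxEventsExceeded(SimulationError):
    """Event budget exhausted; the partial trajectory is attached."""

    def __init__(self, message: str, trajectory: "Trajectory"):
        super().__init__(message)
        self.trajectory = trajectory


class SpeciesState:
    """Integer copy-number vector over named species.

    Counts are non-negative integers (molecules).  The species set is fixed
    at construction; simulations never create species dynamically.
    """

    __slots__ = ("counts",)

    def __init__(self, counts: Mapping[str, int]):
        clean: dict[str, int] = {}
        for name, n in counts.items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for species {name!r}: {n}")
            clean[name] = n
        self.counts = clean

    def __getitem__(self, name: str) -> int:
        return self.counts[name]

    def __setitem__(self, name: str, value: int) -> None:
        if name not in self.counts:
            raise KeyError(f"unknown species {name!r}")
        value = int(value)
        if value < 0:
            raise ValueError(f"negative count for species {name!r}: {value}")
        self.counts[name] = value

    def __contains__(self, name: str) -> bool:
        return name in self.counts

    def __iter__(self):
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other) -> bool:
        if isinstance(other, SpeciesState):
            return self.counts == other.counts
        return NotImplemented

    def __repr__(self) -> str:
        return f"SpeciesState({self.counts!r})"

    def copy(self) -> "SpeciesState":
        return SpeciesState(self.counts)


@dataclass
class KineticReaction:
    """Mass-action reaction with stochastic rate constant ``c``.

    ``c`` is in per-reaction-event units (1/s for the complete propensity
    a = c * h, where h counts distinct reactant combinations).  An empty
    reactant list is a zero-order source ("null > A") with a = c.
    """

    id: str
    c: float
    reactants: list[tuple[str, int]]
    products: list[tuple[str, int]]
    line: int | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.c < 0:
            raise ValueError(f"reaction {self.id!r}: negative rate constant {self.c}")
        for name, nu in list(self.reactants) + list(self.products):
            if nu <= 0:
                raise ValueError(
                    f"reaction {self.id!r}: non-positive coefficient {nu} for {name!r}"
                )


@dataclass
class ImmediateReaction:
    """All-or-nothing rule: fires whenever every trigger species count is at
    least its coefficient, consuming the trigger and emitting the products.

    Declaration order is semantically meaningful: simultaneously satisfiable
    immediates fire in declaration order, and cascades rescan from the first
    immediate after every firing, until quiescence.
    """

    id: str
    trigger: list[tuple[str, int]]
    products: list[tuple[str, int]]
    line: int | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.trigger:
            raise ValueError(f"immediate {self.id!r}: empty trigger")
        for name, nu in list(self.trigger) + list(self.products):
            if nu <= 0:
                raise ValueError(
                    f"immediate {self.id!r}: non-positive coefficient {nu} for {name!r}"
                )


@dataclass
class TimedEvent:
    """Operator control action applied when the clock reaches ``time``.

    kind is one of "add", "remove" (species, integer amount) or "rate"
    (reaction id, new rate constant).
    """

    time: float
    kind: str
    species: str | None = None
    amount: int | None = None
    reaction_id: str | None = None
    value: float | None = None
    line: int | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"timed event at negative time {self.time}")
        if self.kind in ("add", "remove"):
            if self.species is None or self.amount is None or self.amount <= 0:
                raise ValueError(f"{self.kind} event needs a species and a positive amount")
        elif self.kind == "rate":
            if self.reaction_id is None or self.value is None or self.value < 0:
                raise ValueError("rate event needs a reaction id and a non-negative value")
        else:
            raise ValueError(f"unknown timed-event kind {self.kind!r}")


@dataclass
class SimulationConfig:
    t_end: float
    sample_dt: float
    seed: int = 0
    max_events: int = 500_000_000
    immediate_cap: int = DEFAULT_IMMEDIATE_CAP

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be positive")


@dataclass
class Trajectory:
    """Sampled time x species matrix plus cumulative reaction-firing counters.

    Sampling is last-value-carried-forward onto a fixed grid.  ``firings``
    has one column per reaction (kinetic reactions first, then immediates,
    in ``reaction_ids`` order) and is cumulative, hence non-decreasing in
    time.
    """

    times: np.ndarray
    species: list[str]
    counts: np.ndarray  # (n_samples, n_species) int64
    reaction_ids: list[str]
    firings: np.ndarray  # (n_samples, n_reactions) int64, cumulative
    seed: int

    def column(self, species: str) -> np.ndarray:
        return self.counts[:, self.species.index(species)]

    def final_firings(self) -> dict[str, int]:
        return dict(zip(self.reaction_ids, (int(v) for v in self.firings[-1])))

    def to_tsv(self, path) -> None:
        """Tab-separated dump: first column `time`, one column per species."""
        with open(path, "w") as fh:
            fh.write("time\t" + "\t".join(self.species) + "\n")
            for i, t in enumerate(self.times):
                fh.write(f"{t:g}\t" + "\t".join(str(int(v)) for v in self.counts[i]) + "\n")

    def firings_to_tsv(self, path) -> None:
        """Companion firing-counter file: one row per reaction (final totals)."""
        with open(path, "w") as fh:
            fh.write("reaction_id\tfirings\n")
            for rid, n in self.final_firings().items():
                fh.write(f"{rid}\t{n}\n")

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        species = [c for c in df.columns if c != "time"]
        return cls(
            times=df["time"].to_numpy(float),
            species=species,
            counts=df[species].to_numpy(np.int64),
            reaction_ids=[],
            firings=np.zeros((len(df), 0), dtype=np.int64),
            seed=-1,
        )


# ---------------------------------------------------------------------------
# Elementary operations (reference Python implementations; the event loop in
# run() uses the compiled kernels in _engine.py with identical semantics).
# ---------------------------------------------------------------------------


def propensity(r: KineticReaction, s: SpeciesState) -> float:
    """a_j = c_j * h_j with h_j = prod_i C(X_i, nu_i).

    Zero-order reactions (empty reactant list) return c.
    """
    a = r.c
    for name, nu in r.reactants:
        a *= math.comb(s[name], nu)
        if a == 0.0:
            return 0.0
    return a


def sample_next_event(
    reactions: Sequence[KineticReaction], s: SpeciesState, rng: np.random.Generator
):
    """Direct-method draw: (tau, reaction_id), or None (halt) when a0 == 0."""
    a = np.array([propensity(r, s) for r in reactions], dtype=float)
    a0 = a.sum()
    if a0 <= 0.0:
        return HALT
    tau = -math.log(rng.random()) / a0
    u = rng.random() * a0
    j = int(np.searchsorted(np.cumsum(a), u, side="left"))
    j = min(j, len(reactions) - 1)
    return tau, reactions[j].id


def fire_immediates(
    s: SpeciesState,
    immediates: Sequence[ImmediateReaction],
    cap: int = DEFAULT_IMMEDIATE_CAP,
) -> dict[str, int]:
    """Run immediates to quiescence, in declaration order, rescanning from the
    first immediate after every firing.  Returns per-immediate firing counts.

    Mutates ``s`` in place.  Raises ImmediateCascadeError if the cascade
    exceeds ``cap`` firings (self-triggering loop).
    """
    fired = {im.id: 0 for im in immediates}
    total = 0
    i = 0
    while i < len(immediates):
        im = immediates[i]
        if all(s[name] >= nu for name, nu in im.trigger):
            total += 1
            if total > cap:
                raise ImmediateCascadeError(
                    f"immediate cascade exceeded {cap} firings "
                    f"(last fired: {im.id!r}); self-triggering loop?"
                )
            for name, nu in im.trigger:
                s[name] = s[name] - nu
            for name, nu in im.products:
                s[name] = s[name] + nu
            fired[im.id] += 1
            i = 0
        else:
            i += 1
    return fired


def apply_timed_event(
    s: SpeciesState, reactions: Sequence[KineticReaction], e: TimedEvent
) -> None:
    """Apply one control action in place (add/remove molecules, set a rate).

    The caller is responsible for re-running fire_immediates afterwards.
    """
    if e.kind == "add":
        s[e.species] = s[e.species] + e.amount
    elif e.kind == "remove":
        if s[e.species] < e.amount:
            raise TimedEventError(
                f"t={e.time}: cannot remove {e.amount} {e.species!r} "
                f"(only {s[e.species]} present)"
            )
        s[e.species] = s[e.species] - e.amount
    elif e.kind == "rate":
        for r in reactions:
            if r.id == e.reaction_id:
                r.c = e.value
                return
        raise SimulationError(f"rate event targets unknown reaction {e.reaction_id!r}")


# ---------------------------------------------------------------------------
# Compilation to flat arrays + event loop
# ---------------------------------------------------------------------------


@dataclass
class CompiledModel:
    species: list[str]
    index: dict[str, int]
    x0: np.ndarray  # int64
    c: np.ndarray  # float64, kinetic rate constants
    kinetic_ids: list[str]
    immediate_ids: list[str]
    # CSR-style stoichiometry (reactants/products of kinetics, triggers/products of immediates)
    rptr: np.ndarray
    ridx: np.ndarray
    rcoe: np.ndarray
    pptr: np.ndarray
    pidx: np.ndarray
    pcoe: np.ndarray
    tptr: np.ndarray
    tidx: np.ndarray
    tcoe: np.ndarray
    qptr: np.ndarray
    qidx: np.ndarray
    qcoe: np.ndarray
    timed_events: list[TimedEvent]

    @property
    def reaction_ids(self) -> list[str]:
        return self.kinetic_ids + self.immediate_ids


def _csr(pairs_per_row: list[list[tuple[int, int]]]):
    ptr = np.zeros(len(pairs_per_row) + 1, dtype=np.int64)
    idx, coe = [], []
    for i, pairs in enumerate(pairs_per_row):
        for j, nu in pairs:
            idx.append(j)
            coe.append(nu)
        ptr[i + 1] = len(idx)
    return ptr, np.asarray(idx, dtype=np.int64), np.asarray(coe, dtype=np.int64)


def compile_model(model) -> CompiledModel:
    """Flatten a ModelDocument into index arrays for the simulation kernel.

    Raises SimulationError if any reaction, trigger or event references a
    species with no initial-count entry (model-validation error at load).
    """
    species = list(model.initial_counts.keys())
    index = {name: i for i, name in enumerate(species)}

    def lookup(pairs, where):
        out = []
        for name, nu in pairs:
            if name not in index:
                raise SimulationError(f"{where} references unknown species {name!r}")
            out.append((index[name], int(nu)))
        return out

    r_rows, p_rows, c_vals, kin_ids = [], [], [], []
    for r in model.kinetic_reactions:
        r_rows.append(lookup(r.reactants, f"reaction {r.id!r}"))
        p_rows.append(lookup(r.products, f"reaction {r.id!r}"))
        c_vals.append(float(r.c))
        kin_ids.append(r.id)
    t_rows, q_rows, imm_ids = [], [], []
    for im in model.immediate_reactions:
        t_rows.append(lookup(im.trigger, f"immediate {im.id!r}"))
        q_rows.append(lookup(im.products, f"immediate {im.id!r}"))
        imm_ids.append(im.id)
    for e in model.timed_events:
        if e.kind in ("add", "remove") and e.species not in index:
            raise SimulationError(f"timed event references unknown species {e.species!r}")
        if e.kind == "rate" and e.reaction_id not in kin_ids:
            raise SimulationError(f"timed event references unknown reaction {e.reaction_id!r}")

    rptr, ridx, rcoe = _csr(r_rows)
    pptr, pidx, pcoe = _csr(p_rows)
    tptr, tidx, tcoe = _csr(t_rows)
    qptr, qidx, qcoe = _csr(q_rows)
    x0 = np.array([int(model.initial_counts[s]) for s in species], dtype=np.int64)
    if (x0 < 0).any():
        raise SimulationError("negative initial count")
    return CompiledModel(
        species=species,
        index=index,
        x0=x0,
        c=np.asarray(c_vals, dtype=float),
        kinetic_ids=kin_ids,
        immediate_ids=imm_ids,
        rptr=rptr, ridx=ridx, rcoe=rcoe,
        pptr=pptr, pidx=pidx, pcoe=pcoe,
        tptr=tptr, tidx=tidx, tcoe=tcoe,
        qptr=qptr, qidx=qidx, qcoe=qcoe,
        timed_events=sorted(model.timed_events, key=lambda e: e.time),
    )


def run(model, cfg: SimulationConfig) -> Trajectory:
    """Simulate a parsed/built model and sample it onto a fixed time grid.

    The event loop interleaves direct-method SSA steps, timed control
    actions (the clock jumps to the event time when the next tau would
    cross it -- exact by memorylessness of the exponential), and
    immediate-reaction quiescence after every state change.
    """
    from . import _engine

    cm = compile_model(model)
    n_samples = int(math.floor(cfg.t_end / cfg.sample_dt + 1e-9)) + 1
    sample_times = np.arange(n_samples, dtype=float) * cfg.sample_dt

    x = cm.x0.copy()
    c = cm.c.copy()
    nk, ni = len(cm.kinetic_ids), len(cm.immediate_ids)
    counts = np.zeros((n_samples, len(cm.species)), dtype=np.int64)
    fir_out = np.zeros((n_samples, nk + ni), dtype=np.int64)
    fir_kin = np.zeros(nk, dtype=np.int64)
    fir_imm = np.zeros(ni, dtype=np.int64)

    _engine.set_seed(int(cfg.seed) % (2**32))
    # quiescence of the initial state, before the first sample is recorded
    if _engine.quiesce(x, cm.tptr, cm.tidx, cm.tcoe, cm.qptr, cm.qidx, cm.qcoe,
                       fir_imm, cfg.immediate_cap) < 0:
        raise ImmediateCascadeError("immediate cascade in the initial state")
    if (x < 0).any():
        raise SimulationError("immediate reaction drove a count negative at t=0")

    def make_trajectory(spos):
        # pad unreached samples with the last state (truncation only)
        for k in range(spos, n_samples):
            counts[k] = x
            fir_out[k, :nk] = fir_kin
            fir_out[k, nk:] = fir_imm
        return Trajectory(
            times=sample_times, species=list(cm.species), counts=counts,
            reaction_ids=cm.reaction_ids, firings=fir_out, seed=cfg.seed,
        )

    t = 0.0
    spos = 0
    n_events = 0
    rate_index = {rid: i for i, rid in enumerate(cm.kinetic_ids)}

    breakpoints = [e for e in cm.timed_events if e.time <= cfg.t_end]
    segment_ends = [e.time for e in breakpoints] + [cfg.t_end]
    ev_iter = iter(breakpoints + [None])

    for stop, event in zip(segment_ends, ev_iter):
        if stop > t or event is None:
            t, spos, n_events, status = _engine.run_segment(
                x, t, c,
                cm.rptr, cm.ridx, cm.rcoe, cm.pptr, cm.pidx, cm.pcoe,
                cm.tptr, cm.tidx, cm.tcoe, cm.qptr, cm.qidx, cm.qcoe,
                float(stop), sample_times, spos, counts, fir_out,
                fir_kin, fir_imm, int(cfg.max_events), int(cfg.immediate_cap),
                n_events,
            )
            if status == 2:
                raise ImmediateCascadeError(
                    f"immediate cascade exceeded {cfg.immediate_cap} firings at t~{t:g}"
                )
            if status == 1:
                raise MaxEventsExceeded(
                    f"max_events={cfg.max_events} exceeded at t={t:g}",
                    make_trajectory(spos),
                )
        if event is not None:
            if event.kind == "add":
                x[cm.index[event.species]] += event.amount
            elif event.kind == "remove":
                i = cm.index[event.species]
                if x[i] < event.amount:
                    raise TimedEventError(
                        f"t={event.time}: cannot remove {event.amount} "
                        f"{event.species!r} (only {int(x[i])} present)"
                    )
                x[i] -= event.amount
            else:  # rate
                c[rate_index[event.reaction_id]] = event.value
            if _engine.quiesce(x, cm.tptr, cm.tidx, cm.tcoe, cm.qptr, cm.qidx,
                               cm.qcoe, fir_imm, cfg.immediate_cap) < 0:
                raise ImmediateCascadeError(
                    f"immediate cascade after timed event at t={event.time}"
                )

    return make_trajectory(spos)
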