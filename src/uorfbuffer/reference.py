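"""Naive per-site reference simulator.

A straightforward, unoptimized realization of the same update schedule as
:mod:`uorfbuffer.engine`: the mRNA is an explicit occupancy array and each
ribosome is a small mutable record. Because both implementations consume
uniform draws from the same MT19937 stream in the same documented order,
the two produce identical trajectories and counters for a shared seed;
tests exploit this as an independent cross-check of the optimized kernel.

This module favors clarity over speed; use it for small lattices and short
runs only.
"""

from __future__ import annotations

import numpy as np

from .engine import SimCounters
from .layout import MRNALayout, ConfigurationError
from .params import KineticParams

__all__ = ["ReferenceSimulation", "run_reference"]


class _Rib:
    __slots__ = ("pos", "is_80s", "feature", "committed")

    def __init__(self, pos: int):
        self.pos = pos
        self.is_80s = False
        self.feature = -1  # feature index once elongating
        self.committed = False  # failed initiation at the current start codon


class ReferenceSimulation:
    """Stepwise simulation state with an explicit occupancy lattice."""

    def __init__(self, layout: MRNALayout, params: KineticParams, seed: int):
        self.layout = layout
        self.params = params.effective()
        self.rng = np.random.RandomState(np.uint32(seed))
        self.occ = np.zeros(layout.total_len_nt, dtype=bool)  # leading edges
        self.ribs: list[_Rib] = []  # sorted by pos ascending
        n_uorfs = len(layout.uorfs)
        self.init_probs = [self.params.i_uorf, self.params.i_uorf2][:n_uorfs] + [
            self.params.i_cds
        ]
        self.elong_probs = [self.params.v_eu] * n_uorfs + [self.params.v_ec]
        self.start_of = {u.start_nt: k for k, u in enumerate(layout.uorfs)}
        self.start_of[layout.cds_start_nt] = n_uorfs
        self.stops = [u.stop_nt for u in layout.uorfs] + [layout.cds_stop_nt]
        self.n_feat = n_uorfs + 1
        self.counts = {
            "n_ec": 0,
            "n_eu": [0] * n_uorfs,
            "n_loaded": 0,
            "n_dissoc_down": 0,
            "n_dissoc_up": 0,
            "n_runoff": 0,
            "n_actions": 0,
        }

    # -- helpers -----------------------------------------------------------
    def _gap_ok(self, target: int, ahead: "_Rib | None") -> bool:
        return ahead is None or ahead.pos - target >= self.params.footprint_nt

    def _remove(self, rib: _Rib) -> None:
        self.occ[rib.pos] = False
        self.ribs.remove(rib)

    def _move(self, rib: _Rib, target: int) -> None:
        self.occ[rib.pos] = False
        self.occ[target] = True
        rib.pos = target

    # -- one action --------------------------------------------------------
    def attempt_load(self) -> None:
        """5'-end loading attempt; consumes one draw unconditionally."""
        u = self.rng.random_sample()
        if u < self.params.r_in and not self.occ[: self.params.footprint_nt].any():
            rib = _Rib(0)
            self.ribs.insert(0, rib)
            self.occ[0] = True
            self.counts["n_loaded"] += 1

    def step_action(self) -> None:
        """One full action: a loading attempt plus one event per ribosome,
        visited 3'-most first."""
        self.attempt_load()
        for rib in list(reversed(self.ribs)):
            if rib not in self.ribs:  # dislodged earlier in this action
                continue
            if rib.is_80s:
                self._update_80s(rib)
            else:
                self._update_40s(rib)
        self.counts["n_actions"] += 1

    def _ahead(self, rib: _Rib) -> "_Rib | None":
        i = self.ribs.index(rib)
        return self.ribs[i + 1] if i + 1 < len(self.ribs) else None

    def _update_40s(self, rib: _Rib) -> None:
        f = self.start_of.get(rib.pos)
        if f is not None and not rib.committed:
            u = self.rng.random_sample()
            if u < self.init_probs[f]:
                rib.is_80s = True
                rib.feature = f
                return
            rib.committed = True  # leaky scanning from now on at this start
        target = rib.pos + 1
        ahead = self._ahead(rib)
        jammed = target < self.layout.total_len_nt and not self._gap_ok(target, ahead)
        if jammed and (not ahead.is_80s or self.params.k_up == 0.0):
            return  # provably inert: no draw spent
        u = self.rng.random_sample()
        if u >= self.params.v_s:
            return
        if target >= self.layout.total_len_nt:
            self._remove(rib)
            self.counts["n_runoff"] += 1
        elif jammed:
            # collision with an elongating ribosome ahead: the scanning
            # subunit itself may be dislodged (upstream dissociation)
            u2 = self.rng.random_sample()
            if u2 < self.params.k_up:
                self._remove(rib)
                self.counts["n_dissoc_up"] += 1
        else:
            self._move(rib, target)
            rib.committed = False

    def _update_80s(self, rib: _Rib) -> None:
        target = rib.pos + 3
        terminating = target == self.stops[rib.feature]
        ahead = self._ahead(rib)
        jammed = not terminating and not self._gap_ok(target, ahead)
        if jammed and (ahead.is_80s or self.params.k_down == 0.0):
            return  # provably inert: no draw spent
        u = self.rng.random_sample()
        if u >= self.elong_probs[rib.feature]:
            return
        if terminating:
            self._remove(rib)
            if rib.feature == self.n_feat - 1:
                self.counts["n_ec"] += 1
            else:
                self.counts["n_eu"][rib.feature] += 1
        elif jammed:
            # collision with a scanning subunit ahead: downstream dissociation
            u2 = self.rng.random_sample()
            if u2 < self.params.k_down:
                self._remove(ahead)
                self.counts["n_dissoc_down"] += 1
        else:
            self._move(rib, target)

    # -- bookkeeping -------------------------------------------------------
    def counters(self) -> SimCounters:
        c = self.counts
        return SimCounters(
            n_ec=c["n_ec"],
            n_eu=tuple(c["n_eu"]),
            n_loaded=c["n_loaded"],
            n_dissoc_down=c["n_dissoc_down"],
            n_dissoc_up=c["n_dissoc_up"],
            n_runoff=c["n_runoff"],
            n_actions=c["n_actions"],
            n_on_lattice=len(self.ribs),
        )

    def check_invariants(self) -> None:
        """Assert no-overlap, ordering, and ribosome conservation."""
        fp = self.params.footprint_nt
        for a, b in zip(self.ribs, self.ribs[1:]):
            assert b.pos - a.pos >= fp, f"overlap: {a.pos} vs {b.pos}"
        assert self.counters().conservation_ok(), "ribosome conservation violated"


def run_reference(
    layout: MRNALayout, params: KineticParams, n_actions: int, seed: int
) -> SimCounters:
    """Run the naive simulator; API mirror of
    :func:`uorfbuffer.engine.run_simulation`."""
    if n_actions < 1:
        raise ConfigurationError(f"n_actions must be >= 1, got {n_actions}")
    sim = ReferenceSimulation(layout, params, seed)
    for _ in range(n_actions):
        sim.step_action()
    return sim.counters()
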