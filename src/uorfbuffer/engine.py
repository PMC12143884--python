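"""Optimized stochastic simulator of ribosome traffic on one mRNA.

The mRNA is a 1D lattice. Scanning 40S subunits load at the 5' end with
probability ``r_in`` per action, scan 3'-ward one nucleotide at a time
(probability ``v_s``), may convert to elongating 80S ribosomes at uORF/CDS
start codons, and 80S ribosomes step one codon (3 nt) at a time until they
terminate at their feature's stop codon. Both species exclude
``footprint_nt`` nucleotides. A blocked move is a collision; depending on
the dissociation model, an 80S blocked by a 40S may knock that 40S off
(probability ``k_down``) and a 40S blocked by an 80S may itself be knocked
off (probability ``k_up``). 80S-80S and 40S-40S contacts always just block.

One *action* is: one loading attempt, then every ribosome on the lattice,
visited 3'->5', attempts exactly one event. Random draws are consumed in a
fixed documented order (see :func:`_kernel`), so a run is bit-reproducible
from its seed, and the naive reference simulator in
:mod:`uorfbuffer.reference` replays the identical trajectory from the same
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .layout import MRNALayout, ConfigurationError
from .params import KineticParams

__all__ = ["SimCounters", "run_simulation"]

# ribosome kinds in the state arrays
_KIND_40S = 0
_KIND_80S = 1


@dataclass(frozen=True)
class SimCounters:
    """Event tallies from one simulation run.

    ``n_eu`` is a per-uORF tuple (empty for a uORF-less mRNA). Ribosome
    conservation holds after every action:
    ``n_loaded == n_ec + sum(n_eu) + n_dissoc_down + n_dissoc_up
    + n_runoff + n_on_lattice``.
    """

    n_ec: int
    n_eu: tuple[int, ...]
    n_loaded: int
    n_dissoc_down: int
    n_dissoc_up: int
    n_runoff: int
    n_actions: int
    n_on_lattice: int

    @property
    def n_eu_total(self) -> int:
        return sum(self.n_eu)

    def conservation_ok(self) -> bool:
        return self.n_loaded == (
            self.n_ec
            + self.n_eu_total
            + self.n_dissoc_down
            + self.n_dissoc_up
            + self.n_runoff
            + self.n_on_lattice
        )

    def to_dict(self) -> dict:
        return {
            "n_ec": self.n_ec,
            "n_eu": list(self.n_eu),
            "n_loaded": self.n_loaded,
            "n_dissoc_down": self.n_dissoc_down,
            "n_dissoc_up": self.n_dissoc_up,
            "n_runoff": self.n_runoff,
            "n_actions": self.n_actions,
            "n_on_lattice": self.n_on_lattice,
        }


@njit(cache=True)
def _kernel(
    total_len,
    start_lut,  # int8[total_len]: feature index + 1 at start codons, else 0
    stops,  # int64[n_feat]: stop-codon offset per feature (uORFs..., CDS)
    init_probs,  # float64[n_feat]
    elong_probs,  # float64[n_feat]: v_eu for uORFs, v_ec for the CDS
    r_in,
    v_s,
    k_up,
    k_down,
    footprint,
    n_actions,
    seed,
):
    # Draw order per action (fixed; shared with the reference simulator):
    #   1. one uniform for the loading attempt (consumed even when blocked);
    #   2. per ribosome, 3'->5':
    #      40S on a start codon, not yet committed: one uniform vs the
    #        initiation probability; on failure it commits to leaky scanning
    #        and immediately draws one uniform vs v_s for a 1-nt advance;
    #      40S elsewhere (or committed): one uniform vs v_s;
    #      80S: one uniform vs its elongation probability;
    #      a blocked move whose mover/blocker kinds match a dissociation
    #        rule (80S behind 40S with k_down > 0, or 40S behind 80S with
    #        k_up > 0) draws one further uniform vs k_down / k_up; the roll
    #        repeats on every blocked attempt while the contact lasts.
    #      no draw is spent on a provably inert update: a jammed mover whose
    #        blocked advance can neither terminate nor trigger a dissociation
    #        (same-kind blocker, or the relevant k is exactly 0) skips its
    #        move draw, since every outcome is a no-op.
    np.random.seed(seed)
    n_feat = stops.shape[0]
    cap = total_len // footprint + 2
    pos = np.empty(cap, dtype=np.int64)
    kind = np.empty(cap, dtype=np.int8)
    feat = np.empty(cap, dtype=np.int8)  # -1 for 40S, else feature index
    committed = np.zeros(cap, dtype=np.bool_)
    n = 0

    n_ec = 0
    n_eu = np.zeros(n_feat, dtype=np.int64)  # last slot (CDS) unused
    n_loaded = 0
    n_dissoc_down = 0
    n_dissoc_up = 0
    n_runoff = 0

    for _ in range(n_actions):
        # -- loading attempt at the 5' end
        u = np.random.random()
        if u < r_in and (n == 0 or pos[0] >= footprint):
            for j in range(n, 0, -1):
                pos[j] = pos[j - 1]
                kind[j] = kind[j - 1]
                feat[j] = feat[j - 1]
                committed[j] = committed[j - 1]
            pos[0] = 0
            kind[0] = _KIND_40S
            feat[0] = -1
            committed[0] = False
            n += 1
            n_loaded += 1

        # -- per-ribosome updates, 3'-most first
        i = n - 1
        while i >= 0:
            removed_self = False
            if kind[i] == _KIND_40S:
                f = start_lut[pos[i]] - 1
                attempted_move = False
                if f >= 0 and not committed[i]:
                    u = np.random.random()
                    if u < init_probs[f]:
                        kind[i] = _KIND_80S
                        feat[i] = f
                    else:
                        committed[i] = True
                        attempted_move = True
                else:
                    attempted_move = True
                if attempted_move:
                    target = pos[i] + 1
                    jammed = (
                        target < total_len
                        and i + 1 < n
                        and pos[i + 1] - target < footprint
                    )
                    inert = jammed and (
                        kind[i + 1] == _KIND_40S or k_up == 0.0
                    )
                    if not inert:
                        u = np.random.random()
                        if u < v_s:
                            if target >= total_len:
                                n_runoff += 1
                                removed_self = True
                            elif jammed:
                                # blocked by an 80S: upstream dissociation roll
                                u2 = np.random.random()
                                if u2 < k_up:
                                    n_dissoc_up += 1
                                    removed_self = True
                            else:
                                pos[i] = target
                                committed[i] = False
            else:  # 80S
                f = feat[i]
                target = pos[i] + 3
                jammed = (
                    target != stops[f]
                    and i + 1 < n
                    and pos[i + 1] - target < footprint
                )
                inert = jammed and (
                    kind[i + 1] == _KIND_80S or k_down == 0.0
                )
                if not inert:
                    u = np.random.random()
                    if u < elong_probs[f]:
                        if target == stops[f]:
                            if f == n_feat - 1:
                                n_ec += 1
                            else:
                                n_eu[f] += 1
                            removed_self = True
                        elif jammed:
                            # blocked by a 40S: downstream dissociation roll
                            u2 = np.random.random()
                            if u2 < k_down:
                                # remove the downstream blocker (already
                                # updated this action, being 3' of mover)
                                n_dissoc_down += 1
                                for j in range(i + 1, n - 1):
                                    pos[j] = pos[j + 1]
                                    kind[j] = kind[j + 1]
                                    feat[j] = feat[j + 1]
                                    committed[j] = committed[j + 1]
                                n -= 1
                        else:
                            pos[i] = target
            if removed_self:
                for j in range(i, n - 1):
                    pos[j] = pos[j + 1]
                    kind[j] = kind[j + 1]
                    feat[j] = feat[j + 1]
                    committed[j] = committed[j + 1]
                n -= 1
            i -= 1

    return n_ec, n_eu, n_loaded, n_dissoc_down, n_dissoc_up, n_runoff, n, pos[:n].copy(), kind[:n].copy()


def run_simulation(
    layout: MRNALayout,
    params: KineticParams,
    n_actions: int,
    seed: int,
    return_state: bool = False,
):
    """Run ``n_actions`` update actions from an empty lattice.

    Deterministic given ``(layout, params, n_actions, seed)``. Returns a
    :class:`SimCounters`; with ``return_state=True`` also the final
    ``(positions, kinds)`` arrays (kind 0 = 40S, 1 = 80S).
    """
    if n_actions < 1:
        raise ConfigurationError(f"n_actions must be >= 1, got {n_actions}")
    p = params.effective()
    n_uorfs = len(layout.uorfs)
    i_uorf_each = [p.i_uorf, p.i_uorf2][:n_uorfs]
    init_probs = np.asarray(i_uorf_each + [p.i_cds], dtype=np.float64)
    elong_probs = np.asarray([p.v_eu] * n_uorfs + [p.v_ec], dtype=np.float64)
    out = _kernel(
        layout.total_len_nt,
        layout.start_codon_lookup(),
        layout.feature_stops(),
        init_probs,
        elong_probs,
        p.r_in,
        p.v_s,
        p.k_up,
        p.k_down,
        p.footprint_nt,
        int(n_actions),
        np.uint32(seed),
    )
    n_ec, n_eu, n_loaded, n_dd, n_du, n_run, n_left, pos, kinds = out
    counters = SimCounters(
        n_ec=int(n_ec),
        n_eu=tuple(int(x) for x in n_eu[:n_uorfs]),
        n_loaded=int(n_loaded),
        n_dissoc_down=int(n_dd),
        n_dissoc_up=int(n_du),
        n_runoff=int(n_run),
        n_actions=int(n_actions),
        n_on_lattice=int(n_left),
    )
    if return_state:
        return counters, (pos, kinds)
    return counters
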