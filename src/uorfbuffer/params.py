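"""Kinetic parameters of the extended scanning/elongation lattice model."""

from __future__ import annotations

from dataclasses import dataclass, replace

from .layout import ConfigurationError

__all__ = ["KineticParams", "DISSOCIATION_MODELS"]

DISSOCIATION_MODELS = ("downstream", "upstream", "double")

_PROB_FIELDS = ("r_in", "i_uorf", "i_uorf2", "i_cds", "v_s", "v_eu", "v_ec", "k_up", "k_down")


@dataclass(frozen=True)
class KineticParams:
    """Per-action event probabilities.

    Attributes
    ----------
    r_in:
        Probability of loading a new scanning 40S at the 5' end (ribosome
        availability proxy).
    i_uorf, i_uorf2:
        Initiation probability when a 40S sits on the uATG of the first /
        second uORF.
    i_cds:
        Initiation probability at the CDS start codon.
    v_s:
        Probability a 40S advances one nucleotide per update.
    v_eu, v_ec:
        Probability an 80S advances one codon per update inside a uORF /
        the CDS. The CDS default is faster since uORFs tend to encode
        stalling peptides.
    k_up:
        Per-blocked-attempt probability that a scanning 40S blocked by an
        80S ahead is itself dissociated (upstream dissociation).
    k_down:
        Per-blocked-attempt probability that an elongating 80S blocked by a
        40S ahead knocks that 40S off the mRNA (downstream dissociation).
        Collision contacts persist for many actions, so these per-action
        probabilities integrate to much larger per-encounter dissociation
        probabilities; the small default keeps collision losses responding
        smoothly to ribosome loading rather than saturating.
    model:
        "downstream" (k_up forced to 0), "upstream" (k_down forced to 0),
        or "double" (both rules active).
    footprint_nt:
        Exclusion length of either ribosome species; an attempted move that
        would bring two positions closer than this is a collision. The
        default of one codon treats each ribosome as a point particle on a
        codon-sized exclusion grid, the classic TASEP convention; it also
        makes the 5'-end loading capacity (v_s / footprint_nt = 0.1 per
        action) span the standard loading-rate ensemble U(0, 0.1).
    """

    r_in: float = 0.05
    i_uorf: float = 0.2
    i_uorf2: float = 0.0
    i_cds: float = 0.8
    v_s: float = 0.3
    v_eu: float = 0.3
    v_ec: float = 0.5
    k_up: float = 0.0
    k_down: float = 0.02
    model: str = "downstream"
    footprint_nt: int = 3

    def __post_init__(self) -> None:
        if self.model not in DISSOCIATION_MODELS:
            raise ConfigurationError(
                f"model must be one of {DISSOCIATION_MODELS}, got {self.model!r}"
            )
        for name in _PROB_FIELDS:
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ConfigurationError(f"{name}={val} is not a probability in [0, 1]")
        if self.footprint_nt < 3:
            raise ConfigurationError(f"footprint_nt must be >= 3, got {self.footprint_nt}")

    def effective(self) -> "KineticParams":
        """Zero out the dissociation channel the model disables."""
        if self.model == "downstream" and self.k_up != 0.0:
            return replace(self, k_up=0.0)
        if self.model == "upstream" and self.k_down != 0.0:
            return replace(self, k_down=0.0)
        return self
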