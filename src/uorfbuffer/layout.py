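"""mRNA lattice geometry: 5' leader, uORF(s), spacers, CDS, 3' UTR.

Coordinates are 0-based nucleotide offsets on a linear lattice; every ORF
(uORF or CDS) occupies ``3 * len_codons`` nt of sense codons followed by a
3-nt stop codon. A ribosome's position is its 5' leading edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["UORFSpec", "MRNALayout", "build_layout", "ConfigurationError"]

STOP_NT = 3  # a stop codon occupies 3 nt


class ConfigurationError(ValueError):
    """Raised for invalid geometry or kinetic configuration."""


@dataclass(frozen=True)
class UORFSpec:
    """One upstream open reading frame.

    Attributes
    ----------
    start_nt:
        0-based offset of the first nucleotide of the uATG.
    len_codons:
        Sense-codon count (stop codon excluded); must be >= 1.
    stop_nt:
        0-based offset of the first nucleotide of the stop codon,
        always ``start_nt + 3 * len_codons``.
    """

    start_nt: int
    len_codons: int

    @property
    def stop_nt(self) -> int:
        return self.start_nt + 3 * self.len_codons

    @property
    def end_nt(self) -> int:
        """One past the last nucleotide of the stop codon (half-open end)."""
        return self.stop_nt + STOP_NT

    def __post_init__(self) -> None:
        if self.len_codons < 1:
            raise ConfigurationError(f"uORF len_codons must be >= 1, got {self.len_codons}")
        if self.start_nt < 0:
            raise ConfigurationError(f"uORF start_nt must be >= 0, got {self.start_nt}")


@dataclass(frozen=True)
class MRNALayout:
    """Nucleotide-resolution geometry of one mRNA.

    The lattice is the concatenation, 5'->3', of the leader, each uORF
    (codons + stop) with its trailing spacer, the CDS (codons + stop) and
    the 3' UTR.
    """

    leader_len_nt: int
    uorfs: tuple[UORFSpec, ...]
    cds_start_nt: int
    cds_len_codons: int
    utr3_len_nt: int
    total_len_nt: int = field(default=-1)

    @property
    def cds_stop_nt(self) -> int:
        return self.cds_start_nt + 3 * self.cds_len_codons

    def __post_init__(self) -> None:
        if self.cds_len_codons < 1:
            raise ConfigurationError("cds_len_codons must be >= 1")
        expected_total = self.cds_stop_nt + STOP_NT + self.utr3_len_nt
        if self.total_len_nt == -1:
            object.__setattr__(self, "total_len_nt", expected_total)
        elif self.total_len_nt != expected_total:
            raise ConfigurationError(
                f"total_len_nt {self.total_len_nt} inconsistent with geometry ({expected_total})"
            )
        last_end = 0
        for u in self.uorfs:
            if u.start_nt < last_end:
                raise ConfigurationError("uORFs must be disjoint and ordered 5'->3'")
            if u.end_nt > self.cds_start_nt:
                raise ConfigurationError("every uORF must end before the CDS start")
            last_end = u.end_nt

    def start_codon_lookup(self):
        """Per-nucleotide feature table for the simulator.

        Returns an int8 array of length ``total_len_nt`` where position p
        holds ``k + 1`` if p is the start codon of feature k (uORFs in 5'->3'
        order, then the CDS) and 0 otherwise.
        """
        import numpy as np

        lut = np.zeros(self.total_len_nt, dtype=np.int8)
        for k, u in enumerate(self.uorfs):
            lut[u.start_nt] = k + 1
        lut[self.cds_start_nt] = len(self.uorfs) + 1
        return lut

    def feature_stops(self):
        """Stop-codon offset per feature, uORFs first then the CDS."""
        import numpy as np

        stops = [u.stop_nt for u in self.uorfs] + [self.cds_stop_nt]
        return np.asarray(stops, dtype=np.int64)


def build_layout(
    leader_len_nt: int = 150,
    uorf_lens_codons: Sequence[int] = (50,),
    spacer_lens_nt: Sequence[int] | int = 150,
    cds_len_codons: int = 500,
    utr3_len_nt: int = 150,
) -> MRNALayout:
    """Assemble an :class:`MRNALayout` from region lengths.

    Parameters
    ----------
    leader_len_nt:
        Length of the 5' leader upstream of the first uORF (or of the CDS
        when there is no uORF). Default 150 nt.
    uorf_lens_codons:
        Sense-codon length of each uORF, 5'->3'; at most two, may be empty.
    spacer_lens_nt:
        Spacer downstream of each uORF (after its stop codon). A scalar is
        broadcast to all uORFs; with no uORF it is ignored. Default 150 nt.
    cds_len_codons:
        CDS sense-codon count. Default 500.
    utr3_len_nt:
        3' UTR length. Default 150 nt.
    """
    uorf_lens = tuple(int(x) for x in uorf_lens_codons)
    if len(uorf_lens) > 2:
        raise ConfigurationError("at most 2 uORFs are supported")
    if isinstance(spacer_lens_nt, int):
        spacers = (spacer_lens_nt,) * len(uorf_lens)
    else:
        spacers = tuple(int(x) for x in spacer_lens_nt)
    if len(spacers) != len(uorf_lens):
        raise ConfigurationError(
            f"need one spacer per uORF: {len(uorf_lens)} uORFs, {len(spacers)} spacers"
        )
    for name, val in [("leader_len_nt", leader_len_nt), ("utr3_len_nt", utr3_len_nt)]:
        if val < 0:
            raise ConfigurationError(f"{name} must be nonnegative, got {val}")
    if any(s < 0 for s in spacers):
        raise ConfigurationError("spacer lengths must be nonnegative")

    pos = leader_len_nt
    uorfs = []
    for length, spacer in zip(uorf_lens, spacers):
        u = UORFSpec(start_nt=pos, len_codons=length)
        uorfs.append(u)
        pos = u.end_nt + spacer
    return MRNALayout(
        leader_len_nt=leader_len_nt,
        uorfs=tuple(uorfs),
        cds_start_nt=pos,
        cds_len_codons=int(cds_len_codons),
        utr3_len_nt=int(utr3_len_nt),
    )
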