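import numpy as np
import pytest

from uorfbuffer import KineticParams, build_layout


@pytest.fixture(scope="session")
def default_layout():
    """Standard geometry: 150 nt leader, 50-codon uORF, 150 nt spacer,
    500-codon CDS, 150 nt 3' UTR."""
    return build_layout()


@pytest.fixture(scope="session")
def tiny_layout():
    """Short lattice for oracle and stress tests (159 nt)."""
    return build_layout(
        leader_len_nt=30, uorf_lens_codons=(5,), spacer_lens_nt=30,
        cds_len_codons=20, utr3_len_nt=20,
    )


@pytest.fixture(scope="session")
def default_params():
    return KineticParams(i_uorf=0.2, i_cds=0.8)


def random_small_config(rng: np.random.Generator):
    """One random small lattice + kinetic configuration for oracle tests."""
    n_uorfs = int(rng.integers(0, 3))
    layout = build_layout(
        leader_len_nt=int(rng.integers(10, 40)),
        uorf_lens_codons=tuple(int(rng.integers(2, 12)) for _ in range(n_uorfs)),
        spacer_lens_nt=tuple(int(rng.integers(6, 30)) for _ in range(n_uorfs)),
        cds_len_codons=int(rng.integers(5, 30)),
        utr3_len_nt=int(rng.integers(5, 30)),
    )
    params = KineticParams(
        r_in=float(rng.uniform(0, 0.2)),
        i_uorf=float(rng.uniform(0, 0.8)),
        i_uorf2=float(rng.uniform(0, 0.8)),
        i_cds=float(rng.uniform(0.1, 1.0)),
        v_s=float(rng.uniform(0.1, 0.9)),
        v_eu=float(rng.uniform(0.1, 0.9)),
        v_ec=float(rng.uniform(0.1, 0.9)),
        k_up=float(rng.uniform(0, 1)),
        k_down=float(rng.uniform(0, 1)),
        model=str(rng.choice(["downstream", "upstream", "double"])),
        footprint_nt=int(rng.choice([3, 6, 9])),
    )
    return layout, params
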