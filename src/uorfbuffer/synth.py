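"""Synthetic translatome generator and simulator fixture presets.

Emulates the structure of a two-species comparative Ribo-Seq/mRNA-Seq
experiment — negative-binomial counts per feature (uORF or CDS), species,
sample and replicate — with full ground truth (true log2 TE per feature and
species, true log2 beta_u / beta_c / gamma, planted buffered pairs), so
every statistical routine in :mod:`uorfbuffer.stats` can be tested without
any sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import MRNALayout, build_layout
from .params import KineticParams

__all__ = ["TranslatomeConfig", "simulate_translatome", "make_fixture_layouts"]


@dataclass(frozen=True)
class TranslatomeConfig:
    """Generator settings.

    The defaults describe a moderately deep bulk experiment: 2000 genes,
    about half carrying a translated uORF, library sizes of 2e7 (mRNA) and
    1e7 (RPF) reads, NB dispersion 0.05 (between-replicate biological CV of
    ~22% at high counts), interspecific effects drawn log-normally with sd
    0.25 on the log2 scale, and 5% of uORF-bearing genes planted as
    strongly buffered pairs (|log2 beta_u| ~ 2, log2 beta_c = 0).
    """

    n_genes: int = 2000
    uorf_rate: float = 0.5
    two_uorf_rate: float = 0.15  # among uORF-bearing genes
    effect_sd: float = 0.25  # sd of non-planted log2 beta draws
    fraction_buffered: float = 0.05  # of uORF-bearing genes
    buffered_log2bu: float = 2.0
    dispersion: float = 0.05
    mrna_libsize: float = 2e7
    rpf_libsize: float = 1e7
    n_replicates: int = 2
    mean_log_abundance: float = 2.0  # lognormal location of mRNA RPKM
    sd_log_abundance: float = 1.0


def _nb(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draws with mean mu and Var mu + phi mu^2."""
    mu = np.maximum(mu, 1e-12)
    if phi <= 0:
        return rng.poisson(mu)
    size_param = 1.0 / phi
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def simulate_translatome(
    config: TranslatomeConfig = TranslatomeConfig(), seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a two-species count table plus its ground truth.

    Returns ``(counts, truth)``. ``counts`` is tidy with columns
    (feature_id, gene_id, feature_type, species, sample, replicate,
    mrna_count, rpf_count, len_nt, mrna_libsize, rpf_libsize); species are
    "sp1" and "sp2" in the single sample "s1". ``truth`` has one row per
    uORF-CDS pair (genes without uORFs carry the CDS row only) with true
    log2 TEs, log2 beta_u, log2 beta_c, log2 gamma = log2 beta_c - log2
    beta_u (exact), and the planted-buffered flag.
    """
    cfg = config
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if cfg.dispersion < 0 or cfg.mrna_libsize <= 0 or cfg.rpf_libsize <= 0:
        raise ValueError("invalid dispersion or library sizes")
    rng = np.random.default_rng(seed)

    count_rows = []
    truth_rows = []
    for g in range(cfg.n_genes):
        gene = f"g{g:05d}"
        abundance = float(np.exp(rng.normal(cfg.mean_log_abundance, cfg.sd_log_abundance)))
        cds_len = int(rng.integers(600, 3000))
        has_uorf = rng.random() < cfg.uorf_rate
        n_uorfs = 0
        if has_uorf:
            n_uorfs = 2 if rng.random() < cfg.two_uorf_rate else 1
        buffered = has_uorf and rng.random() < cfg.fraction_buffered

        te_cds_sp1 = float(np.exp(rng.normal(0.0, 0.4)))
        log2_beta_c = 0.0 if buffered else float(rng.normal(0.0, cfg.effect_sd))

        features = [("CDS", f"{gene}_cds", cds_len, te_cds_sp1, log2_beta_c)]
        uorf_truth = []
        for k in range(n_uorfs):
            uorf_len = int(rng.integers(30, 300))
            te_u_sp1 = float(np.exp(rng.normal(-1.0, 0.5)))
            if buffered and k == 0:
                log2_beta_u = float(rng.choice([-1.0, 1.0]) * cfg.buffered_log2bu)
            else:
                log2_beta_u = float(rng.normal(0.0, cfg.effect_sd))
            fid = f"{gene}_u{k + 1}"
            features.append(("uORF", fid, uorf_len, te_u_sp1, log2_beta_u))
            uorf_truth.append((fid, te_u_sp1, log2_beta_u, k == 0 and buffered))

        for ftype, fid, flen, te_sp1, log2_beta in features:
            te_sp2 = te_sp1 * 2.0**log2_beta
            for sp, te in (("sp1", te_sp1), ("sp2", te_sp2)):
                for rep in range(1, cfg.n_replicates + 1):
                    # abundance is the mRNA RPKM, so count = RPKM * kb * M reads
                    mu_mrna = abundance * (flen / 1e3) * (cfg.mrna_libsize / 1e6)
                    mu_rpf = abundance * te * (flen / 1e3) * (cfg.rpf_libsize / 1e6)
                    count_rows.append(
                        {
                            "feature_id": fid,
                            "gene_id": gene,
                            "feature_type": ftype,
                            "species": sp,
                            "sample": "s1",
                            "replicate": rep,
                            "mrna_count": int(_nb(rng, np.asarray(mu_mrna), cfg.dispersion)),
                            "rpf_count": int(_nb(rng, np.asarray(mu_rpf), cfg.dispersion)),
                            "len_nt": flen,
                            "mrna_libsize": cfg.mrna_libsize,
                            "rpf_libsize": cfg.rpf_libsize,
                        }
                    )

        base = {
            "gene_id": gene,
            "abundance": abundance,
            "cds_len_nt": cds_len,
            "n_uorfs": n_uorfs,
            "log2te_cds_sp1": np.log2(te_cds_sp1),
            "log2_beta_c": log2_beta_c,
            "dispersion": cfg.dispersion,
        }
        if not uorf_truth:
            truth_rows.append({**base, "uorf_id": None, "log2te_uorf_sp1": np.nan,
                               "log2_beta_u": np.nan, "log2_gamma": np.nan,
                               "buffered": False})
        for fid, te_u, log2_beta_u, is_buf in uorf_truth:
            truth_rows.append(
                {
                    **base,
                    "uorf_id": fid,
                    "log2te_uorf_sp1": np.log2(te_u),
                    "log2_beta_u": log2_beta_u,
                    "log2_gamma": log2_beta_c - log2_beta_u,
                    "buffered": bool(is_buf),
                }
            )

    return pd.DataFrame(count_rows), pd.DataFrame(truth_rows)


def make_fixture_layouts() -> dict[str, tuple[MRNALayout, KineticParams]]:
    """Named (layout, params) presets.

    ``default``: the standard single-uORF geometry — 150 nt leader, 50-codon
    uORF, 150 nt spacer, 500-codon CDS, 150 nt 3' UTR — with v_s=0.3,
    v_Eu=0.3, v_EC=0.5 and the downstream dissociation model.
    ``two_uorf``: the same with a second 50-codon uORF. ``no_uorf``: the
    bare CDS. ``tiny``: a short lattice for oracle and stress tests.
    """
    default_params = KineticParams(
        r_in=0.05, i_uorf=0.2, i_uorf2=0.0, i_cds=0.8,
        v_s=0.3, v_eu=0.3, v_ec=0.5, k_down=0.02, k_up=0.0,
        model="downstream", footprint_nt=3,
    )
    presets = {
        "default": (build_layout(150, (50,), 150, 500, 150), default_params),
        "two_uorf": (
            build_layout(150, (50, 50), (150, 150), 500, 150),
            KineticParams(**{**default_params.__dict__, "i_uorf2": 0.2}),
        ),
        "no_uorf": (build_layout(150, (), (), 500, 150), default_params),
        "tiny": (
            build_layout(20, (4,), 20, 30, 20),
            KineticParams(**{**default_params.__dict__, "r_in": 0.1, "footprint_nt": 9}),
        ),
    }
    return presets
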