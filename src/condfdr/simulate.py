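"""Synthetic two-trait GWAS summary statistics with controlled pleiotropy.

The generator works directly at the z-score level (no individual genotypes):
within each LD block with AR(1) correlation matrix R (parameter ``rho``),

    z_t = R (sqrt(n_t) * beta_t) + eta_t,   eta_t ~ N(0, R),  t in {1, 2},

where the standardized effects beta are drawn from a four-component mixture
over SNPs — null / trait-1-only / trait-2-only / shared — with the shared
component bivariate normal (correlation ``shared_corr``). Two-sided p-values
follow as 2*Phi(-|z|); optional multiplicative chi-square inflation
(``lambda_inject``) is applied to trait 1 so the intergenic genomic-control
machinery has something to recover. The emitted LD source reports the
squared entries of R.

Also packaged here: the worked-example table of 25 novel lymphoma risk loci
(four subtypes) used by the fixture-level tests, transcribed verbatim from
its published source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError
from .io import PAIR_COLUMNS, p_from_z
from .loci import BlockLd


@dataclass
class SimConfig:
    """Study conditions for the synthetic pair.

    Defaults mirror a desk-scale polygenic two-trait design: 100k SNPs in
    50-SNP AR(1) blocks (rho 0.9) across 22 chromosomes; 1 shared causal SNP
    per 1000 plus 2 per 1000 specific to each trait; standardized effect
    scale 0.05 at n = 10,000 samples, so a typical causal |z| is around 5 —
    the borderline-significance regime conditional FDR is designed to mine.
    """

    m: int = 100_000
    n_chrom: int = 22
    spacing_bp: int = 10_000
    block_size: int = 50
    rho: float = 0.9
    pi10: float = 0.002
    pi01: float = 0.002
    pi11: float = 0.001
    effect_sd1: float = 0.05
    effect_sd2: float = 0.05
    shared_corr: float = 0.5
    n1: int = 10_000
    n2: int = 10_000
    lambda_inject: float = 1.0
    frac_intergenic: float = 0.5
    seed: int = 0

    @property
    def pi00(self) -> float:
        return 1.0 - self.pi10 - self.pi01 - self.pi11

    def validate(self) -> None:
        probs = (self.pi00, self.pi10, self.pi01, self.pi11)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-12:
            raise ConfigError("mixture probabilities must be >= 0 and sum to 1")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError("rho must lie in [0, 1)")
        if not (-1.0 <= self.shared_corr <= 1.0):
            raise ConfigError("shared_corr must lie in [-1, 1]")
        if self.effect_sd1 < 0 or self.effect_sd2 < 0:
            raise ConfigError("effect scales must be >= 0")
        if self.lambda_inject < 1.0:
            raise ConfigError("lambda_inject must be >= 1 (deflation not modeled)")
        if self.m < 1 or self.block_size < 1 or self.n_chrom < 1:
            raise ConfigError("m, block_size and n_chrom must be positive")


def _ar1_matrix(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _draw_effects(cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    u = rng.uniform(size=cfg.m)
    shared = u < cfg.pi11
    only1 = (u >= cfg.pi11) & (u < cfg.pi11 + cfg.pi10)
    only2 = (u >= cfg.pi11 + cfg.pi10) & (u < cfg.pi11 + cfg.pi10 + cfg.pi01)
    beta1 = np.zeros(cfg.m)
    beta2 = np.zeros(cfg.m)
    # shared effects: bivariate normal with correlation shared_corr
    ns = int(shared.sum())
    if ns:
        a = rng.standard_normal(ns)
        b = rng.standard_normal(ns)
        r = cfg.shared_corr
        beta1[shared] = cfg.effect_sd1 * a
        beta2[shared] = cfg.effect_sd2 * (r * a + np.sqrt(1 - r * r) * b)
    beta1[only1] = cfg.effect_sd1 * rng.standard_normal(int(only1.sum()))
    beta2[only2] = cfg.effect_sd2 * rng.standard_normal(int(only2.sum()))
    return beta1, beta2, shared | only1, shared | only2


def _block_transform(values: np.ndarray, starts, sizes, mats: dict) -> np.ndarray:
    """Apply per-block matrix (keyed by block size) to a flat vector."""
    out = np.empty_like(values)
    for s, b in zip(starts, sizes):
        out[s:s + b] = mats[b] @ values[s:s + b]
    return out


def pair_to_trait_frames(pair: pd.DataFrame):
    """Split a harmonized pair back into two per-trait record tables (columns
    SNP/CHR/BP/A1/A2/Z/P/FUNC), e.g. to exercise the harmonization path on
    synthetic data."""
    out = []
    for zc, pc in (("Z1", "P1"), ("Z2", "P2")):
        out.append(pd.DataFrame({
            "SNP": pair["SNP"], "CHR": pair["CHR"], "BP": pair["BP"],
            "A1": pair["A1"], "A2": pair["A2"],
            "Z": pair[zc], "P": pair[pc], "FUNC": pair["FUNC"],
        }))
    return tuple(out)


def simulate_pair(config: SimConfig):
    """Generate (harmonized pair, per-SNP truth, LD source) from ``config``.

    Fully reproducible from ``config.seed``. SNPs are laid out contiguously
    over ``n_chrom`` chromosomes at ``spacing_bp`` intervals; LD blocks never
    straddle a chromosome boundary.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # chromosome layout
    per_chrom = np.full(cfg.n_chrom, cfg.m // cfg.n_chrom, dtype=int)
    per_chrom[: cfg.m % cfg.n_chrom] += 1
    per_chrom = per_chrom[per_chrom > 0]
    chrom = np.repeat(np.arange(1, len(per_chrom) + 1), per_chrom).astype(str)
    pos = np.concatenate([
        (np.arange(k) + 1) * cfg.spacing_bp for k in per_chrom
    ]).astype(np.int64)

    # block layout within chromosomes
    starts, sizes = [], []
    offset = 0
    for k in per_chrom:
        for s in range(0, k, cfg.block_size):
            starts.append(offset + s)
            sizes.append(min(cfg.block_size, k - s))
        offset += k
    mats = {}
    chols = {}
    for b in sorted(set(sizes)):
        R = _ar1_matrix(b, cfg.rho)
        mats[b] = R
        chols[b] = np.linalg.cholesky(R)

    beta1, beta2, causal1, causal2 = _draw_effects(cfg, rng)

    independent = cfg.rho == 0.0 or cfg.block_size == 1
    z = {}
    for t, (beta, n) in enumerate([(beta1, cfg.n1), (beta2, cfg.n2)], start=1):
        if independent:  # R = I: skip the per-block products
            z[t] = np.sqrt(n) * beta + rng.standard_normal(cfg.m)
        else:
            signal = _block_transform(np.sqrt(n) * beta, starts, sizes, mats)
            noise = _block_transform(rng.standard_normal(cfg.m), starts, sizes, chols)
            z[t] = signal + noise

    func = np.where(rng.uniform(size=cfg.m) < cfg.frac_intergenic,
                    "intergenic", "intronic")
    snp = np.array([f"sim{i:07d}" for i in range(cfg.m)])

    pair = pd.DataFrame({
        "SNP": snp, "CHR": chrom, "BP": pos,
        "A1": "A", "A2": "G",
        "Z1": z[1], "P1": p_from_z(z[1]),
        "Z2": z[2], "P2": p_from_z(z[2]),
        "FUNC": func, "EXCL": np.zeros(cfg.m, dtype=bool),
    })[PAIR_COLUMNS]
    if cfg.lambda_inject > 1.0:
        pair = inject_inflation(pair, cfg.lambda_inject)

    truth = pd.DataFrame({
        "SNP": snp, "CHR": chrom, "BP": pos,
        "causal1": causal1, "causal2": causal2,
        "beta1": beta1, "beta2": beta2,
    })

    ld = BlockLd(
        [(snp[s:s + b], mats[b] ** 2) for s, b in zip(starts, sizes)],
        window_kb=cfg.block_size * cfg.spacing_bp / 1000,
    )
    return pair, truth, ld


def inject_inflation(pair: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Multiply the primary trait's chi-square statistics by ``lam`` >= 1
    (z1 scaled by sqrt(lam), p1 recomputed). Inverse of genomic-control
    adjustment with the same lambda."""
    if lam < 1.0:
        raise ConfigError("lambda_inject must be >= 1 (deflation not modeled)")
    out = pair.copy()
    out["Z1"] = pair["Z1"].to_numpy() * np.sqrt(lam)
    out["P1"] = p_from_z(out["Z1"].to_numpy())
    return out


def table1_fixture() -> pd.DataFrame:
    """The packaged worked-example table: 25 novel lead SNPs for four B-cell
    lymphoma subtypes (DLBCL, FL, CLL, MZL) with chromosome, position,
    functional class, alleles, z, nominal p, condFDR and positionally mapped
    protein-coding genes; numeric columns parsed, text transcribed verbatim."""
    ref = resources.files("condfdr") / "data" / "table1_novel_loci.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("pos", "z", "p", "condfdr"):
        df[col] = pd.to_numeric(df[col])
    return df
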