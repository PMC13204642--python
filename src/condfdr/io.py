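"""Reading, quality control, allele alignment and intersection of GWAS
summary statistics.

The harmonized two-trait table (the object the conditional-FDR machinery
operates on) is a pandas DataFrame with columns::

    SNP CHR BP A1 A2 Z1 P1 Z2 P2 FUNC EXCL

where A1 is the reference allele, A2 the effect allele, (Z1, P1) the primary
trait and (Z2, P2) the conditioning trait. Coordinates are 1-based on a
single declared genome build; intervals are both-endpoints inclusive.

Per-trait input is any delimited text table (gzip-transparent) with a column
schema mapping file headers onto the canonical record fields.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, EmptyPairError
from .regions import in_regions

logger = logging.getLogger(__name__)

#: canonical single-trait record columns
RECORD_COLUMNS = [
    "snp_id", "chrom", "pos", "ref_allele", "effect_allele",
    "z", "p", "func", "n_studies",
]

#: harmonized two-trait table columns
PAIR_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z1", "P1", "Z2", "P2", "FUNC", "EXCL"]

#: two-sided p-values below this are clamped to keep the normal quantile finite
P_FLOOR = 1e-300

#: relative tolerance for the z/p consistency flag
ZP_REL_TOL = 0.05

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class QcReport:
    """Counts of records removed, flipped, flagged and retained.

    The invariant ``n_input == n_retained + sum(removed.values())`` holds for
    every operation that emits a report.
    """

    n_input: int = 0
    n_retained: int = 0
    removed: dict = field(default_factory=dict)
    n_flipped: int = 0
    n_palindromic: int = 0
    n_zp_inconsistent: int = 0
    n_p_clamped: int = 0

    def add_removed(self, rule: str, count: int) -> None:
        if count:
            self.removed[rule] = self.removed.get(rule, 0) + int(count)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def validate(self) -> None:
        if self.n_input != self.n_retained + self.n_removed:
            raise AssertionError("QcReport counts do not add up")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed": dict(self.removed),
            "n_flipped": self.n_flipped,
            "n_palindromic": self.n_palindromic,
            "n_zp_inconsistent": self.n_zp_inconsistent,
            "n_p_clamped": self.n_p_clamped,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def log(self, stage: str = "qc") -> None:
        logger.info("[%s] input=%d retained=%d removed=%s flipped=%d",
                    stage, self.n_input, self.n_retained, self.removed, self.n_flipped)


def z_from_p(p, direction=1):
    """Signed z score from a two-sided p-value: ``|z| = Phi^-1(1 - p/2)``.

    ``direction`` gives the sign (+1/-1, scalar or array). p-values below
    ``P_FLOOR`` are clamped (with a warning) so the quantile stays finite.
    Raises for p outside (0, 1].
    """
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n_clamped = int(np.sum(p < P_FLOOR))
    if n_clamped:
        warnings.warn(f"{n_clamped} p-value(s) below {P_FLOOR:g} clamped")
        p = np.maximum(p, P_FLOOR)
    d = np.sign(np.atleast_1d(np.asarray(direction, dtype=float)))
    d = np.where(d == 0, 1.0, d)
    z = d * norm.isf(p / 2.0)
    return float(z[0]) if scalar else z


def p_from_z(z):
    """Two-sided p-value from a z score: ``p = 2 Phi(-|z|)``."""
    z = np.asarray(z, dtype=float)
    p = 2.0 * norm.sf(np.abs(z))
    return np.maximum(p, P_FLOOR) if p.ndim else float(max(p, P_FLOOR))


def read_sumstats(path, schema, sep=None):
    """Read one trait's summary statistics into the canonical record frame.

    Parameters
    ----------
    path : str or file
        Delimited text, optionally gzipped.
    schema : dict
        Maps canonical field names (see ``RECORD_COLUMNS``) to the file's
        column headers, e.g. ``{"snp_id": "SNP", "chrom": "CHR", ...}``.
        ``snp_id``, ``chrom``, ``pos``, ``ref_allele``, ``effect_allele``
        and at least one of ``z`` / ``p`` are required.
    sep : str, optional
        Field delimiter; default splits on any whitespace.

    Returns
    -------
    (DataFrame, QcReport)
        Records in file order; rows whose numeric fields fail to parse or
        whose p lies outside (0, 1] are rejected and counted in the report.
    """
    required = ["snp_id", "chrom", "pos", "ref_allele", "effect_allele"]
    missing = [k for k in required if k not in schema]
    if missing:
        raise ConfigError(f"schema lacks required fields: {missing}")
    if "z" not in schema and "p" not in schema:
        raise ConfigError("schema must map at least one of 'z' or 'p'")

    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+",
                     dtype=str, comment="#")
    # optional fields mapped by the schema but absent from the file are
    # ignored; required fields (and having at least one of z/p) are enforced
    schema = {k: v for k, v in schema.items()
              if v in df.columns or k in required}
    if "z" not in schema and "p" not in schema:
        raise ConfigError("input lacks both z and p columns")
    absent = [v for v in schema.values() if v not in df.columns]
    if absent:
        raise ConfigError(f"input lacks columns: {absent}")

    out = pd.DataFrame(index=df.index)
    for canon in RECORD_COLUMNS:
        if canon in schema:
            out[canon] = df[schema[canon]]
        else:
            out[canon] = np.nan

    report = QcReport(n_input=len(out))
    bad = pd.Series(False, index=out.index)

    out["chrom"] = out["chrom"].astype(str).str.removeprefix("chr")
    pos = pd.to_numeric(out["pos"], errors="coerce")
    bad |= pos.isna() | (pos < 1)
    out["pos"] = pos

    for col in ("z", "p"):
        if schema.get(col):
            vals = pd.to_numeric(out[col], errors="coerce")
            # unparseable entries in a mapped column reject the record only if
            # the other statistic is also unusable; handled below
            out[col] = vals
        else:
            out[col] = np.nan
    if schema.get("p"):
        p = out["p"]
        bad |= p.notna() & ((p <= 0) | (p > 1))
        # a mapped-but-unparseable p with no z is malformed
        bad |= p.isna() & out["z"].isna()
    if schema.get("n_studies"):
        out["n_studies"] = pd.to_numeric(out["n_studies"], errors="coerce")
    out["func"] = out["func"].fillna("unknown")

    report.add_removed("malformed", int(bad.sum()))
    out = out[~bad].copy()
    out["pos"] = out["pos"].astype(np.int64)

    # clamp extreme p-values so downstream quantiles are finite
    if schema.get("p"):
        tiny = out["p"].notna() & (out["p"] < P_FLOOR)
        if tiny.any():
            report.n_p_clamped = int(tiny.sum())
            out.loc[tiny, "p"] = P_FLOOR

    # derive z from p (direction +1 when no z given), or flag z/p disagreement
    has_z, has_p = out["z"].notna(), out["p"].notna()
    derive = has_p & ~has_z
    if derive.any():
        out.loc[derive, "z"] = z_from_p(out.loc[derive, "p"].to_numpy(), 1.0)
    both = has_z & has_p
    if both.any():
        implied = p_from_z(out.loc[both, "z"].to_numpy())
        rel = np.abs(implied - out.loc[both, "p"].to_numpy()) / out.loc[both, "p"].to_numpy()
        report.n_zp_inconsistent = int(np.sum(rel > ZP_REL_TOL))
    fill_p = has_z & ~has_p
    if fill_p.any():
        out.loc[fill_p, "p"] = p_from_z(out.loc[fill_p, "z"].to_numpy())

    report.n_retained = len(out)
    report.validate()
    return out.reset_index(drop=True), report


def qc_filter(records, unstable_regions=None, min_studies=None):
    """Remove duplicated/multiallelic positions, records in unstable regions,
    missing/zero effect measures and single-study SNPs.

    Duplicate handling drops *all* records sharing a (chrom, pos) key: the
    conservative, order-independent choice. Positions carried by records with
    differing allele sets are counted as multiallelic, identical allele sets
    as duplicates. Filters report, never raise; the operation is idempotent.
    """
    df = records
    report = QcReport(n_input=len(df))

    key = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
    dup_mask = key.duplicated(keep=False)
    if dup_mask.any():
        alleles = df["ref_allele"].astype(str) + "/" + df["effect_allele"].astype(str)
        n_allele_sets = alleles.groupby(key).transform("nunique")
        multi = dup_mask & (n_allele_sets > 1)
        report.add_removed("multiallelic", int(multi.sum()))
        report.add_removed("duplicate", int((dup_mask & ~multi).sum()))
        df = df[~dup_mask]

    if unstable_regions:
        inside = in_regions(df["chrom"], df["pos"], unstable_regions)
        report.add_removed("unstable_region", int(inside.sum()))
        df = df[~inside]

    # missing or zero effect: no usable statistic at all, p == 0, or a
    # directionless z == 0 with no p to fall back on
    z, p = df["z"], df["p"]
    no_effect = (z.isna() & p.isna()) | (p == 0) | ((z == 0) & p.isna())
    report.add_removed("missing_or_zero_effect", int(no_effect.sum()))
    df = df[~no_effect]

    if min_studies is not None and "n_studies" in df.columns:
        few = df["n_studies"].notna() & (df["n_studies"] < min_studies)
        report.add_removed("single_study", int(few.sum()))
        df = df[~few]

    pal = [
        frozenset((str(a).upper(), str(b).upper())) in _PALINDROMIC
        for a, b in zip(df["ref_allele"], df["effect_allele"])
    ]
    report.n_palindromic = int(np.sum(pal))

    report.n_retained = len(df)
    report.validate()
    return df.reset_index(drop=True), report


def align_to_reference(records, ref):
    """Orient each record so its stored reference allele matches the
    reference-genome allele, negating z (direction) when alleles were swapped.

    ``ref`` maps (chrom, pos) -> reference allele; a dict or a DataFrame with
    columns chrom/pos/allele. Records matching neither orientation, or at
    positions absent from the map, are removed. Idempotent.
    """
    if isinstance(ref, pd.DataFrame):
        ref = {
            (str(c), int(b)): str(a)
            for c, b, a in zip(ref["chrom"], ref["pos"], ref["allele"])
        }
    df = records.copy()
    report = QcReport(n_input=len(df))

    ref_allele = np.array([
        ref.get((str(c), int(b)), "") for c, b in zip(df["chrom"], df["pos"])
    ])
    a1 = df["ref_allele"].astype(str).str.upper().to_numpy()
    a2 = df["effect_allele"].astype(str).str.upper().to_numpy()
    keep_as_is = a1 == ref_allele
    flip = ~keep_as_is & (a2 == ref_allele)
    missing = ref_allele == ""
    unmatched = ~keep_as_is & ~flip & ~missing

    report.add_removed("reference_missing", int(missing.sum()))
    report.add_removed("reference_unmatched", int(unmatched.sum()))
    report.n_flipped = int(flip.sum())

    df.loc[flip, ["ref_allele", "effect_allele"]] = df.loc[
        flip, ["effect_allele", "ref_allele"]
    ].to_numpy()
    df.loc[flip, "z"] = -df.loc[flip, "z"]

    df = df[keep_as_is | flip]
    report.n_retained = len(df)
    report.validate()
    return df.reset_index(drop=True), report


def intersect_pair(primary, conditioning):
    """Build the harmonized two-trait table on the (chrom, pos) intersection.

    Both inputs must already be QC'd and aligned to the same reference so z
    signs are comparable. Joins on genomic position (rsIDs drift between
    sources and are kept only as labels); positions whose allele sets
    disagree between the traits are dropped. Raises ``EmptyPairError`` when
    the traits share no SNPs.
    """
    def keyed(df):
        d = df.copy()
        d["_key"] = d["chrom"].astype(str) + ":" + d["pos"].astype(str)
        return d.set_index("_key")

    p1, p2 = keyed(primary), keyed(conditioning)
    common = p1.index.intersection(p2.index)
    if len(common) == 0:
        raise EmptyPairError("traits share no SNPs after harmonization")
    p1, p2 = p1.loc[common], p2.loc[common]

    consistent = (
        (p1["ref_allele"].astype(str).str.upper()
         == p2["ref_allele"].astype(str).str.upper())
        & (p1["effect_allele"].astype(str).str.upper()
           == p2["effect_allele"].astype(str).str.upper())
    ).to_numpy()
    if not consistent.all():
        logger.info("intersect_pair: dropped %d allele-inconsistent SNPs",
                    int((~consistent).sum()))
    p1, p2 = p1[consistent], p2[consistent]
    if len(p1) == 0:
        raise EmptyPairError("no allele-consistent shared SNPs")

    pair = pd.DataFrame({
        "SNP": p1["snp_id"].to_numpy(),
        "CHR": p1["chrom"].astype(str).to_numpy(),
        "BP": p1["pos"].to_numpy(),
        "A1": p1["ref_allele"].to_numpy(),
        "A2": p1["effect_allele"].to_numpy(),
        "Z1": p1["z"].astype(float).to_numpy(),
        "P1": p1["p"].astype(float).to_numpy(),
        "Z2": p2["z"].astype(float).to_numpy(),
        "P2": p2["p"].astype(float).to_numpy(),
        "FUNC": p1["func"].to_numpy(),
        "EXCL": np.zeros(len(p1), dtype=bool),
    })
    pair = pair.sort_values(
        ["CHR", "BP"], key=lambda s: s.astype(int) if s.name in ("CHR", "BP") else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return pair


def write_pair(pair: pd.DataFrame, path) -> None:
    pair.to_csv(path, sep="\t", index=False)


def read_pair(path) -> pd.DataFrame:
    pair = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in PAIR_COLUMNS if c not in pair.columns and c != "EXCL"]
    if missing:
        raise ConfigError(f"pair table lacks columns: {missing}")
    if "EXCL" not in pair.columns:
        pair["EXCL"] = False
    return pair
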