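"""GWAS summary statistics: data model, I/O, and algebraic conversions.

A study is represented by :class:`SummaryStats`, a thin wrapper around a
pandas DataFrame with canonical columns

    SNP, CHR, BP, EA, OA, EAF, BETA, SE, Z, P, N

holding, per variant, the effect estimate ``BETA`` (theta-hat, on the scale
of trait standard deviations per effect allele for an inverse-normalized
quantitative trait), its standard error ``SE``, the Wald statistic
``Z = BETA/SE``, the two-sided P-value, the effect-allele frequency ``EAF``
and the sample size ``N``.  ``Z`` together with ``EAF`` and ``N`` is a
sufficient summary: ``reconstruct_effects`` recovers (BETA, SE) from it.

P-values are clipped below at ``P_FLOOR`` to avoid exact zeros from
floating-point underflow; a ``LOG10P`` side column, when present, preserves
the unclipped magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: canonical column order for delimited summary-statistic files
CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "Z", "P", "N"]

#: smallest representable P-value; smaller values are clipped (magnitude kept
#: in LOG10P where computed)
P_FLOOR = 1e-300

#: median of the chi-square distribution with 1 df, the null reference for
#: the genomic-control inflation factor
CHI2_MEDIAN_1DF = float(sps.chi2.ppf(0.5, 1))

#: column-name dialects for public meta-analysis downloads; values map
#: canonical names to file headers
DIALECTS = {
    "canonical": {c: c for c in CANONICAL_COLUMNS},
    # public lipid / anthropometric consortium headers
    "glgc": {
        "SNP": "MarkerName",
        "EA": "Allele1",
        "OA": "Allele2",
        "EAF": "Freq.Allele1.HapMapCEU",
        "BETA": "b",
        "SE": "SE",
        "P": "p",
        "N": "N",
    },
}


@dataclass
class LoadReport:
    """Bookkeeping for one file load: rows read, dropped, and back-filled."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped_invalid: int = 0
    n_filled_z: int = 0
    n_filled_effects: int = 0

    def log(self) -> None:
        logger.info(
            "sumstats load: read=%d kept=%d dropped_invalid=%d "
            "filled_z=%d filled_effects=%d",
            self.n_read, self.n_kept, self.n_dropped_invalid,
            self.n_filled_z, self.n_filled_effects,
        )


class SumstatsFormatError(ValueError):
    """A mandatory column is missing or the file is not parseable."""


class SummaryStats:
    """Per-variant association results for one trait/study.

    Parameters
    ----------
    table:
        DataFrame with (a subset of) the canonical columns.  ``SNP``, ``CHR``,
        ``BP`` and ``P`` are mandatory.  Rows are sorted by (CHR, BP) and SNP
        ids must be unique.
    trait_name:
        Label for the trait/study.
    """

    def __init__(self, table: pd.DataFrame, trait_name: str = "trait",
                 load_report: LoadReport | None = None):
        for col in ("SNP", "CHR", "BP", "P"):
            if col not in table.columns:
                raise SumstatsFormatError(f"missing mandatory column: {col}")
        table = table.copy()
        table["CHR"] = table["CHR"].astype(str)
        table["BP"] = table["BP"].astype(np.int64)
        if table["SNP"].duplicated().any():
            dup = table.loc[table["SNP"].duplicated(), "SNP"].iloc[0]
            raise ValueError(f"duplicate variant id: {dup!r}")
        table = table.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
        self.table = table
        self.trait_name = trait_name
        self.load_report = load_report

    @property
    def m(self) -> int:
        """Total number of tested variants."""
        return len(self.table)

    def pvals(self) -> dict[str, float]:
        """Variant id -> P-value mapping (insertion order = genome order)."""
        return dict(zip(self.table["SNP"], self.table["P"]))

    def __repr__(self) -> str:  # pragma: no cover
        return f"SummaryStats(trait={self.trait_name!r}, m={self.m})"

    def write(self, path) -> None:
        """Write tab-delimited text (gzip inferred from extension)."""
        cols = [c for c in CANONICAL_COLUMNS if c in self.table.columns]
        cols += [c for c in self.table.columns if c not in cols]
        self.table[cols].to_csv(path, sep="\t", index=False, float_format="%.12g")


@dataclass
class HarmonizedPair:
    """A test and a truth study restricted to shared, allele-aligned variants."""

    test: SummaryStats
    truth: SummaryStats
    shared_ids: list[str]
    n_flipped: int = 0
    n_dropped_alleles: int = 0


def reconstruct_effects(z, eaf, n):
    """Recover (beta, se) from a Z statistic, allele frequency and sample size.

    For a variance-standardized (inverse-normalized) trait regressed on an
    additive dosage, ``se = 1/sqrt(2 p (1-p) (n + z^2))`` with ``p`` the
    effect-allele frequency, and ``beta = z * se``.  Accepts scalars or
    arrays.

    Raises
    ------
    ValueError
        if any ``eaf`` is outside the open interval (0, 1) or ``n <= 0``.
    """
    z = np.asarray(z, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("eaf must lie strictly between 0 and 1")
    if np.any(n <= 0):
        raise ValueError("n must be positive")
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * (n + z**2))
    beta = z * se
    if beta.ndim == 0:
        return float(beta), float(se)
    return beta, se


def read_sumstats(path, dialect: str | dict = "canonical",
                  trait_name: str | None = None, sep: str = "\t") -> SummaryStats:
    """Read delimited summary statistics into a :class:`SummaryStats`.

    ``dialect`` is either a key of :data:`DIALECTS` or a mapping from
    canonical column names to the file's header names.  Rows violating basic
    invariants (P outside (0, 1], non-positive SE, Z inconsistent with
    BETA/SE, unparseable numerics) are dropped and counted in the load
    report.  Missing Z is filled as BETA/SE; missing BETA/SE is reconstructed
    from (Z, EAF, N) where available.
    """
    colmap = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    raw = pd.read_csv(path, sep=sep)
    rename = {v: k for k, v in colmap.items() if v in raw.columns}
    df = raw.rename(columns=rename)

    for col in ("SNP", "CHR", "BP", "P"):
        if col not in df.columns:
            raise SumstatsFormatError(f"missing mandatory column: {col}")
    has_effects = {"BETA", "SE"} <= set(df.columns)
    has_zfn = {"Z", "EAF", "N"} <= set(df.columns)
    if not (has_effects or has_zfn):
        raise SumstatsFormatError("need either (BETA, SE) or (Z, EAF, N) columns")

    report = LoadReport(n_read=len(df))
    numeric = [c for c in ("BP", "EAF", "BETA", "SE", "Z", "P", "N") if c in df.columns]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")

    ok = df["P"].notna() & (df["P"] > 0) & (df["P"] <= 1) & df["BP"].notna()
    if "SE" in df.columns:
        ok &= df["SE"].isna() | (df["SE"] > 0)
    if "EAF" in df.columns:
        ok &= df["EAF"].isna() | ((df["EAF"] > 0) & (df["EAF"] < 1))
    if {"BETA", "SE", "Z"} <= set(df.columns):
        full = df["BETA"].notna() & df["SE"].notna() & df["Z"].notna()
        with np.errstate(invalid="ignore", divide="ignore"):
            mismatch = np.abs(df["Z"] - df["BETA"] / df["SE"]) > 1e-6 * np.maximum(
                1.0, np.abs(df["Z"]))
        ok &= ~(full & mismatch)
    report.n_dropped_invalid = int((~ok).sum())
    df = df.loc[ok].copy()

    if {"BETA", "SE"} <= set(df.columns):
        need_z = (df["Z"].isna() if "Z" in df.columns
                  else pd.Series(True, index=df.index))
        need_z &= df["BETA"].notna() & df["SE"].notna()
        if need_z.any():
            if "Z" not in df.columns:
                df["Z"] = np.nan
            df.loc[need_z, "Z"] = df.loc[need_z, "BETA"] / df.loc[need_z, "SE"]
            report.n_filled_z = int(need_z.sum())
    if has_zfn:
        if "BETA" not in df.columns:
            df["BETA"] = np.nan
        if "SE" not in df.columns:
            df["SE"] = np.nan
        need_b = (df["BETA"].isna() | df["SE"].isna()) & df["Z"].notna() \
            & df["EAF"].notna() & df["N"].notna()
        if need_b.any():
            beta, se = reconstruct_effects(df.loc[need_b, "Z"],
                                           df.loc[need_b, "EAF"],
                                           df.loc[need_b, "N"])
            df.loc[need_b, "BETA"] = beta
            df.loc[need_b, "SE"] = se
            report.n_filled_effects = int(need_b.sum())

    report.n_kept = len(df)
    report.log()
    if trait_name is None:
        trait_name = str(path)
    return SummaryStats(df, trait_name=trait_name, load_report=report)


def maf_filter(stats: SummaryStats, threshold: float = 0.05) -> SummaryStats:
    """Keep variants with minor-allele frequency strictly above ``threshold``.

    MAF = min(EAF, 1-EAF); the common-variant convention "MAF > 5%" uses a
    strict inequality, so a variant at exactly the threshold is removed.
    """
    eaf = stats.table["EAF"].to_numpy(dtype=float)
    maf = np.minimum(eaf, 1.0 - eaf)
    kept = stats.table.loc[maf > threshold]
    return SummaryStats(kept, trait_name=stats.trait_name)


def harmonize(test: SummaryStats, truth: SummaryStats) -> HarmonizedPair:
    """Restrict two studies to shared variants with aligned effect alleles.

    Variants are matched verbatim on id.  Where the truth study reports the
    same allele pair with effect/other swapped, its BETA and Z are negated
    and EAF reflected; irreconcilable allele pairs are dropped and counted.
    Raises ``ValueError`` on an empty intersection.
    """
    a = test.table.set_index("SNP")
    b = truth.table.set_index("SNP")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared variant ids between test and truth")
    a = a.loc[shared]
    b = b.loc[shared].copy()

    def norm(s):
        return s.astype(str).str.upper()

    same = (norm(a["EA"]) == norm(b["EA"])) & (norm(a["OA"]) == norm(b["OA"]))
    swapped = (norm(a["EA"]) == norm(b["OA"])) & (norm(a["OA"]) == norm(b["EA"]))
    bad = ~(same | swapped)
    if swapped.any():
        idx = b.index[swapped]
        for col, fn in (("BETA", lambda x: -x), ("Z", lambda x: -x),
                        ("EAF", lambda x: 1.0 - x)):
            if col in b.columns:
                b.loc[idx, col] = fn(b.loc[idx, col])
        b.loc[idx, ["EA", "OA"]] = a.loc[idx, ["EA", "OA"]].to_numpy()
    if bad.any():
        logger.warning("harmonize: dropping %d variants with irreconcilable "
                       "alleles", int(bad.sum()))
    keep = shared[~bad.to_numpy()]
    pair = HarmonizedPair(
        test=SummaryStats(a.loc[keep].reset_index(), trait_name=test.trait_name),
        truth=SummaryStats(b.loc[keep].reset_index(), trait_name=truth.trait_name),
        shared_ids=list(keep),
        n_flipped=int(swapped.sum()),
        n_dropped_alleles=int(bad.sum()),
    )
    return pair


def lambda_gc(stats: SummaryStats) -> float:
    """Genomic-control inflation factor: median test chi-square / 0.4549.

    Uses ``Z**2`` when Z is available, otherwise the chi-square quantile
    transform of the P-values (the two give identical results for two-sided
    normal tests).  Values near 1 indicate no systematic inflation.
    """
    t = stats.table
    if "Z" in t.columns and t["Z"].notna().all():
        chi2 = t["Z"].to_numpy(dtype=float) ** 2
    else:
        chi2 = sps.chi2.isf(t["P"].to_numpy(dtype=float), 1)
    if len(chi2) < 10:
        logger.warning("lambda_gc computed on only %d variants", len(chi2))
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)
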