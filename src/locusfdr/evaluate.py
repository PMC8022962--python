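"""Empirical-FDR evaluation of discoveries against a truth set.

The largest available study of a trait (or, in simulation, the generator's
causal variants) serves as "truth".  Loci declared significant in the test
study are labeled true positives when their lead variant is in high LD
with — or, in distance mode, physically near — any truth variant passing
the truth significance cutoff; the rest are false positives.  The
empirical FDR is then V/(V+S) over the labeled loci (0 when nothing is
rejected), the observable analogue of the false discovery proportion Q.

Matching criteria
-----------------
strict   : r^2 > 0.80 with a truth variant at P < 5e-8
relaxed  : r^2 > 0.60 with a truth variant at P < 5e-7
distance : lead within +/-50 kb of a truth variant at P < 5e-8

Matching consults ANY qualifying truth variant, not only truth lead
variants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clump import LocusSet, clump
from .ldmatrix import LDSource
from .procedures import (bayesian_fdr_stepup, bfdp_from_stats, bh, bonferroni,
                         by, estimate_pi1)
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class MatchCriterion:
    """How a test locus is matched to the truth set."""

    mode: str                 # ld_strict | ld_relaxed | distance
    r2_min: float | None = None
    truth_p_max: float = 5e-8
    dist_bp: int | None = None
    #: LD-mode matching only consults truth variants within this distance of
    #: the lead; high LD beyond 1 Mb is negligible for common variants
    ld_horizon_bp: int = 1_000_000

    @classmethod
    def strict(cls) -> "MatchCriterion":
        return cls("ld_strict", r2_min=0.80, truth_p_max=5e-8)

    @classmethod
    def relaxed(cls) -> "MatchCriterion":
        return cls("ld_relaxed", r2_min=0.60, truth_p_max=5e-7)

    @classmethod
    def distance(cls, dist_bp: int = 50_000) -> "MatchCriterion":
        return cls("distance", truth_p_max=5e-8, dist_bp=dist_bp)

    @classmethod
    def named(cls, name: str) -> "MatchCriterion":
        try:
            return {"strict": cls.strict, "relaxed": cls.relaxed,
                    "distance": cls.distance}[name]()
        except KeyError:
            raise ValueError(f"unknown criterion: {name!r}") from None


@dataclass
class TruthSet:
    """Truth variants and their clumped loci.

    ``sig_table`` holds SNP/CHR/BP/P for every truth variant eligible for
    matching; label_loci further filters it by the criterion's truth P
    cutoff.  In known-truth simulation the causal variants enter with P=0
    so they qualify under every cutoff.
    """

    sig_table: pd.DataFrame
    truth_loci: LocusSet
    p_cut: float = 5e-8

    @property
    def n_truth_loci(self) -> int:
        return self.truth_loci.m_star

    @classmethod
    def from_causal_ids(cls, causal_ids, ld: LDSource) -> "TruthSet":
        """Known-truth set for simulation: the generator's causal variants."""
        idx = [ld.index_of(v) for v in causal_ids]
        table = pd.DataFrame({
            "SNP": list(causal_ids),
            "CHR": ld.chrom[idx],
            "BP": ld.pos[idx],
            "P": 0.0,
        })
        from .clump import Locus
        loci = [Locus(r.SNP, [r.SNP], str(r.CHR), int(r.BP), 0.0)
                for r in table.itertuples()]
        return cls(table, LocusSet(loci), p_cut=0.0)


def build_truth(truth_stats: SummaryStats, ld: LDSource, p_cut: float = 5e-8,
                r2_threshold: float = 0.1, window_bp: int = 1_000_000
                ) -> TruthSet:
    """Clump the truth study's significant variants into truth loci."""
    sig = truth_stats.table.loc[truth_stats.table["P"] < p_cut]
    if len(sig) == 0:
        logger.warning("truth set has no significant variants at P < %g; "
                       "every test locus will be labeled a false positive",
                       p_cut)
    # keep moderately significant variants too: relaxed matching may consult
    # truth variants up to a looser cutoff
    elig = truth_stats.table.loc[truth_stats.table["P"] < max(p_cut, 5e-7),
                                 ["SNP", "CHR", "BP", "P"]].reset_index(drop=True)
    loci = clump(SummaryStats(sig, trait_name=truth_stats.trait_name), ld,
                 r2_threshold=r2_threshold, window_bp=window_bp) \
        if len(sig) else LocusSet([])
    return TruthSet(elig, loci, p_cut=p_cut)


@dataclass
class EvalResult:
    """Table-1-style bookkeeping for one procedure's rejected loci."""

    R: int
    V: int
    S: int
    efdr: float
    labels: dict = field(default_factory=dict)   # lead id -> "TP"/"FP"
    matches: dict = field(default_factory=dict)  # lead id -> (match id, r2/dist)
    procedure: str = ""
    alpha: float = float("nan")
    loci: LocusSet | None = None   # the rejected loci that were labeled

    def __post_init__(self):
        assert self.R == self.V + self.S


def efdr(V: int, S: int) -> float:
    """Empirical FDR V/(V+S); defined as 0 when nothing was rejected."""
    if V < 0 or S < 0:
        raise ValueError("counts must be non-negative")
    return V / (V + S) if V + S > 0 else 0.0


def label_loci(test_loci: LocusSet, truth: TruthSet, crit: MatchCriterion,
               ld: LDSource | None) -> EvalResult:
    """Label each test locus TP or FP against the truth set.

    LD modes: the locus is a true positive iff its lead has r^2 strictly
    above ``crit.r2_min`` with any truth variant at P < ``crit.truth_p_max``
    (a lead that is itself such a truth variant matches itself at r^2 = 1).
    Distance mode: iff the lead lies within ``crit.dist_bp`` of any such
    truth variant.  A lead missing from the LD source cannot be matched and
    is labeled FP with a warning.
    """
    cand = truth.sig_table.loc[truth.sig_table["P"] < crit.truth_p_max]
    cand_ids = set(cand["SNP"])
    c_snp = cand["SNP"].to_numpy(dtype=object)
    c_chr = cand["CHR"].astype(str).to_numpy(dtype=object)
    c_bp = cand["BP"].to_numpy(dtype=np.int64)
    labels, matches = {}, {}
    V = S = 0
    for locus in test_loci.loci:
        on_chr = np.flatnonzero(c_chr == locus.chrom)
        is_tp, match = False, None
        if locus.lead_id in cand_ids:
            is_tp, match = True, (locus.lead_id, 1.0)
        elif crit.mode == "distance":
            d = np.abs(c_bp[on_chr] - locus.lead_pos)
            if len(d) and d.min() <= crit.dist_bp:
                j = int(np.argmin(d))
                is_tp, match = True, (c_snp[on_chr[j]], int(d[j]))
        elif len(on_chr):
            near = on_chr[np.abs(c_bp[on_chr] - locus.lead_pos)
                          <= crit.ld_horizon_bp]
            if ld is None or locus.lead_id not in ld:
                logger.warning("lead %s absent from LD source; labeling FP",
                               locus.lead_id)
            elif len(near):
                in_ld = [v for v in c_snp[near] if v in ld]
                if in_ld:
                    r2 = ld.r2_many(locus.lead_id, in_ld)
                    j = int(np.argmax(r2))
                    if r2[j] > crit.r2_min:
                        is_tp, match = True, (in_ld[j], float(r2[j]))
        labels[locus.lead_id] = "TP" if is_tp else "FP"
        matches[locus.lead_id] = match
        if is_tp:
            S += 1
        else:
            V += 1
    return EvalResult(R=V + S, V=V, S=S, efdr=efdr(V, S), labels=labels,
                      matches=matches)


def labels_frame(loci: LocusSet, ev: EvalResult) -> pd.DataFrame:
    """Per-locus label table: LEAD, CHR, BP, P, LABEL, MATCH_ID, MATCH_VALUE
    (r^2 for LD criteria, distance in bp for the distance criterion)."""
    rows = []
    for locus in loci.loci:
        match = ev.matches.get(locus.lead_id)
        rows.append({
            "LEAD": locus.lead_id, "CHR": locus.chrom, "BP": locus.lead_pos,
            "P": locus.lead_p, "LABEL": ev.labels.get(locus.lead_id, ""),
            "MATCH_ID": match[0] if match else "",
            "MATCH_VALUE": match[1] if match else "",
        })
    return pd.DataFrame(rows, columns=["LEAD", "CHR", "BP", "P", "LABEL",
                                       "MATCH_ID", "MATCH_VALUE"])


def compare_thresholds(eval_a: EvalResult, eval_b: EvalResult):
    """Gain from loosening a fixed cutoff: (delta loci, % true of additional).

    ``eval_a`` is the stricter cutoff, ``eval_b`` the looser one; rejection
    sets must be nested so delta = R_b - R_a >= 0.  Returns pct as ``None``
    when no loci were gained.
    """
    delta = eval_b.R - eval_a.R
    if delta < 0:
        raise ValueError("looser cutoff rejected fewer loci; inputs swapped?")
    if delta == 0:
        return 0, None
    return delta, 100.0 * (eval_b.S - eval_a.S) / delta


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal rounding with ties away from zero (printed-table convention).

    Works on the shortest decimal representation of ``x`` so that values
    like 0.565 round to 0.57 despite their binary representation.
    """
    import decimal
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def format_percent(fraction: float) -> float:
    """A proportion as a percentage rounded to two significant figures,
    the precision used in the package's report tables (5.9, 16, 0.57...)."""
    pct = 100.0 * fraction
    if pct == 0:
        return 0.0
    ndigits = 1 - int(math.floor(math.log10(abs(pct))))
    return round_half_up(pct, ndigits)


def evaluation_table(test_stats: SummaryStats, truth: TruthSet, ld: LDSource,
                     methods, criterion: MatchCriterion,
                     r2_threshold: float = 0.1, window_bp: int = 1_000_000,
                     W: float = 0.04, pi1: float | None = None,
                     distance_loci: bool = False):
    """Run several procedures end to end and tabulate their eFDR.

    ``methods`` is a list of (name, level) pairs with name in
    {"p", "bonferroni", "bh", "by", "bfdp"}.  Two clumping regimes apply:
    fixed-threshold procedures clump only their significant variants,
    whereas the adapted BH/BY/BFDP procedures clump ALL tested variants and
    run the step-up on the lead variants, rejecting whole loci.

    Returns ``(table, results)``: a DataFrame with False/True/eFDR columns
    per row and the underlying :class:`EvalResult` per method key.
    """
    ld_thr = None if distance_loci else r2_threshold
    all_loci = None
    rows, results = [], {}
    for name, level in methods:
        if name in ("p", "bonferroni"):
            if name == "p":
                # strict inequality; equivalent to fixed_threshold but
                # without materializing the full id -> p map
                sig = test_stats.table.loc[test_stats.table["P"] < level]
            else:
                res = bonferroni(test_stats.pvals(), level)
                sig = test_stats.table.loc[test_stats.table["SNP"].isin(
                    set(res.rejected_ids))]
            loci = clump(SummaryStats(sig, trait_name=test_stats.trait_name),
                         ld if ld_thr is not None else None,
                         r2_threshold=ld_thr, window_bp=window_bp) \
                if len(sig) else LocusSet([])
        elif name in ("bh", "by", "bfdp"):
            if all_loci is None:
                all_loci = clump(test_stats,
                                 ld if ld_thr is not None else None,
                                 r2_threshold=ld_thr, window_bp=window_bp)
            leads = all_loci.lead_pvals()
            if name == "bh":
                res = bh(leads, level)
            elif name == "by":
                res = by(leads, level)
            else:
                p1 = pi1 if pi1 is not None else estimate_pi1(test_stats)
                t = test_stats.table.set_index("SNP")
                lead_ids = list(leads)
                scores = bfdp_from_stats(t.loc[lead_ids, "Z"].to_numpy(),
                                         t.loc[lead_ids, "SE"].to_numpy(),
                                         W=W, pi1=p1)
                res = bayesian_fdr_stepup(dict(zip(lead_ids, scores)), level)
            loci = all_loci.subset(res.rejected_ids)
        else:
            raise ValueError(f"unknown procedure: {name!r}")
        ev = label_loci(loci, truth, criterion, ld)
        ev.procedure, ev.alpha, ev.loci = name, level, loci
        key = f"{name}:{level:g}"
        results[key] = ev
        rows.append({"procedure": name, "level": level, "R": ev.R,
                     "False": ev.V, "True": ev.S, "eFDR": ev.efdr,
                     "eFDR_pct": format_percent(ev.efdr)})
    return pd.DataFrame(rows), results
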