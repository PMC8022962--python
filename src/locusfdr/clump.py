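"""Greedy P-value-ordered LD clumping of variants into loci.

A locus is a cluster of nearby correlated variants summarized by its lead
(smallest-P) variant.  The greedy loop: take the unassigned variant with
the smallest P-value as lead, assign to its locus every unassigned variant
on the same chromosome within the window whose dosage r^2 with the lead
exceeds the threshold, and repeat until every variant is assigned.  The
result is a partition of the input set.

``distance_clump`` is the same loop with the LD condition removed, grouping
purely by physical distance from the lead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ldmatrix import LDSource
from .sumstats import SummaryStats


@dataclass
class Locus:
    lead_id: str
    member_ids: list[str]
    chrom: str
    lead_pos: int
    lead_p: float

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class LocusSet:
    """An ordered partition of variants into loci (lead P ascending)."""

    loci: list[Locus] = field(default_factory=list)
    r2_threshold: float | None = 0.1
    window_bp: int = 1_000_000

    @property
    def m_star(self) -> int:
        return len(self.loci)

    def lead_pvals(self) -> dict[str, float]:
        """Lead-variant id -> P map, the input to adapted step-up procedures."""
        return {loc.lead_id: loc.lead_p for loc in self.loci}

    def subset(self, lead_ids) -> "LocusSet":
        """Loci whose lead is in ``lead_ids`` (order preserved)."""
        keep = set(lead_ids)
        return LocusSet([l for l in self.loci if l.lead_id in keep],
                        self.r2_threshold, self.window_bp)

    def write(self, path) -> None:
        """PLINK-clump-style table: one row per locus."""
        rows = [{"LEAD": l.lead_id, "CHR": l.chrom, "BP": l.lead_pos,
                 "P": l.lead_p, "N_MEMBERS": l.size,
                 "MEMBER_IDS": ",".join(l.member_ids)} for l in self.loci]
        pd.DataFrame(rows, columns=["LEAD", "CHR", "BP", "P", "N_MEMBERS",
                                    "MEMBER_IDS"]).to_csv(
            path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def read(cls, path) -> "LocusSet":
        df = pd.read_csv(path, sep="\t")
        loci = [Locus(r.LEAD, str(r.MEMBER_IDS).split(","), str(r.CHR),
                      int(r.BP), float(r.P)) for r in df.itertuples()]
        return cls(loci)


def clump(stats: SummaryStats, ld: LDSource | None, r2_threshold: float | None = 0.1,
          window_bp: int = 1_000_000, p_subset: float | None = None) -> LocusSet:
    """Greedy P-ordered clumping of ``stats`` into a :class:`LocusSet`.

    Parameters
    ----------
    stats:
        The variants to clump (all of them, or only those below ``p_subset``).
    ld:
        Dosage-based LD lookup; may be ``None`` when ``r2_threshold`` is
        ``None`` (distance-only clumping).
    r2_threshold:
        Membership requires r^2(lead, member) strictly above this value;
        ``None`` disables the LD condition.
    window_bp:
        Lead-to-member distance bound, inclusive on both ends.
    p_subset:
        If given, only variants with P strictly below this cutoff enter the
        clumping (the regime used for fixed P-value thresholds).

    P-value ties are broken by (CHR, BP, SNP) so the partition is
    deterministic.  Loci on different chromosomes are never merged.
    """
    t = stats.table
    if p_subset is not None:
        t = t.loc[t["P"] < p_subset]
    n = len(t)
    out = LocusSet([], r2_threshold, window_bp)
    if n == 0:
        return out

    ids = t["SNP"].to_numpy(dtype=object)
    chrom = t["CHR"].to_numpy(dtype=object)
    pos = t["BP"].to_numpy(dtype=np.int64)
    p = t["P"].to_numpy(dtype=float)
    if r2_threshold is not None:
        if ld is None:
            raise ValueError("LD source required when r2_threshold is set")
        col = np.array([ld.index_of(v) for v in ids], dtype=np.intp)

    # primary key P, ties by (CHR, BP, SNP)
    order = np.lexsort((ids, pos, chrom, p))
    assigned = np.zeros(n, dtype=bool)
    for i in order:
        if assigned[i]:
            continue
        cand = np.flatnonzero(~assigned & (chrom == chrom[i])
                              & (np.abs(pos - pos[i]) <= window_bp))
        if r2_threshold is not None:
            r2 = ld._r2_idx(col[i], col[cand])
            cand = cand[(r2 > r2_threshold) | (cand == i)]
        assigned[cand] = True
        member_order = cand[np.lexsort((ids[cand], pos[cand]))]
        out.loci.append(Locus(
            lead_id=ids[i], member_ids=list(ids[member_order]),
            chrom=str(chrom[i]), lead_pos=int(pos[i]), lead_p=float(p[i])))
    return out


def distance_clump(stats: SummaryStats, window_bp: int = 1_000_000,
                   p_subset: float | None = None) -> LocusSet:
    """Clump by physical distance from the lead only (no LD condition)."""
    return clump(stats, ld=None, r2_threshold=None, window_bp=window_bp,
                 p_subset=p_subset)
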