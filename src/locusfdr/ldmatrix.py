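"""Pairwise linkage disequilibrium (r^2) from genotype dosage data.

An :class:`LDSource` wraps an n-individuals x M-variants dosage matrix
(values in [0, 2]) together with a variant sidecar (id, chromosome,
position).  r^2 between two variants is the squared Pearson correlation of
their dosage columns, computed in-sample; column means and centered sums of
squares are cached at construction so repeated queries during clumping cost
one dot product each.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class ConstantDosageError(ValueError):
    """LD is undefined for a monomorphic (zero-variance) dosage column."""


class LDSource:
    """In-sample LD lookup over a dense dosage matrix.

    Parameters
    ----------
    dosages:
        (n, M) array of dosage values in [0, 2]; converted to float32.
    ids, chrom, pos:
        Per-column variant id, chromosome and 1-based position.
    """

    def __init__(self, dosages: np.ndarray, ids, chrom, pos):
        dosages = np.asarray(dosages, dtype=np.float32)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        self.dosages = dosages
        self.ids = np.asarray(ids, dtype=object)
        self.chrom = np.asarray([str(c) for c in chrom], dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        if len(self.ids) != dosages.shape[1]:
            raise ValueError("sidecar length does not match matrix columns")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("variant ids must be unique")
        self._index = {vid: i for i, vid in enumerate(self.ids)}
        self._mean = dosages.mean(axis=0, dtype=np.float64)
        # centered sum of squares per column: sum g^2 - n*mean^2
        sq = np.einsum("ij,ij->j", dosages, dosages, dtype=np.float64)
        self._css = sq - dosages.shape[0] * self._mean**2

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, variant_id) -> bool:
        return variant_id in self._index

    def index_of(self, variant_id) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant not in LD source: {variant_id!r}") from None

    def r2(self, id_a, id_b) -> float:
        """Squared dosage correlation between two variants, in [0, 1]."""
        return float(self.r2_many(id_a, [id_b])[0])

    def r2_many(self, lead_id, other_ids) -> np.ndarray:
        """r^2 between one lead variant and a collection of others."""
        i = self.index_of(lead_id)
        js = np.array([self.index_of(v) for v in other_ids], dtype=np.intp)
        return self._r2_idx(i, js)

    def _r2_idx(self, i: int, js: np.ndarray) -> np.ndarray:
        if self._css[i] <= 0:
            raise ConstantDosageError(f"constant dosage column: {self.ids[i]!r}")
        bad = self._css[js] <= 0
        if np.any(bad):
            raise ConstantDosageError(
                f"constant dosage column: {self.ids[js[bad][0]]!r}")
        # float32 BLAS for the raw cross-products; the centering and ratio
        # are done in float64 (r^2 accurate to ~1e-4, ample for thresholding)
        g = np.ascontiguousarray(self.dosages[:, i])
        sub = self.dosages[:, js]
        cross = (g @ sub).astype(np.float64) \
            - self.n * self._mean[i] * self._mean[js]
        r2 = cross**2 / (self._css[i] * self._css[js])
        # finite-sample rounding can push self-correlation epsilon above 1
        return np.clip(r2, 0.0, 1.0)

    # ---- text I/O ---------------------------------------------------------

    def write(self, prefix) -> None:
        """Write ``<prefix>.dosages.tsv`` (n x M, no header) and
        ``<prefix>.variants.tsv`` (SNP, CHR, BP sidecar)."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".dosages.tsv"), self.dosages,
                   fmt="%g", delimiter="\t")
        pd.DataFrame({"SNP": self.ids, "CHR": self.chrom, "BP": self.pos}).to_csv(
            prefix.with_suffix(".variants.tsv"), sep="\t", index=False)

    @classmethod
    def read(cls, prefix) -> "LDSource":
        prefix = Path(prefix)
        dos = np.loadtxt(prefix.with_suffix(".dosages.tsv"), delimiter="\t",
                         ndmin=2)
        side = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t")
        return cls(dos, side["SNP"], side["CHR"], side["BP"])
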