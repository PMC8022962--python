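"""Shared fixtures: summary-stat builders and small synthetic panels."""

import numpy as np
import pandas as pd
import pytest

from locusfdr import LDSource, SimStudyConfig, SummaryStats, make_paired_studies


@pytest.fixture
def make_stats():
    """Factory: SummaryStats from parallel field lists (defaults filled)."""

    def _make(ids, p, chrom=None, pos=None, beta=None, se=None, z=None,
              eaf=None, n=10_000, trait="trait"):
        m = len(ids)
        tbl = pd.DataFrame({
            "SNP": ids,
            "CHR": chrom if chrom is not None else ["1"] * m,
            "BP": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "EA": "A", "OA": "G",
            "P": p,
        })
        tbl["N"] = n
        for col, val in (("BETA", beta), ("SE", se), ("Z", z), ("EAF", eaf)):
            if val is not None:
                tbl[col] = val
        return SummaryStats(tbl, trait_name=trait)

    return _make


@pytest.fixture
def make_panel():
    """Factory: (LDSource, positions) from an explicit dosage matrix."""

    def _make(dosages, pos=None, chrom=None):
        dosages = np.asarray(dosages, dtype=np.float32)
        M = dosages.shape[1]
        ids = [f"v{j}" for j in range(M)]
        pos = pos if pos is not None else np.arange(1, M + 1) * 1000
        chrom = chrom if chrom is not None else ["1"] * M
        return LDSource(dosages, ids, chrom, pos)

    return _make


def random_panel(rng, n=150, n_blocks=4, block_size=5, rho=0.8):
    """A small block-LD panel via the latent AR(1) haplotype construction."""
    cfg = SimStudyConfig(n_test=n, n_truth=n, M=n_blocks * block_size,
                         n_blocks=n_blocks, rho=rho, n_causal=0, hsq=0.0,
                         reps=2)
    from locusfdr.simulate import simulate_genotypes
    return simulate_genotypes(cfg, rng)


@pytest.fixture(scope="session")
def small_pair():
    """A modest paired test/truth study with real signal, shared read-only."""
    cfg = SimStudyConfig(n_test=3000, n_truth=30_000, M=3000, n_blocks=30,
                         n_causal=8, hsq=0.25, reps=2, seed=42)
    return make_paired_studies(cfg, 42)
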