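"""Synthetic GWAS generator: block-LD genotypes, additive quantitative
traits, per-variant association scans, and paired test/truth studies.

Genotypes
---------
Variants come in independent blocks.  Within a block, each of the 2n
haplotypes is a latent AR(1) Gaussian with parameter ``rho``; thresholding
column j at the quantile of its target minor-allele frequency produces the
allele, and the dosage is the sum of the two haplotypes, giving values in
{0, 1, 2} with realistic decaying LD inside blocks and no LD between them.
Blocks are spaced more than the clumping window apart (2 Mb between block
starts, < 200 kb span within a block) so they clump into distinct loci.

Traits
------
A single quantitative trait follows the additive model
``y = sum_j g_j theta_j + eps`` with ``eps ~ N(0, 1 - h2)`` where ``h2``
is the variance explained by the causal variants; the trait is therefore
approximately variance-standardized, matching the inverse-normalized scale
assumed by the effect-reconstruction formula.  Multi-trait generation adds
row-wise Gaussian residuals with a given residual correlation.

Scans
-----
Per variant, simple least squares of the trait on dosage with an
intercept; two-sided P-values from the t distribution with n-2 degrees of
freedom.  :class:`LinearScan` caches the per-column genotype moments so
that repeated scans over fixed genotypes (the replicate design) cost one
matrix-vector product each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .ldmatrix import LDSource
from .sumstats import P_FLOOR, SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class SimStudyConfig:
    """Parameters of one simulated test/truth study pair.

    Defaults are a desk-scale rendition of a consortium-style common-variant
    GWAS: 20,000 variants in 200 LD blocks of 100, a test study of 20,000
    individuals evaluated against a five-fold larger truth study, and 30
    causal blocks explaining 20% of trait variance.
    """

    n_test: int = 20_000
    n_truth: int = 100_000
    M: int = 20_000
    n_blocks: int = 200
    rho: float = 0.95
    maf_range: tuple = (0.05, 0.5)
    n_causal: int = 30
    hsq: float = 0.2
    effect_law: str | list = "halfnormal"   # or an explicit list of effects
    L: int = 1
    sigma: list | None = None               # L x L residual correlation
    share_causals: bool = True
    inverse_normalize: bool = False
    truth_mode: str = "scaled"              # scaled | genotyped
    reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.M % self.n_blocks != 0:
            raise ValueError("M must be a multiple of n_blocks")
        if not 0 < self.n_test <= self.n_truth:
            raise ValueError("need 0 < n_test <= n_truth")
        if isinstance(self.effect_law, str) and not 0 <= self.hsq < 1:
            raise ValueError("hsq must lie in [0, 1)")

    @property
    def block_size(self) -> int:
        return self.M // self.n_blocks

    @classmethod
    def desk_scale(cls, **overrides) -> "SimStudyConfig":
        """Preset with 200 replicates; Monte-Carlo SEs widen ~2.2x vs 1000."""
        kw = {"reps": 200}
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "SimStudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["maf_range"] = list(d["maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class GenotypeMatrix:
    """Dosage pool with block-LD structure."""

    dosages: np.ndarray          # (n, M) float32, values in {0, 1, 2}
    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    mafs: np.ndarray             # target MAFs used at generation
    blocks: list                 # (start_col, end_col, rho) per block

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def M(self) -> int:
        return self.dosages.shape[1]

    def to_ldsource(self) -> LDSource:
        return LDSource(self.dosages, self.ids, self.chrom, self.pos)

    def block_of(self, variant_id) -> int:
        j = int(np.flatnonzero(self.ids == variant_id)[0])
        for b, (s, e, _) in enumerate(self.blocks):
            if s <= j < e:
                return b
        raise KeyError(variant_id)


@dataclass
class TruthModel:
    """Simulation ground truth: causal variants and their effects.

    ``theta`` maps trait name -> {variant id -> effect in trait-SD units};
    ``hsq`` maps trait name -> variance explained.  ``sigma_resid`` is the
    L x L residual covariance (unit total trait variances).
    """

    causal_ids: dict             # trait -> list of ids
    theta: dict                  # trait -> {id -> effect}
    hsq: dict                    # trait -> explained variance
    trait_names: list
    sigma_resid: np.ndarray | None = None

    @property
    def L(self) -> int:
        return len(self.trait_names)

    def all_causal_ids(self) -> list:
        out: list = []
        for t in self.trait_names:
            out += [v for v in self.causal_ids[t] if v not in out]
        return out

    def write(self, path, G: GenotypeMatrix | None = None) -> None:
        rows = []
        for t in self.trait_names:
            for vid in self.causal_ids[t]:
                rows.append({
                    "TRAIT": t, "CAUSAL_ID": vid,
                    "THETA": self.theta[t][vid],
                    "MAF": float(G.mafs[np.flatnonzero(G.ids == vid)[0]])
                    if G is not None else float("nan"),
                    "BLOCK": G.block_of(vid) if G is not None else -1,
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                                  float_format="%.12g")


def simulate_genotypes(config: SimStudyConfig, seed, n: int | None = None
                       ) -> GenotypeMatrix:
    """Draw the dosage pool (thresholded AR(1) haplotype model)."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = config.n_test if config.truth_mode == "scaled" else config.n_truth
    k = config.block_size
    rho = np.float32(config.rho)
    innov = np.float32(np.sqrt(1.0 - float(rho) ** 2))
    # column-major layout: block writes and LD column gathers stay contiguous
    dos = np.empty((n, config.M), dtype=np.float32, order="F")
    mafs = np.empty(config.M)
    pos = np.empty(config.M, dtype=np.int64)
    blocks = []
    # within-block spacing keeps the block span under 200 kb for k <= 130
    spacing = 1_500
    for b in range(config.n_blocks):
        s = b * k
        maf = rng.uniform(*config.maf_range, size=k)
        thr = sps.norm.ppf(maf).astype(np.float32)
        # haplotypes as rows of a (k, 2n) buffer: the AR recursion updates
        # contiguous rows in place over the bulk innovation draw
        hap = rng.standard_normal((k, 2 * n), dtype=np.float32)
        for j in range(1, k):
            hap[j] *= innov
            hap[j] += rho * hap[j - 1]
        alleles = hap < thr[:, None]
        dos[:, s:s + k] = (alleles[:, :n].astype(np.float32)
                           + alleles[:, n:]).T
        mafs[s:s + k] = maf
        pos[s:s + k] = 1 + b * 2_000_000 + spacing * np.arange(k)
        blocks.append((s, s + k, float(rho)))
    ids = np.array([f"snp{j:06d}" for j in range(config.M)], dtype=object)
    chrom = np.array(["1"] * config.M, dtype=object)
    return GenotypeMatrix(dos, ids, chrom, pos, mafs, blocks)


def assign_effects(G: GenotypeMatrix, config: SimStudyConfig, seed
                   ) -> TruthModel:
    """Pick causal variants (one per chosen block) and draw their effects.

    Default law: theta = s * |N(0,1)| with random sign, with the scale s
    calibrated so the total explained variance sum_j var(g_j) theta_j^2
    (empirical dosage variances, standardized trait) equals ``hsq``.  An
    explicit effect list bypasses the calibration and fixes hsq to the
    variance it implies.
    """
    rng = np.random.default_rng(seed)
    if config.n_causal > config.n_blocks:
        raise ValueError("n_causal exceeds the number of blocks")
    trait_names = [f"trait{i+1}" for i in range(config.L)]
    causal_ids: dict = {}
    theta: dict = {}
    hsq: dict = {}
    shared_idx = None
    for t in trait_names:
        if config.share_causals and shared_idx is not None:
            idx = shared_idx
        else:
            blocks = rng.choice(config.n_blocks, size=config.n_causal,
                                replace=False)
            offs = rng.integers(0, config.block_size, size=config.n_causal)
            idx = np.sort(blocks * config.block_size + offs)
            shared_idx = idx
        if config.n_causal == 0:
            causal_ids[t], theta[t], hsq[t] = [], {}, 0.0
            continue
        gvar = G.dosages[:, idx].astype(np.float64).var(axis=0)
        if isinstance(config.effect_law, str):
            if config.effect_law != "halfnormal":
                raise ValueError(f"unknown effect law: {config.effect_law!r}")
            raw = np.abs(rng.standard_normal(config.n_causal)) \
                * rng.choice([-1.0, 1.0], size=config.n_causal)
            scale = np.sqrt(config.hsq / np.sum(gvar * raw**2))
            th = raw * scale
            h2 = config.hsq
        else:
            th = np.asarray(config.effect_law, dtype=float)
            if len(th) != config.n_causal:
                raise ValueError("explicit effect list length != n_causal")
            h2 = float(np.sum(gvar * th**2))
            if h2 >= 1:
                raise ValueError("explicit effects explain >= 100% of variance")
        causal_ids[t] = list(G.ids[idx])
        theta[t] = dict(zip(G.ids[idx], th))
        hsq[t] = h2
    sigma = None
    if config.L > 1:
        sigma = np.asarray(config.sigma, dtype=float) if config.sigma is not None \
            else np.eye(config.L)
        sd = np.sqrt([1.0 - hsq[t] for t in trait_names])
        sigma = np.outer(sd, sd) * sigma
        if np.linalg.eigvalsh(sigma).min() <= 0:
            raise ValueError("residual covariance not positive definite")
    return TruthModel(causal_ids, theta, hsq, trait_names, sigma)


def _genetic_value(G: GenotypeMatrix, truth: TruthModel, trait: str,
                   rows=None) -> np.ndarray:
    ids = truth.causal_ids[trait]
    if not ids:
        n = G.n if rows is None else len(rows)
        return np.zeros(n)
    idx = [int(np.flatnonzero(G.ids == v)[0]) for v in ids]
    th = np.array([truth.theta[trait][v] for v in ids])
    sub = G.dosages[:, idx] if rows is None else G.dosages[np.ix_(rows, idx)]
    return sub.astype(np.float64) @ th


def inverse_normal_transform(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform, Phi^-1((rank - 0.5)/n)."""
    r = sps.rankdata(y)
    return sps.norm.ppf((r - 0.5) / len(y))


def simulate_phenotype(G: GenotypeMatrix, truth: TruthModel, seed,
                       trait: str | None = None, rows=None,
                       inverse_normalize: bool = False,
                       noise_scale: float = 1.0) -> np.ndarray:
    """One trait draw: y = G theta + N(0, 1 - h2), optionally rank-normalized.

    ``noise_scale`` multiplies the residual standard deviation; a value of
    sqrt(n/n_target) emulates the per-variant precision of a study of
    ``n_target`` individuals while only genotyping ``n`` (both the signal
    and the sampling noise of the resulting scan Z statistics then match
    the larger study, up to allele-frequency resampling).
    """
    trait = trait or truth.trait_names[0]
    rng = np.random.default_rng(seed)
    gv = _genetic_value(G, truth, trait, rows)
    resid_sd = noise_scale * np.sqrt(1.0 - truth.hsq[trait])
    y = gv + resid_sd * rng.standard_normal(len(gv))
    return inverse_normal_transform(y) if inverse_normalize else y


def simulate_phenotypes_multi(G: GenotypeMatrix, truth: TruthModel, seed,
                              rows=None) -> np.ndarray:
    """n x L trait matrix with correlated residuals (rows iid N(0, Sigma))."""
    rng = np.random.default_rng(seed)
    n = G.n if rows is None else len(rows)
    gv = np.column_stack([_genetic_value(G, truth, t, rows)
                          for t in truth.trait_names])
    if truth.L == 1:
        resid = np.sqrt(1.0 - truth.hsq[truth.trait_names[0]]) \
            * rng.standard_normal((n, 1))
    else:
        chol = np.linalg.cholesky(truth.sigma_resid)
        resid = rng.standard_normal((n, truth.L)) @ chol.T
    return gv + resid


class LinearScan:
    """Repeated per-variant simple regression scans over fixed genotypes.

    Caches the column means and centered sums of squares of the dosage
    matrix so each scan needs a single matrix-vector product.  Constant
    columns are skipped (with a log message) and absent from the output.
    """

    def __init__(self, G: GenotypeMatrix, rows=None):
        self.G = G
        self.rows = None if rows is None else np.asarray(rows)
        if self.rows is None:
            sub = G.dosages
        elif self.rows.size and np.array_equal(
                self.rows, np.arange(self.rows[0],
                                     self.rows[0] + self.rows.size)):
            # contiguous row range: keep a view, avoid copying the pool
            sub = G.dosages[self.rows[0]:self.rows[0] + self.rows.size]
        else:
            sub = G.dosages[self.rows]
        self._sub = sub
        self.n = sub.shape[0]
        self._mean = sub.mean(axis=0, dtype=np.float64)
        sq = np.einsum("ij,ij->j", sub, sub, dtype=np.float64)
        self._sxx = sq - self.n * self._mean**2
        self._ok = self._sxx > 0
        if not self._ok.all():
            logger.info("scan: skipping %d constant dosage columns",
                        int((~self._ok).sum()))

    def scan(self, y: np.ndarray, trait_name: str = "trait",
             n_report: int | None = None) -> SummaryStats:
        y = np.asarray(y, dtype=np.float64)
        if len(y) != self.n:
            raise ValueError("phenotype length does not match genotypes")
        yc = y - y.mean()
        syy = float(yc @ yc)
        sxy = (yc.astype(np.float32) @ self._sub).astype(np.float64) \
            - 0.0  # means already removed from y
        ok = self._ok
        beta = np.full(self.G.M, np.nan)
        beta[ok] = sxy[ok] / self._sxx[ok]
        ssr = syy - beta[ok] * sxy[ok]
        df = self.n - 2
        sigma2 = np.maximum(ssr, 0.0) / df
        se = np.full(self.G.M, np.nan)
        se[ok] = np.sqrt(sigma2 / self._sxx[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        logp = np.log(2.0) + sps.t.logsf(np.abs(z[ok]), df)
        p = np.full(self.G.M, np.nan)
        p[ok] = np.clip(np.exp(logp), P_FLOOR, 1.0)
        table = pd.DataFrame({
            "SNP": self.G.ids[ok], "CHR": self.G.chrom[ok],
            "BP": self.G.pos[ok], "EA": "A", "OA": "B",
            "EAF": self._mean[ok] / 2.0, "BETA": beta[ok], "SE": se[ok],
            "Z": z[ok], "P": p[ok],
            "N": n_report if n_report is not None else self.n,
            "LOG10P": logp / np.log(10.0),
        })
        return SummaryStats(table, trait_name=trait_name)


def association_scan(G: GenotypeMatrix, y: np.ndarray, rows=None,
                     trait_name: str = "trait") -> SummaryStats:
    """One-shot scan: least squares of y on each dosage with an intercept."""
    return LinearScan(G, rows=rows).scan(y, trait_name=trait_name)


def truth_noise_scale(config: SimStudyConfig) -> float:
    """Residual-noise shrinkage emulating the truth study's sample size on
    the test-sized genotype pool (sqrt(n_pool/n_truth))."""
    return float(np.sqrt(config.n_test / config.n_truth))


@dataclass
class PairedStudy:
    test: SummaryStats
    truth_stats: SummaryStats
    truth_model: TruthModel
    ld: LDSource
    genotypes: GenotypeMatrix


def make_paired_studies(config: SimStudyConfig, seed) -> PairedStudy:
    """Generate a small-n test study and a large-n truth study.

    One genotype pool; the test study scans an independently drawn
    phenotype on ``n_test`` individuals, the truth study on ``n_truth``.
    In the default ``truth_mode="scaled"`` the pool has ``n_test``
    individuals and the truth study is emulated on the same pool with its
    residual noise shrunk by sqrt(n_test/n_truth) (inflated per-variant
    precision); ``truth_mode="genotyped"`` draws the full ``n_truth`` pool
    and scans ``n_truth`` individuals directly.
    """
    ss = np.random.SeedSequence(seed)
    s_geno, s_model, s_test, s_truth = ss.spawn(4)
    G = simulate_genotypes(config, s_geno)
    truth_model = assign_effects(G, config, s_model)
    trait = truth_model.trait_names[0]

    test_rows = np.arange(config.n_test)
    y_test = simulate_phenotype(G, truth_model, s_test, rows=test_rows,
                                inverse_normalize=config.inverse_normalize)
    test = association_scan(G, y_test, rows=test_rows,
                            trait_name=f"{trait}_test")

    if config.truth_mode == "scaled":
        y_truth = simulate_phenotype(G, truth_model, s_truth,
                                     inverse_normalize=config.inverse_normalize,
                                     noise_scale=truth_noise_scale(config))
        truth_stats = LinearScan(G).scan(y_truth,
                                         trait_name=f"{trait}_truth",
                                         n_report=config.n_truth)
    elif config.truth_mode == "genotyped":
        y_truth = simulate_phenotype(G, truth_model, s_truth,
                                     inverse_normalize=config.inverse_normalize)
        truth_stats = association_scan(G, y_truth,
                                       trait_name=f"{trait}_truth")
    else:
        raise ValueError(f"unknown truth_mode: {config.truth_mode!r}")
    return PairedStudy(test, truth_stats, truth_model, G.to_ldsource(), G)
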