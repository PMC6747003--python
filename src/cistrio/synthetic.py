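"""Synthetic genotype/mRNA/protein cohorts with known regulatory patterns.

Each simulated gene carries one causal biallelic variant and a ground-truth
causal structure among genotype ``S``, mRNA ``R`` and protein ``N``, drawn
from the six canonical cis-regulatory patterns:

1. ``S -> R`` only (protein independent of both)
2. ``S -> N`` only
3. ``S -> R`` and ``S -> N`` with independent errors
4. ``S -> R -> N`` (full transcriptional mediation)
5. ``S -> N`` and ``R -> N`` (post-transcriptional genetic effect)
6. ``S -> R``, ``S -> N`` and ``R -> N`` (all three edges)

Genotypes are Hardy-Weinberg draws ``Binomial(2, maf)``; residuals are
Gaussian.  Effect sizes are expressed in trait standard-deviation units per
alt allele so defaults transfer across sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneInterval, GenotypeMatrix, TrioData
from .exceptions import DegenerateDataError, ParameterError

PATTERN_IDS = (1, 2, 3, 4, 5, 6)

#: which effects are active under each generative pattern
PATTERN_EDGES = {
    1: ("RS",),
    2: ("NS",),
    3: ("RS", "NS"),
    4: ("RS", "NR"),
    5: ("NS", "NR"),
    6: ("RS", "NS", "NR"),
}

_MONOMORPHIC_RETRIES = 100

#: below this allele frequency a polymorphic draw is hopeless at any
#: realistic cohort size, so the parameter is rejected outright
MIN_MAF = 1e-3


@dataclass
class SimParams:
    """Generative parameters for one gene's trio.

    Defaults mirror the regime the classifier is benchmarked in: 62
    individuals (a typical LCL cohort), a common variant (MAF 0.3),
    standardized effect 1.0 per active edge and residual SD 0.5.
    """

    n_individuals: int = 62
    maf: float = 0.3
    pattern_id: int = 1
    beta_RS: float = 0.0
    beta_NS: float = 0.0
    beta_NR: float = 0.0
    sigma_R: float = 0.5
    sigma_N: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not MIN_MAF <= self.maf <= 0.5:
            raise ParameterError(
                f"maf must be in [{MIN_MAF}, 0.5], got {self.maf}"
            )
        if self.sigma_R <= 0 or self.sigma_N <= 0:
            raise ParameterError("residual SDs must be positive")
        if self.pattern_id not in PATTERN_IDS:
            raise ParameterError(f"pattern_id must be 1..6, got {self.pattern_id}")
        if self.n_individuals < 2:
            raise ParameterError("need at least 2 individuals")

    @classmethod
    def for_pattern(cls, pattern_id: int, effect: float = 1.0, **kwargs) -> "SimParams":
        """Parameters with ``effect`` on every edge the pattern activates."""
        betas = {f"beta_{e}": effect for e in PATTERN_EDGES[pattern_id]}
        betas.update(kwargs)
        return cls(pattern_id=pattern_id, **betas)


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth record for one simulated gene."""

    gene_id: str
    causal_variant_id: str
    true_pattern: int
    beta_RS: float
    beta_NS: float
    beta_NR: float


@dataclass
class CohortConfig:
    """Layout of a simulated cohort.

    ``genes_per_pattern`` maps pattern id -> number of genes generated
    under that pattern.  Every gene gets one causal variant at its body
    midpoint plus ``n_decoys`` non-causal variants scattered uniformly
    across the cis window and slightly beyond it (to exercise window
    boundaries downstream).
    """

    genes_per_pattern: dict[int, int] = field(
        default_factory=lambda: {p: 1 for p in PATTERN_IDS}
    )
    n_individuals: int = 62
    maf: float = 0.3
    effect: float = 1.0
    sigma_R: float = 0.5
    sigma_N: float = 0.5
    n_decoys: int = 10
    gene_length: int = 5_000
    gene_spacing: int = 200_000
    window_bp: int = 20_000
    decoy_margin: int = 5_000
    chrom: str = "chr1"
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.genes_per_pattern) - set(PATTERN_IDS)
        if bad:
            raise ParameterError(f"unknown pattern ids: {sorted(bad)}")
        if sum(self.genes_per_pattern.values()) < 1:
            raise ParameterError("at least one gene must be requested")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError("missing_rate must be in [0, 1)")


@dataclass
class Cohort:
    """Bundle of everything :func:`simulate_cohort` produces."""

    genotypes: GenotypeMatrix
    mrna: ExpressionMatrix
    protein: ExpressionMatrix
    genes: list[GeneInterval]
    truth: pd.DataFrame


def simulate_genotypes(
    n: int, maf: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` Hardy-Weinberg alt-allele dosages at the given MAF."""
    if not MIN_MAF <= maf <= 0.5:
        raise ParameterError(f"maf must be in [{MIN_MAF}, 0.5], got {maf}")
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.binomial(2, maf, size=n).astype(float)


def _polymorphic_genotypes(
    n: int, maf: float, rng: np.random.Generator
) -> np.ndarray:
    """Genotype draw with at least two classes, retrying bounded times."""
    for _ in range(_MONOMORPHIC_RETRIES):
        s = simulate_genotypes(n, maf, rng)
        if len(np.unique(s)) >= 2:
            return s
    raise DegenerateDataError(
        f"no polymorphic draw in {_MONOMORPHIC_RETRIES} retries (n={n}, maf={maf})"
    )


def _trio_traits(
    s: np.ndarray, params: SimParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """R and N vectors under the pattern's causal structure."""
    p = params
    eps_r = rng.normal(0.0, p.sigma_R, size=s.size)
    eps_n = rng.normal(0.0, p.sigma_N, size=s.size)
    if p.pattern_id == 1:
        r = p.beta_RS * s + eps_r
        n = eps_n
    elif p.pattern_id == 2:
        r = eps_r
        n = p.beta_NS * s + eps_n
    elif p.pattern_id == 3:
        r = p.beta_RS * s + eps_r
        n = p.beta_NS * s + eps_n
    elif p.pattern_id == 4:
        r = p.beta_RS * s + eps_r
        n = p.beta_NR * r + eps_n
    elif p.pattern_id == 5:
        r = eps_r
        n = p.beta_NS * s + p.beta_NR * r + eps_n
    else:  # pattern 6
        r = p.beta_RS * s + eps_r
        n = p.beta_NS * s + p.beta_NR * r + eps_n
    return r, n


def simulate_trio(
    params: SimParams,
    rng: np.random.Generator | None = None,
    gene_id: str = "gene",
    variant_id: str = "snp",
) -> tuple[TrioData, SimTruth]:
    """Simulate one aligned (S, R, N) trio plus its truth record."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    s = _polymorphic_genotypes(params.n_individuals, params.maf, rng)
    r, n = _trio_traits(s, params, rng)
    trio = TrioData(S=s.astype(int), R=r, N=n)
    truth = SimTruth(
        gene_id=gene_id,
        causal_variant_id=variant_id,
        true_pattern=params.pattern_id,
        beta_RS=params.beta_RS,
        beta_NS=params.beta_NS,
        beta_NR=params.beta_NR,
    )
    return trio, truth


def simulate_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Simulate a full cohort: genotypes, two trait matrices, gene
    intervals and a truth table.

    Deterministic given ``(config, seed)``.  Decoy variants are sampled
    independently of the traits (MAF uniform in [0.15, 0.5]) and placed
    uniformly within the cis window extended by ``decoy_margin`` so some
    fall just outside it.
    """
    rng = np.random.default_rng(seed)
    n = config.n_individuals
    samples = [f"s{i:03d}" for i in range(n)]

    genes: list[GeneInterval] = []
    truth_rows: list[SimTruth] = []
    var_meta: list[dict] = []
    dosage_rows: list[np.ndarray] = []
    mrna_rows: list[np.ndarray] = []
    prot_rows: list[np.ndarray] = []
    gene_ids: list[str] = []

    g_index = 0
    for pattern_id in sorted(config.genes_per_pattern):
        for _ in range(config.genes_per_pattern[pattern_id]):
            gene_id = f"g{g_index:04d}_p{pattern_id}"
            start = 100_000 + g_index * config.gene_spacing
            end = start + config.gene_length - 1
            gene = GeneInterval(gene_id, config.chrom, start, end)

            params = SimParams.for_pattern(
                pattern_id,
                effect=config.effect,
                n_individuals=n,
                maf=config.maf,
                sigma_R=config.sigma_R,
                sigma_N=config.sigma_N,
            )
            causal_id = f"v{g_index:04d}_causal"
            trio, truth = simulate_trio(
                params, rng=rng, gene_id=gene_id, variant_id=causal_id
            )

            var_meta.append(
                {
                    "variant_id": causal_id,
                    "chrom": config.chrom,
                    "pos": int(gene.midpoint),
                    "ref": "A",
                    "alt": "G",
                }
            )
            dosage_rows.append(trio.S.astype(float))

            lo = start - config.window_bp - config.decoy_margin
            hi = end + config.window_bp + config.decoy_margin
            decoy_pos = np.sort(rng.integers(lo, hi + 1, size=config.n_decoys))
            for d, pos in enumerate(decoy_pos):
                var_meta.append(
                    {
                        "variant_id": f"v{g_index:04d}_d{d:02d}",
                        "chrom": config.chrom,
                        "pos": int(pos),
                        "ref": "C",
                        "alt": "T",
                    }
                )
                decoy_maf = rng.uniform(0.15, 0.5)
                dosage_rows.append(simulate_genotypes(n, decoy_maf, rng))

            genes.append(gene)
            truth_rows.append(truth)
            gene_ids.append(gene_id)
            mrna_rows.append(trio.R.copy())
            prot_rows.append(trio.N.copy())
            g_index += 1

    variants = pd.DataFrame(var_meta).set_index("variant_id")
    dosages = pd.DataFrame(
        np.vstack(dosage_rows), index=variants.index, columns=samples
    )
    mrna = pd.DataFrame(np.vstack(mrna_rows), index=gene_ids, columns=samples)
    protein = pd.DataFrame(np.vstack(prot_rows), index=gene_ids, columns=samples)

    if config.missing_rate > 0:
        for frame in (mrna, protein):
            mask = rng.random(frame.shape) < config.missing_rate
            frame.values[mask] = np.nan

    truth = pd.DataFrame(
        [
            {
                "gene_id": t.gene_id,
                "causal_variant_id": t.causal_variant_id,
                "true_pattern": t.true_pattern,
                "beta_RS": t.beta_RS,
                "beta_NS": t.beta_NS,
                "beta_NR": t.beta_NR,
            }
            for t in truth_rows
        ]
    ).set_index("gene_id")

    return Cohort(
        genotypes=GenotypeMatrix(variants=variants, dosages=dosages),
        mrna=ExpressionMatrix(mrna, scale="raw"),
        protein=ExpressionMatrix(protein, scale="raw"),
        genes=genes,
        truth=truth,
    )
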