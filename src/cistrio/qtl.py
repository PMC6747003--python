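"""Cis-QTL mapping: single-variant regressions for eQTLs and pQTLs, the
nested-model likelihood-ratio test for protein-specific QTLs (psQTLs), and
Benjamini-Hochberg FDR thresholding.

A psQTL is a variant whose association with protein abundance survives
conditioning on the gene's own mRNA level: the full model
``N ~ 1 + S + R`` is compared with the reduced model ``N ~ 1 + R`` by a
likelihood-ratio test, ``stat = n * ln(RSS_reduced / RSS_full)`` referred
to a chi-square with one degree of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneInterval, GenotypeMatrix
from .exceptions import DegenerateDataError, ParameterError

logger = logging.getLogger(__name__)

QTL_TYPES = ("eQTL", "pQTL", "psQTL")

QTL_COLUMNS = [
    "qtl_type",
    "gene_id",
    "variant_id",
    "chrom",
    "pos",
    "effect",
    "se",
    "stat",
    "p_value",
    "n_used",
]


@dataclass(frozen=True)
class AssocResult:
    effect: float
    se: float
    stat: float
    p_value: float
    n_used: int


@dataclass(frozen=True)
class FdrResult:
    """Benjamini-Hochberg threshold summary for one family of tests."""

    fdr_level: float
    p_cutoff: float
    n_discoveries: int
    n_tests: int
    method: str = "benjamini-hochberg"


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from 0/1/2 dosages; missing entries ignored."""
    d = np.asarray(dosages, dtype=float)
    obs = d[~np.isnan(d)]
    if obs.size == 0:
        raise DegenerateDataError("all dosages missing")
    f = obs.sum() / (2.0 * obs.size)
    return float(min(f, 1.0 - f))


def select_cis_candidates(
    gene: GeneInterval,
    genotypes: GenotypeMatrix,
    window_bp: int = 20_000,
    maf_min: float = 0.10,
) -> list[str]:
    """Variant ids on the gene's chromosome within ``+/- window_bp`` of the
    gene body (1-based inclusive) with MAF strictly above ``maf_min``."""
    v = genotypes.variants
    lo, hi = gene.start - window_bp, gene.end + window_bp
    in_window = (v["chrom"] == gene.chrom) & (v["pos"] >= lo) & (v["pos"] <= hi)
    ids = []
    for vid in v.index[in_window]:
        try:
            maf = compute_maf(genotypes.dosages.loc[vid].to_numpy())
        except DegenerateDataError:
            continue
        if maf > maf_min:
            ids.append(vid)
    return ids


def fit_linear_assoc(trait: np.ndarray, dosages: np.ndarray) -> AssocResult:
    """OLS of trait on dosage with intercept; two-sided t-test, n-2 df.

    Complete-case; constant trait returns slope 0 with p = 1 by
    convention, constant dosage raises (nothing to test).
    """
    y = np.asarray(trait, dtype=float)
    x = np.asarray(dosages, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    n = y.size
    if n < 3:
        raise DegenerateDataError(f"need >= 3 complete cases, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant dosage vector")
    if np.ptp(y) == 0:
        return AssocResult(effect=0.0, se=0.0, stat=0.0, p_value=1.0, n_used=n)
    res = stats.linregress(x, y)
    if res.stderr == 0:  # perfect fit: infinitely significant
        return AssocResult(res.slope, 0.0, np.inf, 0.0, n)
    t = res.slope / res.stderr
    return AssocResult(
        effect=float(res.slope),
        se=float(res.stderr),
        stat=float(t),
        p_value=float(res.pvalue),
        n_used=n,
    )


def _rss(y: np.ndarray, design: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid)


def lrt_psqtl(
    protein: np.ndarray, mrna: np.ndarray, dosages: np.ndarray
) -> AssocResult:
    """LRT of ``N ~ 1 + S + R`` against ``N ~ 1 + R``; chi-square(1) p."""
    y = np.asarray(protein, dtype=float)
    r = np.asarray(mrna, dtype=float)
    s = np.asarray(dosages, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(r) | np.isnan(s))
    y, r, s = y[keep], r[keep], s[keep]
    n = y.size
    if n < 4:
        raise DegenerateDataError(f"need >= 4 complete cases, got {n}")
    if np.ptp(s) == 0:
        raise DegenerateDataError("constant dosage vector")
    if np.ptp(r) > 0 and abs(np.corrcoef(s, r)[0, 1]) > 1 - 1e-12:
        raise DegenerateDataError("dosage and mRNA are perfectly collinear")
    ones = np.ones(n)
    rss_full = _rss(y, np.column_stack([ones, s, r]))
    rss_red = _rss(y, np.column_stack([ones, r]))
    tiny = 1e-12 * max(1.0, float(y @ y))
    if rss_full <= tiny:
        # reduced model already exact -> nothing for S to explain
        if rss_red <= tiny:
            return AssocResult(np.nan, np.nan, 0.0, 1.0, n)
        return AssocResult(np.nan, np.nan, np.inf, 0.0, n)
    stat = max(0.0, n * np.log(rss_red / rss_full))
    p = float(stats.chi2.sf(stat, df=1))
    return AssocResult(effect=np.nan, se=np.nan, stat=stat, p_value=p, n_used=n)


def bh_threshold(p_values: np.ndarray, fdr: float = 0.1) -> FdrResult:
    """Benjamini-Hochberg step-up: the cutoff is the largest sorted
    ``p_(i) <= i * fdr / m``; zero discoveries when no index qualifies."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    crit = fdr * np.arange(1, m + 1) / m
    passing = np.nonzero(order <= crit)[0]
    if passing.size == 0:
        return FdrResult(fdr, 0.0, 0, m)
    cutoff = float(order[passing[-1]])
    return FdrResult(fdr, cutoff, int((p <= cutoff).sum()), m)


def map_all_qtls(
    genotypes: GenotypeMatrix,
    mrna,
    protein,
    genes: list[GeneInterval],
    window_bp: int = 20_000,
    maf_min: float = 0.10,
    fdr: float = 0.1,
    min_cases: int = 10,
) -> tuple[pd.DataFrame, dict[str, FdrResult]]:
    """Run eQTL, pQTL and psQTL tests for every gene x cis candidate.

    Each test uses the complete cases available to it — eQTLs use all
    samples shared between genotypes and mRNA, so their effective n can
    exceed the protein-based tests'.  FDR is controlled separately per
    QTL type.  Returns the per-pair record table (with a ``significant``
    flag) and an :class:`FdrResult` per type.
    """
    gen_samples = set(genotypes.sample_ids)
    mrna_samples = [s for s in mrna.sample_ids if s in gen_samples]
    prot_samples = [s for s in protein.sample_ids if s in gen_samples]
    if not mrna_samples or not prot_samples:
        raise ParameterError("no shared samples between genotypes and traits")
    trio_samples = [s for s in mrna_samples if s in set(prot_samples)]

    rows: list[dict] = []
    for gene in genes:
        candidates = select_cis_candidates(gene, genotypes, window_bp, maf_min)
        has_r = gene.gene_id in mrna.values.index
        has_n = gene.gene_id in protein.values.index
        r_all = mrna.values.loc[gene.gene_id] if has_r else None
        n_all = protein.values.loc[gene.gene_id] if has_n else None
        for vid in candidates:
            dose = genotypes.dosages.loc[vid]
            meta = genotypes.variants.loc[vid]
            base = {
                "gene_id": gene.gene_id,
                "variant_id": vid,
                "chrom": meta["chrom"],
                "pos": int(meta["pos"]),
            }
            if has_r:
                rows.append(
                    _test_row(
                        "eQTL",
                        base,
                        lambda: fit_linear_assoc(
                            r_all[mrna_samples].to_numpy(),
                            dose[mrna_samples].to_numpy(),
                        ),
                        min_cases,
                    )
                )
            if has_n:
                rows.append(
                    _test_row(
                        "pQTL",
                        base,
                        lambda: fit_linear_assoc(
                            n_all[prot_samples].to_numpy(),
                            dose[prot_samples].to_numpy(),
                        ),
                        min_cases,
                    )
                )
            if has_r and has_n:
                rows.append(
                    _test_row(
                        "psQTL",
                        base,
                        lambda: lrt_psqtl(
                            n_all[trio_samples].to_numpy(),
                            r_all[trio_samples].to_numpy(),
                            dose[trio_samples].to_numpy(),
                        ),
                        min_cases,
                    )
                )

    records = pd.DataFrame(
        [r for r in rows if r is not None], columns=QTL_COLUMNS
    )
    records["significant"] = False
    fdr_results: dict[str, FdrResult] = {}
    for qtl_type in QTL_TYPES:
        mask = records["qtl_type"] == qtl_type
        if not mask.any():
            fdr_results[qtl_type] = FdrResult(fdr, 0.0, 0, 0)
            continue
        result = bh_threshold(records.loc[mask, "p_value"].to_numpy(), fdr)
        fdr_results[qtl_type] = result
        if result.n_discoveries:
            records.loc[mask & (records["p_value"] <= result.p_cutoff), "significant"] = True
    return records, fdr_results


def _test_row(qtl_type: str, base: dict, runner, min_cases: int) -> dict | None:
    try:
        res = runner()
    except DegenerateDataError as exc:
        logger.debug("%s %s/%s skipped: %s", qtl_type, base["gene_id"], base["variant_id"], exc)
        return None
    if res.n_used < min_cases:
        logger.debug(
            "%s %s/%s skipped: %d complete cases < %d",
            qtl_type, base["gene_id"], base["variant_id"], res.n_used, min_cases,
        )
        return None
    return {
        "qtl_type": qtl_type,
        **base,
        "effect": res.effect,
        "se": res.se,
        "stat": res.stat,
        "p_value": res.p_value,
        "n_used": res.n_used,
    }


def best_pqtl_per_gene(
    records: pd.DataFrame, genes: list[GeneInterval]
) -> pd.DataFrame:
    """One pQTL per gene: the smallest p-value, significant or not.

    Exact p ties break toward the variant nearest the gene midpoint,
    then the smallest coordinate.  Genes without a tested pQTL are
    omitted with a log notice.
    """
    pqtls = records[records["qtl_type"] == "pQTL"]
    if pqtls.empty:
        raise ParameterError("record table contains no pQTL rows")
    mid = {g.gene_id: g.midpoint for g in genes}
    chosen = []
    for gene_id, grp in pqtls.groupby("gene_id", sort=True):
        grp = grp.assign(_dist=(grp["pos"] - mid.get(gene_id, 0.0)).abs())
        grp = grp.sort_values(["p_value", "_dist", "pos"], kind="mergesort")
        chosen.append(grp.iloc[0].drop("_dist"))
    missing = set(mid) - set(pqtls["gene_id"])
    if missing:
        logger.info("no tested pQTL for %d gene(s): %s", len(missing), sorted(missing)[:5])
    return pd.DataFrame(chosen).reset_index(drop=True)
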