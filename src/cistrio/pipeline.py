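"""End-to-end orchestration: preprocess -> QTL mapping -> trio
classification -> enrichment, with a reproducible run manifest.

Two trio-selection modes mirror the two analysis rounds a cis-regulation
study typically runs:

* ``first_round`` — one trio per gene: the minimum-p pQTL regardless of
  significance (mirrors the best-local-pQTL strategy);
* ``extended`` — every (gene, variant) pair behind a significant eQTL,
  pQTL or psQTL at the configured FDR.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .containers import TrioData
from .enrichment import (
    DEFAULT_REGION_PRECEDENCE,
    StateSegmentation,
    chromatin_ratio_matrix,
    classify_region,
    location_hypergeom,
)
from .exceptions import CistrioError, DegenerateDataError, ParameterError
from .patterns import PATTERN_IDS, classify_trio
from .preprocess import (
    filter_by_missingness,
    normalize_expression,
    remove_principal_components,
)
from .qtl import best_pqtl_per_gene, map_all_qtls

logger = logging.getLogger(__name__)

COORD_COMMENT = "# coordinates: variant pos is 1-based; windows are inclusive\n"


class PipelineError(CistrioError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs for one pipeline run (defaults follow the standard
    cis-analysis settings: +/-20 kb window, MAF > 0.10, FDR 0.1)."""

    genotypes: str = ""
    mrna: str = ""
    protein: str = ""
    genes: str = ""
    states: str | None = None
    regions: str | None = None
    out_dir: str = "cistrio_out"
    window_bp: int = 20_000
    maf_min: float = 0.10
    fdr: float = 0.1
    min_fraction: float = 0.5
    normalize: bool = True
    n_pcs: int = 0
    form: str = "observed"  # observed | mixture
    weight_exponent: float = 1.0
    min_cases: int = 10
    mode: str = "extended"  # extended | first_round
    region_precedence: tuple[str, ...] = DEFAULT_REGION_PRECEDENCE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"extended", "first_round"}:
            raise ParameterError(f"unknown mode: {self.mode!r}")
        if self.form not in {"observed", "mixture"}:
            raise ParameterError(f"unknown likelihood form: {self.form!r}")
        if not 0 < self.fdr < 1:
            raise ParameterError("fdr must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region_precedence"] = list(self.region_precedence)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "region_precedence" in data:
            data["region_precedence"] = tuple(data["region_precedence"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("load")
def _load(config: PipelineConfig):
    genotypes = cio.read_genotypes(config.genotypes)
    mrna = cio.read_expression(config.mrna)
    protein = cio.read_expression(config.protein)
    genes = cio.read_genes_bed(config.genes)
    logger.info(
        "loaded %d variants, %d mRNA genes, %d protein genes, %d intervals",
        len(genotypes.variant_ids), len(mrna.gene_ids),
        len(protein.gene_ids), len(genes),
    )
    return genotypes, mrna, protein, genes


@_stage("preprocess")
def _preprocess(config: PipelineConfig, mrna, protein):
    out = []
    for matrix in (mrna, protein):
        m = filter_by_missingness(matrix, config.min_fraction)
        if config.normalize:
            m = normalize_expression(m)
        if config.n_pcs > 0:
            m = remove_principal_components(m, config.n_pcs)
        out.append(m)
    return out[0], out[1]


@_stage("map-qtl")
def _map(config: PipelineConfig, genotypes, mrna, protein, genes):
    return map_all_qtls(
        genotypes, mrna, protein, genes,
        window_bp=config.window_bp, maf_min=config.maf_min,
        fdr=config.fdr, min_cases=config.min_cases,
    )


@_stage("select-trios")
def _select_trios(config: PipelineConfig, records, genes) -> pd.DataFrame:
    if config.mode == "first_round":
        chosen = best_pqtl_per_gene(records, genes)
        return chosen[["gene_id", "variant_id"]]
    sig = records[records["significant"]]
    return sig[["gene_id", "variant_id"]].drop_duplicates().reset_index(drop=True)


@_stage("classify")
def _classify(config: PipelineConfig, pairs, genotypes, mrna, protein) -> pd.DataFrame:
    shared = [
        s for s in genotypes.sample_ids
        if s in set(mrna.sample_ids) and s in set(protein.sample_ids)
    ]
    rows = []
    n_failed = 0
    for pair in pairs.itertuples(index=False):
        if pair.gene_id not in mrna.values.index or pair.gene_id not in protein.values.index:
            continue
        try:
            trio = TrioData.from_vectors(
                genotypes.dosages.loc[pair.variant_id, shared].to_numpy(),
                mrna.values.loc[pair.gene_id, shared].to_numpy(),
                protein.values.loc[pair.gene_id, shared].to_numpy(),
            )
            fit = classify_trio(
                trio, form=config.form, weight_exponent=config.weight_exponent
            )
        except DegenerateDataError as exc:
            n_failed += 1
            logger.info("trio %s/%s excluded: %s", pair.gene_id, pair.variant_id, exc)
            continue
        row = {
            "gene_id": pair.gene_id,
            "variant_id": pair.variant_id,
            "selected_pattern": fit.selected_pattern,
            "n": fit.n,
        }
        for p in PATTERN_IDS:
            row[f"logL{p}"] = fit.fits[p].log_likelihood
            row[f"BIC{p}"] = fit.bics[p - 1]
            row[f"weight{p}"] = fit.weights[p - 1]
            row[f"converged{p}"] = fit.fits[p].converged
        rows.append(row)
    if n_failed:
        logger.info("%d trio(s) excluded during classification", n_failed)
    return pd.DataFrame(rows)


@_stage("enrich")
def _enrich(config: PipelineConfig, classified, genotypes):
    ratio_table = None
    location_table = None
    if classified.empty:
        return ratio_table, location_table
    pos = genotypes.variants.loc[classified["variant_id"]]
    patterns = classified["selected_pattern"].reset_index(drop=True)
    if config.states:
        seg = StateSegmentation.from_frame(cio.read_states_bed(config.states))
        states = pd.Series(
            [seg.assign(c, p) for c, p in zip(pos["chrom"], pos["pos"])],
            dtype=object,
        )
        n_gap = int(states.isna().sum())
        if n_gap:
            logger.info("%d QTL(s) in annotation gaps excluded from ratios", n_gap)
        ratio_table = chromatin_ratio_matrix(states, patterns)
    if config.regions:
        intervals = cio.read_regions_bed(config.regions)
        regions = pd.Series(
            [
                classify_region(c, p, intervals, config.region_precedence)
                for c, p in zip(pos["chrom"], pos["pos"])
            ],
            dtype=object,
        )
        location_table = location_hypergeom(regions, patterns, fdr=config.fdr)
    return ratio_table, location_table


def _write_table(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        frame.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write result tables plus a manifest.

    Returns the in-memory results keyed by stage.  Any stage failure
    aborts with :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genotypes, mrna_raw, protein_raw, genes = _load(config)
    mrna, protein = _preprocess(config, mrna_raw, protein_raw)
    records, fdr_results = _map(config, genotypes, mrna, protein, genes)
    pairs = _select_trios(config, records, genes)
    classified = _classify(config, pairs, genotypes, mrna, protein)
    ratio_table, location_table = _enrich(config, classified, genotypes)

    _write_table(records, out_dir / "qtls.tsv")
    fdr_frame = pd.DataFrame(
        [
            {
                "qtl_type": t,
                "fdr_level": r.fdr_level,
                "p_cutoff": r.p_cutoff,
                "n_discoveries": r.n_discoveries,
                "n_tests": r.n_tests,
                "method": r.method,
            }
            for t, r in fdr_results.items()
        ]
    )
    fdr_frame.to_csv(out_dir / "fdr_summary.tsv", sep="\t", index=False)
    _write_table(classified, out_dir / "patterns.tsv")
    if ratio_table is not None:
        _write_table(ratio_table.ratio, out_dir / "ratio_matrix.tsv", index=True)
    if location_table is not None:
        _write_table(location_table, out_dir / "location_enrichment.tsv")

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "versions": {
            "cistrio": _version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "genes": len(genes),
            "variants": len(genotypes.variant_ids),
            "qtl_tests": int(len(records)),
            "significant_qtls": int(records["significant"].sum()) if len(records) else 0,
            "trios_classified": int(len(classified)),
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "records": records,
        "fdr": fdr_results,
        "pairs": pairs,
        "classified": classified,
        "ratio": ratio_table,
        "location": location_table,
        "manifest": manifest,
    }


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("cistrio")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def write_cohort(cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort to the standard input dialects and return
    the paths (ready to feed into :class:`PipelineConfig`)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "mrna": out / "mrna.tsv",
        "protein": out / "protein.tsv",
        "genes": out / "genes.bed",
        "truth": out / "truth.tsv",
    }
    cio.write_genotypes_tsv(cohort.genotypes, paths["genotypes"])
    cio.write_expression(cohort.mrna, paths["mrna"])
    cio.write_expression(cohort.protein, paths["protein"])
    cio.write_genes_bed(cohort.genes, paths["genes"])
    cio.write_truth(cohort.truth, paths["truth"])
    return paths
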