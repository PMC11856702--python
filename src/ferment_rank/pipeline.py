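"""End-to-end orchestration: prune → score → select extremes → contrast → enrich.

``run_pipeline`` executes whichever stages the config enables (real users
may have only phenotype or only genotype data), writes every intermediate
table to the output directory, and returns a :class:`RunReport` that is
byte-deterministic for fixed inputs and seed (no timestamps in the body).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .enrichment import overrepresentation_test, read_annotation_table
from .phenotype import (
    DEFAULT_DIRECTIONS,
    load_reference_scores,
    read_phenotype_table,
)
from .scoring import CompositeScoreModel
from .selection import DEFAULT_PRIORITY, PruningPolicy
from .variants import (
    aggregate_genes,
    discriminating_sites,
    filter_nonsynonymous,
    quality_filter,
    read_genotype_tsv,
    read_vcf_genotypes,
    write_genotype_tsv,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one analysis run.

    ``phenotypes`` is a CSV/TSV path, or the literal string ``"fixture"``
    to use the packaged 36-strain reference table (already standardized,
    scores attached as reference metadata). ``vcf`` / ``genotype_tsv`` and
    ``annotation`` are optional; stages without inputs are skipped.
    """

    out_dir: str | Path = "ferment_rank_out"
    phenotypes: str | None = "fixture"
    vcf: str | None = None
    genotype_tsv: str | None = None
    annotation: str | None = None
    direction: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    prune_threshold: float = 0.6
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    k_extremes: int = 3
    min_depth: int = 10
    min_qual: float = 20.0
    min_mq: float = 30.0
    consequence_key: str = "CSQTYPE"
    gene_key: str = "GENE"
    require_full_groups: bool = True
    min_shared_fraction: float = 1.0
    nonsynonymous_only: bool = True
    include_zero_overlap: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        if "priority" in raw:
            raw["priority"] = tuple(raw["priority"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        d["priority"] = list(d["priority"])
        d["direction"] = dict(d["direction"])
        return d


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict[str, Any]
    version: str
    input_hashes: dict[str, str]
    retained_indicators: list[str] | None = None
    eigenvalues: list[float] | None = None
    explained_fraction: list[float] | None = None
    retained_components: list[int] | None = None
    coefficients: dict[str, float] | None = None
    scale_vs_reference: float | None = None
    strong: list[str] | None = None
    weak: list[str] | None = None
    n_sites_input: int | None = None
    n_sites_after_quality: int | None = None
    n_sites_discriminating: int | None = None
    n_genes: int | None = None
    gene_site_counts: dict[str, int] | None = None
    n_terms_enriched: int | None = None
    top_term: str | None = None
    skipped: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        lines = ["# ferment-rank run report", ""]
        lines.append(f"Package version: {self.version}")
        if self.retained_indicators is not None:
            lines.append(f"Retained indicators: {', '.join(self.retained_indicators)}")
        if self.eigenvalues is not None:
            lines.append(
                "Eigenvalues: " + ", ".join(f"{v:.4f}" for v in self.eigenvalues)
            )
        if self.coefficients is not None:
            lines.append(
                "Coefficients: "
                + ", ".join(f"{k}={v:.4f}" for k, v in self.coefficients.items())
            )
        if self.strong is not None:
            lines.append(f"Strong group: {', '.join(self.strong)}")
            lines.append(f"Weak group: {', '.join(self.weak)}")
        if self.n_sites_discriminating is not None:
            lines.append(
                f"Discriminating sites: {self.n_sites_discriminating} across "
                f"{self.n_genes} genes"
            )
        if self.n_terms_enriched is not None:
            lines.append(
                f"Enriched terms reported: {self.n_terms_enriched}"
                + (f" (top: {self.top_term})" if self.top_term else "")
            )
        for s in self.skipped:
            lines.append(f"Stage skipped: {s}")
        return "\n".join(lines) + "\n"


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashes: dict[str, str] = {}
    for name in ("phenotypes", "vcf", "genotype_tsv", "annotation"):
        p = getattr(config, name)
        if p and p != "fixture":
            if not Path(p).exists():
                raise PipelineError(f"stage inputs: {name} path does not exist: {p}")
            hashes[name] = _hash_file(p)
    report = RunReport(config=config.to_dict(), version=__version__, input_hashes=hashes)

    # --- scoring stage -----------------------------------------------------
    groups = None
    if config.phenotypes is None:
        report.skipped.append("scoring (no phenotype input)")
    else:
        try:
            if config.phenotypes == "fixture":
                std = load_reference_scores()
                model = CompositeScoreModel.from_standardized(std)
            else:
                table = read_phenotype_table(config.phenotypes, direction=config.direction)
                policy = PruningPolicy(
                    threshold=config.prune_threshold,
                    priority=tuple(
                        list(config.priority)
                        + [i for i in table.indicators if i not in config.priority]
                    ),
                )
                model = CompositeScoreModel(table, prune=policy)
            results = model.fit(k_extremes=config.k_extremes)
        except Exception as exc:
            raise PipelineError(f"stage scoring: {exc}") from exc
        groups = results.groups
        report.retained_indicators = list(results.kept_indicators or results.std.indicators)
        report.eigenvalues = [float(v) for v in results.eigenvalues]
        report.explained_fraction = [float(v) for v in results.explained_fraction]
        report.retained_components = list(results.retained)
        report.coefficients = {
            ind: float(c) for ind, c in zip(results.std.indicators, results.coefficients)
        }
        report.scale_vs_reference = results.scores.scale
        report.strong = list(groups.strong)
        report.weak = list(groups.weak)
        scores_df = results.scores.to_frame().sort_values("rank")
        scores_df["group"] = [
            "strong" if s in groups.strong else ("weak" if s in groups.weak else "")
            for s in scores_df.index
        ]
        scores_df.to_csv(out / "scores.tsv", sep="\t", float_format="%.6f")
        (out / "summary.txt").write_text(results.summary() + "\n")

    # --- contrast stage ----------------------------------------------------
    contrast = None
    geno_path = config.vcf or config.genotype_tsv
    if geno_path is None:
        report.skipped.append("contrast (no genotype input)")
    elif groups is None:
        report.skipped.append("contrast (no group assignment from scoring)")
    else:
        try:
            if config.vcf:
                matrix = read_vcf_genotypes(
                    config.vcf,
                    consequence_key=config.consequence_key,
                    gene_key=config.gene_key,
                )
            else:
                matrix = read_genotype_tsv(config.genotype_tsv)
            report.n_sites_input = matrix.n_sites
            # fixture strain IDs are bare numbers; VCF samples carry the S prefix
            name_map = {s: s for s in matrix.samples}
            for s in matrix.samples:
                if s.startswith("S") and s[1:].isdigit():
                    name_map.setdefault(s[1:], s)
            group_a = [name_map.get(g, g) for g in groups.strong]
            group_b = [name_map.get(g, g) for g in groups.weak]
            filtered = quality_filter(
                matrix,
                min_depth=config.min_depth,
                min_qual=config.min_qual,
                min_mq=config.min_mq,
            )
            report.n_sites_after_quality = filtered.n_sites
            contrast = discriminating_sites(
                filtered,
                group_a,
                group_b,
                require_full_groups=config.require_full_groups,
                min_shared_fraction=config.min_shared_fraction,
            )
            if config.nonsynonymous_only:
                contrast = filter_nonsynonymous(contrast)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage contrast ({geno_path}): {exc}") from exc
        gene_counts = aggregate_genes(contrast)
        report.n_sites_discriminating = contrast.n_sites_discriminating
        report.n_genes = len(gene_counts)
        report.gene_site_counts = dict(sorted(gene_counts.items()))
        contrast.to_frame().to_csv(out / "discriminating_sites.tsv", sep="\t", index=False)
        with open(out / "gene_summary.tsv", "w") as fh:
            fh.write("gene\tn_sites\n")
            for gene, cnt in sorted(gene_counts.items()):
                fh.write(f"{gene}\t{cnt}\n")
        write_genotype_tsv(
            filtered.subset_sites([h.site_index for h in contrast.hits]),
            out / "discriminating_matrix.tsv",
        )

    # --- enrichment stage --------------------------------------------------
    if config.annotation is None:
        report.skipped.append("enrichment (no annotation input)")
    elif contrast is None or not contrast.hits:
        report.skipped.append("enrichment (no discriminating genes)")
    else:
        try:
            annot = read_annotation_table(config.annotation)
            query = set(aggregate_genes(contrast))
            table = overrepresentation_test(
                query, annot, include_zero_overlap=config.include_zero_overlap
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage enrichment ({config.annotation}): {exc}") from exc
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        report.n_terms_enriched = int(len(table))
        if len(table):
            report.top_term = str(table.iloc[0]["term"])

    (out / "report.json").write_text(report.to_json() + "\n")
    (out / "report.md").write_text(report.to_markdown())
    _assert_report_consistency(report, out)
    return report


def _assert_report_consistency(report: RunReport, out: Path) -> None:
    """Report counts must equal the lengths of the emitted tables."""
    import pandas as pd

    if report.n_sites_discriminating is not None:
        df = pd.read_csv(out / "discriminating_sites.tsv", sep="\t")
        if len(df) != report.n_sites_discriminating:
            raise PipelineError(
                "internal: discriminating-site count disagrees with emitted table"
            )
    if report.n_terms_enriched is not None:
        df = pd.read_csv(out / "enrichment.tsv", sep="\t")
        if len(df) != report.n_terms_enriched:
            raise PipelineError("internal: enrichment count disagrees with emitted table")
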