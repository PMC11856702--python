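"""Synthetic data generators emulating the study's data-generating structure.

Three generators, all deterministic under a seed:

* phenotypes — a latent per-strain fermentation ability drives four
  informative indicators (TTA, specific volume, hardness with a negative
  loading, springiness); redundant proxies (pH tracking TTA at r ≈ 0.99;
  cohesiveness/gumminess/chewiness tracking hardness at r ≈ 0.6–1.0) are
  generated as affine functions of their parent plus noise.
* genotypes — a sites × strains state matrix with planted
  group-discriminating variants: every member of the strong group shares an
  identical non-reference state at a planted site while every member of the
  weak group is reference-consistent. Defaults plant 33 sites over 19 genes
  between two trios, mirroring the headline counts of the study the
  pipeline re-creates. Background sites are i.i.d. noise; by default they
  are rejection-sampled so none accidentally discriminates between the two
  configured groups (disable via ``exclude_background_contrast`` to study
  the strict rule's false-positive behaviour on pure noise).
* annotations — a gene → term table with one planted overrepresented term.

Every generator returns a ``SimTruth`` record whose bookkeeping matches the
emitted data exactly, for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .enrichment import AnnotationTable
from .phenotype import LOWER_IS_BETTER, StrainPhenotypeTable
from .variants import (
    GenotypeMatrix,
    GenotypeState,
    VariantSite,
    _directional_hit,
)

# stream constants so adding one generator never perturbs another
_PHENO_STREAM = 11
_GENO_STREAM = 23
_ANNOT_STREAM = 37


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth bookkeeping for recovery tests."""

    latent_ability: dict[str, float] | None = None
    planted_site_keys: tuple[tuple, ...] | None = None
    planted_genes: tuple[str, ...] | None = None
    planted_complete_keys: tuple[tuple, ...] | None = None
    planted_term: str | None = None
    query_genes: tuple[str, ...] | None = None


# ---------------------------------------------------------------------------
# phenotypes


@dataclass(frozen=True)
class PhenotypeSimConfig:
    """Latent-factor phenotype generator settings.

    ``loadings`` are on the standardized core scale: indicator_core =
    loading · ability + N(0, noise_sd). Output columns are affine-mapped to
    realistic units via ``units`` (mean, scale); affine maps leave every
    correlation untouched. ``redundant`` maps a proxy indicator to
    (parent, slope, proxy noise sd, mean, scale).
    """

    n_strains: int = 36
    loadings: Mapping[str, float] = field(
        default_factory=lambda: {
            "TTA": 0.3,
            "Volume": 0.8,
            "Hardness": -0.8,
            "Springiness": 0.8,
        }
    )
    noise_sd: float = 0.3
    units: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "TTA": (4.0, 1.0),
            "Volume": (2.3, 0.25),
            "Hardness": (25.0, 8.0),
            "Springiness": (7.0, 0.5),
            "pH": (5.1, 0.08),
            "Cohesiveness": (0.72, 0.05),
            "Gumminess": (18.0, 5.0),
            "Chewiness": (90.0, 20.0),
        }
    )
    redundant: Mapping[str, tuple[str, float, float]] = field(
        default_factory=lambda: {
            # proxy: (parent, slope on parent core, proxy noise sd)
            "pH": ("TTA", 1.0, 0.05),  # r ~ 0.99 with TTA
            "Cohesiveness": ("Hardness", 1.0, 0.50),  # r ~ 0.86
            "Gumminess": ("Hardness", 1.0, 0.60),  # r ~ 0.82
            "Chewiness": ("Hardness", 1.0, 0.70),  # r ~ 0.78
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_strains < 2:
            raise ValueError("need at least 2 strains")
        for proxy, (parent, _, nsd) in self.redundant.items():
            if parent not in self.loadings:
                raise ValueError(f"redundant indicator {proxy!r} has unknown parent {parent!r}")
            if nsd < 0:
                raise ValueError(f"negative noise sd for {proxy!r}")


def simulate_phenotypes(
    config: PhenotypeSimConfig | None = None,
) -> tuple[StrainPhenotypeTable, SimTruth]:
    """Draw a strain × indicator table from the latent-ability model."""
    if config is None:
        config = PhenotypeSimConfig()
    rng = _rng(config.seed, _PHENO_STREAM)
    n = config.n_strains
    ability = rng.standard_normal(n)
    strain_ids = tuple(f"S{i + 1}" for i in range(n))
    cores: dict[str, np.ndarray] = {}
    for ind, loading in config.loadings.items():
        cores[ind] = loading * ability + rng.normal(0.0, config.noise_sd, size=n)
    for proxy, (parent, slope, nsd) in config.redundant.items():
        cores[proxy] = slope * cores[parent] + rng.normal(0.0, nsd, size=n)
    indicators = tuple(cores)
    values = np.column_stack(
        [config.units.get(ind, (0.0, 1.0))[0] + config.units.get(ind, (0.0, 1.0))[1] * cores[ind]
         for ind in indicators]
    )
    # hardness and its proxies run opposite to quality; pH mirrors TTA here
    # (redundancy pruning keys on |r|, so the proxy's sign is immaterial)
    direction = {
        ind: LOWER_IS_BETTER
        for ind in indicators
        if ind == "Hardness"
        or (ind in config.redundant and config.redundant[ind][0] == "Hardness")
    }
    table = StrainPhenotypeTable(strain_ids, indicators, values, direction)
    return table, SimTruth(latent_ability=dict(zip(strain_ids, ability.tolist())))


# ---------------------------------------------------------------------------
# genotypes


@dataclass(frozen=True)
class GenotypeSimConfig:
    """Planted-contrast genotype generator settings.

    Defaults mirror the re-created study: 36 strains, two trios
    (strong = S1/S25/S33 vs weak = S18/S20/S35), 33 planted non-synonymous
    discriminating sites over 19 genes among noise background sites.
    """

    n_sites: int = 500
    n_strains: int = 36
    group_a: tuple[str, ...] = ("S1", "S25", "S33")
    group_b: tuple[str, ...] = ("S18", "S20", "S35")
    n_planted: int = 33
    n_planted_genes: int = 19
    planted_het_fraction: float = 0.0  # fraction of planted sites shared as HET rather than HOM_ALT
    frac_nonsyn_planted: float = 1.0
    frac_nonsyn_background: float = 0.3
    background_hom: float = 0.15
    background_het: float = 0.10
    missing_rate: float = 0.0
    quality_failure_rate: float = 0.0  # fraction of background sites emitted below QUAL threshold
    background_gene_pool: int = 150
    exclude_background_contrast: bool = True
    passing_qual: float = 60.0
    failing_qual: float = 10.0
    mapping_quality: float = 55.0
    passing_depth: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_sites:
            raise ValueError("n_planted exceeds n_sites")
        if self.n_planted_genes > self.n_planted and self.n_planted > 0:
            raise ValueError("n_planted_genes exceeds n_planted")
        for name in (
            "planted_het_fraction",
            "frac_nonsyn_planted",
            "frac_nonsyn_background",
            "background_hom",
            "background_het",
            "missing_rate",
            "quality_failure_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background_hom + self.background_het + self.missing_rate > 1:
            raise ValueError("background state probabilities exceed 1")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups overlap")

    @property
    def samples(self) -> tuple[str, ...]:
        names = [f"S{i + 1}" for i in range(self.n_strains)]
        for g in (*self.group_a, *self.group_b):
            if g not in names:
                raise ValueError(f"group member {g!r} outside the S1..S{self.n_strains} panel")
        return tuple(names)


_BASES = np.array(list("ACGT"))


def simulate_genotypes(
    config: GenotypeSimConfig | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a genotype matrix with planted group-discriminating sites."""
    if config is None:
        config = GenotypeSimConfig()
    rng = _rng(config.seed, _GENO_STREAM)
    samples = config.samples
    ia = [samples.index(s) for s in config.group_a]
    ib = [samples.index(s) for s in config.group_b]
    ia_arr, ib_arr = np.array(ia), np.array(ib)

    planted_idx = set(
        rng.choice(config.n_sites, size=config.n_planted, replace=False).tolist()
    )
    planted_genes = tuple(f"PG{j + 1:02d}" for j in range(config.n_planted_genes))
    bg_genes = [f"BG{j + 1:03d}" for j in range(config.background_gene_pool)]

    p_hom, p_het, p_miss = config.background_hom, config.background_het, config.missing_rate
    p_ref = 1.0 - p_hom - p_het - p_miss
    state_codes = np.array(
        [
            GenotypeState.REF_CONSISTENT,
            GenotypeState.HOM_ALT,
            GenotypeState.HET,
            GenotypeState.LOW_QUALITY,
        ],
        dtype=np.int8,
    )
    probs = np.array([p_ref, p_hom, p_het, p_miss])

    sites: list[VariantSite] = []
    states = np.empty((config.n_sites, len(samples)), dtype=np.int8)
    planted_keys: list[tuple] = []
    complete_keys: list[tuple] = []
    planted_gene_cycle = 0

    def sample_background_row() -> np.ndarray:
        for _ in range(200):
            row = rng.choice(state_codes, size=len(samples), p=probs)
            if not config.exclude_background_contrast:
                return row
            a = row[ia_arr]
            b = row[ib_arr]
            if np.any(a == GenotypeState.LOW_QUALITY) or np.any(b == GenotypeState.LOW_QUALITY):
                return row  # strict rule skips such sites anyway
            if (
                _directional_hit(a, b, 1.0) is None
                and _directional_hit(b, a, 1.0) is None
            ):
                return row
        raise RuntimeError("could not sample a non-discriminating background row")

    for i in range(config.n_sites):
        ref, alt = rng.choice(4, size=2, replace=False)
        is_planted = i in planted_idx
        if is_planted:
            gene = planted_genes[planted_gene_cycle % config.n_planted_genes]
            planted_gene_cycle += 1
            nonsyn = rng.random() < config.frac_nonsyn_planted
            shared = (
                GenotypeState.HET
                if rng.random() < config.planted_het_fraction
                else GenotypeState.HOM_ALT
            )
            row = rng.choice(state_codes, size=len(samples), p=probs)
            row[ia_arr] = shared
            row[ib_arr] = GenotypeState.REF_CONSISTENT
            qual = config.passing_qual
        else:
            gene = bg_genes[int(rng.integers(len(bg_genes)))]
            nonsyn = rng.random() < config.frac_nonsyn_background
            row = sample_background_row()
            qual = (
                config.failing_qual
                if rng.random() < config.quality_failure_rate
                else config.passing_qual
            )
        site = VariantSite(
            chrom="chrI",
            pos=1000 * (i + 1),
            ref=str(_BASES[ref]),
            alt=str(_BASES[alt]),
            qual=qual,
            mapping_quality=config.mapping_quality,
            consequence="nonsynonymous" if nonsyn else "synonymous",
            gene=gene,
        )
        states[i] = row
        sites.append(site)
        if is_planted:
            planted_keys.append(site.key)

    # missingness hits planted group cells after planting, so recall under
    # require_full_groups equals the fraction of planted sites with complete
    # data in both groups (background cells drew missingness above)
    if config.missing_rate > 0:
        group_cols = np.concatenate([ia_arr, ib_arr])
        for i in sorted(planted_idx):
            miss = rng.random(len(group_cols)) < config.missing_rate
            states[i, group_cols[miss]] = GenotypeState.LOW_QUALITY
    for i in sorted(planted_idx):
        a_ok = np.all(states[i, ia_arr] != GenotypeState.LOW_QUALITY)
        b_ok = np.all(states[i, ib_arr] != GenotypeState.LOW_QUALITY)
        if a_ok and b_ok:
            complete_keys.append(sites[i].key)

    depths = np.full(states.shape, config.passing_depth, dtype=int)
    depths[states == GenotypeState.LOW_QUALITY] = 0
    matrix = GenotypeMatrix(sites=tuple(sites), samples=samples, states=states, depths=depths)
    truth = SimTruth(
        planted_site_keys=tuple(planted_keys),
        planted_genes=tuple(sorted({sites[i].gene for i in planted_idx})) if planted_idx else (),
        planted_complete_keys=tuple(complete_keys),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(
    n_genes: int = 1000,
    n_terms: int = 50,
    planted_term_size: int = 10,
    query_size: int = 20,
    planted_overlap: int = 8,
    term_size_range: tuple[int, int] = (5, 50),
    seed: int = 0,
) -> tuple[AnnotationTable, set[str], SimTruth]:
    """Random gene → term annotation with one planted overrepresented term."""
    if planted_overlap > min(query_size, planted_term_size):
        raise ValueError("planted_overlap exceeds query or planted term size")
    if planted_term_size > n_genes or query_size > n_genes:
        raise ValueError("sizes exceed the gene universe")
    rng = _rng(seed, _ANNOT_STREAM)
    genes = np.array([f"G{j + 1:04d}" for j in range(n_genes)])
    planted_term = "TERM_PLANTED"
    planted_genes = rng.choice(genes, size=planted_term_size, replace=False)
    in_term = set(planted_genes.tolist())
    overlap = rng.choice(planted_genes, size=planted_overlap, replace=False).tolist()
    outside = np.array(sorted(set(genes.tolist()) - in_term))
    rest = rng.choice(outside, size=query_size - planted_overlap, replace=False).tolist()
    query = set(overlap) | set(rest)
    terms: dict[str, frozenset[str]] = {planted_term: frozenset(in_term)}
    lo, hi = term_size_range
    for t in range(n_terms - 1):
        size = int(rng.integers(lo, hi + 1))
        terms[f"TERM{t + 1:03d}"] = frozenset(rng.choice(genes, size=size, replace=False).tolist())
    annot = AnnotationTable(terms=terms, background=frozenset(genes.tolist()))
    truth = SimTruth(planted_term=planted_term, query_genes=tuple(sorted(query)))
    return annot, query, truth


def write_annotation_tsv(annot: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annot.terms):
            for gene in sorted(annot.terms[term]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# VCF emission

_GT = {
    GenotypeState.REF_CONSISTENT: "0/0",
    GenotypeState.HOM_ALT: "1/1",
    GenotypeState.HET: "0/1",
    GenotypeState.LOW_QUALITY: "./.",
}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=CSQTYPE,Number=1,Type=String,Description="Coding consequence (synonymous/nonsynonymous/other)">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene identifier">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=chrI>
"""


def write_synthetic_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Emit a plain-text VCF 4.2 with GT:DP per sample and QUAL/MQ/annotation
    fields, with fixed float formatting so identical matrices yield
    byte-identical files. Round-trips through ``read_vcf_genotypes``."""
    contigs = sorted({s.chrom for s in matrix.sites})
    header = _VCF_HEADER.replace(
        "##contig=<ID=chrI>\n", "".join(f"##contig=<ID={c}>\n" for c in contigs) or ""
    )
    lines = [header.rstrip("\n")]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples)
    )
    order = sorted(range(matrix.n_sites), key=lambda i: (matrix.sites[i].chrom, matrix.sites[i].pos))
    for i in order:
        site = matrix.sites[i]
        info = []
        if site.mapping_quality is not None:
            info.append(f"MQ={site.mapping_quality:.1f}")
        if site.consequence is not None:
            info.append(f"CSQTYPE={site.consequence}")
        if site.gene is not None:
            info.append(f"GENE={site.gene}")
        cells = []
        for j in range(matrix.n_samples):
            state = int(matrix.states[i, j])
            if state not in _GT:
                raise ValueError(
                    "OTHER_ALT states cannot be serialized to a single-alt record"
                )
            if matrix.depths is None or matrix.depths[i, j] < 0:
                dp = "."
            else:
                dp = str(int(matrix.depths[i, j]))
            cells.append(f"{_GT[state]}:{dp}")
        qual = "." if site.qual is None else f"{site.qual:.1f}"
        lines.append(
            "\t".join(
                [
                    site.chrom,
                    str(site.pos),
                    ".",
                    site.ref,
                    site.alt,
                    qual,
                    "PASS",
                    ";".join(info) or ".",
                    "GT:DP",
                    *cells,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
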