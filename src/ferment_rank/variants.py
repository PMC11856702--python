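"""Genotype matrices and group-discriminating variant contrast.

Each site × strain cell carries one of four observable states relative to
the reference genome: REF_CONSISTENT (both alleles match the reference),
HOM_ALT (both differ), HET (one matches, one differs) or LOW_QUALITY (the
call is unreliable). A site discriminates between two strain groups A and B
when every member of A shares one identical non-reference state s (HOM_ALT
or HET) and no member of B carries s. Both directions are evaluated and
unioned. The contrast is typically restricted to non-synonymous sites and
aggregated per gene.

Multi-allelic records are decomposed into one row per alternate allele;
a genotype that involves a *different* alternate allele than the row's is
reference-inconsistent but matches neither HOM_ALT nor HET for this row, so
it is assigned the OTHER_ALT state, which never anchors nor matches a
shared mutation state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class GenotypeState:
    """Integer codes for per-sample genotype states."""

    REF_CONSISTENT = 0
    HOM_ALT = 1
    HET = 2
    LOW_QUALITY = 3
    OTHER_ALT = 4

    LABELS = {
        REF_CONSISTENT: "REF",
        HOM_ALT: "HOM",
        HET: "HET",
        LOW_QUALITY: "NO",
        OTHER_ALT: "OTHER",
    }
    FROM_LABEL = {v: k for k, v in LABELS.items()}

    #: states that can serve as the shared mutation state s
    MUTATION_STATES = (HOM_ALT, HET)


@dataclass(frozen=True)
class VariantSite:
    """One (decomposed) variant record with its quality and annotation fields."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    mapping_quality: float | None = None
    consequence: str | None = None  # "synonymous" | "nonsynonymous" | "other"
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"positions are 1-based; got {self.pos}")
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Sites × samples genotype-state matrix with per-cell read depths."""

    sites: tuple[VariantSite, ...]
    samples: tuple[str, ...]
    states: np.ndarray  # int8 [n_sites, n_samples]
    depths: np.ndarray | None = None  # int [n_sites, n_samples], -1 = unknown

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(self, "samples", tuple(self.samples))
        states = np.asarray(self.states, dtype=np.int8)
        object.__setattr__(self, "states", states)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        if states.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"state matrix shape {states.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if self.depths is not None:
            depths = np.asarray(self.depths, dtype=int)
            if depths.shape != states.shape:
                raise ValueError("depth matrix shape inconsistent with state matrix")
            object.__setattr__(self, "depths", depths)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        missing = [s for s in names if s not in self.samples]
        if missing:
            raise KeyError(f"sample(s) not in matrix: {missing}")
        return np.array([self.samples.index(s) for s in names], dtype=int)

    def subset_sites(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            sites=tuple(self.sites[i] for i in idx),
            samples=self.samples,
            states=self.states[idx],
            depths=None if self.depths is None else self.depths[idx],
        )


def _classify_gt(alleles: tuple, alt_index: int) -> int:
    """Map a pysam GT allele tuple to a state code for one decomposed alt."""
    if alleles is None or len(alleles) == 0 or any(a is None for a in alleles):
        return GenotypeState.LOW_QUALITY
    alleles = tuple(int(a) for a in alleles)
    if all(a == 0 for a in alleles):
        return GenotypeState.REF_CONSISTENT
    if all(a == alt_index for a in alleles):
        return GenotypeState.HOM_ALT
    if set(alleles) == {0, alt_index}:
        return GenotypeState.HET
    return GenotypeState.OTHER_ALT


_NONSYN_ALIASES = {
    "nonsynonymous",
    "non-synonymous",
    "nonsynonymous_snv",
    "missense",
    "missense_variant",
}
_SYN_ALIASES = {"synonymous", "synonymous_snv", "synonymous_variant"}


def normalize_consequence(raw: str | None) -> str | None:
    if raw is None:
        return None
    low = str(raw).strip().lower()
    if low in _NONSYN_ALIASES:
        return "nonsynonymous"
    if low in _SYN_ALIASES:
        return "synonymous"
    return "other"


def read_vcf_genotypes(
    path: str | Path,
    samples: Sequence[str] | None = None,
    consequence_key: str = "CSQTYPE",
    gene_key: str = "GENE",
    mq_key: str = "MQ",
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a genotype-state matrix.

    Multi-allelic records become one matrix row per alternate allele. GT
    mapping: 0/0 → REF_CONSISTENT, x/x → HOM_ALT, 0/x → HET, ./. →
    LOW_QUALITY, genotypes involving another alt → OTHER_ALT. Consequence
    and gene annotations are taken from the named INFO keys when present.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        header_samples = list(vf.header.samples)
        if samples is None:
            samples = header_samples
        else:
            missing = [s for s in samples if s not in header_samples]
            if missing:
                raise KeyError(f"sample(s) absent from VCF header: {missing}")
        sample_list = list(samples)
        sites: list[VariantSite] = []
        state_rows: list[list[int]] = []
        depth_rows: list[list[int]] = []
        n_malformed = 0
        for rec in vf:
            alts = rec.alts or ()
            mq = rec.info.get(mq_key) if mq_key in rec.info else None
            if isinstance(mq, tuple):
                mq = mq[0]
            csq = rec.info.get(consequence_key) if consequence_key in rec.info else None
            if isinstance(csq, tuple):
                csq = csq[0]
            gene = rec.info.get(gene_key) if gene_key in rec.info else None
            if isinstance(gene, tuple):
                gene = gene[0]
            for ai, alt in enumerate(alts, start=1):
                site = VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=str(alt),
                    qual=None if rec.qual is None else float(rec.qual),
                    mapping_quality=None if mq is None else float(mq),
                    consequence=normalize_consequence(csq),
                    gene=None if gene is None else str(gene),
                )
                row: list[int] = []
                drow: list[int] = []
                for s in sample_list:
                    call = rec.samples[s]
                    try:
                        state = _classify_gt(call.get("GT"), ai)
                    except (TypeError, ValueError):
                        n_malformed += 1
                        state = GenotypeState.LOW_QUALITY
                    dp = call.get("DP")
                    row.append(state)
                    drow.append(-1 if dp is None else int(dp))
                sites.append(site)
                state_rows.append(row)
                depth_rows.append(drow)
    if n_malformed:
        warnings.warn(f"{n_malformed} malformed GT field(s) treated as LOW_QUALITY", stacklevel=2)
    return GenotypeMatrix(
        sites=tuple(sites),
        samples=tuple(sample_list),
        states=np.array(state_rows, dtype=np.int8).reshape(len(sites), len(sample_list)),
        depths=np.array(depth_rows, dtype=int).reshape(len(sites), len(sample_list)),
    )


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Plain-TSV alternative reader.

    Columns: chrom, pos, ref, alt, gene, consequence, then one state column
    per strain with cells in {REF, HOM, HET, NO, OTHER}.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["chrom", "pos", "ref", "alt", "gene", "consequence"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    sample_cols = [c for c in df.columns if c not in fixed]
    if not sample_cols:
        raise ValueError(f"{path}: no strain state columns found")
    sites = tuple(
        VariantSite(
            chrom=r.chrom,
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            gene=None if pd.isna(r.gene) else r.gene,
            consequence=normalize_consequence(None if pd.isna(r.consequence) else r.consequence),
        )
        for r in df.itertuples()
    )
    try:
        states = np.array(
            [[GenotypeState.FROM_LABEL[v.strip()] for v in df[c]] for c in sample_cols],
            dtype=np.int8,
        ).T
    except KeyError as exc:
        raise ValueError(f"{path}: unknown genotype state label {exc}") from None
    return GenotypeMatrix(sites=sites, samples=tuple(sample_cols), states=states)


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """State-matrix export mirroring the heat-map layout (rows = sites,
    columns = strains, cells = state labels)."""
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "pos", "ref", "alt", "gene", "consequence", *matrix.samples]) + "\n")
        for i, site in enumerate(matrix.sites):
            labels = [GenotypeState.LABELS[int(s)] for s in matrix.states[i]]
            fh.write(
                "\t".join(
                    [
                        site.chrom,
                        str(site.pos),
                        site.ref,
                        site.alt,
                        site.gene or "",
                        site.consequence or "",
                        *labels,
                    ]
                )
                + "\n"
            )


def quality_filter(
    matrix: GenotypeMatrix,
    min_depth: int = 10,
    min_qual: float = 20.0,
    min_mq: float = 30.0,
) -> GenotypeMatrix:
    """Site- and cell-level quality filtering.

    Sites with QUAL < min_qual or mapping quality < min_mq are dropped
    (thresholds inclusive: a site exactly at the threshold is retained).
    Per-sample depth below min_depth demotes that cell to LOW_QUALITY.
    Absent QUAL/MQ/DP fields pass with a warning, since third-party VCFs
    vary in which fields they populate.
    """
    if min_depth < 0 or min_qual < 0 or min_mq < 0:
        raise ValueError("quality thresholds must be non-negative")
    keep: list[int] = []
    n_missing_qual = n_missing_mq = 0
    for i, site in enumerate(matrix.sites):
        if site.qual is None:
            n_missing_qual += 1
        elif site.qual < min_qual:
            continue
        if site.mapping_quality is None:
            n_missing_mq += 1
        elif site.mapping_quality < min_mq:
            continue
        keep.append(i)
    if n_missing_qual:
        logger.warning("%d site(s) lack QUAL; treated as passing", n_missing_qual)
    if n_missing_mq:
        logger.warning("%d site(s) lack mapping quality; treated as passing", n_missing_mq)
    out = matrix.subset_sites(keep)
    if out.depths is not None:
        states = out.states.copy()
        low = (out.depths >= 0) & (out.depths < min_depth)
        states[low] = GenotypeState.LOW_QUALITY
        out = replace(out, states=states)
    return out


@dataclass(frozen=True)
class DiscriminatingSite:
    site: VariantSite
    site_index: int
    shared_state: int  # GenotypeState code carried by every member of the sharing group
    direction: str  # "A->B" or "B->A"

    @property
    def shared_state_label(self) -> str:
        return GenotypeState.LABELS[self.shared_state]


@dataclass(frozen=True)
class ContrastResult:
    """Discriminating sites between two strain groups, plus bookkeeping."""

    hits: tuple[DiscriminatingSite, ...]
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    n_sites_tested: int
    n_excluded_low_quality: int = 0
    n_excluded_unannotated: int = 0

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(h.site.gene for h in self.hits if h.site.gene is not None)

    @property
    def n_sites_discriminating(self) -> int:
        return len(self.hits)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "chrom": h.site.chrom,
                    "pos": h.site.pos,
                    "ref": h.site.ref,
                    "alt": h.site.alt,
                    "gene": h.site.gene,
                    "consequence": h.site.consequence,
                    "shared_state": h.shared_state_label,
                    "direction": h.direction,
                }
                for h in self.hits
            ],
            columns=[
                "chrom",
                "pos",
                "ref",
                "alt",
                "gene",
                "consequence",
                "shared_state",
                "direction",
            ],
        )


def _directional_hit(
    sharing: np.ndarray, other: np.ndarray, min_shared_fraction: float
) -> int | None:
    """Return the shared mutation state if `sharing` discriminates against
    `other`, else None. States must be free of LOW_QUALITY already."""
    for s in GenotypeState.MUTATION_STATES:
        n_share = int(np.count_nonzero(sharing == s))
        if n_share == 0:
            continue
        if min_shared_fraction >= 1.0:
            if n_share != len(sharing):
                continue
        elif n_share / len(sharing) < min_shared_fraction:
            continue
        if np.any(other == s):
            continue
        return s
    return None


def discriminating_sites(
    matrix: GenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    require_full_groups: bool = True,
    min_shared_fraction: float = 1.0,
) -> ContrastResult:
    """Find sites where one group's members all share an identical mutation
    state that the other group lacks.

    Direction A→B means every member of A carries the same state
    s ∈ {HOM_ALT, HET} and no member of B carries s; B→A is the mirror.
    Both directions are evaluated and unioned. With ``require_full_groups``
    (default) a site is skipped entirely when any involved strain is
    LOW_QUALITY. ``min_shared_fraction`` < 1 relaxes "all members" to a
    majority threshold (the strict published rule is the 1.0 default).
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError(f"groups overlap: {sorted(set(group_a) & set(group_b))}")
    if not 0 < min_shared_fraction <= 1:
        raise ValueError("min_shared_fraction must be in (0, 1]")
    ia = matrix.sample_index(group_a)
    ib = matrix.sample_index(group_b)
    hits: list[DiscriminatingSite] = []
    n_low = 0
    for i in range(matrix.n_sites):
        a = matrix.states[i, ia]
        b = matrix.states[i, ib]
        if require_full_groups and (
            np.any(a == GenotypeState.LOW_QUALITY) or np.any(b == GenotypeState.LOW_QUALITY)
        ):
            n_low += 1
            continue
        a_eff = a[a != GenotypeState.LOW_QUALITY]
        b_eff = b[b != GenotypeState.LOW_QUALITY]
        if len(a_eff) == 0 or len(b_eff) == 0:
            n_low += 1
            continue
        s = _directional_hit(a_eff, b_eff, min_shared_fraction)
        if s is not None:
            hits.append(DiscriminatingSite(matrix.sites[i], i, s, "A->B"))
        s = _directional_hit(b_eff, a_eff, min_shared_fraction)
        if s is not None:
            hits.append(DiscriminatingSite(matrix.sites[i], i, s, "B->A"))
    return ContrastResult(
        hits=tuple(hits),
        group_a=tuple(group_a),
        group_b=tuple(group_b),
        n_sites_tested=matrix.n_sites,
        n_excluded_low_quality=n_low,
    )


def filter_nonsynonymous(result: ContrastResult) -> ContrastResult:
    """Restrict a contrast to non-synonymous sites; unannotated sites are
    dropped and counted."""
    kept = tuple(h for h in result.hits if h.site.consequence == "nonsynonymous")
    n_unannot = sum(1 for h in result.hits if h.site.consequence is None)
    return replace(
        result,
        hits=kept,
        n_excluded_unannotated=result.n_excluded_unannotated + n_unannot,
    )


def aggregate_genes(result: ContrastResult) -> dict[str, int]:
    """Unique gene IDs among discriminating sites with per-gene site counts.

    Sites hit in both directions are counted once per direction record;
    callers wanting per-site uniqueness should dedupe on ``site.key``."""
    counts: dict[str, int] = {}
    seen: set[tuple] = set()
    for h in result.hits:
        if h.site.gene is None:
            continue
        key = h.site.key
        if key in seen:
            continue
        seen.add(key)
        counts[h.site.gene] = counts.get(h.site.gene, 0) + 1
    return counts


def strict_rule_false_positive_rate(
    state_probs: Mapping[int, float], k_a: int, k_b: int
) -> float:
    """Analytic probability that one site of i.i.d. states discriminates
    between groups of sizes k_a and k_b under the strict all-identical rule.

    Used to benchmark the simulated false-positive count on random
    background. LOW_QUALITY cells abort the site under require_full_groups,
    so the event requires no LOW_QUALITY in either group.
    """
    p = {s: float(state_probs.get(s, 0.0)) for s in range(5)}
    total = sum(p.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"state probabilities must sum to 1, got {total}")
    p_low = p[GenotypeState.LOW_QUALITY]
    prob = 0.0
    # inclusion-exclusion over the two directions and two mutation states
    events = []
    for s in GenotypeState.MUTATION_STATES:
        events.append(("A", s))
        events.append(("B", s))

    def event_prob(evs: list[tuple[str, int]]) -> float:
        # joint probability that each listed (group-all-s, other-group-no-s)
        # event holds; incompatible combinations have probability 0
        a_states = set()
        b_states = set()
        a_forbidden = set()
        b_forbidden = set()
        for side, s in evs:
            if side == "A":
                a_states.add(s)
                b_forbidden.add(s)
            else:
                b_states.add(s)
                a_forbidden.add(s)
        if len(a_states) > 1 or len(b_states) > 1:
            return 0.0
        if a_states & a_forbidden or b_states & b_forbidden:
            return 0.0

        def group_prob(states: set[int], forbidden: set[int], k: int) -> float:
            if states:
                (s,) = states
                return p[s] ** k
            allowed = 1.0 - p_low - sum(p[f] for f in forbidden)
            return max(allowed, 0.0) ** k

        return group_prob(a_states, a_forbidden, k_a) * group_prob(b_states, b_forbidden, k_b)

    from itertools import combinations

    for r in range(1, len(events) + 1):
        sign = (-1) ** (r + 1)
        for combo in combinations(events, r):
            prob += sign * event_prob(list(combo))
    return prob
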