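"""Synthetic diploid-cohort generator with recorded ground truth.

Emulates the statistical structure of a wild/domesticated yeast cohort:
a handful of homozygous "wild" lineages diverged up to ~1.7% from each
other, "domesticated" isolates formed by outcrossing two closely related
haplotypes (heterozygosity up to ~0.5%), aneuploidy with a bias towards
small chromosomes, tandem gene copy-number changes, and alien fragments
copied in from donor genomes at 8-35% divergence.  Read data are emitted
as per-site pileup count tables with Poisson depth and uniform base
error; no read-level simulation is performed.

All randomness flows from a single integer seed; identical seed + spec
give byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}


def seq_to_str(codes: np.ndarray) -> str:
    """Decode a uint8 code array (0..3) to an ACGT string."""
    return BASES[codes].tobytes().decode("ascii")


def str_to_codes(seq: str) -> np.ndarray:
    out = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    for b, i in _CODE.items():
        out[out == ord(b)] = i
    if out.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT characters")
    return out


class GeneInterval(NamedTuple):
    name: str
    chrom: str
    start: int  # 0-based half-open
    end: int


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome layout and gene annotation of the synthetic genome."""

    chromosomes: tuple[tuple[str, int], ...]
    genes: tuple[GeneInterval, ...] = ()
    seed: int = 0

    def __post_init__(self):
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome name")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for g in self.genes:
            if g.chrom not in lengths:
                raise ValueError(f"gene {g.name} on unknown chromosome {g.chrom}")
            if not (0 <= g.start < g.end <= lengths[g.chrom]):
                raise ValueError(f"gene {g.name} outside chromosome {g.chrom}")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


def default_genome_spec(seed: int = 0, scale: float = 1.0,
                        n_genes_per_chrom: int = 2) -> GenomeSpec:
    """A compact 8-chromosome genome echoing the uneven size spectrum of a
    yeast karyotype (small chromosomes first), with genes tiled on each
    chromosome.  ``scale`` multiplies all lengths."""
    base = [("chrI", 12_000), ("chrII", 32_000), ("chrIII", 13_000),
            ("chrIV", 45_000), ("chrV", 26_000), ("chrVI", 14_000),
            ("chrVII", 36_000), ("chrVIII", 28_000)]
    chroms = tuple((n, int(l * scale)) for n, l in base)
    genes = []
    for name, length in chroms:
        # keep ORFs a small fraction of the chromosome so gene-level CNV
        # does not dominate the chromosome median
        gene_len = min(1500, length // 8)
        for k in range(n_genes_per_chrom):
            start = int((k + 0.5) * length / (n_genes_per_chrom + 1))
            end = min(start + gene_len, length)
            genes.append(GeneInterval(f"{name}_g{k + 1}", name, start, end))
    return GenomeSpec(chromosomes=chroms, genes=tuple(genes), seed=seed)


# ---------------------------------------------------------------------------
# sequence evolution


def simulate_ancestor(spec: GenomeSpec) -> dict[str, np.ndarray]:
    """One uniform-random nucleotide sequence per chromosome."""
    rng = np.random.default_rng(spec.seed)
    return {name: rng.integers(0, 4, size=length, dtype=np.uint8)
            for name, length in spec.chromosomes}


def evolve_haplotype(reference: Mapping[str, np.ndarray], divergence: float,
                     rng: np.random.Generator
                     ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Place uniform substitutions at rate ``divergence`` per site.

    Each site mutates independently with probability ``divergence`` (a
    Binomial(L, divergence) total), to one of the three other bases.
    Returns the haplotype and the substituted positions per chromosome.
    """
    if not (0.0 <= divergence <= 0.05):
        raise ValueError("divergence must be in [0, 0.05]")
    hap, positions = {}, {}
    for chrom, seq in reference.items():
        mask = rng.random(seq.size) < divergence
        pos = np.nonzero(mask)[0]
        new = seq.copy()
        # shift by 1..3 mod 4: uniform over the three non-identical bases
        new[pos] = (new[pos] + rng.integers(1, 4, size=pos.size)) % 4
        hap[chrom] = new
        positions[chrom] = pos
    return hap, positions


def evolve_donor(reference: Mapping[str, np.ndarray], divergence: float,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    """A donor genome at deep divergence (0.05-0.40) from the reference.

    Shares coordinates with the reference so that planted fragments stay
    homologous to the conspecific genome at a known identity.
    """
    if not (0.05 <= divergence <= 0.40):
        raise ValueError("donor divergence must be in [0.05, 0.40]")
    hap = {}
    for chrom, seq in reference.items():
        mask = rng.random(seq.size) < divergence
        pos = np.nonzero(mask)[0]
        new = seq.copy()
        new[pos] = (new[pos] + rng.integers(1, 4, size=pos.size)) % 4
        hap[chrom] = new
    return hap


@dataclass
class DiploidGenome:
    """Two same-coordinate haplotypes; true het sites are where they differ."""

    hapA: dict[str, np.ndarray]
    hapB: dict[str, np.ndarray]

    def __post_init__(self):
        if set(self.hapA) != set(self.hapB):
            raise ValueError("haplotypes cover different chromosomes")
        for chrom in self.hapA:
            if self.hapA[chrom].size != self.hapB[chrom].size:
                raise ValueError(f"haplotype length mismatch on {chrom}")

    def het_positions(self) -> dict[str, np.ndarray]:
        return {c: np.nonzero(self.hapA[c] != self.hapB[c])[0] for c in self.hapA}

    def n_het(self) -> int:
        return sum(p.size for p in self.het_positions().values())


def make_diploid(hapA: Mapping[str, np.ndarray],
                 hapB: Mapping[str, np.ndarray]) -> DiploidGenome:
    return DiploidGenome({c: s.copy() for c, s in hapA.items()},
                         {c: s.copy() for c, s in hapB.items()})


# ---------------------------------------------------------------------------
# planted features


class PlantedFragment(NamedTuple):
    donor: str
    chrom: str
    start: int  # 0-based half-open on the shared coordinate system
    end: int
    divergence: float


@dataclass
class DonorLibrary:
    """Donor genomes keyed by taxon, with taxonomy tags for classification.

    Tags follow the introgression-scan convention: ``congeneric`` donors
    (same genus) yield introgression calls, ``outside-genus`` donors HGT.
    """

    genomes: dict[str, dict[str, np.ndarray]]
    tags: dict[str, str]
    divergences: dict[str, float]

    def __post_init__(self):
        for taxon, tag in self.tags.items():
            if tag not in ("congeneric", "outside-genus"):
                raise ValueError(f"unknown tag {tag!r} for donor {taxon}")


def make_donor_library(reference: Mapping[str, np.ndarray],
                       donors: Sequence[tuple[str, str, float]],
                       rng: np.random.Generator) -> DonorLibrary:
    """``donors`` is a sequence of (taxon, tag, divergence)."""
    genomes, tags, divs = {}, {}, {}
    for taxon, tag, div in donors:
        genomes[taxon] = evolve_donor(reference, div, rng)
        tags[taxon] = tag
        divs[taxon] = div
    return DonorLibrary(genomes, tags, divs)


@dataclass
class IsolateTruth:
    """Ground truth for one synthetic isolate."""

    isolate_id: str
    group: str                       # "wild" | "domesticated"
    lineage: str
    parents: tuple[str, str]
    basal_ploidy: int = 2
    chrom_copies: dict[str, int] = field(default_factory=dict)
    gene_factors: dict[str, float] = field(default_factory=dict)
    aliens: list[PlantedFragment] = field(default_factory=list)
    flow_D: float = float("nan")
    n_het_sites: int = 0

    def chrom_delta(self, chrom: str) -> int:
        return self.chrom_copies.get(chrom, self.basal_ploidy) - self.basal_ploidy


def plant_features(diploid: DiploidGenome, truth: IsolateTruth,
                   library: DonorLibrary | None,
                   spec: GenomeSpec) -> DiploidGenome:
    """Apply alien-fragment replacements to both haplotypes.

    Aneuploidy and gene CNV are depth-level features recorded in the
    truth and realised by :func:`simulate_pileups`; alien fragments are
    sequence-level and applied here.  Fragments must not overlap.
    """
    lengths = spec.lengths
    for frag in truth.aliens:
        if frag.end - frag.start < 1_000:
            raise ValueError("alien fragments must be >= 1 kb")
        if not (0 <= frag.start < frag.end <= lengths[frag.chrom]):
            raise ValueError(f"alien fragment outside {frag.chrom}")
    by_chrom: dict[str, list[PlantedFragment]] = {}
    for frag in truth.aliens:
        by_chrom.setdefault(frag.chrom, []).append(frag)
    for chrom, frags in by_chrom.items():
        frags.sort(key=lambda f: f.start)
        for a, b in zip(frags, frags[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping alien fragments on {chrom}")
    for copies in truth.chrom_copies.values():
        if copies < 0:
            raise ValueError("chromosome copy number < 0")
    for frag in truth.aliens:
        if library is None or frag.donor not in library.genomes:
            raise ValueError(f"donor {frag.donor} not in library")
        donor_seq = library.genomes[frag.donor][frag.chrom][frag.start:frag.end]
        diploid.hapA[frag.chrom][frag.start:frag.end] = donor_seq
        diploid.hapB[frag.chrom][frag.start:frag.end] = donor_seq
    truth.n_het_sites = diploid.n_het()
    return diploid


# ---------------------------------------------------------------------------
# observation models


def site_copy_factors(truth: IsolateTruth, spec: GenomeSpec) -> dict[str, np.ndarray]:
    """Per-site copy number relative to basal ploidy (1.0 = basal)."""
    factors = {}
    for chrom, length in spec.chromosomes:
        f = np.full(length,
                    truth.chrom_copies.get(chrom, truth.basal_ploidy)
                    / truth.basal_ploidy)
        factors[chrom] = f
    for gene in spec.genes:
        fac = truth.gene_factors.get(gene.name)
        if fac is not None:
            if fac < 0:
                raise ValueError("gene copy factor < 0")
            factors[gene.chrom][gene.start:gene.end] *= fac
    return factors


def simulate_pileups(diploid: DiploidGenome, reference: Mapping[str, np.ndarray],
                     truth: IsolateTruth, spec: GenomeSpec, mean_depth: float,
                     error_rate: float, rng: np.random.Generator) -> pd.DataFrame:
    """Per-site pileup counts for one isolate.

    depth ~ Poisson(mean_depth x local copy factor); each read draws a
    haplotype uniformly and reports the true base, or with probability
    ``error_rate`` a base uniform over all four.  Columns: chrom, pos
    (1-based), ref, depth, countA, countC, countG, countT.
    """
    if mean_depth < 1:
        raise ValueError("mean depth must be >= 1")
    if not (0.0 <= error_rate <= 0.05):
        raise ValueError("error rate must be in [0, 0.05]")
    factors = site_copy_factors(truth, spec)
    frames = []
    for chrom, length in spec.chromosomes:
        a, b = diploid.hapA[chrom], diploid.hapB[chrom]
        depth = rng.poisson(mean_depth * factors[chrom])
        # per-site base probabilities: mixture of the two haplotype bases
        # plus uniform error
        p = np.full((length, 4), error_rate / 4.0)
        np.add.at(p, (np.arange(length), a), (1.0 - error_rate) / 2.0)
        np.add.at(p, (np.arange(length), b), (1.0 - error_rate) / 2.0)
        counts = _multinomial_rows(depth, p, rng)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": np.arange(1, length + 1),
            "ref": np.array(list(seq_to_str(reference[chrom]))),
            "depth": depth,
            "countA": counts[:, 0],
            "countC": counts[:, 1],
            "countG": counts[:, 2],
            "countT": counts[:, 3],
        }))
    return pd.concat(frames, ignore_index=True)


def _multinomial_rows(n: np.ndarray, p: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Vectorised multinomial with per-row n, via sequential binomials."""
    out = np.zeros((n.size, p.shape[1]), dtype=np.int64)
    remaining = n.astype(np.int64)
    ptail = np.ones(n.size)
    for j in range(p.shape[1] - 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            pj = np.where(ptail > 0, np.clip(p[:, j] / ptail, 0.0, 1.0), 0.0)
        out[:, j] = rng.binomial(remaining, pj)
        remaining -= out[:, j]
        ptail -= p[:, j]
    out[:, -1] = remaining
    return out


def simulate_flow_D(ploidy: float, noise_sd: float,
                    rng: np.random.Generator | None = None) -> float:
    """Relative DNA content per cell: ploidy (haploid reference = 1) plus
    truncated Gaussian instrument noise."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if noise_sd == 0 or rng is None:
        return float(ploidy)
    d = ploidy + rng.normal(0.0, noise_sd)
    while d <= 0:
        d = ploidy + rng.normal(0.0, noise_sd)
    return float(d)


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass(frozen=True)
class CohortParams:
    """Study conditions for a synthetic cohort.

    Defaults mirror the structure of a wild/domesticated yeast
    resequencing panel:
    ~10 homozygous wild lineages spanning pairwise divergences up to
    ~1.7% (per-lineage divergence from the common ancestor uniform in
    [0.001, 0.0085]); domesticated isolates are outcrossed F1s of two
    haplotypes differing by 0.05-0.5% (mean ~0.27%, matching the
    reported 0.0024-0.508% heterozygosity span); ~30% of isolates are
    aneuploid with the extra-copy probability weighted by 1/length
    (small-chromosome bias); gene amplifications at 2-3x and deletions
    in a subset of domesticated isolates; alien fragments from donors at
    8-35% divergence.
    """

    n_wild: int = 10
    n_domesticated: int = 8
    wild_divergence_range: tuple[float, float] = (0.001, 0.0085)
    dom_het_range: tuple[float, float] = (0.0005, 0.005)
    aneuploid_fraction: float = 0.3
    mean_depth: float = 50.0
    error_rate: float = 0.002
    flow_noise_sd: float = 0.05
    donors: tuple[tuple[str, str, float], ...] = (
        ("donorSpar", "congeneric", 0.12),
        ("donorZyg", "outside-genus", 0.30),
        ("donorTdel", "outside-genus", 0.22),
    )
    n_alien_fragments: int = 3
    alien_length_range: tuple[int, int] = (2_000, 6_000)
    n_amplified_genes: int = 2
    n_deleted_genes: int = 1


@dataclass
class SyntheticCohort:
    spec: GenomeSpec
    params: CohortParams
    reference: dict[str, np.ndarray]
    library: DonorLibrary
    isolates: dict[str, DiploidGenome]
    truths: dict[str, IsolateTruth]

    @property
    def isolate_ids(self) -> list[str]:
        return list(self.isolates)

    def pileups(self, seed: int) -> dict[str, pd.DataFrame]:
        """Pileup tables for every isolate, derived from one seed."""
        out = {}
        for i, iid in enumerate(self.isolate_ids):
            rng = np.random.default_rng((seed, 1, i))
            out[iid] = simulate_pileups(
                self.isolates[iid], self.reference, self.truths[iid],
                self.spec, self.params.mean_depth, self.params.error_rate, rng)
        return out

    def flow_table(self) -> pd.DataFrame:
        rows = [{"isolate": iid, "group": t.group, "lineage": t.lineage,
                 "D": t.flow_D, "basal_ploidy": t.basal_ploidy}
                for iid, t in self.truths.items()]
        return pd.DataFrame(rows)

    def truth_json(self) -> str:
        payload = {}
        for iid, t in self.truths.items():
            d = dataclasses.asdict(t)
            d["aliens"] = [f._asdict() for f in t.aliens]
            payload[iid] = d
        return json.dumps(payload, indent=1, sort_keys=True)


def perfect_calls(diploid: DiploidGenome, reference: Mapping[str, np.ndarray],
                  spec: GenomeSpec) -> pd.DataFrame:
    """Noise-free genotype calls straight from the haplotypes.

    Truth-consistency helper: every planted feature must be recoverable
    from the emitted sequences by direct comparison with the unmodified
    genome.  Homozygous sites yield the base, heterozygous sites the
    IUPAC code of the two haplotype alleles.
    """
    from saccpop.snpcall import IUPAC_CODE

    frames = []
    for chrom, length in spec.chromosomes:
        a = seq_to_str(diploid.hapA[chrom])
        b = seq_to_str(diploid.hapB[chrom])
        calls = np.array(list(a))
        het = np.nonzero(diploid.hapA[chrom] != diploid.hapB[chrom])[0]
        for i in het:
            calls[i] = IUPAC_CODE[frozenset((a[i], b[i]))]
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": np.arange(1, length + 1),
            "ref": np.array(list(seq_to_str(reference[chrom]))),
            "call": calls}))
    return pd.concat(frames, ignore_index=True)


def simulate_lineage_cohort(spec: GenomeSpec | None = None,
                            n_lineages: int = 4, per_lineage: int = 3,
                            lineage_divergence_range: tuple[float, float]
                            = (0.0025, 0.0075),
                            within_divergence: float = 0.0003,
                            params: CohortParams | None = None,
                            seed: int = 0) -> SyntheticCohort:
    """A clean multi-lineage cohort for phylogenetic recovery studies.

    Lineage haplotypes diverge from a common ancestor by a uniform draw
    in ``lineage_divergence_range`` (pairwise divergence roughly the
    sum, i.e. 0.5-1.5% at the defaults); each isolate is a diploid of
    two haplotypes evolved a further ``within_divergence`` from its
    lineage haplotype, so within-lineage distances are much smaller
    than between-lineage distances.  No aneuploidy, CNV or alien
    fragments are planted.
    """
    spec = spec if spec is not None else default_genome_spec(seed=seed)
    params = params if params is not None else CohortParams()
    rng = np.random.default_rng((seed, 2))
    reference = simulate_ancestor(spec)
    library = DonorLibrary({}, {}, {})
    isolates: dict[str, DiploidGenome] = {}
    truths: dict[str, IsolateTruth] = {}
    lo, hi = lineage_divergence_range
    for li in range(n_lineages):
        div = float(rng.uniform(lo, hi))
        lineage_hap, _ = evolve_haplotype(reference, div, rng)
        lineage = f"L{li + 1}"
        for k in range(per_lineage):
            hapA, _ = evolve_haplotype(lineage_hap, within_divergence, rng)
            hapB, _ = evolve_haplotype(lineage_hap, within_divergence, rng)
            iid = f"{lineage}_{k + 1}"
            isolates[iid] = make_diploid(hapA, hapB)
            truths[iid] = IsolateTruth(iid, lineage, lineage,
                                       (lineage, lineage))
            truths[iid].n_het_sites = isolates[iid].n_het()
            truths[iid].flow_D = 2.0
    return SyntheticCohort(spec, params, reference, library, isolates, truths)


def _sample_aneuploidy(spec: GenomeSpec, basal: int,
                       rng: np.random.Generator) -> dict[str, int]:
    """Copy-number changes biased towards small chromosomes (weight 1/length),
    duplication-heavy as observed in real aneuploids."""
    names = list(spec.chrom_names)
    lengths = spec.lengths
    w = np.array([1.0 / lengths[n] for n in names])
    w /= w.sum()
    n_affected = int(rng.integers(1, 3))
    chosen = rng.choice(len(names), size=min(n_affected, len(names)),
                        replace=False, p=w)
    copies = {}
    for idx in chosen:
        delta = int(rng.choice([1, 2, -1], p=[0.80, 0.15, 0.05]))
        if basal + delta < 1:
            delta = 1
        copies[names[idx]] = basal + delta
    return copies


def simulate_cohort(spec: GenomeSpec | None = None,
                    params: CohortParams | None = None,
                    seed: int = 0) -> SyntheticCohort:
    """Build a full cohort: wild lineages, outcrossed domesticated isolates,
    planted aneuploidies, gene CNVs and alien fragments, flow-cytometry D."""
    spec = spec if spec is not None else default_genome_spec(seed=seed)
    params = params if params is not None else CohortParams()
    rng = np.random.default_rng((seed, 0))
    reference = simulate_ancestor(spec)
    library = make_donor_library(reference, params.donors, rng)

    isolates: dict[str, DiploidGenome] = {}
    truths: dict[str, IsolateTruth] = {}

    wild_haps = {}
    lo, hi = params.wild_divergence_range
    for i in range(params.n_wild):
        div = float(rng.uniform(lo, hi))
        hap, _ = evolve_haplotype(reference, div, rng)
        lineage = f"W{i + 1}"
        wild_haps[lineage] = hap
        iid = f"wild{i + 1}"
        truths[iid] = IsolateTruth(iid, "wild", lineage, (lineage, lineage))
        isolates[iid] = make_diploid(hap, hap)

    lineage_names = list(wild_haps)
    het_lo, het_hi = params.dom_het_range
    for i in range(params.n_domesticated):
        base_lineage = lineage_names[int(rng.integers(len(lineage_names)))]
        het = float(rng.uniform(het_lo, het_hi))
        hapA, _ = evolve_haplotype(wild_haps[base_lineage], het / 2.0, rng)
        hapB, _ = evolve_haplotype(wild_haps[base_lineage], het / 2.0, rng)
        iid = f"dom{i + 1}"
        truths[iid] = IsolateTruth(iid, "domesticated", f"D{i + 1}",
                                   (f"{base_lineage}a", f"{base_lineage}b"))
        isolates[iid] = make_diploid(hapA, hapB)

    ids = list(isolates)
    # aneuploidy
    for iid in ids:
        if rng.random() < params.aneuploid_fraction:
            truths[iid].chrom_copies = _sample_aneuploidy(
                spec, truths[iid].basal_ploidy, rng)

    # gene CNV: amplifications and deletions concentrated in domesticated
    gene_names = [g.name for g in spec.genes]
    if gene_names:
        amp = [gene_names[int(rng.integers(len(gene_names)))]
               for _ in range(params.n_amplified_genes)]
        dele = [gene_names[int(rng.integers(len(gene_names)))]
                for _ in range(params.n_deleted_genes)]
        for iid in ids:
            if truths[iid].group == "domesticated":
                for g in amp:
                    truths[iid].gene_factors[g] = float(rng.choice([2.0, 3.0]))
                for g in dele:
                    if g not in truths[iid].gene_factors:
                        truths[iid].gene_factors[g] = 0.0

    # alien fragments: each planted into >= 2 carriers on a fixed interval
    donor_names = list(library.genomes)
    frag_chroms = list(spec.chrom_names)
    planted: list[tuple[PlantedFragment, list[str]]] = []
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in frag_chroms}
    for k in range(params.n_alien_fragments):
        donor = donor_names[k % len(donor_names)]
        length = int(rng.integers(*params.alien_length_range))
        for _ in range(50):
            chrom = frag_chroms[int(rng.integers(len(frag_chroms)))]
            cl = spec.lengths[chrom]
            if cl < length + 2_000:
                continue
            start = int(rng.integers(1_000, cl - length - 1_000))
            if all(e <= start or s >= start + length for s, e in used[chrom]):
                used[chrom].append((start, start + length))
                break
        else:  # pragma: no cover - only on pathological specs
            continue
        frag = PlantedFragment(donor, chrom, start, start + length,
                               library.divergences[donor])
        carriers = [ids[int(j)] for j in
                    rng.choice(len(ids), size=min(2 + k % 2, len(ids)),
                               replace=False)]
        planted.append((frag, carriers))
    for frag, carriers in planted:
        for iid in carriers:
            truths[iid].aliens.append(frag)

    for iid in ids:
        plant_features(isolates[iid], truths[iid], library, spec)
        genome_len = spec.total_length
        eff_ploidy = truths[iid].basal_ploidy * sum(
            (truths[iid].chrom_copies.get(c, truths[iid].basal_ploidy)
             / truths[iid].basal_ploidy) * l
            for c, l in spec.chromosomes) / genome_len
        truths[iid].flow_D = simulate_flow_D(eff_ploidy, params.flow_noise_sd, rng)

    return SyntheticCohort(spec, params, reference, library, isolates, truths)
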