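"""Forward simulation of a dioecious F1 cross and bulked sequencing counts.

The model is a single sex-determining locus with three alleles — male (M),
hermaphrodite (H) and female (F) — under the total dominance order
M > H > F.  A female parent (FF) crossed to a male parent (MF) yields an F1
segregating 1:1 female:male; HF x MF yields 2:1:1 male:hermaphrodite:female.

Parents are represented by phased haplotypes over an explicit genome model.
Meiosis draws a Poisson number of crossovers per chromosome (no
interference; Haldane model), so marker-sex linkage emerges mechanistically
when the sex locus sits on a simulated chromosome.  Bulked-segregant
sequencing is emulated by Poisson read depth per variant per bulk and
binomial sampling of the alternate allele with a symmetric per-read error
rate, which is the statistical structure the downstream SNP-index scan
assumes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SexAllele",
    "SexGenotype",
    "GenomeModel",
    "CrossDesign",
    "Offspring",
    "FEMALE",
    "MALE",
    "HERMAPHRODITE",
    "phenotype_of",
    "simulate_offspring",
    "build_bulks",
    "bulk_alt_frequency",
    "simulate_bulk_counts",
    "apply_pseudoexchange",
    "simulate_bsa_experiment",
    "COUNT_COLUMNS",
]

FEMALE = "female"
MALE = "male"
HERMAPHRODITE = "hermaphrodite"

#: column order of the allele-count table produced by :func:`simulate_bulk_counts`
COUNT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_type",
    "refF",
    "altF",
    "refM",
    "altM",
]


class SexAllele(enum.Enum):
    """One allele of the tri-allelic sex locus; dominance M > H > F."""

    M = "M"
    H = "H"
    F = "F"

    @property
    def rank(self) -> int:
        return {"M": 2, "H": 1, "F": 0}[self.value]

    @property
    def phenotype(self) -> str:
        return {"M": MALE, "H": HERMAPHRODITE, "F": FEMALE}[self.value]


@dataclass(frozen=True)
class SexGenotype:
    """Unordered pair of sex alleles, e.g. FF, MF, HF.

    The pair is normalised to (dominant, recessive) order so that equality
    is order-insensitive: ``SexGenotype.parse("FM") == SexGenotype.parse("MF")``.
    """

    alleles: tuple[SexAllele, SexAllele]

    def __post_init__(self) -> None:
        a, b = self.alleles
        if not (isinstance(a, SexAllele) and isinstance(b, SexAllele)):
            raise TypeError("alleles must be SexAllele values")
        ordered = tuple(sorted((a, b), key=lambda x: -x.rank))
        object.__setattr__(self, "alleles", ordered)

    @classmethod
    def parse(cls, text: str) -> "SexGenotype":
        """Build a genotype from a two-letter string such as ``"MF"``."""
        if len(text) != 2:
            raise ValueError(f"expected two allele letters, got {text!r}")
        return cls((SexAllele(text[0]), SexAllele(text[1])))

    def __str__(self) -> str:
        return "".join(a.value for a in self.alleles)


def phenotype_of(genotype: SexGenotype) -> str:
    """Phenotype of a sex genotype under the dominance order M > H > F.

    The dominant allele of the pair determines the phenotype: MF and MH are
    male, HF and HH hermaphrodite, FF female.
    """
    dominant = max(genotype.alleles, key=lambda a: a.rank)
    return dominant.phenotype


@dataclass
class GenomeModel:
    """Chromosome coordinate frame carrying variant positions and the sex locus.

    Parameters
    ----------
    chromosomes
        List of ``(name, length_bp)`` pairs.
    variant_positions
        Per chromosome, sorted unique 1-based positions of segregating
        variants.  Chromosomes without variants may be omitted.
    sex_locus
        ``(chromosome, position)`` of the sex-determining locus, or ``None``
        for a sex trait unlinked to any simulated chromosome.  The position
        need not coincide with a variant.
    """

    chromosomes: list[tuple[str, int]]
    variant_positions: dict[str, np.ndarray] = field(default_factory=dict)
    sex_locus: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for chrom, pos in self.variant_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if chrom not in lengths:
                raise ValueError(f"variants on unknown chromosome {chrom!r}")
            if pos.size and (pos.min() < 1 or pos.max() > lengths[chrom]):
                raise ValueError(f"variant positions outside [1, length] on {chrom}")
            if pos.size and (np.any(np.diff(pos) <= 0)):
                raise ValueError(f"variant positions must be sorted unique on {chrom}")
            self.variant_positions[chrom] = pos
        if self.sex_locus is not None:
            chrom, pos = self.sex_locus
            if chrom not in lengths or not (1 <= pos <= lengths[chrom]):
                raise ValueError("sex locus outside the genome model")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def n_variants(self) -> int:
        return int(sum(p.size for p in self.variant_positions.values()))


@dataclass
class CrossDesign:
    """A phased parental pair and the size of the F1 to draw from it.

    Haplotype arrays have shape ``(2, n_variants)`` per chromosome with
    entries 0 (reference) / 1 (alternate).  Haplotype *i* of each parent
    carries sex allele ``genotype.alleles[i]`` — e.g. for an MF father,
    haplotype 0 is the M-bearing chromosome.
    """

    mother: SexGenotype
    father: SexGenotype
    genome: GenomeModel
    mother_haplotypes: dict[str, np.ndarray]
    father_haplotypes: dict[str, np.ndarray]
    n_offspring: int
    recomb_rate: float = 4.0  # cM per Mb
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_offspring < 0:
            raise ValueError("n_offspring must be non-negative")
        for haps in (self.mother_haplotypes, self.father_haplotypes):
            for chrom, h in haps.items():
                h = np.asarray(h, dtype=np.int8)
                expected = self.genome.variant_positions.get(chrom, np.empty(0)).size
                if h.shape != (2, expected):
                    raise ValueError(
                        f"haplotype array for {chrom} must have shape (2, {expected})"
                    )
                haps[chrom] = h


@dataclass
class Offspring:
    """One F1 individual: inherited haplotypes, sex genotype and phenotype."""

    maternal: dict[str, np.ndarray]
    paternal: dict[str, np.ndarray]
    sex_genotype: SexGenotype
    phenotype: str


def _gamete(
    rng: np.random.Generator,
    haplotypes: dict[str, np.ndarray],
    sex_alleles: tuple[SexAllele, SexAllele],
    genome: GenomeModel,
    recomb_rate: float,
) -> tuple[dict[str, np.ndarray], SexAllele]:
    """Draw one recombinant gamete: crossovers ~ Poisson(genetic length)."""
    gamete: dict[str, np.ndarray] = {}
    sex_allele: SexAllele | None = None
    for chrom, length in genome.chromosomes:
        positions = genome.variant_positions.get(chrom)
        carries_locus = genome.sex_locus is not None and genome.sex_locus[0] == chrom
        if (positions is None or positions.size == 0) and not carries_locus:
            continue
        morgans = length * recomb_rate / 1e6 / 100.0
        n_cross = rng.poisson(morgans)
        breaks = np.sort(rng.integers(1, length + 1, size=n_cross))
        start = int(rng.integers(2))
        if positions is not None and positions.size:
            hap_idx = (start + np.searchsorted(breaks, positions, side="right")) % 2
            h = haplotypes[chrom]
            gamete[chrom] = h[hap_idx, np.arange(positions.size)]
        if carries_locus:
            k = int(np.searchsorted(breaks, genome.sex_locus[1], side="right"))
            sex_allele = sex_alleles[(start + k) % 2]
    if sex_allele is None:
        # sex locus unlinked to any simulated chromosome: independent assortment
        sex_allele = sex_alleles[int(rng.integers(2))]
    return gamete, sex_allele


def simulate_offspring(design: CrossDesign) -> list[Offspring]:
    """Simulate the F1 of a cross by independent meioses in both parents.

    Each offspring receives one recombinant haplotype per parent; the
    crossover count per chromosome per meiosis is Poisson with mean equal to
    the chromosome's genetic length in Morgans (``length_bp *
    recomb_rate / 1e6 / 100``), crossover positions uniform, no
    interference.  The sex allele transmitted by each parent is read off the
    same recombinant framework at the sex-locus position, so marker-sex
    linkage is mechanistic rather than imposed.
    """
    rng = np.random.default_rng(design.seed)
    out: list[Offspring] = []
    for _ in range(design.n_offspring):
        mat, allele_m = _gamete(
            rng, design.mother_haplotypes, design.mother.alleles, design.genome, design.recomb_rate
        )
        pat, allele_p = _gamete(
            rng, design.father_haplotypes, design.father.alleles, design.genome, design.recomb_rate
        )
        geno = SexGenotype((allele_m, allele_p))
        out.append(Offspring(mat, pat, geno, phenotype_of(geno)))
    return out


def build_bulks(
    offspring: list[Offspring], phenotype: str, bulk_size: int, seed: int
) -> list[Offspring]:
    """Draw a bulk: a uniform sample without replacement of one phenotype class."""
    if bulk_size < 0:
        raise ValueError("bulk_size must be non-negative")
    candidates = [o for o in offspring if o.phenotype == phenotype]
    if len(candidates) < bulk_size:
        raise ValueError(
            f"only {len(candidates)} {phenotype} individuals available, "
            f"need {bulk_size} for the bulk"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=bulk_size, replace=False)
    return [candidates[i] for i in idx]


def bulk_alt_frequency(bulk: list[Offspring], genome: GenomeModel) -> dict[str, np.ndarray]:
    """True alternate-allele frequency per variant among the 2n bulk haplotypes."""
    if not bulk:
        raise ValueError("empty bulk")
    freqs: dict[str, np.ndarray] = {}
    for chrom, positions in genome.variant_positions.items():
        if positions.size == 0:
            continue
        total = np.zeros(positions.size, dtype=np.int64)
        for o in bulk:
            total += o.maternal[chrom]
            total += o.paternal[chrom]
        freqs[chrom] = total / (2 * len(bulk))
    return freqs


_BASES = np.array(list("ACGT"))


def simulate_bulk_counts(
    bulk_f: list[Offspring],
    bulk_m: list[Offspring],
    genome: GenomeModel,
    mean_depth_f: float = 32.0,
    mean_depth_m: float = 34.0,
    error_rate: float = 0.001,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate bulked short-read sequencing over the genome's variants.

    Per variant and bulk, read depth is Poisson with the bulk's mean depth
    and the alternate read count is Binomial(depth, q) with
    ``q = p(1-e) + (1-p)e`` where p is the true bulk alternate frequency and
    e the symmetric per-read error rate.

    Returns a table with columns :data:`COUNT_COLUMNS`, sorted by
    (chrom, pos).  Zero-depth records are retained; the scan filters them.
    """
    if not bulk_f or not bulk_m:
        raise ValueError("both bulks must be non-empty")
    if mean_depth_f <= 0 or mean_depth_m <= 0:
        raise ValueError("mean depths must be positive")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    freq_f = bulk_alt_frequency(bulk_f, genome)
    freq_m = bulk_alt_frequency(bulk_m, genome)
    frames = []
    for chrom, _length in genome.chromosomes:
        positions = genome.variant_positions.get(chrom)
        if positions is None or positions.size == 0:
            continue
        n = positions.size
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        rows = {"chrom": chrom, "pos": positions, "ref": _BASES[ref_idx], "alt": _BASES[alt_idx]}
        rows["variant_type"] = "SNP"
        for tag, freqs, mean_depth in (("F", freq_f, mean_depth_f), ("M", freq_m, mean_depth_m)):
            p = freqs[chrom]
            q = p * (1 - error_rate) + (1 - p) * error_rate
            depth = rng.poisson(mean_depth, size=n)
            alt_count = rng.binomial(depth, q)
            rows[f"ref{tag}"] = depth - alt_count
            rows[f"alt{tag}"] = alt_count
        frames.append(pd.DataFrame(rows))
    if not frames:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    df = pd.concat(frames, ignore_index=True)
    return df[COUNT_COLUMNS].sort_values(["chrom", "pos"], ignore_index=True)


def apply_pseudoexchange(records: pd.DataFrame, flip_prob: float, seed: int = 0) -> pd.DataFrame:
    """Randomly swap ref/alt labelling (and counts) at a fraction of variants.

    Models the "pseudoexchange effect" of a heterozygous reference: local
    mislabelling of which allele is the reference flips the sign of the
    per-variant ΔSNP index but leaves |Δ| unchanged, which is why the scan
    works on |Δ|.  Applying the same flip pattern twice restores the input.
    """
    if not (0 <= flip_prob <= 1):
        raise ValueError("flip_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = records.copy()
    flip = rng.random(len(out)) < flip_prob
    if not flip.any():
        return out
    for a, b in (("ref", "alt"), ("refF", "altF"), ("refM", "altM")):
        out.loc[flip, [a, b]] = out.loc[flip, [b, a]].to_numpy()
    return out


def _even_positions(length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions evenly spread over [1, length]."""
    return np.unique(np.linspace(1, length, n, dtype=np.int64))


@dataclass
class SimulatedExperiment:
    """Bundle returned by :func:`simulate_bsa_experiment`."""

    genome: GenomeModel
    design: CrossDesign
    offspring: list[Offspring]
    bulk_f: list[Offspring]
    bulk_m: list[Offspring]
    counts: pd.DataFrame
    phenotypes: pd.DataFrame  # columns: individual, phenotype


def simulate_bsa_experiment(
    seed: int,
    n_offspring: int = 117,
    bulk_size: int = 30,
    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 10_000_000),),
    variants_per_chrom: int = 500,
    sex_locus: tuple[str, int] | None = ("chr1", 5_000_000),
    recomb_rate: float = 4.0,
    mean_depth_f: float = 32.0,
    mean_depth_m: float = 34.0,
    error_rate: float = 0.001,
    frac_mother_het: float = 0.0,
    bulk_phenotypes: tuple[str, str] = (FEMALE, MALE),
) -> SimulatedExperiment:
    """One complete FF x MF bulked-segregant experiment, paper-style defaults.

    Defaults mirror the study design this package models: an F1 of 117,
    bulks of 30 contrasting individuals each, mean depths 32x and 34x.
    Variants are evenly spaced and heterozygous in exactly one parent (a
    pseudo-testcross configuration), with the alternate-bearing haplotype
    chosen at random so that linkage to the sex locus produces an
    |ΔSNP-index| signal of either sign.  By default every site is paternal
    (the configuration the scan's null model describes and the only one
    informative about a paternally segregating locus); ``frac_mother_het``
    dilutes the panel with maternal testcross sites, which behave as null
    sites everywhere.
    """
    rng = np.random.default_rng(seed)
    positions = {name: _even_positions(length, variants_per_chrom) for name, length in chrom_lengths}
    genome = GenomeModel(list(chrom_lengths), positions, sex_locus)
    mother_haps: dict[str, np.ndarray] = {}
    father_haps: dict[str, np.ndarray] = {}
    for chrom, _length in chrom_lengths:
        n = positions[chrom].size
        mother = np.zeros((2, n), dtype=np.int8)
        father = np.zeros((2, n), dtype=np.int8)
        in_mother = rng.random(n) < frac_mother_het
        which_hap = rng.integers(0, 2, size=n)
        idx = np.arange(n)
        mother[which_hap[in_mother], idx[in_mother]] = 1
        father[which_hap[~in_mother], idx[~in_mother]] = 1
        mother_haps[chrom] = mother
        father_haps[chrom] = father
    design = CrossDesign(
        mother=SexGenotype.parse("FF"),
        father=SexGenotype.parse("MF"),
        genome=genome,
        mother_haplotypes=mother_haps,
        father_haplotypes=father_haps,
        n_offspring=n_offspring,
        recomb_rate=recomb_rate,
        seed=int(rng.integers(2**31)),
    )
    offspring = simulate_offspring(design)
    pheno_f, pheno_m = bulk_phenotypes
    bulk_f = build_bulks(offspring, pheno_f, bulk_size, seed=int(rng.integers(2**31)))
    bulk_m = build_bulks(offspring, pheno_m, bulk_size, seed=int(rng.integers(2**31)))
    counts = simulate_bulk_counts(
        bulk_f,
        bulk_m,
        genome,
        mean_depth_f=mean_depth_f,
        mean_depth_m=mean_depth_m,
        error_rate=error_rate,
        seed=int(rng.integers(2**31)),
    )
    phenotypes = pd.DataFrame(
        {
            "individual": [f"Z{i:04d}" for i in range(len(offspring))],
            "phenotype": [o.phenotype for o in offspring],
        }
    )
    return SimulatedExperiment(genome, design, offspring, bulk_f, bulk_m, counts, phenotypes)
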