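"""In-silico PCR, InDel band classification and ORF utilities for the sex marker.

The sex marker is a length-polymorphic PCR product spanning an intronic
insertion carried by the dominant (M/H) haplotypes: females (FF) amplify a
single short band, while males (MF) and hermaphrodites (HF) show the short
band plus a longer one.  The M- and H-linked bands are identical, so the
classifier distinguishes only FF from insertion carriers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "PrimerPair",
    "Amplicon",
    "SEX_MARKER_PRIMERS",
    "FEMALE_BAND",
    "CARRIER_BAND",
    "find_amplicons",
    "classify_sex_bands",
    "cosegregation_check",
    "orf_protein_length",
    "make_marker_templates",
]

_ACGT = re.compile(r"^[ACGT]+$")

#: product lengths (bp) of the female and insertion-carrier marker alleles
FEMALE_BAND = 252
CARRIER_BAND = 273


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'.

    The reverse primer anneals to the plus strand as its reverse complement.
    """

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if not seq or not _ACGT.match(seq):
                raise ValueError(f"primers must be non-empty ACGT strings, got {seq!r}")


#: the intron-spanning primer pair used to genotype the sex InDel
SEX_MARKER_PRIMERS = PrimerPair("AGAAACTAGAGCCTCCGGAA", "AAAATCAAAGCATGGCCCCT")


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on a template, 1-based inclusive coordinates."""

    template_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _find_all(template: str, query: str) -> list[int]:
    hits, i = [], template.find(query)
    while i != -1:
        hits.append(i)
        i = template.find(query, i + 1)
    return hits


def find_amplicons(
    template: str,
    primers: PrimerPair,
    max_len: int = 3000,
    template_id: str = "template",
) -> list[Amplicon]:
    """Exact-match in-silico PCR.

    Every pairing of a forward-primer site with a downstream
    reverse-complement site of the reverse primer yields a product, provided
    the product is no longer than ``max_len``.  No mismatches or degenerate
    bases are tolerated.  Results are sorted by start, then length.
    """
    template = template.upper()
    if not _ACGT.match(template):
        raise ValueError("template must be a non-empty ACGT string")
    if max_len <= max(len(primers.forward), len(primers.reverse)):
        raise ValueError("max_len must exceed the primer lengths")
    rc_rev = str(Seq(primers.reverse).reverse_complement())
    out = []
    for f in _find_all(template, primers.forward):
        start = f + 1
        for r in _find_all(template, rc_rev):
            end = r + len(rc_rev)
            if start < end and end - start + 1 <= max_len:
                out.append(Amplicon(template_id, start, end))
    return sorted(out, key=lambda a: (a.start, a.length))


def classify_sex_bands(
    pattern,
    female_len: int = FEMALE_BAND,
    carrier_len: int = CARRIER_BAND,
    tol: int = 1,
) -> str:
    """Classify one individual's band pattern as 'FF', 'carrier' or 'unknown'.

    The female-allele band alone means FF; female plus carrier band means an
    insertion carrier (MF or HF — the M and H bands are identical, so the
    marker cannot separate them).  Any other pattern is 'unknown'.  Band
    lengths are matched with a ±``tol`` bp tolerance, absorbing 1-bp
    uncertainty in the reported product sizes.
    """
    bands = {int(b) for b in pattern}
    if not bands:
        raise ValueError("empty band pattern")
    if any(b <= 0 for b in bands):
        raise ValueError("band lengths must be positive")
    is_female = {b for b in bands if abs(b - female_len) <= tol}
    is_carrier = {b for b in bands if abs(b - carrier_len) <= tol}
    if is_female and is_carrier:
        return "carrier"
    if is_female and bands == is_female:
        return "FF"
    return "unknown"


def cosegregation_check(
    classifications: dict[str, str], phenotypes: dict[str, str]
) -> tuple[int, list[str]]:
    """Count marker-phenotype recombinants across a population.

    A recombinant is an individual classified FF with a male or
    hermaphrodite phenotype, or classified carrier with a female phenotype;
    'unknown' classifications are never counted.  Returns the recombinant
    count and the sorted individual ids.
    """
    if set(classifications) != set(phenotypes):
        raise ValueError("classification and phenotype tables cover different individuals")
    recombinants = []
    for ind, cls in classifications.items():
        ph = phenotypes[ind]
        if cls == "FF" and ph in ("male", "hermaphrodite"):
            recombinants.append(ind)
        elif cls == "carrier" and ph == "female":
            recombinants.append(ind)
    return len(recombinants), sorted(recombinants)


_STOPS = {"TAA", "TAG", "TGA"}


def orf_protein_length(orf) -> int:
    """Protein length encoded by an ORF: nt/3 - 1 (the stop is untranslated).

    Accepts either the ORF length in nucleotides or the sequence itself, in
    which case it must start with ATG, end with a stop codon and contain no
    internal stop.
    """
    if isinstance(orf, int):
        length = orf
        if length % 3:
            raise ValueError(f"ORF length {length} is not a multiple of 3")
        if length < 6:
            raise ValueError("an ORF needs at least a start and a stop codon")
        return length // 3 - 1
    seq = str(orf).upper()
    if len(seq) % 3:
        raise ValueError(f"ORF length {len(seq)} is not a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[0] != "ATG":
        raise ValueError("ORF must start with ATG")
    if codons[-1] not in _STOPS:
        raise ValueError("ORF must end with a stop codon")
    if any(c in _STOPS for c in codons[:-1]):
        raise ValueError("ORF contains an internal stop codon")
    return len(codons) - 1


def make_marker_templates(
    primers: PrimerPair = SEX_MARKER_PRIMERS,
    product_len: int = FEMALE_BAND,
    insert_len: int = 22,
    seed: int = 0,
) -> tuple[str, str]:
    """Synthetic female and insertion-carrier marker templates.

    Builds a random template on which the primer pair amplifies a product of
    ``product_len`` bp, and a second template identical except for an
    ``insert_len``-bp insertion midway between the primer sites.  These are
    synthetic stand-ins for the real marker locus, useful for simulation and
    demonstration.
    """
    rng = np.random.default_rng(seed)
    rc_rev = str(Seq(primers.reverse).reverse_complement())
    spacer_len = product_len - len(primers.forward) - len(primers.reverse)
    if spacer_len < 0:
        raise ValueError("product_len shorter than the two primers")
    bases = np.array(list("ACGT"))

    def random_seq(n: int) -> str:
        return "".join(rng.choice(bases, size=n))

    # avoid accidental extra primer sites in the random spacer
    for _ in range(100):
        spacer = random_seq(spacer_len)
        insert = random_seq(insert_len)
        female = primers.forward + spacer + rc_rev
        half = spacer_len // 2
        carrier = primers.forward + spacer[:half] + insert + spacer[half:] + rc_rev
        ok = all(
            len(_find_all(t, primers.forward)) == 1 and len(_find_all(t, rc_rev)) == 1
            for t in (female, carrier)
        )
        if ok:
            return female, carrier
    raise RuntimeError("could not build clean templates")  # pragma: no cover
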