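"""Circular mitochondrial genome model: loci, consequences, contexts, arcs, masks.

The 16,569 bp human mtDNA reference (rCRS convention, L-strand sequence,
1-based positions, ``m.`` coordinates) is modelled as a circular molecule.
This module provides

* the locus map (13 protein genes, 22 tRNAs, 2 rRNAs, the D-loop spanning the
  origin, and the aggregate of the 89 positions that fall between annotations),
* functional-consequence calling under the vertebrate mitochondrial genetic
  code, honoring gene strand and reading frame,
* trinucleotide contexts that wrap across the origin,
* the minor/major replication-arc partition delimited by OriH (m.191) and
  OriL (m.5799), and
* homopolymer-run masking.

Because the true rCRS nucleotide string is not redistributable here, the
default genome is a deterministic *synthetic* rCRS-like sequence (see
:func:`synthetic_reference`); the locus coordinates are the standard
published annotation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio import SeqIO

MT_LENGTH = 16569
#: rCRS placeholder position; flagged non-callable.
PLACEHOLDER_POS = 3107
ORI_H = 191
ORI_L = 5799

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]


class ReferenceMismatchError(ValueError):
    """Raised when a variant's stated reference base disagrees with the genome."""


def _check_pos(pos: int) -> None:
    if not 1 <= pos <= MT_LENGTH:
        raise ValueError(f"position {pos} outside 1..{MT_LENGTH}")


@dataclass(frozen=True)
class MtGenome:
    """A circular 16,569 nt mitochondrial genome (L-strand, 1-based)."""

    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != MT_LENGTH:
            raise ValueError(f"mtDNA genome must be {MT_LENGTH} nt, got {len(self.seq)}")
        if set(self.seq) - set("ACGTN"):
            raise ValueError("genome contains non-ACGTN characters")

    def __len__(self) -> int:
        return MT_LENGTH

    def base(self, pos: int) -> str:
        """Base at a 1-based position; arithmetic wraps modulo the length."""
        return self.seq[(pos - 1) % MT_LENGTH]

    def callable_positions(self) -> np.ndarray:
        """All positions except the placeholder N at m.3107."""
        pos = np.arange(1, MT_LENGTH + 1)
        return pos[pos != PLACEHOLDER_POS]


@dataclass(frozen=True)
class Locus:
    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive; end < start means the locus wraps the origin
    strand: str  # 'L' = sense equals reference strand; 'H' = reverse complement
    cls: str     # protein | tRNA | rRNA | D-loop

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    @property
    def length(self) -> int:
        if self.wraps:
            return (MT_LENGTH - self.start + 1) + self.end
        return self.end - self.start + 1

    def positions(self) -> np.ndarray:
        if self.wraps:
            return np.concatenate(
                [np.arange(self.start, MT_LENGTH + 1), np.arange(1, self.end + 1)]
            )
        return np.arange(self.start, self.end + 1)

    def contains(self, pos: int) -> bool:
        if self.wraps:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end


INTERGENIC = "intergenic"


class LocusMap:
    """The 39 region sets: 37 genes, the D-loop, and the intergenic aggregate."""

    def __init__(self, loci: Sequence[Locus]):
        self.loci = list(loci)
        covered = np.zeros(MT_LENGTH + 1, dtype=bool)
        for loc in self.loci:
            covered[loc.positions()] = True
        pos = np.arange(1, MT_LENGTH + 1)
        self.intergenic_positions = pos[~covered[1:]]
        # per-position list of covering loci, precomputed once
        self._cover: list[tuple[Locus, ...]] = [()] * (MT_LENGTH + 1)
        buckets: list[list[Locus]] = [[] for _ in range(MT_LENGTH + 1)]
        for loc in self.loci:
            for p in loc.positions():
                buckets[p].append(loc)
        self._cover = [tuple(b) for b in buckets]

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, name: str) -> Locus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)

    def covering(self, pos: int) -> tuple[Locus, ...]:
        _check_pos(pos)
        return self._cover[pos]

    def region_sets(self) -> dict[str, np.ndarray]:
        """Named position sets used by region burden scans (39 in total)."""
        out = {loc.name: loc.positions() for loc in self.loci}
        out[INTERGENIC] = self.intergenic_positions
        return out


@dataclass(frozen=True)
class ArcMap:
    """Replication arcs delimited by OriH (m.191) and OriL (m.5799).

    m.191 belongs to the minor arc, m.5799 to the major arc: minor =
    [191, 5799), major = the remainder of the circle.
    """

    ori_h: int = ORI_H
    ori_l: int = ORI_L

    def arc_of(self, pos: int) -> str:
        _check_pos(pos)
        return "minor" if self.ori_h <= pos < self.ori_l else "major"

    def positions(self, arc: str) -> np.ndarray:
        pos = np.arange(1, MT_LENGTH + 1)
        minor = (pos >= self.ori_h) & (pos < self.ori_l)
        return pos[minor] if arc == "minor" else pos[~minor]


@dataclass(frozen=True)
class HomopolymerMask:
    positions: frozenset[int]
    min_run: int

    def __contains__(self, pos: int) -> bool:
        return pos in self.positions


def load_locus_map() -> LocusMap:
    with resources.files("mthet.data").joinpath("loci.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    loci = [
        Locus(r.name_, int(r.start), int(r.end), r.strand, r.cls)
        for r in df.rename(columns={"name": "name_", "class": "cls"}).itertuples()
    ]
    return LocusMap(loci)


def assign_locus(pos: int, locus_map: LocusMap) -> list[tuple[str, str]]:
    """All loci covering ``pos``; unannotated positions map to the intergenic aggregate."""
    _check_pos(pos)
    hits = locus_map.covering(pos)
    if not hits:
        return [(INTERGENIC, INTERGENIC)]
    return [(loc.name, loc.cls) for loc in hits]


def trinucleotide_context(pos: int, genome: MtGenome) -> str:
    """L-strand 5'->3' triplet centred on ``pos``; neighbours wrap across the origin."""
    _check_pos(pos)
    return genome.base(pos - 1) + genome.base(pos) + genome.base(pos + 1)


def arc_of(pos: int, arcs: ArcMap) -> str:
    return arcs.arc_of(pos)


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


_SENSE_CACHE: dict[tuple[int, str], str] = {}


def _gene_sense_seq(genome: MtGenome, locus: Locus) -> str:
    key = (hash(genome.seq), locus.name)
    cached = _SENSE_CACHE.get(key)
    if cached is not None:
        return cached
    s = "".join(genome.base(p) for p in locus.positions())
    if locus.strand == "H":
        s = revcomp(s)
    # incomplete terminal codons are completed by polyadenylation of the mRNA
    if len(s) % 3:
        s += "A" * (3 - len(s) % 3)
    _SENSE_CACHE[key] = s
    return s


def _codon_index(locus: Locus, pos: int) -> tuple[int, int]:
    """(codon number, offset within codon) of ``pos`` in the gene's sense frame."""
    positions = locus.positions()
    offset = int(np.nonzero(positions == pos)[0][0])
    if locus.strand == "H":
        offset = locus.length - 1 - offset
    return divmod(offset, 3)


def translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table[codon]


def _protein_consequence(genome: MtGenome, locus: Locus, pos: int, alt: str) -> str:
    sense = _gene_sense_seq(genome, locus)
    idx, within = _codon_index(locus, pos)
    codon = sense[3 * idx : 3 * idx + 3]
    alt_sense = alt if locus.strand == "L" else alt.translate(_COMPLEMENT)
    new = codon[:within] + alt_sense + codon[within + 1 :]
    return "synonymous" if translate_codon(codon) == translate_codon(new) else "non-synonymous"


def consequence(pos: int, ref: str, alt: str, genome: MtGenome, locus_map: LocusMap) -> str:
    """Functional consequence of a single-nucleotide substitution.

    Protein-coding positions are translated with the vertebrate mitochondrial
    code in the gene's own frame (H-strand genes are read reverse-complemented);
    a variant overlapping two genes is non-synonymous if it is non-synonymous
    in any of them. Non-protein loci are labelled by locus class.
    """
    _check_pos(pos)
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if genome.base(pos) != ref:
        raise ReferenceMismatchError(
            f"reference base at m.{pos} is {genome.base(pos)}, not {ref}"
        )
    hits = locus_map.covering(pos)
    proteins = [l for l in hits if l.cls == "protein"]
    if proteins:
        calls = {_protein_consequence(genome, l, pos, alt) for l in proteins}
        return "non-synonymous" if "non-synonymous" in calls else "synonymous"
    if hits:
        return hits[0].cls
    return INTERGENIC


def _runs(seq: str) -> list[tuple[int, int, str]]:
    """(start index, length, base) of maximal runs in a linear string."""
    out = []
    i = 0
    for base, grp in itertools.groupby(seq):
        n = len(list(grp))
        out.append((i, n, base))
        i += n
    return out


def build_homopolymer_mask(
    genome: MtGenome,
    min_run: int = 5,
    extra_regions: Iterable[tuple[int, int]] = (),
) -> HomopolymerMask:
    """Mask positions inside runs of >= ``min_run`` identical bases (circular),
    plus any explicitly configured extra regions (1-based inclusive)."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    runs = _runs(genome.seq)
    # merge a run that wraps the origin
    if len(runs) > 1 and runs[0][2] == runs[-1][2]:
        s0, n0, b = runs[0]
        s1, n1, _ = runs[-1]
        merged = n0 + n1
        runs = runs[1:-1] + [(s1, merged, b)]  # start in the tail, wraps
    masked: set[int] = set()
    for start, n, base in runs:
        if base == "N" or n < min_run:
            continue
        for k in range(n):
            masked.add((start + k) % MT_LENGTH + 1)
    for lo, hi in extra_regions:
        for p in range(lo, hi + 1):
            _check_pos(p)
            masked.add(p)
    return HomopolymerMask(frozenset(masked), min_run)


# ---------------------------------------------------------------------------
# synthetic reference genome

_REFERENCE_SEED = 16569


def synthetic_reference(seed: int = _REFERENCE_SEED) -> MtGenome:
    """Deterministic synthetic rCRS-like genome.

    This is a stand-in for the true rCRS nucleotide string: base composition
    matches the L strand (A .309, C .313, G .131, T .247), protein genes carry
    open reading frames in their annotated frames/strands, m.3107 is the 'N'
    placeholder, the D-loop carries the poly-C tract structure at 303-315, and
    the haplogroup-tagging anchor sites hold their rCRS alleles (m.263 A,
    m.7028 C in a TAC codon, m.11719 G in a GCG codon) so that the canonical
    transitions at those sites have their known consequences.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=MT_LENGTH, p=[0.309, 0.313, 0.131, 0.247])

    locus_map = load_locus_map()
    sense_codons = sorted(set(_MITO_TABLE.forward_table) - set(_MITO_TABLE.stop_codons))

    def write_sense(locus: Locus, offset: int, codon: str) -> None:
        """Write a sense-strand codon into the reference at sense offset (multiple of 3)."""
        positions = locus.positions()
        for k, b in enumerate(codon):
            o = offset + k
            if o >= locus.length:
                continue  # polyadenylation-completed tail, not genomic
            idx = locus.length - 1 - o if locus.strand == "H" else o
            p = positions[idx]
            seq[p - 1] = b if locus.strand == "L" else b.translate(_COMPLEMENT)

    for locus in locus_map:
        if locus.cls != "protein":
            continue
        genome_tmp = MtGenome("".join(seq))
        sense = _gene_sense_seq(genome_tmp, locus)
        for i in range(0, locus.length - 2, 3):
            if sense[i : i + 3] in _MITO_TABLE.stop_codons:
                write_sense(locus, i, str(rng.choice(sense_codons)))
        write_sense(locus, 0, "ATG")

    seq[263 - 1] = "A"
    for p, b in zip(range(7026, 7029), "TAC"):   # MT-CO1 codon holding m.7028C
        seq[p - 1] = b
    for p, b in zip(range(11717, 11720), "GCG"):  # MT-ND4 codon holding m.11719G
        seq[p - 1] = b
    tract = "CCCCCCCTCCCCC"  # 303-315: 7 C, T, 5 C
    for p, b in zip(range(303, 316), tract):
        seq[p - 1] = b
    seq[PLACEHOLDER_POS - 1] = "N"
    return MtGenome("".join(seq))


@dataclass(frozen=True)
class MtAnnotation:
    """Bundle of genome + locus map + arcs + homopolymer mask with cached helpers."""

    genome: MtGenome
    locus_map: LocusMap
    arcs: ArcMap
    mask: HomopolymerMask

    def assign_locus(self, pos: int) -> list[tuple[str, str]]:
        return assign_locus(pos, self.locus_map)

    def consequence(self, pos: int, ref: str, alt: str) -> str:
        return consequence(pos, ref, alt, self.genome, self.locus_map)

    def context(self, pos: int) -> str:
        return trinucleotide_context(pos, self.genome)

    def arc_of(self, pos: int) -> str:
        return self.arcs.arc_of(pos)


@lru_cache(maxsize=1)
def load_annotation(min_run: int = 5) -> MtAnnotation:
    genome = synthetic_reference()
    locus_map = load_locus_map()
    arcs = ArcMap()
    mask = build_homopolymer_mask(genome, min_run=min_run)
    return MtAnnotation(genome, locus_map, arcs, mask)


# ---------------------------------------------------------------------------
# FASTA / BED interchange (1-based inclusive internally, BED 0-based half-open)

def write_fasta(genome: MtGenome, path, name: str = "chrM") -> None:
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(genome.seq), id=name, description="")], str(path), "fasta")


def read_fasta(path) -> MtGenome:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return MtGenome(str(rec.seq).upper())


def write_bed(intervals: Iterable[tuple[str, int, int]], path) -> None:
    """Write named 1-based inclusive intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for name, start, end in intervals:
            fh.write(f"chrM\t{start - 1}\t{end}\t{name}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED into named 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else ""
            out.append((name, int(f[1]) + 1, int(f[2])))
    return out
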