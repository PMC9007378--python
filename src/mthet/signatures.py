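"""Trinucleotide mutational signatures, strand-resolved and arc-resolved.

Substitutions are collapsed to the six pyrimidine-reference changes
(C>A, C>G, C>T, T>A, T>C, T>G) with explicit strand attribution: the rCRS
reference string is the light (L) strand, so a pyrimidine reference base keeps
its change on L, while a purine reference base is complemented and attributed
to the heavy (H) strand. Contexts are reported 5'->3' on the strand carrying
the pyrimidine (so an H-strand context is the reverse complement of the
L-strand triplet), and counts are stratified by replication arc.

Arc asymmetry is tested with a pooled two-proportions Z test, one-tailed for
"greater in the major arc" (the replication-mechanism alternative).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import ArcMap, MtGenome, revcomp, trinucleotide_context

PYRIMIDINE_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: the 96 (substitution, context) pairs in conventional order
CONTEXTS_96 = [
    (sub, five + sub[0] + three)
    for sub in PYRIMIDINE_SUBS
    for five, three in itertools.product("ACGT", repeat=2)
]


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Collapse to a pyrimidine substitution plus the strand carrying it."""
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"invalid bases {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "CT":
        return f"{ref}>{alt}", "L"
    return f"{_COMP[ref]}>{_COMP[alt]}", "H"


@dataclass
class SignatureMatrix:
    """Counts over (substitution, context) x strand x arc strata."""

    counts: pd.DataFrame  # columns: substitution, context, strand, arc, count
    hf_range: tuple[float, float]

    def total(self) -> int:
        return int(self.counts["count"].sum())

    def stratum(self, strand: str, arc: str) -> pd.DataFrame:
        """Full 96-cell table for one strand x arc stratum, with frequencies."""
        sel = self.counts[(self.counts["strand"] == strand)
                          & (self.counts["arc"] == arc)]
        merged = sel.groupby(["substitution", "context"])["count"].sum()
        idx = pd.MultiIndex.from_tuples(CONTEXTS_96,
                                        names=["substitution", "context"])
        out = merged.reindex(idx, fill_value=0).reset_index()
        tot = out["count"].sum()
        out["frequency"] = out["count"] / tot if tot else 0.0
        return out

    def aggregate(self, by=("substitution", "strand", "arc")) -> pd.DataFrame:
        """Collapse the 16 context cells of each substitution (and any other
        margins requested)."""
        return self.counts.groupby(list(by))["count"].sum().reset_index()

    def substitution_count(self, substitution: str, strand: str, arc: str) -> int:
        sel = self.counts[(self.counts["substitution"] == substitution)
                          & (self.counts["strand"] == strand)
                          & (self.counts["arc"] == arc)]
        return int(sel["count"].sum())

    def strand_total(self, strand: str, arc: str) -> int:
        sel = self.counts[(self.counts["strand"] == strand)
                          & (self.counts["arc"] == arc)]
        return int(sel["count"].sum())

    def to_long(self) -> pd.DataFrame:
        out = self.counts.copy()
        totals = out.groupby(["strand", "arc"])["count"].transform("sum")
        out["frequency"] = np.where(totals > 0, out["count"] / totals, 0.0)
        return out


def build_signature_matrix(calls: pd.DataFrame, genome: MtGenome, arcs: ArcMap,
                           hf_range: tuple[float, float] = (0.05, 0.95)) -> SignatureMatrix:
    """Count each heteroplasmic call in its (substitution, context, strand, arc)
    cell; context read on the strand carrying the pyrimidine; contexts
    containing the reference placeholder N are skipped."""
    lo, hi = hf_range
    sel = calls[(calls["hf"] >= lo) & (calls["hf"] <= hi)]
    rows = []
    for pos, ref, alt in zip(sel["pos"], sel["ref"], sel["alt"]):
        sub, strand = classify_substitution(ref, alt)
        ctx = trinucleotide_context(int(pos), genome)
        if "N" in ctx:
            continue
        if strand == "H":
            ctx = revcomp(ctx)
        rows.append((sub, ctx, strand, arcs.arc_of(int(pos))))
    df = (pd.DataFrame(rows, columns=["substitution", "context", "strand", "arc"])
          .groupby(["substitution", "context", "strand", "arc"])
          .size().rename("count").reset_index())
    return SignatureMatrix(df, hf_range)


@dataclass
class AsymmetryTest:
    substitution: str
    strand: str
    x_major: int
    n_major: int
    x_minor: int
    n_minor: int
    z: float
    p: float
    alternative: str = "greater"


def two_proportion_z(x1: int, n1: int, x2: int, n2: int,
                     alternative: str = "greater") -> tuple[float, float]:
    """Pooled two-proportions Z test of p1 vs p2."""
    if n1 == 0 or n2 == 0:
        raise ValueError("both denominators must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        z = 0.0
    else:
        z = (p1 - p2) / se
    if alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def arc_asymmetry_test(matrix: SignatureMatrix, substitution: str, strand: str,
                       alternative: str = "greater") -> AsymmetryTest:
    """Compare the substitution's share of all same-strand substitutions
    between the major and minor arcs (one-tailed: greater in the major arc)."""
    x_major = matrix.substitution_count(substitution, strand, "major")
    n_major = matrix.strand_total(strand, "major")
    x_minor = matrix.substitution_count(substitution, strand, "minor")
    n_minor = matrix.strand_total(strand, "minor")
    z, p = two_proportion_z(x_major, n_major, x_minor, n_minor, alternative)
    return AsymmetryTest(substitution, strand, x_major, n_major, x_minor,
                         n_minor, z, p, alternative)


def all_asymmetry_tests(matrix: SignatureMatrix, alpha: float = 0.05,
                        alternative: str = "greater") -> pd.DataFrame:
    """One test per (substitution, strand) with both arcs populated; the family
    threshold defaults to alpha over the number of tests actually run."""
    rows = []
    for sub in PYRIMIDINE_SUBS:
        for strand in ("H", "L"):
            if (matrix.strand_total(strand, "major") == 0
                    or matrix.strand_total(strand, "minor") == 0):
                continue
            t = arc_asymmetry_test(matrix, sub, strand, alternative)
            rows.append((sub, strand, t.x_major, t.n_major, t.x_minor,
                         t.n_minor, t.z, t.p))
    df = pd.DataFrame(rows, columns=["substitution", "strand", "x_major",
                                     "n_major", "x_minor", "n_minor", "z", "p"])
    df["threshold"] = alpha / len(df) if len(df) else np.nan
    return df
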