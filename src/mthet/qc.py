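"""Variant/sample quality-control cascade for mtDNA heteroplasmy calls.

Stages, in pipeline order:

1. sample coverage (> 95% of mtDNA covered by at least one read),
2. per-call support (depth >= 500x, >= 25 alt reads, both strands, HF >= 5%),
3. homopolymer-region exclusion,
4. within-group heteroplasmic prevalence (> 2% of a group's individuals),
5. reference-panel allele-frequency concordance for homoplasmies
   (|cohort AF - panel AF| > 0.9 in either panel),
6. optional coefficient-of-variation (CV) filter against NUMT-style
   pseudo-heteroplasmies: per-site CV of HF across heteroplasmic carriers,
   removing sites in the bottom percentile of the CV distribution.

Every stage is a pure function returning a subset of its input calls; the
cascade assembles a :class:`FilterReport` with per-stage removal counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import HomopolymerMask

HET_LO, HET_HI = 0.05, 0.95


@dataclass
class QCConfig:
    min_covered_fraction: float = 0.95
    min_depth: int = 500
    min_alt_reads: int = 25
    min_hf: float = 0.05
    max_het_prevalence: float = 0.02
    prevalence_scope: str = "group"  # or "cohort"
    max_af_diff: float = 0.9
    enable_cv_filter: bool = False
    cv_percentile: float = 25.0
    cv_min_carriers: int = 3


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class FilterReport:
    stages: list[FilterStage] = field(default_factory=list)
    calls: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None
    site_stats: pd.DataFrame | None = None

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append(FilterStage(name, n_in, n_in - n_out))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_removed, s.n_out) for s in self.stages],
            columns=["stage", "n_in", "n_removed", "n_out"],
        )

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"stage": s.name, "n_in": s.n_in, "n_removed": s.n_removed,
                 "n_out": s.n_out}
                for s in self.stages
            ],
            "n_calls_out": 0 if self.calls is None else int(len(self.calls)),
            "n_samples_out": 0 if self.samples is None else int(len(self.samples)),
        }


def filter_samples(samples: pd.DataFrame, min_covered_fraction: float = 0.95):
    """Retain samples with covered_fraction strictly above the threshold."""
    keep = samples["covered_fraction"] > min_covered_fraction
    return samples[keep].reset_index(drop=True)


def basic_call_filter(calls: pd.DataFrame, min_depth: int = 500,
                      min_alt_reads: int = 25, min_hf: float = 0.05) -> pd.DataFrame:
    """Depth >= 500x, >= 25 alt reads in total with >= 1 on each strand, HF >= 5%."""
    c = calls
    keep = (
        (c["depth"] >= min_depth)
        & (c["alt_fwd"] + c["alt_rev"] >= min_alt_reads)
        & (c["alt_fwd"] >= 1)
        & (c["alt_rev"] >= 1)
        & (c["hf"] >= min_hf)
    )
    return c[keep]


def homopolymer_site_filter(calls: pd.DataFrame, mask: HomopolymerMask) -> pd.DataFrame:
    if not mask.positions:
        return calls
    return calls[~calls["pos"].isin(mask.positions)]


def _is_het(hf: pd.Series) -> pd.Series:
    return (hf >= HET_LO) & (hf <= HET_HI)


def cohort_prevalence_filter(calls: pd.DataFrame, samples: pd.DataFrame,
                             max_het_prevalence: float = 0.02,
                             scope: str = "group") -> pd.DataFrame:
    """Remove heteroplasmic calls at sites heteroplasmic in more than
    ``max_het_prevalence`` of a group's individuals (strict inequality).

    ``scope="group"`` removes within the offending group only;
    ``scope="cohort"`` pools all groups.
    """
    if calls.empty:
        return calls
    c = calls.merge(samples[["sample_id", "group"]], on="sample_id", how="left")
    c.index = calls.index
    if scope == "cohort":
        c["group"] = "all"
        sizes = pd.Series({"all": samples["sample_id"].nunique()})
    elif scope == "group":
        sizes = samples.groupby("group")["sample_id"].nunique()
    else:
        raise ValueError(f"unknown prevalence scope {scope!r}")
    het = c[_is_het(c["hf"])]
    carriers = (het.groupby(["group", "pos", "alt"])["sample_id"].nunique()
                .rename("n_carriers").reset_index())
    carriers["prev"] = carriers["n_carriers"] / carriers["group"].map(sizes)
    bad = carriers[carriers["prev"] > max_het_prevalence]
    bad_keys = set(zip(bad["group"], bad["pos"], bad["alt"]))
    if not bad_keys:
        return calls
    het_row = _is_het(c["hf"]).to_numpy()
    in_bad = np.fromiter(
        ((g, p, a) in bad_keys for g, p, a in zip(c["group"], c["pos"], c["alt"])),
        dtype=bool, count=len(c))
    return calls[~(het_row & in_bad)]


def panel_concordance_filter(calls: pd.DataFrame, samples: pd.DataFrame,
                             panel_afs: list[pd.DataFrame],
                             max_af_diff: float = 0.9) -> pd.DataFrame:
    """Remove homoplasmic calls (HF > 0.95) at sites whose cohort allele
    frequency differs from a reference panel's by more than ``max_af_diff``
    in either panel; alleles absent from a panel count as panel AF 0."""
    if calls.empty:
        return calls
    hom = calls[calls["hf"] > HET_HI]
    n = samples["sample_id"].nunique()
    af = (hom.groupby(["pos", "alt"])["sample_id"].nunique() / n).rename("cohort_af")
    af = af.reset_index()
    bad: set[tuple[int, str]] = set()
    for panel in panel_afs:
        merged = af.merge(panel[["pos", "alt", "af"]], on=["pos", "alt"], how="left")
        merged["af"] = merged["af"].fillna(0.0)
        over = merged[(merged["cohort_af"] - merged["af"]).abs() > max_af_diff]
        bad.update(zip(over["pos"], over["alt"]))
    if not bad:
        return calls
    in_bad = np.fromiter(((p, a) in bad for p, a in zip(calls["pos"], calls["alt"])),
                         dtype=bool, count=len(calls))
    drop = calls["hf"].gt(HET_HI).to_numpy() & in_bad
    return calls[~drop]


def site_hf_stats(calls: pd.DataFrame, min_carriers: int = 3) -> pd.DataFrame:
    """Per-(pos, alt) HF statistics over heteroplasmic carriers.

    CV = sd(HF)/mean(HF), defined only for sites with at least
    ``min_carriers`` heteroplasmic carriers.
    """
    het = calls[_is_het(calls["hf"])]
    g = het.groupby(["pos", "alt"])["hf"]
    stats = pd.DataFrame({
        "n_het_carriers": g.size(),
        "mean_hf": g.mean(),
        "sd_hf": g.std(ddof=1),
    }).reset_index()
    stats["cv"] = np.where(
        (stats["n_het_carriers"] >= min_carriers) & (stats["mean_hf"] > 0),
        stats["sd_hf"] / stats["mean_hf"],
        np.nan,
    )
    return stats


def cv_site_filter(calls: pd.DataFrame, percentile: float = 25.0,
                   min_carriers: int = 3):
    """Remove all calls at sites whose HF coefficient of variation falls at or
    below the ``percentile``-th percentile of the across-site CV distribution.

    Sites with fewer than ``min_carriers`` heteroplasmic carriers never enter
    the CV distribution and are never removed. Returns (calls, site_stats).
    """
    stats = site_hf_stats(calls, min_carriers=min_carriers)
    cvs = stats["cv"].dropna()
    if cvs.empty:
        warnings.warn("CV filter: no site has enough heteroplasmic carriers; no-op")
        return calls, stats
    cut = np.percentile(cvs.to_numpy(), percentile)
    bad = stats[stats["cv"].notna() & (stats["cv"] <= cut)]
    bad_keys = set(zip(bad["pos"], bad["alt"]))
    keep = [not ((p, a) in bad_keys) for p, a in zip(calls["pos"], calls["alt"])]
    return calls[np.array(keep, dtype=bool)], stats


def apply_qc_cascade(calls: pd.DataFrame, samples: pd.DataFrame,
                     mask: HomopolymerMask,
                     panel_afs: list[pd.DataFrame] | None = None,
                     config: QCConfig | None = None) -> FilterReport:
    """Run the full filter cascade in pipeline order and log per-stage counts."""
    cfg = config or QCConfig()
    report = FilterReport()

    kept_samples = filter_samples(samples, cfg.min_covered_fraction)
    report.add("sample_coverage", len(samples), len(kept_samples))
    c = calls[calls["sample_id"].isin(set(kept_samples["sample_id"]))]
    report.add("calls_of_retained_samples", len(calls), len(c))

    n = len(c)
    c = basic_call_filter(c, cfg.min_depth, cfg.min_alt_reads, cfg.min_hf)
    report.add("basic_call", n, len(c))

    n = len(c)
    c = homopolymer_site_filter(c, mask)
    report.add("homopolymer", n, len(c))

    n = len(c)
    c = cohort_prevalence_filter(c, kept_samples, cfg.max_het_prevalence,
                                 cfg.prevalence_scope)
    report.add("cohort_prevalence", n, len(c))

    if panel_afs:
        n = len(c)
        c = panel_concordance_filter(c, kept_samples, panel_afs, cfg.max_af_diff)
        report.add("panel_concordance", n, len(c))

    if cfg.enable_cv_filter:
        n = len(c)
        c, stats = cv_site_filter(c, cfg.cv_percentile, cfg.cv_min_carriers)
        report.add("cv_numt", n, len(c))
        report.site_stats = stats

    report.calls = c.reset_index(drop=True)
    report.samples = kept_samples
    return report
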