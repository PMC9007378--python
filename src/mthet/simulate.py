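"""Synthetic cohort generator for mtDNA heteroplasmy burden studies.

Emulates, at the variant-call level, the data structure a deep mtDNA
sequencing study of cardiovascular cases and controls produces:

* inherited homoplasmies organised in haplogroup-like haplotypes, with a few
  near-fixed backbone polymorphisms and haplogroup-tagging anchor sites;
* somatic low (HF 5-10%) and intermediate (HF 10-95%) heteroplasmies whose
  per-individual counts follow log-linear negative-binomial models in age and
  case status, and whose positions follow a replication-strand-asymmetric
  transition signature (C>T on the heavy strand / T>C on the light strand,
  enriched in the major arc);
* NUMT-style pseudo-heteroplasmies: fixed sites with near-constant HF across
  carriers;
* artifact calls inside homopolymer runs and strand-biased artifact calls;
* per-sample covariates (age, sex, mean depth, mitochondrial ancestry,
  covered fraction, optional blood pressure / smoking for cases);
* reference-panel allele-frequency tables and conservation / pathogenicity
  score surrogates.

Every call carries a truth label (inherited | somatic | numt | artifact), so
downstream QC and association stages can be tested truth-conditionally.
A single seed drives one root :class:`numpy.random.SeedSequence`; stage
substreams are spawned deterministically, so equal configs give identical
cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .reference import (
    MT_LENGTH,
    MtAnnotation,
    load_annotation,
    revcomp,
)

CALL_COLUMNS = ["sample_id", "pos", "ref", "alt", "hf", "depth", "alt_fwd", "alt_rev"]
SAMPLE_COLUMNS = [
    "sample_id", "group", "age", "sex", "mean_depth", "mt_ancestry",
    "covered_fraction", "sbp", "dbp", "smoker",
]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_ANCHORS = [(263, "A", "G"), (7028, "C", "T"), (11719, "G", "A")]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the study's reported per-individual means (9
    homoplasmies, 1.3 intermediate and 0.3 low heteroplasmies), the
    case effect on intermediate burden (0.27 log-counts; 0.28 for the
    non-synonymous channel), the somatic age slope (0.02 per year on
    low-level burden) and the 99.8% transition share.
    """

    n_cases: int = 700
    n_controls: int = 360
    case_group: str = "HTN"
    age_range: tuple[float, float] = (30.0, 90.0)

    # somatic burden models (log link)
    somatic_rate_intercept: float | None = None  # None -> calibrated from mean_low
    somatic_rate_age_slope: float = 0.02
    intermediate_age_slope: float = 0.001
    case_effect_intermediate: float = 0.27
    case_effect_nonsyn: float = 0.28
    case_effect_low: float = 0.0

    # per-individual mean counts and NB dispersions (var = mu + alpha*mu^2)
    mean_homoplasmies: float = 9.0
    mean_intermediate: float = 1.3
    mean_low: float = 0.3
    dispersion_intermediate: float = 0.75
    dispersion_low: float = 3.8

    # HF shapes within each class
    hf_low_beta: tuple[float, float] = (2.0, 2.0)           # on [0.05, 0.10)
    hf_intermediate_beta: tuple[float, float] = (1.5, 1.5)  # on [0.10, 0.95)

    # shared (inherited) heteroplasmic polymorphisms: fraction of the
    # intermediate mean carried by recurrently heteroplasmic sites whose HF
    # varies freely across carriers (unlike NUMT pseudo-heteroplasmies)
    shared_het_fraction: float = 0.15
    shared_het_sites: int = 30

    # mutational signature of somatic draws
    transition_fraction: float = 0.998
    signature_bias: float = 0.8        # mass of C>T-on-H + T>C-on-L among transitions
    major_arc_enrichment: float = 2.5  # odds multiplier for the favored pair

    # NUMT pseudo-heteroplasmies
    numt_sites: int = 6
    numt_carrier_rate: float = 0.01
    numt_hf_range: tuple[float, float] = (0.06, 0.30)
    numt_hf_jitter: float = 0.01

    # artifacts
    artifact_homopolymer_rate: float = 0.15  # expected artifact calls per sample
    artifact_strand_rate: float = 0.05       # expected one-strand-only calls per sample

    # depth model
    depth_mean: float = 1088.0
    depth_sd: float = 90.0
    depth_site_cv: float = 0.18

    # sample-level structure
    n_haplotypes: int = 150
    lowcov_fraction: float = 0.02
    ancestry_probs: tuple[float, float, float] = (0.95, 0.03, 0.02)

    # panel / score surrogates
    discordant_fraction: float = 0.002
    mutpred_high_fraction: float = 0.15
    score_hf_tilt: float = 3.0

    seed: int = 2022

    def __post_init__(self) -> None:
        for name in ("mean_homoplasmies", "mean_intermediate", "mean_low",
                     "numt_carrier_rate", "artifact_homopolymer_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("transition_fraction", "signature_bias", "discordant_fraction",
                     "mutpred_high_fraction", "lowcov_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticCohort:
    calls: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame
    panel_genbank: pd.DataFrame | None = None
    panel_kg: pd.DataFrame | None = None
    discordant_sites: list[tuple[int, str]] = field(default_factory=list)
    phastcons: pd.DataFrame | None = None
    mutpred: pd.DataFrame | None = None
    numt_site_table: pd.DataFrame | None = None
    config: SimulationConfig | None = None

    def config_tilt(self) -> float:
        return self.config.score_hf_tilt if self.config is not None else 3.0


# ---------------------------------------------------------------------------
# position pools under the signature mechanism

@lru_cache(maxsize=2)
def _position_pools(ann_key: int):
    """For each ordered substitution, callable non-masked positions split by arc,
    with a parallel flag marking draws that would be non-synonymous."""
    ann = load_annotation()
    genome, arcs, mask = ann.genome, ann.arcs, ann.mask
    seq = np.array(list(genome.seq))
    pos = np.arange(1, MT_LENGTH + 1)
    ok = (seq != "N") & ~np.isin(pos, list(mask.positions))
    minor = (pos >= arcs.ori_h) & (pos < arcs.ori_l)
    pools: dict[tuple[str, str], dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for ref in "ACGT":
        sel = ok & (seq == ref)
        for alt in "ACGT":
            if alt == ref:
                continue
            ns = {}
            for arc, arc_sel in (("minor", minor), ("major", ~minor)):
                p = pos[sel & arc_sel]
                flags = np.fromiter(
                    (ann.consequence(int(q), ref, alt) == "non-synonymous" for q in p),
                    dtype=bool, count=len(p),
                )
                ns[arc] = (p, flags)
            pools[(ref, alt)] = ns
    return pools


def _substitution_probs(cfg: SimulationConfig) -> dict[tuple[str, str], float]:
    tf = cfg.transition_fraction
    b = cfg.signature_bias
    probs = {
        ("G", "A"): tf * b / 2,        # C>T on the H strand (favored)
        ("T", "C"): tf * b / 2,        # T>C on the L strand (favored)
        ("C", "T"): tf * (1 - b) / 2,  # C>T on the L strand
        ("A", "G"): tf * (1 - b) / 2,  # T>C on the H strand
    }
    tv = (1 - tf) / 8
    for ref in "ACGT":
        for alt in "ACGT":
            if alt != ref and alt != _TRANSITION[ref]:
                probs[(ref, alt)] = tv
    return probs


_FAVORED = {("G", "A"), ("T", "C")}


def _draw_positions(n: int, cfg: SimulationConfig, rng: np.random.Generator,
                    channel: str | None = None) -> tuple[np.ndarray, list[str], list[str]]:
    """Draw n somatic variant positions (and ref/alt) under the signature model.

    ``channel`` restricts draws to positions whose substitution would be
    non-synonymous (``"nonsyn"``), anything else (``"other"``), or no
    restriction (None).
    """
    pools = _position_pools(0)
    probs = _substitution_probs(cfg)
    subs = list(probs)
    p = np.array([probs[s] for s in subs])
    p = p / p.sum()
    which = rng.choice(len(subs), size=n, p=p)
    out_pos = np.empty(n, dtype=int)
    out_ref: list[str] = [""] * n
    out_alt: list[str] = [""] * n
    for k, (ref, alt) in enumerate(subs):
        idx = np.nonzero(which == k)[0]
        if len(idx) == 0:
            continue
        arcs = {}
        for arc in ("minor", "major"):
            pool, flags = pools[(ref, alt)][arc]
            if channel == "nonsyn":
                pool = pool[flags]
            elif channel == "other":
                pool = pool[~flags]
            arcs[arc] = pool
        n_min, n_maj = len(arcs["minor"]), len(arcs["major"])
        if n_min + n_maj == 0:
            # degenerate channel/type combination: fall back to unrestricted pools
            arcs = {a: pools[(ref, alt)][a][0] for a in ("minor", "major")}
            n_min, n_maj = len(arcs["minor"]), len(arcs["major"])
        w_maj = n_maj * (cfg.major_arc_enrichment if (ref, alt) in _FAVORED else 1.0)
        p_major = w_maj / (w_maj + n_min) if (w_maj + n_min) > 0 else 0.0
        is_major = rng.random(len(idx)) < p_major
        for arc, mask_sel in (("major", is_major), ("minor", ~is_major)):
            take = idx[mask_sel]
            if len(take) == 0:
                continue
            pool = arcs[arc]
            if len(pool) == 0:  # arc empty for this type; use the other arc
                pool = arcs["minor" if arc == "major" else "major"]
            out_pos[take] = rng.choice(pool, size=len(take), replace=True)
        for i in idx:
            out_ref[i] = ref
            out_alt[i] = alt
    return out_pos, out_ref, out_alt


# ---------------------------------------------------------------------------
# cohort generation

def _make_samples(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cases + cfg.n_controls
    ids = [f"S{i:05d}" for i in range(1, n + 1)]
    group = [cfg.case_group] * cfg.n_cases + ["control"] * cfg.n_controls
    age = rng.uniform(*cfg.age_range, size=n)
    sex = rng.choice(["F", "M"], size=n)
    ancestry = rng.choice(["European", "African", "Asian"], size=n, p=cfg.ancestry_probs)
    depth = np.maximum(300.0, rng.normal(cfg.depth_mean, cfg.depth_sd, size=n))
    covered = 0.951 + 0.049 * rng.beta(4.0, 1.2, size=n)
    low = rng.random(n) < cfg.lowcov_fraction
    covered[low] = rng.uniform(0.80, 0.95, size=low.sum())
    is_case = np.array([g != "control" for g in group])
    sbp = np.where(is_case, rng.normal(160.0, 15.0, size=n), np.nan)
    dbp = np.where(is_case, rng.normal(95.0, 10.0, size=n), np.nan)
    smoker = np.where(is_case, (rng.random(n) < 0.3).astype(float), np.nan)
    return pd.DataFrame({
        "sample_id": ids, "group": group, "age": age, "sex": sex,
        "mean_depth": depth, "mt_ancestry": ancestry, "covered_fraction": covered,
        "sbp": sbp, "dbp": dbp, "smoker": smoker,
    })


def _nb_counts(mu: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """NB2 counts via a Poisson-gamma mixture; returns the frailty-scaled means too."""
    if alpha <= 0:
        return rng.poisson(mu)
    frailty = rng.gamma(1.0 / alpha, alpha, size=len(mu))
    return rng.poisson(mu * frailty)


def _calibrated_mu(target_mean: float, lp: np.ndarray) -> np.ndarray:
    """Per-sample means exp(b0 + lp) with b0 set so the grand mean hits target."""
    if target_mean <= 0:
        return np.zeros_like(lp)
    e = np.exp(lp)
    return target_mean * e / e.mean()


def _homoplasmies(cfg: SimulationConfig, samples: pd.DataFrame,
                  rng: np.random.Generator, ann: MtAnnotation):
    genome = ann.genome
    n = len(samples)
    K = cfg.n_haplotypes
    freqs = rng.dirichlet(np.full(K, 0.6))

    callable_pos = genome.callable_positions()
    masked = np.isin(callable_pos, list(ann.mask.positions))
    anchor_pos = [a[0] for a in _ANCHORS]
    pool = callable_pos[~masked & ~np.isin(callable_pos, anchor_pos)]

    # backbone: near-fixed polymorphisms; anchors: haplogroup-tagging (freq > .5)
    n_common = 4
    common_pos = rng.choice(pool, size=n_common, replace=False)
    common_freq = rng.uniform(0.93, 1.0, size=n_common)
    anchor_freq = rng.uniform(0.55, 0.90, size=len(_ANCHORS))

    site_list: list[tuple[int, str, str]] = []
    carrier_mat: list[np.ndarray] = []  # per site: bool over haplotypes
    for p, f in zip(common_pos, common_freq):
        ref = genome.base(int(p))
        site_list.append((int(p), ref, _TRANSITION[ref]))
        carrier_mat.append(rng.random(K) < f)
    for (p, ref, alt), f in zip(_ANCHORS, anchor_freq):
        site_list.append((p, ref, alt))
        carrier_mat.append(rng.random(K) < f)

    shared_per_hap = np.vstack(carrier_mat).sum(axis=0)
    private_mean = max(0.0, cfg.mean_homoplasmies
                       - float(shared_per_hap @ freqs))
    pool_private = pool[~np.isin(pool, common_pos)]
    hap_private: list[np.ndarray] = []
    for k in range(K):
        m = rng.poisson(private_mean)
        hap_private.append(rng.choice(pool_private, size=m, replace=False) if m else
                           np.array([], dtype=int))

    hap_of = rng.choice(K, size=n, p=freqs)
    rows = []
    shared_sites = np.vstack(carrier_mat)  # (n_sites, K)
    for i, sid in enumerate(samples["sample_id"]):
        k = hap_of[i]
        for j, (p, ref, alt) in enumerate(site_list):
            if shared_sites[j, k]:
                rows.append((sid, p, ref, alt))
        for p in hap_private[k]:
            ref = genome.base(int(p))
            alt = _TRANSITION[ref] if rng.random() < 0.95 else str(
                rng.choice([b for b in "ACGT" if b not in (ref, _TRANSITION[ref])]))
            rows.append((sid, int(p), ref, alt))
    df = pd.DataFrame(rows, columns=["sample_id", "pos", "ref", "alt"])
    df["hf"] = 1.0 - 0.05 * rng.beta(1.5, 6.0, size=len(df))
    df["label"] = "inherited"
    return df


def _shared_heteroplasmies(cfg: SimulationConfig, samples: pd.DataFrame,
                           rng: np.random.Generator,
                           ann: MtAnnotation) -> pd.DataFrame:
    """Recurrent inherited heteroplasmies: fixed sites carried by several
    individuals each, with HF drawn independently per carrier (high CV,
    distinguishing them from NUMT artifacts). Case status scales the carrier
    rate by the intermediate-burden case effect, mirroring the burden model."""
    target = cfg.shared_het_fraction * cfg.mean_intermediate
    S = cfg.shared_het_sites
    if target <= 0 or S <= 0:
        return pd.DataFrame(columns=["sample_id", "pos", "ref", "alt", "hf", "label"])
    genome = ann.genome
    callable_pos = genome.callable_positions()
    pool = callable_pos[~np.isin(callable_pos, list(ann.mask.positions))]
    sites = rng.choice(pool, size=S, replace=False)
    raw = rng.uniform(0.3, 1.7, size=S)
    is_case = (samples["group"] != "control").to_numpy()
    case_mult = np.exp(cfg.case_effect_intermediate)
    mean_mult = np.where(is_case, case_mult, 1.0).mean()
    base = raw / raw.sum() * target / mean_mult  # per-site control carrier rate
    lo, hi = 0.10, 0.95
    a, b = cfg.hf_intermediate_beta
    rows = []
    for p, rate in zip(sites, base):
        ref = genome.base(int(p))
        alt = _TRANSITION[ref]
        prob = np.where(is_case, rate * case_mult, rate)
        carriers = samples["sample_id"].to_numpy()[rng.random(len(samples)) < prob]
        for sid in carriers:
            hf = lo + (hi - lo) * rng.beta(a, b)
            rows.append((sid, int(p), ref, alt, float(hf)))
    df = pd.DataFrame(rows, columns=["sample_id", "pos", "ref", "alt", "hf"])
    df["label"] = "inherited"
    return df


def _somatic(cfg: SimulationConfig, samples: pd.DataFrame,
             rng: np.random.Generator, ann: MtAnnotation) -> pd.DataFrame:
    is_case = (samples["group"] != "control").to_numpy().astype(float)
    age = samples["age"].to_numpy()
    rows = []

    # intermediate class: nonsyn and other channels with their own case effects
    pools = _position_pools(0)
    probs = _substitution_probs(cfg)
    # expected non-synonymous share of a signature draw (exact, from the pools)
    s_num = s_den = 0.0
    for (ref, alt), pr in probs.items():
        for arc in ("minor", "major"):
            p, flags = pools[(ref, alt)][arc]
            w_arc = len(p) * (cfg.major_arc_enrichment
                              if (ref, alt) in _FAVORED and arc == "major" else 1.0)
            tot = sum(len(pools[(ref, alt)][a][0])
                      * (cfg.major_arc_enrichment
                         if (ref, alt) in _FAVORED and a == "major" else 1.0)
                      for a in ("minor", "major"))
            if tot == 0:
                continue
            frac = flags.mean() if len(flags) else 0.0
            s_num += pr * (w_arc / tot) * frac
            s_den += pr * (w_arc / tot)
    share_nonsyn = s_num / s_den if s_den else 0.0

    alpha_i = cfg.dispersion_intermediate
    frailty = (rng.gamma(1 / alpha_i, alpha_i, size=len(samples))
               if alpha_i > 0 else np.ones(len(samples)))
    somatic_mean = (1 - cfg.shared_het_fraction) * cfg.mean_intermediate
    channels = [
        ("nonsyn", share_nonsyn * somatic_mean, cfg.case_effect_nonsyn),
        ("other", (1 - share_nonsyn) * somatic_mean, cfg.case_effect_intermediate),
    ]
    lo, hi = 0.10, 0.95
    a, b = cfg.hf_intermediate_beta
    for channel, mean_c, case_eff in channels:
        lp = cfg.intermediate_age_slope * age + case_eff * is_case
        mu = _calibrated_mu(mean_c, lp) * frailty
        counts = rng.poisson(mu)
        total = int(counts.sum())
        if total == 0:
            continue
        pos, ref, alt = _draw_positions(total, cfg, rng, channel=channel)
        hf = lo + (hi - lo) * rng.beta(a, b, size=total)
        sid = np.repeat(samples["sample_id"].to_numpy(), counts)
        rows.append(pd.DataFrame({"sample_id": sid, "pos": pos, "ref": ref,
                                  "alt": alt, "hf": hf}))

    # low class: single channel
    if cfg.somatic_rate_intercept is not None:
        mu = np.exp(cfg.somatic_rate_intercept
                    + cfg.somatic_rate_age_slope * age
                    + cfg.case_effect_low * is_case)
    else:
        lp = cfg.somatic_rate_age_slope * age + cfg.case_effect_low * is_case
        mu = _calibrated_mu(cfg.mean_low, lp)
    counts = _nb_counts(mu, cfg.dispersion_low, rng)
    total = int(counts.sum())
    if total:
        pos, ref, alt = _draw_positions(total, cfg, rng)
        a2, b2 = cfg.hf_low_beta
        hf = 0.05 + 0.05 * rng.beta(a2, b2, size=total)
        sid = np.repeat(samples["sample_id"].to_numpy(), counts)
        rows.append(pd.DataFrame({"sample_id": sid, "pos": pos, "ref": ref,
                                  "alt": alt, "hf": hf}))
    if not rows:
        return pd.DataFrame(columns=["sample_id", "pos", "ref", "alt", "hf", "label"])
    df = pd.concat(rows, ignore_index=True)
    df["label"] = "somatic"
    return df


def _numts(cfg: SimulationConfig, samples: pd.DataFrame,
           rng: np.random.Generator, ann: MtAnnotation):
    genome = ann.genome
    callable_pos = genome.callable_positions()
    pool = callable_pos[~np.isin(callable_pos, list(ann.mask.positions))]
    sites = rng.choice(pool, size=cfg.numt_sites, replace=False)
    levels = rng.uniform(*cfg.numt_hf_range, size=cfg.numt_sites)
    rows = []
    site_rows = []
    for p, level in zip(sites, levels):
        ref = genome.base(int(p))
        alt = _TRANSITION[ref]
        site_rows.append((int(p), ref, alt, float(level)))
        carriers = samples["sample_id"].to_numpy()[rng.random(len(samples))
                                                   < cfg.numt_carrier_rate]
        for sid in carriers:
            hf = float(np.clip(level + rng.normal(0, cfg.numt_hf_jitter), 0.05, 0.94))
            rows.append((sid, int(p), ref, alt, hf))
    df = pd.DataFrame(rows, columns=["sample_id", "pos", "ref", "alt", "hf"])
    df["label"] = "numt"
    sites_df = pd.DataFrame(site_rows, columns=["pos", "ref", "alt", "hf_level"])
    return df, sites_df


def _artifacts(cfg: SimulationConfig, samples: pd.DataFrame,
               rng: np.random.Generator, ann: MtAnnotation) -> pd.DataFrame:
    genome = ann.genome
    mask_pos = np.array(sorted(ann.mask.positions))
    callable_pos = genome.callable_positions()
    rows = []
    for sid in samples["sample_id"]:
        for _ in range(rng.poisson(cfg.artifact_homopolymer_rate)):
            p = int(rng.choice(mask_pos))
            ref = genome.base(p)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rows.append((sid, p, ref, alt, float(rng.uniform(0.05, 0.6)), False))
        for _ in range(rng.poisson(cfg.artifact_strand_rate)):
            p = int(rng.choice(callable_pos))
            ref = genome.base(p)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rows.append((sid, p, ref, alt, float(rng.uniform(0.05, 0.3)), True))
    df = pd.DataFrame(rows, columns=["sample_id", "pos", "ref", "alt", "hf",
                                     "strand_biased"])
    df["label"] = "artifact"
    return df


def _attach_depths(calls: pd.DataFrame, samples: pd.DataFrame,
                   cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    mean_depth = samples.set_index("sample_id")["mean_depth"]
    md = calls["sample_id"].map(mean_depth).to_numpy()
    depth = np.maximum(50, np.rint(rng.normal(md, cfg.depth_site_cv * md))).astype(int)
    alt_total = np.clip(np.rint(calls["hf"].to_numpy() * depth), 1, depth).astype(int)
    fwd = rng.binomial(alt_total, 0.5)
    biased = calls.get("strand_biased")
    if biased is not None:
        b = (biased == True).to_numpy()  # noqa: E712 — NaN rows compare False
        one_strand = rng.random(b.sum()) < 0.5
        fwd_b = np.where(one_strand, alt_total[b], 0)
        fwd[b] = fwd_b
    out = calls.drop(columns=["strand_biased"], errors="ignore").copy()
    out["depth"] = depth
    out["alt_fwd"] = fwd
    out["alt_rev"] = alt_total - fwd
    return out


def generate_cohort(config: SimulationConfig | None = None,
                    annotation: MtAnnotation | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort (calls, samples, truth, panels, scores)."""
    cfg = config or SimulationConfig()
    if cfg.n_cases + cfg.n_controls <= 0:
        raise ValueError("cohort must contain at least one sample")
    ann = annotation or load_annotation()
    streams = np.random.SeedSequence(cfg.seed).spawn(9)
    rngs = [np.random.default_rng(s) for s in streams]

    samples = _make_samples(cfg, rngs[0])
    hom = _homoplasmies(cfg, samples, rngs[1], ann)
    shared = _shared_heteroplasmies(cfg, samples, rngs[8], ann)
    som = _somatic(cfg, samples, rngs[2], ann)
    numt, numt_sites = _numts(cfg, samples, rngs[3], ann)
    art = _artifacts(cfg, samples, rngs[4], ann)

    parts = [df for df in (hom, shared, som, numt, art) if len(df)]
    if not parts:
        raise ValueError("configuration generated no calls at all")
    calls = pd.concat(parts, ignore_index=True)
    calls = calls.drop_duplicates(subset=["sample_id", "pos"], keep="first")
    calls = _attach_depths(calls, samples, cfg, rngs[5])
    truth = calls[["sample_id", "pos", "ref", "alt", "label"]].reset_index(drop=True)
    calls = calls[CALL_COLUMNS].reset_index(drop=True)

    cohort = SyntheticCohort(calls=calls, samples=samples, truth=truth,
                             numt_site_table=numt_sites, config=cfg)
    gb, kg, disc = make_panel_afs(cohort, cfg.discordant_fraction,
                                  seed=int(rngs[6].integers(2**31)))
    cohort.panel_genbank, cohort.panel_kg, cohort.discordant_sites = gb, kg, disc
    pc, mp = make_score_tables(cohort, cfg.mutpred_high_fraction,
                               seed=int(rngs[7].integers(2**31)),
                               annotation=ann)
    cohort.phastcons, cohort.mutpred = pc, mp
    return cohort


# ---------------------------------------------------------------------------
# panels and scores

def cohort_allele_frequencies(calls: pd.DataFrame, n_samples: int,
                              homoplasmic_only: bool = True) -> pd.DataFrame:
    """Per-(pos, alt) allele frequency among the cohort's individuals."""
    sel = calls[calls["hf"] > 0.95] if homoplasmic_only else calls
    af = (sel.groupby(["pos", "ref", "alt"])["sample_id"].nunique() / n_samples)
    return af.rename("af").reset_index()


def make_panel_afs(cohort: SyntheticCohort, discordant_fraction: float = 0.0,
                   n_genbank: int = 6593, n_kg: int = 498, seed: int = 0):
    """Two reference-panel AF tables correlated with the cohort's homoplasmy
    frequencies, except at an injected fraction of discordant sites
    (|cohort AF - panel AF| > 0.9) that exercise the concordance filter."""
    rng = np.random.default_rng(seed)
    af = cohort_allele_frequencies(cohort.calls, len(cohort.samples))
    n_poly = len(af)
    eligible = af[af["af"] > 0.92]
    k = min(int(round(discordant_fraction * n_poly)), len(eligible))
    disc_idx = (rng.choice(eligible.index.to_numpy(), size=k, replace=False)
                if k else np.array([], dtype=int))
    panels = []
    for n_panel in (n_genbank, n_kg):
        # multiplicative jitter keeps rank structure across the frequency
        # spectrum (additive noise would swamp the rare-variant tail)
        p = np.clip(af["af"].to_numpy()
                    * np.exp(rng.normal(0, 0.3, size=n_poly)), 0, 1)
        counts = rng.binomial(n_panel, p)
        out = af[["pos", "ref", "alt"]].copy()
        out["af"] = counts / n_panel
        out.loc[out.index.isin(disc_idx), "af"] = 0.0
        panels.append(out)
    discordant = [(int(af.loc[i, "pos"]), str(af.loc[i, "alt"])) for i in disc_idx]
    return panels[0], panels[1], discordant


def make_score_tables(cohort: SyntheticCohort, high_path_fraction: float = 0.15,
                      seed: int = 0, annotation: MtAnnotation | None = None):
    """Per-site conservation surrogate (D-loop drawn lowest) and per-variant
    pathogenicity surrogate for non-synonymous variants, with a configured
    fraction >= 0.7 and a negative association with carrier HF."""
    ann = annotation or load_annotation()
    rng = np.random.default_rng(seed)
    pos = np.arange(1, MT_LENGTH + 1)
    dloop = ann.locus_map["MT-DLOOP"]
    in_dloop = np.array([dloop.contains(int(p)) for p in pos])
    score = np.where(in_dloop, rng.beta(1.5, 8.0, size=MT_LENGTH),
                     rng.beta(6.0, 2.5, size=MT_LENGTH))
    phastcons = pd.DataFrame({"pos": pos, "score": score})

    calls = cohort.calls
    var = (calls.groupby(["pos", "ref", "alt"])["hf"].mean()
           .rename("mean_hf").reset_index())
    is_ns = var.apply(
        lambda r: ann.consequence(int(r["pos"]), r["ref"], r["alt"]) == "non-synonymous",
        axis=1) if len(var) else pd.Series([], dtype=bool)
    ns = var[np.asarray(is_ns, dtype=bool)].reset_index(drop=True)
    f = high_path_fraction
    if f <= 0:
        p_high = np.zeros(len(ns))
    elif f >= 1:
        p_high = np.ones(len(ns))
    else:
        logit = np.log(f / (1 - f)) + cohort.config_tilt() * (0.45 - ns["mean_hf"].to_numpy())
        p_high = 1 / (1 + np.exp(-logit))
    high = rng.random(len(ns)) < p_high
    score = np.where(high, 0.7 + 0.3 * rng.beta(1.5, 2.5, size=len(ns)),
                     0.7 * rng.beta(2.6, 1.6, size=len(ns)))
    mutpred = ns[["pos", "ref", "alt"]].copy()
    mutpred["score"] = score
    return phastcons, mutpred
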