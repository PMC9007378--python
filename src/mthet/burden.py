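"""Heteroplasmy classification and per-individual burden aggregation.

Classes partition the heteroplasmic fraction (HF) axis half-open upward:
low = [0.05, 0.10), intermediate = [0.10, 0.95), homoplasmy = [0.95, 1].
Burdens are counted per sample, per class and per functional category;
sharing spectra and length-normalised per-locus frequencies summarise the
cohort-level variant landscape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reference import INTERGENIC, MtAnnotation

CLASSES = ["low", "intermediate", "homoplasmy"]
CATEGORIES = ["non-synonymous", "synonymous", "tRNA", "rRNA", "D-loop", INTERGENIC]
SHARING_CLASSES = ["singleton", "2-10", ">10"]


def classify_hf(hf: float) -> str:
    """Heteroplasmy class of a single HF value (sub-5% calls are a QC violation)."""
    if not 0.05 <= hf <= 1.0:
        raise ValueError(f"HF {hf} outside [0.05, 1]; sub-5% calls are removed by QC")
    if hf < 0.10:
        return "low"
    if hf < 0.95:
        return "intermediate"
    return "homoplasmy"


def classify_hf_series(hf: pd.Series) -> pd.Series:
    if ((hf < 0.05) | (hf > 1.0)).any():
        raise ValueError("HF values outside [0.05, 1] present; run QC first")
    return pd.Series(
        np.select([hf < 0.10, hf < 0.95], ["low", "intermediate"], "homoplasmy"),
        index=hf.index, dtype="object",
    )


def variant_categories(calls: pd.DataFrame, annotation: MtAnnotation) -> pd.Series:
    """Functional category per call row (distinct variants looked up once)."""
    distinct = calls[["pos", "ref", "alt"]].drop_duplicates()
    cat = {
        (p, r, a): annotation.consequence(int(p), r, a)
        for p, r, a in distinct.itertuples(index=False)
    }
    return pd.Series(
        [cat[(p, r, a)] for p, r, a in zip(calls["pos"], calls["ref"], calls["alt"])],
        index=calls.index, dtype="object",
    )


def individual_burden(calls: pd.DataFrame, samples: pd.DataFrame,
                      annotation: MtAnnotation) -> pd.DataFrame:
    """Per-sample counts of variants by class x functional category.

    Samples without calls appear with all-zero rows. Columns are a MultiIndex
    (class, category); per-class totals are under (class, 'total').
    """
    unknown = set(calls["sample_id"]) - set(samples["sample_id"])
    if unknown:
        raise ValueError(f"calls reference unknown samples: {sorted(unknown)[:5]}")
    index = pd.Index(samples["sample_id"], name="sample_id")
    cols = pd.MultiIndex.from_product([CLASSES, CATEGORIES + ["total"]])
    out = pd.DataFrame(0, index=index, columns=cols)
    if len(calls):
        c = calls.copy()
        c["cls"] = classify_hf_series(c["hf"])
        c["category"] = variant_categories(c, annotation)
        counts = c.groupby(["sample_id", "cls", "category"]).size()
        pivot = counts.unstack(["cls", "category"], fill_value=0).reindex(
            index=index, fill_value=0)
        for col in pivot.columns:
            out[col] = pivot[col]
        for cls in CLASSES:
            out[(cls, "total")] = out[cls][CATEGORIES].sum(axis=1)
    return out


def sharing_spectrum(calls: pd.DataFrame) -> pd.DataFrame:
    """Carrier count, sharing class and mean HF per distinct (pos, alt)."""
    g = calls.groupby(["pos", "alt"])
    out = pd.DataFrame({
        "n_carriers": g["sample_id"].nunique(),
        "mean_hf": g["hf"].mean(),
    }).reset_index()
    out["sharing_class"] = np.select(
        [out["n_carriers"] == 1, out["n_carriers"] <= 10],
        ["singleton", "2-10"], ">10",
    )
    return out


def locus_frequency(calls: pd.DataFrame, annotation: MtAnnotation) -> pd.DataFrame:
    """Distinct variant sites per class per locus, normalised by locus length.

    A site observed in several classes counts once per class; loci that
    overlap both receive the site. The D-loop wraps the origin; the
    intergenic aggregate is a 89 bp region set.
    """
    region_sets = annotation.locus_map.region_sets()
    lengths = {name: len(pos) for name, pos in region_sets.items()}
    c = calls.copy()
    c["cls"] = classify_hf_series(c["hf"])
    distinct = c[["pos", "alt", "cls"]].drop_duplicates()
    rows = []
    for name, positions in region_sets.items():
        pos_set = set(int(p) for p in positions)
        in_region = distinct[distinct["pos"].isin(pos_set)]
        n_by_class = in_region.groupby("cls")["pos"].size()
        for cls in CLASSES:
            rows.append({
                "locus": name,
                "cls": cls,
                "n_sites": int(n_by_class.get(cls, 0)),
                "length": lengths[name],
                "freq_per_bp": n_by_class.get(cls, 0) / lengths[name],
            })
    return pd.DataFrame(rows)
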