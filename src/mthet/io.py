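"""File I/O: calls (TSV / VCF), samples, panels, scores, configs and run reports.

TSV is the primary interchange format; a minimal multi-sample VCF encoding is
supported for interoperability (heteroplasmic fraction in the ``HF`` FORMAT
field, depth in ``DP``, per-strand alt read support in ``SB``). All numeric
outputs keep full precision; one-significant-figure rounding is applied only
in the human-readable report text.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .qc import QCConfig
from .reference import MT_LENGTH
from .simulate import CALL_COLUMNS, SAMPLE_COLUMNS, SimulationConfig


class SchemaError(ValueError):
    """A file does not match the documented schema."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def validate_calls(calls: pd.DataFrame, path="<calls>") -> pd.DataFrame:
    _require_columns(calls, CALL_COLUMNS, path)
    bad_pos = (~calls["pos"].between(1, MT_LENGTH)).sum()
    bad_hf = (~calls["hf"].between(0, 1)).sum()
    bad_strand = (calls["alt_fwd"] + calls["alt_rev"] > calls["depth"]).sum()
    bad_allele = (calls["ref"] == calls["alt"]).sum()
    problems = {"pos outside 1..16569": int(bad_pos),
                "hf outside [0,1]": int(bad_hf),
                "alt reads exceed depth": int(bad_strand),
                "ref == alt": int(bad_allele)}
    problems = {k: v for k, v in problems.items() if v}
    if problems:
        raise SchemaError(f"{path}: invalid records: {problems}")
    return calls


def read_calls(path) -> pd.DataFrame:
    """Read a call table from TSV or VCF (by extension)."""
    path = Path(path)
    if path.suffix == ".vcf":
        return read_calls_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "ref": str, "alt": str})
    if df.empty and list(df.columns):
        df = df.astype({"pos": int, "depth": int, "alt_fwd": int, "alt_rev": int,
                        "hf": float}, errors="ignore")
    return validate_calls(df, path)


def write_calls(calls: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".vcf":
        write_calls_vcf(calls, path)
    else:
        calls[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def write_calls_vcf(calls: pd.DataFrame, path, contig: str = "chrM") -> None:
    """Minimal multi-sample VCF: GT omitted; HF, DP and SB FORMAT fields."""
    header = pysam.VariantHeader()
    header.contigs.add(contig, length=MT_LENGTH)
    header.formats.add("HF", 1, "Float", "Heteroplasmic fraction")
    header.formats.add("DP", 1, "Integer", "Read depth at the site")
    header.formats.add("SB", 2, "Integer", "Alt-supporting reads (fwd, rev)")
    sample_ids = sorted(calls["sample_id"].unique())
    for sid in sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        keyed = calls.set_index(["pos", "ref", "alt"]).sort_index()
        for (pos, ref, alt), sub in keyed.groupby(level=[0, 1, 2]):
            rec = vf.new_record(contig=contig, start=int(pos) - 1,
                                stop=int(pos), alleles=(ref, alt))
            for row in sub.itertuples():
                sid = row.sample_id
                rec.samples[sid]["HF"] = float(row.hf)
                rec.samples[sid]["DP"] = int(row.depth)
                rec.samples[sid]["SB"] = (int(row.alt_fwd), int(row.alt_rev))
            vf.write(rec)


def read_calls_vcf(path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for sid, fmt in rec.samples.items():
                hf = fmt.get("HF")
                if hf is None:
                    continue
                sb = fmt.get("SB") or (0, 0)
                rows.append((sid, rec.pos, rec.ref, rec.alts[0], float(hf),
                             int(fmt.get("DP") or 0), int(sb[0]), int(sb[1])))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return validate_calls(df, path)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(df, ["sample_id", "group", "age", "sex", "mean_depth",
                          "mt_ancestry", "covered_fraction"], path)
    for col in SAMPLE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[SAMPLE_COLUMNS]


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["pos", "ref", "alt", "af"], path)
    return df


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline configuration and run reports

_KNOWN_SECTIONS = {"simulation", "qc", "paths", "seed", "output_dir",
                   "class_boundaries", "region_tests", "signatures", "association"}


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    paths: dict = field(default_factory=dict)
    seed: int = 2022
    output_dir: str = "mthet_out"
    region_tests: dict = field(default_factory=dict)
    signatures: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
        cfg = cls()
        if "simulation" in raw:
            known = {f.name for f in dataclasses.fields(SimulationConfig)}
            extra = set(raw["simulation"]) - known
            if extra:
                raise SchemaError(f"{path}: unknown simulation key(s) {sorted(extra)}")
            sim = {k: (tuple(v) if isinstance(v, list) else v)
                   for k, v in raw["simulation"].items()}
            cfg.simulation = SimulationConfig(**sim)
        if "qc" in raw:
            known = {f.name for f in dataclasses.fields(QCConfig)}
            extra = set(raw["qc"]) - known
            if extra:
                raise SchemaError(f"{path}: unknown qc key(s) {sorted(extra)}")
            cfg.qc = QCConfig(**raw["qc"])
        for key in ("paths", "region_tests", "signatures", "association"):
            if key in raw:
                setattr(cfg, key, raw[key])
        cfg.seed = raw.get("seed", cfg.seed)
        cfg.output_dir = raw.get("output_dir", cfg.output_dir)
        if "seed" in raw:
            cfg.simulation = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        return cfg

    def to_yaml(self, path) -> None:
        data = {
            "simulation": dataclasses.asdict(self.simulation),
            "qc": dataclasses.asdict(self.qc),
            "paths": self.paths,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class RunReport:
    """Machine-readable record of a pipeline run; the text rendering carries
    the same numbers (thresholds additionally echoed at one significant
    figure, full precision retained in the JSON form)."""

    config_echo: dict = field(default_factory=dict)
    seed: int | None = None
    filter_counts: list = field(default_factory=list)
    results: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_text(self) -> str:
        from .association import echo_threshold

        lines = [f"mthet run report (seed={self.seed})"]
        for st in self.filter_counts:
            lines.append(f"  {st['stage']}: {st['n_in']} -> {st['n_out']} "
                         f"(-{st['n_removed']})")
        for name, val in self.results.items():
            if name.endswith("threshold") and isinstance(val, float):
                lines.append(f"  {name}: {val!r} (reported as {echo_threshold(val)})")
            else:
                lines.append(f"  {name}: {val}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return str(obj)
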