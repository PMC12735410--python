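"""Table IO, run configuration and the end-to-end pipeline.

Delimited-text readers with schema validation, a YAML-backed run
configuration, and ``run_pipeline`` binding the stages together:
simulate (optional) → CUE computation → strategy profiling → driver
statistics, with a JSON manifest (versions, seed, config hash, input
checksums) for reproducibility.  All randomness flows from one configured
seed through named substreams, so adding a stage never shifts another
stage's draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .isotope import LabelingSample, compute_cue_table, results_frame
from .simulate import GeneratorConfig, generate, samples_frame
from .stats import FactorGroups, cue_driver_screen, screen_frame
from .strategies import (
    GeneAbundanceTable,
    load_strategy_map,
    profile_samples,
    profiles_frame,
)

logger = logging.getLogger(__name__)

LABELING_COLUMNS = [
    "sample_id", "o_total", "atpct_labeled", "atpct_control",
    "atpct_label_water", "t_hours", "mbc", "dna_content", "respiration",
]

#: Fixed substream indices per stage; append-only so seeds stay stable.
_STAGE_STREAMS = {"simulate": 0, "compute": 1, "profile": 2, "drivers": 3}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from the run seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_STREAMS[stage],))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def read_table(
    path: str | Path,
    schema: Mapping[str, type] | Sequence[str] | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a CSV/TSV with the delimiter sniffed unless given.

    ``schema`` lists required columns, optionally mapping each to a type to
    coerce to.  Missing columns and unparseable numeric cells raise errors
    naming the offending column (and row, counted from 1 after the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, engine="python", comment="#")
    if schema is not None:
        columns = list(schema)
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path.name}: missing required column(s): {missing}")
        if isinstance(schema, Mapping):
            for col, typ in schema.items():
                if typ in (float, int):
                    coerced = pd.to_numeric(df[col], errors="coerce")
                    bad = coerced.isna() & df[col].notna()
                    if bad.any():
                        row = int(bad.idxmax()) + 1
                        raise ValueError(
                            f"{path.name}: unparseable numeric cell at row "
                            f"{row}, column {col!r}: {df[col][bad].iloc[0]!r}"
                        )
                    df[col] = coerced.astype(float)
                else:
                    df[col] = df[col].astype(str)
    return df


def read_labeling_samples(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[LabelingSample]:
    """Read a labeling table into LabelingSample records.

    ``column_map`` renames file columns to the canonical field names
    (canonical -> file column).
    """
    schema = {c: (str if c == "sample_id" else float) for c in LABELING_COLUMNS}
    df = read_table(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in LABELING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing required column(s): {missing}")
    for col, typ in schema.items():
        if typ is float:
            df[col] = pd.to_numeric(df[col])
    return [
        LabelingSample(**{c: row[c] for c in LABELING_COLUMNS})
        for _, row in df.iterrows()
    ]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    outdir: Path
    seed: int = 0
    alpha: float = 0.05
    permutations: int = 999
    trees: int = 5000
    simulate: bool = True
    samples_path: Path | None = None
    genes_path: Path | None = None
    map_path: Path | None = None
    covariates_path: Path | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    group_columns: dict[str, list[str]] = field(default_factory=dict)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not 0 < self.alpha <= 0.5:
            raise ValueError("alpha must be in (0, 0.5]")
        if self.permutations < 99:
            raise ValueError("permutations must be >= 99")
        if not self.simulate:
            for name in ("samples_path", "genes_path", "map_path"):
                if getattr(self, name) is None:
                    raise ValueError(f"{name} required when simulate is off")

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        if outdir is not None:
            raw["outdir"] = outdir
        raw.setdefault("outdir", "soilcue_run")
        for key in ("samples_path", "genes_path", "map_path", "covariates_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(generator=gen, **raw)

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in vars(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute compute → profile → drivers (simulating inputs if asked).

    Writes per-stage CSV outputs plus ``manifest.json`` into
    ``config.outdir`` and returns the manifest.  Inputs on disk are never
    mutated; a failed stage leaves earlier stage outputs in place and
    re-raises.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "soilcue",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "inputs": {},
        "outputs": {},
        "stages": [],
    }

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        data = generate(config.generator, seed=stage_seed(config.seed, "simulate"))
        samples = data.samples
        genes = data.genes
        smap = data.strategy_map
        covariates = data.covariates
        _write_csv(samples_frame(samples), out / "samples.csv")
        genes.to_tsv(out / "genes.tsv")
        _write_csv(smap.to_frame(), out / "yas_map.csv")
        _write_csv(covariates, out / "covariates.csv", index=True)
        _write_csv(data.truth.samples, out / "truth.csv")
        manifest["stages"].append("simulate")
    else:
        samples = read_labeling_samples(config.samples_path, config.column_map)
        covariates = (
            read_table(config.covariates_path).set_index("sample_id")
            if config.covariates_path
            else None
        )
        for key in ("samples_path", "genes_path", "map_path", "covariates_path"):
            p = getattr(config, key)
            if p is not None:
                manifest["inputs"][key] = {"path": str(p), "sha256": _checksum(Path(p))}

    # --- compute ----------------------------------------------------------
    results = compute_cue_table(samples)
    cue_df = results_frame(results)
    _write_csv(cue_df, out / "cue.csv")
    manifest["stages"].append("compute")
    manifest["outputs"]["cue"] = "cue.csv"

    # --- profile ----------------------------------------------------------
    if not config.simulate:
        genes = GeneAbundanceTable.from_tsv(config.genes_path)
        smap = load_strategy_map(config.map_path)
    profiles = profile_samples(genes, smap, normalize=True)
    prof_df = profiles_frame(profiles)
    _write_csv(prof_df, out / "profiles.csv")
    manifest["stages"].append("profile")
    manifest["outputs"]["profiles"] = "profiles.csv"

    # --- drivers ----------------------------------------------------------
    prof_idx = prof_df.set_index("sample_id")
    cue_idx = cue_df.set_index("sample_id")
    sample_ids = [s for s in cue_idx.index if s in prof_idx.index]
    groups: dict[str, pd.DataFrame] = {}
    a_cols = [c for c in prof_idx.columns if c.startswith("class_")]
    groups["ASG"] = prof_idx.loc[sample_ids, a_cols or ["a_labile", "a_stable"]]
    groups["SSG"] = prof_idx.loc[sample_ids, ["s_total"]]
    if covariates is not None:
        cov = covariates.loc[sample_ids]
        if config.group_columns:
            for name, cols in config.group_columns.items():
                groups[name] = cov[cols]
        else:
            cs = [c for c in cov.columns if c.startswith("cs_")]
            se = [c for c in cov.columns if c.startswith("enz_")]
            if cs:
                groups["CS"] = cov[cs]
            if se:
                groups["SE"] = cov[se]
    screen = cue_driver_screen(
        cue_idx.loc[sample_ids, "cue"].to_numpy(), FactorGroups(groups)
    )
    _write_csv(screen_frame(screen), out / "drivers.csv")
    manifest["stages"].append("drivers")
    manifest["outputs"]["drivers"] = "drivers.csv"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
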