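"""Y–A–S life-history trait scoring of metagenomic gene tables.

Microbial communities trade off investment between high Yield (Y), resource
Acquisition (A) and Stress tolerance (S) strategies.  In this pipeline Y is
represented by carbon use efficiency measured independently; this module
scores the A and S components from an annotated gene-abundance table:

* A-strategy genes encode decomposition of soil carbon substrates and are
  split by substrate lability — labile (mono-, di- and polysaccharides,
  hemicellulose, cellulose, amino sugars) versus stable (lipids, chitin,
  lignin);
* S-strategy genes are stress-tolerance markers (sporulation, osmotic
  stress, etc.) with no substrate class.

Matching is exact on gene id (KO or gene symbol).  Abundances default to
relative abundance per sample, since raw counts are sequencing-depth
confounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABILE_CLASSES = frozenset(
    {
        "monosaccharides",
        "disaccharides",
        "polysaccharides",
        "hemicellulose",
        "cellulose",
        "amino_sugars",
    }
)
STABLE_CLASSES = frozenset({"lipids", "chitin", "lignin"})


@dataclass(frozen=True)
class StrategyEntry:
    gene_id: str
    strategy: str  # "A" or "S"
    substrate_class: str
    lability: str  # "labile", "stable" or "not_applicable"


def _derive_lability(strategy: str, substrate_class: str, gene_id: str) -> str:
    if strategy == "S":
        return "not_applicable"
    if strategy == "A":
        if substrate_class in LABILE_CLASSES:
            return "labile"
        if substrate_class in STABLE_CLASSES:
            return "stable"
        raise ValueError(
            f"{gene_id}: unknown substrate class {substrate_class!r} for an "
            f"A-strategy gene (expected one of "
            f"{sorted(LABILE_CLASSES | STABLE_CLASSES)})"
        )
    raise ValueError(f"{gene_id}: strategy must be 'A' or 'S', got {strategy!r}")


class StrategyMap:
    """Validated gene → (strategy, substrate class, lability) assignments."""

    def __init__(self, entries: Mapping[str, StrategyEntry]):
        if not entries:
            raise ValueError("strategy map is empty")
        self.entries = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def __getitem__(self, gene_id: str) -> StrategyEntry:
        return self.entries[gene_id]

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "StrategyMap":
        """Build from (gene_id, strategy, substrate_class) triples."""
        entries: dict[str, StrategyEntry] = {}
        for gene_id, strategy, substrate_class in records:
            entry = StrategyEntry(
                gene_id=gene_id,
                strategy=strategy,
                substrate_class=substrate_class,
                lability=_derive_lability(strategy, substrate_class, gene_id),
            )
            if gene_id in entries and entries[gene_id] != entry:
                raise ValueError(
                    f"duplicate gene_id {gene_id!r} with conflicting assignment"
                )
            entries[gene_id] = entry
        return cls(entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.gene_id, e.strategy, e.substrate_class, e.lability)
                for e in self.entries.values()
            ],
            columns=["gene_id", "strategy", "substrate_class", "lability"],
        )


def load_strategy_map(path: str | Path) -> StrategyMap:
    """Read a delimited strategy map with columns gene_id, strategy, substrate_class."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else None
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    required = {"gene_id", "strategy", "substrate_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"strategy map missing column(s): {sorted(missing)}")
    if df.empty:
        raise ValueError("strategy map file has no rows")
    return StrategyMap.from_records(
        (str(r.gene_id), str(r.strategy).strip(), str(r.substrate_class).strip())
        for r in df.itertuples()
    )


def example_strategy_map() -> StrategyMap:
    """Small illustrative map for demos and synthetic runs.

    Contains the stable-C degradation genes reported as strongly
    CUE-associated in afforested soils — fabB, fabA (lipid decomposition)
    and hpaE, ACO, iorA (lignin decomposition) — plus placeholder labile-C
    and stress-tolerance genes.  Real analyses need a curated user map; the
    published A/S gene catalogs are not reproduced here.
    """
    return StrategyMap.from_records(
        [
            ("fabB", "A", "lipids"),
            ("fabA", "A", "lipids"),
            ("hpaE", "A", "lignin"),
            ("ACO", "A", "lignin"),
            ("iorA", "A", "lignin"),
            ("bglX", "A", "cellulose"),
            ("xynB", "A", "hemicellulose"),
            ("malZ", "A", "disaccharides"),
            ("nagZ", "A", "amino_sugars"),
            ("spo0A", "S", "sporulation"),
            ("otsA", "S", "osmotic_stress"),
            ("katE", "S", "oxidative_stress"),
        ]
    )


class GeneAbundanceTable:
    """Genes × samples non-negative abundance matrix.

    Thin validated wrapper over a DataFrame indexed by gene id with one
    column per sample.
    """

    def __init__(self, abundance: pd.DataFrame, units_tag: str = "counts"):
        if abundance.index.has_duplicates:
            raise ValueError("duplicate gene_ids in abundance table")
        if abundance.columns.has_duplicates:
            raise ValueError("duplicate sample_ids in abundance table")
        values = abundance.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("abundance table contains missing values")
        if (values < 0).any():
            raise ValueError("abundance table contains negative entries")
        self.abundance = abundance.astype(float)
        self.abundance.index.name = "gene_id"
        self.units_tag = units_tag

    @property
    def gene_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @classmethod
    def from_tsv(cls, path: str | Path, units_tag: str = "counts") -> "GeneAbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        return cls(df, units_tag=units_tag)

    def to_tsv(self, path: str | Path) -> None:
        self.abundance.to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class StrategyProfile:
    """Per-sample strategy aggregates; a_total = a_labile + a_stable."""

    sample_id: str
    a_total: float
    a_labile: float
    a_stable: float
    s_total: float
    per_class: dict[str, float]


PROFILE_COLUMNS = ["sample_id", "a_total", "a_labile", "a_stable", "s_total"]


def map_coverage(table: GeneAbundanceTable, smap: StrategyMap) -> dict[str, object]:
    """Which table genes the map covers; used for logging and QC."""
    matched = [g for g in table.gene_ids if g in smap]
    unmatched = [g for g in table.gene_ids if g not in smap]
    return {
        "n_genes": len(table.gene_ids),
        "n_matched": len(matched),
        "unmatched": unmatched,
    }


def profile_samples(
    table: GeneAbundanceTable,
    smap: StrategyMap,
    normalize: bool = True,
) -> list[StrategyProfile]:
    """Aggregate abundance into A/S strategy scores per sample.

    Genes absent from the map are ignored (logged in a coverage summary).
    With ``normalize`` each sum is divided by the sample's total table
    abundance, giving relative-abundance scores.
    """
    cov = map_coverage(table, smap)
    if cov["n_matched"] == 0:
        unmatched = cov["unmatched"][:5]
        raise ValueError(
            "no overlap between table genes and strategy map; first unmatched "
            f"ids: {unmatched}"
        )
    if cov["unmatched"]:
        logger.info(
            "strategy map covers %d/%d genes; %d unmatched",
            cov["n_matched"],
            cov["n_genes"],
            len(cov["unmatched"]),
        )

    ab = table.abundance
    matched = [g for g in table.gene_ids if g in smap]
    profiles: list[StrategyProfile] = []
    for sample_id in table.sample_ids:
        col = ab[sample_id]
        total = float(col.sum())
        a_labile = a_stable = s_total = 0.0
        per_class: dict[str, float] = {}
        for gene in matched:
            entry = smap[gene]
            value = float(col.loc[gene])
            if entry.strategy == "A":
                per_class[entry.substrate_class] = (
                    per_class.get(entry.substrate_class, 0.0) + value
                )
                if entry.lability == "labile":
                    a_labile += value
                else:
                    a_stable += value
            else:
                s_total += value
        if normalize:
            scale = 1.0 / total if total > 0 else 0.0
            a_labile *= scale
            a_stable *= scale
            s_total *= scale
            per_class = {k: v * scale for k, v in per_class.items()}
        profiles.append(
            StrategyProfile(
                sample_id=sample_id,
                a_total=a_labile + a_stable,
                a_labile=a_labile,
                a_stable=a_stable,
                s_total=s_total,
                per_class=per_class,
            )
        )
    return profiles


def profiles_frame(profiles: Iterable[StrategyProfile]) -> pd.DataFrame:
    """StrategyProfile list as a DataFrame (per-class columns appended)."""
    profiles = list(profiles)
    base = pd.DataFrame(
        [{c: getattr(p, c) for c in PROFILE_COLUMNS} for p in profiles],
        columns=PROFILE_COLUMNS,
    )
    classes = sorted({c for p in profiles for c in p.per_class})
    for cls_name in classes:
        base[f"class_{cls_name}"] = [p.per_class.get(cls_name, 0.0) for p in profiles]
    return base
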