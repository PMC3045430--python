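"""On-disk formats: kinetics matrices, gene sets (GMT), results tables.

All tabular artifacts are TSV, UTF-8, '.' decimal separator, with 'NA'
as the missing token; run summaries are JSON.  Kinetics matrices are
gene-rows x time-columns, one file per parameter (TR or RA) per
replicate, or a single long-form file with columns
``gene  replicate  parameter  time  value``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics_core import GeneKinetics, KineticsError, TimeGrid

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"


@dataclass
class KineticsTable:
    """TR and RA matrices (genes x grid times) for one replicate.

    Missing or unparseable observations are NaN; filtering them out is an
    explicit downstream step, not an I/O side effect.
    """

    grid: TimeGrid
    tr: pd.DataFrame
    ra: pd.DataFrame
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        n = len(self.grid)
        for name, df in (("TR", self.tr), ("RA", self.ra)):
            if df.shape[1] != n:
                raise KineticsError(
                    f"{name} matrix has {df.shape[1]} time columns, grid has {n}"
                )
            if df.index.duplicated().any():
                dup = df.index[df.index.duplicated()][0]
                raise KineticsError(f"duplicate gene id {dup!r} in {name} matrix")
        if not self.tr.index.equals(self.ra.index):
            common = self.tr.index.intersection(self.ra.index)
            self.tr = self.tr.loc[common]
            self.ra = self.ra.loc[common]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tr.index)

    def gene(self, gene_id: str) -> GeneKinetics:
        """Extract one complete (no-missing) gene record."""
        tr = self.tr.loc[gene_id].to_numpy(dtype=float)
        ra = self.ra.loc[gene_id].to_numpy(dtype=float)
        return GeneKinetics(gene_id, self.grid, tr, ra)

    def complete_genes(self) -> list[str]:
        """Genes with no missing values and strictly positive RA."""
        ok_tr = ~self.tr.isna().any(axis=1)
        ok_ra = ~self.ra.isna().any(axis=1) & (self.ra > 0).all(axis=1)
        return list(self.tr.index[ok_tr & ok_ra])


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized against a gene universe."""

    sets: dict[str, list[str]]
    universe: list[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for name, members in list(self.sets.items()):
            seen: list[str] = []
            for g in members:
                if g in uni and g not in seen:
                    seen.append(g)
            dropped = len(members) - len(seen)
            if dropped:
                logger.info("set %s: dropped %d gene(s) outside universe", name, dropped)
            if not seen:
                logger.warning("set %s is empty after harmonization", name)
            self.sets[name] = seen


def _parse_matrix(path: str | Path, grid: TimeGrid) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=[NA_TOKEN])
    if df.shape[1] != len(grid):
        raise KineticsError(
            f"{path.name}: {df.shape[1]} time columns do not match grid "
            f"length {len(grid)} (columns: {list(df.columns)})"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise KineticsError(f"{path.name}: duplicate gene id {dup!r}")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = int(num.isna().sum().sum() - df.isna().sum().sum())
    if bad:
        logger.info("%s: %d unparseable cell(s) set to missing", path.name, bad)
    num.columns = [f"t{t:g}" for t in grid.times]
    num.index.name = "gene"
    return num.astype(float)


def read_kinetics(
    tr_path: str | Path,
    ra_path: str | Path,
    grid: TimeGrid,
    replicate_id: int | None = None,
) -> KineticsTable:
    """Read one replicate from a TR matrix file and an RA matrix file."""
    return KineticsTable(grid, _parse_matrix(tr_path, grid), _parse_matrix(ra_path, grid), replicate_id)


def read_kinetics_long(path: str | Path, grid: TimeGrid) -> list[KineticsTable]:
    """Read a long-form kinetics file into one table per replicate.

    Expected columns: gene, replicate, parameter (TR|RA), time, value.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN])
    required = {"gene", "replicate", "parameter", "time", "value"}
    if not required.issubset(df.columns):
        raise KineticsError(
            f"{path.name}: long-form file needs columns {sorted(required)}"
        )
    times = list(grid.times)
    obs_times = sorted(df["time"].unique())
    if obs_times != times:
        raise KineticsError(
            f"{path.name}: file times {obs_times} do not match grid {times}"
        )
    tables = []
    for rep, sub in df.groupby("replicate", sort=True):
        mats = {}
        for param in ("TR", "RA"):
            p = sub[sub["parameter"] == param]
            if p.duplicated(["gene", "time"]).any():
                raise KineticsError(f"{path.name}: duplicate gene/time in replicate {rep}")
            mat = p.pivot(index="gene", columns="time", values="value")
            mat = mat.reindex(columns=times)
            mat.columns = [f"t{t:g}" for t in times]
            mats[param] = mat
        tables.append(KineticsTable(grid, mats["TR"], mats["RA"], int(rep)))
    return tables


def average_replicates(tables: list[KineticsTable]) -> KineticsTable:
    """Per-gene, per-time mean of TR and RA across replicates (NaN-propagating).

    Averaging precedes decay-rate inversion, so one inversion is done per
    gene on the replicate-mean curves rather than per replicate.
    """
    if not tables:
        raise KineticsError("no replicate tables to average")
    grid = tables[0].grid
    genes = tables[0].tr.index
    for t in tables[1:]:
        if t.grid.times != grid.times:
            raise KineticsError("replicate tables on different time grids")
        genes = genes.intersection(t.tr.index)
    tr = sum(t.tr.loc[genes] for t in tables) / len(tables)
    ra = sum(t.ra.loc[genes] for t in tables) / len(tables)
    return KineticsTable(grid, tr, ra, None)


def read_gene_sets(path: str | Path, universe: list[str] | None = None) -> GeneSetCollection:
    """Read GMT-format gene sets (name, description, members...).

    When ``universe`` is omitted it defaults to the union of all member
    genes, mirroring a dataset-defined universe.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise KineticsError(
                    f"{path.name}:{lineno}: malformed GMT line (need >= 2 fields)"
                )
            name, desc, *members = fields
            if name in sets:
                raise KineticsError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            sets[name] = [m for m in members if m]
            descriptions[name] = desc
    if universe is None:
        universe = sorted({g for members in sets.values() for g in members})
    return GeneSetCollection(sets, list(universe), descriptions)


def _format_float(x) -> str:
    if pd.isna(x):
        return NA_TOKEN
    return f"{x:.6g}"


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with deterministic layout.

    Column order follows the DataFrame; floats are serialized to 6
    significant digits so repeated runs are byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(_format_float)
    out.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, lineterminator="\n")


def write_run_summary(summary: dict, path: str | Path) -> None:
    """Write the machine-readable run summary (JSON, sorted keys)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_config(path: str | Path) -> dict:
    """Read a flat YAML config; all keys optional."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise KineticsError(f"{path}: config must be a mapping")
    return cfg
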