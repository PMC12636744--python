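"""Domain tables, on-disk formats and run configuration.

All tables travel as plain TSV.  Abundance tables follow the MetaPhlAn
merged-profile dialect (pipe-delimited lineage in the first column, one
sample per column, values in percent).  Writers prepend ``#``-comment
header lines recording the package version and a configuration hash;
readers skip them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import JoinError, ParseError, ValidationError

__version__ = "0.1.0"

logger = logging.getLogger("vaxbiome")

#: rank prefix letters in lineage order (MetaPhlAn convention)
RANK_PREFIXES = "kpcofgst"

#: human-readable aliases for taxonomy ranks
RANK_ALIASES = {
    "kingdom": "k",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
    "species": "s",
    "sgb": "t",
    "t": "t",
    "s": "s",
}

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(n?\d+|-)$")


# ---------------------------------------------------------------------------
# domain tables
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Sample x taxon relative-abundance matrix in percent scale.

    ``values`` is indexed by sample id with one column per taxon id;
    absence is encoded as exact 0 (never NaN).  ``taxonomy`` maps each
    taxon id to its pipe-delimited lineage string.
    """

    values: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValidationError("duplicate sample ids in abundance table")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate taxon ids in abundance table")
        if v.isna().any().any():
            raise ValidationError("abundance table contains missing entries")
        if (v.values < 0).any():
            raise ValidationError("abundance table contains negative values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.columns)

    def proportions(self) -> pd.DataFrame:
        """Row-normalized proportions (the single percent->proportion hop)."""
        totals = self.values.sum(axis=1)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0][0]
            raise ValidationError(f"sample {bad!r} has zero total abundance")
        return self.values.div(totals, axis=0)


@dataclass
class GeneFamilyTable:
    """Sample x EC-number gene-family abundance matrix (RPK units)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValidationError("duplicate sample ids in gene-family table")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate EC ids in gene-family table")
        if (v.values < 0).any():
            raise ValidationError("gene-family table contains negative values")
        for ec in v.columns:
            if not _EC_RE.match(str(ec)):
                raise ValidationError(f"invalid EC number: {ec!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def ec_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CovariateTable:
    """Per-sample metadata: subject, cohort, age, sex, timepoint, flags."""

    data: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("subject_id", "cohort")

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        """Raise JoinError naming the first sample absent from metadata."""
        known = set(self.data.index)
        for s in sample_ids:
            if s not in known:
                raise JoinError(f"sample {s!r} has no metadata row")

    def require_columns(self, columns: Iterable[str]) -> None:
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")


@dataclass
class CytokinePanel:
    """Stimulated/control analyte concentrations, optionally with paired
    pre-vaccination values.

    All frames are sample x analyte and share index/columns.
    """

    stimulated: pd.DataFrame
    control: pd.DataFrame
    pre_stimulated: pd.DataFrame | None = None
    pre_control: pd.DataFrame | None = None
    assay: str = "multiplex-pbmc"

    def __post_init__(self) -> None:
        frames = [self.stimulated, self.control]
        if (self.pre_stimulated is None) != (self.pre_control is None):
            raise ValidationError("pre_stimulated and pre_control must come together")
        if self.pre_stimulated is not None:
            frames += [self.pre_stimulated, self.pre_control]
        ref = self.stimulated
        for f in frames:
            if not (f.index.equals(ref.index) and f.columns.equals(ref.columns)):
                raise ValidationError("cytokine frames must share samples and analytes")
            if (f.values < 0).any():
                raise ValidationError("cytokine concentrations must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.stimulated.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.stimulated.columns)

    @property
    def has_pre(self) -> bool:
        return self.pre_stimulated is not None


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    """All printed analysis constants in one place, with their defaults."""

    positivity_ratio_threshold: float = 2.0
    ifng_threshold_iu_ml: float = 0.08
    low_frequency_cutoff: float = 0.10
    elispot_median_default: float = 110.0  # spots per 3e5 PBMC
    booster_fold: float = 2.0
    booster_min_titer: float = 20.0  # ug/mL
    control_floor: float = 0.01  # concentration floor for ratios vs zero control
    q_taxa: float = 0.2
    q_genes_single: float = 0.1
    q_genes_meta_strict: float = 0.01
    q_genes_meta: float = 0.1
    toposcore_upper: float = 0.79
    toposcore_lower: float = 0.5
    permutations: int = 999
    rf_trees: int = 1000
    rf_feature_fraction: float = 0.10
    rf_min_samples_leaf: int = 3
    rf_impurity: str = "gini"
    cv_folds: int = 10
    cv_folds_small: int = 5
    cv_repetitions: int = 10
    top_k: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.low_frequency_cutoff < 1:
            raise ValidationError("low_frequency_cutoff must be in (0, 1)")
        for name in ("positivity_ratio_threshold", "ifng_threshold_iu_ml",
                     "booster_fold", "booster_min_titer", "control_floor"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.toposcore_lower < self.toposcore_upper <= 1:
            raise ValidationError("require 0 <= toposcore_lower < toposcore_upper <= 1")

    def hash(self) -> str:
        payload = {f.name: getattr(self, f.name) for f in fields(self)}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def with_options(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


def _header_lines(config: AnalysisConfig | None) -> str:
    h = config.hash() if config is not None else "none"
    return f"# vaxbiome {__version__}\n# config_hash={h}\n"


# ---------------------------------------------------------------------------
# MetaPhlAn-style merged abundance tables
# ---------------------------------------------------------------------------


def read_metaphlan_merged(path: str | Path, level: str = "sgb",
                          renormalize: bool = False) -> AbundanceTable:
    """Read a MetaPhlAn-style merged profile, keeping rows at one rank.

    The requested ``level`` may be a rank name ("species", "sgb", ...) or
    a single prefix letter.  The rank of a row is the prefix of the last
    lineage field, so each input row belongs to exactly one rank.
    """
    want = RANK_ALIASES.get(level.lower())
    if want is None:
        raise ValidationError(f"unknown taxonomy level {level!r}")

    header: list[str] | None = None
    taxa: list[str] = []
    taxonomy: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                # a '#clade_name...' line is a commented header, keep it
                if header is None and stripped.lower().startswith("clade"):
                    line = stripped
                else:
                    continue
            parts = line.split("\t")
            if header is None:
                header = parts
                samples = header[1:]
                dupes = {s for s in samples if samples.count(s) > 1}
                if dupes:
                    raise ParseError(f"duplicate sample columns: {sorted(dupes)}",
                                     line=lineno)
                continue
            clade = parts[0]
            last = clade.split("|")[-1]
            if len(last) < 3 or last[1:3] != "__" or last[0] not in RANK_PREFIXES:
                raise ParseError(f"unknown rank prefix in clade {last!r}", line=lineno)
            if last[0] != want:
                continue
            if len(parts) != len(header):
                raise ParseError(
                    f"expected {len(header)} columns, got {len(parts)}", line=lineno)
            try:
                vals = [float(x) for x in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"non-numeric cell: {exc}", line=lineno) from None
            taxon_id = last[3:]
            taxa.append(taxon_id)
            taxonomy[taxon_id] = clade
            rows.append(vals)

    if header is None:
        raise ParseError("empty file")
    if not rows:
        raise ParseError(f"no rows at requested rank {level!r}")

    values = pd.DataFrame(np.array(rows).T, index=header[1:], columns=taxa)
    totals = values.sum(axis=1)
    off = totals[(totals - 100.0).abs() > 1.0]
    if len(off):
        logger.warning(
            "%d/%d samples do not sum to 100 (unclassified mass?); e.g. %s=%.2f",
            len(off), len(totals), off.index[0], off.iloc[0])
        if renormalize:
            values = values.div(totals, axis=0) * 100.0
    return AbundanceTable(values=values, taxonomy=taxonomy)


def write_metaphlan_merged(table: AbundanceTable, path: str | Path,
                           config: AnalysisConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        fh.write("clade_name\t" + "\t".join(table.sample_ids) + "\n")
        for taxon in table.taxon_ids:
            lineage = table.taxonomy.get(taxon, f"t__{taxon}")
            vals = table.values[taxon].to_numpy()
            fh.write(lineage + "\t" + "\t".join(repr(float(v)) for v in vals) + "\n")


# ---------------------------------------------------------------------------
# plain-TSV tables
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def _write_tsv(df: pd.DataFrame, path: str | Path,
               config: AnalysisConfig | None, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t", index=index)


def read_metadata(path: str | Path) -> CovariateTable:
    df = _read_tsv(path)
    if "sample_id" not in df.columns:
        raise ParseError("metadata is missing the 'sample_id' column")
    return CovariateTable(df.set_index("sample_id"))


def write_metadata(table: CovariateTable, path: str | Path,
                   config: AnalysisConfig | None = None) -> None:
    _write_tsv(table.data.rename_axis("sample_id").reset_index(), path, config,
               index=False)


def read_gene_families(path: str | Path) -> GeneFamilyTable:
    df = _read_tsv(path, index_col=0)
    return GeneFamilyTable(df.T)


def write_gene_families(table: GeneFamilyTable, path: str | Path,
                        config: AnalysisConfig | None = None) -> None:
    _write_tsv(table.values.T.rename_axis("ec_number"), path, config, index=True)


_CYTO_COLS = ("sample_id", "analyte", "stimulated", "control")


def read_cytokines(path: str | Path, assay: str = "multiplex-pbmc") -> CytokinePanel:
    df = _read_tsv(path)
    missing = [c for c in _CYTO_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"cytokine table missing columns: {missing}")

    def pivot(col: str) -> pd.DataFrame:
        return df.pivot(index="sample_id", columns="analyte", values=col)

    stim, ctrl = pivot("stimulated"), pivot("control")
    pre_s = pre_c = None
    if "pre_stimulated" in df.columns and df["pre_stimulated"].notna().all():
        pre_s, pre_c = pivot("pre_stimulated"), pivot("pre_control")
    return CytokinePanel(stimulated=stim, control=ctrl,
                         pre_stimulated=pre_s, pre_control=pre_c, assay=assay)


def write_cytokines(panel: CytokinePanel, path: str | Path,
                    config: AnalysisConfig | None = None) -> None:
    long = panel.stimulated.stack().rename("stimulated").to_frame()
    long["control"] = panel.control.stack()
    if panel.has_pre:
        long["pre_stimulated"] = panel.pre_stimulated.stack()
        long["pre_control"] = panel.pre_control.stack()
    long = long.rename_axis(["sample_id", "analyte"]).reset_index()
    _write_tsv(long, path, config, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)


def write_results(df: pd.DataFrame, path: str | Path,
                  config: AnalysisConfig | None = None,
                  index: bool = False) -> None:
    _write_tsv(df, path, config, index=index)


def read_cluster_assignments(path: str | Path) -> pd.Series:
    df = _read_tsv(path)
    for col in ("sample_id", "cluster"):
        if col not in df.columns:
            raise ParseError(f"cluster table missing column {col!r}")
    return df.set_index("sample_id")["cluster"].astype(int)


def write_cluster_assignments(cluster: pd.Series, path: str | Path,
                              config: AnalysisConfig | None = None) -> None:
    df = cluster.rename("cluster").rename_axis("sample_id").reset_index()
    _write_tsv(df, path, config, index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
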