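"""Normalization of raw probe intensities and restriction to the splicing-gene panel.

The canonical normalization mirrors the standard single-channel microarray
pipeline: raw intensities are thresholded at 1, log2-transformed, optionally
shifted per sample so that a chosen percentile sits at zero, and finally
baselined per probe by subtracting the across-sample median.  Probe-level
rows are collapsed to genes by the arithmetic mean.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LEVELS = ("probe", "gene")
STAGES = ("raw", "normalized")


@dataclass
class ExpressionMatrix:
    """An expression matrix (rows = probes or genes, columns = samples).

    ``stage`` tracks whether values are raw intensities (linear scale,
    strictly positive once thresholded) or normalized log2 values.
    """

    values: pd.DataFrame
    level: str = "probe"
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids: {dups[:10]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate column ids: {dups[:10]}")

    @property
    def row_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def column_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.level, self.stage)


@dataclass(frozen=True)
class GenePanel:
    """An a-priori gene panel (e.g. spliceosome / splicing-regulation genes)."""

    gene_ids: frozenset
    source_terms: tuple = ()

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("gene panel must be non-empty")

    @classmethod
    def from_iterable(cls, genes: Iterable, source_terms: Iterable = ()) -> "GenePanel":
        genes = list(genes)
        if len(genes) != len(set(genes)):
            log.warning("gene panel contains duplicate ids; deduplicating")
        return cls(frozenset(genes), tuple(source_terms))

    def __contains__(self, gene) -> bool:
        return gene in self.gene_ids

    def __len__(self) -> int:
        return len(self.gene_ids)


def as_probe_map(probe_map: Mapping | pd.Series) -> pd.Series:
    """Coerce a probe -> gene mapping to a Series, enforcing unique probes."""
    if isinstance(probe_map, pd.Series):
        if probe_map.index.duplicated().any():
            dups = probe_map.index[probe_map.index.duplicated()].unique().tolist()
            raise ValueError(f"probe mapped more than once: {dups[:10]}")
        return probe_map
    return pd.Series(dict(probe_map), dtype=object)


def nearest_rank_percentile(values: np.ndarray, fraction: float) -> float:
    """Nearest-rank percentile: the ceil(fraction * n)-th smallest value."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"percentile fraction must be in (0, 1], got {fraction}")
    ordered = np.sort(np.asarray(values, dtype=float))
    rank = math.ceil(fraction * ordered.size)
    return float(ordered[rank - 1])


def normalize_matrix(
    raw: ExpressionMatrix, percentile_shift: float | None = None
) -> ExpressionMatrix:
    """Threshold at 1, log2-transform, optionally percentile-shift, median-baseline.

    Parameters
    ----------
    raw
        Raw-stage probe intensities.
    percentile_shift
        Optional fraction in (0, 1]; when given, each sample column is
        shifted so that its nearest-rank percentile equals 0 (e.g. 0.75
        for a 75th-percentile shift).  Off by default: the canonical
        path is threshold -> log2 -> per-probe median baseline.
    """
    if raw.stage != "raw":
        raise ValueError("normalize_matrix expects a raw-stage matrix")
    values = raw.values.to_numpy(dtype=float, copy=True)
    if not np.all(np.isfinite(values)):
        raise ValueError("raw matrix contains non-finite entries")
    values = np.log2(np.maximum(values, 1.0))
    if percentile_shift is not None:
        for j in range(values.shape[1]):
            values[:, j] -= nearest_rank_percentile(values[:, j], percentile_shift)
    values -= np.median(values, axis=1, keepdims=True)
    frame = pd.DataFrame(values, index=raw.values.index, columns=raw.values.columns)
    return ExpressionMatrix(frame, level=raw.level, stage="normalized")


def filter_panel(
    matrix: ExpressionMatrix, panel: GenePanel, probe_map: Mapping | pd.Series
) -> ExpressionMatrix:
    """Retain exactly the probes whose mapped gene belongs to the panel.

    Probes absent from the map are dropped (logged).  An empty
    intersection is an error and the diagnostic lists panel genes with
    no matching probe.
    """
    if matrix.level != "probe":
        raise ValueError("filter_panel expects a probe-level matrix")
    pmap = as_probe_map(probe_map)
    unmapped = [p for p in matrix.row_ids if p not in pmap.index]
    if unmapped:
        log.warning("dropping %d probes absent from the probe map", len(unmapped))
    keep = [p for p in matrix.row_ids if p in pmap.index and pmap[p] in panel]
    if not keep:
        covered = set(pmap[pmap.index.isin(matrix.row_ids)])
        missing = sorted(set(panel.gene_ids) - covered)
        raise ValueError(
            "no probes match the gene panel; panel genes without probes: "
            f"{missing[:20]}{'...' if len(missing) > 20 else ''}"
        )
    return ExpressionMatrix(matrix.values.loc[keep], level="probe", stage=matrix.stage)


def collapse_probes(
    matrix: ExpressionMatrix,
    probe_map: Mapping | pd.Series,
    on_missing: str = "error",
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to genes by per-sample arithmetic mean.

    Gene row order follows the first appearance of each gene among the
    probe rows.  ``on_missing`` controls probes absent from the map:
    ``"error"`` (default) rejects, ``"drop"`` discards them with a warning.
    """
    if matrix.level != "probe":
        raise ValueError("collapse_probes expects a probe-level matrix")
    if matrix.stage != "normalized":
        raise ValueError("collapse_probes expects a normalized matrix")
    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")
    pmap = as_probe_map(probe_map)
    missing = [p for p in matrix.row_ids if p not in pmap.index]
    if missing:
        if on_missing == "error":
            raise ValueError(f"probes absent from the probe map: {missing[:10]}")
        log.warning("dropping %d unmapped probes before collapsing", len(missing))
    rows = [p for p in matrix.row_ids if p in pmap.index]
    genes = pmap[rows]
    collapsed = matrix.values.loc[rows].groupby(genes.to_numpy(), sort=False).mean()
    collapsed.index.name = matrix.values.index.name
    return ExpressionMatrix(collapsed, level="gene", stage=matrix.stage)
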