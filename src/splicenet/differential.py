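"""Per-gene two-way ANOVA, FDR adjustment, fold-change screening, Venn partitioning.

Each gene is modelled as a two-factor linear model over disease state and
tissue with interaction.  For the unbalanced 2x3 cohort the per-effect sums
of squares are marginal (Type III, sum-to-zero contrast coding): the SS of
an effect is the increase in residual SS when that effect's columns are
dropped from the full model.  Sequential (Type I) SS are available by flag;
the two agree exactly on balanced designs.  All genes share one design
matrix, so the fits are vectorized across the matrix.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import Contrast, STUDY_CONTRASTS, validate_metadata
from .preprocess import ExpressionMatrix

log = logging.getLogger(__name__)

EFFECTS = ("state", "tissue", "interaction")

# Relative scale below which a residual sum of squares counts as zero
# (exact-fit genes): flagged degenerate, p reported at its limiting value.
_DEGENERATE_RTOL = 1e-9


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    return matrix


def _sum_to_zero(labels: pd.Series, levels: Sequence) -> np.ndarray:
    """Sum-to-zero (deviation) coding: len(levels)-1 columns."""
    n = len(labels)
    cols = np.zeros((n, len(levels) - 1))
    arr = labels.to_numpy()
    for j, lev in enumerate(levels[:-1]):
        cols[arr == lev, j] = 1.0
    cols[arr == levels[-1], :] = -1.0
    return cols


def _sse(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each row of Y regressed on X."""
    Q, _ = np.linalg.qr(X)
    resid = Y - (Y @ Q) @ Q.T
    return np.einsum("ij,ij->i", resid, resid)


def two_way_anova(matrix, metadata: pd.DataFrame, ss_type: int = 3) -> pd.DataFrame:
    """Per-gene two-way ANOVA over disease state and tissue with interaction.

    Parameters
    ----------
    matrix
        Gene-level normalized :class:`ExpressionMatrix` (or a plain
        DataFrame, rows = genes, columns = samples).
    metadata
        DataFrame indexed by sample id with ``tissue`` and ``state`` columns
        covering every matrix column.
    ss_type
        3 (default) for marginal sums of squares with sum-to-zero
        contrasts; 1 for sequential SS in the order state, tissue,
        interaction.

    Returns
    -------
    DataFrame indexed by gene with F, raw p and BH-adjusted q per effect,
    the residual degrees of freedom, and a ``degenerate`` flag for genes
    whose residual variance is (numerically) zero; for those the p-value
    is the limiting value (0 when the effect SS is positive, 1 otherwise).
    """
    if ss_type not in (1, 3):
        raise ValueError("ss_type must be 1 or 3")
    frame = _as_frame(matrix)
    validate_metadata(metadata)
    missing = [c for c in frame.columns if c not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:10]}")
    meta = metadata.loc[frame.columns]
    tissue_levels = sorted(meta["tissue"].unique())
    state_levels = sorted(meta["state"].unique())
    a, b = len(tissue_levels), len(state_levels)
    if a < 2 or b < 2:
        raise ValueError("both factors need at least two levels")
    counts = meta.groupby(["tissue", "state"], observed=False).size()
    for t in tissue_levels:
        for s in state_levels:
            if counts.get((t, s), 0) == 0:
                raise ValueError(f"empty factorial cell: ({t!r}, {s!r})")
    n = frame.shape[1]
    df_resid = n - a * b
    if df_resid < 1:
        raise ValueError(f"residual degrees of freedom {df_resid} < 1")

    T = _sum_to_zero(meta["tissue"], tissue_levels)
    S = _sum_to_zero(meta["state"], state_levels)
    TS = np.einsum("ni,nj->nij", T, S).reshape(n, -1)
    one = np.ones((n, 1))
    Y = frame.to_numpy(dtype=float)

    blocks = {"state": S, "tissue": T, "interaction": TS}
    df_effect = {"state": b - 1, "tissue": a - 1, "interaction": (a - 1) * (b - 1)}
    full = np.hstack([one, S, T, TS])
    sse_full = _sse(Y, full)

    ss = {}
    if ss_type == 3:
        for eff in EFFECTS:
            reduced = np.hstack([one] + [blocks[e] for e in EFFECTS if e != eff])
            ss[eff] = np.maximum(_sse(Y, reduced) - sse_full, 0.0)
    else:  # sequential, order: state, tissue, interaction
        prev = _sse(Y, one)
        X = one
        for eff in EFFECTS:
            X = np.hstack([X, blocks[eff]])
            cur = _sse(Y, X)
            ss[eff] = np.maximum(prev - cur, 0.0)
            prev = cur

    grand_resid = Y - Y.mean(axis=1, keepdims=True)
    total_ss = np.einsum("ij,ij->i", grand_resid, grand_resid)
    eps = _DEGENERATE_RTOL * np.maximum(total_ss, 1e-12)
    degenerate = sse_full <= eps
    mse = sse_full / df_resid

    out = {}
    for eff in EFFECTS:
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss[eff] / df_effect[eff]) / mse
        p = stats.f.sf(F, df_effect[eff], df_resid)
        # exact-fit genes: report the limiting F and p rather than raising
        F = np.where(degenerate, np.where(ss[eff] > eps, np.inf, 0.0), F)
        p = np.where(degenerate, np.where(ss[eff] > eps, 0.0, 1.0), p)
        out[f"F_{eff}"] = F
        out[f"p_{eff}"] = p
    result = pd.DataFrame(out, index=frame.index)
    for eff in EFFECTS:
        result[f"q_{eff}"] = benjamini_hochberg(result[f"p_{eff}"].to_numpy())
    result["residual_df"] = df_resid
    result["degenerate"] = degenerate
    if degenerate.any():
        log.warning("%d genes have zero residual variance (flagged degenerate)",
                    int(degenerate.sum()))
    cols = [f"{s}_{e}" for e in EFFECTS for s in ("F", "p", "q")]
    return result[cols + ["residual_df", "degenerate"]]


def benjamini_hochberg(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    arr = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-d sequence of p-values")
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def pairwise_fold_changes(
    matrix,
    metadata: pd.DataFrame,
    contrasts: Sequence[Contrast] = STUDY_CONTRASTS,
) -> pd.DataFrame:
    """Per-gene log2 fold changes for each pairwise contrast.

    log2FC is the difference of group means on the log2 scale (group A
    minus group B); the linear fold-change magnitude is ``2**|log2FC|``.
    """
    frame = _as_frame(matrix)
    validate_metadata(metadata)
    meta = metadata.loc[[c for c in frame.columns]]
    records = []
    for con in contrasts:
        cols_a = meta.index[(meta["tissue"] == con.group_a[0]) & (meta["state"] == con.group_a[1])]
        cols_b = meta.index[(meta["tissue"] == con.group_b[0]) & (meta["state"] == con.group_b[1])]
        if len(cols_a) == 0 or len(cols_b) == 0:
            raise ValueError(f"contrast {con.contrast_id!r} references an empty group")
        lfc = frame[cols_a].mean(axis=1) - frame[cols_b].mean(axis=1)
        rec = pd.DataFrame({
            "gene_id": frame.index,
            "contrast_id": con.contrast_id,
            "kind": con.kind,
            "log2_fc": lfc.to_numpy(),
        })
        records.append(rec)
    out = pd.concat(records, ignore_index=True)
    out["linear_fc_magnitude"] = 2.0 ** out["log2_fc"].abs()
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    return out


def select_degs(
    anova: pd.DataFrame,
    pairwise: pd.DataFrame,
    alpha: float = 0.05,
    fc_cut: float = 2.0,
    gating: str = "effect",
) -> pd.DataFrame:
    """Screen pairwise records: adjusted p < alpha and linear |FC| > fc_cut.

    Both thresholds are strict.  ``gating`` chooses which adjusted ANOVA
    p-value makes a gene eligible for a contrast: ``"effect"`` (default)
    requires q_state or q_interaction below alpha for disease-state
    contrasts and q_tissue or q_interaction for tissue contrasts;
    ``"any"`` accepts any of the three effects.

    Returns the pairwise table with a ``passes_threshold`` column.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if fc_cut < 1:
        raise ValueError("fc_cut must be >= 1 (linear scale)")
    if gating not in ("effect", "any"):
        raise ValueError("gating must be 'effect' or 'any'")
    q = anova[["q_state", "q_tissue", "q_interaction"]]
    if gating == "any":
        eligible = {
            "state": (q < alpha).any(axis=1),
            "tissue": (q < alpha).any(axis=1),
        }
    else:
        eligible = {
            "state": (q["q_state"] < alpha) | (q["q_interaction"] < alpha),
            "tissue": (q["q_tissue"] < alpha) | (q["q_interaction"] < alpha),
        }
    out = pairwise.copy()
    gene_ok = np.zeros(len(out), dtype=bool)
    for kind, mask in eligible.items():
        sel = out["kind"] == kind
        gene_ok[sel] = mask.reindex(out.loc[sel, "gene_id"]).fillna(False).to_numpy()
    out["passes_threshold"] = gene_ok & (out["linear_fc_magnitude"] > fc_cut)
    return out


def deg_sets(selected: pd.DataFrame) -> dict[str, set]:
    """Per-contrast DEG sets from a ``select_degs`` table."""
    hits = selected[selected["passes_threshold"]]
    sets = {cid: set() for cid in selected["contrast_id"].unique()}
    for cid, grp in hits.groupby("contrast_id"):
        sets[cid] = set(grp["gene_id"])
    return sets


@dataclass
class VennPartition:
    """Exhaustive disjoint partition of the union of named sets."""

    set_names: tuple[str, ...]
    regions: dict[frozenset, frozenset] = field(default_factory=dict)

    @property
    def counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def region(self, *names) -> frozenset:
        return self.regions.get(frozenset(names), frozenset())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(1, len(self.set_names) + 1):
            for combo in combinations(self.set_names, r):
                key = frozenset(combo)
                members = sorted(self.regions.get(key, frozenset()), key=str)
                rows.append({
                    "region": "&".join(combo),
                    "n_sets": r,
                    "count": len(members),
                    "members": ";".join(str(m) for m in members),
                })
        return pd.DataFrame(rows)


def venn_partition(sets) -> VennPartition:
    """Partition >= 2 named sets into exhaustive, pairwise-disjoint regions.

    ``sets`` is a mapping name -> iterable, or a sequence of (name,
    iterable) pairs (duplicate names rejected).
    """
    if isinstance(sets, Mapping):
        items = list(sets.items())
    else:
        items = [(name, s) for name, s in sets]
    names = [name for name, _ in items]
    if len(names) != len(set(names)):
        raise ValueError("duplicate set names")
    if len(items) < 2:
        raise ValueError("venn_partition needs at least two sets")
    named = {name: set(s) for name, s in items}
    universe = set().union(*named.values())
    regions: dict[frozenset, set] = {}
    for element in universe:
        key = frozenset(name for name, s in named.items() if element in s)
        regions.setdefault(key, set()).add(element)
    return VennPartition(tuple(names), {k: frozenset(v) for k, v in regions.items()})
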