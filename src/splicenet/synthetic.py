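"""Synthetic factorial expression data, scored interactomes, and annotation sets.

The generator emulates the structure of the study cohort — a 2x3 unbalanced
factorial (tissue x disease state) with group sizes 18/13/10 in motor cortex
and 17/13/10 in spinal cord, multi-probe genes, and i.i.d. Gaussian noise on
the log2 scale — with *planted* effects so every downstream stage has a
recoverable ground truth: main/interaction expression shifts, a scale-free
scored interactome with forced hubs, and annotation sets with a planted
enriched term.  All randomness flows from a single integer seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .design import STATES, STUDY_CONTRASTS, TABLE1_GROUP_SIZES, TISSUES
from .enrichment import AnnotationSet
from .network import Interactome
from .preprocess import ExpressionMatrix, GenePanel

EFFECT_KINDS = ("tissue_main", "state_main", "interaction")


@dataclass(frozen=True)
class PlantedEffect:
    """A planted log2 expression shift for one gene.

    ``cell_shift_log2`` maps (tissue, state) cells to log2 shifts added to
    the gene's baseline; missing cells shift by 0.  ``effect_kind`` must be
    consistent with the pattern: tissue_main shifts depend only on tissue,
    state_main only on state, and interaction patterns must retain a
    nonzero residual after removing both (unweighted) margins.
    """

    gene_id: int
    effect_kind: str
    cell_shift_log2: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.effect_kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.effect_kind!r}")
        if not any(abs(v) > 0 for v in self.cell_shift_log2.values()):
            raise ValueError("planted effect must have a nonzero cell shift")

    def shift_grid(self, tissues: Sequence[str], states: Sequence[str]) -> np.ndarray:
        grid = np.zeros((len(tissues), len(states)))
        for (t, s), v in self.cell_shift_log2.items():
            if t not in tissues or s not in states:
                raise ValueError(f"cell ({t!r}, {s!r}) outside the design grid")
            grid[tissues.index(t), states.index(s)] = v
        return grid

    def validate_kind(self, tissues: Sequence[str], states: Sequence[str]) -> None:
        grid = self.shift_grid(tissues, states)
        grand = grid.mean()
        t_marg = grid.mean(axis=1, keepdims=True) - grand
        s_marg = grid.mean(axis=0, keepdims=True) - grand
        resid = grid - grand - t_marg - s_marg
        tol = 1e-12
        if self.effect_kind == "tissue_main":
            if np.abs(s_marg).max() > tol or np.abs(resid).max() > tol:
                raise ValueError("tissue_main shifts must depend only on tissue")
            if np.ptp(grid.mean(axis=1)) <= tol:
                raise ValueError("tissue_main shifts must vary across tissues")
        elif self.effect_kind == "state_main":
            if np.abs(t_marg).max() > tol or np.abs(resid).max() > tol:
                raise ValueError("state_main shifts must depend only on state")
            if np.ptp(grid.mean(axis=0)) <= tol:
                raise ValueError("state_main shifts must vary across states")
        else:
            if np.abs(resid).max() <= tol:
                raise ValueError("interaction shifts must have a nonzero interaction component")


def plant_state_effect(
    gene_id: int, state: str, shift: float, tissues: Sequence[str] = TISSUES
) -> PlantedEffect:
    """A pure disease-state shift applied in every tissue."""
    return PlantedEffect(
        gene_id, "state_main", {(t, state): float(shift) for t in tissues}
    )


def plant_tissue_effect(
    gene_id: int, tissue: str, shift: float, states: Sequence[str] = STATES
) -> PlantedEffect:
    """A pure tissue shift applied in every disease state."""
    return PlantedEffect(
        gene_id, "tissue_main", {(tissue, s): float(shift) for s in states}
    )


def plant_interaction_effect(
    gene_id: int,
    shift: float,
    tissues: Sequence[str] = TISSUES,
    states: Sequence[str] = ("CTRL", "SALS1"),
) -> PlantedEffect:
    """A margin-free interaction: +/-shift in a 2x2 checkerboard of cells."""
    (t0, t1), (s0, s1) = tissues[:2], states[:2]
    return PlantedEffect(
        gene_id,
        "interaction",
        {
            (t0, s0): float(shift),
            (t0, s1): -float(shift),
            (t1, s0): -float(shift),
            (t1, s1): float(shift),
        },
    )


@dataclass
class DesignSpec:
    """Parameters of one synthetic factorial expression dataset."""

    n_genes: int
    probes_per_gene: int | Mapping[int, int] = 1
    group_sizes: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(TABLE1_GROUP_SIZES)
    )
    baseline_log2_mean: float = 8.0
    noise_sd_log2: float = 0.5
    planted_effects: Sequence[PlantedEffect] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be positive")
        tissues = self.tissues
        states = self.states
        for t in tissues:
            for s in states:
                if self.group_sizes.get((t, s), 0) <= 0:
                    raise ValueError(f"empty factorial cell ({t!r}, {s!r})")
        for eff in self.planted_effects:
            if not 0 <= eff.gene_id < self.n_genes:
                raise ValueError(f"planted gene id {eff.gene_id} out of range")
            eff.validate_kind(tissues, states)

    @property
    def tissues(self) -> tuple[str, ...]:
        seen = dict.fromkeys(t for t, _ in self.group_sizes)
        return tuple(seen)

    @property
    def states(self) -> tuple[str, ...]:
        seen = dict.fromkeys(s for _, s in self.group_sizes)
        return tuple(seen)

    def n_probes(self, gene_id: int) -> int:
        if isinstance(self.probes_per_gene, Mapping):
            return int(self.probes_per_gene.get(gene_id, 1))
        return int(self.probes_per_gene)

    def gene_label(self, gene_id: int) -> str:
        width = max(4, len(str(self.n_genes - 1)))
        return f"G{gene_id:0{width}d}"


@dataclass
class ExpressionDataset:
    """A simulated dataset: raw matrix, metadata, probe map, and ground truth."""

    matrix: ExpressionMatrix
    metadata: pd.DataFrame
    probe_map: pd.Series
    truth: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return self.truth.index.tolist()


def simulate_expression(spec: DesignSpec) -> ExpressionDataset:
    """Simulate a raw probe-level expression dataset with known planted truth.

    Probe intensities are ``2 ** (baseline + cell_shift + noise)`` with
    i.i.d. Gaussian log2 noise per probe and sample; probes of one gene
    share the gene's cell means, so mean-collapsing is the matching
    estimator.  The returned truth table carries per-gene DE flags implied
    exactly by the planted effects and the expected log2FC of every study
    contrast whose cells exist in the design grid.
    """
    rng = np.random.default_rng(spec.seed)
    tissues, states = spec.tissues, spec.states

    sample_ids, tissue_col, state_col = [], [], []
    for t in tissues:
        for s in states:
            for i in range(spec.group_sizes[(t, s)]):
                sample_ids.append(f"{t}_{s}_{i + 1:02d}")
                tissue_col.append(t)
                state_col.append(s)
    metadata = pd.DataFrame(
        {"tissue": tissue_col, "state": state_col},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # per-gene (tissue, state) shift grids, effects additive per gene
    shift = {g: np.zeros((len(tissues), len(states))) for g in range(spec.n_genes)}
    kinds: dict[int, set[str]] = {}
    for eff in spec.planted_effects:
        shift[eff.gene_id] += eff.shift_grid(tissues, states)
        kinds.setdefault(eff.gene_id, set()).add(eff.effect_kind)

    cell_index = np.array(
        [(tissues.index(t), states.index(s)) for t, s in zip(tissue_col, state_col)]
    )
    probe_ids, probe_gene, gene_rows = [], [], []
    for g in range(spec.n_genes):
        label = spec.gene_label(g)
        per_sample = shift[g][cell_index[:, 0], cell_index[:, 1]]
        for j in range(spec.n_probes(g)):
            probe_ids.append(f"{label}_p{j + 1}")
            probe_gene.append(label)
            gene_rows.append(per_sample)
    means = spec.baseline_log2_mean + np.vstack(gene_rows)
    noise = rng.normal(0.0, spec.noise_sd_log2, size=means.shape)
    values = np.exp2(means + noise)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                     columns=sample_ids),
        level="probe",
        stage="raw",
    )
    probe_map = pd.Series(probe_gene, index=pd.Index(probe_ids, name="probe_id"),
                          name="gene_id")

    labels = [spec.gene_label(g) for g in range(spec.n_genes)]
    truth = pd.DataFrame(index=pd.Index(labels, name="gene_id"))
    for flag, kind in (
        ("is_tissue_de", "tissue_main"),
        ("is_state_de", "state_main"),
        ("is_interaction_de", "interaction"),
    ):
        truth[flag] = [kind in kinds.get(g, set()) for g in range(spec.n_genes)]
    grid_cells = set(spec.group_sizes)
    for con in STUDY_CONTRASTS:
        if con.group_a in grid_cells and con.group_b in grid_cells:
            ia = (tissues.index(con.group_a[0]), states.index(con.group_a[1]))
            ib = (tissues.index(con.group_b[0]), states.index(con.group_b[1]))
            truth[f"expected_log2fc_{con.contrast_id}"] = [
                shift[g][ia] - shift[g][ib] for g in range(spec.n_genes)
            ]
    return ExpressionDataset(matrix, metadata, probe_map, truth)


def simulate_interactome(
    n_nodes: int,
    edges_per_new_node: int,
    planted_hubs: Sequence[int] = (),
    score_distribution: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> Interactome:
    """Grow a scored scale-free interactome with optional forced hubs.

    The graph is grown by preferential attachment (connected by
    construction); each planted hub then receives extra uniformly chosen
    attachments until its degree reaches mean + 2*SD of the current degree
    distribution, so it classifies as a hub-bottleneck on the unfiltered
    graph.  Every edge carries an i.i.d. score (standard normal unless a
    ``score_distribution(rng, size)`` callable is given).
    """
    if not (n_nodes > edges_per_new_node >= 1):
        raise ValueError("need n_nodes > edges_per_new_node >= 1")
    for h in planted_hubs:
        if not 0 <= h < n_nodes:
            raise ValueError(f"planted hub id {h} out of range")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_nodes, edges_per_new_node,
                                 seed=int(rng.integers(2**31)))
    hubs = list(dict.fromkeys(planted_hubs))
    for _ in range(10 * n_nodes):
        deg = np.array([g.degree(v) for v in range(n_nodes)], dtype=float)
        cutoff = deg.mean() + 2.0 * deg.std(ddof=0)
        pending = [h for h in hubs if g.degree(h) < cutoff]
        if not pending:
            break
        for h in pending:
            candidates = [v for v in range(n_nodes) if v != h and not g.has_edge(h, v)]
            if not candidates:
                continue
            g.add_edge(h, int(rng.choice(candidates)))
    else:
        raise RuntimeError("failed to force planted hubs above the degree cutoff")

    names = list(labels) if labels is not None else [
        f"G{v:0{max(4, len(str(n_nodes - 1)))}d}" for v in range(n_nodes)
    ]
    if len(names) != n_nodes:
        raise ValueError("labels length must equal n_nodes")
    draw = score_distribution or (lambda r, size: r.standard_normal(size))
    edge_list = sorted(tuple(sorted(e)) for e in g.edges())
    scores = np.asarray(draw(rng, len(edge_list)), dtype=float)
    frame = pd.DataFrame(
        {
            "node_a": [names[a] for a, _ in edge_list],
            "node_b": [names[b] for _, b in edge_list],
            "score": scores,
        }
    )
    return Interactome(frame)


def simulate_annotations(
    universe: Sequence[str],
    n_terms: int,
    planted_term: tuple[str, Sequence[str]] | None = None,
    seed: int = 0,
    size_range: tuple[int, int] = (5, 40),
) -> AnnotationSet:
    """Random annotation sets over a universe, with an optional planted term.

    Background terms draw their members uniformly without replacement;
    the planted term keeps its member list exactly as given.  ``n_terms``
    counts the planted term when present.
    """
    universe = list(universe)
    if n_terms < 1:
        raise ValueError("n_terms must be positive")
    rng = np.random.default_rng(seed)
    terms: dict[str, frozenset] = {}
    if planted_term is not None:
        name, members = planted_term
        stray = set(members) - set(universe)
        if stray:
            raise ValueError(f"planted members outside the universe: {sorted(stray)[:5]}")
        terms[name] = frozenset(members)
    lo, hi = size_range
    hi = min(hi, len(universe))
    lo = min(lo, hi)
    i = 0
    while len(terms) < n_terms:
        name = f"T{i:03d}"
        i += 1
        if name in terms:
            continue
        size = int(rng.integers(lo, hi + 1))
        terms[name] = frozenset(rng.choice(universe, size=size, replace=False))
    return AnnotationSet(terms, frozenset(universe))


@dataclass
class StudyBundle:
    """The packaged synthetic study: expression, interactome, annotations, panel."""

    dataset: ExpressionDataset
    interactome: Interactome
    annotations: AnnotationSet
    panel: GenePanel
    planted_hub_genes: tuple[str, ...]
    planted_term: str


def study_design_spec(seed: int = 0, n_genes: int = 400) -> DesignSpec:
    """Default planted design emulating the study's splicing-gene screen.

    Plants 25 genes up 4-fold in SALS1, 25 down 4-fold in SALS2 (pure
    disease-state effects), 10 cortex-up tissue effects, and 15 margin-free
    interactions, against a 400-gene panel measured by two probes each.
    """
    if n_genes < 80:
        raise ValueError("study design needs at least 80 genes")
    effects: list[PlantedEffect] = []
    for g in range(0, 25):
        effects.append(plant_state_effect(g, "SALS1", 2.0))
    for g in range(25, 50):
        effects.append(plant_state_effect(g, "SALS2", -2.0))
    for g in range(50, 60):
        effects.append(plant_tissue_effect(g, "motor_cortex", 1.5))
    for g in range(60, 75):
        effects.append(plant_interaction_effect(g, 1.5))
    return DesignSpec(
        n_genes=n_genes,
        probes_per_gene=2,
        planted_effects=effects,
        seed=seed,
    )


def study_bundle(seed: int = 0, n_genes: int = 400, n_terms: int = 30) -> StudyBundle:
    """Generate the full synthetic study from one seed.

    The planted annotation term contains 80% of the planted disease-state
    DE genes; four planted interactome hubs are spread over DE and null
    genes.  Sub-seeds for the three generators derive deterministically
    from ``seed``.
    """
    state = np.random.SeedSequence(seed).generate_state(3)
    s_expr, s_net, s_ann = (int(x % 2**31) for x in state)
    spec = study_design_spec(seed=s_expr, n_genes=n_genes)
    dataset = simulate_expression(spec)
    genes = dataset.gene_ids
    hub_ids = (0, 25, n_genes // 2, n_genes - 1)
    interactome = simulate_interactome(
        n_nodes=n_genes,
        edges_per_new_node=2,
        planted_hubs=hub_ids,
        seed=s_net,
        labels=genes,
    )
    state_de = [g for g in range(n_genes)
                if dataset.truth["is_state_de"].iloc[g]]
    n_in_term = int(round(0.8 * len(state_de)))
    planted_members = [spec.gene_label(g) for g in state_de[:n_in_term]]
    term_name = "planted_state_deg_term"
    annotations = simulate_annotations(
        genes, n_terms, planted_term=(term_name, planted_members), seed=s_ann
    )
    panel = GenePanel.from_iterable(genes)
    return StudyBundle(
        dataset,
        interactome,
        annotations,
        panel,
        tuple(spec.gene_label(h) for h in hub_ids),
        term_name,
    )
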