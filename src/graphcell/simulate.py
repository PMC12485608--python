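"""Seeded generators for synthetic corpora, knowledge bases and
perturbation/knockout datasets with planted ground truth.

The generative model is a standard negative-binomial expression simulator
with three planted structures that the rest of the package is designed to
exploit:

* **cell-type programs** — disjoint gene blocks whose log-mean expression is
  raised by ``type_log_fc`` in the cell type that activates them;
* **a regulatory network** — planted TF->target edges with signed weights.
  An edge weight ``w`` is defined as the additive log-scale response of the
  target when its TF is knocked out; in the healthy corpus each TF's
  per-cell stochastic activity drives its targets with coupling ``-w``, so a
  gene that drops on knockout is positively co-expressed with its TF and
  co-expression edges are informative about the network;
* **batch effects** — gene-wise multiplicative log-normal factors plus a
  batch library-size shift.

All generators are bit-reproducible from their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .knowledge import (DEFAULT_COEXPR_THRESHOLD, KnowledgeBase,
                        build_coexpression_edges)
from .training import PerturbationCondition, label_knockout_genes
from .vocab import Vocabulary


@dataclass
class SyntheticSpec:
    n_genes: int = 60
    n_cells: int = 400
    n_cell_types: int = 3
    n_batches: int = 2
    n_programs: int = 3
    program_size: int = 10
    batch_effect_sd: float = 0.3
    noise_dispersion: float = 0.3      # NB over-dispersion: var = mu + a mu^2
    n_tfs: int = 6
    targets_per_tf: int = 3
    # TF regulon activity strong enough that network edges dominate the
    # co-expression ranking over program co-membership (verified against a
    # data-level correlation oracle)
    tf_activity_sd: float = 2.0
    type_log_fc: float = 2.0           # natural-log activation of a type's program
    # wide base-mean range + modest library size give realistic sparsity
    # (~25-30% zeros at 60 genes) and dynamic range
    base_log_mean_low: float = float(np.log(0.2))
    base_log_mean_high: float = float(np.log(5.0))
    library_size: float = 300.0
    library_sd: float = 0.25
    d_text: int = 16
    text_noise_sd: float = 0.1
    chrom_block: int = 20              # genes per synthetic chromosome
    network: list | None = None        # [(tf_idx, tg_idx, w)]; generated if None
    seed: int = 0

    def __post_init__(self):
        if self.n_programs * self.program_size > self.n_genes:
            raise ValueError("programs exceed the gene panel")
        need = self.n_programs * self.program_size + self.n_tfs * (1 + self.targets_per_tf)
        if self.network is None and need > self.n_genes:
            raise ValueError("programs plus network need more genes than available")
        if self.targets_per_tf < 1:
            raise ValueError("every planted TF needs at least one target")
        for n in (self.n_genes, self.n_cells, self.n_cell_types, self.n_batches,
                  self.n_programs, self.program_size):
            if n < 1:
                raise ValueError("all counts must be >= 1")

    # ------------------------------------------------------------ structure
    @property
    def gene_symbols(self) -> list:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def make_vocabulary(self) -> Vocabulary:
        return Vocabulary(self.gene_symbols)

    def program_of(self) -> np.ndarray:
        """Program index per gene, -1 for genes outside every program."""
        prog = np.full(self.n_genes, -1, dtype=np.int64)
        for p in range(self.n_programs):
            prog[p * self.program_size:(p + 1) * self.program_size] = p
        return prog

    def planted_network(self) -> list:
        """[(tf_idx, tg_idx, weight)] with weight = knockout response."""
        if self.network is not None:
            return list(self.network)
        rng = np.random.default_rng(self.seed + 101)
        first = self.n_programs * self.program_size
        tfs = np.arange(first, first + self.n_tfs)
        pool = np.arange(first + self.n_tfs,
                         first + self.n_tfs + self.n_tfs * self.targets_per_tf)
        net = []
        for i, tf in enumerate(tfs):
            for j in range(self.targets_per_tf):
                tg = pool[i * self.targets_per_tf + j]
                w = rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
                net.append((int(tf), int(tg), float(w)))
        return net

    def tf_indices(self) -> np.ndarray:
        return np.unique([tf for tf, _, _ in self.planted_network()])


def _base_log_means(spec: SyntheticSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed + 7)
    return rng.uniform(spec.base_log_mean_low, spec.base_log_mean_high, spec.n_genes)


def _type_effects(spec: SyntheticSpec) -> np.ndarray:
    """(n_cell_types, n_genes) log-mean shifts from program activation."""
    prog = spec.program_of()
    eff = np.zeros((spec.n_cell_types, spec.n_genes))
    for t in range(spec.n_cell_types):
        eff[t, prog == (t % spec.n_programs)] = spec.type_log_fc
    return eff


def _sample_counts(spec: SyntheticSpec, lam: np.ndarray, lib: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with per-cell library size.

    ``lam``: (n_cells, n_genes) log relative expression; ``lib``: (n_cells,).
    """
    rel = np.exp(lam)
    mu = rel / rel.sum(axis=1, keepdims=True) * lib[:, None]
    a = spec.noise_dispersion
    if a > 0:
        rate = rng.gamma(1.0 / a, mu * a)
        return rng.poisson(rate).astype(np.float64)
    return rng.poisson(mu).astype(np.float64)


def _cell_log_means(spec: SyntheticSpec, types: np.ndarray,
                    rng: np.random.Generator,
                    network_scale: float = 1.0,
                    silenced_tfs: set | None = None) -> np.ndarray:
    """Latent per-cell log relative expression before batch effects.

    ``silenced_tfs``: TFs whose stochastic activity is switched off (they are
    knocked out, so they no longer drive their targets).
    """
    base = _base_log_means(spec)
    eff = _type_effects(spec)
    lam = base[None, :] + eff[types]
    silenced = silenced_tfs or set()
    # TF activity drives targets with coupling -w (see module docstring)
    eta = {}
    for tf, tg, w in spec.planted_network():
        if tf not in eta:
            eta[tf] = rng.normal(0.0, spec.tf_activity_sd, len(types))
            if tf not in silenced:
                lam[:, tf] += eta[tf]
        if tf not in silenced:
            lam[:, tg] += (-w * network_scale) * eta[tf]
    return lam


def simulate_corpus(spec: SyntheticSpec, seed: int | None = None):
    """Multi-type, multi-batch count corpus with planted structure.

    Returns ``(adata, truth)``: an AnnData with raw counts and obs columns
    ``cell_type`` / ``batch``, and a dict holding the planted network,
    program membership and generator parameters.
    """
    import anndata as ad

    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = spec.n_cells
    types = rng.integers(0, spec.n_cell_types, n)
    batches = rng.integers(0, spec.n_batches, n)

    lam = _cell_log_means(spec, types, rng)
    # batch effects: gene-wise log-normal factor + library shift
    gene_batch = rng.normal(0.0, spec.batch_effect_sd, (spec.n_batches, spec.n_genes))
    lib_shift = np.exp(rng.normal(0.0, spec.batch_effect_sd, spec.n_batches))
    lam = lam + gene_batch[batches]
    lib = spec.library_size * np.exp(rng.normal(0.0, spec.library_sd, n)) * lib_shift[batches]

    counts = _sample_counts(spec, lam, lib, rng)
    obs = pd.DataFrame({"cell_type": pd.Categorical([f"T{t}" for t in types]),
                        "batch": pd.Categorical([f"B{b}" for b in batches])},
                       index=[f"cell{i}" for i in range(n)])
    var = pd.DataFrame(index=spec.gene_symbols)
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    truth = {"network": spec.planted_network(),
             "programs": spec.program_of(),
             "type_effects": _type_effects(spec),
             "base_log_means": _base_log_means(spec),
             "seed": seed}
    return adata, truth


# --------------------------------------------------------------------------
# knowledge base
# --------------------------------------------------------------------------

def simulate_knowledge_base(spec: SyntheticSpec, seed: int | None = None,
                            n_ref: int = 2000,
                            coexpr_threshold: float = DEFAULT_COEXPR_THRESHOLD
                            ) -> KnowledgeBase:
    """Knowledge base whose edges reflect the planted structure.

    TF->TG edges are the planted network; co-expression edges come from a
    large simulated single-type reference thresholded at
    ``coexpr_threshold``; chromosome ranks are assigned in gene-index
    blocks; text vectors are a program one-hot plus Gaussian noise (genes
    outside programs have no description and exercise the no-text flag).
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed + 1)
    vocab = spec.make_vocabulary()
    offs = vocab.gene_ids[0]

    net = spec.planted_network()
    tf_tg = np.array([(offs + tf, offs + tg) for tf, tg, _ in net],
                     dtype=np.int64).reshape(-1, 2)

    # co-expression from a reference corpus without batch structure
    ref_spec = SyntheticSpec(**{**spec.__dict__,
                                "n_cells": n_ref, "n_batches": 1,
                                "batch_effect_sd": 0.0, "network": net})
    ref, _ = simulate_corpus(ref_spec, seed=seed + 2)
    X = np.asarray(ref.X, dtype=np.float64)
    X = np.log1p(X / X.sum(axis=1, keepdims=True) * 1e4)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X.T)
    corr = np.nan_to_num(corr, nan=0.0)
    corr_df = pd.DataFrame(corr, index=spec.gene_symbols, columns=spec.gene_symbols)
    co = build_coexpression_edges(corr_df, threshold=coexpr_threshold)
    coexpr = np.array([(vocab.id_of(a), vocab.id_of(b)) for a, b, _ in co],
                      dtype=np.int64).reshape(-1, 2)
    co_w = np.array([r for _, _, r in co], dtype=np.float64)

    chrom = pd.DataFrame({
        "gene_id": vocab.gene_ids,
        "chrom": [f"chr{i // spec.chrom_block + 1}" for i in range(spec.n_genes)],
        "rank": [i % spec.chrom_block for i in range(spec.n_genes)],
    })

    prog = spec.program_of()
    text = rng.normal(0.0, spec.text_noise_sd, (spec.n_genes, spec.d_text))
    for g in range(spec.n_genes):
        if prog[g] >= 0:
            text[g, prog[g] % spec.d_text] += 1.0
    present = prog >= 0
    text = text * present[:, None]

    return KnowledgeBase(vocab, tf_tg, coexpr, co_w, chrom, text, present)


# --------------------------------------------------------------------------
# perturbation datasets
# --------------------------------------------------------------------------

@dataclass
class PerturbationDataset:
    """Control and per-condition perturbed count matrices plus planted truth.

    ``planted_shift[c, g]`` is the log-scale latent shift applied to gene g
    under condition c (knocked-out genes themselves are forced to zero
    expression and flagged in ``ko_mask`` instead).
    """

    gene_symbols: list
    control_counts: np.ndarray                  # (n0, G)
    conditions: list                            # list[PerturbationCondition]
    condition_counts: dict                      # label -> (n_c, G)
    planted_shift: np.ndarray                   # (C, G)
    ko_mask: np.ndarray                         # (C, G) bool
    spec: SyntheticSpec = field(repr=False, default=None)


def simulate_perturbation_dataset(spec: SyntheticSpec, conditions,
                                  n_cells_per_condition: int = 100,
                                  seed: int | None = None,
                                  network_scale: float = 1.0
                                  ) -> PerturbationDataset:
    """Single-type control plus per-condition perturbed cells.

    Knocking out gene g forces its expression to zero and shifts each
    planted target's log-mean by the edge weight (one-hop propagation);
    multi-gene conditions sum their effects.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed + 3)
    vocab = spec.make_vocabulary()
    offs = vocab.gene_ids[0]
    net = spec.planted_network()
    tf_set = {tf for tf, _, _ in net}
    n, G = n_cells_per_condition, spec.n_genes
    types = np.zeros(n, dtype=np.int64)  # single cell type, no batch structure
    lib = spec.library_size * np.exp(rng.normal(0.0, spec.library_sd, n))

    lam0 = _cell_log_means(spec, types, rng, network_scale=network_scale)
    control = _sample_counts(spec, lam0, lib, rng)

    conds = [c if isinstance(c, PerturbationCondition)
             else PerturbationCondition.from_symbols(vocab, c) for c in conditions]
    shifts = np.zeros((len(conds), G))
    ko_mask = np.zeros((len(conds), G), dtype=bool)
    cond_counts = {}
    for ci, cond in enumerate(conds):
        ko_idx = [gid - offs for gid in cond.perturbed_genes]
        for g in ko_idx:
            if g not in tf_set:
                warnings.warn(f"{vocab.symbol_of(g + offs)} is not a planted TF; "
                              "no downstream effect")
        lam = _cell_log_means(spec, types, rng, network_scale=network_scale,
                              silenced_tfs=set(ko_idx))
        for tf, tg, w in net:
            if tf in ko_idx:
                lam[:, tg] += w * network_scale
                shifts[ci, tg] += w * network_scale
        ko_mask[ci, ko_idx] = True
        counts = _sample_counts(spec, lam, lib, rng)
        counts[:, ko_idx] = 0.0  # knockout: transcript absent
        cond_counts[cond.label] = counts
    return PerturbationDataset(spec.gene_symbols, control, conds, cond_counts,
                               shifts, ko_mask, spec)


# --------------------------------------------------------------------------
# bulk knockout datasets
# --------------------------------------------------------------------------

@dataclass
class BulkKnockoutDataset:
    gene_symbols: list
    conditions: list                     # list[PerturbationCondition]
    before: np.ndarray                   # (C, G) pseudo-bulk CP10k profiles
    after: np.ndarray                    # (C, G)
    labels: np.ndarray                   # (C, G) object, from label_knockout_genes
    ko_mask: np.ndarray                  # (C, G) bool
    mode: str
    realized_changed_fraction: float
    network_scale: float
    spec: SyntheticSpec = field(repr=False, default=None)


def _cp10k(counts: np.ndarray) -> np.ndarray:
    return counts / counts.sum(axis=1, keepdims=True) * 1e4


def _analytic_changed_fraction(spec: SyntheticSpec, conds, scale: float) -> float:
    """Expected changed-gene fraction (knocked-out genes excluded) from the
    analytic CP10k fold changes at a given network scale."""
    vocab = spec.make_vocabulary()
    offs = vocab.gene_ids[0]
    base = _base_log_means(spec) + _type_effects(spec)[0]
    rel = np.exp(base)
    before = rel / rel.sum() * 1e4
    net = spec.planted_network()
    fracs = []
    for cond in conds:
        ko = [g - offs for g in cond.perturbed_genes]
        lam = base.copy()
        for tf, tg, w in net:
            if tf in ko:
                lam[tg] += w * scale
        rel2 = np.exp(lam)
        rel2[ko] = 0.0
        after = rel2 / rel2.sum() * 1e4
        fold = (after + 1) / (before + 1)
        changed = (fold >= 2) | (fold <= 0.5)
        changed[ko] = False
        fracs.append(changed.mean())
    return float(np.mean(fracs))


def simulate_bulk_knockout_dataset(spec: SyntheticSpec, conditions,
                                   imbalance_target: float = 0.04,
                                   mode: str = "3class",
                                   n_cells: int = 200,
                                   seed: int | None = None
                                   ) -> BulkKnockoutDataset:
    """Before/after pseudo-bulk knockout profiles with per-gene class labels.

    The planted effect sizes are rescaled (bisection on the analytic fold
    changes) so the realized changed-gene fraction over non-knocked-out
    genes lands within two percentage points of ``imbalance_target``; labels
    are recomputed from the emitted profiles so they are self-consistent.
    """
    if not 0 < imbalance_target < 0.5:
        raise ValueError("imbalance_target must lie in (0, 0.5)")
    seed = spec.seed if seed is None else seed
    vocab = spec.make_vocabulary()
    conds = [c if isinstance(c, PerturbationCondition)
             else PerturbationCondition.from_symbols(vocab, c) for c in conditions]

    has_effect = any(w != 0 for _, _, w in spec.planted_network())
    scale = 1.0
    if has_effect:
        lo, hi = 1e-3, 20.0
        for _ in range(60):
            scale = 0.5 * (lo + hi)
            f = _analytic_changed_fraction(spec, conds, scale)
            if abs(f - imbalance_target) <= 0.015:
                break
            if f < imbalance_target:
                lo = scale
            else:
                hi = scale

    pdata = simulate_perturbation_dataset(spec, conds, n_cells_per_condition=n_cells,
                                          seed=seed, network_scale=scale)
    before_prof = _cp10k(pdata.control_counts).mean(axis=0)
    C, G = len(conds), spec.n_genes
    before = np.tile(before_prof, (C, 1))
    after = np.stack([_cp10k(pdata.condition_counts[c.label]).mean(axis=0)
                      for c in conds])
    labels = np.stack([label_knockout_genes(before[i], after[i], mode=mode)
                       for i in range(C)])
    non_ko = ~pdata.ko_mask
    realized = float((labels[non_ko] != "nc").mean())
    if has_effect and abs(realized - imbalance_target) > 0.02:
        warnings.warn(f"realized changed fraction {realized:.3f} outside "
                      f"+/-0.02 of target {imbalance_target:.3f}")
    return BulkKnockoutDataset(spec.gene_symbols, conds, before, after, labels,
                               pdata.ko_mask, mode, realized, scale, spec)
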