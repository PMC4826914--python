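"""Synthetic study generator: ortholog alignments, artifacts, networks, covariates.

Every downstream stage of the pipeline (orthology, filtering, the M8-vs-M7
scan, centrality, association statistics) is exercised on data from this
module, with known truth:

* codon alignments for 5- or 6-taxon ortholog groups evolved under M7
  (site omega ~ Beta(p, q)) or M8 (plus an omega_s > 1 class), site-
  independently along a fixed species tree;
* gene-model annotation artifacts: windows in one taxon rewritten so the
  translated region is singleton-rich, the error mode the alignment
  filters are designed to catch;
* scale-free (preferential-attachment) interaction networks with per-edge
  evidence class and confidence score;
* per-gene covariates rank-correlated with network degree via a Gaussian
  copula, and a binary selection status whose log-odds depend on degree
  (beta1 < 0: selection at the network periphery, yeast-like; beta1 > 0:
  at the center, fly-like).

Site omegas are drawn as continuous deviates (not the discretized classes
used in fitting).  Substitution histories are sampled exactly: the number
of candidate jumps on a branch is Poisson with the uniformization rate and
each jump follows the uniformized transition kernel, which reproduces the
matrix-exponential transition probabilities exactly while vectorizing
across sites.  All randomness derives from one integer seed through named
substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .codon_model import mean_rate_coefficients
from .codons import CODON_AA, CODONS, N_CODONS, NON_TS, NON_TV, SYN_TS, SYN_TV
from .msa import Alignment
from .trees import ArrayTree

_STREAMS = {"genes": 1, "errors": 2, "network": 3, "covariates": 4, "labels": 5}


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Deterministic named RNG substream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name], int(index)))
    )


@dataclass
class TrueLabels:
    """Ground truth for one simulated gene family."""

    regime: str
    site_omegas: np.ndarray
    spike_sites: np.ndarray  # bool; True where the site is in the omega_s class
    error_taxon: str | None = None
    error_columns: set[int] = field(default_factory=set)  # 1-based codon columns


@dataclass
class ErrorSpec:
    """Annotation-artifact injection settings (windows of corrupted codons)."""

    n_windows: int = 1
    window_codons: int = 15

    def __post_init__(self):
        if self.n_windows < 0 or self.window_codons < 1:
            raise ValueError("invalid error spec")


@dataclass
class NetworkSpec:
    """Preferential-attachment interactome shape and edge annotations."""

    n_nodes: int = 2000
    m: int = 3
    p_physical: float = 0.85
    p_ltp: float = 0.35
    score_alpha: float = 4.0
    score_beta: float = 2.0

    def __post_init__(self):
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if self.m < 1 or self.m >= self.n_nodes:
            raise ValueError("attachment parameter m must satisfy 1 <= m < n_nodes")


@dataclass
class EffectSpec:
    """Covariate-degree coupling and the degree dependence of selection.

    P(selected) = logistic(beta0 + beta1 * log(degree + 1)); beta0=None
    centers the logistic at the mean log-degree so roughly half the genes
    are selected regardless of beta1.
    """

    beta1: float = 0.0
    beta0: float | None = None
    rho: dict = field(
        default_factory=lambda: {
            "mrna_abundance": 0.4,
            "protein_abundance": 0.4,
            "protein_length": 0.1,
            "publications": 0.55,
            "breadth": 0.2,
        }
    )

    def __post_init__(self):
        for name, r in self.rho.items():
            if abs(r) >= 1:
                raise ValueError(f"rank correlation for {name} must be in (-1, 1)")


# ---------------------------------------------------------------------------
# Sequence simulation


def _draw_site_omegas(regime: str, params: dict, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    if regime == "M7":
        om = rng.beta(params["p"], params["q"], size=n)
        return om, np.zeros(n, dtype=bool)
    if regime == "M8":
        p0, ws = params["p0"], params["omega_s"]
        if ws < 1.0:
            raise ValueError("omega_s must be >= 1")
        spike = rng.random(n) >= p0
        om = np.where(spike, ws, rng.beta(params["p"], params["q"], size=n))
        return om, spike
    raise ValueError(f"unknown regime {regime!r}")


def _expected_omega(regime: str, params: dict) -> float:
    mean_beta = params["p"] / (params["p"] + params["q"])
    if regime == "M7":
        return mean_beta
    return params["p0"] * mean_beta + (1.0 - params["p0"]) * params["omega_s"]


def _evolve_branch(
    states: np.ndarray,
    t_scaled: float,
    omegas: np.ndarray,
    syn_off: np.ndarray,
    non_off: np.ndarray,
    lam: np.ndarray,
    rng,
) -> np.ndarray:
    """Exact CTMC endpoint sampling on one branch via uniformization.

    The jump count per site is Poisson(lam_i * t); each jump moves by the
    uniformized kernel I + Q_i / lam_i.  Marginally this equals sampling
    the child state from expm(Q_i * t) rows.
    """
    out = states.copy()
    n_jumps = rng.poisson(lam * t_scaled)
    pending = np.nonzero(n_jumps > 0)[0]
    while pending.size:
        cur = out[pending]
        rows = syn_off[cur] + omegas[pending, None] * non_off[cur]
        rows /= lam[pending, None]
        cum = np.cumsum(rows, axis=1)
        u = rng.random(pending.size)
        idx = np.sum(u[:, None] >= cum, axis=1)  # 61 -> virtual (self) jump
        moved = idx < N_CODONS
        out[pending[moved]] = idx[moved]
        n_jumps[pending] -= 1
        pending = pending[n_jumps[pending] > 0]
    return out


def simulate_gene_family(
    tree: ArrayTree,
    n_codons: int,
    regime: str,
    params: dict,
    seed,
    *,
    kappa: float = 2.0,
    pi: np.ndarray | None = None,
) -> tuple[Alignment, TrueLabels]:
    """Simulate one gapless codon alignment under M7 or M8.

    Branch lengths are expected substitutions per codon under the regime's
    omega distribution (the rate matrices are jointly normalized by the
    mixture-expected rate).  `seed` may be an integer or a Generator.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if tree.n_tips < 2:
        raise ValueError("tree must have at least 2 leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = np.full(N_CODONS, 1.0 / N_CODONS) if pi is None else np.asarray(pi, dtype=float)

    omegas, spike = _draw_site_omegas(regime, params, n_codons, rng)
    a, b = mean_rate_coefficients(kappa, pi)
    rho = a + b * _expected_omega(regime, params)

    syn_off = (SYN_TV + kappa * SYN_TS) * pi[None, :]
    non_off = (NON_TV + kappa * NON_TS) * pi[None, :]
    r_syn = syn_off.sum(axis=1)
    r_non = non_off.sum(axis=1)
    lam = (r_syn[None, :] + omegas[:, None] * r_non[None, :]).max(axis=1)

    states = {tree.root: rng.choice(N_CODONS, size=n_codons, p=pi)}
    for parent, child, blen in tree.preorder_edges():
        states[child] = _evolve_branch(
            states[parent], blen / rho, omegas, syn_off, non_off, lam, rng
        )
    seqs = ["".join(CODONS[s] for s in states[i]) for i in range(tree.n_tips)]
    alignment = Alignment(ids=list(tree.tip_labels), seqs=seqs)
    return alignment, TrueLabels(regime=regime, site_omegas=omegas, spike_sites=spike)


def simulate_cohort(config: "SimulationConfig"):
    """Gene families with regimes drawn by `null_fraction`, no network coupling.

    Yields (gene id, Alignment, TrueLabels); a gene evolves under M7 with
    probability null_fraction, else under M8.  Used when selection status
    should be regime-driven rather than tied to network degree.
    """
    tree = config.tree()
    rng = substream(config.seed, "labels")
    for i in range(config.n_genes):
        regime = "M7" if rng.random() < config.null_fraction else "M8"
        params = config.m7_params if regime == "M7" else config.m8_params
        aln, lab = simulate_gene_family(
            tree,
            config.n_codons,
            regime,
            params,
            substream(config.seed, "genes", i),
            kappa=config.kappa,
            pi=config.codon_freqs,
        )
        yield f"g{i:05d}", aln, lab


def inject_annotation_errors(
    alignment: Alignment, error_spec: ErrorSpec, seed, labels: TrueLabels | None = None
) -> tuple[Alignment, TrueLabels]:
    """Corrupt windows of one random taxon so the translation is singleton-rich.

    Every codon in each chosen window is replaced by a random sense codon
    whose amino acid differs from all other taxa at that column, emulating
    a mis-annotated gene model.  Corrupted 1-based codon columns are
    recorded in the returned labels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_codons = alignment.length // 3
    if labels is None:
        labels = TrueLabels(
            regime="?", site_omegas=np.array([]), spike_sites=np.array([], dtype=bool)
        )
    if error_spec.n_windows == 0:
        return alignment, labels
    if error_spec.window_codons > n_codons:
        raise ValueError("error window longer than alignment")

    taxon_idx = int(rng.integers(alignment.n_rows))
    w = error_spec.window_codons
    starts: list[int] = []
    attempts = 0
    while len(starts) < error_spec.n_windows and attempts < 1000:
        s = int(rng.integers(n_codons - w + 1))
        if all(abs(s - s2) >= w for s2 in starts):
            starts.append(s)
        attempts += 1

    rows = [list(s) for s in alignment.seqs]
    columns: set[int] = set(labels.error_columns)
    aa_by_row = [
        [CODON_AA[c] if (c := _codon_index(seq, j)) is not None else None for j in range(n_codons)]
        for seq in alignment.seqs
    ]
    for s in starts:
        for col in range(s, s + w):
            others = {
                aa_by_row[i][col]
                for i in range(alignment.n_rows)
                if i != taxon_idx and aa_by_row[i][col] is not None
            }
            choices = [k for k in range(N_CODONS) if CODON_AA[k] not in others]
            new = int(rng.choice(choices))
            rows[taxon_idx][3 * col : 3 * col + 3] = CODONS[new]
            columns.add(col + 1)
    out = Alignment(ids=list(alignment.ids), seqs=["".join(r) for r in rows])
    labels.error_taxon = alignment.ids[taxon_idx]
    labels.error_columns = columns
    return out, labels


def _codon_index(seq: str, j: int) -> int | None:
    from .codons import CODON_INDEX

    return CODON_INDEX.get(seq[3 * j : 3 * j + 3])


# ---------------------------------------------------------------------------
# Interaction network and covariates


def simulate_network(spec: NetworkSpec, seed) -> nx.Graph:
    """Preferential-attachment interactome seeded from an m-clique.

    Each of the n - m later nodes attaches to m distinct existing nodes
    with probability proportional to degree, giving exactly
    m*(n - m) + C(m, 2) edges and a connected, simple, scale-free graph.
    Edges carry interaction_type, evidence and a 0-1000 confidence score.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, m = spec.n_nodes, spec.m
    ids = [f"g{i:05d}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(ids)
    edges: list[tuple[int, int]] = [(i, j) for i in range(m) for j in range(i + 1, m)]
    repeated: list[int] = [node for e in edges for node in e] or [0]
    for new in range(m, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(repeated[int(rng.integers(len(repeated)))])
        for t in targets:
            edges.append((new, t))
            repeated.extend((new, t))
    for u, v in edges:
        g.add_edge(
            ids[u],
            ids[v],
            interaction_type="physical" if rng.random() < spec.p_physical else "genetic",
            evidence="LTP" if rng.random() < spec.p_ltp else "HTP",
            score=int(round(1000 * rng.beta(spec.score_alpha, spec.score_beta))),
        )
    return g


def _normal_scores(values: np.ndarray, rng) -> np.ndarray:
    """Gaussian copula latent for an observed margin; ties broken at random."""
    n = len(values)
    jitter = rng.random(n) * 1e-9
    order = np.argsort(values + jitter, kind="mergesort")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    return ndtri((ranks - 0.5) / n)


def assign_covariates_and_selection(
    network: nx.Graph, effect_spec: EffectSpec, seed, n_tissues: int = 16, n_replicates: int = 4
) -> pd.DataFrame:
    """Per-gene covariates (copula-correlated with degree) and selection status.

    Marginals: log-normal mRNA and protein abundances, log-normal protein
    length (integer residues), negative-binomial publication counts, and
    per-tissue replicate detection counts in 0..n_replicates tilted by a
    gene-level expression propensity.  Target Spearman correlations with
    degree are induced through a Gaussian copula (rho_pearson =
    2 sin(pi rho_s / 6)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = sorted(network.nodes)
    deg = np.array([network.degree[g] for g in genes], dtype=float)
    z_deg = _normal_scores(deg, rng)

    def coupled_latent(rho_s: float) -> np.ndarray:
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        return r * z_deg + np.sqrt(1.0 - r * r) * rng.standard_normal(len(genes))

    from scipy.stats import lognorm, nbinom, norm

    rho = effect_spec.rho
    u = norm.cdf(coupled_latent(rho.get("mrna_abundance", 0.0)))
    mrna = lognorm.ppf(u, s=1.2, scale=np.exp(3.0))
    u = norm.cdf(coupled_latent(rho.get("protein_abundance", 0.0)))
    prot = lognorm.ppf(u, s=1.4, scale=np.exp(4.0))
    u = norm.cdf(coupled_latent(rho.get("protein_length", 0.0)))
    length = np.maximum(50, np.round(lognorm.ppf(u, s=0.45, scale=420.0))).astype(int)
    u = norm.cdf(coupled_latent(rho.get("publications", 0.0)))
    pubs = nbinom.ppf(u, 1.2, 1.2 / (1.2 + 18.0)).astype(int)

    # Tissue detection counts: propensity latent tilts an exponential-family
    # distribution on {0..n_replicates} per tissue.
    z_breadth = coupled_latent(rho.get("breadth", 0.0))
    ks = np.arange(n_replicates + 1)
    tilts = 1.2 * z_breadth
    logw = tilts[:, None] * (ks[None, :] - n_replicates / 2.0)
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    tissue_counts = np.empty((len(genes), n_tissues), dtype=int)
    for t in range(n_tissues):
        uu = rng.random(len(genes))
        tissue_counts[:, t] = (uu[:, None] >= cum).sum(axis=1)

    log_deg = np.log(deg + 1.0)
    beta0 = effect_spec.beta0
    if beta0 is None:
        beta0 = -effect_spec.beta1 * float(log_deg.mean())
    p_sel = expit(beta0 + effect_spec.beta1 * log_deg)
    selected = rng.random(len(genes)) < p_sel

    df = pd.DataFrame(
        {
            "gene": genes,
            "degree_true": deg.astype(int),
            "selected_true": selected,
            "mrna_abundance": mrna,
            "protein_abundance": prot,
            "protein_length": length,
            "publications": pubs,
        }
    )
    for t in range(n_tissues):
        df[f"tissue_{t + 1:02d}"] = tissue_counts[:, t]
    return df


# ---------------------------------------------------------------------------
# Whole-study configuration


@dataclass
class SimulationConfig:
    """One synthetic study: tree, gene families, artifacts, network, effects."""

    n_genes: int = 300
    n_taxa: int = 5
    tree_newick: str | None = None  # None -> built-in ladder tree
    tree_length: float = 2.0
    n_codons: int = 150
    null_fraction: float = 0.5  # regime mix for network-free cohorts (simulate_cohort)
    m7_params: dict = field(default_factory=lambda: {"p": 2.0, "q": 5.0})
    m8_params: dict = field(
        default_factory=lambda: {"p": 2.0, "q": 5.0, "p0": 0.8, "omega_s": 4.0}
    )
    kappa: float = 2.0
    codon_freqs: np.ndarray | None = None  # None -> equal sense-codon frequencies
    error_fraction: float = 0.1
    error: ErrorSpec = field(default_factory=ErrorSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    effect: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0

    def __post_init__(self):
        for name, v in [("null_fraction", self.null_fraction), ("error_fraction", self.error_fraction)]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.m8_params["omega_s"] < 1.0:
            raise ValueError("omega_s must be >= 1")
        if self.codon_freqs is not None:
            pi = np.asarray(self.codon_freqs, dtype=float)
            if abs(pi.sum() - 1.0) > 1e-9:
                raise ValueError("codon_freqs must sum to 1")

    def tree(self) -> ArrayTree:
        from . import trees

        if self.tree_newick is not None:
            return trees.from_newick(self.tree_newick)
        return trees.default_tree(self.n_taxa, self.tree_length)
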