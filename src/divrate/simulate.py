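"""Seeded generators for dated trees and sequence alignments.

Trees are crown-conditioned (the process starts with 2 lineages at the
crown) and conditioned on an exact extant tip count ``n``, matching the
branching-time convention in which ``x_2`` is the crown age.  For
pure-birth-type models the stage with ``i`` lineages lasts an
exponential waiting time with total rate ``i * lambda_i``, including a
final full waiting time with ``n`` lineages that places the present
strictly after the last branching event.

The two-rate (shift) model has an age-dependent rate, so forward
stage-duration sampling is not directly available (the present is not
known in advance).  It is sampled exactly by the backward
inverse-cumulative-rate construction: going backward from the present,
the stage with ``i`` lineages ends after ``e_i / i`` units of
*transformed* time where ``e_i ~ Exp(1)`` and the transform is the
cumulative rate ``Lambda(age) = int_0^age lambda(u) du``.  For a
constant rate this reduces exactly to the forward scheme.

Alignments are evolved along a tree under HKY85, optionally with
Gamma-distributed among-site rate variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .tree import BranchingTimes, UltrametricTree

__all__ = [
    "TreeSimSpec",
    "SeqSimSpec",
    "simulate_yule",
    "simulate_birth_death",
    "simulate_rate_shift",
    "simulate_ddl_tree",
    "simulate_tree",
    "simulate_alignment",
    "sample_yule_branching_ages",
    "write_standard_fixtures",
]

NUCS = np.array(["A", "C", "G", "T"])


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError(
            "a seed (or an explicit numpy Generator) is required for reproducibility"
        )
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TreeSimSpec:
    """Specification for one simulated tree.

    ``model`` is one of ``yule`` (rate ``lam``), ``birth_death``
    (``lam``, ``mu``), ``yule2rate`` (``r1`` before ``shift_age``,
    ``r2`` after) or ``ddl`` (``r1``, carrying capacity ``k``).
    """

    model: str
    n_tips: int
    lam: float = 0.0
    mu: float = 0.0
    r1: float = 0.0
    r2: float = 0.0
    shift_age: float = 0.0
    k: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.model not in ("yule", "birth_death", "yule2rate", "ddl"):
            raise ValueError(f"unknown tree model: {self.model!r}")
        if self.model == "yule" and not self.lam > 0:
            raise ValueError("yule model needs lam > 0")
        if self.model == "birth_death":
            if not self.lam > 0 or self.mu < 0:
                raise ValueError("birth_death needs lam > 0 and mu >= 0")
            if not self.mu < self.lam:
                raise ValueError("birth_death conditioning needs mu < lam")
        if self.model == "yule2rate":
            if not (self.r1 > 0 and self.r2 > 0 and self.shift_age > 0):
                raise ValueError("yule2rate needs r1, r2, shift_age > 0")
        if self.model == "ddl":
            if not self.r1 > 0 or not self.k > self.n_tips:
                raise ValueError("ddl needs r1 > 0 and k > n_tips")


@dataclass(frozen=True)
class SeqSimSpec:
    """Specification for one simulated alignment evolved along ``tree``."""

    tree: UltrametricTree
    length: int
    kappa: float = 4.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_alpha: float | None = None
    rate_per_unit: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        f = np.asarray(self.base_freqs, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("base_freqs must be non-negative and sum to 1")
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if self.rate_per_unit < 0:
            raise ValueError("rate_per_unit must be >= 0")


# ---------------------------------------------------------------------------
# branching-age samplers
# ---------------------------------------------------------------------------


def sample_yule_branching_ages(
    n_tips: int, lam: float, rng: np.random.Generator
) -> BranchingTimes:
    """Branching ages of a crown-conditioned Yule tree with ``n_tips`` tips.

    Stage durations ``d_i ~ Exp(i * lam)`` for ``i = 2..n``; ages are
    suffix sums.  This is the sampler behind :func:`simulate_yule` and
    the rate-constancy null distribution.
    """
    i = np.arange(2, n_tips + 1)
    d = rng.exponential(1.0 / (i * lam))
    ages = np.cumsum(d[::-1])[::-1]
    return BranchingTimes(n_tips, ages)


def _stage_rate_ages(n_tips, stage_rates, rng) -> BranchingTimes:
    """Ages when the stage with ``i`` lineages has constant rate ``stage_rates[i-2]``."""
    i = np.arange(2, n_tips + 1)
    d = rng.exponential(1.0 / (i * stage_rates))
    ages = np.cumsum(d[::-1])[::-1]
    return BranchingTimes(n_tips, ages)


def _two_rate_ages(n_tips, r1, r2, shift_age, rng) -> BranchingTimes:
    """Backward inverse-Lambda sampling for the two-rate pure birth.

    ``Lambda(a) = r2*a`` for ``a <= s`` and ``r2*s + r1*(a-s)`` above;
    stage ``i`` (backward) advances ``Lambda`` by ``Exp(1)/i``.
    """
    s = shift_age

    def lam_inv(L: float) -> float:
        if L <= r2 * s:
            return L / r2
        return s + (L - r2 * s) / r1

    ages = np.empty(n_tips - 1)
    L = 0.0
    for j, i in enumerate(range(n_tips, 1, -1)):
        L += rng.exponential(1.0) / i
        ages[j] = lam_inv(L)
    return BranchingTimes(n_tips, ages[::-1].copy())


# ---------------------------------------------------------------------------
# tree construction (forward uniform lineage splitting)
# ---------------------------------------------------------------------------


def _tree_from_ages(bt: BranchingTimes, rng: np.random.Generator) -> UltrametricTree:
    """Assemble a labelled topology over given branching ages: at each
    event (oldest first) a uniformly chosen extant lineage splits."""
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = tree.seed_node
    ages = bt.ages  # x_2 .. x_n descending
    # active lineages as (parent_node, start_age)
    active = [(root, ages[0]), (root, ages[0])]
    for age in ages[1:]:
        j = int(rng.integers(len(active)))
        parent, start = active.pop(j)
        node = dendropy.Node()
        parent.add_child(node)
        node.edge.length = start - age
        active.append((node, age))
        active.append((node, age))
    for idx, (parent, start) in enumerate(active, start=1):
        taxon = taxon_namespace.new_taxon(label=f"t{idx}")
        leaf = dendropy.Node(taxon=taxon)
        parent.add_child(leaf)
        leaf.edge.length = start
    return UltrametricTree(tree)


def simulate_yule(spec: TreeSimSpec) -> UltrametricTree:
    """Crown-conditioned constant-rate pure-birth tree with exactly
    ``n_tips`` extant tips."""
    if spec.model != "yule":
        raise ValueError("spec.model must be 'yule'")
    rng = _rng(spec.seed)
    bt = sample_yule_branching_ages(spec.n_tips, spec.lam, rng)
    return _tree_from_ages(bt, rng)


def simulate_rate_shift(spec: TreeSimSpec) -> UltrametricTree:
    """Two-rate pure-birth tree: rate ``r1`` at ages > ``shift_age``,
    ``r2`` at younger ages; conditioned on ``n_tips``."""
    if spec.model != "yule2rate":
        raise ValueError("spec.model must be 'yule2rate'")
    rng = _rng(spec.seed)
    bt = _two_rate_ages(spec.n_tips, spec.r1, spec.r2, spec.shift_age, rng)
    return _tree_from_ages(bt, rng)


def simulate_ddl_tree(spec: TreeSimSpec) -> UltrametricTree:
    """Density-dependent logistic tree: stage rate ``r1 * (1 - i/k)``."""
    if spec.model != "ddl":
        raise ValueError("spec.model must be 'ddl'")
    rng = _rng(spec.seed)
    i = np.arange(2, spec.n_tips + 1)
    rates = spec.r1 * (1.0 - i / spec.k)
    bt = _stage_rate_ages(spec.n_tips, rates, rng)
    return _tree_from_ages(bt, rng)


def simulate_birth_death(
    spec: TreeSimSpec, max_attempts: int = 100_000
) -> UltrametricTree:
    """Forward birth--death simulation, rejection-conditioned on exactly
    ``n_tips`` extant survivors; extinct lineages are pruned and the
    reconstructed (ultrametric) tree returned.

    The present is placed a full ``Exp(n (lam+mu))`` waiting time after
    the extant count first reaches ``n`` (memoryless overshoot; events
    in the overshoot window are ignored -- a documented small-sample
    approximation of exact ``N(present) = n`` conditioning).
    """
    if spec.model != "birth_death":
        raise ValueError("spec.model must be 'birth_death'")
    rng = _rng(spec.seed)
    lam, mu, n = spec.lam, spec.mu, spec.n_tips
    total = lam + mu
    for _attempt in range(max_attempts):
        # forward Gillespie from 2 lineages; each open lineage is
        # (pending dendropy parent node, start time)
        tns = dendropy.TaxonNamespace()
        full = dendropy.Tree(taxon_namespace=tns)
        open_lineages = [(full.seed_node, 0.0), (full.seed_node, 0.0)]
        dead: list[tuple[dendropy.Node, float, float]] = []
        t = 0.0
        while open_lineages:
            m = len(open_lineages)
            if m == n:
                t += rng.exponential(1.0 / (n * total))
                break
            t += rng.exponential(1.0 / (m * total))
            j = int(rng.integers(m))
            parent, start = open_lineages.pop(j)
            if rng.random() < lam / total:  # speciation: close edge, fork
                node = dendropy.Node()
                parent.add_child(node)
                node.edge.length = t - start
                open_lineages.append((node, t))
                open_lineages.append((node, t))
            else:  # extinction: closed leaf short of the present
                dead.append((parent, start, t))
        if len(open_lineages) != n:
            continue
        survivors = []
        for idx, (parent, start) in enumerate(open_lineages, start=1):
            label = f"t{idx}"
            leaf = dendropy.Node(taxon=tns.new_taxon(label=label))
            parent.add_child(leaf)
            leaf.edge.length = t - start
            survivors.append(label)
        for idx, (parent, start, death_t) in enumerate(dead, start=1):
            leaf = dendropy.Node(taxon=tns.new_taxon(label=f"x{idx}"))
            parent.add_child(leaf)
            leaf.edge.length = death_t - start
        # reconstructed tree: drop extinct tips, merge unary nodes
        full.retain_taxa_with_labels(survivors)
        full.suppress_unifurcations()
        while len(full.seed_node.child_nodes()) == 1:
            child = full.seed_node.child_nodes()[0]
            child.parent_node = None
            full.seed_node = child
        full.seed_node.edge.length = None
        return UltrametricTree(full)
    raise RuntimeError(
        f"birth-death rejection sampling failed after {max_attempts} attempts; "
        "lower mu/lam or n_tips"
    )


def simulate_tree(spec: TreeSimSpec) -> UltrametricTree:
    """Dispatch on ``spec.model``."""
    return {
        "yule": simulate_yule,
        "birth_death": simulate_birth_death,
        "yule2rate": simulate_rate_shift,
        "ddl": simulate_ddl_tree,
    }[spec.model](spec)


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------


def hky_rate_matrix(kappa: float, base_freqs) -> np.ndarray:
    """HKY85 rate matrix (order A, C, G, T), normalized to one expected
    substitution per site per unit time at stationarity."""
    pi = np.asarray(base_freqs, dtype=float)
    Q = np.empty((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i_ in range(4):
        for j in range(4):
            if i_ == j:
                continue
            Q[i_, j] = (kappa if (i_, j) in transitions else 1.0) * pi[j]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.sum(pi * np.diag(Q))
    return Q / scale


def simulate_alignment(spec: SeqSimSpec):
    """Evolve sequences along ``spec.tree`` under HKY(+Gamma).

    Branch lengths are in tree time units; per-site expected
    substitutions on a branch of length ``b`` are
    ``rate_per_unit * b * g_s`` where ``g_s`` is the site's Gamma
    multiplier (mean 1) if ``gamma_alpha`` is set.  Returns a
    :class:`divrate.distances.Alignment`.
    """
    from .distances import Alignment

    rng = _rng(spec.seed)
    pi = np.asarray(spec.base_freqs, dtype=float)
    Q = hky_rate_matrix(spec.kappa, pi)
    L = spec.length
    if spec.gamma_alpha is not None:
        site_rates = rng.gamma(spec.gamma_alpha, 1.0 / spec.gamma_alpha, size=L)
    else:
        site_rates = np.ones(L)

    tree = spec.tree._tree
    root_state = rng.choice(4, size=L, p=pi)
    states = {tree.seed_node: root_state}
    labels, rows = [], []
    # eigendecomposition once; per-branch per-site P via eigenvalue scaling
    w, V = np.linalg.eig(Q)
    Vinv = np.linalg.inv(V)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        nu = spec.rate_per_unit * node.edge.length * site_rates  # per-site lengths
        parent_state = states[node.parent_node]
        # P_s = V diag(e^{w nu_s}) Vinv, evaluated rowwise for each site
        E = np.exp(np.outer(nu, w))  # (L, 4)
        rowsel = V[parent_state, :]  # (L, 4)
        probs = np.real(np.einsum("lk,lk,kj->lj", rowsel, E, Vinv))
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(L)
        cdf = np.cumsum(probs, axis=1)
        child_state = (u[:, None] > cdf).sum(axis=1)
        states[node] = child_state
        if node.is_leaf():
            labels.append(node.taxon.label)
            rows.append("".join(NUCS[child_state]))
    return Alignment(labels=labels, rows=rows)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def write_standard_fixtures(out_dir, seed: int = 20260101) -> list[str]:
    """Materialize a small standard test set (Newick + FASTA) with fixed seeds."""
    import os

    from .distances import write_fasta
    from .tree import write_newick

    os.makedirs(out_dir, exist_ok=True)
    written = []
    for n in (10, 20, 50):
        t = simulate_yule(TreeSimSpec("yule", n, lam=0.15, seed=seed + n))
        path = os.path.join(out_dir, f"yule_n{n}.nwk")
        with open(path, "w") as fh:
            fh.write(write_newick(t))
        written.append(path)
    shift = simulate_rate_shift(
        TreeSimSpec("yule2rate", 30, r1=0.5, r2=0.05, shift_age=5.0, seed=seed + 1)
    )
    path = os.path.join(out_dir, "shift_n30.nwk")
    with open(path, "w") as fh:
        fh.write(write_newick(shift))
    written.append(path)
    host = simulate_yule(TreeSimSpec("yule", 12, lam=0.12, seed=seed + 2))
    aln = simulate_alignment(
        SeqSimSpec(
            tree=host,
            length=800,
            kappa=4.0,
            base_freqs=(0.3, 0.2, 0.2, 0.3),
            rate_per_unit=0.005,
            seed=seed + 3,
        )
    )
    path = os.path.join(out_dir, "two_clade_alignment.fasta")
    with open(path, "w") as fh:
        fh.write(write_fasta(aln))
    written.append(path)
    return written
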