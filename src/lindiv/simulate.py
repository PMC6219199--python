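"""Ground-truthed synthetic data: Yule trees, dispersal histories, fixtures.

Everything the pipeline consumes can be generated here with a known truth:
an ultrametric pure-birth (Yule) time tree, a region history simulated as
a continuous-time Markov jump chain along its branches, and per-node
probability vectors that are either the exact one-hot truth or Dirichlet
perturbations of it with controllable sharpness.

The defaults mirror the study system this package targets: ~200 tips,
birth rate 1 /My (root age around 5 My), four regions I–IV with a
continental (region I) root, a slow equal-rates dispersal process, and
posterior-like probability noise.

Randomness is split into independent per-purpose streams (topology,
waiting times, dispersal, Dirichlet noise) spawned from one master seed,
so fixtures stay stable if one stage starts consuming more draws.

The :func:`brute_force_region_counts` oracle counts lineages by the region
of the divergence that founded them (origin lineage in the root's region)
— deliberately the same attribution convention, read from the same
:class:`~lindiv.diversity.Conventions` object, as the estimator, so the
oracle checks the estimator's arithmetic rather than re-litigating the
convention.  :func:`occupancy_region_counts` is the alternative "where do
the lineages actually sit at age t" count, useful for quantifying the
method's approximation bias when lineages move after their founding
divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .asr import CTMCModel
from .diversity import Conventions, DEFAULT_CONVENTIONS
from .regions import DEFAULT_REGIONS, RegionSet, StatePosterior
from .treeio import TimeTree

__all__ = [
    "SimulationConfig",
    "DispersalTruth",
    "simulate_yule",
    "simulate_dispersal",
    "posteriorize",
    "brute_force_region_counts",
    "occupancy_region_counts",
    "make_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_tips: int = 200
    birth_rate: float = 1.0          # /My
    regions: RegionSet = DEFAULT_REGIONS
    dispersal_rate: float = 0.1      # equal-rates q, /My
    root_region: str = "I"
    kappa: float = 50.0              # Dirichlet sharpness; inf = one-hot
    seed: int = 0
    conventions: Conventions = DEFAULT_CONVENTIONS

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if not (self.birth_rate > 0 and np.isfinite(self.birth_rate)):
            raise ValueError("birth_rate must be finite and > 0")
        if self.dispersal_rate < 0 or not np.isfinite(self.dispersal_rate):
            raise ValueError("dispersal_rate must be finite and >= 0")
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0 (np.inf for exact one-hot)")
        self.regions.index(self.root_region)

    def dispersal_model(self) -> CTMCModel:
        return CTMCModel.equal_rates(self.dispersal_rate, self.regions.k)

    def as_dict(self) -> dict:
        return {
            "n_tips": self.n_tips,
            "birth_rate": self.birth_rate,
            "regions": ",".join(self.regions.labels),
            "dispersal_rate": self.dispersal_rate,
            "root_region": self.root_region,
            "kappa": self.kappa,
            "seed": self.seed,
            "include_origin": self.conventions.include_origin,
            "strict_older": self.conventions.strict_older,
            "threshold": self.conventions.threshold,
        }


@dataclass
class DispersalTruth:
    """True node regions plus the full jump record along every branch.

    `node_state` maps node id -> region index; `jumps[child_id]` lists
    ``(age, from_region, to_region)`` events on the branch above `child`,
    ordered from the parent (oldest) downward.
    """

    regions: RegionSet
    node_state: dict[int, int]
    jumps: dict[int, list[tuple[float, int, int]]] = field(default_factory=dict)

    def region_label(self, node: int) -> str:
        return self.regions.labels[self.node_state[node]]


def _streams(seed: int, n: int = 4) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_yule(n_tips: int, birth_rate: float = 1.0,
                  seed: int | np.random.Generator = 0) -> TimeTree:
    """Pure-birth ultrametric tree grown forward until `n_tips` lineages.

    With k extant lineages the next speciation waits Exponential(k·λ); a
    uniformly chosen lineage splits.  After the n-th lineage appears one
    more Exponential(n·λ) interval is drawn and the tree is cut there, so
    the present sits strictly between the last and the (never realized)
    next speciation.  Node ids are re-assigned in preorder by a
    write/parse-free rebuild, matching :func:`lindiv.treeio.parse_tree`.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not (birth_rate > 0 and np.isfinite(birth_rate)):
        raise ValueError("birth rate must be finite and > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # grow with provisional ids; node 0 = root split at forward-time 0
    parent = [-1]
    split_time: list[float | None] = [0.0]  # None for tips
    # each active lineage is represented by the id of the node it descends from
    active_parents = [0, 0]
    t = 0.0
    while len(active_parents) < n_tips:
        k = len(active_parents)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        new_id = len(parent)
        parent.append(active_parents[i])
        split_time.append(t)
        active_parents[i] = new_id
        active_parents.append(new_id)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))

    # materialize tips
    tip_of: list[int] = []
    for p in active_parents:
        new_id = len(parent)
        parent.append(p)
        split_time.append(None)
        tip_of.append(new_id)

    n = len(parent)
    children: list[list[int]] = [[] for _ in range(n)]
    for v in range(1, n):
        children[parent[v]].append(v)

    # renumber in preorder for stable ids
    order: list[int] = []
    stack = [0]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(children[v]))
    remap = {old: new for new, old in enumerate(order)}

    new_parent = np.full(n, -1, dtype=np.int64)
    lengths = np.zeros(n)
    new_children: list[list[int]] = [[] for _ in range(n)]
    tip_labels: dict[int, str] = {}
    times = [st if st is not None else t_end for st in split_time]
    tip_counter = 0
    for old in order:
        new = remap[old]
        if parent[old] >= 0:
            new_parent[new] = remap[parent[old]]
            lengths[new] = times[old] - times[parent[old]]
            new_children[remap[parent[old]]].append(new)
        if split_time[old] is None:
            tip_counter += 1
            tip_labels[new] = f"t{tip_counter}"
    # preorder visiting order already gives children sorted per parent
    return TimeTree(new_parent, lengths, new_children, tip_labels)


def simulate_dispersal(tree: TimeTree, model: CTMCModel,
                       root_state: str | int | np.ndarray | None = None,
                       seed: int | np.random.Generator = 0,
                       regions: RegionSet | None = None) -> DispersalTruth:
    """Simulate the region history down every branch as a CTMC jump chain.

    `root_state` is a region label/index, a prior vector to draw from, or
    None for the model's root prior.  Jump times are recorded as ages.
    """
    if regions is None:
        regions = DEFAULT_REGIONS if model.k == 4 else RegionSet(
            tuple(str(i) for i in range(model.k)))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = model.rate_matrix
    ages = tree.ages()

    if root_state is None:
        s0 = int(rng.choice(model.k, p=model.root_prior))
    elif isinstance(root_state, str):
        s0 = regions.index(root_state)
    elif np.ndim(root_state) == 0:
        s0 = int(root_state)
    else:
        p = np.asarray(root_state, float)
        s0 = int(rng.choice(model.k, p=p / p.sum()))

    state = {tree.root: s0}
    jumps: dict[int, list[tuple[float, int, int]]] = {}
    for v in tree.preorder():
        for c in tree.children(v):
            s = state[v]
            duration = tree.branch_length(c)
            top_age = float(ages[v])
            elapsed = 0.0
            ev: list[tuple[float, int, int]] = []
            while True:
                out_rate = -Q[s, s]
                if out_rate <= 0:
                    break
                elapsed += rng.exponential(1.0 / out_rate)
                if elapsed >= duration:
                    break
                rates = Q[s].copy()
                rates[s] = 0.0
                nxt = int(rng.choice(model.k, p=rates / rates.sum()))
                ev.append((top_age - elapsed, s, nxt))
                s = nxt
            state[c] = s
            if ev:
                jumps[c] = ev
    return DispersalTruth(regions, state, jumps)


def posteriorize(truth: DispersalTruth, kappa: float,
                 seed: int | np.random.Generator = 0,
                 tree: TimeTree | None = None) -> StatePosterior:
    """Posterior-like probability vectors from the one-hot truth.

    Each internal node's vector is drawn from Dirichlet(α) with α = κ on
    the true region and 1 elsewhere (mean mass κ/(κ+K−1) on the truth);
    κ = inf returns exact one-hot vectors.  Tips, when a tree is
    supplied, always get their exact one-hot truth — tip regions are
    observed data, not estimates.
    """
    if not kappa > 0:
        raise ValueError("kappa must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = truth.regions.k
    tips = set(tree.tips) if tree is not None else set()
    probs: dict[int, np.ndarray] = {}
    for node in sorted(truth.node_state):
        s = truth.node_state[node]
        if np.isinf(kappa) or node in tips:
            v = np.zeros(K)
            v[s] = 1.0
        else:
            alpha = np.ones(K)
            alpha[s] = kappa
            v = rng.dirichlet(alpha)
        probs[node] = v
    return StatePosterior(truth.regions, probs, atol=1e-9, renormalize=True)


def brute_force_region_counts(tree: TimeTree, truth: DispersalTruth, t: float,
                              conventions: Conventions = DEFAULT_CONVENTIONS
                              ) -> np.ndarray:
    """Exact integer per-region lineage counts at age `t` (the step-2/3 oracle).

    Each divergence older than `t` founds (out-degree − 1) lineages in the
    divergence's true region; the origin lineage counts in the root's
    region when ``include_origin``.  Plain integer arithmetic, independent
    of the RichnessCurve machinery.
    """
    ages = tree.ages()
    counts = [0] * truth.regions.k
    if conventions.include_origin:
        counts[truth.node_state[tree.root]] += 1
    for v in tree.internal_nodes:
        older = ages[v] > t if conventions.strict_older else ages[v] >= t
        if older:
            counts[truth.node_state[v]] += len(tree.children(v)) - 1
    return np.array(counts)


def occupancy_region_counts(tree: TimeTree, truth: DispersalTruth, t: float
                            ) -> np.ndarray:
    """Per-region counts of where lineages *actually sit* at age `t`.

    Walks every branch crossing age `t` and reads its simulated state at
    that age from the jump record.  Differs from
    :func:`brute_force_region_counts` exactly by the dispersal that
    happened after each lineage's founding divergence; the totals agree.
    """
    ages = tree.ages()
    counts = [0] * truth.regions.k
    if t >= ages[tree.root]:
        counts[truth.node_state[tree.root]] += 1
        return np.array(counts)
    for c in range(tree.n_nodes):
        p = tree.parent(c)
        if p < 0:
            continue
        if ages[c] <= t < ages[p]:
            s = truth.node_state[p]
            for age, _frm, to in truth.jumps.get(c, []):
                if age > t:
                    s = to
                else:
                    break
            counts[s] += 1
    return np.array(counts)


# --------------------------------------------------------------------------
# Fixture files
# --------------------------------------------------------------------------


def _write_text(path: Path, text: str) -> None:
    path.write_text(text, encoding="utf-8")


def make_fixture(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Write a complete, seeded, self-describing input set.

    Files: ``tree.nwk`` (ultrametric Newick), ``tip_regions.tsv`` (tip,
    region), ``node_probs.tsv`` (internal-node probability table),
    ``truth.tsv`` (every node's true region plus its branch jump record)
    and ``config.txt`` (flat key=value echo incl. the seed).  Identical
    config ⇒ byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_topo, rng_disp, rng_post, _ = _streams(config.seed)

    tree = simulate_yule(config.n_tips, config.birth_rate, rng_topo)
    truth = simulate_dispersal(tree, config.dispersal_model(),
                               config.root_region, rng_disp, config.regions)
    post = posteriorize(truth, config.kappa, rng_post, tree)

    paths = {name: out / fn for name, fn in [
        ("tree", "tree.nwk"), ("tips", "tip_regions.tsv"),
        ("probs", "node_probs.tsv"), ("truth", "truth.tsv"),
        ("config", "config.txt")]}

    _write_text(paths["tree"], tree.write_newick() + "\n")

    lines = ["tip\tregion"]
    for v in tree.tips:
        lines.append(f"{tree.label(v)}\t{truth.region_label(v)}")
    _write_text(paths["tips"], "\n".join(lines) + "\n")

    lines = ["node\t" + "\t".join(config.regions.labels)]
    for v in tree.internal_nodes:
        lines.append(str(v) + "\t" + "\t".join(repr(float(x)) for x in post[v]))
    _write_text(paths["probs"], "\n".join(lines) + "\n")

    lines = ["node\tregion\tjumps"]
    for v in range(tree.n_nodes):
        ev = ";".join(f"{age!r}:{f}>{to}" for age, f, to in truth.jumps.get(v, []))
        lines.append(f"{v}\t{truth.region_label(v)}\t{ev}")
    _write_text(paths["truth"], "\n".join(lines) + "\n")

    cfg_lines = [f"{k}={v}" for k, v in config.as_dict().items()]
    _write_text(paths["config"], "\n".join(cfg_lines) + "\n")
    return paths


def simulate_dataset(config: SimulationConfig):
    """In-memory equivalent of :func:`make_fixture`: (tree, truth, posterior)."""
    rng_topo, rng_disp, rng_post, _ = _streams(config.seed)
    tree = simulate_yule(config.n_tips, config.birth_rate, rng_topo)
    truth = simulate_dispersal(tree, config.dispersal_model(),
                               config.root_region, rng_disp, config.regions)
    post = posteriorize(truth, config.kappa, rng_post, tree)
    return tree, truth, post
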