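"""Single-population coalescent simulator under an exponential-expansion model.

The demographic model has four parameters: an ancestral male effective
size ``start_n``, a final size ``end_n``, the time before present when the
expansion ended (``t_end_years``) and the expansion's duration
(``duration_years``).  Backwards in time the population size is

    N(t) = end_n                          0 <= t < t_end
    N(t) = end_n * exp(-beta (t - t_end)) t_end <= t < t_end + duration
    N(t) = start_n                        t >= t_end + duration

with ``beta = ln(end_n / start_n) / duration`` (times in generations), a
forward-time exponential growth from ``start_n`` to ``end_n``.  The
coalescent is the haploid male coalescent: ``N`` counts men and a pair of
lineages coalesces at rate ``1/N`` per generation, so ``k`` lineages merge
at total rate ``C(k,2)/N(t)``.  Waiting times are drawn by closed-form
inversion of the integrated hazard within each epoch, carrying residual
hazard across epoch boundaries; there is no recombination, migration or
selection.

Two consumers share one stream of random coalescent events:
:func:`simulate_genealogy` materialises a single replicate as a
:class:`dendropy.Tree`, while the batch helpers used by the inference
module compute tree summary statistics for hundreds of replicates at once
without building tree objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import dendropy
import numpy as np

__all__ = [
    "ExpansionModel",
    "SimConfig",
    "population_size_at",
    "coalescent_waiting_time",
    "simulate_genealogy",
    "sprinkle_mutations",
    "make_synthetic_observed",
    "batch_statistics",
]

DEFAULT_SEQ_LEN = 8.8e6      # nucleotides of callable Y-chromosome sequence
DEFAULT_MU = 3e-8            # mutations per nucleotide per generation
DEFAULT_GEN_YEARS = 30.0     # years per male generation


@dataclass(frozen=True)
class ExpansionModel:
    """Four-parameter single-expansion demography (sizes in men, times in years)."""

    start_n: float
    end_n: float
    t_end_years: float
    duration_years: float

    def __post_init__(self):
        for name in ("start_n", "end_n", "t_end_years", "duration_years"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.start_n < 1 or self.end_n < 1:
            raise ValueError("population sizes must be >= 1")
        if self.t_end_years < 0 or self.duration_years < 0:
            raise ValueError("times must be non-negative")

    def growth_rate(self, gen_years: float = DEFAULT_GEN_YEARS) -> float:
        """Backward decay rate beta per generation (0 for constant size)."""
        dur_g = self.duration_years / gen_years
        if dur_g == 0.0 or self.start_n == self.end_n:
            return 0.0
        return math.log(self.end_n / self.start_n) / dur_g


@dataclass(frozen=True)
class SimConfig:
    """Biological constants plus sample-size and replication settings."""

    n_tips: int
    seq_len: float = DEFAULT_SEQ_LEN
    mu: float = DEFAULT_MU
    gen_years: float = DEFAULT_GEN_YEARS
    reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("need at least two sampled chromosomes")
        if min(self.seq_len, self.mu, self.gen_years) <= 0:
            raise ValueError("seq_len, mu and gen_years must be positive")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @property
    def snps_per_generation(self) -> float:
        """Expected mutations per generation of branch (mu * seq_len)."""
        return self.mu * self.seq_len

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def population_size_at(
    model: ExpansionModel, t: float, gen_years: float = DEFAULT_GEN_YEARS
) -> float:
    """Male effective size at ``t`` generations before present."""
    if t < 0:
        raise ValueError("time before present must be non-negative")
    te = model.t_end_years / gen_years
    dur = model.duration_years / gen_years
    if t < te:
        return float(model.end_n)
    if t < te + dur:
        beta = model.growth_rate(gen_years)
        return float(model.end_n * math.exp(-beta * (t - te)))
    return float(model.start_n)


def _advance(k, t0, hazard, model, gen_years):
    """Vectorised inverse-hazard step: absolute coalescence times.

    Given ``k`` lineages at times ``t0`` (generations, per replicate) and
    target integrated hazards ``hazard = -ln(u)``, walk the (at most
    three) demographic epochs and return the times at which the next
    coalescence occurs.
    """
    t0 = np.asarray(t0, dtype=float)
    h = np.asarray(hazard, dtype=float).copy()
    C = k * (k - 1) / 2.0
    te = model.t_end_years / gen_years
    tb = te + model.duration_years / gen_years
    beta = model.growth_rate(gen_years)

    a = t0.copy()
    out = np.empty_like(a)
    done = np.zeros(a.shape, dtype=bool)

    # Epoch 1: recent constant size end_n on [0, te)
    m = ~done & (a < te)
    if m.any():
        cap = C * (te - a[m]) / model.end_n
        solve = h[m] <= cap
        idx = np.flatnonzero(m)
        s_idx = idx[solve]
        out[s_idx] = a[s_idx] + h[s_idx] * model.end_n / C
        done[s_idx] = True
        c_idx = idx[~solve]
        h[c_idx] -= cap[~solve]
        a[c_idx] = te

    # Epoch 2: exponential decay from end_n to start_n on [te, tb)
    m = ~done & (a < tb)
    if m.any():
        idx = np.flatnonzero(m)
        if beta == 0.0:
            cap = C * (tb - a[idx]) / model.end_n
            solve = h[idx] <= cap
            s_idx = idx[solve]
            out[s_idx] = a[s_idx] + h[s_idx] * model.end_n / C
            done[s_idx] = True
            c_idx = idx[~solve]
            h[c_idx] -= cap[~solve]
            a[c_idx] = tb
        else:
            x_a = np.exp(beta * (a[idx] - te))
            x_b = model.end_n / model.start_n  # exp(beta * (tb - te))
            cap = C / (model.end_n * beta) * (x_b - x_a)
            solve = h[idx] <= cap
            s_idx = idx[solve]
            out[s_idx] = te + np.log(
                x_a[solve] + h[s_idx] * model.end_n * beta / C
            ) / beta
            done[s_idx] = True
            c_idx = idx[~solve]
            h[c_idx] -= cap[~solve]
            a[c_idx] = tb

    # Epoch 3: ancestral constant size start_n (unbounded)
    m = ~done
    if m.any():
        out[m] = a[m] + h[m] * model.start_n / C
    return out


def coalescent_waiting_time(
    k: int,
    model: ExpansionModel,
    t0: float,
    u: float,
    gen_years: float = DEFAULT_GEN_YEARS,
) -> float:
    """Time increment until the next coalescence of ``k`` lineages.

    Inverts ``integral_{t0}^{t0+s} C(k,2)/N(t) dt = -ln(u)`` in closed
    form; ``u`` is a uniform(0,1) draw.
    """
    if k < 2:
        raise ValueError("need at least two lineages to coalesce")
    if not (0.0 < u < 1.0):
        raise ValueError("u must lie strictly in (0, 1)")
    if t0 < 0:
        raise ValueError("t0 must be non-negative")
    t_new = _advance(k, np.array([t0]), np.array([-math.log(u)]), model, gen_years)
    return float(t_new[0] - t0)


def _simulate_events(model, n, reps, rng, gen_years):
    """Draw coalescent event streams for ``reps`` replicates of ``n`` tips.

    Returns ``(times, first, second)``: merge times (generations, shape
    ``(reps, n-1)``, increasing along axis 1) and the active-slot indices
    of the two lineages merged at each event.  Slot bookkeeping convention
    (shared by every consumer): ``k = n - j`` lineages occupy slots
    ``0..k-1``; the merged pair ``(a, b)`` with ``a < b`` leaves the new
    ancestor in slot ``a`` while slot ``k-1`` is moved into slot ``b``.
    """
    times = np.empty((reps, n - 1))
    first = np.empty((reps, n - 1), dtype=np.int64)
    second = np.empty((reps, n - 1), dtype=np.int64)
    t = np.zeros(reps)
    for j in range(n - 1):
        k = n - j
        u = 1.0 - rng.random(reps)  # in (0, 1]
        h = -np.log(u)
        t = _advance(k, t, h, model, gen_years)
        a = rng.integers(0, k, size=reps)
        b = rng.integers(0, k - 1, size=reps)
        b = b + (b >= a)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        times[:, j] = t
        first[:, j] = lo
        second[:, j] = hi
    return times, first, second


def _stats_from_events(times, first, second, n, branch_transform=None):
    """Normalized-tree summary statistics from raw event streams.

    Computes, per replicate and after rescaling to total branch length
    1.0: the singleton/shared ratio ``r``, the mean ``m`` and population
    standard deviation ``d`` of the ``C(n,2)`` pairwise-TMRCA depths, plus
    the (unnormalized) TMRCA and total length.  Matches
    ``stats.stat_vector`` applied to the corresponding tree.

    ``branch_transform(lengths)`` optionally maps each branch's length in
    generations to another length as the branch is finalised (e.g. a
    Poisson SNP count for infinite-sites mutation).  The resulting trees
    need not be ultrametric: pair depths are the mean of the two
    MRCA-to-tip path lengths, and a zero-length internal branch
    contributes nothing to the shared-SNP sums, which is algebraically the
    same as collapsing it into a polytomy.  Replicates whose transformed
    tree has zero total length get ``r = inf`` and NaN depth statistics.
    """
    reps = times.shape[0]
    rows = np.arange(reps)
    age = np.zeros((reps, n))        # node height in generations (event clock)
    sub = np.zeros((reps, n))        # internal branch length below slot's node
    size = np.ones((reps, n))        # clade size
    psum = np.zeros((reps, n))       # sum over clade tips of node-to-tip path
    qsum = np.zeros((reps, n))       # sum of squared node-to-tip paths
    internal = np.zeros((reps, n), dtype=bool)

    term = np.zeros(reps)      # sum of terminal branch lengths
    intlen = np.zeros(reps)    # sum of internal (non-root) branch lengths
    cross = np.zeros(reps)     # sum over internal branches of l_b * S_b
    sum_d = np.zeros(reps)     # sum over tip pairs of pair depth
    sum_d2 = np.zeros(reps)    # sum of squared pair depths

    for j in range(n - 1):
        k = n - j
        a = first[:, j]
        b = second[:, j]
        t = times[:, j]
        la = t - age[rows, a]
        lb = t - age[rows, b]
        if branch_transform is not None:
            la = branch_transform(la)
            lb = branch_transform(lb)
        ia = internal[rows, a]
        ib = internal[rows, b]
        term += np.where(ia, 0.0, la) + np.where(ib, 0.0, lb)
        intlen += np.where(ia, la, 0.0) + np.where(ib, lb, 0.0)
        cross += np.where(ia, la * sub[rows, a], 0.0) + np.where(
            ib, lb * sub[rows, b], 0.0
        )
        s_new = (
            sub[rows, a]
            + sub[rows, b]
            + np.where(ia, la, 0.0)
            + np.where(ib, lb, 0.0)
        )
        sa = size[rows, a]
        sb = size[rows, b]
        pa, pb = psum[rows, a], psum[rows, b]
        qa, qb = qsum[rows, a], qsum[rows, b]
        # paths measured from the new ancestor: extend each clade by its branch
        pa_m = pa + sa * la
        pb_m = pb + sb * lb
        qa_m = qa + 2.0 * la * pa + sa * la * la
        qb_m = qb + 2.0 * lb * pb + sb * lb * lb
        # pair depth = mean of the two MRCA-to-tip paths
        sum_d += 0.5 * (sb * pa_m + sa * pb_m)
        sum_d2 += 0.25 * (sb * qa_m + sa * qb_m + 2.0 * pa_m * pb_m)
        # merged ancestor into slot a
        age[rows, a] = t
        sub[rows, a] = s_new
        size[rows, a] = sa + sb
        psum[rows, a] = pa_m + pb_m
        qsum[rows, a] = qa_m + qb_m
        internal[rows, a] = True
        # swap-delete: slot k-1 -> slot b
        for arr in (age, sub, size, psum, qsum, internal):
            arr[rows, b] = arr[rows, k - 1]

    total = term + intlen
    n_pairs = n * (n - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_depth = sum_d / n_pairs
        var_depth = np.maximum(sum_d2 / n_pairs - mean_depth**2, 0.0)
        denom = intlen + np.where(total > 0, cross / total, 0.0)
        r = np.where(denom > 0, term / denom, np.inf)
        m = np.where(total > 0, mean_depth / total, np.nan)
        d = np.where(total > 0, np.sqrt(var_depth) / total, np.nan)
    return {
        "r": r,
        "m": m,
        "d": d,
        "tmrca": times[:, -1],
        "total_length": total,
    }


def batch_statistics(model, config: SimConfig, rng, mutate: bool = False) -> dict:
    """Simulate ``config.reps`` genealogies and return per-replicate statistics.

    With ``mutate=True`` the statistics are computed on Poisson SNP counts
    (infinite-sites mutation at ``config.mu * config.seq_len`` per
    generation) instead of the genealogy branch lengths.
    """
    times, first, second = _simulate_events(
        model, config.n_tips, config.reps, rng, config.gen_years
    )
    transform = None
    if mutate:
        rate = config.snps_per_generation
        transform = lambda l: rng.poisson(l * rate).astype(float)  # noqa: E731
    return _stats_from_events(times, first, second, config.n_tips, transform)


def _tree_from_events(times, first, second, n, labels=None):
    """Materialise one replicate's event stream as a dendropy tree."""
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n)]
    ns = dendropy.TaxonNamespace()
    nodes = []
    for lab in labels:
        taxon = dendropy.Taxon(label=lab)
        ns.add_taxon(taxon)
        node = dendropy.Node(taxon=taxon)
        node.age = 0.0
        nodes.append(node)
    slots = list(nodes)
    for j in range(n - 1):
        k = n - j
        a, b, t = int(first[j]), int(second[j]), float(times[j])
        parent = dendropy.Node()
        parent.age = t
        parent.add_child(slots[a])
        parent.add_child(slots[b])
        slots[a] = parent
        slots[b] = slots[k - 1]
    root = slots[0]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
    tree.is_rooted = True
    return tree


def simulate_genealogy(model: ExpansionModel, config: SimConfig, rng) -> dendropy.Tree:
    """Simulate one rooted ultrametric genealogy (branch lengths in generations)."""
    times, first, second = _simulate_events(
        model, config.n_tips, 1, rng, config.gen_years
    )
    return _tree_from_events(times[0], first[0], second[0], config.n_tips)


def sprinkle_mutations(tree: dendropy.Tree, config: SimConfig, rng) -> dendropy.Tree:
    """Poisson infinite-sites mutations: branch lengths (generations) -> SNP counts."""
    out = tree.clone(depth=1)
    rate = config.snps_per_generation
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            mean = (node.edge.length or 0.0) * rate
            node.edge.length = float(rng.poisson(mean))
    return out


def make_synthetic_observed(model: ExpansionModel, config: SimConfig, seed) -> dendropy.Tree:
    """A simulated SNP-count tree emulating an observed haplogroup phylogeny."""
    rng = np.random.default_rng(seed)
    gene = simulate_genealogy(model, config, rng)
    return sprinkle_mutations(gene, config, rng)
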